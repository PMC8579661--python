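"""End-to-end orchestration: simulate/load -> preprocess -> wDC -> normative -> outcome.

A run consumes either a synthetic cohort generated in-process or a cohort
directory on disk (the layout ``Cohort.write`` produces: per-subject BOLD
NIfTI + confound TSV, atlas + label table, brain mask, patient table). It
writes per-subject z-maps, the feature and cohort tables, the outcome-model
report, optional group-level cluster statistics, and a manifest recording
parameters, seeds, package versions and output hashes. Reruns with the same
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .normative import (
    build_feature_table,
    crawford_map,
    summarize_patient,
    tabulate_cohort,
)
from .outcome import SeizureOutcomeModel
from .preprocess import preprocess_volume
from .simulate import Cohort, SimulationConfig, simulate_cohort
from .volume import LabelAtlas, Volume4D
from .wdc import resolve_rois, wdc_zmap
from .groupstats import permutation_cluster_p

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort",
           "load_cohort_dir", "DiskCohort"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs: data source, stage parameters, seed."""

    output_dir: str = "connfp_run"
    data_dir: str | None = None          # None -> simulate in-process
    simulation: dict = field(default_factory=dict)

    drop_volumes: int = 5
    band: tuple[float, float] = (0.01, 0.1)
    poly_order: int = 1
    r_threshold: float = 0.25
    fwhm_mm: float = 8.0
    block_size: int = 1024
    alpha: float = 0.005
    p_remove: float = 0.10
    cutoff: float = 0.5

    run_groupstats: bool = False
    p_form: float = 0.005
    k_min: int = 20
    connectivity: int = 18
    n_perm: int = 500

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.band = tuple(cfg.band)
        return cfg

    def validate(self) -> None:
        if self.data_dir is not None:
            root = Path(self.data_dir)
            required = ["atlas.nii.gz", "labels.tsv", "brain_mask.nii.gz",
                        "patients.csv", "subjects.csv"]
            missing = [f for f in required if not (root / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"data_dir {root} is missing: {', '.join(missing)}"
                )
        if not 0 < self.alpha < 1 or not 0 < self.cutoff < 1:
            raise ValueError("alpha and cutoff must lie in (0, 1)")
        if self.drop_volumes < 0:
            raise ValueError("drop_volumes must be >= 0")


class DiskCohort:
    """Cohort read from a directory with the ``Cohort.write`` layout."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.atlas = LabelAtlas.load(self.root / "atlas.nii.gz",
                                     self.root / "labels.tsv")
        self.subjects = pd.read_csv(self.root / "subjects.csv")
        self._patients = pd.read_csv(self.root / "patients.csv")

    @property
    def patient_table(self) -> pd.DataFrame:
        return self._patients

    @property
    def control_ids(self) -> list[str]:
        return list(self.subjects.loc[self.subjects["group"] == "control", "id"])

    @property
    def patient_ids(self) -> list[str]:
        return list(self.subjects.loc[self.subjects["group"] == "patient", "id"])

    def realize(self, subject_id: str):
        vol = Volume4D.load(self.root / f"{subject_id}_bold.nii.gz")
        conf = pd.read_csv(self.root / f"{subject_id}_confounds.tsv", sep="\t")
        return vol, conf


def load_cohort_dir(root: str | Path) -> DiskCohort:
    return DiskCohort(root)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> Path:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    # deterministic bytes: gzip without the file mtime
    import gzip

    raw = img.to_bytes()
    with open(path, "wb") as fh:
        fh.write(gzip.compress(raw, mtime=0))
    return path


def analyze_cohort(
    cohort: "Cohort | DiskCohort", config: PipelineConfig | None = None
) -> dict:
    """In-memory analysis of a cohort: z-maps, feature table, outcome model.

    Returns a dict with keys ``zmaps`` (id -> 3-D array), ``common_mask``,
    ``features`` (DataFrame) and ``result`` (SeizureOutcomeResults). This is
    the computational core of ``run_pipeline`` without any file output.
    """
    if config is None:
        config = PipelineConfig()
    atlas = cohort.atlas
    mask0 = atlas.brain_mask

    zmaps: dict[str, np.ndarray] = {}
    masks = []
    for sid in list(cohort.control_ids) + list(cohort.patient_ids):
        vol, conf = cohort.realize(sid)
        clean, m = preprocess_volume(
            vol, conf, mask0, drop=config.drop_volumes,
            band=config.band, poly_order=config.poly_order,
        )
        wmap = wdc_zmap(
            clean, m, r_threshold=config.r_threshold,
            fwhm_mm=config.fwhm_mm, block_size=config.block_size,
        )
        zmaps[sid] = wmap.z
        masks.append(m)
    common_mask = np.logical_and.reduce(masks)

    controls = np.stack([zmaps[c] for c in cohort.control_ids])
    patient_table = cohort.patient_table
    summaries = {}
    for _, prow in patient_table.iterrows():
        pid = prow["id"]
        rois = resolve_rois(atlas, prow["side"])
        cmap = crawford_map(zmaps[pid], controls, common_mask, affine=atlas.affine)
        summaries[pid] = summarize_patient(cmap, rois, atlas, alpha=config.alpha)
    features = build_feature_table(summaries, patient_table)

    model = SeizureOutcomeModel.from_feature_table(features)
    result = model.fit_backward(p_remove=config.p_remove)
    return {
        "zmaps": zmaps,
        "common_mask": common_mask,
        "features": features,
        "result": result,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def _stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    def _done(name, t0):
        stage_times[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.1fs", name, stage_times[name])

    # --- source -------------------------------------------------------
    t0 = _stage("source")
    if config.data_dir is None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        cohort: Cohort | DiskCohort = simulate_cohort(SimulationConfig(**sim_kwargs))
    else:
        cohort = load_cohort_dir(config.data_dir)
    atlas = cohort.atlas
    _done("source", t0)

    # --- preprocess + wDC + normative + outcome (in memory) -------------
    t0 = _stage("analysis")
    analysis = analyze_cohort(cohort, config)
    zmaps = analysis["zmaps"]
    for sid, z in zmaps.items():
        p = _write_nifti(z, atlas.affine, out / f"{sid}_wdc_z.nii.gz")
        outputs[f"zmap/{sid}"] = str(p)
    features = analysis["features"]
    features.to_csv(out / "features.csv", index=False)
    outputs["features"] = str(out / "features.csv")
    cohort_tab = tabulate_cohort(features)
    cohort_tab.to_csv(out / "cohort_table.csv", index=False)
    outputs["cohort_table"] = str(out / "cohort_table.csv")

    result = analysis["result"]
    (out / "model_report.txt").write_text(result.summary() + "\n")
    outputs["model_report"] = str(out / "model_report.txt")
    result.coef_frame().to_csv(out / "coefficients.csv")
    outputs["coefficients"] = str(out / "coefficients.csv")
    result.roc().as_frame().to_csv(out / "roc.csv", index=False)
    outputs["roc"] = str(out / "roc.csv")
    _done("analysis", t0)

    # --- optional group statistics ---------------------------------------
    if config.run_groupstats:
        t0 = _stage("groupstats")
        controls = np.stack([zmaps[c] for c in cohort.control_ids])
        patients = np.stack([zmaps[p] for p in cohort.patient_ids])
        cres = permutation_cluster_p(
            controls, patients, mask=analysis["common_mask"],
            p_form=config.p_form, k_min=config.k_min,
            connectivity=config.connectivity, n_perm=config.n_perm,
            seed=config.seed, affine=atlas.affine,
        )
        cres.clusters.to_csv(out / "clusters.csv", index=False)
        outputs["clusters"] = str(out / "clusters.csv")
        _done("groupstats", t0)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "connfp_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "stage_seconds": stage_times,
        "classification": result.classification_table(config.cutoff),
        "auc": result.auc,
        "retained_predictors": result.predictors,
        "outputs_sha256": {k: _sha256(Path(v)) for k, v in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
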