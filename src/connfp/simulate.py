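"""Synthetic resting-state cohorts with planted local-connectivity hubs.

Emulates the study design this package analyses: a small normative sample
of healthy controls and a patient group in which designated temporal-lobe
regions carry elevated local voxel-to-voxel synchronization, with surgical
outcome drawn from a known logistic model on the planted region indicators.
Every downstream stage (degree-centrality mapping, single-case normative
comparison, outcome modelling) can therefore be scored against ground truth.

Generative model for voxel ``v`` in region ``R(v)``::

    x_v(t) = lambda_v * s_R(t) + a * g(t) + noise_sd * eps_v(t)

where ``s_R`` is a latent unit-variance signal shared by all voxels of the
region, ``g`` a low-amplitude global signal, and ``eps_v`` white Gaussian
noise. ``lambda_v`` equals the hub loading inside planted hub regions and a
small baseline everywhere else, so the expected within-hub Pearson
correlation is ``lambda^2 / (lambda^2 + noise_sd^2)`` when ``a = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .volume import LabelAtlas, Volume4D

__all__ = [
    "HubSpec",
    "SimulationConfig",
    "Cohort",
    "make_toy_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_ground_truth",
]

ROI_NAMES = ("mesial", "pole", "lateral")
SIDES = ("left", "right")
RELATIONS = ("ipsilateral", "contralateral")

# Two constituent parcels per study ROI, echoing how the real temporal-lobe
# ROIs are assembled from multiple atlas parcels.
CONSTITUENT_NAMES: dict[str, tuple[str, str]] = {
    "mesial": ("hippocampus", "amygdala"),
    "pole": ("temporal_pole_sup", "temporal_pole_mid"),
    "lateral": ("temporal_mid", "temporal_inf"),
}
REST_NAME = "rest_of_brain"


@dataclass(frozen=True)
class HubSpec:
    """A planted hub: which ROI, on which side relative to resection.

    ``prevalence`` is the fraction of patients that receive this hub;
    exactly ``round(prevalence * n_patients)`` patients are selected, so
    ground-truth indicator marginals are exact by construction.
    """

    roi: str
    side: str  # "ipsilateral" | "contralateral"
    loading: float = 1.0
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.roi not in ROI_NAMES:
            raise ValueError(f"unknown ROI {self.roi!r}; expected one of {ROI_NAMES}")
        if self.side not in RELATIONS:
            raise ValueError(f"side must be ipsilateral/contralateral, got {self.side!r}")
        if self.loading < 0:
            raise ValueError("hub loading must be >= 0")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.roi}_{self.side}"


def _default_hubs() -> tuple[HubSpec, ...]:
    # loading 1.0 with unit noise gives within-hub r = 0.5
    return (
        HubSpec("mesial", "ipsilateral", loading=1.0, prevalence=0.5),
        HubSpec("pole", "ipsilateral", loading=1.0, prevalence=0.5),
    )


def _default_outcome_coefs() -> dict[str, float]:
    # P(seizure-free): hubs in the to-be-resected mesial/pole regions raise
    # the odds of freedom, mirroring the direction of the study's finding.
    return {
        "intercept": -1.5,
        "mesial_ipsilateral": 2.0,
        "pole_ipsilateral": 1.5,
    }


@dataclass
class SimulationConfig:
    """Cohort and acquisition parameters.

    Defaults reproduce the study conditions: 110 volumes at TR = 2 s with
    3x3x4 mm voxels, 18 controls and 30 patients.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 16)
    n_volumes: int = 110
    tr: float = 2.0
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)
    n_controls: int = 18
    n_patients: int = 30
    hub_rois: tuple[HubSpec, ...] = field(default_factory=_default_hubs)
    baseline_loading: float = 0.2
    noise_sd: float = 1.0
    global_amplitude: float = 0.1
    band_limited: bool = True
    band: tuple[float, float] = (0.01, 0.1)
    outcome_coefs: dict[str, float] = field(default_factory=_default_outcome_coefs)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if len(self.grid_dims) != 3 or any(d < 8 for d in self.grid_dims):
            raise ValueError(
                f"grid_dims must be 3 integers each >= 8, got {self.grid_dims}"
            )
        if self.n_volumes < 16:
            raise ValueError("n_volumes must be >= 16")
        if self.tr <= 0 or self.noise_sd <= 0:
            raise ValueError("tr and noise_sd must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("cohort sizes must be positive")
        hubs = []
        for h in self.hub_rois:
            hubs.append(h if isinstance(h, HubSpec) else HubSpec(*h))
        self.hub_rois = tuple(hubs)


# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------

def _axis_sections(extent: int, n_sections: int, min_size: int = 2,
                   max_gap: int = 2) -> tuple[list[tuple[int, int]], int]:
    """Split ``extent`` voxels into ``n_sections`` contiguous runs, inserting
    the largest inter-section gap (up to ``max_gap``) that still leaves every
    section at least ``min_size`` voxels. Returns ([(start, stop)...], gap)."""
    for gap in range(max_gap, -1, -1):
        usable = extent - gap * (n_sections - 1)
        if usable >= min_size * n_sections:
            base, extra = divmod(usable, n_sections)
            sections = []
            start = 0
            for i in range(n_sections):
                size = base + (1 if i < extra else 0)
                sections.append((start, start + size))
                start += size + gap
            return sections, gap
    raise ValueError(
        f"cannot fit {n_sections} sections of >= {min_size} voxels in extent {extent}"
    )


def make_toy_atlas(
    grid_dims: Sequence[int],
    voxel_size: Sequence[float] = (3.0, 3.0, 4.0),
) -> LabelAtlas:
    """Build a rectangular-block stand-in for an anatomical parcellation.

    Twelve disjoint blocks — two constituent parcels for each of
    {mesial, pole, lateral} x {left, right} — sit inside an interior "brain"
    box; remaining interior voxels form a rest-of-brain label and the
    one-voxel border is background. Left/right blocks are mirror images
    about the mid-sagittal plane. The affine is RAS+ built from
    ``voxel_size`` and centred on the grid.
    """
    dims = tuple(int(d) for d in grid_dims)
    if len(dims) != 3 or any(d < 8 for d in dims):
        raise ValueError(
            f"grid {dims} too small to host the toy parcellation; "
            "need at least 8 voxels per axis"
        )
    nx, ny, nz = dims

    # hemisphere x-extent: interior left span [1, lx]; blocks use its inner
    # half so rest-of-brain surrounds the ROIs laterally as well
    lx = (nx - 2) // 2
    wx = max(2, lx // 2)
    x_left = (1, 1 + wx)

    y_secs, _ = _axis_sections(ny - 2, 3)          # mesial / pole / lateral
    y_secs = [(a + 1, b + 1) for a, b in y_secs]   # shift into interior
    z_half = (nz - 2) // 2
    z_parts = [(1, 1 + z_half), (1 + z_half, nz - 1)]

    data = np.zeros(dims, dtype=np.int32)
    rows = []
    label = 0
    for hemi in SIDES:
        for roi, (ys, ye) in zip(ROI_NAMES, y_secs):
            for part, (zs, ze) in zip(CONSTITUENT_NAMES[roi], z_parts):
                label += 1
                if hemi == "left":
                    xs, xe = x_left
                    data[xs:xe, ys:ye, zs:ze] = label
                else:
                    # mirror about the mid-sagittal plane: x -> nx-1-x
                    xs, xe = nx - x_left[1], nx - x_left[0]
                    data[xs:xe, ys:ye, zs:ze] = label
                rows.append({"label": label, "name": part, "hemisphere": hemi})

    rest = label + 1
    interior = np.zeros(dims, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    data[interior & (data == 0)] = rest
    rows.append({"label": rest, "name": REST_NAME, "hemisphere": "none"})

    vs = np.asarray(voxel_size, dtype=float)
    affine = np.diag([*vs, 1.0])
    affine[:3, 3] = -(np.asarray(dims) - 1) / 2.0 * vs
    return LabelAtlas(data=data, affine=affine, table=pd.DataFrame(rows))


def roi_labels(atlas: LabelAtlas, roi: str, hemisphere: str) -> list[int]:
    """Constituent atlas labels of one study ROI in one hemisphere."""
    if roi not in ROI_NAMES:
        raise ValueError(f"unknown ROI {roi!r}")
    names = list(CONSTITUENT_NAMES[roi])
    sel = atlas.table[
        atlas.table["name"].isin(names)
        & (atlas.table["hemisphere"] == hemisphere)
    ]
    if sel.empty:
        raise ValueError(f"atlas has no labels for {roi} {hemisphere}")
    return [int(v) for v in sel["label"]]


# ---------------------------------------------------------------------------
# subject synthesis
# ---------------------------------------------------------------------------

def _band_limit(series: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Ideal band-pass then rescale to unit sample variance."""
    t = series.shape[-1]
    spec = np.fft.rfft(series, axis=-1)
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _latent(rng: np.random.Generator, t: int, config: SimulationConfig) -> np.ndarray:
    s = rng.standard_normal(t)
    if config.band_limited:
        s = _band_limit(s, config.tr, config.band)
    else:
        sd = s.std()
        if sd > 0:
            s = s / sd
    return s


def _make_confounds(rng: np.random.Generator, t: int, tr: float) -> pd.DataFrame:
    """Plausible slow-drift realignment parameters plus WM/CSF signals."""
    cols = {}
    for name, step in (
        ("trans_x", 0.01), ("trans_y", 0.01), ("trans_z", 0.015),
        ("rot_x", 0.0004), ("rot_y", 0.0004), ("rot_z", 0.0004),
    ):
        cols[name] = np.cumsum(rng.normal(0.0, step, size=t))
    for name in ("wm", "csf"):
        slow = _band_limit(rng.standard_normal(t), tr, (0.0, 0.05))
        cols[name] = slow + 0.2 * rng.standard_normal(t)
    return pd.DataFrame(cols)


def simulate_subject(
    config: SimulationConfig,
    atlas: LabelAtlas,
    hub_spec: Sequence[tuple[str, str, float]] = (),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Volume4D, pd.DataFrame]:
    """Synthesize one subject's 4-D volume and confound table.

    ``hub_spec`` lists ``(roi, hemisphere, loading)`` triples in absolute
    left/right terms; all other in-brain voxels load on their region's
    latent at the baseline loading. Identical seeds give identical arrays.
    """
    rng = np.random.default_rng(seed)
    t = config.n_volumes
    mask = atlas.brain_mask
    dims = atlas.data.shape

    # region membership: the six study ROIs plus rest-of-brain
    region_of = np.full(dims, -1, dtype=np.int32)
    region_keys: list[tuple[str, str]] = []
    for hemi in SIDES:
        for roi in ROI_NAMES:
            m = atlas.mask_for_labels(roi_labels(atlas, roi, hemi))
            region_of[m] = len(region_keys)
            region_keys.append((roi, hemi))
    rest_ids = atlas.labels_named([REST_NAME])
    if rest_ids:
        region_of[atlas.mask_for_labels(rest_ids)] = len(region_keys)
    region_keys.append((REST_NAME, "none"))
    n_regions = len(region_keys)

    # baseline synchronization lives within anatomical parcels only; the
    # rest-of-brain compartment shares nothing beyond the global signal
    # (a single coherent background latent would hand every background
    # voxel thousands of chance-suprathreshold partners and drown any hub)
    loadings = np.full(n_regions, config.baseline_loading)
    loadings[-1] = 0.0
    for roi, hemi, lam in hub_spec:
        try:
            idx = region_keys.index((roi, hemi))
        except ValueError:
            raise ValueError(
                f"unknown hub ROI {(roi, hemi)!r}; known regions: {region_keys[:-1]}"
            ) from None
        loadings[idx] = lam

    # deterministic draw order: region latents, global, noise, confounds
    latents = np.stack([_latent(rng, t, config) for _ in range(n_regions)])
    g = _latent(rng, t, config)

    vox_region = region_of[mask]
    if np.any(vox_region < 0):
        raise ValueError("brain mask contains voxels outside every region")
    n_vox = vox_region.size
    signal = loadings[vox_region, None] * latents[vox_region]
    noise = rng.standard_normal((n_vox, t)) * config.noise_sd
    series = signal + config.global_amplitude * g[None, :] + noise

    data = np.zeros((*dims, t))
    data[mask] = series
    vs = np.asarray(config.voxel_size, dtype=float)
    affine = atlas.affine if atlas.affine is not None else np.diag([*vs, 1.0])
    vol = Volume4D(data=data, affine=affine, tr=config.tr)
    confounds = _make_confounds(rng, t, config.tr)
    return vol, confounds


# ---------------------------------------------------------------------------
# cohort synthesis
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_ground_truth(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw patient sides, hub indicators, outcome probabilities and labels.

    This is the outcome-model layer of the cohort on its own (no volumes);
    one row per patient with a column per ``roi_side`` hub indicator.
    Exactly ``round(prevalence * n_patients)`` patients receive each hub.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_patients
    ids = [f"p{i + 1:03d}" for i in range(n)]
    sides = np.array(["left"] * (n - n // 2) + ["right"] * (n // 2))
    rng.shuffle(sides)

    gt = pd.DataFrame({"id": ids, "side": sides})
    logit = np.full(n, config.outcome_coefs.get("intercept", 0.0))
    for hub in config.hub_rois:
        k = int(round(hub.prevalence * n))
        chosen = rng.permutation(n)[:k]
        ind = np.zeros(n, dtype=int)
        ind[chosen] = 1
        gt[hub.key] = ind
        logit += config.outcome_coefs.get(hub.key, 0.0) * ind
    # unplanted ROI/relation combinations are true negatives
    for roi in ROI_NAMES:
        for rel in RELATIONS:
            col = f"{roi}_{rel}"
            if col not in gt.columns:
                gt[col] = 0
    gt["true_prob"] = _sigmoid(logit)
    gt["outcome"] = np.where(rng.random(n) < gt["true_prob"], "SF", "nonSF")
    return gt


def _relative_to_absolute(roi: str, relation: str, side: str) -> tuple[str, str]:
    """Map (roi, ipsi/contra) to (roi, left/right) given resection side."""
    if relation == "ipsilateral":
        return roi, side
    return roi, ("right" if side == "left" else "left")


@dataclass
class Cohort:
    """A synthetic study cohort with retained ground truth.

    Subject volumes are realized on demand (``realize`` / ``iter_subjects``)
    so a full cohort never has to live in memory at once.
    """

    config: SimulationConfig
    atlas: LabelAtlas
    subjects: pd.DataFrame = field(repr=False)   # id, group, side, seed, hubs
    ground_truth: pd.DataFrame = field(repr=False)

    @property
    def patient_table(self) -> pd.DataFrame:
        pats = self.subjects[self.subjects["group"] == "patient"]
        out = pats[["id", "side"]].copy()
        out["outcome"] = self.ground_truth.set_index("id").loc[out["id"], "outcome"].values
        return out.reset_index(drop=True)

    @property
    def control_ids(self) -> list[str]:
        return list(self.subjects.loc[self.subjects["group"] == "control", "id"])

    @property
    def patient_ids(self) -> list[str]:
        return list(self.subjects.loc[self.subjects["group"] == "patient", "id"])

    def realize(self, subject_id: str) -> tuple[Volume4D, pd.DataFrame]:
        row = self.subjects.set_index("id").loc[subject_id]
        return simulate_subject(
            self.config, self.atlas, hub_spec=row["hubs"], seed=int(row["seed"])
        )

    def iter_subjects(self) -> Iterator[tuple[pd.Series, Volume4D, pd.DataFrame]]:
        for _, row in self.subjects.iterrows():
            vol, conf = self.realize(row["id"])
            yield row, vol, conf

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write atlas, mask, per-subject NIfTI + confound TSVs, and tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        self.atlas.save(out / "atlas.nii.gz", out / "labels.tsv")
        paths["atlas"] = out / "atlas.nii.gz"
        paths["labels"] = out / "labels.tsv"
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(self.atlas.brain_mask.astype(np.uint8), self.atlas.affine),
            str(out / "brain_mask.nii.gz"),
        )
        paths["mask"] = out / "brain_mask.nii.gz"
        for row, vol, conf in self.iter_subjects():
            vol.save(out / f"{row['id']}_bold.nii.gz")
            conf.to_csv(out / f"{row['id']}_confounds.tsv", sep="\t", index=False)
        self.subjects[["id", "group", "side"]].to_csv(
            out / "subjects.csv", index=False
        )
        paths["subjects"] = out / "subjects.csv"
        self.patient_table.to_csv(out / "patients.csv", index=False)
        paths["patients"] = out / "patients.csv"
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        paths["ground_truth"] = out / "ground_truth.csv"
        return paths


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Assemble the full synthetic cohort: atlas, subject specs, ground truth.

    Controls carry baseline loadings only; each patient receives the hub
    ROIs the ground-truth draw assigned, converted to absolute hemispheres
    via the patient's resection side. One master seed spawns independent
    per-subject substreams, so any subject is reproducible on its own.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_gt, ss_subj = ss.spawn(2)
    atlas = make_toy_atlas(config.grid_dims, config.voxel_size)
    gt = simulate_ground_truth(config, np.random.default_rng(ss_gt))

    seed_rng = np.random.default_rng(ss_subj)
    n_total = config.n_controls + config.n_patients
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_total)

    rows = []
    for i in range(config.n_controls):
        rows.append({
            "id": f"c{i + 1:03d}", "group": "control", "side": "none",
            "seed": int(seeds[i]), "hubs": [],
        })
    hub_by_key = {h.key: h for h in config.hub_rois}
    for j, (_, g) in enumerate(gt.iterrows()):
        hubs = []
        for key, hub in hub_by_key.items():
            if g[key] == 1:
                roi, hemi = _relative_to_absolute(hub.roi, hub.side, g["side"])
                hubs.append((roi, hemi, hub.loading))
        rows.append({
            "id": g["id"], "group": "patient", "side": g["side"],
            "seed": int(seeds[config.n_controls + j]), "hubs": hubs,
        })
    subjects = pd.DataFrame(rows)
    return Cohort(config=config, atlas=atlas, subjects=subjects, ground_truth=gt)
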