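"""Single-case normative comparison of degree-centrality maps.

Each patient's z-standardized wDC map is compared voxel-wise against a
small normative control sample with the Crawford–Howell modified t-test,

    t = (x - mean_c) / (sd_c * sqrt((N + 1) / N)),   df = N - 1,

the canonical test for one case versus N controls. Per ROI, a voxel counts
as a significant *increase* when its two-tailed p is below alpha (default
0.005) and t > 0; the ROI indicator is 1 iff any such voxel exists, with
the significant-voxel count kept as a companion (confound) variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .wdc import ROIDefinition
from .volume import LabelAtlas

__all__ = [
    "CrawfordMap",
    "ROISummary",
    "crawford_t",
    "crawford_map",
    "summarize_roi",
    "summarize_patient",
    "build_feature_table",
    "tabulate_cohort",
]


def crawford_t(
    case_value: float | np.ndarray,
    control_values: np.ndarray,
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Crawford–Howell t for one case against N controls.

    Works element-wise when ``case_value`` is an array and
    ``control_values`` stacks the control sample along ``axis``. Returns
    ``(t, p_two_tailed, df)``.
    """
    controls = np.asarray(control_values, dtype=float)
    n = controls.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 controls")
    mean = controls.mean(axis=axis)
    sd = controls.std(axis=axis, ddof=1)
    if np.any(sd == 0):
        raise ValueError("control sample has zero variance")
    t = (np.asarray(case_value, dtype=float) - mean) / (sd * np.sqrt((n + 1) / n))
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, df


@dataclass
class CrawfordMap:
    """Voxel-wise single-case t and two-tailed p maps (df = N - 1)."""

    t: np.ndarray
    p: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray


def crawford_map(
    case_zmap: np.ndarray,
    control_zmaps: np.ndarray | list[np.ndarray],
    mask: np.ndarray,
    affine: np.ndarray | None = None,
) -> CrawfordMap:
    """Apply the single-case test at every in-mask voxel.

    ``control_zmaps`` stacks N control maps along the first axis; all maps
    must share the case map's grid.
    """
    controls = np.asarray(control_zmaps, dtype=float)
    case = np.asarray(case_zmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if controls.ndim != case.ndim + 1 or controls.shape[1:] != case.shape:
        raise ValueError(
            f"grid mismatch: case {case.shape}, controls {controls.shape}"
        )
    if mask.shape != case.shape:
        raise ValueError("mask grid does not match the maps")

    tvals, pvals, df = crawford_t(case[mask], controls[:, mask], axis=0)
    t_map = np.zeros_like(case)
    p_map = np.ones_like(case)
    t_map[mask] = tvals
    p_map[mask] = pvals
    if affine is None:
        affine = np.eye(4)
    return CrawfordMap(t=t_map, p=p_map, df=df, mask=mask, affine=affine)


@dataclass(frozen=True)
class ROISummary:
    """Binary "increased wDC" call for one ROI plus its voxel counts."""

    roi: str
    side: str
    indicator: int
    n_sig: int
    n_roi: int
    n_sig_decrease: int = 0


def summarize_roi(
    cmap: CrawfordMap,
    roi: ROIDefinition,
    atlas: LabelAtlas,
    alpha: float = 0.005,
    direction: str = "increase",
) -> ROISummary:
    """Binarize the single-case map within one ROI.

    A voxel is significant iff p < alpha and (for ``direction='increase'``)
    t > 0; the indicator is 1 iff at least one such voxel exists. The count
    of significant decreases is recorded for the log but never enters the
    indicator.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if direction != "increase":
        raise ValueError("only direction='increase' is defined for the indicator")
    roi_mask = roi.mask(atlas) & cmap.mask
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError(f"ROI {roi.name} ({roi.side}) is empty within the mask")
    sig = cmap.p[roi_mask] < alpha
    inc = int(np.count_nonzero(sig & (cmap.t[roi_mask] > 0)))
    dec = int(np.count_nonzero(sig & (cmap.t[roi_mask] < 0)))
    return ROISummary(
        roi=roi.name, side=roi.side, indicator=int(inc >= 1),
        n_sig=inc, n_roi=n_roi, n_sig_decrease=dec,
    )


def summarize_patient(
    cmap: CrawfordMap,
    rois: dict[tuple[str, str], ROIDefinition],
    atlas: LabelAtlas,
    alpha: float = 0.005,
) -> list[ROISummary]:
    """All six ROI summaries for one patient's single-case map."""
    return [summarize_roi(cmap, roi, atlas, alpha=alpha) for roi in rois.values()]


ROI_ORDER = [
    ("mesial", "ipsilateral"), ("pole", "ipsilateral"), ("lateral", "ipsilateral"),
    ("mesial", "contralateral"), ("pole", "contralateral"), ("lateral", "contralateral"),
]


def build_feature_table(
    summaries: dict[str, list[ROISummary]],
    patient_table: pd.DataFrame,
) -> pd.DataFrame:
    """Wide per-patient feature table for the outcome model.

    One row per patient: six binary indicators (``<roi>_<side>_ind``), six
    significant-voxel counts (``_nsig``), and the binary outcome
    (1 = seizure-free).
    """
    pt = patient_table.set_index("id")
    missing = set(summaries) ^ set(pt.index)
    if missing:
        raise ValueError(f"patient id mismatch between summaries and table: {sorted(missing)}")
    rows = []
    for pid, summ in summaries.items():
        row: dict[str, object] = {"id": pid}
        by_key = {(s.roi, s.side): s for s in summ}
        for roi, side in ROI_ORDER:
            s = by_key[(roi, side)]
            row[f"{roi}_{side}_ind"] = s.indicator
            row[f"{roi}_{side}_nsig"] = s.n_sig
        row["outcome"] = int(pt.loc[pid, "outcome"] == "SF")
        rows.append(row)
    return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)


def tabulate_cohort(
    feature_table: pd.DataFrame,
    subset: pd.Index | list[str] | None = None,
) -> pd.DataFrame:
    """Cohort table of "increased wDC" counts per ROI and outcome group.

    For each ROI (rows) and each of {all patients, seizure-free,
    non-seizure-free} (column groups): the count and percentage (one
    decimal) of patients with indicator 1 and 0.
    """
    df = feature_table if subset is None else feature_table[feature_table["id"].isin(list(subset))]
    if df.empty:
        raise ValueError("no patients to tabulate")
    groups = {
        "all": df,
        "SF": df[df["outcome"] == 1],
        "nonSF": df[df["outcome"] == 0],
    }
    rows = []
    for roi, side in ROI_ORDER:
        col = f"{roi}_{side}_ind"
        row: dict[str, object] = {"roi": f"{roi} - {side}"}
        for gname, g in groups.items():
            n = len(g)
            inc = int(g[col].sum()) if n else 0
            row[f"{gname}_n"] = n
            row[f"{gname}_increased"] = inc
            row[f"{gname}_increased_pct"] = round(100.0 * inc / n, 1) if n else 0.0
            row[f"{gname}_not_increased"] = n - inc
            row[f"{gname}_not_increased_pct"] = (
                round(100.0 * (n - inc) / n, 1) if n else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
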