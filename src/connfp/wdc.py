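"""Voxel-wise weighted degree centrality (wDC).

For every in-mask voxel the Pearson correlation with every other in-mask
voxel is computed; correlations strictly above the threshold (default
r > 0.25, positive side only, self excluded) are summed to give the
voxel's weighted degree. Maps are then z-standardized across the mask and
spatially smoothed (8-mm FWHM Gaussian by default), in that order.

The correlation engine is chunked: it never materializes the full
voxel-by-voxel matrix, so peak extra memory is O(voxels * block_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import LabelAtlas, Volume4D, voxel_sizes

__all__ = [
    "WDCMap",
    "ROIDefinition",
    "compute_wdc_raw",
    "standardize_map",
    "smooth_map",
    "wdc_zmap",
    "resolve_rois",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class WDCMap:
    """A weighted degree-centrality map and its computation parameters."""

    raw: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    r_threshold: float
    z: np.ndarray | None = None
    fwhm_mm: float | None = None
    params: dict = field(default_factory=dict)

    def best(self) -> np.ndarray:
        """The most processed map available (z if computed, else raw)."""
        return self.raw if self.z is None else self.z


@dataclass(frozen=True)
class ROIDefinition:
    """One study ROI: name, laterality relative to resection, atlas labels."""

    name: str          # mesial | pole | lateral
    side: str          # ipsilateral | contralateral
    labels: tuple[int, ...]

    def mask(self, atlas: LabelAtlas) -> np.ndarray:
        return atlas.mask_for_labels(self.labels)


def compute_wdc_raw(
    vol: Volume4D,
    mask: np.ndarray,
    r_threshold: float = 0.25,
    block_size: int = 1024,
) -> WDCMap:
    """Weighted degree: sum of suprathreshold positive correlations.

    raw_i = sum_{j != i, r_ij > r_threshold} r_ij over in-mask voxels j.
    The threshold is strict and only positive correlations contribute.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid:
        raise ValueError("mask shape does not match volume grid")
    t = vol.n_volumes
    if t < 3:
        raise ValueError("need at least 3 frames to correlate")
    y = vol.data[mask]  # (v, t)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 in-mask voxels")

    mu = y.mean(axis=1, keepdims=True)
    yc = y - mu
    norms = np.sqrt((yc**2).sum(axis=1))
    if np.all(norms == 0):
        raise ValueError("all in-mask voxels are constant")
    if np.any(norms == 0):
        n_bad = int((norms == 0).sum())
        raise ValueError(
            f"{n_bad} in-mask voxels have zero variance; "
            "clean the mask first (see preprocess_volume)"
        )
    xn = yc / norms[:, None]  # rows have unit norm -> xn @ xn.T is Pearson r

    v = xn.shape[0]
    raw_vec = np.empty(v)
    for start in range(0, v, int(block_size)):
        stop = min(start + int(block_size), v)
        c = xn[start:stop] @ xn.T  # (b, v) correlations
        np.clip(c, -1.0, 1.0, out=c)
        c[:, start:stop][np.eye(stop - start, dtype=bool)] = 0.0  # self
        c[c <= r_threshold] = 0.0
        raw_vec[start:stop] = c.sum(axis=1)

    raw = np.zeros(vol.grid)
    raw[mask] = raw_vec
    return WDCMap(raw=raw, affine=vol.affine, mask=mask, r_threshold=r_threshold)


def standardize_map(wdc: WDCMap, mask: np.ndarray | None = None) -> WDCMap:
    """z-score the raw degrees across in-mask voxels; out-of-mask zeros."""
    mask = wdc.mask if mask is None else np.asarray(mask, dtype=bool)
    vals = wdc.raw[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("raw wDC has zero variance within the mask")
    z = np.zeros_like(wdc.raw)
    z[mask] = (vals - vals.mean()) / sd
    wdc.z = z
    return wdc


def smooth_map(wdc: WDCMap, fwhm_mm: float = 8.0) -> WDCMap:
    """Gaussian-smooth the z map (or raw map if z absent).

    Anisotropic voxels are honoured through the affine: the per-axis sigma
    in voxels is ``FWHM * FWHM_TO_SIGMA / voxel_size_axis``. FWHM 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    src = wdc.best()
    if fwhm_mm == 0:
        out = src.copy()
    else:
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes(wdc.affine)
        out = gaussian_filter(src, sigma=sigma_vox, mode="nearest")
    if wdc.z is None:
        wdc.raw = out
    else:
        wdc.z = out
    wdc.fwhm_mm = fwhm_mm
    return wdc


def wdc_zmap(
    vol: Volume4D,
    mask: np.ndarray,
    r_threshold: float = 0.25,
    fwhm_mm: float = 8.0,
    block_size: int = 1024,
) -> WDCMap:
    """Full map stage: raw weighted degree -> z-standardize -> smooth."""
    m = compute_wdc_raw(vol, mask, r_threshold=r_threshold, block_size=block_size)
    m = standardize_map(m)
    return smooth_map(m, fwhm_mm=fwhm_mm)


# ---------------------------------------------------------------------------
# ROI resolution
# ---------------------------------------------------------------------------

# keywords identifying the constituent parcels of each study ROI in a label
# table; the temporal pole is matched before the lateral gyri so that
# "temporal_pole_sup" is never claimed by the lateral ROI
ROI_KEYWORDS: dict[str, tuple[str, ...]] = {
    "mesial": ("hippocampus", "amygdala", "parahippocampal"),
    "pole": ("temporal_pole",),
    "lateral": ("temporal_sup", "temporal_mid", "temporal_inf"),
}


def _labels_for(table, roi: str, hemisphere: str) -> tuple[int, ...]:
    names = table["name"].astype(str).str.lower()
    hemi = table["hemisphere"].astype(str).str.lower()
    if roi == "lateral":
        in_pole = names.str.contains("temporal_pole")
        pick = names.apply(
            lambda s: any(k in s for k in ROI_KEYWORDS["lateral"])
        ) & ~in_pole
    else:
        pick = names.apply(lambda s: any(k in s for k in ROI_KEYWORDS[roi]))
    sel = table[pick & (hemi == hemisphere)]
    return tuple(int(v) for v in sel["label"])


def resolve_rois(
    atlas: LabelAtlas,
    patient_side: str,
    label_table=None,
) -> dict[tuple[str, str], ROIDefinition]:
    """Map the six study ROIs to ipsi/contralateral label sets.

    Ipsilateral means the side of the planned resection. Returns a dict
    keyed by ``(roi_name, relation)`` with relation in
    {ipsilateral, contralateral}.
    """
    if patient_side not in ("left", "right"):
        raise ValueError(f"patient_side must be left or right, got {patient_side!r}")
    table = atlas.table if label_table is None else label_table
    other = "right" if patient_side == "left" else "left"
    hemis = {"ipsilateral": patient_side, "contralateral": other}

    out: dict[tuple[str, str], ROIDefinition] = {}
    missing = []
    for roi in ("mesial", "pole", "lateral"):
        for relation, hemi in hemis.items():
            labels = _labels_for(table, roi, hemi)
            if not labels:
                missing.append(f"{roi} ({hemi})")
                continue
            absent = [l for l in labels if not np.any(atlas.data == l)]
            if absent:
                missing.append(f"{roi} ({hemi}): labels {absent} empty in atlas")
                continue
            out[(roi, relation)] = ROIDefinition(roi, relation, labels)
    if missing:
        raise ValueError("atlas is missing ROI labels: " + "; ".join(missing))
    return out
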