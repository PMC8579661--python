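"""Time-series cleaning before connectivity: drop, nuisance regression, band-pass.

The pipeline order is fixed — drop initial volumes, regress confounds
(Friston-24 motion expansion + WM + CSF + polynomial trend), then ideal
band-pass 0.01–0.1 Hz. The band-pass is a rectangular frequency-domain
filter (the resting-state toolbox convention), which makes both the
regression and the filter idempotent projections.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .volume import Volume4D

__all__ = [
    "drop_initial_volumes",
    "friston24",
    "build_confound_matrix",
    "regress_confounds",
    "bandpass_filter",
    "preprocess_volume",
]

log = logging.getLogger(__name__)

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def drop_initial_volumes(vol: Volume4D, k: int = 5) -> Volume4D:
    """Remove the first ``k`` frames (default 5, e.g. 110 -> 105)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= vol.n_volumes:
        raise ValueError(
            f"cannot drop {k} frames from a series of {vol.n_volumes}"
        )
    if k == 0:
        return vol
    return Volume4D(data=vol.data[..., k:], affine=vol.affine, tr=vol.tr)


def friston24(motion6: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Friston 24-parameter motion expansion.

    For each of the 6 realignment parameters ``m``: ``m(t)``, ``m(t)^2``,
    ``m(t-1)`` and ``m(t-1)^2``, with the lagged row at t=0 padded with
    zeros.
    """
    if isinstance(motion6, pd.DataFrame):
        names = list(motion6.columns)
        m = motion6.to_numpy(dtype=float)
    else:
        m = np.asarray(motion6, dtype=float)
        names = list(MOTION_COLUMNS)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion matrix must be (t, 6), got {m.shape}")
    lag = np.zeros_like(m)
    lag[1:] = m[:-1]
    cols = {}
    for j, name in enumerate(names):
        cols[name] = m[:, j]
        cols[f"{name}_sq"] = m[:, j] ** 2
        cols[f"{name}_lag"] = lag[:, j]
        cols[f"{name}_lag_sq"] = lag[:, j] ** 2
    return pd.DataFrame(cols)


def build_confound_matrix(
    motion6: np.ndarray | pd.DataFrame,
    wm: np.ndarray,
    csf: np.ndarray,
    n_volumes: int | None = None,
    poly_order: int = 1,
) -> pd.DataFrame:
    """Assemble the nuisance design: Friston-24 + WM + CSF + trend columns.

    Polynomial trend columns run from order 0 (the intercept) up to
    ``poly_order``, so the full design has ``24 + 2 + (poly_order + 1)``
    columns. Constant-zero columns (e.g. an all-zero motion trace) are
    pruned; their names are recorded in ``df.attrs['pruned']``.
    """
    f24 = friston24(motion6)
    wm = np.asarray(wm, dtype=float).ravel()
    csf = np.asarray(csf, dtype=float).ravel()
    t = len(f24)
    if n_volumes is not None and n_volumes != t:
        raise ValueError(
            f"motion table has {t} rows but {n_volumes} volumes were retained"
        )
    if len(wm) != t or len(csf) != t:
        raise ValueError(
            f"confound lengths misaligned: motion {t}, wm {len(wm)}, csf {len(csf)}"
        )
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")

    out = f24.copy()
    out["wm"] = wm
    out["csf"] = csf
    # Legendre-style scaled time in [-1, 1]: well-conditioned trend columns
    tau = np.linspace(-1.0, 1.0, t) if t > 1 else np.zeros(1)
    for p in range(poly_order + 1):
        out[f"trend_{p}"] = tau**p

    zero_cols = [c for c in out.columns if np.all(out[c].to_numpy() == 0.0)]
    if zero_cols:
        log.info("pruning constant-zero confound columns: %s", zero_cols)
        out = out.drop(columns=zero_cols)
    out.attrs["pruned"] = zero_cols
    return out


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    """Raise naming the (near-)collinear columns if the design is deficient."""
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        bad = [names[piv[i]] for i in range(rank, x.shape[1])]
        raise ValueError(
            "confound matrix is rank deficient; collinear columns: "
            + ", ".join(sorted(bad))
        )


def regress_confounds(
    vol: Volume4D,
    confounds: pd.DataFrame | np.ndarray,
    mask: np.ndarray,
) -> Volume4D:
    """Project out the confound columns from every in-mask voxel series.

    Returns the least-squares residuals; out-of-mask voxels are zeroed.
    """
    if isinstance(confounds, pd.DataFrame):
        names = list(confounds.columns)
        x = confounds.to_numpy(dtype=float)
    else:
        x = np.asarray(confounds, dtype=float)
        names = [f"c{j}" for j in range(x.shape[1])]
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid:
        raise ValueError("mask shape does not match volume grid")
    if x.shape[0] != vol.n_volumes:
        raise ValueError(
            f"confounds have {x.shape[0]} rows for {vol.n_volumes} frames"
        )
    _check_full_rank(x, names)

    y = vol.data[mask].T  # (t, v)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = np.zeros_like(vol.data)
    out[mask] = resid.T
    return Volume4D(data=out, affine=vol.affine, tr=vol.tr)


def bandpass_filter(
    vol: Volume4D,
    low: float = 0.01,
    high: float = 0.1,
    mask: np.ndarray | None = None,
) -> Volume4D:
    """Ideal rectangular band-pass in the discrete-Fourier domain.

    Fourier coefficients at frequencies ``low <= f <= high`` are retained,
    all others (including DC whenever ``low > 0``) are zeroed.
    """
    nyquist = 1.0 / (2.0 * vol.tr)
    if low < 0 or high <= low:
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high > nyquist + 1e-12:
        raise ValueError(f"high = {high} Hz exceeds the Nyquist rate {nyquist} Hz")

    t = vol.n_volumes
    freqs = np.fft.rfftfreq(t, d=vol.tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)

    if mask is None:
        series = vol.data.reshape(-1, t)
    else:
        mask = np.asarray(mask, dtype=bool)
        series = vol.data[mask]
    spec = np.fft.rfft(series, axis=-1)
    spec[:, ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=-1)

    out = np.zeros_like(vol.data)
    if mask is None:
        out = filtered.reshape(vol.data.shape)
    else:
        out[mask] = filtered
    return Volume4D(data=out, affine=vol.affine, tr=vol.tr)


def preprocess_volume(
    vol: Volume4D,
    confounds: pd.DataFrame,
    mask: np.ndarray,
    drop: int = 5,
    band: tuple[float, float] = (0.01, 0.1),
    poly_order: int = 1,
) -> tuple[Volume4D, np.ndarray]:
    """Full cleaning pipeline: drop -> confound regression -> band-pass.

    ``confounds`` must carry the 6 realignment columns plus ``wm``/``csf``
    aligned to the *un-dropped* series; rows are sliced alongside the
    volumes. Voxels left with zero variance are removed from the returned
    analysis mask (correlations would be undefined downstream).
    """
    vol = drop_initial_volumes(vol, drop)
    conf = confounds.iloc[drop:].reset_index(drop=True)
    design = build_confound_matrix(
        conf[list(MOTION_COLUMNS)], conf["wm"], conf["csf"],
        n_volumes=vol.n_volumes, poly_order=poly_order,
    )
    vol = regress_confounds(vol, design, mask)
    vol = bandpass_filter(vol, band[0], band[1], mask)

    variances = vol.data[mask].var(axis=-1)
    mask_out = np.asarray(mask, dtype=bool).copy()
    if np.any(variances == 0):
        idx = np.flatnonzero(mask_out.ravel())[variances == 0]
        log.warning("dropping %d zero-variance voxels from analysis mask", idx.size)
        flat = mask_out.ravel()
        flat[idx] = False
        mask_out = flat.reshape(mask_out.shape)
    return vol, mask_out
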