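"""Voxel-wise group comparison of wDC maps with cluster-extent inference.

One-sample (vs 0) and two-sample pooled-variance t maps, thresholded at a
cluster-forming p (default one-tailed 0.005), grouped into connected
components (default 18-connectivity), with components below the minimum
extent (default 20 voxels) discarded. Family-wise correction uses the
permutation distribution of the maximum cluster size: group labels are
permuted for two-sample contrasts and signs flipped for one-sample ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["StatMap", "ClusterResult", "t_map", "find_clusters", "permutation_cluster_p"]

log = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Voxel-wise t statistics for a group contrast."""

    t: np.ndarray
    df: int
    mask: np.ndarray
    contrast: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    zero_variance: np.ndarray | None = None


@dataclass
class ClusterResult:
    """Suprathreshold clusters: extent, peak, and (optionally) corrected p."""

    clusters: pd.DataFrame
    labels: np.ndarray
    threshold_t: float
    k_min: int
    connectivity: int
    n_perm: int | None = None
    null_max_size: np.ndarray | None = None


def _stack(maps) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3-D maps (n, x, y, z)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    return arr


def _t_from_stacks(a: np.ndarray, b: np.ndarray | None):
    """Vectorized one-/two-sample t over the first axis; zero-variance
    voxels get t = 0 and are flagged."""
    if b is None:
        n = a.shape[0]
        mean = a.mean(axis=0)
        sd = a.std(axis=0, ddof=1)
        zero = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
        return t, n - 1, zero
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    zero = sp2 == 0
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (a.mean(axis=0) - b.mean(axis=0)) / denom)
    return t, na + nb - 2, zero


def t_map(
    maps_a,
    maps_b=None,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> StatMap:
    """One-sample (vs 0) or two-sample pooled-variance t map.

    Voxels with zero pooled variance are set to t = 0 and flagged in
    ``StatMap.zero_variance``.
    """
    a = _stack(maps_a)
    b = _stack(maps_b) if maps_b is not None else None
    if b is not None and b.shape[1:] != a.shape[1:]:
        raise ValueError("group grids differ")
    if mask is None:
        mask = np.ones(a.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    t, df, zero = _t_from_stacks(a, b)
    t = np.where(mask, t, 0.0)
    contrast = (
        f"one-sample (n={a.shape[0]})" if b is None
        else f"two-sample (nA={a.shape[0]}, nB={b.shape[0]})"
    )
    if np.any(zero & mask):
        log.warning("%d in-mask voxels had zero variance; t set to 0",
                    int((zero & mask).sum()))
    return StatMap(
        t=t, df=df, mask=mask, contrast=contrast,
        affine=np.eye(4) if affine is None else affine,
        zero_variance=zero & mask,
    )


def _label_clusters(supra: np.ndarray, connectivity: int):
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    return ndimage.label(supra, structure=_STRUCTURES[connectivity])


def _max_cluster_size(supra: np.ndarray, connectivity: int, k_min: int) -> int:
    labels, n = _label_clusters(supra, connectivity)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    sizes = sizes[sizes >= 1]
    return int(sizes.max()) if sizes.size else 0


def find_clusters(
    stat: StatMap,
    p_form: float = 0.005,
    k_min: int = 20,
    connectivity: int = 18,
) -> ClusterResult:
    """Threshold the t map one-tailed and keep clusters of >= k_min voxels."""
    if not 0.0 < p_form < 1.0:
        raise ValueError("p_form must lie in (0, 1)")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    t_crit = float(stats.t.isf(p_form, stat.df))
    supra = (stat.t > t_crit) & stat.mask
    labels, n = _label_clusters(supra, connectivity)

    rows = []
    keep_labels = np.zeros_like(labels)
    kept = 0
    for lab in range(1, n + 1):
        sel = labels == lab
        size = int(sel.sum())
        if size < k_min:
            continue
        kept += 1
        tvals = np.where(sel, stat.t, -np.inf)
        peak_idx = np.unravel_index(np.argmax(tvals), tvals.shape)
        peak_mm = (stat.affine @ np.array([*peak_idx, 1.0]))[:3]
        keep_labels[sel] = kept
        rows.append({
            "cluster": kept,
            "size": size,
            "peak_t": float(stat.t[peak_idx]),
            "peak_ijk": tuple(int(i) for i in peak_idx),
            "peak_mm": tuple(float(v) for v in peak_mm),
        })
    frame = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_t", "peak_ijk", "peak_mm"]
    )
    return ClusterResult(
        clusters=frame, labels=keep_labels, threshold_t=t_crit,
        k_min=k_min, connectivity=connectivity,
    )


def _two_sample_perms(na: int, nb: int, n_perm: int, rng: np.random.Generator):
    """Yield index arrays assigning subjects to group A; exhaustive when
    the number of distinct relabelings is small."""
    from math import comb

    total = na + nb
    n_distinct = comb(total, na)
    if n_distinct <= n_perm:
        log.info("enumerating all %d group relabelings exhaustively", n_distinct)
        return [np.array(c) for c in itertools.combinations(range(total), na)], True
    perms = []
    for _ in range(n_perm):
        perm = rng.permutation(total)
        perms.append(np.sort(perm[:na]))
    return perms, False


def permutation_cluster_p(
    maps_a,
    maps_b=None,
    mask: np.ndarray | None = None,
    p_form: float = 0.005,
    k_min: int = 20,
    connectivity: int = 18,
    n_perm: int = 1000,
    seed: int | None = 0,
    affine: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-extent corrected inference by max-cluster-size permutation.

    Two-sample contrasts permute group labels; one-sample contrasts flip
    map signs. Corrected p of each observed cluster is
    ``(1 + #{null max size >= observed size}) / (n_perm + 1)`` (or the
    exact proportion when the permutation group is enumerated).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    a = _stack(maps_a)
    b = _stack(maps_b) if maps_b is not None else None
    observed = t_map(a, b, mask=mask, affine=affine)
    result = find_clusters(observed, p_form=p_form, k_min=k_min,
                           connectivity=connectivity)
    t_crit = result.threshold_t
    msk = observed.mask

    null_max = []
    exhaustive = False
    if b is None:
        n = a.shape[0]
        if 2 ** n <= n_perm:
            log.info("enumerating all %d sign flips exhaustively", 2 ** n)
            exhaustive = True
            flips = (np.array(bits) for bits in itertools.product((1.0, -1.0), repeat=n))
        else:
            flips = (rng.choice((1.0, -1.0), size=n) for _ in range(n_perm))
        for signs in flips:
            t, _, _ = _t_from_stacks(a * signs[:, None, None, None], None)
            null_max.append(_max_cluster_size((t > t_crit) & msk, connectivity, k_min))
    else:
        stacked = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        perms, exhaustive = _two_sample_perms(na, b.shape[0], n_perm, rng)
        all_idx = np.arange(stacked.shape[0])
        for idx_a in perms:
            idx_b = np.setdiff1d(all_idx, idx_a, assume_unique=True)
            t, _, _ = _t_from_stacks(stacked[idx_a], stacked[idx_b])
            null_max.append(_max_cluster_size((t > t_crit) & msk, connectivity, k_min))

    null_max = np.asarray(null_max)
    m = len(null_max)
    pvals = []
    for size in result.clusters["size"]:
        exceed = int((null_max >= size).sum())
        if exhaustive:
            pvals.append(exceed / m)
        else:
            pvals.append((1 + exceed) / (m + 1))
    result.clusters["corrected_p"] = pvals
    result.n_perm = m
    result.null_max_size = null_max
    return result
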