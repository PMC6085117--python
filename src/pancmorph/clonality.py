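"""Spatial clonality assessment for confetti clone tables.

If clone induction is truly clonal and independent, the probability that two
clones at a given separation share a confetti color should not depend on
distance.  This module computes the distance-resolved same-color pair
probability rescaled by the any-color pair probability, builds a bootstrap
null envelope by randomly reassigning colors at fixed positions from the
per-mouse color frequencies, and corrects clone fragmentation by grouping
same-color clones within a user-chosen radius (single linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PairProbabilityCurve",
    "pair_probability",
    "bootstrap_null",
    "merger_correction",
    "default_bin_edges",
]


@dataclass
class PairProbabilityCurve:
    """Per-distance-bin same-color pair probability, rescaled by all pairs."""

    bin_edges: np.ndarray
    p_same: np.ndarray          # same-color pairs / all pairs per bin
    n_pairs: np.ndarray         # all pairs per bin
    n_same: np.ndarray

    @property
    def rescaled(self) -> np.ndarray:
        """Alias for ``p_same``: already conditional on pairs in the bin."""
        return self.p_same

    @property
    def defined(self) -> np.ndarray:
        """Bins with at least one pair; others are flagged undefined (NaN)."""
        return self.n_pairs > 0


def _positions(clones: pd.DataFrame) -> np.ndarray:
    return clones[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def default_bin_edges(distances: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Ten equal-width bins from 0 to the 95th percentile of pair distances."""
    upper = float(np.quantile(distances, 0.95))
    if upper <= 0:
        upper = float(distances.max()) or 1.0
    return np.linspace(0.0, upper, n_bins + 1)


def _pair_arrays(clones: pd.DataFrame):
    if len(clones) < 2:
        raise ValueError("need at least two clones")
    pos = _positions(clones)
    d = pdist(pos)
    n = len(clones)
    iu, ju = np.triu_indices(n, k=1)
    return d, iu, ju


def _curve(colors: np.ndarray, iu, ju, bin_idx, n_bins) -> np.ndarray:
    same = (colors[iu] == colors[ju]).astype(float)
    tot = np.bincount(bin_idx, minlength=n_bins).astype(float)
    hit = np.bincount(bin_idx, weights=same, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, hit / tot, np.nan), hit, tot


def pair_probability(clones: pd.DataFrame,
                     bin_edges: Optional[Sequence[float]] = None
                     ) -> PairProbabilityCurve:
    """Same-color pair probability per 3D-distance bin, one mouse at a time.

    Rescaling by the any-color pair count makes the curve insensitive to the
    organ's shape: under clonal (independent) induction it is flat.
    """
    d, iu, ju = _pair_arrays(clones)
    if bin_edges is None:
        bin_edges = default_bin_edges(d)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    n_bins = edges.size - 1
    bin_idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins)
    keep = (d >= edges[0]) & (d <= edges[-1])
    bin_idx = np.minimum(bin_idx[keep], n_bins - 1)
    colors = clones["color"].to_numpy()
    p, hit, tot = _curve(colors, iu[keep], ju[keep], bin_idx, n_bins)
    return PairProbabilityCurve(bin_edges=edges, p_same=p, n_pairs=tot.astype(int),
                                n_same=hit.astype(int))


def bootstrap_null(clones: pd.DataFrame,
                   bin_edges: Optional[Sequence[float]] = None,
                   n_boot: int = 1000, alpha: float = 0.05,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (lo, hi) envelope of the rescaled curve under the clonal null.

    Colors are redrawn i.i.d. from the mouse's empirical color frequencies at
    fixed positions, ``n_boot`` times; the envelope is the per-bin
    (alpha/2, 1 - alpha/2) quantile band of the resampled curves.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable envelope quantiles")
    if rng is None:
        rng = np.random.default_rng(seed)
    d, iu, ju = _pair_arrays(clones)
    if bin_edges is None:
        bin_edges = default_bin_edges(d)
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = edges.size - 1
    bin_idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins)
    keep = (d >= edges[0]) & (d <= edges[-1])
    bin_idx = np.minimum(bin_idx[keep], n_bins - 1)
    iu, ju = iu[keep], ju[keep]
    colors = clones["color"].to_numpy()
    uniq, counts = np.unique(colors, return_counts=True)
    freqs = counts / counts.sum()
    n = len(clones)
    curves = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        resampled = uniq[rng.choice(uniq.size, size=n, p=freqs)]
        curves[b], _, _ = _curve(resampled, iu, ju, bin_idx, n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN empty bins
        lo = np.nanquantile(curves, alpha / 2, axis=0)
        hi = np.nanquantile(curves, 1 - alpha / 2, axis=0)
    return lo, hi


def merger_correction(clones: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Group same-color clones within ``radius`` (single linkage) into one.

    Each group becomes a single clone with summed compartment volumes, summed
    branch counts, and a volume-weighted centroid position.  Different colors
    never merge.  The operation is idempotent and conserves per-color volume.
    """
    if radius <= 0:
        raise ValueError("merger radius must be positive")
    vol_cols = ["vol_acinar_um3", "vol_ductal_um3", "vol_islet_um3"]
    out_rows = []
    for color, group in clones.groupby("color", sort=False):
        pos = _positions(group)
        n = len(group)
        if n == 1:
            out_rows.append(group.iloc[0].to_dict())
            continue
        dm = squareform(pdist(pos)) <= radius
        np.fill_diagonal(dm, False)
        n_comp, labels = connected_components(csr_matrix(dm), directed=False)
        for c in range(n_comp):
            sub = group.iloc[np.nonzero(labels == c)[0]]
            if len(sub) == 1:
                out_rows.append(sub.iloc[0].to_dict())
                continue
            vols = sub[vol_cols].sum()
            w = sub[vol_cols].sum(axis=1).to_numpy(dtype=float)
            w = w / w.sum()
            cent = (_positions(sub) * w[:, None]).sum(axis=0)
            row = sub.iloc[0].to_dict()
            row.update({
                "x_um": cent[0], "y_um": cent[1], "z_um": cent[2],
                **{k: float(vols[k]) for k in vol_cols},
            })
            if "n_branches" in sub and sub["n_branches"].notna().all():
                row["n_branches"] = int(sub["n_branches"].sum())
            out_rows.append(row)
    return pd.DataFrame(out_rows).reset_index(drop=True)
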