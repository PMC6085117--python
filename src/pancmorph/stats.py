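"""Clone-level statistics for confetti lineage tracing.

Covers potency classification across the acinar/ductal/islet compartments,
mean-rescaled cumulative size distributions, quantile-quantile agreement
(R^2 against the identity line), exact and asymptotic two-sample rank tests,
chi-square potency comparisons, and a center-versus-periphery spatial split.

Exact Mann-Whitney and Kolmogorov-Smirnov p-values are obtained by full
enumeration of group assignments, which is only feasible (and only used) for
small pooled samples; larger samples fall back to the usual asymptotic
approximations from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "COLORS",
    "COMPARTMENTS",
    "CloneRecord",
    "EmpiricalDistribution",
    "classify_potency",
    "potency_summary",
    "rescaled_distribution",
    "bin_small_sizes",
    "qq_r2",
    "mann_whitney",
    "ks_two_sample",
    "chi_square_potency",
    "center_periphery_split",
]

COLORS = ("CFP", "GFP", "YFP", "RFP")
COMPARTMENTS = ("acinar", "ductal", "islet")

_POTENCY_NAMES = {1: "uni", 2: "bi", 3: "tri"}


@dataclass
class CloneRecord:
    """One traced clone: color, 3D position, per-compartment volumes."""

    clone_id: str
    mouse_id: str
    color: str
    position: tuple[float, float, float]  # microns
    volume_acinar: float
    volume_ductal: float
    volume_islet: float
    n_branches: Optional[int] = None
    induction_day: str = ""
    collection_day: str = ""

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown confetti color {self.color!r}")
        vols = (self.volume_acinar, self.volume_ductal, self.volume_islet)
        if any(v < 0 for v in vols):
            raise ValueError("compartment volumes must be non-negative")
        if all(v == 0 for v in vols):
            raise ValueError("clone must have at least one positive volume")

    def volumes(self) -> dict[str, float]:
        return {
            "acinar": self.volume_acinar,
            "ductal": self.volume_ductal,
            "islet": self.volume_islet,
        }


class EmpiricalDistribution:
    """Mean-rescaled sample of positive sizes with a cumulative-tail view.

    ``tail(x)`` is the fraction of rescaled sizes strictly greater than x,
    e.g. tail(3) = 0.1 means 10% of clones (or subtrees) exceed three times
    the ensemble average size.
    """

    def __init__(self, values: Sequence[float]):
        vals = np.asarray(values, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 1 or np.any(vals <= 0):
            raise ValueError("need a non-empty sample of positive sizes")
        self.values = vals
        self.mean = float(vals.mean())
        self.rescaled = vals / self.mean

    def __len__(self) -> int:
        return self.values.size

    def tail(self, x) -> np.ndarray | float:
        x_arr = np.asarray(x, dtype=float)
        out = (self.rescaled[:, None] > np.atleast_1d(x_arr)[None, :]).mean(axis=0)
        return float(out[0]) if x_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# potency
# ---------------------------------------------------------------------------

def _volumes_of(clone) -> dict[str, float]:
    if isinstance(clone, CloneRecord):
        return clone.volumes()
    # pandas Series / mapping in the clone-table schema
    return {
        "acinar": float(clone["vol_acinar_um3"]),
        "ductal": float(clone["vol_ductal_um3"]),
        "islet": float(clone["vol_islet_um3"]),
    }


def classify_potency(clone, presence_threshold: float = 0.0
                     ) -> tuple[str, frozenset]:
    """Potency (uni/bi/tri) and lineage set of one clone.

    A lineage is present iff its volume strictly exceeds
    ``presence_threshold`` (default 0: strict positivity).
    """
    vols = _volumes_of(clone)
    present = frozenset(k for k, v in vols.items() if v > presence_threshold)
    if not present:
        raise ValueError("empty clone: no compartment above threshold")
    return _POTENCY_NAMES[len(present)], present


def potency_summary(clones: pd.DataFrame, group_by: Optional[str] = None,
                    presence_threshold: float = 0.0) -> pd.DataFrame:
    """Uni/bi/tri-potent fractions (and counts), optionally per mouse or color.

    ``group_by`` is None, ``"mouse"`` or ``"color"``.  Fractions sum to 1 in
    every group.
    """
    if len(clones) == 0:
        raise ValueError("need at least one clone")
    pot = clones.apply(
        lambda row: classify_potency(row, presence_threshold)[0], axis=1)
    key_col = {None: None, "mouse": "mouse_id", "color": "color"}[group_by]
    keys = clones[key_col] if key_col else pd.Series("all", index=clones.index)
    rows = []
    for group, idx in pot.groupby(keys).groups.items():
        sub = pot.loc[idx]
        n = len(sub)
        row = {"group": group, "n_clones": n}
        for p in ("uni", "bi", "tri"):
            row[f"n_{p}"] = int((sub == p).sum())
            row[f"frac_{p}"] = row[f"n_{p}"] / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# size distributions
# ---------------------------------------------------------------------------

def rescaled_distribution(clones: pd.DataFrame, compartment: str
                          ) -> EmpiricalDistribution:
    """Mean-rescaled size distribution of one compartment (or branch counts).

    ``compartment`` is one of acinar/ductal/islet/total/branches; clones with
    zero size in the chosen compartment are excluded from the sample.
    """
    if compartment in COMPARTMENTS:
        sizes = clones[f"vol_{compartment}_um3"].to_numpy(dtype=float)
    elif compartment == "total":
        sizes = (clones[["vol_acinar_um3", "vol_ductal_um3", "vol_islet_um3"]]
                 .sum(axis=1).to_numpy(dtype=float))
    elif compartment == "branches":
        sizes = clones["n_branches"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    sizes = sizes[np.isfinite(sizes) & (sizes > 0)]
    if sizes.size < 2:
        raise ValueError(
            f"need >=2 clones with positive {compartment} size, got {sizes.size}")
    return EmpiricalDistribution(sizes)


def bin_small_sizes(values: np.ndarray, quantile: float) -> np.ndarray:
    """Floor all values below the given sample quantile to a common bin value.

    Mirrors the binning applied to very small clone sizes before rank tests;
    off by default in every caller (pass quantile=0 to disable).
    """
    vals = np.asarray(values, dtype=float).copy()
    if quantile <= 0:
        return vals
    edge = np.quantile(vals, quantile)
    vals[vals < edge] = edge
    return vals


def _quantile_grid(values: np.ndarray, m: int) -> np.ndarray:
    # linear interpolation between order statistics at p = (i - 0.5)/m
    p = (np.arange(1, m + 1) - 0.5) / m
    return np.quantile(np.asarray(values, dtype=float), p, method="linear")


def qq_r2(a: EmpiricalDistribution, b: EmpiricalDistribution) -> float:
    """Coefficient of determination of the QQ plot against f(x) = x.

    Both samples are mean-rescaled, their empirical quantiles evaluated on a
    common grid p = (i - 0.5)/m with m the smaller sample size, and R^2
    computed for the identity prediction: R^2 = 1 means the rescaled
    distributions coincide on the grid.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples must contain >= 2 values")
    m = min(len(a), len(b))
    qa = _quantile_grid(a.rescaled, m)
    qb = _quantile_grid(b.rescaled, m)
    ss_tot = float(np.sum((qb - qb.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("degenerate reference sample: zero quantile variance")
    ss_res = float(np.sum((qb - qa) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def _resolve_mode(mode: str, n_total: int) -> str:
    if mode == "auto":
        return "exact" if n_total <= 12 else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError("mode must be exact, asymptotic or auto")
    return mode


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney test; exact by enumeration for small samples.

    The exact two-sided p-value is the permutation probability of a U at
    least as far from its null mean nm/2 as the observed one, enumerated over
    all C(n+m, n) assignments of the pooled values (ties handled by the 1/2
    convention in U).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    mode = _resolve_mode(mode, a.size + b.size)
    u_obs = _u_statistic(a, b)
    if mode == "asymptotic":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return u_obs, float(res.pvalue)
    pooled = np.concatenate([a, b])
    n = a.size
    center = n * b.size / 2.0
    dev_obs = abs(u_obs - center)
    idx = np.arange(pooled.size)
    count = 0
    total = 0
    for comb in combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    allv = np.concatenate([a, b])
    allv.sort()
    fa = np.searchsorted(np.sort(a), allv, side="right") / a.size
    fb = np.searchsorted(np.sort(b), allv, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_two_sample(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test; exact permutation for small samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    mode = _resolve_mode(mode, a.size + b.size)
    d_obs = _ks_statistic(a, b)
    if mode == "asymptotic":
        res = sps.ks_2samp(a, b, method="asymp")
        return d_obs, float(res.pvalue)
    pooled = np.concatenate([a, b])
    idx = np.arange(pooled.size)
    n = a.size
    count = 0
    total = 0
    for comb in combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        if _ks_statistic(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            count += 1
        total += 1
    return d_obs, count / total


# ---------------------------------------------------------------------------
# contingency and spatial stratification
# ---------------------------------------------------------------------------

def chi_square_potency(table) -> tuple[float, int, float]:
    """Pearson chi-square on a potency x group count table.

    Raises on zero expected counts (pool categories first).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    expected = sps.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count; pool sparse potency categories before testing")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def center_periphery_split(
    clones: pd.DataFrame,
    organ_center: Sequence[float],
    organ_radius_estimate: float,
    center_fraction: float = 2.0 / 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition clones into organ center (inner 2/3) and periphery (outer 1/3).

    A clone is central iff its distance from ``organ_center`` divided by
    ``organ_radius_estimate`` is <= ``center_fraction``.
    """
    if organ_radius_estimate <= 0:
        raise ValueError("organ radius estimate must be positive")
    pos = clones[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    r = np.linalg.norm(pos - np.asarray(organ_center, float)[None, :], axis=1)
    norm_r = r / organ_radius_estimate
    is_center = norm_r <= center_fraction
    return clones[is_center], clones[~is_center]
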