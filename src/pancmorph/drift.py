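"""Neutral drift of precursor pools at ductal termini.

Each growing terminus carries a pool of N self-renewing precursors.  At every
bifurcation the pool is segregated approximately equally between the two
daughter termini, after which each daughter undergoes a round of symmetric
duplication to restore the pool to size N.  Chance segregation lets the
labeled fraction drift, so with increasing branch generation ducts convert to
being fully labeled by a single confetti color or fully unlabeled
("monoclonal conversion").  The conversion rate scales inversely with N,
which is what lets N be inferred from observed conversion profiles.

Labels are arbitrary hashable ids; 0 (UNLABELED) denotes an unlabeled cell.
The per-branch label-count process along any single lineage is a Markov
chain on {0..N} whose labeled-fraction is a martingale, giving the exact
fixation law P(eventual full labeling | k of N labeled) = k/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import DuctalNetwork

__all__ = [
    "UNLABELED",
    "TerminusPool",
    "bifurcate_pool",
    "run_drift",
    "conversion_profile",
    "infer_precursor_number",
    "transition_matrix",
    "fixation_probability_exact",
    "conversion_cdf_exact",
    "simulate_conversion_chains",
    "median_conversion_generation",
    "ensemble_conversion_profile",
]

UNLABELED: Hashable = 0


@dataclass
class TerminusPool:
    """The N precursor slots carried by one terminus, as a label multiset."""

    labels: tuple

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(self.labels) == 0:
            raise ValueError("precursor pool must be non-empty")

    @property
    def n(self) -> int:
        return len(self.labels)

    def counts(self) -> dict:
        out: dict = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def is_monoclonal(self) -> bool:
        """All one color, or all unlabeled (pool label entropy zero)."""
        return len(set(self.labels)) == 1


def bifurcate_pool(pool: TerminusPool, rng: np.random.Generator
                   ) -> tuple[TerminusPool, TerminusPool]:
    """Segregate a pool ~equally between daughters, then duplicate to size N.

    The N cells are partitioned uniformly at random into groups of floor(N/2)
    and ceil(N/2) (group-to-daughter assignment random when N is odd).  Each
    daughter's cells are copied once; for odd N the larger daughter discards
    one uniformly chosen copy and the smaller duplicates one uniformly chosen
    cell again, restoring size N either way.  Both corrections preserve the
    labeled-fraction martingale.
    """
    n = pool.n
    if n == 1:
        # a lone precursor duplicates before the split: both daughters
        # inherit a copy (the only size-preserving rule for N=1)
        return TerminusPool(pool.labels), TerminusPool(pool.labels)
    labels = np.array(pool.labels, dtype=object)
    perm = rng.permutation(n)
    lo, hi = n // 2, n - n // 2
    if rng.random() < 0.5:
        ga, gb = perm[:lo], perm[lo:]
    else:
        ga, gb = perm[lo:], perm[:lo]

    def _duplicate(group: np.ndarray) -> tuple:
        cells = list(labels[group]) * 2
        if len(cells) == n + 1:      # ceil daughter for odd N
            cells.pop(rng.integers(len(cells)))
        elif len(cells) == n - 1:    # floor daughter for odd N
            cells.append(cells[rng.integers(len(cells))])
        return tuple(cells)

    return TerminusPool(_duplicate(ga)), TerminusPool(_duplicate(gb))


# ---------------------------------------------------------------------------
# drift replayed over a bifurcation forest
# ---------------------------------------------------------------------------

def _initial_pool(n: int, initial_labeling, rng: np.random.Generator
                  ) -> TerminusPool:
    if isinstance(initial_labeling, TerminusPool):
        if initial_labeling.n != n:
            raise ValueError("initial pool size does not match N")
        return initial_labeling
    if isinstance(initial_labeling, (list, tuple)):
        if len(initial_labeling) != n:
            raise ValueError("per-cell label assignment must have length N")
        return TerminusPool(tuple(initial_labeling))
    if isinstance(initial_labeling, dict):
        # induction probability per color, independently per cell
        colors = list(initial_labeling)
        probs = np.array([initial_labeling[c] for c in colors], dtype=float)
        if probs.sum() > 1 + 1e-12 or np.any(probs < 0):
            raise ValueError("induction probabilities must be >=0 and sum <=1")
        p = np.concatenate([probs, [1 - probs.sum()]])
        choice = rng.choice(len(colors) + 1, size=n, p=p)
        cells = tuple(colors[c] if c < len(colors) else UNLABELED
                      for c in choice)
        return TerminusPool(cells)
    raise TypeError("initial_labeling must be a pool, a sequence, or a dict")


def run_drift(network: DuctalNetwork, n_precursors: int,
              initial_labeling, seed: Optional[int] = None,
              rng: Optional[np.random.Generator] = None) -> DuctalNetwork:
    """Replay pool dynamics over a network's bifurcation forest.

    Every segment's ``labels`` field is set to the composition of the pool
    that began its construction; bifurcations trigger
    :func:`bifurcate_pool`.  ``initial_labeling`` (applied independently per
    subtree root) is a TerminusPool, a per-cell label sequence, or a dict of
    per-color induction probabilities.
    """
    if n_precursors < 1:
        raise ValueError("need at least one precursor per terminus")
    if rng is None:
        rng = np.random.default_rng(seed)
    children = network.children_map()
    for root in network.roots():
        pool = _initial_pool(n_precursors, initial_labeling, rng)
        stack = [(root.id, pool)]
        while stack:
            seg_id, pool = stack.pop()
            seg = network.segments[seg_id]
            seg.labels = pool.counts()
            kids = children.get(seg_id, [])
            if len(kids) == 2:
                d1, d2 = bifurcate_pool(pool, rng)
                stack.append((kids[0], d1))
                stack.append((kids[1], d2))
            elif len(kids) == 1:
                raise ValueError(
                    f"segment {seg_id} has exactly one child; not a completed "
                    "bifurcation forest")
    return network


def _is_monoclonal_counts(counts: dict) -> bool:
    return len(counts) == 1


def conversion_profile(network: DuctalNetwork) -> pd.DataFrame:
    """Fraction of monoclonal segments per branch generation.

    A segment is monoclonal when the pool that built it was all one color or
    all unlabeled.  Requires :func:`run_drift` to have annotated the network.
    """
    rows: dict[int, list[int]] = {}
    for seg in network.segments.values():
        if seg.labels is None:
            raise ValueError("network carries no drift labels; run run_drift first")
        rows.setdefault(seg.generation, [0, 0])
        rows[seg.generation][0] += 1
        if _is_monoclonal_counts(seg.labels):
            rows[seg.generation][1] += 1
    gens = sorted(rows)
    return pd.DataFrame({
        "generation": gens,
        "n_segments": [rows[g][0] for g in gens],
        "fraction_monoclonal": [rows[g][1] / rows[g][0] for g in gens],
    })


# ---------------------------------------------------------------------------
# exact single-lineage Markov chain on labeled counts
# ---------------------------------------------------------------------------

def transition_matrix(n: int) -> np.ndarray:
    """One-bifurcation transition matrix of the labeled count along a lineage.

    State k in {0..N} is the number of labeled cells in the pool.  Following
    a randomly chosen daughter: the daughter receives h ~ Hypergeom(N, k, m)
    labeled cells of its m in {floor(N/2), ceil(N/2)} drawn cells, then
    duplication (with the odd-N size correction) maps h to the new count.
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    if n == 1:
        return np.eye(2)  # the lone precursor is copied to both daughters
    P = np.zeros((n + 1, n + 1))
    lo, hi = n // 2, n - n // 2
    for k in range(n + 1):
        for m, weight in (((lo, 0.5), (hi, 0.5)) if lo != hi else ((lo, 1.0),)):
            m_size, w = m, weight
            hs = np.arange(max(0, m_size - (n - k)), min(k, m_size) + 1)
            ph = hypergeom.pmf(hs, n, k, m_size)
            for h, p_h in zip(hs, ph):
                if 2 * m_size == n:            # even N: plain doubling
                    P[k, 2 * h] += w * p_h
                elif 2 * m_size == n + 1:      # ceil daughter drops one copy
                    p_drop_lab = h / m_size if m_size else 0.0
                    if 2 * h - 1 >= 0:
                        P[k, 2 * h - 1] += w * p_h * p_drop_lab
                    P[k, min(2 * h, n)] += w * p_h * (1 - p_drop_lab)
                else:                          # floor daughter re-copies one
                    p_add_lab = h / m_size if m_size else 0.0
                    P[k, min(2 * h + 1, n)] += w * p_h * p_add_lab
                    P[k, 2 * h] += w * p_h * (1 - p_add_lab)
    return P


def fixation_probability_exact(n: int, k: int) -> float:
    """Exact absorption probability at the all-labeled state from k of N.

    Solves the linear system for the absorbing chain; by the martingale
    property the answer is k/N, and this routine computes it from the chain
    itself (it is the independent cross-check, not the identity).
    """
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, N]")
    P = transition_matrix(n)
    interior = np.arange(1, n)
    f = np.zeros(n + 1)
    f[n] = 1.0
    if interior.size:
        Q = P[np.ix_(interior, interior)]
        r = P[interior, n]
        f[interior] = np.linalg.solve(np.eye(interior.size) - Q, r)
    return float(f[k])


def conversion_cdf_exact(n: int, k0: int, max_gen: int) -> np.ndarray:
    """P(lineage monoclonal by generation g), g = 0..max_gen, exactly.

    Monoclonal means the labeled count has been absorbed at 0 or N (with a
    single tracked label, pool entropy zero).
    """
    P = transition_matrix(n)
    dist = np.zeros(n + 1)
    dist[k0] = 1.0
    out = np.empty(max_gen + 1)
    out[0] = dist[0] + dist[n]
    for g in range(1, max_gen + 1):
        dist = dist @ P
        out[g] = dist[0] + dist[n]
    return out


# ---------------------------------------------------------------------------
# vectorized Monte-Carlo lineages
# ---------------------------------------------------------------------------

def _chain_step(k: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized one-bifurcation update of labeled counts along lineages."""
    lo, hi = n // 2, n - n // 2
    if lo == hi:
        h = rng.hypergeometric(k, n - k, lo)
        return 2 * h
    take_hi = rng.random(k.shape) < 0.5
    m = np.where(take_hi, hi, lo)
    h = rng.hypergeometric(k, n - k, m)
    new = 2 * h
    # odd-N size corrections
    u = rng.random(k.shape)
    frac = np.divide(h, m, out=np.zeros_like(h, dtype=float), where=m > 0)
    new = np.where(take_hi, new - (u < frac), new + (u < frac))
    return np.clip(new, 0, n)


def simulate_conversion_chains(n: int, n_chains: int, max_gen: int,
                               rng: np.random.Generator, k0: int = 1
                               ) -> np.ndarray:
    """Absorption generation of independent lineages (np.inf if censored)."""
    k = np.full(n_chains, k0, dtype=np.int64)
    t_abs = np.full(n_chains, np.inf)
    absorbed = (k == 0) | (k == n)
    t_abs[absorbed] = 0
    for g in range(1, max_gen + 1):
        live = ~absorbed
        if not live.any():
            break
        k[live] = _chain_step(k[live], n, rng)
        newly = live & ((k == 0) | (k == n))
        t_abs[newly] = g
        absorbed |= newly
    return t_abs


def median_conversion_generation(n: int, k0: int = 1, max_gen: int = 512,
                                 method: str = "exact",
                                 conditional: str = "fixation",
                                 n_chains: int = 20000,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> float:
    """Interpolated median generation at which a duct lineage converts.

    ``conditional="fixation"`` (default) measures lineages that end fully
    labeled -- the ducts a traced clone actually shows converting -- whose
    conversion time grows in proportion to N.  The unconditional time
    (``conditional="none"``) is dominated by early label loss: with a single
    labeled cell, a randomly followed lineage loses the label with
    probability 1/2 at the very first bifurcation whatever N is, so it
    carries no information about the pool size.  The absorption-time
    distribution is discrete, so the median is linearly interpolated through
    the CDF at 1/2 (integer medians tie between neighboring N).
    """
    if conditional not in ("fixation", "none"):
        raise ValueError("conditional must be 'fixation' or 'none'")
    if method == "exact":
        if conditional == "none":
            cdf = conversion_cdf_exact(n, k0, max_gen)
        else:
            P = transition_matrix(n)
            dist = np.zeros(n + 1)
            dist[k0] = 1.0
            mass = np.empty(max_gen + 1)
            mass[0] = dist[n]
            for g in range(1, max_gen + 1):
                dist = dist @ P
                mass[g] = dist[n]
            if mass[-1] <= 0 or (mass[-1] - mass[-2]) > 1e-9 * mass[-1]:
                raise ValueError("fixation mass not converged within max_gen")
            cdf = mass / mass[-1]
    elif method == "mc":
        if rng is None:
            rng = np.random.default_rng(0)
        if conditional == "none":
            t = simulate_conversion_chains(n, n_chains, max_gen, rng, k0=k0)
        else:
            t = _fixation_times_mc(n, n_chains, max_gen, rng, k0)
        gens = np.arange(max_gen + 1)
        cdf = (t[:, None] <= gens[None, :]).mean(axis=0)
        if cdf[-1] <= 0:
            raise ValueError("no converted lineages within max_gen")
        cdf = cdf / cdf[-1]
    else:
        raise ValueError("method must be 'exact' or 'mc'")
    g_hi = int(np.searchsorted(cdf, 0.5))
    if g_hi >= cdf.size:
        raise ValueError("chain not half-converted within max_gen")
    if g_hi == 0:
        return 0.0
    f_lo, f_hi = cdf[g_hi - 1], cdf[g_hi]
    return g_hi - 1 + (0.5 - f_lo) / (f_hi - f_lo)


def _fixation_times_mc(n: int, n_chains: int, max_gen: int,
                       rng: np.random.Generator, k0: int) -> np.ndarray:
    """Absorption generations of lineages that end fully labeled."""
    k = np.full(n_chains, k0, dtype=np.int64)
    t_abs = np.full(n_chains, np.inf)
    fixed = k == n
    lost = k == 0
    t_abs[fixed] = 0
    for g in range(1, max_gen + 1):
        live = ~(fixed | lost)
        if not live.any():
            break
        k[live] = _chain_step(k[live], n, rng)
        newly_fixed = live & (k == n)
        t_abs[newly_fixed] = g
        fixed |= newly_fixed
        lost |= (k == 0)
    return t_abs[fixed]


# ---------------------------------------------------------------------------
# ensemble profiles and N inference
# ---------------------------------------------------------------------------

def ensemble_conversion_profile(n: int, n_subtrees: int, max_gen: int,
                                rng: np.random.Generator, k0: int = 1,
                                max_segments: int = 200_000) -> pd.DataFrame:
    """Conversion profile pooled over full binary subtrees.

    Simulates every segment of ``n_subtrees`` complete binary trees of depth
    ``max_gen`` (lineage correlations retained) and tabulates the monoclonal
    fraction per generation.  The per-generation segment population doubles,
    so beyond ``max_segments`` tracked states the population is thinned by
    uniform random subsampling -- an unbiased estimate of the fraction with a
    bounded memory footprint.
    """
    gens = []
    n_segments = []
    frac = []
    k = np.full(n_subtrees, k0, dtype=np.int64)
    true_count = n_subtrees
    for g in range(max_gen + 1):
        mono = (k == 0) | (k == n)
        gens.append(g)
        n_segments.append(true_count)
        frac.append(float(mono.mean()))
        if g < max_gen:
            # each segment spawns two daughters; absorbed states stay absorbed
            k = np.repeat(k, 2)
            true_count *= 2
            if k.size > max_segments:
                k = k[rng.choice(k.size, size=max_segments, replace=False)]
            live = (k != 0) & (k != n)
            if live.any():
                k[live] = _chain_step(k[live], n, rng)
    return pd.DataFrame({"generation": gens, "n_segments": n_segments,
                         "fraction_monoclonal": frac})


def _profile_score(observed: pd.DataFrame, model: pd.DataFrame) -> float:
    merged = observed.merge(model, on="generation", suffixes=("_obs", "_mod"))
    w = merged["n_segments_obs"].to_numpy(dtype=float)
    d = (merged["fraction_monoclonal_obs"].to_numpy()
         - merged["fraction_monoclonal_mod"].to_numpy())
    return float(np.sum(w * d * d) / np.sum(w))


def infer_precursor_number(observed: pd.DataFrame,
                           candidates: Iterable[int],
                           n_sims: int = 2000,
                           seed: Optional[int] = None,
                           rng: Optional[np.random.Generator] = None,
                           k0: int = 1) -> tuple[int, pd.DataFrame]:
    """Best-fitting precursor number N from a conversion profile.

    For each candidate N an ensemble conversion profile is simulated (one
    initially labeled precursor per terminus) and scored against the observed
    profile by segment-count-weighted mean squared difference of the
    monoclonal fractions over shared generations.  Returns the argmin and the
    full score table.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if len(observed) < 2:
        raise ValueError("observed profile needs >= 2 generations")
    if rng is None:
        rng = np.random.default_rng(seed)
    max_gen = int(observed["generation"].max())
    rows = []
    for n in candidates:
        model = ensemble_conversion_profile(
            n, n_subtrees=n_sims, max_gen=max_gen, rng=rng, k0=min(k0, n))
        rows.append({"N": n, "score": _profile_score(observed, model)})
    table = pd.DataFrame(rows).set_index("N")
    best = int(table["score"].idxmin())
    return best, table
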