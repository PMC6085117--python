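"""Branching-annihilating random-walk model of ductal morphogenesis.

Three rules generate the whole ductal arbor:

1. *Elongate*: every active terminus advances a fixed step along its current
   direction, which wobbles by a small Gaussian angle each step.
2. *Branch*: with a fixed probability per step the terminus bifurcates into
   two daughters at +-theta about the parent direction.
3. *Terminate*: a terminus that moves within the annihilation radius of any
   other duct (including the central duct) becomes inactive, permanently.

All lengths are ratios to the mean separation of adjacent subtree roots along
the central duct (``spacing``), the model's sole key parameter.  Defaults are
chosen so the mean branch length (step_length / branch_prob) equals that
spacing.  ``max_steps`` is the development window: in an open plane the tip
front keeps advancing, so the window bounds the simulated growth period the
way organ harvest bounds the real one.

Proximity is evaluated against the path points the simulation deposits,
which are spaced one elongation step apart -- dense relative to the
annihilation radius.  A terminus ignores deposited points whose arc distance
*through the tree* is within ``self_exclusion_length``: this covers its own
trailing path, the parent junction, and a newborn sibling, all of which are
geodesically near by construction; without the exclusion every tip would
annihilate on its own wake at birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import DuctalNetwork, Segment, Terminus
from .stats import EmpiricalDistribution

__all__ = [
    "SimParams",
    "init_network",
    "step",
    "simulate",
    "ensemble_subtree_distribution",
    "EnsembleDistribution",
]

_CENTRAL = -1   # lineage tag for central-duct points
_FROZEN = -2    # lineage tag for points restored from a serialized network


@dataclass(frozen=True)
class SimParams:
    """All simulator knobs, lengths in units of the inter-subtree spacing."""

    spacing: float = 1.0
    n_initial_termini: int = 40
    step_length: float = 0.05
    branch_prob: float = 0.05
    annihilation_radius: float = 0.25
    branch_angle: float = math.pi / 6  # half-angle per daughter (30 deg)
    angle_noise: float = 0.15
    self_exclusion_length: float = 0.75
    max_steps: int = 500
    seed: int = 0
    root_gap: str = "exponential"  # or "fixed" (tests)

    def validate(self) -> None:
        if not (0.0 < self.branch_prob < 1.0):
            raise ValueError("branch_prob must lie in (0, 1)")
        for name in ("spacing", "step_length", "annihilation_radius",
                     "self_exclusion_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.step_length >= self.spacing:
            raise ValueError("step_length must be smaller than spacing")
        if self.annihilation_radius >= self.spacing:
            raise ValueError("annihilation_radius must be smaller than spacing")
        if self.n_initial_termini < 1:
            raise ValueError("need at least one initial terminus")
        if self.root_gap not in ("exponential", "fixed"):
            raise ValueError("root_gap must be 'exponential' or 'fixed'")


class _PointStore:
    """Deposited path points on a uniform grid (cell size = query radius)."""

    def __init__(self, cell: float, capacity: int = 4096):
        self.cell = cell
        self.n = 0
        self.xy = np.empty((capacity, 2))
        self.tip = np.empty(capacity, dtype=np.int64)
        self.arc = np.empty(capacity)
        self.grid: dict[tuple[int, int], list[int]] = {}

    def _grow(self) -> None:
        cap = self.xy.shape[0] * 2
        self.xy = np.resize(self.xy, (cap, 2))
        self.tip = np.resize(self.tip, cap)
        self.arc = np.resize(self.arc, cap)

    def add(self, pt: np.ndarray, tip_id: int, arc: float) -> None:
        if self.n == self.xy.shape[0]:
            self._grow()
        i = self.n
        self.xy[i] = pt
        self.tip[i] = tip_id
        self.arc[i] = arc
        self.n = i + 1
        key = (int(math.floor(pt[0] / self.cell)),
               int(math.floor(pt[1] / self.cell)))
        self.grid.setdefault(key, []).append(i)

    def query(self, pos: np.ndarray) -> list[int]:
        """Indices in the 3x3 cell block around pos (superset of radius hits)."""
        cx = int(math.floor(pos[0] / self.cell))
        cy = int(math.floor(pos[1] / self.cell))
        out: list[int] = []
        g = self.grid
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                lst = g.get((cx + dx, cy + dy))
                if lst:
                    out.extend(lst)
        return out


class _Tip:
    """Internal mutable state of one active terminus."""

    __slots__ = ("id", "pos", "dirn", "arc", "root_u", "segment_pts",
                 "segment_id", "parent_segment_id", "subtree_id", "generation",
                 "chain_ids", "chain_arcs", "active")

    def __init__(self, id, pos, dirn, arc, root_u, segment_pts, segment_id,
                 parent_segment_id, subtree_id, generation, chain_ids,
                 chain_arcs):
        self.id = id
        self.pos = pos
        self.dirn = dirn
        self.arc = arc
        self.root_u = root_u
        self.segment_pts = segment_pts
        self.segment_id = segment_id
        self.parent_segment_id = parent_segment_id
        self.subtree_id = subtree_id
        self.generation = generation
        self.chain_ids = chain_ids      # tuple of tip ids, root..self
        self.chain_arcs = chain_arcs    # spawn arc of each chain element
        self.active = True


class _SimState:
    """Network under construction plus the spatial acceleration structure."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        params.validate()
        self.params = params
        self.rng = rng
        self.tips: list[_Tip] = []
        self.dead_tips: list[_Tip] = []
        self.segments: dict[int, Segment] = {}
        self.next_tip_id = 0
        self.next_seg_id = 0
        self.chains: dict[int, tuple[tuple, tuple]] = {}
        self.store = _PointStore(cell=params.annihilation_radius)
        self.central_duct: Optional[np.ndarray] = None
        self.steps_run = 0
        self.truncated = False

    def _geodesic_far(self, tip: _Tip, tip_arc: float, q: int, s_p: float
                      ) -> bool:
        """True if a related point is beyond the exclusion arc (rare path)."""
        L = self.params.self_exclusion_length
        q_ids, q_arcs = self.chains[q]
        t_ids, t_arcs = tip.chain_ids, tip.chain_arcs
        m = min(len(q_ids), len(t_ids))
        i = 0
        while i < m and q_ids[i] == t_ids[i]:
            i += 1
        if i == 0:
            return True  # different subtrees: no shared path
        if i < len(t_ids):
            s_j = t_arcs[i]       # junction where the two paths diverge
        elif i < len(q_ids):
            s_j = q_arcs[i]       # tip chain is a prefix of q's (defensive)
        else:
            return (tip_arc - s_p) > L  # identical lineages
        return (tip_arc - s_j) + abs(s_p - s_j) > L

    def collides(self, tip: _Tip, tip_arc: float, pos: np.ndarray) -> bool:
        """Any non-excluded deposited point within the annihilation radius?"""
        idx = self.store.query(pos)
        if not idx:
            return False
        ia = np.asarray(idx)
        xy = self.store.xy[ia]
        d2 = (xy[:, 0] - pos[0]) ** 2 + (xy[:, 1] - pos[1]) ** 2
        r = self.params.annihilation_radius
        near = d2 <= r * r
        if not near.any():
            return False
        ia = ia[near]
        tips_arr = self.store.tip[ia]
        arcs = self.store.arc[ia]
        L = self.params.self_exclusion_length
        # vectorized fast paths: own trail and central duct
        own = tips_arr == tip.id
        if np.any(own & (tip_arc - arcs > L)):
            return True
        central = tips_arr == _CENTRAL
        if np.any(central & (tip_arc + np.abs(arcs - tip.root_u) > L)):
            return True
        if np.any(tips_arr == _FROZEN):
            return True
        rest = ~(own | central | (tips_arr == _FROZEN))
        for q, s_p in zip(tips_arr[rest], arcs[rest]):
            if self._geodesic_far(tip, tip_arc, int(q), float(s_p)):
                return True
        return False


def _rot(v: np.ndarray, theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _new_state(params: SimParams, rng: np.random.Generator) -> _SimState:
    state = _SimState(params, rng)
    p = params
    # inter-root gaps: i.i.d. Exponential(mean=spacing) truncated below at the
    # annihilation radius ("independent adjacent subtrees"), or fixed spacing
    if p.root_gap == "fixed":
        gaps = np.full(p.n_initial_termini, p.spacing)
    else:
        gaps = rng.exponential(p.spacing, size=p.n_initial_termini)
        gaps = np.maximum(gaps, p.annihilation_radius)
    roots_u = np.concatenate([[0.0], np.cumsum(gaps)[:-1]]) + p.spacing / 2
    duct_len = roots_u[-1] + p.spacing / 2
    state.central_duct = np.array([[0.0, 0.0], [duct_len, 0.0]])
    n_duct = int(math.ceil(duct_len / p.step_length)) + 1
    for u in np.linspace(0.0, duct_len, n_duct):
        state.store.add(np.array([u, 0.0]), _CENTRAL, float(u))
    # launch one perpendicular root terminus per gap position
    for k, u in enumerate(roots_u):
        tid = state.next_tip_id
        state.next_tip_id += 1
        base = np.array([u, 0.0])
        dirn = np.array([0.0, 1.0])
        pos = base + p.step_length * dirn
        tip = _Tip(
            id=tid, pos=pos, dirn=dirn, arc=p.step_length, root_u=float(u),
            segment_pts=[base, pos], segment_id=state.next_seg_id,
            parent_segment_id=None, subtree_id=k, generation=0,
            chain_ids=(tid,), chain_arcs=(0.0,),
        )
        state.next_seg_id += 1
        state.chains[tid] = (tip.chain_ids, tip.chain_arcs)
        state.tips.append(tip)
        state.store.add(pos.copy(), tid, tip.arc)
    return state


def _close_segment(state: _SimState, tip: _Tip) -> Segment:
    seg = Segment(
        id=tip.segment_id,
        parent_id=tip.parent_segment_id,
        subtree_id=tip.subtree_id,
        generation=tip.generation,
        polyline=np.asarray(tip.segment_pts),
    )
    state.segments[seg.id] = seg
    return seg


def _advance_state(state: _SimState) -> None:
    """One update of every active terminus, in random order.

    Deposits made earlier in the sweep are visible to later termini, so the
    randomized order removes any systematic update bias.
    """
    p = state.params
    rng = state.rng
    n = len(state.tips)
    order = rng.permutation(n)
    thetas = rng.normal(0.0, p.angle_noise, size=n)
    branch_u = rng.random(n)
    new_tips: list[_Tip] = []
    survivors: list[_Tip] = []
    for j, i in enumerate(order):
        tip = state.tips[i]
        # (1) elongate with direction wobble
        dirn = _rot(tip.dirn, thetas[j])
        pos = tip.pos + p.step_length * dirn
        arc = tip.arc + p.step_length
        # (2) proximity termination wins over branching
        if state.collides(tip, arc, pos):
            tip.segment_pts.append(pos)
            tip.pos, tip.dirn, tip.arc = pos, dirn, arc
            tip.active = False
            _close_segment(state, tip)
            state.dead_tips.append(tip)
            continue
        # (3) stochastic bifurcation
        if branch_u[j] < p.branch_prob:
            tip.segment_pts.append(pos)
            tip.pos, tip.dirn, tip.arc = pos, dirn, arc
            tip.active = False
            parent_seg = _close_segment(state, tip)
            state.dead_tips.append(tip)
            state.store.add(pos.copy(), tip.id, arc)
            for sign in (+1.0, -1.0):
                cid = state.next_tip_id
                state.next_tip_id += 1
                cdir = _rot(dirn, sign * p.branch_angle)
                cpos = pos + p.step_length * cdir
                child = _Tip(
                    id=cid, pos=cpos, dirn=cdir, arc=arc + p.step_length,
                    root_u=tip.root_u,
                    segment_pts=[pos.copy(), cpos],
                    segment_id=state.next_seg_id,
                    parent_segment_id=parent_seg.id,
                    subtree_id=tip.subtree_id,
                    generation=tip.generation + 1,
                    chain_ids=tip.chain_ids + (cid,),
                    chain_arcs=tip.chain_arcs + (arc,),
                )
                state.next_seg_id += 1
                state.chains[cid] = (child.chain_ids, child.chain_arcs)
                state.store.add(cpos.copy(), cid, child.arc)
                new_tips.append(child)
            continue
        # (4) plain elongation
        tip.segment_pts.append(pos)
        tip.pos, tip.dirn, tip.arc = pos, dirn, arc
        state.store.add(pos.copy(), tip.id, arc)
        survivors.append(tip)
    state.tips = survivors + new_tips
    state.steps_run += 1


def _finalize(state: _SimState) -> DuctalNetwork:
    termini: dict[int, Terminus] = {}
    for tip in state.tips:  # still active at max_steps: warning condition
        _close_segment(state, tip)
        state.truncated = True
    for tip in state.dead_tips + state.tips:
        termini[tip.id] = Terminus(
            id=tip.id, position=tip.pos, direction=tip.dirn,
            active=tip.active, segment_id=tip.segment_id,
        )
    return DuctalNetwork(
        central_duct=state.central_duct,
        segments=state.segments,
        termini=termini,
        meta={"truncated": state.truncated, "steps": state.steps_run,
              "params": state.params},
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def init_network(params: SimParams, rng: np.random.Generator) -> DuctalNetwork:
    """Initial condition: perpendicular side termini along the central duct."""
    state = _new_state(params, rng)
    termini = {
        t.id: Terminus(id=t.id, position=t.pos, direction=t.dirn, active=True,
                       segment_id=t.segment_id)
        for t in state.tips
    }
    segments = {
        t.segment_id: Segment(
            id=t.segment_id, parent_id=None, subtree_id=t.subtree_id,
            generation=0, polyline=np.asarray(t.segment_pts),
        )
        for t in state.tips
    }
    return DuctalNetwork(central_duct=state.central_duct, segments=segments,
                         termini=termini, meta={"params": params})


def _state_from_network(network: DuctalNetwork, params: SimParams,
                        rng: np.random.Generator) -> _SimState:
    params.validate()
    state = _SimState(params, rng)
    state.central_duct = network.central_duct
    duct_len = network.central_duct[-1, 0] - network.central_duct[0, 0]
    n_duct = int(math.ceil(duct_len / params.step_length)) + 1
    y0 = network.central_duct[0, 1]
    for u in np.linspace(network.central_duct[0, 0],
                         network.central_duct[-1, 0], n_duct):
        state.store.add(np.array([u, y0]), _CENTRAL, float(u))
    children = network.children_map()
    state.next_seg_id = max(network.segments, default=-1) + 1
    state.next_tip_id = max(network.termini, default=-1) + 1
    term_by_seg = {t.segment_id: t for t in network.termini.values()}
    for seg in network.segments.values():
        pl = seg.polyline
        arcs = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pl, axis=0), axis=1))])
        t = term_by_seg.get(seg.id)
        is_live = t is not None and t.active and seg.id not in children
        if is_live:
            # the tip restarts with a fresh lineage chain; its own polyline
            # points keep the tip id so the trailing-path exclusion holds
            for pt, s in zip(pl, arcs):
                state.store.add(np.asarray(pt, float), t.id, float(s))
            tip = _Tip(
                id=t.id, pos=np.asarray(t.position, float),
                dirn=np.asarray(t.direction, float), arc=float(arcs[-1]),
                root_u=float(pl[0, 0]),
                segment_pts=[np.asarray(q, float) for q in pl],
                segment_id=seg.id, parent_segment_id=seg.parent_id,
                subtree_id=seg.subtree_id, generation=seg.generation,
                chain_ids=(t.id,), chain_arcs=(0.0,),
            )
            state.chains[t.id] = (tip.chain_ids, tip.chain_arcs)
            state.tips.append(tip)
        else:
            for pt, s in zip(pl, arcs):
                state.store.add(np.asarray(pt, float), _FROZEN, float(s))
            state.segments[seg.id] = seg
    return state


def step(network: DuctalNetwork, params: SimParams,
         rng: np.random.Generator) -> DuctalNetwork:
    """Advance a (small) network by one update.

    Convenience wrapper for inspecting single updates; it rebuilds the
    spatial state from the serialized network each call, so long runs should
    use :func:`simulate`.  Frozen (completed) segments act as plain obstacles
    with no geodesic exclusion, which only matters within
    ``self_exclusion_length`` of a restored junction.
    """
    state = _state_from_network(network, params, rng)
    _advance_state(state)
    return _finalize(state)


def simulate(params: SimParams, rng: Optional[np.random.Generator] = None,
             record_history: bool = False) -> DuctalNetwork:
    """Run the model until no termini are active or ``max_steps`` is reached.

    With ``record_history=True`` the returned network's ``meta['history']``
    holds per-step arrays of the mean active-tip distance from the central
    duct and the active-tip count.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = _new_state(params, rng)
    front, n_active = [], []
    while state.tips and state.steps_run < params.max_steps:
        if record_history:
            ys = np.array([t.pos[1] for t in state.tips])
            front.append(float(np.mean(np.abs(ys))))
            n_active.append(len(state.tips))
        _advance_state(state)
    net = _finalize(state)
    if record_history:
        net.meta["history"] = {
            "front_radius": np.asarray(front),
            "n_active": np.asarray(n_active, dtype=int),
        }
    return net


class EnsembleDistribution(EmpiricalDistribution):
    """Pooled, mean-rescaled subtree sizes with a 95% ensemble band.

    The band at x is the empirical (alpha/2, 1-alpha/2) quantile across runs
    of each run's own tail curve (run sizes rescaled by the pooled mean).
    """

    def __init__(self, per_run_sizes: list[np.ndarray], alpha: float = 0.05):
        pooled = np.concatenate(per_run_sizes)
        super().__init__(pooled)
        self._per_run = per_run_sizes
        self._alpha = alpha
        self._pooled_mean = float(np.mean(pooled))

    def band(self, x) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        curves = np.empty((len(self._per_run), x.size))
        for i, sizes in enumerate(self._per_run):
            resc = sizes / self._pooled_mean
            curves[i] = (resc[:, None] > x[None, :]).mean(axis=0)
        lo = np.quantile(curves, self._alpha / 2, axis=0)
        hi = np.quantile(curves, 1 - self._alpha / 2, axis=0)
        return lo, hi


def ensemble_subtree_distribution(
    params: SimParams, n_sims: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> EnsembleDistribution:
    """Subtree-size distribution pooled over an ensemble of simulations."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    from .network import subtree_sizes
    per_run = []
    for _ in range(n_sims):
        net = simulate(params, rng=rng)
        per_run.append(np.asarray(subtree_sizes(net), dtype=float))
    return EnsembleDistribution(per_run)
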