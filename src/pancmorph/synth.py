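"""Synthetic confetti-clone and subtree tables with known ground truth.

Emulates the clonal lineage-tracing experiment end to end: a branching
simulation lays down the ductal arbor of each organ, precursor pools at the
termini drift through successive bifurcations, sparsely induced labels
(four confetti colors at strongly unequal frequencies, RFP-heavy, under 3%
of cells by volume) are conveyed along the growing ducts, and contiguous
labeled masses are booked into clone records with per-compartment volumes.
Every generated table ships with a ground-truth sidecar (true clone
memberships, true precursor number, true potency), so the generator doubles
as the parameter-recovery harness for the inference code.

What it emulates: unequal induction frequencies, low labeling density, mixed
precursor potencies, clone sizes spanning orders of magnitude, spatial
cohesion of clones along subtrees.  What it does not: sectioning artifacts,
imaging noise beyond positional jitter, plexus remodeling, real organ
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .drift import (TerminusPool, UNLABELED, bifurcate_pool,
                    ensemble_conversion_profile)
from .io import write_clone_table, write_network
from .network import DuctalNetwork, Segment, Terminus
from .simulate import SimParams, simulate

__all__ = [
    "SynthConfig",
    "generate_clone_table",
    "generate_subtree_table",
    "independent_color_clones",
    "fragmented_clones",
    "fixture_suite",
]

# RFP-heavy induction ratio RFP:GFP:YFP:CFP = 5:3:3:1 (>5x RFP/CFP imbalance)
_DEFAULT_COLOR_RATIO = {"RFP": 5.0, "GFP": 3.0, "YFP": 3.0, "CFP": 1.0}


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; defaults emulate the E12.5-induction study conditions."""

    sim: SimParams = field(default_factory=SimParams)
    n_precursors: int = 4
    n_organs: int = 3
    induction_fraction: float = 0.025   # target labeled fraction, < 3% by volume
    color_probs: Optional[dict] = None  # per-color induction prob; default 5:3:3:1
    # induced-precursor class mix (multipotent, acinar-committed, ductal-committed);
    # with equal-sized ductal and acinar pools the acinar-committed share is 1/2
    # by construction, and the remaining half splits multipotent vs ductal-committed
    potency_mix: tuple = (0.15, 0.50, 0.35)
    cell_volume: float = 1000.0         # um^3 per cell
    duct_cells_per_spacing: float = 50.0
    acinar_cells_per_spacing: float = 150.0
    islet_emission_prob: float = 0.2    # per segment, trunk delamination event
    delamination_fraction: float = 0.05  # islet volume as fraction of trunk output
    um_per_spacing: float = 150.0
    position_noise: float = 30.0        # um, measurement jitter on centroids
    induction_day: str = "E12.5"
    collection_day: str = "P14"
    seed: int = 0

    def color_induction_probs(self) -> dict:
        ratio = self.color_probs or _DEFAULT_COLOR_RATIO
        tot = sum(ratio.values())
        if tot == 0:
            return {c: 0.0 for c in ratio}
        f = self.induction_fraction
        if not (0.0 <= f <= 0.1):
            raise ValueError("induction_fraction must lie in [0, 0.1]")
        return {c: f * v / tot for c, v in ratio.items()}


def _induce_pools(n: int, probs: dict, p_multi: float,
                  rng: np.random.Generator, clone_registry: list
                  ) -> tuple[TerminusPool, TerminusPool]:
    """Ductal and acinar pools for one root terminus, with sparse induction.

    Each ductal-pool cell is independently induced; an induced ductal cell is
    multipotent with probability ``p_multi``, in which case it also seeds one
    uniformly chosen acinar-pool cell with the same clone label.  Direct
    acinar induction is down-weighted by (1 - p_multi) so the marginal
    per-cell labeling probability is the same in both pools; combined with
    the drift martingale this makes the expected labeled volume fraction of
    every compartment equal the nominal induction fraction.
    """
    colors = list(probs)
    pvec = np.array([probs[c] for c in colors])

    def _draw(n_cells, scale=1.0):
        p = np.concatenate([pvec * scale, [1.0 - pvec.sum() * scale]])
        return rng.choice(len(colors) + 1, size=n_cells, p=p)

    ductal = [UNLABELED] * n
    acinar = [UNLABELED] * n
    for i, c in enumerate(_draw(n)):          # ductal pool
        if c < len(colors):
            cid = len(clone_registry) + 1
            multi = rng.random() < p_multi
            clone_registry.append(
                {"clone_id": cid, "color": colors[c],
                 "class": "multipotent" if multi else "ductal"})
            ductal[i] = cid
            if multi:
                acinar[rng.integers(n)] = cid
    for i, c in enumerate(_draw(n, scale=1.0 - p_multi)):   # acinar pool
        if c < len(colors) and acinar[i] == UNLABELED:
            cid = len(clone_registry) + 1
            clone_registry.append(
                {"clone_id": cid, "color": colors[c], "class": "acinar"})
            acinar[i] = cid
    return TerminusPool(tuple(ductal)), TerminusPool(tuple(acinar))


def _segment_midpoint(seg: Segment) -> np.ndarray:
    pl = seg.polyline
    return pl[len(pl) // 2]


def generate_clone_table(config: SynthConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated clone table plus ground-truth sidecar.

    Returns ``(clones, sidecar)``: the clone table in the standard CSV schema
    and a sidecar with one row per clone giving its true subtree, induced
    precursor class, and the generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    probs = config.color_induction_probs()
    pm = config.potency_mix
    if any(p < 0 for p in pm) or abs(sum(pm) - 1.0) > 1e-9:
        raise ValueError("potency_mix must be non-negative and sum to 1")
    denom = pm[0] + pm[2]
    p_multi = pm[0] / denom if denom > 0 else 0.0
    n = config.n_precursors

    clone_rows: list[dict] = []
    sidecar_rows: list[dict] = []
    organ_totals: dict[str, dict] = {}
    for organ in range(config.n_organs):
        sim_params = replace(config.sim,
                             seed=int(rng.integers(2 ** 31 - 1)))
        net = simulate(sim_params, rng=rng)
        children = net.children_map()
        registry: list[dict] = []
        # accumulate per-clone tallies
        acc: dict[int, dict] = {}

        def _tally(cid, key, amount, seg):
            rec = acc.setdefault(cid, {
                "vol_acinar": 0.0, "vol_ductal": 0.0, "vol_islet": 0.0,
                "n_branches": 0, "wpos": np.zeros(2), "wtot": 0.0,
                "subtrees": set(), "branch_segs": set()})
            rec[key] += amount
            mid = _segment_midpoint(seg)
            rec["wpos"] += amount * mid
            rec["wtot"] += amount
            rec["subtrees"].add(seg.subtree_id)
            rec["branch_segs"].add(seg.id)

        totals = {"ductal": 0.0, "acinar": 0.0, "islet": 0.0}
        for root in net.roots():
            d_pool, a_pool = _induce_pools(n, probs, p_multi, rng, registry)
            stack = [(root.id, d_pool, a_pool)]
            while stack:
                seg_id, dp, ap = stack.pop()
                seg = net.segments[seg_id]
                length = seg.length
                v_duct = length * config.duct_cells_per_spacing * config.cell_volume
                v_acin = length * config.acinar_cells_per_spacing * config.cell_volume
                islet_fires = rng.random() < config.islet_emission_prob
                totals["ductal"] += v_duct
                totals["acinar"] += v_acin
                if islet_fires:
                    totals["islet"] += v_duct * config.delamination_fraction
                for cid, cnt in dp.counts().items():
                    if cid == UNLABELED:
                        continue
                    share = cnt / n
                    _tally(cid, "vol_ductal", share * v_duct, seg)
                    if islet_fires:
                        _tally(cid, "vol_islet",
                               share * v_duct * config.delamination_fraction, seg)
                for cid, cnt in ap.counts().items():
                    if cid == UNLABELED:
                        continue
                    _tally(cid, "vol_acinar", (cnt / n) * v_acin, seg)
                kids = children.get(seg_id, [])
                if len(kids) == 2:
                    d1, d2 = bifurcate_pool(dp, rng)
                    a1, a2 = bifurcate_pool(ap, rng)
                    stack.append((kids[0], d1, a1))
                    stack.append((kids[1], d2, a2))

        organ_totals[f"M{organ + 1}"] = totals
        color_of = {r["clone_id"]: r["color"] for r in registry}
        class_of = {r["clone_id"]: r["class"] for r in registry}
        mouse = f"M{organ + 1}"
        for cid, rec in sorted(acc.items()):
            pos2 = rec["wpos"] / rec["wtot"] * config.um_per_spacing
            jitter = rng.normal(0.0, config.position_noise, size=3)
            vols = (rec["vol_acinar"], rec["vol_ductal"], rec["vol_islet"])
            if all(v <= 0 for v in vols):
                continue
            clone_rows.append({
                "clone_id": f"{mouse}_c{cid}", "mouse_id": mouse,
                "color": color_of[cid],
                "x_um": pos2[0] + jitter[0], "y_um": pos2[1] + jitter[1],
                "z_um": jitter[2],
                "vol_acinar_um3": vols[0], "vol_ductal_um3": vols[1],
                "vol_islet_um3": vols[2],
                "n_branches": len(rec["branch_segs"]),
                "induction": config.induction_day,
                "collection": config.collection_day,
            })
            sidecar_rows.append({
                "clone_id": f"{mouse}_c{cid}", "mouse_id": mouse,
                "true_class": class_of[cid],
                "true_color": color_of[cid],
                "true_n_precursors": n,
                "n_subtrees_touched": len(rec["subtrees"]),
            })
    clones = pd.DataFrame(clone_rows, columns=[
        "clone_id", "mouse_id", "color", "x_um", "y_um", "z_um",
        "vol_acinar_um3", "vol_ductal_um3", "vol_islet_um3",
        "n_branches", "induction", "collection"])
    sidecar = pd.DataFrame(sidecar_rows)
    sidecar.attrs["organ_volumes_um3"] = organ_totals
    return clones, sidecar


def generate_subtree_table(config: SynthConfig) -> pd.DataFrame:
    """Per-subtree branch counts: one row per subtree per simulated organ."""
    from .network import subtree_sizes
    rng = np.random.default_rng(config.seed)
    rows = []
    for organ in range(config.n_organs):
        sim_params = replace(config.sim, seed=int(rng.integers(2 ** 31 - 1)))
        net = simulate(sim_params, rng=rng)
        for k, size in enumerate(subtree_sizes(net)):
            rows.append({"organ_id": f"O{organ + 1}", "subtree_id": k,
                         "n_branches": size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# light-weight planted datasets (no branching simulation)
# ---------------------------------------------------------------------------

def independent_color_clones(n_clones: int, seed: int = 0,
                             extent_um: float = 2000.0,
                             color_ratio: Optional[dict] = None,
                             mouse_id: str = "M1") -> pd.DataFrame:
    """Clone table with i.i.d. colors at uniform positions: the clonal null."""
    rng = np.random.default_rng(seed)
    ratio = color_ratio or _DEFAULT_COLOR_RATIO
    colors = list(ratio)
    p = np.array([ratio[c] for c in colors], dtype=float)
    p /= p.sum()
    pos = rng.uniform(0, extent_um, size=(n_clones, 3))
    vols = rng.lognormal(mean=np.log(5e4), sigma=1.5, size=n_clones)
    return pd.DataFrame({
        "clone_id": [f"{mouse_id}_c{i}" for i in range(n_clones)],
        "mouse_id": mouse_id,
        "color": rng.choice(colors, size=n_clones, p=p),
        "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
        "vol_acinar_um3": vols, "vol_ductal_um3": 0.2 * vols,
        "vol_islet_um3": 0.0, "n_branches": 1,
        "induction": "E12.5", "collection": "P14",
    })


def fragmented_clones(n_clones: int = 60, n_fragmented: int = 15,
                      fragment_distance_um: float = 40.0,
                      seed: int = 0, extent_um: float = 2000.0) -> pd.DataFrame:
    """Clonal-null table plus planted same-color fragment pairs at short range.

    Emulates under-detected clone fragmentation: the short-distance bin shows
    an excess of same-color pairs, which the bootstrap envelope should flag.
    """
    rng = np.random.default_rng(seed)
    base = independent_color_clones(n_clones, seed=seed + 1, extent_um=extent_um)
    frag_rows = []
    src = base.sample(n=n_fragmented, random_state=int(rng.integers(2 ** 31 - 1)))
    for i, (_, row) in enumerate(src.iterrows()):
        offset = rng.normal(size=3)
        offset = offset / np.linalg.norm(offset) * fragment_distance_um
        frag = row.copy()
        frag["clone_id"] = f"{row['clone_id']}_frag"
        frag["x_um"] += offset[0]
        frag["y_um"] += offset[1]
        frag["z_um"] += offset[2]
        frag_rows.append(frag)
    return pd.concat([base, pd.DataFrame(frag_rows)], ignore_index=True)


def _tiny_network() -> DuctalNetwork:
    """Hand-checkable 3-segment network: one root bifurcating once."""
    segs = {
        0: Segment(id=0, parent_id=None, subtree_id=0, generation=0,
                   polyline=[[1.0, 0.0], [1.0, 1.0]]),
        1: Segment(id=1, parent_id=0, subtree_id=0, generation=1,
                   polyline=[[1.0, 1.0], [0.5, 2.0]]),
        2: Segment(id=2, parent_id=0, subtree_id=0, generation=1,
                   polyline=[[1.0, 1.0], [1.5, 2.0]]),
    }
    termini = {
        0: Terminus(id=0, position=[0.5, 2.0],
                    direction=[-0.4472135955, 0.894427191], active=False,
                    segment_id=1),
        1: Terminus(id=1, position=[1.5, 2.0],
                    direction=[0.4472135955, 0.894427191], active=False,
                    segment_id=2),
    }
    return DuctalNetwork(central_duct=[[0.0, 0.0], [2.0, 0.0]],
                         segments=segs, termini=termini)


def fixture_suite(out_dir, seed: int = 11) -> dict:
    """Write the small fixed-seed datasets used across the test pipeline.

    Emits (1) a 4-color clone table with its ground-truth sidecar, (2) a
    fragmented-clone dataset violating clonality at short range, (3) an N=4
    conversion-profile dataset for inference recovery, and (4) a tiny
    hand-checkable network JSON.  Bit-reproducible from the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # denser labeling than the tracing-study default so the small fixture
    # carries enough clones per color/compartment for every downstream test
    cfg = SynthConfig(seed=seed, n_organs=2, induction_fraction=0.08,
                      sim=SimParams(n_initial_termini=20, max_steps=400))
    clones, sidecar = generate_clone_table(cfg)
    write_clone_table(clones, out / "clones.csv")
    sidecar.to_csv(out / "clones_truth.csv", index=False)

    frag = fragmented_clones(seed=seed)
    write_clone_table(frag, out / "clones_fragmented.csv")

    profile = ensemble_conversion_profile(
        n=4, n_subtrees=1000, max_gen=6,
        rng=np.random.default_rng(seed + 2))
    profile.to_csv(out / "conversion_profile_N4.csv", index=False)

    write_network(_tiny_network(), out / "tiny_network.json")
    return {
        "clones": out / "clones.csv",
        "clones_truth": out / "clones_truth.csv",
        "clones_fragmented": out / "clones_fragmented.csv",
        "conversion_profile": out / "conversion_profile_N4.csv",
        "tiny_network": out / "tiny_network.json",
    }
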