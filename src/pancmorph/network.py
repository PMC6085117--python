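"""Ductal network domain types and geometric/topological queries.

The developing pancreas is modelled as a geometric forest of duct segments
hanging off a single central duct: each *subtree* is a duct and all of its
descendant ducts diverging from the central duct, and each *segment* is a
branch between two bifurcation points (or between a bifurcation point and a
terminal tip).  Morphogenesis is treated as effectively two-dimensional, so
all coordinates are 2D, expressed in units of the mean side-branch spacing
along the central duct (the model's single key length scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "NetworkStructureError",
    "EmptyFrontError",
    "Segment",
    "Terminus",
    "DuctalNetwork",
    "subtree_sizes",
    "min_distance",
    "tip_front_radius",
    "duct_density_profile",
    "validate_network",
]


class NetworkStructureError(ValueError):
    """Raised when parent links do not form a forest rooted on the central duct."""


class EmptyFrontError(ValueError):
    """Raised when a tip-front statistic is requested with no active termini."""


def _as_polyline(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array of 2D points")
    if not np.all(np.isfinite(arr)):
        raise ValueError("polyline coordinates must be finite")
    if np.any(np.all(arr[1:] == arr[:-1], axis=1)):
        raise ValueError("consecutive polyline points must be distinct")
    return arr


@dataclass
class Segment:
    """One duct branch: the path between two bifurcation points.

    ``generation`` counts bifurcations from the subtree root (root = 0);
    ``labels`` optionally carries the precursor-pool composition deposited by
    the drift model (mapping label -> cell count at construction).
    """

    id: int
    parent_id: Optional[int]
    subtree_id: int
    generation: int
    polyline: np.ndarray
    labels: Optional[dict] = None

    def __post_init__(self) -> None:
        self.polyline = _as_polyline(self.polyline)

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)))


@dataclass
class Terminus:
    """An (initially active) growing duct end.

    ``active`` flips to False exactly once: ducts irreversibly terminate.
    """

    id: int
    position: np.ndarray
    direction: np.ndarray
    active: bool
    segment_id: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("terminus direction must be a unit vector")


@dataclass
class DuctalNetwork:
    """Geometric forest of duct segments rooted on a central duct."""

    central_duct: np.ndarray
    segments: dict[int, Segment] = field(default_factory=dict)
    termini: dict[int, Terminus] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.central_duct = _as_polyline(self.central_duct)

    # -- convenience accessors -------------------------------------------------
    def children_map(self) -> dict[Optional[int], list[int]]:
        out: dict[Optional[int], list[int]] = {}
        for seg in self.segments.values():
            out.setdefault(seg.parent_id, []).append(seg.id)
        return out

    def roots(self) -> list[Segment]:
        return [s for s in self.segments.values() if s.parent_id is None]

    def active_termini(self) -> list[Terminus]:
        return [t for t in self.termini.values() if t.active]


def validate_network(network: DuctalNetwork) -> None:
    """Check the forest property in O(#segments).

    Raises :class:`NetworkStructureError` on a cycle, a dangling ``parent_id``,
    a subtree whose root is not attached to the central duct, or an
    inconsistent generation index.
    """
    segs = network.segments
    for seg in segs.values():
        if seg.parent_id is not None and seg.parent_id not in segs:
            raise NetworkStructureError(
                f"segment {seg.id} has dangling parent_id {seg.parent_id}"
            )
    # path-compression-free cycle check: walk to root, bounded by #segments
    n = len(segs)
    roots_by_subtree: dict[int, int] = {}
    for seg in segs.values():
        cur, hops = seg, 0
        while cur.parent_id is not None:
            parent = segs[cur.parent_id]
            if parent.generation != cur.generation - 1:
                raise NetworkStructureError(
                    f"segment {cur.id} generation {cur.generation} inconsistent "
                    f"with parent generation {parent.generation}"
                )
            if parent.subtree_id != cur.subtree_id:
                raise NetworkStructureError(
                    f"segment {cur.id} subtree_id differs from its parent's"
                )
            cur = parent
            hops += 1
            if hops > n:
                raise NetworkStructureError("cycle detected in parent links")
        if cur.generation != 0:
            raise NetworkStructureError(
                f"root segment {cur.id} has nonzero generation {cur.generation}"
            )
        prev = roots_by_subtree.setdefault(cur.subtree_id, cur.id)
        if prev != cur.id:
            raise NetworkStructureError(
                f"subtree {cur.subtree_id} has multiple roots ({prev}, {cur.id})"
            )


def subtree_sizes(network: DuctalNetwork) -> list[int]:
    """Branch count of every subtree (segments between bifurcation points).

    The sizes sum to the total number of segments; for a completed simulation
    every subtree is a full binary tree, so each size is odd (2b + 1 for b
    bifurcations).
    """
    validate_network(network)
    counts: dict[int, int] = {}
    for seg in network.segments.values():
        counts[seg.subtree_id] = counts.get(seg.subtree_id, 0) + 1
    return [counts[k] for k in sorted(counts)]


def _point_to_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Exact Euclidean distance from a point to a piecewise-linear path."""
    p = np.asarray(point, dtype=float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    ap = p[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", ap, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(p[None, :] - proj, axis=1)))


def min_distance(
    point,
    network: DuctalNetwork,
    exclude: Iterable[int] = (),
    include_central_duct: bool = True,
) -> float:
    """Distance from ``point`` to the nearest non-excluded duct.

    Returns ``inf`` when every segment (and the central duct, if excluded via
    ``include_central_duct=False``) is excluded.
    """
    excl = set(exclude)
    best = np.inf
    if include_central_duct:
        best = _point_to_polyline_distance(np.asarray(point, float), network.central_duct)
    for seg in network.segments.values():
        if seg.id in excl:
            continue
        d = _point_to_polyline_distance(np.asarray(point, float), seg.polyline)
        if d < best:
            best = d
    return best


def tip_front_radius(network: DuctalNetwork) -> float:
    """Mean distance of the active termini from the central duct.

    The active front self-organizes into a traveling pulse at the periphery of
    the expanding network; this is its radius statistic.
    """
    active = network.active_termini()
    if not active:
        raise EmptyFrontError("network has no active termini")
    dists = [
        _point_to_polyline_distance(t.position, network.central_duct) for t in active
    ]
    return float(np.mean(dists))


def duct_density_profile(
    network: DuctalNetwork,
    n_bands: int = 4,
    outer_radius: Optional[float] = None,
) -> np.ndarray:
    """Duct length per unit area in equal-width bands above the central duct.

    Bands span distances ``[0, outer_radius]`` from the central duct (default:
    the maximum tip distance).  Used to check that the bulk of the network is
    laid down at roughly constant density behind the traveling tip front.
    """
    # each polyline edge is short (one elongation step), so its midpoint
    # weighted by its length is an adequate line-density sample
    mids, lens = [], []
    for seg in network.segments.values():
        pl = seg.polyline
        e = np.diff(pl, axis=0)
        mids.append((pl[:-1] + pl[1:]) / 2)
        lens.append(np.linalg.norm(e, axis=1))
    if not mids:
        return np.zeros(n_bands)
    mids = np.vstack(mids)
    lens = np.concatenate(lens)
    # distance from the central duct; the duct is horizontal by construction
    x0, x1 = network.central_duct[0, 0], network.central_duct[-1, 0]
    dist = np.abs(mids[:, 1] - network.central_duct[0, 1])
    if outer_radius is None:
        outer_radius = float(dist.max())
    if outer_radius <= 0:
        return np.zeros(n_bands)
    width = outer_radius / n_bands
    # restrict to the x-extent of the central duct so the area is well defined
    in_span = (mids[:, 0] >= x0) & (mids[:, 0] <= x1)
    band_idx = np.floor(dist[in_span] / width).astype(int)
    keep = (band_idx >= 0) & (band_idx < n_bands)
    length_per_band = np.bincount(band_idx[keep], weights=lens[in_span][keep],
                                  minlength=n_bands)
    area = width * (x1 - x0)
    return length_per_band / area
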