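"""Sholl analysis and branch-order statistics for traced neurons.

Neuron reconstructions are rooted trees of 2-D points (camera-lucida
projections); the soma is the tree root.  Sholl complexity is the number
of transversal crossings of the dendritic polylines with concentric
circles centred on the soma, by default spaced 25 micrometres apart.
Branch order follows the classical convention: dendrites emanating from
the soma are primary (order 1) and the order increments at each branch
point (a node with two or more children).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["NeuronTrace", "ShollResult", "sholl", "branch_stats"]


@dataclass
class NeuronTrace:
    """Rooted tree of 2-D dendritic polylines.

    ``nodes`` maps node id to an (x, y) point in micrometres; ``parents``
    maps node id to its parent id, with -1 for the single root (the soma).
    """

    nodes: dict
    parents: dict
    cell_class: str = ""

    def __post_init__(self) -> None:
        roots = [i for i, p in self.parents.items() if p == -1]
        if len(roots) != 1:
            raise ValueError(f"trace must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        # orphan / cycle check via rootward walk with visited sets
        ok: set = {self._root}
        for i in self.parents:
            path = []
            j = i
            while j not in ok:
                if j not in self.parents or j in path:
                    raise ValueError(f"node {i}: orphan or cycle in parent chain")
                path.append(j)
                j = self.parents[j]
            ok.update(path)
        for i, p in self.parents.items():
            if p != -1 and np.allclose(self.nodes[i], self.nodes[p]):
                raise ValueError(f"zero-length segment at node {i}")

    @property
    def root(self):
        return self._root

    @property
    def soma(self) -> np.ndarray:
        return np.asarray(self.nodes[self._root], dtype=float)

    def children(self) -> dict:
        ch: dict = {i: [] for i in self.parents}
        for i, p in self.parents.items():
            if p != -1:
                ch[p].append(i)
        for lst in ch.values():
            lst.sort()
        return ch

    def segments(self):
        """All (p0, p1) parent-to-child segments as float arrays."""
        for i, p in self.parents.items():
            if p != -1:
                yield (
                    np.asarray(self.nodes[p], dtype=float),
                    np.asarray(self.nodes[i], dtype=float),
                )


@dataclass
class ShollResult:
    radii: np.ndarray  # micrometres, arithmetic sequence from one interval
    crossings: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.crossings = np.asarray(self.crossings, dtype=int)
        if np.any(self.crossings < 0):
            raise ValueError("crossings must be non-negative")


def _segment_circle_crossings(p0, p1, centre, radius) -> int:
    """Number of transversal intersections of segment p0-p1 with the circle.

    Roots of |p0 + t d - c|^2 = r^2 with t strictly inside (0, 1) count
    once each; a tangential touch (double root) counts zero.
    """
    d = p1 - p0
    f = p0 - centre
    a = float(d @ d)
    b = 2.0 * float(f @ d)
    c = float(f @ f) - radius * radius
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:  # no intersection, or tangential
        return 0
    sq = math.sqrt(disc)
    n = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 < t < 1.0:
            n += 1
    return n


def sholl(trace: NeuronTrace, interval: float = 25.0, max_radius: float | None = None) -> ShollResult:
    """Sholl profile: circle crossings at radii ``interval, 2*interval, ...``.

    Circles are centred on the soma; the profile extends to the first
    multiple of ``interval`` beyond the most distal node (or to
    ``max_radius`` if given).
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    soma = trace.soma
    r_max = max_radius
    if r_max is None:
        dists = [
            float(np.linalg.norm(np.asarray(xy, dtype=float)[:2] - soma))
            for xy in trace.nodes.values()
        ]
        r_max = max(dists) if dists else interval
    n_circ = max(1, int(math.ceil(r_max / interval)))
    radii = interval * np.arange(1, n_circ + 1)
    crossings = np.zeros(n_circ, dtype=int)
    segs = list(trace.segments())
    for k, r in enumerate(radii):
        crossings[k] = sum(
            _segment_circle_crossings(p0, p1, soma, r) for p0, p1 in segs
        )
    return ShollResult(radii=radii, crossings=crossings)


def _decompose_branches(trace: NeuronTrace):
    """Split the tree into branches (maximal unbranched paths).

    Returns a list of dicts with keys ``order``, ``length``,
    ``ends_in_branch_point``.  A branch starts at the soma or at a branch
    point and runs through single-child nodes to a terminal or the next
    branch point.
    """
    ch = trace.children()
    out = []
    stack = [(c, trace.root, 1) for c in reversed(ch[trace.root])]
    while stack:
        node, origin, order = stack.pop()
        length = 0.0
        prev = origin
        cur = node
        while True:
            length += float(
                np.linalg.norm(
                    np.asarray(trace.nodes[cur], float)
                    - np.asarray(trace.nodes[prev], float)
                )
            )
            kids = ch[cur]
            if len(kids) == 1:
                prev, cur = cur, kids[0]
                continue
            break
        is_bp = len(ch[cur]) >= 2
        out.append({"order": order, "length": length, "ends_in_branch_point": is_bp})
        if is_bp:
            for c in reversed(ch[cur]):
                stack.append((c, cur, order + 1))
    return out


def branch_stats(trace: NeuronTrace) -> dict:
    """Branch counts, mean lengths and branching points per order.

    Orders are reported for every order present (Table-style summaries
    conventionally stop at tertiary; higher orders are tallied under
    their own keys).  Returns a dict with ``counts``, ``mean_lengths``
    and ``branching_points``, each mapping order -> value.
    """
    branches = _decompose_branches(trace)
    counts: dict = {}
    lengths: dict = {}
    bps: dict = {}
    for b in branches:
        k = b["order"]
        counts[k] = counts.get(k, 0) + 1
        lengths.setdefault(k, []).append(b["length"])
        if b["ends_in_branch_point"]:
            bps[k] = bps.get(k, 0) + 1
    return {
        "counts": counts,
        "mean_lengths": {k: float(np.mean(v)) for k, v in lengths.items()},
        "branching_points": {k: bps.get(k, 0) for k in counts},
    }
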