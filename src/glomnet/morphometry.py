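"""Arbor-level computations: dotprops, NBLAST, flow centrality, segregation.

Synapse flow centrality scores each skeleton node by the number of
(input synapse, output synapse) pairs whose tree path crosses it; its maximum
defines the axon-dendrite split point. The segregation index then scores, via
entropies of input fractions, how completely inputs and outputs occupy the two
resulting compartments (0 = fully mixed, 1 = fully segregated).

NBLAST similarity converts arbors to point clouds with local tangent vectors
("dotprops") and sums a score f(d, |dot|) over nearest-neighbour matches; the
score of a cloud against itself normalizes the scale so identical morphologies
score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import InputError, Skeleton


# --------------------------------------------------------------------------
# dotprops

@dataclass
class DotProps:
    """Point cloud with unit tangent vectors, the NBLAST substrate."""

    neuron_id: str
    points: np.ndarray    # (N, 3) nm
    tangents: np.ndarray  # (N, 3), unit norm
    single_point: bool = False  # degenerate source flagged

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, dtype=float))
        if len(self.points) < 1:
            raise InputError(f"dotprops {self.neuron_id}: empty point cloud")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InputError(f"dotprops {self.neuron_id}: tangents must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


def _segments(sk: Skeleton) -> list[np.ndarray]:
    """Decompose the tree into unbranched runs of node coordinates."""
    children = sk.children_map()
    root = sk.root
    starts = [root] + [n for n, ch in children.items() if len(ch) > 1 and n != root]
    segs: list[np.ndarray] = []
    for start in starts:
        for child in children[start]:
            run = [start, child]
            while len(children[run[-1]]) == 1:
                run.append(children[run[-1]][0])
            segs.append(np.array([sk.xyz[sk.index_of(n)] for n in run]))
    return segs


def _resample_polyline(coords: np.ndarray, spacing: float) -> np.ndarray:
    """Points every ``spacing`` nm along the polyline (endpoints included)."""
    deltas = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(deltas)])
    total = arclen[-1]
    if total == 0:
        return coords[:1]
    n = max(int(round(total / spacing)), 1)
    samples = np.linspace(0.0, total, n + 1)
    out = np.empty((len(samples), 3))
    for d in range(3):
        out[:, d] = np.interp(samples, arclen, coords[:, d])
    return out


def to_dotprops(sk: Skeleton, spacing: float = 1000.0, k: int = 5) -> DotProps:
    """Resample an arbor to ~``spacing`` nm and fit tangents from k neighbours.

    The tangent at each point is the dominant principal direction of its k
    nearest neighbours (sign-free). A single-node skeleton yields one point
    with an arbitrary unit tangent, flagged via ``single_point``.
    """
    if k < 2:
        raise InputError("to_dotprops requires k >= 2")
    if sk.n_nodes == 1:
        return DotProps(sk.neuron_id, sk.xyz[:1], np.array([[1.0, 0.0, 0.0]]),
                        single_point=True)
    pts = np.vstack([_resample_polyline(seg, spacing) for seg in _segments(sk)])
    # dedupe shared segment endpoints
    pts = np.unique(np.round(pts, 6), axis=0)
    if len(pts) == 1:
        return DotProps(sk.neuron_id, pts, np.array([[1.0, 0.0, 0.0]]),
                        single_point=True)
    tree = cKDTree(pts)
    kk = min(k, len(pts))
    _, idx = tree.query(pts, k=kk)
    tangents = np.empty_like(pts)
    for i in range(len(pts)):
        nbrs = pts[idx[i]] - pts[idx[i]].mean(axis=0)
        # dominant right-singular vector = principal direction
        _, _, vt = np.linalg.svd(nbrs, full_matrices=False)
        tangents[i] = vt[0]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return DotProps(sk.neuron_id, pts, tangents)


# --------------------------------------------------------------------------
# NBLAST scoring

@dataclass
class ParametricScoring:
    """Smooth fallback score f(d, |dot|) = exp(-d/sigma) * |dot|.

    ``sigma`` defaults to 3 um (in nm); f(0, 1) = 1, so the raw self-score of
    an N-point cloud is exactly N.
    """

    sigma: float = 3000.0

    def __call__(self, d: np.ndarray, adot: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(d, float) / self.sigma) * np.asarray(adot, float)


@dataclass
class TableScoring:
    """Binned log-odds score table (distance bins x |dot| bins).

    The on-disk form is delimited text: first column gives distance bin edges
    as ``lo:hi`` (nm), the header row gives |dot| bin edges likewise, and cells
    hold log-odds scores. Queries outside the last distance bin take the last
    bin's value (conventionally strongly negative).
    """

    d_edges: np.ndarray      # (D+1,)
    dot_edges: np.ndarray    # (A+1,)
    values: np.ndarray       # (D, A)

    def __call__(self, d: np.ndarray, adot: np.ndarray) -> np.ndarray:
        d = np.asarray(d, float)
        adot = np.clip(np.asarray(adot, float), 0.0, 1.0)
        di = np.clip(np.searchsorted(self.d_edges, d, side="right") - 1,
                     0, len(self.d_edges) - 2)
        ai = np.clip(np.searchsorted(self.dot_edges, adot, side="right") - 1,
                     0, len(self.dot_edges) - 2)
        return self.values[di, ai]

    @classmethod
    def from_csv(cls, path: str | Path) -> "TableScoring":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = lines[0].split(",")[1:]
        dot_edges = [float(h.split(":")[0]) for h in header] + [float(header[-1].split(":")[1])]
        d_edges: list[float] = []
        rows = []
        for ln in lines[1:]:
            cells = ln.split(",")
            lo, hi = cells[0].split(":")
            if not d_edges:
                d_edges.append(float(lo))
            d_edges.append(float(hi))
            rows.append([float(c) for c in cells[1:]])
        return cls(np.array(d_edges), np.array(dot_edges), np.array(rows))

    def to_csv(self, path: str | Path) -> None:
        header = "," + ",".join(
            f"{self.dot_edges[j]:g}:{self.dot_edges[j+1]:g}"
            for j in range(len(self.dot_edges) - 1)
        )
        lines = [header]
        for i in range(len(self.d_edges) - 1):
            cells = ",".join(f"{v:g}" for v in self.values[i])
            lines.append(f"{self.d_edges[i]:g}:{self.d_edges[i+1]:g},{cells}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class NblastScore:
    query_id: str
    target_id: str
    raw: float
    normalized: float     # raw / self-raw of the query


def _raw_score(query: DotProps, target: DotProps, scoring) -> float:
    tree = cKDTree(target.points)
    d, idx = tree.query(query.points, k=1)
    adot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    return float(np.sum(scoring(d, adot)))


def nblast(query: DotProps, target: DotProps,
           scoring=None) -> NblastScore:
    """Directed NBLAST score of ``query`` against ``target``.

    raw = sum over query points of f(nearest-target distance, |tangent dot|);
    normalized = raw / raw(query, query), so normalized(q, q) == 1 exactly.
    """
    if len(query) == 0 or len(target) == 0:
        raise InputError("nblast requires non-empty dotprops")
    scoring = scoring or ParametricScoring()
    raw = _raw_score(query, target, scoring)
    self_raw = _raw_score(query, query, scoring)
    return NblastScore(query.neuron_id, target.neuron_id, raw, raw / self_raw)


def nblast_mean(a: DotProps, b: DotProps, scoring=None) -> float:
    """Mean of the two directions' normalized scores (symmetric similarity)."""
    return 0.5 * (nblast(a, b, scoring).normalized + nblast(b, a, scoring).normalized)


# --------------------------------------------------------------------------
# flow centrality and segregation

def entropy_bits(p: float) -> float:
    """Binary entropy with natural logs; H(0) = H(1) = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log(p) - (1 - p) * np.log(1 - p))


def segregation_index(compartments: list[tuple[int, int]]) -> float:
    """Entropy-based segregation of inputs vs outputs across compartments.

    ``compartments`` holds (n_inputs, n_outputs) per compartment. With
    p_i = inputs_i / n_i and H the natural-log binary entropy:
    S = 1 - [sum n_i H(p_i)] / [N H(p_total)]. S = 0 by convention when the
    pooled synapse mix is already pure (H(p_total) = 0).
    """
    totals = [(i + o) for i, o in compartments]
    if all(t == 0 for t in totals):
        raise InputError("segregation_index: all compartments empty")
    N = sum(totals)
    total_inputs = sum(i for i, _ in compartments)
    h_total = entropy_bits(total_inputs / N)
    if h_total == 0.0:
        return 0.0
    weighted = sum(t * entropy_bits(i / t) for (i, _), t in zip(compartments, totals) if t > 0)
    s = 1.0 - weighted / (N * h_total)
    return float(min(max(s, 0.0), 1.0))


@dataclass
class ArborSplit:
    """Per-node flow centralities and the resulting axon/dendrite split."""

    neuron_id: str
    node_ids: np.ndarray
    centrifugal: np.ndarray    # I_distal * O_proximal per node
    centripetal: np.ndarray    # I_proximal * O_distal per node
    total: np.ndarray
    split_node: int | None
    compartment: dict[int, str]      # node id -> "axon" | "dendrite"
    segregation: float
    compartment_stats: list[tuple[int, int]] = field(default_factory=list)
    degenerate: bool = False


def _depth_order(sk: Skeleton) -> list[int]:
    """Node ids ordered so every child precedes its parent."""
    children = sk.children_map()
    order: list[int] = []
    stack = [sk.root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(children[n])
    return order[::-1]


def _root_path_distance(sk: Skeleton) -> dict[int, float]:
    children = sk.children_map()
    dist = {sk.root: 0.0}
    stack = [sk.root]
    while stack:
        n = stack.pop()
        for c in children[n]:
            dist[c] = dist[n] + float(
                np.linalg.norm(sk.xyz[sk.index_of(c)] - sk.xyz[sk.index_of(n)])
            )
            stack.append(c)
    return dist


def flow_centrality(sk: Skeleton, input_sites: list[int],
                    output_sites: list[int]) -> ArborSplit:
    """Synapse flow centrality and axon/dendrite split for one neuron.

    For node v with I_d / O_d the input/output counts in the subtree
    at-or-distal to v: centrifugal = I_d * (O_total - O_d), centripetal =
    (I_total - I_d) * O_d, and C(v) their sum — the number of input->output
    synapse pairs whose tree path crosses v. The split node maximizes C
    (ties: closest to root, then smallest id); the side of the split holding
    the larger share of output sites is the axon.
    """
    for site in list(input_sites) + list(output_sites):
        sk.index_of(site)  # raises if the site is not a skeleton node

    ids = [int(n) for n in sk.node_ids]
    n_in: dict[int, int] = {n: 0 for n in ids}
    n_out: dict[int, int] = {n: 0 for n in ids}
    for s in input_sites:
        n_in[int(s)] += 1
    for s in output_sites:
        n_out[int(s)] += 1
    I_total, O_total = len(input_sites), len(output_sites)

    children = sk.children_map()
    I_d = dict(n_in)
    O_d = dict(n_out)
    for n in _depth_order(sk):
        for c in children[n]:
            I_d[n] += I_d[c]
            O_d[n] += O_d[c]

    node_arr = np.array(ids)
    fug = np.array([I_d[n] * (O_total - O_d[n]) for n in ids], dtype=float)
    pet = np.array([(I_total - I_d[n]) * O_d[n] for n in ids], dtype=float)
    total = fug + pet

    if I_total == 0 or O_total == 0:
        return ArborSplit(sk.neuron_id, node_arr, fug, pet, total,
                          split_node=None, compartment={}, segregation=0.0,
                          degenerate=True)

    cmax = total.max()
    dist = _root_path_distance(sk)
    candidates = [ids[i] for i in np.flatnonzero(total == cmax)]
    split = min(candidates, key=lambda n: (dist[n], n))

    # distal compartment: subtree at-or-below the split node
    distal: set[int] = set()
    stack = [split]
    while stack:
        n = stack.pop()
        distal.add(n)
        stack.extend(children[n])

    in_distal, out_distal = I_d[split], O_d[split]
    in_prox, out_prox = I_total - in_distal, O_total - out_distal
    # axon = side carrying the larger share of outputs (tie: distal)
    distal_is_axon = out_distal / O_total >= out_prox / O_total
    compartment = {
        n: ("axon" if (n in distal) == distal_is_axon else "dendrite") for n in ids
    }
    stats = [(in_distal, out_distal), (in_prox, out_prox)]
    nonempty = [c for c in stats if sum(c) > 0]
    seg = segregation_index(nonempty)
    return ArborSplit(sk.neuron_id, node_arr, fug, pet, total, split,
                      compartment, seg, compartment_stats=stats)
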