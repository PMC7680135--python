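"""Cluster-level graph: size-normalized relatedness, top-k neighbor
filtering, 2-D layout and field coloring."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterAssignment, as_weighted
from .corpus_io import Document

log = logging.getLogger(__name__)

#: Default high-level field vocabulary used for cluster coloring.
DEFAULT_FIELDS = [
    "Biology", "Biotechnology", "Brain Sciences", "Chemistry",
    "Computer Science", "Earth Sciences", "Engineering", "Health Sciences",
    "Humanities", "Infectious Diseases", "Medicine", "Physics",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClusterEdge:
    m: int
    n: int
    R: float


def cluster_relatedness(assignment: ClusterAssignment, edges) -> list[ClusterEdge]:
    """Size-normalized cluster-cluster relatedness.

    R(m, n) = sum of r_hyb over cross pairs / sqrt(Nm * Nn), for retained
    clusters with at least one cross edge.  No self-edges.
    """
    membership = {doc: a.level5 for doc, a in assignment.items() if not a.removed}
    sizes: dict[int, int] = {}
    for c in membership.values():
        sizes[c] = sizes.get(c, 0) + 1
    sums: dict[tuple[int, int], float] = {}
    for i, j, w in as_weighted(edges):
        m, n = membership.get(i), membership.get(j)
        if m is None or n is None or m == n:
            continue
        key = (m, n) if m < n else (n, m)
        sums[key] = sums.get(key, 0.0) + w
    return [ClusterEdge(m, n, s / (sizes[m] * sizes[n]) ** 0.5)
            for (m, n), s in sorted(sums.items())]


def topk_neighbors(cluster_edges: list[ClusterEdge], k: int = 15) -> list[ClusterEdge]:
    """Keep edges ranking in the top-k by R for either endpoint (ties at k kept)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_cluster: dict[int, list[ClusterEdge]] = {}
    for e in cluster_edges:
        by_cluster.setdefault(e.m, []).append(e)
        by_cluster.setdefault(e.n, []).append(e)
    keep: set[tuple[int, int]] = set()
    for _, lst in by_cluster.items():
        lst.sort(key=lambda e: -e.R)
        if len(lst) <= k:
            keep.update((e.m, e.n) for e in lst)
        else:
            cutoff = lst[k - 1].R
            keep.update((e.m, e.n) for e in lst if e.R >= cutoff)
    return [e for e in cluster_edges if (e.m, e.n) in keep]


@dataclass
class MapLayout:
    coords: dict[int, tuple[float, float]]
    fields: dict[int, str]
    metadata: dict


def layout(
    cluster_edges: list[ClusterEdge],
    seed: int = 0,
    edge_cut: float = 0.7,
    n_iter: int = 300,
    nodes=None,
) -> dict[int, tuple[float, float]]:
    """Deterministic force-directed 2-D embedding with late edge cutting.

    A simplified simulated-annealing schedule in the OpenOrd spirit:
    spring attraction along (weighted) edges against all-pairs repulsion
    with a cooling step size.  In the last 40% of iterations the
    ``edge_cut`` fraction of the currently-longest edges is ignored,
    letting weakly linked regions drift apart.  Same seed -> identical
    coordinates.
    """
    if not (0.0 <= edge_cut <= 1.0):
        raise ValueError("edge_cut must be in [0, 1]")
    names = sorted({c for e in cluster_edges for c in (e.m, e.n)} | set(nodes or []))
    if not names:
        raise ValueError("empty cluster graph")
    idx = {c: k for k, c in enumerate(names)}
    n = len(names)
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n, 2))
    if n == 1:
        return {names[0]: (float(pos[0, 0]), float(pos[0, 1]))}

    src = np.array([idx[e.m] for e in cluster_edges], dtype=int)
    dst = np.array([idx[e.n] for e in cluster_edges], dtype=int)
    w = np.array([e.R for e in cluster_edges], dtype=float)
    if w.size and w.max() > 0:
        w = w / w.max()
    cut_start = int(n_iter * 0.6)
    n_keep_cut = max(1, int(round(len(w) * (1.0 - edge_cut)))) if w.size else 0

    step = 0.1 * np.sqrt(n)
    for it in range(n_iter):
        # repulsion: inverse-distance on all pairs
        delta = pos[:, None, :] - pos[None, :, :]
        dist2 = (delta ** 2).sum(-1) + 1e-9
        np.fill_diagonal(dist2, np.inf)
        rep = (delta / dist2[..., None]).sum(axis=1)
        disp = rep
        if w.size:
            evec = pos[dst] - pos[src]
            elen = np.sqrt((evec ** 2).sum(-1)) + 1e-12
            active = np.ones(len(w), dtype=bool)
            if it >= cut_start and len(w) > n_keep_cut:
                order = np.argsort(elen, kind="stable")
                active[:] = False
                active[order[:n_keep_cut]] = True
            att = np.zeros_like(pos)
            pull = (w[:, None] * evec) * active[:, None]
            np.add.at(att, src, pull)
            np.add.at(att, dst, -pull)
            disp = disp + att
        norm = np.sqrt((disp ** 2).sum(-1, keepdims=True)) + 1e-12
        cool = step * (1.0 - it / n_iter)
        pos = pos + disp / norm * np.minimum(norm, cool)
    return {c: (float(pos[idx[c], 0]), float(pos[idx[c], 1])) for c in names}


def assign_field(cluster_docs: list[Document],
                 journal_field_map: dict[str, str]) -> str:
    """Plurality field of the cluster's documents; ties broken alphabetically."""
    counts: dict[str, int] = {}
    for d in cluster_docs:
        f = journal_field_map.get(d.journal, UNASSIGNED)
        counts[f] = counts.get(f, 0) + 1
    if not counts:
        return UNASSIGNED
    return min(counts.items(), key=lambda t: (-t[1], t[0]))[0]


def build_map(
    assignment: ClusterAssignment,
    edges,
    documents: list[Document],
    journal_field_map: dict[str, str],
    top_k: int = 15,
    seed: int = 0,
    edge_cut: float = 0.7,
) -> tuple[MapLayout, list[ClusterEdge]]:
    """Cluster relatedness -> top-k filter -> layout -> field coloring."""
    cedges = cluster_relatedness(assignment, edges)
    filtered = topk_neighbors(cedges, k=top_k) if cedges else []
    clusters = sorted(assignment.retained_clusters(level=5))
    coords = layout(filtered, seed=seed, edge_cut=edge_cut, nodes=clusters)
    docs_by_id = {d.doc_id: d for d in documents}
    fields = {}
    for cid, members in assignment.retained_clusters(level=5).items():
        docs = [docs_by_id[m] for m in members if m in docs_by_id]
        fields[cid] = assign_field(docs, journal_field_map)
    meta = {"algorithm": "simplified-openord-schedule", "edge_cut": edge_cut,
            "seed": seed, "top_k": top_k,
            "n_edges_before_filter": len(cedges),
            "n_edges_after_filter": len(filtered)}
    return MapLayout(coords=coords, fields=fields, metadata=meta), filtered


def write_cluster_edges(edges: list[ClusterEdge], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("m\tn\tR\n")
        for e in edges:
            fh.write(f"{e.m}\t{e.n}\t{e.R:.9f}\n")


def write_layout(lay: MapLayout, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster\tX\tY\tfield\n")
        for c in sorted(lay.coords):
            x, y = lay.coords[c]
            fh.write(f"{c}\t{x:.6f}\t{y:.6f}\t{lay.fields.get(c, UNASSIGNED)}\n")
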