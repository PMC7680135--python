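"""Three-level nested document clustering.

The finest level partitions documents directly from the weighted
relatedness edge list using the Leiden algorithm with a constant-Potts
quality (resolution-parameterized; modularity available as an
alternative).  Coarser levels re-cluster the size-normalized aggregated
cluster graph of the level below, which guarantees nesting.  Clusters
below the per-level minimum size are merged into their strongest
neighbor; isolated undersized clusters fall into a residual cluster.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la

from .corpus_io import CitationEdge, Document

log = logging.getLogger(__name__)

WeightedEdge = tuple[str, str, float]


def as_weighted(edges) -> list[WeightedEdge]:
    """Convert RelatednessEdge objects (or (i, j, w) tuples) to plain tuples."""
    out = []
    for e in edges:
        if hasattr(e, "r_hyb"):
            out.append((e.i, e.j, e.r_hyb))
        else:
            i, j, w = e
            out.append((i, j, float(w)))
    return out


@dataclass(frozen=True)
class LevelConfig:
    resolution: float
    min_size: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be a positive integer")


@dataclass
class DocAssignment:
    level5: int
    level4: int = 0
    level3: int = 0
    removed: bool = False


class ClusterAssignment(dict):
    """doc_id -> :class:`DocAssignment`; dict subclass for easy iteration."""

    def clusters(self, level: int = 5) -> dict[int, list[str]]:
        attr = {5: "level5", 4: "level4", 3: "level3"}[level]
        out: dict[int, list[str]] = {}
        for doc_id, a in self.items():
            out.setdefault(getattr(a, attr), []).append(doc_id)
        return out

    def retained_clusters(self, level: int = 5) -> dict[int, list[str]]:
        attr = {5: "level5", 4: "level4", 3: "level3"}[level]
        out: dict[int, list[str]] = {}
        for doc_id, a in self.items():
            if not a.removed:
                out.setdefault(getattr(a, attr), []).append(doc_id)
        return out


def _build_graph(edges: list[WeightedEdge], nodes=None) -> tuple[ig.Graph, list[str]]:
    names = sorted({n for e in edges for n in e[:2]} | set(nodes or []))
    index = {n: k for k, n in enumerate(names)}
    g = ig.Graph(n=len(names))
    g.add_edges([(index[i], index[j]) for i, j, _ in edges])
    g.es["weight"] = [w for _, _, w in edges]
    g.simplify(combine_edges={"weight": "sum"})
    return g, names


def _merge_small(g: ig.Graph, membership: list[int], min_size: int,
                 node_sizes: list[int]) -> list[int]:
    """Merge undersized clusters into their strongest neighbor.

    Strength = summed cross edge weight.  Undersized clusters with no
    neighbors at all collect in a single residual cluster.  Processed
    smallest-first for determinism.
    """
    membership = list(membership)
    residual: set[int] = set()  # vertex ids destined for the residual cluster
    while True:
        sizes: Counter = Counter()
        for v, c in enumerate(membership):
            if v not in residual:
                sizes[c] += node_sizes[v]
        small = sorted((c for c, s in sizes.items() if s < min_size),
                       key=lambda c: (sizes[c], c))
        if not small:
            break
        target = small[0]
        strength: dict[int, float] = {}
        for e in g.es:
            a, b = e.tuple
            ca, cb = membership[a], membership[b]
            if a in residual or b in residual or ca == cb:
                continue
            if ca == target:
                strength[cb] = strength.get(cb, 0.0) + e["weight"]
            elif cb == target:
                strength[ca] = strength.get(ca, 0.0) + e["weight"]
        if strength:
            best = max(strength.items(), key=lambda t: (t[1], sizes[t[0]], -t[0]))[0]
            for v, c in enumerate(membership):
                if c == target and v not in residual:
                    membership[v] = best
        else:
            residual.update(v for v, c in enumerate(membership)
                            if c == target and v not in residual)
    if residual:
        rid = max(membership) + 1
        for v in residual:
            membership[v] = rid
    return membership


def _dense_labels(membership_by_name: dict[str, int]) -> dict[str, int]:
    """Relabel clusters 1..K, ordered by decreasing size then first member."""
    groups: dict[int, list[str]] = {}
    for name, c in membership_by_name.items():
        groups.setdefault(c, []).append(name)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    remap = {c: k + 1 for k, c in enumerate(order)}
    return {name: remap[c] for name, c in membership_by_name.items()}


def cluster_level(
    edges: list[WeightedEdge],
    resolution: float,
    min_size: int,
    seed: int,
    quality: str = "cpm",
    nodes=None,
    node_sizes: dict[str, int] | None = None,
) -> dict[str, int]:
    """One Leiden clustering pass with min-size enforcement.

    Returns node name -> dense positive cluster id.  ``node_sizes`` (for
    aggregated graphs whose nodes stand for document groups) feed both the
    quality function and the min-size rule; default 1 per node.
    """
    edges = as_weighted(edges)
    if not edges:
        raise ValueError("empty edge list")
    if any(w <= 0 for _, _, w in edges):
        raise ValueError("edge weights must be positive")
    g, names = _build_graph(edges, nodes=nodes)
    sizes = [int(node_sizes.get(n, 1)) if node_sizes else 1 for n in names]
    if quality == "cpm":
        part = la.find_partition(
            g, la.CPMVertexPartition, weights="weight",
            resolution_parameter=resolution, node_sizes=sizes, seed=seed)
    elif quality == "modularity":
        part = la.find_partition(
            g, la.RBConfigurationVertexPartition, weights="weight",
            resolution_parameter=resolution, seed=seed)
    else:
        raise ValueError(f"unknown quality function {quality!r}")
    membership = _merge_small(g, list(part.membership), min_size, sizes)
    return _dense_labels({n: c for n, c in zip(names, membership)})


def aggregate_cluster_edges(
    membership: dict[str, int],
    edges: list[WeightedEdge],
    cluster_sizes: dict[int, int],
) -> list[tuple[int, int, float]]:
    """Size-normalized cluster-cluster weights: sum(w) / sqrt(Nm * Nn)."""
    sums: dict[tuple[int, int], float] = {}
    for i, j, w in edges:
        m, n = membership.get(i), membership.get(j)
        if m is None or n is None or m == n:
            continue
        key = (m, n) if m < n else (n, m)
        sums[key] = sums.get(key, 0.0) + w
    return [(m, n, s / (cluster_sizes[m] * cluster_sizes[n]) ** 0.5)
            for (m, n), s in sorted(sums.items())]


def build_hierarchy(
    edges,
    configs: list[LevelConfig],
    seed: int = 0,
    quality: str = "cpm",
) -> ClusterAssignment:
    """Nested 3-level clustering (finest -> coarsest).

    ``configs`` are ordered finest-first with strictly decreasing
    resolutions and non-decreasing minimum sizes; minimum sizes always
    count documents, also at the aggregated levels.
    """
    if len(configs) != 3:
        raise ValueError("exactly 3 level configs required (finest -> coarsest)")
    for a, b in zip(configs, configs[1:]):
        if not (a.resolution > b.resolution):
            raise ValueError("resolutions must strictly decrease finest -> coarsest")
        if a.min_size > b.min_size:
            raise ValueError("minimum sizes must not decrease finest -> coarsest")
    edges = as_weighted(edges)

    m5 = cluster_level(edges, configs[0].resolution, configs[0].min_size,
                       seed=seed, quality=quality)
    assignment = ClusterAssignment(
        (doc, DocAssignment(level5=c)) for doc, c in m5.items())

    parent = m5
    for level_idx, (cfg, attr) in enumerate(
            zip(configs[1:], ("level4", "level3")), start=1):
        sizes = Counter()
        for doc in assignment:
            sizes[parent[doc]] += 1
        agg = aggregate_cluster_edges(parent, edges, sizes)
        agg_named = [(str(m), str(n), w) for m, n, w in agg]
        if agg_named:
            coarse = cluster_level(
                agg_named, cfg.resolution, cfg.min_size,
                seed=seed + level_idx, quality=quality,
                nodes=[str(c) for c in sizes],
                node_sizes={str(c): s for c, s in sizes.items()})
        else:  # single cluster or fully disconnected aggregate
            coarse = _dense_labels({str(c): c for c in sizes})
        current = {doc: coarse[str(parent[doc])] for doc in assignment}
        for doc, a in assignment.items():
            setattr(a, attr, current[doc])
        parent = current

    n5 = len(set(a.level5 for a in assignment.values()))
    n4 = len(set(a.level4 for a in assignment.values()))
    n3 = len(set(a.level3 for a in assignment.values()))
    log.info("hierarchy: %d / %d / %d clusters (fine -> coarse)", n5, n4, n3)
    return assignment


@dataclass
class DegenerateRules:
    """Rule thresholds for flagging whole clusters as degenerate."""

    title_pattern: str = r"erratum|corrigendum|correction"
    title_fraction: float = 0.5
    abstract_missing_fraction: float = 0.9
    mean_refs_below: float = 1.0


def flag_degenerate(
    assignment: ClusterAssignment,
    documents: list[Document],
    rules: DegenerateRules = DegenerateRules(),
    citations: list[CitationEdge] | None = None,
) -> set[int]:
    """Flag degenerate finest-level clusters; removal is whole-cluster.

    A cluster is flagged when the fraction of titles matching the
    configured pattern reaches ``title_fraction``, or when the fraction of
    documents without abstracts reaches ``abstract_missing_fraction`` and
    the mean outgoing reference count is below ``mean_refs_below``.
    Flagged documents get ``removed=True``; the flagged id set is returned.
    """
    pat = re.compile(rules.title_pattern, re.IGNORECASE)
    docs_by_id = {d.doc_id: d for d in documents}
    nrefs: Counter = Counter()
    for e in citations or []:
        nrefs[e.citing_id] += 1
    flagged: set[int] = set()
    for cid, members in assignment.clusters(level=5).items():
        docs = [docs_by_id[m] for m in members if m in docs_by_id]
        if not docs:
            continue
        frac_title = sum(1 for d in docs if pat.search(d.title)) / len(docs)
        frac_noabs = sum(1 for d in docs if not d.abstract.strip()) / len(docs)
        mean_refs = sum(nrefs[d.doc_id] for d in docs) / len(docs)
        if frac_title >= rules.title_fraction or (
                frac_noabs >= rules.abstract_missing_fraction
                and mean_refs < rules.mean_refs_below):
            flagged.add(cid)
    for doc_id, a in assignment.items():
        if a.level5 in flagged:
            a.removed = True
    n_all = len(assignment.clusters(level=5))
    log.info("flag_degenerate: %d of %d clusters flagged; %d retained",
             len(flagged), n_all, retained_after_removal(n_all, len(flagged)))
    return flagged


def retained_after_removal(n_initial: int, *removed_counts: int) -> int:
    """Cluster-removal bookkeeping: initial count minus each removed group."""
    total_removed = sum(removed_counts)
    if total_removed > n_initial:
        raise ValueError("cannot remove more clusters than present")
    return n_initial - total_removed


def write_assignment(assignment: ClusterAssignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tPM5\tPM4\tPM3\tremoved\n")
        for doc_id, a in sorted(assignment.items()):
            fh.write(f"{doc_id}\t{a.level5}\t{a.level4}\t{a.level3}\t{int(a.removed)}\n")


def read_assignment(path) -> ClusterAssignment:
    out = ClusterAssignment()
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            doc_id, l5, l4, l3, removed = line.rstrip("\n").split("\t")
            out[doc_id] = DocAssignment(int(l5), int(l4), int(l3), bool(int(removed)))
    return out
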