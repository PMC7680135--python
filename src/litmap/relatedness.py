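"""Hybrid document-document relatedness.

Combines a direct-citation (DC) component with a text-similarity (SA)
component::

    r_hyb(i,j) = alpha * r_dc(i,j) + (1 - alpha) * r_sa(i,j)

where ``r_dc(i,j) = max(c_ij, c_ji)`` with ``c_ij = 1/nref(i)`` when *i*
cites *j* (nref counted within the corpus), and ``r_sa = S_ij / max(S)``
after per-document top-k truncation.  DC pairs lacking a retained SA score
receive an imputed one (half the smaller endpoint minimum), and ``alpha``
is calibrated so the summed DC and SA contributions are equal (50:50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import CitationEdge, SimilarityRecord

log = logging.getLogger(__name__)

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    """Canonical unordered-pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class RelatednessEdge:
    i: str
    j: str
    r_dc: float
    r_sa: float
    r_hyb: float
    sa_imputed: bool = False


@dataclass
class Calibration:
    alpha: float
    sum_dc: float
    sum_sa: float


@dataclass
class SANormalization:
    """Result of top-k truncation + max-normalization of raw SA scores."""

    r_sa: dict[Pair, float]
    max_score: float                      # global max of retained raw scores
    min_retained: dict[str, float] = field(default_factory=dict)  # per doc, normalized


def compute_dc(citations: list[CitationEdge], docset: set[str],
               normalize: bool = True) -> dict[Pair, float]:
    """Direct-citation relatedness per unordered pair.

    c_ij = 1/nref(i) when i cites j; r_dc = max(c_ij, c_ji), then divided
    by the observed maximum so values lie in (0, 1].  Duplicate citation
    records collapse to one.  Pairs with value 0 are absent.
    """
    by_citing: dict[str, set[str]] = {}
    for e in citations:
        if e.citing_id in docset and e.cited_id in docset:
            by_citing.setdefault(e.citing_id, set()).add(e.cited_id)
    out: dict[Pair, float] = {}
    for citing, cited_set in by_citing.items():
        c = 1.0 / len(cited_set)
        for cited in cited_set:
            key = _pair(citing, cited)
            if c > out.get(key, 0.0):
                out[key] = c
    if normalize and out:
        mx = max(out.values())
        if mx > 0:
            out = {k: v / mx for k, v in out.items()}
    return out


def normalize_sa(records: list[SimilarityRecord], top_k: int = 20) -> SANormalization:
    """Deduplicate, truncate to each document's top-k partners, normalize.

    A pair survives if it is within the top-k of *either* endpoint; ties at
    the k-th score are all kept.  Retained scores are divided by the global
    maximum retained raw score.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    raw: dict[Pair, float] = {}
    for r in records:
        if r.id_a == r.id_b:
            continue
        key = _pair(r.id_a, r.id_b)
        # symmetric scores: duplicates collapse; keep the larger on conflict
        if r.score > raw.get(key, -1.0):
            raw[key] = r.score
    by_doc: dict[str, list[tuple[float, Pair]]] = {}
    for key, s in raw.items():
        by_doc.setdefault(key[0], []).append((s, key))
        by_doc.setdefault(key[1], []).append((s, key))
    keep: set[Pair] = set()
    for doc, lst in by_doc.items():
        lst.sort(key=lambda t: -t[0])
        if len(lst) <= top_k:
            keep.update(key for _, key in lst)
        else:
            cutoff = lst[top_k - 1][0]
            keep.update(key for s, key in lst if s >= cutoff)
    if not keep:
        return SANormalization(r_sa={}, max_score=0.0)
    mx = max(raw[key] for key in keep)
    r_sa = {key: raw[key] / mx for key in keep}
    min_retained: dict[str, float] = {}
    for key, v in r_sa.items():
        for doc in key:
            if v < min_retained.get(doc, float("inf")):
                min_retained[doc] = v
    return SANormalization(r_sa=r_sa, max_score=mx, min_retained=min_retained)


def impute_sa(
    dc_pairs: set[Pair],
    san: SANormalization,
    raw_lookup: dict[Pair, float] | None = None,
    floor: float | None = None,
) -> dict[Pair, tuple[float, bool]]:
    """SA values for every DC pair: observed, raw-outside-top-k, or imputed.

    Imputation rule: half the smaller of the two endpoints' minimum
    retained (normalized) SA scores.  Endpoints with no retained SA score
    at all fall back to ``floor`` (default: half the global minimum
    retained score), logged.
    """
    out: dict[Pair, tuple[float, bool]] = {
        key: (v, False) for key, v in san.r_sa.items()}
    if floor is None:
        floor = 0.5 * min(san.min_retained.values()) if san.min_retained else 0.0
    n_floored = 0
    for key in dc_pairs:
        if key in out:
            continue
        if raw_lookup is not None and key in raw_lookup and san.max_score > 0:
            out[key] = (raw_lookup[key] / san.max_score, False)
            continue
        i, j = key
        mins = [san.min_retained[d] for d in (i, j) if d in san.min_retained]
        if len(mins) == 2:
            val = 0.5 * min(mins)
        else:
            val = floor
            n_floored += 1
        out[key] = (val, True)
    if n_floored:
        log.info("impute_sa: %d pairs fell back to the global floor %g",
                 n_floored, floor)
    return out


def calibrate_alpha(sum_dc: float, sum_sa: float) -> float:
    """Solve ``alpha * sum_dc = (1 - alpha) * sum_sa`` for alpha."""
    if sum_dc <= 0 or sum_sa <= 0:
        raise ValueError("both relatedness sums must be positive")
    return sum_sa / (sum_dc + sum_sa)


def combine_hybrid(
    dc_map: dict[Pair, float],
    sa_map: dict[Pair, tuple[float, bool]],
    alpha: float,
) -> list[RelatednessEdge]:
    """Union of DC and SA pairs with the convex hybrid score.

    Missing components count as 0 (SA-only pairs have r_dc = 0; DC-only
    pairs were imputed upstream so r_sa > 0 there).  Edges are returned in
    sorted pair order for reproducible downstream summations.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    keys = sorted(set(dc_map) | set(sa_map))
    edges = []
    for key in keys:
        r_dc = dc_map.get(key, 0.0)
        r_sa, imputed = sa_map.get(key, (0.0, False))
        edges.append(RelatednessEdge(
            i=key[0], j=key[1], r_dc=r_dc, r_sa=r_sa,
            r_hyb=alpha * r_dc + (1.0 - alpha) * r_sa,
            sa_imputed=imputed))
    return edges


def overlap_percentage(n_overlap: int, n_dc: int) -> float:
    """Percent of DC links that also carry a retained (top-k) SA link."""
    if n_dc <= 0:
        raise ValueError("DC link count must be positive")
    return 100.0 * n_overlap / n_dc


def coverage_percentage(n_with_refs: int, n_total: int) -> float:
    """Percent of corpus documents that have references in the citation source."""
    if n_total <= 0:
        raise ValueError("total document count must be positive")
    return 100.0 * n_with_refs / n_total


@dataclass
class RelatednessResult:
    edges: list[RelatednessEdge]
    calibration: Calibration
    n_dc_pairs: int = 0
    n_sa_pairs: int = 0
    n_overlap: int = 0

    @property
    def overlap_pct(self) -> float:
        return overlap_percentage(self.n_overlap, self.n_dc_pairs)


def build_relatedness(
    citations: list[CitationEdge],
    similarities: list[SimilarityRecord],
    docset: set[str],
    sa_top_k: int = 20,
    alpha: float | str = "calibrate",
    calibrate_after_imputation: bool = True,
) -> RelatednessResult:
    """Full relatedness pipeline: DC + truncated SA + imputation + hybrid.

    ``alpha`` may be a fixed value in (0,1) or ``"calibrate"`` to solve for
    the 50:50 weighting.  By default the calibration sums run over the
    final (post-imputation) edge set; set ``calibrate_after_imputation``
    False to calibrate on retained SA scores only.
    """
    dc_map = compute_dc(citations, docset)
    san = normalize_sa(similarities, top_k=sa_top_k)
    raw_lookup = {}
    for r in similarities:
        if r.id_a != r.id_b:
            key = _pair(r.id_a, r.id_b)
            if r.score > raw_lookup.get(key, -1.0):
                raw_lookup[key] = r.score
    sa_full = impute_sa(set(dc_map), san, raw_lookup=raw_lookup)

    sum_dc = sum(dc_map[k] for k in sorted(dc_map))
    if calibrate_after_imputation:
        sum_sa = sum(sa_full[k][0] for k in sorted(sa_full))
    else:
        sum_sa = sum(san.r_sa[k] for k in sorted(san.r_sa))
    if alpha == "calibrate":
        a = calibrate_alpha(sum_dc, sum_sa) if sum_dc > 0 and sum_sa > 0 else 0.5
    else:
        a = float(alpha)
    edges = combine_hybrid(dc_map, sa_full, a)
    n_overlap = sum(1 for k in dc_map if k in san.r_sa)
    log.info("relatedness: %d DC pairs, %d SA pairs, %d overlap, alpha=%.4f",
             len(dc_map), len(san.r_sa), n_overlap, a)
    return RelatednessResult(
        edges=edges,
        calibration=Calibration(alpha=a, sum_dc=sum_dc, sum_sa=sum_sa),
        n_dc_pairs=len(dc_map), n_sa_pairs=len(san.r_sa), n_overlap=n_overlap)


def write_edges(edges: list[RelatednessEdge], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("i\tj\tr_dc\tr_sa\tr_hyb\tsa_imputed\n")
        for e in edges:
            fh.write(f"{e.i}\t{e.j}\t{e.r_dc:.9f}\t{e.r_sa:.9f}\t"
                     f"{e.r_hyb:.9f}\t{int(e.sa_imputed)}\n")


def read_edges(path) -> list[RelatednessEdge]:
    edges = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            i, j, r_dc, r_sa, r_hyb, imp = line.rstrip("\n").split("\t")
            edges.append(RelatednessEdge(i, j, float(r_dc), float(r_sa),
                                         float(r_hyb), bool(int(imp))))
    return edges
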