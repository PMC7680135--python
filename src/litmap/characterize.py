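"""Cluster characterization: phrase and idiosyncratic-phrase scoring,
central papers, descriptor lists, indicator suite, percentiles and
subset overlays.

Phrase grammar
--------------
Noun phrases are matched over (token, POS) pairs with the pattern

    (JJ* | VBG)* (NN*)+ (VBG)?

i.e. zero or more adjectives or gerunds, one or more nouns, then an
optional gerund — greedy, left-to-right, non-overlapping.  POS tagging is
behind an interface: documents may carry pre-tagged tokens (the synthetic
generator emits them) and a small heuristic tagger is the fallback, so the
grammar itself is tagger-independent.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import rankdata

from .clustering import ClusterAssignment, as_weighted
from .corpus_io import CitationEdge, Document

log = logging.getLogger(__name__)

TaggedToken = tuple[str, str]

_STOPWORDS = frozenset("""
a an the of in on at by for with and or to from as is are was were be been
this that these those it its we our their his her they he she not no than
which who whom what when where how into over under between during after
before against about above below up down out off then once here there all
any both each few more most other some such only own same so too very can
will just should now has have had do does did but if because while using
used use
""".split())


def naive_tagger(text: str) -> list[TaggedToken]:
    """Heuristic fallback POS tagger: stopwords -> DT, *ing -> VBG, else NN.

    Deliberately crude — real corpora should supply pre-tagged tokens or a
    proper tagger; this keeps phrase extraction functional without one.
    """
    tokens = re.findall(r"[A-Za-z][A-Za-z0-9'-]*", text.lower())
    out = []
    for t in tokens:
        if t in _STOPWORDS:
            out.append((t, "DT"))
        elif t.endswith("ing") and len(t) > 4:
            out.append((t, "VBG"))
        else:
            out.append((t, "NN"))
    return out


def _tag_symbol(pos: str) -> str:
    if pos.startswith("JJ"):
        return "a"
    if pos == "VBG":
        return "g"
    if pos.startswith("NN"):
        return "n"
    return "x"


_NP_PATTERN = re.compile(r"[ag]*n+g?")


def match_noun_phrases(tokens: list[TaggedToken]) -> list[str]:
    """Greedy left-to-right maximal matches of the noun-phrase grammar."""
    symbols = "".join(_tag_symbol(pos) for _, pos in tokens)
    phrases = []
    for m in _NP_PATTERN.finditer(symbols):
        phrases.append(" ".join(tokens[k][0].lower() for k in range(m.start(), m.end())))
    return phrases


def doc_phrases(doc: Document, tagger=naive_tagger) -> list[str]:
    """All phrase occurrences in a document's title + abstract."""
    tokens = doc.tagged_tokens
    if tokens is None:
        tokens = tagger((doc.title + " . " + doc.abstract).strip())
    return match_noun_phrases(tokens)


def bootstrap_phrase_counts(
    cluster_docs: list[Document],
    n_samples: int = 20,
    sample_frac: float = 1.0 / 3.0,
    seed: int = 0,
    tagger=naive_tagger,
    phrase_cache: dict[str, list[str]] | None = None,
) -> Counter:
    """Phrase occurrence counts summed over bootstrap subsamples.

    Each of ``n_samples`` samples draws ``ceil(np * sample_frac)`` of the
    cluster's documents without replacement; per-sample occurrence counts
    are summed.  Deterministic given the seed.
    """
    if not cluster_docs:
        raise ValueError("cluster has no documents in the characterization window")
    docs = sorted(cluster_docs, key=lambda d: d.doc_id)
    if phrase_cache is None:
        phrase_cache = {}
    per_doc = []
    for d in docs:
        if d.doc_id not in phrase_cache:
            phrase_cache[d.doc_id] = doc_phrases(d, tagger=tagger)
        per_doc.append(Counter(phrase_cache[d.doc_id]))
    rng = np.random.default_rng(seed)
    size = math.ceil(len(docs) * sample_frac)
    total: Counter = Counter()
    for _ in range(n_samples):
        for k in rng.choice(len(docs), size=size, replace=False):
            total.update(per_doc[k])
    return total


def phrase_score(count: float, np_docs: int, n_samples: int = 20,
                 sample_frac: float = 1.0 / 3.0) -> float:
    """sc = count / (n_samples * np * sample_frac) — occurrences per paper."""
    if np_docs < 1:
        raise ValueError("np must be >= 1")
    return count / (n_samples * np_docs * sample_frac)


def idio_score(sc: float, sctot: float, nptot: int, log_base: float | None = None) -> float:
    """idio = 10 * log(1 + sc/nptot) * sc/sctot (natural log by default)."""
    if sc == 0:
        return 0.0
    if sctot <= 0:
        raise ValueError("sctot must be positive")
    if nptot < 1:
        raise ValueError("nptot must be >= 1")
    lg = math.log(1.0 + sc / nptot)
    if log_base is not None:
        lg /= math.log(log_base)
    return 10.0 * lg * sc / sctot


@dataclass(frozen=True)
class CentralPaper:
    doc_id: str
    score: float
    doc_type: str
    source: str
    n_cited: int


def central_papers(
    cluster_docs: list[Document],
    edges,
    n_core: int = 10,
    n_reviews: int = 5,
) -> tuple[list[CentralPaper], list[CentralPaper]]:
    """Rank documents by summed within-cluster relatedness.

    Scores are normalized to the cluster maximum; the core list excludes
    reviews, the review list contains only reviews.  Ties break by doc_id.
    """
    member = {d.doc_id for d in cluster_docs}
    centrality = {doc_id: 0.0 for doc_id in member}
    for i, j, w in as_weighted(edges):
        if i in member and j in member:
            centrality[i] += w
            centrality[j] += w
    mx = max(centrality.values(), default=0.0)
    docs_by_id = {d.doc_id: d for d in cluster_docs}
    ranked = sorted(member, key=lambda d: (-centrality[d], d))

    def entry(doc_id: str) -> CentralPaper:
        d = docs_by_id[doc_id]
        return CentralPaper(
            doc_id=doc_id,
            score=centrality[doc_id] / mx if mx > 0 else 0.0,
            doc_type=";".join(sorted(d.doc_types)),
            source=f"{doc_id}, {d.title}, {d.journal}, {d.year}",
            n_cited=int(d.metrics.get("cites", 0)))

    core = [entry(d) for d in ranked if not docs_by_id[d].is_review][:n_core]
    reviews = [entry(d) for d in ranked if docs_by_id[d].is_review][:n_reviews]
    return core, reviews


def top_descriptors(cluster_docs: list[Document], key: str, k: int = 10):
    """Ranked (descriptor, count) list; for authors also cites-per-paper.

    Counts documents carrying each descriptor; ties break alphabetically.
    """
    getters = {
        "mesh": lambda d: d.mesh_terms,
        "journal": lambda d: [d.journal] if d.journal else [],
        "category": lambda d: d.categories,
        "author": lambda d: d.authors,
    }
    if key not in getters:
        raise ValueError(f"unknown descriptor key {key!r}")
    counts: Counter = Counter()
    cites: dict[str, list[float]] = {}
    for d in cluster_docs:
        for desc in set(getters[key](d)):
            counts[desc] += 1
            cites.setdefault(desc, []).append(d.metrics.get("cites", 0.0))
    ranked = sorted(counts.items(), key=lambda t: (-t[1], t[0]))[:k]
    if key == "author":
        return [(desc, cnt, sum(cites[desc]) / len(cites[desc]))
                for desc, cnt in ranked]
    return ranked


def growth_rate(n_first: float, n_last: float, years: int = 3,
                smooth: float = 1.0) -> float:
    """Annualized growth ((n_last+s)/(n_first+s))^(1/years) - 1."""
    return ((n_last + smooth) / (n_first + smooth)) ** (1.0 / years) - 1.0


_MEAN_METRICS = {
    "cpp": "cites", "rcr": "rcr", "snip": "snip", "apt": "apt",
    "rlev": "research_level", "fundpp": "funding_types",
    "grantpp": "grants", "starpp": "funding", "nprpp": "patent_cites",
}
_FLAG_METRICS = {
    "ind_fr": "industry_flag", "clin_fr": "clinical_flag",
    "meth_fr": "method_flag", "disc_fr": "discovery_flag",
}

INDICATOR_KEYS = (list(_MEAN_METRICS) + list(_FLAG_METRICS)
                  + ["rev_fr", "trl_fr", "nauth2", "nauth5",
                     "age", "vitality", "growth"])


def cluster_metrics(
    cluster_docs: list[Document],
    citations: list[CitationEdge],
    window: tuple[int, int],
    reference_year: int | None = None,
    doc_years: dict[str, int] | None = None,
    growth_years: int = 3,
    growth_smooth: float = 1.0,
) -> dict[str, float | None]:
    """Indicator values for one cluster over a characterization window.

    Means run over window documents carrying the metric; flag fractions
    over all window documents.  Age is measured from ``reference_year``
    (default: window end); vitality is the inverse mean reference age of
    the window documents' outgoing citations with a 1-year floor; growth
    is annualized over the last ``growth_years`` with +1 smoothing of both
    endpoint counts.
    """
    y0, y1 = window
    if reference_year is None:
        reference_year = y1
    wdocs = [d for d in cluster_docs if y0 <= d.year <= y1]
    out: dict[str, float | None] = {k: None for k in INDICATOR_KEYS}
    if not wdocs:
        log.info("cluster_metrics: empty window %s, all indicators null", window)
        return out

    for name, key in _MEAN_METRICS.items():
        vals = [d.metrics[key] for d in wdocs if key in d.metrics]
        out[name] = sum(vals) / len(vals) if vals else None
    for name, key in _FLAG_METRICS.items():
        out[name] = sum(1 for d in wdocs if d.metrics.get(key, 0) >= 1) / len(wdocs)
    out["rev_fr"] = sum(1 for d in wdocs if d.is_review) / len(wdocs)
    out["trl_fr"] = sum(1 for d in wdocs if d.is_trial) / len(wdocs)

    author_papers: Counter = Counter()
    for d in wdocs:
        for a in set(d.authors):
            author_papers[a] += 1
    out["nauth2"] = sum(1 for c in author_papers.values() if c >= 2)
    out["nauth5"] = sum(1 for c in author_papers.values() if c >= 5)

    out["age"] = reference_year - sum(d.year for d in wdocs) / len(wdocs)

    if doc_years is None:
        doc_years = {}
    wids = {d.doc_id: d.year for d in wdocs}
    ref_ages = []
    for e in citations:
        if e.citing_id in wids and e.cited_id in doc_years:
            ref_ages.append(max(wids[e.citing_id] - doc_years[e.cited_id], 1))
    out["vitality"] = 1.0 / (sum(ref_ages) / len(ref_ages)) if ref_ages else None

    year_counts = Counter(d.year for d in cluster_docs)
    out["growth"] = growth_rate(
        year_counts.get(reference_year - growth_years, 0),
        year_counts.get(reference_year, 0),
        years=growth_years, smooth=growth_smooth)
    return out


def percentile_ranks(values: dict) -> dict:
    """Percentile (0, 100] per key: 100 * midrank / n over non-null values."""
    keys = [k for k, v in values.items() if v is not None]
    out = {k: None for k in values}
    if not keys:
        return out
    ranks = rankdata([values[k] for k in keys], method="average")
    n = len(keys)
    for k, r in zip(keys, ranks):
        out[k] = 100.0 * r / n
    return out


@dataclass(frozen=True)
class OverlayResult:
    cluster: int
    subset_count: int
    subset_fraction: float


def overlay(
    subset_ids: set[str],
    assignment: ClusterAssignment,
    min_count: int = 25,
    min_fraction: float = 0.10,
    cluster_sizes: dict[int, int] | None = None,
) -> tuple[list[OverlayResult], set[int]]:
    """Per-cluster count/concentration of an external document subset.

    Returns one result per retained cluster plus the set of clusters
    meeting both thresholds.  Subset ids absent from the corpus are
    ignored (count logged).
    """
    clusters = assignment.retained_clusters(level=5)
    known = set(assignment)
    unknown = len(set(subset_ids) - known)
    if unknown:
        log.info("overlay: %d subset ids not in corpus, ignored", unknown)
    if cluster_sizes is None:
        cluster_sizes = {c: len(m) for c, m in clusters.items()}
    results = []
    passing: set[int] = set()
    for cid in sorted(clusters):
        cnt = sum(1 for m in clusters[cid] if m in subset_ids)
        size = cluster_sizes.get(cid, len(clusters[cid]))
        frac = cnt / size if size else 0.0
        results.append(OverlayResult(cid, cnt, frac))
        if cnt >= min_count and frac >= min_fraction:
            passing.add(cid)
    return results, passing


# ---------------------------------------------------------------------------
# Profile orchestration
# ---------------------------------------------------------------------------

@dataclass
class ClusterProfile:
    cluster: int
    level4: int = 0
    level3: int = 0
    x: float = 0.0
    y: float = 0.0
    field: str = "unassigned"
    n_docs_total: int = 0
    n_docs_window: int = 0
    annual_counts: dict[int, int] = dc_field(default_factory=dict)
    top_phrases: list = dc_field(default_factory=list)       # (phrase, sc)
    top_idio: list = dc_field(default_factory=list)          # (phrase, idio)
    top_mesh: list = dc_field(default_factory=list)          # (term, count)
    top_journals: list = dc_field(default_factory=list)
    top_categories: list = dc_field(default_factory=list)
    top_authors: list = dc_field(default_factory=list)       # (author, count, cpp)
    central_papers: list = dc_field(default_factory=list)    # CentralPaper
    central_reviews: list = dc_field(default_factory=list)
    indicators: dict = dc_field(default_factory=dict)
    percentiles: dict = dc_field(default_factory=dict)
    overlays: dict = dc_field(default_factory=dict)          # name -> (count, frac)


#: indicators that carry a percentile column in the CLUST sheet
PERCENTILED = ["cpp", "rcr", "snip", "apt", "ind_fr", "nprpp", "clin_fr",
               "fundpp", "grantpp", "starpp", "meth_fr", "disc_fr",
               "rev_fr", "trl_fr"]


def build_profiles(
    documents: list[Document],
    assignment: ClusterAssignment,
    edges,
    citations: list[CitationEdge],
    window: tuple[int, int],
    map_layout=None,
    top_k: int = 10,
    n_core: int = 10,
    n_reviews: int = 5,
    bootstrap_samples: int = 20,
    sample_frac: float = 1.0 / 3.0,
    idio_log_base: float | None = None,
    seed: int = 0,
    overlays: dict[str, set[str]] | None = None,
    tagger=naive_tagger,
) -> list[ClusterProfile]:
    """Compute every descriptor and indicator for each retained cluster."""
    docs_by_id = {d.doc_id: d for d in documents}
    doc_years = {d.doc_id: d.year for d in documents}
    clusters = assignment.retained_clusters(level=5)
    weighted = as_weighted(edges)
    y0, y1 = window

    # phrase pass: per-cluster bootstrap counts on window docs
    phrase_cache: dict[str, list[str]] = {}
    sc_by_cluster: dict[int, dict[str, float]] = {}
    window_docs: dict[int, list[Document]] = {}
    for cid in sorted(clusters):
        members = [docs_by_id[m] for m in clusters[cid] if m in docs_by_id]
        wdocs = [d for d in members if y0 <= d.year <= y1]
        window_docs[cid] = wdocs
        if not wdocs:
            sc_by_cluster[cid] = {}
            continue
        counts = bootstrap_phrase_counts(
            wdocs, n_samples=bootstrap_samples, sample_frac=sample_frac,
            seed=seed + cid, tagger=tagger, phrase_cache=phrase_cache)
        sc_by_cluster[cid] = {
            ph: phrase_score(c, len(wdocs), bootstrap_samples, sample_frac)
            for ph, c in counts.items()}

    sctot: Counter = Counter()
    for scores in sc_by_cluster.values():
        for ph, sc in scores.items():
            sctot[ph] += sc
    nptot: Counter = Counter()
    for cid, wdocs in window_docs.items():
        for d in wdocs:
            for ph in set(phrase_cache.get(d.doc_id, [])):
                nptot[ph] += 1

    # per-cluster within edges for central papers
    membership = {doc: a.level5 for doc, a in assignment.items() if not a.removed}
    within: dict[int, list] = {cid: [] for cid in clusters}
    for i, j, w in weighted:
        m, n = membership.get(i), membership.get(j)
        if m is not None and m == n:
            within[m].append((i, j, w))

    profiles = []
    for cid in sorted(clusters):
        members = [docs_by_id[m] for m in clusters[cid] if m in docs_by_id]
        wdocs = window_docs[cid]
        any_doc = assignment[clusters[cid][0]]
        p = ClusterProfile(
            cluster=cid, level4=any_doc.level4, level3=any_doc.level3,
            n_docs_total=len(members), n_docs_window=len(wdocs),
            annual_counts=dict(sorted(Counter(d.year for d in members).items())))
        if map_layout is not None:
            p.x, p.y = map_layout.coords.get(cid, (0.0, 0.0))
            p.field = map_layout.fields.get(cid, "unassigned")
        scores = sc_by_cluster[cid]
        p.top_phrases = sorted(scores.items(), key=lambda t: (-t[1], t[0]))[:top_k]
        idio = {ph: idio_score(sc, sctot[ph], max(nptot[ph], 1), idio_log_base)
                for ph, sc in scores.items()}
        p.top_idio = sorted(idio.items(), key=lambda t: (-t[1], t[0]))[:top_k]
        p.top_mesh = top_descriptors(wdocs, "mesh", top_k)
        p.top_journals = top_descriptors(wdocs, "journal", top_k)
        p.top_categories = top_descriptors(wdocs, "category", top_k)
        p.top_authors = top_descriptors(wdocs, "author", top_k)
        p.central_papers, p.central_reviews = central_papers(
            wdocs, within[cid], n_core=n_core, n_reviews=n_reviews)
        p.indicators = cluster_metrics(
            members, citations, window, doc_years=doc_years)
        profiles.append(p)

    for key in PERCENTILED:
        pct = percentile_ranks({p.cluster: p.indicators.get(key) for p in profiles})
        for p in profiles:
            p.percentiles[key] = pct[p.cluster]

    if overlays:
        for name, ids in overlays.items():
            results, _ = overlay(ids, assignment,
                                 cluster_sizes={p.cluster: p.n_docs_window
                                                for p in profiles})
            by_cluster = {r.cluster: r for r in results}
            for p in profiles:
                r = by_cluster.get(p.cluster)
                if r is not None:
                    p.overlays[name] = (r.subset_count, r.subset_fraction)
    return profiles
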