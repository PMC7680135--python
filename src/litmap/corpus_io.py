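"""Corpus input/output: the document data model, corpus readers and the
workbook-style output tables.

Input formats
-------------
* documents: JSON-lines (one object per line) or TSV with a header row.
  List-valued fields in TSV are ``|``-separated; the ``metrics`` column is
  a JSON object.
* citations: TSV with header ``citing_id<TAB>cited_id``.
* similarities: TSV with header ``id_a<TAB>id_b<TAB>score``.

All readers apply the journal-exclusion filter at load time and drop edges
whose endpoints are not in the retained document set (with logged counts);
real-world citation and similarity sources are mutually incomplete, so
unknown IDs in edge files are warnings, not errors.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

LIST_SEP = "|"

DOC_COLUMNS = [
    "doc_id", "title", "abstract", "year", "journal",
    "mesh_terms", "authors", "doc_types", "categories", "metrics",
]


class CorpusFormatError(ValueError):
    """Malformed or inconsistent corpus input."""


@dataclass
class Document:
    """One bibliographic record with metadata and optional precomputed metrics."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    year: int = 0
    journal: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    doc_types: set[str] = field(default_factory=set)
    categories: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)
    # optional pre-tagged (token, POS) pairs for title+abstract; when present,
    # phrase extraction uses them instead of invoking a tagger
    tagged_tokens: list[tuple[str, str]] | None = None

    @property
    def is_review(self) -> bool:
        return "review" in self.doc_types

    @property
    def is_trial(self) -> bool:
        return "clinical-trial" in self.doc_types


@dataclass(frozen=True)
class CitationEdge:
    citing_id: str
    cited_id: str


@dataclass(frozen=True)
class SimilarityRecord:
    id_a: str
    id_b: str
    score: float


@dataclass
class CorpusStats:
    """Load-time accounting: how many records each filter dropped."""

    n_documents_read: int = 0
    n_documents_excluded: int = 0
    n_documents_retained: int = 0
    n_citations_read: int = 0
    n_citations_dropped: int = 0
    n_similarities_read: int = 0
    n_similarities_dropped: int = 0


def exclusion_accounting(n_start: int, n_excluded: int) -> int:
    """Retained document count after journal exclusion (n_start - n_excluded)."""
    if n_excluded > n_start:
        raise ValueError("cannot exclude more documents than present")
    return n_start - n_excluded


def _parse_doc_obj(obj: dict, where: str) -> Document:
    try:
        return Document(
            doc_id=str(obj["doc_id"]),
            title=str(obj.get("title", "")),
            abstract=str(obj.get("abstract", "")),
            year=int(obj.get("year", 0)),
            journal=str(obj.get("journal", "")),
            mesh_terms=list(obj.get("mesh_terms", []) or []),
            authors=list(obj.get("authors", []) or []),
            doc_types=set(obj.get("doc_types", []) or []),
            categories=list(obj.get("categories", []) or []),
            metrics={k: float(v) for k, v in (obj.get("metrics", {}) or {}).items()},
            tagged_tokens=[tuple(t) for t in obj["tagged_tokens"]]
            if obj.get("tagged_tokens") else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"{where}: malformed document record: {exc}") from exc


def read_documents(path: str | os.PathLike) -> list[Document]:
    """Read documents from JSON-lines (*.jsonl/*.json) or headered TSV."""
    path = os.fspath(path)
    docs: list[Document] = []
    if path.endswith((".jsonl", ".json")):
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                docs.append(_parse_doc_obj(obj, f"{path}:{lineno}"))
    else:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            missing = [c for c in ("doc_id",) if c not in header]
            if missing:
                raise CorpusFormatError(f"{path}:1: missing columns {missing}")
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header):
                    raise CorpusFormatError(
                        f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
                row = dict(zip(header, parts))
                obj: dict = {
                    "doc_id": row["doc_id"],
                    "title": row.get("title", ""),
                    "abstract": row.get("abstract", ""),
                    "year": row.get("year", 0),
                    "journal": row.get("journal", ""),
                    "mesh_terms": _split_list(row.get("mesh_terms", "")),
                    "authors": _split_list(row.get("authors", "")),
                    "doc_types": _split_list(row.get("doc_types", "")),
                    "categories": _split_list(row.get("categories", "")),
                    "metrics": json.loads(row["metrics"]) if row.get("metrics") else {},
                }
                docs.append(_parse_doc_obj(obj, f"{path}:{lineno}"))
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise CorpusFormatError(f"{path}: duplicate doc_id {d.doc_id!r}")
        seen.add(d.doc_id)
    return docs


def _split_list(text: str) -> list[str]:
    return [t for t in text.split(LIST_SEP) if t] if text else []


def read_citations(path: str | os.PathLike) -> list[CitationEdge]:
    path = os.fspath(path)
    edges: list[CitationEdge] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["citing_id", "cited_id"]:
            raise CorpusFormatError(f"{path}:1: expected header citing_id\\tcited_id")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected 2 fields")
            if parts[0] == parts[1]:
                raise CorpusFormatError(f"{path}:{lineno}: self-citation {parts[0]!r}")
            edges.append(CitationEdge(parts[0], parts[1]))
    return edges


def read_similarities(path: str | os.PathLike) -> list[SimilarityRecord]:
    path = os.fspath(path)
    recs: list[SimilarityRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id_a", "id_b", "score"]:
            raise CorpusFormatError(f"{path}:1: expected header id_a\\tid_b\\tscore")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise CorpusFormatError(f"{path}:{lineno}: expected 3 fields")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
            if score < 0:
                raise CorpusFormatError(f"{path}:{lineno}: negative score")
            recs.append(SimilarityRecord(parts[0], parts[1], score))
    return recs


def filter_corpus(
    documents: list[Document],
    citations: list[CitationEdge],
    similarities: list[SimilarityRecord],
    excluded_journals: set[str] = frozenset(),
) -> tuple[list[Document], list[CitationEdge], list[SimilarityRecord], CorpusStats]:
    """Apply journal exclusion and drop edges with unresolvable endpoints.

    Idempotent: re-applying to its own output changes nothing.
    """
    stats = CorpusStats(
        n_documents_read=len(documents),
        n_citations_read=len(citations),
        n_similarities_read=len(similarities),
    )
    kept = [d for d in documents if d.journal not in excluded_journals]
    stats.n_documents_excluded = len(documents) - len(kept)
    stats.n_documents_retained = exclusion_accounting(
        stats.n_documents_read, stats.n_documents_excluded)
    docset = {d.doc_id for d in kept}
    cites = [e for e in citations if e.citing_id in docset and e.cited_id in docset]
    stats.n_citations_dropped = len(citations) - len(cites)
    sims = [r for r in similarities if r.id_a in docset and r.id_b in docset]
    stats.n_similarities_dropped = len(similarities) - len(sims)
    if stats.n_documents_excluded or stats.n_citations_dropped or stats.n_similarities_dropped:
        log.info(
            "corpus filter: dropped %d documents (excluded journals), "
            "%d citations, %d similarity records",
            stats.n_documents_excluded, stats.n_citations_dropped,
            stats.n_similarities_dropped)
    return kept, cites, sims, stats


def read_corpus(
    doc_path: str | os.PathLike,
    citation_path: str | os.PathLike,
    sa_path: str | os.PathLike,
    excluded_journals: set[str] = frozenset(),
) -> tuple[list[Document], list[CitationEdge], list[SimilarityRecord], CorpusStats]:
    """Load a corpus and apply the exclusion/consistency filters."""
    docs = read_documents(doc_path)
    cites = read_citations(citation_path)
    sims = read_similarities(sa_path)
    return filter_corpus(docs, cites, sims, excluded_journals)


def read_excluded_journals(path: str | os.PathLike) -> set[str]:
    """One journal name per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_documents(documents: list[Document], path: str | os.PathLike) -> None:
    """Write documents as JSON-lines (keeps list-valued fields structured)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in documents:
            obj = {
                "doc_id": d.doc_id, "title": d.title, "abstract": d.abstract,
                "year": d.year, "journal": d.journal,
                "mesh_terms": d.mesh_terms, "authors": d.authors,
                "doc_types": sorted(d.doc_types), "categories": d.categories,
                "metrics": d.metrics,
            }
            if d.tagged_tokens is not None:
                obj["tagged_tokens"] = [list(t) for t in d.tagged_tokens]
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def write_citations(edges: list[CitationEdge], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("citing_id\tcited_id\n")
        for e in edges:
            fh.write(f"{e.citing_id}\t{e.cited_id}\n")


def write_similarities(recs: list[SimilarityRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for r in recs:
            fh.write(f"{r.id_a}\t{r.id_b}\t{r.score:.6f}\n")


CLUST_COLUMNS = [
    "PM5", "PM4", "PM3", "X", "Y", "field", "nptot", "np1519",
    "cpp19", "cpp19_pctl", "rcr", "rcr_pctl", "snip", "snip_pctl",
    "apt", "apt_pctl", "ind_fr", "ind_pctl", "nprpp", "npr_pctl",
    "clin_fr", "clin_pctl", "rlev", "fundpp", "nf_pctl",
    "grantpp", "ng_pctl", "starpp", "star_pctl", "meth_fr", "meth_pctl",
    "disc_fr", "disc_pctl", "rev_fr", "rev_pctl", "trl_fr", "trl_pctl",
    "nauth2", "nauth5", "age", "vit19", "3yrgrw",
]

# ClusterProfile indicator key -> (value column, percentile column or None)
_CLUST_INDICATORS = [
    ("cpp", "cpp19", "cpp19_pctl"), ("rcr", "rcr", "rcr_pctl"),
    ("snip", "snip", "snip_pctl"), ("apt", "apt", "apt_pctl"),
    ("ind_fr", "ind_fr", "ind_pctl"), ("nprpp", "nprpp", "npr_pctl"),
    ("clin_fr", "clin_fr", "clin_pctl"), ("rlev", "rlev", None),
    ("fundpp", "fundpp", "nf_pctl"), ("grantpp", "grantpp", "ng_pctl"),
    ("starpp", "starpp", "star_pctl"), ("meth_fr", "meth_fr", "meth_pctl"),
    ("disc_fr", "disc_fr", "disc_pctl"), ("rev_fr", "rev_fr", "rev_pctl"),
    ("trl_fr", "trl_fr", "trl_pctl"),
]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def write_tables(profiles: list, assignment, out_dir: str | os.PathLike) -> dict[str, str]:
    """Emit the workbook-style TSV sheets.

    Returns a sheet-name -> path map.  ``profiles`` is a list of
    :class:`litmap.characterize.ClusterProfile`; ``assignment`` a
    :class:`litmap.clustering.ClusterAssignment`.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def sheet(name: str, header: list[str], rows: list[list]) -> None:
        p = os.path.join(out_dir, f"{name}.tsv")
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        paths[name] = p

    profiles = sorted(profiles, key=lambda p: p.cluster)

    rows = []
    for p in profiles:
        row = [p.cluster, p.level4, p.level3, p.x, p.y, p.field,
               p.n_docs_total, p.n_docs_window]
        for key, _vc, pc in _CLUST_INDICATORS:
            row.append(p.indicators.get(key))
            if pc is not None:
                row.append(p.percentiles.get(key))
        row += [p.indicators.get("nauth2"), p.indicators.get("nauth5"),
                p.indicators.get("age"), p.indicators.get("vitality"),
                p.indicators.get("growth")]
        rows.append(row)
    sheet("CLUST", CLUST_COLUMNS, rows)

    years = sorted({y for p in profiles for y in p.annual_counts})
    sheet("COUNT", ["PM5"] + [str(y) for y in years],
          [[p.cluster] + [p.annual_counts.get(y, 0) for y in years] for p in profiles])

    for name, attr in [("PHRASE", "top_phrases"), ("IDIO", "top_idio"),
                       ("MESH", "top_mesh"), ("JNL", "top_journals"),
                       ("ASJC", "top_categories")]:
        rows = []
        for p in profiles:
            for rank, (desc, score) in enumerate(getattr(p, attr), 1):
                rows.append([p.cluster, rank, desc, score])
        sheet(name, ["PM5", "rank", "descriptor", "score"], rows)

    rows = []
    for p in profiles:
        for rank, (author, count, cpp) in enumerate(p.top_authors, 1):
            rows.append([p.cluster, rank, count, cpp, author])
    sheet("AUTH", ["PM5", "rank", "count", "cpp", "author"], rows)

    for name, attr in [("CORE", "central_papers"), ("REVIEW", "central_reviews")]:
        rows = []
        for p in profiles:
            for rank, cp in enumerate(getattr(p, attr), 1):
                rows.append([p.cluster, rank, cp.score, cp.doc_type,
                             cp.source, cp.n_cited])
        sheet(name, ["PM5", "rank", "score", "type", "source", "ncited"], rows)

    rows = []
    overlay_names = sorted({name for p in profiles for name in p.overlays})
    header = ["PM5"]
    for name in overlay_names:
        header += [f"#{name}", f"%{name}"]
    for p in profiles:
        row = [p.cluster]
        for name in overlay_names:
            cnt, frac = p.overlays.get(name, (0, 0.0))
            row += [cnt, frac]
        rows.append(row)
    sheet("QUERY", header, rows)

    sheet("ASSIGN", ["doc_id", "PM5", "PM4", "PM3", "removed"],
          [[doc_id, a.level5, a.level4, a.level3, int(a.removed)]
           for doc_id, a in sorted(assignment.items())])
    return paths
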