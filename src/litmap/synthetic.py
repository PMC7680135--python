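"""Synthetic corpora with planted topic structure.

Generates documents, topic-concentrated citation edges, topic-concentrated
similarity scores, topic-specific vocabulary (emitted pre-POS-tagged),
authors, years, document types and per-document metrics — the statistical
structure the pipeline assumes — so every stage is testable offline.
Similarity scores are sampled directly (heavy-tailed, scaled by topic
co-membership) rather than computed from the generated text, so
relatedness-stage tests do not depend on any text model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from . import corpus_io
from .cluster_graph import DEFAULT_FIELDS
from .corpus_io import CitationEdge, Document, SimilarityRecord

_SHARED_NOUNS = ["analysis", "model", "study", "method", "result", "datum",
                 "effect", "system", "approach", "evaluation"]
_SHARED_ADJS = ["novel", "clinical", "significant", "robust", "general"]
_SHARED_GERUNDS = ["screening", "modeling", "sampling"]
_DETERMINERS = ["the", "of", "in", "and", "for"]


@dataclass
class SyntheticConfig:
    n_topics: int = 20
    docs_per_topic: int = 100
    years: tuple[int, int] = (2010, 2019)
    refs_per_doc: float = 10.0
    p_within: float = 0.9
    sa_top_k: int = 20
    sa_within_scale: float = 100.0
    sa_cross_scale: float = 10.0
    vocab_shared: list[str] = dc_field(default_factory=lambda: list(_SHARED_NOUNS))
    vocab_per_topic: int = 6
    authors_per_topic: int = 10
    review_fraction: float = 0.10
    trial_fraction: float = 0.05
    title_tokens: int = 8
    abstract_tokens: int = 40
    # metric name -> (mean, sd) of per-document lognormal/poisson-style draws
    metric_distributions: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "cites": (8.0, 1.0), "rcr": (1.0, 0.5), "snip": (1.2, 0.4),
            "apt": (0.4, 0.2), "research_level": (2.5, 1.0),
            "funding_types": (1.0, 0.0), "grants": (1.2, 0.0),
            "funding": (0.5, 0.3), "patent_cites": (0.3, 0.0),
        })
    flag_probabilities: dict[str, float] = dc_field(
        default_factory=lambda: {
            "industry_flag": 0.10, "clinical_flag": 0.20,
            "method_flag": 0.15, "discovery_flag": 0.10,
        })
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.p_within <= 1):
            raise ValueError("p_within must be in (0, 1]")
        if self.sa_within_scale <= self.sa_cross_scale:
            raise ValueError("sa_within_scale must exceed sa_cross_scale")
        if self.n_topics < 1 or self.docs_per_topic < 1:
            raise ValueError("need at least one topic and one document per topic")
        n = self.n_topics * self.docs_per_topic
        if self.refs_per_doc >= n:
            raise ValueError("refs_per_doc must be smaller than the corpus size")
        if self.years[0] > self.years[1]:
            raise ValueError("invalid year range")


@dataclass
class SyntheticGroundTruth:
    doc_topic: dict[str, int]
    topic_vocab: dict[int, list[str]]
    journal_fields: dict[str, str]


def topic_vocabulary(config: SyntheticConfig) -> dict[int, list[str]]:
    return {t: [f"topic{t}term{k}" for k in range(config.vocab_per_topic)]
            for t in range(config.n_topics)}


def _compose_text(rng: np.random.Generator, n_tokens: int,
                  topic_words: list[str], shared: list[str]):
    """Emit ~n_tokens tagged tokens; topic words appear as isolated nouns."""
    tokens: list[tuple[str, str]] = []
    while len(tokens) < n_tokens:
        u = rng.random()
        if u < 0.40:
            tokens.append((_DETERMINERS[rng.integers(len(_DETERMINERS))], "DT"))
            tokens.append((topic_words[rng.integers(len(topic_words))], "NN"))
        elif u < 0.70:
            tokens.append((_DETERMINERS[rng.integers(len(_DETERMINERS))], "DT"))
            tokens.append((shared[rng.integers(len(shared))], "NN"))
        elif u < 0.90:
            tokens.append((_SHARED_ADJS[rng.integers(len(_SHARED_ADJS))], "JJ"))
            tokens.append((shared[rng.integers(len(shared))], "NN"))
        else:
            tokens.append((_SHARED_GERUNDS[rng.integers(len(_SHARED_GERUNDS))], "VBG"))
    return tokens


def generate_corpus(config: SyntheticConfig):
    """Generate (documents, citations, similarity records, ground truth).

    Deterministic given ``config.seed``.  Citations point only to
    earlier-or-equal years, same-topic with probability ``p_within``.
    Each document draws ``sa_top_k`` similarity partners with within-topic
    scores an order of magnitude above cross-topic ones.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, m = config.n_topics, config.docs_per_topic
    n = K * m
    y0, y1 = config.years
    vocab = topic_vocabulary(config)
    journal_fields = {
        f"journal_{t}": DEFAULT_FIELDS[t % len(DEFAULT_FIELDS)] for t in range(K)}
    authors = {t: [f"author_{t}_{k}" for k in range(config.authors_per_topic)]
               for t in range(K)}
    mesh = {t: [f"mesh_{t}_{k}" for k in range(5)] for t in range(K)}

    topic_of = np.repeat(np.arange(K), m)
    years = rng.integers(y0, y1 + 1, size=n)
    doc_ids = [f"D{k:06d}" for k in range(n)]

    # per-topic multiplicative effect on metric means
    topic_effect = {met: rng.uniform(0.5, 1.5, size=K)
                    for met in config.metric_distributions}

    documents: list[Document] = []
    for k in range(n):
        t = int(topic_of[k])
        title_toks = _compose_text(rng, config.title_tokens, vocab[t],
                                   config.vocab_shared)
        abs_toks = _compose_text(rng, config.abstract_tokens, vocab[t],
                                 config.vocab_shared)
        doc_types = set()
        if rng.random() < config.review_fraction:
            doc_types.add("review")
        if rng.random() < config.trial_fraction:
            doc_types.add("clinical-trial")
        metrics: dict[str, float] = {}
        for met, (mean, sd) in config.metric_distributions.items():
            val = mean * topic_effect[met][t]
            if sd > 0:
                val = max(0.0, float(rng.normal(val, sd)))
            if met in ("cites", "grants", "funding_types", "patent_cites"):
                val = float(rng.poisson(val))
            metrics[met] = round(float(val), 4)
        for flag, p in config.flag_probabilities.items():
            metrics[flag] = float(rng.random() < p)
        n_auth = int(rng.integers(2, 5))
        auth_idx = rng.choice(config.authors_per_topic,
                              size=min(n_auth, config.authors_per_topic),
                              replace=False)
        documents.append(Document(
            doc_id=doc_ids[k],
            title=" ".join(w for w, _ in title_toks),
            abstract=" ".join(w for w, _ in abs_toks),
            year=int(years[k]),
            journal=f"journal_{t}",
            mesh_terms=sorted(mesh[t][i] for i in
                              rng.choice(5, size=2, replace=False)),
            authors=[authors[t][i] for i in auth_idx],
            doc_types=doc_types,
            categories=[journal_fields[f"journal_{t}"]],
            metrics=metrics,
            tagged_tokens=title_toks + abs_toks,
        ))

    by_topic = {t: np.flatnonzero(topic_of == t) for t in range(K)}
    citations: list[CitationEdge] = []
    for k in range(n):
        t = int(topic_of[k])
        nref = int(rng.poisson(config.refs_per_doc))
        targets: set[int] = set()
        for _ in range(nref):
            if rng.random() < config.p_within:
                pool = by_topic[t]
            else:
                other = int(rng.integers(K - 1))
                pool = by_topic[other if other < t else other + 1]
            eligible = pool[years[pool] <= years[k]]
            eligible = eligible[eligible != k]
            if eligible.size == 0:
                continue
            targets.add(int(eligible[rng.integers(eligible.size)]))
        for tgt in sorted(targets):
            citations.append(CitationEdge(doc_ids[k], doc_ids[tgt]))

    sim_scores: dict[tuple[str, str], float] = {}
    for k in range(n):
        t = int(topic_of[k])
        for _ in range(config.sa_top_k):
            within = rng.random() < config.p_within
            if within:
                pool = by_topic[t]
                score = float(rng.exponential(config.sa_within_scale))
            else:
                other = int(rng.integers(K - 1))
                pool = by_topic[other if other < t else other + 1]
                score = float(rng.exponential(config.sa_cross_scale))
            j = int(pool[rng.integers(pool.size)])
            if j == k:
                continue
            a, b = doc_ids[k], doc_ids[j]
            key = (a, b) if a <= b else (b, a)
            if score > sim_scores.get(key, -1.0):
                sim_scores[key] = score
    similarities = [SimilarityRecord(a, b, round(s, 6))
                    for (a, b), s in sorted(sim_scores.items())]

    truth = SyntheticGroundTruth(
        doc_topic={doc_ids[k]: int(topic_of[k]) for k in range(n)},
        topic_vocab=vocab,
        journal_fields=journal_fields)
    return documents, citations, similarities, truth


def default_level_configs():
    """Level configs suited to generator-scale corpora (~10^3 documents).

    The full-corpus literature defaults (resolutions 7.75e-5 / 1e-5 /
    1.25e-6, minimum sizes 75 / 750 / 7500) target ~10^7 documents; at
    generator scale they collapse everything into one cluster.
    """
    from .clustering import LevelConfig
    return [LevelConfig(1.0e-3, 75), LevelConfig(1.0e-4, 150),
            LevelConfig(1.0e-5, 400)]


@dataclass
class RecoveryScores:
    ari: float
    nmi: float
    n_clusters: int


def evaluate_recovery(assignment, ground_truth: SyntheticGroundTruth | dict
                      ) -> RecoveryScores:
    """ARI / NMI between finest-level clusters and planted topics."""
    doc_topic = (ground_truth.doc_topic
                 if isinstance(ground_truth, SyntheticGroundTruth)
                 else dict(ground_truth))
    if hasattr(assignment, "items"):
        labels = {doc: (a.level5 if hasattr(a, "level5") else int(a))
                  for doc, a in assignment.items()}
    else:
        raise TypeError("assignment must be a mapping")
    common = sorted(set(labels) & set(doc_topic))
    if not common:
        raise ValueError("assignment and ground truth share no document ids")
    pred = [labels[d] for d in common]
    true = [doc_topic[d] for d in common]
    return RecoveryScores(
        ari=float(adjusted_rand_score(true, pred)),
        nmi=float(normalized_mutual_info_score(true, pred)),
        n_clusters=len(set(pred)))


def write_corpus(config: SyntheticConfig, out_dir: str | os.PathLike) -> dict[str, str]:
    """Generate and persist a corpus in the exact formats corpus_io reads."""
    documents, citations, similarities, truth = generate_corpus(config)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "documents": os.path.join(out_dir, "documents.jsonl"),
        "citations": os.path.join(out_dir, "citations.tsv"),
        "similarities": os.path.join(out_dir, "similarities.tsv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
        "journal_fields": os.path.join(out_dir, "journal_fields.tsv"),
    }
    corpus_io.write_documents(documents, paths["documents"])
    corpus_io.write_citations(citations, paths["citations"])
    corpus_io.write_similarities(similarities, paths["similarities"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write("doc_id\ttopic\n")
        for doc_id, t in sorted(truth.doc_topic.items()):
            fh.write(f"{doc_id}\t{t}\n")
    with open(paths["journal_fields"], "w", encoding="utf-8") as fh:
        fh.write("journal\tfield\n")
        for j, f in sorted(truth.journal_fields.items()):
            fh.write(f"{j}\t{f}\n")
    return paths


def read_ground_truth(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            doc_id, t = line.rstrip("\n").split("\t")
            out[doc_id] = int(t)
    return out


def read_journal_fields(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            j, f = line.rstrip("\n").split("\t")
            out[j] = f
    return out
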