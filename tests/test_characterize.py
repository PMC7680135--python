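import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from litmap import characterize as ch
from litmap.clustering import ClusterAssignment, DocAssignment
from litmap.corpus_io import CitationEdge, Document


# ---------------------------------------------------------------------------
# noun-phrase grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tokens,expected", [
    ([("novel", "JJ"), ("scoring", "VBG"), ("function", "NN")],
     ["novel scoring function"]),
    ([("the", "DT"), ("cell", "NN")], ["cell"]),
    ([("running", "VBG")], []),
    ([("gene", "NN"), ("expression", "NN"), ("profiling", "VBG")],
     ["gene expression profiling"]),
    ([("deep", "JJ"), ("Learning", "NN"), ("of", "IN"), ("genomes", "NNS")],
     ["deep learning", "genomes"]),
    ([], []),
])
def test_grammar_examples(tokens, expected):
    assert ch.match_noun_phrases(tokens) == expected


def test_grammar_greedy_nonoverlapping():
    toks = [("big", "JJ"), ("data", "NN"), ("mining", "VBG"),
            ("tools", "NNS"), ("for", "IN"), ("biology", "NN")]
    # VBG after nouns is consumed by the first phrase; "tools" starts anew
    assert ch.match_noun_phrases(toks) == ["big data mining", "tools", "biology"]


def test_naive_tagger_supports_grammar():
    phrases = ch.match_noun_phrases(ch.naive_tagger("the novel protein assay"))
    assert phrases == ["novel protein assay"]


# ---------------------------------------------------------------------------
# bootstrap counts and phrase scores
# ---------------------------------------------------------------------------

def _doc_with_phrase(doc_id, n_occurrences):
    toks = []
    for _ in range(n_occurrences):
        toks += [("the", "DT"), ("biomarker", "NN")]
    return Document(doc_id, year=2019, tagged_tokens=toks)


def test_bootstrap_ubiquitous_phrase_count():
    # phrase once per doc -> summed count = n_samples * ceil(np/3), exactly
    docs = [_doc_with_phrase(f"d{k}", 1) for k in range(6)]
    counts = ch.bootstrap_phrase_counts(docs, seed=0)
    assert counts["biomarker"] == 20 * 2  # ceil(6/3) = 2 docs per sample


def test_bootstrap_absent_phrase_absent():
    docs = [_doc_with_phrase(f"d{k}", 1) for k in range(3)]
    assert "unicorn" not in ch.bootstrap_phrase_counts(docs, seed=0)


def test_bootstrap_expected_count_simulation():
    # np=3, samples of 1 doc, phrase in exactly 1 doc once: E[count] = 20/3
    docs = [_doc_with_phrase("d0", 1),
            Document("d1", tagged_tokens=[("assay", "NN")]),
            Document("d2", tagged_tokens=[("assay", "NN")])]
    counts = [ch.bootstrap_phrase_counts(docs, seed=s)["biomarker"]
              for s in range(200)]
    assert np.mean(counts) == pytest.approx(20 / 3, abs=1.0)


def test_bootstrap_deterministic():
    docs = [_doc_with_phrase(f"d{k}", k + 1) for k in range(5)]
    assert (ch.bootstrap_phrase_counts(docs, seed=4)
            == ch.bootstrap_phrase_counts(docs, seed=4))


def test_bootstrap_empty_cluster_is_error():
    with pytest.raises(ValueError):
        ch.bootstrap_phrase_counts([])


@pytest.mark.parametrize("count,np_docs,expected", [
    (40, 6, 1.0), (0, 5, 0.0), (10, 3, 0.5),
])
def test_phrase_score_arithmetic(count, np_docs, expected):
    assert ch.phrase_score(count, np_docs) == pytest.approx(expected)


def test_phrase_score_zero_np_is_error():
    with pytest.raises(ValueError):
        ch.phrase_score(1, 0)


def test_phrase_score_linear_in_count():
    assert ch.phrase_score(20, 7) == pytest.approx(2 * ch.phrase_score(10, 7))


# ---------------------------------------------------------------------------
# idio score
# ---------------------------------------------------------------------------

def test_idio_unique_phrase_reduction():
    sc = 0.8
    assert ch.idio_score(sc, sc, 50) == pytest.approx(10 * math.log(1 + sc / 50))


def test_idio_natural_log_example():
    assert ch.idio_score(1.0, 1.0, 100) == pytest.approx(0.0995, abs=5e-5)


def test_idio_log_base_switch():
    nat = ch.idio_score(1.0, 1.0, 100)
    b10 = ch.idio_score(1.0, 1.0, 100, log_base=10)
    assert b10 == pytest.approx(nat / math.log(10))


def test_idio_dilution_limit():
    assert ch.idio_score(0.5, 1e9, 10) < 1e-8


def test_idio_zero_sc():
    assert ch.idio_score(0.0, 1.0, 10) == 0.0


def test_idio_invalid_inputs():
    with pytest.raises(ValueError):
        ch.idio_score(1.0, 0.0, 10)
    with pytest.raises(ValueError):
        ch.idio_score(1.0, 1.0, 0)


@given(st.floats(0.01, 10), st.floats(1, 1e4), st.integers(1, 10_000))
def test_idio_strictly_decreasing_in_sctot(sc, sctot_factor, nptot):
    sctot = sc * sctot_factor
    assert ch.idio_score(sc, sctot, nptot) >= ch.idio_score(sc, sctot * 1.5, nptot)


# ---------------------------------------------------------------------------
# central papers
# ---------------------------------------------------------------------------

def test_central_papers_star():
    docs = [Document(f"d{k}", year=2019) for k in range(5)]
    edges = [("d0", f"d{k}", 0.5) for k in range(1, 5)]
    core, reviews = ch.central_papers(docs, edges)
    assert core[0].doc_id == "d0"
    assert core[0].score == 1.0
    assert reviews == []


def test_central_papers_all_reviews():
    docs = [Document(f"d{k}", year=2019, doc_types={"review"}) for k in range(3)]
    edges = [("d0", "d1", 1.0), ("d1", "d2", 0.5)]
    core, reviews = ch.central_papers(docs, edges)
    assert core == []
    assert [r.doc_id for r in reviews] == ["d1", "d0", "d2"]


def test_central_papers_matches_brute_force():
    rng = np.random.default_rng(0)
    docs = [Document(f"d{k:02d}", year=2019) for k in range(30)]
    edges = []
    for a in range(30):
        for b in range(a + 1, 30):
            if rng.random() < 0.3:
                edges.append((f"d{a:02d}", f"d{b:02d}", float(rng.random())))
    core, _ = ch.central_papers(docs, edges, n_core=30)
    strength = {d.doc_id: 0.0 for d in docs}
    for i, j, w in edges:
        strength[i] += w
        strength[j] += w
    expected = sorted(strength, key=lambda d: (-strength[d], d))
    assert [c.doc_id for c in core] == expected
    mx = max(strength.values())
    for c in core:
        assert c.score == pytest.approx(strength[c.doc_id] / mx)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def test_top_descriptors_mesh_counting():
    docs = [Document("a", mesh_terms=["A", "B"]),
            Document("b", mesh_terms=["A"]),
            Document("c", mesh_terms=["C"])]
    assert ch.top_descriptors(docs, "mesh") == [("A", 2), ("B", 1), ("C", 1)]


def test_top_descriptors_empty():
    assert ch.top_descriptors([], "journal") == []


def test_top_descriptors_author_cpp():
    docs = [Document("a", authors=["x"], metrics={"cites": 4}),
            Document("b", authors=["x"], metrics={"cites": 6})]
    assert ch.top_descriptors(docs, "author") == [("x", 2, 5.0)]


def test_top_descriptors_unknown_key():
    with pytest.raises(ValueError):
        ch.top_descriptors([], "color")


# ---------------------------------------------------------------------------
# cluster metrics
# ---------------------------------------------------------------------------

def test_mean_cites():
    docs = [Document("a", year=2019, metrics={"cites": 4}),
            Document("b", year=2018, metrics={"cites": 6})]
    out = ch.cluster_metrics(docs, [], window=(2015, 2019))
    assert out["cpp"] == 5.0


def test_growth_closed_form_without_smoothing():
    assert ch.growth_rate(100, 200, smooth=0.0) == pytest.approx(
        2 ** (1 / 3) - 1, abs=1e-6)


def test_growth_smoothing_protects_zero():
    assert ch.growth_rate(0, 7, smooth=1.0) == pytest.approx(8 ** (1 / 3) - 1)


def test_vitality_one_year_old_references():
    docs = [Document("a", year=2019), Document("b", year=2019)]
    cited = Document("c", year=2018)
    cites = [CitationEdge("a", "c"), CitationEdge("b", "c")]
    out = ch.cluster_metrics(docs, cites, window=(2015, 2019),
                             doc_years={"c": 2018})
    assert out["vitality"] == 1.0


def test_reference_age_floor():
    docs = [Document("a", year=2018)]
    cites = [CitationEdge("a", "c")]
    out = ch.cluster_metrics(docs, cites, window=(2015, 2019),
                             doc_years={"c": 2019})  # citing an "older" year
    assert out["vitality"] == 1.0  # age floored at 1


def test_empty_window_all_null():
    docs = [Document("a", year=2000)]
    out = ch.cluster_metrics(docs, [], window=(2015, 2019))
    assert all(v is None for v in out.values())


def test_author_thresholds_and_age():
    docs = [Document(f"d{k}", year=2018, authors=["w"] + (["v"] if k < 2 else []))
            for k in range(5)]
    out = ch.cluster_metrics(docs, [], window=(2015, 2019), reference_year=2019)
    assert out["nauth2"] == 2  # w (5 papers) and v (2 papers)
    assert out["nauth5"] == 1  # only w
    assert out["age"] == pytest.approx(1.0)


def test_flag_fractions_and_doc_types():
    docs = [Document("a", year=2019, metrics={"industry_flag": 1},
                     doc_types={"review"}),
            Document("b", year=2019, metrics={"industry_flag": 0},
                     doc_types={"clinical-trial"})]
    out = ch.cluster_metrics(docs, [], window=(2015, 2019))
    assert out["ind_fr"] == 0.5
    assert out["rev_fr"] == 0.5
    assert out["trl_fr"] == 0.5


# ---------------------------------------------------------------------------
# percentiles
# ---------------------------------------------------------------------------

def test_percentiles_distinct_values():
    out = ch.percentile_ranks({1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0})
    assert out == {1: 25.0, 2: 50.0, 3: 75.0, 4: 100.0}


def test_percentiles_all_ties_midrank():
    out = ch.percentile_ranks({k: 7.0 for k in range(4)})
    assert set(out.values()) == {62.5}


def test_percentiles_single_value():
    assert ch.percentile_ranks({"only": 3.2}) == {"only": 100.0}


def test_percentiles_nulls_stay_null():
    out = ch.percentile_ranks({1: None, 2: 5.0, 3: 1.0})
    assert out[1] is None
    assert out[2] == 100.0 and out[3] == 50.0


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
def test_percentiles_monotone_and_max_100(values):
    d = dict(enumerate(values))
    out = ch.percentile_ranks(d)
    mx = max(values)
    if sum(1 for v in values if v == mx) == 1:  # tied maxima midrank below 100
        for k, v in d.items():
            if v == mx:
                assert out[k] == pytest.approx(100.0)
    for a in d:
        for b in d:
            if d[a] < d[b]:
                assert out[a] < out[b]


# ---------------------------------------------------------------------------
# overlay
# ---------------------------------------------------------------------------

def _assignment(groups):
    a = ClusterAssignment()
    for cid, members in groups.items():
        for m in members:
            a[m] = DocAssignment(level5=cid, level4=1, level3=1)
    return a


def test_overlay_counts_and_fractions():
    a = _assignment({1: [f"a{k}" for k in range(10)],
                     2: [f"b{k}" for k in range(100)]})
    subset = {"a0", "a1", "a2", "b0", "b1"}
    results, passing = ch.overlay(subset, a, min_count=25, min_fraction=0.10)
    by = {r.cluster: r for r in results}
    assert (by[1].subset_count, by[1].subset_fraction) == (3, pytest.approx(0.3))
    assert (by[2].subset_count, by[2].subset_fraction) == (2, pytest.approx(0.02))
    assert passing == set()  # thresholds (25, 0.10) not met


def test_overlay_thresholds():
    a = _assignment({1: [f"a{k}" for k in range(40)]})
    subset = {f"a{k}" for k in range(30)}
    _, passing = ch.overlay(subset, a, min_count=25, min_fraction=0.10)
    assert passing == {1}


def test_overlay_empty_subset():
    a = _assignment({1: ["x"], 2: ["y"]})
    results, passing = ch.overlay(set(), a)
    assert all(r.subset_count == 0 for r in results)
    assert passing == set()


def test_overlay_conservation():
    a = _assignment({1: [f"a{k}" for k in range(5)],
                     2: [f"b{k}" for k in range(5)]})
    subset = {"a0", "a1", "b3", "nope"}
    results, _ = ch.overlay(subset, a)
    assert sum(r.subset_count for r in results) == 3  # "nope" ignored
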