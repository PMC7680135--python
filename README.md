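# litmap

Hybrid citation + text document clustering, mapping and cluster
characterization for bibliographic corpora.

`litmap` builds a topic model of a document corpus in four stages:

1. **Relatedness** — combines direct-citation relatedness
   (`r_dc = max(c_ij, c_ji)` with `c_ij = 1/nref(i)`) and max-normalized
   text-similarity scores truncated to each document's top 20 partners
   into a hybrid edge weight `r_hyb = α·r_dc + (1−α)·r_sa`. Citation-only
   pairs receive an imputed text score (half the smaller endpoint minimum)
   and `α` is calibrated so summed citation and text contributions are
   equal (50:50).
2. **Clustering** — a three-level nested partition via the Leiden
   algorithm (constant-Potts quality, resolution per level), minimum
   cluster sizes enforced by strongest-neighbor merging, coarser levels
   built from the size-normalized aggregated cluster graph so nesting is
   guaranteed. Degenerate clusters (errata titles, missing abstracts with
   few references) are flagged and removed whole.
3. **Map** — cluster-cluster relatedness `R = Σ r_hyb / √(N_m·N_n)`,
   filtered to each cluster's top 15 neighbors, laid out with a seeded
   force-directed schedule with a late edge-cut knob, and colored by the
   plurality field of each cluster's journals.
4. **Characterization** — per-cluster bootstrap noun-phrase scores
   (`sc = count/(20·np/3)`), idiosyncratic phrase re-ranking
   (`idio = 10·log(1 + sc/nptot)·sc/sctot`), central papers and reviews by
   within-cluster relatedness, top MeSH/journal/category/author lists, a
   20-indicator suite (impact, funding, document types, authorship, age,
   vitality, growth) with percentile ranks, and external-subset overlays —
   written as TSV workbook sheets (CLUST, COUNT, PHRASE, IDIO, MESH, JNL,
   AUTH, CORE, REVIEW, QUERY, …).

A synthetic-corpus generator with planted topic structure (topic-
concentrated citations and similarity scores, topic vocabulary emitted
pre-POS-tagged, authors, years, metrics) makes the whole pipeline testable
offline, scored by adjusted Rand index / NMI against the planted topics.

## CLI

```bash
litmap simulate   --config cfg.yaml --seed 1 --out-dir run   # synthetic corpus
litmap build      --config cfg.yaml --seed 1 --out-dir run   # edges + clusters
litmap map        --config cfg.yaml --seed 1 --out-dir run   # layout + fields
litmap characterize --config cfg.yaml --seed 1 --out-dir run # workbook sheets
litmap evaluate   --config cfg.yaml --seed 1 --out-dir run   # ARI/NMI vs truth
litmap report     --out-dir run                              # print manifest
```

The YAML config is optional; every key has a default (top-20 similarity
truncation, top-15 cluster neighbors, layout edge cut 0.7, 20 bootstrap
samples of one third, three-level resolutions/minimum sizes). Example:

```yaml
synthetic: {n_topics: 10, docs_per_topic: 50}
levels:
  - {resolution: 1.0e-3, min_size: 75}
  - {resolution: 1.0e-4, min_size: 150}
  - {resolution: 1.0e-5, min_size: 400}
relatedness: {alpha: calibrate, sa_top_k: 20}
```

Real corpora are read from TSV/JSON-lines inputs (documents, a
`citing_id → cited_id` edge list, an `id_a, id_b, score` similarity list,
an optional journal→field map and excluded-journal list); see
`litmap.corpus_io` for the exact schemas. Each stage appends counts,
seeds and the calibrated α to `manifest.json`, and re-running a stage
with the same inputs and seed reproduces byte-identical artifacts.

## Layout

```
src/litmap/
  corpus_io.py      data model, readers, workbook-style TSV writers
  relatedness.py    DC + SA normalization, imputation, α calibration, hybrid
  clustering.py     Leiden levels, min-size merging, nesting, degeneracy rules
  cluster_graph.py  cluster relatedness, top-k filter, layout, field coloring
  characterize.py   phrases, idio, central papers, indicators, percentiles
  synthetic.py      planted-topic corpus generator + recovery scoring
  cli.py            pipeline driver
tests/              pytest suite incl. test_acceptance.py (criteria 1–5)
scripts/acceptance.py
```
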