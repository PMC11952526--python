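# geoseek

Content-based discovery of gene-expression data series from repository
metadata.

## The problem

Public repositories such as Gene Expression Omnibus (GEO) hold hundreds of
thousands of transcriptomic data series, described by ad hoc free text
(title, summary, overall design). A researcher who has already found a few
series relevant to a topic — say, juvenile idiopathic arthritis — usually
wants more, but keyword search over inconsistent descriptions misses
relevant studies and returns irrelevant ones. `geoseek` implements a
semantic alternative: summarize each series' description as a
fixed-dimension vector (an embedding), average the vectors of the
known-relevant *reference set* into a query profile, and rank every
candidate series by cosine similarity to that profile,

```
score(d) = cos(v̄_ref, v_d) = (v̄_ref · v_d) / (‖v̄_ref‖ ‖v_d‖),
v̄_ref = (1/k) Σᵢ v_rᵢ .
```

The package provides the full workflow around that core:

* **metadata ingest** — series records from a SOFT-style key-value format,
  canonical JSON, or TSV, plus the standard inclusion filters for human
  transcriptomic series (not retired, *Homo sapiens*, array profiling on
  Affymetrix/Illumina/Agilent or high-throughput sequencing on Illumina,
  not a subseries);
* **text preprocessing** — HTML/URL stripping, lowercasing, punctuation
  removal, optional stop-word filtering, and overlapping 256-character
  chunking (20-character overlap) with chunk-embedding averaging;
* **embedding** — a one-function embedder contract with a deterministic
  built-in backend (signed feature-hashing bag of words) and a registry for
  external model adapters;
* **evaluation harness** — the reference/comparison-set experimental
  design, average precision (AUPRC) under class imbalance, recall@n,
  imbalance-ratio sweeps, and cross-condition median-rank model comparison;
* **synthetic corpus generator** — condition-annotated series with a
  tunable lexical signal, so the entire pipeline is testable offline.

## Worked example

Generate a small corpus of 3 conditions × 8 series plus 60 background
series, embed it, and search with four known-relevant series as references:

```bash
geoseek synth --out corpus --seed 11 --conditions 3 \
    --series-per-condition 8 --background 60 --signal 0.8
geoseek embed --input corpus/series.json --out embeddings.tsv \
    --dimension 1024 --seed 11
awk -F'\t' '$1=="cond01"{print $2}' corpus/annotations.tsv | head -4 > refs.txt
geoseek rank --embeddings embeddings.tsv --references refs.txt \
    --out ranked.tsv --embedder hashed-bow-1024 --seed 11
head -8 ranked.tsv
```

```
# embedder=hashed-bow-1024	chunking=false	seed=11
rank	accession	score
1	GSE9000016	0.3583566001729813
2	GSE9000015	0.34196785653215794
3	GSE9000013	0.3334235087261187
4	GSE9000014	0.2690472557650453
5	GSE9000084	0.11118739749916519
6	GSE9000043	0.0935816541791462
```

Condition `cond01` has eight members; four served as references, and the
other four (`GSE9000013`–`GSE9000016`) are exactly the top four results —
their descriptions share the condition's vocabulary, so their embeddings
sit closest to the averaged reference profile. The score column is cosine
similarity; the sharp drop after rank 4 separates the relevant series from
background ones.

The benchmark harness scores such rankings systematically:

```bash
geoseek evaluate --embeddings embeddings.tsv \
    --annotations corpus/annotations.tsv --seed 0 --seed 1 --ratio all --out eval
head -4 eval/results.tsv
```

```
model	condition	seed	imbalance_ratio	auprc
hashed-bow	cond00	0	all	1.0
hashed-bow	cond00	1	all	1.0
hashed-bow	cond01	0	all	1.0
```

For each condition and seed, half the annotated series become the
reference set and the other half are hidden among all remaining series;
AUPRC = 1.0 means every hidden relevant series outranked every
non-relevant one. `geoseek imbalance` repeats the evaluation while
subsampling the non-relevant pool to fixed multiples (1×, 10×, 100×, all)
of the relevant test-set size.

## Library use

```python
from geoseek import CorpusConfig, benchmark_synthetic

results = benchmark_synthetic(CorpusConfig(signal=0.5, seed=0),
                              dimension=4096, seeds=(0, 1, 2))
print({(r.condition, r.seed): round(r.auprc, 3) for r in results})
```

See `docs/methods.md` for the model, the evaluation design, parameter
defaults, and known limitations.
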