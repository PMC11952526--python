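# Methods

## Retrieval model

The unit of retrieval is a *series*: one study record with free-text
metadata. Each series' document is its title, summary, and overall design
(when present), joined in that order. Retrieval assumes a researcher
supplies k known-relevant series (the reference set); the system embeds
every document as a fixed-dimension vector v ∈ ℝᵈ, forms the query profile
v̄ = (1/k) Σ v_rᵢ, and ranks every other series by cosine similarity
cos(v̄, v_d). Cosine is scale-invariant per comparison, so document length
affects only the direction, not the magnitude, of the score.

Two scoring back ends ship with the package:

* **Hashed bag of words** (default). Every whitespace token of the clean
  text is hashed with a keyed 64-bit hash (BLAKE2b, key = seed) to a
  coordinate in [0, d) and a sign in {−1, +1}; the document vector is the
  signed accumulation of token counts. This is the classic feature-hashing
  ("hashing trick") vectorizer: deterministic, dependency-free, and at
  d = 4096 unrelated vocabularies map to nearly orthogonal directions, so
  cosine similarity approximates lexical overlap. It is a real (if simple)
  semantic-free retrieval model, and it is the back end all offline tests
  and benchmarks use.
* **Word overlap baseline**: the number of unique words shared by two
  documents. For a multi-document reference the default profile is the
  union of the reference texts' unique words (mirroring the averaged
  embedding); a pairwise-max variant is available.

External embedding models (transformer sentence encoders, static word
vectors, remote APIs) plug into the same one-function contract — clean text
in, fixed-dimension vector out — through a registry (`register_embedder` or
a `module:callable` entry string). The core package never imports them, so
nothing requires network access or model weights.

### Ties and determinism

All rankings sort by descending score with ties broken by ascending
accession. Every random choice (splits, subsamples, hashing) flows from an
explicit integer seed; rerunning any stage with the same configuration
reproduces byte-identical output files.

## Text preprocessing

Cleaning applies a fixed rule order: HTML-tag strip (regex over `<...>`
spans), URL removal (`http(s)://`, `ftp://`, or `www.`-prefixed tokens),
lowercasing, replacement of every non-alphanumeric character by a space,
whitespace collapse, then optional stop-word removal. Order matters (URL
removal must precede punctuation stripping or URLs dissolve into ordinary
tokens), so one canonical order is mandated. Non-alphanumeric characters
become spaces rather than being deleted, keeping hyphenated compounds as
separate words ("T-cells" → "t cells") instead of fusing them.
Alphanumeric status is decided per Unicode category, so accented names
survive. Cleaning is idempotent; property-based tests fuzz this with
adversarial tags, URLs, and Unicode punctuation.

Stop-word removal is a per-embedder policy: bag-style models (hashed BoW,
word overlap) drop stop words because they carry no lexical signal for
set/count similarity; context-sensitive models keep them. The English
stop-word list ships as a plain text file and can be replaced per run.

### Chunking

Documents longer than a 256-character threshold can be split into
overlapping character windows for back ends with short input limits: window
length 256, stride 236 (20 characters of consecutive-window overlap), the
final window truncated at the text end. The window length equals the
threshold — the simplest consistent choice. The document embedding is then
the unweighted mean of the chunk embeddings (length-weighting was
considered and rejected as the default: the averaged-profile query is also
unweighted). Chunking is off by default for the built-in back end — a bag
of words is order- and window-insensitive, so chunk-averaging only
re-weights tokens shared by overlap regions — and exists primarily for
external adapters; both paths are exercised by tests either way.

## Evaluation design

For each condition with n annotated series and each seed:

1. Uniformly partition the n series into a reference set (⌈n/2⌉) and
   comparison set A (⌊n/2⌋) — the reference set gets the extra member when
   n is odd.
2. Comparison set B is the rest of the evaluated corpus (every candidate
   not annotated with the condition), optionally subsampled to an
   *imbalance ratio* r: round(r·|A|) members, round-half-to-even. The
   sentinel "all" keeps the whole pool.
3. Rank A ∪ B against the averaged reference embedding and score the
   ranking by where A's members land.

**Average precision** is the AUPRC estimator: AP = (1/P) Σ_{positives at
rank k} (hits(k)/k), the exact area under the precision-recall step curve
of a ranked binary list. It is interpolation-free and has a brute-force
oracle, which the tests exploit (exhaustive agreement over all 2¹⁰ label
vectors of length 10, plus a cross-check against scikit-learn's
implementation). **Recall@n** is the fraction of positives in the top n.
The **median-rank table** ranks models within each condition by descending
AUPRC (midranks for ties) and orders models by their median rank across
conditions. **Spearman's ρ** (midranks, via scipy) supports descriptive
correlations such as AUPRC versus embedding dimension; significance
testing is deliberately out of scope.

### Imbalance subsampling is nested

`subsample_imbalance` permutes the sorted pool once per seed and takes a
prefix of the required size. Each subset is uniformly random at its size,
and for a fixed seed the subsets at ratios 1 < 10 < 100 < "all" are nested.
Nesting makes ratio comparisons paired: adding distractors to a fixed
ranking can only demote positives, so per-seed AUPRC is monotonically
non-increasing in the ratio by construction, and the benchmark measures how
fast it degrades rather than re-randomizing the pool at every ratio. One
subsample per (condition, ratio, seed) is shared across models for
comparability.

### Chance level

The expected AP of a uniformly random ranking of P positives among N items
exceeds the prevalence P/N for small P (the first positive's precision has
a heavy right tail). The package's reference point is the exact
expectation, enumerated over the order-statistic distribution of positive
positions: E[AP] = (1/P) Σᵢ Σₖ (i/k)·C(k−1,i−1)C(N−k,P−i)/C(N,P). For 6
positives among 566 candidates this is 0.0210 (prevalence 0.0106); for 5
among 500, 0.0215 (prevalence 0.0100). Zero-signal benchmarks are
calibrated against this value.

## Synthetic corpus

The generator emulates a condition-annotated metadata corpus. Each
condition owns a private token vocabulary, disjoint from all others and
from a shared background vocabulary. A condition series draws each of its
L tokens (L uniform in a configured range) from its condition vocabulary
with probability `signal`, otherwise from the background; unannotated
background series draw all tokens from the background. Tokens are i.i.d. —
no grammar — because the retrieval methods under test are bag-like, so a
lexical mixture suffices to emulate how distinctive a condition's language
is. An optional near-miss mode adds confuser conditions sharing a fraction
of a target condition's vocabulary, emulating clinically overlapping
conditions (off by default).

Defaults (chosen once, as study conditions): 6 conditions × 12 series
(the number of evaluated conditions, and the size of the smallest), 500
background series, background vocabulary 2,000 tokens, condition
vocabularies 100 tokens, signal 0.75, lengths 15–60 tokens (~120–480
characters of clean text, straddling the 256-character chunking threshold
so both chunked and unchunked paths run).

What the generator does **not** emulate: real biomedical language
(synonyms, abbreviations, polysemy), curator disagreement or annotation
errors, correlated document structure, and realistic vocabulary overlap
between related conditions (except the stylized near-miss mode).
Consequently, passing benchmarks show the pipeline's machinery is correct
and well-calibrated — splits, ranking, metrics, imbalance behaviour — but
say nothing about how any particular language model handles real
repository text.

## Problem sizes

The offline benchmarks run at the defaults above: corpus 572 series
(660 for imbalance sweeps, whose 100× ratio needs a pool of 600), hash
dimension 4096, 10 replicates for signal recovery, 20 for zero-signal
calibration, 3 for the imbalance sweep, 200 shuffles for the
random-ranking calibration. At these sizes the full suite and the
reproduction script each complete in seconds on one CPU.

## Numerical and degenerate-input choices

* A zero-norm embedding (empty document under a bag model) raises a
  degenerate-embedding error naming the offending accession rather than
  returning NaN.
* Embeddings are **not** L2-normalized before reference averaging; cosine
  is scale-invariant per pair, but averaging is not, so normalization
  changes multi-reference profiles. Unnormalized is the default (plain
  averaging of raw embeddings); callers can normalize vectors before
  passing them in.
* `round(ratio × |A|)` uses round-half-to-even (Python/IEEE default).
* Records missing a criterion-relevant field (no organisms, no vendor)
  fail that inclusion criterion — conservative exclusion.
* Vendor information is absent from SOFT-style series blocks (they carry
  platform accessions), so the SOFT reader takes an optional
  platform→vendor mapping file; the canonical JSON/TSV dialects carry the
  vendor explicitly.

## Known limitations

* The built-in back end measures lexical, not semantic, similarity;
  synonym-heavy or paraphrased descriptions require an external embedding
  adapter.
* Ranking is exact (full scan); no approximate nearest-neighbor index is
  provided, which is fine at repository-metadata scale (10⁵ documents,
  d ≤ 4096) but not beyond.
* The word-overlap baseline's multi-reference rule (union of unique words)
  is one of several defensible choices; pairwise-max is provided as an
  alternative.
* Condition annotations are treated as complete ground truth; series
  relevant-but-unannotated count as negatives, which underestimates real
  retrieval quality.
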