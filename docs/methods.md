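# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `conceptvec`, in the order the pipeline runs.

## Preprocessing

Sentences are split on terminator runs (`.!?` plus closing brackets)
followed by whitespace and an upper-case letter or digit, with an
abbreviation stop-list (`e.g.`, `et al.`, `fig.` …) suppressing false
boundaries.  Token normalization keeps letters, digits and `_`, keeps `-`
between alphanumerics and `.` between digits (gene symbols and dosages
survive), deletes everything else, lowercases, and lemmatizes.

The lemmatizer is a deliberately small rule-based English suffix stripper
(plural `-s`/`-es`/`-ies`, `-ing`, `-ed`, with guards), applied to a
fixpoint, and pluggable.  The contract downstream stages rely on is not
linguistic accuracy but **idempotence** (`normalize∘normalize =
normalize`) and **determinism** — the same normalizer must run at training
and query time or vocabulary lookups break.  Exact token-level parity with
any industrial NLP toolkit is explicitly not a goal; an adapter can be
plugged in via `Normalizer(lemmatizer=...)`.

Stop-word removal is **not** applied when building training corpora; the
shipped stop-list is applied only in the sentence-similarity path, where
function words otherwise dominate the transport/averaging mass.  Both are
configurable.

## Corpus augmentation

Three variants per input sentence feed training:

1. the base normalized sentence (always);
2. a joined variant — entity mentions first (annotated character spans are
   mapped to token runs via per-token source ranges and fused with `_`),
   then collocation joining over the remaining tokens — emitted when it
   differs from the base;
3. an identifier variant replacing each annotated run with
   `<entity-type>_<entity-id>` (type from the closed set {gene, disease,
   chemical, mutation, species}; identifier lowercased, non-alphanumerics
   to `_`, idempotent re-rendering) — emitted when it differs.

With `separate_variants` the entity-joined and bigram-joined variants are
emitted as two sentences instead of one combined; the combined default
keeps the expansion factor at `1 + P(joined differs) + P(id differs)` ≈ 2
on half-annotated corpora.

Collocations are scored with the count-based score
`score(a,b) = (c(a,b) − δ)·N/(c(a)·c(b))` over adjacent pairs, where N is
the distinct-token count and δ (default 5) a minimum-count discount; pairs
scoring ≥ τ are fused left-to-right greedily, in a single non-recursive
pass (n-grams longer than 2 come from entity annotations, not from
repeated phrase passes).  τ defaults to 1 when building training data and
5 at query time — the unbounded count-based scale is what makes those two
values meaningful.  A consequence worth knowing: an always-adjacent pair
has `score ≈ N/c`, so collocations whose count approaches the vocabulary
size fall back below τ=1; at desk scale the synthetic generator keeps
planted collocation counts an order of magnitude below N.

Overlapping annotation spans are resolved longest-first (ties: earlier
start).  Spans overlapping no token are counted and skipped.  Shuffling is
a seeded permutation over fixed-size buffers (whole corpus when it fits).

## Trainer

Subword skip-gram with negative sampling, written against a numba kernel
(single-threaded, bit-reproducible for a fixed seed; `workers` is accepted
as a capacity knob but training is sequential).

* Representation: a token's vector is the **mean** of its own input vector
  and its hashed character n-gram vectors (lengths minn=3..maxn=6 over the
  boundary-padded token, FNV-1a 32-bit hash mod `bucket_count`).  The mean
  (rather than the sum) keeps magnitudes comparable across tokens with
  different n-gram counts.  The composed mean is also what the model
  stores as its query vectors — the raw input vectors alone carry only a
  fraction of the learned signal, since gradients are spread over all of a
  token's parts.
* Objective: `ℓ = −log σ(u_o·h) − Σ log σ(−u_n·h)` per (center, context)
  pair with k negatives drawn ∝ count^0.75 (a drawn negative equal to the
  context token is skipped).  Gradients of this exact expression are
  applied to the context vectors and distributed as `g/m` over the m
  parts of the center representation; `skipgram_loss_and_grads` is the
  float64 reference implementation the tests check against finite
  differences.
* Window: half-width resampled per center position uniformly in
  {1..window} (dynamic window).
* Down-sampling: keep probability `min(1, (√(f/t)+1)·t/f)` per occurrence;
  a dropped occurrence keeps its position (it vacates the context slot but
  still affects distances), as do tokens below `min_count`.  This
  position-preserving treatment is a documented divergence from
  implementations that compact sentences before windowing.
* Learning rate: linear decay from `alpha` to `min_alpha` over
  `epochs × corpus positions`.
* Initialization: input and bucket vectors uniform in ±0.5/dim from one
  seeded generator; context vectors zero.

Full-scale defaults (α=0.03, min α=1e-4, k=5 negatives, window 20,
dim 152, n-grams 3–6, min_count 5, ns_exponent 0.75, sample 1e-5,
5 epochs, 2²¹ buckets) are the shipped `TrainingConfig`.  Desk-scale
experiments use `desk_scale_config()`: dim 32, window 5, 2¹⁵ buckets, and
sample 1e-3 — at toy vocabulary sizes (~450 types) every token's relative
frequency is far above 1e-5, which would discard nearly all occurrences.
All other values keep their full-scale defaults.

## Vector store

Nearest-neighbor search is one matrix–vector product over the (norm-
cached) vocabulary matrix, with optional token-prefix filtering (e.g.
`gene_` to retrieve only gene concepts) and lexicographic tie-breaking for
reproducibility.  Multi-word query terms are normalized and `_`-joined
into one candidate token; **a term is out-of-vocabulary iff that joined
form is absent from the vocabulary** — subword composition still yields a
usable fallback vector (mean of component-token vectors) but never changes
the OOV accounting, which is vocabulary-membership-based by design.

PCA neighborhood projection mean-centers the selected vectors and projects
onto the top-2 right singular vectors, with each component's largest-
magnitude loading forced positive so plots are reproducible.

Compression keeps the top-K tokens by training frequency (ties:
lexicographic), leaves surviving vectors untouched, keeps token
frequencies (needed for SIF weighting), and by default drops the subword
bucket table — the compressed artifact loses composition for unseen
tokens, which is the expected cost of the size reduction; a flag retains
the buckets.

## Sentence similarity

Preparation mirrors training preprocessing, then removes stop-words,
optionally joins annotated entities, joins collocations at τ=5, and
resolves every token (subword composition allowed; unresolvable tokens
dropped and counted).

* SIF: sentence vector `(1/n) Σ A/(A+p(w)) · v_w` with A = 3e-4 and p(w)
  the relative training-corpus frequency; unseen tokens get the minimum
  observed p(w) (the most conservative, highest weight).  Common-component
  removal (subtracting the batch's first principal component) is
  implemented but **off by default**; it is a batch-level operation that
  changes scores depending on what else is in the batch, and the default
  protocol here scores pairs independently.
* WMD: exact optimal transport between the two sentences' normalized
  bags-of-words, Euclidean ground metric, solved as a transportation LP
  with HiGHS (sentence supports are ≤ ~50 tokens, so exactness is cheap).
  One marginal constraint is dropped for rank; the reported objective is
  clamped at 0.  Greedy nearest-neighbor relaxations are used in tests
  only, as lower-bound oracles.

WMD is reported as a distance; the evaluation harness negates distance-
kind scores (model and, when declared, human) before computing Pearson r
so correlations are comparable across scorers.

## Evaluation harness

Concept benchmarks: both terms resolved (surface form, or identifier
columns in ontology mode, optionally routed through an external id→token
map — the harness never guesses mappings; unmapped ids count as OOV);
pairs with an OOV side are excluded; Pearson r over the rest; used +
excluded = total is asserted in tests.  Results with fewer than 3 usable
pairs or zero variance are flagged undefined, never reported as 0.  The
OOV ratio's denominator is **distinct terms**; mention-level counts are
also reported.

## Synthetic corpus generator

The generator defines the package's study conditions: 8 topics × 50
tokens with Zipf-like within-topic frequencies, 10 000 sentences of
Poisson length (mean 21), each token carrying a latent topic-affinity
vector (primary weight 1.0, one secondary topic 0.3); sentences draw a
topic and sample tokens by affinity.  Planted structure with exact truth
tables:

* synonym groups (identical latent vectors, hence exchangeable contexts);
* collocations (head token always followed by its tail; tails occur
  nowhere else, and entity insertion never splits a pair, so adjacency
  count = emission count exactly);
* entity mentions (2-token surfaces inserted into an exact
  `round(entity_rate·n)` subset of sentences, written as PubTator
  annotations with verified character offsets);
* pair benchmarks (human score = latent cosine + Gaussian noise, sd 0.1;
  optional fabricated OOV terms) and sentence benchmarks (score = 4 ×
  topic overlap + noise, clipped to [0,4]).

What it does **not** emulate: realistic biomedical morphology (token
names share systematic prefixes, so subword effects are stronger and more
uniform than in real text), polysemy, document structure beyond one
sentence per document, annotation noise, and real token frequency tails.
Passing desk-scale recovery therefore shows the pipeline's machinery is
correct and self-consistent — not that any particular correlation level
would be reached on PubMed-scale corpora.

## Numerical and degenerate-input choices

* Cosine is computed in float64 against stored float32 vectors, clamped to
  [−1,1]; zero vectors raise rather than returning 0.
* Ties in nearest-neighbor ranking, vocabulary ordering and compression
  all break lexicographically.
* Gradient checks use a 4th-order central-difference stencil (eps 1e-3),
  whose ~1e-12 truncation error leaves headroom under the 1e-6 relative
  tolerance; sigmoid losses are clamped at 1e-12 before logs in the
  kernel.
* Training raises on non-finite weights; empty vocabularies (over-
  aggressive `min_count`) raise with a diagnostic.
* An embedding model with no bucket table (compressed, or read from a bare
  word2vec text file) returns "absent" for unseen tokens instead of
  composing.

## Desk-scale problem sizes

Tests and the acceptance script run: 10k-sentence corpora (≈210k tokens),
dim 32, 5 epochs; 20-seed replications for synonym recovery and the
end-to-end study; 200-instance oracles for WMD and compression; 100
instances for gradient checks.  These sizes were chosen so the whole suite
replicates comfortably on one CPU while leaving the statistical checks
well-powered (binomial sd of the 20-seed win fraction ≈ 0.05; observed
end-to-end r ≈ 0.85–0.91 against a 0.4 recovery bar).

## Known limitations

* The rule-based lemmatizer over- and under-stems (e.g. `species` →
  `specy`); it is a contract-preserving default, not a linguistic claim.
* WMD cost grows quadratically in sentence support; the intended regime is
  single sentences, and performance on long paragraphs degrades by
  design of the method.
* Multi-worker training is not implemented; `workers` > 1 is accepted but
  runs sequentially.
* The phrase scorer joins only bigrams; longer collocations must come from
  entity annotations.
* Identifier variants depend entirely on the quality of the provided
  annotations; the package consumes PubTator files and never produces
  annotations itself.
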