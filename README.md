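# conceptvec

Biomedical concepts are rarely single words — *chronic fatigue syndrome*,
*Mycobacterium tuberculosis*, MeSH descriptor `D015673` — yet classic word
embeddings assign vectors to single tokens only.  `conceptvec` is a small,
CPU-only toolkit for building **concept** embeddings from biomedical text:
it fuses multi-word concepts into single tokens before training, gives
ontology identifiers (MeSH, NCBI gene, NCBI taxonomy) their own embeddings,
and provides the query and evaluation operations that make such a space
useful — nearest-concept search, concept similarity, sentence similarity,
model compression, and benchmark evaluation.

It is aimed at text-mining practitioners who need fast semantic search,
synonym suggestion, disease–gene/condition relatedness or entity linking
without transformer-scale infrastructure.

## What it does

1. **Preprocess** — sentence splitting, punctuation/special-character
   removal, lowercasing and (rule-based, pluggable) lemmatization,
   identical at training and query time.
2. **Augment** — each sentence is emitted in up to three variants:
   - the base token sequence;
   - a *joined* variant where annotated entity mentions (PubTator offset
     format) and statistically co-occurring bigrams are fused with `_`
     (`chronic_fatigue_syndrome`).  Collocations are scored with
     `score(a,b) = (c(a,b) − δ)·N / (c(a)·c(b))` and joined when the score
     reaches a threshold τ (τ=1 for training data, τ=5 at query time,
     δ=5);
   - an *identifier* variant where each mention is replaced by
     `<entity-type>_<entity-id>` (e.g. `species_9096`,
     `disease_mesh_d005356`), so ontology concepts are embedded jointly
     with free text.
3. **Train** — subword skip-gram with negative sampling: for center c and
   context o with k sampled negatives,
   `ℓ = −log σ(u_o·h_c) − Σᵢ log σ(−u_{nᵢ}·h_c)`, where `h_c` is the mean
   of the token's own vector and its hashed character n-gram vectors
   (lengths 3–6).  Negatives are drawn ∝ count^0.75, frequent tokens are
   down-sampled at threshold t, the window half-width is resampled
   uniformly in {1..W} per position, and the learning rate decays linearly.
   Single-worker runs are bit-reproducible given a seed.
4. **Query** — cosine similarity, top-k nearest concepts as one
   matrix–vector product with optional prefix filters (`gene_`,
   `disease_`...), subword composition for unseen tokens, 2-D PCA
   neighborhood projection, and top-K frequency compression.
5. **Sentence similarity** — SIF weighted averaging
   (`weight(w) = A/(A + p(w))`, A = 3e-4) with cosine, and exact Word
   Mover's Distance (transportation LP over the two sentences'
   normalized bags of words).
6. **Evaluate** — UMNSRS/MayoSRS-style concept benchmarks (cosine vs
   human judgement, Pearson r, OOV pairs excluded and counted) and
   BIOSSES-style sentence benchmarks (distances negated before
   correlating); OOV ratios over distinct terms.
7. **Synthesize** — a seeded generator of topic-structured corpora with
   planted synonyms, collocations, entity annotations and benchmarks, so
   the whole pipeline is testable at desk scale with known ground truth.

## Worked example

```bash
# generate a 10k-sentence synthetic corpus with planted structure
conceptvec synth --seed 7 --out work/

# collocation model, augmentation, training
conceptvec phrases --corpus work/corpus.txt --out work/phrases.pkl
conceptvec augment --corpus work/corpus.txt \
    --annotations work/annotations.pubtator \
    --phrases work/phrases.pkl --seed 7 --out work/augmented.txt
conceptvec train --corpus work/augmented.txt \
    --dim 32 --window 5 --sample 1e-3 --bucket-count 32768 \
    --seed 7 --out work/model.pkl

# evaluate concept similarity against the generated benchmark
conceptvec eval concepts --model work/model.pkl \
    --benchmark work/benchmark_pairs.tsv
```

The `eval concepts` step prints (stderr log plus a TSV row):

```
stage=eval_concepts pearson_r=0.8995921764392306 defined=True pairs_used=200 pairs_excluded=0 oov_ratio_pct=0.0 row_errors=0
```

i.e. the cosine similarities of the trained concept vectors correlate at
r ≈ 0.90 with the benchmark's "human" scores (which, for the synthetic
corpus, are the planted latent topic similarities plus noise), with no
benchmark term out of vocabulary.  Nearest-concept queries work the same
way on real models, e.g.
`conceptvec similar --model work/model.pkl --query "t3w00" -k 10` or, on a
corpus with identifier variants, `--filter gene_` to retrieve only gene
concepts.

## Layout

- `src/conceptvec/preprocess.py` — splitting + normalization
- `src/conceptvec/corpus_io.py` — PubTator, benchmark TSV, corpus and
  word2vec-text vector I/O
- `src/conceptvec/augment.py` — phrase model, entity joining, identifier
  variants, corpus augmentation
- `src/conceptvec/trainer.py` — subword skip-gram / negative sampling
- `src/conceptvec/vectorstore.py` — lookup, nearest neighbors, PCA,
  compression
- `src/conceptvec/sentsim.py` — SIF and Word Mover's Distance
- `src/conceptvec/evalharness.py` — benchmark protocols
- `src/conceptvec/synthcorpus.py` — synthetic corpus generator
- `src/conceptvec/cli.py` — command-line interface
- `docs/methods.md` — models, parameters, design decisions, limitations
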