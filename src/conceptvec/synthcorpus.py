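"""Seeded synthetic corpora with planted, recoverable structure.

The generator emulates the statistical structure the pipeline assumes of
biomedical text, at desk scale and with full ground truth:

* topic-mixture sentences — each token carries a latent topic-affinity
  vector; a sentence draws a topic and samples tokens by affinity, so
  context-prediction training can recover topical relatedness;
* planted synonym groups — token sets sharing identical latent vectors and
  hence exchangeable topic-conditional distributions;
* planted collocations — head/tail token pairs always emitted adjacently,
  so their bigram adjacency count equals the head's emission count exactly;
* entity mentions — multi-token surface runs inserted into a controlled
  fraction of sentences and written out as PubTator-format annotations with
  exact character offsets;
* pair and sentence benchmarks whose "human" scores are latent similarity
  (cosine of topic vectors / topic overlap) plus Gaussian noise.

Truth tables are first-class outputs so test oracles never re-derive
hidden state.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from conceptvec.errors import ContractViolation
from conceptvec.types import (
    AnnotatedSpan,
    BenchmarkRecord,
    Document,
    PairBenchmark,
    Sentence,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_pair_benchmark",
    "generate_sentence_benchmark",
]

_ENTITY_TYPE_CYCLE = ("disease", "gene", "species", "chemical")


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults are the package's study conditions.

    Defaults: 8 topics x 50 tokens, 10 000 sentences averaging 21 tokens
    (the corpus scale every desk-scale experiment in this package uses),
    10 two-member synonym groups, 5 always-adjacent collocations, 30% of
    sentences carrying one annotated entity mention, benchmark noise
    sd 0.1 on latent similarities in [0, 1].
    """

    n_topics: int = 8
    vocab_per_topic: int = 50
    n_sentences: int = 10_000
    sentence_length_mean: float = 21.0
    n_synonym_groups: int = 10
    synonym_group_size: int = 2
    n_collocations: int = 5
    entity_rate: float = 0.3
    n_entities: int = 8
    entity_surface_len: int = 2
    benchmark_noise_sd: float = 0.1
    secondary_topic_weight: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.entity_rate <= 1):
            raise ContractViolation("entity_rate must be in [0, 1]")
        if self.n_topics < 2 or self.vocab_per_topic < 2:
            raise ContractViolation("need >= 2 topics and >= 2 tokens per topic")


@dataclass
class SyntheticCorpus:
    """Generated corpus plus ground truth."""

    spec: SyntheticSpec
    sentences: list[list[str]]                 # token sequences
    documents: list[Document]                  # PubTator-style docs, 1/sentence
    annotated: np.ndarray                      # bool per sentence
    token_theta: dict[str, np.ndarray]         # latent topic-affinity vectors
    synonym_groups: list[tuple[str, ...]]
    collocations: list[tuple[str, str]]
    collocation_counts: dict[tuple[str, str], int]
    entity_catalog: list[tuple[tuple[str, ...], str, str]]
    entity_events: list[tuple[int, int, int, str, str]]  # sent, lo, hi, type, id
    sentence_topics: np.ndarray

    @property
    def raw_lines(self) -> list[str]:
        return [" ".join(toks) for toks in self.sentences]

    def as_sentences(self) -> list[Sentence]:
        """Tokens with source ranges into the space-joined raw line."""
        out = []
        for toks in self.sentences:
            ranges = []
            pos = 0
            for t in toks:
                ranges.append((pos, pos + len(t)))
                pos += len(t) + 1
            out.append(Sentence(list(toks), ranges))
        return out

    def annotated_sentences(self) -> list[tuple[Sentence, list[AnnotatedSpan]]]:
        """(Sentence, spans) pairs ready for the augmentation stage."""
        sents = self.as_sentences()
        return [(s, d.spans) for s, d in zip(sents, self.documents)]

    def latent_cosine(self, tok1: str, tok2: str) -> float:
        t1, t2 = self.token_theta[tok1], self.token_theta[tok2]
        return float(
            t1 @ t2 / (np.linalg.norm(t1) * np.linalg.norm(t2))
        )

    def write(self, outdir: str | Path) -> None:
        """corpus.txt, annotations.pubtator and truth/*.tsv under outdir."""
        from conceptvec import corpus_io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        corpus_io.write_corpus(self.sentences, outdir / "corpus.txt")
        corpus_io.write_pubtator(self.documents, outdir / "annotations.pubtator")
        truth = outdir / "truth"
        truth.mkdir(exist_ok=True)
        with open(truth / "synonyms.tsv", "w") as fh:
            fh.write("group\ttoken\n")
            for g, group in enumerate(self.synonym_groups):
                for tok in group:
                    fh.write(f"{g}\t{tok}\n")
        with open(truth / "collocations.tsv", "w") as fh:
            fh.write("head\ttail\tcount\n")
            for (a, b) in self.collocations:
                fh.write(f"{a}\t{b}\t{self.collocation_counts.get((a, b), 0)}\n")
        with open(truth / "entities.tsv", "w") as fh:
            fh.write("sentence\ttoken_lo\ttoken_hi\tentity_type\tentity_id\n")
            for row in self.entity_events:
                fh.write("\t".join(str(x) for x in row) + "\n")
        with open(truth / "token_topics.tsv", "w") as fh:
            fh.write("token\t" + "\t".join(
                f"topic{k}" for k in range(self.spec.n_topics)) + "\n")
            for tok, theta in sorted(self.token_theta.items()):
                fh.write(tok + "\t" + "\t".join(repr(float(x)) for x in theta) + "\n")


def _build_catalogs(spec: SyntheticSpec):
    """Deterministic token inventory: base vocab, synonyms, collocations, entities."""
    K = spec.n_topics
    theta: dict[str, np.ndarray] = {}

    def make_theta(primary: int, secondary: int) -> np.ndarray:
        v = np.zeros(K)
        v[primary] = 1.0
        v[secondary] = spec.secondary_topic_weight
        return v

    base: list[str] = []
    base_weight: dict[str, float] = {}
    for k in range(K):
        for j in range(spec.vocab_per_topic):
            tok = f"t{k}w{j:02d}"
            base.append(tok)
            theta[tok] = make_theta(k, (k + 1 + j) % K)
            base_weight[tok] = 1.0 / (1.0 + j)  # Zipf-like within-topic ranks

    synonym_groups: list[tuple[str, ...]] = []
    for g in range(spec.n_synonym_groups):
        k = g % K
        th = make_theta(k, (k + 2 + g) % K)
        group = tuple(f"t{k}syn{g}{chr(97 + i)}" for i in range(spec.synonym_group_size))
        for tok in group:
            theta[tok] = th.copy()
            base.append(tok)
            base_weight[tok] = 0.5
        synonym_groups.append(group)

    collocations: list[tuple[str, str]] = []
    for i in range(spec.n_collocations):
        head, tail = f"c{i}head", f"c{i}tail"
        k = i % K
        th = make_theta(k, (k + 3 + i) % K)
        theta[head] = th.copy()
        theta[tail] = th.copy()
        base.append(head)  # tails are only ever emitted after their head
        # rare enough that the collocation score (c-delta)*N/c^2 ~ N/c clears
        # the training threshold tau=1 (needs count below the distinct-token count)
        base_weight[head] = 0.04
        collocations.append((head, tail))

    entity_catalog: list[tuple[tuple[str, ...], str, str]] = []
    for i in range(spec.n_entities):
        surface = tuple(f"ent{i}{chr(120 + j)}" for j in range(spec.entity_surface_len))
        etype = _ENTITY_TYPE_CYCLE[i % len(_ENTITY_TYPE_CYCLE)]
        if etype == "disease":
            eid = f"MESH:D{100000 + i}"
        elif etype == "chemical":
            eid = f"MESH:C{100000 + i}"
        elif etype == "gene":
            eid = str(1000 + i)
        else:
            eid = str(9000 + i)
        k = i % K
        th = make_theta(k, (k + 4 + i) % K)
        for tok in surface:
            theta[tok] = th.copy()
        entity_catalog.append((surface, etype, eid))

    return base, base_weight, theta, synonym_groups, collocations, entity_catalog


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate the corpus, PubTator annotations and truth tables."""
    rng = np.random.default_rng(spec.seed)
    (base, base_weight, theta, synonym_groups, collocations,
     entity_catalog) = _build_catalogs(spec)
    for tok in [t for g in synonym_groups for t in g]:
        if tok not in theta:
            raise ContractViolation(f"planted token {tok} missing latent vector")

    K = spec.n_topics
    base_arr = np.asarray(base)
    theta_mat = np.vstack([theta[t] for t in base])
    w = np.asarray([base_weight[t] for t in base])
    # per-topic sampling distribution: affinity x Zipf-like base weight
    topic_probs = (theta_mat * w[:, None]).T  # (K, n_base)
    topic_probs = topic_probs / topic_probs.sum(axis=1, keepdims=True)

    colloc_tail = {a: b for a, b in collocations}
    n_annotated = int(round(spec.entity_rate * spec.n_sentences))
    annotated_idx = set(
        rng.choice(spec.n_sentences, size=n_annotated, replace=False).tolist()
    ) if n_annotated else set()

    sentences: list[list[str]] = []
    documents: list[Document] = []
    annotated = np.zeros(spec.n_sentences, dtype=bool)
    colloc_counts: dict[tuple[str, str], int] = {c: 0 for c in collocations}
    entity_events: list[tuple[int, int, int, str, str]] = []
    topics = np.empty(spec.n_sentences, dtype=np.int64)

    for si in range(spec.n_sentences):
        z = int(rng.integers(K))
        topics[si] = z
        length = max(3, int(rng.poisson(spec.sentence_length_mean)))
        picks = rng.choice(len(base_arr), size=length, p=topic_probs[z])
        toks: list[str] = []
        for pi in picks:
            tok = str(base_arr[pi])
            toks.append(tok)
            tail = colloc_tail.get(tok)
            if tail is not None:
                toks.append(tail)
                colloc_counts[(tok, tail)] += 1
        spans: list[AnnotatedSpan] = []
        if si in annotated_idx:
            annotated[si] = True
            surface, etype, eid = entity_catalog[int(rng.integers(len(entity_catalog)))]
            # never split a planted head/tail pair: their adjacency count
            # must stay equal to the emission count by construction
            safe = [
                p for p in range(len(toks) + 1)
                if not (0 < p < len(toks)
                        and colloc_tail.get(toks[p - 1]) == toks[p])
            ]
            pos = int(safe[int(rng.integers(len(safe)))])
            toks[pos:pos] = list(surface)
            lo, hi = pos, pos + len(surface)
            entity_events.append((si, lo, hi, etype, eid))
            char_lo = sum(len(t) + 1 for t in toks[:lo])
            mention = " ".join(surface)
            spans.append(
                AnnotatedSpan(char_lo, char_lo + len(mention), mention, etype, eid)
            )
        raw = " ".join(toks)
        documents.append(Document(str(si + 1), raw, "", spans))
        sentences.append(toks)

    return SyntheticCorpus(
        spec=spec,
        sentences=sentences,
        documents=documents,
        annotated=annotated,
        token_theta=theta,
        synonym_groups=synonym_groups,
        collocations=collocations,
        collocation_counts=colloc_counts,
        entity_catalog=entity_catalog,
        entity_events=entity_events,
        sentence_topics=topics,
    )


def generate_pair_benchmark(
    corpus: SyntheticCorpus,
    n_pairs: int,
    seed: int | None = None,
    n_oov_terms: int = 0,
    score_kind: str = "similarity",
) -> tuple[PairBenchmark, list[float]]:
    """Term-pair benchmark: human score = latent cosine + Gaussian noise.

    ``n_oov_terms`` fabricated terms that never occur in the corpus are
    mixed in (each used in one extra pair) to plant out-of-vocabulary
    structure with a known count.  Returns (benchmark, latent cosines) with
    latent values aligned to the non-OOV records.
    """
    spec = corpus.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    vocab = sorted(
        set(corpus.token_theta) - {t for s, _, _ in corpus.entity_catalog for t in s}
    )
    records: list[BenchmarkRecord] = []
    latents: list[float] = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(vocab), size=2, replace=False)
        t1, t2 = vocab[int(i)], vocab[int(j)]
        latent = corpus.latent_cosine(t1, t2)
        score = latent + rng.normal(0.0, spec.benchmark_noise_sd)
        records.append(BenchmarkRecord(t1, t2, float(score)))
        latents.append(latent)
    for o in range(n_oov_terms):
        partner = vocab[int(rng.integers(len(vocab)))]
        score = float(rng.normal(0.5, spec.benchmark_noise_sd))
        records.append(BenchmarkRecord(f"zzoov{o}", partner, score))
    return PairBenchmark(records, score_kind), latents


def generate_sentence_benchmark(
    corpus: SyntheticCorpus,
    n_pairs: int,
    seed: int | None = None,
    sentence_length: int = 10,
) -> tuple[list[tuple[str, str, float]], list[float]]:
    """Sentence pairs at controlled topic overlap; score = 4*overlap + noise.

    Scores are clipped to the [0, 4] human-rating scale.  Returns
    (pairs, true overlaps).
    """
    spec = corpus.spec
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    (base, base_weight, theta, _, _, _) = _build_catalogs(spec)
    base_arr = np.asarray(base)
    theta_mat = np.vstack([theta[t] for t in base])
    w = np.asarray([base_weight[t] for t in base])
    topic_probs = (theta_mat * w[:, None]).T
    topic_probs = topic_probs / topic_probs.sum(axis=1, keepdims=True)

    def sample_sentence(z: int) -> str:
        picks = rng.choice(len(base_arr), size=sentence_length, p=topic_probs[z])
        return " ".join(str(base_arr[p]) for p in picks)

    pairs: list[tuple[str, str, float]] = []
    overlaps: list[float] = []
    for _ in range(n_pairs):
        overlap = float(rng.uniform())
        z1 = int(rng.integers(spec.n_topics))
        z2 = int((z1 + 1 + rng.integers(spec.n_topics - 1)) % spec.n_topics)
        s1 = sample_sentence(z1)
        toks2 = []
        for _ in range(sentence_length):
            z = z1 if rng.uniform() < overlap else z2
            toks2.append(str(base_arr[rng.choice(len(base_arr), p=topic_probs[z])]))
        s2 = " ".join(toks2)
        score = float(np.clip(4.0 * overlap + rng.normal(0, spec.benchmark_noise_sd),
                              0.0, 4.0))
        pairs.append((s1, s2, score))
        overlaps.append(overlap)
    return pairs, overlaps
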