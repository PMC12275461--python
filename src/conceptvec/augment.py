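"""Training-corpus augmentation.

Three sentence variants feed training: the base normalized sentence; a
"joined" variant where annotated entity mentions and then statistically
co-occurring adjacent words are fused with "_" into single concept tokens;
and an "identifier" variant where each annotated mention is replaced by its
ontology surrogate token ``<entity-type>_<entity-id>`` (e.g.
``species_9096``, ``disease_mesh_d005356``), giving ontology concepts their
own embeddings.

Phrase (collocation) scoring is the count-based score

    score(a, b) = (c(a,b) - delta) * N / (c(a) * c(b))

with N the distinct-token count; a pair is joined when the score reaches
the threshold tau (1 when building training data, 5 at query time).
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from conceptvec.errors import ContractViolation
from conceptvec.types import ENTITY_TYPES, AnnotatedSpan, Sentence

__all__ = [
    "PhraseModel",
    "AugmentCounters",
    "train_phrase_model",
    "phrase_score",
    "apply_phrases",
    "join_entities",
    "format_entity_id",
    "substitute_ids",
    "augment_corpus",
    "ID_TOKEN_RE",
    "NORMAL_TOKEN_RE",
]

ID_TOKEN_RE = re.compile(r"^(gene|disease|chemical|mutation|species)_[a-z0-9_]+$")
NORMAL_TOKEN_RE = re.compile(r"^\S+$")


@dataclass
class PhraseModel:
    """Unigram/bigram counts plus the collocation scoring parameters."""

    unigram_counts: dict[str, int] = field(default_factory=dict)
    bigram_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    delta: float = 5.0
    threshold: float = 1.0

    @property
    def vocab_size(self) -> int:
        return len(self.unigram_counts)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {"version": 1, "unigram_counts": self.unigram_counts,
                 "bigram_counts": self.bigram_counts,
                 "delta": self.delta, "threshold": self.threshold},
                fh,
            )

    @classmethod
    def load(cls, path) -> "PhraseModel":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        if d.get("version") != 1:
            raise ContractViolation("unknown phrase-model file version")
        return cls(d["unigram_counts"], d["bigram_counts"], d["delta"], d["threshold"])


def train_phrase_model(
    corpus: Iterable[Sentence], delta: float = 5.0, threshold: float = 1.0
) -> PhraseModel:
    """Count unigrams and adjacent-pair bigrams over a normalized corpus."""
    model = PhraseModel(delta=delta, threshold=threshold)
    uni, bi = model.unigram_counts, model.bigram_counts
    empty = True
    for sent in corpus:
        toks = sent.tokens if isinstance(sent, Sentence) else list(sent)
        empty = False
        for tok in toks:
            uni[tok] = uni.get(tok, 0) + 1
        for a, b in zip(toks, toks[1:]):
            bi[(a, b)] = bi.get((a, b), 0) + 1
    if empty:
        raise ContractViolation("cannot train a phrase model on an empty corpus")
    return model


def phrase_score(model: PhraseModel, a: str, b: str) -> float:
    """Collocation score of the adjacent pair (a, b); -inf when unseen."""
    ca = model.unigram_counts.get(a)
    cb = model.unigram_counts.get(b)
    if ca is None or cb is None:
        return float("-inf")
    cab = model.bigram_counts.get((a, b), 0)
    return (cab - model.delta) * model.vocab_size / (ca * cb)


def apply_phrases(
    model: PhraseModel, sentence: Sentence, threshold: float | None = None
) -> Sentence:
    """Greedy left-to-right single-pass bigram joining.

    When score(tokens[i], tokens[i+1]) >= tau the pair becomes one
    "a_b" token (source ranges merged) and scanning resumes after the pair,
    so joins never overlap and no tri-grams are built recursively.
    """
    tau = model.threshold if threshold is None else threshold
    toks, ranges = sentence.tokens, sentence.source_ranges
    out_t: list[str] = []
    out_r: list[tuple[int, int]] = []
    i = 0
    while i < len(toks):
        if i + 1 < len(toks) and phrase_score(model, toks[i], toks[i + 1]) >= tau:
            out_t.append(toks[i] + "_" + toks[i + 1])
            out_r.append((ranges[i][0], ranges[i + 1][1]))
            i += 2
        else:
            out_t.append(toks[i])
            out_r.append(ranges[i])
            i += 1
    return Sentence(out_t, out_r)


def _resolve_overlaps(spans: list[AnnotatedSpan]) -> list[AnnotatedSpan]:
    """Keep a non-overlapping subset: prefer longer spans, ties by earlier start."""
    chosen: list[AnnotatedSpan] = []
    for sp in sorted(spans, key=lambda s: (-(s.end - s.start), s.start)):
        if all(sp.end <= c.start or sp.start >= c.end for c in chosen):
            chosen.append(sp)
    chosen.sort(key=lambda s: s.start)
    return chosen


@dataclass
class AugmentCounters:
    """Recoverable-event counters emitted by the augmentation stage."""

    spans_no_token: int = 0
    base_emitted: int = 0
    joined_emitted: int = 0
    id_emitted: int = 0

    @property
    def expansion_factor(self) -> float:
        if self.base_emitted == 0:
            return float("nan")
        return (
            self.base_emitted + self.joined_emitted + self.id_emitted
        ) / self.base_emitted


def _span_token_runs(
    sentence: Sentence,
    spans: list[AnnotatedSpan],
    counters: AugmentCounters | None,
) -> list[tuple[int, int, AnnotatedSpan]]:
    """Map spans to maximal token index runs [i, j) via source-range overlap."""
    runs: list[tuple[int, int, AnnotatedSpan]] = []
    taken = [False] * len(sentence)
    for sp in _resolve_overlaps(spans):
        idxs = [
            i
            for i, (s, e) in enumerate(sentence.source_ranges)
            if s < sp.end and e > sp.start and not taken[i]
        ]
        if not idxs:
            if counters is not None:
                counters.spans_no_token += 1
            continue
        lo, hi = idxs[0], idxs[-1] + 1
        for i in range(lo, hi):
            taken[i] = True
        runs.append((lo, hi, sp))
    runs.sort(key=lambda r: r[0])
    return runs


def _rewrite_runs(
    sentence: Sentence,
    runs: list[tuple[int, int, AnnotatedSpan]],
    render,
) -> Sentence:
    out_t: list[str] = []
    out_r: list[tuple[int, int]] = []
    pos = 0
    for lo, hi, sp in runs:
        out_t.extend(sentence.tokens[pos:lo])
        out_r.extend(sentence.source_ranges[pos:lo])
        out_t.append(render(sentence.tokens[lo:hi], sp))
        out_r.append((sentence.source_ranges[lo][0], sentence.source_ranges[hi - 1][1]))
        pos = hi
    out_t.extend(sentence.tokens[pos:])
    out_r.extend(sentence.source_ranges[pos:])
    return Sentence(out_t, out_r)


def join_entities(
    sentence: Sentence,
    spans: list[AnnotatedSpan],
    counters: AugmentCounters | None = None,
) -> Sentence:
    """Fuse each annotated token run into one "_"-joined concept token."""
    runs = _span_token_runs(sentence, spans, counters)
    return _rewrite_runs(sentence, runs, lambda toks, sp: "_".join(toks))


def format_entity_id(entity_type: str, raw_id: str) -> str:
    """Render the ontology surrogate token ``<entity-type>_<entity-id>``.

    The raw identifier is lowercased with every character outside [a-z0-9]
    replaced by "_".  Identifiers already carrying the type prefix are
    passed through unchanged (idempotence), so re-rendering never produces
    ``gene_gene_4137``.
    """
    if entity_type not in ENTITY_TYPES:
        raise ContractViolation(f"unknown entity type {entity_type!r}")
    if not raw_id:
        raise ContractViolation("empty entity id")
    norm = re.sub(r"[^a-z0-9]", "_", raw_id.lower())
    if norm.startswith(entity_type + "_"):
        return norm
    return f"{entity_type}_{norm}"


def substitute_ids(
    sentence: Sentence,
    spans: list[AnnotatedSpan],
    counters: AugmentCounters | None = None,
) -> Sentence:
    """Replace each annotated token run by its ontology surrogate token."""
    runs = _span_token_runs(sentence, spans, counters)
    return _rewrite_runs(
        sentence, runs, lambda toks, sp: format_entity_id(sp.entity_type, sp.entity_id)
    )


def augment_corpus(
    corpus: Iterable[tuple[Sentence, list[AnnotatedSpan]]],
    phrase_model: PhraseModel,
    seed: int,
    threshold: float | None = None,
    separate_variants: bool = False,
    counters: AugmentCounters | None = None,
    shuffle_buffer: int = 1_000_000,
) -> Iterator[Sentence]:
    """Emit base + joined + identifier variants, seeded-shuffled.

    Per input sentence: (a) the base sentence always; (b) the joined
    variant — entities joined first, phrase joining applied to the result —
    when it differs from the base; (c) the identifier variant when it
    differs from the base.  With ``separate_variants`` the entity-joined
    and phrase-joined variants are emitted as two separate sentences.

    Shuffling is a seeded permutation within fixed-size buffers (a full
    shuffle whenever the corpus fits in one buffer).
    """
    tau = phrase_model.threshold if threshold is None else threshold
    rng = np.random.default_rng(seed)
    if counters is None:
        counters = AugmentCounters()

    def variants() -> Iterator[Sentence]:
        for sentence, spans in corpus:
            counters.base_emitted += 1
            yield sentence
            if separate_variants:
                ent = join_entities(sentence, spans, counters)
                if ent.tokens != sentence.tokens:
                    counters.joined_emitted += 1
                    yield ent
                phr = apply_phrases(phrase_model, sentence, tau)
                if phr.tokens != sentence.tokens:
                    counters.joined_emitted += 1
                    yield phr
            else:
                joined = apply_phrases(
                    phrase_model, join_entities(sentence, spans, counters), tau
                )
                if joined.tokens != sentence.tokens:
                    counters.joined_emitted += 1
                    yield joined
            idvar = substitute_ids(sentence, spans, counters)
            if idvar.tokens != sentence.tokens:
                counters.id_emitted += 1
                yield idvar

    buffer: list[Sentence] = []
    for sent in variants():
        buffer.append(sent)
        if len(buffer) >= shuffle_buffer:
            order = rng.permutation(len(buffer))
            for i in order:
                yield buffer[i]
            buffer = []
    order = rng.permutation(len(buffer))
    for i in order:
        yield buffer[i]
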