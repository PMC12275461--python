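"""Sentence similarity over concept embeddings.

Two scorers:

* SIF weighted average — each token vector is weighted by
  ``A / (A + p(w))`` with smoothing constant A (default 3e-4) and relative
  training-corpus frequency p(w); sentence similarity is the cosine of the
  two weighted averages (higher = closer).
* Word Mover's Distance — the sentences become normalized bags-of-words
  (probability mass over distinct tokens) and the score is the optimal
  objective of the transportation problem

      min_T  sum_ij T_ij ||x_i - y_j||_2
      s.t.   sum_j T_ij = w1_i,  sum_i T_ij = w2_j,  T >= 0

  solved exactly (HiGHS LP); lower = closer, so the evaluation harness
  negates it before correlating with human similarity judgements.

Sentence preparation mirrors training-time preprocessing, then removes
stop-words, optionally joins annotated entity mentions, joins collocations
at the query-time threshold tau=5, and resolves each token to a vector
(subword composition allowed; unresolvable tokens dropped and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from conceptvec.augment import PhraseModel, apply_phrases, join_entities
from conceptvec.errors import ContractViolation, EmptySentenceError
from conceptvec.preprocess import Normalizer, normalize_sentence
from conceptvec.stopwords import DEFAULT_STOPWORDS
from conceptvec.trainer import EmbeddingModel
from conceptvec.types import AnnotatedSpan, Sentence
from conceptvec.vectorstore import cosine, vector

__all__ = [
    "QUERY_PHRASE_THRESHOLD",
    "NBow",
    "SifConfig",
    "prepare_sentence",
    "nbow",
    "encode_sif",
    "wmd",
    "sentence_similarity",
]

#: Collocation-joining threshold at query time (training-time joining uses 1).
QUERY_PHRASE_THRESHOLD = 5.0


@dataclass
class NBow:
    """Normalized bag-of-words: distinct tokens, vectors, probability mass."""

    tokens: list[str]
    vectors: np.ndarray  # (n, d)
    weights: np.ndarray  # (n,), positive, sums to 1

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise EmptySentenceError("empty nBOW")
        if len(set(self.tokens)) != len(self.tokens):
            raise ContractViolation("nBOW support tokens must be distinct")
        if not np.all(self.weights > 0):
            raise ContractViolation("nBOW weights must be positive")
        if abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise ContractViolation("nBOW weights must sum to 1")


@dataclass
class SifConfig:
    """Smooth-inverse-frequency weighting parameters.

    ``frequencies`` maps token -> relative training-corpus frequency p(w);
    tokens absent from the map get the minimum observed p(w) (the most
    conservative, highest weight).  ``remove_pc`` subtracts the batch's
    first principal component after averaging (off by default).
    """

    A: float = 3e-4
    frequencies: dict[str, float] = field(default_factory=dict)
    remove_pc: bool = False

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ContractViolation("A must be > 0")

    @classmethod
    def from_model(cls, model: EmbeddingModel, A: float = 3e-4) -> "SifConfig":
        total = model.vocab.total_tokens
        freqs = {
            t: float(c) / total
            for t, c in zip(model.vocab.tokens, model.vocab.counts)
        }
        return cls(A=A, frequencies=freqs)

    def weight(self, token: str) -> float:
        if self.frequencies:
            p = self.frequencies.get(token)
            if p is None:
                p = min(self.frequencies.values())
        else:
            p = 1.0
        return self.A / (self.A + p)


def prepare_sentence(
    raw: str,
    model: EmbeddingModel,
    phrase_model: PhraseModel | None = None,
    annotations: list[AnnotatedSpan] | None = None,
    normalizer: Normalizer | None = None,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    threshold: float = QUERY_PHRASE_THRESHOLD,
) -> list[tuple[str, np.ndarray]]:
    """Normalize, stop-filter, join concepts and resolve vectors for a sentence."""
    sent = normalize_sentence(raw, normalizer)
    if stopwords:
        kept = [(t, r) for t, r in zip(sent.tokens, sent.source_ranges)
                if t not in stopwords]
        sent = Sentence([t for t, _ in kept], [r for _, r in kept])
    if annotations:
        sent = join_entities(sent, annotations)
    if phrase_model is not None:
        sent = apply_phrases(phrase_model, sent, threshold)
    prepared: list[tuple[str, np.ndarray]] = []
    for tok in sent.tokens:
        resolved = vector(model, tok)
        if resolved is not None:
            prepared.append((tok, np.asarray(resolved[0], dtype=np.float64)))
    if not prepared:
        raise EmptySentenceError(f"no token of {raw!r} is resolvable")
    return prepared


def nbow(prepared: list[tuple[str, np.ndarray]]) -> NBow:
    """Collapse a prepared token list into a normalized bag-of-words."""
    order: dict[str, int] = {}
    vecs: list[np.ndarray] = []
    counts: list[int] = []
    for tok, vec in prepared:
        if tok in order:
            counts[order[tok]] += 1
        else:
            order[tok] = len(vecs)
            vecs.append(vec)
            counts.append(1)
    weights = np.asarray(counts, dtype=np.float64)
    weights /= weights.sum()
    return NBow(list(order.keys()), np.vstack(vecs), weights)


def encode_sif(
    prepared: list[tuple[str, np.ndarray]], sif: SifConfig
) -> np.ndarray:
    """SIF sentence vector: (1/n) sum_i [A/(A + p(t_i))] v_i."""
    if not prepared:
        raise EmptySentenceError("cannot encode an empty sentence")
    vecs = np.vstack([v for _, v in prepared]).astype(np.float64)
    w = np.asarray([sif.weight(t) for t, _ in prepared], dtype=np.float64)
    return (w[:, None] * vecs).sum(axis=0) / len(prepared)


def remove_first_pc(vectors: np.ndarray) -> np.ndarray:
    """Batch-level common-component removal for SIF sentence vectors."""
    X = np.asarray(vectors, dtype=np.float64)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    pc = vt[0]
    return X - np.outer(X @ pc, pc)


def wmd(s1: NBow, s2: NBow) -> float:
    """Exact Word Mover's Distance between two normalized bags-of-words."""
    if s1.vectors.shape[1] != s2.vectors.shape[1]:
        raise ContractViolation("dimension mismatch between nBOWs")
    n, m = len(s1.tokens), len(s2.tokens)
    cost = cdist(s1.vectors, s2.vectors, metric="euclidean")
    if n == 1 and m == 1:
        return float(cost[0, 0])
    # transportation LP over the n*m flow variables; one marginal constraint
    # is redundant and dropped for numerical rank
    A_eq = np.zeros((n + m - 1, n * m))
    b_eq = np.zeros(n + m - 1)
    for i in range(n):
        A_eq[i, i * m : (i + 1) * m] = 1.0
        b_eq[i] = s1.weights[i]
    for j in range(m - 1):
        A_eq[n + j, j::m] = 1.0
        b_eq[n + j] = s2.weights[j]
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise ContractViolation(f"transportation LP failed: {res.message}")
    return max(float(res.fun), 0.0)


def sentence_similarity(
    raw1: str,
    raw2: str,
    model: EmbeddingModel,
    phrase_model: PhraseModel | None = None,
    method: str = "wmd",
    sif: SifConfig | None = None,
    annotations1: list[AnnotatedSpan] | None = None,
    annotations2: list[AnnotatedSpan] | None = None,
    **prepare_kwargs,
) -> tuple[float, str]:
    """Score a sentence pair; returns (score, score_kind).

    ``score_kind`` is "similarity" for the SIF cosine (higher = closer) and
    "distance" for WMD (lower = closer) so callers know whether to negate
    before correlating with human similarity judgements.
    """
    p1 = prepare_sentence(raw1, model, phrase_model, annotations1, **prepare_kwargs)
    p2 = prepare_sentence(raw2, model, phrase_model, annotations2, **prepare_kwargs)
    if method == "sif":
        cfg = sif or SifConfig.from_model(model)
        return cosine(encode_sif(p1, cfg), encode_sif(p2, cfg)), "similarity"
    if method == "wmd":
        return wmd(nbow(p1), nbow(p2)), "distance"
    raise ContractViolation(f"unknown method {method!r}")
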