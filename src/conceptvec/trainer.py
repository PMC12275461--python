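"""Subword skip-gram embedding trainer with negative sampling.

The model learns one input vector per vocabulary token plus a table of
hashed character n-gram ("bucket") vectors; a token's representation is the
mean of its own vector and its n-gram bucket vectors, so morphologically
related tokens (``proteobacteria`` / ``deltaproteobacteria``) share
parameters and unseen tokens can still be composed at query time.

Training objective, per (center c, context o) pair with k sampled
negatives n_1..n_k:

    l = -log sigma(u_o . h_c) - sum_i log sigma(-u_{n_i} . h_c)

where h_c is the center representation and u are context vectors.
Negatives are drawn with probability proportional to count(w)^ns_exponent;
frequent tokens are down-sampled with keep probability
min(1, (sqrt(f/t) + 1) * t / f); the context window half-width is resampled
per center position uniformly in {1..window} (dynamic window); the learning
rate decays linearly from ``alpha`` to ``min_alpha`` over
``epochs * corpus positions``.

With ``workers=1`` and a fixed seed the run is bit-reproducible: all
randomness flows from one xorshift64* stream inside the kernel plus one
seeded numpy generator for weight initialization.
"""

from __future__ import annotations

import hashlib
import math
import pickle
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from conceptvec.errors import ContractViolation
from conceptvec.types import Sentence

__all__ = [
    "TrainingConfig",
    "Vocabulary",
    "EmbeddingModel",
    "build_vocabulary",
    "extract_char_ngrams",
    "fnv1a32",
    "negative_table",
    "subsample_keep_prob",
    "skipgram_loss_and_grads",
    "train",
]


@dataclass
class TrainingConfig:
    """Hyperparameter surface of the trainer.

    Defaults are the full-scale training settings; desk-scale experiments
    override dim/window/sample (see the synthetic-corpus module).
    """

    alpha: float = 0.03
    min_alpha: float = 0.0001
    negative: int = 5
    window: int = 20
    dim: int = 152
    minn: int = 3
    maxn: int = 6
    min_count: int = 5
    ns_exponent: float = 0.75
    sample: float = 1e-5
    epochs: int = 5
    bucket_count: int = 2**21
    seed: int = 1
    workers: int = 1  # capacity knob; training is single-threaded/deterministic

    def __post_init__(self) -> None:
        if not (0 < self.min_alpha <= self.alpha):
            raise ContractViolation("require 0 < min_alpha <= alpha")
        if self.minn > self.maxn:
            raise ContractViolation("require minn <= maxn")
        if self.dim < 1 or self.window < 1:
            raise ContractViolation("require dim >= 1 and window >= 1")
        if self.sample <= 0:
            raise ContractViolation("require sample > 0")
        if not (0 <= self.ns_exponent <= 1):
            raise ContractViolation("require 0 <= ns_exponent <= 1")


@dataclass
class Vocabulary:
    """Dense token index: tokens sorted by descending count, ties lexicographic."""

    tokens: list[str]
    counts: np.ndarray  # int64, aligned with tokens
    total_tokens: int  # sum of retained-token counts

    def __post_init__(self) -> None:
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def frequency(self, token: str) -> float:
        """Relative corpus frequency of a vocabulary token."""
        return float(self.counts[self.index[token]]) / self.total_tokens


def desk_scale_config(seed: int = 1, **overrides) -> TrainingConfig:
    """Desk-scale training configuration for synthetic-corpus studies.

    Same objective and surface as the full-scale defaults, scaled to a
    ~10k-sentence corpus: dim 32, window 5, 2^15 subword buckets, and a
    down-sampling threshold of 1e-3 (at toy vocabulary sizes every token's
    relative frequency exceeds 1e-5, which would discard nearly the whole
    corpus).
    """
    params: dict = dict(
        alpha=0.03, dim=32, window=5, epochs=5, min_count=5,
        bucket_count=2**15, sample=1e-3, seed=seed,
    )
    params.update(overrides)
    return TrainingConfig(**params)


def _sentence_tokens(sent) -> Sequence[str]:
    return sent.tokens if isinstance(sent, Sentence) else sent


def build_vocabulary(corpus: Iterable, min_count: int) -> Vocabulary:
    """Exact token counts; tokens with count < min_count are excluded."""
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in _sentence_tokens(sent):
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        ((t, c) for t, c in counts.items() if c >= min_count),
        key=lambda tc: (-tc[1], tc[0]),
    )
    if not kept:
        raise ContractViolation(
            f"no token reaches min_count={min_count} "
            f"({len(counts)} distinct tokens seen)"
        )
    tokens = [t for t, _ in kept]
    arr = np.asarray([c for _, c in kept], dtype=np.int64)
    return Vocabulary(tokens, arr, int(arr.sum()))


def extract_char_ngrams(token: str, minn: int, maxn: int) -> list[str]:
    """All substrings of "<token>" with length in [minn, maxn].

    The boundary-padded full token is therefore itself an n-gram whenever
    its length fits the window.  Order: by start position, then length.
    """
    padded = "<" + token + ">"
    out: list[str] = []
    for start in range(len(padded)):
        for length in range(minn, maxn + 1):
            if start + length <= len(padded):
                out.append(padded[start : start + length])
    return out


def fnv1a32(s: str) -> int:
    """32-bit FNV-1a hash over the UTF-8 bytes of ``s``."""
    h = 0x811C9DC5
    for byte in s.encode("utf-8"):
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


def ngram_bucket_ids(token: str, minn: int, maxn: int, bucket_count: int) -> list[int]:
    return [fnv1a32(g) % bucket_count for g in extract_char_ngrams(token, minn, maxn)]


def subsample_keep_prob(freq: float, t: float) -> float:
    """Keep probability for a token of relative frequency ``freq``."""
    if not (0 < freq <= 1):
        raise ContractViolation("frequency must be in (0, 1]")
    return min(1.0, (math.sqrt(freq / t) + 1.0) * t / freq)


def negative_table(vocab: Vocabulary, exponent: float) -> np.ndarray:
    """Negative-sampling distribution P(w) proportional to count(w)^exponent."""
    weights = np.asarray(vocab.counts, dtype=np.float64) ** exponent
    return weights / weights.sum()


def skipgram_loss_and_grads(
    h: np.ndarray, u_pos: np.ndarray, U_neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and analytic gradients for one (center, context, negatives) instance.

    Reference implementation in float64, used directly by the training
    kernel's math and checkable against finite differences.
    Returns (loss, d/dh, d/du_pos, d/dU_neg).
    """
    sp = 1.0 / (1.0 + np.exp(-float(u_pos @ h)))
    loss = -math.log(max(sp, 1e-300))
    grad_h = (sp - 1.0) * u_pos
    grad_upos = (sp - 1.0) * h
    grad_Uneg = np.zeros_like(U_neg)
    for i in range(U_neg.shape[0]):
        sn = 1.0 / (1.0 + np.exp(-float(U_neg[i] @ h)))
        loss += -math.log(max(1.0 - sn, 1e-300))
        grad_h = grad_h + sn * U_neg[i]
        grad_Uneg[i] = sn * h
    return loss, grad_h, grad_upos, grad_Uneg


# ------------------------------------------------------------------ kernel


@njit(cache=True, fastmath=False)
def _xorshift(x):
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    return x & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, fastmath=False)
def _u01(x):
    # 53-bit uniform in [0, 1)
    return (x >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=False)
def _draw_negative(cdf, u):
    lo = 0
    hi = cdf.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, fastmath=False)
def _train_kernel(
    tokens,        # int32 concatenated sentences, -1 = skipped position
    offsets,       # int64 sentence offsets, len n_sent+1
    max_len,       # int64 longest sentence
    keep_prob,     # float64 per vocab token
    neg_cdf,       # float64 cumulative negative-sampling distribution
    W_in,          # float32 (V, d)
    W_ctx,         # float32 (V, d)
    W_bkt,         # float32 (B, d)
    ng_indptr,     # int64 (V+1,)
    ng_ids,        # int32 bucket ids
    window,
    negative,
    alpha0,
    min_alpha,
    epochs,
    seed,
    loss_sums,     # float64 (epochs,)
    loss_counts,   # int64 (epochs,)
):
    d = W_in.shape[1]
    total_positions = tokens.shape[0] * epochs
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(
        1442695040888963407
    )
    state &= np.uint64(0xFFFFFFFFFFFFFFFF)
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)
    work = np.empty(max_len, dtype=np.int32)
    h = np.empty(d, dtype=np.float32)
    gh = np.empty(d, dtype=np.float32)
    pos_seen = 0
    for ep in range(epochs):
        for si in range(offsets.shape[0] - 1):
            s0 = offsets[si]
            s1 = offsets[si + 1]
            L = s1 - s0
            for j in range(L):
                t = tokens[s0 + j]
                if t >= 0 and keep_prob[t] < 1.0:
                    state = _xorshift(state)
                    if _u01(state) > keep_prob[t]:
                        t = -1
                work[j] = t
            for i in range(L):
                pos_seen += 1
                c = work[i]
                if c < 0:
                    continue
                alpha = alpha0 - (alpha0 - min_alpha) * (
                    (pos_seen - 1) / total_positions
                )
                n0 = ng_indptr[c]
                n1 = ng_indptr[c + 1]
                m = np.float32(1 + (n1 - n0))
                for k in range(d):
                    h[k] = W_in[c, k]
                for g in range(n0, n1):
                    bid = ng_ids[g]
                    for k in range(d):
                        h[k] += W_bkt[bid, k]
                for k in range(d):
                    h[k] /= m
                state = _xorshift(state)
                b = 1 + int(state % np.uint64(window))
                lo = i - b
                if lo < 0:
                    lo = 0
                hi = i + b
                if hi > L - 1:
                    hi = L - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    ctx = work[j]
                    if ctx < 0:
                        continue
                    for k in range(d):
                        gh[k] = np.float32(0.0)
                    # positive pair
                    dot = np.float32(0.0)
                    for k in range(d):
                        dot += W_ctx[ctx, k] * h[k]
                    sp = 1.0 / (1.0 + math.exp(-float(dot)))
                    loss_sums[ep] += -math.log(max(sp, 1e-12))
                    g0 = np.float32((1.0 - sp) * alpha)
                    for k in range(d):
                        gh[k] += g0 * W_ctx[ctx, k]
                    for k in range(d):
                        W_ctx[ctx, k] += g0 * h[k]
                    # negatives
                    for _ in range(negative):
                        state = _xorshift(state)
                        neg = _draw_negative(neg_cdf, _u01(state))
                        if neg == ctx:
                            continue
                        dot = np.float32(0.0)
                        for k in range(d):
                            dot += W_ctx[neg, k] * h[k]
                        sn = 1.0 / (1.0 + math.exp(-float(dot)))
                        loss_sums[ep] += -math.log(max(1.0 - sn, 1e-12))
                        gn = np.float32(-sn * alpha)
                        for k in range(d):
                            gh[k] += gn * W_ctx[neg, k]
                        for k in range(d):
                            W_ctx[neg, k] += gn * h[k]
                    loss_counts[ep] += 1
                    # distribute accumulated gradient to the center's parts
                    inv_m = np.float32(1.0) / m
                    for k in range(d):
                        gh[k] *= inv_m
                    for k in range(d):
                        W_in[c, k] += gh[k]
                    for g in range(n0, n1):
                        bid = ng_ids[g]
                        for k in range(d):
                            W_bkt[bid, k] += gh[k]


# ------------------------------------------------------------------- model


@dataclass
class EmbeddingModel:
    """Trained embedding space: vocabulary vectors + subword bucket vectors.

    ``vectors`` are the query/similarity vectors: the composed
    representation (mean of the token's input vector and its n-gram bucket
    vectors) — the same quantity the training objective optimizes as the
    center representation.  The raw input vectors are kept in
    ``input_vectors`` for reproducibility checks.
    """

    vectors: np.ndarray                 # (V, d) float32 composed query vectors
    context_vectors: np.ndarray | None  # (V, d) float32
    bucket_vectors: np.ndarray | None   # (B, d) float32
    vocab: Vocabulary
    config: TrainingConfig
    epoch_losses: np.ndarray | None = None  # mean pair loss per epoch
    input_vectors: np.ndarray | None = None  # (V, d) raw token input vectors
    _norms: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def weights_hash(self) -> str:
        """SHA-256 over all weight matrices (reproducibility checks)."""
        hsh = hashlib.sha256()
        hsh.update(np.ascontiguousarray(self.vectors).tobytes())
        if self.input_vectors is not None:
            hsh.update(np.ascontiguousarray(self.input_vectors).tobytes())
        if self.context_vectors is not None:
            hsh.update(np.ascontiguousarray(self.context_vectors).tobytes())
        if self.bucket_vectors is not None:
            hsh.update(np.ascontiguousarray(self.bucket_vectors).tobytes())
        return hsh.hexdigest()

    def norms(self) -> np.ndarray:
        """Cached row norms of the vocabulary vectors."""
        if self._norms is None:
            self._norms = np.linalg.norm(self.vectors.astype(np.float64), axis=1)
        return self._norms

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ContractViolation("file does not contain an EmbeddingModel")
        return model


def _encode_corpus(
    sentences: list[Sequence[str]], vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray, int]:
    offsets = np.zeros(len(sentences) + 1, dtype=np.int64)
    for i, s in enumerate(sentences):
        offsets[i + 1] = offsets[i] + len(s)
    tokens = np.empty(int(offsets[-1]), dtype=np.int32)
    pos = 0
    max_len = 1
    for s in sentences:
        max_len = max(max_len, len(s))
        for tok in s:
            tokens[pos] = vocab.index.get(tok, -1)
            pos += 1
    return tokens, offsets, max_len


def _ngram_table(
    vocab: Vocabulary, minn: int, maxn: int, bucket_count: int
) -> tuple[np.ndarray, np.ndarray]:
    indptr = np.zeros(len(vocab) + 1, dtype=np.int64)
    all_ids: list[int] = []
    for i, tok in enumerate(vocab.tokens):
        ids = ngram_bucket_ids(tok, minn, maxn, bucket_count)
        all_ids.extend(ids)
        indptr[i + 1] = len(all_ids)
    return indptr, np.asarray(all_ids, dtype=np.int32)


def train(corpus: Iterable, config: TrainingConfig) -> EmbeddingModel:
    """Train an embedding model on an iterable of Sentences / token lists."""
    sentences = [list(_sentence_tokens(s)) for s in corpus]
    vocab = build_vocabulary(sentences, config.min_count)
    V, d = len(vocab), config.dim

    rng = np.random.default_rng(config.seed)
    W_in = ((rng.random((V, d)) - 0.5) / d).astype(np.float32)
    W_bkt = ((rng.random((config.bucket_count, d)) - 0.5) / d).astype(np.float32)
    W_ctx = np.zeros((V, d), dtype=np.float32)

    if config.epochs > 0:
        tokens, offsets, max_len = _encode_corpus(sentences, vocab)
        indptr, ng_ids = _ngram_table(vocab, config.minn, config.maxn,
                                      config.bucket_count)
        keep = np.array(
            [
                subsample_keep_prob(c / vocab.total_tokens, config.sample)
                for c in vocab.counts
            ],
            dtype=np.float64,
        )
        neg_cdf = np.cumsum(negative_table(vocab, config.ns_exponent))
        neg_cdf[-1] = 1.0
        loss_sums = np.zeros(config.epochs, dtype=np.float64)
        loss_counts = np.zeros(config.epochs, dtype=np.int64)
        _train_kernel(
            tokens, offsets, np.int64(max_len), keep, neg_cdf,
            W_in, W_ctx, W_bkt, indptr, ng_ids,
            config.window, config.negative, config.alpha, config.min_alpha,
            config.epochs, config.seed,
            loss_sums, loss_counts,
        )
        if not (np.all(np.isfinite(W_in)) and np.all(np.isfinite(W_ctx))
                and np.all(np.isfinite(W_bkt))):
            raise ContractViolation("non-finite weights after training")
        with np.errstate(invalid="ignore"):
            epoch_losses = np.where(
                loss_counts > 0, loss_sums / np.maximum(loss_counts, 1), np.nan
            )
    else:
        epoch_losses = None
        indptr, ng_ids = _ngram_table(vocab, config.minn, config.maxn,
                                      config.bucket_count)

    # query vectors = composed representation, as used during training
    composed = np.empty_like(W_in)
    for i in range(V):
        ids = ng_ids[indptr[i] : indptr[i + 1]]
        composed[i] = (W_in[i] + W_bkt[ids].sum(axis=0)) / (1 + len(ids))

    return EmbeddingModel(
        vectors=composed,
        context_vectors=W_ctx,
        bucket_vectors=W_bkt,
        vocab=vocab,
        config=replace(config),
        epoch_losses=epoch_losses,
        input_vectors=W_in,
    )
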