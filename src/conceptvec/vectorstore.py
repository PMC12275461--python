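"""Query operations over a trained embedding space.

Lookup with subword composition for unseen tokens, cosine similarity,
filtered nearest-neighbor search (one matrix-vector product over the
normalized vocabulary matrix), 2-D PCA neighborhood projection, and
top-K frequency compression.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from conceptvec.errors import (
    AbsentVectorError,
    ContractViolation,
    DegenerateProjectionError,
)
from conceptvec.preprocess import Normalizer, normalize_sentence
from conceptvec.trainer import EmbeddingModel, Vocabulary, ngram_bucket_ids

__all__ = [
    "vector",
    "cosine",
    "most_similar",
    "term_vector",
    "project_neighborhood",
    "compress",
]


def vector(model: EmbeddingModel, token: str) -> tuple[np.ndarray, bool] | None:
    """Resolve a normalized token to (vector, in_vocab flag).

    In-vocabulary tokens return their stored representation; unknown tokens
    are composed as the mean of their character n-gram bucket vectors.
    Returns None when the token is unresolvable (no stored vector and no
    extractable n-grams), never a zero placeholder.
    """
    if not token:
        return None
    idx = model.vocab.index.get(token)
    if idx is not None:
        return model.vectors[idx], True
    if model.bucket_vectors is None:
        return None
    cfg = model.config
    ids = ngram_bucket_ids(token, cfg.minn, cfg.maxn, cfg.bucket_count)
    if not ids:
        return None
    return model.bucket_vectors[np.asarray(ids, dtype=np.int64)].mean(axis=0), False


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity, clamped to [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ContractViolation("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ContractViolation("cosine undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def most_similar(
    model: EmbeddingModel,
    token: str,
    k: int = 10,
    prefix_filter: str | None = None,
) -> list[tuple[str, float]]:
    """Top-k vocabulary tokens by cosine, optionally restricted to a prefix.

    Computed as one normalized matrix-vector product; the query token
    itself is excluded; ties broken lexicographically.
    """
    resolved = vector(model, token)
    if resolved is None:
        raise AbsentVectorError(f"cannot resolve {token!r}")
    q, _ = resolved
    q = np.asarray(q, dtype=np.float64)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise AbsentVectorError(f"zero vector for {token!r}")
    norms = model.norms()
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (model.vectors.astype(np.float64) @ (q / qn)) / norms
    scores = np.clip(np.nan_to_num(scores, nan=-2.0), -1.0, 1.0)

    tokens = model.vocab.tokens
    candidates = [
        i
        for i in range(len(tokens))
        if tokens[i] != token
        and (prefix_filter is None or tokens[i].startswith(prefix_filter))
    ]
    candidates.sort(key=lambda i: (-scores[i], tokens[i]))
    return [(tokens[i], float(scores[i])) for i in candidates[:k]]


def term_vector(
    model: EmbeddingModel,
    raw_term: str,
    normalizer: Normalizer | None = None,
) -> tuple[np.ndarray, bool]:
    """Resolve a (possibly multi-word) raw term.

    The term is normalized and ALL its tokens joined with "_" into one
    candidate concept token.  If that token is in the vocabulary the result
    is its vector with ``oov=False``; otherwise ``oov=True`` and the
    returned vector is the mean of the component-token vectors (subword
    composition allowed).  OOV accounting for benchmarks keys on this flag:
    subword composition never rescues a term from being OOV.
    """
    sent = normalize_sentence(raw_term, normalizer)
    if not sent.tokens:
        raise AbsentVectorError(f"term {raw_term!r} normalizes to nothing")
    candidate = "_".join(sent.tokens)
    idx = model.vocab.index.get(candidate)
    if idx is not None:
        return model.vectors[idx], False
    parts = []
    for tok in sent.tokens:
        resolved = vector(model, tok)
        if resolved is not None:
            parts.append(np.asarray(resolved[0], dtype=np.float64))
    if not parts:
        raise AbsentVectorError(f"no component of {raw_term!r} resolvable")
    return np.mean(parts, axis=0), True


def project_neighborhood(
    model: EmbeddingModel, tokens: list[str], dims: int = 2
) -> dict[str, np.ndarray]:
    """Mean-centered PCA projection of a set of concepts onto ``dims`` axes.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so projections are reproducible across runs.
    """
    if len(tokens) < 3:
        raise ContractViolation("need at least 3 tokens to project")
    rows = []
    for tok in tokens:
        resolved = vector(model, tok)
        if resolved is None:
            raise AbsentVectorError(f"cannot resolve {tok!r}")
        rows.append(np.asarray(resolved[0], dtype=np.float64))
    X = np.vstack(rows)
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if np.sum(s > 1e-12 * max(s[0], 1e-300)) < dims:
        raise DegenerateProjectionError(
            f"point set has rank < {dims}; cannot project"
        )
    comps = vt[:dims]
    for i in range(dims):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    coords = Xc @ comps.T
    return {tok: coords[i] for i, tok in enumerate(tokens)}


def compress(
    model: EmbeddingModel, top_k: int, keep_buckets: bool = False
) -> EmbeddingModel:
    """Keep only the ``top_k`` highest-frequency concepts.

    Ranking is by training frequency, ties by lexicographic token order
    (the vocabulary's storage order).  Surviving vectors are untouched;
    subword bucket vectors are dropped unless ``keep_buckets`` (dropping
    them is what makes the compressed artifact small, at the price of no
    longer composing vectors for unseen tokens).  Token frequencies are
    retained for SIF weighting downstream.
    """
    if top_k < 1:
        raise ContractViolation("top_k must be >= 1")
    V = len(model.vocab)
    if top_k > V:
        warnings.warn(f"top_k={top_k} > vocabulary size {V}; keeping all")
        top_k = V
    # vocabulary storage order is already (count desc, token asc)
    tokens = model.vocab.tokens[:top_k]
    counts = model.vocab.counts[:top_k].copy()
    vocab = Vocabulary(tokens, counts, model.vocab.total_tokens)
    return EmbeddingModel(
        vectors=model.vectors[:top_k].copy(),
        context_vectors=(
            model.context_vectors[:top_k].copy()
            if model.context_vectors is not None
            else None
        ),
        bucket_vectors=(
            model.bucket_vectors.copy()
            if keep_buckets and model.bucket_vectors is not None
            else None
        ),
        vocab=vocab,
        config=replace(model.config),
        epoch_losses=model.epoch_losses,
        input_vectors=(
            model.input_vectors[:top_k].copy()
            if model.input_vectors is not None
            else None
        ),
    )
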