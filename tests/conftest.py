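import numpy as np
import pytest

from conceptvec.synthcorpus import SyntheticSpec, generate_corpus
from conceptvec.trainer import (
    EmbeddingModel,
    TrainingConfig,
    Vocabulary,
    desk_scale_config,
    train,
)


def make_model(
    tokens: list[str],
    vectors,
    counts: list[int] | None = None,
    bucket_count: int = 2**10,
    seed: int = 0,
    with_buckets: bool = True,
) -> EmbeddingModel:
    """Hand-built embedding model for unit tests.

    ``tokens`` must already be in vocabulary storage order
    (count descending, ties lexicographic).
    """
    vectors = np.asarray(vectors, dtype=np.float32)
    if counts is None:
        counts = list(range(len(tokens) + 4, 4, -1))
    counts_arr = np.asarray(counts, dtype=np.int64)
    vocab = Vocabulary(list(tokens), counts_arr, int(counts_arr.sum()))
    dim = vectors.shape[1]
    cfg = TrainingConfig(dim=dim, bucket_count=bucket_count, min_count=1, seed=seed)
    rng = np.random.default_rng(seed)
    buckets = (
        ((rng.random((bucket_count, dim)) - 0.5) / dim).astype(np.float32)
        if with_buckets
        else None
    )
    return EmbeddingModel(
        vectors=vectors,
        context_vectors=None,
        bucket_vectors=buckets,
        vocab=vocab,
        config=cfg,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """2000-sentence synthetic corpus with planted structure."""
    return generate_corpus(SyntheticSpec(n_sentences=2000, seed=11))


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """Embeddings trained once on the small corpus (desk-scale config)."""
    return train(small_corpus.sentences, desk_scale_config(seed=11))
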