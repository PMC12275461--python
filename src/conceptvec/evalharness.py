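"""Benchmark protocols: OOV accounting and Pearson correlation evaluation.

Concept benchmarks (UMNSRS/MayoSRS-style tables of term pairs with human
similarity judgements) are scored by cosine similarity of the resolved
term vectors; pairs with at least one out-of-vocabulary side are excluded
from the correlation, and the exclusion counts are reported alongside r so
a low-coverage model cannot silently look good.  A term is OOV iff its
normalized "_"-joined form is absent from the vocabulary (subword
composition does not rescue it).  Sentence benchmarks (BIOSSES-style) use
the sentence scorers; distance scores are negated before correlating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from conceptvec.augment import PhraseModel, format_entity_id
from conceptvec.errors import AbsentVectorError
from conceptvec.preprocess import Normalizer
from conceptvec.sentsim import SifConfig, sentence_similarity
from conceptvec.trainer import EmbeddingModel
from conceptvec.types import PairBenchmark
from conceptvec.vectorstore import cosine, term_vector

__all__ = [
    "BenchmarkResult",
    "OovReport",
    "pearson",
    "oov_ratio",
    "concept_benchmark",
    "sentence_benchmark",
]


@dataclass
class BenchmarkResult:
    pearson_r: float  # nan when undefined
    defined: bool
    n_pairs_used: int
    n_pairs_excluded: int
    oov_terms: int
    total_terms: int

    def __post_init__(self) -> None:
        if self.defined and not (-1.0 <= self.pearson_r <= 1.0):
            raise ValueError("pearson_r out of range")


@dataclass
class OovReport:
    ratio_pct: float          # OOV distinct terms / distinct terms, percent
    n_oov_terms: int
    n_distinct_terms: int
    n_oov_mentions: int       # term occurrences, the alternative denominator
    n_mentions: int


def pearson(x, y) -> tuple[float, bool]:
    """Product-moment correlation; (nan, False) on short or zero-variance input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        return float("nan"), False
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), False
    r = float(stats.pearsonr(x, y).statistic)
    return r, math.isfinite(r)


def _term_is_oov(
    model: EmbeddingModel, term: str, normalizer: Normalizer | None
) -> bool:
    try:
        _, oov = term_vector(model, term, normalizer)
    except AbsentVectorError:
        return True
    return oov


def oov_ratio(
    model: EmbeddingModel,
    benchmark: PairBenchmark,
    normalizer: Normalizer | None = None,
) -> OovReport:
    """Percentage of distinct benchmark terms absent from the vocabulary."""
    seen: dict[str, bool] = {}
    n_mentions = 0
    n_oov_mentions = 0
    for rec in benchmark:
        for term in (rec.term1, rec.term2):
            n_mentions += 1
            if term not in seen:
                seen[term] = _term_is_oov(model, term, normalizer)
            if seen[term]:
                n_oov_mentions += 1
    n_distinct = len(seen)
    n_oov = sum(seen.values())
    pct = 100.0 * n_oov / n_distinct if n_distinct else 0.0
    return OovReport(pct, n_oov, n_distinct, n_oov_mentions, n_mentions)


def _resolve_concept(
    model: EmbeddingModel,
    term: str | None,
    id_mode: str,
    id_map: dict[str, str] | None,
    normalizer: Normalizer | None,
):
    """Return (vector, usable flag) for one side of a benchmark pair."""
    if term is None or term == "":
        return None, False
    if id_mode == "ontology":
        token = id_map.get(term) if id_map is not None else term.lower()
        if token is None:
            return None, False
        idx = model.vocab.index.get(token)
        if idx is None:
            return None, False
        return model.vectors[idx], True
    try:
        vec, oov = term_vector(model, term, normalizer)
    except AbsentVectorError:
        return None, False
    if oov:
        return None, False
    return vec, True


def concept_benchmark(
    model: EmbeddingModel,
    benchmark: PairBenchmark,
    id_mode: str = "term",
    id_map: dict[str, str] | None = None,
    normalizer: Normalizer | None = None,
) -> BenchmarkResult:
    """Pearson r between model cosine and human score over in-vocabulary pairs.

    ``id_mode="term"`` resolves the surface terms; ``id_mode="ontology"``
    resolves the pair's identifier columns, optionally routed through an
    external ``id_map`` (e.g. CUI -> ``disease_mesh_d005356``).  Unmapped or
    unresolvable identifiers count as OOV and exclude the pair.
    """
    oov_flags: dict[str, bool] = {}
    cosines: list[float] = []
    humans: list[float] = []
    excluded = 0
    for rec in benchmark:
        if id_mode == "ontology":
            k1, k2 = rec.id1, rec.id2
        else:
            k1, k2 = rec.term1, rec.term2
        v1, ok1 = _resolve_concept(model, k1, id_mode, id_map, normalizer)
        v2, ok2 = _resolve_concept(model, k2, id_mode, id_map, normalizer)
        for key, ok in ((k1, ok1), (k2, ok2)):
            if key:
                oov_flags[key] = oov_flags.get(key, True) and not ok
        if not (ok1 and ok2):
            excluded += 1
            continue
        cosines.append(cosine(v1, v2))
        humans.append(rec.human_score)
    r, defined = pearson(cosines, humans)
    return BenchmarkResult(
        pearson_r=r,
        defined=defined,
        n_pairs_used=len(cosines),
        n_pairs_excluded=excluded,
        oov_terms=sum(oov_flags.values()),
        total_terms=len(oov_flags),
    )


def sentence_benchmark(
    model: EmbeddingModel,
    pairs: list[tuple[str, str, float]],
    phrase_model: PhraseModel | None = None,
    method: str = "wmd",
    sif: SifConfig | None = None,
    human_score_kind: str = "similarity",
    **kwargs,
) -> BenchmarkResult:
    """Pearson r between sentence scores and human judgements.

    Distance-kind scores (WMD) are multiplied by -1 before correlating so
    that r is comparable across scorers; the same negation applies to the
    human scores when ``human_score_kind`` is "distance".  Pairs whose
    sentences cannot be resolved at all are excluded and counted.
    """
    scores: list[float] = []
    humans: list[float] = []
    excluded = 0
    for s1, s2, human in pairs:
        try:
            score, kind = sentence_similarity(
                s1, s2, model, phrase_model, method=method, sif=sif, **kwargs
            )
        except AbsentVectorError:
            excluded += 1
            continue
        except Exception as exc:  # empty-sentence errors exclude the pair
            from conceptvec.errors import EmptySentenceError

            if isinstance(exc, EmptySentenceError):
                excluded += 1
                continue
            raise
        if kind == "distance":
            score = -score
        scores.append(score)
        humans.append(-human if human_score_kind == "distance" else human)
    r, defined = pearson(scores, humans)
    return BenchmarkResult(
        pearson_r=r,
        defined=defined,
        n_pairs_used=len(scores),
        n_pairs_excluded=excluded,
        oov_terms=0,
        total_terms=0,
    )


def render_id_map(raw_map: dict[str, tuple[str, str]]) -> dict[str, str]:
    """Turn {external_id: (entity_type, raw_id)} into rendered surrogate tokens."""
    return {k: format_entity_id(t, i) for k, (t, i) in raw_map.items()}
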