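"""Shared domain types.

Offset convention: all character offsets are 0-based, half-open.  Entity
annotation offsets index the concatenation ``title + " " + abstract`` of
their document (the public PubTator dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Closed set of entity-annotation types carried through the pipeline.
ENTITY_TYPES = frozenset({"gene", "disease", "chemical", "mutation", "species"})

SCORE_KINDS = ("similarity", "distance")


@dataclass(frozen=True)
class AnnotatedSpan:
    """One entity mention: character range, surface text, type and identifier."""

    start: int
    end: int
    mention: str
    entity_type: str
    entity_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span range [{self.start}, {self.end})")


@dataclass
class Document:
    """A title+abstract text unit with its entity annotations."""

    doc_id: str
    title: str
    abstract: str
    spans: list[AnnotatedSpan] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Concatenated text the span offsets index."""
        return self.title + " " + self.abstract


@dataclass(frozen=True)
class BenchmarkRecord:
    term1: str
    term2: str
    human_score: float
    id1: str | None = None
    id2: str | None = None


@dataclass
class PairBenchmark:
    """A term-pair benchmark with human judgements.

    ``score_kind`` records whether larger human scores mean closer
    ("similarity") or farther ("distance") pairs.
    """

    records: list[BenchmarkRecord]
    score_kind: str = "similarity"

    def __post_init__(self) -> None:
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"score_kind must be one of {SCORE_KINDS}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class Sentence:
    """Normalized token sequence with per-token source character ranges.

    ``source_ranges[i]`` is the (start, end) slice of the raw paragraph the
    i-th token was derived from; ranges are strictly increasing and
    non-overlapping so annotation offsets can be mapped onto token runs.
    """

    tokens: list[str]
    source_ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.source_ranges):
            raise ValueError("tokens and source_ranges length mismatch")

    def __len__(self) -> int:
        return len(self.tokens)

    def validate(self) -> None:
        """Assert the full Sentence invariant (used by tests)."""
        prev_end = -1
        for tok, (s, e) in zip(self.tokens, self.source_ranges):
            if not tok or any(c.isspace() for c in tok):
                raise ValueError(f"bad token {tok!r}")
            if not (prev_end <= s < e):
                raise ValueError(f"ranges not increasing at {tok!r}")
            prev_end = e
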