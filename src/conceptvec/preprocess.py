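"""Sentence segmentation and token normalization.

The same normalizer is used when building the training corpus and when
encoding queries, so that a query token can only hit the vocabulary if the
identical surface form was produced at training time.

Both the sentence splitter and the lemmatizer are deliberately small,
rule-based and pluggable.  The contract downstream stages rely on is not
linguistic perfection but (a) determinism and (b) idempotence:
``normalize(normalize(s)) == normalize(s)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

__all__ = [
    "DEFAULT_ABBREVIATIONS",
    "Normalizer",
    "default_lemmatizer",
    "normalize_sentence",
    "split_sentences",
]

#: Abbreviations that must not terminate a sentence even though they end in ".".
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "et al.", "etc.", "cf.", "ca.", "vs.", "fig.", "figs.",
        "dr.", "prof.", "no.", "nos.", "approx.", "resp.", "spp.", "sp.",
    }
)

# Sentence boundary: terminator run, whitespace, then an upper-case letter or digit.
_BOUNDARY = re.compile(r"[.!?]+[)\]\"']*\s+(?=[A-Z0-9])")

_TOKEN = re.compile(r"\S+")


def split_sentences(
    paragraph: str,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[str, int]]:
    """Split a raw paragraph into sentences.

    Returns ``[(sentence_text, start_offset), ...]`` where ``start_offset``
    is the character position of the sentence in ``paragraph``.  A candidate
    boundary is suppressed when the token ending at it is a known
    abbreviation (case-insensitive).
    """
    if not paragraph.strip():
        return []
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(paragraph):
        head = paragraph[: m.end()].rstrip()
        last_tok = head.split()[-1].lower() if head.split() else ""
        if last_tok in abbreviations:
            continue
        cuts.append(m.end())
    out: list[tuple[str, int]] = []
    start = 0
    for cut in cuts + [len(paragraph)]:
        chunk = paragraph[start:cut]
        stripped = chunk.strip()
        if stripped:
            lead = len(chunk) - len(chunk.lstrip())
            out.append((stripped, start + lead))
        start = cut
    return out


def default_lemmatizer(token: str) -> str:
    """Suffix-stripping English lemmatizer (plural -s/-es/-ies, -ing, -ed).

    Guards are chosen so the map is idempotent: a stripped form never
    matches a rule again.  Input is expected lowercase.
    """
    n = len(token)
    if n > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if n > 4 and token.endswith("sses"):
        return token[:-2]
    if n > 4 and token.endswith("es") and token[-3] in "xzo":
        return token[:-2]
    if (
        n > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is", "ys"))
    ):
        return token[:-1]
    if n >= 6 and token.endswith("ing"):
        stem = token[:-3]
        if len(stem) >= 3 and stem[-1] not in "aeiou":
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "sl":
                stem = stem[:-1]
            return stem
    if n >= 5 and token.endswith("ed"):
        stem = token[:-2]
        # refuse when the stem itself ends in e/ed-prone shapes: keeps idempotence
        if len(stem) >= 3 and stem[-1] not in "aeiou":
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "sl":
                stem = stem[:-1]
            if not (len(stem) >= 5 and stem.endswith("ed")):
                return stem
    return token


@dataclass
class Normalizer:
    """Token-normalization policy applied identically at train and query time.

    Characters kept: letters, digits, "_", plus "-" between two
    alphanumerics and "." between two digits (so gene symbols like
    ``nf-kb`` and dosages like ``0.5`` survive); everything else —
    punctuation, parentheses, special characters — is deleted.
    """

    lowercase: bool = True
    lemmatize: bool = True
    lemmatizer: Callable[[str], str] = field(default=default_lemmatizer, repr=False)

    def normalize_token(self, raw: str) -> str:
        tok = raw.lower() if self.lowercase else raw
        kept: list[str] = []
        for i, ch in enumerate(tok):
            if ch.isalnum() or ch == "_":
                kept.append(ch)
            elif ch == "-":
                if 0 < i < len(tok) - 1 and tok[i - 1].isalnum() and tok[i + 1].isalnum():
                    kept.append(ch)
            elif ch == ".":
                if 0 < i < len(tok) - 1 and tok[i - 1].isdigit() and tok[i + 1].isdigit():
                    kept.append(ch)
        cleaned = "".join(kept)
        if self.lemmatize and cleaned:
            # iterate to a fixpoint: every rule strictly shortens the token,
            # so this terminates and makes normalization idempotent even when
            # one stripped suffix exposes another ("dressings" -> "dress")
            for _ in range(16):  # bounded: guards against cyclic plug-ins
                nxt = self.lemmatizer(cleaned)
                if nxt == cleaned:
                    break
                cleaned = nxt
        return cleaned


from conceptvec.types import Sentence  # noqa: E402  (avoid cycle at import time)


def normalize_sentence(
    raw: str, normalizer: Normalizer | None = None, offset: int = 0
) -> Sentence:
    """Normalize one raw sentence into a :class:`Sentence`.

    ``offset`` is the sentence's start position in its paragraph so that
    ``source_ranges`` index the paragraph, not the sentence slice.  Tokens
    reduced to the empty string by stripping are dropped.
    """
    normalizer = normalizer or Normalizer()
    tokens: list[str] = []
    ranges: list[tuple[int, int]] = []
    for m in _TOKEN.finditer(raw):
        norm = normalizer.normalize_token(m.group())
        if norm:
            tokens.append(norm)
            ranges.append((offset + m.start(), offset + m.end()))
    return Sentence(tokens, ranges)


def normalize_paragraph(
    paragraph: str, normalizer: Normalizer | None = None
) -> list[Sentence]:
    """Split a paragraph and normalize every sentence (offsets preserved)."""
    return [
        normalize_sentence(text, normalizer, offset=off)
        for text, off in split_sentences(paragraph)
    ]


def normalize_corpus(
    lines: Iterable[str], normalizer: Normalizer | None = None
) -> Iterable[Sentence]:
    """Lazily normalize an iterable of paragraphs into sentences."""
    normalizer = normalizer or Normalizer()
    for line in lines:
        yield from normalize_paragraph(line, normalizer)
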