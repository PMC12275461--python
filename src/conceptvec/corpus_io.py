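"""Readers/writers for every on-disk format the pipeline touches.

Formats:

* PubTator offset format (read): ``PMID|t|<title>`` and ``PMID|a|<abstract>``
  lines followed by ``PMID<TAB>start<TAB>end<TAB>mention<TAB>type<TAB>id``
  annotation lines, blank line between documents.  Offsets are 0-based,
  half-open, indexing ``title + " " + abstract``.
* Pair benchmarks (read): TSV with a header; column names configurable.
* Plain-text corpora (read/write): one sentence per line, UTF-8,
  space-delimited tokens; ``.gz`` paths handled transparently.
* Vectors (read/write): the word2vec text format (``"V dim"`` header then
  one ``token v1 .. vdim`` row per token), with subword bucket vectors in an
  optional TSV sidecar ``<path>.subwords`` (versioned header line
  ``#conceptvec-subwords 1 <bucket_count> <dim> <minn> <maxn>``).

All readers are streaming; memory is bounded by the largest single document.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from conceptvec.errors import ContractViolation, FormatError
from conceptvec.types import (
    ENTITY_TYPES,
    AnnotatedSpan,
    BenchmarkRecord,
    Document,
    PairBenchmark,
)

__all__ = [
    "PubtatorResult",
    "read_pubtator",
    "read_pair_benchmark",
    "stream_corpus",
    "write_corpus",
    "write_vectors",
    "read_vectors",
]


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------- PubTator


@dataclass
class PubtatorResult:
    """Documents parsed from a PubTator file plus recoverable-problem counters."""

    documents: list[Document] = field(default_factory=list)
    n_spans_dropped_mismatch: int = 0
    n_spans_dropped_type: int = 0
    line_errors: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


def read_pubtator(path: str | Path) -> PubtatorResult:
    """Parse a PubTator offset-format file into Documents.

    Spans whose mention text does not equal the offset slice of
    ``title + " " + abstract``, or whose type is outside the closed entity
    set, are dropped and counted.  Lines with the wrong field count are
    recorded as (line_number, message) errors and skipped.
    """
    res = PubtatorResult()
    title = abstract = ""
    doc_id: str | None = None
    pending: list[tuple[int, int, int, str, str, str]] = []

    def flush() -> None:
        nonlocal title, abstract, doc_id, pending
        if doc_id is None:
            return
        doc = Document(doc_id, title, abstract)
        text = doc.text
        for lineno, start, end, mention, etype, eid in pending:
            if etype not in ENTITY_TYPES:
                res.n_spans_dropped_type += 1
                continue
            if text[start:end] != mention:
                res.n_spans_dropped_mismatch += 1
                continue
            doc.spans.append(AnnotatedSpan(start, end, mention, etype, eid))
        res.documents.append(doc)
        title = abstract = ""
        doc_id = None
        pending = []

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if "|t|" in line or "|a|" in line:
                parts = line.split("|", 2)
                if len(parts) != 3 or parts[1] not in ("t", "a"):
                    res.line_errors.append((lineno, "malformed title/abstract line"))
                    continue
                pmid, kind, text_part = parts
                if doc_id is not None and pmid != doc_id:
                    flush()
                doc_id = pmid
                if kind == "t":
                    title = text_part
                else:
                    abstract = text_part
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                res.line_errors.append(
                    (lineno, f"expected 6 tab-separated fields, got {len(fields)}")
                )
                continue
            pmid, s, e, mention, etype, eid = fields
            if doc_id is None:
                res.line_errors.append((lineno, "annotation before title line"))
                continue
            try:
                start, end = int(s), int(e)
            except ValueError:
                res.line_errors.append((lineno, "non-integer offsets"))
                continue
            if not (0 <= start < end):
                res.line_errors.append((lineno, "invalid offset range"))
                continue
            pending.append((lineno, start, end, mention, etype, eid))
    flush()
    return res


def write_pubtator(documents: Iterable[Document], path: str | Path) -> int:
    """Serialize Documents in PubTator offset format (inverse of read_pubtator)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for doc in documents:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for sp in doc.spans:
                fh.write(
                    f"{doc.doc_id}\t{sp.start}\t{sp.end}\t{sp.mention}"
                    f"\t{sp.entity_type}\t{sp.entity_id}\n"
                )
            fh.write("\n")
            n += 1
    return n


# ---------------------------------------------------------- pair benchmarks

DEFAULT_COLUMN_MAP = {"term1": "term1", "term2": "term2", "score": "score",
                      "id1": "id1", "id2": "id2"}


def read_pair_benchmark(
    path: str | Path,
    score_kind: str = "similarity",
    column_map: dict[str, str] | None = None,
) -> tuple[PairBenchmark, list[tuple[int, str]]]:
    """Read a TSV term-pair benchmark.

    ``column_map`` maps logical names (term1, term2, score, id1, id2) to the
    file's header names; id columns are optional.  Returns the benchmark and
    a list of (row_index, message) recoverable row errors (e.g. non-numeric
    scores).  A missing mandatory column raises :class:`FormatError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    errors: list[tuple[int, str]] = []
    records: list[BenchmarkRecord] = []
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for logical in ("term1", "term2", "score"):
            if cmap[logical] not in col:
                raise FormatError(
                    f"{path}: mandatory column {cmap[logical]!r} absent from header"
                )
        i1, i2, isc = (col[cmap[k]] for k in ("term1", "term2", "score"))
        iid1 = col.get(cmap["id1"])
        iid2 = col.get(cmap["id2"])
        for rowno, raw in enumerate(fh):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < len(header):
                errors.append((rowno, "short row"))
                continue
            t1, t2 = fields[i1], fields[i2]
            if not t1 or not t2:
                errors.append((rowno, "empty term"))
                continue
            try:
                score = float(fields[isc])
            except ValueError:
                errors.append((rowno, f"non-numeric score {fields[isc]!r}"))
                continue
            if not np.isfinite(score):
                errors.append((rowno, "non-finite score"))
                continue
            records.append(
                BenchmarkRecord(
                    t1, t2, score,
                    fields[iid1] if iid1 is not None else None,
                    fields[iid2] if iid2 is not None else None,
                )
            )
    return PairBenchmark(records, score_kind), errors


def read_sentence_pairs(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a sentence-pair benchmark TSV with columns sentence1/sentence2/score."""
    out: list[tuple[str, str, float]] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for key in ("sentence1", "sentence2", "score"):
            if key not in col:
                raise FormatError(f"{path}: column {key!r} absent")
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            out.append(
                (fields[col["sentence1"]], fields[col["sentence2"]],
                 float(fields[col["score"]]))
            )
    return out


# ----------------------------------------------------------------- corpora


def stream_corpus(path: str | Path) -> Iterator[str]:
    """Yield corpus lines lazily, trailing newline stripped."""
    with _open_text(path) as fh:
        for line in fh:
            yield line.rstrip("\n")


def write_corpus(sentences: Iterable[Sequence[str]], path: str | Path) -> int:
    """Write token sequences one per line, space-delimited; returns line count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for sent in sentences:
            toks = list(sent)
            if not toks:
                raise ContractViolation("empty sentence")
            for tok in toks:
                if not tok or any(c.isspace() for c in tok):
                    raise ContractViolation(f"token contains whitespace: {tok!r}")
            fh.write(" ".join(toks))
            fh.write("\n")
            n += 1
    return n


# ----------------------------------------------------------------- vectors

_SUBWORD_MAGIC = "#conceptvec-subwords 1"


def write_vectors(model, path: str | Path, include_subwords: bool = True) -> None:
    """Write vocabulary vectors in word2vec text format.

    Subword bucket vectors (if the model has them) go to the sidecar
    ``<path>.subwords`` so the main file stays interoperable with standard
    tooling.
    """
    vocab = model.vocab
    if len(vocab) < 1:
        raise ContractViolation("model has no vocabulary vectors")
    dim = model.vectors.shape[1]
    with _open_text(path, "wt") as fh:
        fh.write(f"{len(vocab)} {dim}\n")
        for i, tok in enumerate(vocab.tokens):
            vals = " ".join(repr(float(x)) for x in model.vectors[i])
            fh.write(f"{tok} {vals}\n")
    if include_subwords and model.bucket_vectors is not None:
        cfg = model.config
        with _open_text(str(path) + ".subwords", "wt") as fh:
            fh.write(
                f"{_SUBWORD_MAGIC} {model.bucket_vectors.shape[0]} {dim} "
                f"{cfg.minn} {cfg.maxn}\n"
            )
            for b in range(model.bucket_vectors.shape[0]):
                vals = " ".join(repr(float(x)) for x in model.bucket_vectors[b])
                fh.write(f"{b}\t{vals}\n")


def read_vectors(path: str | Path):
    """Read a word2vec text file (plus optional subword sidecar) into a model.

    Returns a vocabulary-only :class:`~conceptvec.trainer.EmbeddingModel`
    (context vectors are not serialized; counts default to 1 per token when
    no frequency information is available).
    """
    from conceptvec.trainer import EmbeddingModel, TrainingConfig, Vocabulary

    tokens: list[str] = []
    rows: list[np.ndarray] = []
    with _open_text(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: bad header")
        count, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise FormatError(
                    f"{path}: row for {parts[0]!r} has {len(parts) - 1} values, "
                    f"expected {dim}"
                )
            tokens.append(parts[0])
            rows.append(np.asarray([float(x) for x in parts[1:]], dtype=np.float32))
    if len(tokens) != count:
        raise FormatError(f"{path}: header count {count} != {len(tokens)} rows")
    vectors = np.vstack(rows) if rows else np.zeros((0, dim), dtype=np.float32)

    bucket_vectors = None
    minn = maxn = None
    sidecar = Path(str(path) + ".subwords")
    if sidecar.exists():
        with _open_text(sidecar) as fh:
            head = fh.readline().rstrip("\n").split()
            if " ".join(head[:2]) != _SUBWORD_MAGIC:
                raise FormatError(f"{sidecar}: unknown sidecar version")
            n_buckets, sdim, minn, maxn = (int(x) for x in head[2:6])
            if sdim != dim:
                raise FormatError(f"{sidecar}: dimension {sdim} != {dim}")
            bucket_vectors = np.zeros((n_buckets, dim), dtype=np.float32)
            for line in fh:
                bid, vals = line.rstrip("\n").split("\t")
                bucket_vectors[int(bid)] = [float(x) for x in vals.split(" ")]

    counts = np.ones(len(tokens), dtype=np.int64)
    vocab = Vocabulary(tokens, counts, total_tokens=int(counts.sum()))
    cfg = TrainingConfig(dim=dim)
    if minn is not None:
        cfg.minn, cfg.maxn = minn, maxn
    if bucket_vectors is not None:
        cfg.bucket_count = bucket_vectors.shape[0]
    return EmbeddingModel(
        vectors=vectors,
        context_vectors=None,
        bucket_vectors=bucket_vectors,
        vocab=vocab,
        config=cfg,
    )
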