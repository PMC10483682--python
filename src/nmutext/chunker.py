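"""IOB tag sequences to labelled entity spans ("chunks") and back.

Downstream analyses want entities as spans with surface text, not per-token
tags. ``iob_to_chunks`` extracts one span per maximal B-X (I-X)* run and drops
O tokens; ``repair_iob`` first rewrites illegal sequences using the
treat-stray-I-as-begin convention (conlleval-compatible); ``chunks_to_iob`` is
the exact inverse on legal input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .ner import LabeledSequence, TagSchema

__all__ = ["EntitySpan", "repair_iob", "iob_to_chunks", "chunks_to_iob", "write_chunks_tsv"]


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open token span [start, end) carrying one entity label."""

    start: int
    end: int
    label: str
    text: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def repair_iob(tags: Sequence[str], schema: TagSchema) -> list[str]:
    """Rewrite an illegal IOB sequence into legal IOB2; legal input is unchanged.

    A stray I-X (no adjacent preceding B-X/I-X) becomes B-X; an I-Y directly
    after a different entity type becomes B-Y. Idempotent.
    """
    known = set(schema.tags)
    out: list[str] = []
    prev = "O"
    for tag in tags:
        if tag not in known:
            raise ValueError(f"unknown tag {tag!r}")
        if tag.startswith("I-"):
            lab = tag[2:]
            if prev not in (f"B-{lab}", f"I-{lab}"):
                tag = f"B-{lab}"
        out.append(tag)
        prev = tag
    return out


def iob_to_chunks(seq: LabeledSequence) -> list[EntitySpan]:
    """One span per maximal B-X (I-X)* run; O tokens produce nothing.

    Raises on illegal sequences; call :func:`repair_iob` first for raw output.
    """
    spans: list[EntitySpan] = []
    start: int | None = None
    label = ""
    for i, tag in enumerate(seq.tags):
        if tag.startswith("I-"):
            if start is None or tag[2:] != label:
                raise ValueError(
                    f"illegal IOB2 at position {i} ({tag!r}); run repair_iob first"
                )
            continue
        if start is not None:
            spans.append(
                EntitySpan(start, i, label, " ".join(seq.tokens[start:i]))
            )
            start = None
        if tag.startswith("B-"):
            start = i
            label = tag[2:]
        elif tag != "O":
            raise ValueError(f"unknown tag {tag!r}")
    if start is not None:
        spans.append(
            EntitySpan(start, len(seq.tags), label, " ".join(seq.tokens[start:]))
        )
    return spans


def chunks_to_iob(spans: Sequence[EntitySpan], length: int) -> list[str]:
    """Exact inverse of :func:`iob_to_chunks` for non-overlapping in-range spans."""
    tags = ["O"] * length
    last_end = -1
    for span in sorted(spans):
        if span.start < last_end:
            raise ValueError("overlapping spans")
        if span.end > length:
            raise ValueError("span exceeds sequence length")
        tags[span.start] = f"B-{span.label}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.label}"
        last_end = span.end
    return tags


def write_chunks_tsv(
    records: Iterable[tuple[str, Sequence[EntitySpan]]], path: str | Path
) -> None:
    """TSV export: record_id, start, end, label, text — one row per chunk."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("record_id\tstart\tend\tlabel\ttext\n")
        for record_id, spans in records:
            for s in spans:
                fh.write(f"{record_id}\t{s.start}\t{s.end}\t{s.label}\t{s.text}\n")
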