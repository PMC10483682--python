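"""Text cleaning, rule-based sentence splitting, and tokenization.

Social-media text arrives noisy: URLs, @-mentions, hashtags, control characters,
erratic casing and punctuation. ``clean_text`` normalizes a raw post while logging
what was removed; ``split_sentences`` finds sentence boundaries from terminal
punctuation (periods, exclamation/question marks, with ellipsis runs collapsed);
``tokenize`` produces offset-tracked tokens; ``build_token_matrix`` assembles the
record-by-token count matrix consumed by the topic-modelling stage.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import scipy.sparse as sp

__all__ = [
    "CleanText",
    "TokenizedRecord",
    "TokenMatrix",
    "clean_text",
    "split_sentences",
    "tokenize",
    "build_token_matrix",
    "export_token_matrix",
]


@dataclass
class CleanText:
    """Normalized text plus a log of removed character spans (in raw coordinates)."""

    text: str
    removed_spans: list[tuple[int, int, str]] = field(default_factory=list)


_URL_RE = re.compile(r"https?://\S+|www\.\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")


def clean_text(raw: str) -> CleanText:
    """Lowercase and normalize a raw post.

    URLs, @-mentions and control characters are removed and logged with their raw
    character spans; '#' is stripped from hashtags (the word is kept); whitespace
    is collapsed to single spaces. Idempotent: cleaning a clean text is a no-op.
    """
    removed: list[tuple[int, int, str]] = []
    mask = [False] * len(raw)
    for regex, reason in ((_URL_RE, "url"), (_MENTION_RE, "mention")):
        for m in regex.finditer(raw):
            removed.append((m.start(), m.end(), reason))
            for i in range(m.start(), m.end()):
                mask[i] = True
    for i, ch in enumerate(raw):
        if not mask[i] and unicodedata.category(ch) == "Cc" and ch not in "\t\n\r":
            removed.append((i, i + 1, "control"))
            mask[i] = True
    kept = "".join(" " if mask[i] else ch for i, ch in enumerate(raw))
    kept = kept.replace("#", "")
    kept = " ".join(kept.lower().split())
    removed.sort()
    return CleanText(text=kept, removed_spans=removed)


_TERMINAL = {".", "!", "?", "…"}


def split_sentences(text: CleanText | str) -> list[tuple[int, int]]:
    """Return ordered, disjoint (start, end) character spans, one per sentence.

    A sentence ends at a maximal run of terminal punctuation (so ellipses and
    "?!" runs mark a single boundary); trailing text without terminal
    punctuation forms a final sentence. Spans cover every non-whitespace char.
    """
    s = text.text if isinstance(text, CleanText) else text
    spans: list[tuple[int, int]] = []
    start: int | None = None
    i = 0
    n = len(s)
    while i < n:
        ch = s[i]
        if start is None:
            if not ch.isspace():
                start = i
            i += 1
            continue
        if ch in _TERMINAL:
            j = i
            while j < n and s[j] in _TERMINAL:
                j += 1
            spans.append((start, j))
            start = None
            i = j
        else:
            i += 1
    if start is not None:
        end = n
        while end > start and s[end - 1].isspace():
            end -= 1
        spans.append((start, end))
    return spans


@dataclass
class TokenizedRecord:
    """Offset-tracked tokens of one record, grouped by sentence."""

    record_id: str
    sentences: list[list[str]]
    tokens: list[str]
    char_offsets: list[tuple[int, int]]


# Maximal alphanumeric runs; any other non-space character (punctuation, emoji)
# is its own single-character token.
_TOKEN_RE = re.compile(r"[^\W_]+|\S", re.UNICODE)


def tokenize(text: CleanText | str, record_id: str = "") -> TokenizedRecord:
    """Tokenize cleaned text into words and single punctuation marks.

    ``char_offsets`` are half-open spans into the cleaned text; concatenating the
    per-sentence token lists reproduces the flat token list.
    """
    s = text.text if isinstance(text, CleanText) else text
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(s):
        tokens.append(m.group())
        offsets.append((m.start(), m.end()))
    sentences: list[list[str]] = []
    sent_spans = split_sentences(s)
    k = 0
    for s_start, s_end in sent_spans:
        sent: list[str] = []
        while k < len(tokens) and offsets[k][0] < s_end:
            sent.append(tokens[k])
            k += 1
        sentences.append(sent)
    # any stragglers (cannot happen when spans cover all non-whitespace)
    if k < len(tokens):
        sentences.append(tokens[k:])
    return TokenizedRecord(
        record_id=record_id, sentences=sentences, tokens=tokens, char_offsets=offsets
    )


@dataclass
class TokenMatrix:
    """Record-by-token count matrix with a first-occurrence-ordered vocabulary."""

    rows: list[TokenizedRecord]
    vocabulary: dict[str, int]
    counts: sp.csr_matrix

    @property
    def terms(self) -> list[str]:
        return list(self.vocabulary)


def build_token_matrix(records: Sequence[TokenizedRecord]) -> TokenMatrix:
    """Assemble the count matrix; vocabulary indices follow first occurrence."""
    if not records:
        raise ValueError("build_token_matrix requires at least one record")
    vocab: dict[str, int] = {}
    data: list[int] = []
    indices: list[int] = []
    indptr = [0]
    for rec in records:
        row: dict[int, int] = {}
        for tok in rec.tokens:
            j = vocab.setdefault(tok, len(vocab))
            row[j] = row.get(j, 0) + 1
        for j in sorted(row):
            indices.append(j)
            data.append(row[j])
        indptr.append(len(indices))
    counts = sp.csr_matrix(
        (data, indices, indptr), shape=(len(records), max(len(vocab), 1)), dtype=int
    )
    return TokenMatrix(rows=list(records), vocabulary=vocab, counts=counts)


def export_token_matrix(matrix: TokenMatrix, mtx_path: str | Path, vocab_path: str | Path) -> None:
    """Write the counts as MTX-style sparse triplets plus a token<TAB>index TSV."""
    coo = matrix.counts.tocoo()
    with Path(mtx_path).open("w", encoding="utf-8") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v}\n")
    with Path(vocab_path).open("w", encoding="utf-8") as fh:
        for tok, idx in matrix.vocabulary.items():
            fh.write(f"{tok}\t{idx}\n")
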