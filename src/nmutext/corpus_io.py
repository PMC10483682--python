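"""Tweet corpus reading/writing, inclusion/exclusion filtering, and de-identification.

A corpus is an ordered collection of tweet-like records (id, pseudonymous user id,
UTC timestamp, text, medication tag, retweet/quote flags). Filtering applies the
surveillance-study rules — date window, English heuristic, medication-keyword match,
minimum length, no retweets/quotes, plus pluggable bot and non-medical-use
predicates — and attributes every removal to the first failing rule so that the
per-rule counts partition the removed set.
"""

from __future__ import annotations

import csv
import hashlib
import hmac
import io
import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Tweet",
    "Corpus",
    "FilterConfig",
    "FilterReport",
    "DEFAULT_KEYWORD_FAMILIES",
    "read_corpus",
    "write_corpus",
    "apply_filters",
    "deidentify",
    "CorpusError",
]


class CorpusError(ValueError):
    """Malformed corpus input: missing fields, bad timestamps, duplicate ids."""


#: Generic names, trade names and common misspellings for the four medications
#: under surveillance (two opioids, a benzodiazepine, and a stimulant).
DEFAULT_KEYWORD_FAMILIES: dict[str, tuple[str, ...]] = {
    "fentanyl": ("fentanyl", "fentanil", "fentynal", "fentanyl", "duragesic", "actiq"),
    "morphine": ("morphine", "morfine", "morphene", "ms contin", "kadian"),
    "alprazolam": ("alprazolam", "alprazolm", "xanax", "xanex", "zanax", "xans"),
    "adderall": ("adderall", "adderal", "aderall", "aderal", "addy", "addys"),
}


@dataclass(frozen=True)
class Tweet:
    """One record of the corpus.

    ``medication`` is the keyword-family tag assigned at collection time;
    ``user_id`` is raw until :func:`deidentify` replaces it with a keyed digest.
    """

    tweet_id: str
    user_id: str
    timestamp: datetime
    text: str
    medication: str = ""
    is_retweet: bool = False
    is_quote: bool = False

    def __post_init__(self) -> None:
        if not self.tweet_id:
            raise CorpusError("tweet_id must be non-empty")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))
        else:
            object.__setattr__(self, "timestamp", self.timestamp.astimezone(timezone.utc))


class Corpus:
    """An ordered, id-unique sequence of :class:`Tweet` records."""

    def __init__(self, tweets: Iterable[Tweet] = ()):
        self.tweets: list[Tweet] = list(tweets)
        seen: set[str] = set()
        for t in self.tweets:
            if t.tweet_id in seen:
                raise CorpusError(f"duplicate tweet_id {t.tweet_id!r}")
            seen.add(t.tweet_id)

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self.tweets)

    def __getitem__(self, i: int) -> Tweet:
        return self.tweets[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Corpus) and self.tweets == other.tweets


def _accept_all(_: object) -> bool:
    return True


def _latin_heuristic(text: str) -> bool:
    """English stand-in: >= 90% of non-space chars in Basic Latin, >= 1 ASCII letter."""
    chars = [c for c in text if not c.isspace()]
    if not chars:
        return False
    latin = sum(1 for c in chars if ord(c) < 128)
    has_letter = any(c.isascii() and c.isalpha() for c in chars)
    return has_letter and latin / len(chars) >= 0.9


@dataclass
class FilterConfig:
    """Inclusion/exclusion rules for :func:`apply_filters`.

    The date interval is closed on both ends and compared in UTC. Keyword matching
    is case-insensitive whole-token matching over the union of all family terms.
    ``bot_predicate`` and ``nmu_predicate`` are injection points for external
    classifiers; the defaults accept everything.
    """

    date_start: datetime = datetime(2021, 5, 31, tzinfo=timezone.utc)
    date_end: datetime = datetime(2021, 10, 31, 23, 59, 59, tzinfo=timezone.utc)
    keyword_families: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORD_FAMILIES)
    )
    min_tokens: int = 4
    language_predicate: Callable[[str], bool] = _latin_heuristic
    bot_predicate: Callable[[Tweet], bool] = _accept_all
    nmu_predicate: Callable[[Tweet], bool] = _accept_all

    def __post_init__(self) -> None:
        if self.date_start.tzinfo is None:
            self.date_start = self.date_start.replace(tzinfo=timezone.utc)
        if self.date_end.tzinfo is None:
            self.date_end = self.date_end.replace(tzinfo=timezone.utc)
        if self.date_start > self.date_end:
            raise ValueError("date_start must not exceed date_end")
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")
        for fam, terms in self.keyword_families.items():
            if not terms:
                raise ValueError(f"keyword family {fam!r} is empty")


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass; counts partition the removed records."""

    n_in: int = 0
    n_out: int = 0
    counts_removed: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"n_in": self.n_in, "n_out": self.n_out, "counts_removed": self.counts_removed},
            indent=2,
            sort_keys=True,
        )


#: Fixed attribution order: a removed tweet is charged to the FIRST failing rule.
RULE_ORDER = ("date", "language", "keyword", "length", "retweet_quote", "bot", "nmu")

_WORD_RE = re.compile(r"[a-z0-9']+")


def _word_tokens(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


def _failing_rule(tweet: Tweet, config: FilterConfig, keywords: frozenset[str]) -> str | None:
    if not (config.date_start <= tweet.timestamp <= config.date_end):
        return "date"
    if not config.language_predicate(tweet.text):
        return "language"
    tokens = _word_tokens(tweet.text)
    if not any(tok in keywords for tok in tokens):
        return "keyword"
    if len(tokens) < config.min_tokens:
        return "length"
    if tweet.is_retweet or tweet.is_quote:
        return "retweet_quote"
    if not config.bot_predicate(tweet):
        return "bot"
    if not config.nmu_predicate(tweet):
        return "nmu"
    return None


def apply_filters(corpus: Corpus, config: FilterConfig) -> tuple[Corpus, FilterReport]:
    """Apply all inclusion/exclusion rules; never raises on record content.

    Multi-word keyword terms contribute their individual words to the match set
    (whole-token matching), so "ms contin" matches a tweet containing "contin".
    """
    keywords = frozenset(
        word
        for terms in config.keyword_families.values()
        for term in terms
        for word in _word_tokens(term)
    )
    kept: list[Tweet] = []
    counts: dict[str, int] = {}
    for tweet in corpus:
        rule = _failing_rule(tweet, config, keywords)
        if rule is None:
            kept.append(tweet)
        else:
            counts[rule] = counts.get(rule, 0) + 1
    report = FilterReport(n_in=len(corpus), n_out=len(kept), counts_removed=counts)
    return Corpus(kept), report


def deidentify(corpus: Corpus, salt: str) -> Corpus:
    """Replace each user id with a keyed one-way digest (HMAC-SHA256, truncated).

    Deterministic for a given salt; all other fields are preserved bit-exactly.
    """
    if not salt:
        raise ValueError("salt must be non-empty")
    mapping: dict[str, str] = {}
    used: dict[str, str] = {}
    out: list[Tweet] = []
    for tweet in corpus:
        if tweet.user_id not in mapping:
            digest = hmac.new(salt.encode(), tweet.user_id.encode(), hashlib.sha256).hexdigest()
            pseudo = "u" + digest[:16]
            if pseudo == tweet.user_id:
                pseudo = "u" + digest[16:32]
            prior = used.get(pseudo)
            if prior is not None and prior != tweet.user_id:
                raise RuntimeError(f"digest collision between {prior!r} and {tweet.user_id!r}")
            used[pseudo] = tweet.user_id
            mapping[tweet.user_id] = pseudo
        out.append(replace(tweet, user_id=mapping[tweet.user_id]))
    return Corpus(out)


_FIELDS = ("tweet_id", "user_id", "created_at", "text", "medication", "is_retweet", "is_quote")


def _tweet_from_record(rec: Mapping[str, object], line_no: int) -> Tweet:
    for key in ("tweet_id", "user_id", "created_at", "text"):
        if key not in rec or rec[key] in (None, ""):
            raise CorpusError(f"line {line_no}: missing required field {key!r}")
    try:
        ts = datetime.fromisoformat(str(rec["created_at"]))
    except ValueError as exc:
        raise CorpusError(f"line {line_no}: unparseable timestamp {rec['created_at']!r}") from exc

    def as_bool(v: object) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("1", "true", "yes")
        return bool(v)

    return Tweet(
        tweet_id=str(rec["tweet_id"]),
        user_id=str(rec["user_id"]),
        timestamp=ts,
        text=str(rec["text"]),
        medication=str(rec.get("medication", "") or ""),
        is_retweet=as_bool(rec.get("is_retweet", False)),
        is_quote=as_bool(rec.get("is_quote", False)),
    )


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL (one record per line) or CSV with the same header.

    Format is inferred from the suffix when not given. Parse errors name the
    offending line; duplicate tweet ids are an integrity error.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    tweets: list[Tweet] = []
    text = path.read_text(encoding="utf-8")
    if format == "jsonl":
        for line_no, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {line_no}: invalid JSON") from exc
            tweets.append(_tweet_from_record(rec, line_no))
    else:
        reader = csv.DictReader(io.StringIO(text))
        for line_no, rec in enumerate(reader, start=2):  # header is line 1
            if None in rec.values() or None in rec:
                raise CorpusError(f"line {line_no}: wrong number of columns")
            tweets.append(_tweet_from_record(rec, line_no))
    return Corpus(tweets)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus in the JSONL or CSV dialect read back by :func:`read_corpus`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {
            "tweet_id": t.tweet_id,
            "user_id": t.user_id,
            "created_at": t.timestamp.isoformat(),
            "text": t.text,
            "medication": t.medication,
            "is_retweet": t.is_retweet,
            "is_quote": t.is_quote,
        }
        for t in corpus
    ]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for row in rows:
                writer.writerow(
                    {
                        "tweet_id": row["tweet_id"],
                        "user_id": row["user_id"],
                        "created_at": row["created_at"],
                        "text": row["text"],
                        "medication": row["medication"],
                        "is_retweet": str(row["is_retweet"]).lower(),
                        "is_quote": str(row["is_quote"]).lower(),
                    }
                )
    else:
        raise ValueError(f"unknown corpus format {format!r}")
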