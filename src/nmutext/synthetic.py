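"""Synthetic tweet-like corpora with planted ground truth.

No public corpus of medication chatter exists for this pipeline (the source
data is request-only), so every stage is exercised against generated posts:
short, informal, lower-case sentences built from templates with typed entity
slots filled from gazetteers (drugs with misspellings and trade names, adverse
events, symptoms, treatments), latent topic vocabularies with a controllable
off-topic noise rate, timestamps over a five-month window, and one record per
corpus-filter exclusion rule. Generators are pure functions of (config, seed):
the same seed reproduces the corpus bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np

from .chunker import EntitySpan, chunks_to_iob
from .corpus_io import Corpus, FilterConfig, Tweet
from .ner import LabeledSequence

__all__ = [
    "SynthConfig",
    "SynthCorpus",
    "DEFAULT_GAZETTEERS",
    "DEFAULT_TEMPLATES",
    "generate_ner_corpus",
    "generate_topic_corpus",
    "generate_filter_fixture",
    "to_labeled_sequences",
]

#: Entity-term lists. Drug terms cover the four monitored medications plus
#: trade names and common misspellings; ADE/symptom terms are typical effects
#: reported in medication chatter (drowsiness, fatigue, pain, nausea, ...).
DEFAULT_GAZETTEERS: dict[str, tuple[str, ...]] = {
    "DRUG": (
        "fentanyl", "fentanil", "morphine", "morfine", "alprazolam",
        "xanax", "xanex", "adderall", "adderal", "addy",
    ),
    "ADE": (
        "drowsiness", "fatigue", "pain", "nausea", "headaches",
        "dizziness", "hallucinations", "insomnia", "severe cramps",
    ),
    "SYMPTOM": ("anxiety", "panic", "stress", "depression", "adhd"),
    "TREATMENT": ("rehab", "therapy", "counseling", "detox", "group therapy"),
}

#: Short informal skeletons; "{LABEL}" marks a typed entity slot.
DEFAULT_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("i", "took", "{DRUG}", "again", "last", "night"),
    ("my", "{SYMPTOM}", "got", "worse", "after", "quitting", "{DRUG}"),
    ("been", "on", "{DRUG}", "for", "weeks", "and", "the", "{ADE}", "wont", "stop"),
    ("cant", "handle", "this", "{ADE}", "anymore"),
    ("someone", "said", "{TREATMENT}", "helps", "with", "{DRUG}", "withdrawal"),
    ("trying", "{TREATMENT}", "before", "things", "get", "worse"),
    ("friend", "gave", "me", "{DRUG}", "at", "the", "party"),
    ("woke", "up", "with", "{ADE}", "and", "bad", "{SYMPTOM}"),
)

#: Non-entity filler words; disjoint from every gazetteer term so generated
#: corpora are separable (entity words never occur outside planted spans).
_FILLERS: tuple[str, ...] = (
    "stuff", "things", "coffee", "water", "nothing", "something",
    "music", "homework", "walking", "waiting",
)

_MEDICATIONS = ("fentanyl", "morphine", "alprazolam", "adderall")

_DEFAULT_DATE_RANGE = (
    datetime(2021, 5, 31, tzinfo=timezone.utc),
    datetime(2021, 10, 31, tzinfo=timezone.utc),
)


@dataclass
class SynthConfig:
    """Generation parameters; the defaults define the standard study conditions."""

    n_records: int = 200
    seed: int = 0
    gazetteers: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_GAZETTEERS)
    )
    templates: Sequence[Sequence[str]] = DEFAULT_TEMPLATES
    topic_specs: Sequence[tuple[Sequence[str], float]] = ()
    noise_rate: float = 0.0
    entity_rate: float = 0.7
    date_range: tuple[datetime, datetime] = _DEFAULT_DATE_RANGE
    violation_mix: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 0.0 <= self.entity_rate <= 1.0:
            raise ValueError("entity_rate must be in [0, 1]")
        if sum(self.violation_mix.values()) > 1.0 + 1e-9:
            raise ValueError("violation fractions must sum to <= 1")


@dataclass
class SynthCorpus:
    """Generated corpus plus its planted ground truth and a config echo."""

    tweets: Corpus
    gold_ner: list[list[EntitySpan]] = field(default_factory=list)
    gold_topic: list[int] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _uniform_timestamp(rng: np.random.Generator, date_range: tuple[datetime, datetime]) -> datetime:
    start, end = date_range
    span = (end - start).total_seconds()
    return start + timedelta(seconds=float(rng.uniform(0, span)))


def generate_ner_corpus(config: SynthConfig) -> SynthCorpus:
    """Template-filled sentences with exact gold entity spans.

    Each template entity slot is filled from its gazetteer with probability
    ``entity_rate`` (the span is recorded), otherwise with a filler word (no
    span). Filler vocabulary is disjoint from the gazetteers, so the corpus is
    separable: a correct tagger can recover every span.
    """
    rng = np.random.default_rng(config.seed)
    for label in {s[1:-1] for tpl in config.templates for s in tpl if s.startswith("{")}:
        if not config.gazetteers.get(label):
            raise ValueError(f"empty gazetteer for requested label {label!r}")
    tweets: list[Tweet] = []
    gold: list[list[EntitySpan]] = []
    n_slots = 0
    n_planted = 0
    for i in range(config.n_records):
        template = config.templates[rng.integers(len(config.templates))]
        tokens: list[str] = []
        spans: list[EntitySpan] = []
        for part in template:
            if part.startswith("{") and part.endswith("}"):
                n_slots += 1
                label = part[1:-1]
                if rng.random() < config.entity_rate:
                    terms = config.gazetteers[label]
                    term = terms[rng.integers(len(terms))]
                    words = term.split()
                    spans.append(
                        EntitySpan(len(tokens), len(tokens) + len(words), label, term)
                    )
                    tokens.extend(words)
                    n_planted += 1
                else:
                    tokens.append(_FILLERS[rng.integers(len(_FILLERS))])
            else:
                tokens.append(part)
        med = next((s.text.split()[0] for s in spans if s.label == "DRUG"), "")
        tweets.append(
            Tweet(
                tweet_id=f"t{i:05d}",
                user_id=f"user{int(rng.integers(1, max(2, config.n_records // 3)))}",
                timestamp=_uniform_timestamp(rng, config.date_range),
                text=" ".join(tokens),
                medication=med,
            )
        )
        gold.append(spans)
    manifest = {
        "kind": "ner",
        "n_records": config.n_records,
        "seed": config.seed,
        "entity_rate": config.entity_rate,
        "n_slots": n_slots,
        "n_planted": n_planted,
    }
    return SynthCorpus(tweets=Corpus(tweets), gold_ner=gold, manifest=manifest)


def generate_topic_corpus(config: SynthConfig) -> SynthCorpus:
    """Documents drawn from latent topic vocabularies.

    Each record's topic follows the mixing weights; each of its tokens comes
    from the topic's own vocabulary with probability 1 - noise_rate, otherwise
    from the union of all topic vocabularies. Timestamps are uniform over the
    date range.
    """
    if len(config.topic_specs) < 2:
        raise ValueError("generate_topic_corpus requires >= 2 topic_specs")
    rng = np.random.default_rng(config.seed)
    vocabs = [list(spec[0]) for spec in config.topic_specs]
    weights = np.array([spec[1] for spec in config.topic_specs], dtype=float)
    weights = weights / weights.sum()
    union = sorted({w for v in vocabs for w in v})
    tweets: list[Tweet] = []
    gold_topic: list[int] = []
    for i in range(config.n_records):
        topic = int(rng.choice(len(vocabs), p=weights))
        length = int(rng.integers(8, 16))
        words = []
        for _ in range(length):
            if config.noise_rate > 0 and rng.random() < config.noise_rate:
                words.append(union[rng.integers(len(union))])
            else:
                words.append(vocabs[topic][rng.integers(len(vocabs[topic]))])
        tweets.append(
            Tweet(
                tweet_id=f"d{i:05d}",
                user_id=f"user{int(rng.integers(1, max(2, config.n_records // 3)))}",
                timestamp=_uniform_timestamp(rng, config.date_range),
                text=" ".join(words),
                medication=_MEDICATIONS[topic % len(_MEDICATIONS)],
            )
        )
        gold_topic.append(topic)
    manifest = {
        "kind": "topic",
        "n_records": config.n_records,
        "seed": config.seed,
        "noise_rate": config.noise_rate,
        "weights": weights.tolist(),
    }
    return SynthCorpus(tweets=Corpus(tweets), gold_topic=gold_topic, manifest=manifest)


def generate_filter_fixture(seed: int = 0) -> tuple[SynthCorpus, FilterConfig]:
    """One record violating each exclusion rule plus one clean record.

    Returns the fixture corpus together with a :class:`FilterConfig` whose bot
    and non-medical-use predicates flag the planted records (those two rules
    are pluggable classifiers whose defaults accept everything).
    """
    rng = np.random.default_rng(seed)
    base_ts = _uniform_timestamp(rng, _DEFAULT_DATE_RANGE)

    def tweet(tid: str, text: str, ts: datetime | None = None, **kw) -> Tweet:
        return Tweet(
            tweet_id=tid,
            user_id=f"user{int(rng.integers(1, 50))}",
            timestamp=ts or base_ts,
            text=text,
            medication="adderall",
            **kw,
        )

    records = [
        ("clean", tweet("fx_clean", "took some adderall last night cant sleep")),
        ("date", tweet("fx_date", "took some adderall way back then",
                       ts=datetime(2022, 1, 15, tzinfo=timezone.utc))),
        ("language", tweet("fx_lang", "вчера принял много таблеток и не спал")),
        ("keyword", tweet("fx_keyword", "took some pills last night cant sleep")),
        ("length", tweet("fx_length", "adderall insomnia")),
        ("retweet_quote", tweet("fx_retweet", "took some adderall last night cant sleep",
                                is_retweet=True)),
        ("bot", tweet("fx_bot", "buy cheap adderall online right now")),
        ("nmu", tweet("fx_nmu", "my doctor prescribed adderall and it works fine")),
    ]
    violations = {t.tweet_id: rule for rule, t in records if rule != "clean"}
    corpus = Corpus(t for _, t in records)
    config = FilterConfig(
        bot_predicate=lambda tw: violations.get(tw.tweet_id) != "bot",
        nmu_predicate=lambda tw: violations.get(tw.tweet_id) != "nmu",
    )
    manifest = {
        "kind": "filter_fixture",
        "seed": seed,
        "clean_id": "fx_clean",
        "violations": violations,
    }
    return SynthCorpus(tweets=corpus, manifest=manifest), config


def to_labeled_sequences(synth: SynthCorpus) -> list[LabeledSequence]:
    """Convert a generated corpus to IOB2-tagged sequences for tagger training."""
    seqs = []
    for tweet, spans in zip(synth.tweets, synth.gold_ner):
        tokens = tweet.text.split()
        tags = chunks_to_iob(spans, len(tokens))
        seqs.append(LabeledSequence(tuple(tokens), tuple(tags)))
    return seqs
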