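"""Shared fixtures and oracles for the test suite.

The CRF oracles here are deliberately brute force: they enumerate all K^T tag
paths and must stay independent of the dynamic-programming implementations
they check.
"""

from __future__ import annotations

import itertools
from types import SimpleNamespace

import numpy as np
import pytest

from nmutext import ner


def raw_crf_params(K: int, rng: np.random.Generator | None = None) -> SimpleNamespace:
    """A bare CRF parameter bundle (transitions/start/end) with K tags.

    Random scores when an rng is given, zeros otherwise. Duck-types the subset
    of NERParams the CRF operations consume.
    """
    if rng is None:
        T = np.zeros((K, K))
        s = np.zeros(K)
        e = np.zeros(K)
    else:
        T = rng.normal(size=(K, K))
        s = rng.normal(size=K)
        e = rng.normal(size=K)
    return SimpleNamespace(transitions=T, start=s, end=e, schema=SimpleNamespace(n_tags=K))


def enumerate_scores(E: np.ndarray, params) -> dict[tuple[int, ...], float]:
    """Score of every tag path, by direct evaluation of the scoring formula."""
    T, K = E.shape
    out = {}
    for path in itertools.product(range(K), repeat=T):
        s = params.start[path[0]] + E[0, path[0]]
        for t in range(1, T):
            s += params.transitions[path[t - 1], path[t]] + E[t, path[t]]
        out[path] = s + params.end[path[-1]]
    return out


def brute_log_partition(E: np.ndarray, params) -> float:
    scores = np.array(list(enumerate_scores(E, params).values()))
    m = scores.max()
    return float(m + np.log(np.exp(scores - m).sum()))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_schema() -> ner.TagSchema:
    return ner.TagSchema(("DRUG", "ADE"))


def random_legal_tags(rng: np.random.Generator, schema: ner.TagSchema, length: int) -> list[str]:
    """Draw a random IOB2-legal tag sequence by walking the legal-transition graph."""
    tags = list(schema.tags)
    allowed = schema.allowed_transitions()
    start_ok = np.flatnonzero(schema.allowed_start())
    out = [tags[rng.choice(start_ok)]]
    idx = schema.index
    for _ in range(length - 1):
        choices = np.flatnonzero(allowed[idx[out[-1]]])
        out.append(tags[rng.choice(choices)])
    return out
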