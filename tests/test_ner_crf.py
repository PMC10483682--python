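"""Linear-chain CRF correctness against brute-force path enumeration."""

from __future__ import annotations

import numpy as np
import pytest

from nmutext import ner
from nmutext.ner import (
    DecodeError,
    NERConfig,
    TagSchema,
    crf_log_partition,
    crf_nll,
    crf_nll_grad,
    crf_score,
    init_params,
    viterbi_decode,
)

from conftest import brute_log_partition, enumerate_scores, raw_crf_params


class TestCrfScore:
    def test_zero_params_zero_score(self):
        p = raw_crf_params(3)
        E = np.zeros((4, 3))
        for path in ([0, 0, 0, 0], [2, 1, 0, 2]):
            assert crf_score(E, p, path) == 0.0

    def test_length_one_formula(self, rng):
        p = raw_crf_params(3, rng)
        E = rng.normal(size=(1, 3))
        for y in range(3):
            assert crf_score(E, p, [y]) == pytest.approx(p.start[y] + E[0, y] + p.end[y])

    def test_path_probabilities_sum_to_one(self, rng):
        p = raw_crf_params(3, rng)
        E = rng.normal(size=(4, 3))
        logZ = crf_log_partition(E, p)
        total = sum(np.exp(s - logZ) for s in enumerate_scores(E, p).values())
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_out_of_range_tag_rejected(self):
        p = raw_crf_params(2)
        with pytest.raises(ValueError):
            crf_score(np.zeros((2, 2)), p, [0, 5])


class TestLogPartition:
    def test_uniform_case(self):
        p = raw_crf_params(2)
        assert crf_log_partition(np.zeros((3, 2)), p) == pytest.approx(3 * np.log(2))

    def test_length_one_is_logsumexp(self, rng):
        p = raw_crf_params(4, rng)
        E = rng.normal(size=(1, 4))
        expected = np.log(np.exp(p.start + E[0] + p.end).sum())
        assert crf_log_partition(E, p) == pytest.approx(expected)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(25):
            K = int(rng.integers(2, 5))
            T = int(rng.integers(1, 6))
            p = raw_crf_params(K, rng)
            E = rng.normal(size=(T, K)) * 3
            assert crf_log_partition(E, p) == pytest.approx(
                brute_log_partition(E, p), abs=1e-8
            )

    def test_nan_rejected(self):
        p = raw_crf_params(2)
        E = np.zeros((2, 2))
        E[0, 0] = np.nan
        with pytest.raises(ValueError):
            crf_log_partition(E, p)


class TestViterbi:
    def test_zero_transitions_is_positionwise_argmax(self, rng):
        p = raw_crf_params(4)
        E = rng.normal(size=(6, 4))
        path, score = viterbi_decode(E, p)
        assert path == list(np.argmax(E, axis=1))
        assert score == pytest.approx(E.max(axis=1).sum())

    def test_matches_enumerated_argmax(self, rng):
        for _ in range(25):
            K = int(rng.integers(2, 5))
            T = int(rng.integers(1, 6))
            p = raw_crf_params(K, rng)
            E = rng.normal(size=(T, K)) * 3
            path, score = viterbi_decode(E, p)
            best = max(enumerate_scores(E, p).values())
            assert score == pytest.approx(best, abs=1e-9)
            assert crf_score(E, p, path) == pytest.approx(best, abs=1e-9)

    def test_viterbi_score_never_exceeds_log_partition(self, rng):
        for _ in range(10):
            p = raw_crf_params(3, rng)
            E = rng.normal(size=(4, 3))
            _, score = viterbi_decode(E, p)
            assert score <= crf_log_partition(E, p) + 1e-12

    def test_constrained_never_starts_inside_entity(self):
        schema = TagSchema(("DRUG",))
        cfg = NERConfig(constrain_transitions=True)
        params = init_params(schema, cfg, word_dim=4)
        E = np.zeros((3, schema.n_tags))
        E[0, schema.index["I-DRUG"]] = 100.0  # heavily favored but illegal
        path, _ = viterbi_decode(E, params)
        assert schema.tags[path[0]] != "I-DRUG"
        assert schema.is_legal(schema.decode(path))

    def test_all_paths_blocked_raises(self):
        p = raw_crf_params(2)
        p.start[:] = -np.inf
        with pytest.raises(DecodeError):
            viterbi_decode(np.zeros((2, 2)), p)


class TestCrfNll:
    def test_uniform_case(self):
        p = raw_crf_params(3)
        E = np.zeros((4, 3))
        assert crf_nll(p, [(E, [0, 1, 2, 0])]) == pytest.approx(4 * np.log(3))

    def test_gold_only_legal_path_gives_zero(self):
        p = raw_crf_params(3)
        gold = [1, 2]
        p.start[:] = -np.inf
        p.start[1] = 0.0
        p.transitions[:] = -np.inf
        p.transitions[1, 2] = 0.0
        assert crf_nll(p, [(np.zeros((2, 3)), gold)]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumerated_path_probability(self, rng):
        p = raw_crf_params(3, rng)
        E = rng.normal(size=(4, 3))
        gold = [2, 0, 1, 1]
        logZ = brute_log_partition(E, p)
        expected = -(crf_score(E, p, gold) - logZ)
        assert crf_nll(p, [(E, gold)]) == pytest.approx(expected, abs=1e-10)
        assert crf_nll(p, [(E, gold)]) >= 0.0

    def test_gradients_match_finite_differences(self, rng):
        p = raw_crf_params(3, rng)
        E = rng.normal(size=(3, 3))
        gold = [0, 2, 1]
        _, grads = crf_nll_grad(p, [(E, gold)])
        h = 1e-6
        for arr, analytic in (
            (p.transitions, grads["transitions"]),
            (p.start, grads["start"]),
            (p.end, grads["end"]),
            (E, grads["emissions"][0]),
        ):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                fp = crf_nll(p, [(E, gold)])
                arr[idx] = orig - h
                fm = crf_nll(p, [(E, gold)])
                arr[idx] = orig
                num = (fp - fm) / (2 * h)
                denom = max(1e-8, abs(num) + abs(analytic[idx]))
                assert abs(num - analytic[idx]) / denom < 1e-4
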