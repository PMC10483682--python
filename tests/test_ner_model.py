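"""The neural encoder (char-CNN, BiLSTM, projection), training, and prediction."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from nmutext import ner
from nmutext.embeddings import hash_provider
from nmutext.ner import (
    LabeledSequence,
    NERConfig,
    TagSchema,
    char_cnn_features,
    emissions,
    init_params,
    load_params,
    predict,
    read_conll,
    save_params,
    train_ner,
    write_conll,
)


@pytest.fixture
def tiny_config():
    return NERConfig(char_dim=4, char_filters=3, char_window=3, hidden_dim=4, seed=9)


@pytest.fixture
def provider():
    return hash_provider(6, seed=1)


class TestCharCnn:
    def test_single_char_word_shape(self, small_schema, tiny_config):
        params = init_params(small_schema, tiny_config, word_dim=6)
        out = char_cnn_features("a", params)
        assert out.shape == (tiny_config.char_filters,)

    def test_zero_weights_give_nonlinearity_at_zero(self, small_schema, tiny_config):
        params = init_params(small_schema, tiny_config, word_dim=6)
        params.conv_W[:] = 0.0
        params.conv_b[:] = 0.0
        assert np.allclose(char_cnn_features("xanax", params), np.tanh(0.0))

    def test_matches_naive_window_loop(self, small_schema, tiny_config, rng):
        params = init_params(small_schema, tiny_config, word_dim=6)
        word = "adderal"
        out = char_cnn_features(word, params)
        # independent recomputation: explicit window dot products then max
        from nmutext.ner import _CHARS, _UNK_CHAR

        ids = [_CHARS.get(c, _UNK_CHAR) for c in word]
        pad = (tiny_config.char_window - 1) // 2
        E = np.zeros((len(ids) + 2 * pad, tiny_config.char_dim))
        for i, cid in enumerate(ids):
            E[pad + i] = params.char_embed[cid]
        expected = np.full(tiny_config.char_filters, -np.inf)
        for j in range(len(ids)):
            window = E[j : j + tiny_config.char_window].ravel()
            for k in range(tiny_config.char_filters):
                val = np.tanh(window @ params.conv_W[k] + params.conv_b[k])
                expected[k] = max(expected[k], val)
        assert np.allclose(out, expected)

    def test_empty_word_rejected(self, small_schema, tiny_config):
        params = init_params(small_schema, tiny_config, word_dim=6)
        with pytest.raises(ValueError):
            char_cnn_features("", params)


class TestEmissions:
    def test_shape(self, small_schema, tiny_config, provider):
        params = init_params(small_schema, tiny_config, word_dim=6)
        E = emissions(["took", "xanax", "now"], params, provider)
        assert E.scores.shape == (3, small_schema.n_tags)

    def test_zero_weights_give_bias(self, small_schema, tiny_config, provider):
        params = init_params(small_schema, tiny_config, word_dim=6)
        for side in (params.lstm_fw, params.lstm_bw):
            for k in side:
                side[k][:] = 0.0
        params.proj_W[:] = 0.0
        params.proj_b[:] = 0.0
        E = emissions(["a", "b"], params, provider)
        assert np.allclose(E.scores, 0.0)

    def test_reverse_symmetry(self, small_schema, tiny_config, provider):
        params = init_params(small_schema, tiny_config, word_dim=6)
        tokens = ["took", "two", "xanax", "bars"]
        fwd = emissions(tokens, params, provider).scores
        swapped = copy.deepcopy(params)
        swapped.lstm_fw, swapped.lstm_bw = swapped.lstm_bw, swapped.lstm_fw
        h = tiny_config.hidden_dim
        swapped.proj_W = np.concatenate(
            [params.proj_W[:, h:], params.proj_W[:, :h]], axis=1
        )
        rev = emissions(tokens[::-1], swapped, provider).scores
        assert np.allclose(rev, fwd[::-1], atol=1e-12)

    def test_provider_dim_mismatch(self, small_schema, tiny_config):
        params = init_params(small_schema, tiny_config, word_dim=6)
        with pytest.raises(ValueError, match="dim"):
            emissions(["a"], params, hash_provider(5, seed=0))


def _toy_corpus(n=12):
    seqs = []
    for i in range(n):
        if i % 2:
            seqs.append(LabeledSequence(("took", "xanax", "now"), ("O", "B-DRUG", "O")))
        else:
            seqs.append(LabeledSequence(("felt", "pain", "today"), ("O", "B-ADE", "O")))
    return seqs


class TestTraining:
    def test_zero_epochs_returns_initialization(self, small_schema, tiny_config, provider):
        cfg = NERConfig(**{**vars(tiny_config), "epochs": 0})
        params, report = train_ner(_toy_corpus(), small_schema, cfg, provider)
        fresh = init_params(small_schema, cfg, provider.dim, np.random.default_rng(cfg.seed))
        assert np.array_equal(params.proj_W, fresh.proj_W)
        assert report.epoch_nll == []

    def test_same_seed_bit_identical_trace(self, small_schema, tiny_config, provider):
        cfg = NERConfig(**{**vars(tiny_config), "epochs": 3})
        _, r1 = train_ner(_toy_corpus(), small_schema, cfg, provider)
        _, r2 = train_ner(_toy_corpus(), small_schema, cfg, provider)
        assert r1.epoch_nll == r2.epoch_nll

    def test_all_O_training_predicts_all_O(self, small_schema, provider):
        cfg = NERConfig(char_dim=4, char_filters=3, hidden_dim=4, epochs=5, seed=2)
        seqs = [
            LabeledSequence(tuple(f"w{i}{j}" for j in range(4)), ("O",) * 4)
            for i in range(12)
        ]
        params, _ = train_ner(seqs, small_schema, cfg, provider)
        out = predict(("w00", "w01", "other"), params, provider=provider)
        assert set(out.tags) == {"O"}

    def test_illegal_gold_rejected(self, small_schema, tiny_config, provider):
        bad = [LabeledSequence(("a", "b"), ("O", "I-DRUG"))] * 10
        with pytest.raises(ValueError, match="illegal"):
            train_ner(bad, small_schema, tiny_config, provider)

    def test_too_small_corpus_rejected(self, small_schema, tiny_config, provider):
        with pytest.raises(ValueError):
            train_ner(_toy_corpus(4), small_schema, tiny_config, provider)


class TestPredict:
    def test_output_always_iob2_legal(self, small_schema, tiny_config, provider, rng):
        from nmutext.chunker import repair_iob

        params = init_params(small_schema, tiny_config, word_dim=6)
        # random finite weights; constraints stay -inf
        params.proj_b[:] = rng.normal(size=small_schema.n_tags)
        for toks in (("a",), ("x", "y"), ("one", "two", "three", "four")):
            out = predict(toks, params, provider=provider)
            assert small_schema.is_legal(out.tags)
            assert list(out.tags) == repair_iob(out.tags, small_schema)

    def test_pure_per_sequence(self, small_schema, tiny_config, provider):
        params = init_params(small_schema, tiny_config, word_dim=6)
        a = predict(("took", "xanax"), params, provider=provider)
        _ = predict(("unrelated", "words", "here"), params, provider=provider)
        b = predict(("took", "xanax"), params, provider=provider)
        assert a == b


class TestSerialization:
    def test_conll_round_trip(self, tmp_path):
        seqs = _toy_corpus(4)
        write_conll(seqs, tmp_path / "x.conll")
        assert read_conll(tmp_path / "x.conll") == seqs

    def test_params_round_trip_with_sentinels(self, small_schema, tiny_config, tmp_path, provider):
        params = init_params(small_schema, tiny_config, word_dim=6)
        save_params(params, tmp_path / "m.json")
        back = load_params(tmp_path / "m.json")
        assert np.array_equal(back.transitions, params.transitions)  # -inf preserved
        assert np.array_equal(back.char_embed, params.char_embed)
        E1 = emissions(["took", "xanax"], params, provider).scores
        E2 = emissions(["took", "xanax"], back, provider).scores
        assert np.allclose(E1, E2)
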