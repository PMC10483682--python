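"""Dimensionality reduction, density clustering, c-TF-IDF, trajectories, coherence."""

from __future__ import annotations

import math
from datetime import datetime, timezone

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from nmutext.embeddings import EmbeddingProvider
from nmutext.preprocess import build_token_matrix, tokenize
from nmutext.topics import (
    ClusterAssignment,
    ClusterConfig,
    ReductionConfig,
    Topic,
    cluster_docs,
    ctfidf,
    extract_topics,
    reduce_dim,
    topic_coherence,
    topics_over_time,
)


def fixed_provider(table: dict[str, np.ndarray]) -> EmbeddingProvider:
    dim = len(next(iter(table.values())))
    return EmbeddingProvider(
        "fixed", dim, lambda toks: np.stack([np.asarray(table[t], float) for t in toks])
    )


class TestReduceDim:
    def test_identity(self, rng):
        X = rng.normal(size=(5, 4))
        out = reduce_dim(X, ReductionConfig(method="identity", target_dim=4))
        assert np.array_equal(out, X)

    def test_identity_requires_matching_dim(self, rng):
        with pytest.raises(ValueError):
            reduce_dim(rng.normal(size=(5, 4)), ReductionConfig(method="identity", target_dim=2))

    def test_svd_full_rank_preserves_distances(self, rng):
        X = rng.normal(size=(8, 5))
        out = reduce_dim(X, ReductionConfig(method="svd", target_dim=5))
        assert np.allclose(pdist(out), pdist(X), atol=1e-9)

    def test_rank_two_data_reconstructs_exactly(self, rng):
        basis = rng.normal(size=(2, 10))
        coef = rng.normal(size=(30, 2))
        X = coef @ basis
        out = reduce_dim(X, ReductionConfig(method="svd", target_dim=2))
        # all pairwise structure survives: distances equal those of the centered data
        assert np.allclose(pdist(out), pdist(X - X.mean(0)), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(10, 6))
        a = reduce_dim(X, ReductionConfig(target_dim=3))
        b = reduce_dim(X.copy(), ReductionConfig(target_dim=3))
        assert np.array_equal(a, b)

    def test_target_dim_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_dim(rng.normal(size=(5, 3)), ReductionConfig(target_dim=4))


class TestClusterDocs:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(size=(20, 3)) * 0.1
        b = rng.normal(size=(15, 3)) * 0.1 + 10.0
        X = np.vstack([a, b])
        asn = cluster_docs(X, ClusterConfig(min_cluster_size=5, distance_threshold=2.0))
        assert asn.n_clusters == 2
        assert (asn.labels[:20] == 0).all()  # larger blob gets id 0
        assert (asn.labels[20:] == 1).all()

    def test_isolated_point_is_outlier(self, rng):
        blob = rng.normal(size=(6, 2)) * 0.05
        X = np.vstack([blob, [[50.0, 50.0]]])
        asn = cluster_docs(X, ClusterConfig(min_cluster_size=3, distance_threshold=1.0))
        assert asn.labels[-1] == -1
        assert (asn.labels[:-1] == 0).all()

    def test_duplicate_rows_share_label(self, rng):
        row = rng.normal(size=3)
        X = np.vstack([row, row, row, row + 30.0, row + 30.0, row + 30.0])
        asn = cluster_docs(X, ClusterConfig(min_cluster_size=2, distance_threshold=1.0))
        assert asn.labels[0] == asn.labels[1] == asn.labels[2]

    def test_too_few_documents_all_outliers(self, rng):
        asn = cluster_docs(
            rng.normal(size=(3, 2)), ClusterConfig(min_cluster_size=5, distance_threshold=1.0)
        )
        assert (asn.labels == -1).all()


def _matrix(texts):
    return build_token_matrix([tokenize(t) for t in texts])


class TestCtfidf:
    def test_hand_computed_example(self):
        m = _matrix(["drug drug pain", "sleep sleep sleep"])
        asn = ClusterAssignment(labels=np.array([0, 1]))
        ct = ctfidf(m, asn)
        assert ct.A == 3.0
        i = ct.terms.index("drug")
        assert ct.W[0, i] == pytest.approx(2 * math.log(2.5), abs=1e-12)

    def test_zero_iff_absent(self, rng):
        words = ["a", "b", "c", "d", "e"]
        texts = [" ".join(rng.choice(words, size=8)) for _ in range(12)]
        m = _matrix(texts)
        asn = ClusterAssignment(labels=rng.integers(0, 3, size=12))
        ct = ctfidf(m, asn)
        assert (ct.W >= 0).all()
        assert ((ct.W == 0) == (ct.tf == 0)).all()

    def test_single_class_ranking_follows_tf(self):
        m = _matrix(["x x x y y z"])
        ct = ctfidf(m, ClusterAssignment(labels=np.array([0])))
        order = np.argsort(-ct.W[0])
        tf_order = np.argsort(-ct.tf[0])
        assert list(order) == list(tf_order)

    def test_outliers_excluded(self):
        m = _matrix(["drug drug", "drug pain", "noise noise noise"])
        asn = ClusterAssignment(labels=np.array([0, 0, -1]))
        ct = ctfidf(m, asn)
        assert ct.f[ct.terms.index("noise")] == 0

    def test_all_outliers_rejected(self):
        m = _matrix(["a b"])
        with pytest.raises(ValueError):
            ctfidf(m, ClusterAssignment(labels=np.array([-1])))


class TestExtractTopics:
    def test_toy_top_words(self):
        m = _matrix(["drug drug pain", "sleep sleep sleep"])
        ct = ctfidf(m, ClusterAssignment(labels=np.array([0, 1])))
        topics = extract_topics(ct, top_n=1)
        assert topics[0].top_words[0][0] == "drug"
        assert topics[1].top_words[0][0] == "sleep"

    def test_top_n_truncates_to_vocabulary(self):
        m = _matrix(["a b c"])
        ct = ctfidf(m, ClusterAssignment(labels=np.array([0])))
        topics = extract_topics(ct, top_n=99)
        assert len(topics[0].top_words) == 3

    def test_ties_break_lexicographically(self):
        m = _matrix(["beta alpha"])
        ct = ctfidf(m, ClusterAssignment(labels=np.array([0])))
        words = [w for w, _ in extract_topics(ct, top_n=2)[0].top_words]
        assert words == ["alpha", "beta"]


def _ts(year, month, day=15):
    return datetime(year, month, day, tzinfo=timezone.utc)


class TestTopicsOverTime:
    def test_degenerate_single_topic_single_month(self):
        m = _matrix(["a b", "a a", "b b"])
        asn = ClusterAssignment(labels=np.array([0, 0, 0]))
        out = topics_over_time(m, asn, [_ts(2021, 6)] * 3)
        assert len(out.frame) == 1
        assert out.frame.iloc[0]["frequency"] == 3

    def test_frequencies_conserve_documents_per_step(self, rng):
        words = ["a", "b", "c"]
        texts = [" ".join(rng.choice(words, size=5)) for _ in range(20)]
        m = _matrix(texts)
        labels = rng.integers(-1, 2, size=20)
        ts = [_ts(2021, int(m_)) for m_ in rng.integers(6, 9, size=20)]
        asn = ClusterAssignment(labels=labels)
        if asn.n_clusters == 0:
            pytest.skip("degenerate draw")
        out = topics_over_time(m, asn, ts)
        for step, grp in out.frame.groupby("step"):
            expected = sum(
                1 for t, lab in zip(ts, labels) if f"{t.year}-{t.month:02d}" == step and lab >= 0
            )
            assert grp["frequency"].sum() == expected

    def test_planted_doubling_shows_frequency_ratio_two(self):
        texts = ["drug drug"] * 3 + ["drug drug"] * 6
        m = _matrix(texts)
        asn = ClusterAssignment(labels=np.zeros(9, dtype=int))
        ts = [_ts(2021, 6)] * 3 + [_ts(2021, 7)] * 6
        out = topics_over_time(m, asn, ts)
        freq = dict(zip(out.frame["step"], out.frame["frequency"]))
        assert freq["2021-07"] / freq["2021-06"] == 2.0


class TestCoherence:
    def test_identical_vectors_score_one(self):
        v = np.array([1.0, 2.0, 3.0])
        prov = fixed_provider({"a": v, "b": v, "c": v})
        topic = Topic(0, [("a", 1.0), ("b", 0.9), ("c", 0.8)], size=3)
        report = topic_coherence([topic], prov, top_k=3)
        assert report.per_topic[0] == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        prov = fixed_provider(
            {"a": np.array([1.0, 0, 0]), "b": np.array([0, 1.0, 0]), "c": np.array([0, 0, 1.0])}
        )
        topic = Topic(0, [("a", 1.0), ("b", 0.9), ("c", 0.8)], size=3)
        assert topic_coherence([topic], prov, top_k=3).per_topic[0] == 0.0

    def test_hand_computed_pair_mean(self):
        prov = fixed_provider(
            {
                "a": np.array([1.0, 0.0]),
                "b": np.array([0.0, 1.0]),
                "c": np.array([1.0, 1.0]) / math.sqrt(2),
            }
        )
        topic = Topic(0, [("a", 1.0), ("b", 0.9), ("c", 0.8)], size=3)
        expected = (0.0 + math.sqrt(2) / 2 + math.sqrt(2) / 2) / 3
        assert topic_coherence([topic], prov, top_k=3).per_topic[0] == pytest.approx(expected)

    def test_bounded_on_random_inputs(self, rng):
        from nmutext.embeddings import hash_provider

        prov = hash_provider(16, seed=8)
        topics = [
            Topic(i, [(f"w{i}{j}", 1.0 - 0.1 * j) for j in range(5)], size=5) for i in range(6)
        ]
        report = topic_coherence(topics, prov, top_k=5)
        for v in report.per_topic.values():
            assert 0.0 <= v <= 1.0
        assert 0.0 <= report.mean <= 1.0

    def test_single_word_topic_excluded(self):
        prov = fixed_provider({"a": np.array([1.0, 0.0])})
        topic = Topic(0, [("a", 1.0)], size=1)
        report = topic_coherence([topic], prov, top_k=5)
        assert report.per_topic == {}
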