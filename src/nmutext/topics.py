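"""Cluster-based topic modelling over document embeddings.

The pipeline mirrors the BERTopic recipe: reduce document embeddings, cluster
the reduced vectors, and describe each cluster by class-based TF-IDF

    W(t, c) = tf(t, c) * ln(1 + A / f(t))

where tf(t, c) is the frequency of term t in class c, f(t) its total frequency
over all clustered documents, and A the average token count per class. Topic
drift is tracked by re-computing per-timestep term frequencies against the
global IDF; topic quality is scored by the mean pairwise clipped cosine
similarity between the top words' embedding vectors (a 0-1 coherence score).

The default reducer (centered truncated SVD) and clusterer (single-linkage cut
with a minimum-cluster-size outlier rule) are deterministic; UMAP/HDBSCAN-style
algorithms plug in through the ``external`` method hooks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .embeddings import EmbeddingProvider
from .preprocess import TokenMatrix

__all__ = [
    "ReductionConfig",
    "ClusterConfig",
    "ClusterAssignment",
    "CTFIDFMatrix",
    "Topic",
    "TopicsOverTime",
    "CoherenceReport",
    "reduce_dim",
    "cluster_docs",
    "ctfidf",
    "extract_topics",
    "topics_over_time",
    "topic_coherence",
    "topics_to_json",
]

logger = logging.getLogger(__name__)

OUTLIER = -1


@dataclass
class ReductionConfig:
    method: str = "svd"  # svd | identity | external
    target_dim: int = 5
    seed: int = 0
    external_fn: Callable[[np.ndarray, int], np.ndarray] | None = None


@dataclass
class ClusterConfig:
    method: str = "density"  # density | external
    min_cluster_size: int = 5
    distance_threshold: float = 1.0
    metric: str = "euclidean"  # euclidean | cosine
    external_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")


@dataclass
class ClusterAssignment:
    """Per-document labels; -1 marks outliers, clusters numbered by decreasing size."""

    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        labs = self.labels[self.labels != OUTLIER]
        return int(labs.max()) + 1 if labs.size else 0


def reduce_dim(embeddings: np.ndarray, config: ReductionConfig) -> np.ndarray:
    """Project onto the top-k right singular directions of the centered matrix.

    Deterministic sign convention: each component's largest-magnitude loading is
    positive. ``identity`` requires target_dim == input dim and returns the input.
    """
    X = np.asarray(embeddings, dtype=float)
    n, d = X.shape
    k = config.target_dim
    if k > d:
        raise ValueError(f"target_dim {k} exceeds embedding dim {d}")
    if n < 2:
        raise ValueError("need at least 2 documents")
    if config.method == "identity":
        if k != d:
            raise ValueError("identity reduction requires target_dim == dim")
        return X.copy()
    if config.method == "external":
        if config.external_fn is None:
            raise ValueError("external reduction requires external_fn")
        return np.asarray(config.external_fn(X, k), dtype=float)
    if config.method != "svd":
        raise ValueError(f"unknown reduction method {config.method!r}")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:k]
    for i in range(V.shape[0]):
        j = int(np.argmax(np.abs(V[i])))
        if V[i, j] < 0:
            V[i] = -V[i]
    return Xc @ V.T


def cluster_docs(reduced: np.ndarray, config: ClusterConfig) -> ClusterAssignment:
    """Single-linkage agglomeration cut at ``distance_threshold``.

    Components smaller than ``min_cluster_size`` become outliers (-1); surviving
    clusters are renumbered by decreasing size, ties broken by smallest member
    index. ``external`` delegates to a user-supplied labelling function.
    """
    X = np.asarray(reduced, dtype=float)
    n = X.shape[0]
    if n < config.min_cluster_size:
        logger.warning("only %d documents (< min_cluster_size); all marked outliers", n)
        return ClusterAssignment(labels=np.full(n, OUTLIER, dtype=int))
    if config.method == "external":
        if config.external_fn is None:
            raise ValueError("external clustering requires external_fn")
        raw = np.asarray(config.external_fn(X), dtype=int)
    elif config.method == "density":
        dists = pdist(X, metric=config.metric)
        Z = linkage(dists, method="single")
        raw = fcluster(Z, t=config.distance_threshold, criterion="distance")
    else:
        raise ValueError(f"unknown cluster method {config.method!r}")
    labels = np.full(n, OUTLIER, dtype=int)
    comps: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        comps.setdefault(int(c), []).append(i)
    keep = [idx for idx in comps.values() if len(idx) >= config.min_cluster_size]
    keep.sort(key=lambda idx: (-len(idx), idx[0]))
    for new_id, members in enumerate(keep):
        labels[members] = new_id
    return ClusterAssignment(labels=labels)


@dataclass
class CTFIDFMatrix:
    """Class-based TF-IDF weights W(t, c) = tf(t, c) * ln(1 + A / f(t))."""

    classes: list[int]
    terms: list[str]
    tf: np.ndarray        # (n_classes, n_terms)
    A: float              # average token count per class
    f: np.ndarray         # (n_terms,) corpus term frequency over clustered docs
    W: np.ndarray         # (n_classes, n_terms)
    class_sizes: list[int] = field(default_factory=list)


def _idf(A: float, f: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f, dtype=float)
    nz = f > 0
    out[nz] = np.log1p(A / f[nz])
    return out


def ctfidf(token_matrix: TokenMatrix, assignment: ClusterAssignment) -> CTFIDFMatrix:
    """Aggregate token counts per cluster and weight by the shared IDF; outlier
    documents are excluded entirely."""
    labels = np.asarray(assignment.labels)
    if labels.shape[0] != token_matrix.counts.shape[0]:
        raise ValueError("assignment and token matrix disagree on document count")
    n_classes = assignment.n_clusters
    if n_classes == 0:
        raise ValueError("no non-outlier clusters to model")
    counts = token_matrix.counts
    tf = np.zeros((n_classes, counts.shape[1]))
    sizes = []
    for c in range(n_classes):
        members = np.flatnonzero(labels == c)
        sizes.append(len(members))
        tf[c] = np.asarray(counts[members].sum(axis=0)).ravel()
    f = tf.sum(axis=0)
    A = float(tf.sum()) / n_classes
    W = tf * _idf(A, f)[None, :]
    return CTFIDFMatrix(
        classes=list(range(n_classes)),
        terms=token_matrix.terms,
        tf=tf,
        A=A,
        f=f,
        W=W,
        class_sizes=sizes,
    )


@dataclass
class Topic:
    topic_id: int
    top_words: list[tuple[str, float]]
    size: int


def extract_topics(ctfidf_matrix: CTFIDFMatrix, top_n: int = 5) -> list[Topic]:
    """Per cluster, the top_n terms by descending weight; ties break lexicographically."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    topics = []
    terms = ctfidf_matrix.terms
    for c in ctfidf_matrix.classes:
        row = ctfidf_matrix.W[c]
        ranked = sorted(range(len(terms)), key=lambda j: (-row[j], terms[j]))
        top = [(terms[j], float(row[j])) for j in ranked[:top_n]]
        size = ctfidf_matrix.class_sizes[c] if ctfidf_matrix.class_sizes else 0
        topics.append(Topic(topic_id=c, top_words=top, size=size))
    return topics


@dataclass
class TopicsOverTime:
    """Rows (topic_id, step, frequency, weight); frequencies per step conserve
    the number of clustered documents in that step."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _step_label(ts, bin: str) -> str:
    if bin == "month":
        return f"{ts.year:04d}-{ts.month:02d}"
    if bin == "week":
        iso = ts.isocalendar()
        return f"{iso[0]:04d}-W{iso[1]:02d}"
    raise ValueError(f"unknown bin {bin!r}")


def topics_over_time(
    token_matrix: TokenMatrix,
    assignment: ClusterAssignment,
    timestamps: Sequence,
    bin: str = "month",
) -> TopicsOverTime:
    """Per calendar-aligned timestep: document frequency per topic and the
    time-local c-TF-IDF mass (per-step term frequencies times the global IDF)."""
    labels = np.asarray(assignment.labels)
    if len(timestamps) != labels.shape[0]:
        raise ValueError("timestamps must cover all documents")
    global_ct = ctfidf(token_matrix, assignment)
    idf = _idf(global_ct.A, global_ct.f)
    counts = token_matrix.counts
    steps = [_step_label(ts, bin) for ts in timestamps]
    rows = []
    for step in sorted(set(steps)):
        in_step = np.array([s == step for s in steps])
        for c in range(assignment.n_clusters):
            members = np.flatnonzero(in_step & (labels == c))
            if members.size == 0:
                continue
            tf_step = np.asarray(counts[members].sum(axis=0)).ravel()
            weight = float((tf_step * idf).sum())
            rows.append(
                {"topic_id": c, "step": step, "frequency": int(members.size), "weight": weight}
            )
    frame = pd.DataFrame(rows, columns=["topic_id", "step", "frequency", "weight"])
    return TopicsOverTime(frame=frame)


@dataclass
class CoherenceReport:
    per_topic: dict[int, float]
    mean: float

    def to_json(self) -> str:
        return json.dumps(
            {"per_topic": {str(k): v for k, v in self.per_topic.items()}, "mean": self.mean},
            indent=2,
            sort_keys=True,
        )


def topic_coherence(
    topics: Sequence[Topic], provider: EmbeddingProvider, top_k: int = 5
) -> CoherenceReport:
    """Mean over unordered pairs of a topic's top_k words of max(0, cosine).

    Scores therefore lie in [0, 1]: identical word vectors give 1, pairwise
    orthogonal (or opposed) vectors give 0. Topics with fewer than two
    embeddable words are excluded with a warning.
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    per_topic: dict[int, float] = {}
    for topic in topics:
        words = [w for w, _ in topic.top_words[:top_k]]
        if len(words) < 2:
            logger.warning("topic %d has < 2 top words; excluded", topic.topic_id)
            continue
        vecs = provider(words)
        norms = np.linalg.norm(vecs, axis=1)
        ok = norms > 0
        if ok.sum() < 2:
            logger.warning("topic %d has < 2 embeddable words; excluded", topic.topic_id)
            continue
        V = vecs[ok] / norms[ok][:, None]
        sims = []
        for i in range(V.shape[0]):
            for j in range(i + 1, V.shape[0]):
                sims.append(max(0.0, float(V[i] @ V[j])))
        per_topic[topic.topic_id] = float(np.mean(sims))
    mean = float(np.mean(list(per_topic.values()))) if per_topic else 0.0
    return CoherenceReport(per_topic=per_topic, mean=mean)


def topics_to_json(topics: Sequence[Topic]) -> str:
    return json.dumps(
        [
            {"topic_id": t.topic_id, "size": t.size, "top_words": [[w, v] for w, v in t.top_words]}
            for t in topics
        ],
        indent=2,
        sort_keys=True,
    )
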