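"""Topic modelling: embed, reduce, cluster, describe with c-TF-IDF, score coherence.

Generates 600 posts from three disjoint latent vocabularies, mean-pools hashed
token embeddings into document vectors, reduces with centered SVD, clusters
with single-linkage + a minimum-size outlier rule, and prints each recovered
topic's top words with its c-TF-IDF weights, the per-month trajectory, and the
coherence scores (0-1; 1 = the topic's top words have identical embeddings).
"""

import numpy as np

from nmutext import (
    ClusterConfig,
    ReductionConfig,
    SynthConfig,
    build_token_matrix,
    cluster_docs,
    ctfidf,
    embed_document,
    extract_topics,
    generate_topic_corpus,
    hash_provider,
    reduce_dim,
    tokenize,
    topic_coherence,
    topics_over_time,
)

vocabularies = [
    ["anxiety", "panic", "stress", "therapy", "calm", "breathe"],
    ["focus", "exam", "energy", "study", "grades", "caffeine"],
    ["pain", "sleep", "nausea", "hospital", "dose", "relief"],
]
synth = generate_topic_corpus(
    SynthConfig(n_records=600, seed=5, noise_rate=0.0,
                topic_specs=[(v, 1.0) for v in vocabularies])
)

provider = hash_provider(32, seed=9)
records = [tokenize(t.text, record_id=t.tweet_id) for t in synth.tweets]
X = np.stack([embed_document(provider, r.tokens).vector for r in records])
reduced = reduce_dim(X, ReductionConfig(target_dim=2))
assignment = cluster_docs(reduced, ClusterConfig(min_cluster_size=10, distance_threshold=0.15))
print(f"{assignment.n_clusters} clusters, {(assignment.labels == -1).sum()} outliers")

matrix = build_token_matrix(records)
topics = extract_topics(ctfidf(matrix, assignment), top_n=5)
for t in topics:
    words = ", ".join(f"{w} ({v:.1f})" for w, v in t.top_words)
    print(f"topic {t.topic_id} ({t.size} docs): {words}")

trajectory = topics_over_time(matrix, assignment, [t.timestamp for t in synth.tweets])
print("\nper-month document counts (topic 0):")
print(trajectory.frame[trajectory.frame.topic_id == 0][["step", "frequency"]].to_string(index=False))

coherence = topic_coherence(topics, provider, top_k=5)
print(f"\nmean coherence {coherence.mean:.3f} "
      f"(per topic: {', '.join(f'{k}: {v:.3f}' for k, v in coherence.per_topic.items())})")
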