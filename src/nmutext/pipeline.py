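"""End-to-end pipeline: corpus -> filters -> tagger -> chunks -> topics -> reports.

``run_pipeline`` wires the stages together deterministically for a given
(config, seed): it loads or simulates a corpus, de-identifies users, applies the
inclusion/exclusion filters, obtains a trained tagger (loaded, trained from
CoNLL data, or trained on the simulated gold), emits per-tweet entity chunks
and the derived frequency tables (per-label term counts, drug co-mentions per
medication), then clusters document embeddings into topics with per-month
trajectories and coherence scores. Every artifact is a plain-text file under
the output directory; a MANIFEST records which stages completed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import chunker, corpus_io, embeddings, evaluation, ner, preprocess, synthetic, topics

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run; CLI flags override file values."""

    input_path: str | None = None       # JSONL/CSV corpus; None -> simulate
    model_path: str | None = None       # trained tagger JSON; None -> train
    train_conll: str | None = None      # CoNLL training data when not simulating
    out_dir: str = "results"
    seed: int = 0
    n_records: int = 150                # simulated corpus size
    embed_dim: int = 32
    epochs: int = 5
    min_cluster_size: int = 5
    distance_threshold: float = 1.0
    reduction_dim: int = 5
    top_n: int = 5
    coherence_top_k: int = 5
    salt: str = "nmutext"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _write(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest. Raises :class:`PipelineError` on failure
    (partial artifacts are kept, the MANIFEST marks what completed)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": dataclasses.asdict(config), "stages": {}}

    def checkpoint(stage: str, *artifacts: str) -> None:
        manifest["stages"][stage] = {"ok": True, "artifacts": list(artifacts)}
        _write(out / "MANIFEST.json", json.dumps(manifest, indent=2, sort_keys=True))

    def fail(stage: str, message: str) -> PipelineError:
        manifest["stages"][stage] = {"ok": False, "error": message}
        _write(out / "MANIFEST.json", json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineError(stage, message)

    # --- corpus -----------------------------------------------------------
    synth: synthetic.SynthCorpus | None = None
    try:
        if config.input_path is None:
            synth = synthetic.generate_ner_corpus(
                synthetic.SynthConfig(n_records=config.n_records, seed=config.seed)
            )
            corpus = synth.tweets
        else:
            corpus = corpus_io.read_corpus(config.input_path)
        corpus = corpus_io.deidentify(corpus, salt=config.salt)
    except Exception as exc:  # noqa: BLE001 - boundary: report and stop
        raise fail("corpus", str(exc)) from exc
    checkpoint("corpus")

    # --- filters ----------------------------------------------------------
    try:
        filtered, report = corpus_io.apply_filters(corpus, corpus_io.FilterConfig())
        _write(out / "filter_report.json", report.to_json())
    except Exception as exc:  # noqa: BLE001
        raise fail("filters", str(exc)) from exc
    checkpoint("filters", "filter_report.json")

    # --- tagger -----------------------------------------------------------
    provider = embeddings.hash_provider(config.embed_dim, seed=config.seed)
    try:
        if config.model_path is not None:
            params = ner.load_params(config.model_path)
        else:
            if config.train_conll is not None:
                train_seqs = ner.read_conll(config.train_conll)
                labels = sorted(
                    {t[2:] for s in train_seqs for t in s.tags if t != "O"}
                ) or list(ner.DEFAULT_ENTITY_LABELS)
            elif synth is not None:
                train_seqs = synthetic.to_labeled_sequences(synth)
                labels = sorted(synthetic.DEFAULT_GAZETTEERS)
            else:
                raise ValueError("no trained model and no training data provided")
            schema = ner.TagSchema(tuple(labels))
            ner_config = ner.NERConfig(epochs=config.epochs, seed=config.seed)
            params, train_report = ner.train_ner(train_seqs, schema, ner_config, provider)
            _write(
                out / "ner_train_report.json",
                json.dumps(
                    {"epoch_nll": train_report.epoch_nll, "n_sequences": train_report.n_sequences},
                    indent=2,
                ),
            )
            ner.save_params(params, out / "ner_model.json")
    except Exception as exc:  # noqa: BLE001
        raise fail("ner", str(exc)) from exc
    checkpoint("ner", "ner_model.json")

    # --- chunks and entity tables ----------------------------------------
    try:
        tokenized = []
        chunk_rows = []
        term_counts: Counter = Counter()
        co_mentions: Counter = Counter()
        for tweet in filtered:
            rec = preprocess.tokenize(preprocess.clean_text(tweet.text), record_id=tweet.tweet_id)
            tokenized.append(rec)
            if not rec.tokens:
                chunk_rows.append((tweet.tweet_id, []))
                continue
            tagged = ner.predict(rec.tokens, params, provider=provider)
            repaired = chunker.repair_iob(tagged.tags, params.schema)
            spans = chunker.iob_to_chunks(
                ner.LabeledSequence(tagged.tokens, tuple(repaired))
            )
            chunk_rows.append((tweet.tweet_id, spans))
            for span in spans:
                term_counts[(span.label, span.text)] += 1
                if span.label == "DRUG" and tweet.medication and span.text != tweet.medication:
                    co_mentions[(tweet.medication, span.text)] += 1
        chunker.write_chunks_tsv(chunk_rows, out / "chunks.tsv")
        with (out / "entity_counts.tsv").open("w", encoding="utf-8") as fh:
            fh.write("label\tterm\tcount\n")
            for (label, term), cnt in sorted(term_counts.items()):
                fh.write(f"{label}\t{term}\t{cnt}\n")
        with (out / "co_mentions.tsv").open("w", encoding="utf-8") as fh:
            fh.write("medication\tco_mentioned\tcount\n")
            for (med, other), cnt in sorted(co_mentions.items()):
                fh.write(f"{med}\t{other}\t{cnt}\n")
    except Exception as exc:  # noqa: BLE001
        raise fail("chunks", str(exc)) from exc
    checkpoint("chunks", "chunks.tsv", "entity_counts.tsv", "co_mentions.tsv")

    # --- topics -----------------------------------------------------------
    try:
        usable = [(t, r) for t, r in zip(list(filtered), tokenized) if r.tokens]
        if len(usable) < 2:
            raise ValueError("too few usable documents for topic modelling")
        doc_vecs = [
            embeddings.embed_document(provider, r.tokens, record_id=r.record_id).vector
            for _, r in usable
        ]
        import numpy as np

        X = np.stack(doc_vecs)
        k = min(config.reduction_dim, X.shape[1])
        reduced = topics.reduce_dim(X, topics.ReductionConfig(target_dim=k, seed=config.seed))
        assignment = topics.cluster_docs(
            reduced,
            topics.ClusterConfig(
                min_cluster_size=config.min_cluster_size,
                distance_threshold=config.distance_threshold,
            ),
        )
        matrix = preprocess.build_token_matrix([r for _, r in usable])
        if assignment.n_clusters > 0:
            ct = topics.ctfidf(matrix, assignment)
            topic_list = topics.extract_topics(ct, top_n=config.top_n)
            over_time = topics.topics_over_time(
                matrix, assignment, [t.timestamp for t, _ in usable], bin="month"
            )
            coherence = topics.topic_coherence(topic_list, provider, top_k=config.coherence_top_k)
            _write(out / "topics.json", topics.topics_to_json(topic_list))
            over_time.to_csv(out / "topics_over_time.csv")
            _write(out / "coherence.json", coherence.to_json())
        else:
            _write(out / "topics.json", "[]")
            _write(out / "topics_over_time.csv", "topic_id,step,frequency,weight\n")
            _write(out / "coherence.json", json.dumps({"per_topic": {}, "mean": 0.0}))
    except Exception as exc:  # noqa: BLE001
        raise fail("topics", str(exc)) from exc
    checkpoint("topics", "topics.json", "topics_over_time.csv", "coherence.json")

    _write(
        out / "run.log",
        f"seed={config.seed}\nconfig={json.dumps(dataclasses.asdict(config), sort_keys=True)}\n",
    )
    checkpoint("done", "run.log")
    return manifest
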