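"""Entity-level evaluation: exact-match P/R/F1, 70-15-15 holdout, fivefold CV.

A predicted span counts as a true positive only when start, end and label all
match a gold span (no partial credit); micro-averaged scores are the headline,
per-label scores are also reported. Cross-validation reports the per-fold
metrics with mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, TypeVar

import numpy as np

from .chunker import EntitySpan

__all__ = ["EntityEvalReport", "CVReport", "entity_prf", "holdout_split", "cross_validate"]

logger = logging.getLogger(__name__)

T = TypeVar("T")


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    if tp + fp == 0 or tp + fn == 0:
        logger.warning("0/0 metric encountered; reported as 0 by convention")
    return p, r, f1


@dataclass
class EntityEvalReport:
    """Exact-match span scores, micro-averaged and per entity label."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    per_label: dict[str, dict[str, float]] = field(default_factory=dict)

    def metrics(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall, "f1": self.f1}

    def to_json(self) -> str:
        return json.dumps(
            {
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "per_label": self.per_label,
            },
            indent=2,
            sort_keys=True,
        )


def _key(span: EntitySpan) -> tuple[int, int, str]:
    return (span.start, span.end, span.label)


def entity_prf(
    gold: Sequence[Sequence[EntitySpan]], pred: Sequence[Sequence[EntitySpan]]
) -> EntityEvalReport:
    """Score aligned per-record span lists; each gold span is matched at most once."""
    if len(gold) != len(pred):
        raise ValueError("gold and pred must be aligned record lists")
    tp = fp = fn = 0
    by_label: dict[str, list[int]] = {}
    for g_spans, p_spans in zip(gold, pred):
        g_set = {_key(s) for s in g_spans}
        p_set = {_key(s) for s in p_spans}
        for lab in {k[2] for k in g_set | p_set}:
            g_l = {k for k in g_set if k[2] == lab}
            p_l = {k for k in p_set if k[2] == lab}
            cnt = by_label.setdefault(lab, [0, 0, 0])
            cnt[0] += len(g_l & p_l)
            cnt[1] += len(p_l - g_l)
            cnt[2] += len(g_l - p_l)
        tp += len(g_set & p_set)
        fp += len(p_set - g_set)
        fn += len(g_set - p_set)
    p, r, f1 = _prf(tp, fp, fn)
    per_label = {}
    for lab, (ltp, lfp, lfn) in sorted(by_label.items()):
        lp, lr, lf1 = _prf(ltp, lfp, lfn)
        per_label[lab] = {
            "tp": ltp, "fp": lfp, "fn": lfn,
            "precision": lp, "recall": lr, "f1": lf1,
        }
    return EntityEvalReport(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1, per_label=per_label)


def holdout_split(
    corpus: Sequence[T],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[T], list[T], list[T]]:
    """Seeded shuffle, then contiguous slices sized by largest-remainder rounding."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(corpus)
    exact = [r * n for r in ratios]
    sizes = [math.floor(e) for e in exact]
    remainders = sorted(range(3), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [corpus[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


@dataclass
class CVReport:
    """Per-fold metric reports plus mean and sample SD per metric."""

    fold_metrics: list[Mapping[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {"folds": [dict(m) for m in self.fold_metrics], "mean": self.mean, "sd": self.sd},
            indent=2,
            sort_keys=True,
        )

    def table(self) -> str:
        """Human-readable mean ± SD table, one row per metric."""
        lines = ["metric    mean ± SD"]
        for k in self.mean:
            lines.append(f"{k:<9} {self.mean[k]:.3f} ± {self.sd[k]:.3f}")
        return "\n".join(lines)


def cross_validate(
    corpus: Sequence[T],
    k: int = 5,
    seed: int = 0,
    train_fn: Callable[[list[T]], object] | None = None,
    eval_fn: Callable[[object, list[T]], Mapping[str, float] | EntityEvalReport] | None = None,
) -> CVReport:
    """Seeded k-fold CV: near-equal folds, each fold once as the test set.

    ``train_fn`` maps a training subset to a model; ``eval_fn`` maps (model,
    test subset) to a metric mapping (an :class:`EntityEvalReport` is accepted
    and reduced to its P/R/F1). Mean and sample (n-1) SD are reported per metric.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError("corpus smaller than k")
    if train_fn is None or eval_fn is None:
        raise ValueError("train_fn and eval_fn are required")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = np.array_split(order, k)
    fold_metrics: list[Mapping[str, float]] = []
    for i in range(k):
        test_idx = set(folds[i].tolist())
        train = [corpus[j] for j in order if j not in test_idx]
        test = [corpus[j] for j in folds[i]]
        model = train_fn(train)
        result = eval_fn(model, test)
        if isinstance(result, EntityEvalReport):
            result = result.metrics()
        fold_metrics.append(dict(result))
    keys = fold_metrics[0].keys()
    mean = {key: float(np.mean([m[key] for m in fold_metrics])) for key in keys}
    sd = {key: float(np.std([m[key] for m in fold_metrics], ddof=1)) for key in keys}
    return CVReport(fold_metrics=fold_metrics, mean=mean, sd=sd)
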