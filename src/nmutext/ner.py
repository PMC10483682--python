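"""Hybrid neural named-entity tagger: char-CNN + BiLSTM encoder with a linear-chain CRF.

The model scores a tag sequence y for a token sequence x as

    s(x, y) = start[y_1] + sum_t  E[t, y_t] + sum_{t>=2} T[y_{t-1}, y_t] + end[y_T]

where the emission matrix E comes from projecting a bidirectional LSTM run over
per-token features (a pre-trained word embedding concatenated with max-pooled
character-CNN features, which give sub-word robustness to the misspellings that
pervade drug chatter), and T is the learned tag-transition matrix of the CRF.
Training minimizes the negative log-likelihood  logZ(x) - s(x, y_gold)  with the
partition function computed by the forward algorithm in log-space; decoding uses
Viterbi. Transition constraints (no O -> I-X, no B-X/I-X -> I-Y) are hard -inf
sentinels so that decoded output is always a legal IOB2 sequence.

Everything is plain NumPy with analytically derived gradients: CRF gradients via
forward-backward marginals, encoder gradients via backpropagation through time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .embeddings import EmbeddingProvider

__all__ = [
    "TagSchema",
    "NERConfig",
    "NERParams",
    "LabeledSequence",
    "EmissionMatrix",
    "TrainReport",
    "DecodeError",
    "TrainingError",
    "DEFAULT_ENTITY_LABELS",
    "init_params",
    "char_cnn_features",
    "emissions",
    "crf_score",
    "crf_log_partition",
    "viterbi_decode",
    "crf_nll",
    "crf_nll_grad",
    "train_ner",
    "predict",
    "read_conll",
    "write_conll",
    "save_params",
    "load_params",
]

NEG_INF = -np.inf

DEFAULT_ENTITY_LABELS = ("DRUG", "ADE", "SYMPTOM", "TREATMENT", "AGE", "GENDER")

# character inventory: printable ASCII (32..126) plus a trailing UNK row
_CHARS = {chr(c): i for i, c in enumerate(range(32, 127))}
_N_CHARS = len(_CHARS) + 1
_UNK_CHAR = _N_CHARS - 1


class DecodeError(RuntimeError):
    """Every tag path has -inf score (over-constrained instance)."""


class TrainingError(RuntimeError):
    """Non-finite loss encountered during training."""


def _lse(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """log-sum-exp that tolerates -inf blocks (all--inf reduces to -inf)."""
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):  # all--inf block: log(0) -> -inf is the answer
        out = np.log(np.sum(np.exp(a - m_safe), axis=axis)) + np.squeeze(m_safe, axis=axis)
    return out


@dataclass(frozen=True)
class TagSchema:
    """IOB2 tag set over an ordered entity-label list.

    Tags are ordered O, B-X1, I-X1, B-X2, I-X2, ... so that the index map is a
    bijection onto 0..2*len(labels).
    """

    entity_labels: tuple[str, ...] = DEFAULT_ENTITY_LABELS

    def __post_init__(self) -> None:
        if not self.entity_labels:
            raise ValueError("schema needs at least one entity label")
        object.__setattr__(self, "entity_labels", tuple(self.entity_labels))

    @property
    def tags(self) -> tuple[str, ...]:
        out = ["O"]
        for lab in self.entity_labels:
            out += [f"B-{lab}", f"I-{lab}"]
        return tuple(out)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tags)}

    @property
    def n_tags(self) -> int:
        return 2 * len(self.entity_labels) + 1

    def encode(self, tags: Sequence[str]) -> list[int]:
        idx = self.index
        try:
            return [idx[t] for t in tags]
        except KeyError as exc:
            raise ValueError(f"unknown tag {exc.args[0]!r}") from exc

    def decode(self, ids: Sequence[int]) -> list[str]:
        tags = self.tags
        return [tags[i] for i in ids]

    def is_legal(self, tags: Sequence[str]) -> bool:
        prev = "O"
        for t in tags:
            if t.startswith("I-"):
                lab = t[2:]
                if prev not in (f"B-{lab}", f"I-{lab}"):
                    return False
            prev = t
        return True

    def allowed_start(self) -> np.ndarray:
        """Boolean mask over tags legal at position 1 (O and B-X)."""
        return np.array([not t.startswith("I-") for t in self.tags])

    def allowed_transitions(self) -> np.ndarray:
        """Boolean (K, K) mask: entry [i, j] true iff tag j may follow tag i."""
        tags = self.tags
        K = self.n_tags
        ok = np.ones((K, K), dtype=bool)
        for i, ti in enumerate(tags):
            for j, tj in enumerate(tags):
                if tj.startswith("I-"):
                    lab = tj[2:]
                    ok[i, j] = ti in (f"B-{lab}", f"I-{lab}")
        return ok


@dataclass
class NERConfig:
    """Hyperparameters of the tagger; all dimensions are small by default so the
    model trains in seconds on a single CPU."""

    char_dim: int = 16
    char_filters: int = 16
    char_window: int = 3
    hidden_dim: int = 32
    dropout: float = 0.0
    learning_rate: float = 0.3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    constrain_transitions: bool = True

    def __post_init__(self) -> None:
        if self.char_window % 2 == 0:
            raise ValueError("char_window must be odd")
        if min(self.char_dim, self.char_filters, self.hidden_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class NERParams:
    """All trainable tensors plus the schema/config they were built for."""

    schema: TagSchema
    config: NERConfig
    word_dim: int
    char_embed: np.ndarray          # (n_chars, char_dim)
    conv_W: np.ndarray              # (filters, window * char_dim)
    conv_b: np.ndarray              # (filters,)
    lstm_fw: dict[str, np.ndarray]  # W (4h, d_in), U (4h, h), b (4h,)
    lstm_bw: dict[str, np.ndarray]
    proj_W: np.ndarray              # (K, 2h)
    proj_b: np.ndarray              # (K,)
    transitions: np.ndarray         # (K, K); [i, j] = score of j following i
    start: np.ndarray               # (K,)
    end: np.ndarray                 # (K,)


@dataclass(frozen=True)
class LabeledSequence:
    tokens: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must have equal length")


@dataclass
class EmissionMatrix:
    scores: np.ndarray  # (seq_len, n_tags)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] < 1:
            raise ValueError("emission matrix must be (seq_len >= 1, n_tags)")


@dataclass
class TrainReport:
    epoch_nll: list[float] = field(default_factory=list)
    n_sequences: int = 0
    config: NERConfig | None = None


def init_params(
    schema: TagSchema, config: NERConfig, word_dim: int, rng: np.random.Generator | None = None
) -> NERParams:
    """Seeded scaled-normal initialization; transition sentinels applied if constrained."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, K = config.hidden_dim, schema.n_tags
    d_in = word_dim + config.char_filters

    def mat(*shape: int) -> np.ndarray:
        scale = 1.0 / np.sqrt(shape[-1])
        return rng.uniform(-scale, scale, size=shape)

    def lstm() -> dict[str, np.ndarray]:
        return {"W": mat(4 * h, d_in), "U": mat(4 * h, h), "b": np.zeros(4 * h)}

    transitions = np.zeros((K, K))
    start = np.zeros(K)
    end = np.zeros(K)
    if config.constrain_transitions:
        transitions[~schema.allowed_transitions()] = NEG_INF
        start[~schema.allowed_start()] = NEG_INF
    return NERParams(
        schema=schema,
        config=config,
        word_dim=word_dim,
        char_embed=mat(_N_CHARS, config.char_dim),
        conv_W=mat(config.char_filters, config.char_window * config.char_dim),
        conv_b=np.zeros(config.char_filters),
        lstm_fw=lstm(),
        lstm_bw=lstm(),
        proj_W=mat(K, 2 * h),
        proj_b=np.zeros(K),
        transitions=transitions,
        start=start,
        end=end,
    )


# ---------------------------------------------------------------------------
# encoder forward/backward
# ---------------------------------------------------------------------------

def _char_ids(word: str) -> list[int]:
    return [_CHARS.get(c, _UNK_CHAR) for c in word]


def _char_cnn_forward(word: str, params: NERParams) -> tuple[np.ndarray, dict]:
    if not word:
        raise ValueError("char_cnn_features requires a non-empty word")
    cfg = params.config
    ids = _char_ids(word)
    pad = (cfg.char_window - 1) // 2
    E = params.char_embed[ids]  # (m, char_dim)
    E_pad = np.zeros((len(ids) + 2 * pad, cfg.char_dim))
    E_pad[pad : pad + len(ids)] = E
    m = len(ids)
    # windows matrix: (m, window*char_dim)
    windows = np.stack([E_pad[j : j + cfg.char_window].ravel() for j in range(m)])
    Z = windows @ params.conv_W.T + params.conv_b  # (m, filters)
    U = np.tanh(Z)
    argmax = np.argmax(U, axis=0)  # (filters,)
    pooled = U[argmax, np.arange(cfg.char_filters)]
    cache = {"ids": ids, "pad": pad, "windows": windows, "U": U, "argmax": argmax, "m": m}
    return pooled, cache


def char_cnn_features(word: str, params: NERParams) -> np.ndarray:
    """Max-over-time pooled tanh 1-D convolution over the padded character embeddings."""
    pooled, _ = _char_cnn_forward(word, params)
    return pooled


def _char_cnn_backward(dpooled: np.ndarray, cache: dict, params: NERParams, grads: dict) -> None:
    cfg = params.config
    U, argmax, windows = cache["U"], cache["argmax"], cache["windows"]
    pad, ids, m = cache["pad"], cache["ids"], cache["m"]
    dE_pad = np.zeros((m + 2 * pad, cfg.char_dim))
    for k in range(cfg.char_filters):
        j = argmax[k]
        dz = dpooled[k] * (1.0 - U[j, k] ** 2)
        if dz == 0.0:
            continue
        grads["conv_W"][k] += dz * windows[j]
        grads["conv_b"][k] += dz
        dE_pad[j : j + cfg.char_window] += dz * params.conv_W[k].reshape(
            cfg.char_window, cfg.char_dim
        )
    for pos, cid in enumerate(ids):
        grads["char_embed"][cid] += dE_pad[pad + pos]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_forward(X: np.ndarray, p: Mapping[str, np.ndarray], h_dim: int) -> tuple[np.ndarray, dict]:
    n = X.shape[0]
    H = np.zeros((n, h_dim))
    cache: dict = {"i": [], "f": [], "g": [], "o": [], "c": [], "tc": [], "h_prev": [], "c_prev": []}
    h = np.zeros(h_dim)
    c = np.zeros(h_dim)
    W, U, b = p["W"], p["U"], p["b"]
    for t in range(n):
        a = W @ X[t] + U @ h + b
        i = _sigmoid(a[:h_dim])
        f = _sigmoid(a[h_dim : 2 * h_dim])
        g = np.tanh(a[2 * h_dim : 3 * h_dim])
        o = _sigmoid(a[3 * h_dim :])
        cache["h_prev"].append(h)
        cache["c_prev"].append(c)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        H[t] = h
        for key, val in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("tc", tc)):
            cache[key].append(val)
    cache["X"] = X
    return H, cache


def _lstm_backward(
    dH: np.ndarray, cache: dict, p: Mapping[str, np.ndarray], h_dim: int, gp: dict
) -> np.ndarray:
    """BPTT; accumulates into gp['W'], gp['U'], gp['b'] and returns dX."""
    X = cache["X"]
    n = X.shape[0]
    dX = np.zeros_like(X)
    dh_next = np.zeros(h_dim)
    dc_next = np.zeros(h_dim)
    W, U = p["W"], p["U"]
    for t in range(n - 1, -1, -1):
        dh = dH[t] + dh_next
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        tc = cache["tc"][t]
        c_prev = cache["c_prev"][t]
        dc = dc_next + dh * o * (1.0 - tc**2)
        do = dh * tc
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)]
        )
        gp["W"] += np.outer(da, X[t])
        gp["U"] += np.outer(da, cache["h_prev"][t])
        gp["b"] += da
        dh_next = U.T @ da
        dX[t] = W.T @ da
    return dX


def _encoder_forward(
    tokens: Sequence[str],
    params: NERParams,
    provider: EmbeddingProvider,
    dropout_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    if not tokens:
        raise ValueError("emissions requires a non-empty token list")
    if provider.dim != params.word_dim:
        raise ValueError(
            f"provider dim {provider.dim} does not match params word_dim {params.word_dim}"
        )
    cfg = params.config
    word_vecs = provider(tokens)  # (n, d_w)
    char_feats = np.zeros((len(tokens), cfg.char_filters))
    char_caches = []
    for t, tok in enumerate(tokens):
        char_feats[t], cache = _char_cnn_forward(tok if tok else " ", params)
        char_caches.append(cache)
    X = np.concatenate([word_vecs, char_feats], axis=1)
    if dropout_mask is not None:
        X = X * dropout_mask
    h = cfg.hidden_dim
    H_fw, cache_fw = _lstm_forward(X, params.lstm_fw, h)
    H_bw_rev, cache_bw = _lstm_forward(X[::-1], params.lstm_bw, h)
    H = np.concatenate([H_fw, H_bw_rev[::-1]], axis=1)  # (n, 2h)
    E = H @ params.proj_W.T + params.proj_b
    cache = {
        "char_caches": char_caches,
        "cache_fw": cache_fw,
        "cache_bw": cache_bw,
        "H": H,
        "dropout_mask": dropout_mask,
        "n": len(tokens),
    }
    return E, cache


def _encoder_backward(dE: np.ndarray, cache: dict, params: NERParams, grads: dict) -> None:
    cfg = params.config
    h = cfg.hidden_dim
    H = cache["H"]
    grads["proj_W"] += dE.T @ H
    grads["proj_b"] += dE.sum(axis=0)
    dH = dE @ params.proj_W  # (n, 2h)
    dX_fw = _lstm_backward(dH[:, :h], cache["cache_fw"], params.lstm_fw, h, grads["lstm_fw"])
    dX_bw_rev = _lstm_backward(
        dH[:, h:][::-1], cache["cache_bw"], params.lstm_bw, h, grads["lstm_bw"]
    )
    dX = dX_fw + dX_bw_rev[::-1]
    if cache["dropout_mask"] is not None:
        dX = dX * cache["dropout_mask"]
    d_w = params.word_dim
    for t in range(cache["n"]):
        _char_cnn_backward(dX[t, d_w:], cache["char_caches"][t], params, grads)
    # word embeddings come from the (frozen) provider; their gradient is dropped


def emissions(
    tokens: Sequence[str], params: NERParams, provider: EmbeddingProvider
) -> EmissionMatrix:
    """Per-token tag scores from the char-CNN + BiLSTM encoder (no dropout)."""
    E, _ = _encoder_forward(tokens, params, provider)
    return EmissionMatrix(scores=E)


# ---------------------------------------------------------------------------
# linear-chain CRF
# ---------------------------------------------------------------------------

def _scores_of(em: EmissionMatrix | np.ndarray) -> np.ndarray:
    return em.scores if isinstance(em, EmissionMatrix) else np.asarray(em, dtype=float)


def crf_score(
    emissions: EmissionMatrix | np.ndarray, params: NERParams, path: Sequence[int]
) -> float:
    """Unnormalized score of one tag path."""
    E = _scores_of(emissions)
    n, K = E.shape
    if len(path) != n:
        raise ValueError("path length must equal seq_len")
    if any(not 0 <= y < K for y in path):
        raise ValueError("tag index out of range")
    s = params.start[path[0]] + E[0, path[0]]
    for t in range(1, n):
        s += params.transitions[path[t - 1], path[t]] + E[t, path[t]]
    return float(s + params.end[path[-1]])


def _forward_alphas(E: np.ndarray, params: NERParams) -> np.ndarray:
    n, K = E.shape
    alphas = np.empty((n, K))
    alphas[0] = params.start + E[0]
    for t in range(1, n):
        alphas[t] = _lse(alphas[t - 1][:, None] + params.transitions, axis=0) + E[t]
    return alphas


def crf_log_partition(emissions: EmissionMatrix | np.ndarray, params: NERParams) -> float:
    """log sum over all tag paths of exp(score), via the log-space forward recursion."""
    E = _scores_of(emissions)
    if np.isnan(E).any():
        raise ValueError("NaN in emission scores")
    alphas = _forward_alphas(E, params)
    return float(_lse(alphas[-1] + params.end, axis=0))


def viterbi_decode(
    emissions: EmissionMatrix | np.ndarray, params: NERParams
) -> tuple[list[int], float]:
    """Maximum-scoring tag path; ties break toward the lowest tag index."""
    E = _scores_of(emissions)
    if np.isnan(E).any():
        raise ValueError("NaN in emission scores")
    n, K = E.shape
    delta = params.start + E[0]
    back = np.zeros((n, K), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + params.transitions  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + E[t]
    final = delta + params.end
    best = int(np.argmax(final))
    score = float(final[best])
    if not np.isfinite(score):
        raise DecodeError("all tag paths have -inf score")
    path = [best]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, score


def crf_nll(
    params: NERParams,
    batch: Sequence[tuple[EmissionMatrix | np.ndarray, Sequence[int]]],
) -> float:
    """Mean over the batch of logZ - score(gold); non-negative by construction."""
    total = 0.0
    for em, gold in batch:
        s = crf_score(em, params, gold)
        if not np.isfinite(s):
            raise ValueError("gold path has -inf score under the transition constraints")
        total += crf_log_partition(em, params) - s
    return total / len(batch)


def _crf_grad_single(
    E: np.ndarray, params: NERParams, gold: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NLL of one sequence and its gradients wrt (emissions, T, start, end)."""
    n, K = E.shape
    alphas = _forward_alphas(E, params)
    logZ = float(_lse(alphas[-1] + params.end, axis=0))
    betas = np.empty((n, K))
    betas[-1] = params.end
    for t in range(n - 2, -1, -1):
        betas[t] = _lse(params.transitions + (E[t + 1] + betas[t + 1])[None, :], axis=1)
    dE = np.exp(alphas + betas - logZ)  # unary marginals
    dT = np.zeros((K, K))
    for t in range(1, n):
        with np.errstate(invalid="ignore"):
            pair = alphas[t - 1][:, None] + params.transitions + (E[t] + betas[t])[None, :] - logZ
        dT += np.exp(np.nan_to_num(pair, nan=NEG_INF, neginf=NEG_INF))
    dstart = dE[0].copy()
    dend = dE[-1].copy()
    # subtract the gold-path indicators
    gold_score = crf_score(E, params, gold)
    if not np.isfinite(gold_score):
        raise ValueError("gold path has -inf score under the transition constraints")
    dE_total = dE.copy()
    for t, y in enumerate(gold):
        dE_total[t, y] -= 1.0
    for t in range(1, n):
        dT[gold[t - 1], gold[t]] -= 1.0
    dstart[gold[0]] -= 1.0
    dend[gold[-1]] -= 1.0
    return logZ - gold_score, dE_total, dT, dstart, dend


def crf_nll_grad(
    params: NERParams,
    batch: Sequence[tuple[EmissionMatrix | np.ndarray, Sequence[int]]],
) -> tuple[float, dict]:
    """Batch-mean NLL and analytic gradients wrt emissions and CRF parameters."""
    K = params.schema.n_tags
    dT = np.zeros((K, K))
    dstart = np.zeros(K)
    dend = np.zeros(K)
    dEs = []
    total = 0.0
    for em, gold in batch:
        E = _scores_of(em)
        nll, dE, dT_i, ds_i, de_i = _crf_grad_single(E, params, list(gold))
        total += nll
        dEs.append(dE / len(batch))
        dT += dT_i
        dstart += ds_i
        dend += de_i
    m = len(batch)
    return total / m, {
        "emissions": dEs,
        "transitions": dT / m,
        "start": dstart / m,
        "end": dend / m,
    }


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def _zero_grads(params: NERParams) -> dict:
    return {
        "char_embed": np.zeros_like(params.char_embed),
        "conv_W": np.zeros_like(params.conv_W),
        "conv_b": np.zeros_like(params.conv_b),
        "lstm_fw": {k: np.zeros_like(v) for k, v in params.lstm_fw.items()},
        "lstm_bw": {k: np.zeros_like(v) for k, v in params.lstm_bw.items()},
        "proj_W": np.zeros_like(params.proj_W),
        "proj_b": np.zeros_like(params.proj_b),
        "transitions": np.zeros_like(params.transitions),
        "start": np.zeros_like(params.start),
        "end": np.zeros_like(params.end),
    }


def _batch_loss_and_grads(
    seqs: Sequence[LabeledSequence],
    params: NERParams,
    provider: EmbeddingProvider,
    rng: np.random.Generator | None,
) -> tuple[float, dict]:
    """Full-network loss and gradients for one mini-batch (dropout if rng given)."""
    cfg = params.config
    grads = _zero_grads(params)
    total = 0.0
    m = len(seqs)
    for seq in seqs:
        mask = None
        if rng is not None and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            d_in = params.word_dim + cfg.char_filters
            mask = (rng.random((len(seq.tokens), d_in)) < keep) / keep
        E, enc_cache = _encoder_forward(seq.tokens, params, provider, dropout_mask=mask)
        gold = params.schema.encode(seq.tags)
        nll, dE, dT, dstart, dend = _crf_grad_single(E, params, gold)
        total += nll
        grads["transitions"] += dT / m
        grads["start"] += dstart / m
        grads["end"] += dend / m
        _scale = 1.0 / m
        _encoder_backward(dE * _scale, enc_cache, params, grads)
    return total / m, grads


def _sgd_step(params: NERParams, grads: dict, lr: float) -> None:
    params.char_embed -= lr * grads["char_embed"]
    params.conv_W -= lr * grads["conv_W"]
    params.conv_b -= lr * grads["conv_b"]
    for side, g in (("lstm_fw", grads["lstm_fw"]), ("lstm_bw", grads["lstm_bw"])):
        p = getattr(params, side)
        for k in p:
            p[k] -= lr * g[k]
    params.proj_W -= lr * grads["proj_W"]
    params.proj_b -= lr * grads["proj_b"]
    finite = np.isfinite(params.transitions)
    params.transitions[finite] -= lr * grads["transitions"][finite]
    finite_s = np.isfinite(params.start)
    params.start[finite_s] -= lr * grads["start"][finite_s]
    params.end -= lr * grads["end"]


def train_ner(
    corpus: Sequence[LabeledSequence],
    schema: TagSchema,
    config: NERConfig,
    provider: EmbeddingProvider,
) -> tuple[NERParams, TrainReport]:
    """Minimize the CRF negative log-likelihood by seeded mini-batch gradient descent.

    Deterministic for a given (corpus, config, provider): initialization, batch
    order and dropout all derive from ``config.seed``.
    """
    if len(corpus) < 10:
        raise ValueError("train_ner requires at least 10 sequences")
    for seq in corpus:
        schema.encode(seq.tags)  # raises on unknown tags
        if config.constrain_transitions and not schema.is_legal(seq.tags):
            raise ValueError(f"illegal IOB2 gold sequence: {seq.tags}")
    rng = np.random.default_rng(config.seed)
    params = init_params(schema, config, provider.dim, rng)
    report = TrainReport(n_sequences=len(corpus), config=config)
    order = np.arange(len(corpus))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(corpus), config.batch_size):
            batch = [corpus[i] for i in order[lo : lo + config.batch_size]]
            loss, grads = _batch_loss_and_grads(
                batch, params, provider, rng if config.dropout > 0 else None
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            _sgd_step(params, grads, config.learning_rate)
            epoch_loss += loss
            n_batches += 1
        report.epoch_nll.append(epoch_loss / n_batches)
    return params, report


def predict(
    tokens: Sequence[str],
    params: NERParams,
    schema: TagSchema | None = None,
    provider: EmbeddingProvider | None = None,
) -> LabeledSequence:
    """Emissions -> Viterbi -> IOB2 tags (always legal under constrained transitions)."""
    if provider is None:
        raise ValueError("predict requires an embedding provider")
    schema = schema or params.schema
    E = emissions(tokens, params, provider)
    path, _ = viterbi_decode(E, params)
    return LabeledSequence(tokens=tuple(tokens), tags=tuple(schema.decode(path)))


# ---------------------------------------------------------------------------
# CoNLL and parameter serialization
# ---------------------------------------------------------------------------

def read_conll(path: str | Path) -> list[LabeledSequence]:
    """Read token<SPACE>tag lines, blank line between sentences (CoNLL-2003 style)."""
    seqs: list[LabeledSequence] = []
    tokens: list[str] = []
    tags: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            if tokens:
                seqs.append(LabeledSequence(tuple(tokens), tuple(tags)))
                tokens, tags = [], []
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed CoNLL line: {raw!r}")
        tokens.append(parts[0])
        tags.append(parts[-1])
    if tokens:
        seqs.append(LabeledSequence(tuple(tokens), tuple(tags)))
    return seqs


def write_conll(seqs: Sequence[LabeledSequence], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for seq in seqs:
            for tok, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{tok} {tag}\n")
            fh.write("\n")


def _arr(a: np.ndarray) -> list:
    return np.where(np.isfinite(a), a, None).tolist() if np.isinf(a).any() else a.tolist()


def _unarr(lst: object) -> np.ndarray:
    a = np.array(
        [[NEG_INF if v is None else v for v in row] for row in lst]
        if lst and isinstance(lst[0], list)
        else [NEG_INF if v is None else v for v in lst],
        dtype=float,
    )
    return a


def save_params(params: NERParams, path: str | Path) -> None:
    """Serialize the full model (schema + config + tensors) as structured JSON text."""
    doc = {
        "schema": list(params.schema.entity_labels),
        "config": vars(params.config),
        "word_dim": params.word_dim,
        "char_embed": _arr(params.char_embed),
        "conv_W": _arr(params.conv_W),
        "conv_b": _arr(params.conv_b),
        "lstm_fw": {k: _arr(v) for k, v in params.lstm_fw.items()},
        "lstm_bw": {k: _arr(v) for k, v in params.lstm_bw.items()},
        "proj_W": _arr(params.proj_W),
        "proj_b": _arr(params.proj_b),
        "transitions": _arr(params.transitions),
        "start": _arr(params.start),
        "end": _arr(params.end),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_params(path: str | Path) -> NERParams:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return NERParams(
        schema=TagSchema(tuple(doc["schema"])),
        config=NERConfig(**doc["config"]),
        word_dim=int(doc["word_dim"]),
        char_embed=_unarr(doc["char_embed"]),
        conv_W=_unarr(doc["conv_W"]),
        conv_b=_unarr(doc["conv_b"]),
        lstm_fw={k: _unarr(v) for k, v in doc["lstm_fw"].items()},
        lstm_bw={k: _unarr(v) for k, v in doc["lstm_bw"].items()},
        proj_W=_unarr(doc["proj_W"]),
        proj_b=_unarr(doc["proj_b"]),
        transitions=_unarr(doc["transitions"]),
        start=_unarr(doc["start"]),
        end=_unarr(doc["end"]),
    )
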