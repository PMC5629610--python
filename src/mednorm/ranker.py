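"""Convolutional pair-scoring network.

Six layers: word-embedding input, convolution with ReLU over widths
``c`` in ``widths``, 1-max pooling to a length-``p`` encoding per text,
a joint layer concatenating ``[v_m, v_y, v_sem, v_mor]`` where
``v_sem = v_m^T M v_y / p`` (bilinear similarity, standardized by the
encoding length) and ``v_mor`` holds two morphological features, a
fully-connected ReLU hidden layer, and a two-class softmax whose
positive-label probability is the ranking score.

Implemented directly in numpy with analytic gradients; the model is
small enough (tens of thousands of parameters) that a tensor framework
would buy nothing but a heavyweight dependency.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._text import edit_distance, normalize, tokenize
from .lexicon import NIL_ID, MentionRecord, WordStats
from .candidates import Candidate, CandidateSet

__all__ = [
    "NIL_TOKEN",
    "EmbeddingTable",
    "FilterBank",
    "RankerParams",
    "ScoredCandidate",
    "NormalizationResult",
    "embed",
    "conv_feature_map",
    "encode",
    "semantic_similarity",
    "morph_features",
    "score_pair",
    "rank_candidates",
]

#: Reserved token carrying the learned NIL representation.
NIL_TOKEN = "<NIL>"

D_MOR = 2  # shared-word proportion + imf-weighted cosine

_CHECKPOINT_VERSION = 1


def _hash_seed(word: str) -> int:
    return int.from_bytes(hashlib.blake2b(word.encode(), digest_size=4).digest(),
                          "big")


class EmbeddingTable:
    """Word -> length-``t`` vector store with a deterministic OOV policy.

    Unknown words receive a vector drawn from a generator seeded by a
    hash of the word, so the same word always maps to the same vector in
    any process.  New words are appended to the table (and become
    trainable when the table is trained).
    """

    def __init__(self, t: int, init_range: float = 0.25) -> None:
        self.t = t
        self.init_range = init_range
        self.index: dict[str, int] = {}
        self.vectors = np.zeros((0, t))
        self.lookup(NIL_TOKEN)

    def _oov_vector(self, word: str) -> np.ndarray:
        rng = np.random.default_rng(_hash_seed(word))
        return rng.uniform(-self.init_range, self.init_range, self.t)

    def lookup(self, word: str) -> int:
        row = self.index.get(word)
        if row is None:
            row = len(self.index)
            self.index[word] = row
            self.vectors = np.vstack([self.vectors, self._oov_vector(word)])
        return row

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def get(self, word: str) -> np.ndarray:
        row = self.lookup(word)  # may grow self.vectors
        return self.vectors[row]

    def set(self, word: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.t,):
            raise ValueError(f"expected length-{self.t} vector")
        row = self.lookup(word)  # may grow self.vectors
        self.vectors[row] = vector

    @classmethod
    def from_text_file(cls, path, init_range: float = 0.25) -> "EmbeddingTable":
        """Load whitespace-separated embeddings (word + t floats per line)."""
        table: EmbeddingTable | None = None
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                parts = line.split()
                if len(parts) < 2:
                    continue
                word, values = parts[0], np.array(parts[1:], dtype=float)
                if table is None:
                    table = cls(len(values), init_range)
                table.set(word, values)
        if table is None:
            raise ValueError(f"no embeddings found in {path}")
        return table


@dataclass
class FilterBank:
    """Per-width convolution filters: ``weights[c]`` has shape
    (p_c, t, c); ``biases[c]`` has shape (p_c,)."""

    widths: tuple[int, ...]
    weights: dict[int, np.ndarray]
    biases: dict[int, np.ndarray]

    @property
    def p(self) -> int:
        return sum(self.weights[c].shape[0] for c in self.widths)

    @property
    def max_width(self) -> int:
        return max(self.widths)


@dataclass
class RankerParams:
    """All trainable arrays of the pair-scoring network."""

    embeddings: EmbeddingTable
    bank: FilterBank
    M: np.ndarray              # (p, p) bilinear similarity
    W_h: np.ndarray            # (hidden, 2p + 1 + D_MOR)
    b_h: np.ndarray            # (hidden,)
    q0: np.ndarray             # (hidden,)
    q1: np.ndarray             # (hidden,)
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.bank.p

    @classmethod
    def init(
        cls,
        t: int,
        widths: tuple[int, ...],
        p_per_width: int,
        hidden: int,
        rng: np.random.Generator,
        init_range: float = 0.25,
    ) -> "RankerParams":
        embeddings = EmbeddingTable(t, init_range)
        weights, biases = {}, {}
        for c in widths:
            scale = np.sqrt(6.0 / (t * c + 1))
            weights[c] = rng.uniform(-scale, scale, (p_per_width, t, c))
            biases[c] = np.zeros(p_per_width)
        p = p_per_width * len(widths)
        joint = 2 * p + 1 + D_MOR
        M = np.eye(p) + rng.normal(0.0, 0.01, (p, p))
        scale = np.sqrt(6.0 / (joint + hidden))
        W_h = rng.uniform(-scale, scale, (hidden, joint))
        b_h = np.zeros(hidden)
        q0 = rng.normal(0.0, 0.1, hidden)
        q1 = rng.normal(0.0, 0.1, hidden)
        return cls(embeddings, FilterBank(tuple(widths), weights, biases),
                   M, W_h, b_h, q0, q1,
                   meta={"t": t, "widths": list(widths),
                         "p_per_width": p_per_width, "hidden": hidden,
                         "init_range": init_range})

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        words = sorted(self.embeddings.index, key=self.embeddings.index.get)
        header = json.dumps(
            {"version": _CHECKPOINT_VERSION, "t": self.embeddings.t,
             "widths": list(self.bank.widths), "meta": self.meta,
             "vocab": words}
        )
        arrays = {"emb": self.embeddings.vectors, "M": self.M,
                  "W_h": self.W_h, "b_h": self.b_h,
                  "q0": self.q0, "q1": self.q1}
        for c in self.bank.widths:
            arrays[f"conv_w_{c}"] = self.bank.weights[c]
            arrays[f"conv_b_{c}"] = self.bank.biases[c]
        arrays["header"] = np.frombuffer(header.encode(), dtype=np.uint8)
        with open(path, "wb") as handle:
            np.savez(handle, **arrays)

    @classmethod
    def load(cls, path) -> "RankerParams":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header["version"] != _CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version "
                                 f"{header['version']}")
            table = EmbeddingTable(header["t"])
            table.index = {w: i for i, w in enumerate(header["vocab"])}
            table.vectors = data["emb"].copy()
            widths = tuple(header["widths"])
            bank = FilterBank(
                widths,
                {c: data[f"conv_w_{c}"].copy() for c in widths},
                {c: data[f"conv_b_{c}"].copy() for c in widths},
            )
            return cls(table, bank, data["M"].copy(), data["W_h"].copy(),
                       data["b_h"].copy(), data["q0"].copy(),
                       data["q1"].copy(), meta=header.get("meta", {}))


@dataclass(frozen=True)
class ScoredCandidate:
    candidate: Candidate
    score: float
    v_sem: float = 0.0
    v_mor: tuple[float, ...] = ()


@dataclass(frozen=True)
class NormalizationResult:
    mention: MentionRecord
    tier: str
    predicted_id: str | None   # concept id, NIL_ID, or None = no mapping
    score: float
    scored: tuple[ScoredCandidate, ...] = ()
    candidate_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def candidate_tokens(candidate: Candidate) -> list[str]:
    if candidate.concept_id == NIL_ID:
        return [NIL_TOKEN]
    return tokenize(candidate.matched_name)


def embed(tokens: list[str], table: EmbeddingTable, min_len: int) -> np.ndarray:
    """Token matrix of shape (t, max(len(tokens), min_len)).

    Texts shorter than the largest filter width are right-padded with
    zero columns.
    """
    if not tokens:
        tokens = [NIL_TOKEN]
    length = max(len(tokens), min_len)
    x = np.zeros((table.t, length))
    for i, tok in enumerate(tokens):
        x[:, i] = table.get(tok)
    return x


def conv_feature_map(x: np.ndarray, s: np.ndarray, b: float) -> np.ndarray:
    """ReLU feature map of one filter: length ``L - c + 1``."""
    t, c = s.shape
    length = x.shape[1]
    if length < c:
        raise ValueError(f"text of length {length} shorter than filter {c}")
    out = np.empty(length - c + 1)
    for i in range(length - c + 1):
        out[i] = np.maximum(np.tensordot(s, x[:, i : i + c]) + b, 0.0)
    return out


def _conv_pool(x: np.ndarray, bank: FilterBank):
    """Vectorized conv + 1-max pooling.

    Returns the pooled length-p vector and, per width, the pre-ReLU maps
    and argmax positions needed for backprop.
    """
    pooled = []
    cache = {}
    for c in bank.widths:
        w = bank.weights[c]                      # (p_c, t, c)
        n_win = x.shape[1] - c + 1
        windows = np.stack(
            [x[:, i : i + c].ravel() for i in range(n_win)], axis=1
        )                                        # (t*c, n_win)
        pre = w.reshape(w.shape[0], -1) @ windows + bank.biases[c][:, None]
        feat = np.maximum(pre, 0.0)              # (p_c, n_win)
        arg = feat.argmax(axis=1)
        pooled.append(feat[np.arange(feat.shape[0]), arg])
        cache[c] = (windows, pre, arg)
    return np.concatenate(pooled), cache


def encode(x: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Length-p encoding: 1-max pooling over every filter's feature map."""
    return _conv_pool(x, bank)[0]


def semantic_similarity(v_m: np.ndarray, v_y: np.ndarray, M: np.ndarray) -> float:
    """Bilinear similarity ``v_m^T M v_y`` (unscaled)."""
    return float(v_m @ M @ v_y)


def morph_features(
    mention_tokens: list[str],
    candidate_tokens: list[str],
    stats: WordStats,
) -> np.ndarray:
    """Two morphological similarities, both in [0, 1].

    1. shared-word proportion: |words(m) ∩ words(y)| / |words(m) ∪ words(y)|
    2. inverse-mention-frequency-weighted cosine between the two word
       indicator vectors, with weight imf(w) per word.
    """
    wm, wy = set(mention_tokens), set(candidate_tokens)
    if not wm and not wy:
        return np.zeros(D_MOR)
    union = wm | wy
    shared = wm & wy
    proportion = len(shared) / len(union)
    num = sum(stats.imf(w) ** 2 for w in shared)
    nm = np.sqrt(sum(stats.imf(w) ** 2 for w in wm))
    ny = np.sqrt(sum(stats.imf(w) ** 2 for w in wy))
    if nm == 0.0 or ny == 0.0:
        cosine = 1.0 if wm == wy else 0.0
    else:
        cosine = num / (nm * ny)
    return np.array([proportion, cosine])


def _forward(
    mention_toks: list[str],
    cand_toks: list[str],
    params: RankerParams,
    stats: WordStats,
):
    bank = params.bank
    x_m = embed(mention_toks, params.embeddings, bank.max_width)
    x_y = embed(cand_toks, params.embeddings, bank.max_width)
    v_m, cache_m = _conv_pool(x_m, bank)
    v_y, cache_y = _conv_pool(x_y, bank)
    p = bank.p
    v_sem = semantic_similarity(v_m, v_y, params.M) / p
    v_mor = morph_features(mention_toks, cand_toks, stats)
    v_joint = np.concatenate([v_m, v_y, [v_sem], v_mor])
    pre_h = params.W_h @ v_joint + params.b_h
    o_h = np.maximum(pre_h, 0.0)
    z0, z1 = float(o_h @ params.q0), float(o_h @ params.q1)
    zmax = max(z0, z1)
    score = np.exp(z1 - zmax) / (np.exp(z0 - zmax) + np.exp(z1 - zmax))
    cache = {
        "x_m": x_m, "x_y": x_y, "v_m": v_m, "v_y": v_y,
        "cache_m": cache_m, "cache_y": cache_y, "v_sem": v_sem,
        "v_mor": v_mor, "v_joint": v_joint, "pre_h": pre_h, "o_h": o_h,
        "mention_toks": mention_toks, "cand_toks": cand_toks,
    }
    return float(score), cache


def score_pair(
    mention: MentionRecord | str,
    candidate: Candidate,
    params: RankerParams,
    stats: WordStats,
) -> ScoredCandidate:
    """Softmax probability of the positive label for one pair."""
    text = mention.text if isinstance(mention, MentionRecord) else mention
    m_toks = tokenize(text)
    c_toks = candidate_tokens(candidate)
    score, cache = _forward(m_toks, c_toks, params, stats)
    return ScoredCandidate(candidate, score, cache["v_sem"],
                           tuple(cache["v_mor"]))


# ---------------------------------------------------------------------------
# Backward pass (used by the trainer)
# ---------------------------------------------------------------------------

class Gradients:
    """Accumulator mirroring RankerParams' arrays."""

    def __init__(self, params: RankerParams) -> None:
        bank = params.bank
        self.conv_w = {c: np.zeros_like(bank.weights[c]) for c in bank.widths}
        self.conv_b = {c: np.zeros_like(bank.biases[c]) for c in bank.widths}
        self.M = np.zeros_like(params.M)
        self.W_h = np.zeros_like(params.W_h)
        self.b_h = np.zeros_like(params.b_h)
        self.q0 = np.zeros_like(params.q0)
        self.q1 = np.zeros_like(params.q1)
        self.emb: dict[int, np.ndarray] = {}

    def add_embedding(self, row: int, grad: np.ndarray) -> None:
        if row in self.emb:
            self.emb[row] += grad
        else:
            self.emb[row] = grad.copy()


def backward(
    cache: dict, score: float, label: int, params: RankerParams,
    grads: Gradients,
) -> float:
    """Accumulate cross-entropy gradients for one pair; returns the loss."""
    eps = 1e-12
    loss = -np.log(score + eps) if label == 1 else -np.log(1.0 - score + eps)
    g = score - label  # dL/dz1 = -dL/dz0
    o_h = cache["o_h"]
    grads.q1 += g * o_h
    grads.q0 += -g * o_h
    d_o = g * (params.q1 - params.q0)
    d_pre = d_o * (cache["pre_h"] > 0)
    grads.W_h += np.outer(d_pre, cache["v_joint"])
    grads.b_h += d_pre
    d_joint = params.W_h.T @ d_pre
    p = params.p
    d_vm = d_joint[:p].copy()
    d_vy = d_joint[p : 2 * p].copy()
    d_sem = d_joint[2 * p]
    v_m, v_y = cache["v_m"], cache["v_y"]
    grads.M += (d_sem / p) * np.outer(v_m, v_y)
    d_vm += (d_sem / p) * (params.M @ v_y)
    d_vy += (d_sem / p) * (params.M.T @ v_m)

    for side, d_v, toks in (
        ("m", d_vm, cache["mention_toks"]),
        ("y", d_vy, cache["cand_toks"]),
    ):
        x = cache[f"x_{side}"]
        d_x = np.zeros_like(x)
        offset = 0
        for c in params.bank.widths:
            windows, pre, arg = cache[f"cache_{side}"][c]
            p_c = pre.shape[0]
            d_pool = d_v[offset : offset + p_c]
            offset += p_c
            active = pre[np.arange(p_c), arg] > 0
            d_pool = d_pool * active
            grads.conv_b[c] += d_pool
            win = windows[:, arg].T                       # (p_c, t*c)
            grads.conv_w[c] += (d_pool[:, None] * win).reshape(
                params.bank.weights[c].shape
            )
            w_flat = params.bank.weights[c].reshape(p_c, -1)
            contrib = d_pool[:, None] * w_flat            # (p_c, t*c)
            t = x.shape[0]
            for j in range(p_c):
                if d_pool[j] == 0.0:
                    continue
                i = arg[j]
                d_x[:, i : i + c] += contrib[j].reshape(t, c)
        for i, tok in enumerate(toks):
            row = params.embeddings.lookup(tok)
            grads.add_embedding(row, d_x[:, i])
    return float(loss)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _tie_key(mention_norm: str, sc: ScoredCandidate):
    return (
        -sc.score,
        edit_distance(sc.candidate.matched_name, mention_norm),
        sc.candidate.concept_id,
    )


def rank_candidates(
    mention: MentionRecord,
    cand_set: CandidateSet,
    params: RankerParams | None,
    stats: WordStats,
) -> tuple[list[ScoredCandidate], NormalizationResult]:
    """Score and sort a candidate set; the top candidate is the prediction.

    Singleton sets short-circuit with score 1.0 and no net evaluation
    (rule-determined outcomes).  An empty CIII set with NIL disabled
    yields a flagged "no mapping" result.
    """
    ids = tuple(cand_set.concept_ids())
    if not cand_set.candidates:
        result = NormalizationResult(mention, cand_set.tier, None, 0.0, (), ids)
        return [], result
    if cand_set.is_singleton():
        only = cand_set.candidates[0]
        scored = [ScoredCandidate(only, 1.0)]
        result = NormalizationResult(
            mention, cand_set.tier, only.concept_id, 1.0, tuple(scored), ids
        )
        return scored, result
    if params is None:
        raise ValueError("multi-candidate set requires trained parameters")
    scored = [
        score_pair(mention, cand, params, stats)
        for cand in cand_set.candidates
    ]
    mention_norm = normalize(mention.text)
    scored.sort(key=lambda sc: _tie_key(mention_norm, sc))
    top = scored[0]
    result = NormalizationResult(
        mention, cand_set.tier, top.candidate.concept_id, top.score,
        tuple(scored), ids,
    )
    return scored, result
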