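"""Pairwise training, cross-validation, corpus normalization, evaluation.

Training follows the pairwise learning-to-rank scheme: every
(mention, candidate) pair from a mention's candidate set becomes a
binary training example — label 1 iff the candidate's concept id is a
gold id of that mention — and the network minimizes two-class
cross-entropy on the softmax pair score by seeded stochastic gradient
descent.  Mentions whose candidate set is a rule-determined singleton
are excluded from the objective.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from ._text import normalize, tokenize
from .candidates import (
    Candidate,
    CandidateIndex,
    CandidateSet,
    GenConfig,
    generate_candidates,
)
from .lexicon import (
    KnowledgeBase,
    MentionRecord,
    TrainingLexicon,
    WordStats,
    build_abbreviation_map,
    build_training_lexicon,
    compute_word_stats,
)
from .ranker import (
    Gradients,
    NormalizationResult,
    RankerParams,
    ScoredCandidate,
    EmbeddingTable,
    _forward,
    backward,
    candidate_tokens,
    morph_features,
    rank_candidates,
)
from ._text import edit_distance

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledPair",
    "TrainConfig",
    "EvalReport",
    "build_pairs",
    "train",
    "cross_validate",
    "normalize_corpus",
    "evaluate",
]


@dataclass(frozen=True)
class LabeledPair:
    mention: MentionRecord
    candidate: Candidate
    label: int


@dataclass(frozen=True)
class TrainConfig:
    """Network and optimization settings (defaults match the reference
    configuration: t=50, filter widths 2 and 3, 50 filters per width,
    10-fold cross-validation)."""

    t: int = 50
    widths: tuple[int, ...] = (2, 3)
    p_per_width: int = 50
    hidden: int = 100
    lr: float = 0.05
    epochs: int = 5
    seed: int = 0
    init_range: float = 0.25
    folds: int = 10

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        """Flat ``key = value`` config file; unknown keys rejected."""
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                if key == "widths":
                    kwargs[key] = tuple(int(v) for v in value.split(","))
                elif key in ("lr", "init_range"):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class EvalReport:
    accuracy: float
    candidate_recall: float
    ambiguity_rate: float
    n: int
    per_tier: dict[str, dict[str, float]] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "candidate_recall": self.candidate_recall,
            "ambiguity_rate": self.ambiguity_rate,
            "n": self.n,
            "per_tier": self.per_tier,
            "errors": self.errors,
        }


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def _gold_ids(
    record: MentionRecord, lexicon: TrainingLexicon | None
) -> set[str]:
    golds: set[str] = set()
    if record.gold_id is not None:
        golds.add(record.gold_id)
    if lexicon is not None:
        golds |= lexicon.mention_map.get(normalize(record.text), set())
    return golds


def build_pairs(
    records: list[MentionRecord],
    kb: KnowledgeBase,
    lexicon: TrainingLexicon,
    config: GenConfig | None = None,
    docs: dict[str, str] | None = None,
) -> list[LabeledPair]:
    """One labeled pair per (mention, candidate in its set).

    Singleton candidate sets are rule-determined and contribute nothing;
    mentions whose gold id is missing from the set contribute only
    negatives (counted against candidate recall, logged).
    """
    config = config or GenConfig()
    index = CandidateIndex(kb, lexicon)
    abbrev_cache = {}
    pairs: list[LabeledPair] = []
    missing_gold = 0
    for record in records:
        if record.gold_id is None:
            continue
        abbrevs = None
        if docs and record.doc_id in docs:
            if record.doc_id not in abbrev_cache:
                abbrev_cache[record.doc_id] = build_abbreviation_map(
                    docs[record.doc_id]
                )
            abbrevs = abbrev_cache[record.doc_id]
        # leave-one-surface-out: a training mention must not trivially
        # match its own annotation through the training lexicon
        cand_set = generate_candidates(
            record, kb, lexicon, config, abbrevs=abbrevs, index=index,
            exclude_training_surface=normalize(record.text),
        )
        if len(cand_set.candidates) <= 1:
            continue
        golds = _gold_ids(record, lexicon)
        labels = [
            int(c.concept_id in golds) for c in cand_set.candidates
        ]
        if not any(labels):
            missing_gold += 1
        pairs.extend(
            LabeledPair(record, cand, label)
            for cand, label in zip(cand_set.candidates, labels)
        )
    if missing_gold:
        logger.info(
            "build_pairs: %d mentions lack their gold id in the candidate "
            "set (negative-only)", missing_gold,
        )
    return pairs


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    pairs: list[LabeledPair],
    config: TrainConfig,
    stats: WordStats | None = None,
    pretrained: EmbeddingTable | None = None,
) -> RankerParams:
    """Fit RankerParams by per-sample SGD on two-class cross-entropy.

    Deterministic given ``config.seed``.  ``pretrained`` embeddings, if
    provided, overwrite the uniform initialization for their words and
    are then fine-tuned along with everything else.
    """
    if not any(p.label == 1 for p in pairs):
        raise ValueError("training requires at least one positive pair")
    if not any(p.label == 0 for p in pairs):
        raise ValueError("training requires at least one negative pair")
    if stats is None:
        stats = WordStats({}, 0)
    rng = np.random.default_rng(config.seed)
    params = RankerParams.init(
        config.t, config.widths, config.p_per_width, config.hidden, rng,
        config.init_range,
    )
    # materialize the vocabulary in a deterministic order
    tokenized = []
    for pair in pairs:
        m_toks = tokenize(pair.mention.text)
        c_toks = candidate_tokens(pair.candidate)
        for tok in (*m_toks, *c_toks):
            params.embeddings.lookup(tok)
        tokenized.append((m_toks, c_toks, pair.label))
    if pretrained is not None:
        if pretrained.t != config.t:
            raise ValueError(
                f"pretrained embeddings have t={pretrained.t}, "
                f"config has t={config.t}"
            )
        for word, row in pretrained.index.items():
            params.embeddings.set(word, pretrained.vectors[row])

    history: list[float] = []
    lr = config.lr
    for _epoch in range(config.epochs):
        order = rng.permutation(len(tokenized))
        total = 0.0
        for idx in order:
            m_toks, c_toks, label = tokenized[idx]
            score, cache = _forward(m_toks, c_toks, params, stats)
            grads = Gradients(params)
            total += backward(cache, score, label, params, grads)
            _apply_sgd(params, grads, lr)
        history.append(total / max(len(tokenized), 1))
    params.meta["loss_history"] = history
    params.meta["config"] = {
        "t": config.t, "widths": list(config.widths),
        "p_per_width": config.p_per_width, "hidden": config.hidden,
        "lr": config.lr, "epochs": config.epochs, "seed": config.seed,
    }
    logger.info("train: %d pairs, epoch losses %s", len(pairs),
                [round(h, 4) for h in history])
    return params


def _apply_sgd(params: RankerParams, grads: Gradients, lr: float) -> None:
    bank = params.bank
    for c in bank.widths:
        bank.weights[c] -= lr * grads.conv_w[c]
        bank.biases[c] -= lr * grads.conv_b[c]
    params.M -= lr * grads.M
    params.W_h -= lr * grads.W_h
    params.b_h -= lr * grads.b_h
    params.q0 -= lr * grads.q0
    params.q1 -= lr * grads.q1
    for row, grad in grads.emb.items():
        params.embeddings.vectors[row] -= lr * grad


# ---------------------------------------------------------------------------
# Corpus normalization
# ---------------------------------------------------------------------------

def _rank_morphology(
    mention: MentionRecord, cand_set: CandidateSet, stats: WordStats
) -> tuple[list[ScoredCandidate], NormalizationResult]:
    """Morphology-only reference ranker: orders candidates by the two
    morphological features alone (no learned parameters)."""
    ids = tuple(cand_set.concept_ids())
    if not cand_set.candidates:
        return [], NormalizationResult(mention, cand_set.tier, None, 0.0, (), ids)
    if cand_set.is_singleton():
        only = cand_set.candidates[0]
        sc = ScoredCandidate(only, 1.0)
        return [sc], NormalizationResult(
            mention, cand_set.tier, only.concept_id, 1.0, (sc,), ids
        )
    m_toks = tokenize(mention.text)
    m_norm = normalize(mention.text)
    scored = []
    for cand in cand_set.candidates:
        feats = morph_features(m_toks, candidate_tokens(cand), stats)
        # squash the feature sum into (0, 1) so it reads like a score
        scored.append(
            ScoredCandidate(cand, float(feats.sum() / 2.0), 0.0, tuple(feats))
        )
    scored.sort(
        key=lambda sc: (
            -sc.score,
            edit_distance(sc.candidate.matched_name, m_norm),
            sc.candidate.concept_id,
        )
    )
    top = scored[0]
    return scored, NormalizationResult(
        mention, cand_set.tier, top.candidate.concept_id, top.score,
        tuple(scored), ids,
    )


def normalize_corpus(
    records: list[MentionRecord],
    kb: KnowledgeBase,
    lexicon: TrainingLexicon | None,
    params: RankerParams | None,
    config: GenConfig | None = None,
    stats: WordStats | None = None,
    docs: dict[str, str] | None = None,
    method: str = "cnn",
) -> list[NormalizationResult]:
    """Normalize every mention: candidate generation then ranking.

    ``method="morphology"`` ranks by the morphological features only
    (the no-semantics reference used for comparisons).
    """
    config = config or GenConfig()
    if stats is None:
        stats = compute_word_stats(kb, lexicon)
    index = CandidateIndex(kb, lexicon)
    abbrev_cache: dict[str, object] = {}
    results = []
    for record in records:
        abbrevs = None
        if docs and record.doc_id in docs:
            if record.doc_id not in abbrev_cache:
                abbrev_cache[record.doc_id] = build_abbreviation_map(
                    docs[record.doc_id]
                )
            abbrevs = abbrev_cache[record.doc_id]
        cand_set = generate_candidates(
            record, kb, lexicon, config, abbrevs=abbrevs, index=index
        )
        if method == "morphology":
            _, result = _rank_morphology(record, cand_set, stats)
        else:
            _, result = rank_candidates(record, cand_set, params, stats)
        results.append(result)
    return results


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    results: list[NormalizationResult],
    gold: list[MentionRecord] | None = None,
    training_lexicon: TrainingLexicon | None = None,
) -> EvalReport:
    """Accuracy, candidate recall (the ranking ceiling) and diagnostics.

    NIL is an ordinary label: a NIL-gold mention is correct iff the
    prediction is NIL.  Ambiguity is measured over surface forms pooled
    from the evaluated annotations plus the training lexicon.
    """
    gold_map: dict[tuple[str, int, int], str] = {}
    if gold is not None:
        gold_map = {
            (r.doc_id, r.start, r.end): r.gold_id
            for r in gold
            if r.gold_id is not None
        }

    surface_golds: dict[str, set[str]] = {}
    if training_lexicon is not None:
        for surface, ids in training_lexicon.mention_map.items():
            surface_golds.setdefault(surface, set()).update(ids)

    n = correct = recalled = ambiguous = 0
    per_tier: dict[str, dict[str, float]] = {}
    errors: list[dict] = []
    scored_records = []
    for result in results:
        mention = result.mention
        key = (mention.doc_id, mention.start, mention.end)
        gold_id = gold_map.get(key, mention.gold_id)
        if gold_id is None:
            continue
        scored_records.append((result, gold_id))
        surface_golds.setdefault(normalize(mention.text), set()).add(gold_id)

    for result, gold_id in scored_records:
        mention = result.mention
        n += 1
        tier = per_tier.setdefault(
            result.tier, {"n": 0, "correct": 0, "accuracy": 0.0}
        )
        tier["n"] += 1
        ok = result.predicted_id == gold_id
        if ok:
            correct += 1
            tier["correct"] += 1
        else:
            errors.append({
                "doc_id": mention.doc_id,
                "span": [mention.start, mention.end],
                "mention": mention.text,
                "gold": gold_id,
                "predicted": result.predicted_id,
                "tier": result.tier,
            })
        if gold_id in result.candidate_ids:
            recalled += 1
        if len(surface_golds.get(normalize(mention.text), ())) > 1:
            ambiguous += 1

    for tier in per_tier.values():
        tier["accuracy"] = tier["correct"] / tier["n"] if tier["n"] else 0.0
    return EvalReport(
        accuracy=correct / n if n else 0.0,
        candidate_recall=recalled / n if n else 0.0,
        ambiguity_rate=ambiguous / n if n else 0.0,
        n=n,
        per_tier=per_tier,
        errors=errors,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _fold_split(
    n: int, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, folds) if len(fold)]


def cross_validate(
    records: list[MentionRecord],
    kb: KnowledgeBase,
    config: TrainConfig,
    grid: dict[str, list] | None = None,
    gen_config: GenConfig | None = None,
    docs: dict[str, str] | None = None,
) -> tuple[TrainConfig, dict[str, list[float]]]:
    """Seeded k-fold model selection over a hyperparameter grid.

    Returns the best configuration (highest mean fold accuracy, ties to
    the earlier grid point) and the per-fold accuracies of every point.
    """
    grid = grid or {}
    gen_config = gen_config or GenConfig()
    rng = np.random.default_rng(config.seed)
    folds = _fold_split(len(records), config.folds, rng)
    keys = sorted(grid)
    points = list(itertools.product(*(grid[k] for k in keys))) or [()]

    best_config, best_mean = config, -1.0
    all_scores: dict[str, list[float]] = {}
    for values in points:
        overrides = dict(zip(keys, values))
        if "widths" in overrides:
            overrides["widths"] = tuple(overrides["widths"])
        point_config = dc_replace(config, **overrides)
        scores = []
        for held_out in folds:
            test_idx = set(int(i) for i in held_out)
            train_recs = [
                r for i, r in enumerate(records) if i not in test_idx
            ]
            test_recs = [r for i, r in enumerate(records) if i in test_idx]
            lexicon = build_training_lexicon(train_recs)
            stats = compute_word_stats(kb, lexicon)
            pairs = build_pairs(train_recs, kb, lexicon, gen_config, docs)
            try:
                params = train(pairs, point_config, stats)
            except ValueError:
                params = None  # fold too small to train; rules only
            results = normalize_corpus(
                test_recs, kb, lexicon, params, gen_config, stats, docs,
                method="cnn" if params is not None else "morphology",
            )
            scores.append(evaluate(results, training_lexicon=lexicon).accuracy)
        label = ",".join(f"{k}={v}" for k, v in zip(keys, values)) or "default"
        all_scores[label] = scores
        mean = float(np.mean(scores)) if scores else 0.0
        logger.info("cv point %s: mean accuracy %.4f", label, mean)
        if mean > best_mean:
            best_mean, best_config = mean, point_config
    return best_config, all_scores
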