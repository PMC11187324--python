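"""Ensemble consensus with abstention, and evaluation metrics.

Each trained model votes on a slide by thresholding its bag probability at
0.5.  The ensemble decision is the majority class when the majority holds
strictly more than half of the votes; an exact 50% split yields an
*indecision* — the ensemble abstains rather than guesses, and such slides
are flagged for priority human review.  Confidence is the majority vote
fraction (for six models, "at least 4 converged" is exactly confidence
> 0.5).

Metrics follow standard confusion-matrix definitions; AUC uses the
rank-based (Mann-Whitney) formulation with ties counted one half.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata

from .mil import Bag, TrainedModel, forward_bag

POSITIVE = "positive"
NEGATIVE = "negative"
INDECISION = "indecision"

VOTE_THRESHOLD = 0.5


@dataclasses.dataclass
class EnsemblePrediction:
    slide_id: str
    votes: dict[str, int]  # model id -> 0/1
    probabilities: dict[str, float]  # model id -> bag probability
    confidence: float  # majority vote count / number of models
    decision: str  # positive | negative | indecision


@dataclasses.dataclass
class MetricsReport:
    """Per-model metrics and/or three-way ensemble accounting.

    Ratio fields are None when their denominator is zero (undefined, not
    0).  Ensemble percentages are integers produced by largest-remainder
    rounding, so they always sum to 100.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    auc: float | None = None
    percent_correct: int | None = None
    percent_indecision: int | None = None
    percent_incorrect: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def consensus(votes) -> tuple[str, float]:
    """Majority decision over binary votes; an exact tie abstains.

    Returns (decision, confidence) where confidence = max class count / N.
    Permutation-invariant; odd vote counts can never tie.
    """
    votes = [int(v) for v in votes]
    if not votes:
        raise ValueError("consensus requires at least one vote")
    if any(v not in (0, 1) for v in votes):
        raise ValueError("votes must be binary")
    n = len(votes)
    pos = sum(votes)
    neg = n - pos
    confidence = max(pos, neg) / n
    if pos > neg:
        return POSITIVE, confidence
    if neg > pos:
        return NEGATIVE, confidence
    return INDECISION, confidence


def predict_slide(models: list[TrainedModel], bag: Bag) -> EnsemblePrediction:
    """Run every ensemble member on one bag and form the consensus."""
    if bag.instance_count == 0:
        raise ValueError(f"bag {bag.slide_id!r} is empty")
    votes: dict[str, int] = {}
    probs: dict[str, float] = {}
    for i, model in enumerate(models):
        size = model.config.input_size_px
        mid = f"m{i + 1}_{model.config.name}"
        try:
            p, _ = forward_bag(model, bag.instances)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"model {mid} failed on bag {bag.slide_id!r} "
                             f"(input size {size}): {exc}") from exc
        probs[mid] = p
        votes[mid] = int(p >= VOTE_THRESHOLD)
    decision, confidence = consensus(list(votes.values()))
    return EnsemblePrediction(
        slide_id=bag.slide_id,
        votes=votes,
        probabilities=probs,
        confidence=confidence,
        decision=decision,
    )


def binary_metrics(predictions, truths) -> MetricsReport:
    """Confusion-matrix metrics for hard binary predictions."""
    predictions = [int(p) for p in predictions]
    truths = [int(t) for t in truths]
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if not predictions:
        raise ValueError("binary_metrics requires at least one prediction")
    tp = sum(1 for p, t in zip(predictions, truths) if p == 1 and t == 1)
    fp = sum(1 for p, t in zip(predictions, truths) if p == 1 and t == 0)
    tn = sum(1 for p, t in zip(predictions, truths) if p == 0 and t == 0)
    fn = sum(1 for p, t in zip(predictions, truths) if p == 0 and t == 1)
    total = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total,
        precision=precision, recall=recall, f1=f1,
    )


def auc_score(scores, truths) -> float:
    """Probability that a random positive outscores a random negative,
    ties counting one half (rank / Mann-Whitney formulation)."""
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray([int(t) for t in truths])
    if scores.shape != truths.shape:
        raise ValueError("scores and truths must have equal length")
    n_pos = int((truths == 1).sum())
    n_neg = int((truths == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    pos_rank_sum = ranks[truths == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _largest_remainder_percent(counts: list[int]) -> list[int]:
    """Integer percentages summing to 100.  Ties in remainder are broken in
    favor of the *later* category, so the accounting never understates the
    error column (ordering: correct, indecision, incorrect)."""
    total = sum(counts)
    quotas = [100.0 * c / total for c in counts]
    out = [int(np.floor(q)) for q in quotas]
    missing = 100 - sum(out)
    order = sorted(range(len(counts)), key=lambda i: (quotas[i] - out[i], i), reverse=True)
    for i in order[:missing]:
        out[i] += 1
    return out


def ensemble_report(decisions) -> MetricsReport:
    """Three-way accounting of ensemble outcomes.

    ``decisions`` is a sequence over slides with values in
    {"correct", "incorrect", "indecision"}.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("ensemble_report requires at least one decision")
    allowed = {"correct", "indecision", "incorrect"}
    bad = set(decisions) - allowed
    if bad:
        raise ValueError(f"unknown decision values: {sorted(bad)}")
    counts = [decisions.count("correct"), decisions.count("indecision"),
              decisions.count("incorrect")]
    pc, pi, pw = _largest_remainder_percent(counts)
    return MetricsReport(percent_correct=pc, percent_indecision=pi, percent_incorrect=pw)


def evaluate_ensemble(
    predictions: list[EnsemblePrediction], truths: dict[str, int]
) -> tuple[MetricsReport, MetricsReport | None]:
    """Score ensemble predictions against slide truth labels.

    Returns (three-way report, decided-only binary metrics).  Indecision
    slides are excluded from the binary metrics denominators and accounted
    for separately; the binary report is None when every slide was an
    indecision or only one class remains among decided slides' predictions.
    """
    outcome = []
    decided_preds, decided_truths, mean_probs = [], [], []
    for pred in predictions:
        truth = truths[pred.slide_id]
        if pred.decision == INDECISION:
            outcome.append("indecision")
            continue
        hard = 1 if pred.decision == POSITIVE else 0
        outcome.append("correct" if hard == truth else "incorrect")
        decided_preds.append(hard)
        decided_truths.append(truth)
        mean_probs.append(float(np.mean(list(pred.probabilities.values()))))
    report = ensemble_report(outcome)
    binary = None
    if decided_preds:
        binary = binary_metrics(decided_preds, decided_truths)
        if len(set(decided_truths)) == 2:
            binary.auc = auc_score(mean_probs, decided_truths)
    return report, binary
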