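"""Evaluating a genomic partition as a binary classifier of concordance.

A concordant region set predicts, for every joined call, whether the call
will be concordant across pipelines (positive class) -- the prediction is
simply whether the call's anchor position falls inside the set.  Comparing
predictions with the actual decisions of a ground-truth cohort yields a
confusion matrix and the usual derived metrics, of which the false
discovery rate FP/(FP+TP) (discordant calls inside declared-concordant
territory) and the negative predictive value TN/(TN+FN) are the most
informative for variant-filtering use.

``holdout_experiment``/``learning_curve`` reproduce the training protocol:
a random subset of the cohort builds the partition (score -> interpolate ->
threshold) and the held-out samples act as ground truth, replicated under a
seeded generator.  ``fp_flagging_precision`` covers the haploid-truth
setting, where every heterozygous call is by construction a false positive
and the discordant region set is scored on how precisely it flags them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import Decision, JoinedDecision, VariantCall
from .regions import RegionSet
from .scoring import ScoreWeights, aggregate_counts, score_points
from .signal import InterpolationParams, PartitionThresholds, interpolate, partition


@dataclass(frozen=True)
class ConfusionCounts:
    """Positive class = call predicted concordant (inside the region set)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class ClassifierMetrics:
    """Derived rates; a component is None when its denominator is zero."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    fdr: float | None
    npv: float | None


def classify_calls(
    truth: Iterable[JoinedDecision], concordant: RegionSet
) -> ConfusionCounts:
    """Confusion counts of region membership vs actual decisions.

    Predicted positive iff the decision's anchor position lies inside the
    concordant set; actual positive iff the decision is CONCORDANT.
    """
    tp = fp = tn = fn = 0
    for d in truth:
        predicted = concordant.contains(d.contig, d.pos - 1)
        actual = d.decision is Decision.CONCORDANT
        if predicted and actual:
            tp += 1
        elif predicted and not actual:
            fp += 1
        elif not predicted and not actual:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(c: ConfusionCounts) -> ClassifierMetrics:
    """Exact evaluation of the standard binary-classifier rates."""
    if c.total == 0:
        raise ValueError("metrics undefined for zero evaluated calls")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return ClassifierMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        precision=ratio(c.tp, c.tp + c.fp),
        fdr=ratio(c.fp, c.fp + c.tp),
        npv=ratio(c.tn, c.tn + c.fn),
    )


def fp_flagging_precision(
    labeled_calls: Iterable[tuple[VariantCall, bool]], discordant: RegionSet
) -> float | None:
    """Precision of the discordant set at flagging labelled false positives.

    ``labeled_calls`` pairs each call with an is-false-positive flag (e.g.
    heterozygous calls in an effectively haploid genome).  Returns
    labelled-FP calls inside the discordant set divided by all calls inside
    it, or None when no call falls inside.
    """
    inside = flagged = 0
    for call, is_fp in labeled_calls:
        if discordant.contains(call.contig, call.pos - 1):
            inside += 1
            if is_fp:
                flagged += 1
    return flagged / inside if inside else None


# -- holdout training protocol --------------------------------------------

_METRIC_COLS = ["accuracy", "sensitivity", "specificity", "precision", "fdr", "npv"]


def build_partition(
    samples: Sequence[Iterable[JoinedDecision]],
    contig_lengths: Mapping[str, int],
    weights: ScoreWeights | None = None,
    interp: InterpolationParams | None = None,
    thresholds: PartitionThresholds | None = None,
) -> tuple[RegionSet, RegionSet]:
    """Full pipeline from joined decisions to a (concordant, discordant) pair."""
    pts = score_points(aggregate_counts(samples), weights)
    sig = interpolate(pts, interp, contig_lengths)
    return partition(sig, thresholds)


def _evaluate_split(
    train: Sequence[list[JoinedDecision]],
    test: Sequence[list[JoinedDecision]],
    contig_lengths: Mapping[str, int],
    weights: ScoreWeights | None,
    interp: InterpolationParams | None,
    thresholds: PartitionThresholds | None,
) -> dict:
    conc, _ = build_partition(train, contig_lengths, weights, interp, thresholds)
    counts = classify_calls(itertools.chain.from_iterable(test), conc)
    m = metrics(counts)
    row = {
        "n_train": len(train), "n_eval": len(test),
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
    }
    row.update({k: getattr(m, k) for k in _METRIC_COLS})
    return row


def holdout_experiment(
    cohort: Sequence[Iterable[JoinedDecision]],
    train_fraction: float,
    replicates: int,
    seed: int,
    contig_lengths: Mapping[str, int],
    weights: ScoreWeights | None = None,
    interp: InterpolationParams | None = None,
    thresholds: PartitionThresholds | None = None,
) -> pd.DataFrame:
    """Repeatedly split the cohort, train a partition, score the held-out half.

    Returns one row per replicate; :func:`summarize_metrics` reduces the
    table to per-metric mean and standard deviation.  Deterministic for a
    fixed seed.
    """
    cohort = [list(s) for s in cohort]
    n = len(cohort)
    if n < 2:
        raise ValueError("holdout requires a cohort of >= 2 samples")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    k = int(round(train_fraction * n))
    if not 1 <= k <= n - 1:
        raise ValueError(f"degenerate split: {k} training samples of {n}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        perm = rng.permutation(n)
        train = [cohort[i] for i in perm[:k]]
        test = [cohort[i] for i in perm[k:]]
        row = {"replicate": rep}
        row.update(_evaluate_split(train, test, contig_lengths,
                                   weights, interp, thresholds))
        rows.append(row)
    return pd.DataFrame(rows)


def learning_curve(
    cohort: Sequence[Iterable[JoinedDecision]],
    train_sizes: Sequence[int],
    replicates: int,
    seed: int,
    contig_lengths: Mapping[str, int],
    weights: ScoreWeights | None = None,
    interp: InterpolationParams | None = None,
    thresholds: PartitionThresholds | None = None,
) -> pd.DataFrame:
    """Holdout metrics as a function of the training-set size."""
    cohort = [list(s) for s in cohort]
    n = len(cohort)
    rng = np.random.default_rng(seed)
    rows = []
    for size in train_sizes:
        if not 1 <= size <= n - 1:
            raise ValueError(f"degenerate split: {size} training samples of {n}")
        for rep in range(replicates):
            perm = rng.permutation(n)
            train = [cohort[i] for i in perm[:size]]
            test = [cohort[i] for i in perm[size:]]
            row = {"train_size": size, "replicate": rep}
            row.update(_evaluate_split(train, test, contig_lengths,
                                       weights, interp, thresholds))
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_metrics(df: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Mean and standard deviation of each metric, optionally grouped."""
    cols = [c for c in _METRIC_COLS if c in df.columns]
    if by is None:
        return df[cols].agg(["mean", "std"])
    return df.groupby(by)[cols].agg(["mean", "std"])
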