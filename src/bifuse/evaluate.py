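"""Leave-one-trial-out evaluation, majority voting and fusion comparisons.

Each held-out parent trial contributes a pool of sub-trial predictions
(eight under the overlapping augmentation); the pool is reduced to one
trial-level decision by majority vote:

    y_hat = 1 if n_1 > n_0, 0 if n_1 < n_0,

with ties broken (by default) in favour of the class with the larger
summed softmax probability.  Accuracies are reported both at the sub-trial
level (pooled) and at the trial level (after voting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LABELS, SubTrial
from .network import TEMPORAL_KERNEL_GRID

TIE_RULES = ("probability", "zero")


@dataclass
class VotePool:
    """Per-sub-trial predictions of one parent trial."""

    parent_trial_id: str
    predictions: list[int]
    probabilities: np.ndarray | None = None  # (n, 2) softmax outputs

    def __post_init__(self):
        if not all(p in (0, 1) for p in self.predictions):
            raise ValueError("predictions must be 0/1")

    @property
    def n_pred_1(self) -> int:
        return int(sum(self.predictions))

    @property
    def n_pred_0(self) -> int:
        return len(self.predictions) - self.n_pred_1


def majority_vote(pool: VotePool, tie_rule: str = "probability") -> int:
    """Reduce a pool to one label; ties resolved by ``tie_rule``."""
    if not pool.predictions:
        raise ValueError("empty vote pool")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    if pool.n_pred_1 > pool.n_pred_0:
        return 1
    if pool.n_pred_1 < pool.n_pred_0:
        return 0
    if tie_rule == "probability" and pool.probabilities is not None:
        sums = np.asarray(pool.probabilities).sum(axis=0)
        return int(sums[1] > sums[0])
    return 0


@dataclass
class FoldResult:
    parent_trial_id: str
    true_label: int
    pool: VotePool
    voted_label: int


@dataclass
class EvalResult:
    """Fold-level details plus the two accuracy summaries."""

    folds: list[FoldResult]
    configuration: dict = field(default_factory=dict)

    @property
    def trial_accuracy(self) -> float:
        return float(np.mean([f.voted_label == f.true_label for f in self.folds]))

    @property
    def subtrial_accuracy(self) -> float:
        correct = total = 0
        for f in self.folds:
            correct += sum(p == f.true_label for p in f.pool.predictions)
            total += len(f.pool.predictions)
        return correct / total


def group_by_parent(subtrials: list[SubTrial]) -> dict[str, list[SubTrial]]:
    key = lambda s: s.parent_trial_id
    return {k: list(g) for k, g in groupby(sorted(subtrials, key=key), key=key)}


def loo_trial_cv(
    subtrials: list[SubTrial],
    model_factory,
    tie_rule: str = "probability",
) -> EvalResult:
    """One fold per parent trial: its sub-trials form the test pool, all
    other trials' sub-trials train a fresh model from ``model_factory``.

    ``model_factory(fold_index)`` must return an object with
    ``fit(subtrials)`` and ``predict_proba(subtrials) -> (n, 2)``.
    A leakage check fails hard if any test parent id reaches the training
    side.
    """
    groups = group_by_parent(subtrials)
    if len(groups) < 2:
        raise ValueError("leave-one-trial-out needs at least 2 parent trials")
    folds = []
    for k, (held_out, test_subs) in enumerate(groups.items()):
        train_subs = [s for pid, g in groups.items() if pid != held_out for s in g]
        if any(s.parent_trial_id == held_out for s in train_subs):
            raise RuntimeError(f"leakage: parent {held_out} present in training data")
        model = model_factory(k)
        model.fit(train_subs)
        probs = np.asarray(model.predict_proba(test_subs))
        preds = probs.argmax(axis=1).tolist()
        pool = VotePool(held_out, preds, probabilities=probs)
        folds.append(
            FoldResult(
                parent_trial_id=held_out,
                true_label=LABELS.index(test_subs[0].label),
                pool=pool,
                voted_label=majority_vote(pool, tie_rule),
            )
        )
    return EvalResult(folds=folds)


def accuracy_with_and_without_voting(result: EvalResult) -> tuple[float, float]:
    """(sub-trial accuracy, voted trial accuracy)."""
    return result.subtrial_accuracy, result.trial_accuracy


def chance_interval(n_trials: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided binomial interval around 0.5 for n Bernoulli trials."""
    lo = stats.binom.ppf((1 - level) / 2, n_trials, 0.5) / n_trials
    hi = stats.binom.ppf(1 - (1 - level) / 2, n_trials, 0.5) / n_trials
    return float(lo), float(hi)


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the null distribution is exact for
    n <= 25 untied samples and a tie-corrected normal approximation
    otherwise.  All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return 0.0, 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# fusion-stage comparison (Table-2-shaped summary)

_COMPARISONS = ("early-mid", "early-late", "mid-late", "dim0-dim1")


def stage_comparison_table(
    accuracies: dict[tuple[str, int, int], np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries from per-configuration accuracy vectors.

    ``accuracies`` maps (stage, axis_digit, kernel_len) to an array of
    per-participant (or per-replicate) accuracies.  Returns a mean +/- sd
    table and a p-value table with one row per comparison and one column
    per kernel length.
    """
    kernels = sorted({k for (_, _, k) in accuracies})
    mean_rows = {}
    for (stage, axis, kern), acc in sorted(accuracies.items()):
        mean_rows[(f"{stage[0].upper()}_{axis}", kern)] = (
            float(np.mean(acc)), float(np.std(acc)))
    means = pd.DataFrame(
        {
            "mean": {k: v[0] for k, v in mean_rows.items()},
            "sd": {k: v[1] for k, v in mean_rows.items()},
        }
    )
    pvals = pd.DataFrame(index=list(_COMPARISONS), columns=kernels, dtype=float)
    for kern in kernels:
        def pooled(stage):
            return np.concatenate(
                [accuracies[(stage, a, kern)] for a in (0, 1)
                 if (stage, a, kern) in accuracies]
            )
        groups = {s: pooled(s) for s in ("early", "middle", "late")}
        pvals.loc["early-mid", kern] = wilcoxon_signed_rank(groups["early"], groups["middle"])[1]
        pvals.loc["early-late", kern] = wilcoxon_signed_rank(groups["early"], groups["late"])[1]
        pvals.loc["mid-late", kern] = wilcoxon_signed_rank(groups["middle"], groups["late"])[1]
        dim0 = np.concatenate(
            [accuracies[(s, 0, kern)] for s in ("early", "middle") if (s, 0, kern) in accuracies]
        )
        dim1 = np.concatenate(
            [accuracies[(s, 1, kern)] for s in ("early", "middle") if (s, 1, kern) in accuracies]
        )
        pvals.loc["dim0-dim1", kern] = wilcoxon_signed_rank(dim0, dim1)[1]
    return means, pvals


def compare_fusion_stages(
    replicate_subtrials: list[list[SubTrial]],
    model_factory_for,
    kernel_lengths: tuple[int, ...] = TEMPORAL_KERNEL_GRID,
    stages: tuple[str, ...] = ("early", "middle", "late"),
    axes: tuple[int, ...] = (0, 1),
    tie_rule: str = "probability",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, int, int], np.ndarray]]:
    """Run leave-one-trial-out evaluation over the fusion grid.

    ``model_factory_for(stage, axis_digit, kernel_len, replicate)`` returns
    a model factory as accepted by :func:`loo_trial_cv`.  Every replicate
    contributes one accuracy per configuration; the summaries follow the
    comparison layout of :func:`stage_comparison_table`.
    """
    acc: dict[tuple[str, int, int], list[float]] = {}
    for r, subtrials in enumerate(replicate_subtrials):
        for stage in stages:
            for axis in axes:
                for kern in kernel_lengths:
                    factory = model_factory_for(stage, axis, kern, r)
                    result = loo_trial_cv(subtrials, factory, tie_rule)
                    acc.setdefault((stage, axis, kern), []).append(result.trial_accuracy)
    acc_arr = {k: np.asarray(v) for k, v in acc.items()}
    means, pvals = stage_comparison_table(acc_arr)
    return means, pvals, acc_arr
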