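"""Repeated-holdout evaluation harness and its metrics.

Implements the study protocol for comparing BiMM against a plain random
forest: persons (never single knees) are split 70/30 into training and
test sets, both models are fit on the training knees and scored on the
test knees, and the whole procedure is repeated over many independent
partitions. Per-partition records hold the AUC, threshold metrics at a
chosen probability cut-off, iteration counts, and the top-20 covariates by
Mean Decrease Gini; the summary aggregates means +- SD, a two-sample
Welch t-test on the AUC difference, and the variable-importance roll-up
(count of unique top-20 variables across partitions, and the top-10
variables by average score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import OUTCOME_COL, PERSON_COL, validate_cohort
from .core import BiMMModel, RFParams, fit_bimm, fit_plain_rf, predict_bimm
from .exceptions import BimmError, DegenerateOutcomeError, PhiUndefinedError
from .split_functions import SplitFunctionSpec

TOP_K_UNIQUE = 20
TOP_K_MEAN = 10


@dataclass
class PartitionMetrics:
    """Test-set metrics for one method on one partition."""

    partition_id: int
    method: str  # "BiMM" or "RF"
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    false_positive_rate: float
    n_iterations: int
    top_importances: list[tuple[str, float]]


@dataclass
class EvaluationSummary:
    """Aggregate of a repeated-partition experiment.

    ``metrics`` has one row per (partition, method). ``summary`` holds the
    per-method mean and SD of each metric. The t-test fields describe the
    BiMM-minus-RF difference in mean AUC.
    """

    metrics: pd.DataFrame
    summary: pd.DataFrame
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    unique_top_variables: dict[str, int]
    top10_mean_gini: dict[str, list[tuple[str, float]]]
    n_partitions: int
    threshold: float
    diagnostics: dict = field(default_factory=dict)


def partition_by_individual(
    cohort: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort 70/30 (by default) at the individual level.

    Persons are sampled without replacement; both knees of a person land on
    the same side. The training person count is ``round(fraction * n)``.
    """
    validate_cohort(cohort)
    if not 0.0 < train_fraction < 1.0:
        raise BimmError("train_fraction must lie in (0, 1)")
    persons = cohort[PERSON_COL].unique()
    if persons.size < 2:
        raise BimmError("need at least 2 persons to partition")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(persons)
    n_train = int(round(train_fraction * persons.size))
    train_ids = set(shuffled[:n_train].tolist())
    in_train = cohort[PERSON_COL].isin(train_ids)
    return cohort[in_train].copy(), cohort[~in_train].copy()


def compute_auc(y, scores) -> float:
    """Mann-Whitney AUC (probability a random positive outscores a random
    negative, ties counted half)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateOutcomeError("AUC undefined: y has a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def confusion_metrics(
    y, scores, threshold: float
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, false positive rate) at a cut-off.

    Predicted class is 1 iff score is strictly above the threshold, so ties
    at the threshold go to class 0.
    """
    y = np.asarray(y)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateOutcomeError(
            "sensitivity/specificity undefined: y has a single class"
        )
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    sens = tp / n_pos
    spec = tn / n_neg
    acc = (tp + tn) / y.size
    return sens, spec, acc, 1.0 - spec


def phi_coefficient(a: int, b: int, c: int, d: int) -> float:
    """Phi coefficient of the 2x2 table [[a, b], [c, d]].

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); undefined (raised) when
    any margin is zero.
    """
    if min(a, b, c, d) < 0:
        raise BimmError("cell counts must be non-negative")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise PhiUndefinedError("phi undefined: a margin of the 2x2 table is zero")
    return float((a * d - b * c) / math.sqrt(math.prod(margins)))


def two_sample_t(auc_a, auc_b) -> tuple[float, float, float, float]:
    """Welch two-sample t-test on mean(auc_a) - mean(auc_b) with 95% CI."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise BimmError("each sample needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise DegenerateOutcomeError("t-test undefined: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high)


def top_importances(model: BiMMModel, k: int = TOP_K_UNIQUE) -> list[tuple[str, float]]:
    """The k covariates with highest Mean Decrease Gini in a fitted model."""
    imp = model.importances().head(k)
    return list(zip(imp.index.tolist(), imp.to_numpy().tolist()))


def aggregate_importance(
    per_partition: list[list[tuple[str, float]]],
    top_k_unique: int = TOP_K_UNIQUE,
    top_k_mean: int = TOP_K_MEAN,
    absent_as_zero: bool = False,
) -> tuple[int, list[tuple[str, float]]]:
    """Roll up per-partition top-k importance lists.

    Returns the number of unique variables appearing in any list, and the
    ``top_k_mean`` variables with the highest average score. By default a
    variable's score is averaged over the partitions where it made the
    top-k list; with ``absent_as_zero`` the average instead counts missing
    partitions as zeros.
    """
    if not per_partition:
        raise BimmError("no importance lists to aggregate")
    for lst in per_partition:
        if len(lst) != top_k_unique:
            raise BimmError(
                f"each importance list must have exactly {top_k_unique} entries"
            )
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for lst in per_partition:
        for name, score in lst:
            totals[name] = totals.get(name, 0.0) + float(score)
            counts[name] = counts.get(name, 0) + 1
    denom = len(per_partition)
    means = {
        name: total / (denom if absent_as_zero else counts[name])
        for name, total in totals.items()
    }
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return len(totals), ranked[:top_k_mean]


def _score_partition(
    partition_id: int,
    method: str,
    model: BiMMModel,
    test: pd.DataFrame,
    threshold: float,
    k_top: int = TOP_K_UNIQUE,
) -> PartitionMetrics:
    y_test = test[OUTCOME_COL].to_numpy()
    scores = predict_bimm(model, test)
    sens, spec, acc, fpr = confusion_metrics(y_test, scores, threshold)
    return PartitionMetrics(
        partition_id=partition_id,
        method=method,
        auc=compute_auc(y_test, scores),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        false_positive_rate=fpr,
        n_iterations=model.n_iterations,
        top_importances=top_importances(model, k=k_top),
    )


_METRIC_COLS = [
    "auc",
    "sensitivity",
    "specificity",
    "accuracy",
    "false_positive_rate",
    "n_iterations",
]


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and SD of every metric column."""
    return metrics.groupby("method")[_METRIC_COLS].agg(["mean", "std"])


def run_experiment(
    cohort: pd.DataFrame,
    spec: SplitFunctionSpec,
    rf_params: RFParams | None = None,
    n_partitions: int = 100,
    train_fraction: float = 0.7,
    threshold: float = 0.5,
    tolerance: float = 0.5,
    max_iter: int = 50,
    seed: int = 0,
) -> EvaluationSummary:
    """Run the full repeated-partition BiMM-vs-RF comparison.

    Each partition gets its own derived seed for the person split and the
    model fits; a partition whose train or test outcome is single-class is
    resampled with a fresh derived seed (up to 10 attempts, logged in the
    diagnostics). The whole experiment is reproducible from ``seed``.
    """
    validate_cohort(cohort)
    rf_params = rf_params or RFParams()
    # top-20 lists, capped by the covariate count on narrow fixtures
    k_top = min(TOP_K_UNIQUE, len(cohort.columns) - 3)
    records: list[PartitionMetrics] = []
    resampled: list[int] = []
    for pid in range(n_partitions):
        train = test = None
        for attempt in range(10):
            split_seed = np.random.SeedSequence(
                [seed, pid, attempt]
            ).generate_state(1)[0] % (2**31)
            cand_train, cand_test = partition_by_individual(
                cohort, train_fraction, seed=int(split_seed)
            )
            if (
                cand_train[OUTCOME_COL].nunique() == 2
                and cand_test[OUTCOME_COL].nunique() == 2
            ):
                train, test = cand_train, cand_test
                break
            resampled.append(pid)
        if train is None:
            raise DegenerateOutcomeError(
                f"partition {pid}: could not find a two-class split in 10 attempts"
            )
        fit_seed = int(np.random.SeedSequence([seed, pid, 101]).generate_state(1)[0] % (2**31))
        bimm = fit_bimm(
            train, spec, rf_params=rf_params, tolerance=tolerance,
            max_iter=max_iter, seed=fit_seed,
        )
        rf = fit_plain_rf(train, rf_params=rf_params, seed=fit_seed)
        records.append(_score_partition(pid, "BiMM", bimm, test, threshold, k_top))
        records.append(_score_partition(pid, "RF", rf, test, threshold, k_top))

    metrics = pd.DataFrame(
        [
            {
                "partition_id": r.partition_id,
                "method": r.method,
                **{c: getattr(r, c) for c in _METRIC_COLS},
            }
            for r in records
        ]
    )
    summary = summarize_metrics(metrics)
    auc_bimm = metrics.loc[metrics["method"] == "BiMM", "auc"].to_numpy()
    auc_rf = metrics.loc[metrics["method"] == "RF", "auc"].to_numpy()
    t_stat, p_val, ci_low, ci_high = two_sample_t(auc_bimm, auc_rf)
    unique_counts: dict[str, int] = {}
    top10: dict[str, list[tuple[str, float]]] = {}
    for method in ("BiMM", "RF"):
        lists = [r.top_importances for r in records if r.method == method]
        unique_counts[method], top10[method] = aggregate_importance(
            lists, top_k_unique=k_top
        )
    return EvaluationSummary(
        metrics=metrics,
        summary=summary,
        t_statistic=t_stat,
        p_value=p_val,
        ci_low=ci_low,
        ci_high=ci_high,
        unique_top_variables=unique_counts,
        top10_mean_gini=top10,
        n_partitions=n_partitions,
        threshold=threshold,
        diagnostics={"resampled_partitions": resampled, "seed": seed},
    )
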