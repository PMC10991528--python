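"""Performance and group-fairness statistics.

Notation.  For a dataset D = (X, Y, C) with protected attribute X taking
values in a category set, descriptive features Y and binary outcome
C in {0,1}, a classifier produces predictions C-hat.  Per subgroup x,

    TPR_x = E[C-hat | C = 1, X = x]      FPR_x = E[C-hat | C = 0, X = x]

The equal-opportunity difference (EOD) is the spread of subgroup
sensitivities,

    EOD = min_x TPR_x - max_x TPR_x,

stored signed (always <= 0; 0 means every subgroup's positives are found
at the same rate).  The average-odds difference (AOD) applies the same
min-minus-max construction to the per-group sum TPR_x + FPR_x, halved:

    AOD = 1/2 [ min_x (FPR_x + TPR_x) - max_x (FPR_x + TPR_x) ].

The fairness-accuracy score Delta is the weighted harmonic mean of
balanced accuracy and fairness (1 - |EOD|),

    Delta = (1 + beta^2) * BAcc * (1 - |EOD|) / (beta^2 * BAcc + (1 - |EOD|)),

with beta = 0.5 by default, weighting predictive performance above
fairness — the relevant regime when missing true positives has a higher
clinical cost than residual disparity.

Subgroups whose conditioning set is empty (no positives for a TPR, no
negatives for an FPR) get an explicit *undefined* flag, never a silent 0
or a silent drop: the smallest subgroups are the risk case a fairness
audit exists to expose, and metrics that need those rates raise
:class:`~fairdep.errors.UndefinedMetricError` instead of hiding them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import GroupPartition
from .errors import UndefinedMetricError

__all__ = [
    "ScoredPredictions",
    "GroupRates",
    "FairnessReport",
    "group_rates",
    "eod",
    "aod",
    "balanced_accuracy",
    "auc_roc",
    "delta_score",
    "is_fair_eod",
    "tukey_pairwise",
    "mannwhitney_disparity",
    "summarize_folds",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ScoredPredictions:
    """Per-sample predicted probability, hard prediction, label and group.

    ``predictions`` are the hard calls C-hat; when produced by thresholding,
    the convention throughout the package is C-hat = 1 iff score >= t.
    """

    scores: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.predictions = np.asarray(self.predictions).astype(np.int8)
        self.labels = np.asarray(self.labels).astype(np.int8)
        self.group = np.asarray(self.group, dtype=object)
        n = len(self.scores)
        if not (len(self.predictions) == len(self.labels) == len(self.group) == n):
            raise ValueError("scores, predictions, labels and group must have equal length")
        if n and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.scores)

    @classmethod
    def from_scores(cls, scores, labels, group, threshold: float = 0.5) -> "ScoredPredictions":
        scores = np.asarray(scores, dtype=float)
        return cls(
            scores=scores,
            predictions=(scores >= threshold).astype(np.int8),
            labels=labels,
            group=group,
        )

    def subset(self, index: np.ndarray) -> "ScoredPredictions":
        return ScoredPredictions(
            scores=self.scores[index],
            predictions=self.predictions[index],
            labels=self.labels[index],
            group=self.group[index],
        )

    def partition(self) -> GroupPartition:
        cats = sorted(pd.unique(self.group))
        return GroupPartition(
            attribute="group",
            groups={c: np.flatnonzero(self.group == c) for c in cats},
            categories=cats,
        )


@dataclass
class GroupRates:
    """Per-subgroup TPR/FPR with support counts, plus pooled overall rates.

    ``table`` is indexed by category with columns ``tpr``, ``fpr``,
    ``n_pos``, ``n_neg``, ``tpr_defined``, ``fpr_defined``.  An undefined
    rate (empty conditioning set) is NaN with its flag False.
    """

    attribute: str
    table: pd.DataFrame
    overall_tpr: float
    overall_fpr: float

    @property
    def categories(self) -> list[str]:
        return list(self.table.index)

    def defined_tprs(self) -> pd.Series:
        return self.table.loc[self.table["tpr_defined"], "tpr"]

    def defined_sums(self) -> pd.Series:
        ok = self.table["tpr_defined"] & self.table["fpr_defined"]
        sub = self.table.loc[ok]
        return sub["tpr"] + sub["fpr"]


@dataclass
class FairnessReport:
    """Joint performance/fairness summary of one evaluated prediction set."""

    bacc: float
    auc: float
    eod: float
    aod: float
    delta: float
    beta: float
    group_rates: GroupRates | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "bacc": self.bacc,
            "auc": self.auc,
            "eod": self.eod,
            "aod": self.aod,
            "delta": self.delta,
            "beta": self.beta,
        }
        if self.group_rates is not None:
            d["tpr"] = {
                c: (None if not r["tpr_defined"] else float(r["tpr"]))
                for c, r in self.group_rates.table.iterrows()
            }
            d["fpr"] = {
                c: (None if not r["fpr_defined"] else float(r["fpr"]))
                for c, r in self.group_rates.table.iterrows()
            }
        d.update(self.extras)
        return d

    @classmethod
    def from_predictions(
        cls, pred: ScoredPredictions, partition: GroupPartition | None = None, beta: float = 0.5
    ) -> "FairnessReport":
        if partition is None:
            partition = pred.partition()
        rates = group_rates(pred, partition)
        e = eod(rates)
        return cls(
            bacc=balanced_accuracy(pred),
            auc=auc_roc(pred.scores, pred.labels),
            eod=e,
            aod=aod(rates),
            delta=delta_score(balanced_accuracy(pred), e, beta=beta),
            beta=beta,
            group_rates=rates,
        )


# ---------------------------------------------------------------------------
# subgroup rates


def group_rates(pred: ScoredPredictions, partition: GroupPartition) -> GroupRates:
    """Per-subgroup TPR_x = TP_x/P_x and FPR_x = FP_x/N_x, plus pooled rates.

    A group with no positives gets an undefined TPR flag (likewise FPR with
    no negatives); the consumer decides how to treat it.
    """
    rows = {}
    for cat in partition.categories:
        ix = partition.groups[cat]
        y, yhat = pred.labels[ix], pred.predictions[ix]
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        tpr = float((yhat[y == 1] == 1).mean()) if n_pos else np.nan
        fpr = float((yhat[y == 0] == 1).mean()) if n_neg else np.nan
        rows[cat] = {
            "tpr": tpr,
            "fpr": fpr,
            "n_pos": n_pos,
            "n_neg": n_neg,
            "tpr_defined": bool(n_pos),
            "fpr_defined": bool(n_neg),
        }
    y, yhat = pred.labels, pred.predictions
    if not (y == 1).any():
        raise UndefinedMetricError("no positive samples in any group")
    overall_tpr = float((yhat[y == 1] == 1).mean())
    overall_fpr = float((yhat[y == 0] == 1).mean()) if (y == 0).any() else np.nan
    table = pd.DataFrame.from_dict(rows, orient="index").loc[partition.categories]
    return GroupRates(
        attribute=partition.attribute,
        table=table,
        overall_tpr=overall_tpr,
        overall_fpr=overall_fpr,
    )


# ---------------------------------------------------------------------------
# fairness metrics


def eod(rates: GroupRates) -> float:
    """Equal-opportunity difference: min_x TPR_x - max_x TPR_x (in [-1, 0])."""
    tprs = rates.defined_tprs()
    if len(tprs) < 2:
        raise UndefinedMetricError(
            f"EOD needs >=2 groups with defined TPR, have {len(tprs)}"
        )
    return float(tprs.min() - tprs.max())


def aod(rates: GroupRates) -> float:
    """Average-odds difference: half the spread of per-group TPR_x + FPR_x."""
    sums = rates.defined_sums()
    if len(sums) < 2:
        raise UndefinedMetricError(
            f"AOD needs >=2 groups with both rates defined, have {len(sums)}"
        )
    return float(0.5 * (sums.min() - sums.max()))


def balanced_accuracy(pred: ScoredPredictions) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    y, yhat = pred.labels, pred.predictions
    if not ((y == 1).any() and (y == 0).any()):
        raise UndefinedMetricError("balanced accuracy needs both classes present")
    tpr = (yhat[y == 1] == 1).mean()
    tnr = (yhat[y == 0] == 0).mean()
    return float((tpr + tnr) / 2)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve; equals P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC-ROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def delta_score(bacc: float, eod_value: float, beta: float = 0.5) -> float:
    """Weighted harmonic mean of BAcc and fairness (1 - |EOD|).

    beta < 1 weights predictive performance above fairness; beta -> 0
    recovers BAcc exactly.  Defined as 0 in the degenerate case where both
    terms vanish.
    """
    if not 0 <= bacc <= 1:
        raise ValueError(f"BAcc must be in [0, 1], got {bacc}")
    if abs(eod_value) > 1:
        raise ValueError(f"|EOD| must be <= 1, got {eod_value}")
    fair = 1.0 - abs(eod_value)
    denom = beta**2 * bacc + fair
    if denom == 0:
        return 0.0
    return float((1 + beta**2) * bacc * fair / denom)


def is_fair_eod(eod_value: float, band: float = 0.1) -> bool:
    """Label a model fair when EOD falls within +/- ``band`` (default 0.1),
    the conventional acceptance band for equal-opportunity audits."""
    return abs(eod_value) <= band


# ---------------------------------------------------------------------------
# statistical comparison procedures


def tukey_pairwise(fold_rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey honest-significant-difference test on a folds x groups table.

    Treats cross-validation folds as replicates in a balanced one-way
    layout (an approximation: folds share training data).  Returns one row
    per group pair with the mean difference, simultaneous
    ``(1 - alpha)``-level confidence bounds based on the studentized range,
    and a significance flag (CI excludes 0).

    Zero within-group variance across folds degenerates to zero-width
    intervals with a warning.
    """
    groups = list(fold_rates.columns)
    if len(groups) < 2:
        raise UndefinedMetricError("Tukey comparison needs >=2 groups")
    if len(fold_rates) < 2:
        raise UndefinedMetricError("Tukey comparison needs >=2 folds")
    data = fold_rates.to_numpy(dtype=float)
    if np.isnan(data).any():
        raise UndefinedMetricError("fold_rates contains undefined cells")
    k = len(groups)
    n = len(fold_rates)
    means = data.mean(axis=0)
    sse = ((data - means) ** 2).sum()
    df = k * (n - 1)
    mse = sse / df
    if mse == 0:
        warnings.warn("zero within-group variance; Tukey CIs have width 0")
        half = 0.0
    else:
        q_crit = stats.studentized_range.ppf(1 - alpha, k, df)
        half = q_crit * np.sqrt(mse / n)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(groups), 2):
        diff = means[i] - means[j]
        lo, hi = diff - half, diff + half
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def mannwhitney_disparity(scores_a, scores_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two score samples.

    U counts pairs where an a-sample score exceeds a b-sample score, ties
    counting one half.  Exact enumeration for small samples (both sizes
    <= 20, no ties), normal approximation with tie correction otherwise.
    Returns ``(U, two-sided p)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = a.size <= 20 and b.size <= 20
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# fold summaries


def summarize_folds(values, z: float = 1.96) -> dict:
    """Mean with normal-approximation confidence bounds over CV folds."""
    arr = np.asarray(list(values), dtype=float)
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    se = sd / np.sqrt(len(arr)) if len(arr) else float("nan")
    return {
        "mean": mean,
        "sd": sd,
        "ci_low": mean - z * se,
        "ci_high": mean + z * se,
        "n_folds": int(len(arr)),
    }
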