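"""Bias-mitigation techniques for group-fair binary risk prediction.

Three pre-processing methods act on training data before any model is
fitted:

* **Suppression (SUP)** deletes the protected attribute from the feature
  set — the baseline intervention, insufficient whenever proxy features
  carry group information.
* **Reweighing (RW)** assigns each sample the weight
  ``w(x, c) = P(C = c) / P(C = c | X = x)``, making protected attribute
  and outcome statistically independent in the weighted training set
  while leaving feature values untouched.
* **Disparate-impact removal (DIR)** maps every numeric/ordinal feature
  through its within-group quantile onto a common target distribution
  (the per-rank median of the group quantile functions), so that at full
  repair all groups share the same marginal distribution of every
  repaired feature.  A repair level ``lam`` in [0, 1] interpolates
  linearly between the original value (0) and the fully repaired one (1).

Two post-processing methods act on model outputs:

* **Calibrated equalized-odds post-processing (CPP)** equalizes the
  *generalized false-negative rate* g_x = E[1 - score | C = 1, X = x]
  across groups by replacing the scores of a randomly chosen fraction
  alpha of each lower-cost group's samples with that group's base rate
  (the trivial calibrated predictor); alpha solves the mixed-cost
  equality in closed form.
* **Population sensitivity-guided threshold adjustment (PSTA)** leaves
  scores alone and instead assigns *per-group decision thresholds*.
  Groups whose training sensitivity at the reference threshold t0
  (default 0.5) already reaches the overall population's sensitivity S*
  keep t0.  Each remaining (unprivileged) group receives the largest
  threshold t <= t0, searched over that group's observed positive scores,
  such that the group's training sensitivity reaches S* while its FPR
  stays within ``delta`` of the overall population's FPR F*; if no
  threshold satisfies both, the one maximizing sensitivity under the FPR
  cap is used, and if even t0 violates the cap the group is left
  untreated with a warning.  Lowering only unprivileged groups' thresholds
  raises their sensitivity toward the population's without touching the
  privileged groups — the equal-opportunity analogue of a clinician
  lowering the referral bar for an under-detected subpopulation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, partition_by_group
from .errors import UndefinedMetricError, UnsupportedFeatureError
from .metrics import ScoredPredictions

logger = logging.getLogger(__name__)

__all__ = [
    "SampleWeights",
    "RepairModel",
    "CPPMixPolicy",
    "ThresholdPolicy",
    "suppress",
    "reweigh",
    "dir_fit",
    "dir_apply",
    "cpp_fit",
    "cpp_apply",
    "psta_fit",
    "psta_apply",
]


# ---------------------------------------------------------------------------
# SUP


def suppress(cohort: Cohort, attributes: list[str] | str) -> Cohort:
    """Remove protected attributes from the model-visible data.

    The returned cohort keeps the attributes in its ``protected`` table for
    evaluation-time subgroup bookkeeping — suppression only guarantees the
    *model* never sees them.  Features named identically to a protected
    attribute are dropped too.  Idempotent.
    """
    if isinstance(attributes, str):
        attributes = [attributes]
    for a in attributes:
        if a not in cohort.protected.columns:
            raise KeyError(f"{a!r} is not a declared protected attribute")
    features = cohort.features.drop(columns=[a for a in attributes if a in cohort.features], errors="ignore")
    return Cohort(
        ids=cohort.ids,
        protected=cohort.protected,
        features=features,
        labels=cohort.labels,
    )


# ---------------------------------------------------------------------------
# RW


@dataclass
class SampleWeights:
    """Per-sample positive weights with (group, label)-cell provenance.

    Invariant: the weighted total equals the unweighted sample count, and
    in the weighted contingency table the protected attribute and the
    outcome are exactly independent.
    """

    attribute: str
    weights: np.ndarray
    cell_weights: dict[tuple[str, int], float]

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"weight": self.weights})
        if ids is not None:
            df.insert(0, "id", np.asarray(ids))
        return df


def reweigh(cohort: Cohort, attribute: str) -> SampleWeights:
    """Reweigh samples so the protected attribute and outcome decouple.

    Each sample in cell (group x, label c) receives
    ``w(x, c) = P(C = c) / P(C = c | X = x)`` — proportional to the label's
    frequency in the whole population and inversely proportional to its
    frequency within the subgroup.  When X and C are already empirically
    independent every weight is 1; in general the weighted prevalence is
    identical across groups and the weighted (X, C) table factorizes
    exactly.
    """
    part = partition_by_group(cohort, attribute)
    n = cohort.n
    labels = cohort.labels
    p_label = {c: (labels == c).mean() for c in (0, 1)}
    weights = np.empty(n, dtype=float)
    cell_weights: dict[tuple[str, int], float] = {}
    for cat, ix in part.groups.items():
        y = labels[ix]
        for c in (0, 1):
            mask = y == c
            if not mask.any():
                continue
            p_cond = mask.mean()
            w = p_label[c] / p_cond
            cell_weights[(cat, c)] = w
            weights[ix[mask]] = w
    return SampleWeights(attribute=attribute, weights=weights, cell_weights=cell_weights)


# ---------------------------------------------------------------------------
# DIR


@dataclass
class RepairModel:
    """Fitted quantile-repair transform for a set of numeric features.

    Stores, per feature and group, the sorted training values (the
    empirical quantile function).  The target distribution is, at each
    rank u, the median of the group quantile functions Q_x(u).  Repair
    level ``lam`` = 0 is the identity; 1 is full repair.
    """

    attribute: str
    features: list[str]
    lam: float
    group_values: dict[str, dict[str, np.ndarray]]  # feature -> group -> sorted values

    def target_quantile(self, feature: str, u: np.ndarray) -> np.ndarray:
        per_group = np.stack(
            [
                np.quantile(vals, u, method="linear")
                for vals in self.group_values[feature].values()
            ]
        )
        return np.median(per_group, axis=0)


def dir_fit(
    cohort: Cohort, attribute: str, features: list[str] | None = None, lam: float = 1.0
) -> RepairModel:
    """Fit the quantile-repair model on a (training) cohort.

    ``features`` defaults to all numeric feature columns; listing a
    non-numeric column raises :class:`UnsupportedFeatureError` (quantile
    repair is undefined for unordered categories).  Every group needs at
    least 2 observed values per repaired feature.
    """
    if not 0 <= lam <= 1:
        raise ValueError(f"repair level must be in [0, 1], got {lam}")
    part = partition_by_group(cohort, attribute)
    if features is None:
        features = [
            c for c in cohort.features.columns
            if pd.api.types.is_numeric_dtype(cohort.features[c])
        ]
    else:
        for f in features:
            if f not in cohort.features.columns:
                raise KeyError(f"unknown feature {f!r}")
            if not pd.api.types.is_numeric_dtype(cohort.features[f]):
                raise UnsupportedFeatureError(
                    f"feature {f!r} is not numeric/ordinal; quantile repair undefined"
                )
    group_values: dict[str, dict[str, np.ndarray]] = {}
    for f in features:
        col = cohort.features[f].to_numpy(dtype=float)
        per_group = {}
        for cat, ix in part.groups.items():
            vals = np.sort(col[ix])
            if len(vals) < 2:
                raise ValueError(
                    f"group {cat!r} has fewer than 2 values for feature {f!r}"
                )
            per_group[cat] = vals
        group_values[f] = per_group
    return RepairModel(attribute=attribute, features=list(features), lam=lam, group_values=group_values)


def _ecdf_mid(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Mid-distribution ECDF rank of x within sorted_vals, in (0, 1)."""
    left = np.searchsorted(sorted_vals, x, side="left")
    right = np.searchsorted(sorted_vals, x, side="right")
    n = len(sorted_vals)
    u = (left + right) / (2.0 * n)
    return np.clip(u, 0.5 / n, 1 - 0.5 / n)


def dir_apply(model: RepairModel, cohort: Cohort) -> Cohort:
    """Apply a fitted repair model: each value v of sample in group x maps
    to ``(1 - lam) * v + lam * Q_target(F_x(v))``.

    The protected attribute used for repair is excluded from the output
    feature set (its repaired proxies no longer carry its signal; keeping
    the attribute itself would defeat the repair).  Group membership for
    new samples comes from the cohort's protected table; ranks and target
    quantiles are those *fitted* on the training cohort, so no test-time
    information leaks into the transform.
    """
    part = partition_by_group(cohort, model.attribute)
    features = cohort.features.copy()
    for f in model.features:
        col = features[f].to_numpy(dtype=float).copy()
        out = col.copy()
        for cat, ix in part.groups.items():
            if cat not in model.group_values[f]:
                warnings.warn(
                    f"group {cat!r} unseen at fit time; feature {f!r} left unrepaired"
                )
                continue
            u = _ecdf_mid(model.group_values[f][cat], col[ix])
            out[ix] = (1 - model.lam) * col[ix] + model.lam * model.target_quantile(f, u)
        features[f] = out
    features = features.drop(columns=[model.attribute], errors="ignore")
    return Cohort(
        ids=cohort.ids,
        protected=cohort.protected,
        features=features,
        labels=cohort.labels,
    )


# ---------------------------------------------------------------------------
# CPP


@dataclass
class CPPMixPolicy:
    """Per-group randomized mixing policy equalizing generalized FNRs.

    For each group: with probability ``alpha`` a sample's score is replaced
    by the group's base rate (the trivial calibrated predictor); alpha = 0
    is pass-through.  ``costs`` records the fitted generalized FNRs.
    """

    alphas: dict[str, float]
    base_rates: dict[str, float]
    costs: dict[str, float]
    cost: str = "fnr"
    seed: int = 0
    threshold: float = 0.5

    def to_json(self) -> str:
        return json.dumps(
            {
                "cost": self.cost,
                "seed": self.seed,
                "threshold": self.threshold,
                "groups": {
                    g: {
                        "alpha": self.alphas[g],
                        "base_rate": self.base_rates[g],
                        "cost": self.costs[g],
                    }
                    for g in sorted(self.alphas)
                },
            },
            sort_keys=True,
        )


def cpp_fit(pred: ScoredPredictions, cost: str = "fnr", seed: int = 0) -> CPPMixPolicy:
    """Fit the calibrated mixing policy on (training) scores.

    The generalized FNR of group x is g_x = mean(1 - score | C = 1, X = x).
    The group with the largest cost is left untouched; every other group
    mixes toward its trivial predictor with
    ``alpha = (g_max - g_x) / (g_trivial_x - g_x)`` where
    ``g_trivial_x = 1 - base_rate_x``, which makes the expected mixed
    costs equal.  Scores are assumed calibrated probabilities.
    """
    if cost != "fnr":
        raise ValueError("only the false-negative-rate cost is supported")
    groups = sorted(pd.unique(pred.group))
    costs, base_rates = {}, {}
    for g in groups:
        mask = pred.group == g
        y = pred.labels[mask]
        if not (y == 1).any():
            raise UndefinedMetricError(
                f"group {g!r} has no positives; generalized FNR undefined"
            )
        base_rates[g] = float(y.mean())
        costs[g] = float((1 - pred.scores[mask][y == 1]).mean())
    g_max = max(costs.values())
    alphas = {}
    for g in groups:
        if costs[g] >= g_max:
            alphas[g] = 0.0
            continue
        g_triv = 1.0 - base_rates[g]
        denom = g_triv - costs[g]
        if denom <= 0:
            warnings.warn(
                f"group {g!r}: trivial predictor cannot raise cost "
                f"(g_trivial={g_triv:.4f} <= g={costs[g]:.4f}); alpha set to 0"
            )
            alphas[g] = 0.0
            continue
        alphas[g] = float(np.clip((g_max - costs[g]) / denom, 0.0, 1.0))
    return CPPMixPolicy(alphas=alphas, base_rates=base_rates, costs=costs, cost=cost, seed=seed)


def cpp_apply(policy: CPPMixPolicy, pred: ScoredPredictions) -> ScoredPredictions:
    """Apply the mixing policy: in each group, a seeded random fraction
    alpha of samples (stratified by label, to keep the Monte-Carlo noise
    of the positive-class cost small) gets its score replaced by the group
    base rate.  Hard predictions are re-thresholded at ``policy.threshold``.
    """
    rng = np.random.default_rng(policy.seed)
    scores = pred.scores.copy()
    for g in sorted(policy.alphas):
        alpha = policy.alphas[g]
        if alpha == 0:
            continue
        mask = pred.group == g
        for c in (1, 0):
            ix = np.flatnonzero(mask & (pred.labels == c))
            k = int(round(alpha * len(ix)))
            if k:
                chosen = rng.choice(ix, size=k, replace=False)
                scores[chosen] = policy.base_rates[g]
    unseen = set(pd.unique(pred.group)) - set(policy.alphas)
    if unseen:
        warnings.warn(f"groups unseen at fit time passed through: {sorted(unseen)}")
    return ScoredPredictions.from_scores(
        scores=scores, labels=pred.labels, group=pred.group, threshold=policy.threshold
    )


# ---------------------------------------------------------------------------
# PSTA


@dataclass
class ThresholdPolicy:
    """Per-group decision thresholds with the fit-time population anchors.

    Untreated groups carry exactly the reference threshold ``t0``;
    ``overall_sensitivity`` and ``overall_fpr`` are the training-set rates
    at t0 the adjustment was anchored to; ``delta`` is the FPR margin.
    """

    thresholds: dict[str, float]
    t0: float = 0.5
    overall_sensitivity: float = float("nan")
    overall_fpr: float = float("nan")
    delta: float = 0.10
    warnings_: list[str] = field(default_factory=list)

    def threshold_for(self, group: str) -> float:
        return self.thresholds.get(group, self.t0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "t0": self.t0,
                "delta": self.delta,
                "overall_sensitivity": self.overall_sensitivity,
                "overall_fpr": self.overall_fpr,
                "thresholds": {g: self.thresholds[g] for g in sorted(self.thresholds)},
            },
            sort_keys=True,
        )


def psta_fit(
    train: ScoredPredictions, t0: float = 0.5, delta: float = 0.10
) -> ThresholdPolicy:
    """Population sensitivity-guided threshold adjustment.

    Anchors: overall training sensitivity S* and FPR F* at the reference
    threshold t0.  Groups already at or above S* keep t0 (privileged in the
    equal-opportunity sense).  Each unprivileged group gets the largest
    threshold t <= t0 among its observed positive scores (plus t0) with
    group sensitivity(t) >= S* and group FPR(t) <= F* + delta; with no
    fully qualifying threshold, the candidate maximizing sensitivity under
    the FPR cap; if even t0 breaks the cap the group keeps t0 with a
    warning.  Groups with no positives are left untreated with a warning.
    Invariant to sample order.
    """
    if train.n == 0:
        raise ValueError("empty training predictions")
    y, s = train.labels, train.scores
    if not (y == 1).any():
        raise UndefinedMetricError("no positive training samples")
    s_star = float((s[y == 1] >= t0).mean())
    f_star = float((s[y == 0] >= t0).mean()) if (y == 0).any() else 0.0

    thresholds: dict[str, float] = {}
    notes: list[str] = []
    for g in sorted(pd.unique(train.group)):
        mask = train.group == g
        pos = s[mask & (y == 1)]
        neg = s[mask & (y == 0)]
        if len(pos) == 0:
            msg = f"group {g!r} has no positive training samples; left at t0"
            warnings.warn(msg)
            notes.append(msg)
            thresholds[g] = t0
            continue

        def sens(t):
            return (pos >= t).mean()

        def fpr(t):
            return (neg >= t).mean() if len(neg) else 0.0

        if sens(t0) >= s_star:
            thresholds[g] = t0
            continue
        candidates = np.unique(pos[(pos <= t0) & (pos > 0)])
        candidates = np.append(candidates, t0)
        feasible = [
            t for t in candidates if sens(t) >= s_star and fpr(t) <= f_star + delta
        ]
        if feasible:
            thresholds[g] = float(max(feasible))
            continue
        capped = [t for t in candidates if fpr(t) <= f_star + delta]
        if capped:
            # maximize sensitivity under the FPR cap; prefer the larger
            # threshold on ties (less FPR inflation)
            best = max(capped, key=lambda t: (sens(t), t))
            thresholds[g] = float(best)
        else:
            msg = (
                f"group {g!r}: FPR cap F* + delta = {f_star + delta:.4f} "
                f"unsatisfiable even at t0; left at t0"
            )
            warnings.warn(msg)
            notes.append(msg)
            thresholds[g] = t0
    return ThresholdPolicy(
        thresholds=thresholds,
        t0=t0,
        overall_sensitivity=s_star,
        overall_fpr=f_star,
        delta=delta,
        warnings_=notes,
    )


def psta_apply(policy: ThresholdPolicy, pred: ScoredPredictions) -> ScoredPredictions:
    """Threshold predictions group-wise: C-hat = 1 iff score >= t(group).

    Scores are unchanged.  Groups absent from the policy fall back to t0
    with a warning.
    """
    predictions = np.zeros(pred.n, dtype=np.int8)
    for g in pd.unique(pred.group):
        if g not in policy.thresholds:
            warnings.warn(f"group {g!r} unseen at fit time; using t0={policy.t0}")
        t = policy.threshold_for(g)
        mask = pred.group == g
        predictions[mask] = (pred.scores[mask] >= t).astype(np.int8)
    return ScoredPredictions(
        scores=pred.scores.copy(),
        predictions=predictions,
        labels=pred.labels,
        group=pred.group,
    )
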