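"""Cross-validated scenario runner: base vs. mitigated models.

A *scenario* is one cell of the audit grid — a (model kind, cohort,
protected attribute, mitigation) combination.  The runner reproduces the
standard audit protocol: stratified k-fold cross-validation in which
pre-processing transforms (suppression, reweighing, quantile repair) are
fitted on and applied to the training folds only, post-processing
policies (score mixing, per-group thresholds) are fitted on training-fold
model outputs only, and every performance/fairness metric is measured on
the held-out fold.  Hyperparameter tuning, when requested, runs in an
inner (nested) cross-validation loop on the training folds.

The mitigation effect is the before/after difference in fairness metrics;
methods are compared scenario-wise by the fairness-accuracy score Delta,
and :func:`spillover_analysis` quantifies the side effect of treating one
protected attribute on the fairness of the untreated ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .cohort import Cohort
from .errors import ScenarioError, UndefinedMetricError
from .metrics import (
    FairnessReport,
    ScoredPredictions,
    delta_score,
    summarize_folds,
)
from .mitigation import (
    cpp_apply,
    cpp_fit,
    dir_apply,
    dir_fit,
    psta_apply,
    psta_fit,
    reweigh,
    suppress,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "ScenarioSpec",
    "ScenarioResult",
    "train_model",
    "run_scenario",
    "compare_methods",
    "spillover_analysis",
    "DEFAULT_GRIDS",
]

MITIGATIONS = ("none", "sup", "rw", "dir", "cpp", "psta")
MODELS = ("logistic", "xgboost")

# deliberately small default grids; override via ScenarioSpec.param_grid
DEFAULT_GRIDS = {
    "logistic": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "xgboost": {"clf__max_depth": [2, 3, 4], "clf__learning_rate": [0.05, 0.1, 0.3]},
}


@dataclass
class CVScheme:
    """Outer/inner cross-validation layout.  ``inner_k`` only matters when
    a scenario requests hyperparameter tuning."""

    k: int = 10
    inner_k: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("outer fold count k must be >= 2")


@dataclass
class ScenarioSpec:
    """One audit cell: model kind, mitigation, treated attribute, CV plan.

    ``eval_attributes`` lists the protected attributes to report fairness
    on (defaults to the treated attribute; add untreated ones to enable
    spillover analysis).  ``tune`` switches on nested-CV hyperparameter
    search over ``param_grid`` (or the small built-in default grid).
    ``options`` forwards mitigation hyperparameters: ``lam`` (DIR repair
    level), ``t0`` and ``delta`` (PSTA), ``threshold``.
    """

    model: str = "logistic"
    mitigation: str = "none"
    attribute: str = "sex"
    eval_attributes: list[str] = field(default_factory=list)
    cv: CVScheme = field(default_factory=CVScheme)
    beta: float = 0.5
    threshold: float = 0.5
    tune: bool = False
    param_grid: dict | None = None
    options: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.mitigation not in MITIGATIONS:
            raise ValueError(
                f"mitigation must be one of {MITIGATIONS}, got {self.mitigation!r}"
            )
        if not self.eval_attributes:
            self.eval_attributes = [self.attribute]
        elif self.attribute not in self.eval_attributes:
            self.eval_attributes = [self.attribute, *self.eval_attributes]
        known = {"lam", "t0", "delta", "cost"}
        unknown = set(self.options) - known
        if unknown:
            raise ValueError(f"unknown mitigation options: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ScenarioResult:
    """Per-fold fairness reports plus pooled summaries and provenance."""

    spec: dict
    spec_hash: str
    fold_reports: list[dict]  # fold -> {attribute -> report dict}
    policies: list[dict | None]
    summary: dict  # attribute -> metric -> {mean, sd, ci_low, ci_high}
    n_folds_run: int
    n_folds_skipped: int

    def fold_values(self, attribute: str, metric: str) -> np.ndarray:
        return np.array(
            [r[attribute][metric] for r in self.fold_reports if attribute in r]
        )

    def mean(self, attribute: str, metric: str) -> float:
        return self.summary[attribute][metric]["mean"]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "spec": self.spec,
                "spec_hash": self.spec_hash,
                "fold_reports": self.fold_reports,
                "policies": self.policies,
                "summary": self.summary,
                "n_folds_run": self.n_folds_run,
                "n_folds_skipped": self.n_folds_skipped,
            },
            sort_keys=True,
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioResult":
        d = json.loads(text)
        return cls(
            spec=d["spec"],
            spec_hash=d["spec_hash"],
            fold_reports=d["fold_reports"],
            policies=d["policies"],
            summary=d["summary"],
            n_folds_run=d["n_folds_run"],
            n_folds_skipped=d["n_folds_skipped"],
        )


# ---------------------------------------------------------------------------
# model fitting


def _make_estimator(kind: str, seed: int):
    if kind == "logistic":
        clf = LogisticRegression(max_iter=2000)
    else:
        clf = XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            tree_method="hist",
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_model(
    kind: str,
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    seed: int = 0,
    tune: bool = False,
    param_grid: dict | None = None,
    inner_k: int = 3,
):
    """Fit a probability scorer (standardized logistic regression or
    gradient-boosted trees), optionally with per-sample weights and
    nested-CV hyperparameter tuning.  Deterministic given the seed."""
    if kind not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {kind!r}")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ScenarioError("training labels contain a single class")
    est = _make_estimator(kind, seed)
    fit_params = {}
    if weights is not None:
        fit_params["clf__sample_weight"] = np.asarray(weights, dtype=float)
    if tune:
        grid = param_grid if param_grid is not None else DEFAULT_GRIDS[kind]
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, cv=inner, scoring="roc_auc", n_jobs=1)
        search.fit(features, labels, **fit_params)
        return search.best_estimator_
    est.fit(features, labels, **fit_params)
    return est


# ---------------------------------------------------------------------------
# design matrices


def design_matrix(cohort: Cohort, include_protected: list[str]) -> pd.DataFrame:
    """Numeric design matrix: one-hot encodes categorical features and the
    listed protected attributes (encoding is label-free, so building it on
    the full cohort leaks nothing)."""
    parts = [pd.get_dummies(cohort.features, drop_first=True, dtype=float)]
    if include_protected:
        parts.append(
            pd.get_dummies(
                cohort.protected[include_protected], drop_first=True, dtype=float
            )
        )
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# scenario runner


def run_scenario(spec: ScenarioSpec, cohort: Cohort) -> ScenarioResult:
    """Run one cross-validated audit scenario.

    Pre-processing mitigations transform the training folds only; CPP and
    PSTA policies are refit per outer fold on that fold's training scores.
    Folds where a metric is undefined (e.g. a subgroup without positives
    in the held-out fold) are skipped with a warning; the scenario errors
    out if more than half the folds are lost.
    """
    if spec.attribute not in cohort.protected.columns:
        raise KeyError(f"attribute {spec.attribute!r} not in cohort")
    for a in spec.eval_attributes:
        if a not in cohort.protected.columns:
            raise KeyError(f"evaluation attribute {a!r} not in cohort")

    y = cohort.labels
    memberships = {
        a: cohort.protected[a].to_numpy(dtype=object) for a in spec.eval_attributes
    }
    treated_membership = cohort.protected[spec.attribute].to_numpy(dtype=object)

    splitter = StratifiedKFold(
        n_splits=spec.cv.k, shuffle=True, random_state=spec.cv.seed
    )
    split_iter = splitter.split(np.zeros(cohort.n), y if spec.cv.stratified else np.zeros(cohort.n))

    lam = float(spec.options.get("lam", 1.0))
    t0 = float(spec.options.get("t0", spec.threshold))
    delta = float(spec.options.get("delta", 0.10))

    fold_reports: list[dict] = []
    policies: list[dict | None] = []
    n_skipped = 0

    for fold_i, (tr, te) in enumerate(split_iter):
        fold_seed = spec.seed * 10007 + fold_i
        try:
            report, policy = _run_fold(
                spec, cohort, tr, te, y, memberships, treated_membership,
                lam=lam, t0=t0, delta=delta, fold_seed=fold_seed,
            )
        except (UndefinedMetricError, ScenarioError) as exc:
            warnings.warn(f"fold {fold_i} skipped: {exc}")
            n_skipped += 1
            continue
        fold_reports.append(report)
        policies.append(policy)

    if n_skipped > spec.cv.k / 2:
        raise ScenarioError(
            f"{n_skipped}/{spec.cv.k} folds skipped; scenario not evaluable"
        )

    summary = {}
    for a in spec.eval_attributes:
        summary[a] = {}
        for metric in ("bacc", "auc", "eod", "aod", "delta"):
            vals = [r[a][metric] for r in fold_reports if a in r]
            summary[a][metric] = summarize_folds(vals)
    return ScenarioResult(
        spec=spec.to_dict(),
        spec_hash=spec.spec_hash(),
        fold_reports=fold_reports,
        policies=policies,
        summary=summary,
        n_folds_run=len(fold_reports),
        n_folds_skipped=n_skipped,
    )


def _run_fold(
    spec: ScenarioSpec,
    cohort: Cohort,
    tr: np.ndarray,
    te: np.ndarray,
    y: np.ndarray,
    memberships: dict[str, np.ndarray],
    treated_membership: np.ndarray,
    *,
    lam: float,
    t0: float,
    delta: float,
    fold_seed: int,
) -> tuple[dict, dict | None]:
    if len(np.unique(y[tr])) < 2:
        raise ScenarioError("training fold has a single class")

    protected_cols = cohort.protected_attributes
    weights = None
    policy_json: dict | None = None

    if spec.mitigation == "sup":
        work = suppress(cohort, spec.attribute)
        include = [a for a in protected_cols if a != spec.attribute]
        X_full = design_matrix(work, include)
        X_tr, X_te = X_full.iloc[tr], X_full.iloc[te]
    elif spec.mitigation == "dir":
        train_cohort = cohort.subset(tr)
        repair = dir_fit(train_cohort, spec.attribute, lam=lam)
        include = [a for a in protected_cols if a != spec.attribute]
        repaired_tr = dir_apply(repair, train_cohort)
        repaired_te = dir_apply(repair, cohort.subset(te))
        X_tr = design_matrix(repaired_tr, include)
        X_te = design_matrix(repaired_te, include)
        X_te = X_te.reindex(columns=X_tr.columns, fill_value=0.0)
    else:
        X_full = design_matrix(cohort, protected_cols)
        X_tr, X_te = X_full.iloc[tr], X_full.iloc[te]
        if spec.mitigation == "rw":
            weights = reweigh(cohort.subset(tr), spec.attribute).weights

    model = train_model(
        spec.model,
        X_tr,
        y[tr],
        weights=weights,
        seed=fold_seed,
        tune=spec.tune,
        param_grid=spec.param_grid,
        inner_k=spec.cv.inner_k,
    )
    scores_tr = model.predict_proba(X_tr)[:, 1]
    scores_te = model.predict_proba(X_te)[:, 1]

    test_pred = ScoredPredictions.from_scores(
        scores_te, y[te], treated_membership[te], threshold=spec.threshold
    )
    if spec.mitigation in ("cpp", "psta"):
        train_pred = ScoredPredictions.from_scores(
            scores_tr, y[tr], treated_membership[tr], threshold=spec.threshold
        )
        if spec.mitigation == "cpp":
            pol = cpp_fit(train_pred, cost=spec.options.get("cost", "fnr"), seed=fold_seed)
            test_pred = cpp_apply(pol, test_pred)
            policy_json = {"kind": "cpp", "policy": json.loads(pol.to_json())}
        else:
            pol = psta_fit(train_pred, t0=t0, delta=delta)
            test_pred = psta_apply(pol, test_pred)
            policy_json = {"kind": "psta", "policy": json.loads(pol.to_json())}

    report: dict = {}
    for a, member in memberships.items():
        pred_a = ScoredPredictions(
            scores=test_pred.scores,
            predictions=test_pred.predictions,
            labels=test_pred.labels,
            group=member[te],
        )
        rep = FairnessReport.from_predictions(pred_a, beta=spec.beta)
        report[a] = rep.to_dict()
    return report, policy_json


# ---------------------------------------------------------------------------
# method comparison and spillover


def compare_methods(
    results: dict[str, dict[str, ScenarioResult]], beta: float = 0.5
) -> tuple[pd.DataFrame, dict]:
    """Scenario-wise Delta comparison across mitigation methods.

    ``results`` maps scenario name -> method name -> ScenarioResult.
    Delta is computed from each scenario's fold-mean BAcc and fold-mean
    EOD on the treated attribute.  Winner = argmax Delta; exact ties are
    counted for every tied method and flagged.  Returns the per-scenario
    table and a tally with win counts and percentages.
    """
    rows = []
    wins: dict[str, float] = {}
    for scenario, methods in results.items():
        deltas = {}
        for method, res in methods.items():
            attr = res.spec["attribute"]
            bacc = res.mean(attr, "bacc")
            e = res.mean(attr, "eod")
            deltas[method] = delta_score(bacc, e, beta=beta)
        best = max(deltas.values())
        winners = sorted(m for m, d in deltas.items() if d == best)
        tie = len(winners) > 1
        if tie:
            logger.warning("scenario %s: Delta tie among %s", scenario, winners)
        for m in winners:
            wins[m] = wins.get(m, 0) + 1
        for method, d in deltas.items():
            rows.append(
                {
                    "scenario": scenario,
                    "method": method,
                    "delta": d,
                    "winner": method in winners,
                    "tie": tie and method in winners,
                }
            )
    n_scen = len(results)
    tally = {
        "wins": dict(sorted(wins.items())),
        "win_pct": {m: 100.0 * w / n_scen for m, w in sorted(wins.items())},
        "n_scenarios": n_scen,
    }
    return pd.DataFrame(rows), tally


def spillover_analysis(
    base: ScenarioResult, mitigated: ScenarioResult, attributes: list[str]
) -> pd.DataFrame:
    """Fairness change on untreated attributes: |EOD| and |AOD| deltas
    (mitigated - base); positive means fairness worsened."""
    rows = []
    for a in attributes:
        for res, name in ((base, "base"), (mitigated, "mitigated")):
            if a not in res.summary:
                raise KeyError(
                    f"attribute {a!r} was not evaluated in the {name} scenario"
                )
        rows.append(
            {
                "attribute": a,
                "abs_eod_change": abs(mitigated.mean(a, "eod")) - abs(base.mean(a, "eod")),
                "abs_aod_change": abs(mitigated.mean(a, "aod")) - abs(base.mean(a, "aod")),
            }
        )
    return pd.DataFrame(rows)
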