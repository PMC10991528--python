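"""Synthetic cohort and scored-population generators.

Real depression cohorts suitable for fairness audits are restricted or
very large, so the package ships a generator that reproduces the
*statistical structure* those audits rely on:

* group-dependent outcome prevalence (epidemiology consistently reports
  roughly twice the depression prevalence in women as in men, so the
  default sex prevalence ratio is 2:1);
* skewed subgroup sizes and class imbalance anywhere from a few percent
  up to ~40%;
* proxy features — descriptive variables whose distribution shifts with
  the protected attribute, so that merely deleting the attribute does not
  remove group information from the model's inputs.

The outcome model is logistic in the numeric features plus a per-group
intercept.  The intercept for each group is solved numerically (Brent's
method on the group's sampled feature set) so that the *marginal*
prevalence of each group matches its configured target; feature effect
sizes are fixed, illustrative defaults giving a discriminative but
imperfect model, typical of questionnaire-based risk scores.

:func:`generate_scored_population` produces labelled, group-tagged score
sets directly — the fixture of choice for post-processing methods, which
act on model outputs and never see features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort
from .errors import ConfigError
from .metrics import ScoredPredictions

__all__ = [
    "SyntheticConfig",
    "GroupScoreSpec",
    "ScoreSetConfig",
    "generate_cohort",
    "generate_scored_population",
]


@dataclass
class SyntheticConfig:
    """Configuration for :func:`generate_cohort`.

    Parameters
    ----------
    n : total sample count.
    group_spec : per protected attribute, mapping category -> mixture
        proportion.  Proportions must sum to 1.  The attribute whose
        category set matches the ``prevalence`` keys is the *driver*: it
        determines outcome prevalence and proxy shifts.
    prevalence : mapping driver category -> outcome probability in (0, 1).
    n_features : number of informative numeric features (all enter the
        outcome model).
    n_proxy : how many of the informative features are proxies, i.e. have
        group-shifted means.
    proxy_strength : scale of the proxy mean shift (0 = no group signal in
        features).
    noise_sd : standard deviation of the feature noise.
    coef_scale : common effect size of the informative features on the
        log-odds of the outcome.
    alignment : optional mapping ``attribute -> (driver_attribute, p)``:
        the attribute copies the driver's category index with probability
        ``p`` and otherwise draws from the *other* categories (requires
        equal category counts).  For binary attributes p = 1 duplicates
        the driver, p = 0.5 is independence, p = 0 anti-aligns; used to
        study spillover onto correlated untreated attributes.
    seed : fully determines the output.
    """

    n: int = 20000
    group_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"sex": {"female": 0.5, "male": 0.5}}
    )
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"female": 0.08, "male": 0.04}
    )
    n_features: int = 6
    n_proxy: int = 2
    proxy_strength: float = 0.5
    noise_sd: float = 1.0
    coef_scale: float = 0.8
    alignment: dict[str, tuple[str, float]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        if not self.group_spec:
            raise ConfigError("group_spec must declare at least one attribute")
        for attr, cats in self.group_spec.items():
            total = sum(cats.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"proportions for {attr!r} sum to {total}, not 1")
            for cat, p in cats.items():
                if not 0 < p < 1 and len(cats) > 1:
                    raise ConfigError(
                        f"degenerate proportion {p} for {attr}={cat}"
                    )
        driver = self.driver_attribute
        for cat in self.group_spec[driver]:
            if cat not in self.prevalence:
                raise ConfigError(f"prevalence missing for {driver}={cat!r}")
        for cat, p in self.prevalence.items():
            if not 0 < p < 1:
                raise ConfigError(f"prevalence must be in (0,1), got {cat}={p}")
        if not 0 <= self.n_proxy <= self.n_features:
            raise ConfigError("n_proxy must be between 0 and n_features")

    @property
    def driver_attribute(self) -> str:
        """The attribute whose categories key the prevalence mapping;
        falls back to the first declared attribute."""
        prev_keys = set(self.prevalence)
        for attr, cats in self.group_spec.items():
            if prev_keys == set(cats):
                return attr
        return next(iter(self.group_spec))


def _sample_attribute(rng, categories: list[str], probs: list[float], n: int) -> np.ndarray:
    return rng.choice(np.array(categories, dtype=object), size=n, p=probs)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort with configured group mixture, proxy structure and
    group-specific outcome prevalence.

    Empirical group prevalences converge to the configured targets as
    n grows (the per-group intercept is calibrated on the realized feature
    sample).  The same config (including seed) always yields the same
    cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # protected attributes; categories in sorted order for reproducibility
    driver = config.driver_attribute
    protected = {}
    driver_idx = None
    for attr, cats in config.group_spec.items():
        names = sorted(cats)
        probs = [cats[c] for c in names]
        if config.alignment and attr in config.alignment:
            src, p_match = config.alignment[attr]
            src_vals = protected[src]
            src_names = sorted(config.group_spec[src])
            if len(src_names) != len(names):
                raise ConfigError(
                    f"alignment of {attr!r} with {src!r} needs equal category counts"
                )
            src_index = pd.Categorical(src_vals, categories=src_names).codes
            match = rng.random(n) < p_match
            # non-matching draws come from the *other* categories, so small
            # p_match yields genuinely negative association
            offset = rng.integers(1, len(names), size=n)
            other_idx = (src_index + offset) % len(names)
            idx = np.where(match, src_index, other_idx)
            protected[attr] = np.array(names, dtype=object)[idx]
        else:
            protected[attr] = _sample_attribute(rng, names, probs, n)
    driver_names = sorted(config.group_spec[driver])
    driver_idx = pd.Categorical(protected[driver], categories=driver_names).codes

    # features: standard-normal noise; the first n_proxy get group-shifted
    # means.  Shifts are ordered by configured prevalence so that proxies
    # carry the same directional signal as the outcome gap — the structure
    # that makes a deleted attribute recoverable from its proxies.
    feats = rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    if len(driver_names) > 1:
        by_prev = sorted(driver_names, key=lambda c: (config.prevalence[c], c))
        rank = {c: i for i, c in enumerate(by_prev)}
        spread = np.linspace(-1.0, 1.0, len(driver_names))
        codes = np.array([spread[rank[c]] for c in driver_names])
    else:
        codes = np.zeros(1)
    shift = config.proxy_strength * codes[driver_idx]
    feats[:, : config.n_proxy] += shift[:, None]

    # outcome: logistic in features with a per-group intercept calibrated to
    # hit the target marginal prevalence of each driver group
    coefs = np.full(config.n_features, config.coef_scale)
    lp = feats @ coefs
    labels = np.zeros(n, dtype=np.int8)
    for g, name in enumerate(driver_names):
        mask = driver_idx == g
        target = config.prevalence[name]
        lp_g = lp[mask]

        def gap(b, lp_g=lp_g, target=target):
            return expit(b + lp_g).mean() - target

        b = brentq(gap, -40.0, 40.0, xtol=1e-10)
        labels[mask] = (rng.random(mask.sum()) < expit(b + lp_g)).astype(np.int8)

    features = pd.DataFrame(
        feats, columns=[f"feat_{j}" for j in range(config.n_features)]
    )
    ids = pd.Index([f"S{i:06d}" for i in range(n)])
    return Cohort(
        ids=ids,
        protected=pd.DataFrame(protected),
        features=features,
        labels=labels,
    )


@dataclass
class GroupScoreSpec:
    """Score law of one subgroup: sizes and location/scale of the
    (clipped-to-[0,1] Gaussian) score distributions of positives and
    negatives."""

    n_pos: int
    n_neg: int
    pos_loc: float = 0.65
    pos_scale: float = 0.15
    neg_loc: float = 0.35
    neg_scale: float = 0.15


@dataclass
class ScoreSetConfig:
    """Configuration for :func:`generate_scored_population`: one
    :class:`GroupScoreSpec` per group, plus a seed."""

    groups: dict[str, GroupScoreSpec]
    seed: int = 0
    threshold: float = 0.5

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group required")
        for name, g in self.groups.items():
            if g.n_pos < 0 or g.n_neg < 0 or g.n_pos + g.n_neg == 0:
                raise ConfigError(f"group {name!r} has invalid sizes")
            for s in (g.pos_scale, g.neg_scale):
                if s <= 0:
                    raise ConfigError(f"group {name!r} has non-positive scale")


_EPS = 1e-6


def generate_scored_population(config: ScoreSetConfig) -> ScoredPredictions:
    """Draw a labelled, group-tagged score set with per-group score laws.

    Scores are Gaussian in location/scale, clipped into (0, 1); hard
    predictions are taken at ``config.threshold``.  Seed-deterministic.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scores, labels, group = [], [], []
    for name in sorted(config.groups):
        g = config.groups[name]
        s_pos = rng.normal(g.pos_loc, g.pos_scale, size=g.n_pos)
        s_neg = rng.normal(g.neg_loc, g.neg_scale, size=g.n_neg)
        s = np.clip(np.concatenate([s_pos, s_neg]), _EPS, 1 - _EPS)
        scores.append(s)
        labels.append(np.concatenate([np.ones(g.n_pos), np.zeros(g.n_neg)]))
        group.append(np.full(g.n_pos + g.n_neg, name, dtype=object))
    return ScoredPredictions.from_scores(
        scores=np.concatenate(scores),
        labels=np.concatenate(labels),
        group=np.concatenate(group),
        threshold=config.threshold,
    )
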