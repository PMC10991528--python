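"""Tabular cohort data model and I/O.

A cohort is the triple (X, Y, C): categorical protected attributes X,
descriptive features Y, and a binary outcome C (1 = condition present,
the positive class).  Protected attributes define population subgroups;
missing protected values are kept as an explicit ``"Missing"`` category
rather than imputed or dropped, because the smallest, least-observed
subgroups are precisely the ones a fairness audit must not lose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

MISSING_CATEGORY = "Missing"

__all__ = [
    "Cohort",
    "GroupPartition",
    "load_cohort",
    "write_cohort",
    "load_schema",
    "phq9_binarize",
    "partition_by_group",
    "MISSING_CATEGORY",
]


@dataclass
class Cohort:
    """One row per participant: identifiers, protected attributes X,
    descriptive features Y, binary outcome C.

    Invariants enforced at construction: equal row counts and order across
    tables; labels strictly 0/1; every protected column has at least one
    non-missing category.  Missing protected values are recoded to the
    explicit category :data:`MISSING_CATEGORY`.
    """

    ids: pd.Index
    protected: pd.DataFrame
    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.ids = pd.Index(self.ids)
        self.labels = np.asarray(self.labels)
        n = len(self.ids)
        if len(self.protected) != n or len(self.features) != n or len(self.labels) != n:
            raise CohortValidationError(
                f"row-count mismatch: ids={n}, protected={len(self.protected)}, "
                f"features={len(self.features)}, labels={len(self.labels)}"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise CohortValidationError(f"labels must be 0/1, found {sorted(bad)}")
        self.labels = self.labels.astype(np.int8)
        self.protected = self.protected.reset_index(drop=True).copy()
        self.features = self.features.reset_index(drop=True)
        for col in self.protected.columns:
            vals = self.protected[col]
            recoded = vals.astype(object).where(vals.notna(), MISSING_CATEGORY).astype(str)
            if (recoded == MISSING_CATEGORY).all():
                raise CohortValidationError(
                    f"protected column {col!r} has no non-missing category"
                )
            self.protected[col] = recoded

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def protected_attributes(self) -> list[str]:
        return list(self.protected.columns)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def copy(self) -> "Cohort":
        return Cohort(
            ids=self.ids.copy(),
            protected=self.protected.copy(),
            features=self.features.copy(),
            labels=self.labels.copy(),
        )

    def subset(self, index: np.ndarray) -> "Cohort":
        """Row subset (positional indices), preserving order of ``index``."""
        return Cohort(
            ids=self.ids[index],
            protected=self.protected.iloc[index],
            features=self.features.iloc[index],
            labels=self.labels[index],
        )

    def to_frame(self, id_column: str = "id", label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame({id_column: self.ids})
        df = pd.concat(
            [df, self.protected.reset_index(drop=True), self.features.reset_index(drop=True)],
            axis=1,
        )
        df[label_column] = self.labels
        return df


@dataclass
class GroupPartition:
    """Partition of cohort rows by one protected attribute.

    ``groups`` maps each category to the (sorted) positional row indices of
    its members; ``categories`` fixes a deterministic lexicographic order.
    The index sets are disjoint and jointly cover all rows.
    """

    attribute: str
    groups: dict[str, np.ndarray]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = sorted(self.groups)
        sizes = sum(len(ix) for ix in self.groups.values())
        all_ix = np.concatenate([ix for ix in self.groups.values()]) if self.groups else np.array([])
        if len(np.unique(all_ix)) != sizes:
            raise CohortValidationError("partition index sets overlap")

    @property
    def n(self) -> int:
        return sum(len(ix) for ix in self.groups.values())

    def sizes(self) -> dict[str, int]:
        return {cat: len(self.groups[cat]) for cat in self.categories}

    def membership(self) -> np.ndarray:
        """Per-row category labels, aligned with cohort row order."""
        out = np.empty(self.n, dtype=object)
        for cat, ix in self.groups.items():
            out[ix] = cat
        return out


def load_schema(path) -> dict:
    """Read a YAML/JSON column-role schema: keys ``id``, ``label``,
    ``protected`` (list), ``features`` (list)."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    for key in ("label", "protected", "features"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    return schema


def load_cohort(path, schema: dict) -> Cohort:
    """Load a cohort from CSV given a column-role schema.

    ``schema`` maps roles to column names: ``label`` (str), ``protected``
    (list of str), ``features`` (list of str) and optionally ``id``.
    Columns present in the file but not named in the schema are ignored
    with a warning.
    """
    df = pd.read_csv(path)
    label_col = schema["label"]
    protected_cols = list(schema["protected"])
    feature_cols = list(schema["features"])
    id_col = schema.get("id")

    declared = [label_col, *protected_cols, *feature_cols] + ([id_col] if id_col else [])
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"declared columns absent from {path}: {missing}")
    unlisted = [c for c in df.columns if c not in declared]
    if unlisted:
        logger.warning("ignoring unlisted columns in %s: %s", path, unlisted)

    labels = df[label_col].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise CohortValidationError(
            f"label column {label_col!r} contains values outside {{0,1}}"
        )
    ids = df[id_col] if id_col else pd.RangeIndex(len(df))
    return Cohort(
        ids=pd.Index(ids),
        protected=df[protected_cols],
        features=df[feature_cols],
        labels=labels.astype(np.int8),
    )


def write_cohort(cohort: Cohort, path, id_column: str = "id", label_column: str = "label") -> dict:
    """Write a cohort to CSV; returns the schema that round-trips it.

    Floats survive the round trip to 12 significant digits; integers and
    categories bit-exactly.
    """
    df = cohort.to_frame(id_column=id_column, label_column=label_column)
    df.to_csv(path, index=False, float_format="%.12g")
    return {
        "id": id_column,
        "label": label_column,
        "protected": cohort.protected_attributes,
        "features": cohort.feature_names,
    }


def phq9_binarize(scores) -> np.ndarray:
    """Binarize PHQ-9 questionnaire totals into depression labels.

    The PHQ-9 is a 9-item screener with item scores 0-3, hence totals in
    [0, 27]; a total of 10 or more is the standard cutoff for major
    depressive disorder, so label 1 iff score >= 10.
    """
    arr = np.asarray(scores)
    if arr.size and ((arr < 0).any() or (arr > 27).any()):
        bad = arr[(arr < 0) | (arr > 27)]
        raise CohortValidationError(
            f"PHQ-9 totals must lie in [0, 27]; found {bad[:5].tolist()}"
        )
    return (arr >= 10).astype(np.int8)


def partition_by_group(cohort: Cohort, attribute: str) -> GroupPartition:
    """Split cohort rows by the categories of one protected attribute.

    Categories are ordered lexicographically for reproducibility; sizes sum
    to ``cohort.n``.
    """
    if attribute not in cohort.protected.columns:
        raise KeyError(
            f"{attribute!r} is not a declared protected attribute "
            f"(have {cohort.protected_attributes})"
        )
    values = cohort.protected[attribute].to_numpy()
    categories = sorted(pd.unique(values))
    groups = {cat: np.flatnonzero(values == cat) for cat in categories}
    return GroupPartition(attribute=attribute, groups=groups, categories=categories)
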