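"""Core data types, input validation and design-matrix construction.

The analysis is declared once as an :class:`AnalysisSpec` — which column is
the binary outcome, which single column is the exposure, which covariates are
forced into every model (W terms, e.g. age group and sex) and which are
candidates for selection (U terms).  Subject-level records live in a
:class:`Dataset`; :func:`build_design` turns a dataset plus a roster of
included candidate groups into a numeric design matrix with a deterministic
column order.

Categorical covariates are expanded into reference-level dummy indicators
(reference = first level in sorted order) and all dummies of one variable
form a single :class:`CandidateGroup` that enters or leaves models
atomically.  Quantitative covariates pass through unchanged: any re-centring
or rescaling to meaningful units is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DegenerateDesignError

logger = logging.getLogger(__name__)

INTERCEPT = "(intercept)"
#: design-matrix label of the actual-data indicator that replaces the
#: intercept after prior data augmentation
ACTUAL_INDICATOR = "(actual)"

VALID_FAMILIES = ("logistic", "poisson")


@dataclass(frozen=True)
class AnalysisSpec:
    """Declaration of one exposure-effect analysis.

    Parameters
    ----------
    outcome_name
        Column holding the binary (0/1) outcome.
    exposure_name
        Column holding the single-term exposure (binary or quantitative).
    forced
        Covariates forced into every model, in the order they should appear.
    candidates
        Covariates eligible for selection, in evaluation/tie-break order.
    family
        ``"logistic"`` (default) or ``"poisson"``.
    weight_name
        Optional column of positive record weights.
    """

    outcome_name: str
    exposure_name: str
    forced: tuple[str, ...] = ()
    candidates: tuple[str, ...] = ()
    family: str = "logistic"
    weight_name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "forced", tuple(self.forced))
        object.__setattr__(self, "candidates", tuple(self.candidates))
        names = [self.outcome_name, self.exposure_name, *self.forced, *self.candidates]
        if self.weight_name is not None:
            names.append(self.weight_name)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(
                f"analysis roles must name distinct columns; duplicated: {sorted(dupes)}"
            )
        if self.family not in VALID_FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {VALID_FAMILIES}"
            )

    @property
    def analysis_columns(self) -> list[str]:
        cols = [self.outcome_name, self.exposure_name, *self.forced, *self.candidates]
        if self.weight_name is not None:
            cols.append(self.weight_name)
        return cols


@dataclass(frozen=True)
class CandidateGroup:
    """One selectable covariate: a name plus the design columns carrying it.

    A quantitative covariate has a single term column; a categorical one has
    one dummy per non-reference level.  Groups move atomically — selection
    never splits the dummies of one variable.
    """

    name: str
    term_columns: tuple[str, ...]

    def __post_init__(self):
        if not self.term_columns:
            raise ConfigurationError(f"group {self.name!r} has no term columns")
        object.__setattr__(self, "term_columns", tuple(self.term_columns))


@dataclass
class Dataset:
    """Validated subject-level records.

    ``frame`` holds outcome/covariate columns; ``weights`` are positive
    record weights (1 unless the input declared a weight column);
    ``is_actual`` distinguishes real records from pseudo-records appended by
    prior data augmentation.
    """

    frame: pd.DataFrame
    weights: np.ndarray
    is_actual: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.frame)
        if n < 1:
            raise DataError("dataset must contain at least one record")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,):
            raise DataError("weights must align with records")
        if np.any(self.weights <= 0):
            bad = int(np.flatnonzero(self.weights <= 0)[0])
            raise DataError(f"non-positive weight at row {bad}")
        if self.is_actual is None:
            self.is_actual = np.ones(n, dtype=bool)
        else:
            self.is_actual = np.asarray(self.is_actual, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_actual(self) -> int:
        return int(self.is_actual.sum())


def _validate_outcome(values: pd.Series, name: str) -> None:
    arr = pd.to_numeric(values, errors="coerce")
    bad = ~arr.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(
            f"outcome column {name!r} must be 0/1; offending value "
            f"{values.iloc[row]!r} at row {row}"
        )


def read_dataset(path, spec: AnalysisSpec) -> Dataset:
    """Read a CSV file and validate it against ``spec``.

    Rows with a missing value in any analysis column are dropped (the count
    is logged); there is no imputation.
    """
    df = pd.read_csv(path)
    return dataset_from_frame(df, spec)


def dataset_from_frame(df: pd.DataFrame, spec: AnalysisSpec) -> Dataset:
    """Validate an in-memory data frame against ``spec`` (see :func:`read_dataset`)."""
    missing = [c for c in spec.analysis_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"data file is missing required column(s): {missing}"
        )
    df = df.loc[:, spec.analysis_columns].copy()
    n_before = len(df)
    df = df.dropna(axis=0, how="any").reset_index(drop=True)
    if len(df) < n_before:
        logger.warning(
            "dropped %d row(s) with missing analysis values", n_before - len(df)
        )
    if len(df) == 0:
        raise DataError("no complete records remain after dropping missing values")
    _validate_outcome(df[spec.outcome_name], spec.outcome_name)
    df[spec.outcome_name] = df[spec.outcome_name].astype(int)
    if spec.weight_name is not None:
        w = pd.to_numeric(df[spec.weight_name], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            bad = int(np.flatnonzero(~np.isfinite(w) | (w <= 0))[0])
            raise DataError(f"weight column {spec.weight_name!r} must be positive; row {bad}")
        df = df.drop(columns=[spec.weight_name])
    else:
        w = np.ones(len(df))
    if not pd.api.types.is_numeric_dtype(df[spec.exposure_name]):
        raise DataError(
            f"exposure column {spec.exposure_name!r} must be numeric (single term)"
        )
    return Dataset(frame=df, weights=w)


def write_dataset(dataset: Dataset, path) -> None:
    """Write actual records back to CSV (inverse of :func:`read_dataset`)."""
    dataset.frame.loc[dataset.is_actual].to_csv(path, index=False)


def _expand_column(df: pd.DataFrame, name: str) -> tuple[CandidateGroup, pd.DataFrame]:
    """Return the group and numeric term columns for one covariate."""
    col = df[name]
    if pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2:
        return CandidateGroup(name, (name,)), col.to_frame().astype(float)
    if pd.api.types.is_numeric_dtype(col) and set(col.dropna().unique()) <= {0, 1}:
        return CandidateGroup(name, (name,)), col.to_frame().astype(float)
    # categorical: sorted levels, first is the reference
    levels = sorted(col.astype(str).unique())
    terms, frames = [], {}
    for level in levels[1:]:
        label = f"{name}={level}"
        terms.append(label)
        frames[label] = (col.astype(str) == level).astype(float)
    if not terms:
        raise DegenerateDesignError(
            f"covariate {name!r} is constant", columns=[name]
        )
    return CandidateGroup(name, tuple(terms)), pd.DataFrame(frames, index=df.index)


@dataclass
class Design:
    """One model's design matrix, response and weights, ready to fit."""

    X: np.ndarray
    columns: tuple[str, ...]
    y: np.ndarray
    weights: np.ndarray
    is_actual: np.ndarray
    family: str
    exposure: str
    roster: frozenset = frozenset()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_actual(self) -> int:
        return int(self.is_actual.sum())

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelMatrix:
    """Fully expanded design for one analysis, shared by every roster.

    Columns are ordered ``[intercept, exposure, forced terms, candidate
    terms]`` with groups in spec order and dummy terms of a group in sorted
    label order, so identical inputs always yield identical designs.
    Selection engines and the bootstrap work on row/column views of this
    object rather than re-expanding the raw data.
    """

    X: np.ndarray                      # n x P, all groups expanded
    y: np.ndarray
    weights: np.ndarray
    is_actual: np.ndarray
    columns: tuple[str, ...]
    groups: dict[str, tuple[int, ...]]  # group name -> column indices in X
    spec: AnalysisSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_actual(self) -> int:
        return int(self.is_actual.sum())

    @property
    def base_indices(self) -> tuple[int, ...]:
        idx = [0, 1]
        for name in self.spec.forced:
            idx.extend(self.groups[name])
        return tuple(idx)

    def roster_indices(self, included) -> tuple[int, ...]:
        """Column indices for intercept + exposure + forced + ``included``."""
        included = set(included)
        unknown = included - set(self.spec.candidates)
        if unknown:
            raise ConfigurationError(
                f"unknown candidate group(s): {sorted(unknown)}"
            )
        idx = list(self.base_indices)
        for name in self.spec.candidates:  # spec order, not set order
            if name in included:
                idx.extend(self.groups[name])
        return tuple(idx)

    def design(self, included) -> "Design":
        idx = self.roster_indices(included)
        return Design(
            X=self.X[:, idx],
            columns=tuple(self.columns[i] for i in idx),
            y=self.y,
            weights=self.weights,
            is_actual=self.is_actual,
            family=self.spec.family,
            exposure=self.spec.exposure_name,
            roster=frozenset(included),
        )

    def resample(self, row_idx: np.ndarray) -> "ModelMatrix":
        """Row view for bootstrap/jackknife resamples."""
        return ModelMatrix(
            X=self.X[row_idx],
            y=self.y[row_idx],
            weights=self.weights[row_idx],
            is_actual=self.is_actual[row_idx],
            columns=self.columns,
            groups=self.groups,
            spec=self.spec,
        )


def build_model_matrix(dataset: Dataset, spec: AnalysisSpec) -> ModelMatrix:
    """Expand every covariate group once and assemble the full design."""
    df = dataset.frame
    cols: dict[str, np.ndarray] = {INTERCEPT: np.ones(len(df))}
    exp = df[spec.exposure_name]
    if not pd.api.types.is_numeric_dtype(exp):
        raise ConfigurationError(
            f"exposure {spec.exposure_name!r} must be a single numeric/binary column"
        )
    cols[spec.exposure_name] = exp.to_numpy(float)
    groups: dict[str, tuple[int, ...]] = {}
    order: list[str] = [INTERCEPT, spec.exposure_name]
    for name in (*spec.forced, *spec.candidates):
        group, terms = _expand_column(df, name)
        for label in group.term_columns:
            cols[label] = terms[label].to_numpy(float)
            order.append(label)
        groups[name] = group.term_columns
    X = np.column_stack([cols[c] for c in order])
    label_index = {c: i for i, c in enumerate(order)}
    group_idx = {
        name: tuple(label_index[t] for t in terms) for name, terms in groups.items()
    }
    mm = ModelMatrix(
        X=X,
        y=df[spec.outcome_name].to_numpy(float),
        weights=dataset.weights.copy(),
        is_actual=dataset.is_actual.copy(),
        columns=tuple(order),
        groups=group_idx,
        spec=spec,
    )
    _check_rank(mm.X, mm.columns)
    return mm


def _check_rank(X: np.ndarray, columns: tuple[str, ...]) -> None:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank == p:
        return
    offending: list[str] = []
    # constant non-intercept columns
    for j in range(1, p):
        if np.ptp(X[:, j]) == 0:
            offending.append(columns[j])
    # pivoted QR: dependent columns have (numerically) zero R diagonal
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    for k in np.flatnonzero(diag <= tol):
        label = columns[piv[k]]
        if label not in offending:
            offending.append(label)
    raise DegenerateDesignError(
        f"design matrix is rank deficient (rank {rank} < {p}); "
        f"offending column(s): {offending}",
        columns=offending,
    )


def build_design(dataset: Dataset, spec: AnalysisSpec, included=frozenset()) -> Design:
    """Design for one candidate roster, with the deterministic column order
    ``[intercept, exposure, forced terms, included candidate terms]``.
    """
    mm = build_model_matrix(dataset, spec)
    design = mm.design(included)
    _check_rank(design.X, design.columns)
    return design
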