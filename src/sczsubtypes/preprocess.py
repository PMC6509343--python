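"""Normalization and the probe / cohort filters.

Expression arrays arrive as raw probe intensities; downstream modelling
expects quantile-normalized log2 values and a probe set restricted to
transcripts that are reliably detected, numerically clean, and free of
common SNPs in the probe sequence.  Three probe filters are applied
sequentially (NA/Inf -> detection -> SNP) so a probe removed by an earlier
stage is never counted by a later one, and the report totals reconcile
exactly.  The cohort filter restricts subjects to the diagnoses of interest
with a known age at or above a minimum (default 25 years, excluding
children and young adults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError

__all__ = [
    "FilterConfig", "FilterReport", "quantile_normalize", "log2_transform",
    "filter_probes", "filter_cohort",
]


@dataclass(frozen=True)
class FilterConfig:
    """Probe-filter settings.

    ``min_detected_subjects`` may be an absolute count or a fraction of the
    subject total; a fraction scales the rule to other cohort sizes.  The
    default 841/849 reproduces the near-complete detection requirement of a
    ~850-subject array cohort.
    """

    detection_alpha: float = 0.05
    min_detected_subjects: float = 841 / 849
    drop_na_inf: bool = True
    snp_probe_ids: frozenset = field(default_factory=frozenset)

    def validate(self, n_subjects: int) -> None:
        if not 0.0 < self.detection_alpha < 1.0:
            raise ValidationError(
                f"detection_alpha must be in (0, 1), got {self.detection_alpha}")
        if self.detection_threshold(n_subjects) > n_subjects:
            raise ValidationError(
                "min_detected_subjects exceeds the number of subjects "
                f"({self.min_detected_subjects} > {n_subjects})")

    def detection_threshold(self, n_subjects: int) -> int:
        """Minimum number of subjects with a detection call, as a count."""
        m = self.min_detected_subjects
        if 0 < m <= 1 and not float(m).is_integer():
            # fractional rule; guard the ceil against float fuzz such as
            # (841/849) * 849 = 840.9999...
            return int(math.ceil(m * n_subjects - 1e-9))
        return int(m)


@dataclass
class FilterReport:
    """Bookkeeping for the three sequential probe filters."""

    n_input: int
    n_removed_na_inf: int
    n_removed_detection: int
    n_removed_snp: int
    n_retained: int
    removed_ids: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.n_removed_na_inf + self.n_removed_detection
                 + self.n_removed_snp + self.n_retained)
        if total != self.n_input:
            raise ValidationError(
                f"filter report does not reconcile: {self.n_input} input != "
                f"{total} retained + removed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "na_inf", "detection", "snp", "retained"],
                "n": [self.n_input, self.n_removed_na_inf,
                      self.n_removed_detection, self.n_removed_snp,
                      self.n_retained],
            }
        )


def quantile_normalize(values: pd.DataFrame | np.ndarray):
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the column-wise sorted input; after
    normalization every complete column holds exactly the same multiset of
    values.  Tied values within a column all receive the mean of the
    reference values over their rank span, which keeps the map deterministic.
    Missing cells (NaN) are left missing; columns with missing cells are
    mapped through the quantiles of the reference.
    """
    is_frame = isinstance(values, pd.DataFrame)
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValidationError("quantile_normalize expects a non-empty matrix")
    n, m = X.shape
    counts = np.sum(~np.isnan(X), axis=0)
    if np.any(counts == 0):
        j = int(np.argmin(counts))
        raise ValidationError(f"column {j} is entirely missing")

    # reference distribution: mean over columns of sorted values, each
    # column interpolated onto n common quantiles when it has missing cells
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    for j in range(m):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        if len(col) == n:
            ref += col
        elif len(col) == 1:
            ref += col[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, len(col)), col)
    ref /= m

    out = np.full_like(X, np.nan)
    for j in range(m):
        mask = ~np.isnan(X[:, j])
        v = X[mask, j]
        k = len(v)
        if k == n:
            targets_sorted = ref
        elif k == 1:
            targets_sorted = np.array([ref.mean()])
        else:
            targets_sorted = np.interp(np.linspace(0.0, 1.0, k), grid, ref)
        order = np.argsort(v, kind="mergesort")
        targets = np.empty(k)
        targets[order] = targets_sorted
        # ties: average the reference values across the tied rank span
        _, inv = np.unique(v, return_inverse=True)
        sums = np.bincount(inv, weights=targets)
        cnts = np.bincount(inv)
        out[mask, j] = (sums / cnts)[inv]

    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def log2_transform(values: pd.DataFrame | np.ndarray):
    """Elementwise log2; non-positive cells become missing and are counted.

    Returns ``(transformed, n_nonpositive)``.
    """
    is_frame = isinstance(values, pd.DataFrame)
    X = np.asarray(values, dtype=float)
    nonpos = np.isfinite(X) & (X <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nonpos, np.nan, np.log2(np.where(nonpos, np.nan, X)))
    n_nonpos = int(nonpos.sum())
    if is_frame:
        out = pd.DataFrame(out, index=values.index, columns=values.columns)
    return out, n_nonpos


def filter_probes(expr: pd.DataFrame, detection: pd.DataFrame,
                  config: FilterConfig) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three sequential probe filters: NA/Inf, detection, SNP."""
    if not (expr.index.equals(detection.index)
            and expr.columns.equals(detection.columns)):
        raise DimensionError(
            "expression and detection matrices are not aligned "
            f"({expr.shape} vs {detection.shape})")
    config.validate(expr.shape[1])

    removed: dict[str, list] = {}
    current = expr

    if config.drop_na_inf:
        bad = ~np.isfinite(current.to_numpy(dtype=float)).all(axis=1)
        removed["na_inf"] = list(current.index[bad])
        current = current.loc[~bad]
    else:
        removed["na_inf"] = []

    thresh = config.detection_threshold(expr.shape[1])
    det = detection.loc[current.index]
    n_detected = (det.to_numpy(dtype=float) < config.detection_alpha).sum(axis=1)
    fail = n_detected < thresh
    removed["detection"] = list(current.index[fail])
    current = current.loc[~fail]

    snp = current.index.isin(config.snp_probe_ids)
    removed["snp"] = list(current.index[snp])
    current = current.loc[~snp]

    report = FilterReport(
        n_input=expr.shape[0],
        n_removed_na_inf=len(removed["na_inf"]),
        n_removed_detection=len(removed["detection"]),
        n_removed_snp=len(removed["snp"]),
        n_retained=current.shape[0],
        removed_ids=removed,
    )
    return current, report


def filter_cohort(metadata: pd.DataFrame, min_age: float = 25.0,
                  diagnoses: tuple = ("schizophrenia", "control"),
                  ) -> pd.DataFrame:
    """Keep subjects with an eligible diagnosis and known age >= ``min_age``."""
    if "diagnosis" not in metadata or "age" not in metadata:
        raise ValidationError("metadata must have 'diagnosis' and 'age'")
    age = pd.to_numeric(metadata["age"], errors="coerce")
    keep = metadata["diagnosis"].isin(diagnoses) & age.notna() & (age >= min_age)
    return metadata.loc[keep]
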