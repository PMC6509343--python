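"""Per-subtype differential expression and the GABA-marker report.

Once patients carry stable subtype labels, each subtype is compared
separately against the controls with the same robust mixed-effects scan
used for the full cohort.  Splitting a heterogeneous case group this way
can sharply increase detection: a subtype that truly differs stands out
once it is no longer diluted by near-control patients.  "Intermediate"
patients (unstable subtype assignment) are excluded from both groups by
default.

The marker report extracts the fitted rows for a configurable list of
GABAergic interneuron marker genes (GAD1, LHX6, SST, PVALB, NPY, TAC1,
VIP); markers whose probes were filtered out or never tested are reported
as not detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import ModelSpec, de_scan
from .errors import ValidationError
from .stability import INTERMEDIATE

__all__ = ["SubtypeDEResult", "subtype_de_scan", "marker_report",
           "DEFAULT_MARKERS", "count_significant"]

DEFAULT_MARKERS = ("GAD1", "LHX6", "NPY", "TAC1", "VIP", "SST", "PVALB")


@dataclass
class SubtypeDEResult:
    """DE scan of one subtype vs controls."""

    subtype: str
    de_table: pd.DataFrame
    criterion: tuple          # ("bonferroni" | "fdr", alpha)
    n_significant: int
    n_cases: int
    n_controls: int


def count_significant(de_table: pd.DataFrame, criterion: tuple) -> int:
    """Number of probes passing a ("bonferroni"|"fdr", alpha) criterion."""
    method, alpha = criterion
    if not 0 < alpha < 1:
        raise ValidationError(f"criterion alpha must be in (0, 1), got {alpha}")
    col = {"bonferroni": "p_bonf", "fdr": "p_fdr"}.get(method)
    if col is None:
        raise ValidationError(
            f"criterion must be 'bonferroni' or 'fdr', got {method!r}")
    return int((de_table[col] < alpha).sum())


def subtype_de_scan(expr: pd.DataFrame, metadata: pd.DataFrame,
                    labels: pd.Series, subtype: str,
                    spec: ModelSpec = ModelSpec(),
                    criterion: tuple = ("bonferroni", 0.05),
                    include_intermediates: bool = False) -> SubtypeDEResult:
    """Scan controls + one subtype; intermediates excluded by default.

    ``labels`` indexes the patients only; controls are taken from
    ``metadata`` rows whose diagnosis equals the model reference level.
    """
    controls = metadata.index[metadata[spec.diagnosis_col] == spec.reference]
    members = labels.index[labels == subtype]
    if include_intermediates:
        members = members.union(labels.index[labels == INTERMEDIATE])
    if len(members) < 2:
        raise ValidationError(
            f"subtype {subtype!r} has {len(members)} subjects; need >= 2")
    subjects = list(controls) + [s for s in labels.index if s in set(members)]
    missing = set(subjects) - set(expr.columns)
    if missing:
        raise ValidationError(
            f"subjects absent from expression matrix: {sorted(missing)[:5]}")
    sub_meta = metadata.loc[subjects]
    sub_expr = expr.loc[:, subjects]
    table = de_scan(sub_expr, sub_meta, spec)
    return SubtypeDEResult(
        subtype=subtype,
        de_table=table,
        criterion=criterion,
        n_significant=count_significant(table, criterion),
        n_cases=len(members),
        n_controls=len(controls),
    )


def marker_report(de_tables: dict[str, pd.DataFrame],
                  annotation: pd.DataFrame,
                  markers=DEFAULT_MARKERS,
                  gene_col: str = "gene_symbol") -> pd.DataFrame:
    """Per-subtype rows for each marker gene; absent markers flagged.

    ``annotation`` maps probe ids (index) to gene symbols; a marker whose
    probes are absent from a subtype's tested set yields a single
    ``detected=False`` row for that subtype.
    """
    if gene_col not in annotation:
        raise ValidationError(f"annotation lacks a '{gene_col}' column")
    rows = []
    for subtype, table in de_tables.items():
        genes = annotation.loc[annotation.index.intersection(table.index),
                               gene_col]
        for marker in markers:
            probes = genes.index[genes == marker]
            if len(probes) == 0:
                rows.append({"marker": marker, "subtype": subtype,
                             "probe_id": None, "detected": False,
                             "effect": np.nan, "p": np.nan,
                             "p_bonf": np.nan, "p_fdr": np.nan})
                continue
            for probe in probes:
                r = table.loc[probe]
                rows.append({"marker": marker, "subtype": subtype,
                             "probe_id": probe, "detected": True,
                             "effect": float(r["effect"]),
                             "p": float(r["p"]),
                             "p_bonf": float(r["p_bonf"]),
                             "p_fdr": float(r["p_fdr"])})
    return pd.DataFrame(rows, columns=["marker", "subtype", "probe_id",
                                       "detected", "effect", "p", "p_bonf",
                                       "p_fdr"])
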