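"""Perturbation stability of the subject clustering.

The clustering is validated by repeatedly adding bounded random noise to the
covariate-adjusted expression data and re-clustering.  The noise for each
cell is uniform on ±(level × σ), where σ is the standard deviation of the
data (per probe by default, so the perturbation is scale-equivariant across
probes) and "level" is the perturbation level.  A patient whose aligned
cluster assignment differs from the base assignment in one or more of the
runs (100 by default) is relabelled "intermediate" — a subject whose
subtype call is not robust to noise of that magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .subtyping import SubtypingConfig, cluster_subjects, subject_adjacency, tom

__all__ = [
    "StabilityConfig", "StabilityReport", "perturb", "run_stability",
    "stability_grid", "INTERMEDIATE",
]

INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class StabilityConfig:
    """Perturbation settings for one stability run."""

    perturbation_level: float = 0.5
    n_runs: int = 100
    sd_scope: str = "per_probe"      # or "global"
    seed: int = 0

    def validate(self) -> None:
        if self.perturbation_level < 0:
            raise ValidationError("perturbation_level must be >= 0")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.sd_scope not in ("per_probe", "global"):
            raise ValidationError(
                f"sd_scope must be 'per_probe' or 'global', got "
                f"{self.sd_scope!r}")


@dataclass
class StabilityReport:
    """Outcome of one perturbation level."""

    level: float
    base_labels: pd.Series
    misclass_count: pd.Series
    final_labels: pd.Series
    n_runs: int                  # effective denominator (failed runs excluded)
    n_failed_runs: int = 0

    def __post_init__(self) -> None:
        mism = (self.final_labels == INTERMEDIATE) != (self.misclass_count >= 1)
        if mism.any():
            raise ValidationError(
                "relabelling rule violated: intermediate <=> misclass >= 1")

    def summary(self) -> dict:
        counts = self.final_labels.value_counts()
        return {
            "level": self.level,
            "type1": int(counts.get("type1", 0)),
            "type2": int(counts.get("type2", 0)),
            "intermediate": int(counts.get(INTERMEDIATE, 0)),
            "n_runs": self.n_runs,
        }


def perturb(expr_adj: pd.DataFrame, level: float,
            rng: np.random.Generator,
            sd_scope: str = "per_probe") -> pd.DataFrame:
    """Add uniform noise on ±(level × σ) to every cell; fresh each call."""
    if level < 0:
        raise ValidationError("perturbation level must be >= 0")
    if level == 0:
        return expr_adj.copy()
    vals = expr_adj.to_numpy(dtype=float)
    if sd_scope == "per_probe":
        sigma = vals.std(axis=1, ddof=1)[:, None]
    elif sd_scope == "global":
        sigma = vals.std(ddof=1)
    else:
        raise ValidationError(f"unknown sd_scope {sd_scope!r}")
    noise = rng.uniform(-1.0, 1.0, vals.shape) * (level * sigma)
    return pd.DataFrame(vals + noise, index=expr_adj.index,
                        columns=expr_adj.columns)


def _align_to_base(run_labels: pd.Series, base_labels: pd.Series) -> pd.Series:
    """Rename run clusters to maximize agreement with the base labels.

    For two clusters this is the identity-or-swap choice (the 2x2 Hungarian
    assignment); in general each run cluster takes the base name it overlaps
    most, ties broken by name order.
    """
    names = sorted(base_labels.unique())
    run_names = sorted(run_labels.unique())
    if len(names) == 2 and len(run_names) == 2:
        agree_id = int((run_labels == base_labels).sum())
        swap = {run_names[0]: run_names[1], run_names[1]: run_names[0]}
        swapped = run_labels.map(swap)
        agree_sw = int((swapped == base_labels).sum())
        return run_labels if agree_id >= agree_sw else swapped
    mapping = {}
    for rn in run_names:
        members = run_labels.index[run_labels == rn]
        overlap = base_labels.loc[members].value_counts()
        mapping[rn] = overlap.index[0]
    return run_labels.map(mapping)


def run_stability(expr_adj: pd.DataFrame,
                  config_sub: SubtypingConfig = SubtypingConfig(),
                  config_stab: StabilityConfig = StabilityConfig(),
                  base_labels: pd.Series | None = None,
                  expr_for_orientation: pd.DataFrame | None = None,
                  control_centroid=None) -> StabilityReport:
    """Cluster, perturb-and-recluster ``n_runs`` times, relabel flippers.

    ``base_labels`` may be supplied to share one base clustering across
    perturbation levels; otherwise it is computed from the unperturbed data.
    Runs in which clustering degenerates are excluded from the denominator.
    """
    config_sub.validate()
    config_stab.validate()

    def _cluster(data: pd.DataFrame) -> pd.Series:
        adj = subject_adjacency(data, config_sub)
        return cluster_subjects(tom(adj), config_sub,
                                expr_adj=expr_for_orientation,
                                control_centroid=control_centroid)

    if base_labels is None:
        base_labels = _cluster(expr_adj)
    misclass = pd.Series(0, index=base_labels.index, dtype=int)

    rng = np.random.default_rng(config_stab.seed)
    n_ok = 0
    n_failed = 0
    for _ in range(config_stab.n_runs):
        noisy = perturb(expr_adj, config_stab.perturbation_level, rng,
                        config_stab.sd_scope)
        try:
            run_labels = _cluster(noisy)
        except ValidationError:
            n_failed += 1
            continue
        aligned = _align_to_base(run_labels, base_labels)
        misclass += (aligned != base_labels).astype(int)
        n_ok += 1

    final = base_labels.where(misclass == 0, INTERMEDIATE)
    final.name = "subtype"
    return StabilityReport(level=config_stab.perturbation_level,
                           base_labels=base_labels,
                           misclass_count=misclass.rename("misclass_count"),
                           final_labels=final, n_runs=n_ok,
                           n_failed_runs=n_failed)


def stability_grid(expr_adj: pd.DataFrame,
                   config_sub: SubtypingConfig = SubtypingConfig(),
                   levels=(0.0, 0.05, 0.10, 0.25, 0.50),
                   n_runs: int = 100, sd_scope: str = "per_probe",
                   seed: int = 0,
                   expr_for_orientation: pd.DataFrame | None = None,
                   control_centroid=None) -> list[StabilityReport]:
    """One stability report per perturbation level, shared base labels.

    Noise streams are independent across levels (seeds derived from
    ``seed`` via a SeedSequence spawn).
    """
    levels = list(levels)
    if levels != sorted(levels):
        raise ValidationError("perturbation levels must be sorted ascending")
    adj = subject_adjacency(expr_adj, config_sub)
    base = cluster_subjects(tom(adj), config_sub,
                            expr_adj=expr_for_orientation,
                            control_centroid=control_centroid)
    children = np.random.SeedSequence(seed).spawn(len(levels))
    reports = []
    for level, child in zip(levels, children):
        cfg = StabilityConfig(perturbation_level=level, n_runs=n_runs,
                              sd_scope=sd_scope,
                              seed=int(child.generate_state(1)[0] % (2**31)))
        reports.append(run_stability(expr_adj, config_sub, cfg,
                                     base_labels=base,
                                     expr_for_orientation=expr_for_orientation,
                                     control_centroid=control_centroid))
    return reports


def grid_summary(reports: list[StabilityReport]) -> pd.DataFrame:
    """Tabular per-level subtype counts (one row per perturbation level)."""
    return pd.DataFrame([r.summary() for r in reports])
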