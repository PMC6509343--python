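"""Synthetic case/control cohorts with two latent schizophrenia subtypes.

The generator emulates the structure of a post-mortem DLPFC expression-array
study: a control group plus two schizophrenia subtypes, where "type 1"
subjects share the control transcriptome except for a handful of probes and
"type 2" subjects differ at many probes.  Each probe's log2 intensity is

    baseline + covariate effects (age, sex, ethnicity, RIN)
             + batch random intercept + subtype effect + noise,

with Gaussian noise whose SD is inflated by ``outlier_scale`` in a random
``outlier_rate`` fraction of cells (heavy-tailed contamination that motivates
robust estimation downstream).  A fraction of probes is rendered "not
detected": their detection p-values exceed 0.05 in most subjects so that the
detection filter removes them.  Ground truth (subject labels, planted DE
probe sets, planted effect sizes) is carried alongside the data so every
downstream stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study"]

DIAG_CASE = "schizophrenia"
DIAG_CONTROL = "control"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    All expression-scale parameters are in log2 units.  ``seed`` fully
    determines the output: identical config + seed gives bit-identical data.
    """

    n_controls: int = 100
    n_type1: int = 40
    n_type2: int = 40
    n_probes: int = 2000
    n_de_type2: int = 200
    n_de_type1: int = 4
    effect_mean: float = 1.0
    effect_sd: float = 0.2
    # fraction of planted probes that are down- rather than up-regulated;
    # DE signatures mix both directions, and a signed profile is what makes
    # subjects with the signature mutually correlated after per-subject
    # centring (a constant offset across probes carries no correlation)
    effect_down_fraction: float = 0.5
    covariate_effect_scale: float = 0.1
    n_batches: int = 4
    batch_sd: float = 0.2
    noise_sd: float = 0.5
    outlier_rate: float = 0.02
    outlier_scale: float = 10.0
    nondetect_rate: float = 0.05
    snp_probe_rate: float = 0.01
    male_frac_controls: float = 0.65  # controls skew male in ME cohorts
    male_frac_cases: float = 0.5
    type1_subset_of_type2: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_controls", "n_type1", "n_type2", "n_probes",
                     "n_batches"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got "
                                         f"{getattr(self, name)}")
        for name in ("n_de_type1", "n_de_type2"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (self.n_de_type1 <= self.n_de_type2 <= self.n_probes):
            raise ConfigurationError(
                "n_de_type1 <= n_de_type2 <= n_probes required, got "
                f"n_de_type1={self.n_de_type1}, n_de_type2={self.n_de_type2},"
                f" n_probes={self.n_probes}")
        for name in ("outlier_rate", "nondetect_rate", "snp_probe_rate",
                     "male_frac_controls", "male_frac_cases",
                     "effect_down_fraction"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_sd", "covariate_effect_scale", "batch_sd",
                     "noise_sd"):
            if float(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if float(self.outlier_scale) < 1.0:
            raise ConfigurationError("outlier_scale must be >= 1")


@dataclass
class SimulatedStudy:
    """A synthetic cohort plus the ground truth used to generate it."""

    expression: pd.DataFrame        # probes x subjects, log2 units
    detection_pvals: pd.DataFrame   # probes x subjects, in [0, 1]
    metadata: pd.DataFrame          # per subject: diagnosis, age, sex, ...
    annotation: pd.DataFrame        # per probe: gene_symbol, snp_in_probe
    truth_labels: pd.Series         # per subject: control / type1 / type2
    truth_de_probes: dict[str, frozenset]
    truth_effects: pd.DataFrame     # probes x (type1, type2) planted effects
    config: SimulationConfig

    def __post_init__(self) -> None:
        if not (self.expression.shape == self.detection_pvals.shape
                and self.expression.columns.equals(self.detection_pvals.columns)
                and self.expression.index.equals(self.detection_pvals.index)):
            raise ConfigurationError("expression/detection_pvals misaligned")
        if not self.expression.columns.equals(self.metadata.index):
            raise ConfigurationError("expression/metadata subjects misaligned")
        probe_ids = set(self.expression.index)
        for subtype, ids in self.truth_de_probes.items():
            if not set(ids) <= probe_ids:
                raise ConfigurationError(
                    f"truth_de_probes[{subtype}] contains unknown probe ids")


def _truncnorm(rng: np.random.Generator, loc: float, scale: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(loc, scale, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a cohort according to ``config`` (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_subj = config.n_controls + config.n_type1 + config.n_type2
    subjects = [f"subj_{i:04d}" for i in range(n_subj)]
    probes = [f"probe_{i:05d}" for i in range(config.n_probes)]
    labels = np.array(["control"] * config.n_controls
                      + ["type1"] * config.n_type1
                      + ["type2"] * config.n_type2)

    # --- covariates -------------------------------------------------------
    age = rng.uniform(25.0, 80.0, n_subj)
    male_p = np.where(labels == "control",
                      config.male_frac_controls, config.male_frac_cases)
    sex = np.where(rng.random(n_subj) < male_p, "M", "F")
    ethnicity = np.where(rng.random(n_subj) < 0.5, "AA", "CAUC")
    rin = _truncnorm(rng, 8.0, 0.5, 5.0, 10.0, n_subj)
    batch = np.array([f"b{i % config.n_batches:02d}" for i in range(n_subj)])

    metadata = pd.DataFrame(
        {
            "diagnosis": np.where(labels == "control",
                                  DIAG_CONTROL, DIAG_CASE),
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "rin": rin,
            "batch": batch,
        },
        index=pd.Index(subjects, name="sample_id"),
    )

    # --- expression -------------------------------------------------------
    baseline = rng.uniform(6.0, 12.0, config.n_probes)

    # covariate effects on standardized covariates (log2 per covariate SD)
    def _std(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)

    cov = np.column_stack([
        _std(age),
        _std((sex == "M").astype(float)),
        _std((ethnicity == "AA").astype(float)),
        _std(rin),
    ])  # n_subj x 4
    cov_betas = rng.normal(0.0, config.covariate_effect_scale,
                           (config.n_probes, 4))

    batch_codes = np.array([int(b[1:]) for b in batch])
    batch_intercepts = rng.normal(0.0, config.batch_sd,
                                  (config.n_probes, config.n_batches))

    de2_idx = np.sort(rng.choice(config.n_probes, config.n_de_type2,
                                 replace=False))
    if config.type1_subset_of_type2 and config.n_de_type2 > 0:
        de1_idx = de2_idx[:config.n_de_type1]
    else:
        de1_idx = np.sort(rng.choice(config.n_probes, config.n_de_type1,
                                     replace=False))
    # per-probe signed effects: magnitudes ~ N(effect_mean, effect_sd),
    # a configurable fraction down-regulated; shared probes keep one sign
    signs = np.where(rng.random(config.n_probes) < config.effect_down_fraction,
                     -1.0, 1.0)
    eff2 = np.zeros(config.n_probes)
    eff2[de2_idx] = signs[de2_idx] * rng.normal(
        config.effect_mean, config.effect_sd, len(de2_idx))
    eff1 = np.zeros(config.n_probes)
    eff1[de1_idx] = signs[de1_idx] * rng.normal(
        config.effect_mean, config.effect_sd, len(de1_idx))

    values = (baseline[:, None]
              + cov_betas @ cov.T
              + batch_intercepts[:, batch_codes])
    values[:, labels == "type1"] += eff1[:, None]
    values[:, labels == "type2"] += eff2[:, None]

    noise = rng.normal(0.0, config.noise_sd, values.shape)
    outlier_mask = rng.random(values.shape) < config.outlier_rate
    noise[outlier_mask] *= config.outlier_scale
    values += noise

    expression = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                              columns=subjects)

    # --- detection p-values ----------------------------------------------
    n_nondetect = int(round(config.nondetect_rate * config.n_probes))
    nondetect_idx = rng.choice(config.n_probes, n_nondetect, replace=False)
    detection = rng.uniform(0.0, 0.049, values.shape)
    if n_nondetect:
        # undetected in ~80% of subjects -> fails any near-complete
        # detection requirement
        fail = rng.random((n_nondetect, n_subj)) < 0.8
        det_block = detection[nondetect_idx, :]
        det_block[fail] = rng.uniform(0.05, 1.0, int(fail.sum()))
        detection[nondetect_idx, :] = det_block
    detection_pvals = pd.DataFrame(detection, index=expression.index,
                                   columns=subjects)

    # --- annotation (many-to-one probe -> gene) ---------------------------
    gene_idx = (np.arange(config.n_probes) * 0.92).astype(int)
    annotation = pd.DataFrame(
        {
            "gene_symbol": [f"G{g:05d}" for g in gene_idx],
            "snp_in_probe": rng.random(config.n_probes) < config.snp_probe_rate,
        },
        index=expression.index,
    )

    truth_labels = pd.Series(labels, index=metadata.index, name="truth_label")
    truth_de = {
        "type1": frozenset(expression.index[de1_idx]),
        "type2": frozenset(expression.index[de2_idx]),
    }
    truth_effects = pd.DataFrame({"type1": eff1, "type2": eff2},
                                 index=expression.index)

    return SimulatedStudy(expression, detection_pvals, metadata, annotation,
                          truth_labels, truth_de, truth_effects, config)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain dict, rejecting unknown keys."""
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(
            f"unknown simulation config fields: {sorted(unknown)}")
    return SimulationConfig(**d)
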