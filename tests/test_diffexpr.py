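"""Robust mixed-effects fit: OLS oracle, robustness, multiple testing."""

import numpy as np
import pandas as pd
import pytest

import sczsubtypes as scz
from sczsubtypes.diffexpr import ModelSpec, bh_fdr, bonferroni
from sczsubtypes.errors import ModelError, ValidationError


def _single_batch_cohort(seed=0, n=160):
    """Metadata with one batch so the model reduces to (weighted) LS."""
    cfg = scz.SimulationConfig(seed=seed, n_controls=n // 2,
                               n_type1=1, n_type2=n // 2 - 1,
                               n_probes=2, n_de_type2=0, n_de_type1=0,
                               effect_mean=0.0, n_batches=1, batch_sd=0.0)
    return scz.simulate_study(cfg).metadata


def _design_matrix(meta):
    from sczsubtypes.diffexpr import _design
    X, names, Z, _ = _design(meta, ModelSpec())
    return X, names, Z


def test_clean_single_batch_fit_equals_ols_oracle(rng):
    """Without contamination the bounded-influence fit is exactly LS."""
    meta = _single_batch_cohort()
    X, _, Z = _design_matrix(meta)
    assert Z is None
    n = len(meta)
    worst = 0.0
    for _ in range(100):
        beta_true = rng.normal(0, 1, X.shape[1])
        y = X @ beta_true + rng.normal(0, 0.5, n)
        fit = scz.fit_probe(y, meta)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        worst = max(worst, abs(fit.effect - ols[1]))
        assert fit.converged
    assert worst < 1e-6


def test_clean_single_batch_se_matches_ols(rng):
    meta = _single_batch_cohort()
    X, _, _ = _design_matrix(meta)
    n, p = X.shape
    y = X @ rng.normal(0, 1, p) + rng.normal(0, 0.5, n)
    fit = scz.fit_probe(y, meta)
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ ols
    sigma2 = resid @ resid / (n - p)
    se_ols = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    assert fit.se == pytest.approx(se_ols, rel=1e-6)


def test_robust_beats_ols_under_contamination(rng):
    """2% ten-fold outliers: robust effects closer to truth than OLS."""
    meta = _single_batch_cohort()
    X, _, _ = _design_matrix(meta)
    n = len(meta)
    err_rob, err_ols = [], []
    for _ in range(100):
        noise = rng.normal(0, 0.5, n)
        mask = rng.random(n) < 0.02
        noise[mask] *= 10
        y = X @ np.r_[8.0, 1.0, np.zeros(X.shape[1] - 2)] + noise
        fit = scz.fit_probe(y, meta)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        err_rob.append(abs(fit.effect - 1.0))
        err_ols.append(abs(ols[1] - 1.0))
    assert np.mean(err_rob) < np.mean(err_ols)


def test_null_probe_is_not_significant(rng):
    meta = _single_batch_cohort()
    y = rng.normal(8.0, 0.5, len(meta))
    fit = scz.fit_probe(y, meta)
    assert abs(fit.effect) < 0.3
    assert fit.p > 0.01


def test_effect_invariant_to_affine_covariate_rescaling(rng):
    meta = _single_batch_cohort()
    y = rng.normal(8.0, 0.5, len(meta)) + 0.8 * (
        meta["diagnosis"] == "schizophrenia")
    fit1 = scz.fit_probe(y, meta)
    meta2 = meta.copy()
    meta2["age"] = meta2["age"] * 10 + 3
    meta2["rin"] = meta2["rin"] / 2 - 1
    fit2 = scz.fit_probe(y, meta2)
    assert fit1.effect == pytest.approx(fit2.effect, abs=1e-8)


def test_rank_deficiency_error_names_collinear_column():
    meta = _single_batch_cohort()
    meta = meta.copy()
    meta["rin"] = meta["age"] * 2.0       # exactly collinear
    with pytest.raises(ModelError, match="collinear"):
        scz.fit_probe(np.zeros(len(meta)), meta)


def test_planted_effects_recovered_within_monte_carlo_error():
    """Mean estimated minus planted effect compatible with zero."""
    cfg = scz.SimulationConfig(seed=11, n_probes=300, n_de_type2=60,
                               outlier_rate=0.0)
    st = scz.simulate_study(cfg)
    de = scz.de_scan(st.expression, st.metadata)
    planted = sorted(st.truth_de_probes["type2"])
    # pooled scan sees the type-2 effect diluted by the type-1 fraction
    cases = st.truth_labels != "control"
    dilution = ((st.truth_labels == "type2").sum() / cases.sum())
    expected = st.truth_effects.loc[planted, "type2"] * dilution
    diff = de.loc[planted, "effect"] - expected
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 2 * se + 0.02


def test_de_scan_orders_by_p_and_flags_nonfinite(default_study):
    st = default_study
    expr = st.expression.iloc[:30].copy()
    expr.iloc[0, 0] = np.nan
    de = scz.de_scan(expr, st.metadata)
    assert de["error"].notna().sum() == 1
    fitted = de[de["error"].isna()]
    assert fitted["p"].is_monotonic_increasing
    # adjusted p computed over exactly the probes fitted
    assert fitted["p_bonf"].max() <= 1.0
    top = fitted.iloc[0]
    assert top["p_bonf"] == pytest.approx(min(1.0, top["p"] * len(fitted)))


def test_batch_random_intercept_absorbs_batch_shifts(rng):
    """A strong batch offset should not reach the diagnosis effect."""
    cfg = scz.SimulationConfig(seed=21, n_controls=60, n_type1=30,
                               n_type2=30, n_probes=2, n_de_type2=0,
                               n_de_type1=0, effect_mean=0.0,
                               n_batches=4, batch_sd=0.0)
    meta = scz.simulate_study(cfg).metadata
    batch_offsets = {"b00": 0.0, "b01": 2.0, "b02": -1.0, "b03": 0.5}
    y = rng.normal(8.0, 0.3, len(meta)) + meta["batch"].map(batch_offsets)
    fit = scz.fit_probe(y, meta)
    assert fit.tau2 > 0.1                    # batch variance detected
    assert abs(fit.effect) < 0.25


# ------------------------------------------------------- multiple testing
def test_bonferroni_arithmetic_and_cap():
    np.testing.assert_allclose(bonferroni(np.array([0.001]), m=100), [0.1])
    np.testing.assert_allclose(bonferroni(np.array([1.0]), m=7), [1.0])
    np.testing.assert_allclose(bonferroni(np.array([0.0]), m=10**6), [0.0])


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        bonferroni(np.array([1.2]))
    with pytest.raises(ValidationError):
        bonferroni(np.array([0.1, 0.2]), m=1)


def test_bh_fdr_step_up_hand_case():
    # step-up: adjusted = min over j>=i of p_(j) * n / j, here all 0.04
    out = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_fdr_degenerate_cases():
    np.testing.assert_allclose(bh_fdr(np.array([0.3, 0.3, 0.3])),
                               [0.3, 0.3, 0.3])
    np.testing.assert_allclose(bh_fdr(np.array([0.2])), [0.2])


def test_adjustments_preserve_p_value_order(rng):
    p = rng.uniform(size=50)
    order = np.argsort(p)
    for adj in (bonferroni(p), bh_fdr(p)):
        assert (np.diff(adj[order]) >= -1e-12).all()
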