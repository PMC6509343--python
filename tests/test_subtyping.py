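"""Covariate adjustment, adjacency, TOM and subject clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sczsubtypes as scz
from sczsubtypes.errors import ValidationError


def tom_bruteforce(A):
    """Triple-loop oracle for the topological overlap measure."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n)
                         if u != i and u != j)
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def random_adjacency(rng, n):
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


# --------------------------------------------------------------- adjust
def test_residuals_orthogonal_to_covariates(default_study):
    st_ = default_study
    adj = scz.covariate_adjust(st_.expression.iloc[:50], st_.metadata)
    meta = st_.metadata
    for cov in ("age", "rin"):
        corr = np.corrcoef(adj.to_numpy(), meta[cov].to_numpy())[:-1, -1]
        assert np.abs(corr).max() < 1e-8
    sex = (meta["sex"] == "M").astype(float).to_numpy()
    corr = np.corrcoef(adj.to_numpy(), sex)[:-1, -1]
    assert np.abs(corr).max() < 1e-8


def test_adjustment_invariant_to_covariate_shift(default_study):
    st_ = default_study
    meta2 = st_.metadata.copy()
    meta2["age"] = meta2["age"] + 100.0
    a = scz.covariate_adjust(st_.expression.iloc[:20], st_.metadata)
    b = scz.covariate_adjust(st_.expression.iloc[:20], meta2)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)


def test_adjustment_never_uses_diagnosis(default_study):
    """Diagnosis group difference survives the covariate adjustment."""
    st_ = default_study
    planted = sorted(st_.truth_de_probes["type2"])[:10]
    adj = scz.covariate_adjust(st_.expression.loc[planted], st_.metadata)
    type2 = st_.truth_labels == "type2"
    ctrl = st_.truth_labels == "control"
    gap = (adj.loc[:, type2.values].mean(axis=1)
           - adj.loc[:, ctrl.values].mean(axis=1)).abs().mean()
    assert gap > 0.3


# ------------------------------------------------------------- adjacency
def test_adjacency_identical_profiles_give_one():
    probes = [f"p{i}" for i in range(10)]
    base = np.linspace(-1, 1, 10)
    df = pd.DataFrame({"a": base, "b": base, "c": -base},
                      index=probes)
    cfg = scz.SubtypingConfig(network_sign="unsigned", soft_power=6)
    adj = scz.subject_adjacency(df, cfg)
    assert adj.loc["a", "b"] == pytest.approx(1.0)
    assert adj.loc["a", "a"] == 0.0


def test_adjacency_powers_correlation():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    noise = rng.normal(size=40)
    y = -0.5 * x + noise
    # construct exact correlation -0.5 via Gram-Schmidt
    x = (x - x.mean()) / x.std()
    e = noise - noise.mean()
    e -= (e @ x) / (x @ x) * x
    e /= np.linalg.norm(e) / np.sqrt(len(e))
    y = -0.5 * x + np.sqrt(1 - 0.25) * e
    df = pd.DataFrame({"s1": x, "s2": y, "s3": rng.normal(size=40)})
    cfg = scz.SubtypingConfig(network_sign="unsigned", soft_power=6)
    adj = scz.subject_adjacency(df, cfg)
    assert adj.loc["s1", "s2"] == pytest.approx(0.5 ** 6, rel=1e-9)
    signed = scz.subject_adjacency(
        df, scz.SubtypingConfig(network_sign="signed", soft_power=6))
    assert signed.loc["s1", "s2"] == pytest.approx(0.25 ** 6, rel=1e-9)


def test_adjacency_zero_variance_subject_named():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0],
                       "c": [3.0, 1.0, 2.0]})
    with pytest.raises(ValidationError, match="b"):
        scz.subject_adjacency(df, scz.SubtypingConfig())


# ------------------------------------------------------------------- TOM
def test_tom_hand_case_all_half():
    A = np.full((3, 3), 0.5)
    np.fill_diagonal(A, 0.0)
    T = scz.tom(A)
    # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
    assert T[0, 1] == pytest.approx(0.5)
    assert np.allclose(np.diag(T), 1.0)


def test_tom_empty_and_saturated_networks():
    Z = np.zeros((4, 4))
    T = scz.tom(Z)
    assert np.allclose(T[~np.eye(4, dtype=bool)], 0.0)
    S = np.ones((4, 4)) - np.eye(4)
    T = scz.tom(S)
    assert np.allclose(T, 1.0)


def test_tom_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        A = random_adjacency(rng, 8)
        np.testing.assert_allclose(scz.tom(A), tom_bruteforce(A),
                                   atol=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_tom_bounds(seed):
    rng = np.random.default_rng(seed)
    A = random_adjacency(rng, 6)
    T = scz.tom(A)
    assert (T <= 1 + 1e-12).all()
    k = A.sum(axis=1)
    lower = A / (np.minimum.outer(k, k) + 1 - A)
    off = ~np.eye(6, dtype=bool)
    assert (T[off] >= lower[off] - 1e-12).all()


def test_tom_rejects_invalid_adjacency():
    bad = np.array([[0.0, 1.5], [1.5, 0.0]])
    with pytest.raises(ValidationError):
        scz.tom(bad)
    asym = np.array([[0.0, 0.2], [0.4, 0.0]])
    with pytest.raises(ValidationError):
        scz.tom(asym)


# ------------------------------------------------------------- clustering
def _block_tom(sizes, within=0.9, between=0.1):
    n = sum(sizes)
    T = np.full((n, n), between)
    start = 0
    for s in sizes:
        T[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(T, 1.0)
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(T, index=ids, columns=ids)


def test_cluster_recovers_perfect_blocks():
    T = _block_tom([5, 7])
    labels = scz.cluster_subjects(T, scz.SubtypingConfig())
    assert labels.nunique() == 2
    assert labels.iloc[:5].nunique() == 1
    assert labels.iloc[5:].nunique() == 1


def test_two_subjects_two_clusters():
    T = _block_tom([1, 1], within=1.0, between=0.2)
    labels = scz.cluster_subjects(T, scz.SubtypingConfig())
    assert labels.nunique() == 2


def test_more_clusters_than_subjects_errors():
    T = _block_tom([1, 1])
    with pytest.raises(ValidationError):
        scz.cluster_subjects(T, scz.SubtypingConfig(n_clusters=3))


def test_clustering_invariant_to_subject_order(recovery_run):
    T = recovery_run["tom"]
    cfg = scz.SubtypingConfig()
    labels = scz.cluster_subjects(T, cfg)
    rng = np.random.default_rng(0)
    perm = rng.permutation(T.index)
    labels_perm = scz.cluster_subjects(T.loc[perm, perm], cfg)
    agree = (labels_perm.loc[labels.index] == labels).mean()
    assert agree in (0.0, 1.0)   # identical partition up to name swap
    assert labels_perm.value_counts().sort_index().equals(
        labels.value_counts().sort_index())


def test_type2_is_cluster_far_from_control_centroid(recovery_run):
    r = recovery_run
    labels = scz.cluster_subjects(r["tom"], scz.SubtypingConfig(),
                                  expr_adj=r["expr_adj"],
                                  control_centroid=r["centroid"])
    truth = r["truth"]
    assert (labels[truth == "type2"] == "type2").all()
    assert (labels[truth == "type1"] == "type1").all()
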