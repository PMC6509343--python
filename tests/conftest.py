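"""Shared fixtures: synthetic cohorts and the end-to-end recovery run.

Session scope keeps the expensive pieces (full DE scans) computed once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sczsubtypes as scz


@pytest.fixture(scope="session")
def default_study():
    """Two-subtype cohort at the generator defaults (100/40/40, 2000 probes)."""
    return scz.simulate_study(scz.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_run(default_study):
    """Full pipeline on the default cohort: filters, DE scan, clustering.

    Returns a dict with the filtered matrices, the DE table, the probe set,
    adjusted expression, TOM, labels and truth.
    """
    study = default_study
    snp = frozenset(study.annotation.index[study.annotation.snp_in_probe])
    expr_f, report = scz.filter_probes(
        study.expression, study.detection_pvals,
        scz.FilterConfig(snp_probe_ids=snp))
    meta = scz.filter_cohort(study.metadata)
    expr_f = expr_f.loc[:, meta.index]
    de = scz.de_scan(expr_f, meta)
    de_probes = de.index[de["p_bonf"] < 0.05]
    adjusted = scz.covariate_adjust(expr_f, meta)
    cases = meta.index[meta["diagnosis"] == "schizophrenia"]
    controls = meta.index[meta["diagnosis"] == "control"]
    expr_adj = adjusted.loc[de_probes, cases]
    centroid = adjusted.loc[de_probes, controls].mean(axis=1).to_numpy()
    cfg = scz.SubtypingConfig()
    tom_matrix = scz.tom(scz.subject_adjacency(expr_adj, cfg))
    labels = scz.cluster_subjects(tom_matrix, cfg, expr_adj=expr_adj,
                                  control_centroid=centroid)
    return {
        "study": study,
        "filter_report": report,
        "expr_f": expr_f,
        "meta": meta,
        "de": de,
        "de_probes": de_probes,
        "adjusted": adjusted,
        "expr_adj": expr_adj,
        "centroid": centroid,
        "tom": tom_matrix,
        "labels": labels,
        "truth": study.truth_labels.loc[cases],
        "cases": cases,
        "controls": controls,
    }


@pytest.fixture(scope="session")
def boundary_cohort():
    """Well-separated subtypes plus one planted zero-signature subject.

    The planted subject sits at the point of the segment joining the two
    subtype centroids that carries no net subtype signature (zero
    projection onto the centroid difference), i.e. midway between the
    clusters in the network geometry the clustering actually uses.
    """
    study = scz.simulate_study(scz.SimulationConfig(
        seed=3, n_controls=40, n_type1=20, n_type2=20,
        n_probes=600, n_de_type2=100, effect_mean=2.0))
    expr_f, _ = scz.filter_probes(study.expression, study.detection_pvals,
                                  scz.FilterConfig())
    meta = scz.filter_cohort(study.metadata)
    expr_f = expr_f.loc[:, meta.index]
    de = scz.de_scan(expr_f, meta)
    de_probes = de.index[de["p_bonf"] < 0.05]
    adjusted = scz.covariate_adjust(expr_f, meta)
    cases = meta.index[meta["diagnosis"] == "schizophrenia"]
    truth = study.truth_labels.loc[cases]
    expr_adj = adjusted.loc[de_probes, cases]
    c1 = expr_adj.loc[:, truth == "type1"].mean(axis=1).to_numpy()
    c2 = expr_adj.loc[:, truth == "type2"].mean(axis=1).to_numpy()
    d = c2 - c1
    alpha = float(-(c1 @ d) / (d @ d))
    with_boundary = expr_adj.copy()
    with_boundary["boundary"] = c1 + alpha * d
    return {"expr_adj": with_boundary, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
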