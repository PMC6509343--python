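"""End-to-end pipeline: preprocess -> DE -> subtype -> stability -> graphs
-> per-subtype DE, with every intermediate artifact written to disk and a
machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .diffexpr import ModelSpec, de_scan
from .errors import SczSubtypesError
from .preprocess import (FilterConfig, filter_cohort, filter_probes,
                         log2_transform, quantile_normalize)
from .simulate import config_from_dict, simulate_study
from .stability import grid_summary, stability_grid
from .subtype_de import marker_report, subtype_de_scan
from .subtyping import (SubtypingConfig, cluster_subjects, covariate_adjust,
                        subject_adjacency, tom)
from .tomgraph import component_evolution

__all__ = ["run_pipeline"]

log = logging.getLogger("sczsubtypes")

STAGES = ["preprocess", "diffexpr", "subtyping", "stability", "tomgraph",
          "subtype_de"]


def _write_labels(labels: pd.Series, path: Path) -> None:
    labels.rename("subtype").to_frame().to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage error halts the run with the stage named; artifacts written
    by earlier stages are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sczsubtypes",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "stages": [],
    }
    config.to_yaml(out / "config.yaml")

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_cfg = config_from_dict({**config.simulate,
                                        "seed": config.seed})
            study = simulate_study(sim_cfg)
            expr, detection = study.expression, study.detection_pvals
            metadata, annotation = study.metadata, study.annotation
            io.write_table(study.truth_labels.to_frame(), out / "truth.tsv")
        else:
            expr = io.read_expression(config.inputs["expression"])
            detection = io.read_expression(config.inputs["detection"])
            metadata = io.read_metadata(config.inputs["metadata"])
            annotation = io.read_annotation(config.inputs["annotation"])

        # ---- preprocess -------------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        pp = config.preprocess
        n_nonpos = 0
        if not pp.get("already_log2", True):
            expr, n_nonpos = log2_transform(expr)
        if pp.get("quantile_normalize", True):
            expr = quantile_normalize(expr)
        snp_ids = frozenset(
            annotation.index[annotation.get(
                "snp_in_probe", pd.Series(False, index=annotation.index))])
        fc = FilterConfig(
            detection_alpha=float(pp.get("detection_alpha", 0.05)),
            min_detected_subjects=pp.get("min_detected_subjects", 841 / 849),
            snp_probe_ids=snp_ids,
        )
        expr_f, report = filter_probes(expr, detection, fc)
        metadata_f = filter_cohort(metadata, min_age=pp.get("min_age", 25))
        expr_f = expr_f.loc[:, metadata_f.index]
        io.write_expression(expr_f, out / "expression_filtered.tsv")
        io.write_metadata(metadata_f, out / "metadata_filtered.tsv")
        io.write_table(report.to_frame(), out / "filter_report.tsv",
                       index=False)
        with open(out / "filter_report.json", "w") as fh:
            json.dump({"n_input": report.n_input,
                       "n_removed_na_inf": report.n_removed_na_inf,
                       "n_removed_detection": report.n_removed_detection,
                       "n_removed_snp": report.n_removed_snp,
                       "n_retained": report.n_retained,
                       "n_nonpositive_log2": n_nonpos}, fh, indent=2)
        manifest["stages"].append({"name": stage,
                                   "seconds": round(time.time() - t0, 3)})
        log.info("preprocess: %d/%d probes retained, %d subjects",
                 report.n_retained, report.n_input, metadata_f.shape[0])

        # ---- full-cohort DE scan ---------------------------------------
        stage = "diffexpr"
        t0 = time.time()
        spec = ModelSpec(
            case=config.model.get("case", "schizophrenia"),
            reference=config.model.get("reference", "control"),
            robust_tuning=float(config.model.get("robust_tuning", 5.0)),
        )
        de_table = de_scan(expr_f, metadata_f, spec)
        io.write_table(de_table, out / "de_table.tsv")
        manifest["stages"].append({"name": stage,
                                   "seconds": round(time.time() - t0, 3)})

        # ---- subtyping --------------------------------------------------
        stage = "subtyping"
        t0 = time.time()
        sub = config.subtyping
        alpha = float(sub.get("de_alpha_bonf", 0.05))
        de_probes = de_table.index[de_table["p_bonf"] < alpha]
        if len(de_probes) < 2:
            raise SczSubtypesError(
                f"only {len(de_probes)} DE probes at Bonferroni {alpha}; "
                "cannot build a subject network")
        adjusted = covariate_adjust(expr_f, metadata_f)
        cases = metadata_f.index[metadata_f["diagnosis"] == spec.case]
        controls = metadata_f.index[metadata_f["diagnosis"] == spec.reference]
        expr_adj_de = adjusted.loc[de_probes, cases]
        centroid = adjusted.loc[de_probes, controls].mean(axis=1).to_numpy()
        sub_cfg = SubtypingConfig(
            soft_power=float(sub.get("soft_power", 6.0)),
            network_sign=sub.get("network_sign", "unsigned"),
            n_clusters=int(sub.get("n_clusters", 2)),
        )
        adj = subject_adjacency(expr_adj_de, sub_cfg)
        tom_matrix = tom(adj)
        base_labels = cluster_subjects(tom_matrix, sub_cfg,
                                       expr_adj=expr_adj_de,
                                       control_centroid=centroid)
        io.write_table(tom_matrix, out / "tom.tsv")
        _write_labels(base_labels, out / "labels_base.tsv")
        manifest["stages"].append({"name": stage,
                                   "seconds": round(time.time() - t0, 3)})
        log.info("subtyping: %s", base_labels.value_counts().to_dict())

        # ---- perturbation stability ------------------------------------
        stage = "stability"
        t0 = time.time()
        st = config.stability
        reports = stability_grid(
            expr_adj_de, sub_cfg,
            levels=st.get("levels", [0.0, 0.05, 0.10, 0.25, 0.50]),
            n_runs=int(st.get("n_runs", 100)),
            sd_scope=st.get("sd_scope", "per_probe"),
            seed=config.seed,
            expr_for_orientation=expr_adj_de,
            control_centroid=centroid,
        )
        summary = grid_summary(reports)
        io.write_table(summary, out / "stability_summary.tsv", index=False)
        final = reports[-1]
        per_subject = pd.DataFrame({
            "base": final.base_labels,
            "misclass_count": final.misclass_count,
            "subtype": final.final_labels,
        })
        io.write_table(per_subject, out / "labels_final.tsv")
        manifest["stages"].append({"name": stage,
                                   "seconds": round(time.time() - t0, 3)})
        log.info("stability: %s", summary.to_dict("records"))

        # ---- threshold graphs ------------------------------------------
        stage = "tomgraph"
        t0 = time.time()
        evo = component_evolution(
            tom_matrix, final.final_labels,
            config.graph.get("thresholds", [0.05, 0.08, 0.10, 0.12]))
        with open(out / "graph_evolution.json", "w") as fh:
            json.dump(evo.records, fh, indent=2)
        io.write_table(evo.summary, out / "graph_summary.tsv", index=False)
        manifest["stages"].append({"name": stage,
                                   "seconds": round(time.time() - t0, 3)})

        # ---- per-subtype DE --------------------------------------------
        stage = "subtype_de"
        t0 = time.time()
        criterion = (config.criterion.get("method", "bonferroni"),
                     float(config.criterion.get("alpha", 0.05)))
        de_tables = {}
        subtype_counts = {}
        for subtype in ("type1", "type2"):
            res = subtype_de_scan(expr_f, metadata_f, final.final_labels,
                                  subtype, spec, criterion)
            io.write_table(res.de_table, out / f"de_{subtype}.tsv")
            de_tables[subtype] = res.de_table
            subtype_counts[subtype] = res.n_significant
        markers = marker_report(de_tables, annotation)
        io.write_table(markers, out / "marker_report.tsv", index=False)
        with open(out / "subtype_de_counts.json", "w") as fh:
            json.dump({"criterion": list(criterion),
                       "n_significant": subtype_counts}, fh, indent=2)
        manifest["stages"].append({"name": stage,
                                   "seconds": round(time.time() - t0, 3)})
        log.info("subtype DE significant: %s", subtype_counts)

    except SczSubtypesError as exc:
        raise SczSubtypesError(f"stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
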