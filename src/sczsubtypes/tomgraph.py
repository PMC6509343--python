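"""Threshold graphs over the subject TOM similarity.

Patients are nodes; an edge joins two patients whose transcriptome TOM
similarity reaches an edge threshold.  Sweeping the threshold (in the
spirit of persistence barcodes) shows how the cohort fragments: at low
thresholds one connected component, then the subtypes segregate into
separate subgraphs while isolated nodes split off.  Component counts are
monotone non-decreasing in the threshold and edge counts monotone
non-increasing; both are enforced as checked postconditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["threshold_graph", "component_evolution", "ComponentEvolution"]


def _check_tom(tom_matrix: pd.DataFrame) -> np.ndarray:
    T = np.asarray(tom_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValidationError("TOM matrix must be square")
    if not np.allclose(T, T.T, atol=1e-10):
        raise ValidationError("TOM matrix must be symmetric")
    return T


def threshold_graph(tom_matrix: pd.DataFrame, threshold: float,
                    labels: pd.Series | None = None,
                    strict: bool = False) -> nx.Graph:
    """Graph with an edge wherever TOM >= threshold (or > if ``strict``)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    T = _check_tom(tom_matrix)
    subjects = list(tom_matrix.index)
    g = nx.Graph(threshold=threshold)
    for i, s in enumerate(subjects):
        lab = None if labels is None else labels.get(s)
        g.add_node(s, label=lab)
    iu = np.triu_indices_from(T, k=1)
    keep = (T[iu] > threshold) if strict else (T[iu] >= threshold)
    for a, b in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(subjects[a], subjects[b], tom=float(T[a, b]))
    return g


@dataclass
class ComponentEvolution:
    """Per-threshold component structure of the TOM graph."""

    thresholds: list
    records: list            # one dict per threshold

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"threshold": r["threshold"],
             "n_components": r["n_components"],
             "n_isolated": r["n_isolated"],
             "n_edges": r["n_edges"],
             "largest_component": r["component_sizes"][0]}
            for r in self.records
        ])


def component_evolution(tom_matrix: pd.DataFrame,
                        labels: pd.Series | None,
                        thresholds,
                        strict: bool = False) -> ComponentEvolution:
    """Connected components and their label composition per threshold."""
    thresholds = [float(t) for t in thresholds]
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValidationError("thresholds must lie in [0, 1]")
    order = sorted(thresholds)
    n = tom_matrix.shape[0]

    records = []
    prev_components = 0
    prev_edges = None
    for t in order:
        g = threshold_graph(tom_matrix, t, labels=labels, strict=strict)
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=len, reverse=True)
        sizes = [len(c) for c in comps]
        if sum(sizes) != n:
            raise RuntimeError("component sizes do not sum to node count")
        composition = []
        for comp in comps:
            if labels is None:
                composition.append({"n": len(comp)})
            else:
                counts = labels.loc[comp].value_counts().to_dict()
                counts = {str(k): int(v) for k, v in counts.items()}
                counts["n"] = len(comp)
                composition.append(counts)
        rec = {
            "threshold": t,
            "n_components": len(comps),
            "component_sizes": sizes,
            "n_isolated": sum(1 for s in sizes if s == 1),
            "n_edges": g.number_of_edges(),
            "composition": composition,
        }
        if rec["n_components"] < prev_components:
            raise RuntimeError(
                "component count decreased with increasing threshold")
        if prev_edges is not None and rec["n_edges"] > prev_edges:
            raise RuntimeError(
                "edge count increased with increasing threshold")
        prev_components = rec["n_components"]
        prev_edges = rec["n_edges"]
        records.append(rec)
    return ComponentEvolution(thresholds=order, records=records)
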