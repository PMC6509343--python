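"""Subject-level co-expression network clustering.

Patients are clustered from the expression of a differentially expressed
probe set.  Expression is first adjusted for the nuisance covariates (age,
sex, ethnicity, RIN, batch — never diagnosis), then pairwise subject
similarity is built the weighted-network way: a soft-thresholded
correlation adjacency followed by the topological overlap measure (TOM),
which augments the direct edge weight with shared-neighbour weight and is
less noisy than raw correlation.  The network is signed by default: a
patient group carrying a DE signature is *anti*-correlated with the group
lacking it, and an unsigned network would score that anti-correlation as
similarity and merge the groups.  Hierarchical clustering (Ward by
default; a near-control group is internally diffuse and average linkage
tends to chain it onto the signature-carrying block) of the TOM
dissimilarity, cut at two clusters, yields the subtype labels: "type 1"
is the cluster closer to the control centroid (when a control reference
is supplied), so that "type 2" denotes the transcriptome that departs
from controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

__all__ = [
    "SubtypingConfig", "covariate_adjust", "subject_adjacency", "tom",
    "cluster_subjects",
]


@dataclass(frozen=True)
class SubtypingConfig:
    """Network construction and tree-cut settings.

    ``soft_power`` is the exponent applied to subject–subject correlations
    (unsigned: |r|^beta; signed: ((1+r)/2)^beta).  ``probe_set`` restricts
    the correlation to a chosen probe list (typically the DE probes from the
    full-cohort scan); ``None`` uses all probes.
    """

    probe_set: tuple | None = None
    soft_power: float = 6.0
    network_sign: str = "signed"
    linkage_method: str = "ward"
    n_clusters: int = 2

    def validate(self) -> None:
        if self.soft_power < 1:
            raise ValidationError("soft_power must be >= 1")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValidationError(
                f"network_sign must be 'unsigned' or 'signed', got "
                f"{self.network_sign!r}")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")


def covariate_adjust(expr: pd.DataFrame, metadata: pd.DataFrame,
                     covariates: tuple = ("age", "sex", "ethnicity", "rin"),
                     batch_col: str | None = "batch") -> pd.DataFrame:
    """Residualize every probe on the nuisance covariates (not diagnosis).

    Least-squares residuals against intercept + covariates (+ batch
    dummies); exact orthogonality to the adjusted covariates.
    """
    if not expr.columns.equals(metadata.index):
        raise ValidationError("expression columns and metadata index differ")
    cols = [np.ones(len(metadata))]
    for cov in covariates:
        if cov not in metadata:
            raise ValidationError(f"covariate '{cov}' missing from metadata")
        col = metadata[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
        else:
            d = pd.get_dummies(col, drop_first=True)
            cols.extend(d[c].to_numpy(float) for c in d.columns)
    if batch_col is not None and batch_col in metadata:
        d = pd.get_dummies(metadata[batch_col].astype(str), drop_first=True)
        cols.extend(d[c].to_numpy(float) for c in d.columns)
    X = np.column_stack(cols)

    Y = expr.to_numpy(dtype=float).T        # subjects x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)


def subject_adjacency(expr_adj: pd.DataFrame,
                      config: SubtypingConfig = SubtypingConfig()
                      ) -> pd.DataFrame:
    """Soft-thresholded subject x subject adjacency with zero diagonal."""
    config.validate()
    data = expr_adj
    if config.probe_set is not None:
        missing = set(config.probe_set) - set(expr_adj.index)
        if missing:
            raise ValidationError(
                f"probe_set contains unknown probes: {sorted(missing)[:5]}")
        if len(config.probe_set) == 0:
            raise ValidationError("probe_set must be non-empty")
        data = expr_adj.loc[list(config.probe_set)]
    if data.shape[1] < 3 or data.shape[0] < 2:
        raise ValidationError(
            "need at least 3 subjects and 2 probes for adjacency, got "
            f"{data.shape[0]} probes x {data.shape[1]} subjects")
    vals = data.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        j = data.columns[int(np.argmin(sd))]
        raise ValidationError(f"subject '{j}' has zero expression variance")
    cor = np.corrcoef(vals, rowvar=False)
    if config.network_sign == "unsigned":
        adj = np.abs(cor) ** config.soft_power
    else:
        adj = ((1.0 + cor) / 2.0) ** config.soft_power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=data.columns, columns=data.columns)


def tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap of a weighted network.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    k_i the weighted connectivity; diagonal is 1.  Values stay in [0, 1]
    for a valid adjacency (symmetric, entries in [0, 1], zero diagonal).
    """
    is_frame = isinstance(adjacency, pd.DataFrame)
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if np.any(A < 0) or np.any(A > 1):
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if np.any(np.abs(np.diag(A)) > 1e-12):
        raise ValidationError("adjacency diagonal must be zero")

    k = A.sum(axis=1)
    shared = A @ A                        # diag(A)=0, so u != i, j terms only
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    if is_frame:
        return pd.DataFrame(T, index=adjacency.index,
                            columns=adjacency.columns)
    return T


def cluster_subjects(tom_matrix: pd.DataFrame,
                     config: SubtypingConfig = SubtypingConfig(),
                     expr_adj: pd.DataFrame | None = None,
                     control_centroid=None) -> pd.Series:
    """Hierarchical clustering of 1 - TOM, cut into ``n_clusters``.

    Cluster naming: with a control reference (``expr_adj`` holding the
    patients' adjusted expression and ``control_centroid`` the per-probe
    control mean), clusters are ordered by their mean Euclidean distance to
    the control centroid — the closest becomes "type1".  Without a
    reference, the cluster with the larger mean within-cluster TOM (more
    cohesive) is "type1" and the less cohesive is "type2".  Deterministic
    given its inputs.
    """
    config.validate()
    subjects = list(tom_matrix.index)
    n = len(subjects)
    if n < config.n_clusters:
        raise ValidationError(
            f"{n} subjects cannot form {config.n_clusters} clusters")
    T = np.asarray(tom_matrix, dtype=float)
    D = 1.0 - (T + T.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    link = linkage(squareform(D, checks=False), method=config.linkage_method)
    assign = fcluster(link, t=config.n_clusters, criterion="maxclust")

    clusters = sorted(set(assign))
    if control_centroid is not None and expr_adj is not None:
        centroid = np.asarray(control_centroid, dtype=float)
        V = expr_adj.loc[:, subjects].to_numpy(dtype=float)
        dist = np.linalg.norm(V - centroid[:, None], axis=0)
        key = {c: float(np.mean(dist[assign == c])) for c in clusters}
    else:
        key = {}
        for c in clusters:
            members = np.where(assign == c)[0]
            if len(members) < 2:
                key[c] = -1.0            # singleton: maximally cohesive
            else:
                sub = T[np.ix_(members, members)]
                off = sub[~np.eye(len(members), dtype=bool)]
                key[c] = -float(off.mean())
    order = sorted(clusters, key=lambda c: (key[c], c))
    rename = {c: f"type{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in assign],
                       index=pd.Index(subjects, name="sample_id"),
                       name="subtype")
    return labels
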