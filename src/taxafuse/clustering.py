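"""Density-based clustering of collinear effective features.

Feature columns of the (auto-scaled) rule matrix are the points; DBSCAN with
minpts = 2 groups columns whose Euclidean distance is below eps, which for
that minpts is exactly the connected components of the eps-neighbourhood graph
(isolated columns are noise). Each cluster is collapsed to a single column:
the linear combination of its members weighted by the first principal-
component loading. Epsilon is chosen by an ascending grid search that stops at
the first value whose collapsed design matrix is free of aliased (linearly
dependent) columns — the condition under which a GLM would report NA
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .anfis import InferredMatrix

__all__ = [
    "NOISE",
    "ClusterAssignment",
    "ClusteredMatrix",
    "dbscan_features",
    "collapse_clusters",
    "detect_aliased_columns",
    "select_epsilon",
]

NOISE = -1  # marker for unclustered (noise) features


@dataclass
class ClusterAssignment:
    """feature index → cluster id (1-based) or NOISE, plus the parameters used."""

    labels: np.ndarray         # per-feature cluster id, NOISE for noise
    eps: float
    minpts: int

    def members(self) -> dict[int, list[int]]:
        """cluster id → member feature indices (noise excluded)."""
        out: dict[int, list[int]] = {}
        for i, lab in enumerate(self.labels):
            if lab != NOISE:
                out.setdefault(int(lab), []).append(i)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(int(x) for x in self.labels if x != NOISE))


@dataclass
class ClusteredMatrix:
    """Collapsed-feature matrix with per-cluster loadings and provenance."""

    values: np.ndarray                       # effective samples × reduced features
    column_names: list[str]
    loadings: dict[str, dict[str, float]]    # reduced column → {feature: coefficient}
    provenance: dict[str, list[str]]         # reduced column → original features

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def dbscan_features(matrix: np.ndarray, eps: float, minpts: int = 2) -> ClusterAssignment:
    """Cluster feature *columns* of ``matrix`` with DBSCAN (Euclidean).

    With minpts = 2 every non-isolated point is a core point, so the clusters
    are the connected components of the eps-neighbourhood graph.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    points = np.asarray(matrix, dtype=float).T      # features as points
    raw = DBSCAN(eps=eps, min_samples=minpts).fit_predict(points)
    labels = np.where(raw < 0, NOISE, raw + 1)      # 1-based cluster ids
    return ClusterAssignment(labels=labels, eps=float(eps), minpts=minpts)


def _first_pc_loading(block: np.ndarray) -> np.ndarray:
    """Unit-norm leading eigenvector of the covariance of ``block`` columns,
    sign-fixed so its largest-magnitude entry is positive. Zero-variance
    blocks fall back to uniform 1/sqrt(k) loadings."""
    k = block.shape[1]
    centred = block - block.mean(axis=0)
    if np.allclose(centred, 0.0):
        warnings.warn("zero-variance cluster: uniform loadings used", stacklevel=3)
        return np.full(k, 1.0 / np.sqrt(k))
    cov = np.cov(centred, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    v = eigvecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def collapse_clusters(
    matrix: np.ndarray,
    assignment: ClusterAssignment,
    feature_names: list[str] | None = None,
) -> ClusteredMatrix:
    """Replace each cluster's columns by their first-PC linear combination;
    noise columns pass through verbatim with loading 1."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if len(assignment.labels) != p:
        raise ValueError("assignment must cover every feature column")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]

    columns: list[np.ndarray] = []
    names: list[str] = []
    loadings: dict[str, dict[str, float]] = {}
    provenance: dict[str, list[str]] = {}

    members = assignment.members()
    emitted_clusters: set[int] = set()
    for j in range(p):
        lab = int(assignment.labels[j])
        if lab == NOISE:
            name = feature_names[j]
            columns.append(matrix[:, j])
            names.append(name)
            loadings[name] = {name: 1.0}
            provenance[name] = [name]
        elif lab not in emitted_clusters:
            emitted_clusters.add(lab)
            idx = members[lab]
            block = matrix[:, idx]
            v = _first_pc_loading(block)
            name = f"cluster_{lab}"
            columns.append(block @ v)
            names.append(name)
            loadings[name] = {feature_names[i]: float(c) for i, c in zip(idx, v)}
            provenance[name] = [feature_names[i] for i in idx]
    return ClusteredMatrix(
        values=np.column_stack(columns) if columns else np.empty((n, 0)),
        column_names=names,
        loadings=loadings,
        provenance=provenance,
    )


def detect_aliased_columns(design: np.ndarray, tol: float = 1e-7) -> set[int]:
    """Indices of columns linearly dependent on *preceding* columns.

    Sequential orthogonalisation: a column whose residual after projection on
    the span of the previous independent columns falls below ``tol`` times the
    largest column norm is aliased (for a duplicated pair, the later column is
    the one flagged). Empty set iff the design has full column rank.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[0] < 1:
        raise ValueError("design must be a non-empty 2-D matrix")
    n, p = design.shape
    scale = np.sqrt((design**2).sum(axis=0)).max() if p else 0.0
    threshold = tol * max(scale, 1.0)
    basis: list[np.ndarray] = []
    aliased: set[int] = set()
    for j in range(p):
        v = design[:, j].copy()
        for q in basis:
            v -= (q @ design[:, j]) * q
        # second orthogonalisation pass for numerical stability
        for q in basis:
            v -= (q @ v) * q
        norm = np.linalg.norm(v)
        if norm <= threshold:
            aliased.add(j)
        else:
            basis.append(v / norm)
    return aliased


def select_epsilon(
    inferred: InferredMatrix,
    labels: np.ndarray | None = None,
    grid: list[float] | None = None,
    minpts: int = 2,
    tol: float = 1e-7,
) -> tuple[float, ClusterAssignment, ClusteredMatrix]:
    """Ascending eps grid search with the aliased-coefficient stopping rule.

    The default grid runs from 1 to the maximum entry of the *integer* rule
    matrix in steps of 0.5; distances are measured on the auto-scaled columns.
    At each eps the features are clustered and collapsed, a (multinomial)
    logistic regression of the effective labels on the collapsed matrix is
    fitted, and the collapsed design (with intercept) is checked for aliased
    columns; the first eps with none is returned. If no grid value qualifies
    the final one is returned with a warning.
    """
    if labels is None:
        labels = inferred.effective_label
    labels = np.asarray(labels)
    if grid is None:
        top = float(inferred.values.max())
        grid = list(np.arange(1.0, top + 1e-9, 0.5)) or [1.0]
    if len(grid) == 0:
        raise ValueError("eps grid must be non-empty")

    X = inferred.scaled_features
    names = inferred.feature_names
    last: tuple[float, ClusterAssignment, ClusteredMatrix] | None = None
    for eps in grid:
        assignment = dbscan_features(X, eps=float(eps), minpts=minpts)
        clustered = collapse_clusters(X, assignment, names)
        design = np.column_stack([np.ones(X.shape[0]), clustered.values])
        aliased = detect_aliased_columns(design, tol=tol)
        last = (float(eps), assignment, clustered)
        if not aliased:
            _fit_logistic(clustered.values, labels)
            return last
    warnings.warn(
        "no eps on the grid removed all aliased columns; returning the final grid value",
        stacklevel=2,
    )
    return last


def _fit_logistic(X: np.ndarray, labels: np.ndarray) -> LogisticRegression | None:
    """Multinomial (binary for two classes) logistic fit of labels on the
    collapsed matrix; recorded for diagnostics only — the aliasing decision
    is taken by the rank check."""
    if len(np.unique(labels)) < 2 or X.shape[1] == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LogisticRegression(max_iter=200)
        model.fit(X, labels)
    return model
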