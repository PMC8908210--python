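"""Pattern-recognition stages: Pareto scaling, PCA, hierarchical
clustering, and OPLS-DA-derived variable importance (VIP).

Matrices follow the package-wide orientation of features x samples;
samples are the statistical observations, so every routine transposes
internally.  The OPLS-DA here is the Trygg-Wold style orthogonal signal
correction: class-orthogonal components are deflated from X before a
single predictive PLS component is fitted, and VIP is computed on the
predictive component with the usual normalization mean(VIP^2) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class ScaledMatrix:
    """Pareto-scaled values plus the factors needed to invert the scaling.

    Recomposition ``value * scale + mean`` reproduces the input (zero
    variance features, whose scale is undefined, are emitted as zeros and
    listed on ``zero_variance``; their recomposition is the constant
    mean, i.e. still exact).
    """

    values: pd.DataFrame
    means: pd.Series
    scales: pd.Series
    zero_variance: tuple[str, ...] = ()

    def recompose(self) -> pd.DataFrame:
        return self.values.mul(self.scales, axis=0).add(self.means, axis=0)


@dataclass
class LatentModel:
    """Scores/loadings decomposition from PCA or (O)PLS-DA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray  # fractions of total variance
    class_labels: pd.Series | None = None
    vip: pd.Series | None = None
    n_orthogonal: int = 0


@dataclass
class Dendrogram:
    """Agglomerative merge list (scipy linkage matrix) over labeled items."""

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            bl = node.dist - left.dist
            br = node.dist - right.dist
            return f"({render(left)}:{bl:.6g},{render(right)}:{br:.6g})"

        return render(tree) + ";"


# ---------------------------------------------------------------------------


def pareto_scale(data: pd.DataFrame, missing: str = "error") -> ScaledMatrix:
    """Per-feature centering and division by the square root of the
    sample standard deviation.

    Pareto scaling is the metabolomics compromise between no scaling
    (large peaks dominate) and unit-variance scaling (noise inflation).
    Missing cells are rejected by default; ``missing="mean"`` or
    ``"halfmin"`` imputes with the feature mean or half the feature
    minimum before scaling.
    """
    if data.shape[1] < 2:
        raise ValueError("pareto scaling needs at least 2 samples")
    data = data.astype(float)
    if data.isna().any().any():
        if missing == "error":
            raise ValueError("matrix contains missing cells; impute or filter first")
        if missing == "mean":
            data = data.apply(lambda row: row.fillna(row.mean()), axis=1)
        elif missing == "halfmin":
            data = data.apply(lambda row: row.fillna(row.min() / 2.0), axis=1)
        else:
            raise ValueError(f"unknown missing policy: {missing!r}")
    means = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    scales = np.sqrt(sd)
    zero = scales[scales == 0].index
    safe = scales.replace(0, 1.0)
    values = data.sub(means, axis=0).div(safe, axis=0)
    values.loc[zero] = 0.0
    return ScaledMatrix(values, means, scales, tuple(zero))


def pca(data: pd.DataFrame, n_components: int = 2) -> LatentModel:
    """PCA of samples via SVD of the feature-centered matrix.

    Signs are fixed deterministically by making each loading vector's
    largest-magnitude entry positive.  Explained-variance fractions are
    singular values squared over their total, so retaining all components
    sums to 1.
    """
    X = data.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains non-finite values")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (S[0] if S.size else 0)
    rank = int(np.sum(S > tol))
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    evr = (S**2 / np.sum(S**2))[:n_components] if S.size else np.zeros(0)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * S[:n_components]), index=data.columns, columns=comps
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=data.index, columns=comps)
    return LatentModel(scores, loadings, evr)


def hcluster(
    data: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the samples (columns).

    Items are ordered lexicographically by identifier before linkage so
    the merge list is invariant to input column order; scipy's linkage is
    deterministic given that ordering.
    """
    if data.shape[1] < 2:
        raise ValueError("clustering needs at least 2 items")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    labels = tuple(sorted(map(str, data.columns)))
    X = data[list(labels)].to_numpy(dtype=float).T
    if distance == "euclidean":
        D = pdist(X, metric="euclidean")
    elif distance == "correlation":
        D = pdist(X, metric="correlation")  # 1 - Pearson r
    else:
        raise ValueError(f"unsupported distance: {distance!r}")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances (missing values?)")
    Z = hierarchy.linkage(D, method=linkage)
    return Dendrogram(labels, Z)


# ---------------------------------------------------------------------------
# OPLS-DA


def _class_vector(columns, class_labels) -> tuple[np.ndarray, pd.Series]:
    if isinstance(class_labels, Mapping):
        labels = pd.Series([class_labels[c] for c in columns], index=columns)
    else:
        labels = pd.Series(list(class_labels), index=columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    y = np.where(labels.to_numpy() == classes[1], 1.0, -1.0)
    return y, labels


def oplsda_vip(
    data: pd.DataFrame,
    class_labels,
    n_orthogonal: int = 1,
) -> LatentModel:
    """OPLS-DA with one predictive component and VIP scores.

    ``data`` is features x samples, ideally Pareto-scaled upstream;
    columns are centered here in any case.  ``class_labels`` maps (or
    lists, column-aligned) each sample to one of exactly two classes.
    Up to ``n_orthogonal`` class-orthogonal components are deflated from
    X before the predictive component is extracted.  VIP over the single
    predictive component reduces to ``sqrt(p) * |w|`` with the weight
    vector normalized, which guarantees mean(VIP^2) = 1.
    """
    y_raw, labels = _class_vector(data.columns, class_labels)
    X = data.to_numpy(dtype=float).T  # samples x features
    if not np.all(np.isfinite(X)):
        raise ValueError("OPLS-DA input contains non-finite values")
    X = X - X.mean(axis=0, keepdims=True)
    y = y_raw - y_raw.mean()
    total_var = np.sum(X**2)

    ortho_scores, ortho_loads, n_ortho_fit = [], [], 0
    for _ in range(max(0, n_orthogonal)):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nwo = np.linalg.norm(w_o)
        if nwo < 1e-12:
            break  # no orthogonal variation left
        w_o /= nwo
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        ortho_scores.append(t_o)
        ortho_loads.append(p_o)
        n_ortho_fit += 1

    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("class vector is orthogonal to the data")
    w /= nw
    t = X @ w
    p_load = X.T @ t / (t @ t)

    n_features = data.shape[0]
    vip = np.sqrt(n_features) * np.abs(w)

    comps = ["predictive"] + [f"orthogonal{i + 1}" for i in range(n_ortho_fit)]
    scores = pd.DataFrame(
        np.column_stack([t] + ortho_scores), index=data.columns, columns=comps
    )
    loadings = pd.DataFrame(
        np.column_stack([p_load] + ortho_loads), index=data.index, columns=comps
    )
    var_fracs = np.array(
        [np.sum(s**2 * np.sum(l**2)) / total_var
         for s, l in zip([t] + ortho_scores, [p_load] + ortho_loads)]
    )
    return LatentModel(
        scores=scores,
        loadings=loadings,
        explained_variance=var_fracs,
        class_labels=labels,
        vip=pd.Series(vip, index=data.index, name="vip"),
        n_orthogonal=n_ortho_fit,
    )
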