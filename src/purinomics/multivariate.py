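"""Supervised and unsupervised multivariate analysis of z-score matrices.

Implements partial least squares discriminant analysis (PLSDA) by NIPALS
with variable-importance-in-projection (VIP) scores, PCA explained-variance
fractions, Ward/Euclidean dendrograms with newick export, and bagged-tree
permutation importance (mean decrease in accuracy, MDA).

The PLSDA response is a centered one-hot group encoding; for two groups
this reduces to +/-1 coding.  No autoscaling is applied on top of the
control-SD z matrix — the z-scoring step is the single normalization
authority — but predictors and response are mean-centered, as the latent
variable extraction requires.

VIP convention: with unit-norm weight vectors w_a and SS_a the response
sum of squares explained by component a,

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a )

so the mean squared VIP over variables is exactly 1 on every fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.tree import DecisionTreeClassifier

from .preprocess import ZScoreMatrix

#: NIPALS convergence tolerance on the weight vector and iteration cap.
NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class PLSDAModel:
    """Fitted PLSDA decomposition.

    weights: p x A matrix of unit-norm w_a; scores: n x A t_a;
    x_loadings: p x A; y_loadings: q x A; ss: length-A response sum of
    squares explained per component; vip: per-variable VIP (index =
    variable names); explained_y: SS_a as a fraction of total response SS.
    """

    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ss: np.ndarray
    vip: pd.Series
    explained_y: np.ndarray
    variables: pd.Index
    group_levels: list
    x_mean: np.ndarray


def _one_hot(groups: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(groups))
    Y = np.zeros((len(groups), len(levels)))
    for j, g in enumerate(levels):
        Y[np.asarray(groups == g), j] = 1.0
    return Y, levels


def plsda_fit(z, groups: pd.Series, n_components: int = 2) -> PLSDAModel:
    """Fit PLSDA by NIPALS on a z matrix against group membership.

    Components are extracted iteratively; the predictor matrix is deflated
    after each component so scores of distinct components are orthogonal.
    Convergence: weight-vector change < 1e-10 or 500 iterations.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    if isinstance(z, ZScoreMatrix) and not isinstance(groups, pd.Series):
        groups = z.groups
    X = zdf.to_numpy(dtype=float)
    n, p = X.shape
    if n < n_components + 2:
        raise ValueError(f"n = {n} too small for {n_components} components")
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    Y, levels = _one_hot(pd.Series(np.asarray(groups)))
    x_mean = X.mean(axis=0)
    X = X - x_mean
    Y = Y - Y.mean(axis=0)
    if not np.any(X != 0):
        raise ValueError("constant predictor matrix; nothing to decompose")
    ss_y_total = float((Y**2).sum())
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    ss = np.zeros(n_components)
    Xa, Ya = X.copy(), Y.copy()
    for a in range(n_components):
        u = Ya[:, np.argmax((Ya**2).sum(axis=0))].copy()
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = Xa.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError(f"component {a + 1}: degenerate weight vector")
            w_new /= norm
            t = Xa @ w_new
            tt = float(t @ t)
            if tt == 0:
                raise ValueError(f"component {a + 1}: zero-variance score")
            q = Ya.T @ t / tt
            qq = float(q @ q)
            u = (Ya @ q / qq) if qq > 0 else u
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xa @ w
        tt = float(t @ t)
        p_load = Xa.T @ t / tt
        q = Ya.T @ t / tt
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_load, q
        ss[a] = tt * float(q @ q)  # response SS captured by this component
        Xa = Xa - np.outer(t, p_load)
        Ya = Ya - np.outer(t, q)
    if ss.sum() == 0:
        raise ValueError("model explains no response variance")
    vip = pd.Series(
        np.sqrt(p * (W**2 @ ss) / ss.sum()), index=zdf.columns, name="vip"
    )
    return PLSDAModel(
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=Q,
        ss=ss,
        vip=vip,
        explained_y=ss / ss_y_total if ss_y_total > 0 else ss,
        variables=zdf.columns,
        group_levels=levels,
        x_mean=x_mean,
    )


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Per-variable VIP scores of a fitted PLSDA model."""
    if model.ss.sum() == 0:
        raise ValueError("zero total explained response SS; VIP undefined")
    return model.vip


def pca_variance_explained(z, n_components: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Explained-variance fractions of the principal components of z.

    Returns (fractions, cumulative fractions); fractions are non-increasing
    and sum to at most 1.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    X = zdf.to_numpy(dtype=float)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    frac = pca.explained_variance_ratio_
    return frac, np.cumsum(frac)


def ward_dendrogram(z, axis: str = "metabolites"
                    ) -> tuple[np.ndarray, list[str]]:
    """Euclidean/Ward agglomerative merge tree over samples or metabolites.

    Returns the scipy linkage matrix and the leaf labels.  Merge heights
    are non-decreasing (a property of Ward linkage).
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    if axis == "metabolites":
        data, labels = zdf.T.to_numpy(dtype=float), list(zdf.columns)
    elif axis == "samples":
        data, labels = zdf.to_numpy(dtype=float), list(zdf.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'metabolites', got {axis!r}")
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    linkage = hierarchy.linkage(data, method="ward", metric="euclidean")
    return linkage, labels


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            name = str(labels[node.id]).replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class ImportanceResult:
    """Permutation importance from a bagged-tree classifier."""

    mda: pd.Series
    n_trees: int
    seed: int
    oob_accuracy: float


def ensemble_mda(z, groups: pd.Series, n_trees: int = 200, seed: int = 0
                 ) -> ImportanceResult:
    """Mean decrease in accuracy over out-of-bag permutations.

    A bagged forest of unpruned decision trees is grown on bootstrap
    samples; for each tree and variable, the variable's out-of-bag values
    are permuted and MDA_j is the mean drop in out-of-bag accuracy.  Fixed
    seed gives a fixed result.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    if isinstance(z, ZScoreMatrix) and not isinstance(groups, pd.Series):
        groups = z.groups
    X = zdf.to_numpy(dtype=float)
    y, levels = pd.factorize(pd.Series(np.asarray(groups)), sort=True)
    if len(levels) < 2:
        raise ValueError("single class; MDA undefined")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    max_feat = max(1, int(np.sqrt(p)))
    drops = np.zeros(p)
    counts = np.zeros(p)
    oob_accs = []
    for b in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or np.unique(y[boot]).size < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_feat, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        X_oob = X[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y[oob]))
        oob_accs.append(base_acc)
        for j in range(p):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            perm_acc = float(np.mean(tree.predict(X_perm) == y[oob]))
            drops[j] += base_acc - perm_acc
            counts[j] += 1
    if not oob_accs:
        raise ValueError("no tree had out-of-bag samples; increase n_trees or n")
    mda = pd.Series(drops / np.maximum(counts, 1), index=zdf.columns, name="mda")
    return ImportanceResult(
        mda=mda, n_trees=n_trees, seed=seed, oob_accuracy=float(np.mean(oob_accs))
    )
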