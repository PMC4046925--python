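"""Compositional dissimilarity, group-difference testing, ordination and
convex-hull overlap.

Bray--Curtis distances on relative abundances feed ANOSIM / PERMANOVA
permutation tests of timepoint differences; Gower distances feed PCoA;
constrained correspondence analysis (CCA) ordinates chi-square standardized
composition against a metadata factor.  Convex hulls of each group on the
first two ordination axes quantify between-timepoint dissimilarity as one
minus the intersection-over-union of hull areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from shapely.geometry import MultiPoint
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x_i - y_i| / sum(x_i + y_i)
    between samples (columns)."""
    df = getattr(table, "proportions", None)
    if df is None:
        df = getattr(table, "counts", table)
    X = df.to_numpy(dtype=float).T
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("zero-sum sample in Bray-Curtis input")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis"), checks=False), ids=list(df.columns))


def gower_matrix(table) -> DistanceMatrix:
    """Gower distance: mean over features of range-normalized absolute
    differences.  Zero-range features are dropped with a warning."""
    df = getattr(table, "proportions", None)
    if df is None:
        df = getattr(table, "counts", table)
    X = df.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rng_ = X.max(axis=0) - X.min(axis=0)
    keep = rng_ > 0
    if not keep.all():
        logger.warning("gower: dropping %d zero-range feature(s)", (~keep).sum())
    if not keep.any():
        raise ValueError("all features have zero range")
    Xn = X[:, keep] / rng_[keep]
    D = squareform(pdist(Xn, metric="cityblock") / keep.sum(), checks=False)
    return DistanceMatrix(D, ids=list(df.columns))


# ---------------------------------------------------------------------------
# ANOSIM / PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int
    r_between: float
    r_within: float


def _anosim_r(ranks: np.ndarray, between: np.ndarray) -> tuple[float, float, float]:
    m = ranks.size
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return (rb - rw) / (m / 2.0), rb, rw


def _condensed_between(groups: np.ndarray) -> np.ndarray:
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    return groups[iu[0]] != groups[iu[1]]


def _check_groups(groups: np.ndarray) -> None:
    labs, counts = np.unique(groups, return_counts=True)
    if len(labs) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        bad = labs[counts.argmin()]
        raise ValueError(f"group {bad!r} has fewer than 2 samples")


def anosim(
    dist: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> AnosimResult:
    """Analysis of similarities on tied-ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    M = n(n-1)/2; the permutation p-value uses the (1+b)/(1+m) estimator.
    """
    groups = np.asarray(list(groups))
    _check_groups(groups)
    D = dist.data
    n = D.shape[0]
    ranks = rankdata(D[np.triu_indices(n, k=1)])  # midranks
    between = _condensed_between(groups)
    r_obs, rb, rw = _anosim_r(ranks, between)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        r_perm, _, _ = _anosim_r(ranks, _condensed_between(perm))
        if r_perm >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(float(r_obs), float(p), n_permutations, seed, float(rb), float(rw))


def pairwise_anosim(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """One ANOSIM per unordered group pair, with multiplicity-adjusted p."""
    groups = np.asarray(list(groups))
    ids = np.asarray(dist.ids)
    labels = sorted(set(groups), key=list(groups).index)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            mask = (groups == a) | (groups == b)
            sub = dist.filter(ids[mask])
            res = anosim(sub, groups[mask], n_permutations=n_permutations, seed=seed)
            rows.append({"group_a": a, "group_b": b, "R": res.R, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    return out


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    seed: int


def _permanova_stats(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    labs = np.unique(groups)
    for g in labs:
        idx = np.where(groups == g)[0]
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(labs)
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    dist: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """Permutational multivariate analysis of variance (pseudo-F on squared
    distances), with the (1+b)/(1+m) permutation p-value."""
    groups = np.asarray(list(groups))
    _check_groups(groups)
    D2 = dist.data ** 2
    f_obs, r2 = _permanova_stats(D2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_stats(D2, rng.permutation(groups))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, seed)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    method: str                       # "pcoa" or "cca"
    coordinates: pd.DataFrame         # samples x axes
    eigenvalues: np.ndarray           # sorted descending
    proportion_explained: np.ndarray  # share of total variation, percent
    total_inertia: float | None = None
    constrained_inertia: float | None = None
    #: CCA only: axis shares of the constrained (canonical) inertia, percent.
    proportion_constrained: np.ndarray | None = None
    biplot_scores: pd.DataFrame | None = None


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates: eigendecomposition of the double-centered
    -D^2/2 matrix.  Coordinates are scaled by sqrt(eigenvalue); negative
    eigenvalues are reported untouched and excluded from axis shares."""
    D = dist.data
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(D, 0):
        raise ValueError("all distances are zero")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    share = np.zeros_like(vals)
    share[: pos.sum()] = 100.0 * vals[pos] / vals[pos].sum()
    axes = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        method="pcoa",
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=axes),
        eigenvalues=vals,
        proportion_explained=share,
        total_inertia=float(vals[pos].sum()),
    )


def design_matrix(factor) -> pd.DataFrame:
    """Dummy-coded (full-rank, drop-first) design matrix for one factor."""
    s = pd.Series(list(factor))
    dummies = pd.get_dummies(s, drop_first=True, dtype=float)
    if dummies.shape[1] == 0:
        raise ValueError("constraint factor is constant")
    return dummies


def cca(table, constraints) -> OrdinationResult:
    """Canonical correspondence analysis.

    The count table (features x samples) is converted to chi-square
    standardized residuals; the residual matrix is projected, with sample
    weights, onto the constraint space spanned by the factor design, and the
    projection is decomposed by SVD.  Axis shares are reported against both
    the total inertia and the constrained (canonical) inertia.
    """
    df = getattr(table, "counts", None)
    if df is None:
        df = getattr(table, "proportions", table)
    F = df.to_numpy(dtype=float).T  # samples x features
    if np.any(F.sum(axis=1) == 0) or np.any(F.sum(axis=0) == 0):
        raise ValueError("CCA input has an all-zero row or column")
    if isinstance(constraints, pd.DataFrame):
        X = constraints.to_numpy(dtype=float)
        constraint_names = list(constraints.columns)
    else:
        dm = design_matrix(constraints)
        X, constraint_names = dm.to_numpy(), list(dm.columns)

    total = F.sum()
    P = F / total
    r = P.sum(axis=1)          # sample (row) weights
    c = P.sum(axis=0)          # feature (column) weights
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((Q ** 2).sum())

    # weighted centering of the design, then weighted least-squares projection
    Xc = X - (r @ X)[None, :]
    Xw = Xc * np.sqrt(r)[:, None]
    if np.linalg.matrix_rank(Xw) == 0:
        raise ValueError("constraints confounded with a constant")
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    Qhat = H @ Q
    U, S, Vt = np.linalg.svd(Qhat, full_matrices=False)
    eig = S ** 2
    keep = eig > 1e-12
    eig = eig[keep]
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    constrained = float(eig.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        site = (U * S) / np.sqrt(r)[:, None]
    axes = [f"CCA{i+1}" for i in range(len(eig))]
    biplot = pd.DataFrame(
        np.linalg.pinv(Xw) @ U, index=constraint_names, columns=axes
    )
    return OrdinationResult(
        method="cca",
        coordinates=pd.DataFrame(site, index=list(df.columns), columns=axes),
        eigenvalues=eig,
        proportion_explained=100.0 * eig / total_inertia,
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        proportion_constrained=100.0 * eig / constrained,
        biplot_scores=biplot,
    )


# ---------------------------------------------------------------------------
# Convex hulls
# ---------------------------------------------------------------------------

@dataclass
class HullDissimilarity:
    group_a: str
    group_b: str
    area_a: float
    area_b: float
    overlap_area: float
    union_area: float
    dissimilarity: float


def hull_dissimilarity(ordination: OrdinationResult, groups) -> list[HullDissimilarity]:
    """Pairwise 1 - intersection/union of group convex hulls on the first
    two ordination axes.  Groups with fewer than 3 non-collinear points are
    an error."""
    coords = ordination.coordinates.iloc[:, :2].to_numpy()
    groups = np.asarray(list(groups))
    labels = sorted(set(groups), key=list(groups).index)
    hulls = {}
    for g in labels:
        pts = coords[groups == g]
        if len(pts) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if hull.geom_type != "Polygon" or hull.area == 0:
            raise ValueError(f"group {g!r} is degenerate (collinear points)")
        hulls[g] = hull
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            inter = hulls[a].intersection(hulls[b]).area
            union = hulls[a].union(hulls[b]).area
            out.append(
                HullDissimilarity(
                    a, b, hulls[a].area, hulls[b].area, inter, union, 1.0 - inter / union
                )
            )
    return out


def hulls_from_points(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Dissimilarity 1 - IoU between the convex hulls of two point sets."""
    ha = MultiPoint([tuple(p) for p in points_a]).convex_hull
    hb = MultiPoint([tuple(p) for p in points_b]).convex_hull
    return 1.0 - ha.intersection(hb).area / ha.union(hb).area
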