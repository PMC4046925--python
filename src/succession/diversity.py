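"""Alpha diversity: rarefaction, richness/diversity estimation, temporal
trend regression, and bootstrap clustering of per-individual profiles.

Richness is summarized by the observed genus count N and the Chao1
estimator (classic and bias-corrected); diversity by the Shannon index in
natural-log units.  Temporal trends are tested with a Poisson GLM (log
link) for richness and a beta regression (logit mean link) for the Shannon
index mapped into (0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from .abundance_io import AbundanceTable, TIMEPOINT_WEEKS


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column is drawn from the multivariate hypergeometric distribution
    on its count vector, so features absent before rarefaction stay absent.
    """
    depth = int(depth)
    totals = table.sample_totals()
    low = totals[totals < depth]
    if len(low):
        raise ValueError(
            f"sample {low.index[0]!r} has only {low.iloc[0]} reads (< depth {depth})"
        )
    rng = np.random.default_rng(seed)
    cols = {}
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            cols[s] = col.copy()
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    return AbundanceTable(pd.DataFrame(cols, index=table.feature_ids))


def auto_depth(table: AbundanceTable) -> int:
    """Default rarefaction depth: the minimum sample total in the table."""
    return int(table.sample_totals().min())


# ---------------------------------------------------------------------------
# Alpha diversity estimators
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray) -> tuple[int, int, int, float, float]:
    n_obs = int(np.count_nonzero(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    bias_corrected = n_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        classic = n_obs + f1 * f1 / (2.0 * f2)
    else:
        classic = n_obs + f1 * (f1 - 1) / 2.0
    return n_obs, f1, f2, classic, bias_corrected


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample N, singleton/doubleton counts, Chao1 variants and Shannon.

    Returns a DataFrame indexed by sample ID with columns
    ``N, F1, F2, chao1, chao1_bias_corrected, shannon``.
    """
    rows = {}
    for s in table.sample_ids:
        counts = table.counts[s].to_numpy()
        if counts.sum() == 0:
            raise ValueError(f"sample {s!r} is empty")
        n_obs, f1, f2, classic, bc = _chao1(counts)
        rows[s] = {
            "N": n_obs,
            "F1": f1,
            "F2": f2,
            "chao1": classic,
            "chao1_bias_corrected": bc,
            "shannon": _shannon(counts),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Trend regression
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """Intercept/slope fit of a diversity quantity against time."""

    model: str                      # "poisson_glm" or "beta_regression"
    coefficients: np.ndarray        # [intercept, slope] (+ precision for beta)
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    @property
    def slope_p_value(self) -> float:
        return float(self.p_values[1])


def fit_richness_trend(values, times) -> TrendFit:
    """Poisson GLM (log link) of integer richness against time."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(t) == 0:
        raise ValueError("times are all equal")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("richness responses must be nonnegative integers")
    X = sm.add_constant(t)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return TrendFit(
        model="poisson_glm",
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(res.llf),
        converged=bool(res.converged),
    )


def shannon_to_unit(values, divisor: float, compress: bool = True) -> np.ndarray:
    """Map Shannon indices into (0, 1): divide by ``divisor`` (canonically
    ln of the dataset-wide number of distinct features), then apply the
    boundary compression ``y -> (y*(n-1) + 0.5)/n``."""
    y = np.asarray(values, dtype=float) / float(divisor)
    if compress:
        n = len(y)
        y = (y * (n - 1) + 0.5) / n
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("mapped values fall outside (0, 1); check the divisor")
    return y


def fit_diversity_trend(values, times, divisor: float | None = None) -> TrendFit:
    """Beta regression (logit mean link, constant precision) of Shannon
    diversity against time.

    ``values`` may already lie in (0, 1); otherwise supply ``divisor`` to
    apply :func:`shannon_to_unit` first.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if divisor is not None:
        y = shannon_to_unit(y, divisor)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly in (0, 1)")
    if np.ptp(y) == 0:
        raise ValueError("responses constant after mapping")
    X = sm.add_constant(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel(y, X).fit(disp=False)
    retvals = getattr(res, "mle_retvals", None)
    converged = bool(retvals.get("converged", True)) if isinstance(retvals, dict) else True
    return TrendFit(
        model="beta_regression",
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(res.llf),
        converged=converged,
    )


def timepoint_weeks(timepoints) -> np.ndarray:
    """Numeric week codes for infant timepoints (I1..I5 -> 1, 4, 13, 30, 52)."""
    try:
        return np.asarray([TIMEPOINT_WEEKS[t] for t in timepoints], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no week code for timepoint {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Bootstrap clustering of per-individual temporal profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileDendrogram:
    """Average-linkage tree over individuals with bootstrap support per node."""

    leaves: list[str]
    linkage: np.ndarray
    supports: dict[frozenset, float]
    n_boot: int
    support_threshold: float

    def clusters(self, threshold: float | None = None) -> list[frozenset]:
        """Non-trivial nodes (2 <= size < n) with support >= threshold."""
        thr = self.support_threshold if threshold is None else threshold
        n = len(self.leaves)
        return sorted(
            (s for s, v in self.supports.items() if v >= thr and 1 < len(s) < n),
            key=len,
            reverse=True,
        )


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows, robust to constant rows."""
    n = profiles.shape[0]
    sd = profiles.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    d = 1.0 - corr
    for i in range(n):
        for j in range(n):
            if not np.isfinite(d[i, j]):
                d[i, j] = 0.0 if np.allclose(profiles[i], profiles[j]) else 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return d


def _node_sets(linkage: np.ndarray, n: int) -> set[frozenset]:
    members: list[frozenset] = [frozenset([i]) for i in range(n)]
    out = set()
    for a, b, _, _ in linkage:
        merged = members[int(a)] | members[int(b)]
        members.append(merged)
        out.add(merged)
    return out


def cluster_temporal_profiles(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    support_threshold: float = 0.95,
    seed: int = 0,
    standardize: bool = True,
) -> ProfileDendrogram:
    """Cluster individuals by their temporal profiles with bootstrap support.

    Profiles (individuals x timepoints) are centered at the grand mean and
    scaled by the grand standard deviation, compared by correlation distance,
    and agglomerated with average linkage.  Support of an internal node is
    the fraction of bootstrap replicates (timepoints resampled with
    replacement) whose tree contains the same leaf set.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    X = profiles.to_numpy(dtype=float)
    if standardize:
        sd = X.std()
        X = (X - X.mean()) / (sd if sd > 0 else 1.0)
    n, m = X.shape
    from scipy.spatial.distance import squareform

    ref_link = sch.linkage(squareform(_correlation_distance(X), checks=False), method="average")
    ref_sets = _node_sets(ref_link, n)

    rng = np.random.default_rng(seed)
    hits = {s: 0 for s in ref_sets}
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        Xb = X[:, cols]
        link = sch.linkage(
            squareform(_correlation_distance(Xb), checks=False), method="average"
        )
        for s in _node_sets(link, n):
            if s in hits:
                hits[s] += 1

    idx_to_leaf = dict(enumerate(profiles.index))
    supports = {
        frozenset(idx_to_leaf[i] for i in s): hits[s] / n_boot for s in ref_sets
    }
    return ProfileDendrogram(
        leaves=list(profiles.index),
        linkage=ref_link,
        supports=supports,
        n_boot=n_boot,
        support_threshold=support_threshold,
    )
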