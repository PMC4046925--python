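"""Self-organizing-map discovery of temporal abundance patterns with
profile-bootstrap support.

Each feature's temporal profile is its mean relative abundance per
timepoint, centered at the grand mean and scaled by the grand standard
deviation.  A small batch SOM partitions profiles into a few prototype
shapes (decreasing, increasing, transient peak, ...).  Robustness is
assessed by resampling individuals (mother--infant pairs) with replacement:
each of ``n_boot`` replicates rebuilds every feature's profile, all
replicate profiles are clustered jointly on one SOM together with the
reference (full-data) profiles, and a feature's support is the fraction of
replicates in which its replicate profile lands on the same SOM node as its
reference profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance_io import AbundanceTable, SampleMetadata, TIMEPOINTS


@dataclass
class TemporalProfileMatrix:
    """Features x timepoints matrix of standardized mean relative abundances."""

    values: pd.DataFrame
    mean: float
    sd: float

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)


def build_profiles(
    table: AbundanceTable, metadata: SampleMetadata, timepoints=None
) -> TemporalProfileMatrix:
    """Per feature and timepoint, the mean relative abundance over the
    timepoint's samples, then a single global center/scale."""
    tps = list(timepoints) if timepoints is not None else [
        t for t in TIMEPOINTS if metadata.samples_at(t)
    ]
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    rel = table.counts / table.counts.sum(axis=0)
    cols = {}
    for tp in tps:
        samples = [s for s in metadata.samples_at(tp) if s in rel.columns]
        if not samples:
            raise ValueError(f"timepoint {tp!r} has no samples")
        cols[tp] = rel[samples].mean(axis=1)
    M = pd.DataFrame(cols)
    mu, sd = float(M.to_numpy().mean()), float(M.to_numpy().std())
    scaled = (M - mu) / (sd if sd > 0 else 1.0)
    return TemporalProfileMatrix(scaled, mu, sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Batch SOM
# ---------------------------------------------------------------------------

def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    gx, gy = shape
    return np.array([[i, j] for i in range(gx) for j in range(gy)], dtype=float)


def _bmu(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def som_train(
    X: np.ndarray,
    grid_shape: tuple[int, int] = (3, 1),
    n_iterations: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Batch SOM with a Gaussian neighborhood shrinking over epochs.

    Returns (codebook, assignments, per-epoch quantization errors).
    Deterministic given the seed (used only for codebook initialization).
    """
    n_nodes = grid_shape[0] * grid_shape[1]
    if n_nodes < 1:
        raise ValueError("grid must have at least one cell")
    if X.shape[0] < n_nodes:
        raise ValueError("fewer profiles than grid cells")
    rng = np.random.default_rng(seed)
    W = X[rng.choice(X.shape[0], size=n_nodes, replace=False)].astype(float).copy()
    grid = _grid_coords(grid_shape)
    gd2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)
    sigma0 = max(max(grid_shape) / 2.0, 0.6)
    qe_history = []
    for epoch in range(n_iterations):
        sigma = sigma0 * (0.05 / sigma0) ** (epoch / max(n_iterations - 1, 1))
        bmu = _bmu(X, W)
        h = np.exp(-gd2 / (2 * sigma ** 2))  # n_nodes x n_nodes
        num = h[:, bmu] @ X                   # n_nodes x d
        den = h[:, bmu].sum(axis=1)
        ok = den > 0
        W[ok] = num[ok] / den[ok, None]
        bmu = _bmu(X, W)
        # fitted-state quantization error, recorded after the epoch's update
        qe_history.append(float(np.sqrt(((X - W[bmu]) ** 2).sum(axis=1)).mean()))
    return W, _bmu(X, W), qe_history


@dataclass
class SomClustering:
    grid_shape: tuple[int, int]
    codebook: np.ndarray
    assignments: pd.Series                    # feature -> node index
    quantization_errors: list[float]
    supports: pd.Series | None = None         # feature -> support in [0, 1]
    support_thresholds: tuple[float, ...] = ()
    retained: dict[float, dict[int, list[str]]] = field(default_factory=dict)

    def retained_features(self, threshold: float) -> list[str]:
        return sorted(f for fs in self.retained.get(threshold, {}).values() for f in fs)


def som_fit(
    profiles: TemporalProfileMatrix | pd.DataFrame,
    grid_shape: tuple[int, int] = (3, 1),
    n_iterations: int = 20,
    seed: int = 0,
) -> SomClustering:
    """Fit a batch SOM to the profile matrix (no bootstrap support yet)."""
    M = profiles.values if isinstance(profiles, TemporalProfileMatrix) else profiles
    if M.size == 0:
        raise ValueError("empty profile matrix")
    X = M.to_numpy(dtype=float)
    W, bmu, qe = som_train(X, grid_shape, n_iterations, seed)
    return SomClustering(
        grid_shape=grid_shape,
        codebook=W,
        assignments=pd.Series(bmu, index=M.index),
        quantization_errors=qe,
    )


def _replicate_profiles(
    rel: pd.DataFrame,
    metadata: SampleMetadata,
    tps: list[str],
    pair_draw: list[str],
    fallback: pd.DataFrame,
) -> np.ndarray:
    cols = []
    for tp in tps:
        samples = []
        for pair in pair_draw:  # with multiplicity
            s = metadata.sample_for(pair, tp)
            if s is not None and s in rel.columns:
                samples.append(s)
        if samples:
            cols.append(rel[samples].mean(axis=1).to_numpy())
        else:
            cols.append(fallback[tp].to_numpy())
    return np.column_stack(cols)


def bootstrap_som(
    table: AbundanceTable,
    metadata: SampleMetadata,
    n_boot: int = 200,
    grid_shape: tuple[int, int] = (3, 1),
    support_thresholds: tuple[float, ...] = (0.6, 0.8),
    timepoints=None,
    n_iterations: int = 20,
    seed: int = 0,
) -> SomClustering:
    """Profile-bootstrap SOM clustering.

    Individuals are resampled with replacement ``n_boot`` times; every
    replicate's rebuilt feature profiles are pooled with the reference
    profiles and clustered jointly on one SOM.  A feature's support is the
    fraction of replicates whose profile shares the reference profile's
    best-matching unit; clusters are reported at each support threshold.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    tps = list(timepoints) if timepoints is not None else [
        t for t in TIMEPOINTS if metadata.samples_at(t)
    ]
    ref = build_profiles(table, metadata, tps)
    features = list(ref.values.index)
    rel = table.counts / table.counts.sum(axis=0)
    raw_ref = pd.DataFrame(
        {tp: rel[[s for s in metadata.samples_at(tp) if s in rel.columns]].mean(axis=1)
         for tp in tps}
    )
    pairs = metadata.pairs()
    rng = np.random.default_rng(seed)
    blocks = [raw_ref.to_numpy(dtype=float)]
    for _ in range(n_boot):
        draw = [pairs[i] for i in rng.integers(0, len(pairs), size=len(pairs))]
        blocks.append(_replicate_profiles(rel, metadata, tps, draw, raw_ref))
    stacked = np.vstack(blocks)
    mu, sd = stacked.mean(), stacked.std()
    stacked = (stacked - mu) / (sd if sd > 0 else 1.0)

    W, bmu, qe = som_train(stacked, grid_shape, n_iterations, seed)
    n = len(features)
    ref_bmu = bmu[:n]
    rep_bmu = bmu[n:].reshape(n_boot, n)
    support = (rep_bmu == ref_bmu[None, :]).mean(axis=0)

    assignments = pd.Series(ref_bmu, index=features)
    supports = pd.Series(support, index=features)
    retained: dict[float, dict[int, list[str]]] = {}
    for thr in support_thresholds:
        by_node: dict[int, list[str]] = {}
        for f in features:
            if supports[f] >= thr:
                by_node.setdefault(int(assignments[f]), []).append(f)
        retained[thr] = by_node
    return SomClustering(
        grid_shape=grid_shape,
        codebook=W,
        assignments=assignments,
        quantization_errors=qe,
        supports=supports,
        support_thresholds=tuple(support_thresholds),
        retained=retained,
    )


def cluster_mean_profiles(
    clustering: SomClustering,
    profiles: TemporalProfileMatrix,
    threshold: float,
) -> pd.DataFrame:
    """Per retained cluster, the mean standardized profile with a normal
    95 % confidence band over member features."""
    rows = []
    for node, members in clustering.retained.get(threshold, {}).items():
        sub = profiles.values.loc[members]
        mean = sub.mean(axis=0)
        sem = sub.std(axis=0, ddof=1) / np.sqrt(max(len(members), 1))
        for tp in profiles.timepoints:
            rows.append(
                {
                    "node": node,
                    "timepoint": tp,
                    "mean": mean[tp],
                    "ci_low": mean[tp] - 1.96 * sem[tp],
                    "ci_high": mean[tp] + 1.96 * sem[tp],
                    "n_members": len(members),
                }
            )
    return pd.DataFrame(rows)
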