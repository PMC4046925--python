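"""Taxon co-occurrence networks under an environment-stratified null model.

Associations between taxa are scored from a presence/absence matrix across
many samples spanning several environments.  The null model randomizes the
matrix by checkerboard swaps confined within environment strata, so every
taxon's total and per-environment occurrence counts and every sample's
richness are conserved exactly — environmental preference alone can then
never produce an association.  Pairs whose observed co-occurrence count
deviates from the null ensemble by more than a calibrated z threshold are
called aggregations (positive) or segregations (negative); the threshold is
set from ensemble-vs-ensemble comparisons so the estimated false positive
rate stays below a requested bound.  Timecore subnetworks date each
association by the first timepoint at which both endpoints are core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EnvironmentMatrix:
    """Taxa x samples presence/absence with per-sample environment labels."""

    matrix: pd.DataFrame   # 0/1 entries
    labels: pd.Series      # sample -> environment

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("environment matrix entries must be 0/1")
        missing = set(self.matrix.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without environment label: {sorted(missing)[:5]}")

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix.index)

    def dominant_environments(self) -> pd.Series:
        """Per taxon, the environment holding more than half of its
        occurrence samples; otherwise 'cosmopolitan'."""
        envs = self.labels[self.matrix.columns].to_numpy()
        out = {}
        M = self.matrix.to_numpy()
        for i, taxon in enumerate(self.matrix.index):
            present = envs[M[i] == 1]
            if len(present) == 0:
                out[taxon] = "cosmopolitan"
                continue
            vals, counts = np.unique(present, return_counts=True)
            j = counts.argmax()
            out[taxon] = vals[j] if counts[j] > len(present) / 2 else "cosmopolitan"
        return pd.Series(out)


# ---------------------------------------------------------------------------
# Stratified swap null model
# ---------------------------------------------------------------------------

def _swap_in_place(M: np.ndarray, col_pool: np.ndarray, rng, n_attempts: int) -> None:
    """Attempt ``n_attempts`` checkerboard swaps, each within one stratum.

    ``col_pool`` maps each attempt-eligible column to its stratum id; swaps
    pick two columns of the same stratum and two rows forming a 2x2
    checkerboard and flip it, conserving all row, column and stratum sums.
    """
    n_rows = M.shape[0]
    strata = {}
    for col, s in enumerate(col_pool):
        strata.setdefault(s, []).append(col)
    eligible = [np.asarray(cols) for cols in strata.values() if len(cols) >= 2]
    if not eligible:
        return
    weights = np.array([len(c) for c in eligible], dtype=float)
    weights /= weights.sum()
    stratum_idx = rng.choice(len(eligible), size=n_attempts, p=weights)
    for k in range(n_attempts):
        cols = eligible[stratum_idx[k]]
        c1, c2 = rng.choice(cols, size=2, replace=False)
        r1, r2 = rng.choice(n_rows, size=2, replace=False)
        a, b, c, d = M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2]
        if a == d and b == c and a != b:  # checkerboard
            M[r1, c1], M[r1, c2] = b, a
            M[r2, c1], M[r2, c2] = d, c


def null_ensemble(
    env: EnvironmentMatrix,
    n_randomizations: int = 100,
    seed: int = 0,
    burn_in: int | None = None,
    thinning: int | None = None,
) -> list[np.ndarray]:
    """Markov-chain ensemble of stratified fixed-fixed randomizations.

    Burn-in defaults to 10x the number of ones, thinning to 5x, counted in
    attempted swaps.  Strata with fewer than two samples are frozen (warned).
    """
    if env.matrix.shape[0] < 2 or env.matrix.shape[1] < 2:
        raise ValueError("matrix must have at least 2 taxa and 2 samples")
    M = env.matrix.to_numpy(dtype=np.int8).copy()
    col_strata = env.labels[env.matrix.columns].to_numpy()
    vals, counts = np.unique(col_strata, return_counts=True)
    small = vals[counts < 2]
    if len(small):
        logger.warning("strata too small to swap (left fixed): %s", list(small))
    n_ones = int(M.sum())
    burn = 10 * n_ones if burn_in is None else burn_in
    thin = 5 * n_ones if thinning is None else thinning
    rng = np.random.default_rng(seed)
    _swap_in_place(M, col_strata, rng, burn)
    out = []
    for _ in range(n_randomizations):
        _swap_in_place(M, col_strata, rng, thin)
        out.append(M.copy())
    return out


# ---------------------------------------------------------------------------
# Association scoring
# ---------------------------------------------------------------------------

@dataclass
class AssociationNetwork:
    """Undirected genus association graph with signed, z-scored edges."""

    graph: nx.Graph
    z_threshold: float
    fpr_threshold: float

    def edges(self, sign: str | None = None) -> list[tuple[str, str, dict]]:
        return [
            (a, b, d)
            for a, b, d in self.graph.edges(data=True)
            if sign is None or d["sign"] == sign
        ]

    def aggregation_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.graph.nodes(data=True))
        G.add_edges_from(
            (a, b, d) for a, b, d in self.graph.edges(data=True) if d["sign"] == "aggregation"
        )
        return G


def _pair_cooccurrence(M: np.ndarray) -> np.ndarray:
    return (M @ M.T).astype(float)


def calibrate_z_threshold(
    obs_z: np.ndarray,
    ens_z: list[np.ndarray],
    fpr_threshold: float,
    grid: np.ndarray | None = None,
) -> float:
    """Smallest z* on a grid such that the mean number of ensemble-member
    calls (false positives by construction) divided by the number of
    observed calls is below ``fpr_threshold``."""
    if grid is None:
        grid = np.arange(1.0, 6.01, 0.1)
    iu = np.triu_indices(obs_z.shape[0], k=1)
    obs = np.abs(obs_z[iu])
    ens = np.stack([np.abs(z[iu]) for z in ens_z])
    for z_star in grid:
        n_obs_calls = int((obs >= z_star).sum())
        if n_obs_calls == 0:
            continue
        mean_false = float((ens >= z_star).sum(axis=1).mean())
        if mean_false / n_obs_calls <= fpr_threshold:
            return float(z_star)
    return float(grid[-1])


def score_associations(
    env: EnvironmentMatrix,
    ensemble: list[np.ndarray],
    fpr_threshold: float = 0.05,
) -> AssociationNetwork:
    """Score every taxon pair against the null ensemble.

    z = (C - mu)/sigma where C is the observed co-occurrence count and
    mu, sigma are the ensemble moments; pairs with sigma = 0 are skipped.
    The call threshold z* is calibrated with :func:`calibrate_z_threshold`.
    """
    if not ensemble:
        raise ValueError("empty null ensemble")
    M = env.matrix.to_numpy(dtype=np.int8)
    taxa = env.taxa
    C = _pair_cooccurrence(M)
    ens_counts = np.stack([_pair_cooccurrence(E) for E in ensemble])
    mu = ens_counts.mean(axis=0)
    sigma = ens_counts.std(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z_obs = np.where(sigma > 0, (C - mu) / sigma, 0.0)
        ens_z = [np.where(sigma > 0, (E - mu) / sigma, 0.0) for E in ens_counts]
    z_star = calibrate_z_threshold(z_obs, ens_z, fpr_threshold)

    dom = env.dominant_environments()
    G = nx.Graph()
    for t in taxa:
        G.add_node(t, dominant_environment=dom[t])
    n = len(taxa)
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if sigma[i, j] == 0:
                skipped += 1
                continue
            z = z_obs[i, j]
            if z >= z_star:
                G.add_edge(taxa[i], taxa[j], sign="aggregation", z=float(z), count=int(C[i, j]))
            elif z <= -z_star:
                G.add_edge(taxa[i], taxa[j], sign="segregation", z=float(z), count=int(C[i, j]))
    if skipped:
        logger.warning("score_associations: %d pair(s) skipped (sigma = 0)", skipped)
    return AssociationNetwork(G, z_star, fpr_threshold)


# ---------------------------------------------------------------------------
# Timecore subnetworks and motifs
# ---------------------------------------------------------------------------

@dataclass
class TimecoreSubnetwork:
    graph: nx.Graph   # edges annotated with first_appearance and in_mb

    def edges_at(self, timepoint: str) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b, d in self.graph.edges(data=True)
            if d["first_appearance"] == timepoint
        ]


def extract_timecore_subnetwork(parent: AssociationNetwork, timecores) -> TimecoreSubnetwork:
    """Restrict the parent network to pairs co-resident in some timecore.

    Each retained edge is annotated with the earliest timepoint at which
    both endpoints belong to the timecore, and flagged when the pair is in
    the MB (maternal, one year) timecore.  Timecore taxa absent from the
    parent are logged and skipped.
    """
    timecores = list(timecores)
    parent_nodes = set(parent.graph.nodes)
    missing = sorted(set().union(*(tc.features for tc in timecores)) - parent_nodes)
    if missing:
        logger.info("timecore taxa absent from parent network: %s", ", ".join(missing[:10]))
    mb = next((tc.features for tc in timecores if tc.timepoint == "MB"), frozenset())
    ordered = [tc for tc in timecores if tc.timepoint != "MB"]
    G = nx.Graph()
    kept_any = False
    for a, b, d in parent.graph.edges(data=True):
        first = next(
            (tc.timepoint for tc in ordered if a in tc.features and b in tc.features),
            None,
        )
        in_mb = a in mb and b in mb
        if first is None and not in_mb:
            continue
        kept_any = True
        G.add_node(a, **parent.graph.nodes[a])
        G.add_node(b, **parent.graph.nodes[b])
        G.add_edge(a, b, **d, first_appearance=first, in_mb=in_mb)
    if not kept_any:
        raise ValueError("no parent edge intersects the timecores")
    return TimecoreSubnetwork(G)


def find_transitive_motifs(network: AssociationNetwork | nx.Graph):
    """Triangles and maximal cliques (size >= 3) of aggregation edges."""
    G = network.aggregation_graph() if isinstance(network, AssociationNetwork) else G_from(network)
    triangles = [tuple(sorted(c)) for c in nx.enumerate_all_cliques(G) if len(c) == 3]
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(G) if len(c) >= 3]
    return sorted(triangles), sorted(cliques)


def G_from(graph: nx.Graph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(graph.nodes(data=True))
    G.add_edges_from(
        (a, b, d)
        for a, b, d in graph.edges(data=True)
        if d.get("sign", "aggregation") == "aggregation"
    )
    return G


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def write_edge_list(network: AssociationNetwork | TimecoreSubnetwork, path) -> None:
    rows = []
    for a, b, d in network.graph.edges(data=True):
        row = {"taxon_a": a, "taxon_b": b, "sign": d["sign"], "z": d["z"]}
        if "first_appearance" in d:
            row["first_appearance"] = d["first_appearance"]
            row["in_mb"] = d["in_mb"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_list(path, fpr_threshold: float = float("nan")) -> AssociationNetwork:
    df = pd.read_csv(path, sep="\t")
    G = nx.Graph()
    for _, row in df.iterrows():
        G.add_edge(row["taxon_a"], row["taxon_b"], sign=row["sign"], z=float(row["z"]))
    return AssociationNetwork(G, float("nan"), fpr_threshold)
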