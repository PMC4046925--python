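"""Genus-level functional profiles and their dendrogram.

A functional profile is the relative-abundance vector of function subroles
attributable to one genus at one timepoint, computed after pooling all the
timepoint's samples.  Genera enter the analysis only if they reach the
abundance floor (> 1 % of some sample) and cover at least half of the
subroles observed dataset-wide.  Profiles are compared by Bray-Curtis
distance and agglomerated with complete linkage; clades whose tips all
belong to one taxonomic order are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .abundance_io import SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class GenusFunctionProfile:
    genus: str
    timepoint: str
    vector: pd.Series          # relative abundance per subrole; sums to 1
    coverage: float            # fraction of subroles with nonzero mass (genus-wide)

    @property
    def label(self) -> str:
        return f"{self.genus}|{self.timepoint}"


def build_profiles(
    joint_counts: pd.DataFrame,
    metadata: SampleMetadata,
    min_abundance: float = 0.01,
    min_coverage: float = 0.5,
    timepoints=None,
) -> list[GenusFunctionProfile]:
    """Construct (genus, timepoint) functional profiles from long-format
    (genus, subrole, sample, count) joint annotation counts.

    A genus is kept when (a) its share of some sample's counts exceeds
    ``min_abundance`` and (b) across all samples it has counts in at least
    ``min_coverage`` of the subroles observed in the whole dataset.
    Profiles pool all samples of a timepoint before normalizing.
    """
    need = {"genus", "subrole", "sample", "count"}
    if not need <= set(joint_counts.columns):
        raise ValueError(f"joint counts must have columns {sorted(need)}")
    jc = joint_counts[joint_counts["count"] > 0]
    subrole_universe = sorted(jc["subrole"].unique())
    n_universe = len(subrole_universe)

    # abundance filter: genus share of per-sample totals
    per_gs = jc.groupby(["genus", "sample"], sort=False)["count"].sum()
    sample_tot = jc.groupby("sample")["count"].sum()
    share = per_gs / per_gs.index.get_level_values("sample").map(sample_tot)
    max_share = share.groupby("genus").max()

    # coverage filter: distinct subroles per genus across the whole dataset
    coverage = jc.groupby("genus")["subrole"].nunique() / n_universe

    keep = sorted(
        g for g in max_share.index
        if max_share[g] > min_abundance and coverage[g] >= min_coverage
    )
    excluded = sorted(set(max_share.index) - set(keep))
    if excluded:
        logger.info("functional profiles: excluding %d genera: %s",
                    len(excluded), ", ".join(excluded[:10]))
    if not keep:
        raise ValueError("no genus passes the abundance and coverage filters")

    tp_of = metadata.records["timepoint"]
    jc = jc[jc["genus"].isin(keep)].copy()
    jc["timepoint"] = jc["sample"].map(tp_of)
    if jc["timepoint"].isna().any():
        missing = sorted(jc.loc[jc["timepoint"].isna(), "sample"].unique())
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    if timepoints is not None:
        jc = jc[jc["timepoint"].isin(set(timepoints))]

    pooled = jc.groupby(["genus", "timepoint", "subrole"], sort=False)["count"].sum()
    out = []
    for (g, tp), block in pooled.groupby(level=["genus", "timepoint"], sort=False):
        vec = pd.Series(0.0, index=subrole_universe)
        counts = block.droplevel(["genus", "timepoint"])
        vec[counts.index] = counts.to_numpy(dtype=float)
        vec /= vec.sum()
        out.append(GenusFunctionProfile(g, tp, vec, float(coverage[g])))
    out.sort(key=lambda p: (p.genus, p.timepoint))
    return out


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------

@dataclass
class FunctionalDendrogram:
    labels: list[str]                  # one leaf per (genus, timepoint)
    linkage: np.ndarray                # complete-linkage merge tree
    groups: dict[str, int]             # flat group id per leaf at the cut
    collapsed: list[tuple[str, list[str]]]  # (order, leaves) collapsed clades

    def newick(self) -> str:
        """Newick serialization with collapsed-clade labels."""
        tree = sch.to_tree(self.linkage)
        collapsed_leaves = {}
        for order, leaves in self.collapsed:
            for lf in leaves:
                collapsed_leaves[lf] = order
        def fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id].replace(' ', '_')}:{length:.6f}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"
        return fmt(tree, tree.dist) + ";"


def _profile_matrix(profiles) -> tuple[np.ndarray, list[str]]:
    labels = [p.label for p in profiles]
    X = np.vstack([p.vector.to_numpy() for p in profiles])
    return X, labels


def cluster_profiles(
    profiles,
    order_map: dict[str, str] | None = None,
    n_groups: int = 6,
) -> FunctionalDendrogram:
    """Complete-linkage agglomeration of Bray-Curtis distances between
    functional profiles; flat groups cut at ``n_groups``; clades whose tip
    genera share one taxonomic order are collapsed (tips with no order
    annotation stay uncollapsed, with a warning)."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    X, labels = _profile_matrix(profiles)
    Z = sch.linkage(pdist(X, metric="braycurtis"), method="complete")
    flat = sch.fcluster(Z, t=min(n_groups, len(profiles)), criterion="maxclust")
    groups = {lab: int(k) for lab, k in zip(labels, flat)}

    collapsed: list[tuple[str, list[str]]] = []
    if order_map is not None:
        missing = sorted({p.genus for p in profiles} - set(order_map))
        if missing:
            logger.warning("no order annotation for: %s", ", ".join(missing[:10]))
        tree = sch.to_tree(Z)
        def orders_of(node):
            if node.is_leaf():
                genus = profiles[node.id].genus
                return {order_map.get(genus)}, [labels[node.id]]
            lo, ll = orders_of(node.left)
            ro, rl = orders_of(node.right)
            return lo | ro, ll + rl
        def walk(node):
            if node.is_leaf():
                return
            orders, leaves = orders_of(node)
            if len(orders) == 1 and None not in orders and len(leaves) > 1:
                collapsed.append((orders.pop(), leaves))
                return
            walk(node.left)
            walk(node.right)
        walk(tree)
    return FunctionalDendrogram(labels, Z, groups, collapsed)


def group_membership(dendrogram: FunctionalDendrogram) -> pd.DataFrame:
    return pd.DataFrame(
        {"leaf": list(dendrogram.groups), "group": list(dendrogram.groups.values())}
    ).set_index("leaf")
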