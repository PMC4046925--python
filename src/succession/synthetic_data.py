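"""Synthetic mother--infant cohort generator.

Emulates the statistical structure of a 13-pair, 7-timepoint birth-cohort
metagenomic survey so that every downstream analysis stage is testable
without access to the original sample data:

* at one week (I1) each infant's gut is dominated by a single genus, drawn
  in the default configuration from five "founder" genera
  (Bacteroides, Clostridium, Veillonella, Bifidobacterium, Escherichia);
* detected-genus richness rises through I3, drops sharply at the
  solid-food transition (I4) and partially recovers at I5;
* a persistent core of genera is present in every sample;
* between-infant compositional heterogeneity decreases with age;
* function-subrole counts are a multinomial mixture of genus-specific
  functional vectors, so functional composition is genus-linked.

All generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance_io import (
    AbundanceTable,
    INFANT_TIMEPOINTS,
    SampleMetadata,
    TIMEPOINTS,
)

#: Genera that dominate the one-week microbiota of different newborns.
FOUNDER_GENERA = (
    "Bacteroides",
    "Clostridium",
    "Veillonella",
    "Bifidobacterium",
    "Escherichia",
)

#: The ten-genus global core observed across all samples of the cohort.
DEFAULT_CORE_GENERA = (
    "Bacillus",
    "Bacteroides",
    "Clostridium",
    "Enterococcus",
    "Escherichia",
    "Eubacterium",
    "Lactobacillus",
    "Prevotella",
    "Streptococcus",
    "Vibrio",
)

#: Real cohort pair codes and covariates (delivery, peripartum antibiotics,
#: early feeding); four pairs lack the one-month (I2) sample.
_PAIR_TEMPLATE = {
    "MIP01": ("vaginal", False, "breast", True),
    "MIP02": ("vaginal", False, "mixed", True),
    "MIP03": ("vaginal", True, "breast", True),
    "MIP06": ("c_section", True, "breast", True),
    "MIP07": ("c_section", True, "breast", False),
    "MIP08": ("vaginal", False, "breast", True),
    "MIP09": ("vaginal", True, "mixed", True),
    "MIP12": ("c_section", True, "mixed", True),
    "MIP13": ("vaginal", True, "mixed", False),
    "MIP16": ("vaginal", True, "breast", True),
    "MIP17": ("vaginal", False, "breast", False),
    "MIP19": ("vaginal", False, "breast", False),
    "MIP21": ("vaginal", True, "breast", True),
}

#: Timepoint age index used to schedule concentration/heterogeneity; the two
#: maternal occasions sit at the adult end of the scale.
_AGE_INDEX = {"I1": 0, "I2": 1, "I3": 2, "I4": 3, "I5": 4, "MA": 5, "MB": 5}

_DEFAULT_RICHNESS = {
    "I1": 22, "I2": 32, "I3": 45, "I4": 30, "I5": 38, "MA": 55, "MB": 50,
}


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    ``dominance_concentration`` is the Dirichlet concentration at I1 (small
    values concentrate nearly all mass on one genus); the per-timepoint
    concentration grows as ``dominance_concentration / heterogeneity_decay**age``
    so that ``heterogeneity_decay < 1`` yields progressively more homogeneous,
    more even communities with age.  ``richness_trajectory`` sets the expected
    number of detected genera per sample at each timepoint.
    """

    n_pairs: int = 13
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_genera: int = 80
    n_core_genera: int = 10
    dominance_concentration: float = 0.03
    richness_trajectory: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_RICHNESS)
    )
    heterogeneity_decay: float = 0.45
    reads_per_sample: tuple[int, int] = (35_000, 70_000)
    detection_floor: float = 0.02
    founder_override: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_genera > self.n_genera:
            raise ValueError("n_core_genera exceeds n_genera")
        if self.dominance_concentration <= 0:
            raise ValueError("dominance_concentration must be positive")
        if not (0 < self.heterogeneity_decay <= 1):
            raise ValueError("heterogeneity_decay must be in (0, 1]")
        if self.reads_per_sample[0] <= 0 or self.reads_per_sample[1] < self.reads_per_sample[0]:
            raise ValueError("invalid reads_per_sample range")
        for tp in self.timepoints:
            r = self.richness_trajectory.get(tp)
            if r is None or r <= 0:
                raise ValueError(f"richness_trajectory missing or nonpositive at {tp}")
            if r > self.n_genera:
                raise ValueError(
                    f"richness_trajectory at {tp} ({r}) exceeds n_genera ({self.n_genera})"
                )


def _genus_names(n: int) -> list[str]:
    names = list(DEFAULT_CORE_GENERA) + [g for g in FOUNDER_GENERA if g not in DEFAULT_CORE_GENERA]
    extra = [f"Genus{i:03d}" for i in range(1, n + 1)]
    names = (names + extra)[:n]
    return names


def _pair_ids(n_pairs: int) -> tuple[list[str], set[str]]:
    if n_pairs == 13:
        pairs = list(_PAIR_TEMPLATE)
        missing_i2 = {p for p, rec in _PAIR_TEMPLATE.items() if not rec[3]}
        return pairs, missing_i2
    pairs = [f"MIP{i:02d}" for i in range(1, n_pairs + 1)]
    return pairs, set()


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, SampleMetadata]:
    """Draw a full cohort count table and matching metadata.

    Per sample, genus proportions come from a timepoint-specific Dirichlet
    over a per-sample support (core genera always included); counts are
    multinomial at a uniformly drawn sequencing depth, and core genera are
    guaranteed detected.
    """
    rng = np.random.default_rng(spec.seed)
    genera = _genus_names(spec.n_genera)
    core = genera[: spec.n_core_genera]
    pairs, missing_i2 = _pair_ids(spec.n_pairs)

    # heavy-tailed community mean profile shared by the cohort
    ranks = np.arange(1, spec.n_genera + 1, dtype=float)
    base = ranks ** -1.2
    base = rng.permutation(base)
    # keep the core reasonably abundant so forced presence is not artificial
    order = np.argsort(base)[::-1]
    top = order[: spec.n_core_genera]
    core_mass = base[top].copy()
    base[top] = base[: spec.n_core_genera]
    base[: spec.n_core_genera] = core_mass
    base /= base.sum()

    founders = {p: FOUNDER_GENERA[i % len(FOUNDER_GENERA)] for i, p in enumerate(pairs)}
    gidx = {g: i for i, g in enumerate(genera)}

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for pair in pairs:
        for tp in spec.timepoints:
            if tp == "I2" and pair in missing_i2:
                continue
            age = _AGE_INDEX.get(tp, 4)
            conc = spec.dominance_concentration / (spec.heterogeneity_decay ** age)

            # per-sample support: core always in, rest Bernoulli to hit trajectory
            target = spec.richness_trajectory[tp]
            n_extra = spec.n_genera - spec.n_core_genera
            p_extra = min(1.0, max(0.0, (target - spec.n_core_genera) / max(n_extra, 1)))
            support = np.zeros(spec.n_genera, dtype=bool)
            support[[gidx[g] for g in core]] = True
            support[spec.n_core_genera:] = rng.random(n_extra) < p_extra

            alpha = conc * base[support] / base[support].sum() * support.sum()
            props = np.zeros(spec.n_genera)
            props[support] = rng.dirichlet(np.maximum(alpha, 1e-6))
            # small uniform floor over the support keeps support genera
            # detectable at the sampled depths without disturbing dominance
            floor = spec.detection_floor
            props[support] = (1 - floor) * props[support] + floor / support.sum()

            if spec.founder_override and tp == "I1":
                founder = founders[pair]
                fi = gidx[founder]
                frac = rng.uniform(0.55, 0.9)
                props[fi] = 0.0
                rest = props.sum()
                if rest > 0:
                    props *= (1 - frac) / rest
                props[fi] = frac

            depth = int(rng.integers(spec.reads_per_sample[0], spec.reads_per_sample[1] + 1))
            counts = rng.multinomial(depth, props / props.sum())
            for g in core:  # core genera are detected in every sample
                if counts[gidx[g]] == 0:
                    counts[gidx[g]] = 1

            if tp in ("MA", "MB"):
                sample_id = f"{pair}-{tp}"
                delivery, abx, feeding = "na", _PAIR_TEMPLATE.get(pair, ("na", False, "na", True))[1], "na"
            else:
                sample_id = f"{pair}-{tp}"
                delivery, abx, feeding, _ = _PAIR_TEMPLATE.get(pair, ("vaginal", False, "breast", True))
                if tp in ("I4", "I5"):
                    feeding = "solid"
            columns[sample_id] = counts
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "pair_id": pair,
                    "timepoint": tp,
                    "delivery": delivery,
                    "peripartum_antibiotics": abx,
                    "feeding": feeding,
                }
            )

    table = AbundanceTable(pd.DataFrame(columns, index=genera))
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, metadata


# ---------------------------------------------------------------------------
# Genus-linked functional profiles
# ---------------------------------------------------------------------------

@dataclass
class GenusFunctionMap:
    """Per-genus probability vector over function subroles (rows sum to 1)."""

    vectors: pd.DataFrame  # genera x subroles
    groups: pd.Series | None = None  # genus -> functional/phylogenetic group

    def __post_init__(self) -> None:
        arr = self.vectors.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("function map rows must be probability vectors")

    @property
    def subroles(self) -> list[str]:
        return list(self.vectors.columns)


def random_function_map(
    genera,
    n_subroles: int = 108,
    n_groups: int = 6,
    within_group_concentration: float = 400.0,
    seed: int = 0,
) -> GenusFunctionMap:
    """Draw a genus -> subrole probability map with grouped (phylogeny-like)
    structure: genera in the same group share similar vectors."""
    rng = np.random.default_rng(seed)
    genera = list(genera)
    subroles = [f"SR{i:03d}" for i in range(1, n_subroles + 1)]
    group_of = pd.Series(
        [i % n_groups for i in range(len(genera))], index=genera, name="group"
    )
    bases = rng.dirichlet(np.full(n_subroles, 0.6), size=n_groups)
    rows = np.empty((len(genera), n_subroles))
    for i, g in enumerate(genera):
        b = bases[group_of[g]]
        rows[i] = rng.dirichlet(within_group_concentration * b + 1e-3)
    return GenusFunctionMap(pd.DataFrame(rows, index=genera, columns=subroles), group_of)


def generate_function_table(
    taxa: AbundanceTable,
    fmap: GenusFunctionMap,
    seed: int = 0,
    depth=None,
) -> AbundanceTable:
    """Per sample, draw subrole counts from a multinomial whose mixture
    weights are the genus relative abundances times the genus vectors.

    ``depth`` may be None (use each sample's taxon total), an int, or a
    mapping from sample ID to int.
    """
    missing = set(taxa.feature_ids) - set(fmap.vectors.index)
    if missing:
        raise ValueError(f"unmapped genera: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    V = fmap.vectors.loc[taxa.feature_ids].to_numpy()
    cols = {}
    totals = taxa.sample_totals()
    for s in taxa.sample_ids:
        w = taxa.counts[s].to_numpy(dtype=float)
        mix = w @ V
        mix /= mix.sum()
        if depth is None:
            d = int(totals[s])
        elif isinstance(depth, dict):
            d = int(depth[s])
        else:
            d = int(depth)
        cols[s] = rng.multinomial(d, mix)
    return AbundanceTable(pd.DataFrame(cols, index=fmap.subroles))


def joint_function_counts(
    taxa: AbundanceTable, fmap: GenusFunctionMap, seed: int = 0, per_genus_depth_scale: float = 0.1
) -> pd.DataFrame:
    """Long-format (genus, subrole, sample, count) table linking taxa to
    functions, as produced by per-read joint taxonomic+functional annotation."""
    rng = np.random.default_rng(seed)
    V = fmap.vectors
    rows = []
    for s in taxa.sample_ids:
        for g in taxa.feature_ids:
            c = int(round(taxa.counts.loc[g, s] * per_genus_depth_scale))
            if c == 0:
                continue
            draws = rng.multinomial(c, V.loc[g].to_numpy())
            nz = np.nonzero(draws)[0]
            for j in nz:
                rows.append((g, V.columns[j], s, int(draws[j])))
    return pd.DataFrame(rows, columns=["genus", "subrole", "sample", "count"])


# ---------------------------------------------------------------------------
# Environment presence/absence matrices for network inference
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentTruth:
    """Synthetic environment matrix with planted association ground truth."""

    matrix: pd.DataFrame        # taxa x samples, 0/1
    labels: pd.Series           # sample -> environment
    preferences: pd.Series      # taxon -> preferred environment
    aggregated_pairs: list[tuple[str, str]]
    segregated_pairs: list[tuple[str, str]]


def generate_environment_matrix(
    n_genera: int,
    n_samples: int,
    n_environments: int = 3,
    affinity: float = 0.0,
    n_planted_aggregations: int = 0,
    n_planted_segregations: int = 0,
    occupancy_in: float = 0.7,
    occupancy_out: float = 0.15,
    seed: int = 0,
) -> EnvironmentTruth:
    """Presence/absence of taxa across samples from several environments.

    Each taxon occurs with probability ``occupancy_in`` in samples of its
    preferred environment and ``occupancy_out`` elsewhere.  ``affinity``
    couples planted pairs: with probability ``affinity`` the second member of
    an aggregated pair copies the first's occurrence (a segregated pair
    copies its complement); at ``affinity = 0`` all taxa are independent
    given the environment.
    """
    if not (0 <= affinity <= 1):
        raise ValueError("affinity must be in [0, 1]")
    if n_genera < 2 or n_samples < 2 or n_environments < 2:
        raise ValueError("all dimensions must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = [f"Taxon{i:03d}" for i in range(1, n_genera + 1)]
    samples = [f"Env{i:04d}" for i in range(1, n_samples + 1)]
    envs = [f"E{k}" for k in range(1, n_environments + 1)]
    labels = pd.Series([envs[i % n_environments] for i in range(n_samples)], index=samples)
    prefs = pd.Series([envs[rng.integers(n_environments)] for _ in taxa], index=taxa)

    prob = np.where(
        labels.to_numpy()[None, :] == prefs.to_numpy()[:, None], occupancy_in, occupancy_out
    )
    M = (rng.random((n_genera, n_samples)) < prob).astype(np.int8)

    n_pairs = n_planted_aggregations + n_planted_segregations
    if 2 * n_pairs > n_genera:
        raise ValueError("not enough taxa for the requested planted pairs")
    agg, seg = [], []
    k = 0
    for _ in range(n_planted_aggregations):
        a, b = taxa[k], taxa[k + 1]
        prefs[b] = prefs[a]
        copy = rng.random(n_samples) < affinity
        row_b = (rng.random(n_samples) < np.where(labels.to_numpy() == prefs[b], occupancy_in, occupancy_out)).astype(np.int8)
        M[k + 1] = np.where(copy, M[k], row_b)
        agg.append((a, b))
        k += 2
    for _ in range(n_planted_segregations):
        a, b = taxa[k], taxa[k + 1]
        prefs[b] = prefs[a]
        copy = rng.random(n_samples) < affinity
        row_b = (rng.random(n_samples) < np.where(labels.to_numpy() == prefs[b], occupancy_in, occupancy_out)).astype(np.int8)
        M[k + 1] = np.where(copy, 1 - M[k], row_b)
        seg.append((a, b))
        k += 2

    matrix = pd.DataFrame(M, index=taxa, columns=samples)
    return EnvironmentTruth(matrix, labels, prefs, agg, seg)
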