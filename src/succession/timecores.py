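"""Timecores: per-timepoint core feature sets and their set algebra.

A timecore is the set of features (genera or function subroles) detected —
raw count >= 1 by default — in every individual's sample at one timepoint.
The Venn partition of timecores tracks arrival and loss of core features
across succession; the global core is the intersection of all timecores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .abundance_io import AbundanceTable, SampleMetadata, TIMEPOINTS


@dataclass(frozen=True)
class Timecore:
    timepoint: str
    features: frozenset
    n_samples_considered: int


def compute_timecores(
    table: AbundanceTable,
    metadata: SampleMetadata,
    timepoints=None,
    min_count: int = 1,
    min_relative_abundance: float = 0.0,
) -> list[Timecore]:
    """Per timepoint, intersect the detected-feature sets of its samples.

    Detection defaults to raw count >= 1 on unrarefied counts; a stricter
    minimum count or minimum relative abundance may be imposed for
    sensitivity analysis.
    """
    tps = list(timepoints) if timepoints is not None else [
        t for t in TIMEPOINTS if metadata.samples_at(t)
    ]
    out = []
    rel = None
    if min_relative_abundance > 0:
        rel = table.counts / table.counts.sum(axis=0)
    for tp in tps:
        samples = [s for s in metadata.samples_at(tp) if s in table.counts.columns]
        if not samples:
            raise ValueError(f"timepoint {tp!r} has no samples")
        core = None
        for s in samples:
            col = table.counts[s]
            ok = col >= min_count
            if rel is not None:
                ok &= rel[s] >= min_relative_abundance
            detected = frozenset(col.index[ok])
            core = detected if core is None else core & detected
        out.append(Timecore(tp, core, len(samples)))
    return out


def global_core(timecores) -> frozenset:
    """Features present in every timecore."""
    cores = [tc.features for tc in timecores]
    out = cores[0]
    for c in cores[1:]:
        out &= c
    return out


def venn_partition(timecores) -> dict[frozenset, frozenset]:
    """Assign each feature to the exact subset of timecores containing it.

    Returns a mapping from (nonempty) frozensets of timepoint labels to the
    feature set exclusive to exactly those timecores; cells partition the
    union of all timecores.
    """
    if len(timecores) < 2:
        raise ValueError("need at least 2 timecores")
    universe = set().union(*(tc.features for tc in timecores))
    cells: dict[frozenset, set] = {}
    for f in universe:
        key = frozenset(tc.timepoint for tc in timecores if f in tc.features)
        cells.setdefault(key, set()).add(f)
    return {k: frozenset(v) for k, v in cells.items()}


def venn_counts(timecores) -> pd.Series:
    cells = venn_partition(timecores)
    order = [tc.timepoint for tc in timecores]
    keys = sorted(cells, key=lambda k: (len(k), [order.index(t) for t in sorted(k, key=order.index)]))
    return pd.Series(
        {"+".join(sorted(k, key=order.index)): len(cells[k]) for k in keys}, dtype=int
    )


def new_core_arrivals(timecores, at: str, persist_through: str | None = None) -> frozenset:
    """Features joining the core at ``at``: present in timecore(at) but in no
    earlier timecore of the ordered list; optionally restricted to those
    still present at ``persist_through``."""
    order = [tc.timepoint for tc in timecores]
    if at not in order:
        raise ValueError(f"timepoint {at!r} not in the ordered timecores")
    i = order.index(at)
    by_tp = {tc.timepoint: tc.features for tc in timecores}
    arrivals = set(by_tp[at])
    for tp in order[:i]:
        arrivals -= by_tp[tp]
    if persist_through is not None:
        j = order.index(persist_through)
        if j < i:
            raise ValueError("persist_through is earlier than the arrival timepoint")
        arrivals &= by_tp[persist_through]
    return frozenset(arrivals)


def shared_fraction(infant_detected: frozenset, maternal_detected: frozenset) -> float:
    """Percentage of the infant's detected features also detected in the
    mother: 100 * |infant & mother| / |infant|."""
    if not infant_detected:
        raise ValueError("infant detected set is empty")
    return 100.0 * len(frozenset(infant_detected) & frozenset(maternal_detected)) / len(infant_detected)


def pair_sharing(
    table: AbundanceTable,
    metadata: SampleMetadata,
    infant_timepoint: str = "I1",
    maternal_timepoint: str = "MA",
) -> pd.Series:
    """Per mother-infant pair, the percentage of infant genera shared with
    the mother at the stated timepoints."""
    out = {}
    for pair in metadata.pairs():
        si = metadata.sample_for(pair, infant_timepoint)
        sm = metadata.sample_for(pair, maternal_timepoint)
        if si is None or sm is None:
            continue
        out[pair] = shared_fraction(table.detected_set(si), table.detected_set(sm))
    return pd.Series(out)


def membership_table(timecores) -> pd.DataFrame:
    """0/1 feature-by-timecore presence layout."""
    universe = sorted(set().union(*(tc.features for tc in timecores)))
    data = {
        tc.timepoint: [1 if f in tc.features else 0 for f in universe] for tc in timecores
    }
    return pd.DataFrame(data, index=universe)
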