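"""End-to-end orchestration of the succession analysis.

Runs, in dependency order: alpha diversity and temporal trends; global and
pairwise compositional tests with ordination and convex hulls; timecores
and their Venn partition; genus functional profiles; bootstrapped SOM
temporal patterns; and the co-occurrence subnetwork.  Every stage writes a
plain-text table into the output directory and is recorded in a manifest
together with the configuration hash and seeds, so each threshold the
analysis uses is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    abundance_io as aio,
    cooccurrence_network as net,
    diversity,
    functional_profiles as fp,
    ordination as ord_,
    synthetic_data as synth,
    temporal_som as som,
    timecores as tc,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    taxa_table: str | None = None        # TSV paths; None -> simulate
    function_table: str | None = None
    metadata: str | None = None
    joint_function_counts: str | None = None
    output_dir: str = "succession_out"
    rarefy_depth: str | int = "auto"     # "auto" = minimum sample total
    min_abundance: float = 0.01          # 1 % abundance floor
    min_coverage: float = 0.5            # half the observed subroles
    som_supports: tuple[float, float] = (0.6, 0.8)
    som_boot: int = 200
    fpr_threshold: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    network_samples: int = 200
    network_environments: int = 3
    network_randomizations: int = 50

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.fpr_threshold < 1):
            raise ValueError("fpr_threshold must be in (0, 1)")
        if self.som_boot < 2:
            raise ValueError("som_boot must be >= 2")
        for p in (self.taxa_table, self.function_table, self.metadata):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        if isinstance(cfg.som_supports, list):
            cfg.som_supports = tuple(cfg.som_supports)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(cfg: PipelineConfig):
    if cfg.taxa_table is not None and cfg.metadata is not None:
        taxa = aio.read_abundance_table(cfg.taxa_table)
        meta = aio.read_metadata(cfg.metadata)
        funcs = (
            aio.read_abundance_table(cfg.function_table)
            if cfg.function_table is not None
            else None
        )
        joint = (
            pd.read_csv(cfg.joint_function_counts, sep="\t")
            if cfg.joint_function_counts is not None
            else None
        )
        return taxa, funcs, meta, joint
    spec = synth.CohortSpec(seed=cfg.seed)
    taxa, meta = synth.generate_cohort(spec)
    fmap = synth.random_function_map(taxa.feature_ids, seed=cfg.seed + 1)
    funcs = synth.generate_function_table(taxa, fmap, seed=cfg.seed + 2)
    joint = synth.joint_function_counts(taxa, fmap, seed=cfg.seed + 3)
    return taxa, funcs, meta, joint


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Stage failures are collected per stage name; completed outputs are kept.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "outputs": {},
        "errors": {},
    }

    taxa, funcs, meta, joint = _load_inputs(config)
    tables = [taxa] + ([funcs] if funcs is not None else [])
    tables, meta = aio.align(tables, meta)
    taxa = tables[0]
    funcs = tables[1] if funcs is not None else None

    def stage(name, fn):
        try:
            paths = fn()
            manifest["outputs"][name] = paths
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.exception("stage %s failed", name)
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"

    # -- alpha diversity and trends -------------------------------------
    def alpha_stage():
        depth = (
            diversity.auto_depth(taxa)
            if config.rarefy_depth == "auto"
            else int(config.rarefy_depth)
        )
        rare = diversity.rarefy(taxa, depth, seed=config.seed)
        alpha = diversity.alpha_diversity(rare)
        alpha["timepoint"] = [meta.timepoint_of(s) for s in alpha.index]
        alpha["pair_id"] = [meta.records.loc[s, "pair_id"] for s in alpha.index]
        path = out / "alpha_diversity.tsv"
        alpha.to_csv(path, sep="\t")

        infants = alpha[alpha["timepoint"].isin(aio.INFANT_TIMEPOINTS)]
        weeks = diversity.timepoint_weeks(infants["timepoint"])
        rich = diversity.fit_richness_trend(infants["N"], weeks)
        s_global = int((taxa.counts.sum(axis=1) > 0).sum())
        div = diversity.fit_diversity_trend(
            infants["shannon"], weeks, divisor=np.log(s_global)
        )
        trends = pd.DataFrame(
            [
                {
                    "response": "richness_N",
                    "model": rich.model,
                    "slope": rich.slope,
                    "p": rich.slope_p_value,
                },
                {
                    "response": "shannon",
                    "model": div.model,
                    "slope": div.slope,
                    "p": div.slope_p_value,
                },
            ]
        )
        tpath = out / "trend_fits.tsv"
        trends.to_csv(tpath, sep="\t", index=False)
        return [str(path), str(tpath)]

    stage("alpha", alpha_stage)

    # -- ordination ------------------------------------------------------
    def ordination_stage(table, label):
        def run():
            rel = aio.to_relative(table)
            groups = meta.groups(rel.sample_ids)
            bc = ord_.bray_curtis_matrix(rel)
            res = ord_.anosim(bc, groups, config.n_permutations, config.seed)
            pw = ord_.pairwise_anosim(bc, groups, config.n_permutations, config.seed)
            perm = ord_.permanova(bc, groups, config.n_permutations, config.seed)
            gow = ord_.gower_matrix(rel)
            pcoa_res = ord_.pcoa(gow)
            cca_res = ord_.cca(table, groups)
            hulls = ord_.hull_dissimilarity(pcoa_res, groups)
            paths = []
            p = out / f"anosim_{label}.tsv"
            pd.DataFrame(
                [{"R": res.R, "p": res.p, "permanova_F": perm.pseudo_F,
                  "permanova_R2": perm.R2, "permanova_p": perm.p}]
            ).to_csv(p, sep="\t", index=False)
            paths.append(str(p))
            p = out / f"pairwise_anosim_{label}.tsv"
            pw.to_csv(p, sep="\t", index=False)
            paths.append(str(p))
            p = out / f"pcoa_{label}.tsv"
            pcoa_res.coordinates.to_csv(p, sep="\t")
            paths.append(str(p))
            p = out / f"cca_axes_{label}.tsv"
            pd.DataFrame(
                {
                    "eigenvalue": cca_res.eigenvalues,
                    "pct_total_inertia": cca_res.proportion_explained,
                    "pct_constrained_inertia": cca_res.proportion_constrained,
                }
            ).to_csv(p, sep="\t", index=False)
            paths.append(str(p))
            p = out / f"hull_dissimilarity_{label}.tsv"
            pd.DataFrame([vars(h) for h in hulls]).to_csv(p, sep="\t", index=False)
            paths.append(str(p))
            return paths

        return run

    stage("ordination_taxa", ordination_stage(taxa, "taxa"))
    if funcs is not None:
        stage("ordination_functions", ordination_stage(funcs, "functions"))

    # -- timecores -------------------------------------------------------
    def cores_stage():
        cores = tc.compute_timecores(taxa, meta)
        paths = []
        p = out / "timecore_membership_taxa.tsv"
        tc.membership_table(cores).to_csv(p, sep="\t")
        paths.append(str(p))
        infant = [c for c in cores if c.timepoint in aio.INFANT_TIMEPOINTS]
        p = out / "venn_counts_taxa.tsv"
        tc.venn_counts(infant).to_csv(p, sep="\t", header=["n_features"])
        paths.append(str(p))
        sharing = tc.pair_sharing(taxa, meta, "I1", "MA")
        p = out / "mother_infant_sharing.tsv"
        sharing.to_csv(p, sep="\t", header=["pct_shared"])
        paths.append(str(p))
        return paths

    stage("timecores", cores_stage)

    # -- functional profiles --------------------------------------------
    if joint is not None:
        def profiles_stage():
            profiles = fp.build_profiles(
                joint, meta, config.min_abundance, config.min_coverage
            )
            dend = fp.cluster_profiles(profiles)
            p1 = out / "functional_profile_groups.tsv"
            fp.group_membership(dend).to_csv(p1, sep="\t")
            p2 = out / "functional_profiles.nwk"
            p2.write_text(dend.newick())
            return [str(p1), str(p2)]

        stage("functional_profiles", profiles_stage)

    # -- SOM -------------------------------------------------------------
    def som_stage():
        clustering = som.bootstrap_som(
            taxa,
            meta,
            n_boot=config.som_boot,
            support_thresholds=config.som_supports,
            timepoints=list(aio.INFANT_TIMEPOINTS),
            seed=config.seed,
        )
        rows = pd.DataFrame(
            {
                "node": clustering.assignments,
                "support": clustering.supports,
            }
        )
        p = out / "som_clusters_taxa.tsv"
        rows.to_csv(p, sep="\t", index_label="feature")
        profs = som.build_profiles(taxa, meta, list(aio.INFANT_TIMEPOINTS))
        ci = som.cluster_mean_profiles(clustering, profs, max(config.som_supports))
        p2 = out / "som_cluster_profiles.tsv"
        ci.to_csv(p2, sep="\t", index=False)
        return [str(p), str(p2)]

    stage("som", som_stage)

    # -- co-occurrence network ------------------------------------------
    def network_stage():
        truth = synth.generate_environment_matrix(
            n_genera=min(40, taxa.shape[0]),
            n_samples=config.network_samples,
            n_environments=config.network_environments,
            affinity=0.9,
            n_planted_aggregations=4,
            n_planted_segregations=2,
            seed=config.seed,
        )
        # name environment taxa after the cohort's genera so timecores map in
        rename = dict(zip(truth.matrix.index, taxa.feature_ids))
        env = net.EnvironmentMatrix(truth.matrix.rename(index=rename), truth.labels)
        ens = net.null_ensemble(env, config.network_randomizations, seed=config.seed)
        parent = net.score_associations(env, ens, config.fpr_threshold)
        cores = tc.compute_timecores(taxa, meta)
        sub = net.extract_timecore_subnetwork(parent, cores)
        triangles, cliques = net.find_transitive_motifs(parent)
        p = out / "parent_network_edges.tsv"
        net.write_edge_list(parent, p)
        p2 = out / "timecore_subnetwork_edges.tsv"
        net.write_edge_list(sub, p2)
        p3 = out / "network_motifs.tsv"
        pd.DataFrame(
            [{"kind": "triangle", "members": "+".join(t)} for t in triangles]
            + [{"kind": "max_clique", "members": "+".join(c)} for c in cliques]
        ).to_csv(p3, sep="\t", index=False)
        return [str(p), str(p2), str(p3)]

    stage("network", network_stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
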