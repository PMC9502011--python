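"""End-to-end orchestration: simulate -> community -> ordination ->
network -> association -> agronomy.

A run is driven by a :class:`PipelineConfig` (YAML-loadable), executes the
enabled stages in order, writes every intermediate artifact under
``outdir``, and returns a manifest recording the package version, seed,
parameter values and input checksums.  Runs are deterministic under a
fixed seed.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agronomy, association, community, io, network, ordination, simulate
from ._version import __version__


@dataclass
class PipelineConfig:
    """All stage toggles and parameters of one pipeline run.

    Defaults are the study-design settings: rarefaction depth 20,000,
    genus-level network on taxa above 1% mean relative abundance, edge
    FDR cutoff 0.001, RMT threshold grid 0.30-0.95, Manhattan alpha 0.05,
    9,999 Mantel and 999 ANOSIM permutations.
    """

    outdir: str = "nitronet_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_community: bool = True
    run_ordination: bool = True
    run_network: bool = True
    run_association: bool = True
    run_agronomy: bool = True
    # inputs (used when run_simulate is False)
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    env_path: str | None = None
    agronomic_path: str | None = None
    guild_map_path: str | None = None
    # stage parameters
    simulation: dict = field(default_factory=dict)
    depth: int = 20_000
    aggregate_rank: str | None = "genus"
    abundance_threshold: float = 0.01
    abundance_rule: str = "union"
    fdr_method: str = "bh"
    fdr_q_cut: float = 0.001
    rmt_grid: tuple = (0.30, 0.95, 0.01)
    network_scope: str = "joint"
    manhattan_alpha: float = 0.05
    mantel_permutations: int = 9999
    anosim_permutations: int = 999
    comparison: tuple = ("CRU", "CRU+FA")
    reference_treatment: str = "CRU"
    duncan_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _grid(bounds) -> np.ndarray:
    lo, hi, step = bounds
    return np.round(np.arange(lo, hi + step / 2, step), 6)


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
    }

    # ---- inputs / simulation -------------------------------------------
    if config.run_simulate:
        sim_config = simulate.SimulationConfig(seed=config.seed, **config.simulation)
        counts, taxonomy, truth = simulate.simulate_community(sim_config)
        metadata = simulate.sample_metadata(sim_config)
        env = simulate.simulate_environment(truth, counts, sim_config)
        agronomic = simulate.simulate_agronomy(sim_config)
        guild_map = truth.guild_of
        io.write_count_table(counts, outdir / "counts.tsv")
        io.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        io.write_metadata(metadata, outdir / "metadata.tsv")
        io.write_env_matrix(env, outdir / "environment.tsv")
        io.write_agronomic_table(agronomic, outdir / "agronomy.tsv")
        io.write_guild_map(guild_map, outdir / "guilds.tsv")
        io.write_ground_truth(truth, outdir / "ground_truth.json")
        manifest["stages"]["simulate"] = {
            "n_taxa": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "depth": sim_config.depth,
        }
    else:
        needed = {"counts_path": config.counts_path, "metadata_path": config.metadata_path}
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise ValueError(f"simulation disabled but inputs missing: {missing}")
        counts = io.read_count_table(config.counts_path)
        taxonomy = io.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
        metadata = io.read_metadata(config.metadata_path)
        env = io.read_env_matrix(config.env_path) if config.env_path else None
        agronomic = (
            io.read_agronomic_table(config.agronomic_path) if config.agronomic_path else None
        )
        guild_map = io.read_guild_map(config.guild_map_path) if config.guild_map_path else None
        for key, value in (
            ("counts", config.counts_path), ("taxonomy", config.taxonomy_path),
            ("metadata", config.metadata_path), ("environment", config.env_path),
            ("agronomy", config.agronomic_path), ("guilds", config.guild_map_path),
        ):
            if value is not None:
                manifest["inputs"][key] = _sha256(Path(value))

    treatments = metadata["treatment"]

    # ---- community ------------------------------------------------------
    rarefied = rel = filtered = None
    if config.run_community:
        rarefied = community.rarefy(counts, config.depth, seed=config.seed)
        coverage = community.goods_coverage(rarefied)
        coverage.rename("goods_coverage").to_csv(outdir / "coverage.tsv", sep="\t")
        working = rarefied
        if config.aggregate_rank and taxonomy is not None:
            working = community.aggregate(working, taxonomy, config.aggregate_rank)
        rel = community.to_relative_abundance(working)
        filtered = community.filter_mean_abundance(
            rel, treatments.reindex(rel.columns), config.abundance_threshold,
            rule=config.abundance_rule,
        )
        io.write_count_table(rarefied, outdir / "rarefied.tsv")
        filtered.to_csv(outdir / "filtered_relabund.tsv", sep="\t")
        manifest["stages"]["community"] = {
            "n_samples_kept": int(rarefied.shape[1]),
            "mean_goods_coverage": float(coverage.mean()),
            "n_network_taxa": int(filtered.shape[0]),
        }

    # ---- ordination -----------------------------------------------------
    if config.run_ordination:
        if rarefied is None:
            raise ValueError("ordination requires the community stage")
        rel_otu = community.to_relative_abundance(rarefied)
        dm = ordination.bray_curtis(rel_otu)
        ord_result = ordination.pcoa(dm, n_axes=4)
        anosim_result = ordination.anosim(
            dm, treatments.reindex(list(dm.ids)),
            n_perm=config.anosim_permutations, seed=config.seed,
        )
        io.write_distance_matrix(dm, outdir / "bray_curtis.tsv")
        ord_result.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        manifest["stages"]["ordination"] = {
            "pc1_pct": float(100 * ord_result.proportion_explained[0]),
            "pc2_pct": float(100 * ord_result.proportion_explained[1]),
            "anosim_r": anosim_result.r,
            "anosim_p": anosim_result.p_value,
        }

    # ---- network --------------------------------------------------------
    partition = module_abund = net = None
    if config.run_network:
        if filtered is None:
            raise ValueError("network stage requires the community stage")
        corr = network.spearman_matrix(
            filtered, fdr_method=config.fdr_method, q_cut=config.fdr_q_cut
        )
        threshold, diagnostics = network.rmt_threshold(corr, grid=_grid(config.rmt_grid))
        diagnostics.to_csv(outdir / "rmt_diagnostics.tsv", sep="\t", index=False)
        net = network.build_network(
            corr, threshold, q_cut=config.fdr_q_cut, abundance=filtered.mean(axis=1)
        )
        partition = network.detect_modules(net, seed=config.seed)
        module_abund = network.module_abundance(partition, filtered)
        io.export_network(net, outdir / "network")
        partition.module_of.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
        module_abund.to_csv(outdir / "module_abundance.tsv", sep="\t")
        stats_all = network.network_stats(net, partition)
        per_treatment = {}
        if config.network_scope in ("joint", "per_treatment"):
            for trt in sorted(treatments.unique()):
                cols = [s for s in filtered.columns if treatments.get(s) == trt]
                if len(cols) < 4:
                    continue
                sub_corr = network.spearman_matrix(
                    filtered[cols], fdr_method=config.fdr_method, q_cut=config.fdr_q_cut
                )
                sub_net = network.build_network(sub_corr, threshold, q_cut=config.fdr_q_cut)
                per_treatment[trt] = network.network_stats(sub_net)
        manifest["stages"]["network"] = {
            "rmt_threshold": threshold,
            **stats_all,
            "per_treatment": per_treatment,
        }

    # ---- association ----------------------------------------------------
    if config.run_association:
        if partition is None:
            raise ValueError(
                "association stage requires the network stage (module partition missing)"
            )
        if env is None:
            raise ValueError("association stage requires an environmental matrix")
        heatmap = association.module_env_correlation(module_abund, env)
        heatmap.to_csv(outdir / "module_env_correlation.tsv", sep="\t", index=False)
        # module most positively correlated with the environment
        best = heatmap.loc[heatmap.groupby("module")["r"].idxmax()]
        focal_module = best.sort_values("r", ascending=False)["module"].iloc[0]
        group_a = [s for s in filtered.columns if treatments.get(s) == config.comparison[0]]
        group_b = [s for s in filtered.columns if treatments.get(s) == config.comparison[1]]
        manifest["stages"]["association"] = {"focal_module": focal_module}
        if len(group_a) >= 2 and len(group_b) >= 2:
            members = partition.module_of.index[partition.module_of == focal_module]
            manhattan = association.differential_otus(
                filtered, group_a, group_b, taxa=list(members),
                alpha=config.manhattan_alpha, taxonomy=taxonomy, partition=partition,
            )
            manhattan.to_csv(outdir / "manhattan.tsv", sep="\t")
            manifest["stages"]["association"].update(
                {
                    "n_enriched": int((manhattan["status"] == "enriched").sum()),
                    "n_depleted": int((manhattan["status"] == "depleted").sum()),
                }
            )
        if guild_map is not None and taxonomy is not None:
            day_dm = association.day_distance(metadata.loc[list(rarefied.columns)])
            mantel_rows = []
            for guild in sorted(set(guild_map) - {"none"}):
                try:
                    guild_dm = association.guild_distances(
                        community.to_relative_abundance(rarefied), taxonomy, guild_map, guild
                    )
                except ValueError:
                    continue
                for factor in env.columns:
                    env_dm = association.env_factor_distance(env.loc[list(guild_dm.ids)], factor)
                    result = association.partial_mantel(
                        guild_dm, env_dm, day_dm.filter(list(guild_dm.ids)),
                        n_perm=config.mantel_permutations, seed=config.seed,
                    )
                    mantel_rows.append((guild, factor, result.r, result.p_value))
            mantel_table = pd.DataFrame(mantel_rows, columns=["guild", "factor", "r", "p"])
            mantel_table.to_csv(outdir / "guild_mantel.tsv", sep="\t", index=False)
            manifest["stages"]["association"]["n_mantel_tests"] = len(mantel_table)

    # ---- agronomy -------------------------------------------------------
    if config.run_agronomy and agronomic is not None:
        efficiency = agronomy.efficiency_table(
            agronomic, reference=config.reference_treatment
        )
        efficiency.to_csv(outdir / "efficiency.tsv", sep="\t")
        letters = {}
        for column in ("grain_yield", "biomass", "thousand_grain"):
            if column in agronomic.columns:
                duncan = agronomy.anova_duncan(
                    agronomic[column], agronomic["treatment"], alpha=config.duncan_alpha
                )
                duncan.table.to_csv(outdir / f"duncan_{column}.tsv", sep="\t")
                letters[column] = duncan.table["letters"].to_dict()
        yield_means = agronomic.groupby("treatment")["grain_yield"].mean()
        ref = config.reference_treatment
        changes = {
            trt: agronomy.percent_change(v, yield_means[ref])
            for trt, v in yield_means.items()
            if trt != ref and ref in yield_means
        }
        manifest["stages"]["agronomy"] = {
            "yield_change_vs_reference": changes,
            "efficiency": {
                trt: {k: (None if v is None or v != v else float(v)) for k, v in row.items()}
                for trt, row in efficiency.iterrows()
            },
            "duncan_letters": letters,
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
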