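"""End-to-end orchestration: simulate/read -> match -> associate -> normalize -> networks.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage with the
study's default thresholds: association p < 0.001 with a 3-SD genotype
difference rule, epistasis p < 0.001 at 8 df, signal-to-noise 2 acquisition,
2.57-SD DE calls, 2.5 kb cis and 1 Mb region windows, 100 kb LD-proximity
flag, hub threshold 20, TFBS confidence 1.0, and three matched controls per
case.  Every stage writes its table under the output directory and the run
ends with a JSON manifest (paths, row counts, parameter echo, seed, stage
wall times).  Identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import association as assoc
from . import expression as expr
from . import networks as nets
from . import simulate as sim
from .errors import ConfigurationError, PiebaldNetError
from .genotypes import (
    GenotypeTable,
    allele_sharing,
    filter_snps,
    read_genotypes,
    select_controls,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat run configuration; unknown keys are rejected on load."""

    outdir: str = "piebaldnet_run"
    seed: int = 0
    simulate: sim.SimulationConfig | None = None
    genotype_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    intensity_path: str | None = None
    tfbs_path: str | None = None
    annotation_path: str | None = None
    min_call_rate: float = 0.0
    min_maf: float = 0.0
    require_polymorphic: bool = True
    k_controls: int = 3
    assoc_p: float = 0.001
    sd_multiplier: float = 3.0
    epistasis_p: float = 0.001
    proximity_bp: int = 100_000
    exclude_proximal: bool = False
    snr_min: float = 2.0
    de_sd: float = 2.57
    cis_bp: int = 2_500
    region_bp: int = 1_000_000
    hub_threshold: int = 20
    tfbs_confidence: float = 1.0
    min_tf_targets: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        raw = dict(raw)
        if isinstance(raw.get("simulate"), dict):
            sim_known = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
            sim_unknown = set(raw["simulate"]) - sim_known
            if sim_unknown:
                raise ConfigurationError(
                    f"unknown simulate keys: {sorted(sim_unknown)}"
                )
            block = dict(raw["simulate"])
            if "epistasis_penetrance_table" in block:
                block["epistasis_penetrance_table"] = tuple(
                    tuple(row) for row in block["epistasis_penetrance_table"]
                )
            raw["simulate"] = sim.SimulationConfig(**block)
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


def _write(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, sep="\t", index=False)
    return {"path": str(path), "rows": int(len(df))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": config.echo(),
        "stages": {},
        "outputs": {},
        "counters": {},
    }
    stage_name = "setup"

    def stage(name):
        nonlocal stage_name
        stage_name = name
        logger.info("stage %s", name)
        return time.perf_counter()

    def done(t0):
        manifest["stages"][stage_name] = round(time.perf_counter() - t0, 4)

    try:
        # ---------------- inputs -------------------------------------------
        if config.simulate is not None:
            t0 = stage("simulate")
            scfg = dataclasses.replace(config.simulate, seed=config.seed)
            table, truth = sim.simulate_cohort(scfg)
            annotation_df = sim.simulate_gene_annotation(scfg, table, truth)
            intensity_df = sim.simulate_microarray(scfg, truth)
            tfbs_df = sim.simulate_tfbs(scfg, truth)
            gpath = outdir / "genotypes.tsv"
            table.to_files(gpath, outdir / "snp_map.tsv", outdir / "phenotypes.tsv")
            manifest["outputs"]["genotypes"] = {"path": str(gpath), "rows": table.n_animals}
            manifest["outputs"]["annotation"] = _write(annotation_df, outdir / "gene_annotation.tsv")
            manifest["outputs"]["intensity"] = _write(intensity_df, outdir / "intensity.tsv")
            manifest["outputs"]["tfbs"] = _write(tfbs_df, outdir / "tfbs.tsv")
            truth.to_json(outdir / "truth.json")
            manifest["outputs"]["truth"] = {"path": str(outdir / "truth.json")}
            done(t0)
        else:
            t0 = stage("read")
            if not (config.genotype_path and config.map_path and config.phenotype_path):
                raise ConfigurationError(
                    "either a simulate block or genotype/map/phenotype paths are required"
                )
            table = read_genotypes(
                config.genotype_path, config.map_path, config.phenotype_path
            )
            annotation_df = (
                pd.read_csv(config.annotation_path, sep="\t")
                if config.annotation_path
                else None
            )
            intensity_df = (
                pd.read_csv(config.intensity_path, sep="\t")
                if config.intensity_path
                else None
            )
            tfbs_df = (
                pd.read_csv(config.tfbs_path, sep="\t") if config.tfbs_path else None
            )
            truth = None
            done(t0)

        # ---------------- genotype filtering and matching ------------------
        t0 = stage("filter")
        filtered = filter_snps(
            table,
            min_call_rate=config.min_call_rate,
            min_maf=config.min_maf,
            require_polymorphic=config.require_polymorphic,
        )
        manifest["counters"]["snps_input"] = table.n_snps
        manifest["counters"]["snps_after_filter"] = filtered.n_snps
        done(t0)

        t0 = stage("match")
        sharing = allele_sharing(filtered)
        cases = filtered.case_ids
        selected, provenance = select_controls(
            sharing, cases, filtered.control_ids, k_per_case=config.k_controls
        )
        matched = filtered.subset_animals(cases + selected)
        manifest["counters"]["cases"] = len(cases)
        manifest["counters"]["matched_controls"] = len(selected)
        prov_df = pd.DataFrame(
            [(c, i + 1, ctrl) for c, ctrls in provenance.items() for i, ctrl in enumerate(ctrls)],
            columns=["case_id", "rank", "control_id"],
        )
        manifest["outputs"]["matched_controls"] = _write(prov_df, outdir / "matched_controls.tsv")
        done(t0)

        # ---------------- association and epistasis ------------------------
        t0 = stage("associate")
        records = assoc.snp_association(matched)
        significant = assoc.significant_snps(
            records, p_threshold=config.assoc_p, sd_multiplier=config.sd_multiplier
        )
        manifest["counters"]["significant_snps"] = len(significant)
        manifest["outputs"]["association"] = _write(
            assoc.association_frame(records), outdir / "association.tsv"
        )
        done(t0)

        t0 = stage("epistasis")
        sig_ordered = [s for s in matched.snp_ids if s in significant]
        if len(sig_ordered) >= 2:
            pairs = assoc.epistasis_scan(
                matched,
                sig_ordered,
                p_threshold=config.epistasis_p,
                proximity_bp=config.proximity_bp,
            )
            sig_pairs = [p for p in pairs if p.significant]
        else:
            pairs, sig_pairs = [], []
            logger.warning("fewer than two significant SNPs; epistasis scan skipped")
        manifest["counters"]["epistasis_pairs_tested"] = len(pairs)
        manifest["counters"]["epistasis_pairs_significant"] = len(sig_pairs)
        manifest["outputs"]["epistasis"] = _write(
            assoc.epistasis_frame(pairs), outdir / "epistasis.tsv"
        )
        done(t0)

        # ---------------- expression ---------------------------------------
        de_results: list = []
        if intensity_df is not None:
            t0 = stage("normalize")
            acquired = expr.acquire(intensity_df, snr_min=config.snr_min)
            manifest["counters"]["probes_acquired"] = acquired["probe_id"].nunique()
            fit = expr.fit_normalization_model(acquired)
            manifest["counters"]["reml_iterations"] = fit.iterations
            manifest["counters"]["reml_converged"] = bool(fit.converged)
            norm = fit.normalized_expression.reset_index()
            manifest["outputs"]["normalized_expression"] = _write(
                norm, outdir / "normalized_expression.tsv"
            )
            with open(outdir / "variance_components.json", "w") as fh:
                json.dump(fit.variance_components, fh, indent=2)
            manifest["outputs"]["variance_components"] = {
                "path": str(outdir / "variance_components.json")
            }
            done(t0)

            t0 = stage("contrast")
            de_results = expr.compute_contrasts(fit)
            expr.call_de(de_results, sd_threshold=config.de_sd)
            corr = expr.contrast_correlations(de_results, sd_threshold=config.de_sd)
            manifest["outputs"]["de"] = _write(expr.de_frame(de_results), outdir / "de.tsv")
            manifest["outputs"]["contrast_correlations"] = _write(
                corr.reset_index(names="contrast"), outdir / "contrast_correlations.tsv"
            )
            done(t0)

        # ---------------- annotation ---------------------------------------
        mappings = []
        piebald_df = pd.DataFrame()
        if annotation_df is not None:
            t0 = stage("map")
            mappings = ann.map_snps_to_genes(
                matched, annotation_df, region_bp=config.region_bp
            )
            manifest["outputs"]["snp_gene_map"] = _write(
                ann.mapping_frame(mappings), outdir / "snp_gene_map.tsv"
            )
            done(t0)

            t0 = stage("genes")
            piebald_df = ann.call_piebald_genes(
                de_results, records, mappings, significant, cis_bp=config.cis_bp
            )
            manifest["counters"]["piebald_genes"] = len(piebald_df)
            manifest["outputs"]["piebald_genes"] = _write(
                piebald_df, outdir / "piebald_genes.tsv"
            )
            done(t0)

        # ---------------- networks -----------------------------------------
        if annotation_df is not None and tfbs_df is not None and len(piebald_df):
            t0 = stage("network")
            candidates = list(piebald_df["gene_id"])
            regulatory = nets.build_regulatory_network(
                tfbs_df,
                candidates,
                de_results,
                min_confidence=config.tfbs_confidence,
                min_targets=config.min_tf_targets,
            )
            epistatic, hubs = nets.build_epistatic_network(
                sig_pairs,
                mappings,
                de_results,
                hub_threshold=config.hub_threshold,
                exclude_proximal=config.exclude_proximal,
            )
            reduced = nets.reduce_by_hubs(epistatic, hubs)
            manifest["counters"]["regulatory_nodes"] = len(regulatory.nodes)
            manifest["counters"]["epistatic_nodes"] = len(epistatic.nodes)
            manifest["counters"]["hubs"] = len(hubs.hub_ids)
            manifest["counters"]["reduced_nodes"] = len(reduced.nodes)
            manifest["counters"]["reduced_edges"] = len(reduced.edges)
            for name, net in (
                ("regulatory", regulatory),
                ("epistatic", epistatic),
                ("epistatic_reduced", reduced),
            ):
                for fmt, suffix in (("sif", "sif"), ("graphml", "graphml"), ("tsv", "nodes.tsv")):
                    p = nets.export_network(net, outdir / f"{name}.{suffix}", format=fmt)
                    manifest["outputs"][f"{name}_{fmt}"] = {"path": str(p)}
            done(t0)

            t0 = stage("intersect")
            common, merged = nets.intersect_networks(regulatory, epistatic)
            manifest["counters"]["intersection_genes"] = len(common)
            manifest["outputs"]["intersection"] = _write(
                pd.DataFrame({"gene_id": sorted(common)}), outdir / "intersection.tsv"
            )
            nets.export_network(merged, outdir / "merged.graphml", format="graphml")
            manifest["outputs"]["merged_graphml"] = {"path": str(outdir / "merged.graphml")}
            if truth is not None:
                manifest["counters"]["planted_intersection_recovered"] = sorted(
                    common
                ) == sorted(truth.intersection_gene_ids)
            done(t0)

    except Exception as err:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(err)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise PiebaldNetError(f"stage {stage_name!r} failed: {err}") from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
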