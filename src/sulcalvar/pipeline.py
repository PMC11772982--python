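"""End-to-end orchestration of the analysis stages.

``run_pipeline`` drives: simulate -> variant score statistics -> sulcal
traits -> weighted correlation network -> cohort statistics ->
target-gene prioritization, writing every stage's outputs as TSV/JSON
plus a manifest with parameter values, seeds and content hashes so that
a rerun under the same configuration is verifiably identical.
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

from sulcalvar import io as svio
from sulcalvar.config import (
    ConfigurationError,
    NetworkParams,
    SimulationConfig,
    dataclass_from_dict,
)
from sulcalvar.cohort_stats import trait_group_regression
from sulcalvar.prioritization import (
    assign_targets,
    hypergeometric_enrichment,
    nearest_tss_bulk,
    recurrent_targets,
    top_variant_per_participant,
    write_gmt,
)
from sulcalvar.sulcal_similarity import cohort_trait_table
from sulcalvar.synthetic import simulate_study, tss_to_bed6
from sulcalvar.variant_scores import (
    per_participant_extremes,
    score_cohort_tests,
)
from sulcalvar.wcna import build_network, module_trait_correlation

log = logging.getLogger(__name__)

STAGES = ("simulate", "scores", "sulcal", "network", "stats", "prioritize")


@dataclass
class PipelineConfig:
    outdir: str = "sulcalvar_run"
    seed: int = 0
    alpha: float = 0.05
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    stages: tuple[str, ...] = STAGES
    regions: tuple[tuple[str, str], ...] = (("L", "hemisphere"),)

    def validate(self) -> "PipelineConfig":
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        self.simulation.validate()
        self.network.validate()
        if self.network.min_module_size > self.simulation.n_annotations:
            raise ConfigurationError(
                "min_module_size exceeds n_annotations")
        return self


def validate_config(path) -> PipelineConfig:
    """Load and normalize a YAML pipeline configuration.

    Unknown keys raise an error naming them; an empty file yields the
    full-default configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    known = {"outdir", "seed", "alpha", "simulation", "network", "stages",
             "regions"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    sim = dataclass_from_dict(SimulationConfig, raw.get("simulation", {}))
    net = dataclass_from_dict(NetworkParams, raw.get("network", {}))
    cfg = PipelineConfig(
        outdir=str(raw.get("outdir", "sulcalvar_run")),
        seed=int(raw.get("seed", 0)),
        alpha=float(raw.get("alpha", 0.05)),
        simulation=sim,
        network=net,
        stages=tuple(raw.get("stages", STAGES)),
        regions=tuple(tuple(r) for r in raw.get(
            "regions", [["L", "hemisphere"]])),
    )
    if not 0 < cfg.alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    return cfg.validate()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the output manifest."""
    config.validate()
    outdir = svio.ensure_dir(config.outdir)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "simulation": asdict(config.simulation),
            "network": asdict(config.network),
        },
        "outputs": {},
    }
    sim_cfg = SimulationConfig(
        **{**asdict(config.simulation), "seed": config.seed})

    def record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": path.name, "sha256": _hash_file(path)}

    try:
        study = simulate_study(sim_cfg, regions=config.regions)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    if "simulate" in config.stages:
        svio.write_variants_tsv(study["variants"], outdir / "variants.tsv")
        svio.write_scores_tsv(study["scores"], outdir / "scores.tsv")
        svio.write_graphs_json(study["graphs"], outdir / "graphs.json")
        svio.write_bed6(tss_to_bed6(study["tss"]), outdir / "tss.bed")
        write_gmt(study["gene_sets"], outdir / "gene_sets.gmt")
        for name in ("variants.tsv", "scores.tsv", "graphs.json",
                     "tss.bed", "gene_sets.gmt"):
            record(name, outdir / name)

    variants = study["variants"].copy()
    variants["variant_id"] = (
        variants["chrom"] + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ":" + variants["alt"])
    vmeta = variants.set_index("variant_id")
    scores = study["scores"]

    results: dict = {"manifest": manifest}

    if "scores" in config.stages:
        try:
            tests = score_cohort_tests(scores, vmeta["cohort"],
                                       alpha=config.alpha)
        except Exception as exc:
            raise RuntimeError(f"stage scores failed: {exc}") from exc
        tests.to_csv(outdir / "score_tests.tsv", sep="\t", index=False)
        record("score_tests.tsv", outdir / "score_tests.tsv")
        results["score_tests"] = tests

    traits = None
    if "sulcal" in config.stages:
        try:
            case_ids = sorted(
                pid for pid in study["graphs"] if pid.startswith("case"))
            ref_ids = sorted(
                pid for pid in study["graphs"] if pid.startswith("ctrl"))
            traits = cohort_trait_table(
                study["graphs"], reference_ids=ref_ids,
                subject_ids=case_ids + ref_ids)
        except Exception as exc:
            raise RuntimeError(f"stage sulcal failed: {exc}") from exc
        svio.write_trait_table(traits, outdir / "traits.tsv")
        record("traits.tsv", outdir / "traits.tsv")
        results["traits"] = traits

    if "network" in config.stages:
        try:
            maxima, minima = per_participant_extremes(
                scores, vmeta["participant"])
            case_rows = [p for p in maxima.index if p.startswith("case")]
            positive = build_network(
                maxima.loc[case_rows], config.network,
                label_prefix="Positive")
            negative = build_network(
                minima.loc[case_rows], config.network,
                label_prefix="Negative", negate=True)
        except Exception as exc:
            raise RuntimeError(f"stage network failed: {exc}") from exc
        positive.labels.rename("module").to_csv(
            outdir / "modules_positive.tsv", sep="\t",
            index_label="annotation")
        negative.labels.rename("module").to_csv(
            outdir / "modules_negative.tsv", sep="\t",
            index_label="annotation")
        record("modules_positive.tsv", outdir / "modules_positive.tsv")
        record("modules_negative.tsv", outdir / "modules_negative.tsv")
        results["network_positive"] = positive
        results["network_negative"] = negative
        if traits is not None:
            grid = module_trait_correlation(
                positive, traits, alpha=config.alpha)
            grid.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
            record("module_trait.tsv", outdir / "module_trait.tsv")
            results["module_trait"] = grid

    if "stats" in config.stages and traits is not None:
        try:
            status = pd.Series(
                [1.0 if p.startswith("case") else 0.0
                 for p in traits.index], index=traits.index)
            rng = np.random.default_rng(config.seed + 7)
            field_strength = pd.Series(
                rng.choice(["1.5T", "3.0T"], size=len(traits)),
                index=traits.index)
            comparison = trait_group_regression(traits, status,
                                                field_strength)
        except Exception as exc:
            raise RuntimeError(f"stage stats failed: {exc}") from exc
        comparison.to_csv(outdir / "trait_comparison.tsv", sep="\t",
                          index=False)
        record("trait_comparison.tsv", outdir / "trait_comparison.tsv")
        results["trait_comparison"] = comparison

    if "prioritize" in config.stages:
        try:
            target_ann = study["truth"].effect_annotations[0]
            case_vids = vmeta.index[vmeta["cohort"] == "case"]
            top = top_variant_per_participant(
                scores.loc[case_vids, target_ann],
                vmeta.loc[case_vids, "participant"])
            assignments = assign_targets(top, study["tss"])
            recurrent = recurrent_targets(assignments, min_count=2)
            study_genes = sorted({a.gene for a in assignments
                                  if a.gene is not None})
            # background: genes assigned to any case variant
            case_variants = variants[variants["cohort"] == "case"]
            background = set(
                nearest_tss_bulk(case_variants, study["tss"]).dropna()
            ) | set(study_genes)
            enrichment = hypergeometric_enrichment(
                study_genes, sorted(background), study["gene_sets"])
        except Exception as exc:
            raise RuntimeError(f"stage prioritize failed: {exc}") from exc
        recurrent.to_csv(outdir / "recurrent_genes.tsv", sep="\t",
                         index=False)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record("recurrent_genes.tsv", outdir / "recurrent_genes.tsv")
        record("enrichment.tsv", outdir / "enrichment.tsv")
        results["recurrent_genes"] = recurrent
        results["enrichment"] = enrichment

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
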