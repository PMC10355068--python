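"""End-to-end pipeline: config, seed fan-out, stage wiring, manifest.

A :class:`PipelineConfig` (YAML-loadable) drives the full analysis chain on
one dataset: rarefaction -> diversity/biogeography -> core taxa ->
biomarkers -> depth-stratified networks -> RAD model selection -> niche
breadth -> NST -> GMCI.  Every random stage receives its own seed derived
from one master seed by a fixed counter scheme (``master * 1000 + offset``),
so stages stay independently reproducible.  A manifest records versions,
seeds, a parameter hash and the checksum of every output file; re-running
the same config reproduces the manifest bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_taxa import biomarker_screen, summarize_taxa
from .datasets import (
    CommunityDataset,
    OtuTable,
    ValidationError,
    aggregate_rank,
    rarefy,
    read_community_data,
)
from .diversity import (
    alpha_diversity,
    beta_dissimilarity,
    distance_decay,
    geographic_distance,
    latitude_gradient_fit,
)
from .gmci import GmciCalibrationError, assess, build_indicators, calibrate, evaluate
from .network import correlation_network, identify_keystones, network_topology, node_centralities
from .rad import compare_rads
from .simulate import ImpactParams, SimulationParams, concat_datasets, simulate_dataset, simulate_impacted
from .stochasticity import niche_breadth, nst

logger = logging.getLogger(__name__)

# offsets of the master-seed fan-out, one per random stage
STAGE_SEEDS = {
    "simulate": 1,
    "impact": 2,
    "rarefy": 3,
    "mantel": 4,
    "network": 5,
    "rad": 6,
    "nst": 7,
    "gmci": 8,
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; every random stage has an explicit seed."""

    output_dir: str = "gmeb_results"
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    simulate: bool = True                      # generate inputs when no paths given
    n_sites: int = 60
    reads_per_sample: int = 30_000
    pool_richness: int = 300
    rarefaction_depth: int = 23_976            # survey convention; override at desk scale
    depth_bins: str = "0-20,20-40,40-60,60-80,80+"
    core_occurrence: float = 0.5
    core_mean_abund: float = 1e-4
    network_min_mean_abund: float = 1e-4
    network_r_threshold: float = 0.6
    network_p_threshold: float = 0.001
    nst_n_null: int = 200
    nst_max_group: int = 12
    rad_max_samples: int = 20
    gmci_n_impacted: int = 30
    impact_diversity_boost: float = 0.5
    impact_composition_shift: float = 0.5
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed * 1000 + STAGE_SEEDS[stage]) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def parse_depth_bins(text: str) -> list[tuple[float, float, str]]:
    """Parse "0-20,20-40,80+" into [(lo, hi, label), ...]."""
    bins = []
    for part in text.split(","):
        part = part.strip()
        if part.endswith("+"):
            lo = float(part[:-1])
            bins.append((lo, np.inf, part))
        else:
            lo, hi = part.split("-")
            bins.append((float(lo), float(hi), part))
    return bins


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    if config.table_path:
        dataset = read_community_data(
            config.table_path, config.taxonomy_path, config.metadata_path, config.tree_path
        )
        return dataset, None
    if not config.simulate:
        raise ValidationError("no input paths given and simulate disabled")
    sim = simulate_dataset(
        SimulationParams(
            n_sites=config.n_sites,
            pool_richness=config.pool_richness,
            reads_per_sample=config.reads_per_sample,
            seed=config.stage_seed("simulate"),
        )
    )
    return sim.dataset, sim


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing stage outputs and a manifest under
    ``config.output_dir``; returns the manifest dict.  A stage failure halts
    the run with the stage name; completed outputs are preserved."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "gmeb_version": __version__,
        "parameter_hash": config.parameter_hash(),
        "config": dataclasses.asdict(config),
        "seeds": {s: config.stage_seed(s) for s in STAGE_SEEDS},
        "stages": {},
        "outputs": {},
    }
    stage = "input"
    try:
        dataset, sim = _load_or_simulate(config)
        dataset.write(out / "input")
        manifest["stages"]["input"] = {"n_samples": dataset.table.shape[0],
                                       "n_otus": dataset.table.shape[1]}

        stage = "rarefy"
        depth = min(config.rarefaction_depth, int(dataset.table.sample_totals().min()))
        table = rarefy(dataset.table, depth, config.stage_seed("rarefy"))
        rare = CommunityDataset(table, dataset.taxonomy,
                                dataset.metadata.subset(table.sample_ids), dataset.tree)
        manifest["stages"]["rarefy"] = {"depth": depth, "n_kept": table.shape[0]}

        stage = "diversity"
        alpha = pd.DataFrame({
            "shannon": alpha_diversity(table, "shannon"),
            "faith_pd": alpha_diversity(table, "faith_pd", tree=rare.tree),
        })
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        bc = beta_dissimilarity(table)
        pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t")
        geo = geographic_distance(rare.metadata)
        ddr = distance_decay(geo, bc, seed=config.stage_seed("mantel"))
        ldg = latitude_gradient_fit(rare.metadata.data["latitude"], alpha["shannon"])
        fits = {
            "ddr_slope": ddr.fit.slope,
            "ddr_mantel_r": ddr.mantel.r,
            "ddr_mantel_p": ddr.mantel.p_value,
            "ldg_linear_pearson_r": ldg.linear.pearson_r,
            "ldg_quadratic_coefficient": ldg.quadratic.quadratic_coefficient,
            "ldg_peak_latitude": ldg.quadratic.peak,
            "ldg_adj_r2": ldg.quadratic.adj_r_squared,
        }
        (out / "biogeography.json").write_text(json.dumps(fits, indent=2))
        manifest["stages"]["diversity"] = fits

        stage = "core_taxa"
        summary = summarize_taxa(table, config.core_occurrence, config.core_mean_abund)
        summary.to_csv(out / "taxon_summary.tsv", sep="\t", index_label="otu_id")
        manifest["stages"]["core_taxa"] = {
            "n_core": int((summary["class"] == "core").sum()),
            "n_rare": int((summary["class"] == "rare").sum()),
        }

        stage = "biomarkers"
        bins = parse_depth_bins(config.depth_bins)
        depth_m = rare.metadata.data["well_depth"]
        labels = pd.Series("", index=depth_m.index)
        for lo, hi, lab in bins:
            labels[(depth_m >= lo) & (depth_m < hi)] = lab
        genus = aggregate_rank(table, rare.taxonomy, "genus")
        counts = labels.value_counts()
        usable = counts.index[counts >= 3]
        biomarkers = []
        if len(usable) >= 2:
            sel = labels[labels.isin(usable)]
            sub = OtuTable(genus.data.loc[sel.index])
            biomarkers = biomarker_screen(sub, sel)
        pd.DataFrame([dataclasses.asdict(b) for b in biomarkers]).to_csv(
            out / "biomarkers.tsv", sep="\t", index=False)
        manifest["stages"]["biomarkers"] = {"n_biomarkers": len(biomarkers)}

        stage = "network"
        keystones: list[str] = []
        net_stats = {}
        for lo, hi, lab in bins:
            ids = depth_m.index[(depth_m >= lo) & (depth_m < hi)]
            if len(ids) < 10:
                net_stats[lab] = "skipped: <10 samples"
                continue
            sub = OtuTable(genus.data.loc[ids]).drop_empty_otus()
            try:
                net = correlation_network(
                    sub,
                    min_mean_abund=config.network_min_mean_abund,
                    r_threshold=config.network_r_threshold,
                    p_threshold=config.network_p_threshold,
                    seed=config.stage_seed("network"),
                )
            except ValidationError as exc:
                net_stats[lab] = f"skipped: {exc}"
                continue
            if net.n_nodes == 0:
                net_stats[lab] = "empty network"
                continue
            topo = network_topology(net)
            metrics = node_centralities(net)
            ks = identify_keystones(metrics) if len(metrics) >= 5 else []
            keystones.extend(ks)
            net_stats[lab] = {**dataclasses.asdict(topo), "keystones": ks}
            net.edges.to_csv(out / f"network_edges_{lab.replace('+', 'plus')}.tsv",
                             sep="\t", index=False)
        (out / "network_topology.json").write_text(json.dumps(net_stats, indent=2))
        manifest["stages"]["network"] = {
            k: (v if isinstance(v, str) else {"n_nodes": v["n_nodes"], "n_edges": v["n_edges"]})
            for k, v in net_stats.items()
        }
        keystones = sorted(set(keystones))

        stage = "rad"
        rng = np.random.default_rng(config.stage_seed("rad"))
        sample_ids = table.sample_ids[: config.rad_max_samples]
        rad_rows = []
        for i, sid in enumerate(sample_ids):
            cmp_res = compare_rads(table.data.loc[sid].to_numpy(), seed=int(rng.integers(2**31 - 1)))
            rad_rows.append({"sample_id": sid, "best_model": cmp_res.best_model,
                             "verdict": cmp_res.verdict,
                             **{f"aic_{m}": cmp_res.aic_table.get(m, np.nan)
                                for m in cmp_res.aic_table.index}})
        rad_df = pd.DataFrame(rad_rows)
        rad_df.to_csv(out / "rad_aic.tsv", sep="\t", index=False)
        manifest["stages"]["rad"] = {
            "n_samples": len(rad_df),
            "fraction_neutral": float((rad_df["verdict"] == "neutral").mean()),
        }

        stage = "niche"
        nb = niche_breadth(table)
        pd.DataFrame({
            "habitat_niche_breadth": nb.habitat_niche_breadth,
            "mean_niche_breadth": nb.mean_niche_breadth,
        }).to_csv(out / "niche_breadth.tsv", sep="\t", index_label="sample_id")
        manifest["stages"]["niche"] = {
            "mean_habitat_breadth": float(nb.habitat_niche_breadth.mean())
        }

        stage = "nst"
        water = rare.metadata.data["water_type"]
        group = list(water.index[water == water.mode()[0]])[: config.nst_max_group]
        nst_res = nst(table, group=group, n_null=config.nst_n_null,
                      seed=config.stage_seed("nst"))
        nst_res.pairwise.to_csv(out / "nst_pairs.tsv", sep="\t", index=False)
        manifest["stages"]["nst"] = {
            "mean_nst_percent": nst_res.mean_nst_percent,
            "verdict": nst_res.verdict,
            "group_size": len(group),
        }

        stage = "gmci"
        if sim is not None:
            imp = simulate_impacted(
                sim,
                ImpactParams(config.impact_diversity_boost, config.impact_composition_shift,
                             seed=config.stage_seed("impact")),
            )
            imp_ids = imp.dataset.table.sample_ids[: config.gmci_n_impacted]
            impacted = imp.dataset.subset_samples(imp_ids)
            cands = build_indicators(dataset, keystones=keystones)
            try:
                model = calibrate(cands, dataset, impacted, seed=config.stage_seed("gmci"))
                model.to_json(out / "gmci_model.json")
                hb = model.reference["holdout_baseline"]
                hi = model.reference["holdout_impacted"]
                hold = concat_datasets(dataset.subset_samples(hb), impacted.subset_samples(hi))
                lab = pd.Series(["baseline"] * len(hb) + ["impacted"] * len(hi),
                                index=list(hb) + list(hi))
                result = evaluate(model, hold, lab)
                res = assess(model, hold)
                pd.DataFrame({"gmci": res.gmci, "flagged": res.flagged, "label": lab}).to_csv(
                    out / "gmci_assessment.tsv", sep="\t", index_label="sample_id")
                manifest["stages"]["gmci"] = {"n_indicators": len(model.indicators), **result}
            except GmciCalibrationError as exc:
                manifest["stages"]["gmci"] = {"refused": str(exc)}
        else:
            manifest["stages"]["gmci"] = "skipped: GMCI calibration needs an impacted set"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
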