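"""Synthetic community generator emulating continental groundwater surveys.

This module is an explicit stand-in for survey data: it generates
:class:`~gmeb.datasets.CommunityDataset` objects whose statistical structure
matches what the downstream analyses assume, so that every pipeline stage is
testable without sequence archives.  It emulates:

* a lognormal regional species-abundance distribution;
* one dominant phylum holding roughly half of all reads;
* a shallow-water clade whose abundance declines with well depth;
* alpha diversity declining with well depth (environmental filtering that
  sharpens with depth);
* a unimodal latitudinal diversity gradient peaking near 40 deg N (a
  carrying-capacity multiplier on realized site richness);
* distance decay of Bray-Curtis similarity (spatially autocorrelated latent
  environmental axes + Gaussian niche matching);
* an "impact" treatment that raises diversity and shifts composition, like
  reconstructed wells relative to newly constructed ones.

In ``neutral`` mode the niche terms are switched off and every site is a
multinomial draw from the shared regional pool.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datasets import (
    RANKS,
    CommunityDataset,
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
)

__all__ = [
    "SimulationParams",
    "ImpactParams",
    "SimulationResult",
    "simulate_dataset",
    "simulate_impacted",
    "concat_datasets",
]

N_PHYLA = 12
DOMINANT_PHYLUM = "Dominibacteriota"   # Proteobacteria-like generalist clade
SHALLOW_PHYLUM = "Parvulibacteriota"   # Patescibacteria-like depth-sensitive clade


@dataclass
class SimulationParams:
    """Knobs of the synthetic survey; defaults are the shipped study design."""

    n_sites: int = 100
    pool_richness: int = 300
    lognormal_meanlog: float = 0.0
    lognormal_sdlog: float = 1.5
    dominant_phylum_fraction: float = 0.52
    depth_range: tuple[float, float] = (5.0, 100.0)
    depth_filter_strength: float = 1.0
    patescibacteria_depth_slope: float = -0.02  # per metre, on the shallow clade
    latitude_peak: float = 40.0
    latitude_width: float = 10.0
    n_env_axes: int = 2
    dispersal_decay: float = 0.002  # km^-1: range of spatial autocorrelation
    reads_per_sample: int = 30_000
    assembly_mode: str = "deterministic"  # or "neutral"
    seed: int = 0

    def __post_init__(self):
        if self.assembly_mode not in ("deterministic", "neutral"):
            raise ValueError("assembly_mode must be 'deterministic' or 'neutral'")
        if not (0.0 <= self.dominant_phylum_fraction <= 1.0):
            raise ValueError("dominant_phylum_fraction must lie in [0, 1]")
        if self.depth_filter_strength < 0:
            raise ValueError("depth_filter_strength must be >= 0")
        if self.patescibacteria_depth_slope > 0:
            raise ValueError("patescibacteria_depth_slope must be <= 0")


@dataclass
class ImpactParams:
    """Anthropogenic-impact treatment applied to baseline samples."""

    diversity_boost: float = 0.5     # >= 0; flattens the community (evenness up)
    composition_shift: float = 0.5   # in [0, 1]; mixing weight of a contaminant pool
    seed: int = 0

    def __post_init__(self):
        if self.diversity_boost < 0:
            raise ValueError("diversity_boost must be >= 0")
        if not (0.0 <= self.composition_shift <= 1.0):
            raise ValueError("composition_shift must lie in [0, 1]")


@dataclass
class SimulationResult:
    dataset: CommunityDataset
    truth: dict


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _make_taxonomy(otu_ids, phylum_of, rng) -> TaxonomyMap:
    n = len(otu_ids)
    genera = [f"Genus{1 + i // 2:03d}" for i in range(n)]  # ~2 OTUs per genus
    rows = {}
    for i, otu in enumerate(otu_ids):
        phy = phylum_of[i]
        rows[otu] = [
            "Bacteria", phy, f"{phy}_class", f"{phy}_order",
            f"{phy}_family", genera[i], f"{otu}_sp",
        ]
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def _coalescent_merge(lineages: list[tuple[str, float]], rng,
                      t0: float = 0.0) -> tuple[str, float]:
    """Binary random coalescent over (newick, height) lineages; ultrametric."""
    t = t0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        merged = (f"({a[0]}:{t - a[1]:.6f},{b[0]}:{t - b[1]:.6f})", t)
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages[0]


def _make_tree(otu_ids, phylum_of, rng) -> TreeNode:
    """Random ultrametric binary tree whose clades follow the phylum labels."""
    by_phylum: dict[str, list[str]] = {}
    for otu, phy in zip(otu_ids, phylum_of):
        by_phylum.setdefault(phy, []).append(otu)
    clades = [
        _coalescent_merge([(nm, 0.0) for nm in members], rng)
        for phy, members in sorted(by_phylum.items())
    ]
    root_nwk, _ = _coalescent_merge(clades, rng, t0=max(h for _, h in clades))
    return TreeNode.read(io.StringIO(f"{root_nwk}:0.0;"))


def _spatial_field(lat, lon, dispersal_decay, rng) -> np.ndarray:
    """One latent axis: low-order lat/lon trend + spatially correlated noise."""
    from .diversity import EARTH_RADIUS_KM

    latr, lonr = np.radians(lat), np.radians(lon)
    dlat = latr[:, None] - latr[None, :]
    dlon = lonr[:, None] - lonr[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(latr)[:, None] * np.cos(latr)[None, :] * np.sin(dlon / 2) ** 2
    dist_km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    cov = np.exp(-dispersal_decay * dist_km) + 1e-8 * np.eye(len(lat))
    noise = rng.multivariate_normal(np.zeros(len(lat)), cov, method="cholesky")
    trend = rng.normal() * (lat - lat.mean()) / max(lat.std(), 1e-9) \
        + rng.normal() * (lon - lon.mean()) / max(lon.std(), 1e-9)
    field = trend + noise
    return (field - field.mean()) / max(field.std(), 1e-9)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_dataset(params: SimulationParams) -> SimulationResult:
    """Generate one baseline survey (all wells newly constructed)."""
    rng = np.random.default_rng(params.seed)
    S, n = params.pool_richness, params.n_sites
    otu_ids = [f"OTU{i + 1:05d}" for i in range(S)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # --- regional pool: lognormal SAD with a dominant clade ----------------
    pool = rng.lognormal(params.lognormal_meanlog, params.lognormal_sdlog, size=S)
    phyla = [DOMINANT_PHYLUM, SHALLOW_PHYLUM] + [f"Phylum{i:02d}" for i in range(3, N_PHYLA + 1)]
    # ~20% of taxa in the dominant phylum, ~15% in the shallow clade
    probs = np.array([0.20, 0.15] + [0.65 / (N_PHYLA - 2)] * (N_PHYLA - 2))
    phylum_of = rng.choice(phyla, size=S, p=probs)
    phylum_of[:2] = [DOMINANT_PHYLUM, SHALLOW_PHYLUM]  # both clades always occupied
    dom = phylum_of == DOMINANT_PHYLUM
    if 0 < params.dominant_phylum_fraction < 1 and dom.sum() < S:
        target = params.dominant_phylum_fraction
        pool[dom] *= (target / (1 - target)) * pool[~dom].sum() / pool[dom].sum()
    pool /= pool.sum()

    # --- sites -------------------------------------------------------------
    lat = rng.uniform(20.0, 52.0, size=n)
    lon = rng.uniform(80.0, 130.0, size=n)
    depth = rng.uniform(*params.depth_range, size=n)
    water = np.where(rng.random(n) < 0.7, "phreatic", "confined")
    zone_edges = np.quantile(lon, np.linspace(0, 1, 8))
    zone_idx = np.clip(np.searchsorted(zone_edges, lon, side="right") - 1, 0, 6)
    zones = np.array(["I", "II", "III", "IV", "V", "VI", "VII"])[zone_idx]

    env = np.column_stack(
        [_spatial_field(lat, lon, params.dispersal_decay, rng) for _ in range(params.n_env_axes)]
    )
    optima = rng.normal(0.0, 1.0, size=(S, params.n_env_axes))

    # --- per-site expected communities ------------------------------------
    depth_scaled = depth / max(params.depth_range[1], 1e-9)
    expected = np.tile(pool, (n, 1))
    if params.assembly_mode == "deterministic":
        sq = ((env[:, None, :] - optima[None, :, :]) ** 2).sum(axis=2)  # (site, taxon)
        exponent = params.depth_filter_strength * depth_scaled  # filtering sharpens with depth
        expected = expected * np.exp(-0.5 * sq * exponent[:, None])
        # shallow clade declines with depth
        shallow = phylum_of == SHALLOW_PHYLUM
        expected[:, shallow] *= np.exp(params.patescibacteria_depth_slope * depth)[:, None]
        # unimodal latitudinal carrying capacity acting on realized richness
        lat_factor = np.exp(-((lat - params.latitude_peak) ** 2) / (2 * params.latitude_width**2))
        site_richness = np.clip(np.round(0.9 * S * lat_factor).astype(int), 10, S)
        for i in range(n):
            order = np.argsort(expected[i])[::-1]
            expected[i, order[site_richness[i] :]] = 0.0
    expected /= expected.sum(axis=1, keepdims=True)
    if params.assembly_mode == "deterministic" and 0 < params.dominant_phylum_fraction < 1:
        # niche filtering redistributes reads between clades; rebalance the
        # dominant clade on realized expectations so its mean read share hits
        # the target (fixed-point rescaling, a few sweeps suffice)
        target = params.dominant_phylum_fraction
        for _ in range(4):
            share = expected[:, dom].sum(axis=1).mean()
            if abs(share - target) < 1e-4 or share in (0.0, 1.0):
                break
            f = (target / (1 - target)) / (share / (1 - share))
            expected[:, dom] *= f
            expected /= expected.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(params.reads_per_sample, expected[i]) for i in range(n)])
    table = OtuTable(counts, sample_ids, otu_ids)
    taxonomy = _make_taxonomy(otu_ids, phylum_of, rng)
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "latitude": lat,
                "longitude": lon,
                "well_depth": depth,
                "well_type": "newly_constructed",
                "water_type": water,
                "geo_zone": zones,
                **{f"env{a + 1}": env[:, a] for a in range(params.n_env_axes)},
            },
            index=sample_ids,
        )
    )
    tree = _make_tree(otu_ids, phylum_of, rng)
    dataset = CommunityDataset(table, taxonomy, metadata, tree)
    truth = {
        "params": asdict(params),
        "pool": pool,
        "phylum_of_otu": dict(zip(otu_ids, phylum_of)),
        "expected": pd.DataFrame(expected, index=sample_ids, columns=otu_ids),
        "env": env,
        "niche_optima": optima,
    }
    return SimulationResult(dataset=dataset, truth=truth)


def simulate_impacted(baseline: SimulationResult | CommunityDataset,
                      params: ImpactParams) -> SimulationResult:
    """Impacted twin of every baseline sample.

    Each twin's expected community is the baseline expectation mixed with a
    contaminant pool at weight ``composition_shift``, then flattened by the
    exponent ``1 / (1 + diversity_boost)`` (raising evenness, hence
    diversity); counts are redrawn at the original sequencing effort.  Twins
    carry the suffix ``_imp`` and well type ``reconstructed``.
    """
    if isinstance(baseline, SimulationResult):
        dataset, truth = baseline.dataset, baseline.truth
        expected = truth["expected"].to_numpy().copy()
        reads = truth["params"]["reads_per_sample"]
    else:
        dataset = baseline
        expected = dataset.table.counts() / dataset.table.sample_totals().to_numpy()[:, None]
        reads = int(dataset.table.sample_totals().median())
        truth = None
    rng = np.random.default_rng(params.seed)
    S = expected.shape[1]
    contaminant = rng.lognormal(0.0, 1.0, size=S)
    contaminant /= contaminant.sum()
    mixed = (1 - params.composition_shift) * expected + params.composition_shift * contaminant
    flattened = mixed ** (1.0 / (1.0 + params.diversity_boost))
    flattened /= flattened.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(reads, flattened[i]) for i in range(len(flattened))])

    sample_ids = [f"{sid}_imp" for sid in dataset.table.sample_ids]
    table = OtuTable(counts, sample_ids, dataset.table.otu_ids)
    meta = dataset.metadata.data.loc[dataset.table.sample_ids].copy()
    meta.index = sample_ids
    meta["well_type"] = "reconstructed"
    metadata = SampleMetadata(meta)
    out = CommunityDataset(table, dataset.taxonomy, metadata, dataset.tree)
    new_truth = {
        "impact_params": asdict(params),
        "expected": pd.DataFrame(flattened, index=sample_ids, columns=dataset.table.otu_ids),
        "contaminant_pool": contaminant,
        "baseline_truth": truth,
    }
    return SimulationResult(dataset=out, truth=new_truth)


def concat_datasets(a: CommunityDataset, b: CommunityDataset) -> CommunityDataset:
    """Stack two datasets sharing the same OTU space (e.g. baseline + impacted)."""
    if list(a.table.otu_ids) != list(b.table.otu_ids):
        raise ValueError("datasets must share an identical OTU space")
    table = OtuTable(pd.concat([a.table.data, b.table.data], axis=0))
    meta = SampleMetadata(pd.concat([a.metadata.data, b.metadata.data], axis=0))
    return CommunityDataset(table, a.taxonomy, meta, a.tree)
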