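"""Levins niche breadth and the normalized stochasticity ratio (NST).

Niche breadth B_j = 1 / sum_i P_ij^2, where P_ij is the proportion of taxon
j's total found in habitat (sample) i; community-level habitat niche breadth
and mean niche breadth are the sum and average of B over the taxa present in
a sample.

NST compares observed pairwise dissimilarity against a null expectation from
richness-preserving randomizations.  With observed dissimilarity D, null
expectation E, similarity C = 1 - D and E_C = 1 - E, the per-pair
stochasticity ratio is ST = E_C / C when C > E_C (communities more similar
than the null) and ST = E / D otherwise; NST rescales ST so that 0 means
fully deterministic and 1 fully stochastic:

    NST = (ST - ST_det) / (1 - ST_det),  ST_det = E_C or E respectively.

Group means are reported in percent with 50% as the conventional boundary
between more deterministic (< 50%) and more stochastic (> 50%) assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, jaccard

from .datasets import OtuTable, ValidationError, relative_abundance

__all__ = [
    "NicheBreadthResult",
    "NstResult",
    "niche_breadth",
    "null_communities",
    "nst",
    "phylogenetic_nst",
]

logger = logging.getLogger(__name__)


@dataclass
class NicheBreadthResult:
    per_taxon: pd.Series            # B_j
    habitat_niche_breadth: pd.Series  # per sample: sum of B over taxa present
    mean_niche_breadth: pd.Series     # per sample: mean of B over taxa present
    excluded_taxa: list[str] = field(default_factory=list)


def niche_breadth(table: OtuTable, pool_by: pd.Series | None = None) -> NicheBreadthResult:
    """Levins niche breadth per taxon plus per-sample community summaries.

    Habitats default to individual samples; pass *pool_by* (sample id ->
    group label, e.g. geo-zone) to pool samples into coarser habitats before
    computing P_ij.  All-zero taxa are excluded and logged.
    """
    counts = table.data
    if pool_by is not None:
        pooled = counts.groupby(pd.Series(pool_by).loc[counts.index]).sum()
    else:
        pooled = counts
    totals = pooled.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        logger.info("niche_breadth: excluding %d all-zero taxa", len(zero))
    keep = totals.index[totals > 0]
    P = pooled[keep] / totals[keep]
    B = 1.0 / (P**2).sum(axis=0)
    present = counts[keep] > 0
    habitat = present.mul(B, axis=1).sum(axis=1)
    richness = present.sum(axis=1)
    mean = habitat / richness.replace(0, np.nan)
    return NicheBreadthResult(
        per_taxon=B, habitat_niche_breadth=habitat, mean_niche_breadth=mean,
        excluded_taxa=zero,
    )


def null_communities(table: OtuTable, algorithm: str = "PF", n: int = 200,
                     seed: int = 0) -> list[np.ndarray]:
    """Richness-preserving null randomizations of a count table.

    The default "PF" algorithm (proportional occupancy, fixed richness)
    redraws, for every sample, which taxa occur — inclusion probabilities
    proportional to each taxon's regional occurrence frequency (randomized
    systematic probability-proportional-to-size draw), keeping the observed
    sample richness — then redraws the sample's reads multinomially over the
    occupied taxa with probabilities proportional to regional mean relative
    abundance.  Returns *n* arrays of the table's shape.
    """
    if algorithm != "PF":
        raise ValueError(f"unknown null algorithm {algorithm!r}")
    if n < 10:
        raise ValueError("need at least 10 null draws")
    counts = table.counts()
    n_samples, n_taxa = counts.shape
    freq = (counts > 0).mean(axis=0)
    mean_rel = relative_abundance(table).mean(axis=0).to_numpy()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    candidates = np.flatnonzero(freq > 0)
    if richness.max() > candidates.size:
        raise ValidationError("sample richness exceeds the number of occurring taxa")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        null = np.zeros((n_samples, n_taxa), dtype=np.int64)
        for i in range(n_samples):
            occ = _pps_sample(candidates, freq[candidates], int(richness[i]), rng)
            p = mean_rel[occ]
            p = p / p.sum()
            # one guaranteed read per occupied taxon keeps richness exact
            null[i, occ] = 1 + rng.multinomial(totals[i] - len(occ), p)
        draws.append(null)
    return draws


def _pps_sample(units: np.ndarray, weights: np.ndarray, k: int, rng) -> np.ndarray:
    """Fixed-size sample with inclusion probabilities proportional to weight.

    Randomized systematic PPS: inclusion probability is exactly k*w_i/sum(w)
    while k*w_i <= sum(w); heavier units are included outright and the rest
    resampled (the standard certainty-unit reduction).
    """
    units = np.asarray(units)
    w = np.asarray(weights, dtype=float)
    certain: list[np.ndarray] = []
    while True:
        if k <= 0:
            return np.concatenate(certain) if certain else np.array([], dtype=units.dtype)
        pi = k * w / w.sum()
        over = pi >= 1.0
        if not over.any():
            break
        certain.append(units[over])
        k -= int(over.sum())
        units, w = units[~over], w[~over]
    order = rng.permutation(len(units))
    cum = np.cumsum(k * w[order] / w.sum())
    points = rng.random() + np.arange(k)
    picks = np.searchsorted(cum, points, side="right")
    chosen = units[order[picks]]
    return np.concatenate(certain + [chosen]) if certain else chosen


_METRICS = {"bray_curtis": braycurtis, "jaccard": lambda u, v: jaccard(u > 0, v > 0)}


@dataclass
class NstResult:
    pairwise: pd.DataFrame  # columns: sample_i, sample_j, observed, expected, st, nst
    mean_nst_percent: float
    metric: str
    null_model: str
    n_null: int
    seed: int
    verdict: str  # "more_deterministic" (<50%) | "more_stochastic" (>50%)
    skipped_pairs: int = 0


def _pair_nst(D: float, E: float) -> tuple[float, float] | None:
    """Per-pair (ST, NST); None when the null expectation is degenerate."""
    if E <= 0.0 or E >= 1.0:
        return None
    C, E_C = 1.0 - D, 1.0 - E
    if C > E_C:  # observed more similar than expected
        st = E_C / C
        nst_val = (st - E_C) / (1.0 - E_C)
    else:
        if D <= 0.0:
            return None
        st = E / D
        nst_val = (st - E) / (1.0 - E)
    return st, nst_val


def nst(
    table: OtuTable,
    group: list[str] | None = None,
    metric: str = "bray_curtis",
    n_null: int = 200,
    seed: int = 0,
    null_algorithm: str = "PF",
) -> NstResult:
    """Normalized stochasticity ratio over within-group sample pairs."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    sub = table if group is None else OtuTable(table.data.loc[list(group)])
    if sub.shape[0] < 4:
        raise ValidationError("NST needs a group of >= 4 samples")
    dist = _METRICS[metric]
    counts = sub.counts().astype(float)
    m = counts.shape[0]
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    observed = np.array([dist(counts[i], counts[j]) for i, j in pairs])
    nulls = null_communities(sub, algorithm=null_algorithm, n=n_null, seed=seed)
    expected = np.zeros(len(pairs))
    for null in nulls:
        nf = null.astype(float)
        expected += np.array([dist(nf[i], nf[j]) for i, j in pairs])
    expected /= n_null

    rows, skipped = [], 0
    ids = sub.sample_ids
    for (i, j), D, E in zip(pairs, observed, expected):
        res = _pair_nst(float(D), float(E))
        if res is None:
            skipped += 1
            logger.warning("nst: degenerate pair (%s, %s) skipped", ids[i], ids[j])
            continue
        st, nst_val = res
        rows.append((ids[i], ids[j], D, E, st, nst_val))
    if not rows:
        raise ValidationError("every pair was degenerate; NST undefined")
    pairwise = pd.DataFrame(rows, columns=["sample_i", "sample_j", "observed",
                                           "expected", "st", "nst"])
    mean_pct = float(pairwise["nst"].mean() * 100.0)
    verdict = "more_stochastic" if mean_pct > 50.0 else "more_deterministic"
    return NstResult(pairwise=pairwise, mean_nst_percent=mean_pct, metric=metric,
                     null_model=null_algorithm, n_null=n_null, seed=seed,
                     verdict=verdict, skipped_pairs=skipped)


def phylogenetic_nst(
    table: OtuTable, tree, group: list[str] | None = None, n_null: int = 100,
    seed: int = 0,
) -> NstResult:
    """Phylogenetic NST based on between-sample beta mean nearest taxon
    distance (betaMNTD); nulls shuffle tip labels.  Exposed for range and
    determinism; taxonomic NST is the primary contract."""
    sub = table if group is None else OtuTable(table.data.loc[list(group)])
    if sub.shape[0] < 4:
        raise ValidationError("NST needs a group of >= 4 samples")
    otus = sub.otu_ids
    tip_dist = _tip_distance_matrix(tree, otus)
    rel = relative_abundance(sub).to_numpy()
    m = rel.shape[0]
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]

    def bmntd(dmat):
        out = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            pi, pj = rel[i] > 0, rel[j] > 0
            d_ij = dmat[np.ix_(pi, pj)]
            wi = rel[i][pi] / rel[i][pi].sum()
            wj = rel[j][pj] / rel[j][pj].sum()
            out[k] = 0.5 * ((wi * d_ij.min(axis=1)).sum() + (wj * d_ij.min(axis=0)).sum())
        return out

    observed = bmntd(tip_dist)
    rng = np.random.default_rng(seed)
    expected = np.zeros(len(pairs))
    for _ in range(n_null):
        perm = rng.permutation(len(otus))
        expected += bmntd(tip_dist[np.ix_(perm, perm)])
    expected /= n_null
    scale = max(tip_dist.max(), 1e-12)  # map distances into [0, 1] for the ratio formula
    rows, skipped = [], 0
    ids = sub.sample_ids
    for (i, j), D, E in zip(pairs, observed / scale, expected / scale):
        res = _pair_nst(float(D), float(E))
        if res is None:
            skipped += 1
            continue
        st, nst_val = res
        rows.append((ids[i], ids[j], D, E, st, nst_val))
    if not rows:
        raise ValidationError("every pair was degenerate; NST undefined")
    pairwise = pd.DataFrame(rows, columns=["sample_i", "sample_j", "observed",
                                           "expected", "st", "nst"])
    mean_pct = float(pairwise["nst"].mean() * 100.0)
    verdict = "more_stochastic" if mean_pct > 50.0 else "more_deterministic"
    return NstResult(pairwise=pairwise, mean_nst_percent=mean_pct, metric="betaMNTD",
                     null_model="tip_shuffle", n_null=n_null, seed=seed,
                     verdict=verdict, skipped_pairs=skipped)


def _tip_distance_matrix(tree, otus: list[str]) -> np.ndarray:
    dm = tree.tip_tip_distances(set(otus))
    order = [dm.index(o) for o in otus]
    return dm.data[np.ix_(order, order)]
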