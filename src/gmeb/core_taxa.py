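"""Core/rare taxon classification, group-preference tests, biomarker screen.

Core taxa are defined as taxa with occurrence frequency > 50% of samples and
mean relative abundance > 0.01%; regionally rare taxa have mean relative
abundance < 0.001%.  Group preference uses the two-sided Wilcoxon rank-sum
test on relative abundances; the biomarker screen is a Kruskal-Wallis test
with Benjamini-Hochberg control and an abundance floor, yielding a ranked
list of differentially abundant taxa per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import OtuTable, relative_abundance

__all__ = [
    "TaxonSummary",
    "BiomarkerResult",
    "summarize_taxa",
    "group_preference",
    "biomarker_screen",
    "adjust_pvalues",
]

logger = logging.getLogger(__name__)

CORE_OCCURRENCE = 0.5       # strict > 50% of samples
CORE_MEAN_ABUND = 1e-4      # strict > 0.01% mean relative abundance
RARE_MEAN_ABUND = 1e-5      # strict < 0.001%


@dataclass
class TaxonSummary:
    taxon_id: str
    occurrence: float
    mean_abundance: float
    taxon_class: str  # "core" | "rare" | "other"


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, method in {bh, bonferroni}."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def summarize_taxa(
    table: OtuTable,
    core_occurrence: float = CORE_OCCURRENCE,
    core_mean_abund: float = CORE_MEAN_ABUND,
    rare_mean_abund: float = RARE_MEAN_ABUND,
) -> pd.DataFrame:
    """Occurrence frequency, mean relative abundance and core/rare class.

    Returns a DataFrame indexed by taxon with columns ``occurrence``,
    ``mean_abundance`` and ``class``.  Core requires occurrence strictly
    above *core_occurrence* AND mean abundance strictly above
    *core_mean_abund*; rare requires mean abundance strictly below
    *rare_mean_abund*.
    """
    rel = relative_abundance(table)
    occ = (table.data > 0).mean(axis=0)
    mean_ab = rel.mean(axis=0)
    cls = np.where(
        (occ > core_occurrence) & (mean_ab > core_mean_abund),
        "core",
        np.where(mean_ab < rare_mean_abund, "rare", "other"),
    )
    return pd.DataFrame(
        {"occurrence": occ, "mean_abundance": mean_ab, "class": cls},
        index=table.otu_ids,
    )


def group_preference(
    table: OtuTable,
    labels: pd.Series,
    adjust: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon two-sided Wilcoxon rank-sum test between two groups.

    *labels* maps sample id -> group name (exactly two groups, each with at
    least 3 samples).  Preference is the higher-median group when the
    adjusted p-value is below *alpha*, else none.
    """
    labels = pd.Series(labels).astype(str)
    labels = labels.loc[table.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"group_preference needs exactly 2 groups, got {groups}")
    sizes = labels.value_counts()
    if (sizes < 3).any():
        raise ValueError(f"each group needs >= 3 samples, got {sizes.to_dict()}")
    rel = relative_abundance(table)
    a = rel.loc[labels[labels == groups[0]].index].to_numpy()
    b = rel.loc[labels[labels == groups[1]].index].to_numpy()
    stats_, pvals = [], []
    for j in range(a.shape[1]):
        x, y = a[:, j], b[:, j]
        # exact null distribution when feasible (small untied groups), else
        # the normal approximation with tie correction
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (no_ties and max(len(x), len(y)) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stats_.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    stats_, pvals = np.asarray(stats_), np.asarray(pvals)
    adj = adjust_pvalues(pvals, adjust)
    med_a, med_b = np.median(a, axis=0), np.median(b, axis=0)
    pref = np.where(
        adj < alpha, np.where(med_a > med_b, groups[0], groups[1]), "none"
    )
    # a significant taxon with exactly tied medians has no defensible side
    pref = np.where((adj < alpha) & (med_a == med_b), "none", pref)
    return pd.DataFrame(
        {"statistic": stats_, "p_value": pvals, "adjusted_p": adj, "preference": pref},
        index=table.otu_ids,
    )


@dataclass
class BiomarkerResult:
    taxon: str
    group: str
    statistic: float
    adjusted_p: float
    effect: float  # log10 of enriched-group mean over grand mean


def biomarker_screen(
    table: OtuTable,
    labels: pd.Series,
    min_mean_abund: float = 0.005,
    alpha: float = 0.05,
    min_effect: float = 0.0,
) -> list[BiomarkerResult]:
    """Kruskal-Wallis screen for group-enriched taxa.

    For every taxon, a Kruskal-Wallis test on relative abundances across >= 2
    groups (each with >= 3 samples), Benjamini-Hochberg adjusted.  Kept taxa
    need adjusted p < *alpha*, enriched-group mean relative abundance >=
    *min_mean_abund*, and effect (log10 ratio of enriched-group mean to the
    grand mean) >= *min_effect*.  Results are sorted by effect, descending.
    """
    labels = pd.Series(labels).astype(str).loc[table.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("biomarker_screen needs >= 2 groups")
    sizes = labels.value_counts()
    if (sizes < 3).any():
        raise ValueError(f"each group needs >= 3 samples, got {sizes.to_dict()}")
    rel = relative_abundance(table)
    by_group = {g: rel.loc[labels[labels == g].index] for g in groups}

    taxa, stats_list, pvals = [], [], []
    for taxon in table.otu_ids:
        samples = [by_group[g][taxon].to_numpy() for g in groups]
        if rel[taxon].sum() == 0:
            logger.info("biomarker_screen: skipping all-zero taxon %s", taxon)
            continue
        if all(np.ptp(np.concatenate(samples)) == 0 for _ in (0,)):
            # constant across all samples: no group signal by construction
            continue
        h, p = stats.kruskal(*samples)
        taxa.append(taxon)
        stats_list.append(h)
        pvals.append(p)
    if not taxa:
        return []
    adj = adjust_pvalues(pvals, "bh")
    out: list[BiomarkerResult] = []
    grand_mean = rel.mean(axis=0)
    for taxon, h, q in zip(taxa, stats_list, adj):
        if q >= alpha:
            continue
        gmeans = {g: float(by_group[g][taxon].mean()) for g in groups}
        enriched = max(gmeans, key=gmeans.get)
        if gmeans[enriched] < min_mean_abund:
            continue
        gm = float(grand_mean[taxon])
        effect = float(np.log10(gmeans[enriched] / gm)) if gm > 0 else np.inf
        if effect < min_effect:
            continue
        out.append(BiomarkerResult(taxon=taxon, group=enriched, statistic=float(h),
                                   adjusted_p=float(q), effect=effect))
    out.sort(key=lambda b: -b.effect)
    return out
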