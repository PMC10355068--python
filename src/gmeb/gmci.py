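"""Groundwater Microbial Community Index (GMCI).

A multimetric observed/expected (O/E) index for flagging anthropogenic
impact on groundwater microbial communities, in four steps:

1. a baseline (reference) group of undisturbed samples from a comparable
   habitat supplies the expectations;
2. candidate indicators are community diversity (Shannon, Faith PD),
   dominator taxa (core phyla/genera), key species (network keystones) and
   biomarkers, with taxon indicators vetted by occurrence >= 20% and mean
   relative abundance >= 0.5% in the baseline;
3. a seeded 60/40 split calibrates each indicator: its expectation is the
   median over calibration baseline samples and its alarm O/E ratio
   maximizes (accuracy - error) on the calibration split; indicators with
   poor holdout accuracy or error are eliminated;
4. surviving indicators are combined with weights proportional to holdout
   accuracy.  A sample's GMCI is the weighted sum of normalized log O/E
   deviations, scaled so that GMCI = 1.0 is exactly the all-alarms boundary;
   GMCI >= 1.0 flags the sample as impacted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core_taxa import BiomarkerResult, adjust_pvalues, summarize_taxa
from .datasets import CommunityDataset, ValidationError, aggregate_rank, relative_abundance
from .diversity import alpha_diversity

__all__ = [
    "Indicator",
    "GmciModel",
    "GmciAssessment",
    "GmciCalibrationError",
    "build_indicators",
    "calibrate",
    "assess",
    "evaluate",
]

logger = logging.getLogger(__name__)

S_MAX = 10.0  # cap on a single indicator's deviation score (zero observations)
ALARM_THRESHOLD = 1.0


class GmciCalibrationError(RuntimeError):
    """No indicator survived vetting; carries the per-indicator report."""

    def __init__(self, message, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


@dataclass
class Indicator:
    id: str
    kind: str                   # diversity | dominator | key_species | biomarker
    statistic: str              # "shannon" | "faith_pd" | "relative_abundance"
    taxon: str | None = None    # taxon indicators only
    rank: str | None = None     # taxon indicators only
    direction: str = "two_sided"  # two_sided | high | low
    expectation: float | None = None
    alarm_oe: float | None = None
    accuracy: float | None = None
    error: float | None = None
    weight: float | None = None


@dataclass
class GmciModel:
    indicators: list[Indicator]
    reference: dict
    split: float
    seed: int
    vetting_report: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "indicators": [asdict(i) for i in self.indicators],
            "reference": self.reference,
            "split": self.split,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GmciModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            indicators=[Indicator(**d) for d in payload["indicators"]],
            reference=payload["reference"],
            split=payload["split"],
            seed=payload["seed"],
        )


@dataclass
class GmciAssessment:
    gmci: pd.Series                 # per-sample index value
    flagged: pd.Series              # GMCI >= 1.0
    oe_ratios: pd.DataFrame         # samples x indicators
    scores: pd.DataFrame            # samples x indicators, weighted pieces s_i


# ---------------------------------------------------------------------------
# indicator construction
# ---------------------------------------------------------------------------

def _taxon_candidates(dataset: CommunityDataset, rank: str) -> pd.DataFrame:
    agg = aggregate_rank(dataset.table, dataset.taxonomy, rank)
    return summarize_taxa(agg)


def build_indicators(
    baseline: CommunityDataset,
    keystones: list[str] | None = None,
    biomarkers: list[BiomarkerResult] | list[str] | None = None,
    min_occurrence: float = 0.2,
    min_mean_abund: float = 0.005,
) -> list[Indicator]:
    """Candidate indicator list from a baseline (newly constructed wells).

    Diversity indicators (Shannon; Faith PD when a tree is present) are
    always candidates.  Taxon indicators — dominators (core taxa at phylum
    and genus rank), key species (*keystones*, genus level) and *biomarkers*
    (genus level) — must occur in >= *min_occurrence* of baseline samples
    with mean relative abundance >= *min_mean_abund*.
    """
    if (baseline.metadata.data["well_type"] != "newly_constructed").any():
        raise ValidationError("baseline must contain newly constructed wells only")
    indicators: list[Indicator] = [
        Indicator(id="shannon", kind="diversity", statistic="shannon")
    ]
    if baseline.tree is not None:
        indicators.append(Indicator(id="faith_pd", kind="diversity", statistic="faith_pd"))

    summaries = {r: _taxon_candidates(baseline, r) for r in ("phylum", "genus")}

    def passes(rank: str, taxon: str) -> bool:
        s = summaries[rank]
        if taxon not in s.index:
            return False
        row = s.loc[taxon]
        return row["occurrence"] >= min_occurrence and row["mean_abundance"] >= min_mean_abund

    seen: set[tuple[str, str]] = set()

    def add(kind: str, rank: str, taxon: str) -> None:
        key = (rank, taxon)
        if key in seen or not passes(rank, taxon):
            return
        seen.add(key)
        indicators.append(
            Indicator(id=f"{kind}:{rank}:{taxon}", kind=kind,
                      statistic="relative_abundance", taxon=taxon, rank=rank)
        )

    for rank in ("phylum", "genus"):
        core = summaries[rank].index[summaries[rank]["class"] == "core"]
        for taxon in core:
            add("dominator", rank, taxon)
    for taxon in keystones or []:
        add("key_species", "genus", taxon)
    for b in biomarkers or []:
        add("biomarker", "genus", b.taxon if isinstance(b, BiomarkerResult) else b)

    if not indicators:
        raise GmciCalibrationError("empty candidate indicator set")
    return indicators


def indicator_values(dataset: CommunityDataset, indicators: list[Indicator]) -> pd.DataFrame:
    """Samples x indicators matrix of observed statistic values."""
    cols = {}
    rank_tables: dict[str, pd.DataFrame] = {}
    for ind in indicators:
        if ind.statistic == "shannon":
            cols[ind.id] = alpha_diversity(dataset.table, "shannon")
        elif ind.statistic == "faith_pd":
            cols[ind.id] = alpha_diversity(dataset.table, "faith_pd", tree=dataset.tree)
        else:
            if ind.rank not in rank_tables:
                agg = aggregate_rank(dataset.table, dataset.taxonomy, ind.rank)
                rank_tables[ind.rank] = relative_abundance(agg)
            rel = rank_tables[ind.rank]
            if ind.taxon in rel.columns:
                cols[ind.id] = rel[ind.taxon]
            else:
                logger.warning("indicator %s: taxon absent, imputing 0", ind.id)
                cols[ind.id] = pd.Series(0.0, index=rel.index)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _fold(oe: np.ndarray, direction: str) -> np.ndarray:
    """Fold O/E onto the alarmed side: >= 1 means 'at least this deviant'."""
    oe = np.asarray(oe, dtype=float)
    if direction == "two_sided":
        with np.errstate(divide="ignore"):
            return np.where(oe > 0, np.maximum(oe, 1.0 / np.where(oe > 0, oe, 1.0)), np.inf)
    if direction == "high":
        return oe
    if direction == "low":
        with np.errstate(divide="ignore"):
            return np.where(oe > 0, 1.0 / oe, np.inf)
    raise ValueError(direction)


def _flag_rate(folded: np.ndarray, alarm_folded: float) -> float:
    return float(np.mean(folded >= alarm_folded))


def calibrate(
    candidates: list[Indicator],
    baseline: CommunityDataset,
    impacted: CommunityDataset,
    split: float = 0.6,
    accuracy_min: float = 0.5,
    error_max: float = 0.5,
    vetting_alpha: float = 0.05,
    seed: int = 0,
) -> GmciModel:
    """Seeded 60/40 calibration of expectations, alarm ratios and weights.

    Per indicator: expectation = median over calibration baseline samples;
    the alarm O/E ratio maximizes (accuracy - error) on the calibration
    split, where accuracy is the fraction of impacted samples flagged and
    error the fraction of baseline samples flagged.  Vetting then requires,
    on the holdout split: accuracy >= *accuracy_min*, error <= *error_max*,
    and a flag-rate difference that beats chance (one-sided Fisher exact
    test of flagged impacted vs flagged baseline, Benjamini-Hochberg
    adjusted across candidates, at *vetting_alpha*) — without the
    significance screen, chance-level indicators slip through whenever the
    impact effect is absent.  Weights are holdout accuracies normalized to
    sum 1.
    """
    n_base = baseline.table.shape[0]
    n_imp = impacted.table.shape[0]
    if n_base < 10 or n_imp < 5:
        raise ValidationError("calibration needs >= 10 baseline and >= 5 impacted samples")
    rng = np.random.default_rng(seed)
    base_ids = list(np.array(baseline.table.sample_ids)[rng.permutation(n_base)])
    imp_ids = list(np.array(impacted.table.sample_ids)[rng.permutation(n_imp)])
    nb_cal, ni_cal = int(round(split * n_base)), int(round(split * n_imp))
    base_cal, base_hold = base_ids[:nb_cal], base_ids[nb_cal:]
    imp_cal, imp_hold = imp_ids[:ni_cal], imp_ids[ni_cal:]

    vb = indicator_values(baseline, candidates)
    vi = indicator_values(impacted, candidates)

    report_rows = []
    scored: list[tuple[Indicator, float, float, float, float]] = []
    for ind in candidates:
        expectation = float(vb.loc[base_cal, ind.id].median())
        if expectation <= 0:
            report_rows.append((ind.id, np.nan, np.nan, np.nan, np.nan, "zero expectation"))
            continue
        oe_bc = _fold(vb.loc[base_cal, ind.id] / expectation, ind.direction)
        oe_ic = _fold(vi.loc[imp_cal, ind.id] / expectation, ind.direction)
        grid = np.unique(np.concatenate([oe_bc, oe_ic]))
        grid = grid[np.isfinite(grid) & (grid > 1.0 + 1e-9)]
        if grid.size == 0:
            report_rows.append((ind.id, np.nan, np.nan, np.nan, np.nan, "no usable alarm grid"))
            continue
        best_alarm, best_score = None, -np.inf
        for alarm in grid:
            score = _flag_rate(oe_ic, alarm) - _flag_rate(oe_bc, alarm)
            # ties go to the larger (more conservative) alarm ratio
            if score > best_score or (score == best_score and (best_alarm is None or alarm > best_alarm)):
                best_alarm, best_score = float(alarm), score
        oe_bh = _fold(vb.loc[base_hold, ind.id] / expectation, ind.direction)
        oe_ih = _fold(vi.loc[imp_hold, ind.id] / expectation, ind.direction)
        acc = _flag_rate(oe_ih, best_alarm)
        err = _flag_rate(oe_bh, best_alarm)
        a, b = int(round(acc * len(imp_hold))), int(round(err * len(base_hold)))
        p_chance = stats.fisher_exact(
            [[a, len(imp_hold) - a], [b, len(base_hold) - b]], alternative="greater"
        )[1]
        scored.append((Indicator(**{**asdict(ind), "expectation": expectation,
                                    "alarm_oe": best_alarm}), acc, err, best_alarm, p_chance))
    vetted: list[Indicator] = []
    if scored:
        adj = adjust_pvalues([s[4] for s in scored], "bh")
        for (ind, acc, err, alarm, _), q in zip(scored, adj):
            ok = acc >= accuracy_min and err <= error_max and q < vetting_alpha
            status = "vetted" if ok else "eliminated"
            report_rows.append((ind.id, alarm, acc, err, q, status))
            if ok:
                ind.accuracy, ind.error = acc, err
                vetted.append(ind)
    report = pd.DataFrame(report_rows,
                          columns=["indicator", "alarm_oe", "holdout_accuracy",
                                   "holdout_error", "adjusted_p", "status"]).set_index("indicator")
    if not vetted:
        raise GmciCalibrationError(
            "no indicator passed vetting (no reliable impact signal)", report=report
        )
    total_acc = sum(i.accuracy for i in vetted)
    if total_acc <= 0:
        raise GmciCalibrationError("vetted indicators all have zero accuracy", report=report)
    for i in vetted:
        i.weight = i.accuracy / total_acc
    reference = {
        "well_type": "newly_constructed",
        "n_baseline": n_base,
        "n_impacted": n_imp,
        "holdout_baseline": base_hold,
        "holdout_impacted": imp_hold,
    }
    return GmciModel(indicators=vetted, reference=reference, split=split, seed=seed,
                     vetting_report=report)


# ---------------------------------------------------------------------------
# assessment and evaluation
# ---------------------------------------------------------------------------

def assess(model: GmciModel, samples: CommunityDataset | pd.DataFrame) -> GmciAssessment:
    """Score samples against a calibrated model.

    Per indicator i the deviation is s_i = |ln(O_i/E_i)| / |ln(alarm_oe_i)|
    (counted only on the alarmed side for one-sided indicators; capped at
    10 when O = 0); GMCI = sum_i w_i s_i, flagged iff GMCI >= 1.0.
    """
    values = samples if isinstance(samples, pd.DataFrame) else indicator_values(samples, model.indicators)
    oe = pd.DataFrame(index=values.index)
    scores = pd.DataFrame(index=values.index)
    for ind in model.indicators:
        o = values[ind.id].to_numpy(dtype=float)
        ratio = o / ind.expectation
        log_alarm = abs(np.log(ind.alarm_oe))
        with np.errstate(divide="ignore"):
            log_ratio = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), np.nan)
        if ind.direction == "two_sided":
            s = np.abs(log_ratio) / log_alarm
        elif ind.direction == "high":
            s = np.maximum(log_ratio, 0.0) / log_alarm
        else:  # low
            s = np.maximum(-log_ratio, 0.0) / log_alarm
        zero = ~np.isfinite(log_ratio) | np.isnan(s)
        if zero.any():
            logger.warning("assess: %d zero observation(s) for %s capped at %.0f",
                           int(zero.sum()), ind.id, S_MAX)
        s = np.where(zero, S_MAX, np.minimum(s, S_MAX))
        oe[ind.id] = ratio
        scores[ind.id] = ind.weight * s
    gmci = scores.sum(axis=1)
    gmci.name = "gmci"
    return GmciAssessment(gmci=gmci, flagged=gmci >= ALARM_THRESHOLD, oe_ratios=oe,
                          scores=scores)


def evaluate(model: GmciModel, samples: CommunityDataset | pd.DataFrame,
             labels: pd.Series) -> dict[str, float]:
    """Accuracy (flagged impacted / impacted) and error (flagged baseline /
    baseline) of the integrated index on labeled samples."""
    labels = pd.Series(labels).astype(str)
    res = assess(model, samples)
    labels = labels.loc[res.gmci.index]
    n_imp = int((labels == "impacted").sum())
    n_base = int((labels == "baseline").sum())
    if n_imp == 0 or n_base == 0:
        raise ValidationError("evaluate needs both baseline and impacted samples")
    acc = float(res.flagged[labels == "impacted"].mean())
    err = float(res.flagged[labels == "baseline"].mean())
    return {"accuracy": acc, "error": err, "n_impacted": n_imp, "n_baseline": n_base}
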