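"""Alpha/beta diversity and biogeographic regressions.

Implements Shannon diversity (natural log), Faith's phylogenetic diversity
(root path included), Bray-Curtis dissimilarity, great-circle geographic
distances, the distance-decay relationship (log-log OLS on community
similarity, with a Mantel permutation test), and the latitudinal diversity
gradient fits (linear and quadratic OLS, with the quadratic peak location).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.distance import mantel as _skbio_mantel

from .datasets import OtuTable, SampleMetadata, ValidationError, relative_abundance

__all__ = [
    "RegressionFit",
    "MantelResult",
    "DistanceDecayResult",
    "LatitudeGradientResult",
    "alpha_diversity",
    "shannon",
    "faith_pd",
    "beta_dissimilarity",
    "geographic_distance",
    "distance_decay",
    "latitude_gradient_fit",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class RegressionFit:
    """One OLS fit (linear or quadratic) with the headline statistics."""

    kind: str  # "linear" | "quadratic"
    coefficients: np.ndarray  # ascending powers: intercept, slope[, quad]
    adj_r_squared: float
    p_value: float
    pearson_r: float | None = None  # linear fits only
    peak: float | None = None  # quadratic fits with negative curvature

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    @property
    def quadratic_coefficient(self) -> float | None:
        return float(self.coefficients[2]) if self.kind == "quadratic" else None


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class DistanceDecayResult:
    fit: RegressionFit
    mantel: MantelResult
    n_pairs_used: int
    n_pairs_excluded: int


@dataclass
class LatitudeGradientResult:
    linear: RegressionFit
    quadratic: RegressionFit


def shannon(counts) -> float:
    """Shannon index H = -sum p ln p over nonzero proportions (natural log)."""
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValidationError("empty sample: Shannon undefined")
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def faith_pd(counts, otu_ids, tree: TreeNode) -> float:
    """Faith's PD: branch length of the minimal subtree spanning the present
    tips and the root (the root path is included by convention)."""
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValidationError("empty sample: Faith PD undefined")
    tips = {t.name for t in tree.tips()}
    present = [o for o, c in zip(otu_ids, x) if c > 0]
    missing = sorted(set(present) - tips)
    if missing:
        raise ValidationError(f"tree is missing tips for OTUs: {missing}")
    return float(_skbio_faith_pd(x, otu_ids, tree))


def alpha_diversity(
    table: OtuTable, metric: str = "shannon", tree: TreeNode | None = None
) -> pd.Series:
    """Per-sample alpha diversity, metric in {shannon, faith_pd}."""
    if metric == "shannon":
        vals = [shannon(row) for row in table.counts()]
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        vals = [faith_pd(row, table.otu_ids, tree) for row in table.counts()]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.Series(vals, index=table.sample_ids, name=metric)


def beta_dissimilarity(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if table.shape[0] < 2:
        raise ValidationError("need >= 2 samples for beta diversity")
    if (table.sample_totals() == 0).any():
        raise ValidationError("zero-total sample in beta diversity input")
    mat = squareform(pdist(table.counts().astype(float), metric="braycurtis"))
    return DistanceMatrix(mat, ids=table.sample_ids)


def geographic_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distances in km, Earth radius 6371 km."""
    lat = np.radians(metadata.data["latitude"].to_numpy())
    lon = np.radians(metadata.data["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against fp noise
    return DistanceMatrix(d, ids=metadata.sample_ids)


def _ols_fit(x: np.ndarray, y: np.ndarray, kind: str) -> RegressionFit:
    if kind == "linear":
        X = sm.add_constant(x)
    elif kind == "quadratic":
        X = sm.add_constant(np.column_stack([x, x**2]))
    else:  # pragma: no cover
        raise ValueError(kind)
    res = sm.OLS(y, X).fit()
    coefs = np.asarray(res.params, dtype=float)
    pearson_r = None
    peak = None
    if kind == "linear":
        pearson_r = float(stats.pearsonr(x, y)[0]) if np.std(y) > 0 else 0.0
        p_value = float(res.pvalues[1])
    else:
        a = coefs[2]
        if a < 0:
            peak = float(-coefs[1] / (2 * a))
        p_value = float(res.f_pvalue)
    return RegressionFit(
        kind=kind,
        coefficients=coefs,
        adj_r_squared=float(res.rsquared_adj),
        p_value=p_value,
        pearson_r=pearson_r,
        peak=peak,
    )


def distance_decay(
    geo: DistanceMatrix,
    dissim: DistanceMatrix,
    mantel_permutations: int = 999,
    seed: int = 0,
    min_distance_km: float = 1e-3,
) -> DistanceDecayResult:
    """Distance-decay relationship and Mantel test.

    OLS of ln(similarity) on ln(distance) over unordered sample pairs, where
    similarity = 1 - Bray-Curtis dissimilarity.  Pairs closer than
    *min_distance_km* or with zero similarity are excluded (log undefined)
    and counted.  The Mantel statistic is the Pearson correlation of the
    vectorized upper triangles under row/column permutations (one-sided, for
    positive association between the two distance matrices).
    """
    if list(geo.ids) != list(dissim.ids):
        dissim = dissim.filter(geo.ids)
    iu = np.triu_indices(geo.shape[0], k=1)
    d = geo.data[iu]
    sim = 1.0 - dissim.data[iu]
    usable = (d >= min_distance_km) & (sim > 0)
    n_excl = int((~usable).sum())
    if usable.sum() < 3:
        raise ValidationError("fewer than 3 usable pairs for distance decay")
    fit = _ols_fit(np.log(d[usable]), np.log(sim[usable]), "linear")
    r, p, _ = _skbio_mantel(
        geo, dissim, method="pearson", permutations=mantel_permutations,
        alternative="greater", seed=seed,
    )
    mantel = MantelResult(r=float(r), p_value=float(p), n_permutations=mantel_permutations, seed=seed)
    return DistanceDecayResult(
        fit=fit, mantel=mantel, n_pairs_used=int(usable.sum()), n_pairs_excluded=n_excl
    )


def latitude_gradient_fit(latitudes, alpha_values) -> LatitudeGradientResult:
    """Linear and quadratic OLS of alpha diversity on latitude.

    The quadratic fit reports the peak latitude -b/(2a) when the curvature a
    is negative (unimodal gradient).
    """
    x = np.asarray(latitudes, dtype=float)
    y = np.asarray(alpha_values, dtype=float)
    if x.size != y.size:
        raise ValueError("latitudes and alpha values differ in length")
    if x.size < 5:
        raise ValidationError("need at least 5 points for gradient fits")
    if np.ptp(x) == 0:
        raise ValidationError("constant latitude: gradient undefined")
    return LatitudeGradientResult(
        linear=_ols_fit(x, y, "linear"), quadratic=_ols_fit(x, y, "quadratic")
    )
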