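"""Negative-binomial two-group differential expression, shared by all levels.

One engine tests genes, transcripts and exonic regions alike: median-of-ratios
size factors, method-of-moments dispersion estimates shrunk conservatively
toward a fitted mean-dispersion trend, and a per-feature Wald test on the
log fold change between tumor and normal group means, with Bonferroni
correction over the features tested at one level.

The model for a count K in sample s is NB with mean ``mu * s_s`` and variance
``mu * s_s + alpha * (mu * s_s)^2`` where s_s is the sample's size factor and
alpha the feature's dispersion.  The Wald statistic divides the natural-log
fold change of the group means of normalized counts by its delta-method
standard error; p-values come from the normal approximation, two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationModel
from .io import CUTOFFS, CountMatrix, DEResult, SampleMetadata

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # underflow floor applied before multiplicity adjustment


@dataclass
class NBModelFit:
    """Size factors, per-feature dispersions and the fitted dispersion trend."""

    size_factors: pd.Series           # per sample, geometric mean 1
    dispersions: pd.Series            # final (shrunk) per-feature dispersion
    raw_dispersions: pd.Series        # method-of-moments estimates before shrinkage
    trend_coef: tuple[float, float]   # alpha(mu) = a0 + a1 / mu

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if (self.dispersions < 0).any():
            raise ValueError("dispersions must be non-negative")


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over features with an all-positive
    count row, of that sample's count divided by the feature's geometric
    mean across samples.
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    if data.shape[1] < 2:
        raise ValueError("size factor estimation needs at least 2 samples")
    mat = data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "median-of-ratios is undefined (consider a total-count fallback)"
        )
    log_geomean = logs[finite].mean(axis=1, keepdims=True)
    log_ratios = logs[finite] - log_geomean
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=data.columns, name="size_factor")


def _tumor_mask(labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(labels) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"group labels must be tumor/normal; found {sorted(bad)}")
    return labels == "tumor"


def estimate_dispersions(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    design: Sequence[str],
) -> NBModelFit:
    """Method-of-moments dispersions with a conservative trend shrinkage.

    Per feature, the within-group sample variance of normalized counts is
    pooled across the two groups and compared with the overall mean:
    ``alpha = max(0, (s2 - mean) / mean^2)``.  A hyperbolic trend
    ``alpha(mu) = a0 + a1/mu`` is fitted across features by a gamma-family
    regression, and the final dispersion is the elementwise maximum of the
    per-feature estimate and the trend value — the conservative choice for
    family-wise error control on small cohorts.
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    tumor = _tumor_mask(design)
    if tumor.sum() < 2 or (~tumor).sum() < 2:
        raise ValueError("each group needs at least 2 samples to estimate dispersion")
    q = data.to_numpy(dtype=float) / size_factors.loc[data.columns].to_numpy()

    n_t, n_n = int(tumor.sum()), int((~tumor).sum())
    var_t = q[:, tumor].var(axis=1, ddof=1)
    var_n = q[:, ~tumor].var(axis=1, ddof=1)
    pooled_var = ((n_t - 1) * var_t + (n_n - 1) * var_n) / (n_t + n_n - 2)
    mu = q.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - mu) / mu**2
    raw = np.where(mu > 0, np.maximum(raw, 0.0), 0.0)

    a0, a1 = _fit_dispersion_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, 0.0)
    final = np.maximum(raw, trend)

    idx = data.index
    return NBModelFit(
        size_factors=size_factors,
        dispersions=pd.Series(final, index=idx),
        raw_dispersions=pd.Series(raw, index=idx),
        trend_coef=(a0, a1),
    )


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit alpha = a0 + a1/mu over features with positive mean and dispersion."""
    use = (mu > 0) & (alpha > 0)
    if use.sum() < 10:
        return 0.0, 0.0
    x, y = 1.0 / mu[use], alpha[use]
    try:
        import statsmodels.api as sm

        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Identity())).fit(
                start_params=[np.median(y), 0.0], maxiter=100
            )
        a0, a1 = float(res.params[0]), float(res.params[1])
    except Exception:  # singular fits on degenerate inputs: fall back to least squares
        a1, a0 = np.polyfit(x, y, 1)
        a0, a1 = float(a0), float(a1)
    return max(a0, 0.0), max(a1, 0.0)


def _wald_matrix(
    data: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: np.ndarray,
    tumor: np.ndarray,
) -> pd.DataFrame:
    """Vectorized per-feature Wald test; returns means, lfc, z and p columns."""
    sf = size_factors.loc[data.columns].to_numpy()
    q = data.to_numpy(dtype=float) / sf
    mu_t = q[:, tumor].mean(axis=1)
    mu_n = q[:, ~tumor].mean(axis=1)
    n_t, n_n = int(tumor.sum()), int((~tumor).sum())

    # 0.5 pseudocount stabilizes the fold change at zero means
    lfc_nat = np.log(mu_t + 0.5) - np.log(mu_n + 0.5)

    alpha = np.asarray(dispersions, dtype=float)
    inv_sf_t = (1.0 / sf[tumor]).sum()
    inv_sf_n = (1.0 / sf[~tumor]).sum()
    # Var(mean of K_s/s_s) with Var(K_s) = s_s*mu + alpha*(s_s*mu)^2
    var_mu_t = (mu_t * inv_sf_t + alpha * mu_t**2 * n_t) / n_t**2
    var_mu_n = (mu_n * inv_sf_n + alpha * mu_n**2 * n_n) / n_n**2
    # delta method on log(mu + 0.5), consistent with the shifted numerator
    var_log = var_mu_t / (mu_t + 0.5) ** 2 + var_mu_n / (mu_n + 0.5) ** 2
    se = np.sqrt(var_log)

    degenerate = (mu_t == 0) & (mu_n == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc_nat / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(degenerate, 1.0, np.clip(p, _P_FLOOR, 1.0))
    z = np.where(degenerate, 0.0, z)
    lfc_nat = np.where(degenerate, 0.0, lfc_nat)

    return pd.DataFrame(
        {
            "base_mean_normal": mu_n,
            "base_mean_tumor": mu_t,
            "log2_fold_change": lfc_nat / np.log(2.0),
            "stat": z,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=data.index,
    )


def nb_wald_test(
    counts_row: pd.Series,
    size_factors: pd.Series,
    dispersion: float,
    design: Sequence[str],
    level: str = "gene",
    n_tests: int = 1,
) -> DEResult:
    """Wald test for a single feature's counts; see module docstring for the model."""
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    tumor = _tumor_mask(design)
    if tumor.all() or not tumor.any():
        raise ValueError("both groups must be non-empty")
    df = pd.DataFrame([counts_row.to_numpy()], index=["_f"], columns=counts_row.index)
    row = _wald_matrix(df, size_factors, np.array([dispersion]), tumor).iloc[0]
    p_adj = bonferroni_adjust([row.p_value], n_tests)[0]
    name = counts_row.name if counts_row.name is not None else "_f"
    return DEResult(
        feature_id=str(name), level=level,
        base_mean_normal=float(row.base_mean_normal),
        base_mean_tumor=float(row.base_mean_tumor),
        log2_fold_change=float(row.log2_fold_change),
        p_value=float(row.p_value), p_bonferroni=float(p_adj),
        degenerate=bool(row.degenerate),
    )


def test_level(
    counts: CountMatrix,
    metadata: SampleMetadata,
    level: str,
) -> list[DEResult]:
    """Full NB pipeline at one level: size factors, dispersions, Wald, Bonferroni.

    The multiple-testing family is the set of features present in ``counts``,
    i.e. the features tested at this level on this sample subset.
    """
    if counts.level != level:
        raise ValueError(f"count matrix level {counts.level!r} does not match requested {level!r}")
    if not counts.feature_ids:
        return []
    design = list(metadata.tissue_of(counts.sample_ids))
    sf = estimate_size_factors(counts)
    fit = estimate_dispersions(counts, sf, design)
    tumor = _tumor_mask(design)
    table = _wald_matrix(counts.data, sf, fit.dispersions.to_numpy(), tumor)
    m = len(table)
    p_adj = np.minimum(1.0, table["p_value"].to_numpy() * m)
    return [
        DEResult(
            feature_id=str(fid), level=level,
            base_mean_normal=float(row.base_mean_normal),
            base_mean_tumor=float(row.base_mean_tumor),
            log2_fold_change=float(row.log2_fold_change),
            p_value=float(row.p_value), p_bonferroni=float(pa),
            degenerate=bool(row.degenerate),
        )
        for (fid, row), pa in zip(table.iterrows(), p_adj)
    ]


def bonferroni_adjust(p_values: Iterable[float], m: int) -> np.ndarray:
    """Bonferroni: p_adj = min(1, m * p); m must cover the whole test family."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < len(p):
        raise ValueError(f"m={m} smaller than the number of p-values ({len(p)})")
    return np.minimum(1.0, np.maximum(p, _P_FLOOR) * m)


def significant_features(results: Sequence[DEResult], cutoff: float) -> set[str]:
    """Feature ids with Bonferroni-adjusted p at or below the cutoff."""
    return {r.feature_id for r in results if r.p_bonferroni <= cutoff}


def map_to_genes(
    features: Iterable[str], level: str, annot: AnnotationModel
) -> set[str]:
    """Map DE transcripts or exonic regions to their parent genes (DET-G / DEE-G)."""
    features = list(features)
    if level == "gene":
        unknown = [f for f in features if f not in annot.genes]
        if unknown:
            raise ValueError(f"unresolvable gene ids: {unknown[:5]}")
        return set(features)
    if level == "transcript":
        unknown = [f for f in features if f not in annot.transcripts]
        if unknown:
            raise ValueError(f"unresolvable transcript ids: {unknown[:5]}")
        return {annot.transcripts[f].gene_id for f in features}
    if level == "exonic_region":
        unknown = [f for f in features if f not in annot.exonic_regions]
        if unknown:
            raise ValueError(f"unresolvable exonic region ids: {unknown[:5]}")
        return {annot.exonic_regions[f].gene_id for f in features}
    raise ValueError(f"unknown level {level!r}")


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two feature sets within a universe."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap_size: int
    hypergeometric_p: float

    def to_row(self) -> dict:
        return {
            "set_a_size": self.set_a_size,
            "set_b_size": self.set_b_size,
            "universe_size": self.universe_size,
            "overlap_size": self.overlap_size,
            "hypergeometric_p": self.hypergeometric_p,
        }


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Upper-tail hypergeometric P(X >= |A ∩ B|) for draws of |B| from the universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return OverlapResult(
        set_a_size=len(set_a), set_b_size=len(set_b),
        universe_size=len(universe), overlap_size=k,
        hypergeometric_p=min(p, 1.0),
    )
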