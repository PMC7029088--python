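"""Marker ranking and better-than-expected marker detection.

Genes are ranked by the normalized Robinson-Foulds distance (nRF) between
their gene tree and the target genome tree.  Because the nRF ranking alone
rarely shows a clean cutoff, an ordinary least squares regression of nRF on
a divergence predictor (median p-distance by default) is fitted and a
prediction interval (PI) drawn around the line of best fit: genes falling
strictly below the lower PI bound approximate the target tree better than
expected for their level of sequence divergence, and are flagged as
candidate markers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

import numpy as np
import dendropy
from scipy import stats as sps

from .seqstats import GeneStats
from .treekit import gene_to_target_nrf

log = logging.getLogger(__name__)

__all__ = [
    "MarkerRecord",
    "RegressionFit",
    "rank_markers",
    "fit_ols",
    "prediction_interval",
    "flag_outlier_markers",
    "spearman_correlation",
    "bootstrap_paired_nrf",
]


@dataclass
class MarkerRecord:
    """One row of the marker ranking: a gene's nRF joined to its stats."""

    gene_name: str
    nrf: float
    stats: Optional[GeneStats] = None
    rank_nrf: float = math.nan   # 1 = lowest nRF; ties share the mean rank
    predicted: float = math.nan  # regression prediction at this gene's x
    residual: float = math.nan   # nrf - predicted
    pi_lower: float = math.nan
    pi_upper: float = math.nan
    outlier: bool = False


def rank_markers(nrf_by_gene: dict[str, float],
                 stats_by_gene: Optional[dict[str, GeneStats]] = None
                 ) -> list[MarkerRecord]:
    """Join nRF distances with per-gene stats and rank ascending by nRF.

    Genes with undefined (NaN) nRF are excluded with a logged note; ties
    receive the mean of the tied ranks; tied genes are ordered by name.
    """
    stats_by_gene = stats_by_gene or {}
    genes = sorted(nrf_by_gene)
    if stats_by_gene:
        genes = [g for g in genes if g in stats_by_gene]
        if not genes:
            raise ValueError("no genes shared between nRF and stats tables")
    defined = []
    for g in genes:
        if math.isnan(nrf_by_gene[g]):
            log.info("gene %s has undefined nRF; excluded from ranking", g)
        else:
            defined.append(g)
    if not defined:
        raise ValueError("no gene has a defined nRF")
    defined.sort(key=lambda g: (nrf_by_gene[g], g))
    ranks = sps.rankdata([nrf_by_gene[g] for g in defined])
    return [
        MarkerRecord(gene_name=g, nrf=nrf_by_gene[g],
                     stats=stats_by_gene.get(g), rank_nrf=float(r))
        for g, r in zip(defined, ranks)
    ]


@dataclass
class RegressionFit:
    """OLS fit of y on x with the machinery for prediction intervals."""

    predictor: str
    slope: float
    intercept: float
    s: float          # residual standard deviation, sqrt(RSS/(n-2))
    n: int
    mean_x: float
    sxx: float
    level: float = 0.95
    t_quantile: float = math.nan

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


def fit_ols(x: Sequence[float], y: Sequence[float],
            predictor: str = "p_distance",
            level: float = 0.95) -> RegressionFit:
    """Ordinary least squares fit of y on x (via statsmodels)."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: degenerate fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    s = math.sqrt(res.mse_resid)  # RSS / (n - 2)
    return RegressionFit(
        predictor=predictor,
        slope=float(slope),
        intercept=float(intercept),
        s=float(s),
        n=n,
        mean_x=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        level=level,
        t_quantile=float(sps.t.ppf(1 - (1 - level) / 2, n - 2)),
    )


def prediction_interval(fit: RegressionFit, x0):
    """Two-sided prediction interval for a new observation at x0.

    yhat(x0) +/- t_{alpha/2, n-2} * s * sqrt(1 + 1/n + (x0-mean_x)^2/Sxx).
    """
    x0 = np.asarray(x0, dtype=float)
    yhat = fit.predict(x0)
    half = fit.t_quantile * fit.s * np.sqrt(
        1.0 + 1.0 / fit.n + (x0 - fit.mean_x) ** 2 / fit.sxx
    )
    return yhat - half, yhat + half


def flag_outlier_markers(records: list[MarkerRecord],
                         fit: RegressionFit) -> list[MarkerRecord]:
    """Flag genes whose nRF lies strictly below the lower PI bound at their
    predictor value; residuals and bounds are recorded for every gene."""
    for rec in records:
        if rec.stats is None:
            raise ValueError(f"gene {rec.gene_name} has no stats")
        x0 = getattr(rec.stats, fit.predictor)
        lo, hi = prediction_interval(fit, x0)
        rec.predicted = float(fit.predict(x0))
        rec.residual = rec.nrf - rec.predicted
        rec.pi_lower, rec.pi_upper = float(lo), float(hi)
        rec.outlier = bool(rec.nrf < lo)
    return records


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho."""
    n = len(rx)
    rx = (rx - rx.mean())
    denom_x = math.sqrt((rx ** 2).sum())
    count = total = 0
    target = abs(rho_obs) - 1e-12
    ry_c = ry - ry.mean()
    denom_y = math.sqrt((ry_c ** 2).sum())
    for perm in itertools.permutations(range(n)):
        r = float(rx @ ry_c[list(perm)]) / (denom_x * denom_y)
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def spearman_correlation(x: Sequence[float], y: Sequence[float],
                         method: str = "auto") -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided p-value.

    The p-value uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) with
    n-2 df; an exact permutation p is computed for small samples
    (``method="exact"``, allowed up to n=10; chosen automatically for
    n <= 7).  Returns (nan, nan) for a constant input vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "auto":
        method = "exact" if n <= 7 else "t"
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        return rho, _exact_spearman_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, float(p)


def bootstrap_paired_nrf(gene_replicates: Sequence[dendropy.Tree],
                         target_replicates: Sequence[dendropy.Tree],
                         n_draws: int = 100, seed=None,
                         paired: bool = False
                         ) -> tuple[float, list[float]]:
    """Median nRF over random draws of (gene replicate, target replicate).

    Each draw picks one replicate from each list uniformly with replacement
    (independently, or the same index in both lists when ``paired``) and
    computes the gene-to-target nRF.  Returns (median, draws).
    """
    if not gene_replicates or not target_replicates:
        raise ValueError("replicate lists must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    draws: list[float] = []
    for _ in range(n_draws):
        gi = int(rng.integers(len(gene_replicates)))
        if paired:
            ti = gi % len(target_replicates)
        else:
            ti = int(rng.integers(len(target_replicates)))
        draws.append(gene_to_target_nrf(gene_replicates[gi],
                                        target_replicates[ti]))
    return median(draws), draws
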