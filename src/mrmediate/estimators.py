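"""Causal-effect estimators for two-sample MR on harmonized summary data.

Five methods are provided: inverse-variance weighted (the primary
estimator), Egger regression (slope + intercept), weighted median, and
simple/weighted mode, plus the single-variant Wald ratio they all build on.
The IVW and Egger fits use multiplicative random effects: the fixed-effect
standard errors are inflated by the residual scale, floored at 1 so that
under-dispersion falls back to fixed-effect behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .summary_data import HarmonizedSet

#: Normal critical value used for all 95% confidence intervals.
Z95 = 1.96

MODE_GRID_POINTS = 512
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its normal-theory interval.

    ``beta`` is on the log-odds scale for binary outcomes and in SD units
    otherwise; ``or_scale`` holds the exponentiated (OR, CI) triple when
    requested.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    or_scale: Optional[tuple[float, float, float]] = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1e-300 if beta != 0 else 1.0
    return float(max(2.0 * sps.norm.sf(abs(beta / se)), 1e-300))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-variant ratio estimate with first-order standard error."""
    if beta_exp == 0:
        raise UndefinedRatioError("exposure beta is zero")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald_ratio", beta, se, _normal_p(beta, se), 1)


def _require(h: HarmonizedSet, k: int, what: str) -> None:
    if len(h) < k:
        raise InsufficientInstrumentsError(f"{what} needs >= {k} variants, got {len(h)}")


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights 1/se_out^2; multiplicative random effects inflate
    the SE by max(1, sqrt(Q/(J-1))).
    """
    _require(h, 2, "ivw")
    be, _, bo, so = h.arrays()
    w = 1.0 / so**2
    sxx = float(np.sum(w * be**2))
    beta = float(np.sum(w * be * bo)) / sxx
    q = float(np.sum(w * (bo - beta * be) ** 2))
    j = len(h)
    phi = max(1.0, np.sqrt(q / (j - 1)))
    se = phi / np.sqrt(sxx)
    return MREstimate("ivw", beta, float(se), _normal_p(beta, se), j)


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Inputs are oriented so every exposure beta is non-negative (flipping the
    outcome beta in step); both coefficients share the multiplicative
    random-effects inflation with J-2 degrees of freedom.
    """
    _require(h, 3, "egger")
    be, _, bo, so = h.arrays()
    flip = np.sign(be)
    flip[flip == 0] = 1.0
    x = be * flip
    y = bo * flip
    w = 1.0 / so**2
    j = len(h)
    X = np.column_stack([np.ones(j), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(rss / (j - 2)))
    cov = np.linalg.inv(xtwx)
    se = phi * np.sqrt(np.diag(cov))
    intercept = MREstimate(
        "egger_intercept", float(coef[0]), float(se[0]), _normal_p(coef[0], se[0]), j
    )
    slope = MREstimate("egger_slope", float(coef[1]), float(se[1]), _normal_p(coef[1], se[1]), j)
    return slope, intercept


def _ratios_and_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    be, _, bo, so = h.arrays()
    return bo / be, be**2 / so**2


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative weight 0.5 with linear interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error."""
    _require(h, 3, "weighted_median")
    be, se_exp, bo, so = h.arrays()
    point = _weighted_median_point(bo / be, be**2 / so**2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_exp)
        bo_b = rng.normal(bo, so)
        boots[b] = _weighted_median_point(bo_b / be_b, be_b**2 / so**2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", point, se, _normal_p(point, se), len(h))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = phi * 1.06 * spread * j ** (-0.2)
    if h == 0 or not np.isfinite(h):
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, MODE_GRID_POINTS)
    w = weights / np.sum(weights)
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2), axis=1
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: argmax of a Gaussian KDE over the Wald ratios.

    Bandwidth is Silverman's rule scaled by ``phi``; weights are uniform
    (simple mode) or the normalized inverse variance of the ratios
    (weighted mode). SE from a seeded parametric bootstrap.
    """
    _require(h, 3, "mode_estimate")
    be, se_exp, bo, so = h.arrays()

    def point_of(be_, bo_):
        ratios = bo_ / be_
        if weighted:
            weights = be_**2 / so**2  # inverse first-order ratio variance
        else:
            weights = np.ones_like(ratios)
        return _mode_point(ratios, weights, phi)

    point = point_of(be, bo)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = point_of(rng.normal(be, se_exp), rng.normal(bo, so))
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, point, se, _normal_p(point, se), len(h))


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Attach the exponentiated (OR, 95% CI) scale; beta must be log-odds."""
    or_scale = (
        float(np.exp(est.beta)),
        float(np.exp(est.ci_low)),
        float(np.exp(est.ci_high)),
    )
    return replace(est, or_scale=or_scale)


def all_estimators(
    h: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT, seed: int = 0, odds_ratio: bool = True
) -> list[MREstimate]:
    """Run the five reported estimators on one harmonized set."""
    slope, intercept = egger(h)
    ests = [
        ivw(h),
        slope,
        intercept,
        weighted_median(h, n_boot=n_boot, seed=seed),
        mode_estimate(h, weighted=False, n_boot=n_boot, seed=seed + 1),
        mode_estimate(h, weighted=True, n_boot=n_boot, seed=seed + 2),
    ]
    if odds_ratio:
        ests = [to_odds_ratio(e) for e in ests]
    return ests


def estimates_to_frame(estimates: list[MREstimate]):
    """Tidy TSV-ready table (the shape behind forest plots)."""
    import pandas as pd

    rows = []
    for e in estimates:
        row = {
            "method": e.method,
            "nsnp": e.n_snps,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pval": e.pval,
            "or": np.nan,
            "or_ci_low": np.nan,
            "or_ci_high": np.nan,
        }
        if e.or_scale is not None:
            row["or"], row["or_ci_low"], row["or_ci_high"] = e.or_scale
        rows.append(row)
    return pd.DataFrame(rows)
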