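"""Two-step mediation: mediator screening, indirect effects and proportions.

Step 1 estimates the exposure effect on every candidate mediator; step 2
estimates each mediator's effect on the outcome. Both steps apply
Benjamini-Hochberg adjustment across the panel. The indirect effect is the
product of the two step estimates with a first-order delta-method standard
error (cross-covariance assumed zero, the standard two-step assumption for
non-overlapping samples), and the proportion mediated is the indirect
effect over the total effect, in percent — deliberately never renormalized
across mediators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate, Z95, ivw
from .exceptions import MRMediateError, UndefinedProportionError
from .summary_data import (
    GENOME_WIDE_P,
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_KB,
    HarmonizedSet,
    SummaryStats,
    clump,
    harmonize,
    select_instruments,
)

logger = logging.getLogger(__name__)

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NOT_SELECTED = "not_selected"
TIER_FAILED = "failed"

SCREEN_ALPHA = 0.05


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_i = min over j >= i (rank order) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    # guard the m*p/j arithmetic against 1-ulp rounding below the raw p
    adj = np.maximum(adj, p[order])
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


@dataclass
class ScreenConfig:
    """Thresholds shared by both screening steps."""

    p_threshold: float = GENOME_WIDE_P
    outcome_p_exclude: float = GENOME_WIDE_P
    ld: Optional[pd.DataFrame] = None
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_kb: float = DEFAULT_CLUMP_WINDOW_KB
    alpha: float = SCREEN_ALPHA


@dataclass
class StepRecord:
    """One mediator's result from a screening step."""

    mediator_name: str
    estimate: Optional[MREstimate]
    p_adj: Optional[float] = None
    tier: str = TIER_FAILED
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.estimate is not None


def _tier(pval: float, p_adj: float, alpha: float) -> str:
    if pval < alpha and p_adj < alpha:
        return TIER_SIGNIFICANT
    if pval < alpha:
        return TIER_SUGGESTIVE
    return TIER_NOT_SELECTED


def _apply_bh(records: list[StepRecord], alpha: float) -> None:
    ok = [r for r in records if r.ok]
    if not ok:
        return
    adj = bh_adjust([r.estimate.pval for r in ok])
    for r, a in zip(ok, adj):
        r.p_adj = a
        r.tier = _tier(r.estimate.pval, a, alpha)


def _screen_one(exposure_inst: SummaryStats, outcome: SummaryStats, cfg: ScreenConfig):
    h = harmonize(exposure_inst, outcome, cfg.outcome_p_exclude)
    return ivw(h)


def screen_step1(
    exposure: SummaryStats, mediators: list[SummaryStats], cfg: Optional[ScreenConfig] = None
) -> list[StepRecord]:
    """Exposure -> mediator effects (beta1) for every panel member, with BH
    adjustment across the panel. Mediators where the pipeline fails (for
    example zero shared instruments) get a failed record, never a silent
    drop. Instruments are selected from the exposure once and reused."""
    cfg = cfg or ScreenConfig()
    inst = select_instruments(exposure, cfg.p_threshold)
    if cfg.ld is not None:
        inst = clump(inst, cfg.ld, cfg.clump_r2, cfg.clump_window_kb)
    records = []
    for med in mediators:
        try:
            est = _screen_one(inst, med, cfg)
            records.append(StepRecord(med.trait_name, est))
        except MRMediateError as exc:
            logger.warning("step1 failed for %s: %s", med.trait_name, exc)
            records.append(StepRecord(med.trait_name, None, error=str(exc)))
    _apply_bh(records, cfg.alpha)
    return records


def screen_step2(
    mediators: list[SummaryStats], outcome: SummaryStats, cfg: Optional[ScreenConfig] = None
) -> list[StepRecord]:
    """Mediator -> outcome effects (beta2); instruments come from each
    mediator's own GWAS."""
    cfg = cfg or ScreenConfig()
    records = []
    for med in mediators:
        try:
            inst = select_instruments(med, cfg.p_threshold)
            if cfg.ld is not None:
                inst = clump(inst, cfg.ld, cfg.clump_r2, cfg.clump_window_kb)
            est = _screen_one(inst, outcome, cfg)
            records.append(StepRecord(med.trait_name, est))
        except MRMediateError as exc:
            logger.warning("step2 failed for %s: %s", med.trait_name, exc)
            records.append(StepRecord(med.trait_name, None, error=str(exc)))
    _apply_bh(records, cfg.alpha)
    return records


@dataclass(frozen=True)
class IndirectEffect:
    point: float
    se: float
    ci_low: float
    ci_high: float


def indirect_effect(beta1: float, se1: float, beta2: float, se2: float) -> IndirectEffect:
    """Product of coefficients with first-order delta-method SE.

    se = sqrt(beta1^2 se2^2 + beta2^2 se1^2); the cross term is omitted
    (independent samples). Symmetric in the two (beta, se) pairs.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    point = beta1 * beta2
    se = float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))
    return IndirectEffect(point, se, point - Z95 * se, point + Z95 * se)


def proportion_mediated(indirect: float, total: float) -> float:
    """100 * indirect / total; total must be nonzero."""
    if total == 0:
        raise UndefinedProportionError("total effect is zero")
    return 100.0 * indirect / total


@dataclass
class MediationResult:
    """Joined two-step result for one mediator."""

    mediator_name: str
    beta1: Optional[StepRecord]
    beta2: Optional[StepRecord]
    total: float
    indirect: Optional[IndirectEffect] = None
    proportion: Optional[float] = None
    tier: str = TIER_NOT_SELECTED
    direction_consistent: Optional[bool] = None

    @property
    def headline(self) -> bool:
        """Candidate in both steps and direction-consistent with the total."""
        return (
            self.beta1 is not None
            and self.beta2 is not None
            and self.beta1.tier == TIER_SIGNIFICANT
            and self.beta2.tier == TIER_SIGNIFICANT
            and bool(self.direction_consistent)
        )


def run_mediation(
    total: MREstimate, step1: list[StepRecord], step2: list[StepRecord]
) -> list[MediationResult]:
    """Join the two screening steps and compute indirect effects.

    Every panel mediator appears in the output with its tier; the headline
    subset (``.headline``) requires significance in both steps and an
    indirect effect whose sign matches the total effect. Proportions are
    reported as-is, never renormalized.
    """
    s2 = {r.mediator_name: r for r in step2}
    results = []
    for r1 in step1:
        name = r1.mediator_name
        r2 = s2.get(name)
        res = MediationResult(name, r1, r2, total.beta)
        if r1.ok and r2 is not None and r2.ok:
            ind = indirect_effect(
                r1.estimate.beta, r1.estimate.se, r2.estimate.beta, r2.estimate.se
            )
            res.indirect = ind
            res.direction_consistent = bool(np.sign(ind.point) == np.sign(total.beta))
            if total.beta != 0:
                res.proportion = proportion_mediated(ind.point, total.beta)
            tiers = (r1.tier, r2.tier)
            if tiers == (TIER_SIGNIFICANT, TIER_SIGNIFICANT):
                res.tier = TIER_SIGNIFICANT
            elif all(t in (TIER_SIGNIFICANT, TIER_SUGGESTIVE) for t in tiers):
                res.tier = TIER_SUGGESTIVE
            else:
                res.tier = TIER_NOT_SELECTED
        elif not r1.ok or (r2 is not None and not r2.ok):
            res.tier = TIER_FAILED
        results.append(res)
    return results


def _step_cols(prefix: str, rec: Optional[StepRecord]) -> dict:
    if rec is None or not rec.ok:
        return {
            f"{prefix}": np.nan,
            f"{prefix}_ci_low": np.nan,
            f"{prefix}_ci_high": np.nan,
            f"{prefix}_pval": np.nan,
            f"{prefix}_p_adj": np.nan,
        }
    e = rec.estimate
    return {
        f"{prefix}": e.beta,
        f"{prefix}_ci_low": e.ci_low,
        f"{prefix}_ci_high": e.ci_high,
        f"{prefix}_pval": e.pval,
        f"{prefix}_p_adj": rec.p_adj,
    }


def mediation_to_frame(
    results: list[MediationResult],
    headline_only: bool = False,
    categories: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Tidy per-mediator table; the headline view mirrors the published
    layout (category, mediator, beta1 CI, beta2 CI, indirect CI, percent)."""
    categories = categories or {}
    rows = []
    for r in results:
        if headline_only and not r.headline:
            continue
        row = {"category": categories.get(r.mediator_name, ""), "mediator": r.mediator_name}
        row.update(_step_cols("beta1", r.beta1))
        row.update(_step_cols("beta2", r.beta2))
        if r.indirect is not None:
            row.update(
                indirect=r.indirect.point,
                indirect_ci_low=r.indirect.ci_low,
                indirect_ci_high=r.indirect.ci_high,
            )
        else:
            row.update(indirect=np.nan, indirect_ci_low=np.nan, indirect_ci_high=np.nan)
        row["proportion_pct"] = r.proportion if r.proportion is not None else np.nan
        row["tier"] = r.tier
        row["direction_consistent"] = r.direction_consistent
        rows.append(row)
    return pd.DataFrame(rows)
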