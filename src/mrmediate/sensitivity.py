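"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Includes Cochran's Q, the Egger intercept test, a simulation-based
outlier-sum-of-squares procedure (global, per-variant outlier, corrected
estimate and distortion tests), and leave-one-out IVW refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate, egger, ivw
from .exceptions import InsufficientInstrumentsError
from .summary_data import HarmonizedSet

DEFAULT_PRESSO_NSIM = 1000
DISTORTION_N_SUBSETS = 1000


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Q = sum_j w_j (ratio_j - beta_ivw)^2 with w_j = (beta_exp_j/se_out_j)^2."""
    if len(h) < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 variants")
    be, _, bo, so = h.arrays()
    ratios = bo / be
    w = (be / so) ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(h) - 1
    return q, df, float(sps.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(b, se, p) of the Egger regression intercept."""
    _, intercept = egger(h)
    return intercept.beta, intercept.se, intercept.pval


def leave_one_out(h: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """IVW refits each omitting one variant, in input order."""
    if len(h) < 3:
        raise InsufficientInstrumentsError("leave_one_out needs >= 3 variants")
    out = []
    idx = list(range(len(h)))
    for i in idx:
        sub = h.subset([j for j in idx if j != i])
        out.append((h.variants[i].variant_id, ivw(sub)))
    return out


def loo_to_frame(loo: list[tuple[str, MREstimate]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"snp": vid, "beta": e.beta, "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high}
            for vid, e in loo
        ]
    )


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_p: float
    outlier_ids: tuple[str, ...]
    outlier_pvals: dict[str, float]
    corrected: Optional[MREstimate]
    distortion_p: Optional[float]


def _loo_ivw_betas(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes via sum updates; bo may be (n_sim, J)."""
    sxx = np.sum(w * be**2)
    sxy = (w * be * bo).sum(axis=-1, keepdims=True)
    num = sxy - w * be * bo
    den = sxx - w * be**2
    return num / den


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_PRESSO_NSIM,
    signif: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Simulation-based pleiotropy outlier test.

    Global test: observed residual sum of squares around leave-one-out IVW
    predictions, compared with n_sim parametric simulations of the outcome
    betas; empirical p-values use +1 smoothing (floor 1/(n_sim+1)). Outlier
    test: per-variant empirical p of the squared residual, Bonferroni
    corrected over J. Corrected estimate: IVW on unflagged variants.
    Distortion test: the corrected-minus-original difference compared with
    IVW fits dropping random subsets of the same size.
    """
    if len(h) < 4:
        raise InsufficientInstrumentsError("mr_presso needs >= 4 variants")
    rng = np.random.default_rng(seed)
    be, _, bo, so = h.arrays()
    w = 1.0 / so**2
    j = len(h)

    beta_loo = _loo_ivw_betas(be, bo[None, :], w)[0]
    resid_obs = bo - beta_loo * be
    rss_obs = float(np.sum(resid_obs**2))

    # simulate outcome betas around the leave-one-out expectations
    bo_sim = rng.normal(beta_loo * be, so, size=(n_sim, j))
    beta_loo_sim = _loo_ivw_betas(be, bo_sim, w)
    resid_sim = bo_sim - beta_loo_sim * be
    rss_sim = np.sum(resid_sim**2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_p = (1 + np.sum(resid_sim**2 >= resid_obs[None, :] ** 2, axis=0)) / (n_sim + 1)
    per_p_bonf = np.minimum(per_p * j, 1.0)
    flagged = np.flatnonzero(per_p_bonf < signif)
    ids = h.ids()
    outlier_ids = tuple(ids[i] for i in flagged)
    outlier_pvals = {ids[i]: float(per_p_bonf[i]) for i in range(j)}

    corrected: Optional[MREstimate] = None
    distortion_p: Optional[float] = None
    keep = [i for i in range(j) if i not in set(flagged)]
    if len(flagged) and len(keep) >= 2:
        corrected = ivw(h.subset(keep))
        original = ivw(h)
        d_obs = corrected.beta - original.beta
        n_out = len(flagged)
        d_null = np.empty(DISTORTION_N_SUBSETS)
        for b in range(DISTORTION_N_SUBSETS):
            drop = rng.choice(j, size=n_out, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            sxx = np.sum(w[mask] * be[mask] ** 2)
            d_null[b] = np.sum(w[mask] * be[mask] * bo[mask]) / sxx - original.beta
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (DISTORTION_N_SUBSETS + 1)
        )
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals,
        corrected=corrected,
        distortion_p=distortion_p,
    )


@dataclass
class SensitivityReport:
    """Bundle of the full diagnostic battery for one exposure-outcome pair."""

    cochran_q: tuple[float, int, float]
    egger_intercept: tuple[float, float, float]
    presso: Optional[PressoResult]
    loo: list[tuple[str, MREstimate]] = field(default_factory=list)

    def to_blocks(self) -> dict[str, pd.DataFrame]:
        q, df, qp = self.cochran_q
        b, se, p = self.egger_intercept
        blocks = {
            "heterogeneity": pd.DataFrame([{"Q": q, "df": df, "pval": qp}]),
            "pleiotropy": pd.DataFrame([{"intercept": b, "se": se, "pval": p}]),
            "leave_one_out": loo_to_frame(self.loo),
        }
        if self.presso is not None:
            pr = self.presso
            blocks["presso"] = pd.DataFrame(
                [
                    {
                        "global_rss": pr.global_rss,
                        "global_p": pr.global_p,
                        "n_outliers": len(pr.outlier_ids),
                        "outlier_ids": ",".join(pr.outlier_ids),
                        "corrected_beta": pr.corrected.beta if pr.corrected else np.nan,
                        "corrected_se": pr.corrected.se if pr.corrected else np.nan,
                        "distortion_p": pr.distortion_p if pr.distortion_p is not None else np.nan,
                    }
                ]
            )
        return blocks


def run_sensitivity(
    h: HarmonizedSet, n_sim: int = DEFAULT_PRESSO_NSIM, seed: int = 0
) -> SensitivityReport:
    """Run the full battery; MR-PRESSO is skipped below 4 variants."""
    presso = mr_presso(h, n_sim=n_sim, seed=seed) if len(h) >= 4 else None
    return SensitivityReport(
        cochran_q=cochran_q(h),
        egger_intercept=egger_intercept_test(h),
        presso=presso,
        loo=leave_one_out(h),
    )
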