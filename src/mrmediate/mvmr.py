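"""Multivariable IVW: joint direct effects of several exposures on one outcome."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate, _normal_p
from .exceptions import CollinearityError, EmptyResultError, InsufficientInstrumentsError
from .summary_data import (
    GENOME_WIDE_P,
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_KB,
    SummaryStats,
    clump,
    select_instruments,
)


@dataclass(frozen=True)
class MVMRVariant:
    variant_id: str
    beta_exp: tuple[float, ...]  # one per exposure, primary first
    se_exp: tuple[float, ...]
    beta_out: float
    se_out: float


@dataclass
class MVMRSet:
    """Union-of-instruments design matrix for multivariable IVW."""

    exposure_names: list[str]
    variants: list[MVMRVariant]
    audit: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(exposure-beta matrix J x E, beta_out, se_out)."""
        X = np.array([v.beta_exp for v in self.variants], dtype=float)
        y = np.array([v.beta_out for v in self.variants], dtype=float)
        s = np.array([v.se_out for v in self.variants], dtype=float)
        return X, y, s


def build_mvmr_set(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: pd.DataFrame | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
    outcome_p_exclude: float = GENOME_WIDE_P,
) -> MVMRSet:
    """Assemble the union of each exposure's instruments against the outcome.

    Per-exposure selection (and clumping when an LD matrix is supplied)
    happens first; the union of surviving variant ids is then looked up in
    every exposure (missing anywhere -> dropped, audited) and harmonized to
    the outcome with the same rules as the univariable path: palindromic,
    outcome-significant, missing-in-outcome and allele-mismatch variants
    are removed. All betas are aligned to the effect allele of the first
    exposure that carries the variant.
    """
    if len(exposures) < 2:
        raise ValueError("build_mvmr_set needs >= 2 exposures")
    union_ids: list[str] = []
    seen: set[str] = set()
    for exp in exposures:
        inst = select_instruments(exp, p_threshold)
        if ld is not None:
            inst = clump(inst, ld, r2_threshold, window_kb)
        for r in inst.records:
            if r.variant_id not in seen:
                seen.add(r.variant_id)
                union_ids.append(r.variant_id)
    if not union_ids:
        raise EmptyResultError("no instruments in any exposure")

    lookups = [e.by_id() for e in exposures]
    out_lookup = outcome.by_id()
    audit = {
        "missing_in_exposure": 0,
        "missing_in_outcome": 0,
        "palindromic": 0,
        "outcome_significant": 0,
        "allele_mismatch": 0,
    }
    variants: list[MVMRVariant] = []
    for vid in union_ids:
        recs = [lk.get(vid) for lk in lookups]
        if any(r is None for r in recs):
            audit["missing_in_exposure"] += 1
            continue
        ref = recs[0]
        out_rec = out_lookup.get(vid)
        if out_rec is None:
            audit["missing_in_outcome"] += 1
            continue
        if ref.is_palindromic or out_rec.is_palindromic:
            audit["palindromic"] += 1
            continue
        if out_rec.pval < outcome_p_exclude:
            audit["outcome_significant"] += 1
            continue
        betas, ses, ok = [], [], True
        for r in recs:
            if r.effect_allele == ref.effect_allele and r.other_allele == ref.other_allele:
                betas.append(r.beta)
            elif r.effect_allele == ref.other_allele and r.other_allele == ref.effect_allele:
                betas.append(-r.beta)
            else:
                ok = False
                break
            ses.append(r.se)
        if not ok:
            audit["allele_mismatch"] += 1
            continue
        if out_rec.effect_allele == ref.effect_allele and out_rec.other_allele == ref.other_allele:
            beta_out = out_rec.beta
        elif out_rec.effect_allele == ref.other_allele and out_rec.other_allele == ref.effect_allele:
            beta_out = -out_rec.beta
        else:
            audit["allele_mismatch"] += 1
            continue
        variants.append(
            MVMRVariant(vid, tuple(betas), tuple(ses), beta_out, out_rec.se)
        )
    if not variants:
        raise EmptyResultError("no variants retained for MVMR")
    return MVMRSet([e.trait_name for e in exposures], variants, audit)


def mvmr_ivw(m: MVMRSet) -> list[MREstimate]:
    """Weighted multiple regression of beta_out on the exposure-beta matrix.

    No intercept; weights 1/se_out^2; multiplicative random-effects SE
    inflation floored at 1 with J - E residual degrees of freedom. One
    estimate per exposure, in input order.
    """
    X, y, s = m.design()
    j, n_exp = X.shape
    if j <= n_exp:
        raise InsufficientInstrumentsError(
            f"mvmr_ivw needs more variants ({j}) than exposures ({n_exp})"
        )
    w = 1.0 / s**2
    Xw = X * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < n_exp:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{m.exposure_names[a]}~{m.exposure_names[b]}"
            for a in range(n_exp)
            for b in range(a + 1, n_exp)
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise CollinearityError(
            "rank-deficient exposure matrix" + (f" ({'; '.join(pairs)})" if pairs else "")
        )
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(rss / (j - n_exp)))
    cov = np.linalg.inv(xtwx)
    ses = phi * np.sqrt(np.diag(cov))
    return [
        MREstimate("mvmr_ivw", float(coef[e]), float(ses[e]), _normal_p(coef[e], ses[e]), j)
        for e in range(n_exp)
    ]


def mvmr_to_frame(m: MVMRSet, estimates: list[MREstimate]) -> pd.DataFrame:
    rows = []
    for name, e in zip(m.exposure_names, estimates):
        rows.append(
            {
                "exposure": name,
                "nsnp": e.n_snps,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "or": float(np.exp(e.beta)),
                "or_ci_low": float(np.exp(e.ci_low)),
                "or_ci_high": float(np.exp(e.ci_high)),
            }
        )
    return pd.DataFrame(rows)
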