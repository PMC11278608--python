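"""GWAS summary-statistics I/O, instrument selection, clumping and harmonization.

The on-disk dialect is a tab-separated table with one row per variant and
canonical columns ``SNP, chr, pos, effect_allele, other_allele, eaf, beta,
se, pval, n``; a column-name mapping adapts foreign headers. Missing
effect-allele frequency is encoded as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    EmptyResultError,
    MissingEAFError,
    MissingLDError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: Allele pairs that are their own reverse complement and therefore strand-ambiguous.
PALINDROMIC_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})

CANONICAL_COLUMNS = (
    "SNP",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
MANDATORY_COLUMNS = ("SNP", "effect_allele", "other_allele", "beta", "se", "pval")

#: Relative tolerance between the reported p-value and the normal
#: approximation 2*Phi(-|beta/se|) before a row is flagged (published GWAS
#: tables are rounded, so this is a logged flag, not a drop).
PVAL_CONSISTENCY_RTOL = 0.10

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000.0
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-effect-allele estimate: log-odds for binary traits,
    SD units for continuous traits.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def is_valid(self) -> bool:
        """Structural invariants; rows failing these are dropped on read."""
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not np.isfinite(self.beta):
            return False
        if not (np.isfinite(self.se) and self.se > 0):
            return False
        if not (0 < self.pval <= 1):
            return False
        if self.eaf is not None and not (0 < self.eaf < 1):
            return False
        return True

    def pval_consistent(self, rtol: float = PVAL_CONSISTENCY_RTOL) -> bool:
        expected = 2.0 * sps.norm.sf(abs(self.beta / self.se))
        if expected == 0.0:
            return self.pval <= 1e-300 or self.pval < 1e-15
        return abs(self.pval - expected) <= rtol * expected

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in PALINDROMIC_PAIRS


@dataclass
class SummaryStats:
    """A per-trait GWAS summary table with unique variant identifiers."""

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant_id in {self.trait_name}")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.variant_id,
                "chr": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _coerce_optional(value, cast):
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN", "."):
        return None
    return cast(value)


def read_summary_stats(
    path,
    trait_name: Optional[str] = None,
    trait_type: str = "continuous",
    dialect: Optional[Mapping[str, str]] = None,
) -> SummaryStats:
    """Read a summary-statistics TSV, validating and upper-casing alleles.

    ``dialect`` maps canonical column names to the file's actual headers.
    Rows violating per-variant invariants are dropped with a logged count;
    rows whose p-value disagrees with |beta/se| by more than 10% are kept
    but counted in a logged flag.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: unresolvable mandatory column(s) {missing}")

    records: list[VariantAssociation] = []
    n_dropped = 0
    n_flagged = 0
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            rec = VariantAssociation(
                variant_id=str(d["SNP"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                eaf=_coerce_optional(d.get("eaf"), float),
                n=_coerce_optional(d.get("n"), float),
                chrom=_coerce_optional(d.get("chr"), str),
                pos=_coerce_optional(d.get("pos"), lambda v: int(float(v))),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not rec.is_valid() or rec.variant_id in seen:
            n_dropped += 1
            continue
        if not rec.pval_consistent():
            n_flagged += 1
        seen.add(rec.variant_id)
        records.append(rec)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    if n_flagged:
        logger.warning("%s: %d row(s) with p-value inconsistent with beta/se", path, n_flagged)
    return SummaryStats(
        trait_name=trait_name or str(path), trait_type=trait_type, records=records
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write the canonical TSV dialect; round-trips bit-exactly through read."""
    df = stats.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def select_instruments(stats: SummaryStats, p_threshold: float = GENOME_WIDE_P) -> SummaryStats:
    """Retain exactly the records with ``pval < p_threshold``."""
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0,1], got {p_threshold}")
    kept = [r for r in stats.records if r.pval < p_threshold]
    if not kept:
        logger.warning("%s: no variants pass p < %g", stats.trait_name, p_threshold)
    return SummaryStats(stats.trait_name, stats.trait_type, kept)


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square r-squared matrix TSV with variant ids on both axes."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", index=True)


def clump(
    stats: SummaryStats,
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> SummaryStats:
    """Greedy LD clumping by ascending p-value.

    A variant is accepted iff its r-squared with every already-accepted
    variant on the same chromosome within ``window_kb`` is below
    ``r2_threshold``. Ties in p-value break lexicographically on variant_id,
    so the accepted set is invariant to input row order. Output preserves
    input order restricted to the accepted set.
    """
    for r in stats.records:
        if r.variant_id not in ld.index or r.variant_id not in ld.columns:
            raise MissingLDError(f"variant {r.variant_id} absent from LD matrix")
        if r.pos is None or r.chrom is None:
            raise ValueError(f"variant {r.variant_id} lacks position, required for clumping")
    window_bp = window_kb * 1000.0
    order = sorted(stats.records, key=lambda r: (r.pval, r.variant_id))
    accepted: list[VariantAssociation] = []
    for cand in order:
        ok = True
        for acc in accepted:
            if acc.chrom != cand.chrom:
                continue
            if abs(acc.pos - cand.pos) > window_bp:
                continue
            if float(ld.at[cand.variant_id, acc.variant_id]) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(cand)
    keep_ids = {r.variant_id for r in accepted}
    kept = [r for r in stats.records if r.variant_id in keep_ids]
    return SummaryStats(stats.trait_name, stats.trait_type, kept)


@dataclass(frozen=True)
class InstrumentStrength:
    """Instrument-strength summary: per-variant r2, total R2 and F statistic."""

    r2_total: float
    k: int
    n: float
    f_stat: float
    per_variant_r2: tuple[float, ...]

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_INSTRUMENT_F


def f_statistics(stats: SummaryStats, n: float) -> InstrumentStrength:
    """Compute R2 and F = R2(N-K-1)/[K(1-R2)].

    Per-variant variance explained uses 2*eaf*(1-eaf)*beta^2, which assumes
    the trait is standardized to unit variance.
    """
    k = len(stats.records)
    if k == 0:
        raise EmptyInputError("no instruments")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    per = []
    for r in stats.records:
        if r.eaf is None:
            raise MissingEAFError(f"variant {r.variant_id} has no eaf")
        per.append(2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2)
    r2_total = float(np.sum(per))
    if r2_total >= 1.0:
        raise ValueError(f"total R2 = {r2_total:.3f} >= 1; inconsistent inputs")
    f_stat = r2_total * (n - k - 1) / (k * (1.0 - r2_total))
    return InstrumentStrength(
        r2_total=r2_total, k=k, n=n, f_stat=f_stat, per_variant_r2=tuple(per)
    )


@dataclass(frozen=True)
class HarmonizedVariant:
    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: Optional[float] = None


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to the exposure's effect allele."""

    exposure_name: str
    outcome_name: str
    variants: list[HarmonizedVariant]
    audit: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        be = np.array([v.beta_exp for v in self.variants], dtype=float)
        se = np.array([v.se_exp for v in self.variants], dtype=float)
        bo = np.array([v.beta_out for v in self.variants], dtype=float)
        so = np.array([v.se_out for v in self.variants], dtype=float)
        return be, se, bo, so

    def ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def subset(self, indices: Sequence[int]) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            [self.variants[i] for i in indices],
            dict(self.audit),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "SNP": v.variant_id,
                    "beta_exp": v.beta_exp,
                    "se_exp": v.se_exp,
                    "beta_out": v.beta_out,
                    "se_out": v.se_out,
                    "eaf": v.eaf,
                }
                for v in self.variants
            ]
        )


AUDIT_KEYS = ("missing_in_outcome", "palindromic", "outcome_significant", "allele_mismatch")


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    outcome_p_exclude: float = GENOME_WIDE_P,
    raise_on_empty: bool = True,
) -> HarmonizedSet:
    """Align outcome betas to the exposure effect allele, dropping in order:
    variants absent from the outcome; palindromic variants (A/T or C/G,
    regardless of frequency); variants genome-wide significant in the
    outcome; variants whose outcome alleles match in neither orientation.
    Flipped-orientation variants have beta_out negated and outcome eaf
    complemented. The retained eaf is the exposure-side frequency.
    """
    lookup = outcome.by_id()
    audit = {k: 0 for k in AUDIT_KEYS}
    out: list[HarmonizedVariant] = []
    for exp in exposure.records:
        rec = lookup.get(exp.variant_id)
        if rec is None:
            audit["missing_in_outcome"] += 1
            continue
        if exp.is_palindromic or rec.is_palindromic:
            audit["palindromic"] += 1
            continue
        if rec.pval < outcome_p_exclude:
            audit["outcome_significant"] += 1
            continue
        if rec.effect_allele == exp.effect_allele and rec.other_allele == exp.other_allele:
            beta_out = rec.beta
        elif rec.effect_allele == exp.other_allele and rec.other_allele == exp.effect_allele:
            beta_out = -rec.beta
        else:
            audit["allele_mismatch"] += 1
            continue
        out.append(
            HarmonizedVariant(
                variant_id=exp.variant_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=rec.se,
                eaf=exp.eaf,
            )
        )
    if not out and raise_on_empty:
        raise EmptyResultError(
            f"no variants retained harmonizing {exposure.trait_name} -> {outcome.trait_name}"
        )
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, out, audit)
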