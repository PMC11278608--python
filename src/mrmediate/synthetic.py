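"""Synthetic GWAS summary statistics for end-to-end pipeline testing.

A :class:`ScenarioSpec` encodes a linear structural model
exposure -> mediators -> outcome: exposure instruments carry the total
effect to the outcome (optionally plus a pleiotropy term), each mediator
has its own instruments whose outcome effects flow only through that
mediator, and observed betas are the true effects plus sampling noise with
se = 1/sqrt(2*maf*(1-maf)*n) for continuous traits (scaled further by the
case/control split for binary traits). Optional LD blocks add correlated
tag variants so clumping is exercisable.

Also ships a published 69-row benchmark of two-step mediation estimates
(step-1/step-2 betas with CIs, their products, and mediation proportions)
used to regression-test the mediation arithmetic.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ScenarioValidationError
from .summary_data import SummaryStats, VariantAssociation

#: Total (exposure -> outcome) effect on the log-odds scale that the
#: benchmark proportions are expressed against: ln(1.153).
BENCHMARK_TOTAL_EFFECT = math.log(1.153)

_BENCHMARK_TSV = """\
category	mediator	beta1	beta1_lo	beta1_hi	beta2	beta2_lo	beta2_hi	indirect	indirect_lo	indirect_hi	proportion_pct
Amino acids	Total_BCAA	0.075	0.056	0.093	0.445	0.054	0.837	0.033	0.003	0.064	23.288
Amino acids	Tyr	0.051	0.031	0.071	0.271	0.081	0.461	0.014	0.002	0.025	9.684
Amino acids	Val	0.075	0.056	0.093	0.340	0.022	0.658	0.025	0.001	0.050	17.782
Blood pressure	SBP	0.541	0.366	0.716	0.023	0.016	0.030	0.012	0.007	0.018	8.716
Cholesterol	L_HDL_CE_pct	-0.068	-0.089	-0.047	-0.155	-0.299	-0.012	0.011	0.000	0.021	7.408
Cholesterol	L_VLDL_C	0.040	0.019	0.061	0.255	0.109	0.402	0.010	0.002	0.018	7.158
Cholesterol	L_VLDL_CE	0.027	0.006	0.048	0.324	0.180	0.469	0.009	0.001	0.017	6.094
Cholesterol	L_VLDL_FC	0.052	0.030	0.074	0.274	0.132	0.416	0.014	0.005	0.024	9.965
Cholesterol	M_HDL_C_pct	-0.057	-0.077	-0.036	-0.191	-0.319	-0.062	0.011	0.002	0.019	7.556
Cholesterol	M_HDL_CE_pct	-0.055	-0.077	-0.034	-0.214	-0.335	-0.092	0.012	0.004	0.020	8.278
Cholesterol	M_LDL_FC_pct	-0.075	-0.095	-0.055	-0.158	-0.274	-0.042	0.012	0.003	0.021	8.3
Cholesterol	S_HDL_C_pct	-0.052	-0.072	-0.031	-0.156	-0.294	-0.019	0.008	0.000	0.016	5.656
Cholesterol	S_HDL_CE_pct	-0.044	-0.064	-0.024	-0.208	-0.340	-0.076	0.009	0.002	0.016	6.419
Cholesterol	S_LDL_CE_pct	0.025	0.007	0.044	0.205	0.077	0.334	0.005	0.000	0.010	3.642
Cholesterol	S_LDL_FC_pct	-0.069	-0.089	-0.049	-0.171	-0.284	-0.059	0.012	0.003	0.020	8.279
Cholesterol	VLDL_FC	0.028	0.006	0.049	0.309	0.176	0.442	0.009	0.001	0.016	6.033
Cholesterol	XL_VLDL_C	0.044	0.024	0.064	0.317	0.169	0.465	0.014	0.005	0.023	9.804
Cholesterol	XL_VLDL_CE	0.027	0.006	0.048	0.264	0.120	0.408	0.007	0.000	0.014	5.004
Cholesterol	XL_VLDL_FC	0.056	0.035	0.077	0.296	0.152	0.440	0.016	0.006	0.027	11.564
Cholesterol	XXL_VLDL_C	0.061	0.040	0.081	0.259	0.115	0.402	0.016	0.005	0.026	11.001
Cholesterol	XXL_VLDL_CE	0.058	0.037	0.079	0.254	0.126	0.383	0.015	0.005	0.024	10.327
Cholesterol	XXL_VLDL_FC	0.065	0.044	0.085	0.202	0.059	0.345	0.013	0.003	0.023	9.16
Fatty acids	MUFA	0.047	0.026	0.067	0.305	0.164	0.446	0.014	0.005	0.023	9.972
Fatty acids	MUFA_pct	0.062	0.041	0.083	0.201	0.049	0.353	0.013	0.002	0.023	8.764
Fatty acids	Omega_3	0.022	0.004	0.040	0.312	0.218	0.407	0.007	0.001	0.013	4.783
Fatty acids	Omega_6_by_Omega_3	-0.031	-0.048	-0.013	-0.373	-0.524	-0.222	0.011	0.003	0.020	8.052
Fatty acids	Omega_6_pct	-0.062	-0.083	-0.040	-0.297	-0.473	-0.120	0.018	0.005	0.031	12.821
Fatty acids	SFA	0.028	0.008	0.047	0.331	0.164	0.498	0.009	0.001	0.017	6.39
Fatty acids	SFA_pct	0.031	0.013	0.050	0.454	0.131	0.777	0.014	0.001	0.028	9.901
Fatty acids	Total_FA	0.026	0.008	0.044	0.290	0.149	0.430	0.008	0.001	0.014	5.331
Lipoprptein particle concentration	L_VLDL_P	0.058	0.037	0.079	0.287	0.140	0.435	0.017	0.006	0.027	11.672
Lipoprptein particle concentration	S_VLDL_P	0.028	0.008	0.048	0.276	0.149	0.403	0.008	0.001	0.014	5.389
Lipoprptein particle concentration	VLDL_P	0.023	0.003	0.044	0.326	0.197	0.455	0.008	0.000	0.015	5.355
Lipoprptein particle concentration	XL_VLDL_P	0.062	0.041	0.084	0.276	0.150	0.403	0.017	0.007	0.027	12.049
Lipoprptein particle concentration	XXL_VLDL_P	0.067	0.046	0.088	0.246	0.103	0.389	0.017	0.006	0.028	11.605
Phospholipids	L_VLDL_PL	0.057	0.036	0.077	0.269	0.134	0.404	0.015	0.006	0.025	10.668
Phospholipids	L_VLDL_PL_pct	0.036	0.015	0.057	0.227	0.097	0.356	0.008	0.001	0.015	5.748
Phospholipids	S_LDL_PL_pct	-0.033	-0.052	-0.014	-0.212	-0.346	-0.077	0.007	0.001	0.013	4.917
Phospholipids	VLDL_PL	0.028	0.007	0.049	0.287	0.153	0.421	0.008	0.001	0.015	5.629
Phospholipids	XL_VLDL_PL	0.058	0.037	0.079	0.281	0.139	0.423	0.016	0.006	0.027	11.401
Phospholipids	XXL_VLDL_PL	0.068	0.047	0.089	0.221	0.073	0.369	0.015	0.004	0.026	10.547
Phospholipids	XXL_VLDL_PL_pct	0.035	0.017	0.053	0.217	0.062	0.372	0.008	0.001	0.014	5.357
Total lipids	L_VLDL_L	0.058	0.037	0.079	0.292	0.138	0.447	0.017	0.006	0.028	11.828
Total lipids	S_VLDL_L	0.025	0.005	0.044	0.280	0.154	0.407	0.007	0.001	0.013	4.88
Total lipids	VLDL_L	0.044	0.024	0.064	0.314	0.175	0.452	0.014	0.005	0.023	9.725
Total lipids	XL_VLDL_L	0.062	0.041	0.084	0.281	0.151	0.411	0.018	0.007	0.028	12.282
Total lipids	XXL_VLDL_L	0.066	0.045	0.087	0.192	0.033	0.351	0.013	0.001	0.024	8.885
Triglycerides	HDL_TG	0.048	0.030	0.066	0.227	0.131	0.324	0.011	0.005	0.017	7.641
Triglycerides	IDL_TG	0.035	0.016	0.054	0.249	0.118	0.381	0.009	0.002	0.015	6.066
Triglycerides	L_HDL_TG_pct	0.059	0.040	0.079	0.184	0.075	0.293	0.011	0.003	0.018	7.646
Triglycerides	L_LDL_TG	0.036	0.017	0.055	0.258	0.129	0.387	0.009	0.003	0.016	6.56
Triglycerides	L_VLDL_TG	0.064	0.042	0.085	0.257	0.105	0.409	0.016	0.005	0.028	11.521
Triglycerides	LDL_TG	0.039	0.020	0.058	0.253	0.131	0.375	0.010	0.003	0.017	6.938
Triglycerides	M_HDL_TG	0.052	0.033	0.070	0.214	0.116	0.313	0.011	0.005	0.018	7.761
Triglycerides	M_HDL_TG_pct	0.051	0.031	0.071	0.187	0.067	0.308	0.010	0.002	0.017	6.692
Triglycerides	M_LDL_TG	0.044	0.024	0.064	0.247	0.117	0.377	0.011	0.003	0.019	7.594
Triglycerides	M_VLDL_TG	0.052	0.030	0.073	0.303	0.167	0.440	0.016	0.006	0.025	10.969
Triglycerides	S_HDL_TG	0.063	0.043	0.083	0.218	0.107	0.329	0.014	0.005	0.022	9.624
Triglycerides	S_HDL_TG_pct	0.057	0.036	0.078	0.173	0.061	0.284	0.010	0.002	0.017	6.883
Triglycerides	S_LDL_TG	0.055	0.035	0.076	0.276	0.145	0.406	0.015	0.006	0.024	10.664
Triglycerides	S_LDL_TG_pct	0.074	0.052	0.095	0.165	0.031	0.299	0.012	0.002	0.023	8.51
Triglycerides	S_VLDL_TG	0.059	0.037	0.080	0.235	0.124	0.346	0.014	0.005	0.022	9.637
Triglycerides	TG_by_PG	0.067	0.046	0.088	0.161	0.037	0.285	0.011	0.002	0.020	7.526
Triglycerides	Total_TG	0.061	0.040	0.081	0.282	0.155	0.408	0.017	0.007	0.027	11.989
Triglycerides	VLDL_TG	0.063	0.042	0.084	0.260	0.129	0.392	0.016	0.006	0.026	11.485
Triglycerides	XL_HDL_TG_pct	0.065	0.045	0.085	0.198	0.081	0.316	0.013	0.004	0.022	9.035
Triglycerides	XL_VLDL_TG	0.070	0.048	0.092	0.232	0.092	0.372	0.016	0.005	0.027	11.372
Triglycerides	XS_VLDL_TG	0.045	0.024	0.065	0.217	0.092	0.342	0.010	0.002	0.017	6.813
Triglycerides	XXL_VLDL_TG	0.067	0.046	0.089	0.186	0.014	0.359	0.013	0.000	0.025	8.785
"""


def reference_mediation_table() -> pd.DataFrame:
    """The 69-row benchmark table of two-step mediation estimates.

    Columns: category, mediator, beta1 (+ CI), beta2 (+ CI), indirect
    effect (+ CI) and proportion mediated in percent, all as printed in the
    source benchmark. The total effect the proportions refer to is
    :data:`BENCHMARK_TOTAL_EFFECT`.
    """
    return pd.read_csv(io.StringIO(_BENCHMARK_TSV), sep="\t")


@dataclass(frozen=True)
class MediatorSpec:
    """One mediator: its name, the exposure effect on it (a) and its effect
    on the outcome (b); the generative indirect effect is a*b."""

    name: str
    a: float
    b: float
    j_instruments: int = 30


@dataclass(frozen=True)
class PleiotropySpec:
    """Extra direct variant effects on the outcome: none, balanced
    (zero-mean) or directional (nonzero-mean) normal offsets."""

    mode: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0


@dataclass
class ScenarioSpec:
    """Generative parameters for one synthetic GWAS scenario."""

    seed: int
    beta_total: float
    n_exposure: int = 600_000
    n_outcome: int = 400_000
    n_mediator_gwas: int = 100_000
    j_instruments: int = 50
    j_outcome_instruments: int = 0  # outcome-specific instruments (reverse MR)
    beta_reverse: float = 0.0  # outcome -> exposure effect carried by them
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_dist: tuple[float, float] = (0.08, 0.02)
    mediators: list[MediatorSpec] = field(default_factory=list)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    ld_blocks: Optional[tuple[int, float]] = None  # (block size, within-block r2)
    case_fraction: float = 0.1  # binary outcome case/control split
    exposure_binary: bool = True

    def validate(self) -> None:
        v = []
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            v.append(f"maf_range must sit within (0, 0.5], got {self.maf_range}")
        if self.j_instruments < 1:
            v.append("j_instruments must be >= 1")
        for n_name in ("n_exposure", "n_outcome", "n_mediator_gwas"):
            if getattr(self, n_name) < 2:
                v.append(f"{n_name} must be >= 2")
        if not (0 < self.case_fraction < 1):
            v.append("case_fraction must be in (0, 1)")
        if self.pleiotropy.mode not in ("none", "balanced", "directional"):
            v.append(f"unknown pleiotropy mode {self.pleiotropy.mode!r}")
        if self.pleiotropy.mode == "balanced" and self.pleiotropy.mean != 0:
            v.append("balanced pleiotropy must have mean 0")
        if self.ld_blocks is not None:
            size, r2 = self.ld_blocks
            if size < 2 or not (0 < r2 <= 1):
                v.append(f"ld_blocks needs size >= 2 and r2 in (0, 1], got {self.ld_blocks}")
        names = [m.name for m in self.mediators]
        if len(names) != len(set(names)):
            v.append("duplicate mediator names")
        for m in self.mediators:
            if not (np.isfinite(m.a) and np.isfinite(m.b)):
                v.append(f"mediator {m.name}: a and b must be finite")
            if m.j_instruments < 1:
                v.append(f"mediator {m.name}: j_instruments must be >= 1")
        direct = self.beta_total - sum(m.a * m.b for m in self.mediators)
        if not np.isfinite(direct):
            v.append("direct effect beta_total - sum(a*b) is not finite")
        if v:
            raise ScenarioValidationError(v)


@dataclass
class SimulatedData:
    """Output bundle of :func:`simulate_scenario`."""

    exposure: SummaryStats
    outcome: SummaryStats
    mediators: list[SummaryStats]
    ld: pd.DataFrame
    truth: dict


# ordered, non-palindromic allele pairs (effect, other)
_ALLELE_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]


def _obs_table(rng, name, trait_type, ids, alleles, mafs, chroms, positions, true_beta, n, se):
    """Observed summary table: truth + noise, p from the normal approximation."""
    beta_obs = true_beta + rng.normal(0.0, se)
    pval = np.maximum(2.0 * sps.norm.sf(np.abs(beta_obs / se)), 1e-300)
    records = [
        VariantAssociation(
            variant_id=ids[i],
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            beta=float(beta_obs[i]),
            se=float(se[i]),
            pval=float(pval[i]),
            eaf=float(mafs[i]),
            n=float(n),
            chrom=chroms[i],
            pos=int(positions[i]),
        )
        for i in range(len(ids))
    ]
    return SummaryStats(name, trait_type, records)


def simulate_scenario(spec: ScenarioSpec) -> SimulatedData:
    """Draw one synthetic scenario; bit-reproducible for a fixed seed.

    The variant universe is the exposure's instruments plus each mediator's
    own instruments (plus LD-block tags when requested); every trait table
    covers the full universe so harmonization always finds lookups.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # variant universe: exposure instruments, per-mediator instruments,
    # then outcome-specific instruments
    groups = [("exp", spec.j_instruments)] + [
        (f"med{i}", m.j_instruments) for i, m in enumerate(spec.mediators)
    ]
    if spec.j_outcome_instruments:
        groups.append(("out", spec.j_outcome_instruments))
    ids, group_of = [], []
    for tag, count in groups:
        for k in range(count):
            ids.append(f"rs_{tag}_{k}")
            group_of.append(tag)
    n_core = len(ids)

    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, n_core)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), n_core)
    alleles = [_ALLELE_PAIRS[i] for i in allele_idx]
    chroms = [str(1 + i % 22) for i in range(n_core)]
    # spacing far beyond any clumping window keeps core variants independent
    positions = np.arange(n_core) * 20_000_000 + 1

    g_mean, g_sd = spec.gamma_dist
    gamma = np.zeros(n_core)
    is_exp = np.array([g == "exp" for g in group_of])
    gamma[is_exp] = rng.normal(g_mean, g_sd, int(is_exp.sum())) * rng.choice(
        [-1.0, 1.0], int(is_exp.sum())
    )

    # per-mediator instrument effects (delta), same magnitude family
    delta = np.zeros((len(spec.mediators), n_core))
    for i, m in enumerate(spec.mediators):
        mask = np.array([g == f"med{i}" for g in group_of])
        delta[i, mask] = rng.normal(g_mean, g_sd, int(mask.sum())) * rng.choice(
            [-1.0, 1.0], int(mask.sum())
        )

    # true per-variant effects under the linear structural model
    true_exp = gamma.copy()
    true_med = np.zeros((len(spec.mediators), n_core))
    for i, m in enumerate(spec.mediators):
        true_med[i] = m.a * gamma + delta[i]
    true_out = spec.beta_total * gamma
    for i, m in enumerate(spec.mediators):
        true_out += m.b * delta[i]
    is_out = np.array([g == "out" for g in group_of])
    if is_out.any():
        omega = rng.normal(g_mean, g_sd, int(is_out.sum())) * rng.choice(
            [-1.0, 1.0], int(is_out.sum())
        )
        true_out[is_out] = omega
        true_exp[is_out] = spec.beta_reverse * omega
    pl = spec.pleiotropy
    if pl.mode != "none":
        true_out[is_exp] += rng.normal(pl.mean, pl.sd, int(is_exp.sum()))

    # optional LD blocks: tag variants shadowing each exposure instrument
    ld_entries = []
    if spec.ld_blocks is not None:
        size, r2 = spec.ld_blocks
        r = math.sqrt(r2)
        tag_rows = []
        for idx in np.flatnonzero(is_exp):
            block = [ids[idx]]
            for t in range(size - 1):
                tid = f"{ids[idx]}_tag{t}"
                block.append(tid)
                tag_rows.append(
                    dict(
                        tid=tid,
                        maf=mafs[idx],
                        alleles=alleles[idx],
                        chrom=chroms[idx],
                        pos=int(positions[idx]) + 1000 * (t + 1),
                        true_exp=r * true_exp[idx],
                        true_med=r * true_med[:, idx],
                        true_out=r * true_out[idx],
                    )
                )
            ld_entries.append((block, r2))
        for row in tag_rows:
            ids.append(row["tid"])
            mafs = np.append(mafs, row["maf"])
            alleles.append(row["alleles"])
            chroms.append(row["chrom"])
            positions = np.append(positions, row["pos"])
            true_exp = np.append(true_exp, row["true_exp"])
            true_med = np.column_stack([true_med, row["true_med"]])
            true_out = np.append(true_out, row["true_out"])

    n_all = len(ids)
    base_var = 2.0 * mafs * (1.0 - mafs)

    def se_for(n, binary):
        denom = base_var * n
        if binary:
            denom = denom * spec.case_fraction * (1.0 - spec.case_fraction)
        return 1.0 / np.sqrt(denom)

    exp_type = "binary" if spec.exposure_binary else "continuous"
    exposure = _obs_table(
        rng, "exposure", exp_type, ids, alleles, mafs, chroms, positions,
        true_exp, spec.n_exposure, se_for(spec.n_exposure, spec.exposure_binary),
    )
    outcome = _obs_table(
        rng, "outcome", "binary", ids, alleles, mafs, chroms, positions,
        true_out, spec.n_outcome, se_for(spec.n_outcome, True),
    )
    mediators = [
        _obs_table(
            rng, m.name, "continuous", ids, alleles, mafs, chroms, positions,
            true_med[i], spec.n_mediator_gwas, se_for(spec.n_mediator_gwas, False),
        )
        for i, m in enumerate(spec.mediators)
    ]

    ld = pd.DataFrame(np.eye(n_all), index=ids, columns=ids)
    for block, r2 in ld_entries:
        for a in block:
            for b in block:
                if a != b:
                    ld.at[a, b] = r2

    truth = {
        "beta_total": spec.beta_total,
        "direct": spec.beta_total - sum(m.a * m.b for m in spec.mediators),
        "mediators": {m.name: {"a": m.a, "b": m.b, "indirect": m.a * m.b} for m in spec.mediators},
        "gamma": {ids[i]: float(true_exp[i]) for i in range(n_all)},
    }
    return SimulatedData(exposure, outcome, mediators, ld, truth)
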