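import numpy as np
import pytest

from mrmediate.summary_data import (
    HarmonizedSet,
    HarmonizedVariant,
    SummaryStats,
    VariantAssociation,
)


def make_variant(
    vid="rs1",
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=None,
    eaf=0.3,
    n=100_000.0,
    chrom="1",
    pos=1000,
):
    from scipy import stats as sps

    if pval is None:
        pval = float(max(2 * sps.norm.sf(abs(beta / se)), 1e-300))
    return VariantAssociation(
        variant_id=vid,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
        chrom=chrom,
        pos=pos,
    )


def make_stats(records, name="trait", trait_type="continuous"):
    return SummaryStats(name, trait_type, list(records))


def make_hset(beta_exp, beta_out, se_out, se_exp=None, ids=None, name=("exp", "out")):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.001)
    else:
        se_exp = np.asarray(se_exp, dtype=float)
    if ids is None:
        ids = [f"rs{i}" for i in range(len(beta_exp))]
    variants = [
        HarmonizedVariant(ids[i], beta_exp[i], se_exp[i], beta_out[i], se_out[i], 0.3)
        for i in range(len(beta_exp))
    ]
    return HarmonizedSet(name[0], name[1], variants)


def simulate_hset(rng, j=50, beta=0.14, gamma_mean=0.08, gamma_sd=0.02, se_exp=0.002, se_out=0.01):
    """Strong-instrument, no-pleiotropy harmonized set drawn from the
    two-sample sampling model; used by calibration tests."""
    g = rng.normal(gamma_mean, gamma_sd, j) * rng.choice([-1.0, 1.0], j)
    gh = rng.normal(g, se_exp)
    bo = rng.normal(beta * g, se_out)
    return make_hset(gh, bo, np.full(j, se_out), se_exp=np.full(j, se_exp))


@pytest.fixture
def rng():
    return np.random.default_rng(20240713)


@pytest.fixture
def homogeneous_hset():
    """Three variants sharing the exact ratio 0.2."""
    be = np.array([0.1, 0.2, 0.15])
    return make_hset(be, 0.2 * be, [0.01, 0.01, 0.02])
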