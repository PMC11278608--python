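import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.exceptions import (
    ConfigurationError,
    EmptyInputError,
    EmptyResultError,
    MissingEAFError,
    MissingLDError,
)
from mrmediate.summary_data import (
    SummaryStats,
    clump,
    f_statistics,
    harmonize,
    read_summary_stats,
    select_instruments,
    write_summary_stats,
)

from conftest import make_hset, make_stats, make_variant


def write_tsv(path, rows, header="SNP\tchr\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadWrite:
    def test_well_formed_three_rows(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        write_tsv(
            p,
            [
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t5.7e-7\t1000",
                "rs2\t1\t200\tC\tA\t0.2\t-0.05\t0.01\t5.7e-7\t1000",
                "rs3\t2\t300\tg\tt\tNA\t0.0\t0.03\t1.0\t1000",
            ],
        )
        stats = read_summary_stats(p, trait_name="t")
        assert len(stats) == 3
        assert stats.records[2].effect_allele == "G"  # upper-cased
        assert stats.records[2].eaf is None

    def test_zero_se_row_dropped(self, tmp_path, caplog):
        p = tmp_path / "gwas.tsv"
        write_tsv(
            p,
            [
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t5.7e-7\t1000",
                "rs2\t1\t200\tC\tA\t0.2\t0.1\t0.0\t1e-5\t1000",
            ],
        )
        with caplog.at_level("INFO"):
            stats = read_summary_stats(p)
        assert len(stats) == 1
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_round_trip_identity(self, tmp_path, rng):
        records = [
            make_variant(
                vid=f"rs{i}",
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(0.005, 0.05)),
                eaf=None if i % 3 == 0 else float(rng.uniform(0.01, 0.99)),
                pos=int(rng.integers(1, 10**8)),
                chrom=str(rng.integers(1, 23)),
            )
            for i in range(25)
        ]
        stats = make_stats(records, name="rt")
        path = tmp_path / "rt.tsv"
        write_summary_stats(stats, path)
        back = read_summary_stats(path, trait_name="rt")
        assert back.records == stats.records

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tbeta\tse\nrs1\t0.1\t0.01\n")
        with pytest.raises(ConfigurationError):
            read_summary_stats(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("SNP\tchr\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n")
        with pytest.raises(EmptyInputError):
            read_summary_stats(p)

    def test_dialect_mapping(self, tmp_path):
        p = tmp_path / "foreign.tsv"
        p.write_text(
            "rsid\tA1\tA2\tEffect\tStdErr\tP\nrs1\tA\tG\t0.1\t0.02\t5.7e-7\n"
        )
        stats = read_summary_stats(
            p,
            dialect={
                "SNP": "rsid",
                "effect_allele": "A1",
                "other_allele": "A2",
                "beta": "Effect",
                "se": "StdErr",
                "pval": "P",
            },
        )
        assert len(stats) == 1 and stats.records[0].beta == 0.1


class TestSelectInstruments:
    def test_direct_filter(self):
        stats = make_stats(
            [
                make_variant(vid="a", pval=1e-9),
                make_variant(vid="b", pval=1e-7),
                make_variant(vid="c", pval=1e-10),
            ]
        )
        assert len(select_instruments(stats, 5e-8)) == 2

    def test_threshold_one_keeps_all(self):
        stats = make_stats([make_variant(vid=f"v{i}", pval=0.5) for i in range(5)])
        assert len(select_instruments(stats, 1.0)) == 5

    def test_brute_force_oracle_on_synthetic(self):
        import math

        from mrmediate.synthetic import ScenarioSpec, simulate_scenario

        sim = simulate_scenario(
            ScenarioSpec(seed=11, beta_total=math.log(1.153), j_instruments=40, n_exposure=200_000)
        )
        selected = select_instruments(sim.exposure, 5e-8)
        oracle = [r.variant_id for r in sim.exposure.records if r.pval < 5e-8]
        assert selected.to_frame()["SNP"].tolist() == oracle


def diag_ld(ids, pairs=None):
    ld = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b, r2 in pairs or []:
        ld.at[a, b] = r2
        ld.at[b, a] = r2
    return ld


class TestClump:
    def test_dominant_pair(self):
        stats = make_stats(
            [
                make_variant(vid="a", pval=1e-12, pos=1000),
                make_variant(vid="b", pval=1e-9, pos=2000),
            ]
        )
        ld = diag_ld(["a", "b"], [("a", "b", 0.9)])
        kept = clump(stats, ld)
        assert [r.variant_id for r in kept.records] == ["a"]

    def test_independence_keeps_all(self):
        stats = make_stats(
            [make_variant(vid=f"v{i}", pval=1e-9, pos=1000 * i) for i in range(6)]
        )
        assert len(clump(stats, diag_ld([f"v{i}" for i in range(6)]))) == 6

    def test_missing_variant_hard_error(self):
        stats = make_stats([make_variant(vid="a"), make_variant(vid="b")])
        with pytest.raises(MissingLDError):
            clump(stats, diag_ld(["a"]))

    def test_window_limits_conflicts(self):
        # high r2 but far beyond the window: both kept
        stats = make_stats(
            [
                make_variant(vid="a", pval=1e-12, pos=1),
                make_variant(vid="b", pval=1e-9, pos=20_000_001),
            ]
        )
        ld = diag_ld(["a", "b"], [("a", "b", 0.9)])
        assert len(clump(stats, ld, window_kb=10_000)) == 2

    def test_posthoc_verification_oracle(self, rng):
        # 20 variants in 4 LD blocks of 5; within-block r2 above threshold
        ids = [f"v{i:02d}" for i in range(20)]
        records = [
            make_variant(vid=ids[i], pval=float(rng.uniform(1e-12, 1e-8)), pos=1000 + i * 100)
            for i in range(20)
        ]
        pairs = []
        for b in range(4):
            block = ids[5 * b : 5 * b + 5]
            for x in range(5):
                for y in range(x + 1, 5):
                    pairs.append((block[x], block[y], 0.5))
        stats = make_stats(records)
        ld = diag_ld(ids, pairs)
        kept = clump(stats, ld, r2_threshold=0.001, window_kb=10_000)
        kept_ids = {r.variant_id for r in kept.records}
        pmap = {r.variant_id: r.pval for r in records}
        # no retained pair violates the threshold
        for a in kept_ids:
            for b in kept_ids:
                if a != b:
                    assert ld.at[a, b] < 0.001
        # every dropped variant conflicts with a retained better-p variant
        for r in records:
            if r.variant_id not in kept_ids:
                assert any(
                    ld.at[r.variant_id, k] >= 0.001
                    and (pmap[k], k) < (r.pval, r.variant_id)
                    for k in kept_ids
                )

    def test_order_invariance(self, rng):
        ids = [f"v{i}" for i in range(10)]
        records = [
            make_variant(vid=ids[i], pval=float(rng.uniform(1e-10, 1e-8)), pos=1000 + 500 * i)
            for i in range(10)
        ]
        pairs = [(ids[i], ids[i + 1], 0.3) for i in range(9)]
        ld = diag_ld(ids, pairs)
        kept1 = clump(make_stats(records), ld)
        perm = [records[i] for i in rng.permutation(10)]
        kept2 = clump(make_stats(perm), ld)
        assert {r.variant_id for r in kept1.records} == {r.variant_id for r in kept2.records}


class TestFStatistics:
    def test_null_betas(self):
        stats = make_stats([make_variant(vid=f"v{i}", beta=0.0, pval=1.0) for i in range(3)])
        s = f_statistics(stats, 1000)
        assert s.f_stat == 0.0 and s.r2_total == 0.0

    def test_printed_formula_evaluation(self):
        # R2 = 0.05 split over 10 variants, N = 1000 -> F ~ 5.205, weak
        per = 0.005
        beta = np.sqrt(per / (2 * 0.5 * 0.5))
        stats = make_stats(
            [make_variant(vid=f"v{i}", beta=float(beta), eaf=0.5) for i in range(10)]
        )
        s = f_statistics(stats, 1000)
        assert s.r2_total == pytest.approx(0.05)
        assert s.f_stat == pytest.approx(0.05 * 989 / (10 * 0.95))
        assert s.weak

    def test_single_strong_instrument(self):
        stats = make_stats([make_variant(beta=0.1, eaf=0.5)])
        s = f_statistics(stats, 10_000)
        assert s.r2_total == pytest.approx(0.005)
        assert s.f_stat == pytest.approx(0.005 * 9998 / 0.995)
        assert not s.weak

    def test_missing_eaf_names_variant(self):
        stats = make_stats([make_variant(vid="rsX", eaf=None)])
        with pytest.raises(MissingEAFError, match="rsX"):
            f_statistics(stats, 1000)

    def test_per_variant_sums_to_total(self, rng):
        stats = make_stats(
            [
                make_variant(vid=f"v{i}", beta=float(rng.normal(0, 0.05)), eaf=float(rng.uniform(0.1, 0.9)))
                for i in range(20)
            ]
        )
        s = f_statistics(stats, 50_000)
        assert sum(s.per_variant_r2) == pytest.approx(s.r2_total)

    @given(
        r2a=st.floats(0.001, 0.2),
        r2b=st.floats(0.001, 0.2),
        n=st.integers(1000, 10**6),
        k=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_r2_and_n(self, r2a, r2b, n, k):
        def f(r2, n, k):
            return r2 * (n - k - 1) / (k * (1 - r2))

        lo, hi = sorted([r2a, r2b])
        if lo != hi:
            assert f(lo, n, k) < f(hi, n, k)
        assert f(r2a, n, k) < f(r2a, 2 * n, k)


class TestHarmonize:
    def test_flip_orientation(self):
        exp = make_stats([make_variant(vid="rs1", ea="A", oa="G", beta=0.1)], name="e")
        out = make_stats([make_variant(vid="rs1", ea="G", oa="A", beta=0.2, pval=0.5)], name="o")
        h = harmonize(exp, out)
        assert h.variants[0].beta_out == pytest.approx(-0.2)

    def test_palindromic_dropped(self):
        exp = make_stats([make_variant(vid="rs1", ea="A", oa="T")], name="e")
        out = make_stats([make_variant(vid="rs1", ea="A", oa="T", pval=0.5)], name="o")
        h = harmonize(exp, out, raise_on_empty=False)
        assert len(h) == 0 and h.audit["palindromic"] == 1

    def test_ten_variant_fixture_audit(self):
        exp_records = [make_variant(vid=f"rs{i}", ea="A", oa="G", pval=1e-10) for i in range(10)]
        exp_records[3] = make_variant(vid="rs3", ea="C", oa="G", pval=1e-10)  # palindromic
        exp = make_stats(exp_records, name="e")
        out_records = [
            make_variant(vid=f"rs{i}", ea="A", oa="G", beta=0.02, se=0.01, pval=0.3)
            for i in range(10)
            if i != 5  # rs5 missing from outcome
        ]
        out_records[1] = make_variant(vid="rs1", ea="A", oa="G", pval=1e-9)  # outcome-significant
        out = make_stats(out_records, name="o")
        h = harmonize(exp, out)
        assert len(h) == 7
        assert h.audit == {
            "missing_in_outcome": 1,
            "palindromic": 1,
            "outcome_significant": 1,
            "allele_mismatch": 0,
        }
        assert sum(h.audit.values()) == len(exp) - len(h)

    def test_allele_mismatch_dropped(self):
        exp = make_stats([make_variant(vid="rs1", ea="A", oa="G")], name="e")
        out = make_stats([make_variant(vid="rs1", ea="A", oa="C", pval=0.5)], name="o")
        h = harmonize(exp, out, raise_on_empty=False)
        assert len(h) == 0 and h.audit["allele_mismatch"] == 1

    def test_empty_result_error(self):
        exp = make_stats([make_variant(vid="rs1", ea="A", oa="T")], name="e")
        out = make_stats([make_variant(vid="rs1", ea="A", oa="T", pval=0.5)], name="o")
        with pytest.raises(EmptyResultError):
            harmonize(exp, out)

    def test_idempotent(self, rng):
        exp = make_stats(
            [
                make_variant(vid=f"rs{i}", ea="A", oa="G", beta=float(rng.normal(0.1, 0.02)))
                for i in range(8)
            ],
            name="e",
        )
        out = make_stats(
            [
                make_variant(
                    vid=f"rs{i}",
                    ea="G" if i % 2 else "A",
                    oa="A" if i % 2 else "G",
                    beta=float(rng.normal(0, 0.02)),
                    pval=0.4,
                )
                for i in range(8)
            ],
            name="o",
        )
        h1 = harmonize(exp, out)
        # rebuild summary tables from the harmonized set and harmonize again
        exp2 = make_stats(
            [
                make_variant(vid=v.variant_id, ea="A", oa="G", beta=v.beta_exp, se=v.se_exp)
                for v in h1.variants
            ],
            name="e",
        )
        out2 = make_stats(
            [
                make_variant(vid=v.variant_id, ea="A", oa="G", beta=v.beta_out, se=v.se_out, pval=0.4)
                for v in h1.variants
            ],
            name="o",
        )
        h2 = harmonize(exp2, out2)
        assert [(v.variant_id, v.beta_exp, v.beta_out) for v in h2.variants] == [
            (v.variant_id, v.beta_exp, v.beta_out) for v in h1.variants
        ]

    def test_exposure_eaf_retained(self):
        exp = make_stats([make_variant(vid="rs1", ea="A", oa="G", eaf=0.25)], name="e")
        out = make_stats([make_variant(vid="rs1", ea="G", oa="A", eaf=0.9, pval=0.5)], name="o")
        h = harmonize(exp, out)
        assert h.variants[0].eaf == 0.25
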