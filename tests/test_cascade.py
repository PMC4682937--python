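import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from octodart import (
    MarkerMatrix,
    RunConfig,
    SNPAlleleTable,
    chi_square_gof,
    classify_segregation,
    collapse_redundant,
    expand_alleles,
    filter_missing,
    filter_monomorphic,
    filter_rowsum,
    run_cascade,
)
from octodart.cascade import SegClass

from conftest import make_population, presence_column


def chi2_tail_oracle(statistic: float) -> float:
    """Independent closed-form 1-df upper tail: p = erfc(sqrt(x/2))."""
    return float(erfc(math.sqrt(statistic / 2.0)))


class TestExpandAlleles:
    def _table(self, n_snps, n_acc=4):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame(
            rng.integers(0, 2, (2 * n_snps, n_acc)).astype(float),
            index=[f"snp{i // 2}_{'ref' if i % 2 == 0 else 'snp'}" for i in range(2 * n_snps)],
            columns=[f"a{j}" for j in range(n_acc)],
        )
        return SNPAlleleTable(
            snp_ids=[f"snp{i}" for i in range(n_snps)],
            rows=rows,
            row_sum=pd.Series(100.0, index=rows.index),
        )

    def test_doubles_marker_count(self):
        mm = expand_alleles(self._table(3))
        assert mm.n_markers == 6
        assert mm.marker_ids[:2] == ["snp0_ref", "snp0_snp"]

    def test_study_scale_arithmetic(self):
        # 9,386 SNPs scored as presence/absence of each allele -> 18,772 rows
        assert 2 * 9386 == 18772

    def test_odd_row_count_rejected(self):
        t = self._table(2)
        with pytest.raises(ValueError):
            SNPAlleleTable(snp_ids=t.snp_ids, rows=t.rows.iloc[:-1], row_sum=t.row_sum.iloc[:-1])


class TestMonomorphicFilter:
    def test_all_present_is_monomorphic(self):
        pop = make_population({"m": (1, 0)}, {"m": [1.0] * 10})
        kept, mono = filter_monomorphic(pop)
        assert mono == ["m"]

    def test_split_is_kept(self):
        pop = make_population({"m": (1, 0)}, {"m": presence_column(6, 4)})
        kept, mono = filter_monomorphic(pop)
        assert kept == ["m"]

    def test_all_zero_with_missing_is_monomorphic(self):
        pop = make_population({"m": (1, 0)}, {"m": presence_column(0, 7, 3)})
        _, mono = filter_monomorphic(pop)
        assert mono == ["m"]

    def test_all_missing_left_to_missing_filter(self):
        pop = make_population({"m": (1, 0)}, {"m": [np.nan] * 10})
        kept, mono = filter_monomorphic(pop)
        assert kept == ["m"] and mono == []


class TestMissingFilter:
    def test_ten_percent_boundary_at_n94(self):
        pop = make_population(
            {"nine": (1, 0), "ten": (1, 0)},
            {
                "nine": presence_column(45, 40, 9),
                "ten": presence_column(45, 39, 10),
            },
        )
        kept, removed = filter_missing(pop)
        assert kept == ["nine"] and removed == ["ten"]

    def test_missing_parent_excluded(self):
        pop = make_population({"m": (np.nan, 1)}, {"m": presence_column(5, 5)})
        _, removed = filter_missing(pop)
        assert removed == ["m"]

    def test_double_null_parents_excluded(self):
        pop = make_population({"m": (0, 0)}, {"m": presence_column(5, 5)})
        _, removed = filter_missing(pop)
        assert removed == ["m"]


class TestChiSquare:
    @pytest.mark.parametrize(
        "present,absent,ratio,stat,p",
        [
            (47, 47, (1, 1), 0.0, 1.0),
            (60, 34, (1, 1), 7.1915, 0.00733),
            (70, 24, (3, 1), 0.0142, 0.905),
        ],
    )
    def test_worked_examples(self, present, absent, ratio, stat, p):
        res = chi_square_gof(present, absent, ratio)
        assert res.statistic == pytest.approx(stat, abs=5e-4)
        assert res.p_value == pytest.approx(p, abs=5e-3)
        assert res.p_value == pytest.approx(chi2_tail_oracle(res.statistic), abs=1e-10)

    def test_tail_matches_erfc_oracle_over_grid(self):
        """scipy's chi-square survival function agrees with the closed-form
        erfc tail to 1e-10 across statistic values in [0, 50]."""
        from scipy import stats as sps

        grid = np.linspace(0.0, 50.0, 2001)
        ours = sps.chi2.sf(grid, df=1)
        oracle = erfc(np.sqrt(grid / 2.0))
        assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof(0, 0, (1, 1))

    @given(
        present=st.integers(1, 200),
        absent=st.integers(1, 200),
        a=st.integers(1, 15),
        b=st.integers(1, 15),
    )
    @settings(max_examples=100, deadline=None)
    def test_orientation_invariance(self, present, absent, a, b):
        """Swapping present/absent together with the ratio orientation leaves
        the test unchanged."""
        fwd = chi_square_gof(present, absent, (a, b))
        rev = chi_square_gof(absent, present, (b, a))
        assert fwd.statistic == pytest.approx(rev.statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9, abs=1e-300)


class TestClassification:
    def test_perfect_testcross_p1(self):
        pop = make_population({"m": (1, 0)}, {"m": presence_column(47, 47)})
        out = classify_segregation(pop)
        assert out.loc[0, "seg_class"] == SegClass.SIMPLEX_TESTCROSS_P1.value

    def test_intercross_fitting_3_to_1(self):
        pop = make_population({"m": (1, 1)}, {"m": presence_column(70, 24)})
        out = classify_segregation(pop)
        assert out.loc[0, "seg_class"] == SegClass.SIMPLEX_INTERCROSS.value

    def test_duplex_pattern_rejected_simplex_accepted_multiplex(self):
        # parents (1,0) but 70:24 segregation: 1:1 rejected at 0.001,
        # duplex 3:1 accepted at 0.01
        pop = make_population({"m": (1, 0)}, {"m": presence_column(70, 24)})
        out = classify_segregation(pop)
        assert out.loc[0, "seg_class"] == SegClass.MULTIPLEX.value
        assert out.loc[0, "tested_ratio"] == "3:1"

    def test_extreme_distortion(self):
        # 50:44 under parents (1,1): 3:1 strongly rejected; no multiplex
        # ratio (7:1, 13:3, 15:1) is closer, so the allele is distorted
        pop = make_population({"m": (1, 1)}, {"m": presence_column(50, 44)})
        out = classify_segregation(pop)
        assert out.loc[0, "seg_class"] == SegClass.DISTORTED.value

    def test_double_null_pattern_is_internal_error(self):
        pop = make_population({"m": (0, 0)}, {"m": presence_column(5, 5)})
        with pytest.raises(RuntimeError, match="missing filter|\\(0,0\\)"):
            classify_segregation(pop)

    def test_progeny_order_invariance(self):
        col = presence_column(60, 30, 4)
        pop1 = make_population({"m": (1, 0)}, {"m": col})
        pop2 = make_population({"m": (1, 0)}, {"m": col[::-1]})
        a = classify_segregation(pop1)
        b = classify_segregation(pop2)
        assert a.loc[0, "seg_class"] == b.loc[0, "seg_class"]
        assert a.loc[0, "p_value"] == pytest.approx(b.loc[0, "p_value"])

    @pytest.mark.parametrize("alpha_lo,alpha_hi", [(1e-4, 1e-3), (1e-3, 1e-2)])
    def test_raising_alpha_simplex_never_increases_non_simplex(
        self, clean_cross, alpha_lo, alpha_hi
    ):
        kept, _ = filter_monomorphic(clean_cross)
        kept, _ = filter_missing(clean_cross, kept)
        lo = classify_segregation(clean_cross, kept, alpha_simplex=alpha_lo)
        hi = classify_segregation(clean_cross, kept, alpha_simplex=alpha_hi)

        def non_simplex(df):
            return df["seg_class"].isin(
                [SegClass.MULTIPLEX.value, SegClass.DISTORTED.value]
            ).sum()

        assert non_simplex(hi) >= non_simplex(lo)


class TestRowSumFilter:
    def test_threshold_boundary(self):
        pop = make_population(
            {"hi": (1, 1), "lo": (1, 1)},
            {"hi": presence_column(70, 24), "lo": presence_column(70, 24)},
            row_sum={"hi": 600, "lo": 599},
        )
        kept, removed = filter_rowsum(pop, ["hi", "lo"])
        assert kept == ["hi"] and removed == ["lo"]

    def test_scope_is_intercross_only(self):
        # a testcross allele never enters the filter, whatever its depth
        pop = make_population(
            {"tc": (1, 0), "ic": (1, 1)},
            {"tc": presence_column(47, 47), "ic": presence_column(70, 24)},
            row_sum={"tc": 10, "ic": 700},
        )
        kept, removed = filter_rowsum(pop, ["ic"])
        assert kept == ["ic"] and removed == []

    def test_study_scale_arithmetic(self):
        assert 3400 - 2528 == 872

    def test_missing_row_sum_names_allele(self):
        pop = make_population({"m": (1, 1)}, {"m": presence_column(70, 24)})
        pop.row_sum = pop.row_sum.drop("m")
        with pytest.raises(ValueError, match="m"):
            filter_rowsum(pop, ["m"])


class TestRedundancyCollapse:
    def test_identical_columns_collapse(self):
        col = presence_column(15, 15)
        pop = make_population(
            {"a_ref": (1, 0), "b_ref": (1, 0)}, {"a_ref": col, "b_ref": col}
        )
        kept, removed = collapse_redundant(pop, ["a_ref", "b_ref"])
        assert kept == ["a_ref"] and removed == ["b_ref"]

    def test_below_threshold_both_kept(self):
        a = [1.0] * 50 + [0.0] * 50
        b = list(a)
        b[0], b[99] = 0.0, 1.0  # 98% similar
        pop = make_population({"a": (1, 0), "b": (1, 0)}, {"a": a, "b": b})
        kept, removed = collapse_redundant(pop, ["a", "b"])
        assert sorted(kept) == ["a", "b"]

    def test_complementary_alleles_of_one_snp_collapse(self):
        col = presence_column(15, 15)
        comp = [1.0 - v for v in col]
        pop = make_population(
            {"snp1_ref": (1, 0), "snp1_snp": (0, 1)},
            {"snp1_ref": col, "snp1_snp": comp},
        )
        kept, removed = collapse_redundant(pop, ["snp1_ref", "snp1_snp"])
        assert len(kept) == 1 and len(removed) == 1

    def test_low_overlap_pair_skipped(self):
        col = presence_column(5, 5, 20)
        pop = make_population({"a": (1, 0), "b": (1, 0)}, {"a": col, "b": col})
        kept, removed = collapse_redundant(pop, ["a", "b"])
        assert sorted(kept) == ["a", "b"]

    def test_representative_has_fewer_missing(self):
        full = presence_column(15, 15)
        gappy = list(full)
        gappy[0] = np.nan
        pop = make_population({"a": (1, 0), "b": (1, 0)}, {"a": gappy, "b": full})
        kept, _ = collapse_redundant(pop, ["a", "b"])
        assert kept == ["b"]


class TestFullCascade:
    def test_partition_reconciles_on_simulated_cross(self, clean_cross):
        report, selected, table = run_cascade(clean_cross)
        r = report
        assert r.total_alleles == clean_cross.progeny.n_markers
        assert (
            r.monomorphic + r.excluded_missing + r.multiplex + r.distorted
            + r.testcross_total + r.intercross_total
            == r.total_alleles
        )
        assert r.mapping_set == selected.n_markers
        assert table["final_class"].notna().all()

    def test_noisy_cascade_reconciles(self):
        from octodart import CrossSimConfig, simulate_octoploid_cross

        pop = simulate_octoploid_cross(CrossSimConfig(seed=21))
        report, selected, table = run_cascade(pop, RunConfig(seed=21))
        assert report.remaining_after_missing == (
            report.multiplex + report.distorted + report.simplex_total
        )
        assert report.final_selected == report.testcross_total + report.intercross_kept
        assert len(table) == report.total_alleles

    def test_true_composition_recovered_without_noise(self, clean_cross):
        """With no errors and no missing data the report counts match the
        generating composition up to chi-square misclassification error."""
        report, _, table = run_cascade(clean_cross)
        truth = clean_cross.truth.set_index("marker")["dosage_class"]
        merged = table.set_index("marker").join(truth)
        tc1 = merged[merged["dosage_class"] == "simplex_testcross_P1"]
        frac = (tc1["seg_class"] == SegClass.SIMPLEX_TESTCROSS_P1.value).mean()
        assert frac >= 0.99
        assert report.monomorphic == 0
        assert report.excluded_missing == 0
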