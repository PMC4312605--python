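"""TPM arithmetic, the exact Poisson test, chi-square, FDR and screening."""

import itertools

import numpy as np
import pytest
from scipy.stats import nbinom

from droughtmir.datasets import LOG2_ROUNDTRIP_EXCLUSIONS, conserved_mirna_table
from droughtmir.diffexpr import (ac_test, apply_pseudocount,
                                 bh_fdr, chisq_test, expression_table,
                                 log2_ratio, screen, contrast_results, tpm)
from .oracles import ac_pmf, ac_test_by_summation


class TestTpm:
    @pytest.mark.parametrize("mapped,total,expected", [
        (50, 10_000_000, 5.00), (3, 1_000_000, 3.00), (0, 123, 0.0)])
    def test_values(self, mapped, total, expected):
        assert round(tpm(mapped, total), 2) == expected

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            tpm(1, 0)

    def test_pseudocount_substitution(self):
        assert apply_pseudocount(0.0, 0) == (0.01, True)
        assert apply_pseudocount(0.08, 1) == (0.08, False)


class TestLog2Ratio:
    @pytest.mark.parametrize("stress,control,expected", [
        (1.71, 0.25, 2.77),           # upregulated, both genotypes
        (4.08, 1036.32, -7.99),       # strong downregulation
        (0.01, 28.57, -11.48),        # zero count in the stress library
        (0.19, 0.01, 4.25),           # zero count in the control library
        (3.5, 3.5, 0.00),
    ])
    def test_published_anchor_values(self, stress, control, expected):
        assert round(log2_ratio(stress, control), 2) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(0.0, 1.0)


class TestAcTest:
    def test_identical_zero_counts_give_one(self):
        assert ac_test(0, 1000, 0, 1000) == 1.0

    def test_pmf_normalisation(self):
        for x, f in [(0, 1.0), (5, 0.5), (20, 2.0)]:
            total = sum(ac_pmf(y, x, f) for y in range(0, 3000))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        worst = 0.0
        for x, y in itertools.product((0, 1, 2, 5, 10, 25, 50), repeat=2):
            for n1, n2 in ((10_000, 10_000), (10_000, 17_000),
                           (2_000_000, 9_999_999)):
                a = ac_test(x, n1, y, n2)
                b = ac_test_by_summation(x, n1, y, n2)
                worst = max(worst, abs(a - b) / b)
        assert worst < 1e-9

    def test_scale_invariance(self):
        assert ac_test(5, 1_000, 25, 1_000) == \
            pytest.approx(ac_test(5, 1_000_000, 25, 1_000_000), rel=1e-12)

    def test_agrees_with_negative_binomial_tail(self):
        # the conditional distribution of y given x is NB(x+1, 1/(1+f))
        x, y, n1, n2 = 7, 21, 500_000, 750_000
        f = n2 / n1
        lower = nbinom.cdf(y, x + 1, 1 / (1 + f))
        upper = nbinom.sf(y - 1, x + 1, 1 / (1 + f))
        assert ac_test(x, n1, y, n2) == \
            pytest.approx(min(1.0, 2 * min(lower, upper)), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_test(-1, 10, 0, 10)


class TestChisq:
    def test_homogeneous_table_p_one(self):
        stat, p, degenerate = chisq_test(30, 1000, 30, 1000)
        assert stat == 0 and p == 1.0 and not degenerate

    def test_statistic_matches_textbook_formula(self):
        a, b, c, d = 30, 970, 10, 990
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        stat, _, _ = chisq_test(30, 1000, 10, 1000)
        assert stat == pytest.approx(expected)

    def test_symmetric_in_libraries(self):
        assert chisq_test(30, 1000, 10, 2000)[1] == \
            pytest.approx(chisq_test(10, 2000, 30, 1000)[1])

    def test_degenerate_table_flagged(self):
        stat, p, degenerate = chisq_test(0, 10, 0, 10)
        assert p == 1.0 and degenerate


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.03, 0.03, 0.03]) == pytest.approx([0.03] * 3)

    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_order_invariant(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.015])
        perm = np.array([3, 1, 4, 0, 2])
        assert bh_fdr(p)[perm] == pytest.approx(bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestScreen:
    def _results(self, p, q, fold):
        import pandas as pd
        return pd.DataFrame({"p": [p], "q": [q], "fold": [fold]},
                            index=["m1"])

    def test_kept_when_all_criteria_met(self):
        assert len(screen(self._results(0.005, 0.005, 4.0))) == 1

    def test_dropped_on_fdr(self):
        assert len(screen(self._results(0.005, 0.02, 4.0))) == 0

    def test_dropped_on_fold(self):
        assert len(screen(self._results(0.001, 0.001, 1.5))) == 0


def test_expression_table_flags_zero_counts():
    import pandas as pd
    counts = pd.DataFrame({"C1": [0, 10], "T1": [5, 10]}, index=["a", "b"])
    table = expression_table(counts, {"C1": 1_000_000, "T1": 1_000_000})
    assert table.loc["a", "tpm_C1"] == 0.01 and table.loc["a", "zero_C1"]
    assert table.loc["b", "tpm_C1"] == 10.0 and not table.loc["b", "zero_C1"]


def test_contrast_results_satisfy_invariants():
    import pandas as pd
    counts = pd.DataFrame({"C1": [100, 0, 50], "T1": [400, 40, 52]},
                          index=["up", "on", "flat"])
    res = contrast_results(counts, {"C1": 1_000_000, "T1": 1_000_000},
                        "C1", "T1")
    assert ((res["p"] > 0) & (res["p"] <= 1)).all()
    assert (res["q"] >= res["p"]).all()
    assert res.loc["up", "log2_ratio"] == pytest.approx(2.0, abs=0.01)
    kept = screen(res)
    assert set(kept.index) == {"up", "on"}


def test_published_log2_values_recompute_from_published_tpms():
    """The conserved-miRNA table's log2 columns round-trip from the printed
    TPM pairs at 2 decimals (entries known not to round-trip excluded)."""
    table = conserved_mirna_table()
    checked = 0
    for row in table.itertuples():
        for col, stress, control in (("log2_g1", row.tpm_t1, row.tpm_c1),
                                     ("log2_g2", row.tpm_t2, row.tpm_c2)):
            if (row.mirna_id, col) in LOG2_ROUNDTRIP_EXCLUSIONS:
                continue
            printed = getattr(row, col)
            assert abs(round(log2_ratio(stress, control), 2) - printed) \
                <= 0.01 + 1e-9, (row.mirna_id, col)
            checked += 1
    assert checked >= 75    # 92 entries minus the 15 exclusions, both columns
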