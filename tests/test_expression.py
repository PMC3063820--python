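import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import qpcrflux as qf
from qpcrflux.errors import NormalizationError


def _args(fold=4.0, noise=0.15, seed=0, n_tech=3, n_bio=2, e=2.0):
    """Replicate CT arrays for a two-tissue, one-reference experiment."""
    design = qf.DesignSpec(
        genes=["tgt", "r1"],
        tissues=["s", "c"],
        control_tissue="c",
        reference_genes=["r1"],
        true_fold_changes={"tgt": {"s": fold}},
        n_technical=n_tech,
        n_biological=n_bio,
        noise_sd=noise,
        outlier_rate=0.0,
        base_ct={"tgt": 22.0, "r1": 19.0},
    )
    table = qf.simulate_ct_table(design, {"tgt": e, "r1": e}, seed=seed)
    wide = table.pivot_table(index=["tissue", "bio_rep", "tech_rep"], columns="gene", values="ct")
    s, c = wide.loc["s"], wide.loc["c"]
    return (
        s["tgt"].to_numpy(),
        c["tgt"].to_numpy(),
        [s["r1"].to_numpy()],
        [c["r1"].to_numpy()],
        e,
        [e],
    )


class TestPfafflRatio:
    def test_no_difference_gives_unity(self):
        assert qf.pfaffl_ratio(21.0, 21.0, [19.0], [19.0], 1.9, [1.9]) == pytest.approx(1.0)

    def test_one_cycle_with_perfect_doubling_gives_two(self):
        assert qf.pfaffl_ratio(20.0, 21.0, [19.0], [19.0], 2.0, [2.0]) == pytest.approx(2.0)

    def test_printed_ct_example(self, ct_matrix, efficiencies):
        # ADS in young leaves vs old leaves, three references
        ratio = qf.pfaffl_ratio(
            ct_matrix.loc["ADS", "young_leaves"],
            ct_matrix.loc["ADS", "old_leaves"],
            [ct_matrix.loc[g, "young_leaves"] for g in ("beta-actin", "CPR", "PAL")],
            [ct_matrix.loc[g, "old_leaves"] for g in ("beta-actin", "CPR", "PAL")],
            efficiencies["ADS"],
            [efficiencies[g] for g in ("beta-actin", "CPR", "PAL")],
        )
        assert ratio == pytest.approx(98.26, rel=1e-3)

    def test_reciprocity(self):
        fwd = qf.pfaffl_ratio(20.0, 23.0, [19.0, 18.5], [19.4, 18.1], 1.88, [1.9, 1.85])
        rev = qf.pfaffl_ratio(23.0, 20.0, [19.4, 18.1], [19.0, 18.5], 1.88, [1.9, 1.85])
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=15.0, max_value=35.0),
        st.floats(min_value=0.05, max_value=3.0),
        st.floats(min_value=1.05, max_value=2.0),
    )
    def test_monotone_decreasing_in_sample_ct(self, ct, delta, e):
        lo = qf.pfaffl_ratio(ct, 25.0, [20.0], [20.0], e, [1.9])
        hi = qf.pfaffl_ratio(ct + delta, 25.0, [20.0], [20.0], e, [1.9])
        assert hi < lo

    def test_requires_reference(self):
        with pytest.raises(NormalizationError):
            qf.pfaffl_ratio(20.0, 21.0, [], [], 2.0, [])


class TestRandomizationTest:
    def test_identical_groups_not_significant(self):
        p = qf.randomization_test(
            [20.0, 20.0, 20.0], [20.0, 20.0, 20.0],
            [[19.0] * 3], [[19.0] * 3], 2.0, [2.0], n_iter=500, seed=1,
        )
        assert p == pytest.approx(1.0)

    def test_eightfold_change_detected(self):
        p = qf.randomization_test(*_args(fold=8.0, noise=0.1, seed=5), n_iter=2000, seed=5)
        assert p < 0.05

    def test_deterministic_under_seed(self):
        args = _args(fold=3.0, seed=2)
        assert qf.randomization_test(*args, seed=9) == qf.randomization_test(*args, seed=9)

    def test_insufficient_replicates_flagged(self):
        with pytest.warns(UserWarning):
            p = qf.randomization_test([20.0], [21.0, 21.0], [[19.0]], [[19.0, 19.0]], 2.0, [2.0])
        assert np.isnan(p)

    def test_null_pvalues_roughly_uniform(self, null_pvalue_sample):
        # no-effect experiments: the p-value distribution should pass a
        # Kolmogorov-Smirnov uniformity check
        assert stats.kstest(null_pvalue_sample, "uniform").pvalue > 0.01


class TestBootstrapInterval:
    def test_zero_noise_collapses_to_point(self):
        lo, hi = qf.bootstrap_interval(
            [20.0] * 3, [21.0] * 3, [[19.0] * 3], [[19.0] * 3], 2.0, [2.0],
            n_boot=200, seed=1,
        )
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_deterministic_under_seed(self):
        args = _args(fold=4.0, seed=3)
        a = qf.bootstrap_interval(*args, seed=7)
        b = qf.bootstrap_interval(*args, seed=7)
        assert a == b

    def test_contains_point_ratio(self):
        args = _args(fold=4.0, seed=8)
        ratio = qf.pfaffl_ratio(*args)
        lo, hi = qf.bootstrap_interval(*args, seed=8)
        assert lo <= ratio <= hi

    def test_coverage_of_true_ratio(self):
        # percentile intervals at level 0.95 under the design defaults
        seeds = np.random.SeedSequence(0).generate_state(200)
        cover = 0
        for i in range(100):
            args = _args(fold=4.0, noise=0.15, seed=int(seeds[2 * i]) % 2**31)
            lo, hi = qf.bootstrap_interval(
                *args, n_boot=1000, seed=int(seeds[2 * i + 1]) % 2**31
            )
            cover += lo <= 4.0 <= hi
        assert cover >= 90


class TestRelativeExpressionEstimator:
    def test_fit_produces_expected_columns_and_recovers_fold(self):
        design = qf.DesignSpec(
            genes=["tgt", "r1", "r2"],
            tissues=["s", "c"],
            control_tissue="c",
            reference_genes=["r1", "r2"],
            true_fold_changes={"tgt": {"s": 6.0}},
            noise_sd=0.1,
            outlier_rate=0.0,
        )
        eff = {"tgt": 1.88, "r1": 1.9, "r2": 1.91}
        table = qf.simulate_ct_table(design, eff, seed=4)
        model = qf.RelativeExpression(
            reference_genes=["r1", "r2"], control_tissue="c",
            efficiencies=eff, n_iter=500, n_boot=500, seed=4,
        ).fit(table)
        row = model.ratios_.iloc[0]
        assert row["gene"] == "tgt"
        assert row["ratio"] == pytest.approx(6.0, rel=0.35)
        assert row["ci_low"] <= row["ratio"] <= row["ci_high"]
        assert row["n_sample"] == row["n_control"] == 6

    def test_bh_option_adds_adjusted_column(self):
        design = qf.null_design(n_genes=5)
        eff = {g: 1.9 for g in design.genes}
        table = qf.simulate_ct_table(design, eff, seed=1)
        model = qf.RelativeExpression(
            reference_genes=["ref1", "ref2"], control_tissue="control",
            efficiencies=eff, n_iter=200, n_boot=50, seed=1, bh_correct=True,
        ).fit(table)
        assert "p_adj" in model.ratios_
        assert (model.ratios_["p_adj"] >= model.ratios_["p_value"] - 1e-12).all()
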