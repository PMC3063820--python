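import math

import numpy as np
import pytest

import qpcrflux as qf
from qpcrflux.errors import ParameterError


class TestDeltaDeltaCt:
    def test_target_equal_calibrator_is_unity(self, ct_matrix):
        ddct, amount = qf.delta_delta_ct(
            ct_matrix, ("RED1", "flower_buds"), "beta-actin", ("RED1", "flower_buds")
        )
        assert ddct == 0.0 and amount == 1.0

    def test_printed_flower_bud_estimate(self, ct_matrix):
        # ADS vs RED1 within flower buds, beta-actin reference
        ddct, amount = qf.delta_delta_ct(
            ct_matrix, ("ADS", "flower_buds"), "beta-actin", ("RED1", "flower_buds")
        )
        assert ddct == pytest.approx(-8.4, abs=1e-9)
        assert round(amount) == 338

    def test_cross_tissue_estimate(self, ct_matrix):
        # ADS in young leaves against GAS in stems, per-tissue reference
        _, amount = qf.delta_delta_ct(
            ct_matrix, ("ADS", "young_leaves"), "beta-actin", ("GAS", "stems")
        )
        assert round(amount) == 6654

    def test_not_detected_input_propagates(self, ct_matrix):
        ddct, amount = qf.delta_delta_ct(
            ct_matrix, ("ADS", "roots"), "beta-actin", ("GAS", "stems")
        )
        assert math.isnan(ddct) and math.isnan(amount)

    def test_unknown_gene_rejected(self, ct_matrix):
        with pytest.raises(ParameterError):
            qf.delta_delta_ct(ct_matrix, ("nope", "stems"), "beta-actin", ("GAS", "stems"))

    def test_chain_consistency(self, ct_matrix):
        # amounts relative to any calibrator stay mutually consistent
        _, a_c1 = qf.delta_delta_ct(ct_matrix, ("ECS", "stems"), "beta-actin", ("GAS", "stems"))
        _, b_c1 = qf.delta_delta_ct(ct_matrix, ("SQS", "old_leaves"), "beta-actin", ("GAS", "stems"))
        _, a_rel_b = qf.delta_delta_ct(
            ct_matrix, ("ECS", "stems"), "beta-actin", ("SQS", "old_leaves")
        )
        assert a_c1 / b_c1 == pytest.approx(a_rel_b, rel=1e-12)

    def test_equivalence_with_pfaffl_at_perfect_doubling(self, ct_matrix):
        # cross-module oracle: the two ratio formulations coincide at E = 2
        for gene, tissue in [("ADS", "flower_buds"), ("SQS", "young_leaves")]:
            _, amount = qf.delta_delta_ct(
                ct_matrix, (gene, tissue), "beta-actin", (gene, "old_leaves")
            )
            ratio = qf.pfaffl_ratio(
                ct_matrix.loc[gene, tissue],
                ct_matrix.loc[gene, "old_leaves"],
                [ct_matrix.loc["beta-actin", tissue]],
                [ct_matrix.loc["beta-actin", "old_leaves"]],
                2.0,
                [2.0],
            )
            assert ratio == pytest.approx(amount, rel=1e-12)


class TestAmountMatrix:
    def test_calibrator_cell_is_one(self, ct_matrix):
        amounts = qf.amount_matrix(ct_matrix, rounding="paper")
        assert amounts.loc["GAS", "stems"] == 1.0

    def test_sesquiterpene_block_reproduced(self, ct_matrix):
        printed = {
            ("ADS", "flower_buds"): 8780,
            ("ADS", "young_leaves"): 6654,
            ("ADS", "old_leaves"): 69,
            ("ADS", "stems"): 18,
            ("ECS", "flower_buds"): 315,
            ("SQS", "flower_buds"): 830,
            ("SQS", "young_leaves"): 340,
            ("SQS", "old_leaves"): 1780,
            ("ECS", "old_leaves"): 43000,
        }
        amounts = qf.amount_matrix(ct_matrix, rounding="paper")
        for (gene, tissue), value in printed.items():
            assert amounts.loc[gene, tissue] == pytest.approx(value, rel=0.01)

    def test_transformer_interface(self, ct_matrix):
        tf = qf.DeltaDeltaCt(rounding="paper", genes=["ADS"], tissues=["stems"])
        out = tf.fit_transform(ct_matrix)
        assert out.loc["ADS", "stems"] == 18.0


class TestTurnover:
    def test_paper_rounded_scores(self, ct_matrix, kinetics):
        table = qf.turnover_table(
            ct_matrix, kinetics, tissue="flower_buds",
            calibrator=("RED1", "flower_buds"), rounding="paper",
        ).set_index(["enzyme", "substrate"])
        assert table.loc[("FDS1", "IDP"), "relative_turnover"] == 96.0
        assert table.loc[("ALDH1", "DHAA"), "relative_turnover"] == 462.0
        assert table.loc[("ALDH1", "AA"), "relative_turnover"] == 90.0
        assert table.loc[("ADS", "FDP"), "relative_turnover"] == 1.4
        assert table.loc[("RED1", "DHAA"), "relative_turnover"] == 0.3

    def test_zero_kcat_gives_zero_turnover(self):
        const = qf.KineticConstants("x", "s", 1.0, 0.0)
        assert qf.turnover_potential(100.0, const) == 0.0

    def test_missing_kcat_excluded_with_flag(self, ct_matrix, kinetics):
        table = qf.turnover_table(
            ct_matrix, kinetics, tissue="flower_buds", calibrator=("RED1", "flower_buds")
        )
        cyp = table[table["enzyme"] == "CYP71AV1"].iloc[0]
        assert "no_kcat" in cyp["flag"]
        assert math.isnan(cyp["relative_turnover"])
        with pytest.raises(ParameterError):
            qf.turnover_potential(10.0, qf.KineticConstants("x", "s", 1.0, None))

    def test_dbr2_specific_amplicon_flagged_as_discrepant(self, ct_matrix, kinetics):
        # the DBR2-specific amplicon gives a far larger amount than the
        # published 239; the row is flagged rather than forced to match
        table = qf.turnover_table(
            ct_matrix, kinetics, tissue="flower_buds",
            calibrator=("RED1", "flower_buds"), rounding="paper",
        ).set_index(["enzyme", "substrate"])
        row = table.loc[("DBR2", "AA")]
        assert "known_discrepancy" in row["flag"]
        assert row["ddct"] == pytest.approx(-11.8, abs=1e-6)
        assert row["amount"] != 239.0

    def test_constants_validation(self):
        with pytest.raises(ParameterError):
            qf.KineticConstants("x", "s", -1.0, 1.0)
        with pytest.raises(ParameterError):
            qf.KineticConstants("x", "s", 1.0, 1.0, substrate_stoichiometry=3)


class TestCompetitionRatio:
    def _estimate(self, ct_matrix, enzyme, kcat, stoich, tissue):
        const = qf.KineticConstants(enzyme, "FDP", None, kcat, stoich)
        return qf.turnover_estimate(
            ct_matrix, const, tissue, calibrator=("GAS", "stems"), rounding="paper"
        )

    def test_identical_estimates_give_unity(self, ct_matrix):
        a = self._estimate(ct_matrix, "SQS", 1.0, 2, "young_leaves")
        assert qf.competition_ratio(a, a) == pytest.approx(1.0)

    def test_sqs_outcompetes_ads_in_young_leaves(self, ct_matrix):
        sqs = self._estimate(ct_matrix, "SQS", 1.0, 2, "young_leaves")
        ads = self._estimate(ct_matrix, "ADS", 0.004, 1, "young_leaves")
        assert qf.competition_ratio(sqs, ads) == pytest.approx(25.0, abs=1.0)

    def test_flower_bud_ratio_near_47(self, ct_matrix):
        sqs = self._estimate(ct_matrix, "SQS", 1.0, 2, "flower_buds")
        ads = self._estimate(ct_matrix, "ADS", 0.004, 1, "flower_buds")
        assert qf.competition_ratio(sqs, ads) == pytest.approx(47.3, abs=1.0)

    def test_cross_tissue_comparison_rejected(self, ct_matrix):
        a = self._estimate(ct_matrix, "SQS", 1.0, 2, "young_leaves")
        b = self._estimate(ct_matrix, "ADS", 0.004, 1, "stems")
        with pytest.raises(ParameterError):
            qf.competition_ratio(a, b)

    def test_zero_denominator_flagged(self, ct_matrix):
        a = self._estimate(ct_matrix, "SQS", 1.0, 2, "young_leaves")
        b = self._estimate(ct_matrix, "ADS", 0.0, 1, "young_leaves")
        assert math.isnan(qf.competition_ratio(a, b))
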