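"""Counterfactual adjustment and sweep tests against deterministic stubs."""

import numpy as np
import pandas as pd
import pytest

from ohca_interact import (
    AdjustmentSpec,
    EffectModel,
    adjust_records,
    relative_change,
    single_factor_sweep,
    summarize_predictions,
    true_outcome_probability,
    two_factor_grid,
)
from ohca_interact.counterfactual import (
    AdjustmentError,
    eligibility_mask,
    interaction_logit_residual,
)

from conftest import logistic_stub


class TestAdjustRecords:
    def test_zero_delta_is_identity(self, small_cohort):
        out = adjust_records(small_cohort, AdjustmentSpec("contact_to_arrival", 0.0))
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_original_frame_not_mutated(self, small_cohort):
        before = small_cohort.copy()
        adjust_records(small_cohort, AdjustmentSpec("contact_to_arrival", 10.0))
        pd.testing.assert_frame_equal(small_cohort, before)

    def test_non_shockable_records_untouched_by_defib_adjustment(self, small_cohort):
        spec = AdjustmentSpec("contact_to_first_defib", -2.0)
        out = adjust_records(small_cohort, spec)
        nonshock = ~small_cohort["first_rhythm"].isin(["VF", "pulseless_VT"])
        pd.testing.assert_frame_equal(out.loc[nonshock], small_cohort.loc[nonshock])
        # eligible records did move
        elig = eligibility_mask(small_cohort, spec)
        assert elig.sum() > 0
        moved = (
            out.loc[elig, "defib_time_min"].to_numpy()
            != small_cohort.loc[elig, "defib_time_min"].to_numpy()
        )
        clamped = small_cohort.loc[elig, "defib_time_min"].to_numpy() == 0.0
        assert (moved | clamped).all()

    def test_clamping_at_floor(self):
        df = pd.DataFrame([{
            "first_rhythm": "VF", "defib_performed": 1, "defib_time_min": 2.0,
            "adrenaline_given": 0, "adrenaline_time_min": np.nan,
            "witness_type": "family", "age_years": 70,
            "call_to_contact_min": 8.0, "contact_to_arrival_min": 28.0,
        }])
        out = adjust_records(df, AdjustmentSpec("contact_to_first_defib", -5.0))
        assert out.loc[0, "defib_time_min"] == 0.0

    def test_ems_witnessed_excluded_from_drug_adjustment(self, small_cohort):
        spec = AdjustmentSpec("contact_to_first_drug", 5.0)
        mask = eligibility_mask(small_cohort, spec)
        ems = small_cohort["witness_type"].isin(
            ["firefighter", "paramedic", "emergency_lifesaver"]
        ).to_numpy()
        assert not (mask & ems).any()
        assert not (mask & (small_cohort["adrenaline_given"] == 0).to_numpy()).any()

    def test_unknown_factor_rejected(self):
        with pytest.raises(AdjustmentError, match="unknown factor"):
            AdjustmentSpec("transport_speed", 1.0)


class TestSummaries:
    def test_constant_ensemble_mean_mode(self, small_cohort):
        stub = lambda df: np.full((4, len(df)), 0.04)
        val = summarize_predictions(stub, small_cohort.head(1000))
        assert val == pytest.approx(0.04)

    def test_hand_computed_logistic_stub_summary(self):
        eff = EffectModel()
        records = pd.DataFrame([
            dict(age_years=60, witnessed="yes", bystander_cpr="yes", first_rhythm="VF",
                 defib_performed=1, defib_time_min=3.0, adrenaline_given=0,
                 adrenaline_time_min=np.nan, contact_to_arrival_min=20.0,
                 call_to_contact_min=8.0, witness_type="family"),
            dict(age_years=85, witnessed="no", bystander_cpr="no", first_rhythm="asystole",
                 defib_performed=0, defib_time_min=np.nan, adrenaline_given=1,
                 adrenaline_time_min=18.0, contact_to_arrival_min=35.0,
                 call_to_contact_min=9.0, witness_type="none"),
            dict(age_years=74, witnessed="yes", bystander_cpr="no", first_rhythm="PEA",
                 defib_performed=0, defib_time_min=np.nan, adrenaline_given=0,
                 adrenaline_time_min=np.nan, contact_to_arrival_min=28.0,
                 call_to_contact_min=7.0, witness_type="other"),
        ])
        expected = np.mean([
            true_outcome_probability(records.iloc[i].to_dict(), eff) for i in range(3)
        ])
        got = summarize_predictions(logistic_stub(eff), records)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_count_mode_all_below_threshold(self, small_cohort):
        stub = lambda df: np.full((4, len(df)), 0.2)
        assert summarize_predictions(stub, small_cohort.head(50),
                                     "predicted_positive_count") == 0.0

    def test_empty_record_set_rejected(self, small_cohort):
        with pytest.raises(AdjustmentError, match="empty"):
            summarize_predictions(lambda df: np.zeros(0), small_cohort.head(0))

    def test_relative_change_arithmetic(self):
        assert relative_change(0.04, 0.04) == 0.0
        assert relative_change(0.05, 0.04) == pytest.approx(25.0)
        assert relative_change(0.03, 0.04) == pytest.approx(-25.0)
        with pytest.raises(AdjustmentError):
            relative_change(0.1, 0.0)


class TestSingleFactorSweep:
    def test_directions_match_generative_signs(self, included_cohort):
        # with the true model as predictor: transport delay and higher age
        # worsen the prognosis, and vice versa
        stub = logistic_stub(EffectModel())
        sweep = single_factor_sweep(stub, included_cohort, "contact_to_arrival",
                                    deltas=[-5.0, 0.0, 10.0, 20.0])
        assert sweep[0.0] == 0.0
        assert sweep[-5.0] > 0 > sweep[10.0] > sweep[20.0]
        age = single_factor_sweep(stub, included_cohort, "age_years", deltas=[-5.0, 5.0])
        assert age[-5.0] > 0 > age[5.0]

    def test_default_deltas_quoted_sets(self, included_cohort):
        stub = logistic_stub(EffectModel())
        assert set(single_factor_sweep(stub, included_cohort, "age_years")) == {-5.0, 5.0}
        assert set(single_factor_sweep(stub, included_cohort, "call_to_contact")) == {10.0, 20.0}
        assert set(single_factor_sweep(stub, included_cohort, "contact_to_arrival")) == {
            -5.0, 10.0, 20.0}


class TestTwoFactorGrid:
    def test_trivial_all_zero_axes(self, included_cohort):
        g = two_factor_grid(logistic_stub(EffectModel()), included_cohort,
                            "contact_to_arrival", [0.0], "contact_to_first_drug", [0.0])
        assert g.values.shape == (1, 1)
        assert g.values[0, 0] == 0.0

    def test_zero_cell_exact_and_dimensions(self, included_cohort):
        g = two_factor_grid(
            logistic_stub(EffectModel()), included_cohort,
            "contact_to_arrival", [-4.0, 0.0, 4.0],
            "contact_to_first_defib", [-2.0, 0.0, 2.0],
        )
        assert g.values.shape == (3, 3)
        assert g.values[1, 1] == 0.0
        assert np.isfinite(g.values).all()
        assert g.n_eligible["contact_to_arrival"] == len(included_cohort)
        assert 0 < g.n_eligible["contact_to_first_defib"] < len(included_cohort)

    def test_stub_additivity_without_interaction_at_small_deltas(self, included_cohort):
        # no interaction term: percent grid is additive to first order
        eff = EffectModel(transport_x_defib=0.0, transport_x_drug=0.0)
        g = two_factor_grid(
            logistic_stub(eff), included_cohort,
            "contact_to_arrival", [-0.25, 0.0, 0.25],
            "contact_to_first_drug", [-0.25, 0.0, 0.25],
        )
        resid = g.values[2, 2] - g.values[2, 1] - g.values[1, 2] + g.values[1, 1]
        # each cell is O(0.25 min * beta) ~ 1.5%; the residual is second order
        assert abs(g.values[2, 1]) > 10 * abs(resid)
        assert abs(resid) < 0.05

    def test_grid_matches_brute_force_recomputation(self, included_cohort):
        # oracle equivalence on a 5x5 grid, 100 records
        eff = EffectModel()
        records = included_cohort.head(100)
        stub = logistic_stub(eff)
        da = [-4.0, -2.0, 0.0, 2.0, 4.0]
        db = [-2.0, -1.0, 0.0, 1.0, 2.0]
        g = two_factor_grid(stub, records, "contact_to_arrival", da,
                            "contact_to_first_drug", db)
        base = np.mean(stub(records))
        for i, dai in enumerate(da):
            for j, dbj in enumerate(db):
                r = adjust_records(records, AdjustmentSpec("contact_to_arrival", dai))
                r = adjust_records(r, AdjustmentSpec("contact_to_first_drug", dbj))
                want = 100.0 * (np.mean(stub(r)) - base) / base
                if (dai, dbj) == (0.0, 0.0):
                    assert g.values[i, j] == 0.0
                    assert abs(want) < 1e-12
                else:
                    assert g.values[i, j] == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_ineligible_predictions_bit_identical(self, small_cohort):
        stub = logistic_stub(EffectModel())
        spec = AdjustmentSpec("contact_to_first_defib", 3.0)
        adj = adjust_records(small_cohort, spec)
        inelig = ~eligibility_mask(small_cohort, spec)
        p0 = np.asarray(stub(small_cohort))[inelig]
        p1 = np.asarray(stub(adj))[inelig]
        np.testing.assert_array_equal(p0, p1)

    def test_same_factor_axes_rejected(self, small_cohort):
        with pytest.raises(AdjustmentError, match="different factors"):
            two_factor_grid(logistic_stub(EffectModel()), small_cohort,
                            "contact_to_arrival", [0.0], "contact_to_arrival", [0.0])

    def test_train_coverage_reported(self, included_cohort):
        g = two_factor_grid(
            logistic_stub(EffectModel()), included_cohort.head(300),
            "contact_to_arrival", [-10.0, 0.0, 10.0],
            "contact_to_first_drug", [-5.0, 0.0, 5.0],
            train_records=included_cohort.tail(1500),
        )
        assert len(g.train_coverage_a) == 3
        assert len(g.train_coverage_b) == 3
        assert all(0.0 <= c <= 1.0 for c in g.train_coverage_a)

    def test_grid_csv_round_trip(self, included_cohort, tmp_path):
        g = two_factor_grid(logistic_stub(EffectModel()), included_cohort.head(200),
                            "contact_to_arrival", [-2.0, 0.0, 2.0],
                            "contact_to_first_drug", [-1.0, 0.0, 1.0])
        path = tmp_path / "grid.csv"
        g.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.to_numpy(), g.values)


class TestInteractionResidual:
    def test_logit_residual_recovers_gamma_exactly_on_truth(self, included_cohort):
        # under the generative model the mean logit DiD equals gamma*dT*dD
        gamma = -0.01
        eff = EffectModel(transport_x_drug=gamma)
        # avoid clamping: only records with enough headroom
        ok = included_cohort[
            (included_cohort["adrenaline_time_min"].fillna(0) > 5)
            & (included_cohort["contact_to_arrival_min"] > 10)
        ]
        r = interaction_logit_residual(
            logistic_stub(eff), ok, "contact_to_arrival", 10.0,
            "contact_to_first_drug", 5.0,
        )
        assert r == pytest.approx(gamma * 10.0 * 5.0, rel=1e-9)

    def test_no_interaction_gives_zero_residual(self, included_cohort):
        eff = EffectModel(transport_x_defib=0.0, transport_x_drug=0.0)
        r = interaction_logit_residual(
            logistic_stub(eff), included_cohort, "contact_to_arrival", 10.0,
            "contact_to_first_drug", 5.0,
        )
        assert abs(r) < 1e-9
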