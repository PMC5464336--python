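"""ODE engine: construction, conservation, linearity, excretion routing,
and the summary metrics."""

import numpy as np
import pytest

import teapbpk as tp
from teapbpk.engine import STATE_NAMES
from teapbpk.errors import ConsistencyError, DomainError


class TestBuildModel:
    def test_state_layout(self, human_egcg_model):
        assert len(STATE_NAMES) == 20
        assert STATE_NAMES[:3] == ("lung", "arterial", "venous")

    def test_mismatched_species_tags_rejected(self):
        phys = tp.load_species_physiology("rat", 0.26)
        chem = tp.load_catechin_physchem("EGCg")
        pk = tp.load_pk_params("EGCg", "human")  # wrong species
        parts = tp.load_partition_set("EGCg", "rat")
        with pytest.raises(ConsistencyError):
            tp.build_model(phys, chem, pk, parts)

    def test_mismatched_catechin_tags_rejected(self):
        phys = tp.load_species_physiology("rat", 0.26)
        chem = tp.load_catechin_physchem("EC")
        pk = tp.load_pk_params("EGCg", "rat")
        parts = tp.load_partition_set("EGCg", "rat")
        with pytest.raises(ConsistencyError):
            tp.build_model(phys, chem, pk, parts)

    def test_zero_clearance_variant_is_valid(self):
        model = tp.load_model(
            "EGCg", "human", 70, pk_overrides={"CL_bc": 0.0, "CL_rc": 0.0}
        )
        assert model.scaled.CL_b == 0.0


class TestSimulate:
    def test_zero_dose_is_identically_zero(self, human_egcg_model):
        res = tp.simulate(human_egcg_model, tp.DoseEvent("EGCg", 0.0), 10.0)
        assert np.all(res.amounts == 0.0)

    def test_plasma_zero_before_lag(self, human_egcg_result, human_egcg_model):
        tlag = human_egcg_model.scaled.tlag
        before = human_egcg_result.times < tlag - 1e-12
        assert np.all(human_egcg_result.plasma[before] == 0.0)
        after = human_egcg_result.times > tlag + 0.5
        assert np.all(human_egcg_result.plasma[after] > 0.0)

    def test_mass_balance(self, human_egcg_result, human_egcg_dose):
        assert tp.mass_balance(human_egcg_result, human_egcg_dose) < 1e-6

    def test_dose_proportionality(self, human_egcg_model):
        """First-order kinetics: doubling the dose doubles every
        concentration at every output time."""
        lo = tp.simulate(human_egcg_model, tp.DoseEvent("EGCg", 1.0), 24.0)
        hi = tp.simulate(human_egcg_model, tp.DoseEvent("EGCg", 2.0), 24.0)
        mask = lo.plasma > 0
        np.testing.assert_allclose(
            hi.plasma[mask] / lo.plasma[mask], 2.0, rtol=1e-6
        )

    def test_everything_eventually_excreted(self, human_egcg_model):
        res = tp.simulate(human_egcg_model, tp.DoseEvent("EGCg", 5.0), 600.0,
                          output_step=1.0)
        recovered = (res.urine[-1] + res.feces[-1]) / res.dose_ug
        assert recovered == pytest.approx(1.0, abs=1e-4)

    def test_dose_catechin_mismatch(self, human_egcg_model):
        with pytest.raises(ConsistencyError):
            tp.simulate(human_egcg_model, tp.DoseEvent("EC", 1.0), 10.0)

    def test_negative_t_end_rejected(self, human_egcg_model):
        with pytest.raises(DomainError):
            tp.simulate(human_egcg_model, tp.DoseEvent("EGCg", 1.0), -1.0)

    def test_plasma_is_venous_blood_over_blplr(self, human_egcg_result):
        blplr = human_egcg_result.model.physchem.BLPLR
        np.testing.assert_allclose(
            human_egcg_result.plasma,
            human_egcg_result.concentration("venous") / blplr,
        )
        assert tp.plasma_series(human_egcg_result) is human_egcg_result.plasma \
            or np.allclose(tp.plasma_series(human_egcg_result),
                           human_egcg_result.plasma)


class TestClosedFormOracles:
    def test_no_elimination_reaches_well_mixed_equilibrium(self):
        """With all clearances and fecal loss off, the absorbed dose
        equilibrates: every venous outflow concentration equals the
        arterial concentration, whose value follows from the
        partition-weighted total volume."""
        model = tp.load_model(
            "EGCg", "human", 70,
            pk_overrides={"CL_bc": 0.0, "CL_rc": 0.0, "k_rac": 0.0,
                          "k_fc": 0.0, "F": 1.0},
        )
        res = tp.simulate(model, tp.DoseEvent("EGCg", 1.0), 400.0, output_step=2.0)
        phys, P = model.physiology, model.partitions
        tissues = ["liver", "gut", "spleen", "kidney", "muscle", "skin",
                   "adipose", "bone", "brain", "heart", "rest_of_body", "lung"]
        v_eff = phys.volume("blood") + sum(
            phys.volume(t) * P[t] for t in tissues
        )
        c_art_expected = res.dose_ug / v_eff / 1000.0  # ug/mL
        c_art = res.concentration("arterial")[-1]
        assert c_art == pytest.approx(c_art_expected, rel=1e-4)
        # flow consistency: lung outflow CO*C_lung/P equals CO*C_arterial
        c_lung_out = res.concentration("lung")[-1] / P["lung"]
        assert c_lung_out == pytest.approx(c_art, rel=1e-4)
        c_ven = res.concentration("venous")[-1]
        assert c_ven == pytest.approx(c_art, rel=1e-4)

    def test_urine_feces_split_matches_auc_balance_oracle(self):
        """With reabsorption off the enterohepatic loop collapses to
        simple biliary elimination; the terminal urine amount then follows
        in closed form from steady-state AUC balances of the kidney, the
        splanchnic bed and total elimination."""
        model = tp.load_model(
            "EGCg", "human", 70,
            pk_overrides={"k_rac": 0.0, "R_t": 0.0, "CL_rc": 0.5},
        )
        dose = tp.DoseEvent("EGCg", 2.0)
        res = tp.simulate(model, dose, 500.0, output_step=1.0)

        phys = model.physiology
        s = model.scaled
        blplr = model.physchem.BLPLR
        FD = s.F * res.dose_ug
        q_h, q_kd = phys.flow("liver"), phys.flow("kidney")
        cb, cr = s.CL_b / blplr, s.CL_r / blplr
        # unknown arterial AUC A solves total elimination = absorbed dose:
        #   cb * (q_h A + FD)/(q_h + cb) + cr * q_kd A/(q_kd + cr) = FD
        lhs_coeff = cb * q_h / (q_h + cb) + cr * q_kd / (q_kd + cr)
        rhs = FD - cb * FD / (q_h + cb)
        A = rhs / lhs_coeff
        urine_expected = cr * q_kd * A / (q_kd + cr)
        assert res.urine[-1] == pytest.approx(urine_expected, rel=1e-3)
        feces_expected = res.dose_ug - urine_expected
        assert res.feces[-1] == pytest.approx(feces_expected, rel=1e-3)


class TestMetrics:
    def test_cmax_monotone_decreasing_series(self):
        assert tp.cmax([0, 1, 2], [3.0, 2.0, 1.0]) == (3.0, 0.0)

    def test_cmax_interior_peak(self):
        assert tp.cmax([0, 1, 2], [0.0, 2.0, 1.0]) == (2.0, 1.0)

    def test_cmax_empty_series(self):
        with pytest.raises(DomainError):
            tp.cmax([], [])

    def test_auc_constant(self):
        assert tp.auc([0.0, 2.0, 5.0], [3.0, 3.0, 3.0]) == pytest.approx(15.0)

    def test_auc_two_points(self):
        assert tp.auc([0.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_auc_linear_decay_triangle(self):
        assert tp.auc([0.0, 4.0], [2.0, 0.0]) == pytest.approx(4.0)

    def test_auc_unsorted_times(self):
        with pytest.raises(DomainError):
            tp.auc([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])

    def test_mass_balance_zero_dose(self, human_egcg_model):
        res = tp.simulate(human_egcg_model, tp.DoseEvent("EGCg", 0.0), 5.0)
        assert tp.mass_balance(res, tp.DoseEvent("EGCg", 0.0)) == 0.0

    def test_mass_balance_detects_missing_pool(
        self, human_egcg_result, human_egcg_dose
    ):
        import copy

        broken = copy.deepcopy(human_egcg_result)
        i_urine = STATE_NAMES.index("urine")
        renal_fraction = broken.amounts[i_urine, -1] / broken.dose_ug
        broken.amounts[i_urine, :] = 0.0
        assert tp.mass_balance(broken, human_egcg_dose) == pytest.approx(
            renal_fraction, rel=1e-6
        )

    def test_result_frame_columns(self, human_egcg_result):
        df = human_egcg_result.to_frame()
        assert list(df.columns[:2]) == ["time_h", "lung"]
        assert {"plasma", "urine_cum", "feces_cum"} <= set(df.columns)
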