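"""Isotope conversions and rate equations against hand-computed values."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phyllon import errors
from phyllon.constants import DEFAULT_CONSTANTS, IsotopeConstants
from phyllon.tracer import (
    BaselineStats,
    IncubationRecord,
    atom_percent_excess,
    atom_percent_to_delta,
    cn_ratio,
    delta15n_mass_balance,
    delta_to_atom_percent,
    medium_enrichment,
    mix_delta,
    n2_fixation_rate,
    n2_production_rate,
    no3_from_nox,
    nutrient_flux,
    pnr,
    significance_gate,
)


def make_baseline(mean=0.3663, sd=0.0002, n=3, kind="natural_abundance"):
    return BaselineStats(mean_atom_pct=mean, sd_atom_pct=sd, n=n, kind=kind)


class TestDeltaAtomConversion:
    @pytest.mark.parametrize("delta, expected", [
        (0.0, 0.36630),        # air
        (-1000.0, 0.0),        # zero-15N limit
        (180.0, 0.43195),      # USGS32 nitrate standard
    ])
    def test_reference_points(self, delta, expected):
        assert delta_to_atom_percent(delta) == pytest.approx(expected, abs=5e-6)

    def test_rejects_impossible_delta(self):
        with pytest.raises(errors.InvalidDeltaError):
            delta_to_atom_percent(-1000.1)

    @given(st.floats(min_value=-900, max_value=1e6))
    def test_round_trip_identity(self, delta):
        back = atom_percent_to_delta(delta_to_atom_percent(delta))
        assert back == pytest.approx(delta, abs=1e-10, rel=1e-10)

    @given(st.floats(min_value=-999, max_value=1e5), st.floats(min_value=1e-3, max_value=100))
    def test_strictly_increasing(self, delta, step):
        assert delta_to_atom_percent(delta + step) > delta_to_atom_percent(delta)

    def test_nondefault_reference_ratio(self):
        c = IsotopeConstants(r_air_15n=0.004)
        assert delta_to_atom_percent(0.0, c) == pytest.approx(100 * 0.004 / 1.004)


class TestExcessAndGate:
    @pytest.mark.parametrize("sample, mean, expected", [
        (0.80, 0.37, 0.43), (0.37, 0.37, 0.0), (0.30, 0.37, -0.07),
    ])
    def test_excess_is_plain_subtraction(self, sample, mean, expected):
        baseline = make_baseline(mean=mean, sd=0.01)
        assert atom_percent_excess(sample, baseline) == pytest.approx(expected)

    @pytest.mark.parametrize("excess, sd, expected", [
        (0.010, 0.003, True),   # 0.010 > 2.5 * 0.003
        (0.007, 0.003, False),
        (0.001, 0.0, True),     # degenerate zero-SD baseline passes any positive excess
    ])
    def test_gate_threshold(self, excess, sd, expected):
        assert significance_gate(excess, make_baseline(sd=sd)) is expected

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_gate_monotone_in_excess(self, e_small, bump):
        baseline = make_baseline(sd=0.01)
        if significance_gate(e_small, baseline):
            assert significance_gate(e_small + bump, baseline)

    def test_gate_requires_positive_k(self):
        with pytest.raises(ValueError):
            significance_gate(0.5, make_baseline(), k=0)


class TestN2Fixation:
    def record(self, **kw):
        base = dict(site="vent", light="light", epiphytes="present", tracer="15N2",
                    timepoint_h=10.0, replicate_id="r1", atom_pct_15n_tissue=1.9663,
                    pn_tissue_ug=DEFAULT_CONSTANTS.molar_mass_n,  # = 1000 nmol N
                    leaf_area_cm2=10.0)
        base.update(kw)
        return IncubationRecord(**base)

    def test_hand_computed_rate(self):
        # excess 1.6 of 16 atom% medium, 1000 nmol N over 10 h on 10 cm2 -> 1.0
        baseline = make_baseline(mean=0.3663, sd=0.0)
        est = n2_fixation_rate(self.record(), baseline, medium_atom_pct=16.0)
        assert est.value == pytest.approx(1.0, rel=1e-9)
        assert est.units == "nmol N cm-2 h-1"
        assert est.significant

    def test_zero_excess_is_zero_and_not_significant(self):
        baseline = make_baseline(mean=0.3663, sd=0.01)
        est = n2_fixation_rate(self.record(atom_pct_15n_tissue=0.3663), baseline, 16.0)
        assert est.value == 0.0
        assert not est.significant
        assert est.gated_value == 0.0

    def test_linear_in_excess(self):
        baseline = make_baseline(sd=0.0)
        r1 = n2_fixation_rate(self.record(atom_pct_15n_tissue=0.3663 + 0.4), baseline, 16.0)
        r2 = n2_fixation_rate(self.record(atom_pct_15n_tissue=0.3663 + 0.8), baseline, 16.0)
        assert r2.value == pytest.approx(2 * r1.value, rel=1e-12)

    def test_missing_tissue_fields_rejected(self):
        with pytest.raises(errors.IncompleteRecordError):
            n2_fixation_rate(self.record(pn_tissue_ug=None), make_baseline(), 16.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(errors.ZeroDurationError):
            n2_fixation_rate(self.record(timepoint_h=0.0), make_baseline(), 16.0)

    def test_wrong_tracer_rejected(self):
        with pytest.raises(errors.IncompleteRecordError):
            n2_fixation_rate(self.record(tracer="15NH4"), make_baseline(), 16.0)


class TestMediumEnrichment:
    def test_study_mixing(self):
        # 0.65 uM ambient NH4 at natural abundance + 19.35 uM spike at 98 atom%
        got = medium_enrichment(0.65, 0.3663, 19.35, 98.0)
        assert got == pytest.approx(94.83, abs=0.005)

    def test_degenerate_pools(self):
        assert medium_enrichment(1.0, 0.4, 0.0, 98.0) == pytest.approx(0.4)
        assert medium_enrichment(0.0, 0.4, 2.0, 98.0) == pytest.approx(98.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(errors.EmptyPoolError):
            medium_enrichment(0.0, 0.4, 0.0, 98.0)


class TestPnr:
    def record(self, delta, **kw):
        base = dict(site="vent", light="light", epiphytes="present", tracer="15NH4",
                    timepoint_h=5.0, replicate_id="r1", delta15n_no3_permil=delta,
                    leaf_area_cm2=6.0, vial_volume_mL=24.0)
        base.update(kw)
        return IncubationRecord(**base)

    def test_hand_computed_rate(self):
        # excess 0.959 of 95.9 atom%: 1% of a 240 nmol pool over 5 h on 6 cm2
        baseline = make_baseline(mean=0.3663, sd=0.0, kind="t0")
        atom_t = 0.3663 + 0.959
        est = pnr(self.record(atom_percent_to_delta(atom_t)), baseline, 95.9, no3_uM=10.0)
        assert est.value == pytest.approx(80.0, rel=1e-6)
        assert est.units == "pmol N cm-2 h-1"

    def test_zero_excess(self):
        baseline = make_baseline(mean=0.3663, sd=0.001, kind="t0")
        est = pnr(self.record(atom_percent_to_delta(0.3663)), baseline, 95.9, no3_uM=10.0)
        assert est.value == pytest.approx(0.0, abs=1e-9)
        assert not est.significant

    def test_control_subtraction_cancels_equal_rates(self):
        baseline = make_baseline(mean=0.3663, sd=0.0, kind="t0")
        atom_t = 0.3663 + 0.959
        raw = pnr(self.record(atom_percent_to_delta(atom_t)), baseline, 95.9, no3_uM=10.0)
        ctrl_rate_nmol_h = raw.value / 1000.0 * 6.0
        est = pnr(self.record(atom_percent_to_delta(atom_t)), baseline, 95.9, no3_uM=10.0,
                  control_rate_nmol_h=ctrl_rate_nmol_h,
                  control_excess_atom_pct=raw.excess_atom_pct)
        assert est.value == pytest.approx(0.0, abs=1e-9)
        assert est.control_corrected
        assert not est.significant

    def test_missing_delta_rejected(self):
        with pytest.raises(errors.IncompleteRecordError):
            pnr(self.record(None), make_baseline(kind="t0"), 95.9, no3_uM=10.0)


class TestN2Production:
    def test_hand_computed_rate(self):
        # 0.9 nM over 3 h in 24 mL on 6 cm2 -> 1.2 pmol N2 = 2.4 pmol N
        est = n2_production_rate(1.0, 1.9, 2.0, 5.0, 24.0, 6.0)
        assert est.value == pytest.approx(2.4, rel=1e-9)
        molec = n2_production_rate(1.0, 1.9, 2.0, 5.0, 24.0, 6.0, n2_as_molecules=True)
        assert molec.value == pytest.approx(1.2, rel=1e-9)

    def test_flat_concentration_gives_zero(self):
        assert n2_production_rate(1.0, 1.0, 2.0, 5.0, 24.0, 6.0).value == 0.0

    def test_control_slope_cancels(self):
        slope = 0.9 * 0.024 / 3.0
        est = n2_production_rate(1.0, 1.9, 2.0, 5.0, 24.0, 6.0, control_slope_nmol_h=slope)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(errors.InvalidWindowError):
            n2_production_rate(1.0, 1.9, 5.0, 5.0, 24.0, 6.0)


class TestNutrientFlux:
    def test_hand_computed_uptake(self):
        # 2 uM drawdown in 24 mL over 9 h on 6 cm2 -> 0.889 nmol cm-2 h-1 uptake
        est = nutrient_flux(20.0, 18.0, 0.0, 9.0, 24.0, 6.0)
        assert est.value == pytest.approx(0.8889, abs=5e-4)
        assert est.raw_signed_flux == pytest.approx(-est.value)

    def test_no_change_gives_zero(self):
        assert nutrient_flux(20.0, 20.0, 0.0, 9.0, 24.0, 6.0).value == 0.0

    def test_control_change_cancels(self):
        est = nutrient_flux(20.0, 18.0, -2.0, 9.0, 24.0, 6.0)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_release_is_negative_uptake(self):
        est = nutrient_flux(18.0, 20.0, 0.0, 9.0, 24.0, 6.0)
        assert est.value < 0
        assert est.raw_signed_flux > 0

    def test_zero_duration_rejected(self):
        with pytest.raises(errors.ZeroDurationError):
            nutrient_flux(20.0, 18.0, 0.0, 0.0, 24.0, 6.0)


class TestSpeciationAndRatios:
    @pytest.mark.parametrize("nox, no2, expected", [(10.0, 0.5, 9.5), (3.0, 3.0, 0.0)])
    def test_no3_by_difference(self, nox, no2, expected):
        assert no3_from_nox(nox, no2) == pytest.approx(expected)

    def test_impossible_speciation_rejected(self):
        with pytest.raises(errors.NegativeNitrateError):
            no3_from_nox(1.0, 2.0)

    @pytest.mark.parametrize("c, n, expected", [
        (36.0, 3.0, 14.0), (0.0, 3.0, 0.0), (12.0, 14.0, 1.0), (24.0, 14.0, 2.0),
    ])
    def test_molar_cn(self, c, n, expected):
        assert cn_ratio(c, n) == pytest.approx(expected, rel=1e-9)

    def test_cn_undefined_without_nitrogen(self):
        with pytest.raises(errors.UndefinedRatioError):
            cn_ratio(36.0, 0.0)


class TestMassBalance:
    def test_equal_split_symmetry(self):
        assert delta15n_mass_balance(90.0, 1.0, 1.0, 180.0) == pytest.approx(0.0)

    def test_forward_then_invert(self):
        mixed = mix_delta(5.0, 1.0, 1.0, 180.0)
        assert mixed == pytest.approx(92.5)
        assert delta15n_mass_balance(mixed, 1.0, 1.0, 180.0) == pytest.approx(5.0)

    def test_no_standard_is_identity(self):
        assert delta15n_mass_balance(42.0, 1.0, 0.0) == pytest.approx(42.0)

    @given(st.floats(min_value=-50, max_value=100),
           st.floats(min_value=0.05, max_value=20),
           st.floats(min_value=0.0, max_value=20))
    def test_round_trip_any_split(self, delta_sample, cs, cstd):
        mixed = mix_delta(delta_sample, cs, cstd)
        back = delta15n_mass_balance(mixed, cs, cstd)
        assert back == pytest.approx(delta_sample, abs=1e-9, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            delta15n_mass_balance(90.0, 0.0, 1.0)


class TestRecordValidation:
    def test_speciation_checked_at_construction(self):
        with pytest.raises(errors.NegativeNitrateError):
            IncubationRecord(site="vent", light="light", epiphytes="present",
                             tracer="15NH4", timepoint_h=1.0, replicate_id="r1",
                             nox_uM=1.0, no2_uM=2.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            IncubationRecord(site="vent", light="light", epiphytes="present",
                             tracer="15N2", timepoint_h=1.0, replicate_id="r1",
                             nh4_uM=-0.1)
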