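"""Isotope mixing, fractionation and pathway-partition algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crustgas.errors import (
    DegenerateEndMemberError,
    InvalidInputError,
    NoNetProductionError,
)
from crustgas.isotopes import (
    acetate_endmember,
    alpha_to_epsilon,
    apparent_fractionation,
    co2_source_fraction,
    epsilon_to_alpha,
    fraction_new,
    newly_formed_delta,
    newly_formed_series,
    partition_pathways,
    partition_with_uncertainty,
)
from crustgas.synthetic import GeneratorConfig, gen_isotope_series

deltas = st.floats(-150.0, 50.0)


class TestNewlyFormedMethane:
    @pytest.mark.parametrize(
        "a1,a2,expected", [(0.0, 100.0, 1.0), (100.0, 400.0, 0.75), (50.0, 100.0, 0.5)]
    )
    def test_fraction_new(self, a1, a2, expected):
        assert fraction_new(a1, a2) == pytest.approx(expected)

    def test_no_net_production_errors(self):
        with pytest.raises(NoNetProductionError):
            fraction_new(100.0, 100.0)
        with pytest.raises(NoNetProductionError):
            fraction_new(100.0, 50.0)

    @pytest.mark.parametrize(
        "d1,d2,fn,expected",
        [(-60.0, -50.0, 0.5, -40.0), (-30.0, -42.0, 1.0, -42.0), (-70.0, -40.0, 0.75, -30.0)],
    )
    def test_newly_formed_delta(self, d1, d2, fn, expected):
        assert newly_formed_delta(d1, d2, fn) == pytest.approx(expected)

    def test_invalid_fraction_errors(self):
        for fn in (0.0, -0.1, 1.5):
            with pytest.raises(InvalidInputError):
                newly_formed_delta(-60.0, -50.0, fn)

    @given(d1=deltas, d2=deltas, fn=st.floats(1e-6, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_identity(self, d1, d2, fn):
        dn = newly_formed_delta(d1, d2, fn)
        assert fn * dn + (1.0 - fn) * d1 == pytest.approx(d2, abs=1e-9)


class TestFractionation:
    def test_no_fractionation(self):
        res = apparent_fractionation(-20.0, -20.0)
        assert res.alpha_app == pytest.approx(1.0)
        assert res.epsilon_app == pytest.approx(0.0)

    def test_anoxic_treatment_means(self):
        # midpoint CO2 -11.5 permil over CH4 -35 permil
        res = apparent_fractionation(-11.5, -35.0)
        assert res.alpha_app == pytest.approx(988.5 / 965.0, rel=1e-12)
        assert res.alpha_app == pytest.approx(1.0244, abs=5e-5)

    def test_alpha_epsilon_definitions(self):
        assert alpha_to_epsilon(1.0) == pytest.approx(0.0)
        assert alpha_to_epsilon(1.066) == pytest.approx(66.0)
        assert epsilon_to_alpha(25.0) == pytest.approx(1.025)

    def test_round_trip_on_grid(self):
        for alpha in np.linspace(0.9, 1.2, 31):
            assert epsilon_to_alpha(alpha_to_epsilon(alpha)) == pytest.approx(alpha, rel=1e-15)

    def test_delta_floor_guard(self):
        with pytest.raises(InvalidInputError):
            apparent_fractionation(-20.0, -1000.0)


class TestPartition:
    def test_anoxic_means_zero_fractionation_scenario(self):
        part = partition_pathways(-35.0, -20.5, -75.0)
        assert part.f_hydrogenotrophic == pytest.approx(14.5 / 54.5, rel=1e-12)
        assert part.f_acetoclastic == pytest.approx(0.7339, abs=1e-4)
        assert not part.clamped

    def test_shifted_acetate_scenario_clamps_to_pure_acetoclastic(self):
        d_ma = acetate_endmember(-20.5, -25.6)
        assert d_ma == pytest.approx(-46.1)
        part = partition_pathways(-35.0, d_ma, -75.0)
        assert part.clamped
        assert part.raw_fraction < 0
        assert part.f_acetoclastic == 1.0

    def test_end_member_identity(self):
        part = partition_pathways(-75.0, -20.5, -75.0)
        assert part.f_hydrogenotrophic == pytest.approx(1.0)
        assert part.f_acetoclastic == pytest.approx(0.0)

    def test_degenerate_end_members(self):
        with pytest.raises(DegenerateEndMemberError):
            partition_pathways(-35.0, -50.0, -50.0)

    @given(d=deltas, ma=deltas, mc=deltas)
    @settings(max_examples=200, deadline=None)
    def test_closure_and_bounds(self, d, ma, mc):
        if ma == mc:
            return
        part = partition_pathways(d, ma, mc)
        assert part.f_hydrogenotrophic + part.f_acetoclastic == pytest.approx(1.0)
        assert 0.0 <= part.f_hydrogenotrophic <= 1.0

    @given(ma=deltas, mc=deltas, step=st.floats(0.1, 5.0), d=deltas)
    @settings(max_examples=200, deadline=None)
    def test_moving_toward_hydrogenotrophic_end_member_raises_its_fraction(
        self, ma, mc, step, d
    ):
        if abs(ma - mc) < 1.0:
            return
        # move delta_CH4 toward delta_mc without overshooting it
        toward = d + np.sign(mc - d) * min(step, abs(mc - d))
        f0 = partition_pathways(d, ma, mc).f_hydrogenotrophic
        f1 = partition_pathways(toward, ma, mc).f_hydrogenotrophic
        assert f1 >= f0 - 1e-12


class TestCo2SourceAndUncertainty:
    @pytest.mark.parametrize(
        "d_co2,expected", [(-20.5, 0.0), (-4.09, 1.0), (-11.5, 9.0 / 16.41)]
    )
    def test_carbonate_fraction(self, d_co2, expected):
        frac, clamped = co2_source_fraction(d_co2, -20.5, -4.09)
        assert frac == pytest.approx(expected, rel=1e-6)
        assert not clamped

    def test_degenerate_co2_end_members(self):
        with pytest.raises(DegenerateEndMemberError):
            co2_source_fraction(-10.0, -20.5, -20.5)

    def test_zero_ses_give_zero(self):
        part = partition_with_uncertainty(-35.0, -20.5, -75.0)
        assert part.se_f_hydrogenotrophic == pytest.approx(0.0)

    def test_single_se_closed_form(self):
        part = partition_with_uncertainty(-35.0, -20.5, -75.0, se_ch4=2.0)
        assert part.se_f_hydrogenotrophic == pytest.approx(2.0 / 54.5, rel=1e-12)
        assert part.se_f_hydrogenotrophic == pytest.approx(0.0367, abs=1e-4)


class TestEndToEndRecovery:
    def test_noiseless_series_recovers_pathway_mix(self, noiseless_config):
        """Generator truth -> newly-formed deltas -> partition, within 0.01."""
        tracks, truth = gen_isotope_series(noiseless_config)
        for trt, reps in tracks.items():
            for points in reps:
                news = newly_formed_series(points)
                assert news, trt
                mean_new = np.mean([n.delta_new for n in news])
                part = partition_pathways(mean_new, truth["delta_ma"], truth["delta_mc"])
                assert part.f_hydrogenotrophic == pytest.approx(
                    truth["pathway_mix"][trt], abs=0.01
                )

    def test_pure_hydrogenotrophic_series_sits_on_end_member(self, noiseless_config):
        tracks, truth = gen_isotope_series(noiseless_config)
        for points in tracks["FLO"]:  # purely hydrogenotrophic preset
            for p in points:
                assert p.delta_ch4 == pytest.approx(truth["delta_mc"], abs=1e-9)
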