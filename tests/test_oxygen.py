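"""Forward diffusion-reaction model and production-zone inversion."""

import numpy as np
import pytest

from crustgas.errors import InvalidInputError
from crustgas.oxygen import (
    AIR_SATURATION_UMOL_L,
    DEFAULT_DIFFUSIVITY_M2_S,
    DEFAULT_POROSITY,
    OxygenProfile,
    anoxic_boundary,
    fit_production_zones,
    forward_profile,
    solve_profile,
    surface_flux,
)


def finite_difference_profile(edges_um, rates, top, depths_um, porosity, diffusivity):
    """Independent second-order finite-difference oracle on a dense grid.

    Solves beta*C'' = -P with C(0)=top and a ghost-point zero-flux bottom.
    """
    beta = porosity * diffusivity * 1e4  # cm2/s
    z = np.asarray(depths_um, float) / 1e4
    n = z.size
    h = z[1] - z[0]
    assert np.allclose(np.diff(z), h)
    edges_cm = np.asarray(edges_um, float) / 1e4

    def q(zz):  # cumulative integral of P from the surface
        zz = np.clip(zz, edges_cm[0], edges_cm[-1])
        widths = np.clip(zz[:, None], edges_cm[:-1], edges_cm[1:]) - edges_cm[:-1]
        return widths @ np.asarray(rates, float)

    # cell-averaged P keeps the scheme second-order across zone boundaries
    lo, hi = np.clip(z - h / 2, edges_cm[0], None), np.clip(z + h / 2, None, edges_cm[-1])
    p = (q(hi) - q(lo)) / (hi - lo)
    a = np.zeros((n, n))
    b = np.zeros(n)
    a[0, 0] = 1.0
    b[0] = top
    for i in range(1, n - 1):
        a[i, i - 1], a[i, i], a[i, i + 1] = 1.0, -2.0, 1.0
        b[i] = -p[i] * h**2 / beta
    a[n - 1, n - 2], a[n - 1, n - 1] = 2.0, -2.0  # ghost point C_{n} = C_{n-2}
    b[n - 1] = -p[n - 1] * h**2 / beta
    return np.linalg.solve(a, b)


def _profile(depths, concs, **kw):
    return OxygenProfile(depths=np.asarray(depths, float), concentrations=np.asarray(concs, float), **kw)


class TestForwardModel:
    def test_zero_rates_give_flat_profile(self):
        grid = np.linspace(0, 3000, 31)
        conc = forward_profile([0, 3000], [0.0], 250.0, depth_grid_um=grid)
        assert conc == pytest.approx(np.full(31, 250.0))
        sol = solve_profile([0, 3000], [0.0], 250.0)
        assert surface_flux(sol) == pytest.approx(0.0)

    def test_single_zone_mass_conservation(self):
        # consumption rate R over total depth L balances the surface influx
        sol = solve_profile([0, 2500], [-0.0576], 250.0)
        assert surface_flux(sol) == pytest.approx(0.0576 * 0.25, rel=1e-12)

    def test_conservation_over_random_zone_sets(self, rng):
        for _ in range(30):
            k = rng.integers(1, 4)
            interior = np.sort(rng.uniform(100, 2900, size=k - 1))
            edges = np.concatenate([[0.0], interior, [3000.0]])
            rates = rng.uniform(-1.0, 1.0, size=k)
            sol = solve_profile(edges, rates, 250.0)
            integral = np.sum(rates * np.diff(edges) / 1e4)
            assert surface_flux(sol) == pytest.approx(-integral, rel=1e-8, abs=1e-14)

    def test_two_zone_interior_maximum_matches_finite_difference(self):
        edges = [0.0, 1000.0, 3000.0]
        rates = [0.4, -0.1]  # net production: efflux at the surface, interior maximum
        grid = np.linspace(0, 3000, 301)
        analytic = forward_profile(edges, rates, 200.0, depth_grid_um=grid)
        oracle = finite_difference_profile(
            edges, rates, 200.0, grid, DEFAULT_POROSITY, DEFAULT_DIFFUSIVITY_M2_S
        )
        assert np.argmax(analytic) not in (0, len(grid) - 1)  # interior maximum
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(analytic - oracle)) / scale < 1e-3

    def test_fixed_bottom_condition(self):
        sol = solve_profile([0, 2000], [-0.1], 250.0, bottom="fixed", bottom_concentration=100.0)
        assert sol.concentration([2000.0])[0] == pytest.approx(100.0, rel=1e-10)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidInputError):
            solve_profile([0, 1000, 500], [0.1, 0.1], 250.0)
        with pytest.raises(InvalidInputError):
            solve_profile([0, 1000], [0.1, 0.2], 250.0)


class TestInversion:
    def _noiseless(self, edges, rates, top=250.0, step=100.0, offset=True):
        depths = np.arange(edges[0], edges[-1] + 0.5, step)
        conc = forward_profile(edges, rates, top, depth_grid_um=depths)
        if offset and conc.min() < 0:
            conc = conc - conc.min()
        return _profile(depths, np.maximum(conc, 0.0))

    def test_single_zone_self_consistency(self):
        prof = self._noiseless([0.0, 2500.0], [-0.0576])
        fit = fit_production_zones(prof, max_zones=3)
        assert fit.n_zones == 1
        assert fit.zone_rates[0] == pytest.approx(-0.0576, rel=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_two_zone_round_trip(self):
        edges = [0.0, 1000.0, 2500.0]
        rates = [-0.03, -0.01]
        prof = self._noiseless(edges, rates)
        fit = fit_production_zones(prof, max_zones=3)
        assert fit.n_zones == 2
        assert fit.zone_boundaries == pytest.approx(edges)
        assert fit.zone_rates == pytest.approx(rates, rel=1e-2)
        truth_flux = -(rates[0] * 0.1 + rates[1] * 0.15)
        assert fit.surface_flux == pytest.approx(truth_flux, rel=1e-3)

    def test_three_zone_round_trip_tight(self):
        edges = [0.0, 500.0, 1500.0, 3000.0]
        rates = [0.746667, -0.273333, -0.05]
        prof = self._noiseless(edges, rates)
        fit = fit_production_zones(prof, max_zones=3)
        assert fit.n_zones == 3
        assert fit.zone_rates == pytest.approx(rates, rel=1e-3)

    def test_noisy_recovery_of_surface_flux(self, rng):
        """Triplicate profiles at 1% noise recover the flux within 5%."""
        edges = [0.0, 1000.0, 2500.0]
        rates = [-0.03, -0.01]
        depths = np.arange(0.0, 2501.0, 100.0)
        clean = forward_profile(edges, rates, 250.0, depth_grid_um=depths)
        fluxes = []
        for _ in range(3):
            noisy = clean + rng.normal(0.0, 0.01 * 250.0, size=clean.size)
            prof = _profile(depths, np.maximum(noisy, 0.0))
            fluxes.append(fit_production_zones(prof, max_zones=3).surface_flux)
        truth_flux = -(rates[0] * 0.1 + rates[1] * 0.15)
        assert np.mean(fluxes) == pytest.approx(truth_flux, rel=0.05)

    def test_sse_non_increasing_in_zone_count(self, rng):
        from crustgas.oxygen import _best_edges_for_k

        depths = np.arange(0.0, 2501.0, 100.0)
        clean = forward_profile([0, 800, 2500], [-0.04, -0.01], 250.0, depth_grid_um=depths)
        noisy = np.maximum(clean + rng.normal(0, 2.0, clean.size), 0.0)
        prof = _profile(depths, noisy)
        sses = []
        prev = None
        for k in (1, 2, 3):
            edges, _, _, sse = _best_edges_for_k(prof, k, prev)
            sses.append(sse)
            prev = edges
        assert sses[0] >= sses[1] >= sses[2]

    def test_constant_profile_degenerates_to_zero_rate(self):
        prof = _profile(np.arange(0, 2001, 500.0), [200.0] * 5)
        fit = fit_production_zones(prof)
        assert fit.n_zones == 1
        assert fit.zone_rates[0] == 0.0
        assert fit.surface_flux == 0.0


class TestAnoxicBoundary:
    def test_interpolated_boundary(self):
        prof = _profile([0, 500, 1500, 2000], [250.0, 100.0, 2.0, 0.0])
        b = anoxic_boundary(prof, air_saturation=250.0, threshold_fraction=0.01)
        assert b.reached
        # linear interpolation between (500, 100) and (1500, 2) at 2.5 umol/L
        assert b.depth == pytest.approx(500 + (100 - 2.5) / (100 - 2) * 1000, rel=1e-9)

    def test_never_reached(self):
        prof = _profile([0, 500, 1500, 2000], [250.0, 200.0, 150.0, 100.0])
        b = anoxic_boundary(prof, air_saturation=250.0)
        assert not b.reached
        assert np.isnan(b.depth)

    def test_exact_grid_point_crossing(self):
        prof = _profile([0, 500, 1000, 1500], [250.0, 2.5, 1.0, 0.5])
        b = anoxic_boundary(prof, air_saturation=250.0, threshold_fraction=0.01)
        assert b.depth == pytest.approx(500.0)

    def test_transient_dip_does_not_count(self):
        # concentration dips below threshold then recovers: boundary is deeper
        prof = _profile([0, 500, 1000, 1500, 2000], [250.0, 1.0, 50.0, 2.0, 0.5])
        b = anoxic_boundary(prof, air_saturation=250.0, threshold_fraction=0.01)
        assert b.depth > 1000.0
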