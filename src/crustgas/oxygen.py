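"""Steady-state oxygen microprofile modelling and production-zone inversion.

A wet crust a few mm thick develops steep O2 gradients: photosynthesis
produces O2 near the surface, respiration consumes it below, and transport
is by molecular diffusion through the porewater. At steady state

    d/dz( phi * Ds * dC/dz ) + P(z) = 0,

with ``phi`` the porosity, ``Ds`` the sediment diffusion coefficient and
``P(z)`` the net volumetric production rate (negative = consumption). With
``P`` piecewise constant over a small number of depth zones the solution is
piecewise quadratic and C1-continuous, which makes the inverse problem —
find the zone rates that best reproduce a measured microsensor profile —
linear in the rates for fixed zone boundaries. Boundaries are searched over
the measurement grid and the number of zones is selected by nested F-tests,
the classical approach for microprofile interpretation.

Conventions: depth in µm, zero at the crust surface, positive downward;
concentrations in µmol L⁻¹ (numerically equal to nmol cm⁻³); volumetric
rates in nmol cm⁻³ s⁻¹; fluxes in nmol cm⁻² s⁻¹, positive *into* the soil.
Boundary conditions: fixed concentration at the surface and zero flux at
the deepest point (closed microcosm bottom); a fixed-concentration bottom
is available instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "OxygenProfile",
    "ProfileSolution",
    "ProfileFit",
    "AnoxicBoundary",
    "DEFAULT_POROSITY",
    "DEFAULT_DIFFUSIVITY_M2_S",
    "AIR_SATURATION_UMOL_L",
    "solve_profile",
    "forward_profile",
    "surface_flux",
    "fit_production_zones",
    "anoxic_boundary",
]

#: Porosity of a water-saturated silty-loam crust (config-overridable).
DEFAULT_POROSITY = 0.6
#: Effective sediment diffusion coefficient of O2 at 25 degC, m2 s-1.
DEFAULT_DIFFUSIVITY_M2_S = 1.2e-9
#: Air-saturated O2 concentration in fresh water at 25 degC, umol L-1.
AIR_SATURATION_UMOL_L = 253.0

_UM_PER_CM = 1e4


@dataclass
class OxygenProfile:
    """A measured vertical O2 microprofile plus its transport parameters."""

    depths: np.ndarray  # µm, strictly increasing, 0 at the surface
    concentrations: np.ndarray  # µmol L-1
    porosity: float = DEFAULT_POROSITY
    diffusivity: float = DEFAULT_DIFFUSIVITY_M2_S  # m2 s-1
    microcosm_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.depths.ndim != 1 or self.depths.size < 4:
            raise InvalidInputError("a profile needs at least 4 measurement points")
        if self.concentrations.shape != self.depths.shape:
            raise InvalidInputError("depths and concentrations must have equal length")
        if np.any(np.diff(self.depths) <= 0):
            raise InvalidInputError("depths must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise InvalidInputError("concentrations must be >= 0")
        if not (0 < self.porosity <= 1):
            raise InvalidInputError("porosity must be in (0, 1]")
        if self.diffusivity <= 0:
            raise InvalidInputError("diffusivity must be > 0")


@dataclass(frozen=True)
class ProfileSolution:
    """Analytic piecewise-quadratic solution of the steady-state model.

    ``edges_cm`` has length n_zones + 1; within zone i the flux is linear,
    ``J(z) = J_edge[i] + P_i (z − z_i)``, and the concentration quadratic.
    """

    edges_cm: np.ndarray
    rates: np.ndarray  # nmol cm-3 s-1 per zone
    c_top: float  # nmol cm-3 at the upper edge
    beta: float  # phi * Ds, cm2 s-1
    j_edges: np.ndarray  # flux at each edge, nmol cm-2 s-1 (positive down)
    c_edges: np.ndarray  # concentration at each edge

    @property
    def surface_flux(self) -> float:
        """Diffusive flux across the surface, positive into the soil."""
        return float(self.j_edges[0])

    def concentration(self, depths_um: Sequence[float]) -> np.ndarray:
        z = np.asarray(depths_um, dtype=float) / _UM_PER_CM
        if np.any(z < self.edges_cm[0] - 1e-12) or np.any(z > self.edges_cm[-1] + 1e-12):
            raise InvalidInputError("requested depth outside the modelled domain")
        idx = np.clip(np.searchsorted(self.edges_cm, z, side="right") - 1, 0, len(self.rates) - 1)
        dz = z - self.edges_cm[idx]
        # C(z) = C_i - (J_i dz + P_i dz^2 / 2) / beta
        return self.c_edges[idx] - (self.j_edges[idx] * dz + self.rates[idx] * dz**2 / 2.0) / self.beta


def solve_profile(
    zone_boundaries_um: Sequence[float],
    zone_rates: Sequence[float],
    top_concentration: float,
    porosity: float = DEFAULT_POROSITY,
    diffusivity: float = DEFAULT_DIFFUSIVITY_M2_S,
    bottom: str = "no_flux",
    bottom_concentration: float | None = None,
) -> ProfileSolution:
    """Solve the steady-state diffusion-reaction equation analytically.

    ``zone_boundaries_um`` are the n_zones + 1 zone edges (µm, increasing,
    first = surface); ``zone_rates`` the volumetric net production per zone
    (nmol cm-3 s-1, negative = consumption). ``bottom`` is ``"no_flux"``
    (default) or ``"fixed"`` with ``bottom_concentration`` given.
    """
    edges = np.asarray(zone_boundaries_um, dtype=float) / _UM_PER_CM
    rates = np.asarray(zone_rates, dtype=float)
    if edges.ndim != 1 or edges.size != rates.size + 1:
        raise InvalidInputError("need len(zone_boundaries) == len(zone_rates) + 1")
    if np.any(np.diff(edges) <= 0):
        raise InvalidInputError("zone boundaries must be strictly increasing")
    if top_concentration < 0:
        raise InvalidInputError("top concentration must be >= 0")
    if not (0 < porosity <= 1) or diffusivity <= 0:
        raise InvalidInputError("porosity in (0,1] and diffusivity > 0 required")
    beta = porosity * diffusivity * 1e4  # cm2 s-1
    thickness = np.diff(edges)
    cum_prod = np.concatenate([[0.0], np.cumsum(rates * thickness)])  # integral of P from surface
    if bottom == "no_flux":
        j0 = -cum_prod[-1]
    elif bottom == "fixed":
        if bottom_concentration is None:
            raise InvalidInputError("bottom_concentration required for fixed bottom")
        length = edges[-1] - edges[0]
        # integral of cum_prod over depth, zone by zone (trapezoid is exact: linear in z)
        int_q = float(np.sum((cum_prod[:-1] + cum_prod[1:]) / 2.0 * thickness))
        j0 = (beta * (top_concentration - bottom_concentration) - int_q) / length
    else:
        raise InvalidInputError(f"unknown bottom condition {bottom!r}")
    j_edges = j0 + cum_prod
    # C at edges by integrating -J/beta; within a zone J is linear so the
    # trapezoid rule is exact
    c_edges = top_concentration - np.concatenate(
        [[0.0], np.cumsum((j_edges[:-1] + j_edges[1:]) / 2.0 * thickness)]
    ) / beta
    return ProfileSolution(
        edges_cm=edges,
        rates=rates,
        c_top=float(top_concentration),
        beta=beta,
        j_edges=j_edges,
        c_edges=c_edges,
    )


def forward_profile(
    zone_boundaries_um: Sequence[float],
    zone_rates: Sequence[float],
    top_concentration: float,
    porosity: float = DEFAULT_POROSITY,
    diffusivity: float = DEFAULT_DIFFUSIVITY_M2_S,
    depth_grid_um: Sequence[float] | None = None,
    bottom: str = "no_flux",
    bottom_concentration: float | None = None,
) -> np.ndarray:
    """Concentrations of the forward model on ``depth_grid_um``.

    Negative modelled concentrations indicate a physically inconsistent
    parameter set; they are returned as-is (flagged by callers), never
    raised, so the linear inversion can still operate on them.
    """
    if depth_grid_um is None:
        depth_grid_um = np.linspace(zone_boundaries_um[0], zone_boundaries_um[-1], 101)
    sol = solve_profile(
        zone_boundaries_um,
        zone_rates,
        top_concentration,
        porosity,
        diffusivity,
        bottom,
        bottom_concentration,
    )
    return sol.concentration(depth_grid_um)


def surface_flux(solution: ProfileSolution) -> float:
    """Fick's-first-law flux at the surface, J = −phi·Ds·dC/dz|0 (nmol cm-2 s-1).

    Positive means net flux into the soil; with a zero-flux bottom this
    equals the negative depth integral of the volumetric rates.
    """
    return solution.surface_flux


@dataclass(frozen=True)
class ProfileFit:
    """Result of inverting a measured profile for production zones."""

    zone_boundaries: np.ndarray  # µm, n_zones + 1 edges
    zone_rates: np.ndarray  # nmol cm-3 s-1
    surface_flux: float  # nmol cm-2 s-1, positive into the soil
    sse: float  # squared concentration residual, (umol L-1)^2
    n_zones: int
    selection_pvalue: float  # F-test p that justified stopping at n_zones (nan if forced)
    fitted_top_concentration: float
    solution: ProfileSolution
    nonphysical: bool  # fitted profile went negative although measurements are >= 0


@dataclass(frozen=True)
class AnoxicBoundary:
    """Depth below which O2 stays under a fraction of air saturation."""

    depth: float  # µm; nan when the profile never crosses the threshold
    threshold_fraction: float
    reached: bool


def _lstsq_zones(profile: OxygenProfile, edges_um: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares rates (+ free top concentration) for fixed zone edges.

    The forward map is affine in the rates, so each zone contributes a basis
    profile (unit rate, zero top concentration) and the fit is a single
    linear solve. Returns (rates, c_top, sse).
    """
    k = edges_um.size - 1
    cols = [np.ones(profile.depths.size)]
    for i in range(k):
        unit = np.zeros(k)
        unit[i] = 1.0
        cols.append(
            forward_profile(
                edges_um,
                unit,
                0.0,
                profile.porosity,
                profile.diffusivity,
                depth_grid_um=profile.depths,
            )
        )
    design = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(design, profile.concentrations, rcond=None)
    resid = profile.concentrations - design @ coef
    return coef[1:], float(coef[0]), float(resid @ resid)


def _best_edges_for_k(
    profile: OxygenProfile, k: int, prev_edges: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Best zone edges for a k-zone fit: exhaustive for k <= 3, greedy above."""
    depths = profile.depths
    candidates = depths[1:-1]
    outer = np.array([depths[0], depths[-1]])
    best = None
    if k == 1:
        trials: list[tuple[float, ...]] = [()]
    elif k <= 3:
        trials = list(itertools.combinations(candidates, k - 1))
    else:
        # greedy: extend the previous best boundary set by one candidate
        prev_interior = set(prev_edges[1:-1].tolist()) if prev_edges is not None else set()
        trials = [
            tuple(sorted(prev_interior | {c}))
            for c in candidates
            if c not in prev_interior
        ]
    for interior in trials:
        edges = np.concatenate([[outer[0]], list(interior), [outer[1]]])
        rates, c_top, sse = _lstsq_zones(profile, edges)
        if best is None or sse < best[3]:
            best = (edges, rates, c_top, sse)
    assert best is not None
    return best


def fit_production_zones(
    profile: OxygenProfile, max_zones: int = 3, alpha: float = 0.05
) -> ProfileFit:
    """Invert a measured profile for piecewise-constant production zones.

    For each candidate zone count k the least-squares rates are found with
    boundaries searched over the measurement depths (exhaustively for
    k <= 3, greedily above). The accepted k is the smallest for which adding
    a zone does not significantly reduce the SSE by a nested F-test at
    level ``alpha``; an essentially exact fit also stops the search.
    """
    if max_zones < 1:
        raise InvalidInputError("max_zones must be >= 1")
    n = profile.depths.size
    if n <= max_zones + 1:
        raise InsufficientDataError("need more measurement points than zones + 1")
    scale = max(1.0, float(np.max(np.abs(profile.concentrations))))
    exact_tol = (1e-8 * scale) ** 2 * n

    if np.ptp(profile.concentrations) == 0.0:
        # flat profile: no transport, no reaction
        edges = np.array([profile.depths[0], profile.depths[-1]])
        sol = solve_profile(
            edges, [0.0], float(profile.concentrations[0]), profile.porosity, profile.diffusivity
        )
        return ProfileFit(
            zone_boundaries=edges,
            zone_rates=np.array([0.0]),
            surface_flux=0.0,
            sse=0.0,
            n_zones=1,
            selection_pvalue=float("nan"),
            fitted_top_concentration=float(profile.concentrations[0]),
            solution=sol,
            nonphysical=False,
        )

    fits: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    prev_edges = None
    for k in range(1, max_zones + 1):
        fit = _best_edges_for_k(profile, k, prev_edges)
        fits.append(fit)
        prev_edges = fit[0]

    def n_params(k: int) -> int:
        return 2 * k  # k rates + (k-1) interior boundaries + free top concentration

    selected = max_zones
    pvalue = float("nan")
    for k in range(1, max_zones + 1):
        sse_k = fits[k - 1][3]
        if sse_k <= exact_tol:
            selected, pvalue = k, float("nan")
            break
        if k == max_zones:
            selected = k
            break
        sse_k1 = fits[k][3]
        df_extra = n_params(k + 1) - n_params(k)
        df_resid = n - n_params(k + 1)
        if df_resid <= 0:
            selected = k
            break
        if sse_k1 <= exact_tol:
            # the richer model is essentially exact; F-statistic diverges
            continue
        f_stat = ((sse_k - sse_k1) / df_extra) / (sse_k1 / df_resid)
        p = float(stats.f.sf(max(f_stat, 0.0), df_extra, df_resid))
        if p > alpha:
            selected, pvalue = k, p
            break

    edges, rates, c_top, sse = fits[selected - 1]
    sol = solve_profile(edges, rates, c_top, profile.porosity, profile.diffusivity)
    fitted = sol.concentration(profile.depths)
    return ProfileFit(
        zone_boundaries=edges,
        zone_rates=rates,
        surface_flux=sol.surface_flux,
        sse=sse,
        n_zones=selected,
        selection_pvalue=pvalue,
        fitted_top_concentration=c_top,
        solution=sol,
        nonphysical=bool(np.any(fitted < -1e-9 * scale)),
    )


def anoxic_boundary(
    profile: OxygenProfile,
    air_saturation: float = AIR_SATURATION_UMOL_L,
    threshold_fraction: float = 0.01,
) -> AnoxicBoundary:
    """Depth below which O2 stays under ``threshold_fraction`` of air saturation.

    The boundary is the shallowest depth where the concentration first drops
    below the threshold *and remains below it* for all deeper measurements,
    linearly interpolated between the bracketing points.
    """
    if air_saturation <= 0:
        raise InvalidInputError("air_saturation must be > 0")
    thr = threshold_fraction * air_saturation
    below = profile.concentrations < thr
    if not below[-1]:
        return AnoxicBoundary(depth=float("nan"), threshold_fraction=threshold_fraction, reached=False)
    # first index from which everything below stays under the threshold
    idx = int(np.max(np.nonzero(~below)[0]) + 1) if np.any(~below) else 0
    if idx == 0:
        return AnoxicBoundary(
            depth=float(profile.depths[0]), threshold_fraction=threshold_fraction, reached=True
        )
    c_hi, c_lo = profile.concentrations[idx - 1], profile.concentrations[idx]
    z_hi, z_lo = profile.depths[idx - 1], profile.depths[idx]
    depth = z_hi + (c_hi - thr) / (c_hi - c_lo) * (z_lo - z_hi)
    return AnoxicBoundary(depth=float(depth), threshold_fraction=threshold_fraction, reached=True)
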