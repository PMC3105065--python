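"""Stable carbon isotope calculus for methanogenic pathway partitioning.

In most soils methane arises from two pathways with very different carbon
isotope fractionation: acetate cleavage (acetoclastic, small fractionation)
and CO2 reduction with H2 (hydrogenotrophic, large fractionation). Headspace
δ13C of CH4 and CO2 therefore carries a pathway signal that four pieces of
algebra extract:

1. *Newly formed methane.*  Headspace CH4 accumulates, so the δ13C measured
   at time 2 mixes old and new methane. With ``f_n`` the fraction of methane
   at time 2 that formed during the interval, two-pool mass balance
   ``δ2 = f_n·δn + (1 − f_n)·δ1`` solved for ``δn`` gives the signature of
   the increment alone.
2. *Apparent fractionation factor* ``α_app = (δ_CO2 + 1000)/(δ_CH4 + 1000)``,
   the diagnostic ratio between substrate CO2 and product CH4.
3. ``ε = (α − 1)·1000`` — the same quantity in per mil.
4. *Two-end-member partition.*  Given signatures of purely acetoclastic
   (``δ_ma``) and purely hydrogenotrophic (``δ_mc``) methane, the
   hydrogenotrophic fraction is the linear mixing coordinate
   ``f_mc = (δ_CH4 − δ_ma)/(δ_mc − δ_ma)``.

All deltas are ‰ vs V-PDB.  ``δ_mc`` is best calibrated from an incubation
in which acetoclastic methanogenesis is chemically inhibited with methyl
fluoride (CH3F); ``δ_ma`` from soil organic carbon plus an assumed
acetate-to-methane fractionation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


from .errors import DegenerateEndMemberError, InvalidInputError, NoNetProductionError

__all__ = [
    "IsotopePoint",
    "NewMethaneResult",
    "FractionationResult",
    "PathwayPartition",
    "EndMemberConfig",
    "fraction_new",
    "newly_formed_delta",
    "apparent_fractionation",
    "alpha_to_epsilon",
    "epsilon_to_alpha",
    "partition_pathways",
    "acetate_endmember",
    "co2_source_fraction",
    "partition_with_uncertainty",
]

_DELTA_FLOOR = -1000.0  # ‰; a sample with zero 13C sits exactly at -1000


def _check_delta(value: float, name: str) -> None:
    if value <= _DELTA_FLOOR:
        raise InvalidInputError(f"{name} must be > {_DELTA_FLOOR} permil, got {value}")


@dataclass(frozen=True)
class IsotopePoint:
    """Paired δ13C of CH4 and CO2 with the CH4 amount at one sampling day."""

    time: float  # days
    delta_ch4: float  # ‰ vs V-PDB
    delta_co2: float  # ‰ vs V-PDB
    ch4_amount: float  # nmol gdw-1

    def __post_init__(self) -> None:
        _check_delta(self.delta_ch4, "delta_ch4")
        _check_delta(self.delta_co2, "delta_co2")
        if self.ch4_amount < 0:
            raise InvalidInputError("ch4_amount must be >= 0")


@dataclass(frozen=True)
class NewMethaneResult:
    """δ13C of the methane formed within one sampling interval."""

    delta_new: float  # ‰
    fraction_new: float  # (0, 1]
    interval: tuple[float, float]  # (time1, time2) days


@dataclass(frozen=True)
class FractionationResult:
    """Apparent CO2→CH4 fractionation, as a factor and in per mil."""

    alpha_app: float
    epsilon_app: float  # ‰, = (alpha - 1) * 1000


@dataclass(frozen=True)
class PathwayPartition:
    """Hydrogenotrophic/acetoclastic split of total methanogenesis.

    ``raw_fraction`` keeps the unclamped mixing coordinate for diagnostics;
    ``clamped`` flags that it fell outside [0, 1] (the measured δ13C lay
    beyond an end member, e.g. purely acetoclastic production with an
    end-member scenario more negative than the measurement).
    """

    f_hydrogenotrophic: float
    f_acetoclastic: float
    delta_ma: float  # ‰, acetoclastic end member
    delta_mc: float  # ‰, hydrogenotrophic end member
    clamped: bool
    raw_fraction: float
    se_f_hydrogenotrophic: float | None = None


@dataclass(frozen=True)
class EndMemberConfig:
    """End-member scenario for pathway and CO2-source partitioning.

    ``acetate_to_methane_fractionation`` is the ‰ shift applied to the soil
    organic carbon value to obtain δ_ma (the organic-C-to-acetate step is
    assumed nearly unfractionating); scenarios of 0 and −25.6‰ bracket
    literature values for acetate cleavage.
    """

    delta_organic: float = -20.5  # ‰, soil organic carbon
    delta_carbonate: float = -4.09  # ‰, soil carbonate
    acetate_to_methane_fractionation: float = 0.0  # ‰, <= 0 in realistic scenarios
    delta_mc: float = -75.0  # ‰, CH3F-calibrated hydrogenotrophic end member

    @property
    def delta_ma(self) -> float:
        return acetate_endmember(self.delta_organic, self.acetate_to_methane_fractionation)


def fraction_new(amount1: float, amount2: float) -> float:
    """Fraction of the methane present at time 2 that formed in (t1, t2]."""
    if amount1 < 0:
        raise InvalidInputError("amount1 must be >= 0")
    if amount2 <= amount1:
        raise NoNetProductionError(
            f"no net CH4 production over interval (amount1={amount1}, amount2={amount2})"
        )
    return (amount2 - amount1) / amount2


def newly_formed_delta(delta1: float, delta2: float, f_new: float) -> float:
    """δ13C of the methane increment, from two-pool mass balance.

    ``δn = (δ2 − (1 − f_n)·δ1)/f_n``; with ``f_n = 1`` the whole pool is
    new and δn is δ2 itself.
    """
    if not (0.0 < f_new <= 1.0):
        raise InvalidInputError(f"fraction_new must be in (0, 1], got {f_new}")
    _check_delta(delta1, "delta1")
    _check_delta(delta2, "delta2")
    return (delta2 - (1.0 - f_new) * delta1) / f_new


def newly_formed_series(points: Sequence[IsotopePoint]) -> list[NewMethaneResult]:
    """δ13C of newly formed methane for every consecutive interval.

    Intervals without net production are skipped (they carry no new-methane
    signal), mirroring how zero-increment samplings are treated in practice.
    """
    results: list[NewMethaneResult] = []
    for p1, p2 in zip(points, points[1:]):
        try:
            f_n = fraction_new(p1.ch4_amount, p2.ch4_amount)
        except NoNetProductionError:
            continue
        results.append(
            NewMethaneResult(
                delta_new=newly_formed_delta(p1.delta_ch4, p2.delta_ch4, f_n),
                fraction_new=f_n,
                interval=(p1.time, p2.time),
            )
        )
    return results


def apparent_fractionation(delta_co2: float, delta_ch4: float) -> FractionationResult:
    """Apparent fractionation factor α_app = (δ_CO2 + 1000)/(δ_CH4 + 1000)."""
    _check_delta(delta_co2, "delta_co2")
    _check_delta(delta_ch4, "delta_ch4")
    alpha = (delta_co2 + 1000.0) / (delta_ch4 + 1000.0)
    return FractionationResult(alpha_app=alpha, epsilon_app=alpha_to_epsilon(alpha))


def alpha_to_epsilon(alpha: float) -> float:
    """ε (‰) = (α − 1) × 1000."""
    if alpha <= 0:
        raise InvalidInputError("alpha must be > 0")
    return (alpha - 1.0) * 1000.0


def epsilon_to_alpha(epsilon: float) -> float:
    """α = ε/1000 + 1; exact inverse of :func:`alpha_to_epsilon`."""
    return epsilon / 1000.0 + 1.0


def partition_pathways(delta_ch4: float, delta_ma: float, delta_mc: float) -> PathwayPartition:
    """Two-end-member split of CH4 between hydrogenotrophic and acetoclastic sources.

    The raw mixing coordinate is clamped to [0, 1] with the ``clamped`` flag
    set, since values outside the interval mean the measurement lies beyond
    an end-member scenario and the partition saturates at a pure pathway.
    """
    for v, n in ((delta_ch4, "delta_ch4"), (delta_ma, "delta_ma"), (delta_mc, "delta_mc")):
        _check_delta(v, n)
    if delta_ma == delta_mc:
        raise DegenerateEndMemberError("delta_ma and delta_mc must differ")
    raw = (delta_ch4 - delta_ma) / (delta_mc - delta_ma)
    f_mc = min(max(raw, 0.0), 1.0)
    return PathwayPartition(
        f_hydrogenotrophic=f_mc,
        f_acetoclastic=1.0 - f_mc,
        delta_ma=delta_ma,
        delta_mc=delta_mc,
        clamped=(f_mc != raw),
        raw_fraction=raw,
    )


def acetate_endmember(delta_organic: float, acetate_to_methane_fractionation: float) -> float:
    """δ_ma from soil organic carbon and the acetate→CH4 fractionation shift."""
    return delta_organic + acetate_to_methane_fractionation


def co2_source_fraction(
    delta_co2: float, delta_organic: float, delta_carbonate: float
) -> tuple[float, bool]:
    """Fraction of headspace CO2 derived from carbonate rather than organic matter.

    Two-pool mixing between the organic-carbon and carbonate δ13C end
    members; returns ``(fraction, clamped)``.
    """
    _check_delta(delta_co2, "delta_co2")
    if delta_organic == delta_carbonate:
        raise DegenerateEndMemberError("organic and carbonate end members must differ")
    raw = (delta_co2 - delta_organic) / (delta_carbonate - delta_organic)
    frac = min(max(raw, 0.0), 1.0)
    return frac, frac != raw


def partition_with_uncertainty(
    delta_ch4: float,
    delta_ma: float,
    delta_mc: float,
    se_ch4: float = 0.0,
    se_ma: float = 0.0,
    se_mc: float = 0.0,
) -> PathwayPartition:
    """Pathway partition with a first-order (delta-method) standard error.

    With ``f = (x − a)/(c − a)`` (x = δ_CH4, a = δ_ma, c = δ_mc):
    ``∂f/∂x = 1/(c−a)``, ``∂f/∂a = (x−c)/(c−a)²``, ``∂f/∂c = −(x−a)/(c−a)²``;
    the SE is the quadrature sum of the propagated terms, evaluated at the
    unclamped coordinate.
    """
    if min(se_ch4, se_ma, se_mc) < 0:
        raise InvalidInputError("standard errors must be >= 0")
    base = partition_pathways(delta_ch4, delta_ma, delta_mc)
    span = delta_mc - delta_ma
    d_x = 1.0 / span
    d_a = (delta_ch4 - delta_mc) / span**2
    d_c = -(delta_ch4 - delta_ma) / span**2
    se = math.sqrt((d_x * se_ch4) ** 2 + (d_a * se_ma) ** 2 + (d_c * se_mc) ** 2)
    return PathwayPartition(
        f_hydrogenotrophic=base.f_hydrogenotrophic,
        f_acetoclastic=base.f_acetoclastic,
        delta_ma=delta_ma,
        delta_mc=delta_mc,
        clamped=base.clamped,
        raw_fraction=base.raw_fraction,
        se_f_hydrogenotrophic=se,
    )
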