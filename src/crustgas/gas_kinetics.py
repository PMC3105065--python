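"""Headspace gas kinetics: mixing ratios to absolute amounts and production rates.

Microcosms are closed vessels with a known headspace volume over a weighed
layer of dry crust. Gas chromatograph readings come back as mixing ratios
(ppmv); converting them through the ideal gas law to nmol and normalising by
soil dry weight puts every treatment on a common per-gram basis, after which
a production (or consumption) rate is the ordinary-least-squares slope of
amount versus time.

Withdrawal of headspace gas by the sampling syringe is ignored: sample
volumes are small relative to the ~100 mL headspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import constants, stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "TreatmentCode",
    "GasTimeSeries",
    "RateEstimate",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_PRESSURE_PA",
    "FULL_WINDOW",
    "LATE_WINDOW",
    "mixing_ratio_to_amount",
    "amount_per_gdw_series",
    "estimate_production_rate",
    "summarize_rates",
]

#: Incubation temperature (25 degC) applied when an input row has no value.
DEFAULT_TEMPERATURE_K = 298.15
#: Standard pressure applied when an input row has no value.
DEFAULT_PRESSURE_PA = 101325.0

#: Entire incubation period, days since wetting.
FULL_WINDOW = (0.0, 42.0)
#: Post-lag window used for the treatment-effect statistics.
LATE_WINDOW = (14.0, 42.0)

_GASES = frozenset({"CH4", "CO2", "H2", "O2"})
_WETTING = {"F": "flooded", "W": "wet-drained"}
_LIGHT = {"L": "light", "D": "dark"}
_HEADSPACE = {"N": "anoxic", "O": "oxic"}


@dataclass(frozen=True)
class TreatmentCode:
    """One cell of the 2x2x2 factorial design, e.g. ``FDN``.

    wetting: ``F`` (flooded) or ``W`` (wet-drained);
    light: ``L`` (light) or ``D`` (dark);
    headspace: ``N`` (N2, anoxic) or ``O`` (air, 21% O2, oxic).
    """

    wetting: str
    light: str
    headspace: str

    def __post_init__(self) -> None:
        if self.wetting not in _WETTING:
            raise InvalidInputError(f"wetting must be one of {sorted(_WETTING)}, got {self.wetting!r}")
        if self.light not in _LIGHT:
            raise InvalidInputError(f"light must be one of {sorted(_LIGHT)}, got {self.light!r}")
        if self.headspace not in _HEADSPACE:
            raise InvalidInputError(f"headspace must be one of {sorted(_HEADSPACE)}, got {self.headspace!r}")

    @classmethod
    def from_string(cls, code: str) -> "TreatmentCode":
        code = code.strip().upper()
        if len(code) != 3:
            raise InvalidInputError(f"treatment code must have three letters, got {code!r}")
        return cls(code[0], code[1], code[2])

    @property
    def is_oxic_or_oxygenic(self) -> bool:
        """True for every treatment except the strictly anoxic (dark + N2) ones.

        Light treatments produce O2 internally by photosynthesis even under an
        N2 headspace, so only dark-N2 microcosms are strictly anoxic.
        """
        return not (self.light == "D" and self.headspace == "N")

    def __str__(self) -> str:
        return f"{self.wetting}{self.light}{self.headspace}"


@dataclass
class GasTimeSeries:
    """Headspace mixing ratios of one gas in one microcosm over the incubation."""

    microcosm_id: str
    treatment: TreatmentCode
    gas: str
    times: np.ndarray  # days since wetting
    mixing_ratios: np.ndarray  # ppmv
    headspace_volume: float  # mL
    soil_dry_weight: float  # g
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    pressure: float = DEFAULT_PRESSURE_PA  # Pa

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mixing_ratios = np.asarray(self.mixing_ratios, dtype=float)
        if self.gas not in _GASES:
            raise InvalidInputError(f"gas must be one of {sorted(_GASES)}, got {self.gas!r}")
        if self.times.ndim != 1 or self.times.size < 2:
            raise InvalidInputError("times must be a 1-d array with at least 2 points")
        if self.mixing_ratios.shape != self.times.shape:
            raise InvalidInputError("times and mixing_ratios must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise InvalidInputError("times must be non-negative (days since wetting)")
        if np.any(self.mixing_ratios < 0):
            raise InvalidInputError("mixing ratios must be >= 0 ppmv")
        for name in ("headspace_volume", "soil_dry_weight", "temperature", "pressure"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class RateEstimate:
    """OLS production rate with its slope standard error and fit quality."""

    rate: float  # nmol gdw-1 d-1 (negative allowed, e.g. O2 consumption)
    standard_error: float
    r_squared: float
    n_points: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidInputError("a rate estimate needs at least 2 points")
        if self.standard_error < 0:
            raise InvalidInputError("standard_error must be >= 0")


def mixing_ratio_to_amount(
    ppmv: float,
    volume_ml: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    pressure_pa: float = DEFAULT_PRESSURE_PA,
) -> float:
    """Convert a headspace mixing ratio to an absolute amount in nmol.

    Ideal gas law: the total moles in the headspace are ``P*V/(R*T)``; the
    target gas is the ppmv fraction of that. Returns nmol.
    """
    if volume_ml <= 0 or temperature_k <= 0 or pressure_pa <= 0:
        raise InvalidInputError("volume, temperature and pressure must all be > 0")
    if ppmv < 0:
        raise InvalidInputError("mixing ratio must be >= 0 ppmv")
    total_mol = pressure_pa * (volume_ml * 1e-6) / (constants.R * temperature_k)
    return ppmv * 1e-6 * total_mol * 1e9


def amount_per_gdw_series(series: GasTimeSeries) -> np.ndarray:
    """Convert a whole time series to nmol per gram dry soil."""
    amounts = np.array(
        [
            mixing_ratio_to_amount(p, series.headspace_volume, series.temperature, series.pressure)
            for p in series.mixing_ratios
        ]
    )
    return amounts / series.soil_dry_weight


def estimate_production_rate(
    amounts: Sequence[float],
    times: Sequence[float],
    window: tuple[float, float] = FULL_WINDOW,
) -> RateEstimate:
    """OLS slope of amount (nmol gdw-1) versus time (d) within ``window``.

    The intercept is free: the regression is not forced through the origin,
    so a detection lag in the first days does not bias the slope.
    """
    amounts = np.asarray(amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need at least 2 points inside window [{lo}, {hi}], found {int(mask.sum())}"
        )
    x, y = times[mask], amounts[mask]
    fit = stats.linregress(x, y)
    # r-value is nan for a perfectly flat response; report r^2 = 0 then
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    se = 0.0 if np.isnan(fit.stderr) else float(fit.stderr)
    return RateEstimate(
        rate=float(fit.slope),
        standard_error=se,
        r_squared=r2,
        n_points=int(mask.sum()),
        window=(float(lo), float(hi)),
    )


def summarize_rates(estimates: Mapping[str, Iterable[RateEstimate]]) -> pd.DataFrame:
    """Per-treatment mean rate and standard error over replicate microcosms.

    SE is sd/sqrt(n) over replicate slopes (NaN when n = 1, matching how a
    single replicate cannot yield a dispersion estimate).
    """
    rows = []
    for treatment, reps in estimates.items():
        rates = np.array([r.rate for r in reps], dtype=float)
        if rates.size == 0:
            raise InsufficientDataError(f"treatment {treatment!r} has no replicates")
        se = float(np.std(rates, ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else np.nan
        rows.append(
            {
                "treatment": str(treatment),
                "mean_rate_nmol_gdw_d": float(rates.mean()),
                "se_rate_nmol_gdw_d": se,
                "n_replicates": int(rates.size),
            }
        )
    return pd.DataFrame(rows).set_index("treatment")
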