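"""Synthetic microcosm data with known ground truth for every pipeline stage.

The generators emulate a 2x2x2 factorial crust-microcosm incubation
(flooded/wet-drained x light/dark x N2/air headspace, triplicates, 42 days,
weekly sampling): linear CH4 accumulation at treatment-specific rates with
multiplicative measurement noise; isotope series built by exact two-pool
mass balance from configurable pathway fractions and end members; steady
state O2 microprofiles from the piecewise-constant production-zone forward
model; and qPCR plates whose Ct values come from true copy numbers through
a standard curve with Gaussian cycle noise.

Default presets mirror the treatment-level means the study design targets
(e.g. flooded-dark-anoxic CH4 at 3800 nmol gdw-1 d-1, a -75 permil
hydrogenotrophic end member, a 1.066 CH3F-calibrated fractionation factor,
katE fold-change presets per matched treatment pair), so recovery tests
exercise realistic magnitudes. Every generator is deterministic under a
fixed seed and returns its ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .gas_kinetics import (
    DEFAULT_PRESSURE_PA,
    DEFAULT_TEMPERATURE_K,
    GasTimeSeries,
    TreatmentCode,
    mixing_ratio_to_amount,
)
from .isotopes import IsotopePoint
from .oxygen import (
    DEFAULT_DIFFUSIVITY_M2_S,
    DEFAULT_POROSITY,
    OxygenProfile,
    solve_profile,
)
from .qpcr import QpcrRecord

__all__ = [
    "GeneratorConfig",
    "TRUE_CH4_RATES",
    "PATHWAY_F_HYDROGENOTROPHIC",
    "TREATMENT_DELTA_CO2",
    "DELTA_ORGANIC",
    "DELTA_CARBONATE",
    "DELTA_MC",
    "CH3F_ALPHA",
    "KATE_FOLD_PRESETS",
    "O2_ZONE_PRESETS",
    "gen_gas_timeseries",
    "gen_isotope_series",
    "gen_ch3f_series",
    "gen_oxygen_profiles",
    "gen_qpcr_plate",
    "write_inputs",
]

TREATMENTS = ("FLN", "FLO", "FDN", "FDO", "WLN", "WLO", "WDN", "WDO")

#: True CH4 production per treatment, nmol gdw-1 d-1. The strictly anoxic
#: (dark + N2) treatments are orders of magnitude above the oxic/oxygenic
#: ones; the four light treatments share the oxic/oxygenic mean.
TRUE_CH4_RATES: dict[str, float] = {
    "FDN": 3800.0,
    "WDN": 1500.0,
    "FDO": 41.6,
    "WDO": 9.2,
    "FLN": 21.7,
    "FLO": 21.7,
    "WLN": 21.7,
    "WLO": 21.7,
}

#: Fraction of CH4 from H2/CO2 per treatment: mixed pathways only where
#: strictly anoxic, purely hydrogenotrophic wherever O2 is around.
PATHWAY_F_HYDROGENOTROPHIC: dict[str, float] = {
    t: (0.27 if t in ("FDN", "WDN") else 1.0) for t in TREATMENTS
}

#: Headspace delta13C-CO2 per treatment (permil): carbonate-influenced and
#: heavier in the strictly anoxic microcosms, organic-derived elsewhere.
TREATMENT_DELTA_CO2: dict[str, float] = {
    t: (-11.5 if t in ("FDN", "WDN") else -20.0) for t in TREATMENTS
}

DELTA_ORGANIC = -20.5  # permil, soil organic carbon
DELTA_CARBONATE = -4.09  # permil, soil carbonate
DELTA_MC = -75.0  # permil, hydrogenotrophic end member (CH3F calibration)
CH3F_ALPHA = 1.066  # apparent fractionation with acetoclastic pathway inhibited

#: katE relative-expression (2^-ddCt) truths per matched pair, second vs
#: first treatment of the pair.
KATE_FOLD_PRESETS: dict[str, dict[tuple[str, str], float]] = {
    "katE-Methanocella": {
        ("FLN", "FLO"): 0.16,
        ("WLN", "WLO"): 0.30,
        ("FDN", "FDO"): 3.21,
        ("WDN", "WDO"): 2.37,
    },
    "katE-Methanosarcina": {
        ("FLN", "FLO"): 1.36,
        ("WLN", "WLO"): 1.09,
        ("FDN", "FDO"): 0.35,
        ("WDN", "WDO"): 0.06,
    },
}

#: True gene copies per gdw per assay and treatment. Anoxic communities sit
#: at 1e8-1e9 copies, oxic/oxygenic ones at 1e5-1e7.
TRUE_COPIES: dict[str, dict[str, float]] = {
    "total-mcrA": {
        "FDN": 1.15e9,
        "WDN": 3.0e8,
        "FLN": 1.0e7,
        "FDO": 1.0e6,
        "FLO": 1.0e6,
        "WLN": 1.0e6,
        "WDO": 5.0e5,
        "WLO": 4.16e5,
    },
    "Methanosarcina-mcrA": {
        t: (0.3 if t in ("FDN", "WDN") else 0.01) * c
        for t, c in {
            "FDN": 1.15e9,
            "WDN": 3.0e8,
            "FLN": 1.0e7,
            "FDO": 1.0e6,
            "FLO": 1.0e6,
            "WLN": 1.0e6,
            "WDO": 5.0e5,
            "WLO": 4.16e5,
        }.items()
    },
    "archaeal-16S": {
        t: 5.0 * c
        for t, c in {
            "FDN": 1.15e9,
            "WDN": 3.0e8,
            "FLN": 1.0e7,
            "FDO": 1.0e6,
            "FLO": 1.0e6,
            "WLN": 1.0e6,
            "WDO": 5.0e5,
            "WLO": 4.16e5,
        }.items()
    },
}

#: O2 production-zone presets (edges um, rates nmol cm-3 s-1, top umol L-1).
#: Light treatments: photosynthetic production above a respiration zone,
#: anoxic below ~1500 um. Dark oxic: single consumption zone with O2
#: penetrating to ~2.5 mm. Rates chosen to keep modelled concentrations
#: non-negative at the default porosity and diffusivity.
O2_ZONE_PRESETS: dict[str, dict] = {
    "light": {
        "edges_um": [0.0, 500.0, 1500.0, 3000.0],
        "rates": [0.746667, -0.273333, 0.0],
        "top_umol_l": 250.0,
        "depth_step_um": 100.0,
    },
    "dark_oxic": {
        "edges_um": [0.0, 2500.0],
        "rates": [-0.0576],
        "top_umol_l": 250.0,
        "depth_step_um": 100.0,
    },
}

_CURVE_SLOPE = -3.3219  # cycles per decade, perfect amplification efficiency
_CURVE_INTERCEPT = 37.0  # Ct at a single copy


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of the synthetic experiment; defaults are the presets above."""

    seed: int = 42
    treatments: tuple[str, ...] = TREATMENTS
    true_rates: dict[str, float] = field(default_factory=lambda: dict(TRUE_CH4_RATES))
    gas_noise_sd: float = 0.1  # multiplicative, on cumulative amounts
    pathway_mix: dict[str, float] = field(
        default_factory=lambda: dict(PATHWAY_F_HYDROGENOTROPHIC)
    )
    delta_co2: dict[str, float] = field(default_factory=lambda: dict(TREATMENT_DELTA_CO2))
    delta_ma: float = DELTA_ORGANIC  # zero acetate-to-methane fractionation scenario
    delta_mc: float = DELTA_MC
    delta_noise_sd: float = 0.5  # permil, additive on reported deltas
    profile_noise_sd_fraction: float = 0.01  # of the top concentration
    ct_noise_sd: float = 0.15  # cycles
    days: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0)
    replicates: int = 3
    headspace_ml: float = 100.0
    soil_gdw: float = 20.0
    temperature_k: float = DEFAULT_TEMPERATURE_K
    pressure_pa: float = DEFAULT_PRESSURE_PA

    def __post_init__(self) -> None:
        for name in ("gas_noise_sd", "delta_noise_sd", "profile_noise_sd_fraction", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


def _amount_to_ppmv(amount_nmol: float, config: GeneratorConfig) -> float:
    per_ppmv = mixing_ratio_to_amount(
        1.0, config.headspace_ml, config.temperature_k, config.pressure_pa
    )
    return amount_nmol / per_ppmv


def gen_gas_timeseries(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[GasTimeSeries], dict]:
    """CH4 (plus simple CO2/H2/O2 trajectories) per microcosm, with truth.

    Cumulative CH4 per gram is ``rate * day * (1 + e)`` with multiplicative
    Gaussian noise, floored at zero, then expressed as a headspace mixing
    ratio through the inverse ideal-gas conversion.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    days = np.asarray(config.days, dtype=float)
    series: list[GasTimeSeries] = []
    truth: dict = {"true_rates": dict(config.true_rates), "gas_noise_sd": config.gas_noise_sd}
    for trt in config.treatments:
        rate = config.true_rates[trt]
        oxic = trt[2] == "O"
        light = trt[1] == "L"
        for rep in range(1, config.replicates + 1):
            mid = f"{trt}-{rep}"
            eps = rng.normal(0.0, config.gas_noise_sd, size=days.size)
            ch4_gdw = np.maximum(rate * days * (1.0 + eps), 0.0)
            ch4_ppmv = np.array([_amount_to_ppmv(a * config.soil_gdw, config) for a in ch4_gdw])
            # companion gases from simple saturating / constant trajectories
            co2_ppmv = (600.0 if light else 2000.0) * (1.0 - np.exp(-days / 7.0)) * (
                1.0 + rng.normal(0.0, config.gas_noise_sd, size=days.size)
            )
            h2_ppmv = np.full(days.size, 5.0 if light else (0.5 if not oxic else 0.01))
            o2_ppmv = np.full(days.size, 209500.0 if oxic else 100.0)
            for gas, ppmv in (
                ("CH4", ch4_ppmv),
                ("CO2", np.maximum(co2_ppmv, 0.0)),
                ("H2", h2_ppmv),
                ("O2", o2_ppmv),
            ):
                series.append(
                    GasTimeSeries(
                        microcosm_id=mid,
                        treatment=TreatmentCode.from_string(trt),
                        gas=gas,
                        times=days.copy(),
                        mixing_ratios=ppmv,
                        headspace_volume=config.headspace_ml,
                        soil_dry_weight=config.soil_gdw,
                        temperature=config.temperature_k,
                        pressure=config.pressure_pa,
                    )
                )
    return series, truth


def _isotope_track(
    rate: float,
    f_h2: float,
    delta_ma: float,
    delta_mc: float,
    delta_co2: float,
    days: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> list[IsotopePoint]:
    """One microcosm's isotope series by exact incremental mass balance."""
    delta_new = f_h2 * delta_mc + (1.0 - f_h2) * delta_ma
    points: list[IsotopePoint] = []
    amount = 0.0
    delta_cum = 0.0
    for day in days:
        new_amount = rate * day
        if new_amount > 0.0:
            increment = new_amount - amount
            delta_cum = (amount * delta_cum + increment * delta_new) / new_amount
            amount = new_amount
            points.append(
                IsotopePoint(
                    time=float(day),
                    delta_ch4=delta_cum + rng.normal(0.0, noise_sd),
                    delta_co2=delta_co2 + rng.normal(0.0, noise_sd),
                    ch4_amount=amount,
                )
            )
    return points


def gen_isotope_series(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[dict[str, list[list[IsotopePoint]]], dict]:
    """Isotope time series per treatment (list of replicate tracks), with truth.

    New methane in every interval is split between the pathways by the
    configured hydrogenotrophic fraction; the cumulative delta13C-CH4 follows
    by exact mass balance and Gaussian permil noise is added to the reported
    deltas only.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    days = np.asarray(config.days, dtype=float)
    out: dict[str, list[list[IsotopePoint]]] = {}
    for trt in config.treatments:
        tracks = []
        for _ in range(config.replicates):
            tracks.append(
                _isotope_track(
                    config.true_rates[trt],
                    config.pathway_mix[trt],
                    config.delta_ma,
                    config.delta_mc,
                    config.delta_co2[trt],
                    days,
                    config.delta_noise_sd,
                    rng,
                )
            )
        out[trt] = tracks
    truth = {
        "pathway_mix": dict(config.pathway_mix),
        "delta_ma": config.delta_ma,
        "delta_mc": config.delta_mc,
        "delta_co2": dict(config.delta_co2),
    }
    return out, truth


def gen_ch3f_series(
    alpha: float = CH3F_ALPHA,
    delta_co2: float = -20.0,
    rate: float = 50.0,
    days: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0),
    noise_sd: float = 0.5,
    seed: int = 7,
) -> tuple[list[IsotopePoint], dict]:
    """Pure-hydrogenotrophic series emulating a CH3F-inhibited incubation.

    With acetoclastic methanogenesis chemically inhibited all methane forms
    from CO2 at fractionation ``alpha``, so the true end member is
    ``delta_mc = (delta_co2 + 1000)/alpha − 1000``.
    """
    if alpha <= 0:
        raise InvalidInputError("alpha must be > 0")
    rng = np.random.default_rng(seed)
    delta_mc = (delta_co2 + 1000.0) / alpha - 1000.0
    points = _isotope_track(
        rate, 1.0, 0.0, delta_mc, delta_co2, np.asarray(days, dtype=float), noise_sd, rng
    )
    return points, {"alpha_true": alpha, "delta_mc_true": delta_mc, "delta_co2": delta_co2}


def gen_oxygen_profiles(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[OxygenProfile], dict]:
    """Steady-state O2 profiles for every oxic/oxygenic microcosm, with truth.

    Each profile is the analytic forward solution of its treatment's zone
    preset plus additive Gaussian noise (clipped at zero, as a microsensor
    cannot read negative concentrations). Anoxic-dark treatments carry no O2
    profile.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    profiles: list[OxygenProfile] = []
    truth: dict = {"presets": {}, "noise_sd_fraction": config.profile_noise_sd_fraction}
    for trt in config.treatments:
        light = trt[1] == "L"
        oxic = trt[2] == "O"
        if not light and not oxic:
            continue  # strictly anoxic: no O2 to profile
        preset = O2_ZONE_PRESETS["light" if light else "dark_oxic"]
        edges = np.asarray(preset["edges_um"], dtype=float)
        rates = np.asarray(preset["rates"], dtype=float)
        top = float(preset["top_umol_l"])
        depths = np.arange(edges[0], edges[-1] + 0.5, preset["depth_step_um"])
        sol = solve_profile(edges, rates, top, DEFAULT_POROSITY, DEFAULT_DIFFUSIVITY_M2_S)
        clean = sol.concentration(depths)
        truth["presets"][trt] = {
            "edges_um": edges.tolist(),
            "rates": rates.tolist(),
            "top_umol_l": top,
            "surface_flux": sol.surface_flux,
        }
        for rep in range(1, config.replicates + 1):
            noisy = clean + rng.normal(0.0, config.profile_noise_sd_fraction * top, size=clean.size)
            profiles.append(
                OxygenProfile(
                    depths=depths.copy(),
                    concentrations=np.maximum(noisy, 0.0),
                    porosity=DEFAULT_POROSITY,
                    diffusivity=DEFAULT_DIFFUSIVITY_M2_S,
                    microcosm_id=f"{trt}-{rep}",
                    treatment=trt,
                )
            )
    return profiles, truth


def gen_qpcr_plate(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[QpcrRecord], dict]:
    """qPCR records for abundance assays and katE expression pairs, with truth.

    Abundance wells: Ct = intercept + slope*log10(true copies) + noise.
    Expression wells: per treatment a gene (DNA) and transcript (cDNA) well
    pair whose Delta-Ct offsets encode the configured fold-change presets.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    records: list[QpcrRecord] = []
    for assay, per_trt in TRUE_COPIES.items():
        for trt in config.treatments:
            copies = per_trt[trt]
            for rep in range(1, config.replicates + 1):
                ct = _CURVE_INTERCEPT + _CURVE_SLOPE * np.log10(copies) + rng.normal(
                    0.0, config.ct_noise_sd
                )
                records.append(
                    QpcrRecord(
                        assay=assay,
                        sample_id=f"{trt}-{rep}",
                        template="DNA",
                        replicate=rep,
                        ct=float(ct),
                        curve_slope=_CURVE_SLOPE,
                        curve_intercept=_CURVE_INTERCEPT,
                    )
                )
    # expression: encode the fold presets in Delta-Ct offsets
    base_delta_ct = 3.0  # transcript minus gene cycles in the first pair member
    for assay, pairs in KATE_FOLD_PRESETS.items():
        for (trt_a, trt_b), fold in pairs.items():
            for trt, dct in ((trt_a, base_delta_ct), (trt_b, base_delta_ct - np.log2(fold))):
                for rep in range(1, config.replicates + 1):
                    gene_ct = 24.0 + rng.normal(0.0, config.ct_noise_sd)
                    transcript_ct = gene_ct + dct + rng.normal(0.0, config.ct_noise_sd)
                    records.append(
                        QpcrRecord(
                            assay=f"{assay}-gene",
                            sample_id=f"{trt}-{rep}",
                            template="DNA",
                            replicate=rep,
                            ct=float(gene_ct),
                            curve_slope=_CURVE_SLOPE,
                            curve_intercept=_CURVE_INTERCEPT,
                        )
                    )
                    records.append(
                        QpcrRecord(
                            assay=f"{assay}-transcript",
                            sample_id=f"{trt}-{rep}",
                            template="cDNA",
                            replicate=rep,
                            ct=float(transcript_ct),
                            curve_slope=_CURVE_SLOPE,
                            curve_intercept=_CURVE_INTERCEPT,
                        )
                    )
    truth = {
        "true_copies": {a: dict(d) for a, d in TRUE_COPIES.items()},
        "fold_presets": {
            a: {f"{k[0]}-{k[1]}": v for k, v in d.items()} for a, d in KATE_FOLD_PRESETS.items()
        },
        "curve_slope": _CURVE_SLOPE,
        "curve_intercept": _CURVE_INTERCEPT,
        "ct_noise_sd": config.ct_noise_sd,
    }
    return records, truth


def write_inputs(out_dir: str | Path, config: GeneratorConfig | None = None) -> dict[str, Path]:
    """Emit the four pipeline input CSVs plus a ground-truth JSON sidecar.

    Floats are printed at fixed precision so repeated runs with the same
    config are byte-identical.
    """
    config = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gas, gas_truth = gen_gas_timeseries(config)
    gas_rows = []
    for s in gas:
        for day, ppmv in zip(s.times, s.mixing_ratios):
            gas_rows.append(
                {
                    "microcosm_id": s.microcosm_id,
                    "treatment": str(s.treatment),
                    "gas": s.gas,
                    "day": day,
                    "ppmv": ppmv,
                    "headspace_ml": s.headspace_volume,
                    "soil_gdw": s.soil_dry_weight,
                    "temp_k": s.temperature,
                    "pressure_pa": s.pressure,
                }
            )
    gas_path = out / "gas_timeseries.csv"
    pd.DataFrame(gas_rows).to_csv(gas_path, index=False, float_format="%.6g")

    iso, iso_truth = gen_isotope_series(config)
    iso_rows = []
    for trt, tracks in iso.items():
        for rep, track in enumerate(tracks, start=1):
            for p in track:
                iso_rows.append(
                    {
                        "microcosm_id": f"{trt}-{rep}",
                        "treatment": trt,
                        "day": p.time,
                        "delta_ch4": p.delta_ch4,
                        "delta_co2": p.delta_co2,
                        "ch4_nmol_gdw": p.ch4_amount,
                    }
                )
    iso_path = out / "isotopes.csv"
    pd.DataFrame(iso_rows).to_csv(iso_path, index=False, float_format="%.6g")

    profiles, o2_truth = gen_oxygen_profiles(config)
    o2_rows = []
    for prof in profiles:
        for depth, conc in zip(prof.depths, prof.concentrations):
            o2_rows.append(
                {
                    "microcosm_id": prof.microcosm_id,
                    "treatment": prof.treatment,
                    "depth_um": depth,
                    "conc_umol_l": conc,
                }
            )
    o2_path = out / "o2_profiles.csv"
    pd.DataFrame(o2_rows).to_csv(o2_path, index=False, float_format="%.6g")

    plate, qpcr_truth = gen_qpcr_plate(config)
    qpcr_rows = [
        {
            "assay": r.assay,
            "sample_id": r.sample_id,
            "treatment": r.sample_id.rsplit("-", 1)[0],
            "template": r.template,
            "replicate": r.replicate,
            "ct": r.ct,
            "curve_slope": r.curve_slope,
            "curve_intercept": r.curve_intercept,
            "dilution": 1.0,
            "gdw": 1.0,
        }
        for r in plate
    ]
    qpcr_path = out / "qpcr.csv"
    pd.DataFrame(qpcr_rows).to_csv(qpcr_path, index=False, float_format="%.6g")

    truth_path = out / "ground_truth.json"
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "gas": gas_truth,
        "isotopes": iso_truth,
        "oxygen": o2_truth,
        "qpcr": qpcr_truth,
    }
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {
        "gas_timeseries": gas_path,
        "isotopes": iso_path,
        "o2_profiles": o2_path,
        "qpcr": qpcr_path,
        "ground_truth": truth_path,
    }
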