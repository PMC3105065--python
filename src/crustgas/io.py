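"""Validated tabular IO and the end-to-end pipeline orchestration.

Readers are thin pandas wrappers that enforce a column schema up front
(missing columns, unparsable cells and duplicate keys abort with the
offending row numbers) so stage code can assume clean inputs. The
``run_pipeline`` entry point chains every stage over the four input CSVs
and writes per-stage tables plus one machine-readable summary JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from . import factorial_stats, gas_kinetics, isotopes, oxygen, qpcr, upscaling
from .errors import CrustGasError, SchemaError
from .gas_kinetics import GasTimeSeries, TreatmentCode
from .isotopes import EndMemberConfig, IsotopePoint
from .oxygen import OxygenProfile

log = logging.getLogger("crustgas")

__all__ = [
    "TableSchema",
    "GAS_SCHEMA",
    "ISOTOPE_SCHEMA",
    "O2_SCHEMA",
    "QPCR_SCHEMA",
    "RunConfig",
    "read_table",
    "run_pipeline",
]


@dataclass(frozen=True)
class TableSchema:
    """Column names with target dtypes, optional columns, and a uniqueness key."""

    name: str
    columns: dict[str, str]  # column -> 'str' | 'float' | 'int'
    key: tuple[str, ...] = ()
    optional: frozenset[str] = frozenset()


GAS_SCHEMA = TableSchema(
    name="gas_timeseries",
    columns={
        "microcosm_id": "str",
        "treatment": "str",
        "gas": "str",
        "day": "float",
        "ppmv": "float",
        "headspace_ml": "float",
        "soil_gdw": "float",
        "temp_k": "float",
        "pressure_pa": "float",
    },
    key=("microcosm_id", "day", "gas"),
    optional=frozenset({"temp_k", "pressure_pa"}),
)

ISOTOPE_SCHEMA = TableSchema(
    name="isotopes",
    columns={
        "microcosm_id": "str",
        "treatment": "str",
        "day": "float",
        "delta_ch4": "float",
        "delta_co2": "float",
        "ch4_nmol_gdw": "float",
    },
    key=("microcosm_id", "day"),
)

O2_SCHEMA = TableSchema(
    name="o2_profiles",
    columns={
        "microcosm_id": "str",
        "treatment": "str",
        "depth_um": "float",
        "conc_umol_l": "float",
    },
    key=("microcosm_id", "depth_um"),
)

QPCR_SCHEMA = TableSchema(
    name="qpcr",
    columns={
        "assay": "str",
        "sample_id": "str",
        "treatment": "str",
        "template": "str",
        "replicate": "int",
        "ct": "float",
        "curve_slope": "float",
        "curve_intercept": "float",
        "dilution": "float",
        "gdw": "float",
    },
    key=("assay", "sample_id", "template", "replicate"),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against ``schema``.

    Returns a DataFrame with a ``row`` column holding 1-based data row
    numbers for error reporting downstream.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.columns if c not in df.columns and c not in schema.optional]
    if missing:
        raise SchemaError(f"{schema.name}: missing required column(s) {missing}")
    df.insert(0, "row", np.arange(1, len(df) + 1))
    for col, kind in schema.columns.items():
        if col not in df.columns:
            df[col] = ""  # optional column entirely absent
            continue
        if kind == "str":
            continue
        blank = df[col].str.strip() == ""
        if blank.any() and col not in schema.optional:
            rows = df.loc[blank, "row"].tolist()
            raise SchemaError(f"{schema.name}: empty {col!r} cells at row(s) {rows}")
        converted = pd.to_numeric(df[col].where(~blank, None), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            rows = df.loc[bad, "row"].tolist()
            raise SchemaError(f"{schema.name}: unparsable {col!r} cells at row(s) {rows}")
        if kind == "int":
            converted = converted.astype("Int64")
        df[col] = converted
    if schema.key:
        dup = df.duplicated(subset=list(schema.key), keep=False)
        if dup.any():
            rows = df.loc[dup, "row"].tolist()
            raise SchemaError(
                f"{schema.name}: duplicate {schema.key} key at row(s) {rows}"
            )
    return df


def gas_series_from_table(df: pd.DataFrame) -> list[GasTimeSeries]:
    """Group a validated gas table into per-(microcosm, gas) time series.

    Missing temperature/pressure cells fall back to the package defaults
    (25 degC, 1 atm); the substitution is logged once per series.
    """
    out: list[GasTimeSeries] = []
    for (mid, gas), grp in df.groupby(["microcosm_id", "gas"], sort=True):
        grp = grp.sort_values("day")
        temp = grp["temp_k"].dropna()
        pres = grp["pressure_pa"].dropna()
        if temp.empty or pres.empty:
            log.info(
                "gas series %s/%s: applying default temperature/pressure", mid, gas
            )
        out.append(
            GasTimeSeries(
                microcosm_id=str(mid),
                treatment=TreatmentCode.from_string(str(grp["treatment"].iloc[0])),
                gas=str(gas),
                times=grp["day"].to_numpy(dtype=float),
                mixing_ratios=grp["ppmv"].to_numpy(dtype=float),
                headspace_volume=float(grp["headspace_ml"].iloc[0]),
                soil_dry_weight=float(grp["soil_gdw"].iloc[0]),
                temperature=float(temp.iloc[0]) if not temp.empty else gas_kinetics.DEFAULT_TEMPERATURE_K,
                pressure=float(pres.iloc[0]) if not pres.empty else gas_kinetics.DEFAULT_PRESSURE_PA,
            )
        )
    return out


@dataclass
class RunConfig:
    """Paths and per-stage knobs for an end-to-end run."""

    gas_csv: Path
    isotopes_csv: Path
    o2_csv: Path
    qpcr_csv: Path
    out_dir: Path
    rate_window: tuple[float, float] = gas_kinetics.FULL_WINDOW
    end_members: EndMemberConfig = field(default_factory=EndMemberConfig)
    acetate_scenarios: tuple[float, ...] = (0.0, -25.6)
    porosity: float = oxygen.DEFAULT_POROSITY
    diffusivity: float = oxygen.DEFAULT_DIFFUSIVITY_M2_S
    air_saturation: float = oxygen.AIR_SATURATION_UMOL_L
    max_zones: int = 3
    zone_alpha: float = 0.05
    expression_pairs: tuple[tuple[str, str], ...] = (
        ("FLN", "FLO"),
        ("WLN", "WLO"),
        ("FDN", "FDO"),
        ("WDN", "WDO"),
    )
    wet_weeks: tuple[float, ...] = (2.0, 7.0)
    crust_areal_density: float = upscaling.DEFAULT_CRUST_AREAL_DENSITY
    desert_area_km2: float = upscaling.DEFAULT_DESERT_AREA_KM2

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        em = raw.pop("end_members", {})
        kwargs = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("gas_csv", "isotopes_csv", "o2_csv", "qpcr_csv", "out_dir"):
            if key not in kwargs:
                raise SchemaError(f"run config: missing required key {key!r}")
            kwargs[key] = Path(kwargs[key])
        for tup_key in ("rate_window", "acetate_scenarios", "wet_weeks"):
            if tup_key in kwargs:
                kwargs[tup_key] = tuple(kwargs[tup_key])
        if "expression_pairs" in kwargs:
            kwargs["expression_pairs"] = tuple(tuple(p) for p in kwargs["expression_pairs"])
        cfg = cls(**kwargs)
        if em:
            cfg.end_members = EndMemberConfig(**em)
        return cfg


def _rates_stage(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    df = read_table(cfg.gas_csv, GAS_SCHEMA)
    series = gas_series_from_table(df)
    per_micro = []
    grouped: dict[str, list[gas_kinetics.RateEstimate]] = {}
    for s in series:
        if s.gas != "CH4":
            continue
        est = gas_kinetics.estimate_production_rate(
            gas_kinetics.amount_per_gdw_series(s), s.times, cfg.rate_window
        )
        grouped.setdefault(str(s.treatment), []).append(est)
        per_micro.append(
            {
                "microcosm_id": s.microcosm_id,
                "treatment": str(s.treatment),
                "rate_nmol_gdw_d": est.rate,
                "se_nmol_gdw_d": est.standard_error,
                "r_squared": est.r_squared,
                "n_points": est.n_points,
            }
        )
    summary = gas_kinetics.summarize_rates(grouped)
    log.info("rates stage: %d CH4 series -> %d treatments", len(per_micro), len(summary))
    return pd.DataFrame(per_micro), summary.reset_index().to_dict(orient="records")


def _isotope_stage(cfg: RunConfig) -> dict:
    df = read_table(cfg.isotopes_csv, ISOTOPE_SCHEMA)
    results: dict = {}
    for trt, grp in df.groupby("treatment", sort=True):
        alphas: list[float] = []
        new_deltas: list[float] = []
        for _, sub in grp.groupby("microcosm_id"):
            sub = sub.sort_values("day")
            points = [
                IsotopePoint(
                    time=float(r.day),
                    delta_ch4=float(r.delta_ch4),
                    delta_co2=float(r.delta_co2),
                    ch4_amount=float(r.ch4_nmol_gdw),
                )
                for r in sub.itertuples()
            ]
            alphas.extend(
                isotopes.apparent_fractionation(p.delta_co2, p.delta_ch4).alpha_app
                for p in points
            )
            new_deltas.extend(
                r.delta_new for r in isotopes.newly_formed_series(points)
            )
        alpha_mean = float(np.mean(alphas))
        mean_new_delta = float(np.mean(new_deltas)) if new_deltas else float("nan")
        partitions = {}
        for scen in cfg.acetate_scenarios:
            d_ma = isotopes.acetate_endmember(cfg.end_members.delta_organic, scen)
            part = isotopes.partition_pathways(
                mean_new_delta, d_ma, cfg.end_members.delta_mc
            )
            partitions[f"acetate_fractionation_{scen:g}"] = {
                "f_hydrogenotrophic": part.f_hydrogenotrophic,
                "f_acetoclastic": part.f_acetoclastic,
                "clamped": part.clamped,
                "raw_fraction": part.raw_fraction,
            }
        co2_frac, co2_clamped = isotopes.co2_source_fraction(
            float(grp["delta_co2"].mean()),
            cfg.end_members.delta_organic,
            cfg.end_members.delta_carbonate,
        )
        results[str(trt)] = {
            "alpha_app": alpha_mean,
            "epsilon_app_permil": isotopes.alpha_to_epsilon(alpha_mean),
            "mean_newly_formed_delta_permil": mean_new_delta,
            "partitions": partitions,
            "co2_fraction_from_carbonate": co2_frac,
            "co2_fraction_clamped": co2_clamped,
        }
    log.info("isotope stage: %d treatments", len(results))
    return results


def _oxygen_stage(cfg: RunConfig) -> dict:
    df = read_table(cfg.o2_csv, O2_SCHEMA)
    results: dict = {}
    for mid, grp in df.groupby("microcosm_id", sort=True):
        grp = grp.sort_values("depth_um")
        profile = OxygenProfile(
            depths=grp["depth_um"].to_numpy(dtype=float),
            concentrations=grp["conc_umol_l"].to_numpy(dtype=float),
            porosity=cfg.porosity,
            diffusivity=cfg.diffusivity,
            microcosm_id=str(mid),
            treatment=str(grp["treatment"].iloc[0]),
        )
        fit = oxygen.fit_production_zones(profile, cfg.max_zones, cfg.zone_alpha)
        boundary = oxygen.anoxic_boundary(profile, cfg.air_saturation)
        results[str(mid)] = {
            "treatment": profile.treatment,
            "n_zones": fit.n_zones,
            "zone_boundaries_um": fit.zone_boundaries.tolist(),
            "zone_rates_nmol_cm3_s": fit.zone_rates.tolist(),
            "surface_flux_nmol_cm2_s": fit.surface_flux,
            "sse": fit.sse,
            "selection_pvalue": fit.selection_pvalue,
            "nonphysical": fit.nonphysical,
            "anoxic_boundary_um": boundary.depth,
            "anoxic_boundary_reached": boundary.reached,
        }
    log.info("oxygen stage: %d profiles", len(results))
    return results


def _qpcr_stage(cfg: RunConfig) -> dict:
    df = read_table(cfg.qpcr_csv, QPCR_SCHEMA)
    results: dict = {"copies": {}, "expression": {}}
    expr_mask = df["assay"].str.endswith(("-gene", "-transcript"))
    for assay, grp in df[~expr_mask].groupby("assay", sort=True):
        per_trt = {}
        for trt, sub in grp.groupby("treatment", sort=True):
            vals = [
                qpcr.copies_from_ct(
                    float(r.ct),
                    float(r.curve_slope),
                    float(r.curve_intercept),
                    float(r.dilution),
                    float(r.gdw),
                ).copies_per_gdw
                for r in sub.itertuples()
            ]
            per_trt[str(trt)] = {
                "mean_copies_per_gdw": float(np.mean(vals)),
                "se_copies_per_gdw": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan"),
                "n": len(vals),
            }
        results["copies"][str(assay)] = per_trt
    # taxon-to-reference copy ratios (reference assays target whole communities)
    references = [a for a in results["copies"] if a in ("total-mcrA", "archaeal-16S")]
    taxa = [a for a in results["copies"] if a not in references]
    results["ratios"] = {}
    for taxon in taxa:
        for ref in references:
            per_trt_ratio = {}
            for trt, quant in results["copies"][taxon].items():
                ref_quant = results["copies"].get(ref, {}).get(trt)
                if ref_quant is None:
                    continue
                ratio, exceeds_one = qpcr.copy_ratio(
                    quant["mean_copies_per_gdw"], ref_quant["mean_copies_per_gdw"]
                )
                per_trt_ratio[trt] = {"ratio": ratio, "exceeds_one": exceeds_one}
            results["ratios"][f"{taxon}/{ref}"] = per_trt_ratio
    # relative expression per base assay and treatment pair
    expr = df[expr_mask].copy()
    if not expr.empty:
        expr["base_assay"] = expr["assay"].str.replace(r"-(gene|transcript)$", "", regex=True)
        expr["role"] = np.where(expr["assay"].str.endswith("-gene"), "gene", "transcript")
        for base, grp in expr.groupby("base_assay", sort=True):
            wide = grp.pivot_table(
                index=["treatment", "replicate"], columns="role", values="ct"
            )
            wide["delta_ct"] = wide["transcript"] - wide["gene"]
            per_pair = {}
            for trt_a, trt_b in cfg.expression_pairs:
                try:
                    dct_a = wide.loc[trt_a, "delta_ct"].sort_index().to_numpy()
                    dct_b = wide.loc[trt_b, "delta_ct"].sort_index().to_numpy()
                except KeyError:
                    continue
                rel = qpcr.delta_delta_ct(dct_a, dct_b, pair=(trt_a, trt_b))
                per_pair[f"{trt_a}-{trt_b}"] = {
                    "fold_change": rel.fold_change,
                    "standard_error": rel.standard_error,
                    "n_pairs": rel.n_pairs,
                }
            results["expression"][str(base)] = per_pair
    log.info(
        "qpcr stage: %d abundance assays, %d expression assays",
        len(results["copies"]),
        len(results["expression"]),
    )
    return results


def _write_qpcr_tables(qpcr_summary: dict, out: Path) -> None:
    """Flatten the qPCR stage results into copies/ratios/expression TSVs."""
    copies_rows = [
        {"assay": assay, "treatment": trt, **vals}
        for assay, per_trt in qpcr_summary.get("copies", {}).items()
        for trt, vals in per_trt.items()
    ]
    if copies_rows:
        pd.DataFrame(copies_rows).to_csv(
            out / "qpcr_copies.tsv", sep="\t", index=False, float_format="%.6g"
        )
    ratio_rows = [
        {"ratio_of": name, "treatment": trt, **vals}
        for name, per_trt in qpcr_summary.get("ratios", {}).items()
        for trt, vals in per_trt.items()
    ]
    if ratio_rows:
        pd.DataFrame(ratio_rows).to_csv(
            out / "qpcr_ratios.tsv", sep="\t", index=False, float_format="%.6g"
        )
    expr_rows = [
        {"assay": assay, "pair": pair, **vals}
        for assay, per_pair in qpcr_summary.get("expression", {}).items()
        for pair, vals in per_pair.items()
    ]
    if expr_rows:
        pd.DataFrame(expr_rows).to_csv(
            out / "qpcr_expression.tsv", sep="\t", index=False, float_format="%.6g"
        )


def _stats_stage(rates_per_micro: pd.DataFrame) -> dict:
    if rates_per_micro.empty:
        return {}
    df = rates_per_micro.copy()
    df["wetting"] = df["treatment"].str[0]
    df["light"] = df["treatment"].str[1]
    df["headspace"] = df["treatment"].str[2]
    out: dict = {}
    try:
        df["log_rate"] = factorial_stats.log_transform(df["rate_nmol_gdw_d"].to_numpy())
        table = factorial_stats.factorial_anova(
            factorial_stats.FactorialDataset.from_dataframe(df, "log_rate")
        )
        out["anova_log_ch4_rate"] = table.reset_index().to_dict(orient="records")
    except CrustGasError as exc:
        out["anova_log_ch4_rate"] = {"skipped": str(exc)}
    # light vs dark-oxic comparison on raw rates
    light = df.loc[df["light"] == "L", "rate_nmol_gdw_d"].to_numpy()
    dark_oxic = df.loc[(df["light"] == "D") & (df["headspace"] == "O"), "rate_nmol_gdw_d"].to_numpy()
    if light.size >= 2 and dark_oxic.size >= 2:
        t, dof, p = factorial_stats.welch_t_test(light, dark_oxic)
        out["light_vs_dark_oxic_t_test"] = {"t": t, "df": dof, "p": p}
    return out


def _upscale_stage(cfg: RunConfig, rate_summary: list[dict]) -> dict:
    oxic = [
        r
        for r in rate_summary
        if TreatmentCode.from_string(r["treatment"]).is_oxic_or_oxygenic
    ]
    if not oxic:
        return {}
    mean_rate = float(np.mean([r["mean_rate_nmol_gdw_d"] for r in oxic]))
    grid = upscaling.scenario_grid(
        mean_rate, cfg.wet_weeks, cfg.crust_areal_density, cfg.desert_area_km2
    )
    return {
        "oxic_oxygenic_mean_rate_nmol_gdw_d": mean_rate,
        "scenarios": grid.to_dict(orient="records"),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and write per-stage outputs plus a summary.

    Returns the summary dict (also written to ``out_dir/summary.json``).
    Stage failures propagate as :class:`CrustGasError` with the stage name
    prepended.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "gas_kinetics"
    try:
        per_micro, rate_summary = _rates_stage(cfg)
        per_micro.to_csv(out / "rates_per_microcosm.tsv", sep="\t", index=False, float_format="%.6g")
        summary["rates"] = {"per_treatment": rate_summary, "window_days": list(cfg.rate_window)}
        stage = "isotope_partitioning"
        summary["isotopes"] = _isotope_stage(cfg)
        stage = "oxygen_profiles"
        summary["oxygen"] = _oxygen_stage(cfg)
        stage = "qpcr_quant"
        summary["qpcr"] = _qpcr_stage(cfg)
        _write_qpcr_tables(summary["qpcr"], out)
        stage = "factorial_stats"
        summary["stats"] = _stats_stage(per_micro)
        anova = summary["stats"].get("anova_log_ch4_rate")
        if isinstance(anova, list):
            pd.DataFrame(anova).to_csv(
                out / "anova_log_ch4_rate.tsv", sep="\t", index=False, float_format="%.6g"
            )
        stage = "upscaling"
        summary["upscaling"] = _upscale_stage(cfg, rate_summary)
    except CrustGasError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    (out / "summary.json").write_text(json.dumps(_round_floats(summary, 6), indent=2, sort_keys=True))
    return summary


def _round_floats(obj, sig: int):
    """Round floats to ``sig`` significant digits for stable golden files."""
    if isinstance(obj, float):
        if obj == 0 or not np.isfinite(obj):
            return obj
        from math import floor, log10

        return round(obj, -int(floor(log10(abs(obj)))) + sig - 1)
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj
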