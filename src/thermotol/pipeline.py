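"""Orchestration: simulate -> analyze -> report.

Ties the generator and the two analysis engines together behind a single
seeded configuration, producing machine-parseable TSV/CSV reports shaped
like the study's summary tables:

* a tolerance report (one row per randomization-test comparison per assay,
  with group medians and bootstrap CIs),
* a viability report (quasi-binomial model comparison block plus the
  per-temperature randomization-test block and a fitted-curve export),
* a microclimate summary (per-sensor means, daily amplitudes, heap-vs-air
  offsets),
* an arithmetic-identity check over the published medians and differences.

Every stage derives its own seed from the master seed with a stable hash,
so reports are byte-identical across runs of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults as _defaults
from . import synthetic, viability
from .errors import ConfigError
from .resampling import bootstrap_median_ci, randomization_test
from .synthetic import ASSAY_UNITS, GroupSpec, TemperatureLogSpec, ViabilityCurveSpec

__all__ = [
    "AnalysisConfig",
    "derive_seed",
    "load_config",
    "run_tolerance_analysis",
    "run_viability_analysis",
    "summarize_microclimate",
    "verify_printed_identities",
    "run_all",
]

logger = logging.getLogger(__name__)

#: (assay-restricted) comparison plan: Md_a-b within the given stratifier
_RAMPING_ASSAYS = ("heat_ramp", "cold_ramp")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class AnalysisConfig:
    """Full description of one pipeline run.

    When ``tolerance_path`` / ``viability_path`` are set, data are read from
    those CSVs; otherwise they are generated from the spec lists (defaults:
    the shipped study-calibrated specs).
    """

    seed: int = 0
    n_perm: int = 100_000
    n_boot: int = 10_000
    ci_level: float = 0.95
    benign_temps: tuple[float, ...] = (20.0, 25.0)
    out_dir: str | Path | None = None
    tolerance_specs: tuple[GroupSpec, ...] = field(
        default_factory=lambda: tuple(_defaults.default_tolerance_specs())
    )
    viability_specs: tuple[ViabilityCurveSpec, ...] = field(
        default_factory=lambda: tuple(_defaults.default_viability_specs())
    )
    templog_spec: TemperatureLogSpec = field(
        default_factory=_defaults.default_templog_spec
    )
    tolerance_path: str | Path | None = None
    viability_path: str | Path | None = None
    templog_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigError("n_perm and n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must be in (0, 1)")

    def fast(self) -> "AnalysisConfig":
        """Reduced resampling budgets (n_perm 5,000; n_boot 1,000)."""
        return replace(self, n_perm=5_000, n_boot=1_000)


def load_config(path: str | Path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a JSON or YAML file.

    Recognized top-level keys: ``seed, n_perm, n_boot, ci_level,
    benign_temps, out_dir, tolerance_path, viability_path, templog_path``,
    plus generator overrides ``tolerance_groups`` (list of GroupSpec
    fields), ``viability_curves`` (list of ViabilityCurveSpec fields) and
    ``temperature_log`` (TemperatureLogSpec fields).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    kwargs: dict = {}
    for key in ("seed", "n_perm", "n_boot", "ci_level", "out_dir",
                "tolerance_path", "viability_path", "templog_path"):
        if key in raw:
            kwargs[key] = raw[key]
    if "benign_temps" in raw:
        kwargs["benign_temps"] = tuple(float(t) for t in raw["benign_temps"])
    if "tolerance_groups" in raw:
        kwargs["tolerance_specs"] = tuple(
            GroupSpec(**g) for g in raw["tolerance_groups"]
        )
    if "viability_curves" in raw:
        kwargs["viability_specs"] = tuple(
            ViabilityCurveSpec(
                **{**c, "coefficients": tuple(c["coefficients"]),
                   **({"temperatures": tuple(c["temperatures"])}
                      if "temperatures" in c else {})}
            )
            for c in raw["viability_curves"]
        )
    if "temperature_log" in raw:
        kwargs["templog_spec"] = TemperatureLogSpec(**raw["temperature_log"])
    return AnalysisConfig(**kwargs)


def _tolerance_data(config: AnalysisConfig) -> pd.DataFrame:
    if config.tolerance_path is not None:
        return pd.read_csv(config.tolerance_path)
    return synthetic.generate_tolerance_data(
        list(config.tolerance_specs), derive_seed(config.seed, "tolerance_data")
    )


def _viability_data(config: AnalysisConfig) -> pd.DataFrame:
    if config.viability_path is not None:
        return pd.read_csv(config.viability_path)
    frames = [
        synthetic.generate_viability_data(
            spec, derive_seed(config.seed, f"viability_data:{spec.treatment}")
        )
        for spec in config.viability_specs
    ]
    return pd.concat(frames, ignore_index=True)


def _comparison_plan(data: pd.DataFrame) -> list[tuple[str, str, dict, dict]]:
    """All configured comparisons as (assay, label, selector_a, selector_b)."""
    plan = []
    for assay in sorted(data["assay"].unique()):
        sub = data.loc[data["assay"] == assay]
        treatments = set(sub["treatment"])
        sexes = sorted(set(sub["sex"]))
        for sex in sexes:
            plan.append(
                (assay, f"lab25-field/{sex}",
                 {"treatment": "lab25", "sex": sex},
                 {"treatment": "field", "sex": sex})
            )
        for treatment in ("field", "lab25"):
            if treatment in treatments:
                plan.append(
                    (assay, f"male-female/{treatment}",
                     {"treatment": treatment, "sex": "male"},
                     {"treatment": treatment, "sex": "female"})
                )
        if assay in _RAMPING_ASSAYS and "lab13" in treatments:
            for sex in sexes:
                plan.append(
                    (assay, f"lab13-field/{sex}",
                     {"treatment": "lab13", "sex": sex},
                     {"treatment": "field", "sex": sex})
                )
                plan.append(
                    (assay, f"lab13-lab25/{sex}",
                     {"treatment": "lab13", "sex": sex},
                     {"treatment": "lab25", "sex": sex})
                )
    return plan


def _select(data: pd.DataFrame, assay: str, sel: dict) -> np.ndarray:
    mask = data["assay"] == assay
    for col, val in sel.items():
        mask &= data[col] == val
    return data.loc[mask, "value"].to_numpy(dtype=float)


def run_tolerance_analysis(
    config: AnalysisConfig, data: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Run all configured tolerance comparisons.

    For each assay: lab25 vs field within each sex, male vs female within
    the field and lab25 treatments, and — for the ramping assays, when
    13 deg C-reared flies are present — lab13 vs field and lab13 vs lab25
    within each sex. Every comparison is a difference-in-medians
    randomization test; every group median carries a percentile bootstrap
    CI. Missing groups are reported as untestable rows rather than aborting
    the run.
    """
    if data is None:
        data = _tolerance_data(config)
    ci_cache: dict[tuple, tuple] = {}

    def group_ci(assay, sel, values):
        key = (assay, tuple(sorted(sel.items())))
        if key not in ci_cache:
            ci = bootstrap_median_ci(
                values,
                n_boot=config.n_boot,
                level=config.ci_level,
                seed=derive_seed(config.seed, f"boot:{key}"),
            )
            ci_cache[key] = (ci.median, ci.lower, ci.upper)
        return ci_cache[key]

    rows = []
    for assay, label, sel_a, sel_b in _comparison_plan(data):
        a = _select(data, assay, sel_a)
        b = _select(data, assay, sel_b)
        row = {
            "assay": assay,
            "units": ASSAY_UNITS[assay],
            "comparison": label,
            "n_a": int(a.size),
            "n_b": int(b.size),
        }
        if a.size < 2 or b.size < 2:
            logger.warning("untestable comparison %s/%s: missing group", assay, label)
            rows.append({**row, "status": "untestable"})
            continue
        res = randomization_test(
            a, b, n_perm=config.n_perm,
            seed=derive_seed(config.seed, f"perm:{assay}:{label}"),
        )
        med_a, lo_a, hi_a = group_ci(assay, sel_a, a)
        med_b, lo_b, hi_b = group_ci(assay, sel_b, b)
        rows.append(
            {
                **row,
                "md_a": med_a, "ci_a_lower": lo_a, "ci_a_upper": hi_a,
                "md_b": med_b, "ci_b_lower": lo_b, "ci_b_upper": hi_b,
                "md_diff": res.md_diff,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "exact": res.exact,
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)


def run_viability_analysis(
    config: AnalysisConfig, data: pd.DataFrame | None = None
) -> dict:
    """Fit the viability models and run the standardized per-temperature tests.

    Returns a dict with the full/reduced/null fits, the full-vs-null and
    interaction F-tests, the standardized vial table, the per-temperature
    randomization-test table and a fitted-curve export (temperature grid,
    fitted probability, standardized fitted value per treatment).
    """
    if data is None:
        data = _viability_data(config)
    full = viability.fit_quasibinomial_cubic(data, with_interaction=True)
    reduced = viability.fit_quasibinomial_cubic(data, with_interaction=False)
    null = viability.fit_intercept_only(data)
    f_interaction = viability.f_test_nested(full, reduced)
    f_full_vs_null = viability.f_test_nested(full, null)

    standardized = viability.standardize_viability(data, config.benign_temps)
    per_temp = viability.per_temperature_tests(
        standardized,
        n_perm=config.n_perm,
        seed=derive_seed(config.seed, "viability_per_temp"),
    )

    grid = np.round(np.arange(11.0, 33.0 + 1e-9, 0.25), 2)
    curve_rows = []
    benign = set(float(t) for t in config.benign_temps)
    for treatment in full.treatments:
        p_grid = full.predict(grid, treatment)
        p_benign = full.predict(sorted(benign), treatment)
        rel = p_grid / p_benign.mean()
        for t, p, r in zip(grid, p_grid, rel):
            curve_rows.append(
                {"treatment": treatment, "temperature": t,
                 "fitted_probability": p, "standardized_fitted": r}
            )
    curves = pd.DataFrame(curve_rows)

    model_comparison = pd.DataFrame(
        [
            {
                "test": "full_vs_null",
                "f_stat": f_full_vs_null.f_stat,
                "df_num": f_full_vs_null.df_num,
                "df_den": f_full_vs_null.df_den,
                "p_value": f_full_vs_null.p_value,
                "dispersion_phi": full.dispersion_phi,
            },
            {
                "test": "interaction",
                "f_stat": f_interaction.f_stat,
                "df_num": f_interaction.df_num,
                "df_den": f_interaction.df_den,
                "p_value": f_interaction.p_value,
                "dispersion_phi": full.dispersion_phi,
            },
        ]
    )
    return {
        "full_fit": full,
        "reduced_fit": reduced,
        "null_fit": null,
        "f_interaction": f_interaction,
        "f_full_vs_null": f_full_vs_null,
        "model_comparison": model_comparison,
        "standardized": standardized,
        "per_temperature": per_temp,
        "fitted_curves": curves,
    }


def summarize_microclimate(log: pd.DataFrame) -> pd.DataFrame:
    """Per-sensor summary over whole logging days.

    Keeps only dates with a complete set of readings for every sensor, then
    reports per-sensor mean temperature, mean daily amplitude (daily max
    minus min averaged over days) and mean offset from the air sensor.
    """
    required = {"timestamp", "sensor", "temp_c"}
    if not required <= set(log.columns):
        raise ValueError(f"log must have columns {sorted(required)}")
    df = log.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.date
    # a whole day has all readings implied by the sampling cadence, for
    # every sensor; the cadence is inferred from consecutive timestamps
    step = ts.loc[df["sensor"] == df["sensor"].iloc[0]].diff().dropna().min()
    expected = int(pd.Timedelta(days=1) / step)
    counts = df.groupby(["sensor", "date"]).size()
    per_day = counts.groupby("date").min()
    whole_days = per_day.index[per_day >= expected]
    if len(whole_days) < 1:
        raise ValueError("need at least one whole day of records per sensor")
    df = df.loc[df["date"].isin(set(whole_days))]

    rows = []
    air_mean = float(df.loc[df["sensor"] == "air", "temp_c"].mean())
    for sensor, grp in df.groupby("sensor", sort=True):
        daily = grp.groupby("date")["temp_c"]
        rows.append(
            {
                "sensor": sensor,
                "n_days": int(len(whole_days)),
                "mean_temp": float(grp["temp_c"].mean()),
                "daily_amplitude": float((daily.max() - daily.min()).mean()),
                "offset_vs_air": float(grp["temp_c"].mean()) - air_mean,
            }
        )
    return pd.DataFrame(rows)


def verify_printed_identities(literals: dict | None = None) -> pd.DataFrame:
    """Check the arithmetic identities among the published medians and diffs.

    The published group medians and median differences are mutually
    redundant (e.g. the lab25-minus-field CTmin difference must equal the
    difference of the printed group medians); each identity is recomputed
    from its components and compared with the printed value at 1e-9.
    """
    lit = _defaults.PUBLISHED if literals is None else literals
    ctmin = lit["ctmin_median"]
    d25 = lit["md_lab25_field"]
    d13f = lit["md_lab13_field"]
    d1325 = lit["md_lab13_lab25"]
    sex = lit["md_males_females"]
    checks = [
        ("cold_ramp_female_lab25_minus_field",
         ctmin[("lab25", "female")] - ctmin[("field", "female")],
         d25[("cold_ramp", "female")]),
        ("cold_ramp_male_lab25_minus_field",
         ctmin[("lab25", "male")] - ctmin[("field", "male")],
         d25[("cold_ramp", "male")]),
        ("cold_ramp_field_male_minus_female",
         ctmin[("field", "male")] - ctmin[("field", "female")],
         sex[("cold_ramp", "field")]),
        ("cold_ramp_female_lab13_consistency",
         d13f[("cold_ramp", "female")] + ctmin[("field", "female")]
         - ctmin[("lab25", "female")],
         d1325[("cold_ramp", "female")]),
        ("cold_ramp_male_lab13_consistency",
         d13f[("cold_ramp", "male")] + ctmin[("field", "male")]
         - ctmin[("lab25", "male")],
         d1325[("cold_ramp", "male")]),
        ("heat_ramp_female_lab13_consistency",
         d13f[("heat_ramp", "female")] - d25[("heat_ramp", "female")],
         d1325[("heat_ramp", "female")]),
        ("heat_ramp_male_lab13_consistency",
         d13f[("heat_ramp", "male")] - d25[("heat_ramp", "male")],
         d1325[("heat_ramp", "male")]),
    ]
    rows = [
        {
            "identity": name,
            "computed": computed,
            "expected": expected,
            "abs_error": abs(computed - expected),
            "passed": abs(computed - expected) <= 1e-9,
        }
        for name, computed, expected in checks
    ]
    return pd.DataFrame(rows)


def run_all(config: AnalysisConfig) -> dict:
    """Simulate every stream, run both analyses, verify identities.

    When ``config.out_dir`` is set, writes the simulated CSVs and all
    report tables there. Returns the in-memory results dict. Raises
    :class:`ThermotolError` subclasses on failure; a failed printed-identity
    check raises ``ValueError``.
    """
    t0 = time.perf_counter()
    tolerance_data = _tolerance_data(config)
    viability_data = _viability_data(config)
    templog = (
        pd.read_csv(config.templog_path)
        if config.templog_path is not None
        else synthetic.generate_temperature_log(
            config.templog_spec, derive_seed(config.seed, "templog")
        )
    )
    logger.info("simulated inputs in %.2fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    tolerance_report = run_tolerance_analysis(config, tolerance_data)
    logger.info("tolerance analysis in %.2fs", time.perf_counter() - t1)

    t2 = time.perf_counter()
    viability_report = run_viability_analysis(config, viability_data)
    logger.info("viability analysis in %.2fs", time.perf_counter() - t2)

    microclimate = summarize_microclimate(templog)
    identities = verify_printed_identities()
    if not identities["passed"].all():
        raise ValueError(
            "printed-identity check failed:\n"
            + identities.loc[~identities["passed"]].to_string(index=False)
        )

    results = {
        "tolerance_data": tolerance_data,
        "viability_data": viability_data,
        "templog": templog,
        "tolerance_report": tolerance_report,
        "viability": viability_report,
        "microclimate": microclimate,
        "identities": identities,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tolerance_data.to_csv(out / "tolerance_data.csv", index=False)
        viability_data.to_csv(out / "viability_data.csv", index=False)
        templog.to_csv(out / "temperature_log.csv", index=False)
        tolerance_report.to_csv(out / "tolerance_report.tsv", sep="\t", index=False)
        viability_report["model_comparison"].to_csv(
            out / "viability_model_comparison.tsv", sep="\t", index=False
        )
        viability_report["per_temperature"].to_csv(
            out / "viability_per_temperature.tsv", sep="\t", index=False
        )
        viability_report["fitted_curves"].to_csv(
            out / "viability_fitted_curves.csv", index=False
        )
        microclimate.to_csv(out / "microclimate_summary.tsv", sep="\t", index=False)
        identities.to_csv(out / "printed_identities.tsv", sep="\t", index=False)
    return results
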