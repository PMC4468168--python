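"""Synthetic assay data with the statistical structure the analysis assumes.

Three generators, one per data stream:

* :func:`generate_tolerance_data` — individual thermal-tolerance scores
  (knockdown time, 2 h chill-coma recovery time, CTmin, CTmax) per
  treatment x sex group, drawn from a location-shifted gamma family so that
  each group has a configurable median, spread and skew. Real tolerance
  data violate normality and homoscedasticity; the generator reproduces
  exactly those violations.
* :func:`generate_viability_data` — egg-to-adult viability vials
  (eggs set, adults emerged) on a cubic-logistic thermal performance curve
  with beta-binomial (intra-vial correlation) overdispersion.
* :func:`generate_temperature_log` — half-hourly microhabitat logger
  traces: a sinusoidal daily air-temperature cycle plus compost-heap
  sensors offset above air temperature with damped daily amplitude,
  mimicking the fermentation-heated overwintering habitat.

All generators are deterministic for a fixed (spec, seed) pair and return
tidy :class:`pandas.DataFrame` objects matching the CSV schemas used by the
rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ConfigError

__all__ = [
    "TREATMENTS",
    "SEXES",
    "ASSAYS",
    "ASSAY_UNITS",
    "GroupSpec",
    "ViabilityCurveSpec",
    "TemperatureLogSpec",
    "generate_tolerance_data",
    "generate_viability_data",
    "generate_temperature_log",
    "cubic_logistic_probability",
]

TREATMENTS = ("field", "lab25", "lab13")
SEXES = ("male", "female")
ASSAYS = ("heat_knockdown", "heat_ramp", "ccr2h", "cold_ramp")

#: measurement unit per assay: times in minutes, ramp endpoints in deg C
ASSAY_UNITS = {
    "heat_knockdown": "min",
    "heat_ramp": "degC",
    "ccr2h": "min",
    "cold_ramp": "degC",
}


@dataclass(frozen=True)
class GroupSpec:
    """One treatment x sex x assay group of individually scored flies.

    ``target_median`` is the population median of the generated scores
    (minutes for the time assays, deg C for the ramping assays); ``spread``
    is the population standard deviation and ``skew`` the population
    skewness of the location-shifted gamma family used for sampling
    (``skew = 0`` falls back to a normal distribution, ``spread = 0`` to a
    degenerate constant sample).
    """

    treatment: str
    sex: str
    assay: str
    target_median: float
    spread: float
    skew: float = 0.0
    n: int = 25

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ConfigError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.sex not in SEXES:
            raise ConfigError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.assay not in ASSAYS:
            raise ConfigError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if not np.isfinite(self.target_median):
            raise ConfigError("target_median must be finite")
        if not self.spread >= 0:
            raise ConfigError(f"spread must be >= 0, got {self.spread}")
        if self.n < 2:
            raise ConfigError(f"n must be >= 2, got {self.n}")

    @property
    def units(self) -> str:
        return ASSAY_UNITS[self.assay]


def _sample_skewed(rng: np.random.Generator, spec: GroupSpec) -> np.ndarray:
    """Draw ``spec.n`` values with the requested median, sd and skewness.

    Shifted gamma family: for skewness g != 0 use a gamma with shape
    k = (2/|g|)^2 (gamma skewness is 2/sqrt(k)), scaled to sd ``spread``,
    sign-flipped for g < 0, and re-centered so the *population median*
    equals ``target_median`` exactly.
    """
    if spec.spread == 0.0:
        return np.full(spec.n, float(spec.target_median))
    if spec.skew == 0.0:
        return rng.normal(spec.target_median, spec.spread, size=spec.n)
    shape = (2.0 / abs(spec.skew)) ** 2
    scale = spec.spread / np.sqrt(shape)  # gamma sd = sqrt(shape) * scale
    gmed = stats.gamma.ppf(0.5, shape, scale=scale)
    draws = rng.gamma(shape, scale, size=spec.n)
    signed = np.sign(spec.skew) * (draws - gmed)
    return spec.target_median + signed


def generate_tolerance_data(specs: Sequence[GroupSpec], seed) -> pd.DataFrame:
    """Generate individual tolerance scores for a list of group specs.

    Returns a long-format frame with columns
    ``fly_id, treatment, sex, assay, value`` — one row per fly — drawn in
    spec order from a single seeded stream (same (specs, seed) gives
    byte-identical CSV output).
    """
    if len(specs) == 0:
        raise ConfigError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        values = _sample_skewed(rng, spec)
        ids = [
            f"{spec.treatment}_{spec.sex}_{spec.assay}_{i + 1:03d}"
            for i in range(spec.n)
        ]
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": ids,
                    "treatment": spec.treatment,
                    "sex": spec.sex,
                    "assay": spec.assay,
                    "value": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: default developmental temperatures (deg C) of the viability design
DEFAULT_TEMPERATURES = (11.0, 14.0, 17.0, 20.0, 25.0, 27.0, 29.0, 31.0, 32.0, 33.0)


def _zscore(temps: np.ndarray, center: float, scale: float) -> np.ndarray:
    return (np.asarray(temps, dtype=float) - center) / scale


def cubic_logistic_probability(
    temperatures, coefficients, center: float, scale: float
) -> np.ndarray:
    """Viability probability on a cubic logit curve of standardized temperature.

    ``logit p = b0 + b1 z + b2 z^2 + b3 z^3`` with ``z = (T - center)/scale``.
    """
    b = np.asarray(coefficients, dtype=float)
    if b.shape != (4,):
        raise ConfigError("coefficients must be a 4-vector (b0..b3)")
    z = _zscore(np.asarray(temperatures, dtype=float), center, scale)
    return expit(b[0] + b[1] * z + b[2] * z**2 + b[3] * z**3)


@dataclass(frozen=True)
class ViabilityCurveSpec:
    """Egg-to-adult viability design for one parental treatment.

    ``coefficients`` are logit-scale cubic coefficients for the
    centered/scaled temperature ``z = (T - temp_center)/temp_scale``;
    by default the centering uses the mean/sd of ``temperatures`` so the
    generator and the fitted model share the same standardization.
    ``overdispersion_rho`` is the beta-binomial intra-vial correlation:
    the variance of a vial's count is inflated over binomial by the factor
    ``1 + (eggs_per_vial - 1) * rho``; ``rho = 0`` is exact binomial
    sampling.
    """

    treatment: str
    coefficients: tuple[float, float, float, float]
    overdispersion_rho: float = 0.0
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    vials_per_temp: int = 20
    eggs_per_vial: int = 20
    temp_center: float | None = None
    temp_scale: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in ("field", "lab25"):
            raise ConfigError(
                f"viability treatment must be 'field' or 'lab25', got {self.treatment!r}"
            )
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (4,) or not np.all(np.isfinite(coeffs)):
            raise ConfigError("coefficients must be 4 finite logit-scale values")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ConfigError(
                f"overdispersion_rho must be in [0, 1), got {self.overdispersion_rho}"
            )
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size < 2 or np.any(np.diff(temps) <= 0):
            raise ConfigError("temperatures must be strictly increasing")
        if self.vials_per_temp < 1:
            raise ConfigError("vials_per_temp must be >= 1")
        if self.eggs_per_vial < 1:
            raise ConfigError("eggs_per_vial must be >= 1")

    @property
    def standardization(self) -> tuple[float, float]:
        """(center, scale) of the temperature standardization."""
        temps = np.asarray(self.temperatures, dtype=float)
        center = float(temps.mean()) if self.temp_center is None else self.temp_center
        scale = float(temps.std()) if self.temp_scale is None else self.temp_scale
        return center, scale

    def probabilities(self) -> np.ndarray:
        """True viability probability at each design temperature."""
        center, scale = self.standardization
        return cubic_logistic_probability(
            self.temperatures, self.coefficients, center, scale
        )


def generate_viability_data(spec: ViabilityCurveSpec, seed) -> pd.DataFrame:
    """Generate viability vials for one treatment.

    Returns one row per vial with columns
    ``vial_id, treatment, temperature, eggs_set, adults_emerged``. With
    ``rho > 0`` each vial's success probability is drawn from a
    Beta(p(1-rho)/rho, (1-p)(1-rho)/rho) before binomial sampling
    (beta-binomial counts); with ``rho = 0`` counts are exactly binomial.
    """
    rng = np.random.default_rng(seed)
    probs = spec.probabilities()
    rho = spec.overdispersion_rho
    rows = []
    for temp, p in zip(spec.temperatures, probs):
        m = spec.vials_per_temp
        if rho > 0.0 and 0.0 < p < 1.0:
            a = p * (1.0 - rho) / rho
            b = (1.0 - p) * (1.0 - rho) / rho
            p_vial = rng.beta(a, b, size=m)
        else:
            p_vial = np.full(m, p)
        counts = rng.binomial(spec.eggs_per_vial, p_vial)
        for j, c in enumerate(counts):
            rows.append(
                (
                    f"{spec.treatment}_T{temp:g}_v{j + 1:02d}",
                    spec.treatment,
                    float(temp),
                    spec.eggs_per_vial,
                    int(c),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["vial_id", "treatment", "temperature", "eggs_set", "adults_emerged"],
    )


@dataclass(frozen=True)
class TemperatureLogSpec:
    """Microhabitat logger simulation: one air and two compost-heap sensors.

    Air temperature follows ``air_mean + air_daily_amplitude *
    sin(2 pi (h - 9)/24)`` (daily peak mid-afternoon). Each heap sensor adds
    ``heap_offset`` (fermentation heating, ~8 deg C above air in early
    winter) and multiplies the daily sinusoid by its ``amplitude_damping``
    factor (thermal buffering, stronger at depth). Gaussian noise of sd
    ``noise_sd`` is added per reading, then readings are quantized to
    0.1 deg C, mimicking logger resolution.
    """

    start: str | datetime
    end: str | datetime
    interval_minutes: int = 30
    air_mean: float = 2.0
    air_daily_amplitude: float = 4.0
    heap_offset: float = 8.0
    amplitude_damping: Mapping[str, float] = field(
        default_factory=lambda: {"heap_top": 0.35, "heap_bottom": 0.12}
    )
    noise_sd: float = 0.0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.interval_minutes < 1 or (24 * 60) % self.interval_minutes != 0:
            raise ConfigError("interval_minutes must divide a day evenly")
        start, end = self.period
        if end <= start:
            raise ConfigError("end must be after start")
        for sensor, d in self.amplitude_damping.items():
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"amplitude_damping[{sensor!r}] must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    @property
    def period(self) -> tuple[datetime, datetime]:
        def _dt(x):
            return datetime.fromisoformat(x) if isinstance(x, str) else x

        return _dt(self.start), _dt(self.end)


def generate_temperature_log(spec: TemperatureLogSpec, seed) -> pd.DataFrame:
    """Generate logger traces with columns ``timestamp, sensor, temp_c``.

    ``timestamp`` is ISO-8601; sensors are ``air`` plus the keys of
    ``spec.amplitude_damping``; the sampling interval is
    ``spec.interval_minutes``, half-hourly by default.
    """
    rng = np.random.default_rng(seed)
    start, end = spec.period
    step = timedelta(minutes=spec.interval_minutes)
    n_steps = int((end - start) / step)
    times = [start + i * step for i in range(n_steps + 1)]
    hours = np.array(
        [(t - start.replace(hour=0, minute=0, second=0, microsecond=0)).total_seconds() / 3600.0
         for t in times]
    )
    daily = np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)

    frames = []
    sensors = {"air": (0.0, 1.0)}
    sensors.update(
        {name: (spec.heap_offset, d) for name, d in spec.amplitude_damping.items()}
    )
    for sensor, (offset, damping) in sensors.items():
        trace = spec.air_mean + offset + damping * spec.air_daily_amplitude * daily
        if spec.noise_sd > 0:
            trace = trace + rng.normal(0.0, spec.noise_sd, size=trace.shape)
        if spec.quantize:
            trace = np.round(trace * 10.0) / 10.0
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": [t.isoformat() for t in times],
                    "sensor": sensor,
                    "temp_c": trace,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
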