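"""Thermal-performance-curve analysis of egg-to-adult viability.

Egg-to-adult viability across constant developmental temperatures is
modelled as a grouped-binomial (vial-level) logistic regression with
temperature entering as a cubic polynomial of the centered/scaled
temperature, a parental-treatment indicator and, in the full model, the
treatment x polynomial interaction:

    logit p = b0 + b1 z + b2 z^2 + b3 z^3
              [+ g0 t + g1 t z + g2 t z^2 + g3 t z^3]

with ``z = (T - mean(T)) / sd(T)`` over the vials entering the fit and
``t`` the treatment indicator. Extra-binomial variation among vials
(overdispersion) is handled quasi-likelihood style: point estimates are the
ordinary binomial IRLS fit, standard errors are scaled by ``sqrt(phi)`` and
model comparisons use F-tests with ``phi = Pearson chi^2 / df_resid`` of the
full model in the denominator.

Curve *shape* comparisons use benign-temperature standardization: each
vial's proportion is divided by its treatment's mean proportion at the
benign temperatures (20 and 25 deg C by default), after which treatments
are compared at every non-benign temperature with the difference-in-medians
randomization test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, FittingError
from .resampling import PermutationResult, randomization_test

__all__ = [
    "QuasiBinomialFit",
    "NestedFTest",
    "fit_quasibinomial_cubic",
    "fit_intercept_only",
    "f_test_nested",
    "standardize_viability",
    "per_temperature_tests",
    "DEFAULT_BENIGN_TEMPS",
]

logger = logging.getLogger(__name__)

DEFAULT_BENIGN_TEMPS = frozenset({20.0, 25.0})

_BASE_TERMS = ("intercept", "z", "z2", "z3", "treat")
_INTERACTION_TERMS = ("treat_z", "treat_z2", "treat_z3")


@dataclass(frozen=True)
class QuasiBinomialFit:
    """A fitted quasi-binomial cubic-logistic viability model.

    ``params``/``bse`` are indexed by term name; ``bse`` is already scaled
    by ``sqrt(dispersion_phi)``. ``temp_center``/``temp_scale`` record the
    temperature standardization so the curve can be evaluated on new
    temperatures, and :meth:`raw_scale_coefficients` re-expresses the
    polynomial on raw deg C for interpretability.
    """

    params: pd.Series
    bse: pd.Series
    dispersion_phi: float
    deviance: float
    pearson_chi2: float
    df_resid: int
    fitted_probabilities: np.ndarray
    term_names: tuple[str, ...]
    n_obs: int
    temp_center: float
    temp_scale: float
    treatments: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.term_names)

    def predict(self, temperatures, treatment: str) -> np.ndarray:
        """Fitted viability probability at given temperatures for one
        treatment."""
        z = (np.asarray(temperatures, dtype=float) - self.temp_center) / self.temp_scale
        t = 0.0 if treatment == self.treatments[0] else 1.0
        eta = np.zeros_like(z)
        cols = {"intercept": 1.0, "z": z, "z2": z**2, "z3": z**3, "treat": t,
                "treat_z": t * z, "treat_z2": t * z**2, "treat_z3": t * z**3}
        for name in self.term_names:
            eta = eta + self.params[name] * cols[name]
        return 1.0 / (1.0 + np.exp(-eta))

    def raw_scale_coefficients(self) -> pd.Series:
        """Polynomial coefficients re-expressed in powers of raw deg C.

        Returns the expansion of the fitted logit polynomial(s) in T rather
        than z, with names ``T0..T3`` (reference-treatment curve) and, when
        interactions are present, ``treat_T0..treat_T3`` (additive treatment
        contrast curve).
        """
        m, s = self.temp_center, self.temp_scale

        def expand(c0, c1, c2, c3):
            # substitute z = (T - m)/s into c0 + c1 z + c2 z^2 + c3 z^3
            poly = np.polynomial.Polynomial([-m / s, 1.0 / s])
            total = c0 + c1 * poly + c2 * poly**2 + c3 * poly**3
            coef = np.zeros(4)
            got = np.asarray(total.coef if hasattr(total, "coef") else [total])
            coef[: got.size] = got
            return coef

        p = self.params
        out = {}
        base = expand(p["intercept"], p.get("z", 0.0), p.get("z2", 0.0), p.get("z3", 0.0))
        for i, v in enumerate(base):
            out[f"T{i}"] = v
        if "treat" in p.index:
            contrast = expand(
                p["treat"], p.get("treat_z", 0.0), p.get("treat_z2", 0.0), p.get("treat_z3", 0.0)
            )
            for i, v in enumerate(contrast):
                out[f"treat_T{i}"] = v
        return pd.Series(out)


@dataclass(frozen=True)
class NestedFTest:
    """Quasi-likelihood F-test comparing nested viability models."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"treatment", "temperature", "eggs_set", "adults_emerged"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"viability records missing columns: {sorted(missing)}")
    df = records.reset_index(drop=True)
    if (df["eggs_set"] < 1).any():
        raise ValueError("eggs_set must be >= 1 for every vial")
    bad = (df["adults_emerged"] < 0) | (df["adults_emerged"] > df["eggs_set"])
    if bad.any():
        raise ValueError("adults_emerged must lie in [0, eggs_set]")
    return df


def _design_matrix(df: pd.DataFrame, terms: tuple[str, ...], center: float, scale: float,
                   treatments: tuple[str, ...]) -> np.ndarray:
    z = (df["temperature"].to_numpy(dtype=float) - center) / scale
    t = (df["treatment"].to_numpy() == treatments[1]).astype(float) if len(treatments) > 1 else np.zeros(len(df))
    cols = {
        "intercept": np.ones(len(df)),
        "z": z,
        "z2": z**2,
        "z3": z**3,
        "treat": t,
        "treat_z": t * z,
        "treat_z2": t * z**2,
        "treat_z3": t * z**3,
    }
    return np.column_stack([cols[name] for name in terms])


def _glm_fit(df: pd.DataFrame, terms: tuple[str, ...], center: float, scale: float,
             treatments: tuple[str, ...]) -> QuasiBinomialFit:
    X = _design_matrix(df, terms, center, scale, treatments)
    endog = np.column_stack(
        [df["adults_emerged"].to_numpy(), (df["eggs_set"] - df["adults_emerged"]).to_numpy()]
    )
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    if not getattr(res, "converged", True):
        raise FittingError(
            f"IRLS did not converge in 100 iterations (deviance trace: "
            f"{getattr(res, 'fit_history', {}).get('deviance', 'unavailable')})"
        )
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if np.any(fitted <= 1e-10) or np.any(fitted >= 1 - 1e-10) or np.any(np.abs(res.params) > 30):
        raise FittingError("separation detected: fitted probabilities at 0/1 with diverging coefficients")
    df_resid = int(res.df_resid)
    if df_resid <= 0:
        raise ValueError("model is saturated: df_resid must be positive")
    phi = float(res.pearson_chi2) / df_resid
    params = pd.Series(np.asarray(res.params, dtype=float), index=list(terms))
    bse = pd.Series(np.asarray(res.bse, dtype=float) * np.sqrt(phi), index=list(terms))
    return QuasiBinomialFit(
        params=params,
        bse=bse,
        dispersion_phi=phi,
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=df_resid,
        fitted_probabilities=fitted,
        term_names=tuple(terms),
        n_obs=len(df),
        temp_center=center,
        temp_scale=scale,
        treatments=treatments,
    )


def fit_quasibinomial_cubic(records: pd.DataFrame, with_interaction: bool = True) -> QuasiBinomialFit:
    """Fit the cubic-logistic viability model with quasi-binomial dispersion.

    Parameters
    ----------
    records
        Vial-level frame with columns ``treatment, temperature, eggs_set,
        adults_emerged`` covering exactly two treatments and at least five
        distinct temperatures.
    with_interaction
        Include the treatment x polynomial interaction terms (full model)
        or only the additive treatment shift (reduced model).
    """
    df = _validate_records(records)
    treatments = tuple(sorted(df["treatment"].unique()))
    if len(treatments) != 2:
        raise ValueError(f"exactly 2 treatments required, got {treatments}")
    temps = df["temperature"].to_numpy(dtype=float)
    if len(np.unique(temps)) < 5:
        raise ValueError("at least 5 distinct temperatures required for a cubic fit")
    center, scale = float(temps.mean()), float(temps.std())
    terms = _BASE_TERMS + (_INTERACTION_TERMS if with_interaction else ())
    return _glm_fit(df, terms, center, scale, treatments)


def fit_intercept_only(records: pd.DataFrame) -> QuasiBinomialFit:
    """Null model: a single mean viability across all vials (logit scale)."""
    df = _validate_records(records)
    treatments = tuple(sorted(df["treatment"].unique()))
    temps = df["temperature"].to_numpy(dtype=float)
    scale = float(temps.std()) or 1.0
    return _glm_fit(df, ("intercept",), float(temps.mean()), scale, treatments)


def f_test_nested(full: QuasiBinomialFit, reduced: QuasiBinomialFit) -> NestedFTest:
    """Overdispersion-corrected F-test of nested quasi-binomial models.

    ``F = [(dev_reduced - dev_full) / df_num] / phi_full`` referred to an
    F distribution on ``(df_num, full.df_resid)`` degrees of freedom.
    """
    if not set(reduced.term_names) <= set(full.term_names):
        raise ValueError("models are not nested: reduced terms must be a subset of full terms")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted to different numbers of vials")
    df_num = full.n_params - reduced.n_params
    df_den = full.df_resid
    if df_num == 0:
        return NestedFTest(f_stat=0.0, df_num=0, df_den=df_den, p_value=1.0)
    f_stat = max(0.0, (reduced.deviance - full.deviance) / df_num / full.dispersion_phi)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return NestedFTest(f_stat=float(f_stat), df_num=df_num, df_den=df_den, p_value=p)


def standardize_viability(
    records: pd.DataFrame, benign_temps=DEFAULT_BENIGN_TEMPS
) -> pd.DataFrame:
    """Express each vial's viability relative to its treatment's benign mean.

    The benign mean is the average vial proportion over all vials of that
    treatment at the benign temperatures; each vial's proportion is divided
    by it, so curve shape can be compared across treatments independently
    of overall level. Benign-temperature vials are retained and flagged
    (``is_benign``); by construction their relative viability averages to 1
    within each treatment.
    """
    df = _validate_records(records)
    benign = frozenset(float(t) for t in benign_temps)
    if not benign:
        raise ConfigError("benign_temps must be non-empty")
    df["proportion"] = df["adults_emerged"] / df["eggs_set"]
    df["is_benign"] = df["temperature"].astype(float).isin(benign)
    out = []
    for treatment, grp in df.groupby("treatment", sort=True):
        present = set(grp.loc[grp["is_benign"], "temperature"].astype(float))
        if present != benign:
            missing = sorted(benign - present)
            raise ValueError(
                f"treatment {treatment!r} has no vials at benign temperature(s) {missing}"
            )
        benign_mean = float(grp.loc[grp["is_benign"], "proportion"].mean())
        if benign_mean <= 0.0:
            raise ValueError(f"benign-temperature mean viability is 0 for {treatment!r}")
        g = grp.copy()
        g["relative_viability"] = g["proportion"] / benign_mean
        g["benign_mean_used"] = benign_mean
        out.append(g)
    cols = [
        "vial_id", "treatment", "temperature", "eggs_set", "adults_emerged",
        "proportion", "relative_viability", "benign_mean_used", "is_benign",
    ]
    result = pd.concat(out, ignore_index=True)
    return result[[c for c in cols if c in result.columns]]


def per_temperature_tests(
    standardized: pd.DataFrame,
    n_perm: int = 100_000,
    seed=None,
    treatment_a: str = "lab25",
    treatment_b: str = "field",
    holm: bool = False,
) -> pd.DataFrame:
    """Randomization tests on standardized viability at each stress temperature.

    For every non-benign temperature, the vial-level relative viabilities of
    the two treatments are compared with the difference-in-medians
    randomization test (``Md = median(treatment_a) - median(treatment_b)``).
    Temperatures where either treatment is absent are skipped with a logged
    warning. P-values are reported unadjusted; ``holm=True`` adds a
    Holm-corrected column.
    """
    required = {"treatment", "temperature", "relative_viability", "is_benign"}
    missing = required - set(standardized.columns)
    if missing:
        raise ValueError(f"standardized frame missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    stress = standardized.loc[~standardized["is_benign"]]
    for temp in sorted(stress["temperature"].unique()):
        at_t = stress.loc[stress["temperature"] == temp]
        a = at_t.loc[at_t["treatment"] == treatment_a, "relative_viability"].to_numpy()
        b = at_t.loc[at_t["treatment"] == treatment_b, "relative_viability"].to_numpy()
        if a.size < 2 or b.size < 2:
            logger.warning(
                "skipping %.6g degC: needs >= 2 vials of both %r and %r",
                temp, treatment_a, treatment_b,
            )
            continue
        res: PermutationResult = randomization_test(a, b, n_perm=n_perm, seed=rng)
        rows.append(
            {
                "temperature": float(temp),
                "md_diff": res.md_diff,
                "p_value": res.p_value,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "n_perm": res.n_perm,
                "exact": res.exact,
            }
        )
    table = pd.DataFrame(rows)
    if holm and not table.empty:
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_holm"] = adj
    return table
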