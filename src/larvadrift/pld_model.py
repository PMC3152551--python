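"""Temperature scaling of planktonic larval duration (PLD).

Fits the exponential-quadratic mixed model of O'Connor-type metabolic
scaling:

    ln(PLD)_ij = beta0 + u_0i + beta1 * ln(T_ij/Tc)
                 + beta2 * [ln(T_ij/Tc)]^2 + eps_ij

with species random intercepts u_0i ~ N(0, tau^2), residuals
eps_ij ~ N(0, sigma^2), and reference temperature Tc = 15 degC.  The
model is estimated by REML.  Species intercepts are recovered as BLUPs
(shrinkage predictors); predictions for an unobserved cold-water species
use the largest lecithotrophic BLUP intercept so that the estimated
larval lifetime is an upper bound.  Prediction intervals are obtained by
Monte-Carlo simulation of the model's uncertainty terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reference temperature of the scaling model, degrees Celsius.
TC_DEFAULT = 15.0

#: Species removed before fitting as outliers.
OUTLIER_SPECIES = (
    "Laqueus californianus",
    "Limulus polyphemus",
    "Callianassa tyrrhena",
)


@dataclass(frozen=True)
class PLDRecord:
    species: str
    feeding_mode: str  # "lecithotrophic" or "planktotrophic"
    T: float  # water temperature, degC
    pld_days: float

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("temperature must be > 0 degC")
        if not self.pld_days > 0:
            raise ValueError("pld_days must be > 0")


@dataclass
class PLDModel:
    """Fitted fixed effects, variance components and species BLUPs."""

    beta0: float
    beta1: float
    beta2: float
    se_beta: np.ndarray  # standard errors of (beta0, beta1, beta2)
    cov_beta: np.ndarray  # 3x3 covariance of the fixed effects
    tau2: float  # between-species intercept variance
    sigma2: float  # residual variance
    Tc: float = TC_DEFAULT
    blups: dict = field(default_factory=dict)  # species -> u_0i
    converged: bool = True

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "se_beta": list(map(float, self.se_beta)),
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "Tc": self.Tc,
            "blups": {k: float(v) for k, v in self.blups.items()},
            "converged": self.converged,
        }


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "feeding_mode": [r.feeding_mode for r in records],
            "T_celsius": [r.T for r in records],
            "pld_days": [r.pld_days for r in records],
        }
    )


def prepare_pld_data(records) -> pd.DataFrame:
    """Drop the named outlier species; returns a tidy DataFrame."""
    df = _as_frame(records)
    n0 = len(df)
    df = df[~df["species"].isin(OUTLIER_SPECIES)].reset_index(drop=True)
    if len(df) < n0:
        logger.info("removed %d record(s) from outlier species", n0 - len(df))
    return df


def fit_pld_model(records, Tc: float = TC_DEFAULT) -> PLDModel:
    """REML fit of the exponential-quadratic random-intercept model."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = _as_frame(records)
    if df["species"].nunique() < 2 or len(df) < 6:
        raise ValueError("need >= 2 species and >= 6 records to fit the model")
    if df.groupby("species").size().max() == 1:
        raise ValueError(
            "one record per species: variance components are unidentifiable"
        )
    df = df.assign(
        log_pld=np.log(df["pld_days"]),
        z=np.log(df["T_celsius"] / Tc),
    )
    df["z2"] = df["z"] ** 2

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        md = smf.mixedlm("log_pld ~ z + z2", df, groups=df["species"])
        fit = md.fit(reml=True)
    converged = getattr(fit, "converged", True) and not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )
    if not converged:
        logger.warning("mixed-model fit did not converge cleanly")

    fe = fit.fe_params
    tau2 = float(fit.cov_re.iloc[0, 0])
    sigma2 = float(fit.scale)
    cov = np.asarray(fit.cov_params().iloc[:3, :3])
    model = PLDModel(
        beta0=float(fe["Intercept"]),
        beta1=float(fe["z"]),
        beta2=float(fe["z2"]),
        se_beta=np.asarray(fit.bse[:3]),
        cov_beta=cov,
        tau2=tau2,
        sigma2=sigma2,
        Tc=Tc,
        converged=converged,
    )
    model.blups = {
        sp: _blup_offset(model, g) for sp, g in df.groupby("species")
    }
    return model


def _blup_offset(model: PLDModel, group: pd.DataFrame) -> float:
    """Shrinkage predictor u_0i = (tau2/(tau2 + sigma2/n_i)) * mean residual."""
    z = np.log(group["T_celsius"] / model.Tc)
    resid = (
        np.log(group["pld_days"]) - (model.beta0 + model.beta1 * z + model.beta2 * z**2)
    )
    n_i = len(group)
    denom = model.tau2 + model.sigma2 / n_i
    if denom == 0:
        return 0.0
    return float(model.tau2 / denom * resid.mean())


def blup_intercept(model: PLDModel, records, species: str) -> float:
    """Species intercept beta0 + u_0i from the fitted model."""
    df = _as_frame(records)
    group = df[df["species"] == species]
    if group.empty:
        raise KeyError(f"species {species!r} not present in the fitted data")
    return model.beta0 + _blup_offset(model, group)


def max_lecithotrophic_intercept(model: PLDModel, records) -> tuple[str, float]:
    """The lecithotrophic species with the largest BLUP intercept."""
    df = _as_frame(records)
    lec = df[df["feeding_mode"] == "lecithotrophic"]["species"].unique()
    if len(lec) == 0:
        raise ValueError("no lecithotrophic species in the data")
    best = max(lec, key=lambda sp: model.blups.get(sp, -np.inf))
    return best, model.beta0 + model.blups[best]


def predict_pld(
    intercept: float,
    beta1: float,
    beta2: float,
    T,
    Tc: float = TC_DEFAULT,
):
    """Point PLD (days): exp(intercept + beta1*ln(T/Tc) + beta2*ln(T/Tc)^2)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 degC")
    z = np.log(T / Tc)
    out = np.exp(intercept + beta1 * z + beta2 * z**2)
    return float(out) if out.ndim == 0 else out


def pld_interval(
    model: PLDModel,
    intercept: float,
    T: float,
    n_sim: int = 10000,
    rng: np.random.Generator | None = None,
    include_fixed_uncertainty: bool = True,
    include_residual: bool = False,
    include_species_variance: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo 2.5th/97.5th percentile PLD interval at temperature T.

    The default interval propagates the fixed-effect estimation
    uncertainty about the chosen intercept (the between-species variance
    is excluded once a species intercept is fixed, and the pure residual
    is excluded from the population-level curve); the residual and
    species-variance terms can be switched on.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    if rng is None:
        rng = np.random.default_rng()
    z = np.log(T / model.Tc)
    ln_point = intercept + model.beta1 * z + model.beta2 * z**2
    ln_draws = np.full(n_sim, ln_point)
    if include_fixed_uncertainty:
        db = rng.multivariate_normal(np.zeros(3), model.cov_beta, size=n_sim)
        ln_draws = ln_draws + db[:, 0] + db[:, 1] * z + db[:, 2] * z**2
    if include_species_variance and model.tau2 > 0:
        ln_draws = ln_draws + rng.normal(0.0, np.sqrt(model.tau2), size=n_sim)
    if include_residual and model.sigma2 > 0:
        ln_draws = ln_draws + rng.normal(0.0, np.sqrt(model.sigma2), size=n_sim)
    lo, hi = np.percentile(np.exp(ln_draws), [2.5, 97.5])
    return float(lo), float(hi)


# -- climatological temperature profile --------------------------------------

#: Depth (m) and temperature (degC) anchors of a typical western tropical
#: Pacific water column (climatological annual means).
_PACIFIC_PROFILE_DEPTH = np.array(
    [0.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0, 1600.0, 2000.0, 2500.0]
)
_PACIFIC_PROFILE_TEMP = np.array(
    [28.0, 24.0, 18.0, 10.0, 7.0, 5.5, 4.5, 3.7, 2.6, 2.2, 1.9]
)


def deep_pacific_temperature(depth_m):
    """Climatological water temperature (degC) at depth in the tropical
    south-west Pacific, monotone-interpolated between standard-profile
    anchors.  Serves as the station temperature source when no in-situ
    climatology file is supplied."""
    from scipy.interpolate import PchipInterpolator

    interp = PchipInterpolator(_PACIFIC_PROFILE_DEPTH, _PACIFIC_PROFILE_TEMP)
    depth_m = np.clip(np.asarray(depth_m, dtype=float), 0.0, 2500.0)
    out = interp(depth_m)
    return float(out) if out.ndim == 0 else out


def station_pld_table(
    model: PLDModel,
    stations,
    intercept: float,
    n_sim: int = 10000,
    rng: np.random.Generator | None = None,
    temperatures: dict | None = None,
) -> pd.DataFrame:
    """Per-station PLD point predictions with 95% intervals.

    The station temperature is the minimum temperature over its sampling
    depth range (i.e. the temperature at the maximum depth), from the
    supplied table or from the climatological profile.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for st in stations:
        if temperatures is not None and st.station_id in temperatures:
            T = float(temperatures[st.station_id])
        else:
            T = float(deep_pacific_temperature(st.depth_max_m))
        point = predict_pld(intercept, model.beta1, model.beta2, T, model.Tc)
        lo, hi = pld_interval(model, intercept, T, n_sim=n_sim, rng=rng)
        rows.append(
            {
                "station_id": st.station_id,
                "group": st.group,
                "depth_max_m": st.depth_max_m,
                "T_celsius": T,
                "pld_days": point,
                "pld_lo_days": lo,
                "pld_hi_days": hi,
            }
        )
    return pd.DataFrame(rows)
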