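"""Nectar standardization, secretion-curve fitting and resource availability.

Field measurements record nectar volume (µl) and refractometer concentration
(% Brix) per flower and time slot under one of two protocols:

* **cumulative** — each slot samples freshly opened, previously unsampled
  flowers, so each reading already reflects production accumulated since
  anthesis;
* **dynamic** — the same flowers are drained repeatedly, so later readings
  must be corrected by adding the previously extracted volume (and carrying
  the concentration forward, nectar concentration being roughly constant
  within a species).

Standardized sugar mass (mg) per flower and hour is modelled per species with
a Poisson GLM on sugar content in µg (rounded to integers) with linear and
quadratic hour terms and log link:

    E[µg sugar at hour t] = exp(b0 + b1 t + b2 t^2)

The fitted curves interpolate hourly per-flower production; multiplying by
each species' total flower count over the sampling period gives the plant
resource-availability matrix M3 (plants x hour bins, mg sugar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "brix_to_concentration",
    "harmonize_dynamic",
    "sugar_mass",
    "standardize_nectar",
    "NectarCurve",
    "NectarSecretionGLM",
    "fit_nectar_curve",
    "predict_hourly_production",
    "build_availability_matrix",
    "scale_dense_flower_count",
    "DEFAULT_HOUR_GRID",
]

#: left edges of the 12 one-hour bins 06:00-18:00 used for matrix M3
DEFAULT_HOUR_GRID = tuple(range(6, 18))

# Refractometer temperature corrections to the 20 °C reference (° Brix to add
# to the reading), tabulated by solution temperature and Brix; interpolated
# bilinearly.  Standard sucrose-refractometry correction values.
_CORR_TEMPS = np.array([10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0])
_CORR_BRIX = np.array([0.0, 10.0, 20.0, 30.0])
_CORR = np.array(
    [
        [-0.50, -0.54, -0.58, -0.61],
        [-0.27, -0.29, -0.31, -0.33],
        [0.00, 0.00, 0.00, 0.00],
        [0.32, 0.34, 0.36, 0.38],
        [0.67, 0.71, 0.75, 0.79],
        [1.04, 1.10, 1.16, 1.21],
        [1.45, 1.53, 1.60, 1.67],
    ]
)


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation beyond the table ends."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


def sucrose_density(brix) -> np.ndarray:
    """Density (g/ml) of a B % w/w sucrose solution (standard quadratic fit)."""
    b = np.asarray(brix, dtype=float)
    return 0.9982 + 3.85e-3 * b + 1.66e-5 * b * b


def brix_to_concentration(brix_pct, temperature_c):
    """Temperature-corrected sugar concentration in mg per ml.

    The Brix reading is first adjusted to the 20 °C reference via the
    refractometer correction table (bilinear interpolation), then converted
    with mg/ml = 10 * B * d(B), d(B) the density of a B % w/w sucrose
    solution.  A zero reading means no solute and maps to 0 regardless of
    temperature.
    """
    b = np.asarray(brix_pct, dtype=float)
    t = np.asarray(temperature_c, dtype=float)
    if np.any((b < 0) | (b > 85)):
        raise ValueError("brix_pct out of range [0, 85]")
    if np.any((t < 0) | (t > 45)):
        raise ValueError("temperature_c out of range [0, 45] degC")
    # correction at each tabulated temperature for this Brix, then across T
    corr_at_b = np.array([_interp_extrap(b, _CORR_BRIX, row) for row in _CORR])
    corr = _interp_extrap(t, _CORR_TEMPS, corr_at_b) if b.ndim == 0 else np.array(
        [_interp_extrap(np.atleast_1d(ti), _CORR_TEMPS, corr_at_b[:, i])[0] for i, ti in enumerate(np.atleast_1d(t))]
    )
    b20 = np.clip(b + corr, 0.0, None)
    b20 = np.where(b == 0, 0.0, b20)  # no solute -> zero whatever the temperature
    out = 10.0 * b20 * sucrose_density(b20)
    return float(out) if np.ndim(brix_pct) == 0 else out


_SAMPLE_KEY = ["plant", "individual", "flower"]


def harmonize_dynamic(samples: pd.DataFrame, use_observed_concentration: bool = False) -> pd.DataFrame:
    """Make dynamic-protocol measurements comparable with cumulative ones.

    For each repeatedly drained flower (rows sharing plant/individual/flower,
    ordered by slot): the first slot is unchanged; each later slot's corrected
    volume is the observed volume plus the previous slot's corrected volume,
    with the concentration carried forward from the previous slot (set
    ``use_observed_concentration=True`` to keep observed Brix readings where
    the observed volume is positive).  A slot with zero observed volume takes
    the previous slot's corrected volume and concentration verbatim.
    Cumulative-protocol rows pass through unchanged.
    """
    out = samples.copy()
    dyn = out[out["protocol"] == "dynamic"]
    for key, grp in dyn.groupby(_SAMPLE_KEY, sort=False):
        slots = grp["slot"].to_numpy(dtype=float)
        if np.any(np.diff(slots) <= 0):
            raise ValueError(f"slots not strictly increasing for flower {key}")
        vols = grp["volume_ul"].to_numpy(dtype=float).copy()
        brix = grp["brix_pct"].to_numpy(dtype=float).copy()
        for i in range(1, len(grp)):
            if vols[i] == 0:
                vols[i] = vols[i - 1]
                brix[i] = brix[i - 1]
            else:
                vols[i] = vols[i] + vols[i - 1]
                if not use_observed_concentration:
                    brix[i] = brix[i - 1]
        out.loc[grp.index, "volume_ul"] = vols
        out.loc[grp.index, "brix_pct"] = brix
    return out


def sugar_mass(volume_ul, concentration_mg_ml):
    """Sugar mass (mg) = nectar volume (ml) x concentration (mg/ml)."""
    v = np.asarray(volume_ul, dtype=float)
    c = np.asarray(concentration_mg_ml, dtype=float)
    if np.any(v < 0) or np.any(c < 0):
        raise ValueError("volume and concentration must be non-negative")
    out = v / 1000.0 * c
    return float(out) if np.ndim(volume_ul) == 0 and np.ndim(concentration_mg_ml) == 0 else out


def standardize_nectar(samples: pd.DataFrame, use_observed_concentration: bool = False) -> pd.DataFrame:
    """Harmonize protocols and add concentration (mg/ml) and sugar_mg columns."""
    out = harmonize_dynamic(samples, use_observed_concentration=use_observed_concentration)
    conc = np.array(
        [brix_to_concentration(b, t) for b, t in zip(out["brix_pct"], out["temperature_c"])]
    )
    out["concentration_mg_ml"] = conc
    out["sugar_mg"] = sugar_mass(out["volume_ul"].to_numpy(), conc)
    return out


@dataclass
class NectarCurve:
    """Per-species log-quadratic secretion curve on the log-µg scale."""

    plant: str
    b0: float
    b1: float
    b2: float
    deviance: float = float("nan")
    n: int = 0
    converged: bool = True

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2])

    def predict_ug(self, hours) -> np.ndarray:
        t = np.asarray(hours, dtype=float)
        return np.exp(self.b0 + self.b1 * t + self.b2 * t * t)


class NectarSecretionGLM(BaseEstimator, RegressorMixin):
    """Poisson GLM of sugar production (µg) on hour and hour squared.

    ``fit(hours, sugar_mg)`` regresses integer µg sugar (mg x 1000, rounded
    half-up when ``integer_response`` is set, per the measurement convention)
    on hour-of-day with a quadratic term and log link.  Requires observations
    at >= 3 distinct hours.

    Attributes
    ----------
    coef_ : ndarray (b0, b1, b2) on the log-µg scale
    deviance_, n_obs_, converged_ : fit diagnostics
    hour_range_ : (min, max) of training hours; prediction outside this
        domain raises (no extrapolation).
    """

    def __init__(self, integer_response: bool = True):
        self.integer_response = integer_response

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        sugar_mg = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != sugar_mg.shape:
            raise ValueError("hours and sugar values must align")
        if np.unique(t).size < 3:
            raise ValueError("need samples at >= 3 distinct time slots to fit a quadratic curve")
        resp = sugar_mg * 1000.0
        if self.integer_response:
            resp = np.floor(resp + 0.5)  # round half up to integer µg
        design = sm.add_constant(np.column_stack([t, t * t]))
        model = sm.GLM(resp, design, family=sm.families.Poisson())
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise RuntimeError(f"Poisson GLM failed to fit: {exc}") from exc
        if not res.converged:
            raise RuntimeError(f"Poisson GLM did not converge (deviance {res.deviance:.3g})")
        self.coef_ = np.asarray(res.params, dtype=float)
        self.bse_ = np.asarray(res.bse, dtype=float)
        self.deviance_ = float(res.deviance)
        self.n_obs_ = int(t.size)
        self.converged_ = bool(res.converged)
        self.hour_range_ = (float(t.min()), float(t.max()))
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        lo, hi = self.hour_range_
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"hours outside the fitted domain [{lo}, {hi}] (no extrapolation)")
        b0, b1, b2 = self.coef_
        return np.exp(b0 + b1 * t + b2 * t * t) / 1000.0  # mg


def fit_nectar_curve(samples: pd.DataFrame, integer_response: bool = True) -> NectarCurve:
    """Fit one species' secretion curve from standardized samples.

    ``samples`` must carry ``slot`` and ``sugar_mg`` columns for a single
    plant (see :func:`standardize_nectar`).
    """
    plants = samples["plant"].unique() if "plant" in samples.columns else np.array([""])
    if plants.size > 1:
        raise ValueError(f"samples span multiple plants: {sorted(plants)}")
    est = NectarSecretionGLM(integer_response=integer_response)
    est.fit(samples["slot"].to_numpy(), samples["sugar_mg"].to_numpy())
    return NectarCurve(
        plant=str(plants[0]),
        b0=float(est.coef_[0]),
        b1=float(est.coef_[1]),
        b2=float(est.coef_[2]),
        deviance=est.deviance_,
        n=est.n_obs_,
        converged=est.converged_,
    )


def predict_hourly_production(curve: NectarCurve, hours=DEFAULT_HOUR_GRID) -> pd.Series:
    """Per-flower sugar production (mg) at each requested clock hour."""
    t = np.asarray(hours, dtype=float)
    if np.any(t < 6) or np.any(t > 18):
        raise ValueError("hours outside the fitted domain [6, 18] (no extrapolation)")
    return pd.Series(curve.predict_ug(t) / 1000.0, index=list(hours), name=curve.plant)


def build_availability_matrix(
    curves, flower_totals, hours=DEFAULT_HOUR_GRID
) -> pd.DataFrame:
    """Plant x hour-bin resource availability (matrix M3).

    Entry (plant, h) = predicted per-flower sugar (mg) at hour h times the
    plant's total flower count over the sampling period.  Plants with zero
    flowers yield all-zero rows.
    """
    if isinstance(curves, dict):
        curve_map = curves
    else:
        curve_map = {c.plant: c for c in curves}
    missing = [p for p in curve_map if p not in flower_totals]
    if missing:
        raise KeyError(f"missing flower totals for plants: {missing}")
    rows = {}
    for plant, curve in curve_map.items():
        rows[plant] = predict_hourly_production(curve, hours) * float(flower_totals[plant])
    out = pd.DataFrame(rows).T.rename_axis(index="plant", columns="hour")
    out.attrs["hours"] = list(hours)
    return out


def scale_dense_flower_count(branch_counts, total_branches: int) -> int:
    """Estimate a dense plant's flower count from a five-branch subsample.

    Mean flowers per sampled branch times the total branch count, rounded to
    the nearest integer.
    """
    counts = np.asarray(branch_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("branch_counts must be non-empty")
    if not (1 <= counts.size <= 5):
        raise ValueError("expected counts for 1-5 branches")
    if total_branches < 1:
        raise ValueError("total_branches must be >= 1")
    return int(np.floor(counts.mean() * total_branches + 0.5))
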