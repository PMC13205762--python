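"""Power-law scaling models and time-space equivalence algebra.

Single-variable models (natural logs throughout):

    SAR/PAR:  ln S (or ln PD) = z1 * ln A + b
    STR/PTR:  ln S (or ln PD) = w1 * ln T + b

Interaction model (STAR for richness, PTAR for phylogenetic diversity):

    ln S = z * ln A + w * ln T + u * ln A * ln T + b

where z is the spatial scaling rate over one time unit, w the temporal
scaling rate at one area unit, and u the area x time interaction. The
time-space equivalence ratio exp((z - w)/u) is the area whose temporal
scaling rate equals the spatial scaling rate over one time unit.

Because u couples the two axes, the exponents are unit-dependent; converting
a fit between units (m² -> km², months -> years) must use the exact change
of log-variables implemented in :func:`rescale_units`, not a naive rescale.

Fits are ordinary least squares in log-log space, implemented with
``numpy.linalg.lstsq`` (a fast closed form reused thousands of times inside
permutation loops) and cross-checked against statsmodels OLS in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PowerLawModel",
    "StarModel",
    "EquivalenceRatio",
    "fit_power_law",
    "fit_star",
    "equivalence_ratio",
    "rescale_units",
    "DegenerateDesignError",
    "UndefinedRatioError",
]

_RESPONSES = ("richness", "pd")
_PREDICTORS = {"area": "area_m2", "time": "time_months"}


class DegenerateDesignError(ValueError):
    """Raised when the log-log regression design is rank deficient."""


class UndefinedRatioError(ValueError):
    """Raised when the equivalence ratio is requested for u = 0."""


def _check_surface(surface: pd.DataFrame, response: str, cols: list[str]) -> pd.DataFrame:
    if response not in _RESPONSES:
        raise ValueError(f"response must be one of {_RESPONSES}")
    sub = surface.dropna(subset=[response])
    for c in cols + [response]:
        if (sub[c] <= 0).any():
            raise ValueError(f"non-positive values in column {c!r}; cannot take logs")
    return sub


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and R² (intercept must be column 0)."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    return beta, r2


class PowerLawModel(BaseEstimator):
    """Single-variable log-log power law (SAR, PAR, STR, or PTR).

    Parameters
    ----------
    predictor : 'area' or 'time'.
    response : 'richness' or 'pd'.

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``n_points_``, ``degenerate_`` (True when the response is constant and
    the slope/R² are reported as 0), ``model_`` (SAR/PAR/STR/PTR tag).
    """

    def __init__(self, predictor: str = "area", response: str = "richness"):
        self.predictor = predictor
        self.response = response

    def fit(self, surface: pd.DataFrame) -> "PowerLawModel":
        if self.predictor not in _PREDICTORS:
            raise ValueError("predictor must be 'area' or 'time'")
        col = _PREDICTORS[self.predictor]
        sub = _check_surface(surface, self.response, [col])
        if len(sub) < 3:
            raise ValueError("need >= 3 rows with positive predictor and response")
        x = np.log(sub[col].to_numpy(dtype=float))
        y = np.log(sub[self.response].to_numpy(dtype=float))
        if np.ptp(x) == 0:
            raise DegenerateDesignError(f"predictor {col!r} has zero variance")
        self.degenerate_ = bool(np.ptp(y) == 0)
        if self.degenerate_:
            self.slope_, self.intercept_, self.r_squared_ = 0.0, float(y[0]), 0.0
        else:
            beta, self.r_squared_ = _ols(np.column_stack([np.ones_like(x), x]), y)
            self.intercept_, self.slope_ = float(beta[0]), float(beta[1])
        self.n_points_ = len(sub)
        self.model_ = {
            ("area", "richness"): "SAR",
            ("area", "pd"): "PAR",
            ("time", "richness"): "STR",
            ("time", "pd"): "PTR",
        }[(self.predictor, self.response)]
        return self

    def predict(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.exp(self.intercept_ + self.slope_ * np.log(v))


class StarModel(BaseEstimator):
    """Interaction time-area power law (STAR/PTAR).

    OLS of ln(response) on [1, ln A, ln T, ln A ln T]. Fitted attributes:
    ``z_`` (spatial exponent), ``w_`` (temporal exponent), ``u_``
    (interaction), ``b_`` (intercept), ``r_squared_``, ``n_points_``,
    ``area_unit_``, ``time_unit_``.
    """

    def __init__(self, response: str = "richness"):
        self.response = response

    def fit(
        self,
        surface: pd.DataFrame,
        area_unit: str = "m2",
        time_unit: str = "month",
    ) -> "StarModel":
        sub = _check_surface(surface, self.response, ["area_m2", "time_months"])
        if len(sub) < 5:
            raise ValueError("need >= 5 rows to fit the interaction model")
        la = np.log(sub["area_m2"].to_numpy(dtype=float))
        lt = np.log(sub["time_months"].to_numpy(dtype=float))
        if np.ptp(la) == 0 or np.ptp(lt) == 0:
            raise DegenerateDesignError(
                "need >= 2 distinct area sizes and >= 2 distinct time lengths"
            )
        y = np.log(sub[self.response].to_numpy(dtype=float))
        X = np.column_stack([np.ones_like(la), la, lt, la * lt])
        if np.linalg.matrix_rank(X) < 4:
            raise DegenerateDesignError("rank-deficient lnA/lnT/lnA*lnT design")
        beta, self.r_squared_ = _ols(X, y)
        self.b_, self.z_, self.w_, self.u_ = map(float, beta)
        self.n_points_ = len(sub)
        self.area_unit_ = area_unit
        self.time_unit_ = time_unit
        return self

    def predict(self, area, time) -> np.ndarray:
        la, lt = np.log(np.asarray(area, float)), np.log(np.asarray(time, float))
        return np.exp(self.b_ + self.z_ * la + self.w_ * lt + self.u_ * la * lt)

    def exponents(self) -> dict:
        return {"z": self.z_, "w": self.w_, "u": self.u_, "b": self.b_}


def fit_star_arrays(la: np.ndarray, lt: np.ndarray, ln_s: np.ndarray):
    """Fast STAR fit on pre-logged arrays: returns (b, z, w, u), R².

    Used inside permutation loops where thousands of refits are needed;
    raises DegenerateDesignError on a rank-deficient design.
    """
    X = np.column_stack([np.ones_like(la), la, lt, la * lt])
    if np.ptp(la) == 0 or np.ptp(lt) == 0:
        raise DegenerateDesignError("degenerate permuted design")
    beta, r2 = _ols(X, ln_s)
    return beta, r2


def fit_power_law(
    surface: pd.DataFrame, predictor: str = "area", response: str = "richness"
) -> PowerLawModel:
    """Fit a single-variable power law; thin wrapper over PowerLawModel."""
    return PowerLawModel(predictor=predictor, response=response).fit(surface)


def fit_star(surface: pd.DataFrame, response: str = "richness") -> StarModel:
    """Fit the interaction STAR/PTAR model; thin wrapper over StarModel."""
    return StarModel(response=response).fit(surface)


@dataclass(frozen=True)
class EquivalenceRatio:
    """Time-space equivalence: area per time unit with equal scaling rates."""

    value: float
    basis: str
    area_unit: str
    time_unit: str
    small_interaction: bool = False

    def __float__(self) -> float:
        return self.value


def equivalence_ratio(fit: StarModel, u_tolerance: float = 1e-6) -> EquivalenceRatio:
    """exp((z - w)/u) in the fit's current units.

    Undefined at u = 0; a warning flag is set when |u| < ``u_tolerance``
    (the ratio then explodes numerically and should not be interpreted).
    """
    if fit.u_ == 0:
        raise UndefinedRatioError("equivalence ratio is undefined when u = 0")
    small = abs(fit.u_) < u_tolerance
    if small:
        warnings.warn(
            f"|u| = {abs(fit.u_):.2e} < {u_tolerance:g}; equivalence ratio unstable",
            stacklevel=2,
        )
    return EquivalenceRatio(
        value=float(np.exp((fit.z_ - fit.w_) / fit.u_)),
        basis=fit.response,
        area_unit=fit.area_unit_,
        time_unit=fit.time_unit_,
        small_interaction=small,
    )


def rescale_units(
    fit: StarModel,
    area_factor: float,
    time_factor: float,
    area_unit: "str | None" = None,
    time_unit: "str | None" = None,
) -> StarModel:
    """Convert a fitted interaction model to new area/time units.

    ``area_factor`` is old-units-per-new-unit of area (m² per km² = 1e6),
    ``time_factor`` likewise for time (months per year = 12). Writing
    ln A_old = ln a + ln A_new (and similarly for T), the exponents map as

        z' = z + u ln t,   w' = w + u ln a,   u' = u,
        b' = b + z ln a + w ln t + u ln a ln t,

    and the equivalence ratio transforms exactly as ratio' = ratio * t / a.
    """
    if area_factor <= 0 or time_factor <= 0:
        raise ValueError("unit factors must be positive")
    ln_a, ln_t = np.log(area_factor), np.log(time_factor)
    out = StarModel(response=fit.response)
    out.z_ = fit.z_ + fit.u_ * ln_t
    out.w_ = fit.w_ + fit.u_ * ln_a
    out.u_ = fit.u_
    out.b_ = fit.b_ + fit.z_ * ln_a + fit.w_ * ln_t + fit.u_ * ln_a * ln_t
    out.r_squared_ = fit.r_squared_
    out.n_points_ = fit.n_points_
    out.area_unit_ = area_unit or f"{fit.area_unit_}x{area_factor:g}"
    out.time_unit_ = time_unit or f"{fit.time_unit_}x{time_factor:g}"
    return out
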