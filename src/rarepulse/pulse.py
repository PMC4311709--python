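"""Lagged moisture -> soil CO2 pulse regression.

Rewetting dry soil triggers a pulse of respiration (the Birch effect). On a
12-h time step, soil CO2 concentration follows its own lag plus the current
and previous soil moisture:

    CO2(t) = b0 + b1 * CO2(t-1) + b2 * moisture(t) + b3 * moisture(t-1) + e(t)

with b2 > 0 (wetting stimulates respiration) and b3 < 0 (the pulse decays
as the added water drains/evaporates). Sensor residuals are serially
correlated, so the ordinary least squares fit is refined by iterated
Cochrane-Orcutt AR(1) quasi-differencing; Newey-West (HAC) standard errors
are available as an alternative that leaves the point estimates at OLS.

The module follows the statsmodels idiom: build a :class:`PulseModel` from
a :class:`SensorSeries` (or DataFrame), call :meth:`PulseModel.fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`PulseModelResults`, whose ``summary()`` renders a fit table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InvalidParameterError, SingularFitError

PARAM_NAMES = ("intercept", "co2_lag", "moisture", "moisture_lag")


@dataclass
class SensorSeries:
    """Equally spaced soil sensor series: moisture, CO2 and temperature.

    ``moisture`` is volumetric (m3 H2O per m3 soil), ``co2`` in ppmv.
    Temperature (degC) is carried for completeness but unused by the model.
    """

    time_h: np.ndarray
    moisture: np.ndarray
    co2: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.moisture = np.asarray(self.moisture, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
        n = len(self.time_h)
        if len(self.moisture) != n or len(self.co2) != n:
            raise InvalidParameterError("sensor series columns must have equal length")
        if n >= 2:
            steps = np.diff(self.time_h)
            if not np.allclose(steps, steps[0]):
                raise InvalidParameterError("sensor series must be equally spaced")
            if steps[0] <= 0:
                raise InvalidParameterError("time must be strictly increasing")
        if np.isnan(self.moisture).any() or np.isnan(self.co2).any():
            raise InvalidParameterError("sensor series contains missing values")
        if (self.moisture < 0).any():
            raise InvalidParameterError("moisture must be nonnegative")

    def __len__(self) -> int:
        return len(self.time_h)

    @property
    def step_h(self) -> float:
        if len(self) < 2:
            raise InvalidParameterError("need >= 2 points to define a step")
        return float(self.time_h[1] - self.time_h[0])

    def to_frame(self) -> pd.DataFrame:
        data = {"timestamp": self.time_h, "moisture": self.moisture, "co2_ppmv": self.co2}
        data["temperature"] = (
            self.temperature if self.temperature is not None else np.full(len(self), np.nan)
        )
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SensorSeries":
        temp = df["temperature"].to_numpy() if "temperature" in df else None
        return cls(
            time_h=df["timestamp"].to_numpy(),
            moisture=df["moisture"].to_numpy(),
            co2=df["co2_ppmv"].to_numpy(),
            temperature=temp,
        )


def aggregate(series: SensorSeries, window_h: float) -> SensorSeries:
    """Block-average a sensor series to a coarser analysis step.

    Each output point is the arithmetic mean of the input points falling in
    its half-open window ``[t, t + window_h)``; a trailing partial window is
    dropped. ``window_h`` must be a positive multiple of the input spacing.
    """
    step = series.step_h
    ratio = window_h / step
    if window_h <= 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise InvalidParameterError(
            f"window {window_h} h must be a positive multiple of the spacing {step} h"
        )
    k = int(round(ratio))
    n_out = len(series) // k
    if n_out == 0:
        raise InvalidParameterError("series shorter than one aggregation window")

    def block(x):
        return x[: n_out * k].reshape(n_out, k).mean(axis=1)

    return SensorSeries(
        time_h=series.time_h[: n_out * k : k],
        moisture=block(series.moisture),
        co2=block(series.co2),
        temperature=None if series.temperature is None else block(series.temperature),
    )


def _design(series: SensorSeries) -> tuple[np.ndarray, np.ndarray]:
    """Response CO2(t) and regressors [1, CO2(t-1), moisture(t), moisture(t-1)]."""
    y = series.co2[1:]
    X = np.column_stack(
        [
            np.ones(len(y)),
            series.co2[:-1],
            series.moisture[1:],
            series.moisture[:-1],
        ]
    )
    return y, X


class PulseModel:
    """Lagged moisture -> CO2 regression model bound to one sensor series.

    Parameters
    ----------
    series
        :class:`SensorSeries`, already aggregated to the analysis time step.
        The first observation only contributes its lag, so ``n_obs`` of the
        fit equals ``len(series) - 1``.
    """

    def __init__(self, series: SensorSeries):
        if len(series) < 8:
            raise InvalidParameterError(
                "need at least 8 aggregated observations to fit 4 coefficients"
            )
        self.series = series
        self.endog, self.exog = _design(series)
        # a merely rank-deficient design (constant moisture) degrades to an
        # AR(1) model via the pseudoinverse; only the fully degenerate case
        # (constant moisture AND constant CO2) is unfittable
        if np.ptp(series.moisture) == 0 and np.ptp(series.co2) == 0:
            raise SingularFitError("constant moisture and constant CO2: nothing to fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, window_h: float | None = None) -> "PulseModel":
        """Build from a sensor DataFrame (`timestamp,moisture,temperature,co2_ppmv`),
        optionally aggregating to ``window_h`` first."""
        series = SensorSeries.from_frame(df)
        if window_h is not None:
            series = aggregate(series, window_h)
        return cls(series)

    # -- fitting ---------------------------------------------------------------

    def fit(
        self,
        correction: str = "ar1",
        tol: float = 1e-6,
        maxiter: int = 50,
        hac_maxlags: int | None = None,
    ) -> "PulseModelResults":
        """Fit the model.

        ``correction="ar1"`` runs iterated Cochrane-Orcutt: OLS, estimate the
        AR(1) coefficient rho from lag-1 residual autocorrelation,
        quasi-difference all variables, refit, and repeat until rho changes
        by less than ``tol`` (or ``maxiter`` sweeps, in which case the last
        iterate is returned with ``converged=False`` and a warning).
        ``correction="hac"`` keeps the OLS point estimates and reports
        Newey-West standard errors. ``correction="none"`` is plain OLS.
        """
        if correction not in ("ar1", "hac", "none"):
            raise InvalidParameterError(f"unknown correction {correction!r}")
        y, X = self.endog, self.exog

        if correction in ("hac", "none"):
            model = sm.OLS(y, X)
            if correction == "hac":
                lags = hac_maxlags if hac_maxlags is not None else max(1, int(len(y) ** (1 / 4)))
                res = model.fit(cov_type="HAC", cov_kwds={"maxlags": lags})
            else:
                res = model.fit()
            return self._package(res.params, res.bse, rho=0.0, n_iter=1, converged=True,
                                 correction=correction, sm_results=res)

        # iterated Cochrane-Orcutt
        rho = 0.0
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        converged = False
        n_iter = 0
        sm_res = None
        ss_tot = float(((y - y.mean()) ** 2).sum())
        for n_iter in range(1, maxiter + 1):
            resid = y - X @ beta
            ss_res = float(resid @ resid)
            if ss_tot > 0 and ss_res <= 1e-16 * ss_tot:
                # numerically perfect fit: residuals are rounding noise and
                # carry no autocorrelation information
                rho = 0.0
                sm_res = sm.OLS(y, X).fit()
                beta = np.asarray(sm_res.params)
                converged = True
                break
            denom = float(resid[:-1] @ resid[:-1])
            rho_new = float(resid[1:] @ resid[:-1]) / denom if denom > 1e-300 else 0.0
            rho_new = float(np.clip(rho_new, -0.999, 0.999))
            y_star = y[1:] - rho_new * y[:-1]
            X_star = X[1:] - rho_new * X[:-1]
            sm_res = sm.OLS(y_star, X_star).fit()
            beta = np.asarray(sm_res.params)
            if abs(rho_new - rho) < tol:
                rho = rho_new
                converged = True
                break
            rho = rho_new
        if not converged:
            warnings.warn(
                f"Cochrane-Orcutt did not converge in {maxiter} iterations "
                f"(last rho={rho:.4f}); returning last iterate",
                RuntimeWarning,
                stacklevel=2,
            )
        return self._package(beta, np.asarray(sm_res.bse), rho=rho, n_iter=n_iter,
                             converged=converged, correction="ar1", sm_results=sm_res)

    def _package(self, params, bse, rho, n_iter, converged, correction, sm_results) -> "PulseModelResults":
        y, X = self.endog, self.exog
        params = np.asarray(params, dtype=float)
        resid = y - X @ params
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        bse = np.asarray(bse, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvalues = np.where(bse > 0, params / bse, np.inf * np.sign(params))
        return PulseModelResults(
            model=self,
            params=pd.Series(params, index=PARAM_NAMES),
            bse=pd.Series(bse, index=PARAM_NAMES),
            tvalues=pd.Series(tvalues, index=PARAM_NAMES),
            rsquared=float(np.clip(rsq, 0.0, 1.0)),
            rsquared_transformed=float(sm_results.rsquared) if sm_results is not None else float("nan"),
            rho=float(rho),
            n_obs=len(y),
            n_iter=n_iter,
            converged=converged,
            correction=correction,
            resid=resid,
        )


@dataclass
class PulseModelResults:
    """Estimates, uncertainties and diagnostics of a fitted pulse model.

    ``rsquared`` is computed on the original (undifferenced) CO2 scale from
    the final coefficients; ``rsquared_transformed`` is the R-squared of the
    last quasi-differenced regression (they coincide for plain OLS).
    """

    model: PulseModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    rsquared: float
    rsquared_transformed: float
    rho: float
    n_obs: int
    n_iter: int
    converged: bool
    correction: str
    resid: np.ndarray = field(repr=False)

    def predict(self, series: SensorSeries | None = None) -> pd.DataFrame:
        """One-step-ahead predictions from observed lags.

        Returns a DataFrame of length ``n - 1`` with columns
        ``time_h, observed, predicted``.
        """
        series = series if series is not None else self.model.series
        y, X = _design(series)
        return pd.DataFrame(
            {
                "time_h": series.time_h[1:],
                "observed": y,
                "predicted": X @ self.params.to_numpy(),
            }
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "tvalues": {k: float(v) for k, v in self.tvalues.items()},
            "rsquared": self.rsquared,
            "rsquared_transformed": self.rsquared_transformed,
            "rho": self.rho,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "correction": self.correction,
        }

    def summary(self) -> str:
        lines = [
            "Lagged moisture -> CO2 pulse regression",
            f"  correction: {self.correction}   n_obs: {self.n_obs}   "
            f"rho: {self.rho:+.4f}   iterations: {self.n_iter}"
            + ("" if self.converged else "   [NOT CONVERGED]"),
            f"  R-squared (original scale): {self.rsquared:.4f}   "
            f"(transformed scale): {self.rsquared_transformed:.4f}",
            "",
            f"  {'term':<14}{'coef':>14}{'std err':>12}{'t':>10}",
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"  {name:<14}{self.params[name]:>14.4f}{self.bse[name]:>12.4f}"
                f"{self.tvalues[name]:>10.2f}"
            )
        return "\n".join(lines)


def fit_pulse_model(series: SensorSeries, correction: str = "ar1", **kwargs) -> PulseModelResults:
    """Convenience wrapper: ``PulseModel(series).fit(...)``."""
    return PulseModel(series).fit(correction=correction, **kwargs)


def predict(series: SensorSeries, fit: PulseModelResults) -> pd.DataFrame:
    """One-step-ahead predicted CO2 for ``series`` under a fitted model."""
    return fit.predict(series)
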