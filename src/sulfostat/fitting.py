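"""Dose-response and calibration fitting.

Implements the parameter-estimation steps of the modelling pipeline:

* the normalized variable-slope dose-response ("log(inhibitor) vs.
  normalized response") fit with top fixed at 1 and bottom at 0, from
  either endpoint plate data or growth rates, exposed statsmodels-style
  as a :class:`DoseResponse` model whose ``fit()`` returns a
  :class:`DoseResponseResults` with standard errors, confidence intervals
  and a ``summary()`` table;
* exponential-window growth-rate estimation from replicated growth
  curves;
* the ordinary least-squares log-log regression of sulfide on %SRM; and
* IC50 fold-change between two fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .params import SulfideCalibration

__all__ = [
    "GradientPlate",
    "GrowthCurveSet",
    "DoseResponse",
    "DoseResponseResults",
    "ConvergenceError",
    "normalize_to_control",
    "fit_dose_response",
    "estimate_growth_rate",
    "dose_response_from_growth_rates",
    "fit_sulfide_calibration",
    "ic50_fold_change",
]

_LN10 = np.log(10.0)


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed even after the grid-search restart."""


@dataclass(frozen=True)
class GradientPlate:
    """Endpoint responses along a perchlorate dilution gradient.

    ``concentrations`` (mM) must contain 0 (the control wells); nonzero
    concentrations are expected to form a descending two-fold series
    (other grids are accepted with a warning).  ``responses`` are the raw
    endpoint measurements (growth or sulfide), one per concentration
    entry; replicate wells appear as repeated concentration values.
    """

    concentrations: tuple
    responses: tuple

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.size != resp.size:
            raise ValueError("concentrations and responses must match in length")
        if not np.any(conc == 0):
            raise ValueError("plate must contain a 0 mM control series")
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0 mM")
        nz = np.unique(conc[conc > 0])[::-1]
        ratios = nz[:-1] / nz[1:]
        if nz.size >= 2 and not np.allclose(ratios, 2.0, rtol=0.05):
            warnings.warn(
                "nonzero concentrations are not a two-fold dilution series",
                stacklevel=2,
            )
        object.__setattr__(self, "concentrations", tuple(conc))
        object.__setattr__(self, "responses", tuple(resp))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GradientPlate":
        """Build from a tidy table with columns concentration_mM, response."""
        return cls(tuple(df["concentration_mM"]), tuple(df["response"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"concentration_mM": self.concentrations, "response": self.responses}
        )


@dataclass(frozen=True)
class GrowthCurveSet:
    """Replicated growth curves, one per perchlorate level.

    ``data`` is a tidy frame with columns ``time_h``, ``perchlorate_mM``,
    ``replicate``, ``measurement`` (OD or sulfide mM).  Each curve needs
    at least 4 strictly increasing time points.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_h", "perchlorate_mM", "replicate", "measurement"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"growth-curve table missing columns: {sorted(missing)}")
        for (level, rep), grp in self.data.groupby(["perchlorate_mM", "replicate"]):
            t = grp["time_h"].to_numpy()
            if t.size < 4:
                raise ValueError(
                    f"curve (p={level}, rep={rep}) has fewer than 4 time points"
                )
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"curve (p={level}, rep={rep}) times must strictly increase"
                )

    @property
    def levels(self) -> np.ndarray:
        return np.sort(self.data["perchlorate_mM"].unique())


def normalize_to_control(plate: GradientPlate) -> pd.DataFrame:
    """Divide every response by the mean 0 mM control response.

    Returns a tidy frame (concentration_mM, response) where the control
    wells average to 1.  A non-positive control mean is an error — the
    normalisation would flip or blow up the curve.
    """
    conc = np.asarray(plate.concentrations)
    resp = np.asarray(plate.responses)
    control_mean = resp[conc == 0].mean()
    if not control_mean > 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return pd.DataFrame(
        {"concentration_mM": conc, "response": resp / control_mean}
    )


def _model_response(log_p_molar: np.ndarray, log_ic50: float,
                    hill_slope: float) -> np.ndarray:
    """Normalized variable-slope curve y = 1/(1 + 10^((logIC50 - x) h))."""
    z = (log_ic50 - log_p_molar) * hill_slope
    return expit(-_LN10 * z)


class DoseResponse:
    """Normalized variable-slope inhibition model on log-molar concentration.

    Two free parameters, LogIC50 (log10 mol/L) and HillSlope (signed,
    negative for inhibitors); top and bottom of the curve are fixed at 1
    and 0.  0 mM points serve normalisation only and are excluded from
    the fit (their log-concentration is undefined).

    Parameters
    ----------
    concentrations_mM : array-like
        Perchlorate concentrations in mM; zeros are dropped.
    responses : array-like
        Control-normalised responses, one per concentration.
    source : str
        Provenance tag, ``"endpoint"`` or ``"growth_rate"``.

    Examples
    --------
    >>> model = DoseResponse.from_plate(plate)        # doctest: +SKIP
    >>> res = model.fit()                             # doctest: +SKIP
    >>> res.log_ic50, res.hill_slope                  # doctest: +SKIP
    """

    def __init__(self, concentrations_mM, responses, source: str = "endpoint"):
        conc = np.asarray(concentrations_mM, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if conc.size != resp.size:
            raise ValueError("concentrations and responses must match in length")
        keep = conc > 0
        conc, resp = conc[keep], resp[keep]
        if np.unique(conc).size < 4:
            raise ValueError(
                "need >= 4 distinct nonzero concentrations for a 2-parameter fit"
            )
        if np.any(resp < -0.1) or np.any(resp > 1.2):
            raise ValueError(
                "normalized responses must lie in [-0.1, 1.2]; "
                "normalize to the 0 mM control first"
            )
        self.log_p_molar = np.log10(conc / 1000.0)
        self.responses = resp
        self.source = source

    @classmethod
    def from_plate(cls, plate: GradientPlate) -> "DoseResponse":
        norm = normalize_to_control(plate)
        return cls(norm["concentration_mM"], norm["response"], source="endpoint")

    def _start(self) -> tuple:
        # LogIC50 starts at the log-concentration nearest response 0.5;
        # HillSlope starts at -1.
        i = int(np.argmin(np.abs(self.responses - 0.5)))
        return (self.log_p_molar[i], -1.0)

    def _sse(self, params) -> float:
        r = self.responses - _model_response(self.log_p_molar, *params)
        return float(r @ r)

    def fit(self, ci_method: str = "asymptotic", n_boot: int = 500,
            seed: int = 0) -> "DoseResponseResults":
        """Nonlinear least squares; grid-search restart on failure.

        ``ci_method`` is ``"asymptotic"`` (linearised covariance, the
        default) or ``"bootstrap"`` (case resampling, ``n_boot`` draws).
        """
        x, y = self.log_p_molar, self.responses
        popt, pcov = self._solve(x, y)
        resid = y - _model_response(x, *popt)
        sse = float(resid @ resid)
        dof = max(y.size - 2, 1)
        if ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            draws = []
            for _ in range(n_boot):
                idx = rng.integers(0, y.size, y.size)
                try:
                    draws.append(self._solve(x[idx], y[idx])[0])
                except ConvergenceError:
                    continue
            draws = np.asarray(draws)
            bse = draws.std(axis=0, ddof=1)
            ci = np.percentile(draws, [2.5, 97.5], axis=0).T
        else:
            bse = np.sqrt(np.diag(pcov))
            tval = stats.t.ppf(0.975, dof)
            ci = np.column_stack([popt - tval * bse, popt + tval * bse])
        return DoseResponseResults(
            log_ic50=float(popt[0]),
            hill_slope=float(popt[1]),
            bse=tuple(float(v) for v in bse),
            _conf_int=tuple(map(tuple, ci)),
            residual_sse=sse,
            n_points=int(y.size),
            source=self.source,
            model=self,
        )

    def _solve(self, x, y) -> tuple:
        p0 = self._start()
        try:
            popt, pcov = optimize.curve_fit(
                _model_response, x, y, p0=p0,
                bounds=([-np.inf, -np.inf], [np.inf, 0.0]),
                maxfev=10000,
            )
            return popt, pcov
        except (RuntimeError, ValueError):
            pass
        # Grid-search fallback over the documented parameter box.
        grid_l = np.linspace(-4.0, 0.0, 41)
        grid_h = np.linspace(-5.0, -0.1, 25)
        best, best_sse = None, np.inf
        for li in grid_l:
            for hi in grid_h:
                r = y - _model_response(x, li, hi)
                sse = float(r @ r)
                if sse < best_sse:
                    best, best_sse = (li, hi), sse
        try:
            popt, pcov = optimize.curve_fit(
                _model_response, x, y, p0=best,
                bounds=([-np.inf, -np.inf], [np.inf, 0.0]),
                maxfev=10000,
            )
            return popt, pcov
        except (RuntimeError, ValueError) as exc:
            raise ConvergenceError(
                f"dose-response fit failed; best grid point {best} "
                f"(SSE {best_sse:.4g})"
            ) from exc


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted dose-response parameters with uncertainty and diagnostics."""

    log_ic50: float
    hill_slope: float
    bse: tuple
    _conf_int: tuple
    residual_sse: float
    n_points: int
    source: str
    model: DoseResponse = field(repr=False, compare=False, default=None)

    @property
    def ic50_mM(self) -> float:
        return 1000.0 * 10.0 ** self.log_ic50

    @property
    def log_ic50_ci(self) -> tuple:
        """95% confidence interval on LogIC50 (log10 mol/L)."""
        return self._conf_int[0]

    @property
    def hill_slope_ci(self) -> tuple:
        return self._conf_int[1]

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self._conf_int),
            index=["log_ic50", "hill_slope"],
            columns=["lower", "upper"],
        )

    def predict(self, concentrations_mM) -> np.ndarray:
        c = np.asarray(concentrations_mM, dtype=float)
        return _model_response(np.log10(c / 1000.0), self.log_ic50, self.hill_slope)

    def to_dict(self) -> dict:
        return {
            "log_ic50": self.log_ic50,
            "hill_slope": self.hill_slope,
            "ic50_mM": self.ic50_mM,
            "log_ic50_ci": list(self.log_ic50_ci),
            "hill_slope_ci": list(self.hill_slope_ci),
            "residual_sse": self.residual_sse,
            "n_points": self.n_points,
            "source": self.source,
        }

    def summary(self) -> str:
        lo, hi = self.log_ic50_ci
        hlo, hhi = self.hill_slope_ci
        lines = [
            "Dose-response fit (normalized, variable slope)",
            "=" * 54,
            f"source:        {self.source}",
            f"n points:      {self.n_points}",
            f"LogIC50:       {self.log_ic50: .4f}  "
            f"(95% CI {lo: .4f}, {hi: .4f})  [log10 M]",
            f"IC50:          {self.ic50_mM: .3f} mM",
            f"HillSlope:     {self.hill_slope: .4f}  "
            f"(95% CI {hlo: .4f}, {hhi: .4f})",
            f"residual SSE:  {self.residual_sse: .4g}",
        ]
        return "\n".join(lines)


def fit_dose_response(concentrations_mM, normalized_responses,
                      source: str = "endpoint", **fit_kw) -> DoseResponseResults:
    """Convenience wrapper: build a :class:`DoseResponse` and fit it."""
    return DoseResponse(concentrations_mM, normalized_responses,
                        source=source).fit(**fit_kw)


def _window_regression(t, logy):
    slope, intercept, r, _, _ = stats.linregress(t, logy)
    return slope, (0.0 if np.isnan(r) else r * r)


def estimate_growth_rate(curves: GrowthCurveSet, min_points: int = 4,
                         r2_threshold: float = 0.9) -> pd.DataFrame:
    """Exponential-phase growth rate per perchlorate level.

    For each level, replicate measurements are pooled and a sliding
    window (every contiguous run of >= ``min_points`` time points) is
    scored by the R^2 of a linear regression of ln(measurement) on time.
    Among windows within 1e-6 of the best R^2 the steepest is taken, so a
    flat saturated tail cannot shadow the exponential phase.  Windows
    never reaching ``r2_threshold`` yield a flagged estimate with a
    warning.

    Returns a frame with columns perchlorate_mM, rate_per_h, r_squared,
    window_start_h, window_end_h, flagged.
    """
    rows = []
    for level, grp in curves.data.groupby("perchlorate_mM"):
        grp = grp[grp["measurement"] > 0]
        times = np.sort(grp["time_h"].unique())
        best = None  # (r2, slope, t0, t1)
        candidates = []
        for i in range(len(times)):
            for j in range(i + min_points - 1, len(times)):
                window = grp[grp["time_h"].between(times[i], times[j])]
                slope, r2 = _window_regression(
                    window["time_h"].to_numpy(),
                    np.log(window["measurement"].to_numpy()),
                )
                candidates.append((r2, slope, times[i], times[j]))
        if not candidates:
            rows.append(
                {"perchlorate_mM": level, "rate_per_h": 0.0, "r_squared": 0.0,
                 "window_start_h": np.nan, "window_end_h": np.nan,
                 "flagged": True}
            )
            warnings.warn(f"no usable window at p={level} mM", stacklevel=2)
            continue
        best_r2 = max(c[0] for c in candidates)
        near = [c for c in candidates if c[0] >= best_r2 - 1e-6]
        r2, slope, t0, t1 = max(near, key=lambda c: (c[1], c[3] - c[2]))
        flagged = r2 < r2_threshold
        if flagged:
            warnings.warn(
                f"growth-rate window at p={level} mM has R^2={r2:.3f} "
                f"< {r2_threshold}; estimate flagged",
                stacklevel=2,
            )
        rows.append(
            {"perchlorate_mM": level, "rate_per_h": slope, "r_squared": r2,
             "window_start_h": t0, "window_end_h": t1, "flagged": flagged}
        )
    return pd.DataFrame(rows)


def dose_response_from_growth_rates(rates, **fit_kw) -> DoseResponseResults:
    """Fit the inhibition curve to control-normalised growth rates.

    ``rates`` is either the frame returned by
    :func:`estimate_growth_rate` or a mapping {perchlorate_mM: rate}.
    The 0 mM control rate (mean, if replicated) must be positive; all
    rates are divided by it before fitting.
    """
    if isinstance(rates, dict):
        df = pd.DataFrame(
            {"perchlorate_mM": list(rates), "rate_per_h": list(rates.values())}
        )
    else:
        df = rates
    control = df.loc[df["perchlorate_mM"] == 0, "rate_per_h"]
    if control.empty:
        raise ValueError("a 0 mM control rate is required")
    control_rate = control.mean()
    if not control_rate > 0:
        raise ValueError(f"control growth rate must be > 0, got {control_rate}")
    nz = df[df["perchlorate_mM"] > 0]
    # a batch culture cannot shrink in this model: slightly negative rate
    # estimates from flat, noisy curves are floored at zero
    normalized = np.clip(nz["rate_per_h"] / control_rate, 0.0, 1.2)
    return fit_dose_response(
        nz["perchlorate_mM"], normalized, source="growth_rate", **fit_kw,
    )


def fit_sulfide_calibration(srm_percents, sulfide_mMs,
                            on_means: bool = False) -> SulfideCalibration:
    """OLS regression of log10(sulfide) on log10(%SRM).

    ``on_means`` averages replicate pairs sharing an %SRM value before
    regressing (recorded in the result's ``fit_on`` field); the default
    uses every point.  Requires >= 3 positive pairs.
    """
    x = np.asarray(srm_percents, dtype=float)
    y = np.asarray(sulfide_mMs, dtype=float)
    if x.size != y.size:
        raise ValueError("srm_percents and sulfide_mMs must match in length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log regression requires strictly positive values")
    if on_means:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False).mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if x.size < 3:
        raise ValueError("need >= 3 pairs for the calibration regression")
    lx, ly = np.log10(x), np.log10(y)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    return SulfideCalibration(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_points=int(x.size),
        fit_on="replicate_means" if on_means else "all_points",
    )


def ic50_fold_change(fit_treated: DoseResponseResults,
                     fit_control: DoseResponseResults) -> float:
    """IC50 ratio treated/control: ``10**(logIC50_t - logIC50_c)``."""
    return 10.0 ** (fit_treated.log_ic50 - fit_control.log_ic50)
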