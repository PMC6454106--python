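"""Pointwise model functions: inhibition curve and sulfide conversion.

These two scalar maps are composed by every other module:

* the variable-slope dose-response curve giving the fraction ``y`` of the
  maximal growth rate retained at a perchlorate concentration ``P``:

  .. math:: y = \\frac{1}{1 + 10^{(\\mathrm{LogIC50} - \\log_{10} P)\\,h}}

  with ``P`` in mol/L inside the log (the API takes mM) and ``h`` the
  signed (negative) Hill slope; and

* the empirical log-log regression converting total SRM percent to
  effluent sulfide, ``[sulfide] = 10^{a \\log_{10} N_t + b}``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params import StrainParams, SulfideCalibration

__all__ = [
    "inhibition_fraction",
    "effective_growth_rate",
    "sulfide_from_srm",
    "srm_from_sulfide",
]

_LN10 = np.log(10.0)


def _maybe_scalar(x: np.ndarray, scalar: bool) -> float | np.ndarray:
    return float(x[0]) if scalar else x


def inhibition_fraction(p, strain: StrainParams):
    """Fraction of the maximal growth rate retained at perchlorate ``p`` (mM).

    Returns 1 exactly at ``p = 0`` (continuous limit of the curve) and 0.5
    exactly at the IC50.  Monotone non-increasing in ``p`` for a negative
    Hill slope.  Accepts scalars or arrays; ``p < 0`` raises ``ValueError``.
    """
    p_arr = np.asarray(p, dtype=float)
    scalar = p_arr.ndim == 0
    p_arr = np.atleast_1d(p_arr)
    if np.any(p_arr < 0) or np.any(np.isnan(p_arr)):
        raise ValueError("perchlorate concentration must be >= 0 mM")
    with np.errstate(divide="ignore"):
        log_p_molar = np.log10(p_arr / 1000.0)  # -inf at p = 0
    z = (strain.log_ic50 - log_p_molar) * strain.hill_slope
    # 1/(1 + 10^z) written through the logistic for overflow safety;
    # z -> -inf at p = 0 gives exactly 1.
    y = expit(-_LN10 * z)
    return _maybe_scalar(y, scalar)


def effective_growth_rate(p, strain: StrainParams):
    """Specific growth rate mu(P) = mu_max * y(P), 1/h, at perchlorate ``p`` mM."""
    return strain.mu_max * inhibition_fraction(p, strain)


def sulfide_from_srm(n_t, calib: SulfideCalibration):
    """Convert total SRM percent to effluent sulfide (mM).

    Domain error for non-positive ``n_t`` (the regression lives in log-log
    space); simulation callers floor ``n_t`` before converting.
    """
    n_arr = np.asarray(n_t, dtype=float)
    scalar = n_arr.ndim == 0
    n_arr = np.atleast_1d(n_arr)
    if np.any(n_arr <= 0) or np.any(np.isnan(n_arr)):
        raise ValueError("total SRM percent must be > 0 for the log-log conversion")
    s = 10.0 ** (calib.slope * np.log10(n_arr) + calib.intercept)
    return _maybe_scalar(s, scalar)


def srm_from_sulfide(s, calib: SulfideCalibration):
    """Exact inverse of :func:`sulfide_from_srm` (sulfide mM -> SRM percent)."""
    if calib.slope == 0:
        raise ValueError("calibration slope must be nonzero to invert")
    s_arr = np.asarray(s, dtype=float)
    scalar = s_arr.ndim == 0
    s_arr = np.atleast_1d(s_arr)
    if np.any(s_arr <= 0) or np.any(np.isnan(s_arr)):
        raise ValueError("sulfide must be > 0 mM to invert the log-log regression")
    n = 10.0 ** ((np.log10(s_arr) - calib.intercept) / calib.slope)
    return _maybe_scalar(n, scalar)
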