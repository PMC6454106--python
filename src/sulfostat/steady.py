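"""Closed-form steady-state and threshold analytics.

These are the algebraic consequences of the logistic-chemostat equations,
used both for interpretation (when does the planktonic pool wash out?
what sulfide level does wall growth sustain?) and as independent oracles
for the numerical integrator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import effective_growth_rate, sulfide_from_srm
from .params import StrainParams, SulfideCalibration

__all__ = [
    "planktonic_steady_state",
    "washout_condition",
    "critical_perchlorate",
    "inhibited_sulfide_floor",
    "rebound_time",
    "NO_REBOUND",
    "steady_state_table",
]

NO_REBOUND = "no rebound"


def planktonic_steady_state(strain: StrainParams, k_p: float, dilution: float,
                            p: float = 0.0) -> float:
    """Long-run planktonic SRM percent at constant perchlorate ``p`` (mM).

    The logistic-minus-washout fixed point ``Kp (1 - D/mu(p))`` when
    ``mu(p) > D``; 0 (washout) otherwise.  The tie ``mu(p) = D`` is
    assigned to washout.
    """
    if dilution < 0:
        raise ValueError("dilution must be >= 0")
    mu = effective_growth_rate(p, strain)
    if mu > dilution:
        return k_p * (1.0 - dilution / mu)
    return 0.0


def washout_condition(strain: StrainParams, dilution: float, p: float) -> bool:
    """True when the planktonic pool washes out: ``mu(p) < D``."""
    return bool(effective_growth_rate(p, strain) < dilution)


def critical_perchlorate(strain: StrainParams, dilution: float,
                         tol: float = 1e-10) -> float:
    """Perchlorate concentration (mM) at which ``mu(p) = D``.

    Inflow above this threshold washes the planktonic pool out; below it,
    a positive steady state persists.  Solved by bracketed root finding on
    the monotone inhibition curve to ``|mu(p) - D| < tol``.
    """
    if strain.mu_max <= dilution:
        raise ValueError(
            "mu_max <= D: the population washes out even untreated, "
            "no finite critical concentration exists"
        )
    if dilution <= 0:
        raise ValueError("dilution must be > 0 for a finite threshold")

    def f(log_p):
        return effective_growth_rate(10.0 ** log_p, strain) - dilution

    lo, hi = -12.0, 12.0  # log10 mM; spans any physical concentration
    root = brentq(f, lo, hi, xtol=1e-14)
    p = 10.0 ** root
    assert abs(effective_growth_rate(p, strain) - dilution) < tol
    return p


def inhibited_sulfide_floor(k_a: float, calib: SulfideCalibration) -> float:
    """Sulfide (mM) sustained by the attached pool alone after washout.

    With the planktonic compartment washed out the attached pool sits at
    its carrying capacity, so the floor is the calibration evaluated at
    ``Nt = Ka``; zero when there is no attachment.
    """
    if k_a < 0:
        raise ValueError("k_a must be >= 0")
    if k_a == 0:
        return 0.0
    return float(sulfide_from_srm(k_a, calib))


def rebound_time(sim_result, pre_treatment_level: float,
                 tolerance: float = 0.1):
    """Hours from treatment cessation until sulfide recovers.

    Recovery means sulfide first reaching ``(1 - tolerance)`` times the
    pre-treatment level after the cessation breakpoint.  An untreated run
    already at that level reports 0; a run whose sulfide never recovers
    within the horizon reports :data:`NO_REBOUND`.
    """
    if not pre_treatment_level > 0:
        raise ValueError("pre_treatment_level must be > 0")
    config = sim_result.config
    threshold = (1.0 - tolerance) * pre_treatment_level
    treated = any(c > 0 for _, c in config.schedule)
    cessation = config.treatment_cessation_time()
    if treated and cessation is None:
        raise ValueError("schedule has treatment but no cessation breakpoint")
    if not treated:
        if sim_result.sulfide[0] >= threshold:
            return 0.0
        cessation = 0.0
    after = sim_result.times >= cessation
    hits = after & (sim_result.sulfide >= threshold)
    if not hits.any():
        return NO_REBOUND
    return float(sim_result.times[hits][0] - cessation)


def steady_state_table(strain: StrainParams, k_p: float, k_a: float,
                       dilution: float, calib: SulfideCalibration,
                       gradient) -> pd.DataFrame:
    """Tabulate mu(p), washout flag, steady n_p and floor sulfide on a gradient."""
    rows = []
    for p in np.asarray(gradient, dtype=float):
        mu = effective_growth_rate(p, strain)
        n_p = planktonic_steady_state(strain, k_p, dilution, p)
        n_t = n_p + k_a
        rows.append(
            {
                "perchlorate_mM": p,
                "mu_per_h": mu,
                "washout": washout_condition(strain, dilution, p),
                "steady_n_p_pct": n_p,
                "steady_n_t_pct": n_t,
                "steady_sulfide_mM": float(sulfide_from_srm(max(n_t, 1e-6), calib)),
            }
        )
    return pd.DataFrame(rows)
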