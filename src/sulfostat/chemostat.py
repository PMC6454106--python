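"""Continuous-culture simulation of perchlorate-inhibited sulfidogenesis.

The vessel is a well-mixed chemostat of volume ``V`` (mL) fed at flow
``F`` (mL/h), dilution rate ``D = F/V``.  Three coupled states evolve:

* perchlorate, a linear wash-in/wash-out balance
  ``dP/dt = D (P_in(t) - P)`` with a piecewise-constant inflow schedule;
* planktonic SRM, logistic growth minus washout
  ``dNp/dt = mu(P) Np (1 - Np/Kp) - D Np``;
* surface-attached SRM, logistic growth with no washout
  ``dNa/dt = mu(P) Na (1 - Na/Ka)``.

``mu(P) = mu_max * y(P)`` couples the compartments to the dose-response
curve.  The compartments do not exchange biomass.  Abundances are percent
of community; sulfide is obtained from ``Nt = Np + Na`` through the
log-log calibration.

Batch (no-flow) co-culture growth across a perchlorate gradient, used to
emulate endpoint plate assays for mixtures of strains, lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import effective_growth_rate, sulfide_from_srm
from .params import CompartmentParams, StrainParams, SulfideCalibration

__all__ = [
    "ChemostatConfig",
    "SimResult",
    "SimulationError",
    "perchlorate_trajectory",
    "simulate",
    "simulate_batch_mixture",
    "effective_mixture_dose_response",
]

# Nt is floored here before the log-log sulfide conversion (log(0) guard).
SULFIDE_CONVERSION_FLOOR_PCT = 1e-6


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid state."""


@dataclass(frozen=True)
class ChemostatConfig:
    """Full configuration of one chemostat run.

    ``schedule`` is an ordered list of ``(t_start_h, inflow_perchlorate_mM)``
    segments; the first must start at t = 0 and starts must strictly
    increase.  ``initial_state = None`` starts the vessel at its untreated
    steady state ``(Kp (1 - D/mu_max), Ka, 0)``, matching the protocol of
    treating only after sulfide production has stabilised.
    """

    strain: StrainParams
    compartments: CompartmentParams
    calib: SulfideCalibration
    volume_ml: float = 125.0
    flow_ml_per_h: float = 2.6
    schedule: tuple = ((0.0, 0.0),)
    t_end_h: float = 1000.0
    initial_state: tuple | None = None  # (n_p %, n_a %, P mM)
    n_p_floor: float = 1e-9  # percent; keeps deep washout recoverable
    output_dt_h: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise ValueError("volume_ml must be > 0")
        if self.flow_ml_per_h < 0:
            raise ValueError("flow_ml_per_h must be >= 0")
        if not self.t_end_h > 0:
            raise ValueError("t_end_h must be > 0")
        sched = tuple((float(t), float(c)) for t, c in self.schedule)
        if not sched or sched[0][0] != 0.0:
            raise ValueError("schedule must start with a segment at t = 0")
        starts = [t for t, _ in sched]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must strictly increase")
        if any(c < 0 for _, c in sched):
            raise ValueError("inflow perchlorate must be >= 0 mM")
        object.__setattr__(self, "schedule", sched)

    @property
    def dilution(self) -> float:
        """Dilution rate D = F/V, 1/h."""
        return self.flow_ml_per_h / self.volume_ml

    @property
    def residence_time_h(self) -> float:
        """Hydraulic residence time V/F, h."""
        if self.flow_ml_per_h == 0:
            return np.inf
        return self.volume_ml / self.flow_ml_per_h

    def steady_initial_state(self) -> tuple:
        """Untreated steady state (n_p, n_a, P=0) used when none is given."""
        d = self.dilution
        mu = self.strain.mu_max
        n_p = self.compartments.k_p * (1.0 - d / mu) if mu > d else 0.0
        n_p = max(n_p, self.n_p_floor)
        return (n_p, self.compartments.k_a, 0.0)

    def resolved_initial_state(self) -> tuple:
        if self.initial_state is not None:
            n_p, n_a, p0 = (float(v) for v in self.initial_state)
            if min(n_p, n_a, p0) < 0:
                raise ValueError("initial state must be non-negative")
            return (n_p, n_a, p0)
        return self.steady_initial_state()

    def segment_bounds(self) -> list:
        """Schedule as closed segments [(t0, t1, inflow_mM), ...] up to t_end."""
        starts = [t for t, _ in self.schedule] + [self.t_end_h]
        return [
            (starts[i], starts[i + 1], self.schedule[i][1])
            for i in range(len(self.schedule))
            if starts[i] < self.t_end_h
        ]

    def treatment_cessation_time(self) -> float | None:
        """Time of the last >0 -> 0 inflow transition, or None if absent."""
        cess = None
        for (t0, c0), (t1, c1) in zip(self.schedule, self.schedule[1:]):
            if c0 > 0 and c1 == 0:
                cess = t1
        return cess


@dataclass
class SimResult:
    """Time-indexed model trajectories from one simulated run."""

    times: np.ndarray
    n_p: np.ndarray
    n_a: np.ndarray
    perchlorate: np.ndarray
    sulfide: np.ndarray
    config: ChemostatConfig

    @property
    def n_t(self) -> np.ndarray:
        return self.n_p + self.n_a

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "n_p_pct": self.n_p,
                "n_a_pct": self.n_a,
                "n_t_pct": self.n_t,
                "perchlorate_mM": self.perchlorate,
                "sulfide_mM": self.sulfide,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Quick-look sulfide/perchlorate trajectory plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.sulfide, label="sulfide (mM)")
        ax2 = ax.twinx()
        ax2.plot(self.times, self.perchlorate, color="C3", alpha=0.6,
                 label="perchlorate (mM)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("sulfide (mM)")
        ax2.set_ylabel("perchlorate (mM)")
        return ax


def perchlorate_trajectory(config: ChemostatConfig, t):
    """Closed-form perchlorate concentration (mM) at time(s) ``t``.

    Within a schedule segment with constant inflow ``P_in`` the balance
    ``dP/dt = D (P_in - P)`` integrates to
    ``P(t) = P_in + (P_seg_start - P_in) exp(-D dt)``.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0) or np.any(t_arr > config.t_end_h + 1e-9):
        raise ValueError("t must lie within [0, t_end_h]")
    d = config.dilution
    p = np.empty_like(t_arr)
    p_seg = config.resolved_initial_state()[2]
    for t0, t1, p_in in config.segment_bounds():
        mask = (t_arr >= t0) & (t_arr <= t1) if t1 >= config.t_end_h else (
            (t_arr >= t0) & (t_arr < t1)
        )
        p[mask] = p_in + (p_seg - p_in) * np.exp(-d * (t_arr[mask] - t0))
        p_seg = p_in + (p_seg - p_in) * np.exp(-d * (t1 - t0))
    return float(p[0]) if scalar else p


def _rhs(config: ChemostatConfig, p_in: float, p_seg0: float, t_seg0: float):
    # perchlorate decouples from the biology and is linear, so within a
    # segment it is evaluated by its exact solution rather than
    # co-integrated; the biomass ODEs then see an error-free mu(t)
    k_p = config.compartments.k_p
    k_a = config.compartments.k_a
    d = config.dilution
    strain = config.strain

    def p_exact(t):
        return p_in + (p_seg0 - p_in) * np.exp(-d * (t - t_seg0))

    def rhs(t, y):
        n_p, n_a = y
        mu = effective_growth_rate(p_exact(t), strain)
        dn_p = mu * n_p * (1.0 - n_p / k_p) - d * n_p
        dn_a = mu * n_a * (1.0 - n_a / k_a) if k_a > 0 else 0.0
        return (dn_p, dn_a)

    return rhs, p_exact


def simulate(config: ChemostatConfig, times=None) -> SimResult:
    """Integrate the model over the treatment schedule.

    Integration restarts at every schedule breakpoint (the inflow is
    discontinuous there), using a stiff-capable adaptive solver (LSODA,
    rtol/atol from the config); within each segment the linear
    perchlorate balance is evaluated by its exact exponential solution,
    so mu(t) carries no solver error.  The planktonic state is floored at
    ``config.n_p_floor`` so rebound from deep washout remains possible.
    Output is sampled on ``times`` or on a uniform grid of
    ``output_dt_h``.
    """
    if config.compartments.k_a == 0 and config.resolved_initial_state()[1] > 0:
        raise ValueError("k_a = 0 requires a zero attached inoculum")
    if times is None:
        times = np.arange(0.0, config.t_end_h + config.output_dt_h / 2,
                          config.output_dt_h)
        times[-1] = min(times[-1], config.t_end_h)
    times = np.asarray(times, dtype=float)

    n_p0, n_a0, p0 = config.resolved_initial_state()
    state = np.array([n_p0, n_a0], dtype=float)
    p_seg = p0
    out = np.empty((times.size, 3))
    filled = np.zeros(times.size, dtype=bool)

    for t0, t1, p_in in config.segment_bounds():
        state[0] = max(state[0], config.n_p_floor)
        mask = (times >= t0 - 1e-12) & (
            (times < t1) if t1 < config.t_end_h else (times <= t1 + 1e-12)
        )
        t_eval = times[mask]
        rhs, p_exact = _rhs(config, p_in, p_seg, t0)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            state,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=config.rtol,
            atol=config.atol,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE solver failed in segment [{t0}, {t1}] h: {sol.message}"
            )
        if t_eval.size:
            out[mask, :2] = sol.y.T
            out[mask, 2] = p_exact(t_eval)
            filled |= mask
        state = sol.y[:, -1].copy()
        p_seg = p_exact(t1)

    if not filled.all():
        raise SimulationError("output grid points fell outside all segments")

    if out.min() < -1e-6:
        raise SimulationError(
            f"negative state encountered (min {out.min():.3g}); "
            "tighten rtol/atol"
        )
    out = np.clip(out, 0.0, None)
    out[:, 0] = np.maximum(out[:, 0], config.n_p_floor)

    n_t = out[:, 0] + out[:, 1]
    sulfide = sulfide_from_srm(
        np.maximum(n_t, SULFIDE_CONVERSION_FLOOR_PCT), config.calib
    )
    return SimResult(
        times=times,
        n_p=out[:, 0],
        n_a=out[:, 1],
        perchlorate=out[:, 2],
        sulfide=np.asarray(sulfide),
        config=config,
    )


def simulate_batch_mixture(
    strains,
    initial_percents,
    p: float,
    duration: float,
    capacity: float = 100.0,
    times=None,
):
    """Batch (no dilution) growth of a strain mixture at fixed perchlorate.

    Each strain grows logistically at its own inhibited rate
    ``mu_i = mu_max,i * y_i(p)`` against one shared ceiling (the strains
    compete for a single niche):

    ``dN_i/dt = mu_i N_i (1 - sum_j N_j / K)``

    Returns ``(final_percents, total)``; pass ``times`` to obtain the full
    trajectory as a third element.
    """
    strains = list(strains)
    if not strains:
        raise ValueError("need at least one strain")
    n0 = np.asarray(initial_percents, dtype=float)
    if n0.size != len(strains):
        raise ValueError("strains and initial_percents must have equal length")
    if np.any(n0 < 0):
        raise ValueError("initial abundances must be >= 0")
    if not duration > 0:
        raise ValueError("duration must be > 0")
    mus = np.array([effective_growth_rate(p, s) for s in strains])

    def rhs(t, y):
        crowd = 1.0 - y.sum() / capacity
        return mus * y * crowd

    t_eval = None if times is None else np.asarray(times, dtype=float)
    sol = solve_ivp(rhs, (0.0, duration), n0, method="LSODA",
                    t_eval=t_eval, rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise SimulationError(f"batch mixture solve failed: {sol.message}")
    final = sol.y[:, -1]
    if times is None:
        return final, float(final.sum())
    return final, float(final.sum()), sol.y


def effective_mixture_dose_response(
    strains,
    initial_percents,
    gradient,
    duration: float,
    capacity: float = 100.0,
) -> pd.DataFrame:
    """Endpoint dose-response of a strain mixture across a gradient.

    Emulates the plate assay: grow the mixture in batch at each gradient
    concentration for ``duration`` hours, then normalise the total final
    biomass to the 0 mM control well.  The gradient must contain a 0 mM
    control.  Returns a DataFrame with columns ``concentration_mM`` and
    ``response`` (control-normalised, ~[0, 1]).
    """
    grad = np.asarray(gradient, dtype=float)
    if not np.any(grad == 0):
        raise ValueError("gradient must include a 0 mM control well")
    totals = np.array(
        [
            simulate_batch_mixture(strains, initial_percents, p, duration,
                                   capacity=capacity)[1]
            for p in grad
        ]
    )
    control = totals[grad == 0].mean()
    return pd.DataFrame(
        {"concentration_mM": grad, "response": totals / control}
    )
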