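"""Synthetic-data generation with known ground truth.

Every input the analysis pipeline consumes can be generated here:
replicated chemostat sulfide/%SRM time series under on/off treatment
schedules, two-fold serial-dilution gradient plates, batch growth curves
at fixed perchlorate, and a toy genus-level relative-abundance table from
which the %SRM signal can be re-extracted.  All generators are
seed-deterministic (identical seed, identical output) and return the
noise-free truth alongside the observations so recovery can be scored.

Sulfide observation noise is multiplicative-lognormal by default:
replicate scatter in chemostat sulfide data scales roughly with the
mean, which additive noise cannot mimic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .chemostat import ChemostatConfig, SimResult, simulate
from .core import effective_growth_rate, inhibition_fraction
from .fitting import GradientPlate, GrowthCurveSet
from .params import StrainParams

__all__ = [
    "NoiseModel",
    "SyntheticChemostatSeries",
    "gen_chemostat_timeseries",
    "gen_plate_gradient",
    "gen_growth_curves",
    "gen_community_table",
    "srm_fraction_from_table",
    "SRM_GENERA",
]

# The four SRM genera whose summed relative abundance defines %SRM, with
# the fixed proportions used to split the synthetic SRM mass among them
# (Desulfovibrio-dominant).
SRM_GENERA = {
    "Desulfovibrio": 0.60,
    "Desulforhopalus": 0.15,
    "Desulfocurvus": 0.15,
    "Desulfomicrobium": 0.10,
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification.

    kind : "multiplicative-lognormal" (sd is the log-space standard
        deviation) or "additive-gaussian" (sd in measurement units).
    seed : integer seed; identical seeds give bit-identical output.
    """

    kind: str = "multiplicative-lognormal"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sd == 0:
            return values.copy()
        if self.kind == "multiplicative-lognormal":
            return values * np.exp(rng.normal(0.0, self.sd, values.shape))
        return values + rng.normal(0.0, self.sd, values.shape)


@dataclass
class SyntheticChemostatSeries:
    """Observed replicate series plus the noise-free truth behind them."""

    observations: pd.DataFrame  # time_h, replicate, sulfide_mM, srm_pct
    truth: SimResult
    noise: NoiseModel

    def write(self, outdir) -> None:
        """Write observations CSV per replicate plus a ground-truth sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rep, grp in self.observations.groupby("replicate"):
            grp.to_csv(outdir / f"chemostat_rep{rep}.csv", index=False)
        self.truth.to_frame().to_csv(outdir / "chemostat_truth.csv", index=False)
        sidecar = {
            "noise": asdict(self.noise),
            "strain": asdict(self.truth.config.strain),
            "schedule": list(self.truth.config.schedule),
        }
        (outdir / "chemostat_truth.json").write_text(json.dumps(sidecar, indent=2))


def gen_chemostat_timeseries(
    config: ChemostatConfig,
    noise: NoiseModel,
    replicates: int = 3,
    sampling_interval_h: float = 12.0,
    include_srm: bool = True,
) -> SyntheticChemostatSeries:
    """Simulate once, then draw noisy replicate observations.

    Observations are taken every ``sampling_interval_h`` (default 12 h,
    mimicking at-most-daily manual sampling) and perturbed per replicate
    by the noise model; the underlying noise-free :class:`SimResult` is
    returned alongside.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    times = np.arange(0.0, config.t_end_h + 1e-9, sampling_interval_h)
    truth = simulate(config, times=times)
    rng = noise.rng()
    frames = []
    for rep in range(1, replicates + 1):
        obs = {
            "time_h": times,
            "replicate": rep,
            "sulfide_mM": noise.apply(truth.sulfide, rng),
        }
        if include_srm:
            obs["srm_pct"] = noise.apply(truth.n_t, rng)
        frames.append(pd.DataFrame(obs))
    return SyntheticChemostatSeries(
        observations=pd.concat(frames, ignore_index=True),
        truth=truth,
        noise=noise,
    )


def gen_plate_gradient(
    strain: StrainParams,
    top_mM: float = 500.0,
    n_dilutions: int = 12,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 1,
    control_signal: float = 1.0,
) -> GradientPlate:
    """Two-fold serial-dilution endpoint plate for one strain.

    Concentrations run ``{top, top/2, ..., top/2^(n-1), 0}``; the
    noise-free response at concentration ``p`` is
    ``control_signal * y(p)`` with ``y`` the strain's inhibition
    fraction, so control-normalising a noise-free plate returns the
    inhibition curve exactly.
    """
    if n_dilutions < 4:
        raise ValueError("need >= 4 dilutions for a fittable gradient")
    conc = top_mM / 2.0 ** np.arange(n_dilutions)
    conc = np.append(conc, 0.0)
    clean = control_signal * inhibition_fraction(conc, strain)
    rng = noise.rng()
    all_conc, all_resp = [], []
    for _ in range(replicates):
        all_conc.append(conc)
        all_resp.append(noise.apply(clean, rng))
    return GradientPlate(
        tuple(np.concatenate(all_conc)), tuple(np.concatenate(all_resp))
    )


def gen_growth_curves(
    strain: StrainParams,
    perchlorate_levels,
    duration_h: float = 48.0,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    dt_h: float = 2.0,
    n0: float = 0.01,
    capacity: float = 1.0,
    lag_h: float = 0.0,
) -> GrowthCurveSet:
    """Batch logistic growth curves at fixed perchlorate levels.

    Each curve follows the closed-form logistic
    ``N(t) = K / (1 + (K/N0 - 1) exp(-mu (t - lag)))`` (flat at ``N0``
    during the lag) with intrinsic rate ``mu = mu(p)``; the duration
    should cover a few doublings at ``mu_max`` for rate estimation to
    have an exponential window to find.
    """
    levels = np.asarray(perchlorate_levels, dtype=float)
    doublings = strain.mu_max * duration_h / np.log(2.0)
    if doublings < 3:
        warnings.warn(
            f"duration covers only {doublings:.1f} doublings at mu_max; "
            "rate estimation may lack an exponential window",
            stacklevel=2,
        )
    times = np.arange(0.0, duration_h + 1e-9, dt_h)
    rng = noise.rng()
    rows = []
    for level in levels:
        mu = effective_growth_rate(level, strain)
        t_eff = np.clip(times - lag_h, 0.0, None)
        clean = capacity / (1.0 + (capacity / n0 - 1.0) * np.exp(-mu * t_eff))
        for rep in range(1, replicates + 1):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": times,
                        "perchlorate_mM": level,
                        "replicate": rep,
                        "measurement": noise.apply(clean, rng),
                    }
                )
            )
    return GrowthCurveSet(pd.concat(rows, ignore_index=True))


def gen_community_table(
    n_t_trajectory,
    filler_taxa: int = 8,
    concentration_param: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genus-level relative-abundance table embedding a known %SRM signal.

    The SRM mass of each sample is split across the four SRM genera in
    fixed (Desulfovibrio-dominant) proportions; the remaining mass is
    split across ``filler_taxa`` exchangeable filler genera by a
    symmetric Dirichlet draw.  Rows sum to 100.
    """
    n_t = np.asarray(n_t_trajectory, dtype=float)
    if np.any(n_t <= 0) or np.any(n_t >= 100):
        raise ValueError("n_t values must lie strictly within (0, 100) percent")
    if filler_taxa < 1:
        raise ValueError("need at least one filler taxon")
    rng = np.random.default_rng(seed)
    fillers = [f"Filler_{i:02d}" for i in range(1, filler_taxa + 1)]
    rows = []
    for nt in n_t:
        row = {g: nt * frac for g, frac in SRM_GENERA.items()}
        weights = rng.dirichlet(np.full(filler_taxa, concentration_param))
        row.update({g: (100.0 - nt) * w for g, w in zip(fillers, weights)})
        rows.append(row)
    table = pd.DataFrame(rows)
    table.index.name = "sample"
    return table


def srm_fraction_from_table(table: pd.DataFrame, srm_genus_list=None):
    """Row-wise %SRM: summed relative abundance of the listed genera.

    Genera absent from the table contribute 0 (with a warning), matching
    how a fixed marker-genus list is applied to a survey table that may
    not contain every genus.
    """
    if srm_genus_list is None:
        srm_genus_list = list(SRM_GENERA)
    srm_genus_list = list(srm_genus_list)
    if not srm_genus_list:
        raise ValueError("genus list must be non-empty")
    present = [g for g in srm_genus_list if g in table.columns]
    missing = sorted(set(srm_genus_list) - set(present))
    if missing:
        warnings.warn(f"genera not in table treated as 0: {missing}", stacklevel=2)
    if not present:
        return pd.Series(np.zeros(len(table)), index=table.index, name="srm_pct")
    return table[present].sum(axis=1).rename("srm_pct")
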