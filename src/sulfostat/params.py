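"""Parameter containers and published presets.

The model carries SRM abundance on a 0-100 "percent of community" scale
(never a 0-1 fraction) and perchlorate concentrations in mM throughout the
public API.  The one deliberate unit subtlety lives in the dose-response
curve: ``log_ic50`` is the base-10 log of a *molar* concentration, so the
community preset's ``log_ic50 = -1.914`` corresponds to an IC50 of
``10**-1.914 mol/L ~= 12.2 mM``.  Conversion happens inside
:func:`sulfostat.core.inhibition_fraction`, never at call sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "StrainParams",
    "SulfideCalibration",
    "CompartmentParams",
    "get_strain_preset",
    "get_calibration_preset",
    "get_compartment_preset",
    "get_vessel_preset",
    "list_presets",
]


@dataclass(frozen=True)
class StrainParams:
    """Growth and inhibition constants for a strain or whole community.

    Parameters
    ----------
    name : str
        Label (e.g. ``"community"``, ``"bmsr"``).
    mu_max : float
        Maximal specific growth rate, 1/h. Must be positive.
    log_ic50 : float
        log10 of the half-inhibitory perchlorate concentration in mol/L.
    hill_slope : float
        Signed slope of the variable-slope dose-response curve; negative
        for an inhibitor.
    """

    name: str
    mu_max: float
    log_ic50: float
    hill_slope: float

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not self.hill_slope < 0:
            raise ValueError(
                f"hill_slope must be < 0 (inhibition), got {self.hill_slope}"
            )
        ic50 = 10.0 ** self.log_ic50
        if not (math.isfinite(ic50) and ic50 > 0):
            raise ValueError(f"10**log_ic50 not a finite concentration: {self.log_ic50}")

    @property
    def ic50_mM(self) -> float:
        """Half-inhibitory concentration on the API's mM scale."""
        return 1000.0 * 10.0 ** self.log_ic50


@dataclass(frozen=True)
class SulfideCalibration:
    """Log-log regression mapping total SRM (%) to sulfide (mM).

    ``sulfide = 10 ** (slope * log10(n_t) + intercept)``
    """

    slope: float
    intercept: float
    r_squared: float | None = None
    n_points: int | None = None
    fit_on: str | None = None  # "all_points" | "replicate_means" | None (preset)

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class CompartmentParams:
    """Carrying capacities (percent of community) of the two SRM pools.

    ``k_a = 0`` is allowed and models a purely planktonic vessel with no
    wall growth.
    """

    k_p: float
    k_a: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_p > 0:
            raise ValueError(f"k_p must be > 0, got {self.k_p}")
        if self.k_a < 0:
            raise ValueError(f"k_a must be >= 0, got {self.k_a}")


def _load_presets() -> dict:
    text = resources.files("sulfostat").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def list_presets() -> dict:
    """Return the raw preset tables (strains, calibrations, compartments)."""
    return _load_presets()


def get_strain_preset(name: str) -> StrainParams:
    strains = _load_presets()["strains"]
    try:
        entry = strains[name]
    except KeyError:
        raise KeyError(f"unknown strain preset {name!r}; have {sorted(strains)}") from None
    return StrainParams(**entry)


def get_calibration_preset(name: str = "default") -> SulfideCalibration:
    entry = _load_presets()["calibrations"][name]
    return SulfideCalibration(**entry)


def get_compartment_preset(name: str = "default") -> CompartmentParams:
    entry = _load_presets()["compartments"][name]
    return CompartmentParams(**entry)


def get_vessel_preset(name: str = "default") -> dict:
    """Vessel geometry: ``{"volume_ml": ..., "flow_ml_per_h": ...}``."""
    return dict(_load_presets()["vessel"][name])
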