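"""Elementary per-period dynamics.

Pure functions for the circadian cycle, the classic circadian bounds, the
homeostatic (sleep-pressure) update, the AR(1) environmental state, and the
reusable bank of standard-normal draws shared across calibration objective
evaluations (common random numbers).

Time-unit conventions
---------------------
The homeostatic decay constants ``nu_W``/``nu_S`` are quoted in hours. The
update uses a per-period factor ``exp(-1 / nu_periods)``, i.e. ``nu`` is an
e-folding constant. The conversion hours -> periods is
``nu_periods = nu_hours * q / 24`` (see :func:`nu_to_periods`); pass
``ln2_half_life=True`` to instead interpret ``nu`` as a true half-life,
which divides the e-folding constant by ln 2.

The AR persistence ``rho`` is quoted per hour. The default per-period
factor is ``rho**(24/q)`` (``per_hour``); the alternative ``per_day_root``
convention uses ``rho**(1/q)``. Only the per-hour reading reproduces the
calibrated species sleep moments, which is why it is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ClassicParams

__all__ = [
    "DrawBank",
    "make_draw_bank",
    "circadian",
    "classic_bounds",
    "nu_to_periods",
    "decay_factor",
    "rho_per_period",
    "homeostat_step",
    "env_step",
]


@dataclass(frozen=True)
class DrawBank:
    """An ordered, reproducible bank of standard-normal variates.

    The same bank is reused verbatim across all objective evaluations of a
    calibration so that the simulated-moment objective is a deterministic
    function of the parameters (common random numbers).
    """

    draws: np.ndarray
    seed: int
    length: int

    def __post_init__(self) -> None:
        if self.draws.shape != (self.length,):
            raise ValueError("draws length does not match declared length")


def make_draw_bank(length: int, seed: int) -> DrawBank:
    """Draw ``length`` standard-normal variates from a seeded PCG64 stream."""
    if length <= 0:
        raise ValueError("length must be positive")
    draws = np.random.default_rng(seed).standard_normal(length)
    return DrawBank(draws=draws, seed=seed, length=length)


def circadian(t, q: int):
    """Circadian level y = -cos(2*pi*t/q), periodic with period ``q``.

    Period index 0 is midnight: y is lowest (-1) at midnight and highest
    (+1) at midday. Accepts scalar or array ``t``.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    return -np.cos(2.0 * np.pi * np.asarray(t) / q)


def classic_bounds(y, p: ClassicParams):
    """Upper/lower circadian thresholds of the classic two-process model."""
    return p.Hbar_u + p.a * np.asarray(y), p.Hbar_l - p.a * np.asarray(y)


def nu_to_periods(nu_hours: float, q: int, ln2_half_life: bool = False) -> float:
    """Convert a decay constant in hours to model periods.

    Default treats ``nu`` as an e-folding time; ``ln2_half_life=True``
    rescales so that ``nu`` is the time to halve the distance to the
    asymptote.
    """
    nu = nu_hours * q / 24.0
    return nu / math.log(2.0) if ln2_half_life else nu


def decay_factor(nu_hours: float, q: int, ln2_half_life: bool = False) -> float:
    """Per-period decay multiplier exp(-1/nu_periods)."""
    return math.exp(-1.0 / nu_to_periods(nu_hours, q, ln2_half_life))


def homeostat_step(
    H: float,
    asleep: bool,
    upper: float,
    lower: float,
    nu_W: float,
    nu_S: float,
    q: int,
) -> float:
    """One exponential step of the homeostat toward the active asymptote.

    Awake it rises toward ``upper`` with constant ``nu_W``; asleep it falls
    toward ``lower`` with ``nu_S``. ``H`` must lie in [lower, upper].
    """
    if not lower <= H <= upper:
        raise ValueError(f"H={H} outside [{lower}, {upper}]")
    if asleep:
        return lower + (H - lower) * decay_factor(nu_S, q)
    return upper + (H - upper) * decay_factor(nu_W, q)


def rho_per_period(rho: float, q: int, convention: str = "per_hour") -> float:
    """Per-period AR persistence factor under the chosen convention."""
    if convention == "per_day_root":
        return rho ** (1.0 / q)
    if convention == "per_hour":
        return rho ** (24.0 / q)
    raise ValueError(f"unknown rho convention {convention!r}")


def env_step(
    z: float,
    eps: float,
    rho: float,
    sigma: float,
    q: int,
    convention: str = "per_hour",
) -> float:
    """One AR(1) step of the environmental state: z' = phi*z + sigma*eps."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return rho_per_period(rho, q, convention) * z + sigma * eps
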