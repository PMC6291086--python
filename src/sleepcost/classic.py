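"""The classic deterministic two-process model as a threshold switcher.

Sleep pressure H rises exponentially toward the asymptote mu while awake
and decays toward zero while asleep; the state switches to sleep at the
first period where H is at or above the circadian upper threshold, and
back to wake at the first period where it is at or below the lower
threshold. In discrete time the crossing lands at the first period
at-or-beyond the bound, so period-exact properties (e.g. the half-time
symmetry of a fully symmetric parameterization) hold only up to one period
per cycle.

Used as a baseline and for the implicit-opportunity-cost property: shifting
both asymptotes upward (more reward to being awake) yields weakly less
sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ClassicParams
from .processes import circadian, classic_bounds, decay_factor

__all__ = ["ClassicTrajectory", "simulate_classic"]


@dataclass
class ClassicTrajectory:
    t: np.ndarray
    H: np.ndarray
    H_u: np.ndarray
    H_l: np.ndarray
    asleep: np.ndarray
    params: ClassicParams

    def asleep_fraction(self) -> float:
        return float(np.mean(self.asleep))

    def __len__(self) -> int:
        return len(self.t)


def simulate_classic(
    p: ClassicParams,
    days: int,
    H0: float | None = None,
    asleep0: bool = False,
    lower_asymptote: float = 0.0,
    upper_asymptote: float | None = None,
) -> ClassicTrajectory:
    """Run the threshold-switching model for ``days`` days.

    ``upper_asymptote`` defaults to ``p.mu``; both asymptotes are exposed
    so the implicit-opportunity-cost comparative static (raise both
    together) can be exercised directly.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    upper = p.mu if upper_asymptote is None else upper_asymptote
    lower = lower_asymptote
    if upper <= lower:
        raise ValueError("upper asymptote must exceed the lower one")
    if H0 is None:
        H0 = 0.5 * (p.Hbar_u + p.Hbar_l)
    if not (p.Hbar_l - p.a) <= H0 <= (p.Hbar_u + p.a):
        raise ValueError("H0 outside the circadian band")
    q = p.q
    n = q * days
    t = np.arange(n)
    y = circadian(t, q)
    Hu, Hl = classic_bounds(y, p)
    dW = decay_factor(p.nu_W, q)
    dS = decay_factor(p.nu_S, q)
    H = np.empty(n)
    asleep = np.empty(n, dtype=np.int8)
    h = float(H0)
    state = bool(asleep0)
    for i in range(n):
        # the state entering the period drives this period's H movement;
        # a threshold crossing flips the state from the next period on
        if state:
            h = lower + (h - lower) * dS
        else:
            h = upper + (h - upper) * dW
        H[i] = h
        asleep[i] = state
        if state and h <= Hl[i]:
            state = False
        elif not state and h >= Hu[i]:
            state = True
    return ClassicTrajectory(t=t, H=H, H_u=Hu, H_l=Hl, asleep=asleep, params=p)
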