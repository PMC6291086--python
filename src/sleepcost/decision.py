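"""Per-period utility evaluation and the myopic sleep/wake choice.

Each period the animal enters knowing its sleep stock H_{t-1} and previous
action A_{t-1}, observes the circadian level y_t and environmental state
z_t, and picks the action A_t in {awake=0, asleep=1} with the larger
one-period utility

    U(A) = 1[A=0] * [exp(z) * xi * (mu_W - H_prev)**eta]**gamma
           - chi * |H_next(A) - y|**kappa
           - lam * |A - A_prev|

where H_next(A) is the homeostatic update under the candidate action. The
foraging (opportunity-cost) term is active only while awake — non-circadian
utility while sleeping is zero — and the weight chi multiplies the
circadian penalty, the placement under which the species parameters are
calibrated. There is no lookahead: the choice is myopic by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams
from .processes import decay_factor

__all__ = [
    "ChoiceContext",
    "ChoiceResult",
    "waking_utility",
    "circadian_penalty",
    "action_utility",
    "choose",
]

AWAKE, ASLEEP = 0, 1


@dataclass(frozen=True)
class ChoiceContext:
    """State entering a period: sleep stock, previous action, y and z."""

    H_prev: float
    A_prev: int
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.A_prev not in (AWAKE, ASLEEP):
            raise ValueError("A_prev must be 0 (awake) or 1 (asleep)")


@dataclass(frozen=True)
class ChoiceResult:
    """Chosen action, the resulting homeostat level, and both candidates."""

    A: int
    H_next: float
    U: float
    U_wake: float
    U_sleep: float


def waking_utility(
    H_prev: float, z: float, p: ModelParams, xi: float | None = None
) -> float:
    """Utility from foraging while awake: [exp(z)*xi*(mu_W-H)**eta]**gamma.

    Zero when the sleep stock is exhausted (H_prev = mu_W); increasing in
    the environmental state z; scaled by the opportunity cost xi.
    """
    if H_prev > p.mu_W:
        raise ValueError("H_prev exceeds the waking asymptote mu_W")
    xi_eff = p.xi if xi is None else xi
    return (math.exp(z) * xi_eff * (p.mu_W - H_prev) ** p.eta) ** p.gamma


def circadian_penalty(H_next: float, y: float, p: ModelParams) -> float:
    """Weighted penalty chi*|H - y|**kappa for straying from the cycle."""
    return p.chi * abs(H_next - y) ** p.kappa


def h_next(ctx_H: float, A: int, p: ModelParams) -> float:
    """Homeostatic update under candidate action A (awake rises, sleep falls)."""
    if A == ASLEEP:
        return p.mu_S + (ctx_H - p.mu_S) * decay_factor(p.nu_S, p.q)
    return p.mu_W + (ctx_H - p.mu_W) * decay_factor(p.nu_W, p.q)


def action_utility(
    ctx: ChoiceContext, A: int, p: ModelParams, xi: float | None = None
) -> float:
    """Total one-period utility of candidate action A in the given context."""
    if A not in (AWAKE, ASLEEP):
        raise ValueError("action must be 0 (awake) or 1 (asleep)")
    Hn = h_next(ctx.H_prev, A, p)
    u = -circadian_penalty(Hn, ctx.y, p) - p.lam * abs(A - ctx.A_prev)
    if A == AWAKE:
        u += waking_utility(ctx.H_prev, ctx.z, p, xi=xi)
    return u


def choose(ctx: ChoiceContext, p: ModelParams, xi: float | None = None) -> ChoiceResult:
    """Myopic argmax over the two candidate actions.

    Exact ties keep the previous action: any infinitesimal switching cost
    would resolve them that way, and it keeps the simulator deterministic.
    """
    u_wake = action_utility(ctx, AWAKE, p, xi=xi)
    u_sleep = action_utility(ctx, ASLEEP, p, xi=xi)
    if u_sleep > u_wake:
        A = ASLEEP
    elif u_wake > u_sleep:
        A = AWAKE
    else:
        A = ctx.A_prev
    return ChoiceResult(
        A=A,
        H_next=h_next(ctx.H_prev, A, p),
        U=max(u_wake, u_sleep),
        U_wake=u_wake,
        U_sleep=u_sleep,
    )
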