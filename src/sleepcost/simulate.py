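"""Trajectory simulation for the opportunity-cost sleep model.

Three entry points:

- :func:`simulate` — stochastic runs driven by a reusable bank of normal
  draws (the workhorse for moment matching),
- :func:`simulate_stylized` — the noise-free deterministic run iterated to
  its one-day limit cycle (the "stylized day" used for episode counts and
  the per-period utility range),
- :func:`simulate_scheduled` — a time-of-day schedule of opportunity-cost
  multipliers, for demos of scheduled foraging value (e.g. zero cost at
  night, positive by day).

The per-period recursion is compiled with numba; :mod:`sleepcost.decision`
holds the readable single-period reference implementation, and the test
suite asserts the two agree period by period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import ModelParams, validate
from .processes import DrawBank, decay_factor, rho_per_period

__all__ = ["Trajectory", "simulate", "simulate_stylized", "simulate_scheduled"]


class ConvergenceError(RuntimeError):
    """Stylized run failed to reach a one-day limit cycle."""

    def __init__(self, msg: str, last_two_days=None):
        super().__init__(msg)
        self.last_two_days = last_two_days


@dataclass
class Trajectory:
    """Per-period series of one simulation run (burn-in already removed).

    ``t`` are absolute period indices from the start of the simulation
    (t % q = 0 is midnight), so the circadian phase of every row is
    recoverable. 1 = asleep in ``A``.
    """

    t: np.ndarray
    A: np.ndarray
    H: np.ndarray
    z: np.ndarray
    U: np.ndarray
    y: np.ndarray
    params: ModelParams
    seed: int | None = None
    burn_in_days: int = 0
    stylized: bool = False
    cycle_days: int = 1

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("A", "H", "z", "U", "y"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory series must share one length")

    def __len__(self) -> int:
        return len(self.t)


@njit(cache=True)
def _run_kernel(
    q,
    kappa,
    eta,
    gamma,
    phi,
    decay_W,
    decay_S,
    mu_W,
    mu_S,
    lam,
    chi,
    sigma,
    xi_sched,
    eps,
    H0,
    A0,
    z0,
):
    n = eps.shape[0]
    A = np.empty(n, np.int8)
    H = np.empty(n)
    Z = np.empty(n)
    U = np.empty(n)
    Y = np.empty(n)
    Hp = H0
    Ap = A0
    z = z0
    twopi = 2.0 * np.pi
    for i in range(n):
        z = phi * z + sigma * eps[i]
        phase = i % q
        y = -np.cos(twopi * phase / q)
        Hw = mu_W + (Hp - mu_W) * decay_W
        Hs = mu_S + (Hp - mu_S) * decay_S
        xi_t = xi_sched[phase]
        Uw = (
            (np.exp(z) * xi_t * (mu_W - Hp) ** eta) ** gamma
            - chi * abs(Hw - y) ** kappa
            - (lam if Ap == 1 else 0.0)
        )
        Us = -chi * abs(Hs - y) ** kappa - (lam if Ap == 0 else 0.0)
        if Uw > Us:
            a = 0
        elif Us > Uw:
            a = 1
        else:
            a = Ap
        A[i] = a
        H[i] = Hw if a == 0 else Hs
        Z[i] = z
        Y[i] = y
        U[i] = Uw if a == 0 else Us
        Hp = H[i]
        Ap = a
    return A, H, Z, U, Y


def _check_params(p: ModelParams) -> None:
    problems = validate(p)
    if problems:
        raise ValueError("invalid parameters: " + "; ".join(problems))


def _kernel_args(p: ModelParams, xi_schedule: np.ndarray | None):
    if xi_schedule is None:
        xi_sched = np.full(p.q, float(p.xi))
    else:
        xi_sched = np.asarray(xi_schedule, dtype=float) * p.xi
        if xi_sched.shape != (p.q,):
            raise ValueError(f"xi schedule must have length q={p.q}")
    return (
        p.q,
        p.kappa,
        p.eta,
        p.gamma,
        rho_per_period(p.rho, p.q, p.rho_convention),
        decay_factor(p.nu_W, p.q),
        decay_factor(p.nu_S, p.q),
        p.mu_W,
        p.mu_S,
        p.lam,
        p.chi,
        p.sigma,
        xi_sched,
    )


def simulate(
    p: ModelParams,
    days: int,
    bank: DrawBank | None = None,
    seed: int | None = None,
    H0: float = 0.0,
    A0: int = 0,
    burn_in_days: int = 10,
    xi_schedule: np.ndarray | None = None,
) -> Trajectory:
    """Simulate ``days`` days after discarding ``burn_in_days`` of burn-in.

    Draws are consumed in bank order, one per period; pass a shared
    ``bank`` for common-random-number calibration, or a ``seed`` to build
    one ad hoc. The run starts at midnight with the given initial
    homeostat level and action.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    _check_params(p)
    if not p.mu_S <= H0 <= p.mu_W:
        raise ValueError("H0 must lie in [mu_S, mu_W]")
    n = p.q * (days + burn_in_days)
    if bank is None:
        if seed is None:
            raise ValueError("provide either a draw bank or a seed")
        from .processes import make_draw_bank

        bank = make_draw_bank(n, seed)
    if bank.length < n:
        raise ValueError(
            f"draw bank too short: {bank.length} < q*(days+burn_in) = {n}"
        )
    A, H, Z, U, Y = _run_kernel(
        *_kernel_args(p, xi_schedule), bank.draws[:n], float(H0), int(A0), 0.0
    )
    skip = p.q * burn_in_days
    t = np.arange(n)
    return Trajectory(
        t=t[skip:],
        A=A[skip:],
        H=H[skip:],
        z=Z[skip:],
        U=U[skip:],
        y=Y[skip:],
        params=p,
        seed=bank.seed,
        burn_in_days=burn_in_days,
    )


def simulate_stylized(
    p: ModelParams,
    max_days: int = 400,
    tol: float = 1e-9,
    max_cycle_days: int = 7,
) -> Trajectory:
    """Noise-free run (z = 0) iterated to its deterministic limit cycle.

    Starts from H0 = 0, awake, at midnight. The map is a contraction in H
    under periodic forcing, so trajectories settle onto a limit cycle
    whose period is a whole number of days — usually one, but some
    parameterizations (e.g. the wild sloth) lock onto a multi-day cycle.
    Convergence is declared at the first day whose action pattern matches
    the day ``k`` days earlier exactly and whose homeostat path matches
    within ``tol``, for the smallest ``k <= max_cycle_days``; the returned
    trajectory covers the full ``k``-day cycle (``cycle_days = k``) with
    period indices 0..k*q-1 starting at midnight.
    """
    if max_days < 2:
        raise ValueError("max_days must be >= 2")
    p0 = p.replace(sigma=0.0)
    _check_params(p0)
    q = p0.q
    eps = np.zeros(q * max_days)
    A, H, Z, U, Y = _run_kernel(*_kernel_args(p0, None), eps, 0.0, 0, 0.0)
    Ad = A.reshape(max_days, q)
    Hd = H.reshape(max_days, q)
    for k in range(1, max_cycle_days + 1):
        for d in range(k, max_days):
            if np.array_equal(Ad[d], Ad[d - k]) and (
                np.max(np.abs(Hd[d] - Hd[d - k])) < tol
            ):
                sl = slice((d - k) * q, d * q)
                return Trajectory(
                    t=np.arange(k * q),
                    A=A[sl],
                    H=H[sl],
                    z=Z[sl],
                    U=U[sl],
                    y=Y[sl],
                    params=p0,
                    seed=None,
                    burn_in_days=d - k,
                    stylized=True,
                    cycle_days=k,
                )
    raise ConvergenceError(
        f"no limit cycle of <= {max_cycle_days} days within {max_days} days",
        last_two_days=(Ad[-2:], Hd[-2:]),
    )


def simulate_scheduled(
    p: ModelParams,
    xi_schedule: np.ndarray,
    days: int,
    bank: DrawBank | None = None,
    seed: int | None = None,
    **kwargs,
) -> Trajectory:
    """Simulate with a per-phase opportunity-cost multiplier schedule.

    ``xi_schedule`` has length q; the effective opportunity cost in phase
    t mod q is ``xi * xi_schedule[t mod q]``. A schedule of ones reduces
    exactly to :func:`simulate`.
    """
    xi_schedule = np.asarray(xi_schedule, dtype=float)
    if xi_schedule.shape != (p.q,):
        raise ValueError(f"xi schedule must have length q={p.q}")
    if np.any(xi_schedule < 0):
        raise ValueError("xi schedule multipliers must be >= 0")
    return simulate(p, days, bank=bank, seed=seed, xi_schedule=xi_schedule, **kwargs)
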