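# Methods

## Model

Time is discrete with `q` periods per day (default 144, i.e. 10-minute
periods; period `t mod q = 0` is midnight). The state is the homeostatic
sleep pressure `H` (bounded by the sleeping and waking asymptotes
`μ_S < H < μ_W`), the previous action, and an AR(1) environmental state `z`
that scales the value of foraging.

Each period the animal enters knowing `H_{t−1}` and `A_{t−1}`, observes the
circadian level `y_t = −cos(2πt/q)` and the current `z_t`, and picks the
action with the larger one-period utility:

- **Foraging utility** (awake only): `[e^{z} ξ (μ_W − H_{t−1})^η]^γ`. It is
  zero when the sleep stock is exhausted (`H = μ_W`) and rises as the animal
  is better rested or the environment richer. `ξ` is the opportunity-cost
  scale, normalized to 1 for captive animals.
- **Circadian penalty**: `χ |H_t(A) − y_t|^κ`, where `H_t(A)` is the
  homeostatic update under the candidate action. κ = 2 is a quadratic
  penalty; as κ → ∞ the penalty becomes a hard band of width 1 around the
  cycle and the classic two-process threshold behaviour re-emerges (this is
  verified as a property test with κ = 40).
- **Switching cost**: `λ |A_t − A_{t−1}|`, which suppresses micro-sleep and
  controls how polyphasic the pattern is.

The choice is myopic — a one-period argmax over the two actions, no
lookahead. Exact ties keep the previous action (any infinitesimal switching
cost resolves them that way, and it keeps the simulator deterministic).

Two notational readings of the utility function are possible; the
implementation uses the one under which the species parameters are
calibrated: the indicator on the foraging term means *awake* (non-circadian
utility while sleeping is zero), and χ multiplies the circadian penalty.

## Unit conventions

- **Homeostatic decay.** `ν_W`, `ν_S` are quoted in hours and treated as
  e-folding constants: the per-period factor is `exp(−1/ν̃)` with
  `ν̃ = ν·q/24` (8 h → 48 periods). The alternative, reading ν as a true
  half-life (divide by ln 2), is available via
  `nu_to_periods(..., ln2_half_life=True)`; it was rejected because it
  halves the stylized elephant's episode count (2 instead of the observed
  4) and degrades the stochastic moment match.
- **AR persistence.** `ρ` is quoted per hour; the per-period factor is
  `ρ^(24/q)` (`rho_convention="per_hour"`, the default). The alternative
  `per_day_root` (`ρ^(1/q)`) is implemented behind the same switch; it
  makes the environment so persistent that the wild-elephant simulation
  overshoots the observed moments severalfold, so the per-hour reading is
  the default.
- Hours per day of sleep = (asleep periods) × 24/q.

## Simulation

- **Update order** within a period: advance `z` first, then choose — the
  decision sees the current period's environment.
- **Initial conditions**: `H0 = 0` (clipped to `[μ_S, μ_W]` by the caller if
  needed), awake, at midnight; `z0 = 0` (the unconditional mean). A default
  burn-in of 10 days is discarded before any statistic; the homeostat map is
  a contraction and the AR state mixes within a few days, so initial
  conditions do not survive the burn-in.
- **Draw banks.** Stochastic runs consume a pre-drawn, seeded bank of
  standard-normal variates in order (numpy PCG64). A calibration generates
  its bank once and reuses it for every objective evaluation, making the
  objective a deterministic function of the parameters (common random
  numbers).
- **Kernel.** The per-period recursion is compiled with numba. The pure
  Python `decision` module is the readable reference implementation; the
  test suite checks the two agree period by period on stochastic runs.

### Stylized (noise-free) runs

`simulate_stylized` sets σ = 0 and iterates until the trajectory repeats:
convergence is declared at the first day whose action pattern equals the
day `k` days earlier exactly, with the homeostat path matching within 1e−9,
for the smallest `k ≤ 7`. Most parameterizations lock onto a one-day cycle
(the elephant presets converge within ~10 days); the wild-sloth benchmark
locks onto a genuine four-day cycle, so the returned trajectory carries
`cycle_days` and episode counts are reported per day of the cycle. The
utility range (max − min of realized per-period utility) is taken over the
whole returned cycle.

## Summary statistics

- A **sleep episode** is a maximal run of consecutive asleep periods,
  attributed to the day containing its first period; on a stylized cycle the
  series is treated as cyclic so a run spanning the boundary counts once.
- **Daily summaries** use day boundaries every `q` periods from the
  trajectory start and the population SD (divide by n); at the simulated
  scales the sample/population distinction is ~1e−5 of the value.
- `make_fixture` builds action series with an exact requested run
  structure so the summary stage is tested independently of the simulator
  (round-trip property: `episodes ∘ make_fixture = id`).

## Calibration

Two free parameters per animal group are fitted by matching the simulated
mean and SD of daily sleep hours to observed values: captive groups fit the
free asymptote (μ_S for short sleepers, μ_W for long sleepers) together
with σ, wild groups fix that asymptote at its captive value and fit (ξ, σ).
The loss is `|Δmean| + |ΔSD|` in hours, minimized with Nelder–Mead
(xatol = fatol = 1e−4, ≤ 500 evaluations). Candidates violating the
parameter invariants receive a large finite penalty (1e6) so the simplex
retreats rather than crashing.

Because daily sleep hours are quantized in steps of 24/q, the loss surface
contains flat plateaus on which a simplex can collapse prematurely. The
optimizer therefore always restarts once from the best point; if the first
pass ended with a loss above 0.01 h the restart uses a widened simplex with
one vertex per coordinate pulled strongly toward zero, which in testing
recovers the optimum from observed stalls. Default starting points:
(ξ, σ) = (5.0, 0.1) for wild fits; the preset asymptote and σ = 0.01 for
captive fits.

Default problem sizes are 10,000 simulated days for forward moments and
20,000 days per calibration objective evaluation (a bank of 2.88M draws).
These are the package's desk-scale defaults; all scale knobs (`sim_days`,
`days`) are exposed for larger runs.

## What the generator does and does not emulate

The simulator itself is the synthetic-data source: it produces wake/sleep
indicator series with realistic polyphasic structure, circadian phase
preference, and day-to-day variability driven by a single persistent
environmental factor. It does **not** model REM/non-REM microstructure,
seasonality or weather beyond the AR state, social constraints, or
measurement error in activity scoring — so matching its moments shows the
model can rationalize observed sleep *quantities and variability*, not that
it captures sleep physiology. `simulate_scheduled` adds a deterministic
time-of-day profile of opportunity cost (e.g. foraging value only in
daylight) for demonstration; it is excluded from calibration.

## Known limitations

- The elephant parameterization is tightly pinned down: forward simulation
  at the calibrated values reproduces the target moments to ≤1% and the
  wild calibration recovers ξ within ~2%. The sloth (long-sleeper) regime
  is less settled: the wild-sloth moment match implies ξ ≈ 5.1–5.2 rather
  than ~6.3, its stylized cycle is four days long with ~32 episodes/day,
  and small changes in the sleeping-asymptote normalization move these
  results materially. Conclusions for long sleepers should be treated as
  sensitive to that normalization.
- The stylized utility range depends on the entire utility scale (it is
  dominated by the worst midnight penalty) and is therefore sensitive to ξ;
  it is reported over the full converged cycle.
- The myopic rule is a modelling choice, not an approximation to a dynamic
  program; no lookahead variant is provided.
- The classic threshold model exhibits one-period discretization artifacts:
  symmetric parameterizations sleep half the time only up to one period per
  cycle, and the steady-state pattern may alternate with a two-day period.
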