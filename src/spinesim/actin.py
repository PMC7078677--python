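"""Stochastic actin dynamics at a single polymerization focus.

A focus is a localized cluster of short actin filaments.  Each filament is
characterized only by the states of its two ends: the barbed (+) end is
uncapped (force-generating) until a capping event removes the filament from
the simulation, and the minus (-) end is either capped/Arp2/3-bound
(``m_c`` filaments) or uncapped (``m_u`` filaments).  The number of
force-generating barbed ends is ``B = m_c + m_u``.

Per time-step of length dt, each existing filament (in order) can

1. branch, adding a new filament with an Arp2/3-capped minus end, with
   probability ``dt * gamma_branch``, where the per-filament branching rate

       gamma_branch = phi * k_on * delta * a
                      * exp(-||F_mem|| * delta / (kBT * B)) / B

   is the free treadmilling velocity attenuated by the opposing membrane
   force via the Brownian-ratchet factor and shared among the B barbed
   ends of the focus;
2. have its barbed end capped (removal) with probability ``dt * gamma_cap``;
3. have its minus end uncapped with probability ``dt * gamma_uncap``;
4. be severed at an uncapped minus end (removal) with probability
   ``dt * gamma_sever``.

Newly branched filaments are not processed until the next step.  ``B = 0``
is absorbing: a dead focus never revives.

Since all filaments within a class share identical rates, the per-filament
sweep is sampled with chained binomial draws per class, which is
statistically identical to iterating over filaments and much faster.

The deterministic twin of the stochastic model treats ``m_c`` and ``m_u``
as continuous and yields a steady state B* that the long-run mean of the
stochastic focus matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "FocusState",
    "branching_rate",
    "step_focus_state",
    "steady_state_barbed_ends",
    "simulate_focus",
    "simulate_focus_ensemble",
]


@dataclass(frozen=True)
class FocusState:
    """Filament counts by minus-end state.

    ``m_c``: uncapped barbed end, capped minus end.
    ``m_u``: uncapped barbed end, uncapped minus end.
    """

    m_c: int
    m_u: int

    def __post_init__(self) -> None:
        if self.m_c < 0 or self.m_u < 0:
            raise ValueError("filament counts must be non-negative")

    @property
    def B(self) -> int:
        """Number of force-generating (uncapped) barbed ends."""
        return self.m_c + self.m_u

    @property
    def alive(self) -> bool:
        return self.B > 0


def branching_rate(F_norm: float, B: int, params: ModelParams) -> float:
    """Per-filament branching rate (s^-1) under an opposing force.

    ``phi * k_on * delta * a * exp(-F_norm * delta / (kBT * B)) / B``.
    """
    if B < 1:
        raise ValueError("branching rate undefined for a dead focus (B = 0)")
    if F_norm < 0:
        raise ValueError("force magnitude must be non-negative")
    v_free = params.phi * params.k_on * params.delta * params.a
    return v_free * np.exp(-F_norm * params.delta / (params.kBT * B)) / B


def _clamped_probs(F_norm: float, B: int, params: ModelParams):
    dt = params.dt
    p_b = min(1.0, dt * branching_rate(F_norm, B, params))
    p_cap = min(1.0, dt * params.gamma_cap)
    p_unc = min(1.0, dt * params.gamma_uncap)
    p_sev = min(1.0, dt * params.gamma_sever)
    return p_b, p_cap, p_unc, p_sev


def step_focus_state(
    state: FocusState,
    F_norm: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> FocusState:
    """Advance one focus by one time-step.

    The branching probability is evaluated with B frozen at the step start;
    new branches join ``m_c`` but are not themselves processed this step.
    A filament whose minus end uncaps in this sweep can also be severed in
    the same sweep (events are applied in branch, cap, uncap, sever order
    per filament).
    """
    if not state.alive:
        raise ValueError("cannot step a dead focus (B = 0); remove it instead")
    p_b, p_cap, p_unc, p_sev = _clamped_probs(F_norm, state.B, params)

    branches = rng.binomial(state.B, p_b)

    # minus-end-capped class: cap (remove) -> uncap -> possible same-sweep sever
    surv_c = state.m_c - rng.binomial(state.m_c, p_cap)
    uncapped_now = rng.binomial(surv_c, p_unc)
    m_c_left = surv_c - uncapped_now
    uncapped_surviving = uncapped_now - rng.binomial(uncapped_now, p_sev)

    # minus-end-uncapped class: cap (remove) -> sever (remove)
    surv_u = state.m_u - rng.binomial(state.m_u, p_cap)
    m_u_left = surv_u - rng.binomial(surv_u, p_sev)

    return FocusState(m_c=m_c_left + branches, m_u=m_u_left + uncapped_surviving)


def steady_state_barbed_ends(F_norm: float, params: ModelParams) -> float:
    """Steady-state barbed-end count B* of the deterministic rate equations.

    Treating the counts as continuous with the total per-focus branching
    rate ``ghat(B) = phi k_on delta a exp(-F_norm delta/(kBT B))``:

        m_c* = ghat(B*) / (gamma_uncap + gamma_cap)
        m_u* = gamma_uncap m_c* / (gamma_sever + gamma_cap)

    so B* solves ``B = K exp(-c/B)`` with ``c = F_norm delta / kBT``.  The
    largest (stable) positive root is returned; 0.0 signals no positive
    root (the focus cannot sustain itself at that force).
    """
    if F_norm < 0:
        raise ValueError("force magnitude must be non-negative")
    from scipy.optimize import brentq

    v_free = params.phi * params.k_on * params.delta * params.a
    denom_c = params.gamma_uncap + params.gamma_cap
    if denom_c <= 0:
        return 0.0
    gain = 1.0 / denom_c
    if params.gamma_sever + params.gamma_cap > 0:
        gain *= 1.0 + params.gamma_uncap / (params.gamma_sever + params.gamma_cap)
    K = v_free * gain
    if K <= 0:
        return 0.0
    c = F_norm * params.delta / params.kBT
    if c == 0.0:
        return K

    def g(B: float) -> float:
        return B - K * np.exp(-c / B)

    # scan downward from B = K for the stable root (g changes - to +)
    grid = np.geomspace(K, K * 1e-8, 400)
    upper = K
    for B in grid:
        if g(B) < 0.0:
            return float(brentq(g, B, upper, xtol=1e-12, rtol=1e-14))
        upper = B
    return 0.0


def simulate_focus(
    initial_B: int,
    F_norm: float,
    params: ModelParams,
    rng: np.random.Generator,
    max_time: float = 3600.0,
):
    """Simulate one focus until extinction (or *max_time*).

    Starts with all ``initial_B`` filaments minus-end capped.  Returns
    ``(lifetime, trace)`` where *trace* holds B after every step; a focus
    still alive at *max_time* is censored there.
    """
    if initial_B < 1:
        raise ValueError("initial_B must be >= 1")
    state = FocusState(m_c=int(initial_B), m_u=0)
    max_steps = int(round(max_time / params.dt))
    trace = np.empty(max_steps, dtype=np.int64)
    steps = 0
    while state.alive and steps < max_steps:
        state = step_focus_state(state, F_norm, params, rng)
        trace[steps] = state.B
        steps += 1
    return steps * params.dt, trace[:steps]


def simulate_focus_ensemble(
    initial_B: int,
    F_norm: float,
    params: ModelParams,
    rng: np.random.Generator,
    n_runs: int,
    max_time: float = 3600.0,
):
    """Vectorized ensemble of independent single-focus simulations.

    Returns ``(lifetimes, mean_B)``: per-run extinction time (s, censored at
    *max_time*) and per-run mean of B over the steps the focus was alive.
    """
    if initial_B < 1:
        raise ValueError("initial_B must be >= 1")
    dt = params.dt
    m_c = np.full(n_runs, int(initial_B), dtype=np.int64)
    m_u = np.zeros(n_runs, dtype=np.int64)
    lifetimes = np.full(n_runs, max_time)
    b_sum = np.zeros(n_runs)
    b_count = np.zeros(n_runs, dtype=np.int64)

    p_cap = min(1.0, dt * params.gamma_cap)
    p_unc = min(1.0, dt * params.gamma_uncap)
    p_sev = min(1.0, dt * params.gamma_sever)
    v_free = params.phi * params.k_on * params.delta * params.a
    c = F_norm * params.delta / params.kBT

    max_steps = int(round(max_time / dt))
    for step in range(max_steps):
        B = m_c + m_u
        alive = B > 0
        if not alive.any():
            break
        Ba = B[alive]
        p_b = np.minimum(1.0, dt * v_free * np.exp(-c / Ba) / Ba)

        branches = rng.binomial(Ba, p_b)
        surv_c = m_c[alive] - rng.binomial(m_c[alive], p_cap)
        unc = rng.binomial(surv_c, p_unc)
        m_c_left = surv_c - unc
        unc_surv = unc - rng.binomial(unc, p_sev)
        surv_u = m_u[alive] - rng.binomial(m_u[alive], p_sev + p_cap - p_sev * p_cap)
        # note: cap-then-sever on the m_u class collapses to one removal
        # probability 1-(1-p_cap)(1-p_sev) since both outcomes are removal
        m_c[alive] = m_c_left + branches
        m_u[alive] = surv_u + unc_surv

        died = alive & ((m_c + m_u) == 0)
        lifetimes[died] = (step + 1) * dt
        newB = m_c + m_u
        b_sum[alive] += newB[alive]
        b_count[alive] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_b = np.where(b_count > 0, b_sum / np.maximum(b_count, 1), 0.0)
    return lifetimes, mean_b
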