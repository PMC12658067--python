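"""Stochastic kinetics of the T7 replisome as a torque-dependent rotary motor.

The replisome couples a hexameric helicase and a DNA polymerase (DNAP) at the
fork.  Each base pair replicated rotates the parental duplex by 1/10.5 of a
turn, so torsional stress builds up unless it is relaxed.  The motor model
captures, per enzyme composition:

* a smooth torque–velocity relation that vanishes at a per-trace stall torque
  drawn from a Gaussian,
* Poisson entry into exponential-duration pauses,
* fork regression (biased reverse stepping) while stalled, which releases the
  injected turns,
* loss of restart competence ("inactivation") during a prolonged stall, with
  a rate lowered by DNAP occupancy of the helicase C-terminal domain (CTD).

Condition presets (WT, ΔCt, ΔCt exo-, DNAP-only, helicase-only) carry the
Gaussian stall-torque statistics and regression rates reported for each
composition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

__all__ = [
    "MotorParams",
    "MotorState",
    "MOTOR_PRESETS",
    "motor_preset",
    "pause_free_velocity",
    "draw_stall_torque",
    "step_motor",
    "restart_probability",
    "inactivation_rate_at",
]

#: Modes of the motor state machine.
MODES = ("loading", "active", "paused", "stalled_regressing", "inactive")


@dataclass(frozen=True)
class MotorParams:
    """Kinetic parameters of one replisome composition.

    ``v0`` is the zero-torque pause-free velocity in turns/s; ``tv_shape``
    the concavity of the torque–velocity curve; ``tv_floor_torque`` the
    torque at or below which the motor runs at ``v0`` (0 for two-motor
    replisomes; the melting plateau for the weak single-enzyme conditions,
    whose stall torques sit near zero).  ``regression_rate_scale`` is the
    mean fork regression speed while stalled, in bp/min.  Restart
    competence decays at ``inactivation_rate`` during a stall, reduced by
    DNAP occupancy with half-saturation ``restart_halfsat_dnap`` when the
    helicase CTD is present.
    """

    condition_label: str = "WT"
    v0: float = 8.0
    stall_torque_mean: float = 21.9
    stall_torque_sd: float = 4.4
    tv_shape: float = 1.2536
    tv_floor_torque: float = 0.0
    pause_entry_rate: float = 0.10
    pause_mean_duration: float = 2.0
    regression_rate_scale: float = 81.2
    inactivation_rate: float = 0.004
    restart_halfsat_dnap: float = 20.0
    restart_floor: float = 0.0
    ctd_present: bool = True
    loading_delay_mean: float = 5.0
    helical_pitch: float = 10.5

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("v0 must be non-negative")
        if self.stall_torque_sd < 0:
            raise ValueError("stall_torque_sd must be non-negative")
        if not 0.0 <= self.restart_floor <= 1.0:
            raise ValueError("restart_floor must lie in [0, 1]")
        if self.pause_entry_rate < 0 or self.pause_mean_duration <= 0:
            raise ValueError("pause kinetics must be non-negative / positive")

    def with_overrides(self, **kwargs) -> "MotorParams":
        return replace(self, **kwargs)


# Stall-torque statistics per composition follow the Gaussian fits reported
# for N = 19 / 16 / 16 / 16 traces.  Regression rates are calibrated so the
# model's observable — the mean regression over one minute of stalling —
# equals the reported 80 / 240 / 340 bp.  Regression halts once the stored
# (+) strain is released, so for a stall-torque draw Γs the releasable strain
# is S = (n_b + (Γs − Γ_b)/s_p)·pitch and the observed one-minute mean is
# E[min(rate·60 s, S)]; inverting that expectation for the Gaussian Γs of
# each composition gives underlying rates 81.2 / 249.1 / 384.3 bp/min.
# ΔCt exo- shares the ΔCt stall statistics (no separate figure is reported
# for it).
MOTOR_PRESETS: dict[str, MotorParams] = {
    "WT": MotorParams(),
    "dCt": MotorParams(
        condition_label="dCt",
        stall_torque_mean=19.4,
        stall_torque_sd=3.0,
        regression_rate_scale=249.1,
        ctd_present=False,
    ),
    "dCt_exo": MotorParams(
        condition_label="dCt_exo",
        stall_torque_mean=19.4,
        stall_torque_sd=3.0,
        regression_rate_scale=384.3,
        ctd_present=False,
    ),
    "DNAP_only": MotorParams(
        condition_label="DNAP_only",
        v0=4.0,
        stall_torque_mean=-1.5,
        stall_torque_sd=2.4,
        tv_floor_torque=-10.0,
        regression_rate_scale=0.0,
        ctd_present=False,
    ),
    "helicase_only": MotorParams(
        condition_label="helicase_only",
        v0=4.0,
        stall_torque_mean=1.2,
        stall_torque_sd=5.0,
        tv_floor_torque=-10.0,
        regression_rate_scale=0.0,
        ctd_present=False,
    ),
}


def motor_preset(label: str, **overrides) -> MotorParams:
    """Look up a condition preset, optionally overriding fields."""
    try:
        base = MOTOR_PRESETS[label]
    except KeyError as exc:
        raise KeyError(
            f"unknown condition {label!r}; known: {sorted(MOTOR_PRESETS)}"
        ) from exc
    return base.with_overrides(**overrides) if overrides else base


@dataclass
class MotorState:
    """Instantaneous state of one simulated replisome."""

    time: float = 0.0
    fork_position: float = 0.0  # bp replicated (net)
    mode: str = "loading"
    drawn_stall_torque: float = math.nan
    stall_entry_time: float | None = None
    pause_exit_time: float | None = None
    restart_competent: bool = True

    @property
    def injected_turns(self) -> float:
        """Net turns injected into the parental duplex: bp replicated / pitch."""
        return self.fork_position / 10.5


def pause_free_velocity(torque: float, params: MotorParams, stall_torque: float | None = None) -> float:
    """Pause-free rotation rate (turns/s) at a given torque.

    v(Γ) = v0 · (1 − r^shape) with r the torque's fractional position between
    ``tv_floor_torque`` and the drawn stall torque, clipped to [0, 1]; smooth,
    non-increasing, and zero at and above the stall torque.  ``stall_torque``
    defaults to the preset mean (i.e. the ensemble-typical motor).
    """
    gs = params.stall_torque_mean if stall_torque is None else stall_torque
    g0 = params.tv_floor_torque
    if gs <= g0:
        return 0.0
    r = (torque - g0) / (gs - g0)
    r = min(max(r, 0.0), 1.0)
    return params.v0 * (1.0 - r**params.tv_shape)


def draw_stall_torque(params: MotorParams, rng: np.random.Generator | int) -> float:
    """One per-trace Gaussian stall-torque draw N(mean, sd^2)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = float(rng.normal(params.stall_torque_mean, params.stall_torque_sd))
    # A draw at or below the velocity floor cannot stall by torque buildup;
    # censor just above the floor (rare: sub-percent for all presets).
    return max(g, params.tv_floor_torque + 0.3)


def inactivation_rate_at(dnap_conc: float, params: MotorParams) -> float:
    """Inactivation rate (1/s) during a stall at the given DNAP concentration.

    DNAP occupancy of the helicase CTD protects the fork; without the CTD the
    concentration has no effect.
    """
    if dnap_conc < 0:
        raise ValueError("dnap_conc must be non-negative")
    occupancy = (
        dnap_conc / (dnap_conc + params.restart_halfsat_dnap) if params.ctd_present else 0.0
    )
    return params.inactivation_rate * (1.0 - occupancy)


def restart_probability(stall_duration: float, dnap_conc: float, params: MotorParams) -> float:
    """Probability that a replisome stalled for ``stall_duration`` can restart.

    Survival of the single-exponential inactivation process, floored at
    ``restart_floor``: p = floor + (1 − floor)·exp(−k(c)·t).
    """
    if stall_duration < 0:
        raise ValueError("stall_duration must be non-negative")
    k = inactivation_rate_at(dnap_conc, params)
    return params.restart_floor + (1.0 - params.restart_floor) * math.exp(-k * stall_duration)


def draw_inactivation_time(dnap_conc: float, params: MotorParams, rng: np.random.Generator) -> float:
    """Time from stall entry to loss of restart competence (may be inf)."""
    if params.restart_floor > 0 and rng.random() < params.restart_floor:
        return math.inf
    k = inactivation_rate_at(dnap_conc, params)
    if k <= 0:
        return math.inf
    return float(rng.exponential(1.0 / k))


def step_motor(
    state: MotorState,
    torque: float,
    dt: float,
    params: MotorParams,
    rng: np.random.Generator,
    stall_epsilon: float = 0.2,
) -> MotorState:
    """Advance the motor state machine by one time step.

    Discrete-time kinetics: while ``active`` the fork advances by
    v(Γ)·dt·pitch bp and may enter a pause (Poisson); a ``paused`` motor
    exits after an exponential dwell; when the torque comes within
    ``stall_epsilon`` of the drawn stall torque the motor enters
    ``stalled_regressing``, where it reverse-steps 1 bp at the regression
    rate; ``inactive`` and ``loading`` states only advance the clock.

    The caller owns the torque (via the tether mechanics) and any protocol-
    driven transitions (loading completion, relaxation, reactivation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = replace(state)
    s.time = state.time + dt
    if s.mode in ("loading", "inactive"):
        return s
    if s.mode == "paused":
        if s.pause_exit_time is not None and s.time >= s.pause_exit_time:
            s.mode = "active"
            s.pause_exit_time = None
        return s
    if s.mode == "active":
        if torque >= s.drawn_stall_torque - stall_epsilon:
            s.mode = "stalled_regressing"
            s.stall_entry_time = state.time
            return s
        if params.pause_entry_rate > 0 and rng.random() < params.pause_entry_rate * dt:
            s.mode = "paused"
            s.pause_exit_time = s.time + rng.exponential(params.pause_mean_duration)
            return s
        v = pause_free_velocity(torque, params, s.drawn_stall_torque)
        s.fork_position = state.fork_position + v * dt * params.helical_pitch
        return s
    if s.mode == "stalled_regressing":
        rate = params.regression_rate_scale / 60.0  # bp/s
        if rate > 0 and rng.random() < rate * dt:
            s.fork_position = max(state.fork_position - 1.0, 0.0)
        return s
    raise ValueError(f"unknown motor mode {s.mode!r}")
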