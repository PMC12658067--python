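"""Couple motor kinetics to tether mechanics under the four experiment schedules.

Protocols
---------
``aot_constant_torque``
    Angular-optical-trap mode: unwind, load, let torsion build to a set
    torque, then rotate the cylinder to follow the replisome so the torque is
    clamped while the rotation rate is read out.
``aot_stall``
    The cylinder is fixed after the initial unwind, so replication winds the
    parental duplex up to the replisome's stall torque; the stalled fork then
    regresses, releasing turns.
``aot_restart``
    As ``aot_stall``, then after a set stall time the cylinder unwinds the
    tether to a low torque (at most ``relax_max_turns`` turns), mimicking
    topoisomerase relaxation, and the replisome may restart and stall again.
``mt_restart``
    Magnetic-tweezers variant at 1.0 pN: a fixed 100-turn unwinding fully
    relaxes the torsion; restart is visible as a renewed extension decrease
    once the replisome (+) buckles the DNA again.
``gyrase_probe``
    Magnetic tweezers at 1.5 pN with gyrase continuously removing (+) turns;
    the remaining parental length is probed every ``probe_period`` seconds by
    a fast ±``probe_turns`` excursion that momentarily brings the tether to
    its maximum extension.

Each simulation returns an instrument-like :class:`TraceRecord` (time,
extension, force, torque, device turns) plus a ground-truth
:class:`EventLog`.  Mechanical equilibrium is assumed at every time step
(quasi-static tether), and the force is constant within a protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

from . import mechanics as mech_mod
from .mechanics import MechanicsParams
from .motor import (
    MotorParams,
    MotorState,
    draw_inactivation_time,
    draw_stall_torque,
    step_motor,
)

__all__ = [
    "Protocol",
    "TraceRecord",
    "EventLog",
    "ConfigError",
    "simulate_trace",
    "simulate_ensemble",
    "PROTOCOL_KINDS",
]

PROTOCOL_KINDS = (
    "aot_constant_torque",
    "aot_stall",
    "aot_restart",
    "mt_restart",
    "gyrase_probe",
)

MODE_CODES = {"loading": 0, "active": 1, "paused": 2, "stalled_regressing": 3, "inactive": 4}
MODE_NAMES = {v: k for k, v in MODE_CODES.items()}


class ConfigError(ValueError):
    """Inconsistent protocol/parameter combination."""


@dataclass(frozen=True)
class Protocol:
    """One experimental schedule with all timing and turn parameters.

    Use :meth:`Protocol.for_kind` to obtain kind-appropriate defaults
    (forces, initial unwinds, the 12.6 pN·nm clamp, ...).
    """

    kind: str
    force: float = 1.0
    parental_length: float = 5000.0
    initial_unwind_turns: float = 40.0
    device_rate: float = 10.0  # turns/s for the initial unwind ramp
    torque_clamp: float | None = None
    observe_duration: float = 80.0  # s of clamped observation
    stall_hold: float = 90.0  # s of recorded stalling past stall entry
    stall_wait: float = 60.0  # s of stalling before relaxation (restart kinds)
    stall_wait_sd: float = 0.0
    relax_target_torque: float = 6.0
    relax_max_turns: float = 50.0
    aot_unwind_rate: float = 30.0
    mt_unwind_turns: float = 100.0
    mt_unwind_rate: float = 10.0
    post_unwind_duration: float = 120.0
    probe_period: float = 18.0
    probe_turns: float = 100.0
    probe_rate: float = 30.0
    total_duration: float = 240.0  # gyrase mode only
    gyrase_conc: float = 0.0
    gyrase_delay: float = 0.0
    gyrase_vmax: float = 15.0  # turns/s removed at saturating gyrase
    gyrase_km: float = 5.0  # nM half-saturation
    dnap_conc: float = 1.0
    sampling_rate: float = 100.0
    extension_noise_sd: float = 10.0
    drift_rate: float = 0.0  # nm/s slow instrumental drift
    max_duration: float = 900.0  # hard cap on any phase-driven schedule

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ConfigError(f"unknown protocol kind {self.kind!r}")
        for name in (
            "sampling_rate",
            "device_rate",
            "aot_unwind_rate",
            "mt_unwind_rate",
            "probe_rate",
            "probe_period",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.force <= 0 or self.parental_length <= 0:
            raise ConfigError("force and parental_length must be positive")
        if self.kind == "aot_constant_torque":
            if self.torque_clamp is None:
                raise ConfigError("aot_constant_torque requires torque_clamp")
        elif self.torque_clamp is not None:
            raise ConfigError(f"torque_clamp is only valid in aot_constant_torque mode, not {self.kind}")
        if self.extension_noise_sd < 0:
            raise ConfigError("extension_noise_sd must be non-negative")

    @classmethod
    def for_kind(cls, kind: str, **overrides) -> "Protocol":
        """Protocol with the kind's standard defaults applied."""
        defaults: dict = {}
        if kind == "aot_constant_torque":
            defaults = dict(force=1.0, initial_unwind_turns=40.0, torque_clamp=12.6)
        elif kind == "aot_stall":
            defaults = dict(force=1.0, initial_unwind_turns=40.0)
        elif kind == "aot_restart":
            defaults = dict(force=1.0, initial_unwind_turns=40.0, stall_wait=60.0)
        elif kind == "mt_restart":
            defaults = dict(
                force=1.0,
                initial_unwind_turns=30.0,
                stall_wait=240.0,
                stall_wait_sd=17.0,
            )
        elif kind == "gyrase_probe":
            defaults = dict(
                force=1.5,
                initial_unwind_turns=30.0,
                gyrase_conc=20.0,
                dnap_conc=1.0,
            )
        else:
            raise ConfigError(f"unknown protocol kind {kind!r}")
        defaults.update(overrides)
        return cls(kind=kind, **defaults)

    def with_overrides(self, **kwargs) -> "Protocol":
        return replace(self, **kwargs)


@dataclass
class TraceRecord:
    """Simulated (or recorded) instrument time series plus metadata."""

    metadata: dict
    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    torque: np.ndarray
    device_turns: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("extension", "force", "torque", "device_turns"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("time", "extension", "force", "torque", "device_turns"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"column {name} contains non-finite values")

    @property
    def sampling_rate(self) -> float:
        return float(self.metadata.get("sampling_rate", 1.0 / (self.time[1] - self.time[0])))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "extension_nm": self.extension,
                "force_pN": self.force,
                "torque_pNnm": self.torque,
                "device_turns": self.device_turns,
            }
        )


@dataclass
class EventLog:
    """Ground truth of one simulated trace, for testing and validation."""

    loading_time: float
    pause_intervals: list
    stall_entry_time: float | None
    drawn_stall_torque: float
    inactivation_time: float | None
    restarted: bool | None
    second_stall_entry_time: float | None
    unwind_start: float | None
    unwind_end: float | None
    stall_wait_actual: float | None
    fork_truth: np.ndarray
    net_turns_truth: np.ndarray
    mode_codes: np.ndarray

    def checkpoints(self, interval: float = 1.0, sampling_rate: float = 100.0):
        """(time, fork bp) ground-truth checkpoints every ``interval`` seconds."""
        step = max(1, int(round(interval * sampling_rate)))
        idx = np.arange(0, len(self.fork_truth), step)
        return idx / sampling_rate, self.fork_truth[idx]

    @property
    def regression_distance(self) -> float | None:
        """bp regressed between maximum forward position and relaxation onset."""
        if self.stall_entry_time is None or self.unwind_start is None:
            return None
        i1 = min(len(self.fork_truth) - 1, int(self.unwind_start * self._fs))
        peak = float(np.max(self.fork_truth[: i1 + 1]))
        return peak - float(self.fork_truth[i1])

    _fs: float = 100.0


class _Sim:
    """Mutable simulation assembly: phase-by-phase sample accumulation."""

    def __init__(self, protocol: Protocol, motor: MotorParams, mech: MechanicsParams, rng):
        self.p = protocol
        self.m = motor
        self.mech = mech
        self.rng = rng
        self.dt = 1.0 / protocol.sampling_rate
        self.pitch = motor.helical_pitch
        # Static calibration constants at the trace force / initial length.
        self.k_twist = mech_mod.twist_torque_slope(protocol.parental_length, mech)
        self.g_buck = mech_mod.buckling_torque(protocol.force, mech)
        self.n_buck = self.g_buck / self.k_twist
        self.s_plect = mech.plectoneme_torque_slope
        self.plateau = mech.melting_torque_plateau
        self.g_max = mech_mod.max_torque(protocol.parental_length, protocol.force, mech)
        # State.
        self.state = MotorState(mode="loading", drawn_stall_torque=draw_stall_torque(motor, rng))
        self.n_dev = 0.0
        self.n_relaxed = 0.0  # turns removed by gyrase
        # Records.
        self.fork: list = []
        self.dev: list = []
        self.nnet: list = []
        self.mode: list = []
        # Events.
        self.stall_entry_time: float | None = None
        self.second_stall_entry_time: float | None = None
        self.inactivation_time: float | None = None
        self.restarted: bool | None = None
        self.unwind_start: float | None = None
        self.unwind_end: float | None = None
        self.loading_time: float = 0.0
        self.stall_wait_actual: float | None = None
        self.clamp_engage_time: float | None = None
        self.probe_times: list = []

    # -- mechanics (scalar fast path, consistent with mechanics module) -----
    def torque_at(self, n_net: float) -> float:
        if n_net > self.n_buck:
            return self.g_buck + self.s_plect * (n_net - self.n_buck)
        return max(self.k_twist * n_net, self.plateau)

    def turns_at_torque(self, torque: float) -> float:
        if torque <= self.g_buck:
            return torque / self.k_twist
        return self.n_buck + (torque - self.g_buck) / self.s_plect

    @property
    def n_net(self) -> float:
        return self.state.fork_position / self.pitch + self.n_dev - self.n_relaxed

    @property
    def time(self) -> float:
        return len(self.fork) * self.dt

    # -- phase helpers ------------------------------------------------------
    def _record(self) -> None:
        self.fork.append(self.state.fork_position)
        self.dev.append(self.n_dev)
        self.nnet.append(self.n_net)
        self.mode.append(MODE_CODES[self.state.mode])

    def run_flat(self, duration: float) -> None:
        """Quiescent span: nothing moves except the clock (vectorized)."""
        n = int(round(duration / self.dt))
        if n <= 0:
            return
        self.fork.extend([self.state.fork_position] * n)
        self.dev.extend([self.n_dev] * n)
        self.nnet.extend([self.n_net] * n)
        self.mode.extend([MODE_CODES[self.state.mode]] * n)
        self.state.time += n * self.dt

    def run_device_ramp(self, delta_turns: float, rate: float) -> None:
        """Rotate the device by ``delta_turns`` at ``rate`` turns/s (motor frozen)."""
        n = max(1, int(round(abs(delta_turns) / rate / self.dt)))
        step = delta_turns / n
        fork = self.state.fork_position
        code = MODE_CODES[self.state.mode]
        for _ in range(n):
            self.n_dev += step
            self.fork.append(fork)
            self.dev.append(self.n_dev)
            self.nnet.append(self.n_net)
            self.mode.append(code)
        self.state.time += n * self.dt

    def run_stalled(self, duration: float) -> None:
        """Stalled fork regressing by Poisson 1-bp reverse steps (vectorized)."""
        n = int(round(duration / self.dt))
        if n <= 0:
            return
        rate = self.m.regression_rate_scale / 60.0
        fork0 = self.state.fork_position
        if rate > 0:
            # Arrival times of reverse steps within the span.
            n_steps = self.rng.poisson(rate * duration)
            times = np.sort(self.rng.uniform(0.0, duration, n_steps))
            counts = np.searchsorted(times, np.arange(1, n + 1) * self.dt, side="right")
        else:
            counts = np.zeros(n, dtype=int)
        # Regression is driven by the stored (+) torsional stress; it stops
        # once the tether is torsionally relaxed (net turns = 0).  The floor
        # never lifts a fork that is already below it (weak motors stall with
        # the tether still underwound).
        fork_floor = min(max((self.n_relaxed - self.n_dev) * self.pitch, 0.0), fork0)
        forks = np.maximum(fork0 - counts.astype(float), fork_floor)
        self.fork.extend(forks.tolist())
        self.dev.extend([self.n_dev] * n)
        base = self.n_dev - self.n_relaxed
        self.nnet.extend((forks / self.pitch + base).tolist())
        self.mode.extend([MODE_CODES["stalled_regressing"]] * n)
        self.state.fork_position = float(forks[-1])
        self.state.time += n * self.dt

    def run_active(
        self,
        max_duration: float,
        stop_on_stall: bool = True,
        clamp: float | None = None,
        gyrase: bool = False,
    ) -> str:
        """Step the motor until stall entry, clamp engagement, or timeout.

        Returns one of ``"stall"``, ``"clamp"``, ``"timeout"``.
        With ``clamp`` engaged (not None and already reached), the device
        follows the motor so the net turns are pinned.  With ``gyrase``,
        (+) turns are removed at the saturating gyrase rate and probe
        excursions are layered on the device angle by the caller's schedule.
        """
        n_max = int(round(max_duration / self.dt))
        st = self.state
        for _ in range(n_max):
            n_net = self.n_net
            torque = self.torque_at(n_net)
            prev_fork = st.fork_position
            st = step_motor(st, torque, self.dt, self.m, self.rng)
            # The template is finite: replication stops at its end.
            st.fork_position = min(st.fork_position, self.p.parental_length)
            self.state = st
            if st.mode == "stalled_regressing" and stop_on_stall:
                # Snap the final sub-step creep so the peak torque equals the
                # drawn stall torque exactly (sub-resolution correction).
                target = min(st.drawn_stall_torque, self.g_max - 0.1)
                st.fork_position = max(
                    (self.turns_at_torque(target) - self.n_dev + self.n_relaxed) * self.pitch,
                    0.0,
                )
                self._record()
                return "stall"
            if clamp is not None:
                # Feedback: the device absorbs every injected turn.
                self.n_dev -= (st.fork_position - prev_fork) / self.pitch
            self._record()
            if clamp is None and self.p.torque_clamp is not None:
                if self.torque_at(self.n_net) >= self.p.torque_clamp:
                    return "clamp"
        return "timeout"

    # -- assembly -----------------------------------------------------------
    def finalize(self, condition: str, seed_repr, l_rem_dependent: bool = False):
        p, mech = self.p, self.mech
        n = len(self.fork)
        time = np.arange(n) * self.dt
        fork = np.asarray(self.fork)
        dev = np.asarray(self.dev)
        nnet = np.asarray(self.nnet)
        modes = np.asarray(self.mode, dtype=np.int8)
        torque = np.asarray(
            mech_mod.torque_of_turns(nnet, p.parental_length, p.force, mech)
        )
        if l_rem_dependent:
            # Probe readouts report the shrinking parental duplex: evaluate the
            # hat curve at the remaining parental length (the tether runs
            # through the nascent lagging side in the gyrase geometry).
            l_rem = np.maximum(p.parental_length - fork, 1.0)
            z0 = mech_mod.zero_turn_extension(1.0, p.force, mech) * l_rem
            n_b = self.n_buck
            a = mech.prebuckling_extension_curvature
            z_shoulder = z0 - a * n_b**2
            ext = np.where(
                nnet < 0,
                z0 - mech.unwinding_extension_slope * np.abs(nnet),
                np.where(
                    nnet <= n_b,
                    z0 - a * nnet**2,
                    z_shoulder + mech.plectoneme_extension_slope * (nnet - n_b),
                ),
            )
            ext = np.clip(ext, 0.0, None)
        else:
            ext = np.asarray(
                mech_mod.extension_of_turns(nnet, p.parental_length, p.force, mech)
            )
        # Instrument noise: additive white Gaussian on extension; torque noise
        # propagated through the local mechanics slope |dG/dz| (clipped to keep
        # it finite across the flat top of the hat curve).
        if p.extension_noise_sd > 0:
            ext = ext + self.rng.normal(0.0, p.extension_noise_sd, n)
            dg_dn = np.where(nnet > self.n_buck, self.s_plect, self.k_twist)
            dz_dn = np.where(
                nnet > self.n_buck,
                abs(mech.plectoneme_extension_slope),
                np.maximum(2.0 * mech.prebuckling_extension_curvature * np.abs(nnet), 2.0),
            )
            torque_sd = np.clip(p.extension_noise_sd * dg_dn / dz_dn, 0.05, 0.5)
            torque = torque + self.rng.normal(0.0, 1.0, n) * torque_sd
        if p.drift_rate != 0.0:
            ext = ext + p.drift_rate * time
        ext = np.clip(ext, 0.0, None)

        pauses = _runs_to_intervals(modes == MODE_CODES["paused"], self.dt)
        meta = {
            "protocol": p.kind,
            "condition": condition,
            "parental_length": p.parental_length,
            "force": p.force,
            "seed": seed_repr,
            "sampling_rate": p.sampling_rate,
            "extension_noise_sd": p.extension_noise_sd,
            "dnap_conc": p.dnap_conc,
            "gyrase_conc": p.gyrase_conc,
            "initial_unwind_turns": p.initial_unwind_turns,
            "clamp_engage_time": self.clamp_engage_time,
            "unwind_start": self.unwind_start,
            "unwind_end": self.unwind_end,
            "probe_times": list(self.probe_times),
            "probe_window": 2.0 * p.probe_turns / p.probe_rate if p.kind == "gyrase_probe" else None,
            "stall_wait": self.stall_wait_actual,
            "torque_clamp": p.torque_clamp,
        }
        trace = TraceRecord(
            metadata=meta,
            time=time,
            extension=ext,
            force=np.full(n, p.force),
            torque=torque,
            device_turns=dev,
        )
        log = EventLog(
            loading_time=self.loading_time,
            pause_intervals=pauses,
            stall_entry_time=self.stall_entry_time,
            drawn_stall_torque=self.state.drawn_stall_torque,
            inactivation_time=self.inactivation_time,
            restarted=self.restarted,
            second_stall_entry_time=self.second_stall_entry_time,
            unwind_start=self.unwind_start,
            unwind_end=self.unwind_end,
            stall_wait_actual=self.stall_wait_actual,
            fork_truth=fork,
            net_turns_truth=nnet,
            mode_codes=modes,
            _fs=p.sampling_rate,
        )
        return trace, log


def _runs_to_intervals(mask: np.ndarray, dt: float) -> list:
    """Contiguous True runs of ``mask`` as (start_s, end_s) tuples."""
    if mask.size == 0 or not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return [(float(s * dt), float(e * dt)) for s, e in zip(starts, ends)]


def _begin(sim: _Sim) -> None:
    """Initial unwind ramp followed by the stochastic loading delay."""
    p = sim.p
    sim.run_device_ramp(-p.initial_unwind_turns, p.device_rate)
    delay = float(sim.rng.exponential(sim.m.loading_delay_mean)) if sim.m.loading_delay_mean > 0 else 0.0
    sim.run_flat(delay)
    sim.loading_time = sim.time
    sim.state.mode = "active"


def simulate_trace(
    protocol: Protocol,
    motor: MotorParams,
    mech: MechanicsParams | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[TraceRecord, EventLog]:
    """Simulate one trace under ``protocol`` and return it with its ground truth."""
    mech = mech or MechanicsParams()
    if motor.helical_pitch != mech.helical_pitch:
        raise ConfigError("motor and mechanics helical pitch disagree")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    sim = _Sim(protocol, motor, mech, rng)
    kind = protocol.kind
    if kind == "aot_constant_torque":
        _simulate_constant_torque(sim)
        l_rem = False
    elif kind == "aot_stall":
        _simulate_stall(sim)
        l_rem = False
    elif kind in ("aot_restart", "mt_restart"):
        _simulate_restart(sim)
        l_rem = False
    elif kind == "gyrase_probe":
        _simulate_gyrase(sim)
        l_rem = True
    else:  # pragma: no cover - guarded by Protocol validation
        raise ConfigError(f"unknown protocol kind {kind!r}")
    return sim.finalize(
        motor.condition_label, repr((ss.entropy, ss.spawn_key)), l_rem_dependent=l_rem
    )


def _simulate_constant_torque(sim: _Sim) -> None:
    p = sim.p
    _begin(sim)
    outcome = sim.run_active(p.max_duration, stop_on_stall=True)
    if outcome == "clamp":
        # Engage the feedback exactly at the clamp torque.
        sim.state.fork_position = (
            (sim.turns_at_torque(p.torque_clamp) - sim.n_dev + sim.n_relaxed) * sim.pitch
        )
        sim.clamp_engage_time = sim.time
        sim.run_active(p.observe_duration, stop_on_stall=True, clamp=p.torque_clamp)
    if sim.state.mode == "stalled_regressing":
        sim.stall_entry_time = sim.state.stall_entry_time
        sim.run_stalled(max(0.0, p.observe_duration - (sim.time - (sim.clamp_engage_time or 0.0))))


def _simulate_stall(sim: _Sim) -> None:
    p = sim.p
    _begin(sim)
    outcome = sim.run_active(p.max_duration, stop_on_stall=True)
    if outcome == "stall":
        sim.stall_entry_time = sim.state.stall_entry_time
        sim.run_stalled(p.stall_hold)


def _simulate_restart(sim: _Sim) -> None:
    p = sim.p
    _begin(sim)
    outcome = sim.run_active(p.max_duration, stop_on_stall=True)
    if outcome != "stall":
        sim.restarted = None
        return
    sim.stall_entry_time = sim.state.stall_entry_time
    wait = p.stall_wait
    if p.stall_wait_sd > 0:
        wait = max(1.0, float(sim.rng.normal(p.stall_wait, p.stall_wait_sd)))
    sim.stall_wait_actual = wait
    t_inact = draw_inactivation_time(p.dnap_conc, sim.m, sim.rng)
    competent = t_inact > wait
    if not competent:
        sim.inactivation_time = sim.stall_entry_time + t_inact
    sim.run_stalled(wait)
    # Torsional relaxation by device unwinding.
    sim.unwind_start = sim.time
    if p.kind == "aot_restart":
        n_target = sim.turns_at_torque(p.relax_target_torque)
        delta = min(p.relax_max_turns, max(0.0, sim.n_net - n_target))
        sim.run_device_ramp(-delta, p.aot_unwind_rate)
    else:
        sim.run_device_ramp(-p.mt_unwind_turns, p.mt_unwind_rate)
    sim.unwind_end = sim.time
    sim.restarted = bool(competent)
    if competent:
        sim.state.mode = "active"
        outcome = sim.run_active(p.post_unwind_duration, stop_on_stall=True)
        if outcome == "stall":
            sim.second_stall_entry_time = sim.state.stall_entry_time
            remaining = p.post_unwind_duration - (sim.time - sim.unwind_end)
            sim.run_stalled(max(0.0, remaining))
    else:
        sim.state.mode = "inactive"
        sim.run_flat(p.post_unwind_duration)


def _simulate_gyrase(sim: _Sim) -> None:
    """Continuous stepping with gyrase relaxation and periodic probe excursions."""
    p = sim.p
    sim.run_device_ramp(-p.initial_unwind_turns, p.device_rate)
    delay = float(sim.rng.exponential(sim.m.loading_delay_mean)) if sim.m.loading_delay_mean > 0 else 0.0
    sim.run_flat(delay)
    sim.loading_time = sim.time
    sim.state.mode = "active"

    dt = sim.dt
    r_gyr = p.gyrase_vmax * p.gyrase_conc / (p.gyrase_km + p.gyrase_conc) if p.gyrase_conc > 0 else 0.0
    probe_window = 2.0 * p.probe_turns / p.probe_rate
    base_dev = sim.n_dev
    t_inact = math.inf
    next_probe = sim.time + p.probe_period
    t_end = sim.time + p.total_duration
    while sim.time < t_end:
        t = sim.time
        # Device angle: base plus triangular probe excursion.
        if t >= next_probe:
            sim.probe_times.append(next_probe)
            next_probe += p.probe_period
        offset = 0.0
        if sim.probe_times:
            dt_probe = t - sim.probe_times[-1]
            if 0.0 <= dt_probe < probe_window:
                half = probe_window / 2.0
                offset = -p.probe_rate * dt_probe if dt_probe < half else -p.probe_rate * (probe_window - dt_probe)
        sim.n_dev = base_dev + offset
        # Gyrase removes (+) turns after its arrival.
        if r_gyr > 0 and t >= p.gyrase_delay and sim.n_net > 0:
            sim.n_relaxed += min(r_gyr * dt, max(sim.n_net, 0.0))
        torque = sim.torque_at(sim.n_net)
        prev_mode = sim.state.mode
        sim.state = step_motor(sim.state, torque, dt, sim.m, sim.rng)
        # The template is finite: replication stops at its end.
        sim.state.fork_position = min(sim.state.fork_position, p.parental_length)
        if sim.state.mode == "stalled_regressing":
            if prev_mode != "stalled_regressing" and sim.stall_entry_time is None:
                sim.stall_entry_time = sim.state.stall_entry_time
                t_inact = draw_inactivation_time(p.dnap_conc, sim.m, sim.rng)
            # Relaxation below buckling lets a competent motor resume.
            if torque <= sim.g_buck:
                stalled_for = t - (sim.state.stall_entry_time or t)
                if stalled_for < t_inact:
                    sim.state.mode = "active"
                    sim.restarted = True
                else:
                    sim.state.mode = "inactive"
                    if sim.inactivation_time is None:
                        sim.inactivation_time = (sim.state.stall_entry_time or t) + t_inact
                    sim.restarted = False
        sim._record()
    if sim.restarted is None and sim.stall_entry_time is None:
        sim.restarted = True  # never stalled: continuous replication


def simulate_ensemble(
    protocol: Protocol,
    motor: MotorParams,
    mech: MechanicsParams | None = None,
    n_traces: int = 1,
    seed: int = 0,
) -> list[tuple[TraceRecord, EventLog]]:
    """Simulate ``n_traces`` independent traces with per-trace derived seeds.

    Per-trace streams come from ``numpy.random.SeedSequence(seed).spawn``, so
    the ensemble is bit-reproducible and trace *i* is independent of the
    ensemble size.
    """
    if n_traces < 1:
        raise ConfigError("n_traces must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traces)
    return [simulate_trace(protocol, motor, mech, seed=child) for child in children]
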