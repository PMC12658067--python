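"""Restart classification and ensemble statistics after torsional relaxation.

Covers the three restart assays: the angular-optical-trap protocol, where the
restart stall torque after the relaxation unwinding measures restart
efficiency; the magnetic-tweezers protocol at 1.0 pN, where a trace counts
as restarted if the replisome (+)-buckles the DNA again after the unwinding
(a sustained extension decrease); and the gyrase protocol, where a replisome
counts as restarted once it has progressed at least 2000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import mechanics as mech_mod
from .analyze import (
    AnalysisError,
    ForkTrajectory,
    StallEvent,
    _smooth,
    extract_stall_torque,
    fork_position_from_extension,
)
from .mechanics import CalibrationCurve, MechanicsParams
from .simulate import TraceRecord

__all__ = [
    "RestartOutcome",
    "CorrelationResult",
    "restart_stall_torque",
    "classify_mt_restart",
    "classify_gyrase_restart",
    "restart_fraction",
    "regression_restart_correlation",
    "turns_at_stall",
    "summarize_aot_restart_trace",
]


@dataclass
class RestartOutcome:
    """Per-trace restart summary used for grouped statistics."""

    trace_id: str
    protocol: str
    restarted: bool
    initial_stall_torque: float | None = None
    restart_stall_torque: float | None = None
    regression_distance: float | None = None
    stall_duration: float | None = None
    dnap_conc: float | None = None
    gyrase_conc: float | None = None
    ctd_present: bool | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.restart_stall_torque is not None and not self.protocol.startswith("aot"):
            raise AnalysisError("restart stall torque is an AOT-only quantity")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise AnalysisError("Pearson r out of range")
        if not 0.0 < self.p <= 1.0:
            raise AnalysisError("p-value out of range")


def _unwind_interval(trace: TraceRecord, min_turns: float = 2.0) -> tuple[int, int]:
    """Locate the last device unwinding run (start, end sample indices).

    The relaxation step is the last contiguous stretch over which the device
    turns decrease by at least ``min_turns``.
    """
    dev = np.asarray(trace.device_turns)
    dec = np.diff(dev) < -1e-12
    if not dec.any():
        raise AnalysisError("no unwinding step found in device record")
    d = np.diff(dec.astype(np.int8))
    starts = (np.flatnonzero(d == 1) + 1).tolist()
    ends = (np.flatnonzero(d == -1) + 1).tolist()
    if dec[0]:
        starts.insert(0, 0)
    if dec[-1]:
        ends.append(len(dec))
    for s, e in reversed(list(zip(starts, ends))):
        if dev[s] - dev[e] >= min_turns:
            return s, e
    raise AnalysisError("no unwinding step of sufficient magnitude found")


def restart_stall_torque(
    trace: TraceRecord,
    window: float = 60.0,
    smooth_window: float = 0.5,
) -> float:
    """Maximum torque within ``window`` seconds after the relaxation unwinding.

    Mirrors the initial stall-torque rule; a fully active replisome climbs
    back to a torque close to its initial stall torque, an inactive one stays
    near the relaxation target.
    """
    if trace.metadata.get("protocol") not in (None, "aot_restart"):
        raise AnalysisError("restart_stall_torque expects an aot_restart trace")
    _, i_end = _unwind_interval(trace)
    fs = trace.sampling_rate
    g = _smooth(trace.torque[i_end:], smooth_window * fs)
    i1 = min(len(g), int(round(window * fs)) + 1)
    if i1 < 2:
        raise AnalysisError("no samples after the unwinding step")
    return float(np.max(g[:i1]))


def classify_mt_restart(
    trace: TraceRecord,
    mech: MechanicsParams | None = None,
    min_sustain: float = 10.0,
    noise_sigmas: float = 3.0,
    smooth_window: float = 0.5,
) -> bool:
    """Classify a magnetic-tweezers restart trace.

    A restarted replisome re-buckles the DNA after the unwinding step, which
    shows up as a sustained extension decrease; an inactive one leaves the
    extension flat.  The decision threshold is the extension drop from the
    hat-curve maximum to the buckling shoulder plus ``noise_sigmas`` times the
    per-sample noise level (estimated from the high-frequency residual), and
    the drop must persist for at least ``min_sustain`` seconds.
    """
    mech = mech or MechanicsParams()
    if trace.metadata.get("protocol") not in (None, "mt_restart"):
        raise AnalysisError("classify_mt_restart expects an mt_restart trace")
    _, i_end = _unwind_interval(trace)
    fs = trace.sampling_rate
    ext = np.asarray(trace.extension[i_end:], dtype=float)
    if len(ext) < int(2 * min_sustain * fs):
        raise AnalysisError("post-unwinding segment too short to classify")
    smoothed = _smooth(ext, smooth_window * fs)
    noise_sd = float(np.std(ext - smoothed))
    force = float(np.median(trace.force))
    length = float(trace.metadata["parental_length"])
    n_b = mech_mod.buckling_turns(length, force, mech)
    shoulder_drop = mech.prebuckling_extension_curvature * n_b**2
    threshold = shoulder_drop + noise_sigmas * max(noise_sd, 1.0)
    baseline = float(np.max(smoothed))
    below = smoothed < baseline - threshold
    if not below.any():
        return False
    # Longest contiguous run below threshold.
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [below.size]])
    longest = max(e - s for s, e in zip(starts, ends))
    return bool(longest >= min_sustain * fs)


def classify_gyrase_restart(traj: ForkTrajectory, threshold: float = 2000.0) -> bool:
    """Restarted if the probe-derived fork progressed at least ``threshold`` bp."""
    pos = traj.position[traj.valid]
    if pos.size == 0:
        return False
    return bool(np.nanmax(pos) >= threshold)


def restart_fraction(outcomes, group_keys=("condition",), exact_ci: bool = False):
    """Fraction restarted per group with binomial standard errors.

    Wald SE sqrt(p(1-p)/n) by default; with ``exact_ci`` a Clopper–Pearson
    95% interval is added.
    """
    import pandas as pd

    outcomes = list(outcomes)
    if not outcomes:
        raise AnalysisError("no outcomes supplied")
    rows = [
        {**{k: getattr(o, k) for k in group_keys}, "restarted": bool(o.restarted)}
        for o in outcomes
    ]
    df = pd.DataFrame(rows)
    out = []
    for key, sub in df.groupby(list(group_keys), dropna=False):
        n = len(sub)
        p = float(sub["restarted"].mean())
        row = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        row.update({"fraction": p, "se": float(np.sqrt(p * (1 - p) / n)), "n": n})
        if exact_ci:
            k = int(sub["restarted"].sum())
            lo = stats.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
            hi = stats.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
            row.update({"ci_low": float(lo), "ci_high": float(hi)})
        out.append(row)
    return pd.DataFrame(out)


def regression_restart_correlation(outcomes) -> CorrelationResult:
    """Pearson correlation between regression distance during the initial
    stall and the restart stall torque, with a two-sided t-test p-value."""
    pairs = [
        (o.regression_distance, o.restart_stall_torque)
        for o in outcomes
        if o.regression_distance is not None
        and o.restart_stall_torque is not None
        and np.isfinite(o.regression_distance)
        and np.isfinite(o.restart_stall_torque)
    ]
    if len(pairs) < 3:
        raise AnalysisError("need at least 3 finite (regression, torque) pairs")
    x, y = map(np.asarray, zip(*pairs))
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(pairs))


def turns_at_stall(
    stall_torque: float,
    force: float,
    parental_length: float,
    mech: MechanicsParams | None = None,
) -> float:
    """Excess turns stored in the tether when the torque reaches the stall level.

    Thin reporting wrapper over the mechanics inversion; only meaningful at
    or above the buckling torque (the stalled DNA is plectonemic).
    """
    mech = mech or MechanicsParams()
    g_b = mech_mod.buckling_torque(force, mech)
    if stall_torque < g_b:
        raise mech_mod.MechanicsError(
            f"stall torque {stall_torque} pN·nm below buckling ({g_b:.2f} pN·nm)"
        )
    return mech_mod.turns_of_torque(stall_torque, parental_length, force, mech)


def summarize_aot_restart_trace(
    trace: TraceRecord,
    cal: CalibrationCurve,
    mech: MechanicsParams | None = None,
    window: float = 60.0,
) -> RestartOutcome:
    """Build a :class:`RestartOutcome` from one AOT restart trace.

    The initial stall torque uses the standard 60 s maximum-torque rule up to
    the relaxation unwinding; the regression distance runs from the maximum
    forward fork position to the position at the unwinding start; the trace
    counts as restarted if the restart stall torque reaches the buckling
    torque again (only an active replisome can re-buckle the DNA).
    """
    mech = mech or MechanicsParams()
    i_start, i_end = _unwind_interval(trace)
    fs = trace.sampling_rate
    pre = TraceRecord(
        metadata=dict(trace.metadata),
        time=trace.time[:i_start],
        extension=trace.extension[:i_start],
        force=trace.force[:i_start],
        torque=trace.torque[:i_start],
        device_turns=trace.device_turns[:i_start],
    )
    initial: StallEvent | None = extract_stall_torque(pre, window=window, mech=mech)
    g_restart = restart_stall_torque(trace, window=window)
    traj = fork_position_from_extension(pre, cal)
    pos = _smooth(traj.filled_position(), 0.5 * fs)
    regression = float(np.max(pos) - pos[-1])
    stall_duration = None
    if initial is not None:
        stall_duration = float(trace.time[i_start] - initial.onset)
    g_buck = mech_mod.buckling_torque(float(np.median(trace.force)), mech)
    return RestartOutcome(
        trace_id=str(trace.metadata.get("seed", "")),
        protocol="aot_restart",
        restarted=bool(g_restart >= g_buck),
        initial_stall_torque=None if initial is None else initial.stall_torque,
        restart_stall_torque=g_restart,
        regression_distance=regression,
        stall_duration=stall_duration,
        dnap_conc=trace.metadata.get("dnap_conc"),
        gyrase_conc=trace.metadata.get("gyrase_conc"),
        condition=trace.metadata.get("condition"),
    )
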