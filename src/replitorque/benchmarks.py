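"""Headline-number recomputations on freshly simulated ensembles.

Each function regenerates the relevant ensemble at the study's trace counts,
runs the blind analysis pipeline on it, and reports the recovered quantity:
stall-torque Gaussian means per composition, 60 s fork regression,
magnetic-tweezers restart fractions versus DNAP concentration, the
constant-torque rotation rate, and the two analytic mechanics anchors.
"""

from __future__ import annotations

import numpy as np

from .analyze import (
    detect_pauses,
    estimate_velocities,
    extract_stall_torque,
    fit_stall_histogram,
    fork_position_from_extension,
    regression_curve,
)
from .mechanics import MechanicsParams, buckling_torque, default_calibration, turns_of_torque
from .motor import motor_preset
from .restart import classify_mt_restart
from .simulate import Protocol, simulate_ensemble

__all__ = [
    "stall_torque_recovery",
    "regression_at_60s",
    "mt_restart_fraction",
    "constant_torque_rotation_rate",
    "buckling_anchor",
    "turns_at_22",
    "run_all",
]

#: Trace counts of the stall-torque histograms per composition.
STALL_ENSEMBLE_N = {"WT": 19, "dCt": 16, "DNAP_only": 16, "helicase_only": 16}
#: Trace counts of the regression ensembles per composition.
REGRESSION_ENSEMBLE_N = {"WT": 48, "dCt": 22, "dCt_exo": 12}


def stall_torque_recovery(condition: str, n: int, seed: int, mech: MechanicsParams | None = None):
    """Gaussian-fit mean/sd of pipeline-extracted stall torques (pN·nm)."""
    mech = mech or MechanicsParams()
    protocol = Protocol.for_kind("aot_stall")
    motor = motor_preset(condition)
    pairs = simulate_ensemble(protocol, motor, mech, n_traces=n, seed=seed)
    torques = []
    for trace, _ in pairs:
        ev = extract_stall_torque(trace, mech=mech)
        if ev is not None:
            torques.append(ev.stall_torque)
    mean, sd, diag = fit_stall_histogram(torques)
    return {"mean": mean, "sd": sd, "n": len(torques), "fit": diag}


def regression_at_60s(condition: str, n: int, seed: int, mech: MechanicsParams | None = None):
    """Mean fork regression (bp) 60 s after the maximum forward position."""
    mech = mech or MechanicsParams()
    protocol = Protocol.for_kind("aot_stall")
    motor = motor_preset(condition)
    pairs = simulate_ensemble(protocol, motor, mech, n_traces=n, seed=seed)
    cal = default_calibration(protocol.parental_length, protocol.force, mech)
    trajs = [fork_position_from_extension(trace, cal) for trace, _ in pairs]
    curve = regression_curve(trajs)
    return {"regression_bp": curve.regression_at(60.0), "n": n}


def mt_restart_fraction(
    dnap_conc: float,
    n: int,
    seed: int,
    condition: str = "WT",
    mech: MechanicsParams | None = None,
):
    """Restart fraction after a ~240 s stall, classified by re-buckling."""
    mech = mech or MechanicsParams()
    protocol = Protocol.for_kind("mt_restart", dnap_conc=dnap_conc)
    motor = motor_preset(condition)
    pairs = simulate_ensemble(protocol, motor, mech, n_traces=n, seed=seed)
    flags = [classify_mt_restart(trace, mech) for trace, _ in pairs]
    return {"fraction": float(np.mean(flags)), "n": n}


def constant_torque_rotation_rate(
    n: int,
    seed: int,
    clamp: float = 12.6,
    condition: str = "WT",
    mech: MechanicsParams | None = None,
):
    """Ensemble-mean pause-free rotation rate (turns/s) at a torque clamp."""
    mech = mech or MechanicsParams()
    protocol = Protocol.for_kind("aot_constant_torque", torque_clamp=clamp)
    motor = motor_preset(condition)
    pairs = simulate_ensemble(protocol, motor, mech, n_traces=n, seed=seed)
    cal = default_calibration(protocol.parental_length, protocol.force, mech)
    rates = []
    for trace, _ in pairs:
        t0 = trace.metadata.get("clamp_engage_time")
        if t0 is None:
            continue
        traj = fork_position_from_extension(trace, cal)
        sel = traj.time >= t0
        sub = type(traj)(traj.time[sel], traj.position[sel], traj.valid[sel], traj.source, traj.calibration)
        pauses = detect_pauses(sub)
        est = estimate_velocities(sub, pauses)
        if est.pause_free_defined:
            rates.append(est.v_pause_free / mech.helical_pitch)
    return {"rate_turns_per_s": float(np.mean(rates)), "n": len(rates)}


def buckling_anchor(mech: MechanicsParams | None = None):
    """Critical (+) buckling torque at 1.0 pN (pN·nm)."""
    return {"torque": buckling_torque(1.0, mech or MechanicsParams()), "n": 1}


def turns_at_22(mech: MechanicsParams | None = None):
    """Turns stored at 22 pN·nm on the 5 kb parental template at 1.0 pN."""
    return {"turns": turns_of_torque(22.0, 5000.0, 1.0, mech or MechanicsParams()), "n": 1}


def run_all(seed: int) -> dict:
    """Every headline quantity, recomputed from scratch, keyed descriptively."""
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(16)]
    out: dict = {}
    out["stall_torque_wt"] = _pack(stall_torque_recovery("WT", STALL_ENSEMBLE_N["WT"], subseeds[0]), "mean")
    out["stall_torque_dct"] = _pack(stall_torque_recovery("dCt", STALL_ENSEMBLE_N["dCt"], subseeds[1]), "mean")
    out["stall_torque_dnap_only"] = _pack(
        stall_torque_recovery("DNAP_only", STALL_ENSEMBLE_N["DNAP_only"], subseeds[2]), "mean"
    )
    out["stall_torque_helicase_only"] = _pack(
        stall_torque_recovery("helicase_only", STALL_ENSEMBLE_N["helicase_only"], subseeds[3]), "mean"
    )
    out["regression_60s_wt"] = _pack(regression_at_60s("WT", REGRESSION_ENSEMBLE_N["WT"], subseeds[4]), "regression_bp")
    out["regression_60s_dct"] = _pack(regression_at_60s("dCt", REGRESSION_ENSEMBLE_N["dCt"], subseeds[5]), "regression_bp")
    out["regression_60s_dct_exo"] = _pack(
        regression_at_60s("dCt_exo", REGRESSION_ENSEMBLE_N["dCt_exo"], subseeds[6]), "regression_bp"
    )
    frac1 = mt_restart_fraction(1.0, 100, subseeds[7])
    frac100 = mt_restart_fraction(100.0, 100, subseeds[8])
    out["mt_restart_pct_1nM"] = {"value": 100.0 * frac1["fraction"], "n": frac1["n"]}
    out["mt_restart_pct_100nM"] = {"value": 100.0 * frac100["fraction"], "n": frac100["n"]}
    out["buckling_torque_1pN"] = _pack(buckling_anchor(), "torque")
    out["turns_at_22pNnm"] = _pack(turns_at_22(), "turns")
    out["rotation_rate_at_12p6"] = _pack(constant_torque_rotation_rate(15, subseeds[9]), "rate_turns_per_s")
    return out


def _pack(result: dict, key: str) -> dict:
    return {"value": float(result[key]), "n": int(result["n"])}
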