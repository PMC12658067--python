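"""Restart classification, fractions, correlations, and ground-truth agreement."""

import math

import numpy as np
import pytest

from replitorque.analyze import AnalysisError, ForkTrajectory
from replitorque.mechanics import MechanicsParams, MechanicsError, buckling_torque, default_calibration, turns_of_torque
from replitorque.motor import motor_preset
from replitorque.restart import (
    CorrelationResult,
    RestartOutcome,
    classify_gyrase_restart,
    classify_mt_restart,
    regression_restart_correlation,
    restart_fraction,
    restart_stall_torque,
    summarize_aot_restart_trace,
    turns_at_stall,
)
from replitorque.simulate import Protocol, simulate_ensemble, simulate_trace


def _traj_from_positions(positions):
    pos = np.asarray(positions, dtype=float)
    t = np.arange(len(pos), dtype=float)
    return ForkTrajectory(t, pos, valid=np.isfinite(pos))


def test_gyrase_threshold_boundary():
    assert classify_gyrase_restart(_traj_from_positions([100.0, 1999.0])) is False
    assert classify_gyrase_restart(_traj_from_positions([100.0, 2500.0])) is True
    assert classify_gyrase_restart(_traj_from_positions([2000.0])) is True  # "at least"
    empty = ForkTrajectory(np.array([0.0]), np.array([np.nan]), np.array([False]))
    assert classify_gyrase_restart(empty) is False


def _outcome(restarted, condition="WT", **kw):
    return RestartOutcome(
        trace_id="x", protocol="mt_restart", restarted=restarted, condition=condition, **kw
    )


def test_restart_fraction_wald_se():
    outcomes = [_outcome(True)] * 3 + [_outcome(False)] * 7
    table = restart_fraction(outcomes)
    row = table.iloc[0]
    assert row["fraction"] == pytest.approx(0.3)
    assert row["se"] == pytest.approx(math.sqrt(0.3 * 0.7 / 10))
    assert row["n"] == 10


def test_restart_fraction_all_false_and_exact_ci():
    outcomes = [_outcome(False)] * 8
    table = restart_fraction(outcomes, exact_ci=True)
    row = table.iloc[0]
    assert row["fraction"] == 0.0 and row["se"] == 0.0
    assert row["ci_low"] == 0.0
    assert 0.0 < row["ci_high"] < 1.0
    with pytest.raises(AnalysisError):
        restart_fraction([])


def test_restart_fraction_groups():
    outcomes = [_outcome(True, "WT")] * 2 + [_outcome(False, "dCt")] * 3
    table = restart_fraction(outcomes).set_index("condition")
    assert table.loc["WT", "fraction"] == 1.0
    assert table.loc["dCt", "fraction"] == 0.0


def test_correlation_perfectly_anticorrelated():
    outcomes = [
        RestartOutcome(
            trace_id=str(i), protocol="aot_restart", restarted=True,
            regression_distance=float(x), restart_stall_torque=30.0 - 2.0 * x,
        )
        for i, x in enumerate(range(8))
    ]
    res = regression_restart_correlation(outcomes)
    assert res.r == pytest.approx(-1.0, abs=1e-9)
    assert res.p < 1e-6 and res.n == 8


def test_correlation_hand_computed():
    # Pearson r via explicit sums, independent of scipy.
    x = [0.0, 1.0, 2.0, 3.0]
    y = [1.0, 3.0, 2.0, 4.0]
    mx, my = sum(x) / 4, sum(y) / 4
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    expected = num / den
    outcomes = [
        RestartOutcome(
            trace_id=str(i), protocol="aot_restart", restarted=True,
            regression_distance=a, restart_stall_torque=b,
        )
        for i, (a, b) in enumerate(zip(x, y))
    ]
    res = regression_restart_correlation(outcomes)
    assert res.r == pytest.approx(expected, rel=1e-9)
    assert 0.0 < res.p <= 1.0


def test_correlation_validation():
    short = [
        RestartOutcome(trace_id="a", protocol="aot_restart", restarted=True,
                       regression_distance=1.0, restart_stall_torque=2.0)
    ] * 2
    with pytest.raises(AnalysisError):
        regression_restart_correlation(short)
    flat = [
        RestartOutcome(trace_id=str(i), protocol="aot_restart", restarted=True,
                       regression_distance=1.0, restart_stall_torque=float(i))
        for i in range(4)
    ]
    with pytest.raises(AnalysisError):
        regression_restart_correlation(flat)
    with pytest.raises(AnalysisError):
        CorrelationResult(r=1.5, p=0.5, n=3)
    with pytest.raises(AnalysisError):
        CorrelationResult(r=0.5, p=0.0, n=3)


def test_restart_outcome_aot_only_field():
    with pytest.raises(AnalysisError):
        RestartOutcome(trace_id="x", protocol="mt_restart", restarted=True,
                       restart_stall_torque=20.0)


def test_turns_at_stall():
    assert turns_at_stall(22.0, 1.0, 5000.0) == pytest.approx(
        turns_of_torque(22.0, 5000.0, 1.0)
    )
    with pytest.raises(MechanicsError):
        turns_at_stall(5.0, 1.0, 5000.0)  # below buckling: not plectonemic


def test_mt_classifier_agrees_with_ground_truth():
    # >= 95% agreement with the EventLog at the default noise level.
    mech = MechanicsParams()
    motor = motor_preset("WT")
    total, agree = 0, 0
    for conc, seed in ((1.0, 101), (100.0, 202)):
        protocol = Protocol.for_kind("mt_restart", dnap_conc=conc)
        for trace, log in simulate_ensemble(protocol, motor, mech, n_traces=30, seed=seed):
            total += 1
            agree += classify_mt_restart(trace, mech) == bool(log.restarted)
    assert agree / total >= 0.95


def test_gyrase_classifier_agrees_with_ground_truth():
    mech = MechanicsParams()
    from replitorque.analyze import fork_positions_from_probes

    total, agree = 0, 0
    # Restarting arm: saturating gyrase from the start.
    p_go = Protocol.for_kind("gyrase_probe", total_duration=120.0)
    for trace, log in simulate_ensemble(p_go, motor_preset("WT"), mech, n_traces=8, seed=303):
        total += 1
        agree += classify_gyrase_restart(fork_positions_from_probes(trace, mech)) == bool(log.restarted)
    # Non-restarting arm: gyrase arrives late and the stalled replisome has
    # already lost restart competence.
    p_dead = Protocol.for_kind("gyrase_probe", total_duration=120.0, gyrase_delay=40.0)
    dead = motor_preset("WT", inactivation_rate=100.0)
    for trace, log in simulate_ensemble(p_dead, dead, mech, n_traces=8, seed=404):
        total += 1
        agree += classify_gyrase_restart(fork_positions_from_probes(trace, mech)) == bool(log.restarted)
    assert agree / total >= 0.95


def test_restart_fraction_monotone_in_stall_duration():
    # Simulated ensembles (n = 50 per duration): fraction non-increasing.
    mech = MechanicsParams()
    motor = motor_preset("WT")
    fractions = []
    for wait, seed in ((60.0, 11), (240.0, 12), (600.0, 13)):
        protocol = Protocol.for_kind(
            "mt_restart", stall_wait=wait, stall_wait_sd=0.0, dnap_conc=1.0
        )
        flags = [
            classify_mt_restart(trace, mech)
            for trace, _ in simulate_ensemble(protocol, motor, mech, n_traces=50, seed=seed)
        ]
        fractions.append(np.mean(flags))
    assert fractions[0] >= fractions[1] >= fractions[2]


def test_aot_restart_summary_and_diagonal():
    # Restart stall torque <= initial stall torque + 2x torque-noise sd.
    mech = MechanicsParams()
    protocol = Protocol.for_kind("aot_restart", stall_wait=30.0)
    cal = default_calibration(protocol.parental_length, protocol.force, mech)
    pairs = simulate_ensemble(protocol, motor_preset("WT"), mech, n_traces=8, seed=55)
    noise_sd = 0.5  # upper bound of the propagated torque noise
    n_restarted = 0
    for trace, log in pairs:
        out = summarize_aot_restart_trace(trace, cal, mech)
        assert out.protocol == "aot_restart"
        assert out.restart_stall_torque is not None
        if out.initial_stall_torque is not None:
            assert out.restart_stall_torque <= out.initial_stall_torque + 2 * noise_sd + 1.0
        assert out.regression_distance is not None and out.regression_distance >= -5.0
        n_restarted += out.restarted
        # Classification consistency: restarted means the torque re-crossed buckling.
        if out.restarted:
            assert out.restart_stall_torque >= buckling_torque(1.0, mech)
    assert 0 <= n_restarted <= 8


def test_restart_stall_torque_requires_unwind():
    from replitorque.simulate import TraceRecord

    n = 1000
    trace = TraceRecord(
        metadata={"sampling_rate": 100.0, "protocol": "aot_restart"},
        time=np.arange(n) / 100.0,
        extension=np.full(n, 1000.0),
        force=np.full(n, 1.0),
        torque=np.zeros(n),
        device_turns=np.zeros(n),  # the device never unwinds
    )
    with pytest.raises(AnalysisError):
        restart_stall_torque(trace)
    with pytest.raises(AnalysisError):
        restart_stall_torque(trace.__class__(
            metadata={**trace.metadata, "protocol": "mt_restart"},
            time=trace.time, extension=trace.extension, force=trace.force,
            torque=trace.torque, device_turns=trace.device_turns,
        ))
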