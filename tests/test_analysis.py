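"""Analysis pipeline: reconstruction, pause detection, velocities, stall fits."""

import numpy as np
import pytest

from replitorque.analyze import (
    AnalysisError,
    ForkTrajectory,
    PauseSegment,
    detect_pauses,
    estimate_velocities,
    extract_stall_torque,
    fit_stall_histogram,
    fork_position_from_extension,
    fork_positions_from_probes,
    regression_curve,
    torque_velocity_table,
)
from replitorque.mechanics import (
    MechanicsParams,
    buckling_turns,
    default_calibration,
    extension_of_turns,
)
from replitorque.motor import motor_preset
from replitorque.simulate import Protocol, TraceRecord, simulate_trace

FS = 50.0


def _traj(time, pos):
    time = np.asarray(time, dtype=float)
    pos = np.asarray(pos, dtype=float)
    return ForkTrajectory(time=time, position=pos, valid=np.ones(len(pos), bool))


def _ramp_with_pause(v1, t_pause, dur_pause, v2, total, fs=FS):
    """Piecewise trajectory: slope v1, flat pause, slope v2."""
    t = np.arange(0.0, total, 1.0 / fs)
    pos = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti < t_pause:
            pos[i] = v1 * ti
        elif ti < t_pause + dur_pause:
            pos[i] = v1 * t_pause
        else:
            pos[i] = v1 * t_pause + v2 * (ti - t_pause - dur_pause)
    return _traj(t, pos)


def test_no_pauses_on_steady_ramp():
    # 42 bp/s: dwell ~0.024 s/bp, far below the 0.1 s/bp threshold.
    t = np.arange(0.0, 100.0, 1.0 / FS)
    assert detect_pauses(_traj(t, 42.0 * t)) == []


def test_single_inserted_pause_detected():
    traj = _ramp_with_pause(40.0, 20.0, 5.0, 40.0, 60.0)
    pauses = detect_pauses(traj)
    assert len(pauses) == 1
    p = pauses[0]
    assert p.start == pytest.approx(20.0, abs=1.0)
    assert p.duration == pytest.approx(5.0, abs=1.5)


def test_fully_stalled_trace_is_one_pause():
    t = np.arange(0.0, 30.0, 1.0 / FS)
    pauses = detect_pauses(_traj(t, np.zeros_like(t)))
    assert len(pauses) == 1
    assert pauses[0].duration == pytest.approx(30.0, abs=0.5)


def test_detect_pauses_too_short_raises():
    with pytest.raises(AnalysisError):
        detect_pauses(_traj([0.0], [0.0]))


def test_pause_segment_validation():
    with pytest.raises(AnalysisError):
        PauseSegment(start=5.0, end=5.0, position_span=0.0)


def test_pause_free_velocity_hand_example():
    # 10 s at 40 bp/s + 30 s at 20 bp/s (pause excised) ->
    # duration-weighted (10*40 + 30*20)/40 = 25 bp/s.
    traj = _ramp_with_pause(40.0, 10.0, 10.0, 20.0, 50.0)
    pauses = [PauseSegment(start=10.0, end=20.0, position_span=0.0)]
    est = estimate_velocities(traj, pauses)
    assert est.pause_free_defined
    assert est.v_pause_free == pytest.approx(25.0, abs=0.5)
    assert est.v_with_pauses < est.v_pause_free  # the pause drags the mean down


def test_window_truncated_by_regression_cutoff():
    # Rise for 30 s at 10 bp/s, then regress at 20 bp/s; the 100 bp cutoff is
    # hit 5 s into the regression.
    fs = FS
    t = np.arange(0.0, 60.0, 1.0 / fs)
    pos = np.where(t < 30.0, 10.0 * t, 300.0 - 20.0 * (t - 30.0))
    est = estimate_velocities(_traj(t, pos), [])
    assert est.window[1] == pytest.approx(35.0, abs=0.2)


def test_all_paused_window_has_undefined_pause_free_velocity():
    t = np.arange(0.0, 20.0, 1.0 / FS)
    traj = _traj(t, np.zeros_like(t))
    est = estimate_velocities(traj, [PauseSegment(0.0, 20.0, 0.0)])
    assert not est.pause_free_defined
    assert np.isnan(est.v_pause_free)


def test_estimate_velocities_needs_samples():
    with pytest.raises(AnalysisError):
        estimate_velocities(_traj([0.0, 1.0], [0.0, 1.0]), [])


def test_filled_position_interpolates_flags():
    t = np.arange(5.0)
    pos = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
    traj = ForkTrajectory(t, pos, valid=np.isfinite(pos))
    assert traj.filled_position()[2] == pytest.approx(2.0)
    bad = ForkTrajectory(t, np.full(5, np.nan), valid=np.zeros(5, bool))
    with pytest.raises(AnalysisError):
        bad.filled_position()


def _synthetic_torque_trace(torque, fs=100.0):
    n = len(torque)
    t = np.arange(n) / fs
    z = np.full(n, 100.0)
    return TraceRecord(
        metadata={"sampling_rate": fs, "protocol": "aot_stall"},
        time=t,
        extension=z,
        force=np.full(n, 1.0),
        torque=np.asarray(torque, dtype=float),
        device_turns=np.zeros(n),
    )


def test_extract_stall_torque_plateau():
    fs = 100.0
    t = np.arange(0.0, 120.0, 1.0 / fs)
    g = np.minimum(21.0, 0.5 * t)  # ramp, plateau at 21 from t=42 s
    ev = extract_stall_torque(_synthetic_torque_trace(g), mech=MechanicsParams())
    assert ev is not None
    assert ev.stall_torque == pytest.approx(21.0, abs=0.05)
    assert ev.onset == pytest.approx(42.0, abs=2.0)


def test_extract_stall_torque_none_when_flat():
    g = np.full(2000, 0.2)
    assert extract_stall_torque(_synthetic_torque_trace(g)) is None
    assert extract_stall_torque(_synthetic_torque_trace(g[:5])) is None


def test_extract_stall_torque_buckling_rule_option():
    fs = 100.0
    t = np.arange(0.0, 120.0, 1.0 / fs)
    g = np.minimum(21.0, 0.5 * t)
    ev = extract_stall_torque(_synthetic_torque_trace(g), onset_rule="buckling")
    assert ev is not None
    # Buckling (12.6 pN*nm at 1 pN) is crossed at t = 25.2 s.
    assert ev.onset == pytest.approx(25.2, abs=2.0)
    assert ev.stall_torque == pytest.approx(21.0, abs=0.05)


def test_fit_stall_histogram_consistency():
    rng = np.random.default_rng(99)
    draws = rng.normal(21.9, 4.4, 10_000)
    mu, sd, diag = fit_stall_histogram(draws)
    assert abs(mu - 21.9) / 21.9 < 0.01
    assert abs(sd - 4.4) / 4.4 < 0.05
    assert diag["n"] == 10_000


def test_fit_stall_histogram_small_and_degenerate():
    with pytest.raises(AnalysisError):
        fit_stall_histogram([1.0, 2.0, 3.0, 4.0])
    mu, sd, diag = fit_stall_histogram([7.0] * 10)
    assert mu == 7.0 and sd == 0.0
    assert diag["method"] == "gaussian_mle"


def test_regression_curve_single_trace_identity():
    fs = FS
    t = np.arange(0.0, 100.0, 1.0 / fs)
    pos = np.where(t < 30.0, 10.0 * t, 300.0 - 2.0 * (t - 30.0))
    curve = regression_curve([_traj(t, pos)], smooth_window=0.0)
    assert curve.regression_at(60.0) == pytest.approx(120.0, abs=1.0)
    assert np.all(curve.sem == 0.0)
    assert np.all(curve.n_per_point == 1)
    with pytest.raises(AnalysisError):
        curve.regression_at(1e6)
    with pytest.raises(AnalysisError):
        regression_curve([])


def test_regression_curve_sem_formula():
    # Two straight lines regressing at 1 and 3 bp/s: mean 2 bp/s, and
    # SEM = sd/sqrt(2) with sd = |1-3|*t/sqrt(2).
    fs = FS
    t = np.arange(0.0, 50.0, 1.0 / fs)
    trajs = [_traj(t, -1.0 * t), _traj(t, -3.0 * t)]
    curve = regression_curve(trajs, smooth_window=0.0)
    assert curve.regression_at(10.0) == pytest.approx(20.0, abs=0.5)
    i = np.argmin(np.abs(curve.time_grid - 10.0))
    expected_sem = np.std([-10.0, -30.0], ddof=1) / np.sqrt(2)
    assert curve.sem[i] == pytest.approx(expected_sem, abs=0.5)


def test_fork_reconstruction_noiseless_round_trip():
    # Pipeline identity on the (+) descending branch: <= 0.5 turn error.
    p = Protocol.for_kind("aot_stall", extension_noise_sd=0.0, stall_hold=30.0)
    m = motor_preset("WT", pause_entry_rate=0.0)
    trace, log = simulate_trace(p, m, seed=21)
    cal = default_calibration(p.parental_length, p.force)
    traj = fork_position_from_extension(trace, cal)
    n_b = buckling_turns(p.parental_length, p.force)
    mask = log.net_turns_truth > n_b + 0.5
    assert mask.sum() > 100
    err_turns = np.abs(traj.position[mask] - log.fork_truth[mask]) / 10.5
    assert np.nanmax(err_turns) <= 0.5


def test_fork_reconstruction_force_mismatch_raises():
    p = Protocol.for_kind("aot_stall", stall_hold=10.0)
    trace, _ = simulate_trace(p, motor_preset("WT"), seed=1)
    cal = default_calibration(p.parental_length, 2.0)
    with pytest.raises(AnalysisError):
        fork_position_from_extension(trace, cal)


def test_out_of_range_extension_flagged_not_dropped():
    cal = default_calibration(5000.0, 1.0)
    n = 600
    t = np.arange(n) / 100.0
    ext = np.full(n, 500.0)
    ext[100] = 1e5  # far outside the calibrated range
    trace = TraceRecord(
        metadata={"sampling_rate": 100.0},
        time=t,
        extension=ext,
        force=np.full(n, 1.0),
        torque=np.zeros(n),
        device_turns=np.zeros(n),
    )
    traj = fork_position_from_extension(trace, cal)
    assert not traj.valid[100] and traj.valid[99]
    assert len(traj.position) == n


def test_probe_readout_tracks_truth():
    p = Protocol.for_kind("gyrase_probe", total_duration=100.0)
    trace, log = simulate_trace(p, motor_preset("WT"), seed=4)
    traj = fork_positions_from_probes(trace)
    # Readouts are timestamped at the extension maximum inside each probe
    # window, so the spacing matches the 18 s schedule only approximately.
    assert np.allclose(np.diff(traj.time), 18.0, atol=4.0)
    fs = p.sampling_rate
    for tk, pos in zip(traj.time, traj.position):
        truth = log.fork_truth[int(round(tk * fs))]
        assert abs(pos - truth) < 60.0


def test_probe_readout_requires_schedule():
    p = Protocol.for_kind("aot_stall", stall_hold=10.0)
    trace, _ = simulate_trace(p, motor_preset("WT"), seed=1)
    with pytest.raises(AnalysisError):
        fork_positions_from_probes(trace)


def test_torque_velocity_table_shape():
    fs = FS
    t = np.arange(0.0, 40.0, 1.0 / fs)
    groups = {
        5.0: [_traj(t, 60.0 * t)],
        12.6: [_traj(t, 42.0 * t), _traj(t, 40.0 * t)],
        20.0: [],
    }
    with pytest.warns(UserWarning):
        table = torque_velocity_table(groups)
    assert list(table["torque_pNnm"]) == [5.0, 12.6]
    assert table.loc[table["torque_pNnm"] == 12.6, "n"].item() == 2
    row = table[table["torque_pNnm"] == 12.6].iloc[0]
    assert row["v_pause_free"] == pytest.approx(41.0, abs=0.5)
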