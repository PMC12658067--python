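"""Run configuration, the end-to-end pipeline, and the auditable run log.

A :class:`RunConfig` bundles everything a full simulate → analyze → restart
run needs: mechanics/motor/protocol parameters, ensemble size, master seed
and output directory, plus every analysis threshold (all defaulted to the
standard values: 0.5 s smoothing, 0.1 s/bp dwell threshold, 60 s / 100 bp
velocity window, +6 pN·nm relaxation target, 50/100 turn unwinds, 30 turn/s
probe rate, 18 s probing period, 2000 bp gyrase restart criterion).  Configs
round-trip losslessly through YAML and unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analyze import (
    detect_pauses,
    estimate_velocities,
    extract_stall_torque,
    fit_stall_histogram,
    fork_position_from_extension,
    fork_positions_from_probes,
    regression_curve,
)
from .mechanics import MechanicsParams, default_calibration
from .motor import motor_preset
from .restart import (
    classify_gyrase_restart,
    classify_mt_restart,
    restart_stall_torque,
)
from .simulate import ConfigError, Protocol, simulate_ensemble
from .io import write_event_log, write_trace

__all__ = ["AnalysisThresholds", "RunConfig", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisThresholds:
    """Every analysis threshold, recorded in the run log for auditability."""

    smooth_window_s: float = 0.5
    dwell_threshold_s_per_bp: float = 0.1
    velocity_window_s: float = 60.0
    regression_cutoff_bp: float = 100.0
    stall_window_s: float = 60.0
    relax_target_torque_pNnm: float = 6.0
    relax_max_turns: float = 50.0
    mt_unwind_turns: float = 100.0
    probe_rate_turns_per_s: float = 30.0
    probe_period_s: float = 18.0
    gyrase_restart_threshold_bp: float = 2000.0
    mt_restart_min_sustain_s: float = 10.0


def _from_mapping(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    protocol_kind: str = "aot_stall"
    condition: str = "WT"
    n_traces: int = 1
    seed: int = 0
    out_dir: str | None = None
    schema_version: int = CONFIG_SCHEMA_VERSION
    mechanics: dict = field(default_factory=dict)
    motor_overrides: dict = field(default_factory=dict)
    protocol_overrides: dict = field(default_factory=dict)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)

    def __post_init__(self) -> None:
        if self.n_traces < 1:
            raise ConfigError("n_traces must be >= 1")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported config schema version {self.schema_version}"
            )
        if isinstance(self.thresholds, dict):
            self.thresholds = _from_mapping(AnalysisThresholds, self.thresholds, "thresholds")
        # Build eagerly so a bad config fails at load time.
        self.build_protocol()
        self.build_motor()
        self.build_mechanics()

    # -- construction -------------------------------------------------------
    def build_mechanics(self) -> MechanicsParams:
        return _from_mapping(MechanicsParams, dict(self.mechanics), "mechanics")

    def build_motor(self):
        return motor_preset(self.condition, **self.motor_overrides)

    def build_protocol(self) -> Protocol:
        return Protocol.for_kind(self.protocol_kind, **self.protocol_overrides)

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        data = asdict(self)
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        return _from_mapping(cls, data, "config")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))


def _per_trace_row(i, trace, log, cal, mech, thr: AnalysisThresholds) -> dict:
    kind = trace.metadata["protocol"]
    row: dict = {"trace": i, "protocol": kind, "condition": trace.metadata["condition"]}
    if kind == "gyrase_probe":
        traj = fork_positions_from_probes(trace, mech)
        row["final_position_bp"] = float(np.nanmax(traj.position)) if traj.position.size else float("nan")
        row["restarted"] = classify_gyrase_restart(traj, thr.gyrase_restart_threshold_bp)
        return row
    traj = fork_position_from_extension(trace, cal)
    stall = extract_stall_torque(trace, window=thr.stall_window_s, mech=mech, smooth_window=thr.smooth_window_s)
    row["stall_torque_pNnm"] = None if stall is None else stall.stall_torque
    if kind == "aot_constant_torque":
        t0 = trace.metadata.get("clamp_engage_time")
        if t0 is not None:
            sel = traj.time >= t0
            sub = type(traj)(traj.time[sel], traj.position[sel], traj.valid[sel], traj.source, traj.calibration)
            pauses = detect_pauses(sub, thr.smooth_window_s, thr.dwell_threshold_s_per_bp)
            est = estimate_velocities(sub, pauses, thr.velocity_window_s, thr.regression_cutoff_bp)
            row["v_with_pauses_bp_s"] = est.v_with_pauses
            row["v_pause_free_bp_s"] = est.v_pause_free if est.pause_free_defined else None
            row["n_pauses"] = len(pauses)
    if kind == "mt_restart":
        row["restarted"] = classify_mt_restart(trace, mech, min_sustain=thr.mt_restart_min_sustain_s)
    if kind == "aot_restart":
        row["restart_stall_torque_pNnm"] = restart_stall_torque(trace, window=thr.stall_window_s)
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, analyze, and summarize one ensemble; optionally write files.

    Returns a results bundle: the traces/logs, the per-trace result table,
    ensemble summaries, and the run log.  Deterministic under a fixed seed.
    """
    import pandas as pd

    mech = config.build_mechanics()
    motor = config.build_motor()
    protocol = config.build_protocol()
    thr = config.thresholds

    try:
        pairs = simulate_ensemble(protocol, motor, mech, config.n_traces, config.seed)
    except Exception as exc:
        raise ConfigError(f"simulate stage failed: {exc}") from exc

    cal = default_calibration(protocol.parental_length, protocol.force, mech)
    rows = []
    trajs = []
    try:
        for i, (trace, log) in enumerate(pairs):
            rows.append(_per_trace_row(i, trace, log, cal, mech, thr))
            if protocol.kind in ("aot_stall",):
                trajs.append(fork_position_from_extension(trace, cal))
    except Exception as exc:
        raise ConfigError(f"analyze stage failed: {exc}") from exc

    table = pd.DataFrame(rows)
    summary: dict = {"n_traces": config.n_traces}
    torques = [r["stall_torque_pNnm"] for r in rows if r.get("stall_torque_pNnm") is not None]
    if len(torques) >= 5:
        mu, sd, diag = fit_stall_histogram(torques)
        summary["stall_torque_fit_mean"] = mu
        summary["stall_torque_fit_sd"] = sd
        summary["stall_torque_fit_method"] = diag["method"]
    if trajs:
        curve = regression_curve(trajs, smooth_window=thr.smooth_window_s)
        if curve.time_grid[-1] >= 60.0:
            summary["regression_at_60s_bp"] = curve.regression_at(60.0)
    if "restarted" in table.columns:
        summary["restart_fraction"] = float(table["restarted"].mean())

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "protocol": protocol.kind,
        "condition": config.condition,
        "thresholds": asdict(thr),
    }
    bundle = {"table": table, "summary": summary, "run_log": run_log, "pairs": pairs}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (trace, log) in enumerate(pairs):
            write_trace(trace, out / f"trace_{i:04d}.tsv")
            write_event_log(log, out / f"events_{i:04d}.tsv")
        table.to_csv(out / "per_trace.tsv", sep="\t", index=False)
        (out / "run_log.yaml").write_text(
            yaml.safe_dump({**run_log, "summary": summary}, sort_keys=True), encoding="utf-8"
        )
    return bundle
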