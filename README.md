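# replitorque

Simulation and trace analysis of a DNA replisome working against torsion.

A replisome copying torsionally constrained DNA injects one (+) turn into the
parental duplex for every 10.5 bp it replicates.  Under a stretching force the
accumulating torque first twists the duplex, then — past a critical torque —
buckles it into a plectoneme whose growth shortens the tether.  This package
models that coupled system at the level a single-molecule instrument sees it:

- **`mechanics`** — quasi-static torsional mechanics of a stretched DNA
  tether: hat curve (extension vs. turns), (+) buckling at 12.6 pN·nm under
  1.0 pN, a melting-torque plateau under unwinding, and the invertible
  torque↔turns map used to calibrate measurements.
- **`motor`** — the T7 replisome as a stochastic torque-dependent rotary
  motor: a concave torque–velocity curve that vanishes at a per-trace
  Gaussian stall torque, Poisson pausing, fork regression while stalled, and
  loss of restart competence during prolonged stalls (protected by DNAP
  occupancy of the helicase C-terminal domain).
- **`simulate`** — couples motor to mechanics under five experimental
  schedules: angular-optical-trap torque clamp, AOT stall, AOT relaxation /
  restart, magnetic-tweezers restart (100-turn unwinding at 1.0 pN), and
  gyrase-assisted replication with periodic fork probing.
- **`analyze`** — the blind measurement pipeline: fork reconstruction from
  extension via the calibration curve, dwell-time pause detection (0.5 s
  smoothing, 0.1 s/bp threshold), pause-free velocities, stall-torque
  extraction (max torque within 60 s of stall onset), ensemble regression
  curves aligned at the maximum forward position.
- **`restart`** — restart classification for all three assays (AOT re-stall
  torque, magnetic-tweezers re-buckling, ≥ 2000 bp gyrase progression),
  grouped fractions with binomial errors, regression↔restart correlations.
- **`io` / `config` / `cli`** — TSV trace files with lossless metadata
  headers, YAML run configs with a versioned schema, and a `replitorque`
  command line (`simulate`, `analyze`, `restart`, `report`, `accept`).

## Worked example

Simulate one wild-type stall trace, then recover the stall torque blind —
without looking at the ground truth the simulator also returns:

```python
import replitorque as rt

protocol = rt.Protocol.for_kind("aot_stall")
motor = rt.motor_preset("WT")
trace, truth = rt.simulate_trace(protocol, motor, seed=7)

event = rt.extract_stall_torque(trace)
print(f"drawn stall torque : {truth.drawn_stall_torque:.2f} pN nm")
print(f"recovered          : {event.stall_torque:.2f} pN nm (onset t = {event.onset:.1f} s)")

cal = rt.default_calibration(protocol.parental_length, protocol.force)
traj = rt.fork_position_from_extension(trace, cal)
print(f"peak fork position : {max(traj.filled_position()):.0f} bp")
```

Output:

```
drawn stall torque : 21.91 pN nm
recovered          : 21.90 pN nm (onset t = 49.1 s)
peak fork position : 973 bp
```

The same flow is available from the shell:

```sh
replitorque simulate --protocol aot_stall --condition WT --n 19 --seed 1 --out runs/wt
replitorque analyze --traces runs/wt --out runs/wt/per_trace.tsv
```

## Documentation

`docs/methods.md` describes the model, every parameter with its rationale,
the generator's realism limits, and the numerical choices made in the
analysis pipeline.
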