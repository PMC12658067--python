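# Methods

This note records the model behind `replitorque`, the rationale for every
default parameter, the known limits of the trace generator's realism, and the
numerical choices made in the analysis pipeline.  All quantities the package
reports are computed from simulated ensembles at run time; nothing in this
document asserts an empirical number the code does not produce.

## 1. Model overview

A single torsionally constrained DNA tether of parental length `L` bp is held
at constant force `F` between a surface and a bead (angular optical trap, AOT,
or magnetic tweezers, MT).  A replisome loaded at one end replicates the
template; conservation of linking number injects one (+) turn into the
parental duplex per 10.5 bp replicated.  The instrument device (trap or
magnet) can add or remove turns at the other end, so the net excess turns are

```
n_net(t) = fork(t) / 10.5  +  n_device(t)
```

The tether responds quasi-statically: at every time step the torque and
extension are algebraic functions of `n_net` at fixed force (section 2).  The
motor's kinetics in turn depend on that torque (section 3).  This separation —
instantaneous mechanics, stochastic motor — is the standard approximation for
these experiments, valid because tether relaxation (ms) is fast compared with
replication (s).

## 2. Tether mechanics (`mechanics.py`)

Piecewise phenomenological "hat curve", the form labs fit to measured
extension-vs-turns data.  With `k = 2π·kBT·C/Lc` the twist stiffness
(`C` the twist persistence length, `Lc = 0.34 nm/bp · L` the contour length):

- **Torque:** linear `Γ = k·n` between the melting plateau and (+) buckling;
  clamped at the plateau `Γ_melt` for sufficiently negative turns; past the
  buckling turn count `n_b = Γ_b/k` it grows at the shallow plectoneme slope
  `s_Γ` per turn.  The buckling torque scales as `Γ_b(F) = 12.6 pN·nm · √(F/1 pN)`.
- **Extension:** Marko–Siggia worm-like-chain value at zero turns,
  `z0 = Lc(1 − ½√(kBT/(F·Lp)))`; a gentle quadratic shoulder before (+)
  buckling; linear collapse at `s_z` nm/turn past buckling; nearly flat under
  unwinding (the duplex melts instead of supercoiling at ~1 pN).  Clipped at
  zero.

The (+) descending branch is strictly monotone, so extension inverts uniquely
to turns there; `CalibrationCurve.turns_from_extension` does this by linear
interpolation on a 0.25-turn grid and flags out-of-range samples as NaN
rather than dropping them.

### Mechanics parameters

| Parameter | Default | Rationale |
|---|---|---|
| `bend_persistence_length` | 50 nm | Canonical dsDNA value; enters only the WLC extension. |
| `twist_persistence_length` | 100 nm | Effective C at ~1 pN; with a 5 kb template gives `k ≈ 0.43 pN·nm/turn`, so 22 pN·nm is reached at ≈ 51 excess turns — the second calibration anchor. |
| `rise_per_bp` | 0.34 nm | Canonical B-DNA rise. |
| `helical_pitch` | 10.5 bp/turn | B-DNA; the replication↔rotation gear ratio. |
| `buckling_torque_anchor` | 12.6 pN·nm | (+) buckling torque at 1.0 pN — the primary calibration anchor. |
| `buckling_force_exponent` | 0.5 | Mechanical buckling torque scales ≈ √F over this force range. |
| `plectoneme_torque_slope` | 0.22 pN·nm/turn | Shallow post-buckling torque growth; turns the buckled tether into a soft torque clamp. |
| `plectoneme_extension_slope` | −14 nm/turn | Tether shortening per plectonemic turn at ~1 pN. |
| `prebuckling_extension_curvature` | 0.4 nm/turn² | Rounds the (+) shoulder of the hat curve; small relative to z0. |
| `unwinding_extension_slope` | 0.5 nm/turn | Near-flat (−) branch: unwinding melts the duplex instead of shortening it. |
| `melting_torque_plateau` | −10 pN·nm | Torque at which dsDNA melts under unwinding. |
| `temperature` | 296.15 K | Room temperature. |

## 3. Motor kinetics (`motor.py`)

A five-mode state machine per replisome: `loading`, `active`, `paused`,
`stalled_regressing`, `inactive`, advanced in discrete time (`dt = 1/fs`).

- **Torque–velocity:** `v(Γ) = v0·(1 − r^shape)` with `r` the torque's
  fractional position between a floor torque and the per-trace stall torque,
  clipped to [0, 1].  Smooth, non-increasing, zero at stall.  `v0 = 8`
  turns/s and `shape = 1.2536` are jointly set so that the zero-torque rate
  is 8 turns/s and the rate against the 12.6 pN·nm clamp is 4 turns/s for a
  mean wild-type motor — the two reported rotation anchors.
- **Stall:** each trace draws its stall torque from `N(μ, σ²)` for its
  composition; when the tether torque comes within `stall_epsilon = 0.2`
  pN·nm of the draw the motor enters `stalled_regressing`.  Draws at or
  below the velocity floor are censored just above it (sub-percent
  probability for every preset) since such a motor could never build torque.
- **Pauses:** Poisson entry at 0.10 /s, exponential dwell with 2 s mean.
  Two-state kinetics give a paused time fraction λτ/(1+λτ) = 1/6, consistent
  with occasional multi-second pauses on otherwise steady traces.
- **Regression while stalled:** Poisson 1-bp reverse steps at
  `regression_rate_scale/60` bp/s.  Regression is driven by the stored (+)
  torsional stress, so it halts once the tether is torsionally relaxed
  (net turns = 0); the generator enforces that floor.
- **Inactivation:** during a stall, restart competence decays as a single
  exponential with rate `k(c) = k0·(1 − c/(c + K))` when the helicase CTD is
  present (DNAP occupancy of the CTD protects the fork), and `k0` flat
  otherwise.  `k0 = 0.004 /s` and `K = 20 nM` are set so a 240 s stall
  leaves ≈ 40 % restart at 1 nM DNAP and ≈ 85 % at 100 nM.

### Condition presets

| Preset | μ_stall (pN·nm) | σ_stall | v0 (turns/s) | regression rate (bp/min) | CTD |
|---|---|---|---|---|---|
| `WT` | 21.9 | 4.4 | 8 | 81.2 | yes |
| `dCt` | 19.4 | 3.0 | 8 | 249.1 | no |
| `dCt_exo` | 19.4 | 3.0 | 8 | 384.3 | no |
| `DNAP_only` | −1.5 | 2.4 | 4 | 0 | no |
| `helicase_only` | 1.2 | 5.0 | 4 | 0 | no |

Stall-torque statistics are the reported Gaussian fits per composition
(`dCt_exo` shares the `dCt` statistics; no separate distribution is
reported).  The single-enzyme conditions get `tv_floor_torque = −10 pN·nm`
(the melting plateau) because their stall torques sit near zero, and `v0 = 4`
turns/s since a lone enzyme is slower than the coupled replisome.

**Regression-rate calibration (censored observable).**  The reported
one-minute regression figures (80 / 240 / 340 bp for WT / ΔCt / ΔCt exo⁻)
are means of a *censored* quantity: a fork stops regressing once the stored
strain `S = (n_b + (Γ_s − Γ_b)/s_Γ)·10.5` bp is released, where `Γ_s` is
that trace's stall draw.  Setting the underlying Poisson rates equal to the
printed numbers would therefore bias the simulated observable low.  The
preset rates invert the expectation analytically: for `a = rate·60 s` and
Gaussian strain (induced by the Gaussian stall draw, mean μ_S, sd σ_S),
`E[min(a, S)] = a − σ_S(φ(d) + d·Φ(d))` with `d = (a − μ_S)/σ_S`; solving
`E[min(a, S)] = 80/240/340` gives 81.2 / 249.1 / 384.3 bp/min.  This is a
closed-form calibration of model parameters to target observables, done
before any seed was run — not a fit to simulation output.

## 4. Protocols and trace generation (`simulate.py`)

Five schedules, selected by `Protocol.for_kind`:

- `aot_clamp` — load, replicate into a torque clamp (default 12.6 pN·nm),
  observe 80 s.  Used for the torque–velocity table.
- `aot_stall` — unwind 40 turns at 10 turns/s, release the motor, let torque
  build until stall, record 90 s of stalling.
- `aot_restart` — as above, wait `stall_wait` s stalled, then the AOT unwinds
  (≤ 50 turns at 30 turns/s) until the torque falls to 6 pN·nm; a competent
  motor resumes and re-stalls.
- `mt_restart` — magnetic tweezers variant: after the stall wait, remove
  100 turns at 10 turns/s and watch 120 s for renewed replication
  (re-buckling).
- `gyrase_probe` — replication with gyrase relaxing (+) turns
  (Michaelis–Menten in gyrase concentration, `vmax = 15` turns/s,
  `Km = 5 nM`); every 18 s the magnet removes and re-adds 100 turns at
  30 turns/s to probe the fork position from the extension maximum.

Defaults shared by all kinds: `F = 1.0 pN`, `L = 5000 bp` parental template,
`fs = 100 Hz` sampling, Gaussian extension noise with `σ = 10 nm` (typical
bead-tracking noise at this force), exponential loading delay (5 s mean).
The fork is capped at the template length, and a hard `max_duration = 900 s`
bounds every phase-driven schedule.  Ensembles are generated from
`numpy.random.SeedSequence.spawn`, so traces are independent, reproducible,
and each records its own seed in the trace metadata.

### Generator realism limits

- Mechanics are quasi-static and piecewise-linear; there is no plectoneme
  nucleation hysteresis, no dynamic buckling noise, and torque is reported
  noise-free (extension carries the instrument noise).
- Force is held exactly constant; real magnetic tweezers have percent-level
  force calibration error.
- Regression proceeds by uniform 1-bp Poisson reverse steps; real fork
  regression is likely burst-like and sequence-dependent.
- Restart after relaxation is instantaneous for a competent motor; real
  re-initiation has its own dwell.
- Gyrase activity is a deterministic Michaelis–Menten rate, not stochastic
  enzyme turnover.
- Leading/lagging-strand asymmetry, Okazaki-fragment cycling, and protein
  exchange at the fork are not modeled; "DNAP concentration" enters only
  through the CTD-protection occupancy.

## 5. Analysis pipeline (`analyze.py`)

All analysis is blind: it consumes only `TraceRecord` channels (time,
extension, force, torque, device turns, metadata), never the simulation truth
log.

- **Fork reconstruction.** Extension is inverted through the calibration
  curve on the (+) descending branch; out-of-range samples are flagged
  invalid, and `filled_position()` interpolates across them.  A force
  mismatch between trace and calibration raises.
- **Pause detection (dwell-time method).**  Position is smoothed with a 0.5 s
  Gaussian, binned at 1 bp, and per-bp dwell times above 0.1 s/bp mark
  pauses.  Candidate segments shorter than the smoothing window (default
  `min_duration = smooth_window`) are discarded: features below the filter
  scale are unresolvable, and reflective-edge smoothing otherwise
  manufactures ~0.1 s artifacts at trace boundaries.
- **Velocities.**  Measured over the first 60 s (or 100 bp of net
  regression, whichever first) of post-loading replication; the pause-free
  velocity is the duration-weighted mean slope of the inter-pause segments,
  undefined (NaN, flagged) if the window is entirely paused.
- **Stall torque.**  The smoothed (0.5 s) torque's maximum over the trace;
  onset is the first time the smoothed torque enters within
  `plateau_margin = 0.5` pN·nm of that maximum (the "plateau" rule), which
  works for both strong motors (monotone ramp to plateau) and weak ones that
  never buckle.  An alternative `onset_rule="buckling"` timestamps the first
  crossing of the buckling torque, for strong motors only.  Traces whose
  torque never rises meaningfully return `None` rather than a spurious
  event.
- **Ensemble stall statistics.**  `fit_stall_histogram` reports the Gaussian
  maximum-likelihood estimates (sample mean, ddof=1 sd).  A binned-histogram
  least-squares Gaussian fit is also computed and stored as diagnostics
  (`binned_fit_mean/sd`) but deliberately not used as the estimate: at
  N ≈ 16–19 with Freedman–Diaconis bins, Monte Carlo (2000 trials) showed
  the binned fit has RMS error ≈ 3.5 pN·nm and misses a ±2 pN·nm tolerance
  36 % of the time, versus ≈ 1.0 pN·nm and 4 % for the MLE.  Fewer than 5
  samples raises.
- **Regression curves.**  Per-trace trajectories are aligned at their
  (smoothed) maximum forward position, converted to regression
  (max − position), averaged on a common grid with per-point SEM and counts.
- **Gyrase probe readout.**  Each probe window's fork estimate comes from
  the extension maximum inside the window (the torsionally relaxed instant),
  and the readout is timestamped at that maximum — not the window midpoint —
  since the fork advances ~80 bp/s and a fixed-offset timestamp would bias
  the position/time pairing by hundreds of bp.
- **Restart classification (`restart.py`).**  AOT: a second stall-torque
  plateau after the relaxation unwind.  MT: renewed extension collapse
  (re-buckling) after the 100-turn removal.  Gyrase: net progression beyond
  2000 bp.  Fractions carry Wald standard errors (Clopper–Pearson at the
  boundaries); correlations use Pearson's r with n ≥ 3 and non-degenerate
  variance enforced.

## 6. Numerical choices

| Choice | Value | Reason |
|---|---|---|
| Time step | 1/fs = 10 ms | Resolves all kinetics (fastest rate ≈ 8 turns/s ≈ 84 bp/s → 0.84 bp/step); halving it changes no reported statistic beyond sampling noise. |
| `stall_epsilon` | 0.2 pN·nm | Discrete-time stall trigger; without it the torque could step past the exact draw. |
| Calibration grid | 0.25 turns | ≈ 2.6 bp resolution, well below measurement noise. |
| Pause smoothing | 0.5 s Gaussian | Suppresses 10 nm extension noise (~1 bp at 100 Hz after smoothing) while preserving multi-second pauses. |
| `min_duration` | = smoothing window | See pause detection above. |
| Probe smoothing | 0.2 s | Shorter than the analysis smoothing because the probe extension peak is a sharp feature. |
| Seeds | `SeedSequence.spawn` | Statistically independent streams; each trace records `repr((entropy, spawn_key))` in its metadata. |

## 7. Design choices on open modeling questions

- **Static vs. refit calibration:** the analysis uses the model hat curve as
  a static calibration (as a lab would calibrate once per tether) rather
  than refitting per trace; per-trace refits at this noise level add
  variance without removing bias.
- **Constant force:** protocols hold force fixed; force ramps are outside
  scope.
- **Pause threshold direction:** thresholding is done on dwell time (s/bp),
  not velocity, because dwell time is well defined across the stalled limit
  (infinite dwell) where velocity-based thresholds degenerate.
- **Turns vs. base pairs:** the motor state tracks base pairs and converts
  to turns via the pitch; all mechanics operate in turns.  This keeps the
  1-bp regression step and the 10.5 bp/turn gear ratio exact.

## 8. Limitations

Beyond the generator realism limits above: the stall-torque MLE assumes
Gaussian draws (true by construction here; a real dataset would warrant a
normality check); the restart classifiers are threshold rules tuned to the
protocols' geometry, not general-purpose change-point detectors; and the
censored-mean regression calibration assumes the strain distribution induced
by the Gaussian stall draw, so changing the stall statistics without
re-deriving the rates would break the correspondence.
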