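"""Quasi-static torsional mechanics of a stretched, torsionally constrained DNA tether.

The tether is modeled phenomenologically, the way single-molecule labs use a
measured "hat curve": a melting plateau under unwinding, a linear twist regime
around zero turns, and a plectonemic regime past the (+) buckling transition.
Torque and extension are functions of the net excess turns stored in the
parental duplex at fixed force.  The free parameters are calibrated to two
experimental anchors: (+) buckling at 12.6 pN·nm under 1.0 pN of force, and
~51 excess turns stored when the torque reaches 22 pN·nm on a ~5 kb parental
template.

Sign convention: positive turns overwind the duplex ((+) supercoiling) and
positive torque resists further overwinding by the replisome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import io as _io

import numpy as np

__all__ = [
    "KB",
    "MechanicsParams",
    "CalibrationCurve",
    "buckling_torque",
    "torque_of_turns",
    "extension_of_turns",
    "turns_of_torque",
    "max_torque",
    "zero_turn_extension",
    "buckling_turns",
    "twist_torque_slope",
    "make_calibration_curve",
]

#: Boltzmann constant in pN·nm/K.
KB = 0.0138064852


class MechanicsError(ValueError):
    """Invalid input or out-of-range request to the mechanics model."""


@dataclass(frozen=True)
class MechanicsParams:
    """Parameters of the torsional-mechanical tether model.

    Attributes
    ----------
    bend_persistence_length:
        Bending persistence length of dsDNA (nm).
    twist_persistence_length:
        Effective twist persistence length (nm); sets the pre-buckling
        torsional stiffness of the parental duplex.
    rise_per_bp:
        Helical rise (nm/bp).
    helical_pitch:
        Base pairs per helical turn; the replisome injects one (+) turn per
        this many bp replicated.
    buckling_torque_anchor:
        Critical (+) buckling torque at the anchor force of 1.0 pN (pN·nm).
    buckling_force_exponent:
        Buckling torque scales as ``force**exponent`` through the anchor.
    plectoneme_torque_slope:
        Post-buckling torque growth (pN·nm per excess turn).
    plectoneme_extension_slope:
        Post-buckling extension change (nm per excess turn; negative).
    prebuckling_extension_curvature:
        Quadratic extension decrease before buckling (nm/turn^2); gives the
        hat curve its rounded (+) shoulder.
    unwinding_extension_slope:
        Small linear extension loss per (−) turn (nm/turn); the curve is
        nearly flat under unwinding because the duplex melts.
    melting_torque_plateau:
        Torque plateau under unwinding (pN·nm, negative).
    temperature:
        Temperature (K).
    """

    bend_persistence_length: float = 50.0
    twist_persistence_length: float = 100.0
    rise_per_bp: float = 0.34
    helical_pitch: float = 10.5
    buckling_torque_anchor: float = 12.6
    buckling_force_exponent: float = 0.5
    plectoneme_torque_slope: float = 0.22
    plectoneme_extension_slope: float = -14.0
    prebuckling_extension_curvature: float = 0.4
    unwinding_extension_slope: float = 0.5
    melting_torque_plateau: float = -10.0
    temperature: float = 296.15

    def __post_init__(self) -> None:
        if self.helical_pitch <= 0:
            raise MechanicsError("helical_pitch must be positive")
        if self.plectoneme_extension_slope >= 0:
            raise MechanicsError("plectoneme_extension_slope must be negative")
        if self.melting_torque_plateau >= 0:
            raise MechanicsError("melting_torque_plateau must be negative")
        if self.rise_per_bp <= 0 or self.temperature <= 0:
            raise MechanicsError("rise_per_bp and temperature must be positive")

    @property
    def kbt(self) -> float:
        """Thermal energy kBT in pN·nm."""
        return KB * self.temperature

    def contour_length(self, length_bp: float) -> float:
        """Contour length (nm) of ``length_bp`` base pairs of duplex."""
        if length_bp <= 0:
            raise MechanicsError("parental length must be positive")
        return length_bp * self.rise_per_bp

    def with_overrides(self, **kwargs) -> "MechanicsParams":
        return replace(self, **kwargs)


def _check_force(force: float) -> None:
    if not np.isfinite(force) or force <= 0:
        raise MechanicsError(f"force must be positive and finite, got {force!r}")


def buckling_torque(force: float, params: MechanicsParams | None = None) -> float:
    """Critical torque (pN·nm) at which (+) plectoneme formation begins.

    Scales as ``force**buckling_force_exponent`` through the 1.0 pN anchor,
    so with default parameters ``buckling_torque(1.0) == 12.6`` exactly.
    """
    params = params or MechanicsParams()
    _check_force(force)
    return params.buckling_torque_anchor * force**params.buckling_force_exponent


def twist_torque_slope(parental_length: float, params: MechanicsParams | None = None) -> float:
    """Pre-buckling torque per excess turn (pN·nm/turn): 2π·kBT·C / Lc."""
    params = params or MechanicsParams()
    lc = params.contour_length(parental_length)
    return 2.0 * np.pi * params.kbt * params.twist_persistence_length / lc


def buckling_turns(parental_length: float, force: float, params: MechanicsParams | None = None) -> float:
    """Excess turns at the (+) buckling transition."""
    params = params or MechanicsParams()
    return buckling_torque(force, params) / twist_torque_slope(parental_length, params)


def zero_turn_extension(parental_length: float, force: float, params: MechanicsParams | None = None) -> float:
    """Worm-like-chain extension (nm) of the torsionally relaxed tether.

    Marko–Siggia high-force interpolation: z = Lc (1 − 0.5·sqrt(kBT/(F·Lp))).
    """
    params = params or MechanicsParams()
    _check_force(force)
    lc = params.contour_length(parental_length)
    factor = 1.0 - 0.5 * np.sqrt(params.kbt / (force * params.bend_persistence_length))
    return lc * max(factor, 0.0)


def extension_per_bp(force: float, params: MechanicsParams | None = None) -> float:
    """Extension contributed per bp of relaxed duplex at this force (nm/bp)."""
    params = params or MechanicsParams()
    return zero_turn_extension(1.0, force, params)


def torque_of_turns(
    turns,
    parental_length: float,
    force: float,
    params: MechanicsParams | None = None,
):
    """Torque (pN·nm) stored in the tether at a given number of excess turns.

    Piecewise response: clamped at the melting plateau for sufficiently
    negative turns, linear (slope ∝ 1/parental length) between melting and
    (+) buckling, then growing with ``plectoneme_torque_slope`` per turn.
    Accepts scalars or arrays.
    """
    params = params or MechanicsParams()
    _check_force(force)
    k = twist_torque_slope(parental_length, params)
    n_b = buckling_torque(force, params) / k
    g_b = buckling_torque(force, params)
    turns = np.asarray(turns, dtype=float)
    linear = k * turns
    plect = g_b + params.plectoneme_torque_slope * (turns - n_b)
    out = np.where(turns > n_b, plect, np.maximum(linear, params.melting_torque_plateau))
    if out.ndim == 0:
        return float(out)
    return out


def extension_of_turns(
    turns,
    parental_length: float,
    force: float,
    params: MechanicsParams | None = None,
):
    """Tether extension (nm) versus excess turns at fixed force (the hat curve).

    Maximum at zero turns; nearly flat under unwinding (melting); a gentle
    quadratic shoulder before (+) buckling; linear collapse with
    ``plectoneme_extension_slope`` past buckling.  Clipped at zero (bead on
    the surface).  Accepts scalars or arrays.
    """
    params = params or MechanicsParams()
    z0 = zero_turn_extension(parental_length, force, params)
    n_b = buckling_turns(parental_length, force, params)
    a = params.prebuckling_extension_curvature
    turns = np.asarray(turns, dtype=float)
    z_shoulder = z0 - a * n_b**2
    pos_pre = z0 - a * turns**2
    pos_post = z_shoulder + params.plectoneme_extension_slope * (turns - n_b)
    neg = z0 - params.unwinding_extension_slope * np.abs(turns)
    out = np.where(turns < 0, neg, np.where(turns <= n_b, pos_pre, pos_post))
    out = np.clip(out, 0.0, None)
    if out.ndim == 0:
        return float(out)
    return out


def max_torque(parental_length: float, force: float, params: MechanicsParams | None = None) -> float:
    """Largest torque representable before the model extension reaches zero."""
    params = params or MechanicsParams()
    n_b = buckling_turns(parental_length, force, params)
    z_shoulder = zero_turn_extension(parental_length, force, params) - (
        params.prebuckling_extension_curvature * n_b**2
    )
    n_zero = n_b + z_shoulder / abs(params.plectoneme_extension_slope)
    return buckling_torque(force, params) + params.plectoneme_torque_slope * (n_zero - n_b)


def turns_of_torque(
    torque: float,
    parental_length: float,
    force: float,
    params: MechanicsParams | None = None,
) -> float:
    """Invert :func:`torque_of_turns` on the (+) branch.

    Raises
    ------
    MechanicsError
        If the requested torque lies below the melting plateau or above the
        model maximum at this force.
    """
    params = params or MechanicsParams()
    _check_force(force)
    if not np.isfinite(torque):
        raise MechanicsError("torque must be finite")
    if torque < params.melting_torque_plateau:
        raise MechanicsError(
            f"torque {torque} pN·nm below the melting plateau "
            f"({params.melting_torque_plateau} pN·nm)"
        )
    g_max = max_torque(parental_length, force, params)
    if torque > g_max:
        raise MechanicsError(
            f"torque {torque} pN·nm above the model maximum ({g_max:.2f} pN·nm)"
        )
    k = twist_torque_slope(parental_length, params)
    g_b = buckling_torque(force, params)
    if torque <= g_b:
        return float(torque / k)
    return float(g_b / k + (torque - g_b) / params.plectoneme_torque_slope)


@dataclass
class CalibrationCurve:
    """Tabulated extension/torque versus applied turns at fixed force.

    Used to convert a measured extension back to the number of excess turns
    (and hence, via the helical pitch, to base pairs replicated).  Only the
    descending (+)-supercoiled branch is invertible.
    """

    force: float
    parental_length: float
    turn_grid: np.ndarray
    extension_values: np.ndarray
    torque_values: np.ndarray
    params: MechanicsParams = field(default_factory=MechanicsParams)

    def __post_init__(self) -> None:
        self.turn_grid = np.asarray(self.turn_grid, dtype=float)
        self.extension_values = np.asarray(self.extension_values, dtype=float)
        self.torque_values = np.asarray(self.torque_values, dtype=float)
        if self.turn_grid.ndim != 1 or np.any(np.diff(self.turn_grid) <= 0):
            raise MechanicsError("turn grid must be 1-D and strictly increasing")
        if not (len(self.turn_grid) == len(self.extension_values) == len(self.torque_values)):
            raise MechanicsError("calibration columns must have equal length")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.extension_values))

    def turns_from_extension(self, extension):
        """Invert extension to turns on the (+) descending branch.

        Samples outside the tabulated extension range come back as NaN
        (flagged, not a hard failure).
        """
        i0 = self.peak_index
        branch_turns = self.turn_grid[i0:]
        branch_ext = self.extension_values[i0:]
        # np.interp needs ascending x; the branch extension is descending.
        ext = np.asarray(extension, dtype=float)
        lo, hi = branch_ext[-1], branch_ext[0]
        out = np.interp(ext, branch_ext[::-1], branch_turns[::-1])
        out = np.where((ext < lo) | (ext > hi), np.nan, out)
        if out.ndim == 0:
            return float(out)
        return out

    def to_table(self) -> str:
        """3-column delimited table (turns, extension_nm, torque_pNnm)."""
        buf = _io.StringIO()
        buf.write("turns\textension_nm\ttorque_pNnm\n")
        for n, z, g in zip(self.turn_grid, self.extension_values, self.torque_values):
            buf.write(f"{n:.6g}\t{z:.6g}\t{g:.6g}\n")
        return buf.getvalue()


def make_calibration_curve(
    parental_length: float,
    force: float,
    turn_grid,
    params: MechanicsParams | None = None,
) -> CalibrationCurve:
    """Tabulate the hat curve and torque response over ``turn_grid``."""
    params = params or MechanicsParams()
    grid = np.asarray(turn_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise MechanicsError("turn_grid must be 1-D, strictly increasing, length >= 2")
    return CalibrationCurve(
        force=force,
        parental_length=parental_length,
        turn_grid=grid,
        extension_values=extension_of_turns(grid, parental_length, force, params),
        torque_values=torque_of_turns(grid, parental_length, force, params),
        params=params,
    )


def default_calibration(
    parental_length: float = 5000.0,
    force: float = 1.0,
    params: MechanicsParams | None = None,
    max_turns: float | None = None,
) -> CalibrationCurve:
    """Calibration curve spanning melting to extension collapse at 0.25-turn steps."""
    params = params or MechanicsParams()
    if max_turns is None:
        n_b = buckling_turns(parental_length, force, params)
        z_sh = zero_turn_extension(parental_length, force, params) - (
            params.prebuckling_extension_curvature * n_b**2
        )
        max_turns = n_b + z_sh / abs(params.plectoneme_extension_slope)
    grid = np.arange(-60.0, float(max_turns) + 0.25, 0.25)
    return make_calibration_curve(parental_length, force, grid, params)
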