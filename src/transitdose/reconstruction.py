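"""Dose reconstruction from EPID transit signals.

Three levels of reconstruction are provided, all built on the calibrated
correlation function F(w) and scatter factor f(d, r):

* :func:`midpoint_dose` — dose at the midpoint P of the chord traversed by
  the beam central axis,
  ``Dm = S't * f(d, r) / F(w) * ((SAD + d)/SAD)^2``;
* :func:`offaxis_dose` — dose on an off-axis fan line when the chord
  midpoint sits at the isocenter, ``D = Sto / F(wo)``;
* :func:`profile_dose` — the full dose profile along the lateral segment
  through the central-axis chord midpoint (apex to lung), via the
  per-fan-line reconstruction factor C of :func:`fanline_c_factor`:

  ``C = f(d,r)/F(w') * ((SAD+d1)/SAD)^2 * ((SAD+d1)/(SAD+d1+d2))^2
  * exp(-mu_en/rho * w2')``

  where d1 locates the half-radiological-thickness point P' of the chord,
  d2 is the signed P'-to-P0 leg and w2' its radiological thickness.  On
  the central axis (d1 = d, d2 = 0) C degenerates to the midpoint formula.

Points within a configurable margin (default 1 cm) of a density interface
are flagged and excluded from dose reporting: lateral electronic
equilibrium does not hold there and the homogeneous-phantom calibration is
unreliable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    CorrelationModel,
    ScatterModel,
    correlation_eval,
    scatter_eval,
)
from .geometry import (
    BeamGeometry,
    ChordGeometry,
    FanLine,
    PhantomSlice,
    apex_sagitta,
    chord_through,
    inverse_square,
    sagitta_radius,
)

__all__ = [
    "PhysicsConstants",
    "TransitProfile",
    "DoseProfile",
    "midpoint_dose",
    "offaxis_dose",
    "attenuation_factor",
    "fanline_c_factor",
    "profile_dose",
    "exclude_interfaces",
]

#: interface-detection step in relative density between adjacent samples
INTERFACE_DENSITY_STEP = 0.2


@dataclass(frozen=True)
class PhysicsConstants:
    """Beam-quality constants for the exponential attenuation leg.

    ``mu_en_over_rho`` is the water mass energy-absorption coefficient
    [cm^2/g] at the beam's mean photon energy (1.7 MeV for a 6 MV beam).
    """

    mu_en_over_rho: float = 2.73e-2

    def __post_init__(self) -> None:
        if self.mu_en_over_rho <= 0:
            raise ValueError("mu_en_over_rho must be positive")


@dataclass
class TransitProfile:
    """Transit signals sampled on fan lines, indexed by their
    isocenter-plane lateral position [cm].

    ``signals`` may contain NaN where a sample is missing (e.g. shifted
    out of support by alignment resampling).
    """

    positions: np.ndarray  # cm at the isocenter plane, strictly increasing
    signals: np.ndarray  # CU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.positions.shape != self.signals.shape:
            raise ValueError("positions and signals must have the same shape")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        valid = self.signals[np.isfinite(self.signals)]
        if np.any(valid < 0):
            raise ValueError("signals must be non-negative")

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(self.positions)))

    def copy(self) -> "TransitProfile":
        return TransitProfile(
            self.positions.copy(), self.signals.copy(), dict(self.meta)
        )


@dataclass
class DoseProfile:
    """Reconstructed dose along the apex-to-lung segment.

    ``excluded`` flags points not usable for QA, with a reason string in
    ``exclusion_reason`` ('' where valid).
    """

    positions: np.ndarray  # cm along the reconstruction segment
    dose: np.ndarray  # Gy (NaN where excluded for out-of-body)
    c_factor: np.ndarray  # Gy/CU
    excluded: np.ndarray  # bool
    exclusion_reason: np.ndarray  # str
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return ~self.excluded


def midpoint_dose(
    st_prime: float,
    w: float,
    d: float,
    r: float,
    calib: tuple[CorrelationModel, ScatterModel],
    sad: float = 100.0,
) -> float:
    """Dose [Gy] at the central-axis chord midpoint P.

    Parameters
    ----------
    st_prime : float
        Transit signal [CU] read at the midpoint projection on the EPID.
    w : float
        Chord thickness [cm] crossed by the central axis.
    d : float
        Signed midpoint offset from the isocenter [cm] (positive away
        from the source).
    r : float
        Equivalent cylinder radius [cm] for the scatter factor.
    calib : (CorrelationModel, ScatterModel)
    sad : float
        Source-to-axis distance [cm].
    """
    corr, scat = calib
    f_w = correlation_eval(corr, w)
    if f_w <= 0:
        raise ValueError(f"F(w)={f_w:g} is non-positive at w={w:g} cm")
    return st_prime * scatter_eval(scat, d, r) / f_w * inverse_square(sad, d)


def offaxis_dose(
    sto: float, wo: float, calib: tuple[CorrelationModel, ScatterModel]
) -> float:
    """Dose [Gy] on an off-axis fan line with the chord midpoint at the
    isocenter: ``Sto / F(wo)`` (the midpoint formula with d=0, f=1)."""
    corr, _ = calib
    f_w = correlation_eval(corr, wo)
    if f_w <= 0:
        raise ValueError(f"F(w)={f_w:g} is non-positive at wo={wo:g} cm")
    return sto / f_w


def attenuation_factor(w2_signed: float, constants: PhysicsConstants) -> float:
    """exp(-mu_en/rho * w2') for the signed radiological leg P' -> P0."""
    return math.exp(-constants.mu_en_over_rho * w2_signed)


def fanline_c_factor(
    chord: ChordGeometry,
    calib: tuple[CorrelationModel, ScatterModel],
    constants: PhysicsConstants,
    beam: BeamGeometry,
) -> float:
    """Dose-reconstruction factor C [Gy/CU] for one fan line.

    ``chord.d`` and ``chord.r`` must carry the central-axis chord's offset
    and equivalent radius (the scatter factor is assumed constant along
    the reconstruction segment).
    """
    if chord.w_prime <= 0:
        raise ValueError("chord has non-positive radiological thickness")
    sad = beam.sad
    if sad + chord.d1 + chord.d2 <= 0:
        raise ValueError(
            f"degenerate fan-line geometry: SAD+d1+d2 = "
            f"{sad + chord.d1 + chord.d2:g} <= 0"
        )
    corr, scat = calib
    f_w = correlation_eval(corr, chord.w_prime)
    if f_w <= 0:
        raise ValueError(
            f"F(w')={f_w:g} is non-positive at w'={chord.w_prime:g} cm"
        )
    f = scatter_eval(scat, chord.d, chord.r)
    return (
        f / f_w
        * inverse_square(sad, chord.d1)
        * ((sad + chord.d1) / (sad + chord.d1 + chord.d2)) ** 2
        * attenuation_factor(chord.w2_prime, constants)
    )


def central_axis_chord(
    slice_: PhantomSlice,
    beam: BeamGeometry,
    calib: tuple[CorrelationModel, ScatterModel] | None = None,
    apex_direction: float = -1.0,
) -> ChordGeometry:
    """Chord traversed by the beam central axis, with the equivalent
    cylinder radius derived from the apex sagitta.

    Flat or unresolvable contours fall back to the largest calibrated
    radius (with a warning).
    """
    fan = FanLine.from_iso(0.0, beam)
    chord = chord_through(slice_, fan, beam)
    if not chord.inside:
        return chord
    p_mid = fan.point_at(beam.sad + chord.d, beam)
    cp = apex_sagitta(slice_, p_mid, apex_direction=apex_direction)
    fallback_r = max(calib[1].radii) if calib is not None else 14.5
    if not np.isfinite(cp) or cp <= 0:
        warnings.warn(
            "could not resolve the apex sagitta; falling back to the "
            f"largest calibrated radius r={fallback_r:g} cm",
            UserWarning,
            stacklevel=2,
        )
        chord.r = fallback_r
    else:
        chord.cp = cp
        chord.r = sagitta_radius(chord.w, cp)
    return chord


def exclude_interfaces(
    slice_: PhantomSlice,
    points: np.ndarray,
    margin: float = 1.0,
    step: float | None = None,
) -> np.ndarray:
    """Boolean mask over ``points`` (N, 2) on a line segment: True within
    ``margin`` cm of a density interface.

    Interfaces are adjacent-sample density steps exceeding
    ``INTERFACE_DENSITY_STEP`` (0.2 relative-density units) when the
    segment is resampled at ``step`` (default: the grid spacing).
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        return np.zeros(len(pts), dtype=bool)
    if step is None:
        step = slice_.spacing
    p0, p1 = pts[0], pts[-1]
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(np.ceil(length / step)) + 1)
    s = np.linspace(0.0, length, n)
    line = p0 + np.outer(s / length, p1 - p0)
    rho = slice_.density_at(line)
    jumps = np.abs(np.diff(rho)) > INTERFACE_DENSITY_STEP
    if not np.any(jumps):
        return np.zeros(len(pts), dtype=bool)
    # collapse runs of flagged steps into single interface positions
    idx = np.nonzero(jumps)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    groups = np.split(idx, breaks + 1)
    interfaces = np.array([(s[g[0]] + s[g[-1] + 1]) / 2.0 for g in groups])
    s_pts = np.linalg.norm(pts - p0, axis=1)
    dist = np.min(np.abs(s_pts[:, None] - interfaces[None, :]), axis=1)
    if margin == 0:
        return dist <= step / 2.0
    return dist < margin


def profile_dose(
    profile: TransitProfile,
    slice_: PhantomSlice,
    beam: BeamGeometry,
    calib: tuple[CorrelationModel, ScatterModel],
    constants: PhysicsConstants = PhysicsConstants(),
    exclusion_margin: float = 1.0,
    apex_direction: float = -1.0,
) -> DoseProfile:
    """Reconstruct the dose profile along the lateral segment through the
    central-axis chord midpoint P.

    For every transit sample the fan line through its isocenter-plane
    position is traced through the slice; the target point P0 is the
    intersection of that fan line with the horizontal segment ``y = d``
    (through P); ``D = Sto * C``.  The scatter factor uses the
    central-axis chord's ``d`` and equivalent radius throughout.

    Points are excluded (flag + reason, dose NaN for out-of-body) when the
    fan line misses the body, P0 falls outside the body, the sample is
    missing, or P0 lies within ``exclusion_margin`` cm of a density
    interface.
    """
    axis = central_axis_chord(slice_, beam, calib, apex_direction)
    n = len(profile.positions)
    dose = np.full(n, np.nan)
    c_fac = np.full(n, np.nan)
    excluded = np.ones(n, dtype=bool)
    reason = np.array(["out-of-body"] * n, dtype=object)
    if not axis.inside:
        return DoseProfile(
            positions=profile.positions.copy(), dose=dose, c_factor=c_fac,
            excluded=excluded, exclusion_reason=reason,
            meta={"diagnostic": "central axis does not intersect the body"},
        )
    y_cd = axis.d  # the reconstruction segment: y = d through P

    p0_pts = np.empty((n, 2))
    for i, x_iso in enumerate(profile.positions):
        fan = FanLine.from_iso(float(x_iso), beam)
        dir_y = fan.direction(beam)[1]
        t_p0 = (y_cd + beam.sad) / dir_y
        p0_pts[i] = fan.point_at(t_p0, beam)

        chord = chord_through(slice_, fan, beam, target_y=y_cd)
        if not chord.inside:
            continue
        # P0 must itself lie inside the body
        if slice_.density_at(p0_pts[i][None, :])[0] <= slice_.body_threshold:
            continue
        chord.d = axis.d
        chord.r = axis.r
        c = fanline_c_factor(chord, calib, constants, beam)
        c_fac[i] = c
        if np.isfinite(profile.signals[i]):
            dose[i] = profile.signals[i] * c
            excluded[i] = False
            reason[i] = ""
        else:
            reason[i] = "missing-signal"

    near_iface = exclude_interfaces(slice_, p0_pts, margin=exclusion_margin)
    newly = near_iface & ~excluded
    excluded |= near_iface
    reason[newly] = "interface"

    return DoseProfile(
        positions=p0_pts[:, 0],
        dose=dose,
        c_factor=c_fac,
        excluded=excluded,
        exclusion_reason=reason,
        meta={
            "axis_w": axis.w, "axis_w_prime": axis.w_prime,
            "axis_d": axis.d, "axis_r": axis.r,
            "exclusion_margin_cm": exclusion_margin,
        },
    )
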