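"""Rays, chords and radiological path lengths in a 2D slice model.

The model lives in the CT slice containing the isocenter.  Coordinates are
continuous centimetres with the isocenter at the origin:

* ``x`` — lateral coordinate, along the dose-reconstruction segment
  (breast apex toward negative ``x`` by convention);
* ``y`` — depth along the beam central axis, increasing *away* from the
  source, which sits at ``(0, -SAD)``.

A *fan line* is the ray from the source through a lateral position on the
EPID plane (at ``y = SED - SAD``); the same ray crosses the isocenter
plane (``y = 0``) at ``epid_coord * SAD / SED``.  Off-axis geometry is
always expressed as signed distances measured from the source along the
fan line, relative to the SAD: a point at source distance ``t`` has signed
offset ``t - SAD`` (positive when farther from the source than the
isocenter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "BeamGeometry",
    "PhantomSlice",
    "ChordGeometry",
    "FanLine",
    "sagitta_radius",
    "radiological_path",
    "chord_through",
    "project_iso_to_epid",
    "project_epid_to_iso",
    "inverse_square",
    "sterling_equivalent_square",
]

ALLOWED_WEDGES = (0.0, 15.0, 30.0)


@dataclass(frozen=True)
class BeamGeometry:
    """Treatment-beam geometry for a lateral (tangential) irradiation.

    Parameters
    ----------
    sad : float
        Source-to-axis distance [cm].
    sed : float
        Source-to-EPID distance [cm]; must exceed ``sad``.
    field_length : float
        Field extent along the phantom/patient axis [cm].
    field_width : float
        Field extent across the beam in the slice plane [cm].
    wedge_angle : float
        Hard-wedge angle in degrees; one of 0, 15, 30.
    gantry : float
        Gantry angle in degrees (90 for the lateral phantom setup).
    """

    sad: float = 100.0
    sed: float = 150.0
    field_length: float = 20.0
    field_width: float = 20.0
    wedge_angle: float = 0.0
    gantry: float = 90.0

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ValueError(f"sad must be positive, got {self.sad}")
        if self.sed <= self.sad:
            raise ValueError(f"sed ({self.sed}) must exceed sad ({self.sad})")
        if self.wedge_angle not in ALLOWED_WEDGES:
            raise ValueError(
                f"wedge_angle must be one of {ALLOWED_WEDGES}, got {self.wedge_angle}"
            )

    @property
    def source(self) -> np.ndarray:
        """Source position in slice coordinates [cm]."""
        return np.array([0.0, -self.sad])

    @property
    def magnification(self) -> float:
        """Isocenter-plane to EPID-plane scale factor, SED/SAD."""
        return self.sed / self.sad


@dataclass
class PhantomSlice:
    """A 2D relative-electron-density map (water = 1.0) on a uniform grid.

    ``grid[i, j]`` is the density at the cell centre
    ``(origin[0] + j * spacing, origin[1] + i * spacing)`` — axis 0 is the
    depth ``y``, axis 1 the lateral ``x``.
    """

    grid: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    body_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be a 2D array")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.any(self.grid < 0):
            raise ValueError("densities must be non-negative")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the cell-centre bounding box [cm]."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        return (x0, x0 + (nx - 1) * self.spacing, y0, y0 + (ny - 1) * self.spacing)

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinearly interpolated density at ``points`` of shape (N, 2) [cm].

        Points outside the grid read zero (air).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0 = self.origin
        rows = (pts[:, 1] - y0) / self.spacing
        cols = (pts[:, 0] - x0) / self.spacing
        return map_coordinates(
            self.grid, np.vstack([rows, cols]), order=1, mode="constant", cval=0.0
        )


@dataclass(frozen=True)
class FanLine:
    """A ray from the source through matched EPID / isocenter-plane positions."""

    source: tuple[float, float]
    epid_coord: float
    iso_coord: float

    @classmethod
    def from_iso(cls, iso_coord: float, beam: BeamGeometry) -> "FanLine":
        return cls(
            source=tuple(beam.source),
            epid_coord=project_iso_to_epid(iso_coord, beam),
            iso_coord=float(iso_coord),
        )

    @classmethod
    def from_epid(cls, epid_coord: float, beam: BeamGeometry) -> "FanLine":
        return cls(
            source=tuple(beam.source),
            epid_coord=float(epid_coord),
            iso_coord=project_epid_to_iso(epid_coord, beam),
        )

    def direction(self, beam: BeamGeometry) -> np.ndarray:
        """Unit vector from the source toward the EPID."""
        d = np.array([self.iso_coord, 0.0]) - beam.source
        return d / np.linalg.norm(d)

    def point_at(self, t: float | np.ndarray, beam: BeamGeometry) -> np.ndarray:
        """Point(s) at source distance ``t`` [cm] along the ray."""
        t = np.asarray(t, dtype=float)
        return beam.source + np.multiply.outer(t, self.direction(beam))


@dataclass
class ChordGeometry:
    """Geometry of one fan line's traversal of the body.

    All offsets are signed source distances relative to the SAD
    (positive = farther from the source).  ``d`` and ``r`` describe the
    *central-axis* chord (they parameterise the scatter factor f(d, r));
    ``d1``, ``d2`` and ``w2_prime`` are specific to this fan line and a
    target point P0 on the reconstruction segment.
    """

    w: float
    w_prime: float
    d: float = 0.0
    d1: float = 0.0
    d2: float = 0.0
    w2_prime: float = 0.0
    cp: float = float("nan")
    r: float = float("nan")
    inside: bool = True

    @classmethod
    def outside_field(cls) -> "ChordGeometry":
        """Marker for a fan line that never crosses the body contour."""
        return cls(w=0.0, w_prime=0.0, inside=False)


def sagitta_radius(w: float, cp: float) -> float:
    """Equivalent-cylinder radius from a chord and its sagitta.

    A circle through the two chord endpoints and the apex at perpendicular
    distance ``cp`` from the chord midpoint has radius
    ``r = (w^2 + 4 cp^2) / (8 cp)``.

    Parameters
    ----------
    w : float
        Chord length [cm], > 0.
    cp : float
        Sagitta (apex-to-chord-midpoint distance) [cm], > 0.
    """
    if w <= 0 or cp <= 0:
        raise ValueError(f"w and cp must be positive, got w={w}, cp={cp}")
    return (w * w + 4.0 * cp * cp) / (8.0 * cp)


def radiological_path(
    slice_: PhantomSlice,
    p0: np.ndarray,
    p1: np.ndarray,
    step: float | None = None,
) -> float:
    """Water-equivalent length of the segment ``p0 -> p1`` [cm].

    Midpoint-rule line integral of relative electron density sampled every
    ``step`` cm (default half the grid spacing).  Zero for a degenerate
    segment or one fully in air.
    """
    if step is None:
        step = slice_.spacing / 2.0
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0.0:
        return 0.0
    n = max(1, int(np.ceil(length / step)))
    h = length / n
    mids = p0 + np.outer((np.arange(n) + 0.5) * h / length, p1 - p0)
    return float(np.sum(slice_.density_at(mids)) * h)


def _refine_contour(
    t: np.ndarray,
    rho: np.ndarray,
    t_cross: float,
    window: float,
    threshold: float,
) -> float:
    """Relocate a contour crossing to the half-rise of the local density
    step.

    Thresholds near zero sit at the foot of the one-cell interpolation
    ramp of a discretised contour and bias the surface outward by nearly
    a full cell; the half-maximum of the local step is unbiased for
    symmetric ramps.
    """
    sel = (t >= t_cross - window) & (t <= t_cross + window)
    if np.count_nonzero(sel) < 3:
        return t_cross
    level = max(threshold, 0.5 * float(np.max(rho[sel])))
    cand = _crossings(t[sel], rho[sel], level)
    if cand.size == 0:
        return t_cross
    return float(cand[np.argmin(np.abs(cand - t_cross))])


def _crossings(t: np.ndarray, values: np.ndarray, level: float) -> np.ndarray:
    """Sub-sample positions where ``values`` crosses ``level`` (linear interp)."""
    v = values - level
    idx = np.nonzero(v[:-1] * v[1:] < 0)[0]
    frac = v[idx] / (v[idx] - v[idx + 1])
    interp = t[idx] + frac * (t[idx + 1] - t[idx])
    exact = t[np.nonzero(v == 0)[0]]
    out = np.concatenate([interp, exact])
    out.sort()
    return out


def chord_through(
    slice_: PhantomSlice,
    fan: FanLine,
    beam: BeamGeometry,
    target_y: float | None = None,
    step: float | None = None,
) -> ChordGeometry:
    """Trace one fan line through the slice.

    Locates the body entry/exit by ``body_threshold`` crossings of the
    interpolated density, integrates the radiological thickness, and finds
    the half-radiological-thickness point P'.  If ``target_y`` is given,
    the target point P0 is the intersection of the fan line with the
    horizontal line ``y = target_y`` (the reconstruction segment), and the
    signed ``d2`` / ``w2_prime`` legs from P' to P0 are filled in.

    Returns an ``outside-field`` marker (``inside=False``) when the ray
    misses the body entirely.
    """
    if step is None:
        step = slice_.spacing / 2.0
    xmin, xmax, ymin, ymax = slice_.extent
    # source distance range that covers the grid along this ray
    t_lo = max(0.0, ymin + beam.sad - 2.0 * slice_.spacing)
    t_hi = (ymax + beam.sad) / max(fan.direction(beam)[1], 1e-9) + 2.0 * slice_.spacing
    n = max(4, int(np.ceil((t_hi - t_lo) / step)))
    t = np.linspace(t_lo, t_hi, n + 1)
    pts = fan.point_at(t, beam)
    rho = slice_.density_at(pts)

    cross = _crossings(t, rho, slice_.body_threshold)
    if cross.size < 2 or not np.any(rho > slice_.body_threshold):
        return ChordGeometry.outside_field()
    win = 2.0 * slice_.spacing
    t_in = _refine_contour(t, rho, float(cross[0]), win, slice_.body_threshold)
    t_out = _refine_contour(t, rho, float(cross[-1]), win, slice_.body_threshold)
    if t_out <= t_in:
        return ChordGeometry.outside_field()
    w = t_out - t_in

    # cumulative radiological thickness from entry, trapezoid on the fine grid
    seg = np.linspace(t_in, t_out, max(8, int(np.ceil(w / step)) + 1))
    seg_rho = slice_.density_at(fan.point_at(seg, beam))
    cum = np.concatenate(
        [[0.0], np.cumsum((seg_rho[:-1] + seg_rho[1:]) / 2.0 * np.diff(seg))]
    )
    w_prime = float(cum[-1])
    t_half = float(np.interp(w_prime / 2.0, cum, seg))
    d1 = t_half - beam.sad

    d2 = 0.0
    w2p = 0.0
    if target_y is not None:
        dir_y = fan.direction(beam)[1]
        t_p0 = (target_y + beam.sad) / dir_y
        d2 = t_half - t_p0
        lo, hi = sorted((t_half, t_p0))
        w2p = float(np.interp(hi, seg, cum, left=0.0, right=w_prime))
        w2p -= float(np.interp(lo, seg, cum, left=0.0, right=w_prime))
        # radiological thickness outside the chord support is zero
        w2p = float(np.sign(d2)) * w2p

    return ChordGeometry(
        w=w, w_prime=w_prime, d1=d1, d2=d2, w2_prime=w2p,
        d=(t_in + t_out) / 2.0 - beam.sad,
    )


def apex_sagitta(
    slice_: PhantomSlice,
    p: np.ndarray,
    apex_direction: float = -1.0,
    step: float | None = None,
    max_reach: float = 40.0,
) -> float:
    """Distance from the chord midpoint ``p`` to the body contour along the
    lateral (profile) direction toward the apex [cm].

    Returns ``nan`` when no contour crossing is found within ``max_reach``.
    """
    if step is None:
        step = slice_.spacing / 2.0
    sgn = 1.0 if apex_direction >= 0 else -1.0
    s = np.arange(0.0, max_reach, step)
    pts = np.column_stack([p[0] + sgn * s, np.full_like(s, p[1])])
    rho = slice_.density_at(pts)
    cross = _crossings(s, rho, slice_.body_threshold)
    if cross.size == 0:
        return float("nan")
    return _refine_contour(
        s, rho, float(cross[0]), 2.0 * slice_.spacing, slice_.body_threshold
    )


def project_iso_to_epid(iso_coord: float, beam: BeamGeometry) -> float:
    """Lateral isocenter-plane position projected onto the EPID plane [cm]."""
    return iso_coord * beam.sed / beam.sad


def project_epid_to_iso(epid_coord: float, beam: BeamGeometry) -> float:
    """Lateral EPID-plane position back-projected to the isocenter plane [cm]."""
    return epid_coord * beam.sad / beam.sed


def inverse_square(sad: float, d: float) -> float:
    """Inverse-square distance factor ((SAD + d)/SAD)^2 for a signed offset d."""
    if sad + d <= 0:
        raise ValueError(f"sad + d must be positive, got sad={sad}, d={d}")
    return ((sad + d) / sad) ** 2


def sterling_equivalent_square(a: float, b: float) -> float:
    """Sterling equivalent-square side of an a x b field: 2ab/(a+b) [cm]."""
    if a <= 0 or b <= 0:
        raise ValueError(f"field sides must be positive, got {a} x {b}")
    return 2.0 * a * b / (a + b)
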