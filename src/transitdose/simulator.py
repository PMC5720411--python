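"""Synthetic phantoms, forward transit signals, and cohort generators.

Every other module is testable without measured data: this module builds
the cylindrical water phantoms and a breast-shaped slice with a
low-density lung region, and generates transit-signal profiles that are
*consistent with the calibrated model* — the forward model inverts the
per-fan-line dose-reconstruction relation (``Sto = D_true / C``) rather
than simulating radiation transport.  Round-trip tests are therefore
exact at zero noise by construction, which isolates the geometry,
alignment and noise behaviour under test.

Measurement noise is multiplicative Gaussian with SD equal to half the
stated 2 SD reproducibility (default 0.5% 2 SD); all randomness flows
through an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from .calibration import (
    CalibrationSample,
    CorrelationModel,
    ScatterModel,
    correlation_eval,
)
from .geometry import BeamGeometry, FanLine, PhantomSlice, chord_through
from .reconstruction import (
    PhysicsConstants,
    TransitProfile,
    central_axis_chord,
    fanline_c_factor,
)

__all__ = [
    "SimulationConfig",
    "CalibrationSet",
    "SimulatedSession",
    "make_cylinder_slice",
    "make_breast_slice",
    "forward_transit",
    "generate_calibration_set",
    "apply_misalignment",
    "simulate_cohort",
]

#: open-beam plateau signal [CU] outside the body projection, for edge
#: detection; roughly twice the transit level behind ~16 cm of water at
#: the 1.8 Gy daily fraction
DEFAULT_OPEN_SIGNAL = 3.0


@dataclass
class SimulationConfig:
    """Study conditions for a simulated treatment course."""

    beam: BeamGeometry = field(default_factory=BeamGeometry)
    true_dose: float = 1.8  # Gy at the breast midpoint (daily fraction)
    noise_2sd: float = 0.5  # percent, EPID signal reproducibility (2 SD)
    shift_s: float = 0.0  # cm, rigid setup shift along the profile
    open_signal: float = DEFAULT_OPEN_SIGNAL  # CU
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_2sd < 0:
            raise ValueError("noise_2sd must be non-negative")


class CalibrationSet(NamedTuple):
    """Synthetic calibration measurements for the two fits."""

    correlation: list[CalibrationSample]
    scatter: list[CalibrationSample]


class SimulatedSession(NamedTuple):
    """One simulated therapy session with its ground truth."""

    profile: TransitProfile
    truth: dict


def _grid_slice(
    mask_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    extent: tuple[float, float, float, float],
    spacing: float,
) -> PhantomSlice:
    xmin, xmax, ymin, ymax = extent
    nx = int(round((xmax - xmin) / spacing))
    ny = int(round((ymax - ymin) / spacing))
    # cell centres offset by half a cell so that round-number contours
    # fall between samples (keeps the discretised surface unbiased)
    x = xmin + (np.arange(nx) + 0.5) * spacing
    y = ymin + (np.arange(ny) + 0.5) * spacing
    xx, yy = np.meshgrid(x, y)
    return PhantomSlice(
        grid=mask_fn(xx, yy), spacing=spacing,
        origin=(x[0], y[0]),
    )


def make_cylinder_slice(
    r: float,
    spacing: float = 0.25,
    offset_d: float = 0.0,
    margin: float = 3.0,
) -> PhantomSlice:
    """Cylindrical water phantom: density 1 inside a circle of radius
    ``r`` [cm] centred at (0, ``offset_d``) — the chord midpoint of the
    central axis then sits at signed offset ``offset_d`` from the
    isocenter.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if r < 2.0 * spacing:
        raise ValueError(f"radius {r} cm too small for spacing {spacing} cm")

    def mask(xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        return (xx**2 + (yy - offset_d) ** 2 <= r * r).astype(float)

    extent = (-r - margin, r + margin,
              offset_d - r - margin, offset_d + r + margin)
    return _grid_slice(mask, extent, spacing)


def make_breast_slice(
    apex_radius: float = 7.0,
    chest_depth: float = 8.0,
    lung_density: float = 0.3,
    spacing: float = 0.25,
    apex_offset: float = 3.0,
    chest_half_height: float | None = None,
    lung_margin: float = 1.0,
    margin: float = 3.0,
) -> PhantomSlice:
    """Breast-shaped slice for a lateral tangential beam.

    A half-disc of tissue (radius ``apex_radius`` [cm]) protrudes from a
    rectangular chest wall toward negative ``x``; the apex sits at
    ``x = -apex_offset``.  A lung region of relative density
    ``lung_density`` is embedded in the chest, recessed ``lung_margin``
    cm behind the wall.  The beam central axis (x = 0) crosses the breast
    parallel to the chest wall.  The density map has exactly three
    levels: air (0), tissue (1), lung.
    """
    if min(apex_radius, chest_depth, spacing) <= 0:
        raise ValueError("dimensions must be positive")
    if not 0.0 <= lung_density <= 1.0:
        raise ValueError("lung_density must be in [0, 1]")
    if apex_offset >= apex_radius:
        raise ValueError(
            "apex_offset must be smaller than apex_radius for the central "
            "axis to cross the breast"
        )
    wall_x = apex_radius - apex_offset
    half_h = chest_half_height if chest_half_height is not None else apex_radius
    if lung_margin >= min(chest_depth, half_h):
        raise ValueError("lung_margin leaves no room for the lung region")

    def mask(xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        breast = ((xx - wall_x) ** 2 + yy**2 <= apex_radius**2) & (xx <= wall_x)
        chest = (xx >= wall_x) & (xx <= wall_x + chest_depth) & (np.abs(yy) <= half_h)
        lung = (
            (xx >= wall_x + lung_margin)
            & (xx <= wall_x + chest_depth - lung_margin / 2.0)
            & (np.abs(yy) <= half_h - lung_margin)
        )
        rho = np.zeros_like(xx)
        rho[breast | chest] = 1.0
        rho[lung] = lung_density
        return rho

    extent = (-apex_offset - margin, wall_x + chest_depth + margin,
              -max(apex_radius, half_h) - margin,
              max(apex_radius, half_h) + margin)
    return _grid_slice(mask, extent, spacing)


def forward_transit(
    slice_: PhantomSlice,
    beam: BeamGeometry,
    calib: tuple[CorrelationModel, ScatterModel],
    constants: PhysicsConstants = PhysicsConstants(),
    true_dose: float | Callable[[np.ndarray], np.ndarray] = 1.8,
    positions: np.ndarray | None = None,
    noise_2sd: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    open_signal: float = DEFAULT_OPEN_SIGNAL,
    apex_direction: float = -1.0,
) -> TransitProfile:
    """Forward-generate a transit-signal profile from a known dose.

    Per fan line on a uniform isocenter-plane grid, the signal is
    ``Sto = D_true(P0) / C`` with C the same reconstruction factor the
    inverse uses; fan lines missing the body read the open-beam plateau.
    ``true_dose`` is a constant [Gy] or a callable of the lateral
    position along the reconstruction segment.  Multiplicative Gaussian
    noise with SD ``noise_2sd/2`` percent is applied (seeded).
    """
    if positions is None:
        xmin, xmax, _, _ = slice_.extent
        positions = np.arange(xmin, xmax + 1e-9, 0.1)
    positions = np.asarray(positions, dtype=float)

    axis = central_axis_chord(slice_, beam, calib, apex_direction)
    if not axis.inside:
        raise ValueError("central axis does not intersect the body")
    y_cd = axis.d

    dose_fn = true_dose if callable(true_dose) else (
        lambda x, _v=float(true_dose): np.full_like(np.asarray(x, float), _v)
    )

    signals = np.empty_like(positions)
    for i, x_iso in enumerate(positions):
        fan = FanLine.from_iso(float(x_iso), beam)
        chord = chord_through(slice_, fan, beam, target_y=y_cd)
        t_p0 = (y_cd + beam.sad) / fan.direction(beam)[1]
        p0 = fan.point_at(t_p0, beam)
        in_body = (
            chord.inside
            and slice_.density_at(p0[None, :])[0] > slice_.body_threshold
        )
        if in_body:
            chord.d = axis.d
            chord.r = axis.r
            c = fanline_c_factor(chord, calib, constants, beam)
            d_true = float(np.atleast_1d(dose_fn(p0[0]))[0])
            if c <= 0:
                raise ValueError(f"non-positive C factor at x={x_iso:g} cm")
            signals[i] = d_true / c
        else:
            signals[i] = open_signal

    if noise_2sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        signals = signals * (1.0 + rng.normal(0.0, noise_2sd / 2.0 / 100.0,
                                              signals.shape))
    return TransitProfile(
        positions=positions,
        signals=signals,
        meta={
            "axis_w": axis.w, "axis_w_prime": axis.w_prime,
            "axis_d": axis.d, "axis_r": axis.r,
            "noise_2sd_percent": noise_2sd, "seed": seed,
            "open_signal": open_signal,
        },
    )


def generate_calibration_set(
    calib: tuple[CorrelationModel, ScatterModel],
    radii: tuple[float, ...] | None = None,
    w_grid: np.ndarray | None = None,
    d_grid: np.ndarray | None = None,
    noise_2sd: float = 0.5,
    seed: int | None = None,
    dm: float = 1.8,
    wedges: tuple[float, ...] = (15.0, 30.0),
) -> CalibrationSet:
    """Synthetic calibration measurements from a known model.

    Correlation samples have ``st/dm = F(w) (1 + eps)``; scatter samples
    carry ``S't(d) = St(0) / f(d, r) * (1 + eps)`` so the fitted ratios
    follow the generating slopes.  ``eps`` is Gaussian with SD
    ``noise_2sd/2`` percent, seeded.
    """
    corr, scat = calib
    if radii is None:
        radii = scat.radii
    if w_grid is None:
        w_grid = np.linspace(*corr.valid_w, 40)
    if d_grid is None:
        d_grid = np.arange(-4.0, 4.0 + 1e-9, 1.0)
    w_grid = np.asarray(w_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if w_grid.size == 0 or d_grid.size == 0:
        raise ValueError("w_grid and d_grid must be non-empty")
    rng = np.random.default_rng(seed)
    sd = noise_2sd / 2.0 / 100.0

    def eps() -> float:
        return float(rng.normal(0.0, sd)) if sd > 0 else 0.0

    correlation = [
        CalibrationSample(
            w=float(w),
            st=correlation_eval(corr, float(w)) * dm * (1.0 + eps()),
            dm=dm,
            wedge=wedges[i % len(wedges)],
            r=radii[i % len(radii)],
        )
        for i, w in enumerate(w_grid)
    ]

    scatter: list[CalibrationSample] = []
    for r in radii:
        w_ref = 2.0 * r  # diameter chord of the calibration cylinder
        st0 = correlation_eval(corr, w_ref) * dm
        f0 = float(np.interp(r, scat.radii, scat.f0))
        for d in d_grid:
            f = f0 * float(d) + 1.0
            noise = 1.0 + eps() if not np.isclose(d, 0.0) else 1.0
            scatter.append(
                CalibrationSample(
                    w=w_ref, st=st0 / f * noise, dm=dm, r=float(r), d=float(d)
                )
            )
    return CalibrationSet(correlation=correlation, scatter=scatter)


def apply_misalignment(profile: TransitProfile, shift_s: float) -> TransitProfile:
    """Rigidly translate the signal by ``shift_s`` cm (the patient — not
    the EPID — moving), resampled on the original position grid.

    Samples shifted out of the acquired support are NaN.
    """
    new_sig = np.interp(
        profile.positions - shift_s, profile.positions, profile.signals,
        left=np.nan, right=np.nan,
    )
    meta = dict(profile.meta)
    meta["applied_shift_cm"] = meta.get("applied_shift_cm", 0.0) + shift_s
    return TransitProfile(profile.positions.copy(), new_sig, meta)


def simulate_cohort(
    slice_: PhantomSlice,
    beam: BeamGeometry,
    calib: tuple[CorrelationModel, ScatterModel],
    n_sessions: int,
    setup_sd_mm: float = 3.5,
    systematic_mm: float = 1.5,
    cc_sd_mm: float = 5.3,
    seed: int | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
    true_dose: float = 1.8,
    noise_2sd: float = 0.5,
    positions: np.ndarray | None = None,
    open_signal: float = DEFAULT_OPEN_SIGNAL,
) -> list[SimulatedSession]:
    """Simulate a course of therapy sessions with random setup shifts.

    Per session a shift along the profile direction is drawn from
    Normal(``systematic_mm``, ``setup_sd_mm``) [mm] and applied to the
    noiseless forward profile; cranio-caudal shifts (recorded but not
    corrected in the 2D model) are drawn with SD ``cc_sd_mm``.  Noise is
    added after the shift.  The truth record carries the applied shift,
    the generating midpoint dose and the reference (planned) breast-edge
    position.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    base = forward_transit(
        slice_, beam, calib, constants, true_dose=true_dose,
        positions=positions, noise_2sd=0.0, open_signal=open_signal,
    )
    from .alignment import breast_edge_position  # local: avoids import cycle

    ref_edge = breast_edge_position(base)
    sd_n = noise_2sd / 2.0 / 100.0
    sessions = []
    for k in range(n_sessions):
        shift_cm = float(rng.normal(systematic_mm, setup_sd_mm)) / 10.0
        cc_mm = float(rng.normal(0.0, cc_sd_mm))
        prof = apply_misalignment(base, shift_cm)
        if sd_n > 0:
            noisy = prof.signals * (1.0 + rng.normal(0.0, sd_n, prof.signals.shape))
            prof = TransitProfile(prof.positions, noisy, prof.meta)
        prof.meta["session"] = k
        sessions.append(
            SimulatedSession(
                profile=prof,
                truth={
                    "reference_edge_cm": ref_edge,
                    "shift_cm": shift_cm,
                    "cc_shift_mm": cc_mm,
                    "dm_true": float(true_dose),
                    "axis_w_prime": base.meta["axis_w_prime"],
                    "axis_d": base.meta["axis_d"],
                    "axis_r": base.meta["axis_r"],
                },
            )
        )
    return sessions
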