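"""Setup-shift estimation by 1D portal-image / reference profile alignment.

During treatment the patient may sit shifted with respect to the planning
CT.  The transit-signal profile acquired on the EPID (the digital portal
image read along the apex-to-lung direction) then no longer matches the
planned reference, and the signal at the nominal midpoint projection
corresponds to a different chord of the breast.  This module formalises
the clinical image-matching step as 1D edge alignment: the breast edge is
the 50% crossing between the open-beam plateau and the attenuated level,
and the setup shift is the edge displacement from the planned reference,
reported at the isocenter plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import BeamGeometry
from .reconstruction import TransitProfile

__all__ = [
    "AlignmentResult",
    "AlignmentError",
    "SamplingWindow",
    "breast_edge_position",
    "estimate_shift",
    "resample_aligned",
    "sample_window_mean",
]


class AlignmentError(RuntimeError):
    """No usable breast edge could be found in a profile."""


@dataclass(frozen=True)
class AlignmentResult:
    """Estimated setup shift along the profile direction.

    ``shift_s`` is the displacement [cm] at the isocenter plane, positive
    when the acquired edge moved toward increasing position.  The
    ``confidence`` score in [0, 1] reflects edge sharpness (1 = the edge
    resolves within one grid step).
    """

    shift_s: float
    edge_dpi: float
    edge_ref: float
    confidence: float = 1.0


@dataclass(frozen=True)
class SamplingWindow:
    """EPID sampling window: mean of (2*half_width+1)^2 pixels (default
    5x5 = 25) around a point, with the aS500 pixel pitch at the EPID
    plane."""

    half_width: int = 2
    pixel_pitch: float = 0.0784  # cm at the EPID plane

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")


def _edge_levels(signals: np.ndarray) -> tuple[float, float]:
    finite = signals[np.isfinite(signals)]
    if finite.size < 4:
        raise AlignmentError("too few valid samples to locate an edge")
    top = np.sort(finite)[-max(1, finite.size // 10):]
    plateau = float(np.median(top))
    low = float(np.min(finite))
    return plateau, low


def breast_edge_position(profile: TransitProfile) -> float:
    """Position [cm] of the breast edge in a transit profile.

    The edge is where the signal crosses 50% of the span between the
    open-beam plateau (median of the top decile of samples) and the
    minimum attenuated level, located sub-grid by linear interpolation.
    The first crossing from the open side is returned.
    """
    sig = profile.signals
    pos = profile.positions
    plateau, low = _edge_levels(sig)
    if plateau - low < 0.05 * max(plateau, 1e-12):
        raise AlignmentError(
            "no edge: profile has no contrast between plateau and "
            "attenuated region"
        )
    level = (plateau + low) / 2.0
    v = np.where(np.isfinite(sig), sig, np.inf) - level
    sign_change = np.sign(v[:-1]) * np.sign(v[1:]) < 0
    idx = np.nonzero(sign_change & np.isfinite(v[:-1]) & np.isfinite(v[1:]))[0]
    if idx.size == 0:
        raise AlignmentError("no edge: signal never crosses the 50% level")
    i = idx[0]
    frac = v[i] / (v[i] - v[i + 1])
    return float(pos[i] + frac * (pos[i + 1] - pos[i]))


def estimate_shift(
    dpi: TransitProfile,
    reference_edge: float,
    beam: BeamGeometry | None = None,
    measured_at_epid: bool = False,
) -> AlignmentResult:
    """Setup shift of an acquired profile relative to the planned edge.

    ``shift_s = edge(dpi) - reference_edge``, reported at the isocenter
    plane.  Set ``measured_at_epid=True`` when both the profile positions
    and the reference edge are EPID-plane coordinates; they are then
    scaled by SAD/SED.
    """
    edge = breast_edge_position(dpi)
    shift = edge - reference_edge
    if measured_at_epid:
        if beam is None:
            raise ValueError("beam geometry required to rescale EPID-plane shifts")
        shift *= beam.sad / beam.sed
        edge *= beam.sad / beam.sed
        reference_edge *= beam.sad / beam.sed
    span = dpi.positions[-1] - dpi.positions[0]
    if abs(shift) > span / 2.0:
        warnings.warn(
            f"estimated shift {shift:.2f} cm exceeds half the profile span",
            UserWarning,
            stacklevel=2,
        )
    # sharpness: fraction of the plateau-low span covered per grid step at the edge
    plateau, low = _edge_levels(dpi.signals)
    i = int(np.searchsorted(dpi.positions, edge)) if not measured_at_epid else 0
    i = int(np.clip(i, 1, len(dpi.positions) - 1))
    local_step = abs(float(dpi.signals[i] - dpi.signals[i - 1]))
    confidence = float(np.clip(local_step / max(plateau - low, 1e-12), 0.0, 1.0))
    return AlignmentResult(
        shift_s=float(shift), edge_dpi=edge, edge_ref=float(reference_edge),
        confidence=confidence,
    )


def resample_aligned(dpi: TransitProfile, shift_s: float) -> TransitProfile:
    """Undo a setup shift: translate the profile by ``-shift_s`` and
    resample linearly onto the original grid.

    Samples that would come from outside the acquired support are NaN.
    """
    new_sig = np.interp(
        dpi.positions + shift_s, dpi.positions, dpi.signals,
        left=np.nan, right=np.nan,
    )
    meta = dict(dpi.meta)
    meta["applied_shift_cm"] = meta.get("applied_shift_cm", 0.0) - shift_s
    return TransitProfile(dpi.positions.copy(), new_sig, meta)


def sample_window_mean(
    image_or_profile: np.ndarray | TransitProfile,
    center,
    window: SamplingWindow = SamplingWindow(),
    beam: BeamGeometry | None = None,
) -> float:
    """Mean EPID signal over the sampling window.

    For a 2D array, ``center`` is a (row, col) pixel index and the mean is
    over the (2h+1)^2 window, clipped at the borders (with a warning).
    For a 1D :class:`TransitProfile`, ``center`` is an isocenter-plane
    position [cm] and the mean is over 2h+1 samples spaced by the pixel
    pitch back-projected to the isocenter plane (SAD/SED scaling; a
    default 100/150 beam is assumed when none is given).
    """
    h = window.half_width
    if isinstance(image_or_profile, TransitProfile):
        prof = image_or_profile
        scale = beam.sad / beam.sed if beam is not None else 100.0 / 150.0
        pitch_iso = window.pixel_pitch * scale
        offsets = (np.arange(-h, h + 1)) * pitch_iso
        pts = float(center) + offsets
        if pts[0] < prof.positions[0] or pts[-1] > prof.positions[-1]:
            warnings.warn(
                "sampling window clipped at the profile support",
                UserWarning, stacklevel=2,
            )
            pts = np.clip(pts, prof.positions[0], prof.positions[-1])
        vals = np.interp(pts, prof.positions, prof.signals)
        if not np.all(np.isfinite(vals)):
            raise AlignmentError("sampling window covers missing samples")
        return float(np.mean(vals))

    img = np.asarray(image_or_profile, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image or a TransitProfile")
    if img.size == 0:
        raise ValueError("empty image")
    r, c = int(center[0]), int(center[1])
    r0, r1 = r - h, r + h + 1
    c0, c1 = c - h, c + h + 1
    if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
        warnings.warn("sampling window clipped at the image border",
                      UserWarning, stacklevel=2)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
    block = img[r0:r1, c0:c1]
    if block.size == 0:
        raise ValueError("sampling window has empty support")
    return float(np.mean(block))
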