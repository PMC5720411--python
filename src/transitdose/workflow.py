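"""End-to-end in-vivo check: align, sample the midpoint signal, and
reconstruct the QA ratio for a session."""

from __future__ import annotations

import numpy as np

from .alignment import (
    SamplingWindow,
    estimate_shift,
    resample_aligned,
    sample_window_mean,
)
from .calibration import CorrelationModel, ScatterModel
from .geometry import BeamGeometry, PhantomSlice
from .qa import QASessionRecord
from .reconstruction import TransitProfile, central_axis_chord, midpoint_dose

__all__ = ["analyze_session"]


def analyze_session(
    profile: TransitProfile,
    slice_: PhantomSlice,
    beam: BeamGeometry,
    calib: tuple[CorrelationModel, ScatterModel],
    dm_tps: float,
    reference_edge: float | None = None,
    align: bool = True,
    window: SamplingWindow = SamplingWindow(),
    session_id: str = "session",
    field_id: str = "medial",
) -> QASessionRecord:
    """Run one in-vivo dosimetry check on an acquired transit profile.

    When ``align`` is True the profile is first registered to the planned
    ``reference_edge`` (1D breast-edge alignment) so that the transit
    signal is read at the projection of the *planned* breast midpoint.
    The midpoint signal is the sampling-window mean around the central
    axis; the dose follows the midpoint reconstruction with the planned
    central-axis chord (radiological thickness, offset d and equivalent
    radius taken from the planning slice).
    """
    shift = 0.0
    working = profile
    if align:
        if reference_edge is None:
            raise ValueError("reference_edge is required when align=True")
        result = estimate_shift(profile, reference_edge)
        shift = result.shift_s
        working = resample_aligned(profile, shift)

    axis = central_axis_chord(slice_, beam, calib)
    if not axis.inside:
        raise ValueError("central axis does not intersect the body")
    st_prime = sample_window_mean(working, 0.0, window, beam)
    dm = midpoint_dose(
        st_prime, axis.w_prime, axis.d, axis.r, calib, sad=beam.sad
    )
    return QASessionRecord(
        session_id=session_id, field_id=field_id,
        dm=dm, dm_tps=float(dm_tps), shift_s=float(shift),
    )
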