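"""QA ratios, uncertainty budgets, tolerance levels and cohort reports.

The quality-assurance statistic is the ratio ``R = Dm / Dm,TPS`` between
the in-vivo reconstructed midpoint dose and the treatment-planning-system
prediction.  Tolerance levels for R come from propagating the method's
component uncertainties (all stated as 2 SD percentages) in quadrature,
together with the TPS calculation uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UncertaintyBudget",
    "QASessionRecord",
    "QAReport",
    "ratio_r",
    "quadrature",
    "tolerance_level",
    "session_report",
    "misalignment_stats",
]

#: component uncertainties (2 SD, percent) of the midpoint-dose equation
#: for the clinical 6 MV setup, in budget order
DEFAULT_MIDPOINT_ITEMS: tuple[tuple[str, float], ...] = (
    ("signal reproducibility and MU linearity", 1.1),
    ("correlation-function fit F(w)", 2.0),
    ("scatter-factor fits f(d,r)", 0.5),
    ("inverse-square approximation", 1.0),
    ("radiological thickness w' (CT number calibration)", 1.0),
    ("equivalent square field (Sterling approximation)", 1.0),
    ("linac output factor variability", 2.0),
    ("long-term EPID calibration stability", 2.0),
    ("DPI vs DRR alignment", 2.0),
)

#: published rounded quadrature of the nine midpoint items (2 SD, percent);
#: direct quadrature of the listed values gives ~4.52 — both are exposed
PRINTED_MIDPOINT_2SD = 4.4

#: TPS (AAA) calculation uncertainty in homogeneous tissue (2 SD, percent)
DEFAULT_TPS_2SD = 3.0

#: extra legs for the profile equation: exponential-term uncertainty and
#: the radiological thickness of the P'-P0 leg (2 SD, percent)
DEFAULT_PROFILE_EXTRA_ITEMS: tuple[tuple[str, float], ...] = (
    ("exponential attenuation term (mean-energy spread)", 0.5),
    ("radiological thickness along d2", 1.0),
)


@dataclass
class UncertaintyBudget:
    """A list of (label, percent 2 SD) uncertainty components."""

    items: tuple[tuple[str, float], ...] = DEFAULT_MIDPOINT_ITEMS
    tps_uncertainty: float = DEFAULT_TPS_2SD

    def __post_init__(self) -> None:
        if any(p < 0 for _, p in self.items) or self.tps_uncertainty < 0:
            raise ValueError("uncertainty components must be non-negative")

    @property
    def percents(self) -> list[float]:
        return [p for _, p in self.items]

    @property
    def quadrature_2sd(self) -> float:
        """Quadrature of the listed components (2 SD, percent)."""
        return quadrature(self.percents)

    def tolerance(self, rounding: str = "integer") -> float:
        """Tolerance level for R: quadrature with the TPS uncertainty."""
        return tolerance_level(self.quadrature_2sd, self.tps_uncertainty, rounding)


@dataclass
class QASessionRecord:
    """One in-vivo check: reconstructed vs planned midpoint dose."""

    session_id: str
    field_id: str  # e.g. 'medial' / 'lateral'
    dm: float  # Gy, reconstructed
    dm_tps: float  # Gy, planned
    shift_s: float = 0.0  # cm, applied alignment shift
    within_tolerance: bool | None = None

    def __post_init__(self) -> None:
        if self.dm <= 0 or self.dm_tps <= 0:
            raise ValueError("dm and dm_tps must be positive")

    @property
    def ratio_r(self) -> float:
        return self.dm / self.dm_tps


@dataclass
class QAReport:
    """Cohort summary of R ratios and setup misalignments."""

    n_sessions: int
    mean_r: float
    sd_r_percent: float
    fraction_within_percent: float
    tolerance_percent: float
    flagged: tuple[str, ...] = ()
    misalignment_sigma_mm: dict = field(default_factory=dict)
    misalignment_systematic_mm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_within_percent <= 100.0):
            raise ValueError("fraction_within_percent must be in [0, 100]")


def ratio_r(dm: float, dm_tps: float) -> float:
    """QA ratio R = Dm / Dm,TPS."""
    if dm_tps <= 0:
        raise ValueError(f"dm_tps must be positive, got {dm_tps}")
    return dm / dm_tps


def quadrature(percents) -> float:
    """Combine independent uncertainty components in quadrature [percent]."""
    p = list(percents)
    if not p:
        raise ValueError("quadrature of an empty list is undefined")
    if any(x < 0 for x in p):
        raise ValueError("uncertainty components must be non-negative")
    return math.sqrt(sum(x * x for x in p))


def tolerance_level(
    recon_percent: float, tps_percent: float, rounding: str = "integer"
) -> float:
    """Tolerance for R: quadrature of reconstruction and TPS uncertainties.

    ``rounding`` is 'integer' (whole percent, the clinical action level)
    or 'one decimal'.
    """
    if recon_percent < 0 or tps_percent < 0:
        raise ValueError("uncertainties must be non-negative")
    q = quadrature([recon_percent, tps_percent])
    if rounding == "integer":
        return float(round(q))
    if rounding == "one decimal":
        return round(q, 1)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def session_report(
    records: list[QASessionRecord],
    tolerance: float = 5.0,
    shifts_mm: dict | None = None,
) -> QAReport:
    """Summarise a cohort of QA sessions.

    Computes the mean R, its SD in percent, the fraction of sessions with
    ``|R - 1| <= tolerance/100``, and flags the sessions beyond tolerance.
    Optional per-direction setup shifts [mm] are summarised via
    :func:`misalignment_stats`.
    """
    if not records:
        raise ValueError("session_report requires at least one record")
    r = np.array([rec.ratio_r for rec in records])
    sd_r = float(np.std(r, ddof=1) * 100.0) if r.size > 1 else 0.0
    within = np.abs(r - 1.0) <= tolerance / 100.0
    for rec, ok in zip(records, within):
        rec.within_tolerance = bool(ok)
    flagged = tuple(
        f"{rec.session_id}/{rec.field_id}: R={rec.ratio_r:.3f}"
        for rec, ok in zip(records, within) if not ok
    )
    sigma: dict = {}
    systematic: dict = {}
    if shifts_mm:
        for direction, values in shifts_mm.items():
            sd, mean = misalignment_stats(values)
            sigma[direction] = sd
            systematic[direction] = mean
    return QAReport(
        n_sessions=len(records),
        mean_r=float(np.mean(r)),
        sd_r_percent=sd_r,
        fraction_within_percent=float(np.mean(within) * 100.0),
        tolerance_percent=float(tolerance),
        flagged=flagged,
        misalignment_sigma_mm=sigma,
        misalignment_systematic_mm=systematic,
    )


def misalignment_stats(shifts_mm) -> tuple[float, float]:
    """(SD, mean) of setup shifts along one direction [mm].

    The mean is the systematic setup error; the SD the random component.
    """
    arr = np.asarray(list(shifts_mm), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 shifts per direction")
    return float(np.std(arr, ddof=1)), float(np.mean(arr))
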