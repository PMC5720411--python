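"""Correlation-function and scatter-factor calibration.

The transit-dosimetry calibration relates the EPID transit signal behind a
water-equivalent thickness ``w`` to the dose at the chord midpoint:

* the *correlation function* ``F(w) = a1 w^2 + a2 w + a3`` [CU/Gy] is the
  ratio of transit signal to midplane dose, fitted over cylindrical water
  phantoms;
* the *scatter factor* ``f(d, r) = f0(r) d + 1`` corrects the signal for
  the change in phantom-to-EPID scatter when the chord midpoint sits a
  signed distance ``d`` [cm] from the isocenter, for an equivalent
  cylinder radius ``r`` [cm].

Published coefficients for a 6 MV beam with an aS500 EPID at SED 150 cm
ship as package defaults (:func:`load_default_tables`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrelationModel",
    "ScatterModel",
    "CalibrationSample",
    "CalibrationWarning",
    "correlation_eval",
    "correlation_fit",
    "scatter_eval",
    "scatter_fit",
    "load_default_tables",
]

#: default correlation coefficients (6 MV, pooled 15°/30° wedges)
DEFAULT_A = (5.819e-4, 2.880e-2, 5.480e-1)
#: default scatter slopes f0(r) [1/cm] at the four calibration radii [cm]
DEFAULT_RADII = (6.0, 8.3, 10.7, 14.5)
DEFAULT_F0 = (0.998e-3, 1.487e-3, 2.094e-3, 2.756e-3)


class CalibrationWarning(UserWarning):
    """Raised when a model is evaluated outside its calibrated range."""


@dataclass
class CorrelationModel:
    """Quadratic correlation function F(w) = a1 w^2 + a2 w + a3.

    Units: a1 [CU/(Gy cm^2)], a2 [CU/(Gy cm)], a3 [CU/Gy].  ``valid_w``
    is the chord-thickness interval spanned by the calibration phantoms;
    evaluation outside it warns but does not fail.
    """

    a1: float
    a2: float
    a3: float
    valid_w: tuple[float, float] = (5.0, 29.0)
    fit_residual_2sd: float | None = None  # percent, from correlation_fit

    def coefficients(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])


@dataclass
class ScatterModel:
    """Per-radius linear scatter slopes f0(r) for f(d, r) = f0(r) d + 1."""

    radii: tuple[float, ...] = DEFAULT_RADII
    f0: tuple[float, ...] = DEFAULT_F0
    valid_d: tuple[float, float] = (-4.0, 4.0)
    fit_residual_2sd: float | None = None  # percent, from scatter_fit

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.f0):
            raise ValueError("radii and f0 must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration measurement: transit signal vs dose for one chord."""

    w: float  # chord thickness [cm]
    st: float  # transit signal [CU]
    dm: float  # midplane dose [Gy]
    wedge: float = 0.0  # wedge angle [deg]
    field_length: float = 20.0  # cm
    r: float = float("nan")  # phantom radius [cm]
    d: float = 0.0  # phantom displacement [cm]

    def __post_init__(self) -> None:
        if self.st <= 0 or self.dm <= 0:
            raise ValueError(
                f"st and dm must be positive, got st={self.st}, dm={self.dm}"
            )


def correlation_eval(model: CorrelationModel, w: float | np.ndarray) -> float | np.ndarray:
    """F(w) [CU/Gy] for chord thickness ``w`` [cm].

    Warns when ``w`` lies outside the calibrated ``valid_w`` interval;
    raises for non-positive ``w``.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr <= 0):
        raise ValueError("chord thickness w must be positive")
    lo, hi = model.valid_w
    if np.any((w_arr < lo) | (w_arr > hi)):
        warnings.warn(
            f"w outside the calibrated range [{lo:g}, {hi:g}] cm; "
            "F(w) is extrapolated",
            CalibrationWarning,
            stacklevel=2,
        )
    out = model.a1 * w_arr**2 + model.a2 * w_arr + model.a3
    return float(out) if np.isscalar(w) else out


def correlation_fit(samples: list[CalibrationSample]) -> CorrelationModel:
    """Least-squares quadratic fit of St/Dm versus w.

    Pools all samples regardless of wedge angle (the calibrated ratios are
    wedge-independent within measurement reproducibility).  Requires at
    least four samples spanning at least three distinct thicknesses.
    Stores ``fit_residual_2sd`` as twice the SD of the percent residuals.
    """
    if len(samples) < 4:
        raise ValueError(f"need >= 4 samples, got {len(samples)}")
    w = np.array([s.w for s in samples])
    y = np.array([s.st / s.dm for s in samples])
    if np.unique(w).size < 3:
        raise ValueError(
            f"need >= 3 distinct w values to fit a quadratic, got "
            f"{np.unique(w).size} (w spans {w.min():g}-{w.max():g} cm)"
        )
    a1, a2, a3 = np.polyfit(w, y, 2)
    fitted = np.polyval([a1, a2, a3], w)
    resid_pct = (fitted / y - 1.0) * 100.0
    return CorrelationModel(
        a1=a1, a2=a2, a3=a3,
        valid_w=(float(w.min()), float(w.max())),
        fit_residual_2sd=float(2.0 * np.std(resid_pct)),
    )


def _interp_f0(model: ScatterModel, r: float) -> float:
    radii = np.asarray(model.radii)
    if r < radii[0] or r > radii[-1]:
        warnings.warn(
            f"radius r={r:g} cm outside the calibrated range "
            f"[{radii[0]:g}, {radii[-1]:g}] cm; f0 clamped to the table end",
            CalibrationWarning,
            stacklevel=3,
        )
    return float(np.interp(r, radii, np.asarray(model.f0)))


def scatter_eval(model: ScatterModel, d: float, r: float) -> float:
    """f(d, r) = f0(r) d + 1, with f0 linearly interpolated in r.

    f0 is clamped (with a warning) outside the tabulated radii; |d| beyond
    the calibrated ``valid_d`` range also warns.
    """
    lo, hi = model.valid_d
    if d < lo or d > hi:
        warnings.warn(
            f"displacement d={d:g} cm outside the calibrated "
            f"[{lo:g}, {hi:g}] cm range",
            CalibrationWarning,
            stacklevel=2,
        )
    return _interp_f0(model, r) * d + 1.0


def scatter_fit(samples: list[CalibrationSample]) -> ScatterModel:
    """Per-radius linear fit of St/S't versus displacement d.

    ``samples`` carry S't in their ``st`` field; the reference St for each
    radius is the sample (mean) at d = 0.  The ratio St/S't is regressed
    on d with the intercept fixed at 1 (slope = sum(d y)/sum(d^2) on
    y = ratio - 1).  Requires >= 3 distinct d per radius including d = 0.
    """
    by_r: dict[float, list[CalibrationSample]] = {}
    for s in samples:
        by_r.setdefault(float(s.r), []).append(s)

    radii, slopes, resid_pct = [], [], []
    for r in sorted(by_r):
        group = by_r[r]
        d = np.array([s.d for s in group])
        st = np.array([s.st for s in group])
        if np.unique(d).size < 3:
            raise ValueError(
                f"radius r={r:g}: need >= 3 distinct d values, got "
                f"{np.unique(d).size}"
            )
        at_zero = np.isclose(d, 0.0)
        if not np.any(at_zero):
            raise ValueError(f"radius r={r:g}: no d=0 reference sample")
        st_ref = float(np.mean(st[at_zero]))
        ratio = st_ref / st
        slope = float(np.sum(d * (ratio - 1.0)) / np.sum(d * d))
        fitted = slope * d + 1.0
        radii.append(r)
        slopes.append(slope)
        resid_pct.extend(((fitted / ratio - 1.0) * 100.0).tolist())

    return ScatterModel(
        radii=tuple(radii),
        f0=tuple(slopes),
        fit_residual_2sd=float(2.0 * np.std(resid_pct)),
    )


def load_default_tables() -> tuple[CorrelationModel, ScatterModel]:
    """The packaged 6 MV calibration: correlation coefficients and f0(r)."""
    a1, a2, a3 = DEFAULT_A
    return (
        CorrelationModel(a1=a1, a2=a2, a3=a3),
        ScatterModel(radii=DEFAULT_RADII, f0=DEFAULT_F0),
    )
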