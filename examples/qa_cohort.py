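"""QA a simulated treatment course with and without alignment correction.

Simulates 40 therapy sessions of a breast phantom with random setup
errors (SD 5 mm plus a 1.5 mm systematic component), runs the in-vivo
check on every session both ways, and prints the cohort statistics
against the tolerance level derived from the uncertainty budget.
"""

import numpy as np

from transitdose import (
    BeamGeometry,
    UncertaintyBudget,
    analyze_session,
    load_default_tables,
    make_breast_slice,
    session_report,
    simulate_cohort,
)

beam = BeamGeometry()
calib = load_default_tables()
slice_ = make_breast_slice()

budget = UncertaintyBudget()
tolerance = budget.tolerance("integer")
print(f"reconstruction uncertainty (quadrature of {len(budget.items)} items): "
      f"{budget.quadrature_2sd:.1f}% (2 SD)")
print(f"tolerance level for R with {budget.tps_uncertainty:.0f}% TPS "
      f"uncertainty: +-{tolerance:.0f}%\n")

sessions = simulate_cohort(
    slice_, beam, calib, n_sessions=40,
    setup_sd_mm=5.0, systematic_mm=1.5, noise_2sd=0.5, seed=0,
)
ref_edge = sessions[0].truth["reference_edge_cm"]

aligned, unaligned, shifts_mm = [], [], []
for k, s in enumerate(sessions):
    aligned.append(analyze_session(
        s.profile, slice_, beam, calib, dm_tps=1.8,
        reference_edge=ref_edge, session_id=f"s{k:02d}"))
    unaligned.append(analyze_session(
        s.profile, slice_, beam, calib, dm_tps=1.8,
        align=False, session_id=f"s{k:02d}"))
    shifts_mm.append(aligned[-1].shift_s * 10.0)

rep_on = session_report(aligned, tolerance=tolerance,
                        shifts_mm={"apex-lung": shifts_mm})
rep_off = session_report(unaligned, tolerance=tolerance)

print(f"{'':28s}{'aligned':>10s}{'unaligned':>12s}")
print(f"{'mean R':28s}{rep_on.mean_r:>10.3f}{rep_off.mean_r:>12.3f}")
print(f"{'SD of R':28s}{rep_on.sd_r_percent:>9.1f}%{rep_off.sd_r_percent:>11.1f}%")
print(f"{'fraction within tolerance':28s}"
      f"{rep_on.fraction_within_percent:>9.0f}%"
      f"{rep_off.fraction_within_percent:>11.0f}%")
sigma = rep_on.misalignment_sigma_mm["apex-lung"]
syst = rep_on.misalignment_systematic_mm["apex-lung"]
print(f"\nestimated setup error: sigma {sigma:.1f} mm, "
      f"systematic {syst:+.1f} mm (true: 5.0 / +1.5 mm)")
print("ignoring setup shifts inflates the apparent dose discrepancies: "
      "the same sessions fail QA far more often")
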