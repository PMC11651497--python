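#!/usr/bin/env python
"""Regress standard base excess (beta = 16.2) on PCO2, per study.

If SBE were CO2-invariant in vivo its slope against PCO2 would be zero.
Reports each study's pooled OLS slope with 95% CI and p-value, and the
per-subject SBE excursions from the lowest-PCO2 (baseline) exposure.

Reads results/cohort.csv and results/volunteers.csv (run 01 first);
writes results/sbe_regression.json (+ .txt summary).
"""

from pathlib import Path

from bexcess import fit_sbe_slope, max_delta_sbe, read_observations
from bexcess.io import write_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_observations(RESULTS / "cohort.csv")
    volunteers = read_observations(RESULTS / "volunteers.csv")
    fits = {
        sid: fit_sbe_slope(cohort.subset(sid), 16.2)
        for sid in cohort.study_ids
    }
    fits["volunteers_default_noise"] = fit_sbe_slope(volunteers, 16.2)
    deltas = max_delta_sbe(volunteers, 16.2)
    write_report(
        {
            "per_study_fits": fits,
            "deltas": deltas,
            "config": {"beta": 16.2, "level": 0.95},
        },
        RESULTS / "sbe_regression.json",
    )
    for sid, fit in fits.items():
        verdict = "CO2-dependent" if fit.p_value < 0.05 else "no drift detected"
        print(f"{sid}: slope {fit.slope:+.4f} mmol/L per mmHg "
              f"(95% CI {fit.ci_low:.4f} to {fit.ci_high:.4f}, "
              f"p={fit.p_value:.3g}) -> {verdict}")
    print(f"volunteer SBE deltas span {deltas.cohort_min:+.2f} to "
          f"{deltas.cohort_max:+.2f} mmol/L across {deltas.n_subjects} subjects")


if __name__ == "__main__":
    main()
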