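"""Full cohort analysis for the adenosine intervention.

Runs calibration-free analysis of the simulated adenosine cohort:
per-preparation fits for tension, ATP and ACh, derived parameters,
per-preparation percentage reductions (tension/ATP averaged over 1 and
2 Hz, ACh at 20 Hz) and the paired tests.  The printed pattern is the
study's central finding: tension and ATP release fall together at low
frequency while ACh release is untouched.
"""

import argparse
from pathlib import Path

import pandas as pd

from detrusorfit import analyze_cohort

def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/simulated/adenosine"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis_adenosine"))
    args = ap.parse_args()

    tension = pd.read_csv(args.sim_dir / "tension.csv")
    release = pd.read_csv(args.sim_dir / "release.csv")
    res = analyze_cohort(tension, release)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    res.fits.to_csv(args.out_dir / "fits.csv", index=False)
    res.table2_frame().to_csv(args.out_dir / "table2.csv", index=False)
    res.table3_frame().to_csv(args.out_dir / "table3.csv", index=False)

    row = res.table3[0]
    print(f"adenosine vs control (n = {row.n}):")
    print(f"  tension reduction (1-2 Hz): {row.tension_redn_mean:5.1f} ± {row.tension_redn_sd:.1f} %"
          f"   p = {row.tension_p:.2g}")
    print(f"  ATP reduction (1-2 Hz):     {row.atp_redn_mean:5.1f} ± {row.atp_redn_sd:.1f} %"
          f"   p = {row.atp_p:.2g}")
    print(f"  ACh change (20 Hz):         {row.ach_redn_mean:5.1f} ± {row.ach_redn_sd:.1f} %"
          f"   p = {row.ach_p:.2f} (not significant -> release spared)")


if __name__ == "__main__":
    main()
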