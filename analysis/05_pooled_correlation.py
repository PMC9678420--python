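"""Pool interventions: tension-vs-ATP reduction correlation and the
frequency profile of the adenosine effect.

Across interventions acting on the presynaptic A1/cAMP/PKA axis (and the
no-effect antagonist control), the low-frequency tension reduction
tracks the ATP-release reduction — the quantitative case that the
contractile effect is purinergic.  The reduction-versus-frequency
profile is fitted with the sigmoid reduction model to summarise the
low-frequency selectivity.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from detrusorfit import analyze_cohort, fit_reduction_profile, percent_reduction, pooled_correlation

PRESETS = ("adenosine", "cpa", "neca", "camps_rp", "dpcpx")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results/correlation.json"))
    args = ap.parse_args()

    rows = []
    for name in PRESETS:
        tension = pd.read_csv(args.sim_dir / name / "tension.csv")
        release = pd.read_csv(args.sim_dir / name / "release.csv")
        res = analyze_cohort(tension, release, measures=("tension", "atp"))
        rows.append(res.table3[0])
        print(f"{name:<10s} tension {rows[-1].tension_redn_mean:6.1f} %   "
              f"ATP {rows[-1].atp_redn_mean:6.1f} %")

    corr = pooled_correlation(rows)
    print(f"\nPearson r = {corr['r']:.2f} (p = {corr['p_value']:.4f}, "
          f"{corr['n_interventions']} interventions)")

    # frequency profile of the adenosine tension reduction
    t = pd.read_csv(args.sim_dir / "adenosine" / "tension.csv")
    t = t.assign(norm=lambda d: d.tension_mN / d.weight_mg)
    wide = t.pivot_table(index=["prep_id", "frequency_hz"], columns="condition",
                         values="norm").reset_index()
    wide["reduction"] = [percent_reduction(c, i)
                         for c, i in zip(wide["control"], wide["adenosine"])]
    profile = wide.groupby("frequency_hz")["reduction"].mean()
    fit = fit_reduction_profile(profile.index.values, profile.values)
    print(f"reduction profile: {fit.params.t_lf:.1f} % at low frequency, "
          f"half-transition at {fit.params.k:.1f} Hz")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({
        **corr,
        "reduction_profile": {"t_lf_pct": fit.params.t_lf, "t_hf_pct": fit.params.t_hf,
                              "k_hz": fit.params.k, "m": fit.params.m},
    }, indent=2))


if __name__ == "__main__":
    main()
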