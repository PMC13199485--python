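#!/usr/bin/env python
"""Stage 2 — explant shape dynamics: roundness decay, V50/slope, F test.

Simulates roundness time courses for two genotype groups whose extension
timing differs (control V50 = 9.0 hpf vs delayed V50 = 9.6 hpf, as when a
sulfatase-pathway gene is overexpressed), applies the inclusion rule
(roundness < 0.5 by 12 hpf), fits the Boltzmann sigmoid per group, compares
the groups with the extra sum-of-squares F test, and calls per-explant
extension onsets.  Writes fits, the test report, and onsets to results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cet import synthdata as sd
from cet.shape import compare_fits_f_test, extension_onset_from_series, fit_boltzmann, include_explant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/02_explant_shape"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    groups = {}
    for label, v50, sub in (("control", 9.0, 0), ("delayed", 9.6, 1)):
        spec = sd.SimShapeSpec(n_explants=12, v50_hpf=v50, noise_sd=0.02,
                               seed=args.seed * 2 + sub)
        series = sd.gen_shape_series(spec, group=label)
        kept = [s for s in series if include_explant(s).include]
        groups[label] = kept

    fit_rows = []
    for label, ss in groups.items():
        fit = fit_boltzmann(ss, seed=args.seed)
        fit_rows.append({"group": label, "n_explants": len(ss), "bottom": fit.bottom,
                         "top": fit.top, "v50_hpf": fit.v50, "slope_hpf": fit.slope,
                         "sse": fit.sse, "df": fit.df})
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(args.out / "fits.csv", index=False)

    ft = compare_fits_f_test(groups, seed=args.seed)
    with open(args.out / "f_test.json", "w") as fh:
        json.dump({"f": ft.f_stat, "df_num": ft.df_num, "df_den": ft.df_den,
                   "p": ft.p_value}, fh, indent=2)

    onsets = pd.DataFrame([
        {"explant_id": s.explant_id, "group": g,
         "onset_hpf": extension_onset_from_series(s)}
        for g, ss in groups.items() for s in ss])
    onsets.to_csv(args.out / "onsets.csv", index=False)

    for _, r in fits.iterrows():
        print(f"{r['group']}: V50 = {r['v50_hpf']:.2f} hpf, slope = {r['slope_hpf']:.2f} hpf "
              f"({int(r['n_explants'])} explants)")
    print(f"extra sum-of-squares F({ft.df_num},{ft.df_den}) = {ft.f_stat:.1f}, p = {ft.p_value:.2e}")
    med = onsets.groupby("group")["onset_hpf"].median()
    print("median extension onset:", ", ".join(f"{g} {v:.2f} hpf" for g, v in med.items()))


if __name__ == "__main__":
    main()
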