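#!/usr/bin/env python
"""Shift of the Kd-voltage curve between symmetric and asymmetric K+.

Simulates the Mg2+ dose design in symmetric 100 mM K+ and in 20 mM external /
100 mM internal K+ (E_K ~ -40 mV), fits both Kd-voltage curves, and reports
the voltage displacement of the asymmetric curve relative to the symmetric
one (least-squares alignment of log Kd).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from kirblock import generate_experiment, kd_curve, kd_shift
from kirblock.designs import dose_response_design

warnings.filterwarnings("ignore", message=".*steady state.*")


def main(seed: int, outdir: Path) -> None:
    curves = {}
    for name, k_out, v_min in (("sym_100", 100.0, -60.0), ("asym_20_100", 20.0, -100.0)):
        cells = dose_response_design(genotype="WT", blocker="Mg", k_out=k_out)
        exp = generate_experiment(cells, seed=seed, name=name)
        curves[name] = kd_curve(exp, genotype="WT", v_min=v_min, v_max=60.0)
        print(f"{name}: fitted {len(curves[name].entries)} voltages "
              f"({len(curves[name].skipped)} skipped)")

    rows = []
    for name, curve in curves.items():
        for v, fit in curve.entries.items():
            rows.append({"condition": name, "v_mV": v, "kd_M": fit.kd})
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "kd_curves_k_conditions.csv", index=False)

    shift = kd_shift(curves["asym_20_100"], curves["sym_100"])
    print(f"\nKd-V shift of the 20/100 curve relative to symmetric 100 mM: "
          f"{shift:+.1f} mV")
    print("(E_K moves by -40 mV; a much smaller curve shift indicates weak "
          "flux coupling of the Mg2+ block)")
    print(f"wrote {outdir / 'kd_curves_k_conditions.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.outdir)
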