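#!/usr/bin/env python
"""Fit S-state models to the synthetic flash patterns and compare them.

For each preparation the noiseless pattern is fitted with the five-state
model (per-transition misses, fast/slow release bifurcation) and with the
two classic Kok variants (equal misses, equal misses + double hits).  The
recovered five-state parameters are compared against the generating values
and the Kok fits illustrate why the homogeneous models cannot reproduce the
observed oscillations.

Writes results/pattern_fits.csv (generating vs recovered) and
results/model_comparison.csv (pfq and ratios per model).
"""

import argparse
from pathlib import Path

import pandas as pd

from flashox import FlashProtocol, normalize_to_y3, simulate_pattern
from flashox.fitting import compare_models, fit_five_s, fit_kok
from flashox.presets import FIVE_S_ROWS

PARAM_NAMES = ("alpha0", "alpha1", "alpha2", "alpha3", "d", "C", "s0", "s1", "s2", "s3")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    protocol = FlashProtocol.standard()
    fit_rows, cmp_rows = [], []
    for row, params in FIVE_S_ROWS.items():
        pattern = normalize_to_y3(simulate_pattern(params, protocol))
        five = fit_five_s(pattern, seed=args.seed)
        kok1 = fit_kok(pattern, variant="equal", seed=args.seed)
        kok2 = fit_kok(pattern, variant="equal+double", seed=args.seed)

        truth = {
            "alpha0": params.alpha[0], "alpha1": params.alpha[1],
            "alpha2": params.alpha[2], "alpha3": params.alpha[3],
            "d": params.d, "C": params.C,
            "s0": params.init[0], "s1": params.init[1],
            "s2": params.init[2], "s3": params.init[3],
        }
        print(f"\n{row}: five-state pfq = {five.pfq:.2e}")
        for name in PARAM_NAMES:
            fit_rows.append({
                "preparation": row, "parameter": name,
                "generating": truth[name], "recovered": five.params[name],
                "abs_error": abs(five.params[name] - truth[name]),
            })
        headline = {k: five.params[k] for k in ("alpha2", "d", "C", "s1")}
        print("    recovered  alpha2=%(alpha2).3f d=%(d).3f C=%(C).4f S1=%(s1).3f" % headline)

        for entry in compare_models([five, kok1, kok2]):
            cmp_rows.append({"preparation": row, **entry})
            print(f"    {entry['model_kind']:>10}: pfq={entry['pfq']:.2e} "
                  f"ratio={entry['ratio']:.1f}")

    pd.DataFrame(fit_rows).to_csv(args.out_dir / "pattern_fits.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(args.out_dir / "model_comparison.csv", index=False)
    print(f"\nwrote {args.out_dir / 'pattern_fits.csv'} and model_comparison.csv")
    print("The five-state fits return the generating total miss, damping ratio C "
          "and fast fraction d; the homogeneous Kok variants fit the same patterns "
          "orders of magnitude worse, mirroring the need for unequal misses and a "
          "bifurcated S3 -> S0 step.")


if __name__ == "__main__":
    main()
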