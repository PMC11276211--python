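#!/usr/bin/env python
"""Fit the biphasic O2-release kinetics Y3(dt) for the three preparations.

Generates Y3-versus-interval datasets on the 5-500 ms grid (3 replicates,
measurement-scale noise plus a noiseless reference), fits one- and
two-component saturating relaxation models, runs the corrected-AIC
component selection, and applies the fixed-time-constant counter-check:
can protein-depleted kinetics be reproduced with the intact-membrane time
constants?

Writes results/kinetics_fits.csv and results/kinetics_selection.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from flashox.kinetics import fit_relaxation, fixed_tau_check, select_n_components
from flashox.presets import BIEXP_ROWS
from flashox.synth import generate_kinetics_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--noise-sd", type=float, default=0.02)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    fit_rows, sel_rows = [], []
    taus = {}
    for row, truth in BIEXP_ROWS.items():
        for label, sd in (("noiseless", 0.0), ("noisy", args.noise_sd)):
            ds = generate_kinetics_dataset(
                truth, noise_sd=sd, n_replicates=3, seed=args.seed
            )
            report = select_n_components(ds, seed=args.seed)
            n = report["selected"]
            params, result = report["fits"][n]
            sel_rows.append({
                "preparation": row, "condition": label, "selected": n,
                "aicc_1": report["aicc"][1], "aicc_2": report["aicc"][2],
            })
            fit_rows.append({
                "preparation": row, "condition": label, "n_components": n,
                "a_fast": params.a_fast, "tau_fast": params.tau_fast,
                "a_slow": params.a_slow, "tau_slow": params.tau_slow,
                "true_a_fast": truth.a_fast, "true_tau_fast": truth.tau_fast,
                "true_a_slow": truth.a_slow, "true_tau_slow": truth.tau_slow,
                "mse": result.pfq,
            })
            if label == "noiseless":
                taus[row] = params
                print(f"{row} ({label}): {n} component(s) selected; "
                      f"A_fast={params.a_fast:.3f} tau_fast={params.tau_fast} "
                      f"A_slow={params.a_slow:.3f} tau_slow={params.tau_slow:.2f} ms")

    pq, opq = taus["pq"], taus["opq"]
    print(f"\nslow/fast separation after PsbP+PsbQ removal: "
          f"{pq.tau_slow / pq.tau_fast:.2f}x (about 3.5x)")
    print(f"further slow-phase acceleration after PsbO removal: "
          f"{pq.tau_slow / opq.tau_slow:.2f}x (about 1.7x)")

    ds_opq = generate_kinetics_dataset(BIEXP_ROWS["opq"], noise_sd=0.0, seed=args.seed)
    chk = fixed_tau_check(ds_opq, (taus["control"].tau_fast, taus["control"].tau_slow))
    _, free = fit_relaxation(ds_opq, n_components=1, seed=args.seed)
    rss_free = float(free.residuals @ free.residuals)
    print(f"\nfixed-tau counter-check (opq data, control time constants): "
          f"rss={chk['rss']:.3e} vs free single-component rss={rss_free:.2e} - "
          "the depleted kinetics cannot be described by the intact-membrane phases.")

    pd.DataFrame(fit_rows).to_csv(args.out_dir / "kinetics_fits.csv", index=False)
    pd.DataFrame(sel_rows).to_csv(args.out_dir / "kinetics_selection.csv", index=False)
    print(f"\nwrote {args.out_dir / 'kinetics_fits.csv'} and kinetics_selection.csv")


if __name__ == "__main__":
    main()
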