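#!/usr/bin/env python
"""Simulate flash-induced O2 yield patterns for the three preparations.

Generates the 16-flash, 300 ms-spaced oxygen yield patterns of intact PSII
BBY membranes ("control") and of preparations lacking PsbP+PsbQ ("pq") or
PsbO+PsbP+PsbQ ("opq"), both noiseless and as noisy replicate sets at the
measurement noise scale, and cross-checks the deterministic ensemble model
against the per-center Monte-Carlo sampler.

Writes results/patterns.csv (noiseless, Y3-normalized, one column per
preparation) and results/pattern_replicates.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from flashox import FlashProtocol, normalize_to_y3, simulate_pattern
from flashox.presets import FIVE_S_ROWS
from flashox.synth import generate_pattern_dataset, monte_carlo_pattern


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    protocol = FlashProtocol.standard()
    table = {"flash": np.arange(1, 17)}
    rep_rows = []
    for row, params in FIVE_S_ROWS.items():
        pattern = normalize_to_y3(simulate_pattern(params, protocol))
        table[row] = pattern.amplitudes
        peak = int(np.argmax(pattern.amplitudes[:5])) + 1
        print(f"{row}: first maximum at flash {peak}, "
              f"Y2/Y3 = {pattern.amplitudes[1]:.3f}, "
              f"Y15/Y3 = {pattern.amplitudes[14]:.3f}")

        mc = normalize_to_y3(monte_carlo_pattern(params, protocol, 200_000, args.seed))
        worst = np.max(np.abs(mc.amplitudes - pattern.amplitudes))
        print(f"    Monte-Carlo cross-check (2e5 centers): "
              f"max |deterministic - sampled| = {worst:.4f}")

        for rep_idx, rep in enumerate(
            generate_pattern_dataset(params, protocol, 0.02, 3, args.seed), start=1
        ):
            for k, amp in enumerate(rep.amplitudes, start=1):
                rep_rows.append(
                    {"preparation": row, "replicate": rep_idx, "flash": k, "amplitude": amp}
                )

    pd.DataFrame(table).to_csv(args.out_dir / "patterns.csv", index=False)
    pd.DataFrame(rep_rows).to_csv(args.out_dir / "pattern_replicates.csv", index=False)
    print(f"\nwrote {args.out_dir / 'patterns.csv'} and pattern_replicates.csv")
    print("The control pattern shows the damped period-4 oscillation peaking at "
          "flash 3 (dark-adapted centers sit mostly in S1); protein removal damps "
          "the oscillation further through larger early-transition misses.")


if __name__ == "__main__":
    main()
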