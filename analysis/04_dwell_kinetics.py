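#!/usr/bin/env python
"""Dwell-time kinetics: observed decay rates and microscopic rate constants.

Extracts dwells from the idealized paths, fits each state's dwell-time
histogram with a single exponential (Freedman-Diaconis bins, frame-aligned),
counts transition frequencies by a 50-trace x 50-rep bootstrap, splits the
observed rates into microscopic rate constants, and removes the
missed-event bias by re-simulating from the fitted rates through the same
pipeline (parametric bootstrap). Compares everything against the generating
truth.

Outputs: dwells.csv, rates_raw.csv, rates_corrected.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polfret import kinetics, recovery, trace_io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"
DATA = ROOT / "scratch" / "analysis"
SEED = 2026
FRAME_DT = 0.1


def main() -> None:
    _, paths = trace_io.read_idealized(DATA / "idealized.csv")
    dwells = kinetics.extract_dwells(paths)
    dwells.df.to_csv(DATA / "dwells.csv", index=False)
    print(f"{len(dwells.df)} dwells from {len(paths)} traces")

    raw, sds, est = recovery._rates_from_paths(paths, FRAME_DT, SEED)
    est.to_frame().to_csv(OUT / "rates_raw.csv", index=False)

    sims = [
        recovery._simulate_and_recover(
            raw, n_traces=len(paths), duration=60.0, frame_dt=FRAME_DT,
            seed=SEED + 100 + m, analysis_seed=SEED + 200 + m,
        )
        for m in range(3)
    ]
    rows = []
    for name in recovery.RATE_NAMES:
        bias = float(np.mean([s[name] for s in sims])) / raw[name]
        corrected = raw[name] / bias
        true = recovery.TRUE_RATES[name]
        rows.append(
            {"rate": name, "true_per_s": true, "raw_per_s": raw[name],
             "bias_factor": bias, "corrected_per_s": corrected,
             "sd_per_s": sds[name] / bias,
             "rel_error_pct": 100 * (corrected - true) / true}
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "rates_corrected.csv", index=False)
    print(table.round(3).to_string(index=False))
    worst = table["rel_error_pct"].abs().max()
    print(f"\nlargest relative error after bias correction: {worst:.1f}%")


if __name__ == "__main__":
    main()
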