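#!/usr/bin/env python
"""Per-cell bimodal decay separation on simulated recordings.

Simulates cells with a fast (2 ms, putative sensory) and a slow (8 ms,
putative corticothalamic) mEPSC population, runs the full chain —
detection, 30-70% decay fitting, multimodality test, Akima-spline critical
value, Type 1/2 classification — and compares the recovered split with the
planted event labels.  Writes results/decay_classification.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from synquant import ExperimentConfig, simulate_trace
from synquant.pipeline import analyze_trace


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cells", type=int, default=10)
    ap.add_argument("--duration", type=float, default=120.0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = ExperimentConfig()
    rows = []
    for i in range(args.n_cells):
        raw, truth = simulate_trace(duration=args.duration, tau_jitter=0.2,
                                    seed=args.seed * 3000 + i)
        summary, events, dist, typed = analyze_trace(raw, cfg)
        row = {"cell": i, "n_events": summary.n_events,
               "frequency_hz": summary.mean_frequency,
               "multimodality_p": dist.multimodality_p if dist else np.nan,
               "critical_value_ms": dist.critical_value if dist and dist.separable else np.nan,
               "planted_type1_rate_hz": 1.5, "planted_type2_rate_hz": 1.5}
        if typed:
            row["type1_frequency_hz"] = typed.type1_frequency
            row["type2_frequency_hz"] = typed.type2_frequency
        rows.append(row)

    df = pd.DataFrame(rows)
    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "decay_classification.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.4f")

    ok = df["critical_value_ms"].notna()
    print(f"{ok.sum()}/{len(df)} cells separable; all multimodality p < 0.05: "
          f"{(df['multimodality_p'] < 0.05).all()}")
    print(f"median critical value {df['critical_value_ms'].median():.2f} ms "
          f"(planted component means 2 and 8 ms)")
    print(f"mean Type 1 rate {df.loc[ok, 'type1_frequency_hz'].mean():.2f} Hz, "
          f"Type 2 rate {df.loc[ok, 'type2_frequency_hz'].mean():.2f} Hz (planted 1.5 / 1.5)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
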