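"""Displacement-pathway classification of SSB -> RecO exchange traces.

Simulates a 1000-trace displacement ensemble in which 1.5% of traces pass
through the low-FRET intermediate (the RecO-ssDNA-SSB ternary state at
E ~ 0.2) on their way from the SSB-bound level (E ~ 0.6) to the RecO-bound
level (E ~ 0.8), segments and classifies every trace, and compares the
classifier's category table against the generator's ground-truth paths.
Writes results/displacement_summary.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from smexchange.synthetic import TraceSimConfig, simulate_trace
from smexchange.traces import (
    classification_summary,
    classify_trace,
    compute_trace_fret,
    segment_states,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-traces", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results/displacement_summary.tsv"))
    args = ap.parse_args()

    p_int, k_exit, k_low = 0.015, 0.02, 0.2
    Q = np.array(
        [
            [0.0, 0.0, k_low],
            [p_int * k_exit, 0.0, (1 - p_int) * k_exit],
            [0.0, 0.0, 0.0],
        ]
    )
    root = np.random.default_rng(args.seed)
    classes = []
    for _ in range(args.n_traces):
        tr = simulate_trace(
            TraceSimConfig(
                states=[("LOW", 0.2, 0.05), ("MID", 0.6, 0.05), ("HIGH", 0.8, 0.05)],
                rate_matrix=Q,
                duration=300.0,
                injection_time=30.0,
                initial_state=1,
                noise_sd=10.0,
                seed=int(root.integers(2**31)),
            )
        )
        seg = segment_states(
            compute_trace_fret(tr), [0.2, 0.6, 0.8], frame_interval=tr.frame_interval
        )
        classes.append(classify_trace(seg, 30.0))

    summary = classification_summary(classes)
    table = summary.rename("fraction").to_frame()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t")
    print(table.to_string())
    via_pct = 100 * (
        summary["DISPLACEMENT_VIA_INTERMEDIATE"] + summary["MULTI_TRANSITION"]
    )
    print(
        f"intermediate-state traces: {via_pct:.1f}% of the ensemble "
        f"(generator probability {100 * p_int:.1f}%)"
    )


if __name__ == "__main__":
    main()
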