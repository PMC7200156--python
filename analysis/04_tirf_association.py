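"""TIRF binding peaks and association kinetics of RecO on ssDNA.

Part 1: pools 100 simulated single-bound-state traces per condition and
fits the cumulative FRET histograms — the SSB-bound complex peaks at 0.62,
the RecO-bound complex at 0.83.

Part 2: simulates exponential binding times at 0.2/0.5/1.0 uM for the two
ground-truth second-order association constants (8.4e4 M^-1 s^-1 for bare
dT70, 7.5e3 M^-1 s^-1 for SSB-coated dT70), converts each concentration to
k_obs = 1/<t>, and regresses k_obs on concentration through the origin.

Writes results/tirf_peaks.tsv and results/association_constants.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from smexchange.burst import fit_fret_histogram
from smexchange.synthetic import TraceSimConfig, simulate_binding_times, simulate_trace
from smexchange.traces import compute_trace_fret, fit_association_constant


def pooled_peak(peak: float, seed: int) -> tuple[float, float]:
    root = np.random.default_rng(seed)
    pooled = []
    for _ in range(100):
        tr = simulate_trace(
            TraceSimConfig(
                states=[("bound", peak, 0.08)],
                rate_matrix=np.zeros((1, 1)),
                duration=300.0,
                seed=int(root.integers(2**31)),
            )
        )
        pooled.append(compute_trace_fret(tr))
    (comp,) = fit_fret_histogram(np.concatenate(pooled), 1)
    return comp.mean, comp.sd


def association(k_a: float, seed: int) -> tuple[float, float]:
    conc = [0.2e-6, 0.5e-6, 1.0e-6]
    df = simulate_binding_times(k_a, conc, 200, seed=seed)
    pts = [(c, 1.0 / g["waiting_time"].mean()) for c, g in df.groupby("concentration")]
    weights = [200 / k**2 for _, k in pts]
    fit = fit_association_constant(pts, weights=weights)
    return fit.rate, fit.uncertainty


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    peak_rows = []
    for label, peak, off in (("ssb_dT70", 0.62, 0), ("reco_dT70", 0.83, 1)):
        mean, sd = pooled_peak(peak, args.seed + off)
        peak_rows.append(
            {
                "complex": label,
                "peak_true": peak,
                "peak_fitted": round(mean, 4),
                "width_fitted": round(sd, 4),
            }
        )
    peaks = pd.DataFrame(peak_rows)
    peaks.to_csv(args.outdir / "tirf_peaks.tsv", sep="\t", index=False)
    print(peaks.to_string(index=False))

    assoc_rows = []
    for label, k_a, off in (("bare_dT70", 8.4e4, 2), ("ssb_coated_dT70", 7.5e3, 3)):
        slope, err = association(k_a, args.seed + off)
        assoc_rows.append(
            {
                "substrate": label,
                "k_a_true_per_M_s": k_a,
                "k_a_fitted_per_M_s": float(f"{slope:.4g}"),
                "k_a_stderr": float(f"{err:.3g}"),
                "rel_error_pct": round(100 * abs(slope - k_a) / k_a, 2),
            }
        )
    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(args.outdir / "association_constants.tsv", sep="\t", index=False)
    print(assoc.to_string(index=False))
    print(
        "RecO binds bare ssDNA an order of magnitude faster than SSB-coated ssDNA"
    )


if __name__ == "__main__":
    main()
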