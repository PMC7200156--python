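"""Two-color colocalization of labelled SSB and ssDNA with bleach control.

Simulates pair trajectories under acceptor photobleaching alone (the
no-treatment control, which emulates the 72%-at-4.5-min control fraction)
and under bleaching plus dissociation, evaluates the colocalized fraction
at 4.5 min, and shows that dividing by the control isolates the
dissociation survival exp(-k_d t) on a (k_bleach, k_diss) grid.
Writes results/colocalization.tsv.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from smexchange.coloc import bleaching_corrected_fraction, coloc_fraction
from smexchange.synthetic import ColocSimConfig, simulate_coloc

T_EVAL = 270.0  # 4.5 min
# bleach rate chosen so the control fraction at 4.5 min is ~72%
K_BLEACH_CONTROL = -math.log(0.72) / T_EVAL


def fraction(k_b: float, k_d: float, seed: int, n_pairs: int = 2000) -> float:
    sim = simulate_coloc(
        ColocSimConfig(
            n_pairs=n_pairs,
            acceptor_bleach_rate=k_b,
            dissociation_rate=k_d,
            seed=seed,
        )
    )
    return coloc_fraction(sim.presence, sim.times, eval_time=T_EVAL).fraction_at_eval


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/colocalization.tsv"))
    args = ap.parse_args()

    rows = []
    for i, k_b in enumerate((K_BLEACH_CONTROL, 2 * K_BLEACH_CONTROL)):
        ctrl = fraction(k_b, 0.0, seed=args.seed + 10 * i)
        for j, k_d in enumerate((1e-3, 4e-3)):
            obs = fraction(k_b, k_d, seed=args.seed + 10 * i + j + 1)
            rows.append(
                {
                    "k_bleach_per_s": float(f"{k_b:.3g}"),
                    "k_diss_per_s": k_d,
                    "control_fraction": round(ctrl, 3),
                    "observed_fraction": round(obs, 3),
                    "corrected_fraction": round(
                        bleaching_corrected_fraction(obs, ctrl), 3
                    ),
                    "exp_minus_kd_t": round(math.exp(-k_d * T_EVAL), 3),
                }
            )
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        "corrected fractions track exp(-k_d t) regardless of the bleach rate: "
        "the no-treatment control removes photobleaching"
    )


if __name__ == "__main__":
    main()
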