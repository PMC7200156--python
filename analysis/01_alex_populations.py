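"""ALEX burst populations of the dT70 / SSB-dT70 / RecO-dT70 system.

Simulates a 10,000-burst ensemble of the three dual-labelled species
(E = 0.09, 0.58, 0.78) plus a 30% donor-only contaminant, applies the
0.25 < S < 0.75 stoichiometry gate, and decomposes the gated FRET histogram
into three Gaussians.  Writes the recovered population table to
results/alex_populations.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from smexchange.burst import fit_fret_histogram, select_fret_species
from smexchange.synthetic import AlexSimConfig, SpeciesSpec, simulate_alex_bursts

TRUTH = [("free", 0.09), ("ssb_bound", 0.58), ("reco_bound", 0.78)]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/alex_populations.tsv"))
    args = ap.parse_args()

    f = 0.7 / 3
    species = [SpeciesSpec(name, e, 0.07, 0.5, 0.05, f) for name, e in TRUTH]
    species.append(SpeciesSpec("donor_only", 0.05, 0.05, 0.95, 0.03, 0.3))

    bursts = simulate_alex_bursts(
        AlexSimConfig(species=species, n_bursts=10_000, seed=args.seed)
    )
    kept = select_fret_species(bursts, 0.25, 0.75)
    comps = fit_fret_histogram([b.e for b in kept], 3)

    rows = []
    for comp, (name, e_true) in zip(comps, TRUTH):
        rows.append(
            {
                "species": name,
                "e_true": e_true,
                "e_fitted": round(comp.mean, 4),
                "sd_fitted": round(comp.sd, 4),
                "area_bursts": round(comp.area, 1),
            }
        )
    table = pd.DataFrame(rows)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    print(f"{len(bursts)} bursts simulated, {len(kept)} retained by the S gate")
    print(table.to_string(index=False))
    worst = (table["e_fitted"] - table["e_true"]).abs().max()
    print(f"largest |fitted - true| population center: {worst:.4f} E units")


if __name__ == "__main__":
    main()
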