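# smexchange

Single-molecule FRET analysis of protein exchange on single-stranded DNA,
built around the model system of *Deinococcus radiodurans* SSB being
displaced from poly-dT ssDNA by the recombination mediator RecO. The
package provides the complete analysis chain for three experiment types —
solution-phase ALEX burst spectroscopy, surface-tethered TIRF time traces,
and dual-color colocalization — together with a synthetic-data generator
that produces every input with known ground truth, so each stage of the
chain is verifiable by parameter recovery without any experimental data.

## Who this is for

Single-molecule spectroscopists analysing (or planning) measurements of
protein–nucleic-acid binding, competition and exchange: burst-wise E/S
histograms, binding isotherms, population kinetics, dwell-time statistics,
displacement-pathway classification, and colocalization survival with
photobleaching control.

## The quantities computed

**ALEX bursts.** Each detected single-molecule transit carries three photon
counts — donor emission under donor excitation (I_DD), acceptor emission
under donor excitation (I_DA), acceptor emission under acceptor excitation
(I_AA) — giving the apparent FRET efficiency and stoichiometry

    E = I_DA / (I_DD + I_DA),        S = (I_DD + I_DA) / (I_DD + I_DA + I_AA).

Doubly labelled molecules are sorted with the gate 0.25 < S < 0.75, the 1-D
FRET histogram of the gated bursts is decomposed into Gaussian populations,
and component areas A_i feed three fits:

- bound fraction θ = A_bound / (A_bound + A_free) versus concentration C,
  fitted with the Hill isotherm θ(C) = Cⁿ/(K_dⁿ + Cⁿ) (K_d is the
  half-saturation concentration);
- population fractions versus time, with the SSB-bound fraction relaxing as
  f(t) = f_∞ + (f₀ − f_∞)·exp(−k·t) under excess competitor (k is the
  exchange rate);
- burst counts per species versus ground truth, for generator validation.

**TIRF traces.** Per-frame E = I_A/(I_D + I_A) is segmented onto discrete
levels (~0.2 bare ssDNA / stretched intermediate, ~0.6 SSB-bound, ~0.8
RecO-bound) by nearest-level thresholding with short-run suppression.
From the segmentation come binding times t after solution injection
(k_obs = 1/⟨t⟩, with the second-order association constant k_a as the slope
of k_obs versus concentration), dwell-time distributions fitted by single
exponentials (rate = 1/⟨lifetime⟩), and a per-trace displacement-pathway
classification (no binding / direct displacement / displacement via the
low-FRET intermediate / intermediate return / multi-transition).

**Colocalization.** Two-channel spot detection, rigid-offset pairing, and
the colocalized fraction at a fixed evaluation time (4.5 min), with
bleaching removed by dividing by a no-treatment control: for independent
exponential losses, observed = exp(−k_bleach·t)·exp(−k_diss·t), so the
ratio isolates dissociation.

## Worked example

```python
import numpy as np
from smexchange.synthetic import AlexSimConfig, SpeciesSpec, simulate_alex_bursts
from smexchange.burst import select_fret_species, fit_fret_histogram

species = [
    SpeciesSpec("free",       0.09, 0.07, 0.5, 0.05, 0.7 / 3),
    SpeciesSpec("ssb_bound",  0.58, 0.07, 0.5, 0.05, 0.7 / 3),
    SpeciesSpec("reco_bound", 0.78, 0.07, 0.5, 0.05, 0.7 / 3),
    SpeciesSpec("donor_only", 0.05, 0.05, 0.95, 0.03, 0.3),
]
bursts = simulate_alex_bursts(AlexSimConfig(species=species, n_bursts=10_000, seed=1))
kept = select_fret_species(bursts, 0.25, 0.75)        # stoichiometry gate
comps = fit_fret_histogram([b.e for b in kept], 3)    # 3-Gaussian decomposition
for c in comps:
    print(f"E = {c.mean:.3f}  sd = {c.sd:.3f}  area = {c.area:.0f} bursts")
```

prints

```
E = 0.082  sd = 0.070  area = 2474 bursts
E = 0.592  sd = 0.077  area = 2567 bursts
E = 0.796  sd = 0.064  area = 2066 bursts
```

— the three generating population centers (0.09, 0.58, 0.78) recovered
within 0.017 E units after the stoichiometry gate removed the 30%
donor-only contaminant (6961 of 10,000 bursts retained).

## Analysis scripts

The numbered drivers under `analysis/` run each study end to end and write
their tables to `results/`:

| script | what it computes |
| --- | --- |
| `01_alex_populations.py` | S-gated 3-Gaussian population recovery |
| `02_binding_isotherms.py` | Hill fits of the 0.28 nM and 79 nM titrations |
| `03_exchange_kinetics.py` | exponential exchange-rate fits (1.10e-3, 5.02e-4 s⁻¹) |
| `04_tirf_association.py` | cumulative-histogram peaks (0.62, 0.83) and k_a slopes |
| `05_displacement_pathways.py` | trace classification and pathway table |
| `06_colocalization.py` | colocalization survival and bleach correction grid |

A `smexchange` CLI exposes the same operations on files
(`simulate-alex`, `analyze-alex`, `fit-kd`, `fit-exchange`, `analyze-tirf`,
`fit-association`, `analyze-coloc`, ...); every run writes a JSON report
echoing its full configuration and seed.

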