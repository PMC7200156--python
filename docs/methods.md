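# Methods

This note records the models implemented in `smexchange`, the assumptions
behind the synthetic-data generator, and the numerical choices in the fits
— the package's own account of what it computes and why.

## The system and its observables

The analyses target a three-species single-molecule FRET system: a 70-nt
poly-dT ssDNA labelled with a donor/acceptor pair reports its compaction
state through E ≈ 0.09 when bare, E ≈ 0.58 when wrapped by the SSB
homodimer, and E ≈ 0.78 when bound by RecO (solution-phase ALEX values;
the surface-tethered TIRF geometry reads ~0.2 / ~0.6 / ~0.8 for the same
states, with pooled histogram peaks at 0.62 and 0.83). All E and S values
are *apparent*: no gamma factor, donor leakage or direct-excitation
corrections are applied anywhere, so fitted population centers are
comparable only between measurements analysed the same way.

## Synthetic-data generator

Every analysis input can be generated with its ground truth attached, so
downstream recovery tests never re-derive what the generator already knows.

**ALEX bursts** are generated at the count level. A burst picks its species
by mixture weight; its total photon count is a shifted Poisson (minimum 20
photons, mean `burst_size_mean` = 100) — a deliberately simple stand-in for
the heavy-tailed burst-size spread of diffusing molecules that avoids
modelling diffusion paths. The counts are split by nested binomials: a
fraction S into the donor-excitation phase, then a fraction E of those into
the acceptor channel. The species parameters `e_sd`/`s_sd` specify the
*observed* histogram widths; because the binomial split already contributes
shot variance ≈ e(1−e)/(s·N̄) per burst, the per-burst Gaussian jitter of
(e, s) is drawn with that expected contribution deconvolved (floored at
zero when shot noise alone reaches the requested width), and the jitter is
a proper truncated normal on [0, 1] rather than a clipped one, so no point
mass accumulates at the edges. Optional stream output places bursts at
random times and timestamps photons consistently with the 100 µs laser
alternation, for exercising burst detection; background is Poisson per
channel at `background_rate` photons per 0.6 ms bin.

**Exchange series** draw per-bin species counts from a multinomial whose
SSB-bound probability relaxes as f(t) = f_∞ + (f₀ − f_∞)e^(−kt) within the
bound pool, the RecO-bound probability rising complementarily and the free
fraction constant. Burst times are spread uniformly across each time bin —
molecules diffuse through the detection spot throughout the acquisition
window — which keeps re-binned bin centers aligned with the generating
grid. Per-burst E values are truncated normals around the three species
centers (default width 0.07).

**Titrations** draw the bound fraction at each concentration as a binomial
over `bursts_per_point` with success probability θ(C) = Cⁿ/(K_dⁿ+Cⁿ);
`bursts_per_point=None` returns the exact expectation (noiseless).

**TIRF traces** sample a hidden continuous-time Markov chain (Gillespie)
over labelled FRET states, held in its initial state until
`injection_time` — injection models the flow-channel solution exchange as
an instantaneous switch-on of the rate matrix. Frames are read at 100 ms;
per-frame E is jittered by the state width, intensities are
I·E and I·(1−E) plus Gaussian channel noise, and photobleaching is one
irreversible exponential step per channel (acceptor bleach reroutes all
signal to the donor channel; donor bleach silences both). What the
generator does **not** emulate: triplet blinking, spectral cross-talk,
baseline drift, intensity aperiodicity of real EMCCD noise, or diffusion
through the confocal volume. Passing tests therefore demonstrate the
correctness of the analysis logic under idealised noise, not robustness to
every artifact of real recordings.

**Colocalization pairs** lose their acceptor partner at the earlier of a
bleaching and a dissociation event, both exponential. In image mode the
pairs are rendered as Gaussian PSF spots (channel B rigidly offset) with
Poisson counting noise; spot positions are rejection-sampled to at least
4 PSF widths apart, emulating the sparse surface densities used in
single-molecule imaging.

All generators are bit-reproducible from (config, seed).

## Analysis models and numerical choices

**Burst detection** is fixed-bin thresholding at the 0.6 ms acquisition
bin: contiguous runs of bins with ≥ `count_threshold` photons form one
burst; bursts below 20 photons are discarded. This is the simplest scheme
consistent with binned APD acquisition; sliding-window search is not
needed at the signal-to-background of the targeted measurements.

**Histogram decomposition** fits a sum of Gaussians to the binned FRET
histogram (bin width 0.02 E units) by least squares, initialised at sample
quantiles unless centers are supplied; component areas are returned in
burst units. Fitting the histogram (rather than a mixture likelihood)
matches how population areas are conventionally extracted; an EM mixture
fit is provided as a cross-check route and agrees within bin resolution.
Degenerate all-identical input pins the width at the 1e-3 lower bound.

**Hill fits** float the coefficient n by default (n = 1 can be fixed);
K_d is reported with its standard error, and a curve never crossing
θ = 0.5 is flagged `extrapolated_kd` rather than rejected.

**Exchange fits** use the single-exponential relaxation with free plateau —
the standard two-state form under excess ligand; the plateau can be fixed
at 0 for complete exchange. Because the model is linear in (f₀, f_∞) at
fixed k, initialisation scans k on a log grid with the linear subproblem
solved exactly (variable projection); initial values are kept strictly
inside the [0, 1] bounds because MINPACK's bound transformation freezes a
parameter that starts exactly on a bound, and the refinement uses the
trust-region-reflective least-squares method, which handles the box bounds
natively and converges cleanly on exactly representable (noiseless) input.
Bins are weighted by their inverse binomial variance f(1−f)/n. Species
windows for re-counting fractions from burst E values default to
(0–0.30), (0.44–0.68), (0.68–0.92): ±2 population widths around the
centers, clipped to the midpoint where adjacent windows would overlap.
Window leakage (a 0.58-centred burst read above 0.68, etc.) rescales the
observed amplitude and plateau but not the rate, which is why the plateau
floats by default.

**Trace segmentation** assigns each frame to the nearest level within
`half_width` = 0.12 E units, else UNASSIGNED, then iteratively merges runs
shorter than `min_dwell` = 3 frames (0.3 s) into a flanking state, the
longer flank winning and the earlier one on a tie. The 3-frame floor
rejects single-frame shot noise while resolving intermediate dwells of a
few hundred milliseconds; all thresholds are configurable. Levels must be
separated by more than one half-width so the nearest assignment is
unambiguous away from midpoints.

**Dwell rates** are reported as the reciprocal of the mean lifetime, which
is both the maximum-likelihood rate for exponential dwells and what a
single-exponential fit of the dwell histogram returns. Dwells truncated by
the end of a trace or by bleaching are excluded by default (conservative);
samples of fewer than 10 dwells are flagged low-confidence with the
reciprocal-mean fallback.

**Association constants** regress k_obs = 1/⟨binding time⟩ on
concentration through the origin (no intercept: pseudo-first-order
kinetics with negligible background association). Since
sd(k_obs) ≈ k_obs/√n for a reciprocal exponential mean, callers weight
points by n/k_obs²; the unweighted fit is the default for externally
supplied rates of unknown provenance.

**Pathway classification** reads the post-injection dwell sequence:
never leaving the SSB level is NO_BINDING; ending at the RecO level with
zero / one / two-or-more intermediate visits is DISPLACEMENT_DIRECT /
DISPLACEMENT_VIA_INTERMEDIATE / MULTI_TRANSITION; visiting the
intermediate but ending back at the SSB (or intermediate) level is
INTERMEDIATE_RETURN. The one-versus-many boundary between
"via-intermediate" and "multi-transition" is a genuine design choice (no
operational criterion is standard); the summary therefore also reports the
pooled displacement total and the pooled intermediate share, which are
insensitive to that boundary. The bare-ssDNA state and the intermediate
share E ≈ 0.2 and are disambiguated by context: a low-FRET dwell after an
SSB-bound dwell post-injection is an intermediate.

**Colocalization** calls a partner present while its intensity stays above
half its initial plateau (trace mode) or while a spot is detected within
the pairing radius of its initial position (image mode). Channel
registration is a rigid offset — adequate for synthetic data and small
fields of view, and a documented limitation for real dual-view optics with
field-dependent distortion. The evaluation time defaults to 4.5 min
(270 s) and the correction divides by the no-treatment control fraction,
exact for independent exponential losses.

## Problem sizes

The packaged studies and the acceptance script use 10⁴ bursts for
population recovery, 8 concentrations × 1000 bursts for isotherms, 12 bins
× 500 bursts for exchange series, 200 binding times per concentration, 100
traces × 3000 frames for histogram peaks, and 1000 traces for
classification — sizes at which recovery errors are a few percent, chosen
to mirror realistic single-session data volumes.

## Known limitations

- Threshold segmentation, not HMM: adequate for the well-separated levels
  of this system; an HMM would be the extension point for overlapping
  levels (e.g. 50–60-nt substrates where bound-state E values converge).
- The exchange-rate estimator at 12 × 500 bursts has ≈7% sampling sd; a
  single realisation can deviate by up to ~15%.
- No photophysics beyond single-step bleaching; no drift or bleed-through
  correction of raw movies.
- The generator's burst-size law and background statistics are simple
  placeholders exposed in config, not calibrated to any instrument.
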