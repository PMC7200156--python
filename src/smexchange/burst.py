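"""ALEX burst analysis: E/S computation, species sorting, and solution-phase fits.

In an alternating-laser-excitation (ALEX) measurement each diffusing molecule
produces a photon burst classified into three streams: donor emission under
donor excitation (``i_dd``), acceptor emission under donor excitation
(``i_da``, the FRET channel) and acceptor emission under acceptor excitation
(``i_aa``).  The apparent FRET efficiency and stoichiometry of a burst are

    E = i_da / (i_dd + i_da)
    S = (i_dd + i_da) / (i_dd + i_da + i_aa)

No gamma, leakage or direct-excitation corrections are applied: the pipeline
works with apparent values throughout.  Doubly labelled molecules are sorted
with the stoichiometry gate 0.25 < S < 0.75; donor-only molecules sit at
S ~ 1 and acceptor-only at S ~ 0.

Population quantification fits a sum of Gaussians to the 1-D FRET histogram
of the gated bursts; component areas feed the bound fraction
theta = A_bound / (A_bound + A_free), Hill-isotherm Kd fits, and
single-exponential exchange-rate fits of population-versus-time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from lmfit.models import GaussianModel

__all__ = [
    "PhotonStream",
    "Burst",
    "GaussianComponent",
    "KineticSeries",
    "TitrationCurve",
    "RateFit",
    "UndefinedRatioError",
    "FitError",
    "detect_bursts",
    "compute_es",
    "attach_es",
    "select_fret_species",
    "fit_fret_histogram",
    "fit_fret_mixture",
    "binding_fraction",
    "hill_theta",
    "fit_kd",
    "fractions_vs_time",
    "exchange_model",
    "fit_exchange_rate",
]

# Photon labels: excitation phase and detection channel are 0 = donor laser /
# donor channel, 1 = acceptor laser / acceptor channel.
DONOR, ACCEPTOR = 0, 1


class UndefinedRatioError(ZeroDivisionError):
    """A burst ratio (E or S) is undefined because its denominator is zero."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge; the message carries diagnostics."""


@dataclass
class PhotonStream:
    """Timestamped photon record from an ALEX measurement.

    ``excitation_phase`` and ``detection_channel`` are integer arrays aligned
    with ``timestamps`` (0 = donor, 1 = acceptor).  Timestamps are seconds
    from the start of acquisition and must be nondecreasing.
    """

    timestamps: np.ndarray
    excitation_phase: np.ndarray
    detection_channel: np.ndarray
    alternation_period: float = 100e-6
    duration: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.excitation_phase = np.asarray(self.excitation_phase, dtype=np.int8)
        self.detection_channel = np.asarray(self.detection_channel, dtype=np.int8)
        if not (
            len(self.timestamps)
            == len(self.excitation_phase)
            == len(self.detection_channel)
        ):
            raise ValueError("photon arrays must have equal length")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be nondecreasing")
        if self.duration is None:
            self.duration = float(self.timestamps[-1]) if len(self.timestamps) else 0.0

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class Burst:
    """One single-molecule transit with its three ALEX photon counts."""

    t_start: float
    t_end: float
    i_dd: int
    i_da: int
    i_aa: int
    e: float = math.nan
    s: float = math.nan
    true_species: str | None = None  # generator ground truth, None for real data

    @property
    def total(self) -> int:
        return self.i_dd + self.i_da + self.i_aa


@dataclass
class GaussianComponent:
    """One Gaussian population of a FRET histogram; area is in burst units."""

    mean: float
    sd: float
    area: float


@dataclass
class KineticSeries:
    """Per-time-bin species fractions (columns: free, SSB-bound, RecO-bound)."""

    bin_centers: np.ndarray
    fractions: np.ndarray  # shape (n_bins, n_species); NaN rows mark empty bins
    counts: np.ndarray
    species: tuple[str, ...] = ("free", "ssb_bound", "reco_bound")
    bursts: pd.DataFrame | None = None  # per-burst (time, e, s, true_species)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        occupied = self.counts > 0
        sums = self.fractions[occupied].sum(axis=1)
        if occupied.any() and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("fractions in occupied bins must sum to 1")


@dataclass
class TitrationCurve:
    """Concentration -> bound fraction series from a titration."""

    concentrations: np.ndarray  # molar
    theta: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta must lie in [0, 1]")


@dataclass
class RateFit:
    """Result of a rate/affinity fit: value, standard error, and model detail.

    ``rate`` carries the headline parameter in the units of ``units``
    (s^-1 for first-order rates, M^-1 s^-1 for association slopes, molar
    for dissociation constants).
    """

    rate: float
    uncertainty: float
    model: str
    units: str = "s^-1"
    params: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# burst detection and E/S
# ---------------------------------------------------------------------------

def detect_bursts(
    stream: PhotonStream,
    bin_time: float = 0.6e-3,
    count_threshold: int = 15,
    min_photons: int = 20,
) -> list[Burst]:
    """Find single-molecule bursts by fixed-bin thresholding.

    The photon record is binned at ``bin_time`` (0.6 ms matches the
    acquisition binning of the ALEX setup this emulates); contiguous runs of
    bins holding at least ``count_threshold`` photons become one burst each.
    Bursts with fewer than ``min_photons`` total photons are discarded.
    """
    if bin_time <= 0:
        raise ValueError("bin_time must be positive")
    if count_threshold <= 0:
        raise ValueError("count_threshold must be positive")
    if len(stream) == 0:
        return []

    duration = max(stream.duration or 0.0, float(stream.timestamps[-1]) + bin_time)
    edges = np.arange(0.0, duration + bin_time, bin_time)
    counts, _ = np.histogram(stream.timestamps, bins=edges)
    hot = counts >= count_threshold

    bursts: list[Burst] = []
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
    for start, stop in zip(boundaries[::2], boundaries[1::2]):
        t0, t1 = edges[start], edges[stop]
        sel = slice(
            np.searchsorted(stream.timestamps, t0, side="left"),
            np.searchsorted(stream.timestamps, t1, side="left"),
        )
        phase = stream.excitation_phase[sel]
        chan = stream.detection_channel[sel]
        i_dd = int(np.sum((phase == DONOR) & (chan == DONOR)))
        i_da = int(np.sum((phase == DONOR) & (chan == ACCEPTOR)))
        i_aa = int(np.sum((phase == ACCEPTOR) & (chan == ACCEPTOR)))
        if i_dd + i_da + i_aa < min_photons:
            continue
        bursts.append(Burst(t_start=float(t0), t_end=float(t1), i_dd=i_dd, i_da=i_da, i_aa=i_aa))
    attach_es(bursts, strict=False)
    return bursts


def compute_es(burst: Burst) -> tuple[float, float]:
    """Apparent FRET efficiency and stoichiometry of one burst.

    Raises :class:`UndefinedRatioError` when a denominator is zero, which is
    a different condition from E = 0 or S = 0 (e.g. an acceptor-only burst
    has no defined E at all).
    """
    dex = burst.i_dd + burst.i_da
    total = dex + burst.i_aa
    if dex <= 0:
        raise UndefinedRatioError("E undefined: no donor-excitation photons")
    if total <= 0:
        raise UndefinedRatioError("S undefined: burst has no photons")
    return burst.i_da / dex, dex / total


def attach_es(bursts: Sequence[Burst], strict: bool = True) -> Sequence[Burst]:
    """Fill the ``e``/``s`` fields of each burst in place.

    With ``strict=False`` undefined ratios are recorded as NaN instead of
    raising, so ensemble pipelines tolerate acceptor-only contaminants.
    """
    for b in bursts:
        try:
            b.e, b.s = compute_es(b)
        except UndefinedRatioError:
            if strict:
                raise
            total = b.total
            b.e = math.nan
            b.s = 0.0 if total > 0 else math.nan
    return bursts


def select_fret_species(
    bursts: Sequence[Burst], s_min: float = 0.25, s_max: float = 0.75
) -> list[Burst]:
    """Keep doubly labelled bursts: those with s_min < S < s_max (strict).

    The default gate 0.25 < S < 0.75 rejects donor-only (S ~ 1) and
    acceptor-only (S ~ 0) molecules.  Order is preserved and the operation
    is idempotent.
    """
    if s_min >= s_max:
        raise ValueError("s_min must be below s_max")
    return [b for b in bursts if s_min < b.s < s_max]


# ---------------------------------------------------------------------------
# histogram decomposition and bound fraction
# ---------------------------------------------------------------------------

def fit_fret_histogram(
    e_values: Sequence[float],
    n_components: int,
    bin_width: float = 0.02,
    init_means: Sequence[float] | None = None,
    sd_min: float = 1e-3,
) -> list[GaussianComponent]:
    """Decompose a 1-D FRET histogram into ``n_components`` Gaussians.

    The histogram (bin width 0.02 E units by default) is fitted by
    least squares with a sum of Gaussian peaks, mirroring how population
    areas are extracted from measured FRET histograms.  Component areas are
    returned in burst units (area under the peak divided by bin width), and
    components come back sorted by mean.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    e = np.asarray(e_values, dtype=float)
    e = e[np.isfinite(e)]
    if len(e) < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} values for {n_components} components, got {len(e)}"
        )

    if np.ptp(e) < sd_min:  # degenerate: a single spike
        comps = [GaussianComponent(mean=float(e.mean()), sd=sd_min, area=float(len(e)))]
        return comps * n_components if n_components == 1 else comps + [
            GaussianComponent(mean=float(e.mean()), sd=sd_min, area=0.0)
            for _ in range(n_components - 1)
        ]

    lo = min(0.0, e.min()) - bin_width
    hi = max(1.0, e.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(e, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if init_means is None:
        qs = (np.arange(n_components) + 0.5) / n_components
        init_means = np.quantile(e, qs)
    init_means = np.sort(np.asarray(init_means, dtype=float))

    model = None
    params = None
    for i, mu in enumerate(init_means):
        g = GaussianModel(prefix=f"g{i}_")
        p = g.make_params(
            center=mu,
            sigma=max(0.05, bin_width),
            amplitude=len(e) * bin_width / n_components,
        )
        p[f"g{i}_sigma"].set(min=sd_min, max=1.0)
        p[f"g{i}_amplitude"].set(min=0.0)
        p[f"g{i}_center"].set(min=lo, max=hi)
        if model is None:
            model, params = g, p
        else:
            model = model + g
            params.update(p)

    result = model.fit(counts, params, x=centers)
    if not result.success:
        raise FitError(f"histogram fit did not converge: {result.message}")

    comps = [
        GaussianComponent(
            mean=float(result.params[f"g{i}_center"].value),
            sd=float(result.params[f"g{i}_sigma"].value),
            area=float(result.params[f"g{i}_amplitude"].value) / bin_width,
        )
        for i in range(n_components)
    ]
    comps.sort(key=lambda c: c.mean)
    return comps


def fit_fret_mixture(
    e_values: Sequence[float], n_components: int, seed: int = 0
) -> list[GaussianComponent]:
    """Likelihood-based cross-check of :func:`fit_fret_histogram`.

    Fits a Gaussian mixture to the raw E values by EM; areas are the mixture
    weights scaled to burst counts.  Used to confirm that binning does not
    bias the histogram decomposition.
    """
    from sklearn.mixture import GaussianMixture

    e = np.asarray(e_values, dtype=float)
    e = e[np.isfinite(e)].reshape(-1, 1)
    gm = GaussianMixture(n_components=n_components, random_state=seed, n_init=3).fit(e)
    comps = [
        GaussianComponent(
            mean=float(m), sd=float(np.sqrt(v)), area=float(w * len(e))
        )
        for m, v, w in zip(gm.means_.ravel(), gm.covariances_.ravel(), gm.weights_)
    ]
    comps.sort(key=lambda c: c.mean)
    return comps


def binding_fraction(
    components: Sequence[GaussianComponent], bound_index: int, free_index: int
) -> float:
    """Bound fraction theta = A_bound / (A_bound + A_free) from fitted areas."""
    a_bound = components[bound_index].area
    a_free = components[free_index].area
    if a_bound + a_free <= 0:
        raise ValueError("both component areas are zero; theta undefined")
    return a_bound / (a_bound + a_free)


# ---------------------------------------------------------------------------
# Hill isotherm
# ---------------------------------------------------------------------------

def hill_theta(c: np.ndarray, kd: float, n: float) -> np.ndarray:
    """Hill binding isotherm theta(C) = C^n / (Kd^n + C^n)."""
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = c[pos] ** n / (kd**n + c[pos] ** n)
    return out


def fit_kd(curve: TitrationCurve, fix_hill_n: float | None = None) -> RateFit:
    """Fit the Hill equation to a titration and return Kd with its error.

    Kd is the half-saturation concentration: theta(Kd) = 0.5 identically
    under the Hill form, so the fitted Kd is directly the concentration at
    which half the ssDNA is bound.  The Hill coefficient floats by default;
    pass ``fix_hill_n`` to pin it (n = 1 for noncooperative binding).
    A curve that never crosses theta = 0.5 yields an extrapolated Kd and is
    flagged as such.
    """
    if len(curve.concentrations) < 4:
        raise ValueError("need at least 4 concentration points")

    model = Model(hill_theta, independent_vars=["c"])
    pos = curve.concentrations[curve.concentrations > 0]
    kd0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    params = model.make_params(kd=kd0, n=1.0)
    params["kd"].set(min=1e-30)
    params["n"].set(min=0.1, max=10.0)
    if fix_hill_n is not None:
        params["n"].set(value=fix_hill_n, vary=False)

    result = model.fit(curve.theta, params, c=curve.concentrations)
    if not result.success:
        raise FitError(f"Hill fit did not converge: {result.message}")

    flags = []
    if curve.theta.max() < 0.5:
        flags.append("extrapolated_kd")
    kd = float(result.params["kd"].value)
    err = float(result.params["kd"].stderr or 0.0)
    return RateFit(
        rate=kd,
        uncertainty=err,
        model="hill",
        units="M",
        params={
            "n": float(result.params["n"].value),
            "n_stderr": float(result.params["n"].stderr or 0.0),
            "theta_at_kd": 0.5,
        },
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# population kinetics
# ---------------------------------------------------------------------------

def fractions_vs_time(
    bursts_with_times: pd.DataFrame,
    species_windows: Sequence[tuple[float, float]],
    bin_width: float,
    species: Sequence[str] = ("free", "ssb_bound", "reco_bound"),
) -> KineticSeries:
    """Per-time-bin species fractions from burst E values.

    ``bursts_with_times`` needs columns ``time`` and ``e``.  Each species is
    an E window (lo, hi); windows must be disjoint.  Bursts falling outside
    every window are excluded from the denominator; bins with no in-window
    bursts get NaN fractions and count 0 (flagged empty).
    """
    windows = [tuple(map(float, w)) for w in species_windows]
    for (lo1, hi1), (lo2, hi2) in zip(sorted(windows), sorted(windows)[1:]):
        if hi1 > lo2:
            raise ValueError("species windows must be disjoint")
    if len(windows) != len(species):
        raise ValueError("one window per species required")

    t = np.asarray(bursts_with_times["time"], dtype=float)
    e = np.asarray(bursts_with_times["e"], dtype=float)
    t_max = t.max() if len(t) else bin_width
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    if edges[-1] <= t_max:
        edges = np.append(edges, edges[-1] + bin_width)
    n_bins = len(edges) - 1

    which = np.full(len(e), -1)
    for i, (lo, hi) in enumerate(windows):
        which[(e >= lo) & (e < hi)] = i
    in_window = which >= 0

    bin_idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    fractions = np.full((n_bins, len(windows)), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = (bin_idx == b) & in_window
        n = int(sel.sum())
        counts[b] = n
        if n:
            fractions[b] = [np.sum(which[sel] == i) / n for i in range(len(windows))]

    centers = 0.5 * (edges[:-1] + edges[1:])
    return KineticSeries(
        bin_centers=centers, fractions=fractions, counts=counts, species=tuple(species)
    )


def exchange_model(t: np.ndarray, k: float, f0: float, f_inf: float) -> np.ndarray:
    """Single-exponential relaxation f(t) = f_inf + (f0 - f_inf) exp(-k t)."""
    return f_inf + (f0 - f_inf) * np.exp(-k * np.asarray(t, dtype=float))


def fit_exchange_rate(
    series: KineticSeries,
    species_index: int = 1,
    fix_plateau: float | None = None,
    min_amplitude: float = 0.05,
) -> RateFit:
    """Fit the decay of one species fraction with a single exponential.

    The default ``species_index`` 1 follows the SSB-bound population, whose
    first-order replacement by RecO under excess ligand gives
    f(t) = f_inf + (f0 - f_inf) exp(-k t).  The plateau f_inf floats unless
    ``fix_plateau`` pins it (0 for complete exchange).  Bins are weighted by
    their inverse binomial variance f(1-f)/n, so sparsely and densely
    sampled bins contribute proportionately.  A series whose fitted
    amplitude is below ``min_amplitude`` is flagged ``no_exchange``.
    """
    mask = series.counts > 0
    if mask.sum() < 5:
        raise ValueError("need at least 5 occupied time bins")
    t = series.bin_centers[mask]
    f = series.fractions[mask, species_index]

    # Variable-projection initial search: for each candidate k the model is
    # linear in (f0, f_inf), so scan k on a log grid and keep the best
    # linear solution.  This keeps the refinement out of the f0 = 1 corner
    # when the first bin sits well after t = 0.
    span = float(t.max() - t.min()) or 1.0
    best = (np.inf, 2.0 / span, float(f[0]), float(f[-1]))
    for k_try in np.geomspace(0.05 / span, 50.0 / span, 40):
        basis = np.column_stack([np.exp(-k_try * t), np.ones_like(t)])
        (amp, off), ssr, *_ = np.linalg.lstsq(basis, f, rcond=None)
        ssr = float(np.sum((basis @ [amp, off] - f) ** 2))
        if ssr < best[0]:
            # keep inits strictly inside the [0, 1] bounds: a parameter
            # starting exactly on a bound is frozen by the fit machinery
            best = (
                ssr,
                k_try,
                float(np.clip(amp + off, 1e-6, 1 - 1e-6)),
                float(np.clip(off, 1e-6, 1 - 1e-6)),
            )
    _, k0, f0_init, finf_init = best

    model = Model(exchange_model, independent_vars=["t"])
    params = model.make_params(k=k0, f0=f0_init, f_inf=finf_init)
    params["k"].set(min=0.0)
    params["f0"].set(min=0.0, max=1.0)
    params["f_inf"].set(min=0.0, max=1.0)
    if fix_plateau is not None:
        params["f_inf"].set(value=fix_plateau, vary=False)

    n = series.counts[mask].astype(float)
    var = np.clip(f * (1 - f), 1e-3, None) / n
    # trust-region reflective handles the box bounds without the parameter
    # transformation that stalls MINPACK on exactly-solvable input
    result = model.fit(
        f, params, t=t, weights=1.0 / np.sqrt(var), method="least_squares"
    )
    if not result.success:
        raise FitError(f"exchange fit did not converge: {result.message}")

    k = float(result.params["k"].value)
    f0 = float(result.params["f0"].value)
    f_inf = float(result.params["f_inf"].value)
    flags = []
    if abs(f0 - f_inf) < min_amplitude:
        flags.append("no_exchange")
    return RateFit(
        rate=k,
        uncertainty=float(result.params["k"].stderr or 0.0),
        model="single_exponential",
        units="s^-1",
        params={"f0": f0, "f_inf": f_inf, "half_life": math.log(2) / k if k > 0 else math.inf},
        flags=tuple(flags),
    )
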