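"""Synthetic single-molecule data with known ground truth.

Every input the analysis consumes can be generated here with its generating
parameters attached, so each downstream stage is verifiable by parameter
recovery: ALEX burst ensembles from mixtures of FRET species, titration
curves from a Hill isotherm, population-exchange time series, TIRF intensity
traces from a continuous-time Markov chain over FRET states (with an
injection event, channel noise and irreversible photobleaching), exponential
binding-time samples, and two-color colocalization pair trajectories with
optional rendered image stacks.

Defaults emulate the measurement conditions the analysis was designed for:
0.6 ms ALEX binning with 100 us laser alternation, 100 ms TIRF frames with
5 min records, species centered at E = 0.09 (bare dT70 ssDNA), 0.58
(SSB-coated) and 0.78 (RecO-bound), and a 70-nt poly-dT substrate probed at
50-100 pM.  All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burst import Burst, KineticSeries, PhotonStream, TitrationCurve, attach_es

__all__ = [
    "SpeciesSpec",
    "AlexSimConfig",
    "TraceSimConfig",
    "ColocSimConfig",
    "FretTrace",
    "ColocSim",
    "simulate_alex_bursts",
    "simulate_exchange_series",
    "simulate_titration",
    "simulate_trace",
    "simulate_binding_times",
    "simulate_coloc",
    "render_spots",
    "DEFAULT_SPECIES_E",
]

# Population centers of the three-species system: bare dT70 ssDNA, the
# SSB-ssDNA complex, and the RecO-ssDNA complex.
DEFAULT_SPECIES_E = {"free": 0.09, "ssb_bound": 0.58, "reco_bound": 0.78}


@dataclass
class SpeciesSpec:
    """One FRET species of a burst mixture: (E, S) center, width, and weight."""

    name: str
    e_mean: float
    e_sd: float
    s_mean: float
    s_sd: float
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_mean <= 1.0 and 0.0 <= self.s_mean <= 1.0):
            raise ValueError("e_mean and s_mean must lie in [0, 1]")
        if self.e_sd <= 0 or self.s_sd <= 0:
            raise ValueError("e_sd and s_sd must be positive")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class AlexSimConfig:
    """Configuration of an ALEX burst-ensemble simulation.

    Bursts are generated at the count level by default: the total photon
    number of a burst is a shifted Poisson (minimum ``burst_size_min``
    photons, mean ``burst_size_mean``), split into the three detection
    streams by nested binomial draws — a fraction S lands in the
    donor-excitation phase and a fraction E of those in the acceptor
    channel.  ``background_rate`` is photons per bin per channel.
    """

    species: list[SpeciesSpec]
    n_bursts: int = 10_000
    burst_size_mean: float = 100.0
    burst_size_min: int = 20
    background_rate: float = 0.0
    bin_time: float = 0.6e-3
    duration: float = 600.0
    alternation_period: float = 100e-6
    burst_duration: float = 1.2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bursts < 0:
            raise ValueError("n_bursts must be >= 0")
        if self.burst_size_mean <= 0 or self.bin_time <= 0:
            raise ValueError("burst_size_mean and bin_time must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        total = sum(sp.fraction for sp in self.species)
        if self.species and abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1 (got {total})")


@dataclass
class TraceSimConfig:
    """Configuration of a TIRF trace simulation.

    ``states`` lists (label, e_mean, e_sd); ``rate_matrix`` holds first-order
    transition rates in s^-1 (off-diagonals; diagonal ignored).  The hidden
    state path is a continuous-time Markov chain sampled at ``frame_interval``
    (100 ms default).  Before ``injection_time`` the chain is held in
    ``initial_state`` — injection models the flow-channel solution exchange
    as an instantaneous switch-on of the rate matrix.  Per-frame intensities
    are donor = I(1-E) and acceptor = I·E with Gaussian channel noise;
    photobleaching is one irreversible exponential step per channel.
    """

    states: list[tuple[str, float, float]]
    rate_matrix: np.ndarray
    frame_interval: float = 0.1
    duration: float = 300.0
    injection_time: float = 0.0
    initial_state: int = 0
    total_intensity: float = 1000.0
    noise_sd: float = 30.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.states)
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix must be square over the state list")
        off = self.rate_matrix[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("rate_matrix off-diagonals must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0.0 <= self.injection_time <= self.duration):
            raise ValueError("need duration >= injection_time >= 0")


@dataclass
class ColocSimConfig:
    """Configuration of a two-color colocalization simulation.

    Each donor-channel spot (labelled DNA) starts with a colocalized
    acceptor-channel partner (labelled protein); the partner disappears at
    the earlier of an acceptor photobleaching event and a dissociation
    event, both exponential.  In ``image_mode`` the pair set is additionally
    rendered into two image stacks with Gaussian point-spread-function spots
    (channel B shifted by ``channel_offset``) and Poisson counting noise.
    """

    n_pairs: int = 100
    acceptor_bleach_rate: float = 0.0
    dissociation_rate: float = 0.0
    duration: float = 300.0
    frame_interval: float = 1.0
    image_mode: bool = False
    psf_sigma: float = 1.2
    image_shape: tuple[int, int] = (64, 64)
    spot_photons: float = 2000.0
    background: float = 10.0
    channel_offset: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acceptor_bleach_rate < 0 or self.dissociation_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.image_mode and self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive in image mode")


@dataclass
class FretTrace:
    """Two-channel TIRF intensity time series at a fixed frame interval.

    ``truth`` carries generator ground truth (per-frame state indices, the
    continuous-time path, bleach times) and is None for real data.
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    injection_time: float | None = None
    metadata: dict = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("channels must have equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ColocSim:
    """Colocalization pair trajectories with ground truth, optionally images."""

    times: np.ndarray
    presence: np.ndarray  # (n_pairs, n_frames) bool: both partners present
    truth: pd.DataFrame  # per pair: t_bleach, t_diss, t_loss, x, y
    stack_a: np.ndarray | None = None
    stack_b: np.ndarray | None = None


# ---------------------------------------------------------------------------
# ALEX bursts
# ---------------------------------------------------------------------------

def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, size=None
) -> np.ndarray | float:
    """Normal(mean, sd) truncated to [0, 1] — no point mass at the edges."""
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_alex_bursts(
    config: AlexSimConfig, return_stream: bool = False
) -> list[Burst] | tuple[list[Burst], PhotonStream]:
    """Draw an ALEX burst ensemble from a mixture of FRET species.

    Each burst picks a species by mixture weight, jitters its (E, S) around
    the species center (Gaussian, truncated to [0, 1]), draws a total photon
    count, and splits it by nested binomials.  With ``return_stream`` the
    bursts are also placed at random times in the record and expanded into a
    timestamped photon stream whose excitation phases are consistent with
    the laser alternation period, for exercising burst detection.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_bursts
    weights = np.array([sp.fraction for sp in config.species])
    idx = rng.choice(len(config.species), size=n, p=weights)

    sizes = config.burst_size_min + rng.poisson(
        max(config.burst_size_mean - config.burst_size_min, 0.0), size=n
    )
    n_bg_bins = max(int(round(config.burst_duration / config.bin_time)), 1)

    # The species e_sd/s_sd parameterize the OBSERVED histogram widths; the
    # binomial photon split already contributes shot variance
    # ~ e(1-e) / (s * size_mean), so the per-burst jitter is drawn with that
    # expected contribution deconvolved (floored at zero when shot noise
    # alone reaches the requested width).
    jitter = []
    for sp in config.species:
        n_dex = max(sp.s_mean * config.burst_size_mean, 1.0)
        e_shot = sp.e_mean * (1.0 - sp.e_mean) / n_dex
        s_shot = sp.s_mean * (1.0 - sp.s_mean) / max(config.burst_size_mean, 1.0)
        jitter.append(
            (
                math.sqrt(max(sp.e_sd**2 - e_shot, 0.0)),
                math.sqrt(max(sp.s_sd**2 - s_shot, 0.0)),
            )
        )

    t_starts = np.sort(rng.uniform(0.0, config.duration, size=n))
    bursts: list[Burst] = []
    for j in range(n):
        sp = config.species[idx[j]]
        e_j, s_j = jitter[idx[j]]
        e = float(_truncnorm(rng, sp.e_mean, e_j)) if e_j > 0 else sp.e_mean
        s = float(_truncnorm(rng, sp.s_mean, s_j)) if s_j > 0 else sp.s_mean
        size = int(sizes[j])
        n_dex = rng.binomial(size, s)
        i_da = rng.binomial(n_dex, e)
        i_dd = n_dex - i_da
        i_aa = size - n_dex
        if config.background_rate > 0:
            bg = rng.poisson(config.background_rate * n_bg_bins, size=3)
            i_dd += bg[0]
            i_da += bg[1]
            i_aa += bg[2]
        bursts.append(
            Burst(
                t_start=float(t_starts[j]),
                t_end=float(t_starts[j] + config.burst_duration),
                i_dd=int(i_dd),
                i_da=int(i_da),
                i_aa=int(i_aa),
                true_species=sp.name,
            )
        )
    attach_es(bursts, strict=False)

    if not return_stream:
        return bursts

    ts, phase, chan = [], [], []
    half = config.alternation_period / 2.0
    for b in bursts:
        for count, (ph, ch) in (
            (b.i_dd, (0, 0)),
            (b.i_da, (0, 1)),
            (b.i_aa, (1, 1)),
        ):
            if count == 0:
                continue
            base = rng.uniform(b.t_start, b.t_end, size=count)
            # snap each photon into the half-period of its excitation phase
            cycle = np.floor(base / config.alternation_period) * config.alternation_period
            t = cycle + rng.uniform(0.0, half, size=count) + (half if ph else 0.0)
            ts.append(t)
            phase.append(np.full(count, ph, dtype=np.int8))
            chan.append(np.full(count, ch, dtype=np.int8))
    if ts:
        ts = np.concatenate(ts)
        order = np.argsort(ts, kind="stable")
        stream = PhotonStream(
            timestamps=ts[order],
            excitation_phase=np.concatenate(phase)[order],
            detection_channel=np.concatenate(chan)[order],
            alternation_period=config.alternation_period,
            duration=config.duration,
        )
    else:
        stream = PhotonStream(
            timestamps=np.empty(0),
            excitation_phase=np.empty(0, dtype=np.int8),
            detection_channel=np.empty(0, dtype=np.int8),
            alternation_period=config.alternation_period,
            duration=config.duration,
        )
    return bursts, stream


# ---------------------------------------------------------------------------
# exchange kinetics and titrations
# ---------------------------------------------------------------------------

def simulate_exchange_series(
    k_exch: float,
    f_ssb0: float,
    f_free: float,
    time_bins: np.ndarray,
    bursts_per_bin: int,
    seed: int = 0,
    f_ssb_inf: float = 0.0,
    species_e: tuple[float, float, float] = (0.09, 0.58, 0.78),
    e_sd: float = 0.07,
    bin_width: float | None = None,
    return_bursts: bool = True,
) -> KineticSeries:
    """Population time course of the SSB-to-RecO exchange on ssDNA.

    Within the bound pool (fraction ``1 - f_free`` of molecules, constant in
    time) the SSB-bound share relaxes as

        f(t) = f_inf + (f0 - f_inf) exp(-k_exch t)

    with the RecO-bound share rising complementarily.  Observed per-bin
    fractions are multinomial draws of ``bursts_per_bin`` bursts.  With
    ``return_bursts`` the series also carries a burst table (time, e, s,
    true_species) whose E values are Gaussian around ``species_e``, so the
    full histogram pipeline can be run on it.  Burst times are spread
    uniformly across each bin (molecules diffuse through the detection spot
    throughout the acquisition window); ``bin_width`` defaults to the
    spacing of ``time_bins``.
    """
    if k_exch < 0:
        raise ValueError("k_exch must be >= 0")
    if not (0.0 <= f_ssb0 <= 1.0 and 0.0 <= f_free <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    time_bins = np.asarray(time_bins, dtype=float)
    if len(time_bins) == 0:
        raise ValueError("time_bins must be nonempty")

    rng = np.random.default_rng(seed)
    bound = 1.0 - f_free
    f_ssb = bound * (f_ssb_inf + (f_ssb0 - f_ssb_inf) * np.exp(-k_exch * time_bins))
    probs = np.column_stack([np.full_like(f_ssb, f_free), f_ssb, bound - f_ssb])
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)

    names = ("free", "ssb_bound", "reco_bound")
    counts = np.array([rng.multinomial(bursts_per_bin, p) for p in probs])
    fractions = counts / counts.sum(axis=1, keepdims=True)

    if bin_width is None:
        bin_width = float(np.median(np.diff(time_bins))) if len(time_bins) > 1 else 0.0

    bursts = None
    if return_bursts:
        rows = []
        for t, row in zip(time_bins, counts):
            for sp, c in enumerate(row):
                if c == 0:
                    continue
                e = _truncnorm(rng, species_e[sp], e_sd, size=c)
                s = _truncnorm(rng, 0.5, 0.05, size=c)
                times = (
                    rng.uniform(t - bin_width / 2, t + bin_width / 2, size=c)
                    if bin_width > 0
                    else np.full(c, t)
                )
                rows.append(
                    pd.DataFrame(
                        {"time": times, "e": e, "s": s, "true_species": names[sp]}
                    )
                )
        bursts = pd.concat(rows, ignore_index=True)

    return KineticSeries(
        bin_centers=time_bins,
        fractions=fractions,
        counts=np.full(len(time_bins), bursts_per_bin),
        species=names,
        bursts=bursts,
    )


def simulate_titration(
    kd: float,
    hill_n: float,
    concentrations: np.ndarray,
    bursts_per_point: int | None,
    seed: int = 0,
) -> TitrationCurve:
    """Concentration series of bound fractions from a Hill isotherm.

    Expected theta(C) = C^n / (Kd^n + C^n); the observed fraction at each
    concentration is a binomial draw over ``bursts_per_point`` bursts, or
    the exact expectation when ``bursts_per_point`` is None (noiseless).
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be >= 0")
    theta = concentrations**hill_n / (kd**hill_n + concentrations**hill_n)
    theta = np.where(concentrations > 0, theta, 0.0)
    if bursts_per_point is None:
        return TitrationCurve(concentrations, theta, np.zeros(len(theta), dtype=int))
    rng = np.random.default_rng(seed)
    obs = rng.binomial(bursts_per_point, theta) / bursts_per_point
    return TitrationCurve(
        concentrations, obs, np.full(len(theta), bursts_per_point)
    )


# ---------------------------------------------------------------------------
# TIRF traces
# ---------------------------------------------------------------------------

def _sample_ctmc(
    rng: np.random.Generator,
    rates: np.ndarray,
    state0: int,
    t0: float,
    t_end: float,
) -> list[tuple[float, int]]:
    """Gillespie path of a continuous-time Markov chain on [t0, t_end)."""
    path = [(t0, state0)]
    t, s = t0, state0
    while True:
        out = rates[s].copy()
        out[s] = 0.0
        total = out.sum()
        if total <= 0:
            break
        t = t + rng.exponential(1.0 / total)
        if t >= t_end:
            break
        s = int(rng.choice(len(out), p=out / total))
        path.append((t, s))
    return path


def simulate_trace(config: TraceSimConfig) -> FretTrace:
    """One TIRF FRET trace from a hidden Markov state path.

    The chain is held in ``initial_state`` until ``injection_time``, then
    evolves under ``rate_matrix``.  Acceptor bleaching reroutes all signal
    to the donor channel (FRET lost); donor bleaching silences both.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.frame_interval))
    time = np.arange(n_frames) * config.frame_interval

    path = _sample_ctmc(
        rng, config.rate_matrix, config.initial_state, config.injection_time, config.duration
    )
    change_times = np.array([t for t, _ in path])
    change_states = np.array([s for _, s in path])
    # state at each frame start; frames before injection sit in the initial state
    frame_state = change_states[
        np.clip(np.searchsorted(change_times, time, side="right") - 1, 0, None)
    ]
    frame_state[time < config.injection_time] = config.initial_state

    t_dbleach = (
        rng.exponential(1.0 / config.donor_bleach_rate)
        if config.donor_bleach_rate > 0
        else math.inf
    )
    t_ableach = (
        rng.exponential(1.0 / config.acceptor_bleach_rate)
        if config.acceptor_bleach_rate > 0
        else math.inf
    )

    e_means = np.array([e for _, e, _ in config.states])
    e_sds = np.array([sd for _, _, sd in config.states])
    e_frame = np.clip(
        rng.normal(e_means[frame_state], e_sds[frame_state]), 0.0, 1.0
    )

    acceptor = config.total_intensity * e_frame
    donor = config.total_intensity * (1.0 - e_frame)
    lost_fret = time >= t_ableach
    acceptor[lost_fret] = 0.0
    donor[lost_fret] = config.total_intensity
    dark = time >= t_dbleach
    acceptor[dark] = 0.0
    donor[dark] = 0.0
    acceptor = acceptor + rng.normal(0.0, config.noise_sd, size=n_frames)
    donor = donor + rng.normal(0.0, config.noise_sd, size=n_frames)

    return FretTrace(
        time=time,
        donor=donor,
        acceptor=acceptor,
        frame_interval=config.frame_interval,
        injection_time=config.injection_time,
        metadata={"n_states": len(config.states)},
        truth={
            "frame_state": frame_state,
            "path": path,
            "state_labels": [lbl for lbl, _, _ in config.states],
            "t_donor_bleach": t_dbleach,
            "t_acceptor_bleach": t_ableach,
        },
    )


def simulate_binding_times(
    k_a: float,
    concentrations: np.ndarray,
    n_per_conc: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential waiting times for binding at pseudo-first-order rates.

    At ligand concentration C the waiting time to the first binding event is
    exponential with rate k_a * C (k_a in M^-1 s^-1, C in molar).  Returns a
    table with columns ``concentration`` and ``waiting_time``.
    """
    if k_a <= 0:
        raise ValueError("k_a must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for c in np.asarray(concentrations, dtype=float):
        w = rng.exponential(1.0 / (k_a * c), size=n_per_conc)
        frames.append(pd.DataFrame({"concentration": c, "waiting_time": w}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def render_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    psf_sigma: float,
    spot_photons: float,
    background: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render Gaussian PSF spots plus Poisson noise on one frame.

    Positions are (x, y) in pixel-center convention; the spot integral is
    ``spot_photons`` counts over the frame.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    norm = spot_photons / (2.0 * math.pi * psf_sigma**2)
    for x, y in np.atleast_2d(positions):
        img += norm * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * psf_sigma**2))
    return rng.poisson(img).astype(float)


def simulate_coloc(config: ColocSimConfig) -> ColocSim:
    """Paired two-color presence trajectories, optionally with image stacks.

    Each pair starts colocalized; the acceptor partner is lost at
    t_loss = min(bleach, dissociation), each exponential with its configured
    rate (infinite when the rate is zero).  ``presence[i, j]`` is True while
    both partners of pair i are present in frame j.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.frame_interval)) + 1
    times = np.arange(n_frames) * config.frame_interval

    def draw(rate: float) -> np.ndarray:
        if rate <= 0:
            return np.full(config.n_pairs, math.inf)
        return rng.exponential(1.0 / rate, size=config.n_pairs)

    t_bleach = draw(config.acceptor_bleach_rate)
    t_diss = draw(config.dissociation_rate)
    t_loss = np.minimum(t_bleach, t_diss)
    presence = times[None, :] < t_loss[:, None]

    h, w = config.image_shape
    margin = 4.0 * config.psf_sigma + max(abs(config.channel_offset[0]), abs(config.channel_offset[1]))
    # sparse surface: spots rejection-sampled to stay optically resolvable
    min_sep = 4.0 * config.psf_sigma
    xs, ys = [], []
    while len(xs) < config.n_pairs:
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if config.image_mode and any(
            (cx - px) ** 2 + (cy - py) ** 2 < min_sep**2 for px, py in zip(xs, ys)
        ):
            continue
        xs.append(cx)
        ys.append(cy)
    x, y = np.array(xs), np.array(ys)
    truth = pd.DataFrame(
        {"t_bleach": t_bleach, "t_diss": t_diss, "t_loss": t_loss, "x": x, "y": y}
    )

    stack_a = stack_b = None
    if config.image_mode:
        pos_a = np.column_stack([x, y])
        pos_b = pos_a + np.asarray(config.channel_offset)
        stack_a = np.empty((n_frames, h, w))
        stack_b = np.empty((n_frames, h, w))
        for j in range(n_frames):
            stack_a[j] = render_spots(
                (h, w), pos_a, config.psf_sigma, config.spot_photons, config.background, rng
            )
            present = presence[:, j]
            stack_b[j] = render_spots(
                (h, w),
                pos_b[present] if present.any() else np.empty((0, 2)),
                config.psf_sigma,
                config.spot_photons,
                config.background,
                rng,
            )
    return ColocSim(times=times, presence=presence, truth=truth, stack_a=stack_a, stack_b=stack_b)
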