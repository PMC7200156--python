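"""TIRF smFRET trace analysis: segmentation, kinetics and classification.

Surface-tethered ssDNA carrying a donor/acceptor pair reports protein
binding through discrete FRET levels: ~0.2 for bare ssDNA (and for the
stretched intermediate of the displacement reaction), ~0.6 for the
SSB-coated complex and ~0.8 for the RecO-bound complex.  Traces are
segmented by nearest-level thresholding, dwell times are fitted with single
exponentials, binding times after solution injection give pseudo-first-order
association rates whose concentration dependence yields the second-order
constant, and each displacement trace is classified by its post-injection
path (direct SSB->RecO handoff versus passage through the low-FRET
intermediate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .burst import RateFit
from .synthetic import FretTrace

__all__ = [
    "StateSegmentation",
    "Dwell",
    "TraceCategory",
    "TraceClass",
    "compute_trace_fret",
    "alive_span",
    "filter_traces",
    "segment_states",
    "find_binding_time",
    "fit_dwell_rate",
    "fit_association_constant",
    "classify_trace",
    "classification_summary",
]

UNASSIGNED = -1


@dataclass
class Dwell:
    """An uninterrupted visit to one FRET level."""

    state: int  # index into level_centers
    t_start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class StateSegmentation:
    """Per-frame state labels plus the ordered dwell list of a trace."""

    labels: np.ndarray  # per-frame level index, UNASSIGNED where no level fits
    level_centers: np.ndarray
    frame_interval: float
    dwells: list[Dwell] = field(default_factory=list)

    @property
    def level_names(self) -> list[str]:
        """LOW/MID/HIGH naming by ascending level center (2 levels: LOW/HIGH)."""
        order = np.argsort(self.level_centers)
        names = (
            ["LOW", "HIGH"] if len(order) == 2 else ["LOW", "MID", "HIGH"][: len(order)]
        )
        out = [""] * len(order)
        for name, idx in zip(names, order):
            out[idx] = name
        return out


class TraceCategory(str, Enum):
    NO_BINDING = "NO_BINDING"
    DISPLACEMENT_DIRECT = "DISPLACEMENT_DIRECT"
    DISPLACEMENT_VIA_INTERMEDIATE = "DISPLACEMENT_VIA_INTERMEDIATE"
    INTERMEDIATE_RETURN = "INTERMEDIATE_RETURN"
    MULTI_TRANSITION = "MULTI_TRANSITION"


@dataclass
class TraceClass:
    """Displacement-pathway classification of one trace."""

    category: TraceCategory
    n_low_visits: int = 0
    n_high_transitions: int = 0

    def __post_init__(self) -> None:
        if (
            self.category is TraceCategory.DISPLACEMENT_VIA_INTERMEDIATE
            and self.n_low_visits < 1
        ):
            raise ValueError("via-intermediate requires at least one LOW visit")


# ---------------------------------------------------------------------------
# FRET computation and trace selection
# ---------------------------------------------------------------------------

def compute_trace_fret(
    trace: FretTrace, background_floor: float | None = None
) -> np.ndarray:
    """Per-frame apparent FRET efficiency E = acceptor / (donor + acceptor).

    Frames whose total intensity falls below ``background_floor`` (default:
    20% of the 95th-percentile total, which tracks the unbleached plateau
    even when most of the record is post-bleach) get NaN instead of a
    spurious ratio.
    """
    total = trace.donor + trace.acceptor
    if not np.any(total > 0):
        raise ValueError("trace has no signal in either channel")
    if background_floor is None:
        background_floor = 0.2 * float(np.percentile(total, 95))
    e = np.full(len(trace), np.nan)
    ok = total > background_floor
    e[ok] = trace.acceptor[ok] / total[ok]
    return e


def alive_span(trace: FretTrace, background_floor: float | None = None) -> float:
    """Seconds from the start of the trace to its last above-floor frame."""
    e = compute_trace_fret(trace, background_floor)
    alive = np.flatnonzero(np.isfinite(e))
    if len(alive) == 0:
        return 0.0
    return float(trace.time[alive[-1]] + trace.frame_interval)


def filter_traces(
    traces: Sequence[FretTrace],
    min_duration: float = 210.0,
    background_floor: float | None = None,
) -> list[FretTrace]:
    """Keep traces whose unbleached span is at least ``min_duration`` seconds.

    The 3.5 min default excludes dye-bleaching events from binding-fraction
    counts while leaving enough record to observe slow association.
    """
    return [
        t for t in traces if alive_span(t, background_floor) >= min_duration
    ]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (start, length, value)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i - start, int(labels[start])))
            start = i
    return out


def segment_states(
    e_series: np.ndarray,
    level_centers: Sequence[float],
    half_width: float = 0.12,
    min_dwell_frames: int = 3,
    frame_interval: float = 0.1,
) -> StateSegmentation:
    """Threshold-segment an E series into discrete FRET levels.

    Each frame is assigned to the nearest level within ``half_width``, else
    UNASSIGNED; levels must be separated by more than the half width so the
    nearest assignment is unambiguous away from window midpoints (ties at a
    midpoint go to the lower level).  Runs shorter than ``min_dwell_frames``
    are merged into a flanking state (the earlier one on a tie), which
    rejects single-frame shot-noise excursions while keeping the shortest
    genuine intermediate dwells.  Dwells are emitted for assigned runs.
    """
    if np.any(np.diff(np.sort(level_centers)) <= half_width):
        raise ValueError("level centers must be separated by more than half_width")
    centers = np.asarray(level_centers, dtype=float)  # keep caller order

    e = np.asarray(e_series, dtype=float)
    dist = np.abs(e[:, None] - centers[None, :])
    nearest = np.nanargmin(np.where(np.isnan(dist), np.inf, dist), axis=1)
    labels = np.where(
        np.isfinite(e) & (dist[np.arange(len(e)), nearest] <= half_width),
        nearest,
        UNASSIGNED,
    ).astype(int)

    # iteratively absorb short runs into a flanking state
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        for i, (start, length, _val) in enumerate(runs):
            if length >= min_dwell_frames:
                continue
            prev_val = runs[i - 1][2] if i > 0 else None
            next_val = runs[i + 1][2] if i + 1 < len(runs) else None
            prev_len = runs[i - 1][1] if i > 0 else -1
            next_len = runs[i + 1][1] if i + 1 < len(runs) else -1
            if prev_val is None and next_val is None:
                continue
            if next_val is None or (prev_val is not None and prev_len >= next_len):
                new = prev_val  # tie -> earlier state
            else:
                new = next_val
            labels[start : start + length] = new
            changed = True
            break

    dwells = [
        Dwell(state=val, t_start=start * frame_interval, duration=length * frame_interval)
        for start, length, val in _runs(labels)
        if val != UNASSIGNED
    ]
    return StateSegmentation(
        labels=labels,
        level_centers=centers,
        frame_interval=frame_interval,
        dwells=dwells,
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def find_binding_time(
    seg: StateSegmentation,
    injection_time: float,
    target_state: int,
    min_stable_frames: int = 3,
) -> float:
    """Waiting time from injection to the first stable visit of a state.

    Returns NaN when the trace never reaches ``target_state`` after
    injection (the no-binding outcome).  A dwell counts as stable when it
    lasts at least ``min_stable_frames`` frames.
    """
    t_total = len(seg.labels) * seg.frame_interval
    if not (0.0 <= injection_time <= t_total):
        raise ValueError("injection_time must fall within the trace")
    min_len = min_stable_frames * seg.frame_interval
    for d in seg.dwells:
        if (
            d.state == target_state
            and d.t_start + d.duration > injection_time
            and d.duration >= min_len
        ):
            return max(d.t_start - injection_time, 0.0)
    return math.nan


def fit_dwell_rate(
    dwells: Sequence[float] | Sequence[Dwell],
    censored: Sequence[bool] | None = None,
) -> RateFit:
    """Transition rate from a dwell-time sample as 1 / mean lifetime.

    For exponentially distributed dwells the maximum-likelihood rate is the
    reciprocal of the average lifetime, which is also what a
    single-exponential fit of the dwell-time distribution returns.  Dwells
    truncated by the end of a trace or by bleaching should be flagged in
    ``censored``; they are excluded from the estimate.  Fewer than 10 usable
    dwells still yields the reciprocal mean but flagged low-confidence.
    """
    durations = np.array(
        [d.duration if isinstance(d, Dwell) else float(d) for d in dwells]
    )
    if censored is not None:
        durations = durations[~np.asarray(censored, dtype=bool)]
    if len(durations) == 0:
        raise ValueError("no usable dwells")
    mean = float(durations.mean())
    rate = 1.0 / mean
    flags = () if len(durations) >= 10 else ("low_confidence",)
    return RateFit(
        rate=rate,
        uncertainty=rate / math.sqrt(len(durations)),
        model="exponential_mle",
        units="s^-1",
        params={"mean_lifetime": mean, "n_dwells": int(len(durations))},
        flags=flags,
    )


def fit_association_constant(
    rates_by_concentration: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
    fit_intercept: bool = False,
) -> RateFit:
    """Second-order association constant from k_obs versus concentration.

    Fits k_obs = k_a * C (through the origin by default) by weighted least
    squares; the slope k_a is in M^-1 s^-1.  ``rates_by_concentration`` is a
    list of (concentration, k_obs) pairs, one per condition.
    """
    pts = np.asarray(rates_by_concentration, dtype=float)
    if len(np.unique(pts[:, 0])) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    c, k = pts[:, 0], pts[:, 1]
    w = np.ones(len(c)) if weights is None else np.asarray(weights, dtype=float)

    if fit_intercept:
        X = np.column_stack([c, np.ones(len(c))])
    else:
        X = c[:, None]
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], k * sw, rcond=None)
    resid = k - X @ beta
    dof = max(len(c) - X.shape[1], 1)
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = sigma2 * np.linalg.inv((X * w[:, None]).T @ X)
    slope = float(beta[0])
    return RateFit(
        rate=slope,
        uncertainty=float(np.sqrt(cov[0, 0])),
        model="linear_through_origin" if not fit_intercept else "linear",
        units="M^-1 s^-1",
        params={"intercept": float(beta[1]) if fit_intercept else 0.0},
    )


# ---------------------------------------------------------------------------
# displacement-pathway classification
# ---------------------------------------------------------------------------

def classify_trace(
    seg: StateSegmentation,
    injection_time: float,
    low: int = 0,
    mid: int = 1,
    high: int = 2,
) -> TraceClass:
    """Classify a displacement trace by its post-injection state path.

    The trace starts SSB-bound (MID).  Rules, applied to the dwell sequence
    after ``injection_time``:

    - never leaves MID -> NO_BINDING;
    - reaches HIGH with no LOW visit -> DISPLACEMENT_DIRECT;
    - exactly one LOW visit on the way to a terminal HIGH ->
      DISPLACEMENT_VIA_INTERMEDIATE;
    - two or more LOW visits ending HIGH -> MULTI_TRANSITION (repeated
      passage through the intermediate before displacement completes);
    - visited LOW but ends back in MID or LOW -> INTERMEDIATE_RETURN.

    ``n_low_visits`` counts LOW dwells after the first post-injection MID
    dwell; ``n_high_transitions`` counts entries into HIGH.
    """
    post = [
        d
        for d in seg.dwells
        if d.t_start + d.duration > injection_time
    ]
    if not post:
        raise ValueError("segmentation has no dwells after injection")

    states = [d.state for d in post]
    n_low = sum(1 for s in states if s == low)
    n_high = sum(
        1
        for i, s in enumerate(states)
        if s == high and (i == 0 or states[i - 1] != high)
    )
    terminal = states[-1]

    if terminal == high:
        if n_low == 0:
            cat = TraceCategory.DISPLACEMENT_DIRECT
        elif n_low == 1:
            cat = TraceCategory.DISPLACEMENT_VIA_INTERMEDIATE
        else:
            cat = TraceCategory.MULTI_TRANSITION
    elif n_low > 0:
        cat = TraceCategory.INTERMEDIATE_RETURN
    else:
        cat = TraceCategory.NO_BINDING
    return TraceClass(category=cat, n_low_visits=n_low, n_high_transitions=n_high)


def classification_summary(classes: Sequence[TraceClass]) -> pd.Series:
    """Category fractions plus displacement totals over a trace ensemble.

    Terminal categories are mutually exclusive and their fractions sum to 1.
    ``displacement_total`` pools every path that ends displaced (direct,
    via-intermediate, multi-transition); ``via_intermediate_share`` is the
    share of displacements that passed through the intermediate at least
    once.
    """
    if not classes:
        raise ValueError("empty ensemble")
    n = len(classes)
    frac = {
        cat.value: sum(1 for c in classes if c.category is cat) / n
        for cat in TraceCategory
    }
    displaced = (
        frac["DISPLACEMENT_DIRECT"]
        + frac["DISPLACEMENT_VIA_INTERMEDIATE"]
        + frac["MULTI_TRANSITION"]
    )
    via = frac["DISPLACEMENT_VIA_INTERMEDIATE"] + frac["MULTI_TRANSITION"]
    frac["displacement_total"] = displaced
    frac["via_intermediate_share"] = via / displaced if displaced > 0 else math.nan
    frac["n_traces"] = n
    return pd.Series(frac)
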