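"""Fluorescence-trace analysis: probe conversion, normalisation, initial
rates and steady-state levels.

The quantities extracted here are the ones reported for the proteoliposome
assays: the linear initial decay rate ``a0 + k1*t`` of the normalised ACMA
signal (k1 in min^-1), the steady-state interior pH over the 30 s window
preceding the nigericin event, and the vesicle orientation fraction from
intact-versus-solubilised labelling intensities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import ProbeCalibration, pyranine_pH
from .vesicle import EventSchedule

__all__ = [
    "Trace",
    "FitResult",
    "SteadyStateLevel",
    "LinearDecayModel",
    "ratio_trace_to_pH",
    "normalize_acma",
    "initial_rate",
    "steady_state_level",
    "orientation_fraction",
    "aggregate_replicates",
]


@dataclass
class Trace:
    """A timestamped fluorescence trace with named channels.

    ``channels`` maps channel names ("I404"/"I454" for pyranine,
    "F_acma" for ACMA) to intensity arrays aligned with ``time``.
    """

    time: np.ndarray
    channels: dict
    events: Optional[EventSchedule] = None
    replicate_id: str = "r0"
    sampling_dt: float = 0.6

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != self.time.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = ch

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Trace":
        df = pd.read_csv(path)
        time = df.pop("time_s").to_numpy()
        return cls(time=time, channels={c: df[c].to_numpy() for c in df.columns}, **kwargs)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, **self.channels}).to_csv(path, index=False)


@dataclass(frozen=True)
class FitResult:
    """Linear-decay fit ``F = a0 + slope*t``; ``k1`` is the decay rate
    magnitude in min^-1."""

    a0: float
    k1: float
    slope_per_min: float
    stderr: float  # per minute
    window: tuple
    r_squared: float
    n: int

    def summary(self) -> str:
        return (
            f"linear decay fit over [{self.window[0]:.1f}, {self.window[1]:.1f}] s "
            f"(n={self.n}):  a0={self.a0:.4f}, k1={self.k1:.4g} min^-1 "
            f"(slope {self.slope_per_min:+.4g} +/- {self.stderr:.2g} min^-1, "
            f"R^2={self.r_squared:.4f})"
        )


@dataclass(frozen=True)
class SteadyStateLevel:
    level: float
    sd: float
    window: tuple
    n: int


def ratio_trace_to_pH(trace: Trace, cal: ProbeCalibration = ProbeCalibration()) -> np.ndarray:
    """Convert a two-channel pyranine trace to a pH series (elementwise).

    NaN samples are propagated and flagged with a warning, never dropped.
    """
    for ch in ("I404", "I454"):
        if ch not in trace.channels:
            raise ValueError(f"missing pyranine channel {ch!r}")
    i404 = trace.channels["I404"]
    i454 = trace.channels["I454"]
    nan_mask = np.isnan(i404) | np.isnan(i454)
    if nan_mask.any():
        warnings.warn(f"{int(nan_mask.sum())} NaN sample(s) in pyranine trace", stacklevel=2)
    out = np.full_like(i404, np.nan)
    ok = ~nan_mask
    if np.any((i404[ok] <= 0) | (i454[ok] <= 0)):
        raise ValueError("intensities must be > 0")
    out[ok] = cal.slope_a * np.log10(i404[ok] / i454[ok]) + cal.intercept_b
    return out


def normalize_acma(trace: Trace, baseline_s: float = 60.0) -> np.ndarray:
    """Normalise an ACMA trace to a unit baseline.

    The baseline (dF = 1.0) is the mean over the first ``baseline_s`` seconds;
    the output is scale-invariant in the raw signal.
    """
    if "F_acma" not in trace.channels:
        raise ValueError("missing ACMA channel 'F_acma'")
    if trace.time[-1] < baseline_s:
        raise ValueError("trace shorter than the baseline window")
    first_event = trace.events.events[0].time if trace.events and trace.events.events else math.inf
    if first_event < baseline_s:
        raise ValueError("first event occurs inside the baseline window")
    f = trace.channels["F_acma"]
    base = float(np.mean(f[trace.time <= baseline_s]))
    if base <= 0:
        raise ValueError("non-positive baseline")
    return f / base


class LinearDecayModel:
    """Ordinary least squares fit of ``a0 + slope*t`` to a signal window.

    ``fit()`` returns a :class:`FitResult` with the slope in min^-1 and its
    standard error.  Times are taken relative to the window start, so ``a0``
    is the signal level at the triggering event.
    """

    def __init__(self, time_s: np.ndarray, signal: np.ndarray, window: tuple):
        t = np.asarray(time_s, dtype=float)
        y = np.asarray(signal, dtype=float)
        t0, t1 = window
        mask = (t >= t0) & (t <= t1) & ~np.isnan(y)
        if mask.sum() < 5:
            raise ValueError("need >= 5 samples in the fit window")
        self.t = t[mask]
        self.y = y[mask]
        self.window = (float(t0), float(t1))
        if np.ptp(self.t) == 0:
            raise ValueError("degenerate window")

    def fit(self) -> FitResult:
        t_min = (self.t - self.t[0]) / 60.0
        res = stats.linregress(t_min, self.y)
        return FitResult(
            a0=float(res.intercept),
            k1=abs(float(res.slope)),
            slope_per_min=float(res.slope),
            stderr=float(res.stderr),
            window=self.window,
            r_squared=float(res.rvalue**2),
            n=len(self.t),
        )


def initial_rate(
    trace_or_series,
    window: Optional[tuple] = None,
    time_s: Optional[np.ndarray] = None,
    channel: str = "F_acma",
) -> FitResult:
    """Fit the initial linear decay of a signal after the triggering event.

    Accepts a :class:`Trace` (the window defaults to event -> event + 30 s
    for ACMA or + 10 s for pyranine) or a plain series plus ``time_s``.
    """
    if isinstance(trace_or_series, Trace):
        trace = trace_or_series
        t = trace.time
        y = trace.channels[channel] if channel in trace.channels else trace.channels["I404"]
        if window is None:
            if trace.events is None or not trace.events.events:
                raise ValueError("no window given and no events on the trace")
            t0 = trace.events.events[0].time
            span = 30.0 if channel == "F_acma" else 10.0
            window = (t0, t0 + span)
    else:
        if time_s is None or window is None:
            raise ValueError("series input requires time_s and window")
        t, y = np.asarray(time_s, float), np.asarray(trace_or_series, float)
    return LinearDecayModel(t, y, window).fit()


def steady_state_level(
    series: np.ndarray,
    time_s: np.ndarray,
    schedule: EventSchedule,
    window_s: float = 30.0,
) -> SteadyStateLevel:
    """Mean level over the window ending at the nigericin event.

    Samples at or after the nigericin time are excluded.
    """
    t_nig = schedule.first_time("add_nigericin")
    if t_nig is None:
        raise ValueError("schedule has no nigericin event")
    t = np.asarray(time_s, float)
    y = np.asarray(series, float)
    mask = (t >= t_nig - window_s) & (t < t_nig)
    if mask.sum() <= 10:
        raise ValueError("steady-state window must contain > 10 samples")
    return SteadyStateLevel(
        level=float(np.mean(y[mask])),
        sd=float(np.std(y[mask], ddof=1)),
        window=(t_nig - window_s, t_nig),
        n=int(mask.sum()),
    )


def orientation_fraction(
    I_intact: float, I_solubilized: float, tag_side: str, tol: float = 0.05
) -> float:
    """N-side-inward orientation fraction from tag-labelling intensities.

    The exposed-tag fraction is ``f = I_intact / I_solubilized``; for a tag on
    the P-side an exposed tag means the N-side faces inward, so the N-inward
    fraction is ``f``; for an N-side tag it is ``1 - f``.
    """
    if tag_side not in ("N", "P"):
        raise ValueError("tag_side must be 'N' or 'P'")
    if not I_solubilized > 0:
        raise ValueError("I_solubilized must be > 0")
    f = I_intact / I_solubilized
    if f > 1.0 + tol:
        raise ValueError(f"intact/solubilised ratio {f:.3f} exceeds 1 beyond tolerance")
    f = min(f, 1.0)
    return f if tag_side == "P" else 1.0 - f


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Replicate aggregation as mean +/- SD (matching figure conventions)."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0
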