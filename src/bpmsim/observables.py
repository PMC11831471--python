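"""Per-particle measurement quantities derived from event traces.

The sensor signal of one particle is its *switching activity*: the frequency
of transitions between the bound (at least one PSB-SSB bond) and unbound
states inside an observation window.  This module converts exact event traces
into state traces, switching activities, occupancy fractions and bound/unbound
lifetime sets, and can re-sample a state trace at a finite video frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reaction_model import SECONDS_PER_HOUR
from .simulate import EventTrace

__all__ = [
    "StateTrace",
    "LifetimeSet",
    "state_trace",
    "switching_activity",
    "single_bound_fraction",
    "bound_fraction",
    "lifetimes",
    "frame_sample",
    "observables_table",
]


@dataclass
class StateTrace:
    """Piecewise-constant bound/unbound state over a window.

    ``change_times`` are the strictly increasing switch instants inside the
    window; the state starts as ``start_bound`` at ``window_start`` and
    alternates at every change point.
    """

    window_start: float
    window_end: float
    change_times: np.ndarray
    start_bound: bool

    def __post_init__(self) -> None:
        self.change_times = np.asarray(self.change_times, dtype=float)
        if self.window_end <= self.window_start:
            raise ValueError("window must have positive length")
        if len(self.change_times):
            if not np.all(np.diff(self.change_times) > 0):
                raise ValueError("change points must be strictly increasing")
            if (
                self.change_times[0] <= self.window_start
                or self.change_times[-1] >= self.window_end
            ):
                raise ValueError("change points must lie strictly inside the window")

    @property
    def duration(self) -> float:
        return self.window_end - self.window_start

    @property
    def n_switches(self) -> int:
        return len(self.change_times)

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """Boolean bound state evaluated at the given instants."""
        times = np.asarray(times, dtype=float)
        k = np.searchsorted(self.change_times, times, side="right")
        return (k % 2 == 0) == self.start_bound

    def intervals(self) -> list[tuple[float, float, bool, bool]]:
        """Maximal constant-state intervals as (start, end, bound, censored).

        The first and last intervals touch the window edges and are censored
        (their true length is unknown).
        """
        edges = np.concatenate(
            ([self.window_start], self.change_times, [self.window_end])
        )
        out = []
        bound = self.start_bound
        n = len(edges) - 1
        for i in range(n):
            censored = i == 0 or i == n - 1
            out.append((float(edges[i]), float(edges[i + 1]), bound, censored))
            bound = not bound
        return out


@dataclass
class LifetimeSet:
    """Bound and unbound interval durations, censored edge intervals separate."""

    bound_s: np.ndarray
    unbound_s: np.ndarray
    bound_censored_s: np.ndarray
    unbound_censored_s: np.ndarray


def state_trace(trace: EventTrace, window: tuple[float, float] | None = None) -> StateTrace:
    """Bound/unbound state of a particle over a window of its event trace.

    The state is bound exactly where the bond number satisfies ``b >= 1``;
    change points are the 0 <-> 1 crossings of ``b`` (a 1 -> 2 transition is
    not a switch: a multivalently bound particle is still bound).
    """
    t, b = trace.b_steps(window)
    bound = b >= 1
    flips = np.nonzero(bound[1:] != bound[:-1])[0]
    change_times = t[flips + 1]
    # an event at exactly the window start does not create an interior change point
    keep = (change_times > t[0]) & (change_times < t[-1])
    return StateTrace(
        window_start=float(t[0]),
        window_end=float(t[-1]),
        change_times=change_times[keep],
        start_bound=bool(bound[0]),
    )


def switching_activity(state: StateTrace) -> float:
    """Switching events per hour: change points divided by window length."""
    return state.n_switches / state.duration * SECONDS_PER_HOUR


def _occupancy_fraction(trace: EventTrace, window, predicate) -> float:
    t, b = trace.b_steps(window)
    dt = np.diff(t)
    total = t[-1] - t[0]
    return float(np.sum(dt[predicate(b)]) / total)


def single_bound_fraction(trace: EventTrace, window=None) -> float:
    """Fraction of window time with exactly one PSB-SSB bond."""
    return _occupancy_fraction(trace, window, lambda b: b == 1)


def bound_fraction(trace: EventTrace, window=None) -> float:
    """Fraction of window time in the bound state (``b >= 1``)."""
    return _occupancy_fraction(trace, window, lambda b: b >= 1)


def lifetimes(state: StateTrace) -> LifetimeSet:
    """Bound/unbound interval durations; window-edge intervals are censored.

    Censored intervals are excluded from the main duration arrays (and hence
    from lifetime means computed on them) because their true length is
    unknown; they are returned separately.
    """
    bound_u, unbound_u, bound_c, unbound_c = [], [], [], []
    for t0, t1, bound, censored in state.intervals():
        d = t1 - t0
        if d <= 0:
            continue
        target = (bound_c if censored else bound_u) if bound else (
            unbound_c if censored else unbound_u
        )
        target.append(d)
    return LifetimeSet(
        bound_s=np.asarray(bound_u),
        unbound_s=np.asarray(unbound_u),
        bound_censored_s=np.asarray(bound_c),
        unbound_censored_s=np.asarray(unbound_c),
    )


def frame_sample(state: StateTrace, frame_rate: float) -> StateTrace:
    """State trace as seen by a camera sampling at ``frame_rate`` (Hz).

    The state is evaluated at the frame instants; excursions shorter than one
    frame period that fall between frames vanish, so the output switch count
    never exceeds the input's.  Detected changes are timed at the first frame
    showing the new state.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    period = 1.0 / frame_rate
    n = int(np.floor(state.duration / period)) + 1
    frames = state.window_start + np.arange(n) * period
    vals = state.states_at(frames)
    flips = np.nonzero(vals[1:] != vals[:-1])[0]
    change_times = frames[flips + 1]
    keep = (change_times > state.window_start) & (change_times < state.window_end)
    return StateTrace(
        window_start=state.window_start,
        window_end=state.window_end,
        change_times=change_times[keep],
        start_bound=bool(vals[0]),
    )


def observables_table(
    traces: list[EventTrace],
    windows: list[tuple[float, float]],
) -> pd.DataFrame:
    """Per-particle, per-window observables table.

    Columns: particle_id, window_start_s, window_end_s, activity_per_h,
    single_bound_fraction, n_switches.
    """
    rows = []
    for i, tr in enumerate(traces):
        pid = tr.particle_id if tr.particle_id is not None else i
        for w in windows:
            st = state_trace(tr, w)
            rows.append(
                {
                    "particle_id": pid,
                    "window_start_s": w[0],
                    "window_end_s": w[1],
                    "activity_per_h": switching_activity(st),
                    "single_bound_fraction": single_bound_fraction(tr, w),
                    "n_switches": st.n_switches,
                }
            )
    return pd.DataFrame(rows)
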