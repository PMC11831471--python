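"""Fourier phase-shift classification of per-particle signal traces.

Under a descending concentration ladder, a particle whose dose-response curve
(DRC) is bell-shaped reaches its maximum activity at a higher concentration,
i.e. *earlier in the series*, than the sigmoidal ensemble mean.  The
fundamental-frequency Fourier phase of the particle's activity-versus-time
signal over one series, relative to the ensemble mean signal, therefore
separates DRC shapes: positive phase shift = earlier response = bell-like.

Particles are binned into six contiguous phase bins of width pi/6 (default
span [-pi/3, 2*pi/3], covering the named sigmoidal bin (-pi/6, 0) and bell
bin (pi/6, pi/3) plus their surroundings); bin-resolved mean DRCs and the
migration of bins across series track how binder loss reshapes responses over
the full experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import ExperimentResult, classify_shape

__all__ = [
    "PhaseResult",
    "DEFAULT_BIN_EDGES",
    "wrap_phase",
    "phase_shift",
    "assign_bins",
    "phase_table",
    "bin_resolved_drcs",
    "track_migration",
    "MigrationSummary",
]

TWO_PI = 2.0 * math.pi

#: Six contiguous bins of width pi/6 spanning [-pi/3, 2*pi/3].
DEFAULT_BIN_EDGES = tuple(np.pi / 6.0 * k for k in range(-2, 5))


@dataclass
class PhaseResult:
    """Phase shift of one particle's signal in one series.

    ``dphi`` is wrapped to (-pi, pi]; positive means the particle's signal
    features occur earlier in time than the ensemble's.  ``bin`` is the
    phase-bin index (0-5) or ``None`` when unassigned (amplitude below floor,
    zero amplitude, or phase outside the bin span).
    """

    particle_id: int | str
    series: int | str
    dphi: float
    amplitude: float
    bin: int | None = None
    message: str = ""


def wrap_phase(phi: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    w = math.remainder(phi, TWO_PI)
    if w <= -math.pi:
        w = math.pi
    return w


def _fundamental(signal: np.ndarray) -> complex:
    """DFT coefficient at one cycle per record of the mean-subtracted signal."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    n = len(x)
    return complex(np.fft.rfft(x)[1]) * 2.0 / n


def phase_shift(
    particle_signal,
    ensemble_signal,
    particle_id: int | str = 0,
    series: int | str = 0,
) -> PhaseResult:
    """Fundamental-frequency phase of a particle signal relative to the ensemble.

    Both signals are the activities of one concentration series, sampled once
    per application, mean-subtracted before the DFT.  The phase difference
    ``arg(particle) - arg(ensemble)`` is wrapped to (-pi, pi]; with the
    standard DFT sign convention a signal advanced by one sample (features
    earlier in time) gets ``dphi = +2*pi/N``.

    A zero-amplitude ensemble is an error (no reference phase); a
    zero-amplitude particle yields an unassigned result with a diagnostic.
    """
    p = np.asarray(particle_signal, dtype=float)
    e = np.asarray(ensemble_signal, dtype=float)
    if len(p) != len(e):
        raise ValueError("particle and ensemble signals must have equal length")
    if len(p) < 4:
        raise ValueError("need at least 4 samples per series")
    ce = _fundamental(e)
    if abs(ce) == 0.0:
        raise ValueError("ensemble signal has zero amplitude at the fundamental")
    cp = _fundamental(p)
    if abs(cp) == 0.0:
        return PhaseResult(
            particle_id, series, dphi=float("nan"), amplitude=0.0,
            message="zero particle amplitude at the fundamental",
        )
    dphi = wrap_phase(np.angle(cp) - np.angle(ce))
    return PhaseResult(particle_id, series, dphi=dphi, amplitude=abs(cp))


def assign_bins(
    results: list[PhaseResult],
    bin_edges=DEFAULT_BIN_EDGES,
    amplitude_floor: float = 0.0,
) -> np.ndarray:
    """Assign each result to a phase bin; returns the histogram counts.

    ``bin_edges`` are 7 increasing edges defining 6 contiguous bins of equal
    width pi/6.  Bins are half-open on the left: a value exactly on an inner
    edge goes to the lower bin.  Results with amplitude below
    ``amplitude_floor``, non-finite phase, or phase outside the span stay
    unassigned (``bin = None``).  Counts sum to the number of assigned
    particles.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) != 7 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be 7 strictly increasing values (6 bins)")
    widths = np.diff(edges)
    if not np.allclose(widths, np.pi / 6.0, atol=1e-9):
        raise ValueError("bins must have width pi/6")
    hist = np.zeros(6, dtype=int)
    for r in results:
        r.bin = None
        if not np.isfinite(r.dphi) or r.amplitude < amplitude_floor:
            continue
        if not (edges[0] < r.dphi <= edges[-1]):
            continue
        idx = int(np.searchsorted(edges, r.dphi, side="left")) - 1
        r.bin = idx
        hist[idx] += 1
    return hist


def phase_table(
    result: ExperimentResult,
    bin_edges=DEFAULT_BIN_EDGES,
    amplitude_floor_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-particle, per-series phase table of a simulated experiment.

    The ensemble reference of each series is the mean activity per application
    over all particles.  The amplitude floor for bin assignment is
    ``amplitude_floor_frac`` times the ensemble fundamental amplitude of that
    series.  Columns: particle_id, series, dphi_rad, amplitude, bin.
    """
    rows = []
    for s in range(result.design.n_series):
        ensemble = result.ensemble_signal(s)
        floor = amplitude_floor_frac * abs(_fundamental(ensemble))
        sub = result.drc_table[result.drc_table.series == s]
        piv = sub.pivot(index="particle_id", columns="application", values="activity_per_h")
        series_results = []
        for pid in piv.index:
            series_results.append(
                phase_shift(piv.loc[pid].to_numpy(), ensemble, particle_id=int(pid), series=s)
            )
        assign_bins(series_results, bin_edges, amplitude_floor=floor)
        for r in series_results:
            rows.append(
                {
                    "particle_id": r.particle_id,
                    "series": r.series,
                    "dphi_rad": r.dphi,
                    "amplitude": r.amplitude,
                    "bin": -1 if r.bin is None else r.bin,
                }
            )
    return pd.DataFrame(rows)


def bin_resolved_drcs(
    result: ExperimentResult,
    first_series_bins: dict[int, int],
) -> pd.DataFrame:
    """Mean DRC per phase bin per series.

    Bin membership is fixed from the first series for the whole experiment.
    Columns: bin, series, application, conc_M, mean_activity_per_h, n.  Bins
    with no particles are simply absent from the table (flagged by the
    caller's bin list).
    """
    tab = result.drc_table.copy()
    tab["bin"] = tab["particle_id"].map(first_series_bins)
    tab = tab.dropna(subset=["bin"])
    tab = tab[tab["bin"] >= 0]
    g = (
        tab.groupby(["bin", "series", "application"])
        .agg(
            conc_M=("conc_M", "first"),
            mean_activity_per_h=("activity_per_h", "mean"),
            n=("particle_id", "nunique"),
        )
        .reset_index()
    )
    g["bin"] = g["bin"].astype(int)
    return g


@dataclass
class MigrationSummary:
    """How phase bins (fixed from series 1) evolve over the experiment."""

    trajectories: pd.DataFrame  # initial_bin, series, mean_dphi, mean_amplitude, n
    modal_classes: pd.DataFrame  # initial_bin, first_series_class, last_series_class


def track_migration(
    result: ExperimentResult,
    phases: pd.DataFrame,
    bell_ratio: float = 0.8,
    floor_activity: float = 2.0,
) -> MigrationSummary:
    """Per-initial-bin trajectories of mean phase, amplitude and shape class.

    ``phases`` is the output of :func:`phase_table`.  Particles are grouped by
    their series-0 bin; for every later series the group's mean phase shift
    and mean amplitude are reported, together with the modal per-particle
    shape class in the first and last series.
    """
    first = phases[phases.series == 0].set_index("particle_id")["bin"]
    merged = phases.merge(
        first.rename("initial_bin"), left_on="particle_id", right_index=True
    )
    merged = merged[merged.initial_bin >= 0]
    traj = (
        merged.groupby(["initial_bin", "series"])
        .agg(
            mean_dphi=("dphi_rad", "mean"),
            mean_amplitude=("amplitude", "mean"),
            n=("particle_id", "nunique"),
        )
        .reset_index()
    )

    last_series = result.design.n_series - 1
    classes: dict[tuple[int, int], str] = {}
    for series in (0, last_series):
        for curve in result.series_curves(series):
            classes[(int(curve.particle_id), series)] = classify_shape(
                curve, bell_ratio, floor_activity
            )
    rows = []
    for ib, group in merged[merged.series == 0].groupby("initial_bin"):
        pids = group.particle_id.tolist()
        modal = {}
        for series in (0, last_series):
            labels = [classes[(pid, series)] for pid in pids]
            vals, counts = np.unique(labels, return_counts=True)
            modal[series] = str(vals[np.argmax(counts)])
        rows.append(
            {
                "initial_bin": int(ib),
                "first_series_class": modal[0],
                "last_series_class": modal[last_series],
            }
        )
    return MigrationSummary(
        trajectories=traj, modal_classes=pd.DataFrame(rows)
    )
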