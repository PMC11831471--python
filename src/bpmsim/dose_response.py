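"""Synthetic concentration-ladder experiments and dose-response analysis.

The emulated protocol applies ``n_series`` identical series of fluid
applications to the same particles; each series steps through a descending
concentration ladder (highest analyte first, a blank last) and every
application is observed for a fixed tracking span.  With the defaults
(10 series x 8 applications, 15 min tracking + dead time per application) one
series spans 2.5 h and the whole experiment 25 h.

Per particle, the switching activity in every observed window yields a
dose-response curve (DRC) per series and a time-averaged DRC over series.
Curves are classified as sigmoidal (monotone competition response), bell
(interior maximum: multivalent binding suppresses switching at low analyte)
or non-responsive, and sigmoidal curves get a four-parameter-logistic EC50.
Populations with Poisson-distributed binder numbers reproduce the
transducer-to-transducer heterogeneity of real particle ensembles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from ._rng import substream, substream_seed
from .observables import state_trace, switching_activity
from .reaction_model import RateConstants, TransducerConfig
from .simulate import ConcentrationProfile, EventTrace, Segment, simulate

__all__ = [
    "default_ladder",
    "ExperimentDesign",
    "DoseResponseCurve",
    "PopulationSpec",
    "build_profile",
    "particle_drc",
    "classify_shape",
    "fit_ec50",
    "Ec50Fit",
    "sample_population",
    "run_experiment",
    "ExperimentResult",
    "heterogeneity_summary",
    "HeterogeneitySummary",
    "estimate_loss_rate",
    "LossRateFit",
]

SECONDS_PER_HOUR = 3600.0


def default_ladder(
    kd: float = 1.0e-7, n_applications: int = 8, lo: float = 1e-2, hi: float = 1e2
) -> tuple[float, ...]:
    """Descending concentration ladder: log-spaced from ``hi*kd`` down to
    ``lo*kd`` plus a final blank (zero analyte)."""
    concs = np.logspace(math.log10(hi * kd), math.log10(lo * kd), n_applications - 1)
    return tuple(float(c) for c in concs) + (0.0,)


@dataclass(frozen=True)
class ExperimentDesign:
    """Schedule of one concentration-ladder experiment.

    ``ladder`` is applied high -> low within every series and must be
    non-increasing; the default ends in a blank.  ``dead_time_s`` is the
    untracked span after each observation (fluid handling), chosen so that one
    default series spans exactly 2.5 h.
    """

    n_series: int = 10
    n_applications: int = 8
    obs_duration_s: float = 900.0
    dead_time_s: float = 225.0
    ladder: tuple[float, ...] = field(default_factory=default_ladder)

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_applications < 1:
            raise ValueError("n_series and n_applications must be >= 1")
        if self.obs_duration_s <= 0 or self.dead_time_s < 0:
            raise ValueError("durations must be positive (dead time >= 0)")
        if len(self.ladder) != self.n_applications:
            raise ValueError(
                f"ladder length {len(self.ladder)} != n_applications {self.n_applications}"
            )
        lad = np.asarray(self.ladder)
        if np.any(lad < 0):
            raise ValueError("ladder concentrations must be >= 0")
        if np.any(np.diff(lad) > 0):
            raise ValueError("ladder must be applied high to low (non-increasing)")

    @property
    def application_duration_s(self) -> float:
        return self.obs_duration_s + self.dead_time_s

    @property
    def series_duration_s(self) -> float:
        return self.n_applications * self.application_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.n_series * self.series_duration_s

    def window(self, series: int, application: int) -> tuple[float, float]:
        """Observed window (start, end) of one application of one series."""
        t0 = series * self.series_duration_s + application * self.application_duration_s
        return (t0, t0 + self.obs_duration_s)

    def blank_applications(self) -> list[int]:
        return [i for i, c in enumerate(self.ladder) if c == 0.0]


def build_profile(design: ExperimentDesign) -> ConcentrationProfile:
    """Concentration profile of the full experiment.

    Each application contributes an observed segment (tracking span) followed
    by an unobserved dead-time segment at the same concentration; the total
    span is ``n_series * series_duration``.
    """
    segments: list[Segment] = []
    for s in range(design.n_series):
        for a, conc in enumerate(design.ladder):
            t0, t1 = design.window(s, a)
            segments.append(Segment(t0, design.obs_duration_s, conc, observed=True))
            if design.dead_time_s > 0:
                segments.append(Segment(t1, design.dead_time_s, conc, observed=False))
    return ConcentrationProfile(tuple(segments))


@dataclass
class DoseResponseCurve:
    """Activity versus concentration for one particle (or an ensemble).

    ``series`` is the series index, or ``"time-averaged"`` for the mean over
    all series (in which case ``sd`` holds the per-point standard deviation
    over series).  Concentrations are stored in applied (descending) order.
    """

    particle_id: int | str
    series: int | str
    concentrations: np.ndarray
    activities: np.ndarray
    sd: np.ndarray | None = None
    shape_class: str | None = None
    ec50: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if len(self.concentrations) != len(self.activities):
            raise ValueError("concentrations and activities must have equal length")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if len(self.sd) != len(self.activities):
                raise ValueError("sd length mismatch")


@dataclass(frozen=True)
class PopulationSpec:
    """A particle population with Poisson-distributed binder numbers.

    The default means (3 particle-side, 8 substrate-side binders) put the bulk
    of the population in the monovalent/sigmoidal regime while leaving a
    sizable multivalent (bell-shaped) minority, mirroring the heterogeneity a
    real particle ensemble shows.
    """

    n_particles: int = 500
    mean_n_psb: float = 3.0
    mean_n_ssb: float = 8.0
    rates: RateConstants = field(default_factory=RateConstants)
    loss_rate_psb: float = 0.0
    loss_rate_ssb: float = 0.0
    master_seed: int = 0
    bond_rate_scales_with_ssb: bool = True
    loss_severs_bonds: bool = False

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.mean_n_psb < 0 or self.mean_n_ssb < 0:
            raise ValueError("Poisson means must be >= 0")


def sample_population(spec: PopulationSpec) -> list[TransducerConfig]:
    """Independent Poisson draws of binder counts, one transducer per particle."""
    rng = substream(spec.master_seed, "population")
    n_psb = rng.poisson(spec.mean_n_psb, size=spec.n_particles)
    n_ssb = rng.poisson(spec.mean_n_ssb, size=spec.n_particles)
    return [
        TransducerConfig(
            n_psb=int(p),
            n_ssb=int(s),
            rates=spec.rates,
            loss_rate_psb=spec.loss_rate_psb,
            loss_rate_ssb=spec.loss_rate_ssb,
            bond_rate_scales_with_ssb=spec.bond_rate_scales_with_ssb,
            loss_severs_bonds=spec.loss_severs_bonds,
        )
        for p, s in zip(n_psb, n_ssb)
    ]


def _window_activities(trace: EventTrace, design: ExperimentDesign) -> np.ndarray:
    """(n_series, n_applications) switching activities (events/h)."""
    out = np.empty((design.n_series, design.n_applications))
    for s in range(design.n_series):
        for a in range(design.n_applications):
            out[s, a] = switching_activity(state_trace(trace, design.window(s, a)))
    return out


def particle_drc(
    trace: EventTrace,
    design: ExperimentDesign,
    particle_id: int | str = 0,
) -> tuple[list[DoseResponseCurve], DoseResponseCurve]:
    """Per-series DRCs and the time-averaged DRC of one particle."""
    if trace.end_time + 1e-9 < design.total_duration_s:
        raise ValueError(
            f"trace horizon {trace.end_time} s shorter than the design "
            f"({design.total_duration_s} s)"
        )
    act = _window_activities(trace, design)
    concs = np.asarray(design.ladder)
    per_series = [
        DoseResponseCurve(particle_id, s, concs, act[s]) for s in range(design.n_series)
    ]
    averaged = DoseResponseCurve(
        particle_id,
        "time-averaged",
        concs,
        act.mean(axis=0),
        sd=act.std(axis=0, ddof=0),
    )
    return per_series, averaged


def classify_shape(
    drc: DoseResponseCurve,
    bell_ratio: float = 0.8,
    floor_activity: float = 2.0,
) -> str:
    """Classify a DRC as ``"sigmoidal"``, ``"bell"`` or ``"non-responsive"``.

    Non-responsive: maximum activity below ``floor_activity`` (events/h).
    Bell: the maximum occurs at an interior concentration (neither the top
    concentration nor the blank end) *and* the blank-end activity is below
    ``bell_ratio`` times the maximum.  Everything else is sigmoidal.
    Concentrations are assumed stored in applied (descending) order.
    """
    act = drc.activities
    if len(act) == 0:
        raise ValueError("empty dose-response curve")
    imax = int(np.argmax(act))
    amax = float(act[imax])
    if amax < floor_activity:
        return "non-responsive"
    interior = 0 < imax < len(act) - 1
    if interior and act[-1] < bell_ratio * amax:
        return "bell"
    return "sigmoidal"


@dataclass
class Ec50Fit:
    """Result of a four-parameter logistic fit to a sigmoidal DRC."""

    ec50: float | None
    top: float | None = None
    bottom: float | None = None
    hill: float | None = None
    converged: bool = False
    extrapolated: bool = False
    message: str = ""


def _logistic4(conc: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float):
    # competition format: activity decreases with concentration
    ec50 = 10.0**log_ec50
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)


def fit_ec50(drc: DoseResponseCurve) -> Ec50Fit:
    """Four-parameter logistic fit in log concentration.

    Requires a sigmoidal curve with at least four concentration points.  The
    blank (zero concentration) anchors the top asymptote exactly.  An EC50
    outside the non-zero ladder range is flagged ``extrapolated``.
    """
    if drc.shape_class not in (None, "sigmoidal"):
        raise ValueError(f"EC50 is defined for sigmoidal curves, not {drc.shape_class!r}")
    conc = drc.concentrations
    act = drc.activities
    if len(conc) < 4:
        raise ValueError("need at least 4 concentration points")
    pos = conc[conc > 0]
    top0 = float(act[conc == 0].mean()) if np.any(conc == 0) else float(act[-1])
    bottom0 = float(act[0])
    # initial EC50: concentration nearest the half-activity level
    half = bottom0 + 0.5 * (top0 - bottom0)
    i0 = int(np.argmin(np.abs(act - half)))
    c0 = conc[i0] if conc[i0] > 0 else float(np.sqrt(pos.max() * pos.min()))
    lo, hi = float(pos.min()), float(pos.max())
    try:
        with warnings.catch_warnings():
            # the parameter covariance is unused; flat blanks make it singular
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _logistic4,
                conc,
                act,
                p0=[top0, bottom0, math.log10(c0), 1.0],
                bounds=(
                    [0.0, 0.0, math.log10(lo) - 4, 0.2],
                    [np.inf, np.inf, math.log10(hi) + 4, 5.0],
                ),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        return Ec50Fit(ec50=None, converged=False, message=f"fit failed: {exc}")
    top, bottom, log_ec50, hill = popt
    ec50 = float(10.0**log_ec50)
    return Ec50Fit(
        ec50=ec50,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        converged=True,
        extrapolated=not (lo <= ec50 <= hi),
    )


@dataclass
class ExperimentResult:
    """Everything produced by one simulated ladder experiment."""

    design: ExperimentDesign
    population: list[TransducerConfig]
    drc_table: pd.DataFrame  # particle_id, series, application, conc_M, activity_per_h, n_switches
    master_seed: int

    def particle_series_matrix(self, particle_id: int) -> np.ndarray:
        sub = self.drc_table[self.drc_table.particle_id == particle_id]
        return (
            sub.pivot(index="series", columns="application", values="activity_per_h")
            .to_numpy()
        )

    def time_averaged_curves(self) -> list[DoseResponseCurve]:
        concs = np.asarray(self.design.ladder)
        curves = []
        g = self.drc_table.groupby(["particle_id", "application"])["activity_per_h"]
        mean = g.mean().unstack()
        sd = g.std(ddof=0).unstack()
        for pid in mean.index:
            curves.append(
                DoseResponseCurve(
                    int(pid), "time-averaged", concs, mean.loc[pid].to_numpy(),
                    sd=sd.loc[pid].to_numpy(),
                )
            )
        return curves

    def series_curves(self, series: int) -> list[DoseResponseCurve]:
        concs = np.asarray(self.design.ladder)
        sub = self.drc_table[self.drc_table.series == series]
        piv = sub.pivot(index="particle_id", columns="application", values="activity_per_h")
        return [
            DoseResponseCurve(int(pid), series, concs, piv.loc[pid].to_numpy())
            for pid in piv.index
        ]

    def ensemble_signal(self, series: int) -> np.ndarray:
        """Ensemble mean activity per application of one series."""
        sub = self.drc_table[self.drc_table.series == series]
        return (
            sub.groupby("application")["activity_per_h"].mean().sort_index().to_numpy()
        )

    def blank_activity_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(window mid-times in hours, ensemble mean blank activity) per series."""
        blanks = self.design.blank_applications()
        if not blanks:
            raise ValueError("design has no blank (zero-concentration) application")
        times, acts = [], []
        for s in range(self.design.n_series):
            for a in blanks:
                w = self.design.window(s, a)
                times.append(0.5 * (w[0] + w[1]) / SECONDS_PER_HOUR)
                sub = self.drc_table[
                    (self.drc_table.series == s) & (self.drc_table.application == a)
                ]
                acts.append(float(sub["activity_per_h"].mean()))
        return np.asarray(times), np.asarray(acts)


def run_experiment(
    spec: PopulationSpec,
    design: ExperimentDesign | None = None,
    record: str = "bonds",
) -> ExperimentResult:
    """Sample a population, simulate the full protocol, tabulate activities.

    Traces are processed one particle at a time (substream ``particle/<i>``)
    and discarded after their window activities are extracted, so memory stays
    flat in the population size.
    """
    design = design or ExperimentDesign()
    population = sample_population(spec)
    profile = build_profile(design)
    concs = np.asarray(design.ladder)
    rows = []
    for i, config in enumerate(population):
        seed = substream_seed(spec.master_seed, f"particle/{i}")
        trace = simulate(config, profile, seed=seed, record=record)
        for s in range(design.n_series):
            for a in range(design.n_applications):
                st = state_trace(trace, design.window(s, a))
                rows.append(
                    (i, s, a, concs[a], switching_activity(st), st.n_switches)
                )
    drc_table = pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "series",
            "application",
            "conc_M",
            "activity_per_h",
            "n_switches",
        ],
    )
    return ExperimentResult(
        design=design, population=population, drc_table=drc_table,
        master_seed=spec.master_seed,
    )


@dataclass
class HeterogeneitySummary:
    """Population-level summary of time-averaged DRCs."""

    class_counts: dict[str, int]
    ec50_quantiles: dict[float, float]
    ensemble_curve: DoseResponseCurve
    n_particles: int


def heterogeneity_summary(
    curves: list[DoseResponseCurve],
    bell_ratio: float = 0.8,
    floor_activity: float = 2.0,
) -> HeterogeneitySummary:
    """Shape-class counts, EC50 quantiles and the ensemble mean DRC.

    The ensemble curve is the unweighted mean activity per concentration over
    all particles and is itself classified.  EC50 quantiles (25/50/75%) are
    computed over converged fits of the sigmoidal particles.
    """
    if not curves:
        raise ValueError("need at least one curve")
    counts: dict[str, int] = {"sigmoidal": 0, "bell": 0, "non-responsive": 0}
    ec50s = []
    for c in curves:
        c.shape_class = classify_shape(c, bell_ratio, floor_activity)
        counts[c.shape_class] += 1
        if c.shape_class == "sigmoidal":
            fit = fit_ec50(c)
            if fit.converged and not fit.extrapolated:
                c.ec50 = fit.ec50
                ec50s.append(fit.ec50)
    mean_act = np.mean([c.activities for c in curves], axis=0)
    ensemble = DoseResponseCurve(
        "ensemble", "time-averaged", curves[0].concentrations, mean_act,
        sd=np.std([c.activities for c in curves], axis=0, ddof=0),
    )
    ensemble.shape_class = classify_shape(ensemble, bell_ratio, floor_activity)
    qs = {}
    if ec50s:
        arr = np.asarray(ec50s)
        qs = {q: float(np.quantile(arr, q)) for q in (0.25, 0.5, 0.75)}
    return HeterogeneitySummary(
        class_counts=counts,
        ec50_quantiles=qs,
        ensemble_curve=ensemble,
        n_particles=len(curves),
    )


@dataclass
class LossRateFit:
    """Linear blank-window fit of the ensemble activity decrease.

    ``rate_pct_per_h`` is ``-slope/intercept * 100``: the percent-per-hour
    decrease relative to the extrapolated activity at t = 0 (positive =
    decreasing signal).  ``se_pct_per_h`` is propagated from the full
    covariance of the ordinary-least-squares fit.
    """

    rate_pct_per_h: float
    se_pct_per_h: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n: int
    ok: bool = True
    message: str = ""


def estimate_loss_rate(blank_activities, window_times_h) -> LossRateFit:
    """Binder-loss rate from ensemble blank activities versus time.

    Fits ``activity = intercept + slope * t`` by ordinary least squares over
    the blank windows and reports ``-slope/intercept * 100`` %/h with a
    delta-method standard error.  Requires at least three blank windows
    spanning more than two hours.  A non-positive fitted intercept is flagged
    (the rate is then meaningless).
    """
    y = np.asarray(blank_activities, dtype=float)
    t = np.asarray(window_times_h, dtype=float)
    if len(y) != len(t):
        raise ValueError("activities and times must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 blank windows")
    if t.max() - t.min() <= 2.0:
        raise ValueError("blank windows must span more than 2 hours")
    x = np.column_stack([np.ones_like(t), t])
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    intercept, slope = beta
    resid = y - x @ beta
    dof = len(y) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(x.T @ x)
    intercept_se, slope_se = np.sqrt(np.diag(cov))
    if intercept <= 0:
        return LossRateFit(
            rate_pct_per_h=np.nan, se_pct_per_h=np.nan, slope=slope,
            intercept=intercept, slope_se=slope_se, intercept_se=intercept_se,
            n=len(y), ok=False, message="non-positive fitted intercept",
        )
    ratio = -slope / intercept
    # delta method for var(-slope/intercept) with the full 2x2 covariance
    g = np.array([slope / intercept**2, -1.0 / intercept])  # d ratio / d(intercept, slope)
    var = float(g @ cov @ g)
    return LossRateFit(
        rate_pct_per_h=100.0 * ratio,
        se_pct_per_h=100.0 * math.sqrt(max(var, 0.0)),
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        n=len(y),
    )
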