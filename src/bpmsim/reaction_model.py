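"""Discrete-state kinetic model of a single particle transducer.

A tethered particle carries ``n_psb`` particle-side binders (PSBs, e.g.
antibodies) that compete between analyte molecules in solution (concentration
``[A]``, molar) and ``n_ssb`` substrate-side binders (SSBs, analyte-analogue
molecules on the sensing surface).  All binding and unbinding steps are
independent Poisson processes; the system state is the pair ``(a, b)`` with
``a`` analyte-occupied PSBs and ``b`` PSB-SSB bonds.  The particle is *bound*
whenever ``b >= 1`` and *unbound* otherwise — the observable that drives the
sensor signal.

For small binder numbers and no binder loss, the model is a finite
continuous-time Markov chain (CTMC) whose stationary distribution can be
solved exactly.  That solution is the oracle used throughout the test suite to
validate the stochastic simulator, and it also provides exact dose-response
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REACTIONS",
    "RateConstants",
    "TransducerConfig",
    "SystemState",
    "propensities",
    "enumerate_states",
    "generator_matrix",
    "stationary_distribution",
    "stationary_switching_activity",
    "stationary_single_bound_fraction",
    "stationary_bound_fraction",
    "stationary_drc",
    "oracle_ec50",
]

#: Reaction labels, in the fixed order used by :func:`propensities` and by the
#: stochastic simulator.
REACTIONS = (
    "analyte_capture",
    "analyte_release",
    "bond_form",
    "bond_break",
    "psb_loss",
    "ssb_loss",
)

SECONDS_PER_HOUR = 3600.0

#: Default cap on binder counts for the exact CTMC solve.  Beyond this only the
#: stochastic simulation path is supported (state space grows quadratically).
DEFAULT_STATE_CAP = 12


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the four reversible interactions.

    Parameters
    ----------
    k_on:
        Analyte association rate constant, 1/(M s).
    k_off_analyte:
        Analyte dissociation rate constant, 1/s.
    k_on_star:
        Effective PSB-SSB bond formation rate constant, 1/s.  This is an
        effective first-order constant; the encounter physics behind it is out
        of scope.
    k_off_bond:
        PSB-SSB bond dissociation rate constant, 1/s.

    By default the two dissociation constants are equal (a single ``k_off``),
    matching the competition-sensor chemistry the model emulates; they are
    carried separately so the assumption can be relaxed.
    """

    k_on: float = 1.0e5
    k_off_analyte: float = 0.01
    k_on_star: float = 1.0e-3
    k_off_bond: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off_analyte", "k_on_star", "k_off_bond"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    @property
    def kd_analyte(self) -> float:
        """Analyte equilibrium constant k_off_analyte / k_on (M)."""
        if self.k_on == 0:
            return np.inf
        return self.k_off_analyte / self.k_on


@dataclass(frozen=True)
class TransducerConfig:
    """One particle transducer: binder counts, rates, and loss rates.

    ``bond_rate_scales_with_ssb`` selects the bond-formation combinatorics:
    with the default (mass action on discrete counts) the propensity is
    ``k_on_star * f * s`` with ``f`` free PSBs and ``s`` free SSBs; the
    alternative uses ``k_on_star * f`` independent of the number of free SSBs
    (as long as at least one is available).

    ``loss_severs_bonds`` selects whether first-order binder loss can remove a
    binder that is currently engaged in a bond (severing it).  By default loss
    applies to unbonded binders only, so bond release and binder loss stay
    distinct processes.
    """

    n_psb: int = 1
    n_ssb: int = 1
    rates: RateConstants = field(default_factory=RateConstants)
    loss_rate_psb: float = 0.0
    loss_rate_ssb: float = 0.0
    bond_rate_scales_with_ssb: bool = True
    loss_severs_bonds: bool = False

    def __post_init__(self) -> None:
        if int(self.n_psb) != self.n_psb or self.n_psb < 0:
            raise ValueError(f"n_psb must be a non-negative integer, got {self.n_psb}")
        if int(self.n_ssb) != self.n_ssb or self.n_ssb < 0:
            raise ValueError(f"n_ssb must be a non-negative integer, got {self.n_ssb}")
        if self.loss_rate_psb < 0 or self.loss_rate_ssb < 0:
            raise ValueError("loss rates must be >= 0")

    @property
    def loss_free(self) -> bool:
        return self.loss_rate_psb == 0.0 and self.loss_rate_ssb == 0.0

    def without_loss(self) -> "TransducerConfig":
        return replace(self, loss_rate_psb=0.0, loss_rate_ssb=0.0)


@dataclass
class SystemState:
    """Instantaneous state: occupied PSBs, bonds, and current binder counts."""

    a: int
    b: int
    n_psb_current: int
    n_ssb_current: int

    def validate(self) -> None:
        if self.a < 0:
            raise ValueError(f"invariant violated: a >= 0 (a={self.a})")
        if self.b < 0:
            raise ValueError(f"invariant violated: b >= 0 (b={self.b})")
        if self.a + self.b > self.n_psb_current:
            raise ValueError(
                "invariant violated: a + b <= n_psb_current "
                f"(a={self.a}, b={self.b}, n_psb_current={self.n_psb_current})"
            )
        if self.b > self.n_ssb_current:
            raise ValueError(
                f"invariant violated: b <= n_ssb_current (b={self.b}, n_ssb_current={self.n_ssb_current})"
            )

    @property
    def bound(self) -> bool:
        """The particle is bound iff at least one PSB-SSB bond exists."""
        return self.b >= 1

    @classmethod
    def empty(cls, config: TransducerConfig) -> "SystemState":
        return cls(a=0, b=0, n_psb_current=config.n_psb, n_ssb_current=config.n_ssb)


def propensities(
    state: SystemState, config: TransducerConfig, analyte_conc: float
) -> list[tuple[str, float]]:
    """Propensities of the six reactions, in :data:`REACTIONS` order.

    ``f = n_psb_current - a - b`` are free PSBs and ``s = n_ssb_current - b``
    free SSBs.  Analyte capture fires at ``k_on*[A]*f``, analyte release at
    ``k_off_analyte*a``, bond formation at ``k_on_star*f*s`` (or ``k_on_star*f``
    under the alternative combinatorics), bond release at ``k_off_bond*b``.
    Loss propensities cover unbonded binders only unless
    ``loss_severs_bonds`` is set, in which case they cover all current binders.
    """
    state.validate()
    if analyte_conc < 0:
        raise ValueError(f"analyte concentration must be >= 0, got {analyte_conc}")
    r = config.rates
    f = state.n_psb_current - state.a - state.b
    s = state.n_ssb_current - state.b
    if config.bond_rate_scales_with_ssb:
        p_bond = r.k_on_star * f * s
    else:
        p_bond = r.k_on_star * f * (1.0 if s > 0 else 0.0)
    if config.loss_severs_bonds:
        p_loss_psb = config.loss_rate_psb * state.n_psb_current
        p_loss_ssb = config.loss_rate_ssb * state.n_ssb_current
    else:
        p_loss_psb = config.loss_rate_psb * (f + state.a)
        p_loss_ssb = config.loss_rate_ssb * s
    return [
        ("analyte_capture", r.k_on * analyte_conc * f),
        ("analyte_release", r.k_off_analyte * state.a),
        ("bond_form", p_bond),
        ("bond_break", r.k_off_bond * state.b),
        ("psb_loss", p_loss_psb),
        ("ssb_loss", p_loss_ssb),
    ]


def enumerate_states(
    config: TransducerConfig, cap: int = DEFAULT_STATE_CAP
) -> list[tuple[int, int]]:
    """All reachable ``(a, b)`` states of the loss-free chain.

    States are returned in a fixed deterministic order: outer loop over the
    bond number ``b`` (ascending), inner loop over the analyte occupancy ``a``
    (ascending), subject to ``a + b <= n_psb`` and ``b <= n_ssb``.

    The exact oracle only applies to the loss-free model; configs with loss
    rates or with binder counts above ``cap`` are refused.
    """
    if not config.loss_free:
        raise ValueError("exact state enumeration applies to the loss-free model only")
    n_p, n_s = config.n_psb, config.n_ssb
    if n_p > cap or n_s > cap:
        n_states = sum(n_p - b + 1 for b in range(min(n_p, n_s) + 1))
        raise ValueError(
            f"binder counts ({n_p}, {n_s}) exceed the oracle cap {cap}; the state "
            f"space would hold {n_states} states — use the stochastic simulator "
            "or raise `cap` explicitly"
        )
    states = []
    for b in range(min(n_p, n_s) + 1):
        for a in range(n_p - b + 1):
            states.append((a, b))
    return states


def generator_matrix(
    config: TransducerConfig,
    analyte_conc: float,
    cap: int = DEFAULT_STATE_CAP,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """States and CTMC generator ``Q`` (rows sum to zero) of the loss-free chain."""
    states = enumerate_states(config, cap=cap)
    index = {st: i for i, st in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    jumps = {
        "analyte_capture": (1, 0),
        "analyte_release": (-1, 0),
        "bond_form": (0, 1),
        "bond_break": (0, -1),
    }
    for (a, b), i in index.items():
        st = SystemState(a, b, config.n_psb, config.n_ssb)
        for label, rate in propensities(st, config, analyte_conc):
            if rate <= 0 or label not in jumps:
                continue
            da, db = jumps[label]
            j = index[(a + da, b + db)]
            q[i, j] += rate
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return states, q


def stationary_distribution(
    config: TransducerConfig,
    analyte_conc: float,
    cap: int = DEFAULT_STATE_CAP,
) -> dict[tuple[int, int], float]:
    """Exact stationary distribution ``pi`` of the loss-free chain.

    Solves ``pi Q = 0`` with normalization; the chain has a single recurrent
    class for any non-degenerate rate set, so the solution is unique.  A
    solve that fails the global-balance residual or produces negative mass
    raises a diagnostic.
    """
    states, q = generator_matrix(config, analyte_conc, cap=cap)
    n = len(states)
    m = q.T.copy()
    m[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        pi = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate rates
        raise ValueError(
            f"stationary solve failed ({exc}); the chain may have multiple "
            "recurrent classes (e.g. all dissociation rates zero)"
        ) from exc
    if pi.min() < -1e-9:
        raise ValueError(
            f"stationary solve produced negative probability (min {pi.min():.3e}); "
            "the generator is ill-conditioned for these rates"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ q).max()
    scale = max(1.0, np.abs(q).max())
    if resid > 1e-10 * scale:
        raise ValueError(f"global balance residual too large: {resid:.3e}")
    return {st: float(p) for st, p in zip(states, pi)}


def _unbound_to_bound_flux(
    config: TransducerConfig, analyte_conc: float, pi: dict[tuple[int, int], float]
) -> float:
    flux = 0.0
    for (a, b), p in pi.items():
        if b != 0:
            continue
        st = SystemState(a, 0, config.n_psb, config.n_ssb)
        rate = dict(propensities(st, config, analyte_conc))["bond_form"]
        flux += p * rate
    return flux


def stationary_switching_activity(
    config: TransducerConfig,
    analyte_conc: float,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Long-run switching activity in events per hour.

    A switching event is any unbound->bound or bound->unbound transition, so
    the activity is twice the stationary probability flux out of the unbound
    (``b = 0``) states.
    """
    if config.n_ssb == 0 or config.n_psb == 0 or config.rates.k_on_star == 0:
        return 0.0
    pi = stationary_distribution(config, analyte_conc, cap=cap)
    return 2.0 * _unbound_to_bound_flux(config, analyte_conc, pi) * SECONDS_PER_HOUR


def stationary_single_bound_fraction(
    config: TransducerConfig,
    analyte_conc: float,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Stationary fraction of time with exactly one PSB-SSB bond."""
    if config.n_ssb == 0 or config.n_psb == 0 or config.rates.k_on_star == 0:
        return 0.0
    pi = stationary_distribution(config, analyte_conc, cap=cap)
    return float(sum(p for (a, b), p in pi.items() if b == 1))


def stationary_bound_fraction(
    config: TransducerConfig,
    analyte_conc: float,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Stationary fraction of time in the bound state (``b >= 1``)."""
    if config.n_ssb == 0 or config.n_psb == 0 or config.rates.k_on_star == 0:
        return 0.0
    pi = stationary_distribution(config, analyte_conc, cap=cap)
    return float(sum(p for (a, b), p in pi.items() if b >= 1))


def stationary_drc(
    config: TransducerConfig,
    concentrations,
    cap: int = DEFAULT_STATE_CAP,
) -> np.ndarray:
    """Exact dose-response curve: switching activity (events/h) per concentration."""
    return np.array(
        [stationary_switching_activity(config, c, cap=cap) for c in concentrations]
    )


def oracle_ec50(
    config: TransducerConfig,
    conc_lo: float,
    conc_hi: float,
    n_grid: int = 200,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Half-activity concentration from a dense exact dose-response curve.

    The activity at zero analyte anchors the top of the curve; the returned
    concentration is where the oracle activity crosses half that value
    (log-interpolated).  Intended for monotone (sigmoidal) regimes.
    """
    top = stationary_switching_activity(config, 0.0, cap=cap)
    if top <= 0:
        raise ValueError("transducer is non-responsive: zero activity at blank")
    grid = np.logspace(np.log10(conc_lo), np.log10(conc_hi), n_grid)
    act = stationary_drc(config, grid, cap=cap)
    half = 0.5 * top
    below = np.nonzero(act <= half)[0]
    if len(below) == 0:
        raise ValueError("activity never falls to half its blank value in range")
    i = below[0]
    if i == 0:
        return float(grid[0])
    # log-linear interpolation between the bracketing grid points
    x0, x1 = np.log10(grid[i - 1]), np.log10(grid[i])
    y0, y1 = act[i - 1], act[i]
    t = (half - y0) / (y1 - y0)
    return float(10 ** (x0 + t * (x1 - x0)))
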