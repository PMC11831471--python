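"""Shared test utilities: batch-mean Monte Carlo errors and brute-force oracles."""

from __future__ import annotations

import numpy as np

from bpmsim import ConcentrationProfile, TransducerConfig, simulate
from bpmsim.observables import (
    bound_fraction,
    single_bound_fraction,
    state_trace,
    switching_activity,
)


def batch_estimates(trace, total_s: float, n_batches: int = 10):
    """Per-batch (bound fraction, single-bound fraction, activity/h) arrays."""
    edges = np.linspace(0.0, total_s, n_batches + 1)
    bf, sbf, act = [], [], []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        w = (float(t0), float(t1))
        bf.append(bound_fraction(trace, w))
        sbf.append(single_bound_fraction(trace, w))
        act.append(switching_activity(state_trace(trace, w)))
    return np.array(bf), np.array(sbf), np.array(act)


def mean_and_se(batch_values: np.ndarray) -> tuple[float, float]:
    k = len(batch_values)
    return float(np.mean(batch_values)), float(np.std(batch_values, ddof=1) / np.sqrt(k))


def long_run(config: TransducerConfig, conc: float, hours: float, seed: int):
    profile = ConcentrationProfile.constant(conc, hours * 3600.0)
    return simulate(config, profile, seed=seed, record="bonds")


def naive_switch_times(trace, t0: float, t1: float) -> list[float]:
    """Brute-force full scan for bound/unbound flips strictly inside (t0, t1)."""
    out = []
    prev_bound = trace.state0.b >= 1
    for i in range(len(trace.times)):
        t = float(trace.times[i])
        nb = bool(trace.b[i] >= 1)
        if nb != prev_bound and t0 < t < t1:
            out.append(t)
        prev_bound = nb
    return out
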