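"""Run configuration: defaults, provenance tags, YAML round-tripping.

Every tunable parameter of the pipeline lives in one nested ``RunConfig``.
Each parameter carries a provenance tag: ``"protocol"`` for values the
emulated experimental protocol states (series counts, tracking spans, the
measured binder-loss scale) and ``"assumed"`` for package-chosen defaults
(rate constants, ladder span, classification thresholds, phase-bin span),
which were not published and must be treated as adjustable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dose_response import ExperimentDesign, PopulationSpec, default_ladder
from .motion import MotionParams
from .reaction_model import RateConstants

__all__ = ["RunConfig", "ClassificationConfig", "PhaseConfig", "PARAM_PROVENANCE"]

#: dotted parameter name -> provenance tag
PARAM_PROVENANCE = {
    "rates.k_on": "assumed",
    "rates.k_off_analyte": "assumed",
    "rates.k_on_star": "assumed",
    "rates.k_off_bond": "assumed",
    "population.n_particles": "assumed",
    "population.mean_n_psb": "assumed",
    "population.mean_n_ssb": "assumed",
    "loss.lambda_psb_per_s": "protocol",  # scale set by the measured 1.6 %/h product loss
    "loss.lambda_ssb_per_s": "protocol",
    "design.n_series": "protocol",
    "design.n_applications": "protocol",
    "design.obs_duration_s": "protocol",
    "design.dead_time_s": "assumed",
    "design.ladder": "assumed",
    "classification.bell_ratio": "assumed",
    "classification.floor_activity_per_h": "assumed",
    "phase.bin_edges": "assumed",
    "phase.amplitude_floor_frac": "assumed",
    "motion.*": "assumed",
}


@dataclass(frozen=True)
class ClassificationConfig:
    bell_ratio: float = 0.8
    floor_activity_per_h: float = 2.0


@dataclass(frozen=True)
class PhaseConfig:
    bin_span_low: float = -math.pi / 3.0
    bin_span_high: float = 2.0 * math.pi / 3.0
    amplitude_floor_frac: float = 0.1

    @property
    def bin_edges(self) -> tuple[float, ...]:
        return tuple(
            self.bin_span_low + k * (self.bin_span_high - self.bin_span_low) / 6.0
            for k in range(7)
        )


@dataclass(frozen=True)
class RunConfig:
    """Full parameter set of one pipeline run."""

    seed: int = 0
    rates: RateConstants = field(default_factory=RateConstants)
    n_particles: int = 500
    mean_n_psb: float = 3.0
    mean_n_ssb: float = 8.0
    lambda_psb_per_s: float = 0.0
    lambda_ssb_per_s: float = 0.0
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    motion: MotionParams = field(default_factory=MotionParams)

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(
            n_particles=self.n_particles,
            mean_n_psb=self.mean_n_psb,
            mean_n_ssb=self.mean_n_ssb,
            rates=self.rates,
            loss_rate_psb=self.lambda_psb_per_s,
            loss_rate_ssb=self.lambda_ssb_per_s,
            master_seed=self.seed,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "rates": dataclasses.asdict(self.rates),
            "population": {
                "n_particles": self.n_particles,
                "mean_n_psb": self.mean_n_psb,
                "mean_n_ssb": self.mean_n_ssb,
            },
            "loss": {
                "lambda_psb_per_s": self.lambda_psb_per_s,
                "lambda_ssb_per_s": self.lambda_ssb_per_s,
            },
            "design": {
                "n_series": self.design.n_series,
                "n_applications": self.design.n_applications,
                "obs_duration_s": self.design.obs_duration_s,
                "dead_time_s": self.design.dead_time_s,
                "ladder": list(self.design.ladder),
            },
            "classification": dataclasses.asdict(self.classification),
            "phase": dataclasses.asdict(self.phase),
            "motion": dataclasses.asdict(self.motion),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        rates = RateConstants(**d.get("rates", {}))
        pop = d.get("population", {})
        loss = d.get("loss", {})
        des = dict(d.get("design", {}))
        if "ladder" in des:
            des["ladder"] = tuple(des["ladder"])
        else:
            n_app = des.get("n_applications", 8)
            des["ladder"] = default_ladder(rates.kd_analyte, n_app)
        return cls(
            seed=int(d.get("seed", 0)),
            rates=rates,
            n_particles=int(pop.get("n_particles", 500)),
            mean_n_psb=float(pop.get("mean_n_psb", 3.0)),
            mean_n_ssb=float(pop.get("mean_n_ssb", 8.0)),
            lambda_psb_per_s=float(loss.get("lambda_psb_per_s", 0.0)),
            lambda_ssb_per_s=float(loss.get("lambda_ssb_per_s", 0.0)),
            design=ExperimentDesign(**des),
            classification=ClassificationConfig(**d.get("classification", {})),
            phase=PhaseConfig(**d.get("phase", {})),
            motion=MotionParams(**d.get("motion", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Stable content hash of the configuration (first 12 hex digits)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
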