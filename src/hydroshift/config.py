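"""Pipeline and model configuration with schema-validated YAML round-trip.

All thresholds the analysis depends on live here so a run is fully
reproducible from one document: QC cutoffs, the post-MLE low-level filter,
model/optimizer settings, simulation parameters, and seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class QCConfig:
    detp_threshold: float = 0.01  # detection p above this = failed measurement
    probe_fail_sample_frac: float = 0.05  # probe dropped if failed in > this fraction of samples
    sample_fail_probe_frac: float = 0.10  # sample dropped if > this fraction of probes failed
    glial_cutoff: float = 0.50  # samples with glial proportion strictly above are removed
    low_level_cutoff: float = 0.01  # probes with mean beta_m or beta_h below are removed
    channels: str = "joint"  # joint | bs | oxbs: which detection matrices drive failure rules

    def validate(self) -> None:
        for name in ("detp_threshold", "probe_fail_sample_frac",
                     "sample_fail_probe_frac", "glial_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"qc.{name} must be in (0, 1), got {v}")
        if not (0.0 <= self.low_level_cutoff < 1.0):
            raise ValidationError(
                f"qc.low_level_cutoff must be in [0, 1), got {self.low_level_cutoff}"
            )
        if self.channels not in ("joint", "bs", "oxbs"):
            raise ValidationError(f"qc.channels must be joint|bs|oxbs, got {self.channels!r}")


@dataclass
class ModelConfig:
    clamp_eps: float = 1e-3  # beta values pushed into [eps, 1-eps]; ~array detection floor
    quadrature_nodes: int = 20  # Gauss-Hermite nodes for the random-intercept integral
    tol: float = 1e-8  # optimizer convergence tolerance
    max_iter: int = 500
    fdr_alpha: float = 0.05
    min_per_group: int = 3  # probes with fewer complete pairs per group are skipped
    standardize_covariates: bool = True  # center/scale glial and PMI (b3 test unaffected)
    backend: str = "beta"  # beta | lmm_logit (fast fallback: linear mixed model on logits)
    se_method: str = "sandwich"  # sandwich (cluster-robust by sample) | observed (information)

    def validate(self) -> None:
        if not (0.0 < self.clamp_eps < 0.01):
            raise ValidationError(f"model.clamp_eps must be in (0, 0.01), got {self.clamp_eps}")
        if self.quadrature_nodes < 5:
            raise ValidationError("model.quadrature_nodes must be >= 5")
        if not (0.0 <= self.fdr_alpha <= 1.0):
            raise ValidationError("model.fdr_alpha must be in [0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValidationError("model.tol must be > 0 and model.max_iter >= 1")
        if self.backend not in ("beta", "lmm_logit"):
            raise ValidationError(f"model.backend must be beta|lmm_logit, got {self.backend!r}")
        if self.se_method not in ("sandwich", "observed"):
            raise ValidationError(
                f"model.se_method must be sandwich|observed, got {self.se_method!r}"
            )


@dataclass
class MLEConfig:
    boundary_as_missing: bool = False  # stricter mode: drop h=0 boundary cells


@dataclass
class SimulationConfig:
    n_control: int = 29
    n_pd: int = 27
    n_probes: int = 2000
    prop_idmc: float = 0.10
    delta_magnitude: float = 0.10  # signed mC<->hmC shift size in the disease group
    phi_bs: float = 100.0  # beta-noise precision, BS channel
    phi_oxbs: float = 60.0  # oxBS chemistry is harsher -> noisier channel
    fail_rate_bs: float = 0.002
    fail_rate_oxbs: float = 0.02
    glial_effect: float = 0.5  # logit-scale coefficient on (centered) glial proportion
    pmi_effect: float = 0.05  # logit-scale coefficient on (centered) PMI
    pure_shift: bool = True  # effects conserve total modification (m+h) exactly
    shift_direction: str = "both"  # both | toward_hmc | toward_mc (sign of delta)

    def validate(self) -> None:
        if self.n_control < 0 or self.n_pd < 0:
            raise ValidationError("simulate.n_control / n_pd must be >= 0")
        if not (0.0 <= self.prop_idmc <= 1.0):
            raise ValidationError("simulate.prop_idmc must be in [0, 1]")
        if self.phi_bs <= 0 or self.phi_oxbs <= 0:
            raise ValidationError("simulate.phi_* must be > 0")
        for name in ("fail_rate_bs", "fail_rate_oxbs"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"simulate.{name} must be in [0, 1]")
        if self.shift_direction not in ("both", "toward_hmc", "toward_mc"):
            raise ValidationError(
                f"simulate.shift_direction must be both|toward_hmc|toward_mc, "
                f"got {self.shift_direction!r}"
            )


@dataclass
class PipelineConfig:
    """Top-level configuration; serializable round-trip via YAML."""

    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    mle: MLEConfig = field(default_factory=MLEConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> "PipelineConfig":
        self.qc.validate()
        self.model.validate()
        self.simulate.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {
            "qc": QCConfig, "mle": MLEConfig, "model": ModelConfig,
            "simulate": SimulationConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in known:
                sub_cls = known[key]
                valid = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(val) - valid
                if unknown:
                    raise ValidationError(f"config section {key!r}: unknown key(s) {sorted(unknown)}")
                kwargs[key] = sub_cls(**val)
            elif key == "seed":
                kwargs[key] = int(val)
            else:
                raise ValidationError(f"unknown config key {key!r}")
        return cls(**kwargs).validate()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(doc)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
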