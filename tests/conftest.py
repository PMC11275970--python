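"""Shared fixtures: small synthetic bundles and the two study-scale runs
(all-null and mixed) that several calibration/power tests share."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hydroshift.config import PipelineConfig
from hydroshift.pipeline import run_pipeline, simulate_inputs
from hydroshift.types import MLEEstimate, PairedBetaSet


def make_config(seed: int = 0, **sim_kwargs) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed)
    for k, v in sim_kwargs.items():
        setattr(cfg.simulate, k, v)
    return cfg.validate()


@pytest.fixture(scope="session")
def small_inputs():
    """A small but complete synthetic bundle (150 probes, 10+10 samples)."""
    cfg = make_config(seed=42, n_control=10, n_pd=10, n_probes=150, prop_idmc=0.2)
    return cfg, simulate_inputs(cfg)


@pytest.fixture(scope="session")
def small_run(small_inputs):
    cfg, inputs = small_inputs
    return cfg, inputs, run_pipeline(cfg, inputs)


@pytest.fixture(scope="session")
def null_run():
    """All-null cohort at study scale: 28+28 samples, 2000 probes, no effects."""
    cfg = make_config(
        seed=20260922, n_control=28, n_pd=28, n_probes=2000, prop_idmc=0.0
    )
    inputs = simulate_inputs(cfg)
    return cfg, inputs, run_pipeline(cfg, inputs)


@pytest.fixture(scope="session")
def mixed_run():
    """Mixed cohort: 2000 probes, 10% carrying a pure +0.10 mC->hmC shift."""
    cfg = make_config(
        seed=20260923, n_control=28, n_pd=28, n_probes=2000,
        prop_idmc=0.10, delta_magnitude=0.10, shift_direction="toward_hmc",
    )
    inputs = simulate_inputs(cfg)
    return cfg, inputs, run_pipeline(cfg, inputs)


def toy_mle(m: np.ndarray, h: np.ndarray, probe_ids=None, sample_ids=None) -> MLEEstimate:
    """Wrap plain arrays as an MLEEstimate (all-interior flags)."""
    m = np.asarray(m, dtype=float)
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(m.shape[0])]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(m.shape[1])]
    idx = pd.Index(probe_ids, name="probe_id")
    cols = pd.Index(sample_ids)
    flags = pd.DataFrame("interior", index=idx, columns=cols)
    return MLEEstimate(
        beta_m=pd.DataFrame(m, index=idx, columns=cols),
        beta_h=pd.DataFrame(np.asarray(h, dtype=float), index=idx, columns=cols),
        flags=flags,
    )


def toy_paired(bs: np.ndarray, oxbs: np.ndarray) -> PairedBetaSet:
    bs = np.asarray(bs, dtype=float)
    idx = pd.Index([f"cg{i:05d}" for i in range(bs.shape[0])], name="probe_id")
    cols = pd.Index([f"S{j:03d}" for j in range(bs.shape[1])])
    return PairedBetaSet(
        bs=pd.DataFrame(bs, index=idx, columns=cols),
        oxbs=pd.DataFrame(np.asarray(oxbs, dtype=float), index=idx, columns=cols),
    )
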