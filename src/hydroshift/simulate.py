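"""Synthetic paired BS/oxBS data with the structure the analysis assumes.

The generator emulates an EPIC-like paired experiment on sorted neuronal
nuclei: bimodal true methylation (m), low-level hydroxymethylation (h)
concentrated in the brain-typical 5-20% range, a disease-associated pure
mC<->hmC shift at a controlled fraction of probes, beta-distributed
measurement noise per channel (harsher for oxBS), detection-p failure
structure, and covariates matching the cohort the analysis was designed
around (postmortem parietal cortex, male, ~80 years old).

Ground truth is retained (:class:`SimulationTruth`) so downstream stages can
be tested for parameter recovery, calibration, power, and sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .types import PairedBetaSet, SampleRecord, ValidationError, validate_sheet


@dataclass
class CohortParams:
    """Covariate distributions per group; defaults mirror the target cohort."""

    age_mean: tuple[float, float] = (79.3, 79.4)  # (control, PD)
    age_sd: tuple[float, float] = (9.1, 7.1)
    age_range: tuple[float, float] = (53.0, 93.0)
    pmi_mean: tuple[float, float] = (3.25, 3.27)
    pmi_sd: tuple[float, float] = (0.81, 0.83)
    pmi_range: tuple[float, float] = (1.8, 5.5)
    # Glial proportion after neuron enrichment: beta(8, 15), mean ~0.35,
    # so the > 0.50 exclusion bites occasionally, as it did in practice.
    glial_a: float = 8.0
    glial_b: float = 15.0
    sex: str = "male"


@dataclass
class SimulationTruth:
    """Generator ground truth for parameter-recovery tests.

    Per probe: control-group true fractions ``m0`` (5mC) and ``h0`` (5hmC)
    and a signed shift ``delta`` — disease-group means are ``m0 - delta`` and
    ``h0 + delta``, so a positive delta is a shift toward 5hmC and total
    modification m + h is conserved exactly (pure-shift model).
    """

    probe_ids: list[str]
    m0: np.ndarray
    h0: np.ndarray
    delta: np.ndarray
    phi_bs: float
    phi_oxbs: float
    fail_rate_bs: float
    fail_rate_oxbs: float
    cov_effects: tuple[float, float]  # logit-scale (glial, pmi) coefficients
    seed: int
    pure_shift: bool = True
    delta_m: np.ndarray | None = None  # used only when pure_shift is False
    delta_h: np.ndarray | None = None

    @property
    def is_idmc(self) -> np.ndarray:
        return self.delta != 0.0

    def validate(self) -> "SimulationTruth":
        m1 = self.m0 - self.delta
        h1 = self.h0 + self.delta
        ok = (
            (self.m0 >= 0) & (self.h0 >= 0) & (self.m0 + self.h0 <= 1.0)
            & (m1 >= 0) & (h1 >= 0) & (m1 + h1 <= 1.0)
        )
        if not np.all(ok):
            raise ValidationError(
                f"simulation truth violates simplex at probe "
                f"{self.probe_ids[int(np.argmax(~ok))]!r}"
            )
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m0": self.m0,
                "h0": self.h0,
                "delta": self.delta,
                "is_idmc": self.is_idmc,
            },
            index=pd.Index(self.probe_ids, name="probe_id"),
        )


def simulate_cohort(
    n_control: int,
    n_pd: int,
    seed: int,
    params: CohortParams | None = None,
) -> list[SampleRecord]:
    """Draw a sample sheet with group, age, PMI, and glial proportion.

    Ages and PMIs are normal draws clipped to the plausible cohort range;
    glial proportion is beta-distributed in [0, 1]; sex defaults to male
    (the analyzable cohort was male-only after QC).
    """
    if n_control < 0 or n_pd < 0:
        raise ValidationError("n_control and n_pd must be >= 0")
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    records = []
    for gi, (group, n) in enumerate((("control", n_control), ("PD", n_pd))):
        age = np.clip(
            rng.normal(params.age_mean[gi], params.age_sd[gi], size=n), *params.age_range
        )
        pmi = np.clip(
            rng.normal(params.pmi_mean[gi], params.pmi_sd[gi], size=n), *params.pmi_range
        )
        glial = rng.beta(params.glial_a, params.glial_b, size=n)
        tag = "C" if group == "control" else "P"
        for k in range(n):
            records.append(
                SampleRecord(
                    sample_id=f"{tag}{k + 1:03d}",
                    group=group,
                    sex=params.sex,
                    age_years=float(age[k]),
                    pmi_hours=float(pmi[k]),
                    glial_proportion=float(glial[k]),
                )
            )
    return validate_sheet(records)


def simulate_truth(
    n_probes: int,
    prop_idmc: float,
    delta_magnitude: float,
    seed: int,
    config: SimulationConfig | None = None,
) -> SimulationTruth:
    """Draw per-probe ground truth (m0, h0, delta).

    m0 is bimodal (mixture of a low and a high beta component, as CpG
    methylation is); h0 is low-level with mean ~0.12, reflecting the high
    but still minor 5hmC fraction in neuronal DNA. ``floor(prop_idmc *
    n_probes)`` probes receive a shift of +/- ``delta_magnitude`` with
    random sign, assigned only where the simplex constraints allow it.
    """
    if n_probes < 1:
        raise ValidationError("n_probes must be >= 1")
    if not (0.0 <= prop_idmc <= 1.0):
        raise ValidationError("prop_idmc must be in [0, 1]")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    # bimodal methylation: ~35% lowly methylated, ~65% highly methylated
    low = rng.random(n_probes) < 0.35
    m0 = np.where(low, rng.beta(1.5, 12.0, n_probes), rng.beta(10.0, 3.0, n_probes))
    h0 = rng.beta(3.0, 22.0, n_probes)  # mean 0.12, sd ~0.06
    # joint resample where the pair exceeds the simplex
    bad = m0 + h0 > 1.0
    while np.any(bad):
        k = int(bad.sum())
        lo = rng.random(k) < 0.35
        m0[bad] = np.where(lo, rng.beta(1.5, 12.0, k), rng.beta(10.0, 3.0, k))
        h0[bad] = rng.beta(3.0, 22.0, k)
        bad = m0 + h0 > 1.0

    n_effect = int(np.floor(prop_idmc * n_probes))
    delta = np.zeros(n_probes)
    if n_effect > 0:
        if delta_magnitude <= 0:
            raise ValidationError("delta_magnitude must be > 0 when prop_idmc > 0")
        if cfg.shift_direction == "toward_hmc":
            sign = np.ones(n_probes)
        elif cfg.shift_direction == "toward_mc":
            sign = -np.ones(n_probes)
        else:
            sign = np.where(rng.random(n_probes) < 0.5, 1.0, -1.0)
        # a positive delta needs m0 headroom, a negative one needs h0 headroom
        feasible = np.where(sign > 0, m0 >= delta_magnitude, h0 >= delta_magnitude)
        if cfg.shift_direction == "both":
            # flip the sign where only the other direction fits
            other_ok = np.where(sign > 0, h0 >= delta_magnitude, m0 >= delta_magnitude)
            sign = np.where(~feasible & other_ok, -sign, sign)
            feasible = np.where(sign > 0, m0 >= delta_magnitude, h0 >= delta_magnitude)
        candidates = np.flatnonzero(feasible)
        if candidates.size < n_effect:
            raise ValidationError(
                f"cannot place {n_effect} effect probes: only {candidates.size} "
                f"probes can absorb a shift of {delta_magnitude}"
            )
        chosen = rng.choice(candidates, size=n_effect, replace=False)
        delta[chosen] = sign[chosen] * delta_magnitude

    probe_ids = [f"cg{k:08d}" for k in range(n_probes)]
    return SimulationTruth(
        probe_ids=probe_ids,
        m0=m0,
        h0=h0,
        delta=delta,
        phi_bs=cfg.phi_bs,
        phi_oxbs=cfg.phi_oxbs,
        fail_rate_bs=cfg.fail_rate_bs,
        fail_rate_oxbs=cfg.fail_rate_oxbs,
        cov_effects=(cfg.glial_effect, cfg.pmi_effect),
        seed=seed,
        pure_shift=cfg.pure_shift,
    ).validate()


def _channel_means(truth: SimulationTruth, sheet: list[SampleRecord]) -> tuple[np.ndarray, np.ndarray]:
    """True per-probe x per-sample channel means on the probability scale.

    BS reads total modification (m + h); oxBS reads m only. Covariate
    effects act on the logit of each channel mean, with covariates centered
    at the cohort mean so probe-level means stay at the truth marginally.
    """
    group = np.array([1.0 if r.group == "PD" else 0.0 for r in sheet])
    glial = np.array([r.glial_proportion for r in sheet])
    pmi = np.array([r.pmi_hours for r in sheet])
    c_glial, c_pmi = truth.cov_effects
    shift = c_glial * (glial - glial.mean()) + c_pmi * (pmi - pmi.mean())  # (s,)

    m = truth.m0[:, None] - truth.delta[:, None] * group[None, :]  # (p, s)
    h = truth.h0[:, None] + truth.delta[:, None] * group[None, :]
    eps = 1e-9
    mu_bs = expit(logit(np.clip(m + h, eps, 1 - eps)) + shift[None, :])
    mu_ox = expit(logit(np.clip(m, eps, 1 - eps)) + shift[None, :])
    return mu_bs, mu_ox


def simulate_betas(
    truth: SimulationTruth,
    sheet: list[SampleRecord],
    seed: int | None = None,
) -> tuple[PairedBetaSet, pd.DataFrame, pd.DataFrame]:
    """Draw observed beta matrices and detection-p matrices.

    Observed beta ~ Beta(mean * phi, (1 - mean) * phi) per channel. A
    fraction ``fail_rate_*`` of entries per channel fail: their detection
    p-value is drawn above 0.01 and their beta is set missing; passing
    entries draw detection p uniformly below 0.01.
    """
    if not sheet or len(truth.probe_ids) == 0:
        raise ValidationError("truth and samples must be non-empty")
    if truth.phi_bs <= 0 or truth.phi_oxbs <= 0:
        raise ValidationError("beta-noise precision phi must be > 0")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    mu_bs, mu_ox = _channel_means(truth, sheet)

    def draw_channel(mu, phi, fail_rate):
        a = np.clip(mu * phi, 1e-8, None)
        b = np.clip((1.0 - mu) * phi, 1e-8, None)
        beta = rng.beta(a, b)
        # beta draws landing numerically on 0/1 are nudged into (0, 1)
        tiny = np.finfo(float).tiny
        beta = np.clip(beta, tiny, 1.0 - np.finfo(float).epsneg)
        failed = rng.random(mu.shape) < fail_rate
        detp = np.where(
            failed,
            0.01 + rng.random(mu.shape) * 0.99,
            rng.random(mu.shape) * 0.01,
        )
        beta = np.where(failed, np.nan, beta)
        return beta, detp

    beta_bs, detp_bs = draw_channel(mu_bs, truth.phi_bs, truth.fail_rate_bs)
    beta_ox, detp_ox = draw_channel(mu_ox, truth.phi_oxbs, truth.fail_rate_oxbs)

    idx = pd.Index(truth.probe_ids, name="probe_id")
    cols = pd.Index([r.sample_id for r in sheet], name=None)
    paired = PairedBetaSet(
        bs=pd.DataFrame(beta_bs, index=idx, columns=cols),
        oxbs=pd.DataFrame(beta_ox, index=idx, columns=cols),
    )
    return (
        paired,
        pd.DataFrame(detp_bs, index=idx, columns=cols),
        pd.DataFrame(detp_ox, index=idx, columns=cols),
    )


def simulate_manifest(
    truth: SimulationTruth,
    seed: int,
    masked_frac: float = 0.05,
    genic_frac: float = 0.65,
) -> pd.DataFrame:
    """Invent a probe manifest for the truth's probes.

    Probes are scattered over two chromosomes with unique positions; a
    fraction are masked (standing in for cross-reactive/SNP probes), genic
    probes get 1-2 gene symbols and an array feature class, the rest are
    intergenic.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.probe_ids)
    chroms = rng.choice(["chr1", "chr2"], size=n)
    pos = np.zeros(n, dtype=int)
    for c in ("chr1", "chr2"):
        sel = chroms == c
        pos[sel] = np.sort(rng.choice(np.arange(1, 10_000_001), size=int(sel.sum()), replace=False))
    genic = rng.random(n) < genic_frac
    features = np.where(
        genic,
        rng.choice(["Body", "TSS1500", "TSS200", "5'UTR", "3'UTR"], size=n, p=[0.5, 0.2, 0.1, 0.1, 0.1]),
        "intergenic",
    )
    gene_pool = np.array([f"GENE{k:04d}" for k in range(max(20, n // 3))])
    symbols = []
    for k in range(n):
        if not genic[k]:
            symbols.append("")
        elif rng.random() < 0.1:  # occasional multi-gene (and duplicate) fields
            g1, g2 = rng.choice(gene_pool, size=2, replace=False)
            symbols.append(f"{g1};{g2}" if rng.random() < 0.7 else f"{g1};{g1}")
        else:
            symbols.append(str(rng.choice(gene_pool)))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "gene_symbols": symbols,
            "feature": features,
            "masked": rng.random(n) < masked_frac,
        },
        index=pd.Index(truth.probe_ids, name="probe_id"),
    )


def simulate_chrom_states(
    manifest: pd.DataFrame,
    seed: int,
    tile: int = 2000,
    states: tuple[str, ...] = ("TSS", "Enh", "Tx", "ReprPC", "Quies"),
) -> pd.DataFrame:
    """Tile each chromosome with fixed-width labeled intervals (BED4 semantics)."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub in manifest.groupby("chrom"):
        hi = int(sub["pos"].max()) + tile
        starts = np.arange(0, hi, tile)
        labels = rng.choice(states, size=starts.size)
        for s, lab in zip(starts, labels):
            rows.append((chrom, int(s), int(s + tile), str(lab)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def simulate_from_model(
    n_per_group: int,
    b: tuple[float, float, float, float, float, float],
    sigma_u: float,
    phi: float,
    seed: int,
) -> pd.DataFrame:
    """Draw one probe's paired data directly from the interaction model.

    Used for parameter recovery: rows follow the model's own data-generating
    process — logit(mu) = b0 + b1*group + b2*modtype + b3*group*modtype +
    b4*glial + b5*pmi + u_sample, y ~ Beta(mu*phi, (1-mu)*phi). Returns a
    long-format frame with one mC row and one hmC row per sample.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.repeat([0.0, 1.0], n_per_group)
    glial = rng.normal(0.0, 1.0, n)
    pmi = rng.normal(0.0, 1.0, n)
    u = rng.normal(0.0, sigma_u, n)
    rows = []
    b0, b1, b2, b3, b4, b5 = b
    for j in range(n):
        for mod in (0.0, 1.0):
            eta = b0 + b1 * group[j] + b2 * mod + b3 * group[j] * mod
            eta += b4 * glial[j] + b5 * pmi[j] + u[j]
            mu = expit(eta)
            y = rng.beta(mu * phi, (1 - mu) * phi)
            rows.append((f"S{j:04d}", mod, y, group[j], glial[j], pmi[j]))
    return pd.DataFrame(rows, columns=["sample_id", "modtype", "y", "group", "glial", "pmi"])
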