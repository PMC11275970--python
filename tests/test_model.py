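"""Interaction model: design construction, BH-FDR against an independent
step-up implementation, histogram diagnostics, symmetry/equivariance of the
fit, and a quadrature/maximization oracle on small instances."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

from hydroshift.config import ModelConfig
from hydroshift.model import (
    DesignError,
    bh_fdr,
    build_long_design,
    classify_direction,
    fit_all,
    fit_probe,
    marginal_loglik,
    pvalue_histogram,
)
from hydroshift.simulate import simulate_cohort, simulate_from_model
from hydroshift.types import SampleRecord, ValidationError

from .conftest import toy_mle


def step_up_reference(p):
    """Independent BH step-up: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_bh_hand_computed_example():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_trivial_cases():
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValidationError):
        bh_fdr([0.5, 1.5])


def test_bh_matches_independent_reference_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(500):
        p = rng.random(rng.integers(1, 60))
        q = bh_fdr(p)
        np.testing.assert_allclose(q, step_up_reference(p), atol=1e-12)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted p


def test_pvalue_histogram_labels():
    rng = np.random.default_rng(1)
    ok = 0
    for _ in range(20):
        _, label = pvalue_histogram(rng.random(10_000))
        ok += label == "uniform-ish"
    assert ok >= 19
    _, label = pvalue_histogram(np.full(200, 0.001))
    assert label == "anti-conservative"
    _, label = pvalue_histogram(np.full(200, 0.999))
    assert label == "conservative"
    with pytest.raises(ValidationError):
        pvalue_histogram([])
    with pytest.raises(ValidationError):
        pvalue_histogram([0.5], bins=1)


def test_classify_direction():
    assert classify_direction(2.1) == "toward_hmC"
    assert classify_direction(-0.3) == "toward_mC"
    assert classify_direction(0.0, with_flag=True) == ("toward_mC", True)
    with pytest.raises(ValidationError):
        classify_direction(np.nan)


def _sheet(n=8):
    return [
        SampleRecord(f"S{j:03d}", "PD" if j % 2 else "control", "male",
                     70.0 + j, 3.0 + 0.1 * j, 0.2 + 0.01 * j)
        for j in range(n)
    ]


def test_build_long_design_row_counts_and_clamping():
    sheet = _sheet(8)
    m = np.full((1, 8), 0.5)
    h = np.full((1, 8), 0.1)
    h[0, 0] = 0.0  # clamps to eps
    mle = toy_mle(m, h, sample_ids=[r.sample_id for r in sheet])
    cfg = ModelConfig()
    design = build_long_design(mle, sheet, "cg00000", cfg)
    assert len(design) == 16  # two rows per sample
    assert design["y"].min() == pytest.approx(cfg.clamp_eps)
    assert design["y"].between(cfg.clamp_eps, 1 - cfg.clamp_eps).all()

    # a sample missing one mark drops both of its rows
    h2 = h.copy()
    h2[0, 3] = np.nan
    mle2 = toy_mle(m, h2, sample_ids=[r.sample_id for r in sheet])
    assert len(build_long_design(mle2, sheet, "cg00000", cfg)) == 14


def test_build_long_design_min_group_rule():
    sheet = _sheet(4)  # 2 per group < default minimum of 3
    mle = toy_mle(np.full((1, 4), 0.5), np.full((1, 4), 0.1),
                  sample_ids=[r.sample_id for r in sheet])
    with pytest.raises(DesignError, match="complete"):
        build_long_design(mle, sheet, "cg00000")


def test_fit_probe_exact_symmetry_gives_null_interaction():
    # identical group means in both modalities force b3 ~ 0
    sheet = _sheet(12)
    rng = np.random.default_rng(3)
    base_m = rng.random(6) * 0.3 + 0.3
    base_h = rng.random(6) * 0.1 + 0.05
    m = np.tile(np.repeat(base_m, 2), (1, 1))
    h = np.tile(np.repeat(base_h, 2), (1, 1))
    mle = toy_mle(m, h, sample_ids=[r.sample_id for r in sheet])
    # covariates constant so the symmetry is exact
    sheet = [SampleRecord(r.sample_id, r.group, r.sex, 75.0, 3.0, 0.3) for r in sheet]
    res = fit_probe(build_long_design(mle, sheet, "cg00000"), ModelConfig())
    assert abs(res.b3) < 1e-5


def test_fit_probe_label_equivariance():
    # swapping group labels negates b1 and b3 and leaves p unchanged
    df = simulate_from_model(25, (-1.0, 0.3, -1.5, 0.4, 0.1, 0.0), 0.2, 40.0, seed=4)
    cfg = ModelConfig()
    r1 = fit_probe(df, cfg)
    flipped = df.assign(group=1.0 - df["group"])
    r2 = fit_probe(flipped, cfg)
    assert r2.b3 == pytest.approx(-r1.b3, abs=1e-4)
    assert r2.b1 == pytest.approx(-r1.b1, abs=1e-3)
    assert r2.p == pytest.approx(r1.p, abs=1e-4)


def test_fit_probe_recovers_known_interaction():
    df = simulate_from_model(400, (-1.0, 0.1, -2.0, 0.5, 0.2, -0.1), 0.3, 50.0, seed=5)
    res = fit_probe(df, ModelConfig())
    assert res.converged
    assert res.b3 == pytest.approx(0.5, abs=3 * res.se_b3)
    assert res.sigma_u == pytest.approx(0.3, abs=0.1)
    assert np.exp(res.log_phi) == pytest.approx(50.0, rel=0.25)


def test_fit_probe_constant_covariate_dropped():
    df = simulate_from_model(20, (-1.0, 0.2, -1.5, 0.3, 0.0, 0.0), 0.2, 40.0, seed=6)
    df["glial"] = 0.35  # constant
    res = fit_probe(df, ModelConfig())
    assert res.converged
    assert res.b4 == 0.0


def test_marginal_loglik_matches_direct_integration():
    # Gauss-Hermite marginalization vs brute-force numeric integration of
    # the random intercept, on a tiny design
    df = simulate_from_model(4, (-0.5, 0.2, -1.0, 0.3, 0.0, 0.0), 0.4, 30.0, seed=7)
    cfg = ModelConfig(min_per_group=2)
    res = fit_probe(df, cfg)
    theta = np.array([res.b0, res.b1, res.b2, res.b3, res.b4, res.b5,
                      res.log_phi, np.log(res.sigma_u), 1.0])

    wide = df.pivot_table(index="sample_id", columns="modtype", values="y", sort=False)
    meta = df.drop_duplicates("sample_id").set_index("sample_id").loc[wide.index]
    y = wide.to_numpy()
    group = meta["group"].to_numpy()
    glial = meta["glial"].to_numpy()
    pmi = meta["pmi"].to_numpy()
    # covariates were standardized inside the fit; reproduce that here
    glial = (glial - glial.mean()) / glial.std()
    pmi = (pmi - pmi.mean()) / pmi.std()
    phi = np.exp(theta[6])
    sig = np.exp(theta[7])

    def beta_logpdf(v, mu):
        from scipy.stats import beta as beta_dist
        return beta_dist.logpdf(v, mu * phi, (1 - mu) * phi)

    ll_direct = 0.0
    for j in range(y.shape[0]):
        def integrand(u, j=j):
            eta0 = theta[0] + theta[1] * group[j] + theta[4] * glial[j] + theta[5] * pmi[j] + u
            eta1 = eta0 + theta[2] + theta[3] * group[j]
            dens = np.exp(beta_logpdf(y[j, 0], expit(eta0))
                          + beta_logpdf(y[j, 1], expit(eta1)))
            return dens * np.exp(-0.5 * (u / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        val, _ = integrate.quad(integrand, -8 * sig, 8 * sig, limit=200)
        ll_direct += np.log(val)

    x, w = np.polynomial.hermite.hermgauss(cfg.quadrature_nodes)
    ll_gh = marginal_loglik(theta, y, group, glial, pmi, x, np.log(w))
    assert ll_gh == pytest.approx(ll_direct, abs=1e-4)

    # and the optimizer's solution is a maximum: random perturbations never win
    rng = np.random.default_rng(8)
    for _ in range(100):
        pert = theta.copy()
        pert[:8] += rng.normal(0, 0.05, 8)
        assert marginal_loglik(pert, y, group, glial, pmi, x, np.log(w)) <= ll_gh + 1e-6


def test_fit_all_order_invariance_and_duplicates():
    sheet = simulate_cohort(6, 6, seed=9)
    rng = np.random.default_rng(9)
    n = 5
    m = rng.random((n, 12)) * 0.4 + 0.3
    h = rng.random((n, 12)) * 0.15 + 0.02
    ids = [f"cg{i:05d}" for i in range(n)]
    mle = toy_mle(m, h, probe_ids=ids, sample_ids=[r.sample_id for r in sheet])
    cfg = ModelConfig()
    res1 = fit_all(mle, sheet, ids, cfg)
    res2 = fit_all(mle, sheet, ids[::-1], cfg)
    for pid in ids:
        assert res1.loc[pid, "b3"] == res2.loc[pid, "b3"]
        assert res1.loc[pid, "p"] == res2.loc[pid, "p"]

    # a duplicated probe (same data under a second id) gets identical coefficients
    m2 = np.vstack([m, m[:1]])
    h2 = np.vstack([h, h[:1]])
    mle2 = toy_mle(m2, h2, probe_ids=ids + ["cg_dup"],
                   sample_ids=[r.sample_id for r in sheet])
    res3 = fit_all(mle2, sheet, ids + ["cg_dup"], cfg)
    assert res3.loc["cg_dup", "b3"] == res3.loc[ids[0], "b3"]


def test_fit_all_q_over_converged_only():
    sheet = simulate_cohort(6, 6, seed=10)
    rng = np.random.default_rng(10)
    m = rng.random((3, 12)) * 0.4 + 0.3
    h = rng.random((3, 12)) * 0.15 + 0.02
    h[0, :10] = np.nan  # too few complete pairs -> skipped
    mle = toy_mle(m, h, sample_ids=[r.sample_id for r in sheet])
    res = fit_all(mle, sheet, list(mle.beta_m.index), ModelConfig())
    assert not res.iloc[0]["converged"]
    assert np.isnan(res.iloc[0]["q"])
    conv = res[res["converged"]]
    np.testing.assert_allclose(conv["q"], step_up_reference(conv["p"].to_numpy()))


def test_lmm_backend_runs_and_agrees_in_sign():
    df = simulate_from_model(60, (-1.0, 0.1, -1.5, 0.8, 0.1, 0.0), 0.2, 60.0, seed=11)
    beta = fit_probe(df, ModelConfig())
    lmm = fit_probe(df, ModelConfig(backend="lmm_logit"))
    assert lmm.backend == "lmm_logit" and lmm.converged
    assert np.sign(lmm.b3) == np.sign(beta.b3)
    assert lmm.p < 0.05 and beta.p < 0.05
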