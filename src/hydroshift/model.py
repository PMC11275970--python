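"""Per-CpG disease x modification interaction model.

For each probe the paired (beta_m, beta_h) values are stacked long — one mC
row and one hmC row per sample — and fit with a beta-family mixed model:

    y_jk ~ Beta(mu_jk * phi, (1 - mu_jk) * phi)
    logit(mu_jk) = b0 + b1*group_j + b2*modtype_k + b3*group_j*modtype_k
                 + b4*glial_j + b5*pmi_j + u_j,      u_j ~ N(0, sigma_u^2)

with the sample-level random intercept u_j integrated out by Gauss-Hermite
quadrature. The interaction coefficient b3 is the quantity of interest: a
positive b3 means the disease group shifts modification from 5mC toward
5hmC relative to controls.

Inference on b3 is a cluster-robust Wald test: the default standard error
is the sandwich estimator with samples as the independent clusters, and
z = b3 / se_b3 is referred to a t distribution with (n_samples - 1)
degrees of freedom — the standard finite-sample reference for
cluster-robust inference. The robust variance matters here: the paired
deconvolution makes beta_m and beta_h share the oxBS measurement with
opposite signs, so their errors anti-correlate within a sample, and a
nonnegative-variance random intercept cannot represent that (sigma_u
collapses to zero); the model-based information SE is then badly
anti-conservative while the sandwich SE remains valid under arbitrary
within-sample dependence. The information SE (normal reference) is kept as
a config option. Benjamini-Hochberg FDR is applied across probes.

A fast fallback backend (``lmm_logit``) fits a linear mixed model on
logit-transformed y with the same design; it is clearly labeled in results
and is not the canonical model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit
from scipy.stats import binomtest, norm, t as student_t
from statsmodels.stats.multitest import multipletests

from .config import ModelConfig
from .types import MLEEstimate, SampleRecord, ValidationError, sheet_to_frame

log = logging.getLogger(__name__)

TOWARD_HMC = "toward_hmC"
TOWARD_MC = "toward_mC"

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_PI = 0.5 * np.log(np.pi)

DESIGN_COLUMNS = ["sample_id", "modtype", "y", "group", "glial", "pmi"]


class DesignError(ValidationError):
    """A probe's design cannot support the interaction model."""


@dataclass
class IDMCResult:
    """Interaction-model output for one probe."""

    probe_id: str
    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    se_b3: float
    z: float
    p: float
    sigma_u: float
    log_phi: float
    converged: bool
    n_used: int
    backend: str = "beta"
    q: float = np.nan
    direction: str = ""


def clamp_unit(y: np.ndarray, eps: float) -> np.ndarray:
    """Push values into [eps, 1 - eps]; the beta likelihood needs open (0, 1)."""
    return np.clip(y, eps, 1.0 - eps)


def classify_direction(b3: float, with_flag: bool = False):
    """Sign convention for the interaction term.

    b3 > 0: relative decrease in 5mC with an increase in 5hmC in the disease
    group (shift toward hmC); b3 < 0 the reverse. Exactly zero is labeled
    toward_mC by convention and flagged when ``with_flag`` is set.
    """
    if not np.isfinite(b3):
        raise ValidationError(f"b3 must be finite, got {b3}")
    label = TOWARD_HMC if b3 > 0 else TOWARD_MC
    if with_flag:
        return label, b3 == 0.0
    return label


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pvalue_histogram(pvals, bins: int = 20):
    """Equal-width p-value histogram with a calibration label.

    Labels ``anti-conservative`` when the first bin significantly exceeds
    the uniform expectation (one-sided binomial test at 0.01),
    ``conservative`` when the last bin does, else ``uniform-ish``. The
    anti-conservative shape — uniform with an overabundance of low p-values
    — is the expected diagnostic for a well-specified model over a mix of
    null and signal probes.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("pvalue_histogram: empty input")
    if bins < 2:
        raise ValidationError("pvalue_histogram: bins must be >= 2")
    counts, _ = np.histogram(p, bins=bins, range=(0.0, 1.0))
    n = int(p.size)
    first = binomtest(int(counts[0]), n, 1.0 / bins, alternative="greater").pvalue
    last = binomtest(int(counts[-1]), n, 1.0 / bins, alternative="greater").pvalue
    if first < 0.01:
        label = "anti-conservative"
    elif last < 0.01:
        label = "conservative"
    else:
        label = "uniform-ish"
    return counts, label


def build_long_design(
    mle: MLEEstimate,
    sheet: list[SampleRecord],
    probe_id: str,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Stack one probe's paired values into the model's long format.

    One mC row (modtype 0) and one hmC row (modtype 1) per sample with both
    values present; samples missing either value are dropped (the pairing
    is what the model tests). y is clamped into [eps, 1 - eps].
    """
    cfg = config or ModelConfig()
    if probe_id not in mle.beta_m.index or probe_id not in mle.beta_h.index:
        raise DesignError(f"probe {probe_id!r} absent from MLE matrices")
    meta = sheet_to_frame(sheet)
    samples = [s for s in mle.sample_ids if s in meta.index]
    ym = mle.beta_m.loc[probe_id, samples].to_numpy(dtype=float)
    yh = mle.beta_h.loc[probe_id, samples].to_numpy(dtype=float)
    keep = ~np.isnan(ym) & ~np.isnan(yh)
    rows = []
    for sid, m_val, h_val, ok in zip(samples, ym, yh, keep):
        if not ok:
            continue
        rec = meta.loc[sid]
        grp = 1.0 if rec["group"] == "PD" else 0.0
        for mod, val in ((0.0, m_val), (1.0, h_val)):
            rows.append(
                (sid, mod, float(np.clip(val, cfg.clamp_eps, 1 - cfg.clamp_eps)),
                 grp, float(rec["glial_proportion"]), float(rec["pmi_hours"]))
            )
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    n_ctrl = design.loc[design["modtype"] == 0, "group"].eq(0.0).sum()
    n_pd = design.loc[design["modtype"] == 0, "group"].eq(1.0).sum()
    if n_ctrl < cfg.min_per_group or n_pd < cfg.min_per_group:
        raise DesignError(
            f"probe {probe_id!r}: only {n_ctrl} control / {n_pd} PD complete "
            f"pairs (need >= {cfg.min_per_group} each)"
        )
    return design


def _unpack_design(design: pd.DataFrame, eps: float):
    """Long design -> per-sample arrays: y (n, 2), group/glial/pmi (n,)."""
    if design.empty:
        raise DesignError("empty design")
    wide = design.pivot_table(
        index="sample_id", columns="modtype", values="y", sort=False
    )
    if set(wide.columns) != {0.0, 1.0} or wide.isna().any().any():
        raise DesignError("design must have exactly one mC and one hmC row per sample")
    order = wide.index
    meta = design.drop_duplicates("sample_id").set_index("sample_id").loc[order]
    y = clamp_unit(wide[[0.0, 1.0]].to_numpy(dtype=float), eps)
    return (
        y,
        meta["group"].to_numpy(dtype=float),
        meta["glial"].to_numpy(dtype=float),
        meta["pmi"].to_numpy(dtype=float),
    )


def marginal_loglik(theta, y, group, glial, pmi, gh_x, gh_logw) -> float:
    """Gauss-Hermite marginal log-likelihood at
    theta = (b0..b5, log_phi, log_sigma_u, loading)."""
    return -_nll_grad(np.asarray(theta, float), y, group, glial, pmi, gh_x, gh_logw)[0]


def _nll_grad(theta, y, group, glial, pmi, gh_x, gh_logw, per_sample=False):
    """Negative marginal log-likelihood and its analytic gradient.

    With ``per_sample`` the per-sample score contributions (n, 9) are
    returned as a third element — the ingredients of the cluster-robust
    (sandwich) variance, with samples as the independent clusters.
    """
    b0, b1, b2, b3, b4, b5, lphi, lsig, lam = theta
    phi = np.exp(lphi)
    sig = np.exp(lsig)
    base = b0 + b1 * group + b4 * glial + b5 * pmi  # (n,)
    slope = b2 + b3 * group  # (n,)
    u = _SQRT2 * sig * gh_x  # (K,) random-effect values at the nodes
    load = np.array([1.0, lam])  # modality loadings (mC, hmC)
    # eta: (n, 2, K); modtype enters the fixed part only in the hmC column
    eta = (
        base[:, None, None]
        + np.stack([np.zeros_like(slope), slope], axis=1)[:, :, None]
        + load[None, :, None] * u[None, None, :]
    )
    # keep mu strictly inside (0, 1) so the beta log-density stays finite
    mu = expit(np.clip(eta, -35.0, 35.0))
    mu = np.clip(mu, 1e-14, 1.0 - 1e-14)
    a = mu * phi
    b = (1.0 - mu) * phi
    ly = np.log(y)[:, :, None]
    l1y = np.log1p(-y)[:, :, None]
    lp = (a - 1.0) * ly + (b - 1.0) * l1y - (gammaln(a) + gammaln(b) - gammaln(phi))
    s = lp.sum(axis=1) + gh_logw[None, :]  # (n, K)
    smax = s.max(axis=1, keepdims=True)
    es = np.exp(s - smax)
    tot = es.sum(axis=1)
    ll = float((smax[:, 0] + np.log(tot)).sum() - y.shape[0] * _LOG_SQRT_PI)

    r = (es / tot[:, None])[:, None, :]  # posterior node weights, (n, 1, K)
    psi_a = digamma(a)
    psi_b = digamma(b)
    g_eta = phi * mu * (1.0 - mu) * ((ly - l1y) - psi_a + psi_b) * r  # (n, 2, K)
    per_row = g_eta.sum(axis=2)  # (n, 2)
    row_sum = per_row.sum(axis=1)  # (n,)
    mod_sum = per_row[:, 1]
    lsig_n = ((g_eta * load[None, :, None]).sum(axis=1) * u[None, :]).sum(axis=1)  # (n,)
    lam_n = (g_eta[:, 1, :] * u[None, :]).sum(axis=1)  # (n,)
    d_phi = (mu * ly + (1.0 - mu) * l1y - mu * psi_a - (1.0 - mu) * psi_b
             + digamma(phi)) * r
    phi_n = d_phi.sum(axis=(1, 2)) * phi  # (n,)
    scores = np.column_stack(
        [
            row_sum,
            row_sum * group,
            mod_sum,
            mod_sum * group,
            row_sum * glial,
            row_sum * pmi,
            phi_n,
            lsig_n,
            lam_n,
        ]
    )
    grad = scores.sum(axis=0)
    if per_sample:
        return -ll, -grad, scores
    return -ll, -grad


def _start_values(y, group, glial, pmi):
    """Moment-based initialization from an OLS fit on logits."""
    n = y.shape[0]
    z = logit(y)  # (n, 2)
    X = np.column_stack(
        [
            np.ones(2 * n),
            np.repeat(group, 2),
            np.tile([0.0, 1.0], n),
            np.repeat(group, 2) * np.tile([0.0, 1.0], n),
            np.repeat(glial, 2),
            np.repeat(pmi, 2),
        ]
    )
    zv = z.reshape(-1)
    beta, *_ = np.linalg.lstsq(X, zv, rcond=None)
    mu_hat = expit(X @ beta)
    resid = zv - X @ beta
    v = float(np.var(y.reshape(-1) - mu_hat))
    phi0 = float(np.clip(np.mean(mu_hat * (1 - mu_hat)) / max(v, 1e-10) - 1.0, 2.0, 1e4))
    # mC-row logit residual scale starts sigma_u
    rm = resid.reshape(n, 2)[:, 0]
    v_m = float(np.var(rm))
    sig0 = float(np.clip(np.sqrt(max(v_m, 1e-6)) * 0.7, 0.01, 2.0))
    return np.concatenate([beta, [np.log(phi0), np.log(sig0), 1.0]])


# theta = (b0..b5, log_phi, log_sigma_u, loading); the hmC loading of the
# random intercept is pinned at 1 — it is a parameter slot only so the score
# vector keeps a fixed layout.
_BOUNDS = (
    [(-30.0, 30.0)] * 6
    + [(np.log(0.5), np.log(1e6)), (np.log(1e-3), np.log(10.0)), (1.0, 1.0)]
)


def _numeric_hessian(fun_grad, theta, free_idx):
    """Central-difference Hessian of the NLL over the free parameters,
    built from the analytic gradient."""
    k = len(free_idx)
    H = np.zeros((k, k))
    for col, i in enumerate(free_idx):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h
        tm[i] -= h
        gp = fun_grad(tp)[1][free_idx]
        gm = fun_grad(tm)[1][free_idx]
        H[:, col] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_probe(
    design: pd.DataFrame,
    config: ModelConfig | None = None,
    probe_id: str = "",
) -> IDMCResult:
    """Maximize the marginal likelihood for one probe and Wald-test b3."""
    cfg = config or ModelConfig()
    if cfg.backend == "lmm_logit":
        return _fit_probe_lmm(design, cfg, probe_id)
    y, group, glial, pmi = _unpack_design(design, cfg.clamp_eps)
    if np.unique(group).size < 2:
        raise DesignError(f"probe {probe_id!r}: only one group present")

    cov_scale = {}
    cov = {"glial": glial, "pmi": pmi}
    fixed_zero = []
    for k, (name, vec) in enumerate(cov.items()):
        sd = vec.std()
        if sd == 0.0:
            log.warning("probe %r: covariate %s constant, dropped", probe_id, name)
            cov[name] = np.zeros_like(vec)
            fixed_zero.append(4 + k)
            cov_scale[name] = (0.0, 1.0)
        elif cfg.standardize_covariates:
            cov[name] = (vec - vec.mean()) / sd
            cov_scale[name] = (vec.mean(), sd)
        else:
            cov_scale[name] = (0.0, 1.0)
    glial, pmi = cov["glial"], cov["pmi"]

    gh_x, gh_w = np.polynomial.hermite.hermgauss(cfg.quadrature_nodes)
    gh_logw = np.log(gh_w)
    args = (y, group, glial, pmi, gh_x, gh_logw)

    theta0 = _start_values(y, group, glial, pmi)
    bounds = list(_BOUNDS)
    for i in fixed_zero:
        theta0[i] = 0.0
        bounds[i] = (0.0, 0.0)

    res = minimize(
        _nll_grad,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-6},
    )
    theta = res.x
    converged = bool(res.success and np.all(np.isfinite(theta)))

    se_b3 = np.nan
    if converged:
        # parameters pinned by configuration or sitting on an active bound
        # (sigma_u collapsing to ~0 is the common case) are excluded from
        # the curvature/variance computation
        free = []
        for i in range(9):
            lo, hi = bounds[i]
            if lo == hi or min(theta[i] - lo, hi - theta[i]) < 1e-8:
                continue
            free.append(i)
        if 3 not in free:
            converged = False
        else:
            H = _numeric_hessian(lambda t: _nll_grad(t, *args), theta, free)
            if cfg.se_method == "sandwich":
                scores = _nll_grad(theta, *args, per_sample=True)[2][:, free]
                se_b3 = _sandwich_se(H, scores, free.index(3))
            else:
                se_b3 = _se_from_hessian(H, free.index(3), free, theta)
            if not np.isfinite(se_b3) or se_b3 <= 0:
                converged = False
    if converged:
        z = theta[3] / se_b3
        if cfg.se_method == "sandwich":
            p = 2.0 * student_t.sf(abs(z), df=y.shape[0] - 1)
        else:
            p = 2.0 * norm.sf(abs(z))
    else:
        z = np.nan
        p = np.nan

    return IDMCResult(
        probe_id=probe_id,
        b0=theta[0], b1=theta[1], b2=theta[2], b3=theta[3],
        b4=theta[4], b5=theta[5],
        se_b3=float(se_b3), z=float(z), p=float(p),
        sigma_u=float(np.exp(theta[7])),
        log_phi=float(theta[6]),
        converged=converged,
        n_used=int(y.shape[0]),
        backend="beta",
    )


def _sandwich_se(H, scores, target):
    """Cluster-robust Wald SE: V = H^-1 (sum_j s_j s_j^T) H^-1 with samples
    as clusters, scaled by the G/(G-1) small-sample factor."""
    n = scores.shape[0]
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H, rcond=1e-10)
    B = scores.T @ scores
    V = Hinv @ B @ Hinv * (n / max(n - 1, 1))
    v = V[target, target]
    return np.sqrt(v) if v > 0 else np.nan


def _se_from_hessian(H, target, free, theta):
    """Wald SE for the target free parameter from the observed information.

    When the variance-component direction is flat (sigma_u at its bound) the
    Hessian is near-singular there; drop that row/column and invert the rest.
    """
    def try_inv(mat, idx):
        try:
            cov = np.linalg.inv(mat)
        except np.linalg.LinAlgError:
            return np.nan
        v = cov[idx, idx]
        return np.sqrt(v) if v > 0 else np.nan

    se = try_inv(H, target)
    if np.isfinite(se):
        return se
    # retry without the variance-component directions (flat when sigma_u
    # sits at its bound, which also leaves the loading unidentified)
    keep = [k for k, i in enumerate(free) if i not in (7, 8)]
    if target in keep:
        se = try_inv(H[np.ix_(keep, keep)], keep.index(target))
    return se


def _fit_probe_lmm(design: pd.DataFrame, cfg: ModelConfig, probe_id: str) -> IDMCResult:
    """Fast fallback: linear mixed model on logit(y), same design."""
    import statsmodels.formula.api as smf

    df = design.copy()
    df["z"] = logit(clamp_unit(df["y"].to_numpy(dtype=float), cfg.clamp_eps))
    if cfg.standardize_covariates:
        for c in ("glial", "pmi"):
            sd = df[c].std(ddof=0)
            if sd > 0:
                df[c] = (df[c] - df[c].mean()) / sd
    md = smf.mixedlm("z ~ group * modtype + glial + pmi", df, groups=df["sample_id"])
    try:
        fit = md.fit(reml=False)
        conv = bool(fit.converged)
    except Exception:  # noqa: BLE001 - non-convergence surfaces many ways
        return IDMCResult(probe_id, *[np.nan] * 6, np.nan, np.nan, np.nan,
                          np.nan, np.nan, False, len(df) // 2, backend="lmm_logit")
    fe = fit.fe_params
    b3 = float(fe["group:modtype"])
    se = float(fit.bse_fe["group:modtype"])
    z = b3 / se
    return IDMCResult(
        probe_id=probe_id,
        b0=float(fe["Intercept"]), b1=float(fe["group"]), b2=float(fe["modtype"]),
        b3=b3, b4=float(fe["glial"]), b5=float(fe["pmi"]),
        se_b3=se, z=float(z), p=float(2.0 * norm.sf(abs(z))),
        sigma_u=float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))),
        log_phi=np.nan,
        converged=conv,
        n_used=len(df) // 2,
        backend="lmm_logit",
    )


RESULT_COLUMNS = [
    "b0", "b1", "b2", "b3", "b4", "b5", "se_b3", "z", "p", "q",
    "direction", "sigma_u", "log_phi", "converged", "n_used", "backend",
]


def fit_all(
    mle: MLEEstimate,
    sheet: list[SampleRecord],
    probes,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Fit every probe independently; BH-FDR over converged probes only.

    Probes whose design cannot support the model (too few complete pairs per
    group) appear with ``converged = False`` and no p/q, so the output row
    set always matches the requested probe set. Deterministic given inputs.
    """
    cfg = config or ModelConfig()
    probes = list(probes)
    missing = [p for p in probes if p not in mle.beta_m.index]
    if missing:
        raise ValidationError(f"probes absent from MLE matrices, e.g. {missing[:5]}")
    rows = []
    for pid in probes:
        try:
            design = build_long_design(mle, sheet, pid, cfg)
            res = fit_probe(design, cfg, probe_id=pid)
        except DesignError as exc:
            log.info("probe skipped: %s", exc)
            res = IDMCResult(pid, *[np.nan] * 6, np.nan, np.nan, np.nan,
                             np.nan, np.nan, False, 0, backend=cfg.backend)
        rows.append(res)

    out = pd.DataFrame(
        {
            "b0": [r.b0 for r in rows], "b1": [r.b1 for r in rows],
            "b2": [r.b2 for r in rows], "b3": [r.b3 for r in rows],
            "b4": [r.b4 for r in rows], "b5": [r.b5 for r in rows],
            "se_b3": [r.se_b3 for r in rows], "z": [r.z for r in rows],
            "p": [r.p for r in rows], "q": np.nan,
            "direction": [
                classify_direction(r.b3) if np.isfinite(r.b3) else "" for r in rows
            ],
            "sigma_u": [r.sigma_u for r in rows],
            "log_phi": [r.log_phi for r in rows],
            "converged": [r.converged for r in rows],
            "n_used": [r.n_used for r in rows],
            "backend": [r.backend for r in rows],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    conv = out["converged"] & np.isfinite(out["p"])
    if not conv.any():
        raise ValidationError("fit_all: zero converged probes")
    out.loc[conv, "q"] = bh_fdr(out.loc[conv, "p"].to_numpy())
    return out
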