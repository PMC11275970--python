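"""Constrained maximum-likelihood deconvolution of 5mC and 5hmC.

The BS channel reads total modification (m + h); the oxBS channel reads
true methylation (m) only. With effective read-equivalents n_bs, n_ox the
binomial-style log-likelihood is

    L(m, h) = n_bs * [b_bs*log(m+h) + (1-b_bs)*log(1-m-h)]
            + n_ox * [b_ox*log(m)   + (1-b_ox)*log(1-m)]

maximized over the simplex m >= 0, h >= 0, m + h <= 1. The maximizer has a
closed form: when b_bs >= b_ox the unconstrained solution (m = b_ox,
h = b_bs - b_ox) is feasible; otherwise the optimum sits on the h = 0 edge
at the weight-pooled mean m = (n_bs*b_bs + n_ox*b_ox) / (n_bs + n_ox).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    FLAG_BOUNDARY_H0,
    FLAG_INTERIOR,
    FLAG_MISSING,
    MLEEstimate,
    PairedBetaSet,
    ValidationError,
    check_aligned,
)


def _xlogy(x, y):
    """x * log(y) with the convention 0 * log(0) = 0."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nz = x != 0
    with np.errstate(divide="ignore"):
        out = np.where(nz, x * np.log(np.where(nz, y, 1.0)), 0.0)
    return out


def mle_loglik(beta_bs, beta_ox, n_bs, n_ox, m, h):
    """Log-likelihood L(m, h); inputs may be scalars or broadcastable arrays.

    (m, h) must lie in the constraint simplex. Degenerate log terms follow
    the 0*log(0) := 0 convention, so e.g. L(1, 0) at beta values of 1 is 0.
    """
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    tol = 1e-12
    if np.any(m < -tol) or np.any(h < -tol) or np.any(m + h > 1 + tol):
        raise ValidationError("(m, h) outside the constraint simplex")
    for nm, v in (("beta_bs", beta_bs), ("beta_ox", beta_ox)):
        v = np.asarray(v, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValidationError(f"{nm} outside [0, 1]")
    t = np.clip(m + h, 0.0, 1.0)
    mc = np.clip(m, 0.0, 1.0)
    ll = n_bs * (_xlogy(beta_bs, t) + _xlogy(1.0 - np.asarray(beta_bs, float), 1.0 - t))
    ll = ll + n_ox * (_xlogy(beta_ox, mc) + _xlogy(1.0 - np.asarray(beta_ox, float), 1.0 - mc))
    return ll if ll.shape else float(ll)


def oxbs_mle_cell(beta_bs: float, beta_ox: float, n_bs: float = 1.0, n_ox: float = 1.0):
    """Closed-form constrained MLE for one probe x sample cell.

    Returns ``(beta_m, beta_h, flag)`` where flag is ``interior`` when the
    unconstrained solution is feasible and ``boundary_h0`` when the estimate
    is projected onto the h = 0 edge.
    """
    for nm, v in (("beta_bs", beta_bs), ("beta_ox", beta_ox)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{nm}={v} outside [0, 1]")
    if n_bs <= 0 or n_ox <= 0:
        raise ValidationError("weights must be strictly positive")
    if beta_bs > beta_ox:
        return beta_ox, beta_bs - beta_ox, FLAG_INTERIOR
    m = (n_bs * beta_bs + n_ox * beta_ox) / (n_bs + n_ox)
    return m, 0.0, FLAG_BOUNDARY_H0


def oxbs_mle_matrix(paired: PairedBetaSet, boundary_as_missing: bool = False) -> MLEEstimate:
    """Cell-wise constrained MLE over an aligned BS/oxBS pair.

    A cell missing in either channel is missing in the output. Weights
    default to 1 where absent. With ``boundary_as_missing`` the stricter
    convention used by some pipelines is applied: cells whose estimate is
    projected onto h = 0 are set missing instead of reported as (pooled, 0).
    """
    check_aligned(paired.bs, paired.oxbs, "oxbs_mle_matrix")
    bs = paired.bs.to_numpy(dtype=float)
    ox = paired.oxbs.to_numpy(dtype=float)
    n_bs = (paired.weights_bs.to_numpy(dtype=float)
            if paired.weights_bs is not None else np.ones_like(bs))
    n_ox = (paired.weights_oxbs.to_numpy(dtype=float)
            if paired.weights_oxbs is not None else np.ones_like(ox))

    missing = np.isnan(bs) | np.isnan(ox)
    interior = ~missing & (bs > ox)
    boundary = ~missing & ~interior

    m = np.full_like(bs, np.nan)
    h = np.full_like(bs, np.nan)
    m[interior] = ox[interior]
    h[interior] = bs[interior] - ox[interior]
    pooled = (n_bs * bs + n_ox * ox) / (n_bs + n_ox)
    m[boundary] = pooled[boundary]
    h[boundary] = 0.0

    flags = np.full(bs.shape, FLAG_MISSING, dtype=object)
    flags[interior] = FLAG_INTERIOR
    flags[boundary] = FLAG_BOUNDARY_H0
    if boundary_as_missing:
        m[boundary] = np.nan
        h[boundary] = np.nan
        flags[boundary] = FLAG_MISSING

    idx, cols = paired.bs.index, paired.bs.columns
    return MLEEstimate(
        beta_m=pd.DataFrame(m, index=idx, columns=cols),
        beta_h=pd.DataFrame(h, index=idx, columns=cols),
        flags=pd.DataFrame(flags, index=idx, columns=cols),
    )
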