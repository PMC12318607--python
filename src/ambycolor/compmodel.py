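"""Bayesian multilevel bivariate regression on the two ILR balances.

The response is the pair ``(z1, z2)`` of isometric log-ratio balances of
the (black, yellow, clear) pixel composition, modelled jointly as

    (z1, z2) ~ MVNormal(mu, Sigma)
    mu = B_time + B_mother + B_father + B_mother:father
         + B_mother:time + B_father:time + U[clutch]

with a homoscedastic 2x2 residual covariance Sigma and correlated
2-vector clutch intercepts ``U ~ MVNormal(0, Tau)``.  Posterior cell
means are mapped back to the simplex through the inverse ILR, so every
posterior draw is a valid composition.

Priors: Normal(0, 2.5) on fixed effects, Exponential(1) on the scales of
Sigma and Tau, LKJ(2) on their correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ambycolor import coda
from ambycolor.darkness import PriorConfig
from ambycolor.designmat import COMPOSITION_TERMS, build_design_matrix
from ambycolor.inference import hdci, rhat_ess
from ambycolor.sampler import FitResult, SamplerConfig, run_ensemble

__all__ = [
    "ilr_responses",
    "fit_composition",
    "predict_composition",
    "posterior_predictive_composition",
]

_LOG2PI = np.log(2.0 * np.pi)


def ilr_responses(data: pd.DataFrame) -> np.ndarray:
    """(n, 2) ILR responses from count columns (or pass-through z1/z2)."""
    if {"z1", "z2"}.issubset(data.columns):
        return data[["z1", "z2"]].to_numpy(float)
    counts = data[["n_black", "n_yellow", "n_clear"]].to_numpy(float)
    return coda.ilr_forward(coda.close(counts))


class _CompositionPosterior:
    """Vectorised log posterior.

    Layout: ``[B (p*2), log_s1, log_s2, atanh_rs, log_t1, log_t2,
    atanh_rt, U_raw (C*2)]`` with non-centred correlated clutch effects
    ``U = diag(t) @ L(rho) @ U_raw``.
    """

    def __init__(self, X, clutch_idx, n_clutches, Z, priors: PriorConfig):
        self.X, self.ci, self.C, self.Z = X, clutch_idx, n_clutches, Z
        self.p = X.shape[1]
        self.priors = priors
        self.ndim = 2 * self.p + 6 + 2 * self.C

    def unpack(self, theta):
        p, C = self.p, self.C
        B = theta[..., : 2 * p].reshape(*theta.shape[:-1], p, 2)
        log_s = theta[..., 2 * p : 2 * p + 2]
        t_rs = theta[..., 2 * p + 2]
        log_t = theta[..., 2 * p + 3 : 2 * p + 5]
        t_rt = theta[..., 2 * p + 5]
        U_raw = theta[..., 2 * p + 6 :].reshape(*theta.shape[:-1], C, 2)
        return B, log_s, t_rs, log_t, t_rt, U_raw

    def _clutch_effects(self, log_t, t_rt, U_raw):
        t = np.exp(log_t)  # (..., 2)
        rho = np.tanh(t_rt)[..., None]  # broadcasts over clutches
        u1 = U_raw[..., 0]
        u2 = rho * u1 + np.sqrt(1 - rho**2) * U_raw[..., 1]
        return np.stack(
            [t[..., 0:1] * u1, t[..., 1:2] * u2], axis=-1
        )  # (..., C, 2)

    def residuals(self, theta):
        B, log_s, t_rs, log_t, t_rt, U_raw = self.unpack(theta)
        U = self._clutch_effects(log_t, t_rt, U_raw)
        mu = np.einsum("np,...pk->...nk", self.X, B) + U[..., self.ci, :]
        return self.Z - mu, np.exp(log_s), np.tanh(t_rs)

    def pointwise(self, theta):
        e, s, r = self.residuals(theta)
        s1, s2 = s[..., 0][..., None], s[..., 1][..., None]
        r = r[..., None]
        q = (
            (e[..., 0] / s1) ** 2
            - 2 * r * e[..., 0] * e[..., 1] / (s1 * s2)
            + (e[..., 1] / s2) ** 2
        ) / (1 - r**2)
        logdet = 2 * np.log(s1) + 2 * np.log(s2) + np.log1p(-(r**2))
        return -0.5 * (q + logdet + 2 * _LOG2PI)

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        B, log_s, t_rs, log_t, t_rt, U_raw = self.unpack(theta)
        ll = self.pointwise(theta).sum(axis=-1)
        sd = self.priors.fixed_sd
        lp = -0.5 * (B**2).sum(axis=(-1, -2)) / sd**2
        lp += -0.5 * (U_raw**2).sum(axis=(-1, -2))
        rate = self.priors.tau_rate
        for ls in (log_s, log_t):  # Exponential(rate) via log scale
            lp += (-rate * np.exp(ls) + ls).sum(axis=-1)
        for tr in (t_rs, t_rt):  # LKJ(2) via atanh: (1-r^2) * Jacobian
            lp += 2.0 * np.log1p(-np.tanh(tr) ** 2)
        out = ll + lp
        return np.where(np.isfinite(out), out, -np.inf)


def fit_composition(
    data: pd.DataFrame,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    terms=COMPOSITION_TERMS,
) -> FitResult:
    """Fit the bivariate ILR regression to an observation table.

    `data` needs the design columns plus either ``n_black, n_yellow,
    n_clear`` counts or precomputed ``z1, z2`` balances.
    """
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    if len(data) == 0:
        raise ValueError("empty observation table")
    Z = ilr_responses(data)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite ILR responses")

    X, cols, clutch_idx, clutch_ids = build_design_matrix(data, terms)
    post = _CompositionPosterior(X, clutch_idx, len(clutch_ids), Z, priors)

    center = np.zeros(post.ndim)
    center[0:2] = Z.mean(axis=0)  # intercept pair
    center[2 * post.p : 2 * post.p + 2] = np.log(Z.std(axis=0).clip(1e-3))
    center[2 * post.p + 3 : 2 * post.p + 5] = -2.0

    chains, acceptance = run_ensemble(post, post.ndim, center, sampler)
    B, log_s, t_rs, log_t, t_rt, U_raw = post.unpack(chains)
    U = post._clutch_effects(log_t, t_rt, U_raw)
    draws = {
        "B": B,
        "sigma_scales": np.exp(log_s),
        "sigma_corr": np.tanh(t_rs),
        "tau_scales": np.exp(log_t),
        "tau_corr": np.tanh(t_rt),
        "U": U,
    }

    flat = chains.reshape(-1, post.ndim)
    pointwise = post.pointwise(flat)

    diag = rhat_ess(
        {
            "B": B.reshape(*B.shape[:2], -1),
            "sigma_scales": draws["sigma_scales"],
            "sigma_corr": draws["sigma_corr"],
            "tau_scales": draws["tau_scales"],
        }
    )
    converged = bool(
        (diag["rhat"] < 1.01).all() and (diag["ess_bulk"] > 400).all()
    )
    return FitResult(
        model="composition[" + "+".join(terms) + "]",
        draws=draws,
        pointwise_loglik=pointwise,
        diagnostics=diag,
        converged=converged,
        meta={
            "terms": tuple(terms),
            "colnames": cols,
            "clutch_ids": clutch_ids,
            "acceptance": acceptance,
            "n_obs": len(Z),
        },
    )


def _cell_z_draws(fit: FitResult, cells: pd.DataFrame) -> np.ndarray:
    """(total_draws, n_cells, 2) population-level cell-mean balances."""
    from ambycolor.darkness import _cell_matrix

    Xc = _cell_matrix(fit, cells)
    B = fit.flat("B")  # (draws, p, 2)
    return np.einsum("np,dpk->dnk", Xc, B)


def predict_composition(
    fit: FitResult, cells: pd.DataFrame, prob: float = 0.95
) -> pd.DataFrame:
    """Posterior mean and per-part HDCI of each cell's composition.

    Each draw's cell-mean balance pair is mapped through the inverse ILR
    so the draw itself is a composition summing to 1; the per-part
    posterior means of this nonlinear map need not sum exactly to 1.
    """
    z = _cell_z_draws(fit, cells)
    parts = coda.ilr_inverse(z)  # (draws, cells, 3)
    rows = []
    for i in range(parts.shape[1]):
        row = {}
        for j, part in enumerate(("black", "yellow", "clear")):
            lo, hi = hdci(parts[:, i, j], prob)
            row[f"p_{part}"] = float(parts[:, i, j].mean())
            row[f"p_{part}_low"] = lo
            row[f"p_{part}_high"] = hi
        rows.append(row)
    out = cells.reset_index(drop=True)[["mother", "father", "exposure_h"]].copy()
    return pd.concat([out, pd.DataFrame(rows)], axis=1)


def posterior_predictive_composition(
    fit: FitResult,
    cells: pd.DataFrame,
    total_pixels: int = 105_000,
    seed: int = 0,
    n_draws: int | None = None,
) -> pd.DataFrame:
    """Simulate new pixel compositions from the posterior predictive.

    Per retained posterior draw and cell, adds bivariate-normal residual
    noise from that draw's Sigma to the cell-mean balances, maps through
    the inverse ILR, and allocates `total_pixels` by a multinomial draw.
    """
    rng = np.random.default_rng(seed)
    z = _cell_z_draws(fit, cells)
    s = fit.flat("sigma_scales")
    r = fit.flat("sigma_corr")
    total = z.shape[0]
    take = np.arange(total)
    if n_draws is not None and n_draws < total:
        take = rng.choice(total, size=n_draws, replace=False)
    rows = []
    for d in take:
        e1 = rng.standard_normal(z.shape[1])
        e2 = rng.standard_normal(z.shape[1])
        z1 = z[d, :, 0] + s[d, 0] * e1
        z2 = z[d, :, 1] + s[d, 1] * (r[d] * e1 + np.sqrt(1 - r[d] ** 2) * e2)
        props = coda.ilr_inverse(np.stack([z1, z2], axis=-1))
        for i in range(z.shape[1]):
            nb, ny, nc = rng.multinomial(total_pixels, props[i])
            rows.append(
                {
                    "draw": int(d),
                    "cell": i,
                    "n_black": int(nb),
                    "n_yellow": int(ny),
                    "n_clear": int(nc),
                }
            )
    return pd.DataFrame(rows)
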