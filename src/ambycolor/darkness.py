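"""Bayesian beta distributional regression for larval skin darkness.

The response is the mean patch darkness ``y in (0, 1)`` and is modelled
as ``y ~ Beta(mu * phi, (1 - mu) * phi)``, with linear predictors on
both distribution parameters:

    logit(mu)  = b_time + b_mother + b_father + b_mother:father + u_mu[clutch]
    log(phi)   = g_time + g_mother + g_father + g_mother:father + u_phi[clutch]

Exposure time is a four-level categorical factor; reference cell is 0 h,
*texanum* mother, *texanum* father.  Clutch intercepts on the two
predictors are independent, each Normal(0, tau) with its own tau.

Priors (weakly informative, config-overridable): Normal(0, 2.5) on all
fixed effects on the link scales, Exponential(1) on tau_mu and tau_phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from ambycolor.designmat import (
    DARKNESS_TERMS,
    NONREF_GENOTYPE,
    build_design_matrix,
)
from ambycolor.inference import hdci, rhat_ess
from ambycolor.sampler import FitResult, SamplerConfig, run_ensemble

__all__ = [
    "PriorConfig",
    "beta_loglik",
    "fit_darkness",
    "predict_darkness",
    "relative_effect",
    "nudge_boundary",
]

_ETA_CLIP = 30.0  # |linear predictor| bound; expit/exp are saturated past this


@dataclass(frozen=True)
class PriorConfig:
    """Prior scales for the fixed effects and random-effect SDs."""

    fixed_sd: float = 2.5
    tau_rate: float = 1.0  # Exponential rate on tau


def beta_loglik(y, mu, phi):
    """Log density of Beta with mean `mu` and precision `phi` at `y`.

    Shapes broadcast; every y must lie strictly inside (0, 1).
    """
    y, mu, phi = np.asarray(y, float), np.asarray(mu, float), np.asarray(phi, float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly in (0, 1); nudge boundaries first")
    if np.any((mu <= 0) | (mu >= 1)) or np.any(phi <= 0):
        raise ValueError("need 0 < mu < 1 and phi > 0")
    a, b = mu * phi, (1.0 - mu) * phi
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


def nudge_boundary(y, n_pixels: int = 105_000):
    """Pull boundary proportions into (0, 1): ``(y*(n-1) + 0.5) / n``."""
    y = np.asarray(y, float)
    return (y * (n_pixels - 1) + 0.5) / n_pixels


class _DarknessPosterior:
    """Vectorised log posterior over walker batches.

    Parameter vector layout:
    ``[beta (p), gamma (p), log_tau_mu, log_tau_phi, u_mu_raw (C),
    u_phi_raw (C)]`` with non-centred clutch effects
    ``u = tau * u_raw``.
    """

    def __init__(self, X, clutch_idx, n_clutches, y, priors: PriorConfig):
        self.X, self.ci, self.C = X, clutch_idx, n_clutches
        self.y = y
        self.p = X.shape[1]
        self.priors = priors
        self.ndim = 2 * self.p + 2 + 2 * self.C

    def unpack(self, theta):
        p, C = self.p, self.C
        beta = theta[..., :p]
        gamma = theta[..., p : 2 * p]
        lt_mu = theta[..., 2 * p]
        lt_phi = theta[..., 2 * p + 1]
        u_mu_raw = theta[..., 2 * p + 2 : 2 * p + 2 + C]
        u_phi_raw = theta[..., 2 * p + 2 + C :]
        return beta, gamma, lt_mu, lt_phi, u_mu_raw, u_phi_raw

    def linpreds(self, theta):
        beta, gamma, lt_mu, lt_phi, u_mu_raw, u_phi_raw = self.unpack(theta)
        tau_mu = np.exp(lt_mu)[..., None]
        tau_phi = np.exp(lt_phi)[..., None]
        eta_mu = beta @ self.X.T + (tau_mu * u_mu_raw)[..., self.ci]
        eta_phi = gamma @ self.X.T + (tau_phi * u_phi_raw)[..., self.ci]
        mu = expit(np.clip(eta_mu, -_ETA_CLIP, _ETA_CLIP))
        phi = np.exp(np.clip(eta_phi, -_ETA_CLIP, _ETA_CLIP))
        eps = 1e-12
        return np.clip(mu, eps, 1 - eps), phi

    def pointwise(self, theta):
        mu, phi = self.linpreds(theta)
        return beta_loglik(self.y, mu, phi)

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        beta, gamma, lt_mu, lt_phi, u_mu_raw, u_phi_raw = self.unpack(theta)
        ll = self.pointwise(theta).sum(axis=-1)
        sd = self.priors.fixed_sd
        lp = -0.5 * (beta**2).sum(-1) / sd**2 - 0.5 * (gamma**2).sum(-1) / sd**2
        lp += -0.5 * (u_mu_raw**2).sum(-1) - 0.5 * (u_phi_raw**2).sum(-1)
        # Exponential(rate) prior on tau, sampled as log tau (+ Jacobian)
        rate = self.priors.tau_rate
        lp += -rate * np.exp(lt_mu) + lt_mu - rate * np.exp(lt_phi) + lt_phi
        out = ll + lp
        return np.where(np.isfinite(out), out, -np.inf)


def fit_darkness(
    data: pd.DataFrame,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    terms=DARKNESS_TERMS,
) -> FitResult:
    """Fit the beta distributional regression to an observation table.

    `data` needs the design columns plus ``darkness``; boundary values
    are rejected (use :func:`nudge_boundary` first).  Returns a
    :class:`FitResult` whose ``converged`` flag reports the R-hat/ESS
    contract for the fixed effects and tau parameters.
    """
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    if len(data) == 0:
        raise ValueError("empty observation table")
    y = data["darkness"].to_numpy(float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("darkness must lie strictly in (0, 1)")

    X, cols, clutch_idx, clutch_ids = build_design_matrix(data, terms)
    post = _DarknessPosterior(X, clutch_idx, len(clutch_ids), y, priors)

    center = np.zeros(post.ndim)
    ybar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    mom_phi = max(ybar * (1 - ybar) / max(y.var(), 1e-6) - 1.0, 2.0)
    center[0] = logit(ybar)
    center[post.p] = np.log(mom_phi)
    center[2 * post.p] = center[2 * post.p + 1] = -2.0  # log tau

    chains, acceptance = run_ensemble(post, post.ndim, center, sampler)
    nc, nd, _ = chains.shape
    beta, gamma, lt_mu, lt_phi, u_mu_raw, u_phi_raw = post.unpack(chains)
    draws = {
        "beta_mu": beta,
        "gamma_phi": gamma,
        "tau_mu": np.exp(lt_mu),
        "tau_phi": np.exp(lt_phi),
        "u_mu": np.exp(lt_mu)[..., None] * u_mu_raw,
        "u_phi": np.exp(lt_phi)[..., None] * u_phi_raw,
    }

    flat = chains.reshape(-1, post.ndim)
    pointwise = post.pointwise(flat)

    diag = rhat_ess(
        {"beta_mu": beta, "gamma_phi": gamma, "tau_mu": draws["tau_mu"],
         "tau_phi": draws["tau_phi"]}
    )
    converged = bool(
        (diag["rhat"] < 1.01).all() and (diag["ess_bulk"] > 400).all()
    )
    return FitResult(
        model="darkness[" + "+".join(terms) + "]",
        draws=draws,
        pointwise_loglik=pointwise,
        diagnostics=diag,
        converged=converged,
        meta={
            "terms": tuple(terms),
            "colnames": cols,
            "clutch_ids": clutch_ids,
            "acceptance": acceptance,
            "n_obs": len(y),
        },
    )


def _cell_mu_draws(fit: FitResult, cells: pd.DataFrame, level: str):
    """(total_draws, n_cells) posterior draws of each cell's mean darkness."""
    cells = cells.copy()
    if "clutch_id" not in cells:
        cells["clutch_id"] = "_prediction_"
    Xc = _cell_matrix(fit, cells)
    beta = fit.flat("beta_mu")
    eta = beta @ Xc.T
    if level == "clutch":
        u = fit.flat("u_mu")
        lookup = {c: i for i, c in enumerate(fit.meta["clutch_ids"])}
        idx = [lookup.get(c, None) for c in cells["clutch_id"]]
        if any(i is None for i in idx):
            raise ValueError("clutch-level prediction for unknown clutch")
        eta = eta + u[:, idx]
    elif level != "population":
        raise ValueError("level must be 'population' or 'clutch'")
    return expit(eta)


def _cell_matrix(fit: FitResult, cells: pd.DataFrame) -> np.ndarray:
    """Design matrix for new cells in the fitted column order.

    Columns are reconstructed from the fitted column names, so the
    treatment coding (and in particular the exposure reference level) is
    the one used at fit time, regardless of which levels appear in
    `cells`.
    """
    import re

    mother = (cells["mother"] == NONREF_GENOTYPE).to_numpy(float)
    father = (cells["father"] == NONREF_GENOTYPE).to_numpy(float)
    hours = cells["exposure_h"].to_numpy(float)

    out = np.zeros((len(cells), len(fit.meta["colnames"])))
    for j, name in enumerate(fit.meta["colnames"]):
        m = re.fullmatch(r"(mother:|father:)?time\[(\d+(?:\.\d+)?)h\]", name)
        if name == "intercept":
            out[:, j] = 1.0
        elif name == f"mother[{NONREF_GENOTYPE}]":
            out[:, j] = mother
        elif name == f"father[{NONREF_GENOTYPE}]":
            out[:, j] = father
        elif name == "mother:father":
            out[:, j] = mother * father
        elif m:
            dummy = (hours == float(m.group(2))).astype(float)
            if m.group(1) == "mother:":
                dummy = dummy * mother
            elif m.group(1) == "father:":
                dummy = dummy * father
            out[:, j] = dummy
        else:  # pragma: no cover
            raise ValueError(f"unrecognised design column {name!r}")
    return out


def predict_darkness(
    fit: FitResult,
    cells: pd.DataFrame,
    level: str = "population",
    prob: float = 0.95,
) -> pd.DataFrame:
    """Posterior mean and HDCI of mean darkness for each design cell."""
    mu = _cell_mu_draws(fit, cells, level)
    rows = []
    for i in range(mu.shape[1]):
        lo, hi = hdci(mu[:, i], prob)
        rows.append({"mean": mu[:, i].mean(), "hdci_low": lo, "hdci_high": hi})
    out = cells.reset_index(drop=True)[["mother", "father", "exposure_h"]].copy()
    return pd.concat([out, pd.DataFrame(rows)], axis=1)


def relative_effect(
    fit: FitResult,
    cell_a: dict,
    cell_b: dict,
    prob: float = 0.95,
) -> dict:
    """Percent change in mean darkness of cell_a relative to cell_b.

    Computed draw-wise on the response scale as
    ``100 * (mu_a - mu_b) / mu_b`` and summarised by the posterior mean
    and HDCI.
    """
    cells = pd.DataFrame([cell_a, cell_b])
    mu = _cell_mu_draws(fit, cells, level="population")
    pct = 100.0 * (mu[:, 0] - mu[:, 1]) / mu[:, 1]
    lo, hi = hdci(pct, prob)
    return {"mean": float(pct.mean()), "hdci_low": lo, "hdci_high": hi}
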