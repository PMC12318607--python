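"""Posterior summaries, convergence diagnostics and model comparison.

* `hdci` — the highest-density continuous interval: the shortest
  contiguous interval containing a given fraction of sorted draws.
* `waic` — the Watanabe–Akaike criterion from the pointwise posterior
  log-likelihood matrix, with the variance-based effective-parameter
  penalty and an SE over observations.
* `psis_loo` — Pareto-smoothed importance-sampling leave-one-out
  cross-validation (delegated to arviz), with per-observation Pareto
  k-hat diagnostics; k-hat > 0.7 is flagged.
* `rhat_ess` — rank-normalised split R-hat and bulk/tail effective
  sample sizes (delegated to arviz).
* `compare_models` — an elpd-ranked table with pairwise difference SEs
  computed from pointwise elpd differences against the best model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "InformationCriterion",
    "hdci",
    "waic",
    "psis_loo",
    "rhat_ess",
    "compare_models",
]

PARETO_K_THRESHOLD = 0.7


@dataclass
class InformationCriterion:
    """elpd-scale predictive criterion (WAIC or PSIS-LOO)."""

    kind: str
    elpd: float
    penalty: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray | None = None
    flags: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.pointwise.shape[0]


def hdci(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing `prob` of the draws.

    For a unimodal posterior this is the sample estimate of the
    highest-density interval.  Implemented as an exhaustive scan over
    windows of ``ceil(prob * n)`` sorted draws.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0 or not np.all(np.isfinite(x)):
        raise ValueError("hdci needs a non-empty finite sample")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    # window [i, i + m - 1] holds exactly m draws
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _check_loglik(ll) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim == 3:  # (chain, draw, obs)
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, obs)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    return ll


def waic(pointwise_loglik) -> InformationCriterion:
    """WAIC from a (draws x observations) log-likelihood matrix.

    ``elpd_i = log mean_d exp(ll_di) - var_d(ll_di)``, log-sum-exp
    stabilised, with the total SE taken over observations.
    """
    ll = _check_loglik(pointwise_loglik)
    S, n = ll.shape
    lppd = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(n)
    elpd_i = lppd - p_i
    se = float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    flags = []
    if np.any(p_i > 0.4):
        flags.append("p_waic_i > 0.4 for some observations")
    return InformationCriterion(
        kind="waic",
        elpd=float(elpd_i.sum()),
        penalty=float(p_i.sum()),
        se=se,
        pointwise=elpd_i,
        flags=flags,
    )


def psis_loo(pointwise_loglik) -> InformationCriterion:
    """PSIS-LOO from a (draws x observations) log-likelihood matrix."""
    import arviz as az

    ll = _check_loglik(pointwise_loglik)
    S, n = ll.shape
    idata = az.from_dict(
        posterior={"_dummy": np.zeros((1, S))},
        log_likelihood={"y": ll[None, :, :]},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    flags = []
    n_bad = int(np.sum(k > PARETO_K_THRESHOLD))
    if n_bad:
        flags.append(f"{n_bad} observations with pareto k > {PARETO_K_THRESHOLD}")
    return InformationCriterion(
        kind="loo",
        elpd=float(res.elpd_loo),
        penalty=float(res.p_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i),
        pareto_k=k,
        flags=flags,
    )


def rhat_ess(draws: dict) -> pd.DataFrame:
    """Per-parameter rank-normalised split R-hat and bulk/tail ESS.

    `draws` maps parameter name to a ``(chain, draw, ...)`` array; extra
    trailing axes are reported as separate indexed rows.
    """
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=draws)
        r = az.rhat(idata)
        bulk = az.ess(idata, method="bulk")
        tail = az.ess(idata, method="tail")
    rows = []
    for name in draws:
        rv = np.atleast_1d(np.asarray(r[name]))
        bv = np.atleast_1d(np.asarray(bulk[name]))
        tv = np.atleast_1d(np.asarray(tail[name]))
        for i in range(rv.size):
            label = name if rv.size == 1 else f"{name}[{i}]"
            rows.append(
                {
                    "parameter": label,
                    "rhat": float(rv.ravel()[i]),
                    "ess_bulk": float(bv.ravel()[i]),
                    "ess_tail": float(tv.ravel()[i]),
                }
            )
    return pd.DataFrame(rows)


def compare_models(
    fits: dict,
    criterion: str = "loo",
) -> pd.DataFrame:
    """Rank models by elpd with pairwise-difference SEs.

    `fits` maps model name to either a FitResult-like object exposing
    ``pointwise_loglik`` or a raw (draws x obs) log-likelihood matrix.
    The returned table is sorted best-first; ``elpd_diff`` and
    ``se_diff`` are relative to the best model, with the SE computed
    from the pointwise elpd differences.
    """
    if criterion not in ("waic", "loo"):
        raise ValueError("criterion must be 'waic' or 'loo'")
    crit_fn = waic if criterion == "waic" else psis_loo
    ics = {}
    for name, fit in fits.items():
        ll = getattr(fit, "pointwise_loglik", fit)
        ics[name] = crit_fn(ll)
    order = sorted(ics, key=lambda k: ics[k].elpd, reverse=True)
    best = ics[order[0]]
    rows = []
    for rank, name in enumerate(order):
        ic = ics[name]
        diff_i = best.pointwise - ic.pointwise
        n = diff_i.size
        se_diff = float(np.sqrt(n * diff_i.var(ddof=1))) if rank else 0.0
        rows.append(
            {
                "model": name,
                "rank": rank,
                "elpd": ic.elpd,
                "penalty": ic.penalty,
                "se": ic.se,
                "elpd_diff": best.elpd - ic.elpd,
                "se_diff": se_diff,
                "flags": "; ".join(ic.flags),
            }
        )
    return pd.DataFrame(rows)
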