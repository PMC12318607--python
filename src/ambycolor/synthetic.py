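"""Model-based synthetic observations with known ground truth.

Default parameter values are chosen so a simulated study resembles the
real one: *texanum* x *texanum* larvae around darkness 0.30 unexposed and
compositions dominated by clear skin, *barbouri* maternal and paternal
effects raising darkness and melanophore cover, and exposure effects that
rise steeply to 4 h and then plateau.  Clutch random intercepts are drawn
once per clutch from Normal(0, tau) (bivariate normal with covariance Tau
for the composition model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ambycolor import coda
from ambycolor.designmat import (
    COMPOSITION_TERMS,
    DARKNESS_TERMS,
    build_design_matrix,
)

__all__ = [
    "DarknessParams",
    "CompositionParams",
    "simulate_darkness",
    "simulate_composition",
    "simulate_dataset",
]

PATCH_PIXELS = 105_000  # 250 x 420 standard patch


def _coef_vector(coefs: dict, colnames: list[str], what: str) -> np.ndarray:
    missing = [c for c in colnames if c not in coefs]
    if missing:
        raise ValueError(f"{what} missing coefficients for columns {missing}")
    return np.array([coefs[c] for c in colnames], dtype=float)


@dataclass
class DarknessParams:
    """Ground truth for the beta distributional regression.

    `beta_mu` are logit-mean coefficients, `gamma_phi` log-precision
    coefficients, both keyed by design-matrix column name.  `tau_mu` and
    `tau_phi` are the standard deviations of the (independent) clutch
    random intercepts on the two predictors.
    """

    beta_mu: dict = field(
        default_factory=lambda: {
            "intercept": -0.85,
            "time[1h]": 0.18,
            "time[4h]": 0.37,
            "time[12h]": 0.42,
            "mother[barbouri]": 0.54,
            "father[barbouri]": 0.22,
            "mother:father": 0.03,
        }
    )
    gamma_phi: dict = field(
        default_factory=lambda: {
            "intercept": 3.2,
            "time[1h]": -0.20,
            "time[4h]": -0.30,
            "time[12h]": -0.30,
            "mother[barbouri]": 0.20,
            "father[barbouri]": 0.10,
            "mother:father": 0.00,
        }
    )
    tau_mu: float = 0.15
    tau_phi: float = 0.10

    def to_dict(self) -> dict:
        return {
            "beta_mu": dict(self.beta_mu),
            "gamma_phi": dict(self.gamma_phi),
            "tau_mu": self.tau_mu,
            "tau_phi": self.tau_phi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DarknessParams":
        return cls(**d)


@dataclass
class CompositionParams:
    """Ground truth for the bivariate ILR regression.

    `B` maps design-matrix column name to the (z1, z2) effect pair.
    `sigma_scales`/`sigma_corr` parameterise the 2x2 residual covariance,
    `tau_scales`/`tau_corr` the clutch random-intercept covariance.
    """

    B: dict = field(
        default_factory=lambda: {
            "intercept": (-0.60, -0.40),
            "time[1h]": (0.45, 0.35),
            "time[4h]": (0.75, 0.50),
            "time[12h]": (0.85, 0.55),
            "mother[barbouri]": (0.25, 0.15),
            "father[barbouri]": (0.12, 0.08),
            "mother:father": (0.05, 0.03),
            "mother:time[1h]": (0.30, 0.25),
            "mother:time[4h]": (0.45, 0.35),
            "mother:time[12h]": (0.50, 0.40),
            "father:time[1h]": (0.10, 0.10),
            "father:time[4h]": (0.20, 0.15),
            "father:time[12h]": (0.22, 0.18),
        }
    )
    sigma_scales: tuple = (0.35, 0.30)
    sigma_corr: float = 0.20
    tau_scales: tuple = (0.15, 0.12)
    tau_corr: float = 0.30

    @property
    def Sigma(self) -> np.ndarray:
        return _cov2(self.sigma_scales, self.sigma_corr)

    @property
    def Tau(self) -> np.ndarray:
        return _cov2(self.tau_scales, self.tau_corr)

    def to_dict(self) -> dict:
        return {
            "B": {k: list(v) for k, v in self.B.items()},
            "sigma_scales": list(self.sigma_scales),
            "sigma_corr": self.sigma_corr,
            "tau_scales": list(self.tau_scales),
            "tau_corr": self.tau_corr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositionParams":
        d = dict(d)
        d["B"] = {k: tuple(v) for k, v in d["B"].items()}
        d["sigma_scales"] = tuple(d["sigma_scales"])
        d["tau_scales"] = tuple(d["tau_scales"])
        return cls(**d)


def _cov2(scales, corr) -> np.ndarray:
    s1, s2 = scales
    cov = np.array(
        [[s1 * s1, corr * s1 * s2], [corr * s1 * s2, s2 * s2]], dtype=float
    )
    if np.any(np.linalg.eigvalsh(cov) < -1e-12) or abs(corr) >= 1:
        raise ValueError("covariance is not positive definite")
    return cov


def _clutch_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_darkness(
    design: pd.DataFrame,
    params: DarknessParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw one darkness value in (0, 1) per design row.

    Per row, ``y ~ Beta(mu * phi, (1 - mu) * phi)`` with
    ``logit(mu)`` and ``log(phi)`` the linear predictors (fixed effects
    plus the row's clutch intercepts).
    """
    params = params or DarknessParams()
    if params.tau_mu < 0 or params.tau_phi < 0:
        raise ValueError("tau must be non-negative")
    X, cols, clutch_idx, clutch_ids = build_design_matrix(design, DARKNESS_TERMS)
    beta = _coef_vector(params.beta_mu, cols, "beta_mu")
    gamma = _coef_vector(params.gamma_phi, cols, "gamma_phi")

    rng = _clutch_rng(seed)
    u_mu = rng.normal(0.0, params.tau_mu, size=len(clutch_ids))
    u_phi = rng.normal(0.0, params.tau_phi, size=len(clutch_ids))
    mu = expit(X @ beta + u_mu[clutch_idx])
    phi = np.exp(X @ gamma + u_phi[clutch_idx])
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    # guard against FP underflow at the boundaries
    eps = np.finfo(float).tiny
    return np.clip(y, eps, 1.0 - 1e-16)


def simulate_composition(
    design: pd.DataFrame,
    params: CompositionParams | None = None,
    total_pixels: int = PATCH_PIXELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (n_black, n_yellow, n_clear) pixel counts per design row.

    The (z1, z2) balance pair is drawn from the bivariate normal with the
    fixed-effect + clutch-intercept mean and residual covariance Sigma,
    inverse-ILR-transformed to proportions, and allocated to
    `total_pixels` by a multinomial draw.
    """
    params = params or CompositionParams()
    if total_pixels < 3:
        raise ValueError("total_pixels must be >= 3")
    Sigma, Tau = params.Sigma, params.Tau  # validates PD
    X, cols, clutch_idx, clutch_ids = build_design_matrix(
        design, COMPOSITION_TERMS
    )
    B = np.array([params.B[c] for c in cols]) if all(
        c in params.B for c in cols
    ) else None
    if B is None:
        raise ValueError(
            f"B missing coefficients for {[c for c in cols if c not in params.B]}"
        )

    rng = _clutch_rng(seed)
    U = rng.multivariate_normal(np.zeros(2), Tau, size=len(clutch_ids))
    z_mean = X @ B + U[clutch_idx]
    z = z_mean + rng.multivariate_normal(np.zeros(2), Sigma, size=len(design))
    props = coda.ilr_inverse(z)
    counts = np.array([rng.multinomial(total_pixels, p) for p in props])
    return pd.DataFrame(
        counts, columns=["n_black", "n_yellow", "n_clear"], index=design.index
    )


def simulate_dataset(
    design: pd.DataFrame,
    darkness_params: DarknessParams | None = None,
    composition_params: CompositionParams | None = None,
    total_pixels: int = PATCH_PIXELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Full synthetic observation table: design columns + darkness + counts.

    Darkness and composition use independent streams derived from `seed`,
    so either half is reproducible on its own.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    y = simulate_darkness(
        design, darkness_params, seed=ss[0].generate_state(1)[0] % (2**31)
    )
    counts = simulate_composition(
        design,
        composition_params,
        total_pixels,
        seed=ss[1].generate_state(1)[0] % (2**31),
    )
    out = design.copy()
    out["darkness"] = y
    return pd.concat([out, counts], axis=1)


def save_ground_truth(path, darkness_params, composition_params, seed):
    payload = {
        "seed": int(seed),
        "darkness_params": darkness_params.to_dict(),
        "composition_params": composition_params.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_ground_truth(path):
    with open(path) as fh:
        payload = json.load(fh)
    return (
        DarknessParams.from_dict(payload["darkness_params"]),
        CompositionParams.from_dict(payload["composition_params"]),
        payload["seed"],
    )
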