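"""Rejection probability of the complete-case test under an MNAR mechanism.

When the causal null ``p_t = p_c`` holds but missingness is not at random,
the complete-case two-proportion test targets the observed-response rates
``p~_tau``, which differ across arms, so its rejection probability drifts
away from the nominal size — increasingly so with sample size.  This module
maps that rejection probability over sensitivity points, by an asymptotic
normal approximation and by Monte Carlo.

The asymptotic approximation conditions on the expected complete-case sizes
``m_tau = (1 - q_tau) n_tau`` (binomial variation in the number observed is
ignored; the Monte-Carlo routine serves as its oracle): with
``mu = p~_c - p~_t``, pooled ``p* = (m_c p~_c + m_t p~_t) / (m_c + m_t)``,
null-style s.e. ``s0 = sqrt(p*(1-p*)(1/m_c + 1/m_t))`` and alternative-style
``s1 = sqrt(p~_c(1-p~_c)/m_c + p~_t(1-p~_t)/m_t)``, the two-sided rejection
probability is

    Phi((-z s0 - mu)/s1) + 1 - Phi((z s0 - mu)/s1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .errors import UndefinedStatisticError
from .missingness_model import SelectionModel, simulate_tables
from .plausibility_region import PlausibilityRegion

__all__ = [
    "RejectionProbabilityResult",
    "cc_rejection_probability",
    "cc_rejection_probability_mc",
    "max_rejection_probability",
]


@dataclass(frozen=True)
class RejectionProbabilityResult:
    model: SelectionModel
    method: str  # "asymptotic" | "monte_carlo"
    prob_reject: float
    z_crit: float
    two_sided: bool
    replicates: Optional[int] = None
    seed: Optional[int] = None
    mc_se: Optional[float] = None


def _asymptotic_prob_arrays(
    p_c, p_t, pi_c, pi_t, r_c, r_t, n_c, n_t, z_crit, two_sided
):
    """Vectorized asymptotic rejection probability; infeasible points -> NaN."""
    r_c = np.asarray(r_c, float)
    r_t = np.asarray(r_t, float)
    q_c = (1.0 - p_c + r_c * p_c) * pi_c
    q_t = (1.0 - p_t + r_t * p_t) * pi_t
    feasible = (r_c * pi_c <= 1.0) & (r_t * pi_t <= 1.0) & (q_c < 1.0) & (q_t < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mbar_c = (1.0 - q_c) * n_c
        mbar_t = (1.0 - q_t) * n_t
        pt_c = p_c * (1.0 - r_c * pi_c) / (1.0 - q_c)
        pt_t = p_t * (1.0 - r_t * pi_t) / (1.0 - q_t)
        mu = pt_c - pt_t
        pstar = (mbar_c * pt_c + mbar_t * pt_t) / (mbar_c + mbar_t)
        s0 = np.sqrt(pstar * (1.0 - pstar) * (1.0 / mbar_c + 1.0 / mbar_t))
        s1 = np.sqrt(pt_c * (1.0 - pt_c) / mbar_c + pt_t * (1.0 - pt_t) / mbar_t)
        upper = norm.sf((z_crit * s0 - mu) / s1)
        prob = upper + (norm.cdf((-z_crit * s0 - mu) / s1) if two_sided else 0.0)
    return np.where(feasible, prob, np.nan)


def cc_rejection_probability(
    model: SelectionModel, z_crit: float = 1.96, two_sided: bool = True
) -> RejectionProbabilityResult:
    """Asymptotic probability that the complete-case test rejects."""
    for arm in ("c", "t"):
        p, pi, r, n = model.arm(arm)
        if (1.0 - p + r * p) * pi >= 1.0 or (1.0 - (1.0 - p + r * p) * pi) * n <= 0:
            raise UndefinedStatisticError(
                f"zero expected complete cases in arm {arm}; rejection probability undefined"
            )
    prob = _asymptotic_prob_arrays(
        model.p_c, model.p_t, model.pi_c, model.pi_t,
        model.r_c, model.r_t, model.n_c, model.n_t, z_crit, two_sided,
    )
    return RejectionProbabilityResult(
        model=model,
        method="asymptotic",
        prob_reject=float(prob),
        z_crit=float(z_crit),
        two_sided=two_sided,
    )


def cc_rejection_probability_mc(
    model: SelectionModel,
    z_crit: float = 1.96,
    replicates: int = 10_000,
    seed: Optional[int] = None,
    two_sided: bool = True,
) -> RejectionProbabilityResult:
    """Monte-Carlo rejection probability from multinomial trial draws.

    Replicates with an undefined statistic (an empty arm, or pooled
    proportion 0 or 1) count as non-rejections — a conservative convention.
    """
    if replicates < 100:
        raise ValueError(f"replicates must be >= 100, got {replicates}")
    draws = simulate_tables(model, replicates, seed)
    y_c, m_c = draws["y_c"].astype(float), draws["m_c"].astype(float)
    y_t, m_t = draws["y_t"].astype(float), draws["m_t"].astype(float)
    y_tot, m_tot = y_c + y_t, m_c + m_t
    defined = (m_c > 0) & (m_t > 0) & (y_tot > 0) & (y_tot < m_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = y_tot / m_tot
        z = (y_c / m_c - y_t / m_t) / np.sqrt(
            pbar * (1.0 - pbar) * (1.0 / m_t + 1.0 / m_c)
        )
    rejected = (np.abs(z) >= z_crit) if two_sided else (z >= z_crit)
    rejected = rejected & defined
    prob = float(np.mean(rejected))
    return RejectionProbabilityResult(
        model=model,
        method="monte_carlo",
        prob_reject=prob,
        z_crit=float(z_crit),
        two_sided=two_sided,
        replicates=replicates,
        seed=seed if isinstance(seed, int) else None,
        mc_se=float(np.sqrt(prob * (1.0 - prob) / replicates)),
    )


def max_rejection_probability(
    p: float,
    pi_c: float,
    pi_t: float,
    n_c: int,
    n_t: int,
    region: PlausibilityRegion,
    z_crit: float = 1.96,
    two_sided: bool = True,
    resolution: int = 101,
    boundary_count: int = 512,
) -> Tuple[float, Tuple[float, float]]:
    """Worst-case rejection probability over the region under the causal null.

    ``p_t = p_c = p`` throughout; returns the maximum asymptotic probability
    and the (r_c, r_t) at which it occurs, after a boundary polish.
    """
    pts = region.points(resolution, boundary_count)
    probs = _asymptotic_prob_arrays(
        p, p, pi_c, pi_t, pts[:, 0], pts[:, 1], n_c, n_t, z_crit, two_sided
    )
    idx = int(np.nanargmax(probs))
    best = float(probs[idx])
    arg = (float(pts[idx, 0]), float(pts[idx, 1]))

    if region.a > 1.0:
        n_grid = len(pts) - boundary_count
        b_idx = int(np.nanargmax(probs[n_grid:]))
        angle = 2.0 * np.pi * b_idx / boundary_count
        width = 2.0 * (2.0 * np.pi / boundary_count)

        def negative(t: float) -> float:
            r_c, r_t = region.boundary_point(t)
            val = _asymptotic_prob_arrays(
                p, p, pi_c, pi_t, r_c, r_t, n_c, n_t, z_crit, two_sided
            )
            return -float(val) if np.isfinite(val) else np.inf

        res = minimize_scalar(
            negative, bounds=(angle - width, angle + width), method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun > best:
            best = float(-res.fun)
            arg = region.boundary_point(float(res.x))
    return best, arg
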