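"""Sample-size machinery when the sensitivity analysis is the primary analysis.

If the robust rule (reject only when Z(r_c, r_t) >= z_{1-alpha} everywhere on
the plausibility region R) is used at analysis time, the sample size must be
inflated beyond the complete-data requirement n* to preserve power.  Because
the distribution of the minimized statistic is intractable, the expected-Z
surface

    theta_R(r_c, r_t) = min_{(R_c, R_t) in R} E_{(R_c, R_t)} Z(r_c, r_t)

is used instead (expectation and minimization exchanged), where the inner
expectation is approximated by evaluating the score statistic on the
real-valued expected table at sample size n* under the true mechanism
(R_c, R_t) with the design's marginal missingness q held fixed.  The
inflation factor is then

    n / n* = [(z_{1-alpha} + z_{1-beta}) / min_{(r_c, r_t) in R} theta_R]^2,

with the MAR singleton recovering the usual 1/(1-q).  If the minimized theta
is not positive, no sample size attains the desired power: the design is
unattainable, and the region scale at which theta_min first reaches zero is
the infinite inflation boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InfeasibleParameterError, ValidationError
from .missingness_model import SelectionModel, pi_from_q, simulate_tables
from .plausibility_region import PlausibilityRegion
from .score_test import _z_arrays

__all__ = [
    "DesignSpec",
    "DesignResult",
    "n_star_complete",
    "theta",
    "inflation_factor",
    "attainability_scan",
    "simulated_power",
    "ROUNDED_Z_SUM",
]

ROUNDED_Z_SUM = 3.24  # z_{0.975} + z_{0.90} rounded to two decimals


@dataclass(frozen=True)
class DesignSpec:
    """Design-stage inputs: rates, error levels, missingness, region."""

    p_c: float
    p_t: float
    region: PlausibilityRegion
    q_c: float = 0.10
    q_t: float = 0.10
    alpha: float = 0.025  # one-sided
    beta: float = 0.10
    n_star: Optional[int] = None

    def __post_init__(self) -> None:
        if self.p_c == self.p_t:
            raise ValidationError("design requires p_c != p_t")
        for name in ("p_c", "p_t"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValidationError(f"{name} must lie in (0, 0.5), got {v}")
        for name in ("q_c", "q_t"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1), got {v}")

    @property
    def z_sum(self) -> float:
        return float(norm.ppf(1.0 - self.alpha) + norm.ppf(1.0 - self.beta))

    def resolved_n_star(self) -> int:
        if self.n_star is not None:
            return int(self.n_star)
        return n_star_complete(self.p_c, self.p_t, self.alpha, self.beta)


@dataclass(frozen=True)
class DesignResult:
    spec: DesignSpec
    theta_min: float
    theta_argmin: Tuple[float, float]  # analysis point (r_c, r_t)
    least_favorable: Tuple[float, float]  # true mechanism (R_c, R_t)
    attainable: bool
    inflation: float  # inf when unattainable
    n_required: Optional[int]
    n_star: int
    z_sum: float

    def to_dict(self) -> dict:
        return {
            "theta_min": self.theta_min,
            "theta_argmin": list(self.theta_argmin),
            "least_favorable": list(self.least_favorable),
            "attainable": self.attainable,
            "inflation": self.inflation,
            "n_required": self.n_required,
            "n_star": self.n_star,
            "z_sum": self.z_sum,
        }


def n_star_complete(
    p_c: float, p_t: float, alpha: float = 0.025, beta: float = 0.10
) -> int:
    """Per-group complete-data sample size for power 1 - beta.

    Smallest n for which the complete-case Z evaluated on the no-missingness
    expected table reaches ``z_{1-alpha} + z_{1-beta}``; symmetric in the two
    rates.  Closed form: ``n = (z_a + z_b)^2 2 pbar(1-pbar) / (p_c - p_t)^2``.
    """
    if p_c == p_t:
        raise ValidationError("sample size undefined for p_c == p_t")
    z_sum = norm.ppf(1.0 - alpha) + norm.ppf(1.0 - beta)
    pbar = 0.5 * (p_c + p_t)
    n_real = z_sum**2 * 2.0 * pbar * (1.0 - pbar) / (p_c - p_t) ** 2
    return int(math.ceil(n_real - 1e-9))


def _expected_count_arrays(spec: DesignSpec, R_c: np.ndarray, R_t: np.ndarray, n: float):
    """Expected per-arm counts at size ``n`` under true mechanisms (R_c, R_t).

    The design's marginal missingness q is held fixed across mechanisms, so
    pi varies with the true ratio: pi = q / (1 - p + R p).  Raises when any
    evaluated mechanism is infeasible (pi > 1 or R pi > 1).
    """
    out = {}
    for arm, R in (("c", R_c), ("t", R_t)):
        p = getattr(spec, f"p_{arm}")
        q = getattr(spec, f"q_{arm}")
        pi = q / (1.0 - p + R * p)
        if np.any(pi > 1.0 + 1e-12) or np.any(R * pi > 1.0 + 1e-12):
            raise InfeasibleParameterError(
                f"q_{arm} = {q} infeasible for some true ratio in the region "
                f"(requires pi > 1 or R pi > 1)"
            )
        y = p * (1.0 - R * pi) * n
        out[f"y_{arm}"] = y
        out[f"m_{arm}"] = np.full_like(y, (1.0 - q) * n)
    return out


def _theta_surface(
    spec: DesignSpec,
    anal_pts: np.ndarray,
    true_pts: np.ndarray,
    n: float,
) -> np.ndarray:
    """theta_R at each analysis point: columns of the (true x analysis) Z matrix
    reduced by their minimum over true mechanisms."""
    counts = _expected_count_arrays(spec, true_pts[:, 0], true_pts[:, 1], n)
    zmat = _z_arrays(
        counts["y_c"][:, None],
        counts["m_c"][:, None],
        n,
        counts["y_t"][:, None],
        counts["m_t"][:, None],
        n,
        anal_pts[None, :, 0],
        anal_pts[None, :, 1],
    )
    return zmat


def theta(
    spec: DesignSpec,
    r_c: float,
    r_t: float,
    resolution: int = 61,
    boundary_count: int = 256,
) -> float:
    """Expected-Z surface at one analysis point: the minimum over true
    mechanisms in the region of the score Z on the expected table at n*."""
    true_pts = spec.region.points(resolution, boundary_count)
    anal = np.array([[r_c, r_t]], dtype=float)
    zmat = _theta_surface(spec, anal, true_pts, float(spec.resolved_n_star()))
    return float(np.min(zmat))


def inflation_factor(
    spec: DesignSpec,
    resolution: int = 61,
    boundary_count: int = 256,
    rounded_z: bool = False,
) -> DesignResult:
    """Double minimization of the expected-Z surface and the implied n / n*.

    The same lattice-plus-boundary discretization serves for both the true
    mechanisms (R_c, R_t) and the analysis points (r_c, r_t).  A non-positive
    minimized theta means the desired power is unattainable at any n; the
    inflation is then reported as infinite, not as an error.
    """
    n_star = spec.resolved_n_star()
    pts = spec.region.points(resolution, boundary_count)
    # chunk the true-mechanism axis: keeps each (chunk x A) block cache-friendly
    n_pts = len(pts)
    theta_by_anal = np.full(n_pts, np.inf)
    true_idx = np.zeros(n_pts, dtype=int)
    chunk = max(1, int(2**18 // max(n_pts, 1)) + 1)
    for start in range(0, n_pts, chunk):
        block = _theta_surface(spec, pts, pts[start : start + chunk], float(n_star))
        block_min = np.min(block, axis=0)
        improved = block_min < theta_by_anal
        theta_by_anal[improved] = block_min[improved]
        true_idx[improved] = np.argmin(block, axis=0)[improved] + start
    a_idx = int(np.argmin(theta_by_anal))
    t_idx = int(true_idx[a_idx])
    theta_min = float(theta_by_anal[a_idx])

    z_sum = ROUNDED_Z_SUM if rounded_z else spec.z_sum
    attainable = theta_min > 0.0
    if attainable:
        inflation = float((z_sum / theta_min) ** 2)
        n_required = int(math.ceil(inflation * n_star))
    else:
        inflation = float("inf")
        n_required = None
    return DesignResult(
        spec=spec,
        theta_min=theta_min,
        theta_argmin=(float(pts[a_idx, 0]), float(pts[a_idx, 1])),
        least_favorable=(float(pts[t_idx, 0]), float(pts[t_idx, 1])),
        attainable=attainable,
        inflation=inflation,
        n_required=n_required,
        n_star=n_star,
        z_sum=float(z_sum),
    )


def attainability_scan(
    spec: DesignSpec,
    a_values: Sequence[float],
    resolution: int = 61,
    boundary_count: int = 256,
    rounded_z: bool = False,
) -> pd.DataFrame:
    """Inflation factors over an ascending family of region scales.

    Returns one row per ``a`` with theta_min, inflation and attainability;
    the smallest unattainable ``a`` locates the infinite inflation boundary.
    """
    a_values = list(a_values)
    if any(b < a for a, b in zip(a_values, a_values[1:])):
        raise ValidationError("a_values must be ascending")
    rows = []
    for a in a_values:
        res = inflation_factor(
            replace(spec, region=replace(spec.region, a=float(a))),
            resolution=resolution,
            boundary_count=boundary_count,
            rounded_z=rounded_z,
        )
        rows.append(
            {
                "a": float(a),
                "theta_min": res.theta_min,
                "inflation": res.inflation,
                "n_required": res.n_required,
                "attainable": res.attainable,
            }
        )
    return pd.DataFrame(rows)


def simulated_power(
    spec: DesignSpec,
    n: int,
    true_point: Tuple[float, float],
    replicates: int = 500,
    seed: Optional[int] = None,
    resolution: int = 41,
    boundary_count: int = 128,
    z_crit: Optional[float] = None,
    points: Optional[np.ndarray] = None,
) -> float:
    """Monte-Carlo robust-rejection rate at per-group size ``n``.

    Trials are simulated under the design's alternative (p_c, p_t) with the
    true mechanism ``true_point = (R_c, R_t)`` and fixed marginal missingness
    q; each replicate applies the robust rule over the region (or over the
    supplied ``points``).  Replicates where the statistic is undefined at any
    scanned point count as non-rejections.  Validation tool for the
    expected-table approximation behind :func:`inflation_factor`.
    """
    if z_crit is None:
        z_crit = float(norm.ppf(1.0 - spec.alpha))
    R_c, R_t = true_point
    model = SelectionModel.from_q(
        p_c=spec.p_c, p_t=spec.p_t, q_c=spec.q_c, q_t=spec.q_t,
        n_c=int(n), n_t=int(n), r_c=R_c, r_t=R_t,
    )
    draws = simulate_tables(model, replicates, seed)
    if points is None:
        points = spec.region.points(resolution, boundary_count)
    points = np.asarray(points, dtype=float)
    zmat = _z_arrays(
        draws["y_c"][:, None].astype(float),
        draws["m_c"][:, None].astype(float),
        float(n),
        draws["y_t"][:, None].astype(float),
        draws["m_t"][:, None].astype(float),
        float(n),
        points[None, :, 0],
        points[None, :, 1],
    )
    zmin = np.min(np.where(np.isnan(zmat), -np.inf, zmat), axis=1)
    return float(np.mean(zmin >= z_crit))
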