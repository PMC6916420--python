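"""Elliptical plausibility regions for the missingness ratios (r_c, r_t).

On the log scale ``gamma_tau = log r_tau``, the region of deviations from MAR
considered credible is the ellipse

    R_a = {(gamma_c, gamma_t) :
           (gamma_t + gamma_c)^2 + (gamma_t - gamma_c)^2 / (1 - e^2)
           <= 4 (log a)^2},

with major axis along ``gamma_t = gamma_c`` (same-signed deviations are more
plausible than opposite-signed ones) and eccentricity ``e``.  The boundary
meets the diagonal at ``r = a`` and ``1/a`` and the anti-diagonal at
``exp(+-sqrt(1-e^2) log a)``.  MAR, the point (1, 1), is always contained.
``a = 2`` ("optimistic") and ``a = 5`` ("skeptical") with ``e = 0.9`` are the
conventional presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple, Union

import numpy as np

from .errors import ValidationError

__all__ = ["PlausibilityRegion", "optimistic", "skeptical", "region_from_config"]

_REL_TOL = 1e-9  # boundary membership tolerance on the quadratic form


@dataclass(frozen=True)
class PlausibilityRegion:
    a: float
    e: float = 0.9

    def __post_init__(self) -> None:
        if not (self.a >= 1.0 and np.isfinite(self.a)):
            raise ValidationError(
                f"region scale a must be >= 1 (a and 1/a bound the same ellipse), got {self.a}"
            )
        if not 0.0 <= self.e < 1.0:
            raise ValidationError(f"eccentricity e must lie in [0, 1), got {self.e}")

    @property
    def log_a(self) -> float:
        return float(np.log(self.a))

    @property
    def semi_diag(self) -> float:
        """Half-extent along the diagonal: |gamma| <= log a there."""
        return self.log_a

    @property
    def semi_antidiag(self) -> float:
        """Half-extent along the anti-diagonal: sqrt(1 - e^2) log a."""
        return float(np.sqrt(1.0 - self.e**2) * self.log_a)

    def quadratic_form(self, r_c, r_t) -> np.ndarray:
        """LHS of the defining inequality, at (r_c, r_t) on the ratio scale."""
        r_c = np.asarray(r_c, dtype=float)
        r_t = np.asarray(r_t, dtype=float)
        if np.any(r_c <= 0) or np.any(r_t <= 0):
            raise ValidationError("missingness ratios must be positive")
        g_c, g_t = np.log(r_c), np.log(r_t)
        return (g_t + g_c) ** 2 + (g_t - g_c) ** 2 / (1.0 - self.e**2)

    def contains(self, r_c, r_t) -> np.ndarray:
        bound = 4.0 * self.log_a**2
        return self.quadratic_form(r_c, r_t) <= bound * (1.0 + _REL_TOL) + _REL_TOL

    def vertices(self) -> np.ndarray:
        """The four boundary vertices, as (r_c, r_t) rows (diag then anti-diag)."""
        L, b = self.semi_diag, self.semi_antidiag
        gammas = np.array([[L, L], [-L, -L], [-b, b], [b, -b]])
        return np.exp(gammas)

    def grid(self, resolution: int = 101) -> np.ndarray:
        """Lattice of contained (r_c, r_t) points, in gamma space.

        A regular ``resolution x resolution`` lattice over the bounding box of
        the ellipse, filtered by membership; (1, 1) and the four vertices are
        always included.
        """
        if resolution < 3:
            raise ValidationError(f"resolution must be >= 3, got {resolution}")
        if self.a == 1.0:
            return np.array([[1.0, 1.0]])
        half = self.log_a * np.sqrt(2.0 - self.e**2)  # max |gamma| over the ellipse
        axis = np.linspace(-half, half, resolution)
        g_c, g_t = np.meshgrid(axis, axis)
        pts = np.exp(np.column_stack([g_c.ravel(), g_t.ravel()]))
        pts = pts[self.contains(pts[:, 0], pts[:, 1])]
        pts = np.vstack([pts, [[1.0, 1.0]], self.vertices()])
        return np.unique(pts, axis=0)

    def boundary(self, count: int = 512) -> np.ndarray:
        """``count`` points exactly on the boundary, ordered by angle.

        The ellipse is parameterized in the rotated frame ``u = (g_c + g_t) /
        sqrt(2)``, ``v = (g_t - g_c) / sqrt(2)`` with semi-axes ``sqrt(2) log
        a`` and ``sqrt(2) sqrt(1 - e^2) log a``; ``count = 4`` returns the
        vertices.
        """
        if count < 4:
            raise ValidationError(f"count must be >= 4, got {count}")
        return np.exp(self._boundary_gamma(2.0 * np.pi * np.arange(count) / count))

    def _boundary_gamma(self, angle) -> np.ndarray:
        angle = np.atleast_1d(np.asarray(angle, dtype=float))
        u = np.sqrt(2.0) * self.semi_diag * np.cos(angle)
        v = np.sqrt(2.0) * self.semi_antidiag * np.sin(angle)
        return np.column_stack([(u - v) / np.sqrt(2.0), (u + v) / np.sqrt(2.0)])

    def boundary_point(self, angle: float) -> Tuple[float, float]:
        """Single boundary point (r_c, r_t) at the given ellipse angle."""
        g = self._boundary_gamma(angle)[0]
        return float(np.exp(g[0])), float(np.exp(g[1]))

    def points(self, resolution: int = 101, boundary_count: int = 512) -> np.ndarray:
        """Union of the interior lattice and the boundary discretization."""
        if self.a == 1.0:
            return np.array([[1.0, 1.0]])
        return np.vstack([self.grid(resolution), self.boundary(boundary_count)])


def optimistic(e: float = 0.9) -> PlausibilityRegion:
    """R_2: small deviations from ignorability considered plausible."""
    return PlausibilityRegion(a=2.0, e=e)


def skeptical(e: float = 0.9) -> PlausibilityRegion:
    """R_5: large deviations from ignorability considered plausible."""
    return PlausibilityRegion(a=5.0, e=e)


_PRESETS = {"optimistic": optimistic, "skeptical": skeptical}


def region_from_config(config: Union[str, Mapping]) -> PlausibilityRegion:
    """Build a region from ``{"a": ..., "e": ...}``, ``{"preset": ...}``,
    a preset name, or a CLI-style string ``"a=5,e=0.9"``."""
    if isinstance(config, PlausibilityRegion):
        return config
    if isinstance(config, str):
        if config in _PRESETS:
            return _PRESETS[config]()
        parts = dict(item.split("=", 1) for item in config.split(",") if "=" in item)
        if not parts:
            raise ValidationError(
                f"cannot parse region {config!r}; expected 'a=5,e=0.9' or a preset name"
            )
        return PlausibilityRegion(a=float(parts["a"]), e=float(parts.get("e", 0.9)))
    if "preset" in config:
        name = config["preset"]
        if name not in _PRESETS:
            raise ValidationError(f"unknown region preset {name!r}")
        return _PRESETS[name]()
    return PlausibilityRegion(a=float(config["a"]), e=float(config.get("e", 0.9)))
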