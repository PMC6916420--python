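"""Selection model for non-ignorable missingness of a binary response.

Per arm ``tau``, the true failure probability is ``p_tau``; the probability
that a response is missing given success is ``pi_tau`` and given failure is
``r_tau * pi_tau``.  The ratio ``r_tau`` is the sensitivity parameter:
``r_c = r_t = 1`` is missing at random (MAR), and the impact of any deviation
from MAR on observable quantities is fully captured by ``(r_c, r_t)``.

Closed forms used throughout the package:

* marginal missingness      ``q = (1 - p + r p) pi``
* observed failure rate     ``p~ = p (1 - r pi) / (1 - q)``
* expected counts           ``E[y] = p (1 - r pi) n``, ``E[m] = (1 - q) n``

A subject in arm ``tau`` falls in one of four multinomial cells
(fail-observed, fail-missing, success-observed, success-missing) with
probabilities ``p(1-r pi), p r pi, (1-p)(1-pi), (1-p) pi``; the Monte-Carlo
simulator draws one multinomial per arm, which is exactly the joint law of
the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .errors import InfeasibleParameterError, UndefinedStatisticError, ValidationError
from .trial_tables import TrialTable

__all__ = [
    "SelectionModel",
    "CellProbabilities",
    "pi_from_q",
    "marginal_missingness",
    "observed_failure_prob",
    "cell_probabilities",
    "expected_table",
    "simulate_table",
    "simulate_tables",
    "model_from_config",
]

_ARMS = ("c", "t")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SelectionModel:
    """MNAR mechanism ``(p_c, p_t, pi_c, pi_t, r_c, r_t)`` with arm sizes."""

    p_c: float
    p_t: float
    pi_c: float
    pi_t: float
    n_c: int
    n_t: int
    r_c: float = 1.0
    r_t: float = 1.0

    def __post_init__(self) -> None:
        for arm in _ARMS:
            p = getattr(self, f"p_{arm}")
            pi = getattr(self, f"pi_{arm}")
            r = getattr(self, f"r_{arm}")
            n = getattr(self, f"n_{arm}")
            _check_prob(f"p_{arm}", p)
            _check_prob(f"pi_{arm}", pi)
            if not (r > 0.0 and np.isfinite(r)):
                raise ValidationError(f"r_{arm} must be a finite positive ratio, got {r}")
            if r * pi > 1.0 + 1e-12:
                raise InfeasibleParameterError(
                    f"r_{arm} * pi_{arm} = {r * pi:.6g} > 1: "
                    "missingness probability given failure exceeds 1"
                )
            if n < 0:
                raise ValidationError(f"n_{arm} must be >= 0, got {n}")

    @classmethod
    def from_q(
        cls,
        p_c: float,
        p_t: float,
        q_c: float,
        q_t: float,
        n_c: int,
        n_t: int,
        r_c: float = 1.0,
        r_t: float = 1.0,
    ) -> "SelectionModel":
        """Specify the mechanism by marginal missingness ``q`` per arm.

        ``pi`` is recovered with :func:`pi_from_q`; design-stage inputs fix
        ``q`` across hypothesized ``(r_c, r_t)`` while ``pi`` varies.
        """
        return cls(
            p_c=p_c,
            p_t=p_t,
            pi_c=pi_from_q(p_c, r_c, q_c),
            pi_t=pi_from_q(p_t, r_t, q_t),
            n_c=n_c,
            n_t=n_t,
            r_c=r_c,
            r_t=r_t,
        )

    def arm(self, arm: str) -> tuple:
        if arm not in _ARMS:
            raise ValidationError(f"arm must be 'c' or 't', got {arm!r}")
        return (
            getattr(self, f"p_{arm}"),
            getattr(self, f"pi_{arm}"),
            getattr(self, f"r_{arm}"),
            getattr(self, f"n_{arm}"),
        )


@dataclass(frozen=True)
class CellProbabilities:
    """Per-arm multinomial cell probabilities of the selection model."""

    fail_observed: float
    fail_missing: float
    success_observed: float
    success_missing: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.fail_observed, self.fail_missing, self.success_observed, self.success_missing]
        )


def pi_from_q(p: float, r: float, q: float) -> float:
    """Invert ``q = (1 - p + r p) pi`` for the success-missingness ``pi``.

    Raises if the implied ``pi`` is not a probability or if ``r * pi > 1``.
    """
    _check_prob("p", p)
    _check_prob("q", q)
    if not (r > 0.0 and np.isfinite(r)):
        raise ValidationError(f"r must be a finite positive ratio, got {r}")
    pi = q / (1.0 - p + r * p)
    if pi > 1.0 + 1e-12:
        raise InfeasibleParameterError(
            f"q = {q} with p = {p}, r = {r} requires pi = {pi:.6g} > 1"
        )
    if r * pi > 1.0 + 1e-12:
        raise InfeasibleParameterError(
            f"q = {q} with p = {p}, r = {r} requires r * pi = {r * pi:.6g} > 1 "
            "(missingness given failure exceeds 1)"
        )
    return min(pi, 1.0)


def marginal_missingness(model: SelectionModel, arm: str) -> float:
    """Marginal probability ``q_tau`` that a response in ``arm`` is missing."""
    p, pi, r, _ = model.arm(arm)
    return (1.0 - p + r * p) * pi


def observed_failure_prob(model: SelectionModel, arm: str) -> float:
    """Failure probability ``p~_tau`` among subjects with non-missing responses.

    Undefined when ``q_tau = 1`` (every response missing).  At ``r = 1`` (MAR)
    this reduces to ``p_tau`` for any ``pi``.
    """
    p, pi, r, _ = model.arm(arm)
    q = (1.0 - p + r * p) * pi
    if q >= 1.0:
        raise UndefinedStatisticError(
            f"observed failure probability undefined in arm {arm}: q = 1 (all responses missing)"
        )
    return p * (1.0 - r * pi) / (1.0 - q)


def cell_probabilities(model: SelectionModel, arm: str) -> CellProbabilities:
    p, pi, r, _ = model.arm(arm)
    return CellProbabilities(
        fail_observed=p * (1.0 - r * pi),
        fail_missing=p * r * pi,
        success_observed=(1.0 - p) * (1.0 - pi),
        success_missing=(1.0 - p) * pi,
    )


def expected_table(model: SelectionModel) -> TrialTable:
    """Expected summary table under the mechanism; counts are real-valued.

    No rounding is applied: downstream design formulas are evaluated at
    expectations and rounding would bias them.
    """
    counts = {}
    for arm in _ARMS:
        p, pi, r, n = model.arm(arm)
        q = (1.0 - p + r * p) * pi
        counts[f"y_{arm}"] = p * (1.0 - r * pi) * n
        counts[f"m_{arm}"] = (1.0 - q) * n
        counts[f"n_{arm}"] = float(n)
    return TrialTable(**counts)


def simulate_tables(
    model: SelectionModel,
    replicates: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> dict:
    """Draw ``replicates`` tables; returns arrays ``y_c, m_c, y_t, m_t``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for arm in _ARMS:
        _, _, _, n = model.arm(arm)
        cells = rng.multinomial(int(n), cell_probabilities(model, arm).as_array(), size=replicates)
        out[f"y_{arm}"] = cells[:, 0]
        out[f"m_{arm}"] = cells[:, 0] + cells[:, 2]
    return out

def simulate_table(
    model: SelectionModel,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> TrialTable:
    """One multinomial draw per arm from the mechanism's joint law."""
    draws = simulate_tables(model, 1, seed)
    return TrialTable(
        y_c=int(draws["y_c"][0]),
        m_c=int(draws["m_c"][0]),
        n_c=int(model.n_c),
        y_t=int(draws["y_t"][0]),
        m_t=int(draws["m_t"][0]),
        n_t=int(model.n_t),
    )


def model_from_config(config: Mapping) -> SelectionModel:
    """Build a model from a YAML/JSON-style mapping.

    Layout: ``{p_c, p_t, n_c, n_t, r_c, r_t, missingness: {mode: "pi"|"q",
    pi_c/pi_t or q_c/q_t (or a common pi/q)}}``.  ``pi`` is canonical
    internally; ``q`` specifications are converted via :func:`pi_from_q`.
    """
    miss = config.get("missingness", {})
    mode = miss.get("mode", "pi")
    common = {
        "p_c": config["p_c"],
        "p_t": config["p_t"],
        "n_c": config["n_c"],
        "n_t": config["n_t"],
        "r_c": config.get("r_c", 1.0),
        "r_t": config.get("r_t", 1.0),
    }
    if mode == "pi":
        pi_c = miss.get("pi_c", miss.get("pi"))
        pi_t = miss.get("pi_t", miss.get("pi"))
        if pi_c is None or pi_t is None:
            raise ValidationError("missingness mode 'pi' requires pi or pi_c/pi_t")
        return SelectionModel(pi_c=pi_c, pi_t=pi_t, **common)
    if mode == "q":
        q_c = miss.get("q_c", miss.get("q"))
        q_t = miss.get("q_t", miss.get("q"))
        if q_c is None or q_t is None:
            raise ValidationError("missingness mode 'q' requires q or q_c/q_t")
        return SelectionModel.from_q(q_c=q_c, q_t=q_t, **common)
    raise ValidationError(f"unknown missingness mode {mode!r}; expected 'pi' or 'q'")
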