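"""2x2 trial tables with missing binary responses.

A randomized trial with a binary endpoint (failure = 1, e.g. "dead";
success = 0, "alive") and incomplete follow-up reduces, per arm
``tau in {c, t}``, to three counts:

* ``y`` — observed failures,
* ``m`` — non-missing responses,
* ``n`` — subjects randomized,

with ``0 <= y <= m <= n``.  This module provides the container type, CSV/JSON
I/O, the complete-case Z statistic (the signed square root of the Pearson
chi-square on the observed 2x2 table), and the deterministic extreme-case
imputations (best/worst case, all-alive, all-dead) used as bounds in
sensitivity analysis.
"""

from __future__ import annotations

import json
import numbers
import os
from dataclasses import asdict, dataclass, replace
from typing import IO, Mapping, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "TrialTable",
    "CompleteCaseResult",
    "read_table",
    "write_table",
    "complete_case_stats",
    "impute_extreme",
    "EXTREME_CASES",
]

EXTREME_CASES = ("worst", "best", "all_alive", "all_dead")


@dataclass(frozen=True)
class TrialTable:
    """Summary counts for a two-arm trial with missing binary responses.

    Counts may be real-valued (expected tables under a missingness mechanism
    carry non-integer expectations); tables read from data files are
    validated to be integral by :func:`read_table`.
    """

    y_c: float
    m_c: float
    n_c: float
    y_t: float
    m_t: float
    n_t: float

    def __post_init__(self) -> None:
        for arm in ("c", "t"):
            y = getattr(self, f"y_{arm}")
            m = getattr(self, f"m_{arm}")
            n = getattr(self, f"n_{arm}")
            for name in (f"y_{arm}", f"m_{arm}", f"n_{arm}"):
                value = getattr(self, name)
                if not isinstance(value, numbers.Real) or not np.isfinite(value):
                    raise ValidationError(f"{name} must be a finite number, got {value!r}")
            if y < 0:
                raise ValidationError(f"y_{arm} must be >= 0, got {y}")
            if y > m:
                raise ValidationError(f"y_{arm} (= {y}) exceeds m_{arm} (= {m})")
            if m > n:
                raise ValidationError(f"m_{arm} (= {m}) exceeds n_{arm} (= {n})")

    @property
    def missing_c(self) -> float:
        return self.n_c - self.m_c

    @property
    def missing_t(self) -> float:
        return self.n_t - self.m_t

    @property
    def n_total(self) -> float:
        return self.n_c + self.n_t

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        """Two-row frame with the CSV dialect used by :func:`read_table`."""
        return pd.DataFrame(
            {
                "arm": ["c", "t"],
                "failures": [self.y_c, self.y_t],
                "observed": [self.m_c, self.m_t],
                "randomized": [self.n_c, self.n_t],
            }
        )


@dataclass(frozen=True)
class CompleteCaseResult:
    """Complete-case summary: per-arm proportions, pooled Z, odds ratio."""

    phat_c: float
    phat_t: float
    pbar: float
    z_tilde: float
    odds_ratio: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return asdict(self)


_FIELDS = ("y_c", "m_c", "n_c", "y_t", "m_t", "n_t")


def _table_from_mapping(record: Mapping, require_int: bool = True) -> TrialTable:
    missing = [f for f in _FIELDS if f not in record]
    if missing:
        raise ValidationError(f"record is missing count fields: {', '.join(missing)}")
    values = {}
    for f in _FIELDS:
        v = record[f]
        if require_int:
            if float(v) != int(v):
                raise ValidationError(f"{f} must be an integer count, got {v!r}")
            v = int(v)
        values[f] = v
    return TrialTable(**values)


def read_table(source: Union[str, os.PathLike, IO, Mapping]) -> TrialTable:
    """Read and validate a trial table.

    Accepts a mapping with keys ``y_c, m_c, n_c, y_t, m_t, n_t``, a path to a
    JSON file with those keys, or a path/stream holding a two-row CSV with
    header ``arm,failures,observed,randomized`` (arms ``c`` and ``t``).
    """
    if isinstance(source, Mapping):
        return _table_from_mapping(source)
    if isinstance(source, (str, os.PathLike)) and str(source).endswith(".json"):
        with open(source) as fh:
            return _table_from_mapping(json.load(fh))
    frame = pd.read_csv(source)
    expected_cols = {"arm", "failures", "observed", "randomized"}
    if not expected_cols.issubset(frame.columns):
        raise ValidationError(
            f"CSV must have columns {sorted(expected_cols)}, got {list(frame.columns)}"
        )
    frame = frame.set_index(frame["arm"].astype(str).str.strip())
    record = {}
    for arm in ("c", "t"):
        if arm not in frame.index:
            raise ValidationError(f"CSV must contain a row for arm {arm!r}")
        row = frame.loc[arm]
        record[f"y_{arm}"] = row["failures"]
        record[f"m_{arm}"] = row["observed"]
        record[f"n_{arm}"] = row["randomized"]
    return _table_from_mapping(record)


def write_table(table: TrialTable, path: Union[str, os.PathLike, IO]) -> None:
    """Write a table in the two-row CSV dialect accepted by :func:`read_table`."""
    table.to_frame().to_csv(path, index=False)


def complete_case_stats(table: TrialTable) -> CompleteCaseResult:
    """Complete-case two-proportion Z test of the observed failure rates.

    The statistic is

        Z = (phat_c - phat_t) / sqrt(pbar (1 - pbar) (1/m_t + 1/m_c)),

    with ``phat_tau = y_tau / m_tau`` and pooled ``pbar``; positive values
    favour arm t (lower failure rate among complete cases).  Equals the
    signed square root of the Pearson chi-square statistic on the observed
    2x2 table.  The odds ratio is reported t-versus-c on failures (< 1
    favours t).
    """
    if table.m_c <= 0 or table.m_t <= 0:
        raise UndefinedStatisticError("complete-case Z undefined: an arm has no observed responses")
    phat_c = table.y_c / table.m_c
    phat_t = table.y_t / table.m_t
    pbar = (table.y_c + table.y_t) / (table.m_c + table.m_t)
    if pbar <= 0.0 or pbar >= 1.0:
        raise UndefinedStatisticError(
            "complete-case Z undefined: pooled proportion is 0 or 1 (zero variance)"
        )
    se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / table.m_t + 1.0 / table.m_c))
    z = (phat_c - phat_t) / se
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_ratio = float(
            np.float64(table.y_t * (table.m_c - table.y_c))
            / np.float64(table.y_c * (table.m_t - table.y_t))
        )
    p_two = 2.0 * norm.sf(abs(z))
    return CompleteCaseResult(
        phat_c=float(phat_c),
        phat_t=float(phat_t),
        pbar=float(pbar),
        z_tilde=float(z),
        odds_ratio=odds_ratio,
        p_two_sided=float(p_two),
    )


def impute_extreme(table: TrialTable, case: str) -> TrialTable:
    """Resolve all missing responses deterministically.

    ``worst``     missing in t are failures, missing in c successes
                  (adverse for t; the r_c -> 0, r_t -> inf limit);
    ``best``      the mirror image (r_c -> inf, r_t -> 0);
    ``all_alive`` every missing response is a success;
    ``all_dead``  every missing response is a failure.

    The returned table has ``m = n`` in both arms.
    """
    if case not in EXTREME_CASES:
        raise ValidationError(f"unknown imputation case {case!r}; expected one of {EXTREME_CASES}")
    add_c = add_t = 0.0
    if case == "worst":
        add_t = table.missing_t
    elif case == "best":
        add_c = table.missing_c
    elif case == "all_dead":
        add_c, add_t = table.missing_c, table.missing_t
    return replace(
        table,
        y_c=table.y_c + add_c,
        m_c=table.n_c,
        y_t=table.y_t + add_t,
        m_t=table.n_t,
    )
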