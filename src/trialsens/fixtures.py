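"""Packaged example data and named scenario builders.

The worked-example table (a two-arm trial with "dead"/"alive"/"missing"
counts per arm) and the nine hypothetical tables sharing a complete-case Z
of about 2.80 ship as CSV files in ``trialsens/data``; named scenarios
reconstruct the parameter sets behind the operating-characteristic and
design illustrations, so every analysis in the package runs without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Union

import pandas as pd

from .design import DesignSpec
from .errors import ValidationError
from .missingness_model import SelectionModel
from .plausibility_region import PlausibilityRegion, skeptical
from .trial_tables import TrialTable, read_table

__all__ = ["PaperFixture", "table2_fixture", "table3_fixture", "table3_rows", "scenario"]


@dataclass(frozen=True)
class PaperFixture:
    name: str
    table: TrialTable
    expected: dict


def _data_path(name: str):
    return resources.files("trialsens.data").joinpath(name)


def table2_fixture() -> PaperFixture:
    """Worked example: dead/alive/missing of 38/51/11 (control) and 21/70/9
    (experimental), 100 randomized per arm."""
    with resources.as_file(_data_path("table2.csv")) as path:
        table = read_table(path)
    return PaperFixture(
        name="table2",
        table=table,
        expected={
            "z_tilde": 2.80,
            "p_two_sided": 0.005,
            "z_best": 4.15,
            "z_worst": 1.19,
            "min_z_optimistic": 2.6,
            "min_z_skeptical": 2.3,
        },
    )


def table3_rows() -> pd.DataFrame:
    """All nine hypothetical tables as printed, with decision columns."""
    with resources.as_file(_data_path("table3.csv")) as path:
        return pd.read_csv(path)


def table3_fixture(row: str) -> PaperFixture:
    """One hypothetical table (rows ``a`` .. ``i``).

    The per-arm missing counts are authoritative (they fix m = n - missing);
    the percent-missing column is informational only.
    """
    frame = table3_rows().set_index("row")
    if row not in frame.index:
        raise ValidationError(f"unknown table row {row!r}; expected 'a'..'i'")
    rec = frame.loc[row]
    n = int(rec["n"])
    table = TrialTable(
        y_c=int(rec["dead_c"]),
        m_c=n - int(rec["missing_c"]),
        n_c=n,
        y_t=int(rec["dead_t"]),
        m_t=n - int(rec["missing_t"]),
        n_t=n,
    )
    return PaperFixture(
        name=f"table3-{row}",
        table=table,
        expected={
            "z_tilde": 2.80,
            "odds_ratio": float(rec["odds_ratio"]),
            "pct_missing": float(rec["pct_missing"]),
            "reject_optimistic": rec["reject_r2"] == "Y",
            "reject_skeptical": rec["reject_r5"] == "Y",
        },
    )


# operating-characteristic panels: p_c = p_t = 0.3, pi common to both arms,
# 100 / 1000 / 5000 per group across columns and pi 0.05 / 0.10 / 0.15 down rows
_OC_PANELS = {
    "fig2-A": (0.05, 100), "fig2-B": (0.05, 1000), "fig2-C": (0.05, 5000),
    "fig2-D": (0.10, 100), "fig2-E": (0.10, 1000), "fig2-F": (0.10, 5000),
    "fig2-G": (0.15, 100), "fig2-H": (0.15, 1000), "fig2-I": (0.15, 5000),
}

# design panels: 90% power, one-sided 0.025, p_c = 0.3; n* pinned to the
# conventional round sizes for the stated p_t
_DESIGN_PANELS = {
    "fig5-A": (0.116, 100),
    "fig5-B": (0.236, 1000),
    "fig5-C": (0.279, 10000),
}


def scenario(name: str) -> Union[SelectionModel, DesignSpec]:
    """Named parameter sets for the illustration scenarios.

    ``fig2-A`` .. ``fig2-I`` return :class:`SelectionModel` instances under
    the causal null; ``fig4`` and ``fig5-A/B/C`` return
    :class:`DesignSpec` instances (``fig4``: q = 0.10, n* = 1000, region
    a = 2.30; ``fig5-*``: q = 0.10 and the skeptical region by default —
    use :func:`dataclasses.replace` to vary q or the region scale).
    """
    if name in _OC_PANELS:
        pi, n = _OC_PANELS[name]
        return SelectionModel(p_c=0.3, p_t=0.3, pi_c=pi, pi_t=pi, n_c=n, n_t=n)
    if name == "fig4":
        return DesignSpec(
            p_c=0.3, p_t=0.236, q_c=0.10, q_t=0.10,
            region=PlausibilityRegion(a=2.30, e=0.9), n_star=1000,
        )
    if name in _DESIGN_PANELS:
        p_t, n_star = _DESIGN_PANELS[name]
        return DesignSpec(
            p_c=0.3, p_t=p_t, q_c=0.10, q_t=0.10, region=skeptical(), n_star=n_star
        )
    raise ValidationError(f"unknown scenario {name!r}")
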