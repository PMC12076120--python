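"""Reporting-odds-ratio disproportionality signals on 2x2 drug–event tables.

The 2x2 table for a (drug, event) pair counts reports, not rows: a report
contributes to the event column if any of its preferred terms matches. A
signal is called positive when the lower 95% confidence bound of the ROR
exceeds 1 and the pair has at least three reports; a Bonferroni flag marks
results whose Wald p-value survives correction across the preferred terms
tested for the same drug and stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError

#: Age-bin schemes; bins are [low, high) in years.
AGE_SCHEMES = {
    "methods": [("<18", 0.0, 18.0), ("18-65", 18.0, 65.0), (">=65", 65.0, math.inf)],
    "results": [
        ("<18", 0.0, 18.0),
        ("18-65", 18.0, 65.0),
        ("65-85", 65.0, 86.0),
        (">85", 86.0, math.inf),
    ],
}

OVERALL = "overall"


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts: a = drug & event, b = drug only, c = event only, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


class RorStats(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    zero_cell_corrected: bool


def ror_ci(table: ContingencyTable, level: float = 0.95) -> RorStats:
    """ROR with Wald confidence interval and two-sided z-test on the log scale.

    Any zero cell triggers the Haldane–Anscombe correction (+0.5 to every
    cell), reported via the ``zero_cell_corrected`` flag. An all-zero table is
    undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise EmptyInputError("ROR undefined on an all-zero table")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    p_value = 2 * sps.norm.sf(abs(log_ror) / se)
    return RorStats(ror, ci_low, ci_high, p_value, corrected)


def _report_level(reports: pd.DataFrame) -> pd.DataFrame:
    """Unique (report, drug, pt) triples plus per-report demographics."""
    cols = ["report_id", "drug_name", "pt_name", "sex", "age_years"]
    return reports.loc[:, cols].drop_duplicates(subset=["report_id", "drug_name", "pt_name"])


def _stratum_mask(frame: pd.DataFrame, stratum: str, age_scheme: str) -> pd.Series:
    """Boolean row mask for a stratum label such as 'overall', 'sex:F', 'age:18-65'."""
    if stratum == OVERALL:
        return pd.Series(True, index=frame.index)
    kind, _, value = stratum.partition(":")
    if kind == "sex":
        if value not in ("F", "M"):
            raise ValueError(f"unknown sex stratum {value!r}")
        return frame["sex"] == value
    if kind == "age":
        for label, lo, hi in AGE_SCHEMES[age_scheme]:
            if label == value:
                age = frame["age_years"]
                return age.notna() & (age >= lo) & (age < hi)
        raise ValueError(f"unknown age bin {value!r} in scheme {age_scheme!r}")
    raise ValueError(f"unknown stratum {stratum!r}")


def expand_strata(strata: Iterable[str], age_scheme: str = "methods") -> list[str]:
    """Expand shorthand 'sex' / 'age' entries into their concrete strata."""
    out: list[str] = []
    for s in strata:
        if s == "sex":
            out += ["sex:F", "sex:M"]
        elif s == "age":
            out += [f"age:{label}" for label, _, _ in AGE_SCHEMES[age_scheme]]
        else:
            out.append(s)
    return out


def build_table(
    reports: pd.DataFrame,
    drug: str,
    pt: str,
    stratum: str = OVERALL,
    age_scheme: str = "methods",
) -> ContingencyTable:
    """2x2 report-count table for one drug–event pair within one stratum."""
    frame = _report_level(reports)
    frame = frame.loc[_stratum_mask(frame, stratum, age_scheme)]
    if frame.empty:
        return ContingencyTable(0, 0, 0, 0)
    grouped = frame.groupby("report_id", sort=False)
    has_drug = grouped["drug_name"].agg(lambda s: (s == drug).any())
    has_pt = grouped["pt_name"].agg(lambda s: (s == pt).any())
    a = int((has_drug & has_pt).sum())
    b = int((has_drug & ~has_pt).sum())
    c = int((~has_drug & has_pt).sum())
    d = int((~has_drug & ~has_pt).sum())
    return ContingencyTable(a, b, c, d)


def detect_signals(
    reports: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    pts: Sequence[str] | None = None,
    strata: Sequence[str] = (OVERALL,),
    alpha: float = 0.05,
    level: float = 0.95,
    age_scheme: str = "methods",
    min_count: int = 3,
) -> pd.DataFrame:
    """One ROR signal row per (drug, preferred term, stratum) with a ≥ 1.

    The Bonferroni family is the number of preferred terms tested for the
    same drug within the same stratum. Missing sex/age rows are excluded from
    the corresponding stratified analyses but retained in 'overall'.
    """
    frame = _report_level(reports)
    if drugs is None:
        drugs = sorted(frame["drug_name"].unique())
    strata = expand_strata(strata, age_scheme)

    rows = []
    for stratum in strata:
        sub = frame.loc[_stratum_mask(frame, stratum, age_scheme)]
        if sub.empty:
            continue
        n_total = sub["report_id"].nunique()
        # cross-tabulate at report level: single drug and PT per report is the
        # common case; any-match semantics preserved via drop_duplicates above
        pair_counts = (
            sub.drop_duplicates(subset=["report_id", "drug_name", "pt_name"])
            .groupby(["drug_name", "pt_name"], sort=False)["report_id"]
            .nunique()
        )
        drug_totals = sub.groupby("drug_name", sort=False)["report_id"].nunique()
        pt_totals = sub.groupby("pt_name", sort=False)["report_id"].nunique()
        for drug in drugs:
            n_drug = int(drug_totals.get(drug, 0))
            if n_drug == 0:
                continue
            pair = pair_counts.loc[drug] if drug in pair_counts.index.get_level_values(0) else None
            if pair is None:
                continue
            tested_pts = [p for p in (pts if pts is not None else pair.index) if p in pair.index]
            m = len(tested_pts)
            for pt in tested_pts:
                a = int(pair[pt])
                if a < 1:
                    continue
                n_pt = int(pt_totals.get(pt, 0))
                table = ContingencyTable(a, n_drug - a, n_pt - a, n_total - n_drug - n_pt + a)
                stats = ror_ci(table, level=level)
                rows.append(
                    {
                        "drug": drug,
                        "pt": pt,
                        "stratum": stratum,
                        "a": a,
                        "ror": stats.ror,
                        "ci_low": stats.ci_low,
                        "ci_high": stats.ci_high,
                        "p": stats.p_value,
                        "bonferroni_significant": stats.p_value < alpha / m,
                        "positive_signal": stats.ci_low > 1.0 and a >= min_count,
                        "zero_cell_corrected": stats.zero_cell_corrected,
                    }
                )
    columns = [
        "drug",
        "pt",
        "stratum",
        "a",
        "ror",
        "ci_low",
        "ci_high",
        "p",
        "bonferroni_significant",
        "positive_signal",
        "zero_cell_corrected",
    ]
    return pd.DataFrame(rows, columns=columns)
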