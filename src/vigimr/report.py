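"""Publication-shaped output tables and printed-ratio verification.

Besides assembling the descriptive, signal, onset-time and MR tables, this
module carries a small regression harness: a bundled fixture of printed
(numerator, denominator, percent) triples whose arithmetic is recomputed and
compared at two decimals, guarding the half-up rounding convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import meddra
from .rounding import percent_of

logger = logging.getLogger(__name__)


@dataclass
class DescriptiveSummary:
    """Per-drug and overall psychiatric-event report counts and percents."""

    per_drug: pd.DataFrame  # drug, n_reports, n_psychiatric, percent
    overall_reports: int
    overall_psychiatric: int
    overall_percent: float
    sex_breakdown: pd.DataFrame  # drug, sex, n_reports
    age_breakdown: pd.DataFrame  # drug, age_bin, n_reports


def descriptive_summary(
    reports: pd.DataFrame,
    dictionary: meddra.PTDictionary,
    drug_list: list[str] | None = None,
    age_scheme: str = "results",
) -> DescriptiveSummary:
    """Counts and percents of psychiatric-event reports, per drug and overall."""
    from .signal import AGE_SCHEMES  # local import avoids a cycle at module load

    if drug_list is None:
        drug_list = sorted(reports["drug_name"].unique()) if not reports.empty else []
    is_psy = (
        meddra.classify_series(reports["pt_name"], dictionary) == meddra.PSYCHIATRIC
        if not reports.empty
        else pd.Series(dtype=bool)
    )

    rows, sex_rows, age_rows = [], [], []
    total_n = total_psy = 0
    for drug in drug_list:
        sub = reports.loc[reports["drug_name"] == drug] if not reports.empty else reports
        if sub.empty and drug not in set(reports.get("drug_name", pd.Series(dtype=str))):
            logger.warning("drug %r absent from the report table; zero row emitted", drug)
        n = int(sub["report_id"].nunique()) if not sub.empty else 0
        n_psy = int(sub.loc[is_psy.reindex(sub.index, fill_value=False), "report_id"].nunique()) if n else 0
        rows.append(
            {
                "drug": drug,
                "n_reports": n,
                "n_psychiatric": n_psy,
                "percent": percent_of(n_psy, n) if n else 0.0,
            }
        )
        total_n += n
        total_psy += n_psy
        if n:
            for sex, cnt in sub.groupby("sex")["report_id"].nunique().items():
                sex_rows.append({"drug": drug, "sex": sex, "n_reports": int(cnt)})
            age = pd.to_numeric(sub["age_years"], errors="coerce")
            for label, lo, hi in AGE_SCHEMES[age_scheme]:
                mask = age.notna() & (age >= lo) & (age < hi)
                age_rows.append(
                    {
                        "drug": drug,
                        "age_bin": label,
                        "n_reports": int(sub.loc[mask, "report_id"].nunique()),
                    }
                )
    return DescriptiveSummary(
        per_drug=pd.DataFrame(rows, columns=["drug", "n_reports", "n_psychiatric", "percent"]),
        overall_reports=total_n,
        overall_psychiatric=total_psy,
        overall_percent=percent_of(total_psy, total_n) if total_n else 0.0,
        sex_breakdown=pd.DataFrame(sex_rows, columns=["drug", "sex", "n_reports"]),
        age_breakdown=pd.DataFrame(age_rows, columns=["drug", "age_bin", "n_reports"]),
    )


def verify_printed_arithmetic(rows) -> pd.DataFrame:
    """Recompute each (numerator, denominator, printed_percent) row.

    Accepts an iterable of triples or a frame with those columns; returns the
    input annotated with the recomputed percent and a pass flag at 2 decimals.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows, columns=["numerator", "denominator", "printed_percent"])
    out = rows.copy()
    out["recomputed_percent"] = [
        percent_of(int(n), int(d)) for n, d in zip(out["numerator"], out["denominator"])
    ]
    out["passed"] = out["recomputed_percent"] == out["printed_percent"].astype(float)
    return out


def load_printed_ratio_fixture() -> pd.DataFrame:
    """The bundled fixture of published proportion rows (label, numerator,
    denominator, printed_percent)."""
    ref = resources.files("vigimr").joinpath("data/printed_ratios.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def write_outputs(
    outdir,
    descriptive: DescriptiveSummary | None = None,
    signals: pd.DataFrame | None = None,
    tto_table: pd.DataFrame | None = None,
    mr_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write whichever output tables were produced; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        written[name] = path

    if descriptive is not None:
        per_drug = descriptive.per_drug.copy()
        per_drug.loc[len(per_drug)] = {
            "drug": "ALL",
            "n_reports": descriptive.overall_reports,
            "n_psychiatric": descriptive.overall_psychiatric,
            "percent": descriptive.overall_percent,
        }
        _write("descriptive.tsv", per_drug)
        _write("descriptive_sex.tsv", descriptive.sex_breakdown)
        _write("descriptive_age.tsv", descriptive.age_breakdown)
    if signals is not None:
        _write("signals.tsv", signals)
    if tto_table is not None:
        _write("tto_table1.tsv", tto_table)
    if mr_table is not None:
        _write("mr_tableS3.tsv", mr_table)
    return written
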