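"""Tabular dialects used across the pipeline.

Two text formats are defined here: the spontaneous-report table and the
per-trait GWAS summary-statistic table. Both are plain tab-separated files
with a fixed header so that every stage (simulator, ingest, signal, tto, mr)
reads and writes the same thing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical column order of the spontaneous-report table.
REPORT_COLUMNS = [
    "report_id",
    "case_id",
    "version",
    "drug_name",
    "role_code",
    "pt_name",
    "sex",
    "age_years",
    "event_date",
    "start_date",
]

ROLE_CODES = ("PS", "SS", "C", "I")
SEX_CODES = ("F", "M", "U")

#: Canonical column order of a GWAS summary-statistic table. ``chrom`` and
#: ``pos`` are optional on input (distance clumping degrades without them).
GWAS_COLUMNS = [
    "snp",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
]


def write_reports(reports: pd.DataFrame, path) -> None:
    """Write a report table as TSV, keeping only the canonical columns.

    Dates are emitted as ISO-8601 ``YYYY-MM-DD``; missing ages and dates
    become empty fields.
    """
    out = reports.loc[:, REPORT_COLUMNS].copy()
    for col in ("event_date", "start_date"):
        dt = pd.to_datetime(out[col], errors="coerce")
        out[col] = dt.dt.strftime("%Y-%m-%d").fillna("")
    age = pd.to_numeric(out["age_years"], errors="coerce")
    out["age_years"] = age.map(lambda v: "" if pd.isna(v) else f"{v:g}")
    out.to_csv(path, sep="\t", index=False)


def read_reports(path) -> pd.DataFrame:
    """Read a report table; unparseable dates become missing, ages numeric."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report table missing columns: {missing}")
    df["version"] = pd.to_numeric(df["version"], errors="coerce").fillna(0).astype(int)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    for col in ("event_date", "start_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    return df


def write_gwas(stats: pd.DataFrame, path) -> None:
    cols = [c for c in GWAS_COLUMNS if c in stats.columns]
    stats.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="")


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistic table missing columns: {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return df
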