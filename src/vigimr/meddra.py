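"""Flat preferred-term → event-class dictionary and report-level counting.

A licensed terminology cannot ship with the package, so a stub dictionary
covering the psychiatric preferred terms needed by the analyses is bundled;
any user-supplied dictionary in the same two-column format is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .errors import EmptyInputError
from .rounding import percent_of

logger = logging.getLogger(__name__)

PSYCHIATRIC = "psychiatric"
OTHER = "other"
_CLASSES = (PSYCHIATRIC, OTHER)


@dataclass
class PTDictionary:
    """Case-insensitive preferred-term → class map."""

    entries: dict[str, str] = field(default_factory=dict)
    version_tag: str = ""

    def __post_init__(self):
        normalized = {}
        for pt, label in self.entries.items():
            key = pt.strip().casefold()
            if key in normalized and normalized[key] != label:
                raise ValueError(f"preferred term {pt!r} listed with conflicting classes")
            if label not in _CLASSES:
                raise ValueError(f"unknown class {label!r} for {pt!r}")
            normalized[key] = label
        self.entries = normalized


class Fraction(NamedTuple):
    numerator: int
    denominator: int
    percent: float  # 100 * numerator / denominator, rounded half-up to 2 dp


def load_pt_dictionary(path=None) -> PTDictionary:
    """Load a dictionary file (default: the bundled stub).

    Format: an optional ``#version<TAB><tag>`` first line, then tab-separated
    ``pt_name<TAB>class`` rows with class in {psychiatric, other}.
    """
    if path is None:
        ref = resources.files("vigimr").joinpath("data/pt_dictionary.tsv")
        with resources.as_file(ref) as p:
            return load_pt_dictionary(p)
    version_tag = ""
    entries = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if parts[0] == "version" and len(parts) == 2:
                    version_tag = parts[1]
                continue
            pt, label = line.split("\t")
            entries[pt] = label
    return PTDictionary(entries=entries, version_tag=version_tag)


def classify_pt(pt_name: str, dictionary: PTDictionary) -> str:
    """Class of one preferred term; unknown terms default to 'other'."""
    label = dictionary.entries.get(str(pt_name).strip().casefold())
    if label is None:
        logger.warning("preferred term %r not in dictionary; classed as other", pt_name)
        return OTHER
    return label


def classify_series(pt_names: pd.Series, dictionary: PTDictionary) -> pd.Series:
    keys = pt_names.astype(str).str.strip().str.casefold()
    out = keys.map(dictionary.entries)
    n_unknown = int(out.isna().sum())
    if n_unknown:
        logger.warning("%d preferred-term occurrences not in dictionary; classed as other",
                       n_unknown)
    return out.fillna(OTHER)


def psychiatric_report_fraction(reports: pd.DataFrame, dictionary: PTDictionary) -> Fraction:
    """Share of reports with at least one psychiatric preferred term.

    Counting is report-level: a report with several psychiatric terms counts
    once in the numerator; the denominator is the number of distinct reports.
    """
    if reports.empty:
        raise EmptyInputError("proportion undefined on an empty report table")
    is_psy = classify_series(reports["pt_name"], dictionary) == PSYCHIATRIC
    denominator = int(reports["report_id"].nunique())
    numerator = int(reports.loc[is_psy, "report_id"].nunique())
    return Fraction(numerator, denominator, percent_of(numerator, denominator))
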