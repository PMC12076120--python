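"""Report-table ingestion: deduplication, suspect-role filtering, drug naming.

Case deduplication follows the spontaneous-report convention that the latest
version of a case supersedes earlier submissions: one row group is kept per
``case_id`` — the highest ``version``, ties broken by latest ``event_date``
and then by lexicographically largest ``report_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .io import read_reports, write_reports  # noqa: F401  (re-exported interface)

logger = logging.getLogger(__name__)


def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Keep the winning row group per case_id; empty input passes through."""
    if reports.empty:
        return reports.copy()
    ordered = reports.sort_values(
        by=["case_id", "version", "event_date", "report_id"],
        kind="mergesort",
        na_position="first",
    )
    winners = ordered.drop_duplicates(subset="case_id", keep="last")[["case_id", "report_id"]]
    row_keys = pd.MultiIndex.from_frame(reports[["case_id", "report_id"]])
    keep = row_keys.isin(pd.MultiIndex.from_frame(winners))
    return reports.loc[keep].copy()


def filter_primary_suspect(reports: pd.DataFrame) -> pd.DataFrame:
    """Restrict to rows where the drug is the primary suspect (role PS)."""
    return reports.loc[reports["role_code"] == "PS"].copy()


@dataclass
class DrugNameMap:
    """Alias → canonical drug-name mapping, matched case-insensitively."""

    canonical_by_alias: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "DrugNameMap":
        """Build from (alias, canonical) pairs; duplicate aliases across
        canonicals are a configuration error."""
        mapping: dict[str, str] = {}
        for alias, canonical in pairs:
            key = str(alias).strip().casefold()
            if key in mapping and mapping[key] != canonical:
                raise ConfigurationError(
                    f"alias {alias!r} maps to both {mapping[key]!r} and {canonical!r}"
                )
            mapping[key] = canonical
        return cls(mapping)

    @classmethod
    def from_file(cls, path) -> "DrugNameMap":
        """Load a two-column tab-separated (alias, canonical) file."""
        table = pd.read_csv(path, sep="\t", comment="#", header=None, names=["alias", "canonical"])
        return cls.from_pairs(table.itertuples(index=False))

    def lookup(self, name: str) -> str | None:
        return self.canonical_by_alias.get(str(name).strip().casefold())


def normalize_drug(reports: pd.DataFrame, name_map: DrugNameMap) -> pd.DataFrame:
    """Replace drug names by their canonical form; unmatched names pass through
    unchanged and are logged once each."""
    out = reports.copy()
    unmatched = set()

    def _canon(name: str) -> str:
        hit = name_map.lookup(name)
        if hit is None:
            unmatched.add(name)
            return name
        return hit

    out["drug_name"] = out["drug_name"].map(_canon)
    for name in sorted(unmatched):
        logger.warning("drug name %r not in alias map; kept verbatim", name)
    return out
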