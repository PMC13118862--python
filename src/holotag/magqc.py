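"""MAG (metagenome-assembled genome) quality filtering and summaries.

Operates on CheckM-style tabular statistics: completeness %,
contamination %, genome size in Mb. The retention rule is
completeness > 20 (exclusive), contamination < 10 (exclusive), and
genome size within [1, 6] Mb inclusive. A curated 57-MAG quality table
ships with the package as ``holotag.magqc.packaged_table()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = [
    "MAGRecord",
    "filter_mags",
    "summarize_mags",
    "read_mag_table",
    "packaged_table",
]

#: accepted column aliases (CheckM exports capitalized headers)
_ALIASES = {
    "mag_id": {"mag_id", "id", "bin id", "bin_id"},
    "completeness": {"completeness", "completeness (%)"},
    "contamination": {"contamination", "contamination (%)"},
    "genome_size": {"genome_size", "genome size", "genome size (m)",
                    "genome size (mb)"},
}


@dataclass(frozen=True)
class MAGRecord:
    mag_id: str
    completeness: float  # percent, [0, 100]
    contamination: float  # percent, >= 0
    genome_size: float  # megabases, > 0

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise InputError(
                f"{self.mag_id}: completeness {self.completeness} "
                "outside [0, 100]"
            )
        if self.contamination < 0:
            raise InputError(
                f"{self.mag_id}: negative contamination"
            )
        if self.genome_size <= 0:
            raise InputError(f"{self.mag_id}: non-positive genome size")


def filter_mags(
    records: Iterable[MAGRecord],
    comp_min: float = 20.0,
    cont_max: float = 10.0,
    size_range: tuple[float, float] = (1.0, 6.0),
) -> tuple[list[MAGRecord], list[tuple[MAGRecord, list[str]]]]:
    """Split records into retained and (rejected, reasons).

    Completeness and contamination bounds are exclusive ("above 20%",
    "below 10%"); the size window is inclusive.
    """
    lo, hi = size_range
    retained: list[MAGRecord] = []
    rejected: list[tuple[MAGRecord, list[str]]] = []
    for rec in records:
        reasons = []
        if not rec.completeness > comp_min:
            reasons.append("completeness")
        if not rec.contamination < cont_max:
            reasons.append("contamination")
        if not lo <= rec.genome_size <= hi:
            reasons.append("genome_size")
        if reasons:
            rejected.append((rec, reasons))
        else:
            retained.append(rec)
    return retained, rejected


def summarize_mags(records: Iterable[MAGRecord]) -> dict:
    """n, mean and sample (n-1) SD of each quality metric.

    SDs are None for a single record. Report consumers round to 2 dp;
    the returned values are unrounded.
    """
    records = list(records)
    if not records:
        raise InputError("summarize_mags: empty input")
    out: dict = {"n": len(records)}
    for metric in ("completeness", "contamination", "genome_size"):
        values = np.array([getattr(r, metric) for r in records])
        out[f"mean_{metric}"] = float(values.mean())
        out[f"sd_{metric}"] = (
            float(values.std(ddof=1)) if len(values) > 1 else None
        )
    return out


def _canonical_columns(df: pd.DataFrame, path: str) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower()
        for canon, names in _ALIASES.items():
            if key in names:
                mapping[col] = canon
    df = df.rename(columns=mapping)
    missing = set(_ALIASES) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing columns {sorted(missing)} "
            f"(found {list(df.columns)})"
        )
    return df


def read_mag_table(path: str) -> list[MAGRecord]:
    """Read a TSV of MAG quality statistics (CheckM-style headers
    accepted)."""
    df = _canonical_columns(pd.read_csv(path, sep="\t"), str(path))
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MAGRecord(
                    mag_id=str(row.mag_id),
                    completeness=float(row.completeness),
                    contamination=float(row.contamination),
                    genome_size=float(row.genome_size),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row {rownum}: {exc}")
    return records


def packaged_table() -> list[MAGRecord]:
    """The packaged 57-MAG quality table."""
    ref = resources.files("holotag.data") / "mag_quality.tsv"
    with resources.as_file(ref) as path:
        return read_mag_table(str(path))
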