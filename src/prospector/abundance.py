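"""Per-contig abundance as a percentage of non-rRNA reads.

Quantification itself (read mapping, expected counts) is upstream of
this package; counts arrive as a table and are only normalized and
banded here.  The abundance bands follow the convention that ~0.01% of
non-rRNA reads is average abundance for a virus in a culture library and
≥1.2% is very high.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

AVERAGE_MAX_PERCENT = 0.01
VERY_HIGH_MIN_PERCENT = 1.2


@dataclass
class AbundanceRecord:
    contig_id: str
    read_count: int
    total_non_rrna: int
    percent: float


def abundance(read_count: int, total_non_rrna: int) -> float:
    """Read count as a percentage of non-rRNA reads (2 decimals)."""
    if total_non_rrna <= 0:
        raise ValueError("total non-rRNA read count must be positive")
    if read_count < 0 or read_count > total_non_rrna:
        raise ValueError("read count must lie in [0, total]")
    return round(100.0 * read_count / total_non_rrna, 2)


def classify_abundance(percent: float) -> str:
    """Band an abundance percentage: ``average`` (≤0.01), ``high``, or
    ``very_high`` (≥1.2)."""
    if percent <= AVERAGE_MAX_PERCENT:
        return "average"
    if percent >= VERY_HIGH_MIN_PERCENT:
        return "very_high"
    return "high"


def abundance_table(
    counts: dict[str, int], total_non_rrna: int
) -> pd.DataFrame:
    """Abundance records for a whole library, one row per contig."""
    rows = []
    for contig_id, count in counts.items():
        pct = abundance(count, total_non_rrna)
        rows.append(
            {
                "contig_id": contig_id,
                "read_count": count,
                "total_non_rrna": total_non_rrna,
                "percent": pct,
                "abundance_class": classify_abundance(pct),
            }
        )
    return pd.DataFrame(rows)


def read_counts_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["contig_id"], df["read_count"].astype(int)))
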