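"""RPKM-based relative expression of SPF transcripts and clade aggregates.

Expression of each precursor transcript is quantified as RPKM (reads per
kilobase of transcript per million mapped reads):

    RPKM = total_reads / ((length_bp / 1000) * (total_mapped / 1e6))

where ``total_mapped`` is the number of reads mapped to the SPF coding set
— the only denominator consistent with the reference expression table this
package ships. Relative expression divides each transcript's RPKM by the
sum over all SPF transcripts, so the mapped-read denominator cancels.

All arithmetic is done on unrounded values; rounding (half-up, at the
stated number of decimals) happens only at report time. Group aggregates
are reported to 1 decimal at or above 0.1% and 2 decimals below, matching
the precision such cumulative claims are customarily quoted at.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

GROUPS = ("courtship_beta", "alpha", "male_specific", "other")

#: Reads mapped to the SPF coding set in the reference male-cloaca run.
REFERENCE_TOTAL_MAPPED = 1_153_834


@dataclass(frozen=True)
class ExpressionRow:
    id: str
    length_bp: int
    total_reads: int
    unique_reads: int
    rpkm: float = 0.0
    relative_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: non-positive transcript length")
        if self.unique_reads > self.total_reads:
            raise ValueError(f"{self.id}: unique reads exceed total reads")


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as printed report tables expect."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rpkm(total_reads: int, length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads (unrounded)."""
    if length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if total_reads < 0:
        raise ValueError("read count cannot be negative")
    return total_reads / ((length_bp / 1000) * (total_mapped / 1e6))


def compute_rpkm(
    rows: list[ExpressionRow], total_mapped: int
) -> list[ExpressionRow]:
    """Populate the rpkm field of every row."""
    return [
        replace(r, rpkm=rpkm(r.total_reads, r.length_bp, total_mapped))
        for r in rows
    ]


def relative_expression(rows: list[ExpressionRow]) -> list[ExpressionRow]:
    """Populate relative_pct = 100 * rpkm / sum(rpkm), on unrounded RPKMs."""
    total = sum(r.rpkm for r in rows)
    if total <= 0:
        raise ValueError("all RPKM values are zero; cannot normalise")
    return [replace(r, relative_pct=100 * r.rpkm / total) for r in rows]


def clade_aggregate(
    rows: list[ExpressionRow], clades: Mapping[str, str]
) -> dict[str, float]:
    """Cumulative relative expression per clade group, report-rounded.

    Sums are taken on unrounded relative percentages, then rounded to 1
    decimal (>= 0.1%) or 2 decimals (< 0.1%).
    """
    missing = [r.id for r in rows if r.id not in clades]
    if missing:
        raise KeyError(f"no clade group for transcript(s): {missing}")
    sums: dict[str, float] = {}
    for r in rows:
        g = clades[r.id]
        sums[g] = sums.get(g, 0.0) + r.relative_pct
    return {
        g: round_half_up(v, 1 if v >= 0.1 else 2) for g, v in sums.items()
    }


def family_read_fraction(family_reads: int, total_reads: int) -> float:
    """Percentage of all library reads that belong to the SPF family."""
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    if family_reads > total_reads:
        raise ValueError("family reads exceed total reads")
    if family_reads < 0:
        raise ValueError("family reads cannot be negative")
    return round_half_up(100 * family_reads / total_reads, 1)


def read_counts_tsv(path: str | Path) -> list[ExpressionRow]:
    """Read a counts table (id, length_bp, total_reads, unique_reads)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ExpressionRow(
            str(r.id), int(r.length_bp), int(r.total_reads), int(r.unique_reads)
        )
        for r in df.itertuples(index=False)
    ]


def load_reference_table() -> list[ExpressionRow]:
    """The packaged 14-row male-cloaca SPF expression table."""
    with resources.as_file(
        resources.files("spfid.data").joinpath("table2.tsv")
    ) as p:
        return read_counts_tsv(p)


def expression_report(
    rows: list[ExpressionRow], clades: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Report table with RPKM at 1 decimal and relative expression at 2."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "length_bp": [r.length_bp for r in rows],
            "rpkm": [round_half_up(r.rpkm, 1) for r in rows],
            "unique_reads": [r.unique_reads for r in rows],
            "total_reads": [r.total_reads for r in rows],
            "relative_pct": [round_half_up(r.relative_pct, 2) for r in rows],
        }
    )
    if clades is not None:
        df["group"] = [clades[r.id] for r in rows]
    return df
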