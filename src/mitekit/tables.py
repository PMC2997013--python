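"""Published per-family count tables and the report arithmetic over them.

The packaged fixtures mirror the study's two summary tables for the 17
silkworm MITE families: per-family fragmentary/full-length copy counts
(with TSD, TIR, size, AT content and superfamily annotation) and per-family
insertion-site category counts with the randomised control row.  The report
layer recomputes every derived total and percentage from the raw counts and
flags rows whose printed totals disagree with their own category sums
rather than silently correcting them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Table1Row",
    "Table2Row",
    "CountsFixture",
    "load_fixture",
    "round_half_away",
    "full_length_pct",
    "gene_region_pct",
    "table_consistency_report",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero (table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Table1Row:
    family_id: str
    tsd: str
    tir: str
    size_bp: int
    at_pct: int
    n_fragmentary: int   # No.FC
    n_full_length: int   # No.FLC
    known_family: str


@dataclass(frozen=True)
class Table2Row:
    family_id: str
    n_analyzed: int
    flank5: int
    exon: int
    intron: int
    flank3: int
    total_printed: int

    @property
    def category_sum(self) -> int:
        return self.flank5 + self.exon + self.intron + self.flank3


# Per-family copy counts and element characteristics.
TABLE1: tuple[Table1Row, ...] = (
    Table1Row("BmMITE-1", "WW", "TCGATGGCTCCAATGAACACTAC", 234, 68, 216, 44, "Novel"),
    Table1Row("BmMITE-2", "TA/AT", "TGAGTCGACTATTATCAAAG", 278, 67, 419, 2371, "Hoshidandy"),
    Table1Row("BmMITE-3", "TA", "GATATGTGTCGTTCG", 306, 54, 12, 34, "Stowaway-like"),
    Table1Row("BmMITE-4", "TWA", "GGGTCAATTCCCACTGAAAGAGCAGCGGC", 567, 44, 9, 7, "Tourist-like"),
    Table1Row("BmMITE-5", "TWA",
              "AGCCTTGTTCGCACTAAGCGAGTATTTTAGTCGAGTACCGAGTAATTTAGTGGCTAAA",
              213, 61, 53, 81, "Tourist-like"),
    Table1Row("BmMITE-6", "TWA", "GGGCCTGTGCACACCACGTTTTTTAA", 270, 52, 11, 8, "Tourist-like"),
    Table1Row("BmMITE-7", "TDA", "TGCTGGAACCACACTGCG", 548, 55, 7, 13, "Organdy"),
    Table1Row("BmMITE-8", "TA", "TATATCGACGCTTGAAAGGCAAAC", 266, 67, 1364, 147, "Stowaway-like"),
    Table1Row("BmMITE-9", "ATT", "GGTAGTTTTCCAATTACAG", 418, 63, 75, 88, "Novel"),
    Table1Row("BmMITE-10", "ATAT", "CGTCGCTGTCAAACCAAAATCTGCTATGTGCAA", 258, 70, 142, 159, "Novel"),
    Table1Row("BmMITE-11", "ATATAT", "GTGGGATT", 238, 67, 1, 15, "Novel"),
    Table1Row("BmMITE-12", "TTCATTT", "TTACTTTGCA", 210, 73, 20, 121, "Novel"),
    Table1Row("BmMITE-13", "NNNNNNNN", "CAAGGGCGGATCCAG", 263, 59, 69, 171, "Pegasus-like"),
    Table1Row("BmMITE-14", "NNNNNNNN", "CAGTGGCGGATTA", 431, 59, 12, 22, "Pegasus-like"),
    Table1Row("BmMITE-15", "NNNNNNNN", "CAGTGGCGTACCTA", 300, 65, 0, 9, "Pegasus-like"),
    Table1Row("BmMITE-16", "NNNNNNNN", "CAGTGGCGGATTT", 265, 55, 18, 25, "Pegasus-like"),
    Table1Row("BmMITE-17", "TTACTGTAT", "GCGCGCGAGTTCATGT", 494, 59, 20, 22, "Novel"),
)

# Per-family insertion-site category counts; printed totals kept verbatim.
TABLE2: tuple[Table2Row, ...] = (
    Table2Row("BmMITE-1", 260, 38, 3, 53, 61, 155),
    Table2Row("BmMITE-2", 2790, 482, 15, 651, 643, 1791),
    Table2Row("BmMITE-3", 46, 12, 0, 16, 15, 43),
    Table2Row("BmMITE-4", 16, 2, 2, 3, 8, 15),
    Table2Row("BmMITE-5", 134, 22, 8, 26, 25, 81),
    Table2Row("BmMITE-6", 19, 3, 4, 6, 3, 16),
    Table2Row("BmMITE-7", 20, 4, 0, 8, 4, 16),
    Table2Row("BmMITE-8", 1511, 225, 23, 431, 365, 1044),
    Table2Row("BmMITE-9", 163, 40, 0, 26, 58, 124),
    Table2Row("BmMITE-10", 301, 32, 0, 96, 57, 185),
    Table2Row("BmMITE-11", 16, 1, 0, 2, 3, 6),
    Table2Row("BmMITE-12", 141, 18, 0, 16, 21, 55),
    Table2Row("BmMITE-13", 240, 54, 2, 42, 49, 147),
    Table2Row("BmMITE-14", 34, 7, 0, 16, 7, 30),
    Table2Row("BmMITE-15", 9, 5, 1, 1, 2, 11),
    Table2Row("BmMITE-16", 43, 14, 1, 9, 10, 34),
    Table2Row("BmMITE-17", 42, 3, 1, 25, 12, 41),
)

# Printed marginal rows, kept verbatim (the Total row's 3794 exceeds the sum
# of its category columns by 2; the report flags this instead of fixing it).
TABLE2_TOTAL = Table2Row("Total", 5785, 962, 60, 1427, 1343, 3794)
TABLE2_CONTROL = Table2Row("Control", 5000, 712, 152, 453, 653, 1970)


@dataclass(frozen=True)
class CountsFixture:
    table1: tuple[Table1Row, ...]
    table2: tuple[Table2Row, ...]
    table2_total: Table2Row
    table2_control: Table2Row


def load_fixture() -> CountsFixture:
    """Return the packaged per-family count tables."""
    return CountsFixture(TABLE1, TABLE2, TABLE2_TOTAL, TABLE2_CONTROL)


def full_length_pct(n_fragmentary: int, n_full_length: int) -> int:
    """Integer percentage of full-length copies among all copies of a family."""
    total = n_fragmentary + n_full_length
    if total == 0:
        raise ValueError("family with zero copies has no full-length ratio")
    return round_half_away(100.0 * n_full_length / total)


def gene_region_pct(in_region: int, total: int) -> int:
    """Integer percentage of copies that fall in or within 5 kb of a gene."""
    if total == 0:
        raise ValueError("zero copies analysed")
    return round_half_away(100.0 * in_region / total)


def table_consistency_report(fixture: CountsFixture | None = None) -> dict:
    """Recompute totals, ratios and percentages from the raw fixture counts.

    Returns a dict with genome-wide copy totals, per-family full-length
    percentages, the gene-region percentage, and a list of rows whose
    printed totals disagree with the sum of their own category columns.
    """
    fx = fixture or load_fixture()
    n_frag = sum(r.n_fragmentary for r in fx.table1)
    n_full = sum(r.n_full_length for r in fx.table1)
    per_family_pct = {
        r.family_id: full_length_pct(r.n_fragmentary, r.n_full_length)
        for r in fx.table1
    }
    inconsistencies = []
    for row in (*fx.table2, fx.table2_total):
        if row.total_printed != row.category_sum:
            inconsistencies.append({
                "row": row.family_id,
                "printed_total": row.total_printed,
                "category_sum": row.category_sum,
            })
    in_gene = fx.table2_total.total_printed
    total_copies_t2 = fx.table2_total.n_analyzed
    return {
        "total_copies": n_frag + n_full,
        "intact_total": n_full,
        "fragmentary_total": n_frag,
        "full_length_pct": per_family_pct,
        "gene_region_pct": gene_region_pct(in_gene, total_copies_t2),
        "control_gene_region_pct": gene_region_pct(
            fx.table2_control.total_printed, fx.table2_control.n_analyzed),
        "inconsistent_rows": inconsistencies,
    }
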