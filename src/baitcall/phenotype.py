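"""Phenotype-fraction calculator for categorical microscopy counts.

Cells expressing each fluorescent bait construct were categorised by a
blinded observer as having no droplets, intranuclear spheres, or large
spheres.  This module computes the percentage of cells with spheres from
the raw category counts and validates each row's internal consistency
(the categories must partition the YFP-positive cells, and a printed
percentage must match the one recomputed from the counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PhenotypeCountRow",
    "percent_with_spheres",
    "validate_rows",
    "SPHERE_FORMATION_COUNTS",
    "load_phenotype_table",
]


@dataclass
class PhenotypeCountRow:
    """Category counts for one construct: cells without droplets, with
    spheres, and with large spheres, out of all YFP-positive cells."""

    construct: str
    total_yfp_positive: int
    n_without: int
    n_spheres: int
    n_large_spheres: int
    printed_percent: int | None = None  # percentage as published, if any

    def category_sum(self) -> int:
        return self.n_without + self.n_spheres + self.n_large_spheres


def percent_with_spheres(row: PhenotypeCountRow) -> int:
    """Integer percent of cells with spheres (small or large).

    round(100 * (spheres + large) / total) to the nearest integer, ties
    away from zero (display granularity of the source counts).
    """
    if row.total_yfp_positive <= 0:
        raise ValueError("total YFP-positive cell count must be positive")
    frac = 100.0 * (row.n_spheres + row.n_large_spheres) / row.total_yfp_positive
    return int(math.floor(frac + 0.5))


def validate_rows(rows: list[PhenotypeCountRow]) -> pd.DataFrame:
    """Check each row's partition and printed-percent consistency.

    Violations are reported, never silently fixed: the returned frame has
    one row per construct with the computed percent and boolean flags
    ``sum_ok`` (categories partition the total) and ``percent_ok``
    (printed percent equals the recomputed one, NA when none printed).
    """
    out = []
    for row in rows:
        computed = percent_with_spheres(row)
        out.append(
            {
                "construct": row.construct,
                "total": row.total_yfp_positive,
                "computed_percent": computed,
                "printed_percent": row.printed_percent,
                "sum_ok": row.category_sum() == row.total_yfp_positive,
                "percent_ok": (
                    None
                    if row.printed_percent is None
                    else computed == row.printed_percent
                ),
            }
        )
    return pd.DataFrame(out).set_index("construct")


# Published quantification of sphere formation by each construct:
# (total YFP-positive, without droplets, with spheres, with large spheres,
# printed percent).  The ΔRRM2 row's printed 47% is not reproducible from
# its printed counts (90/197 = 45.7%); validate_rows flags it.
SPHERE_FORMATION_COUNTS: list[PhenotypeCountRow] = [
    PhenotypeCountRow("WT", 373, 373, 0, 0, 0),
    PhenotypeCountRow("dRRM1", 318, 318, 0, 0, 0),
    PhenotypeCountRow("dRRM2", 197, 107, 77, 13, 47),
    PhenotypeCountRow("dZnF1", 182, 182, 0, 0, 0),
    PhenotypeCountRow("dZnF2", 80, 80, 0, 0, 0),
    PhenotypeCountRow("S85C", 167, 167, 0, 0, 0),
    PhenotypeCountRow("S85C-dRRM2", 196, 141, 55, 0, 28),
    PhenotypeCountRow("F115C", 138, 138, 0, 0, 0),
    PhenotypeCountRow("F115C-dRRM2", 101, 17, 81, 3, 83),
]


def load_phenotype_table(path) -> list[PhenotypeCountRow]:
    """Read a TSV of phenotype counts (columns: construct, total_yfp_positive,
    n_without, n_spheres, n_large_spheres, optional printed_percent)."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for _, r in df.iterrows():
        printed = r.get("printed_percent")
        rows.append(
            PhenotypeCountRow(
                construct=str(r["construct"]),
                total_yfp_positive=int(r["total_yfp_positive"]),
                n_without=int(r["n_without"]),
                n_spheres=int(r["n_spheres"]),
                n_large_spheres=int(r["n_large_spheres"]),
                printed_percent=None if pd.isna(printed) else int(printed),
            )
        )
    return rows
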