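"""Double-label immunostaining co-expression quantification.

From counts of target-protein-positive cells, marker-positive cells
(TAS1R3-GFP, 5HT, or GAD1-GFP), and double-labelled cells, computes the two
co-expression percentages: double/target (what fraction of cells expressing
the protein of interest carry the cell-type marker) and double/marker (what
fraction of the marked cell type expresses the protein).

Percentages are formatted by truncation toward zero at one decimal place;
a truncated value that lands on a whole number is printed without the
decimal (e.g. "100", "41"). The exact raw value is always reported
alongside the formatted string.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CoexpressionCounts",
    "CoexpressionSummary",
    "format_pct",
    "summarize",
    "summarize_table",
    "load_table2_counts",
]


def load_table2_counts() -> pd.DataFrame:
    """Packaged double-label cell-count fixture (published co-expression
    counts for synaptic and semaphorin-pathway proteins against the
    TAS1R3-GFP, 5HT and GAD1-GFP markers), with the printed percentage
    strings for comparison."""
    with resources.files("tastecells.data").joinpath("table2_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"printed_pct_of_target": str, "printed_pct_of_marker": str})


@dataclass(frozen=True)
class CoexpressionCounts:
    marker_name: str
    target_name: str
    n_target_pos: int
    n_marker_pos: int
    n_double: int

    def __post_init__(self) -> None:
        for name in ("n_target_pos", "n_marker_pos", "n_double"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_double > min(self.n_target_pos, self.n_marker_pos):
            raise ValueError(
                f"{self.marker_name}/{self.target_name}: n_double={self.n_double} exceeds "
                f"min(n_target_pos={self.n_target_pos}, n_marker_pos={self.n_marker_pos})"
            )


@dataclass(frozen=True)
class CoexpressionSummary:
    counts: CoexpressionCounts
    pct_of_target: float | None  # 100 * double / target-positive
    pct_of_marker: float | None  # 100 * double / marker-positive
    fmt_of_target: str
    fmt_of_marker: str


def format_pct(numerator: int, denominator: int) -> str:
    """Percentage truncated to one decimal, via exact integer arithmetic.

    floor(100 * num / den * 10) / 10, rendered without the decimal when the
    truncated value is a whole number ("100", "41") and with one decimal
    otherwise ("94.5").
    """
    if denominator == 0:
        return "NA"
    tenths = (1000 * numerator) // denominator
    if tenths % 10 == 0:
        return str(tenths // 10)
    return f"{tenths // 10}.{tenths % 10}"


def summarize(counts: CoexpressionCounts) -> CoexpressionSummary:
    """Both co-expression percentages for one marker/target pair.

    Zero denominators yield None percentages and "NA" strings rather than an
    error, so a table with an empty category still summarizes.
    """
    pt = 100.0 * counts.n_double / counts.n_target_pos if counts.n_target_pos else None
    pm = 100.0 * counts.n_double / counts.n_marker_pos if counts.n_marker_pos else None
    return CoexpressionSummary(
        counts=counts,
        pct_of_target=pt,
        pct_of_marker=pm,
        fmt_of_target=format_pct(counts.n_double, counts.n_target_pos),
        fmt_of_marker=format_pct(counts.n_double, counts.n_marker_pos),
    )


def summarize_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Summarize a table of double-label counts (one row per marker/target).

    Expects columns marker, target, n_target_pos, n_marker_pos, n_double
    (``marker_name``/``target_name`` also accepted). Row order is preserved;
    an invalid row raises with its index named.
    """
    cols = {c: c for c in rows.columns}
    cols.setdefault("marker", "marker_name" if "marker_name" in rows.columns else "marker")
    cols.setdefault("target", "target_name" if "target_name" in rows.columns else "target")
    out = []
    for idx, row in rows.iterrows():
        try:
            counts = CoexpressionCounts(
                marker_name=str(row[cols["marker"]]),
                target_name=str(row[cols["target"]]),
                n_target_pos=int(row["n_target_pos"]),
                n_marker_pos=int(row["n_marker_pos"]),
                n_double=int(row["n_double"]),
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"row {idx}: {err}") from err
        s = summarize(counts)
        out.append(
            dict(
                marker=counts.marker_name,
                target=counts.target_name,
                n_target_pos=counts.n_target_pos,
                n_marker_pos=counts.n_marker_pos,
                n_double=counts.n_double,
                pct_of_target=s.pct_of_target,
                pct_of_marker=s.pct_of_marker,
                coexpressed_over_target=(
                    f"{counts.n_double}/{counts.n_target_pos} ({s.fmt_of_target}%)"
                ),
                coexpressed_over_marker=(
                    f"{counts.n_double}/{counts.n_marker_pos} ({s.fmt_of_marker}%)"
                ),
                fmt_of_target=s.fmt_of_target,
                fmt_of_marker=s.fmt_of_marker,
            )
        )
    return pd.DataFrame(
        out,
        columns=[
            "marker", "target", "n_target_pos", "n_marker_pos", "n_double",
            "pct_of_target", "pct_of_marker",
            "coexpressed_over_target", "coexpressed_over_marker",
            "fmt_of_target", "fmt_of_marker",
        ],
    )
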