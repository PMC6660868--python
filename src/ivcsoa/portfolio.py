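"""Portfolio-level aggregation: ranking, corporate index, band summaries.

Given the scored profiles of every establishment, this module produces what
the regulator actually plans inspections from: a deterministic ranking
(worst first), the corporate aggregated risk index IRAC — the 90th
percentile of IRA over the portfolio, so 90% of establishments sit at or
below it — the band-by-product-line count table with percentages, and the
effectiveness indicator (sanitary measures per visit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .domain import Band, ComponentScores, round_half_up

__all__ = [
    "BAND_ORDER",
    "PortfolioError",
    "PortfolioSummary",
    "effectiveness",
    "irac",
    "rank_establishments",
    "summarize",
    "write_report",
]

#: Report column order, most to least urgent.
BAND_ORDER = (Band.muy_alto, Band.alto, Band.moderado, Band.bajo)


class PortfolioError(ValueError):
    """Invalid portfolio input (empty, duplicate ids)."""


def irac(iras: Sequence[float]) -> float:
    """Corporate aggregated risk index: 90th percentile of the IRA values.

    Uses linear interpolation between closest ranks so the figure is
    bit-reproducible across runs.
    """
    values = np.asarray(list(iras), dtype=float)
    if values.size == 0:
        raise PortfolioError("IRAC of an empty portfolio is undefined")
    return float(np.percentile(values, 90, method="linear"))


def _rank_key(p: ComponentScores) -> tuple[float, float, str]:
    return (-p.ira, -p.soa, p.establishment_id)


def rank_establishments(profiles: Sequence[ComponentScores]) -> list[str]:
    """Inspection priority order: descending IRA, ties by descending SOA
    component, then lexicographic id.  Total and deterministic."""
    ids = [p.establishment_id for p in profiles]
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise PortfolioError(f"duplicate establishment ids: {dups}")
    return [p.establishment_id for p in sorted(profiles, key=_rank_key)]


@dataclass(frozen=True)
class PortfolioSummary:
    """Band-by-product-line counts with margins, percentages, IRAC, ranking.

    ``counts`` has product lines as rows and bands as columns plus a
    ``total`` margin row/column.  ``band_percentages`` are shares of the
    whole portfolio per band; ``line_percentages`` per product line — both
    full precision (round at display time).
    """

    counts: pd.DataFrame
    band_percentages: dict[Band, float]
    line_percentages: dict[str, float]
    irac: float
    ranking: list[str]

    @property
    def n_establishments(self) -> int:
        return int(self.counts.loc["total", "total"])


def summarize(profiles: Sequence[ComponentScores]) -> PortfolioSummary:
    """Aggregate scored profiles into the portfolio summary table."""
    if not profiles:
        raise PortfolioError("cannot summarize an empty portfolio")
    df = pd.DataFrame(
        {
            "product_line": [p.product_line for p in profiles],
            "band": [p.band.value for p in profiles],
        }
    )
    band_cols = [b.value for b in BAND_ORDER]
    counts = (
        pd.crosstab(df["product_line"], df["band"])
        .reindex(columns=band_cols, fill_value=0)
        .astype(int)
    )
    counts.index.name = "product_line"
    counts.columns.name = None
    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)

    n = len(profiles)
    band_pct = {b: 100.0 * counts.loc["total", b.value] / n for b in BAND_ORDER}
    line_pct = {
        line: 100.0 * counts.loc[line, "total"] / n
        for line in counts.index
        if line != "total"
    }
    return PortfolioSummary(
        counts=counts,
        band_percentages=band_pct,
        line_percentages=line_pct,
        irac=irac([p.ira for p in profiles]),
        ranking=rank_establishments(profiles),
    )


def effectiveness(measures: int, visited: int) -> float:
    """Sanitary-control effectiveness: measures applied per 100 visits."""
    if visited <= 0:
        raise PortfolioError("effectiveness undefined for zero visits")
    if measures < 0:
        raise PortfolioError("negative measure count")
    return 100.0 * measures / visited


def _fmt(x: float, ndigits: int, spanish: bool) -> str:
    s = f"{round_half_up(x, ndigits):.{ndigits}f}"
    return s.replace(".", ",") if spanish else s


def write_report(
    summary: PortfolioSummary,
    out_dir: Union[str, Path],
    *,
    spanish_decimals: bool = False,
    top_n: int | None = None,
) -> None:
    """Emit the summary as delimited text plus a human-readable table.

    Writes ``summary_counts.csv`` (counts with margins), ``ranking.csv``
    (priority order) and ``report.txt`` mirroring the band-by-line layout
    with per-band percentage shares and the IRAC.  ``spanish_decimals``
    renders comma decimals in the text report only; CSV files always use
    dot decimals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.counts.to_csv(out / "summary_counts.csv", encoding="utf-8")
    ranking = summary.ranking if top_n is None else summary.ranking[:top_n]
    pd.DataFrame({"rank": range(1, len(ranking) + 1), "establishment_id": ranking}).to_csv(
        out / "ranking.csv", index=False, encoding="utf-8"
    )

    lines = ["Establishments by sanitary risk band", ""]
    header = ["product_line"] + [b.value for b in BAND_ORDER] + ["total"]
    widths = [max(24, len(header[0]))] + [max(10, len(h)) for h in header[1:]]
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
    for line_name in summary.counts.index:
        row = [str(line_name)] + [
            str(int(summary.counts.loc[line_name, c])) for c in header[1:]
        ]
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
    shares = ["share_by_band_pct"] + [
        _fmt(summary.band_percentages[b], 2, spanish_decimals) for b in BAND_ORDER
    ] + ["100"]
    lines.append("  ".join(c.ljust(w) for c, w in zip(shares, widths)))
    lines.append("")
    lines.append(f"IRAC (90th percentile of IRA): {_fmt(summary.irac, 2, spanish_decimals)}")
    lines.append(f"Establishments scored: {summary.n_establishments}")
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
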