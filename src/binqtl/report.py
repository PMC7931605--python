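"""Map-level summary reporting.

Produces the publication-style per-chromosome table (bin counts and
genetic lengths with a Total row) and the derived population averages:
mean recombination events per individual (total events / population
size) and mean bin size (covered genome / bin count).  The same code
path serves freshly computed maps and the shipped reference tables for
the two melon F2 populations.
"""

from __future__ import annotations

import pandas as pd

from .linkmap import map_summary, retabulate
from . import data

__all__ = ["population_averages", "report_summary", "published_summary"]


def population_averages(
    total_events: float,
    n_individuals: int,
    covered_mb: float | None = None,
    n_bins: int | None = None,
) -> dict:
    """Derived per-population averages.

    ``mean_events_per_individual = total_events / n_individuals``;
    ``mean_bin_kb = covered_mb * 1000 / n_bins`` when both are given.
    """
    out = {"mean_events_per_individual": total_events / n_individuals}
    if covered_mb is not None and n_bins is not None and n_bins > 0:
        out["mean_bin_kb"] = covered_mb * 1000.0 / n_bins
    return out


def report_summary(
    map_df: pd.DataFrame | None = None,
    per_chrom: pd.DataFrame | None = None,
    total_events: float | None = None,
    n_individuals: int | None = None,
    covered_mb: float | None = None,
) -> dict:
    """Tabulate a linkage map (or supplied per-chromosome rows).

    Returns ``{"table": per-chromosome DataFrame with Total row,
    "averages": dict}``.  Exactly one of ``map_df`` (a built linkage
    map) or ``per_chrom`` (pre-computed ``chrom, n_bins, length_cm``
    rows) must be given.
    """
    if (map_df is None) == (per_chrom is None):
        raise ValueError("supply exactly one of map_df or per_chrom")
    table = map_summary(map_df) if map_df is not None else retabulate(per_chrom)
    total_bins = int(table.loc[table["chrom"] == "Total", "n_bins"].iat[0])
    averages: dict = {}
    if total_events is not None and n_individuals:
        averages = population_averages(
            total_events, n_individuals, covered_mb, total_bins
        )
    return {"table": table, "averages": averages}


def published_summary(population: str) -> dict:
    """Re-tabulated summary of one of the shipped reference maps.

    ``population`` is ``"WAP"`` or ``"MAP"``.  Totals and averages are
    recomputed from the per-chromosome rows and population statistics,
    not read off pre-summed columns.
    """
    chrom_stats = data.load_chromosome_stats()
    pop_stats = data.load_population_stats()
    rows = chrom_stats[chrom_stats["population"] == population][
        ["chrom", "n_bins", "length_cm"]
    ]
    if rows.empty:
        raise ValueError(f"unknown population {population!r}")
    stats = pop_stats[pop_stats["population"] == population].iloc[0]
    result = report_summary(
        per_chrom=rows,
        total_events=float(stats["total_recombination_events"]),
        n_individuals=int(stats["n_individuals"]),
        covered_mb=float(stats["covered_mb"]),
    )
    table = result["table"]
    total = table[table["chrom"] == "Total"].iloc[0]
    result["total_bins"] = int(total["n_bins"])
    result["total_cm"] = float(total["length_cm"])
    return result
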