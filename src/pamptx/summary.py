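"""Count and percentage summaries of classification and clustering output.

Two percentage styles are used throughout: prose-style integers
(half-up rounding, e.g. "12% (262/2114)") and table-style two-decimal
percentages (e.g. "44.58%(1136/2548)"). Zero denominators yield ``None`` /
an ``NA`` marker, never a division error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from pamptx.classify import (
    CAT_BOTH,
    CAT_MPK6_INDEP,
    CAT_PARTIAL,
    DIR_INDUCED,
    DIR_REPRESSED,
)

NA_MARKER = "NA"


def percent_int(numerator: int, denominator: int) -> int | None:
    """Prose-style integer percentage with half-up rounding; None when undefined."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def percent_2dp(numerator: int, denominator: int) -> float | None:
    """Table-style percentage at two decimals; None when undefined."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 2)


def format_fraction(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Render ``44.58%(1136/2548)``-style cells; NA on zero denominators."""
    if denominator == 0:
        return NA_MARKER
    if decimals == 0:
        return f"{percent_int(numerator, denominator)}%({numerator}/{denominator})"
    pct = 100.0 * numerator / denominator
    return f"{pct:.{decimals}f}%({numerator}/{denominator})"


@dataclass(frozen=True)
class DirectionCounts:
    """Counts for one direction at one timepoint."""

    total: int
    dependent: int

    def dependent_percent(self) -> int | None:
        return percent_int(self.dependent, self.total)


@dataclass(frozen=True)
class SubdivisionCounts:
    """Split of the dependent set at one timepoint."""

    mpk6_dependent: int
    mpk6_independent: int

    @property
    def total(self) -> int:
        return self.mpk6_dependent + self.mpk6_independent

    def dependent_share_percent(self) -> int | None:
        return percent_int(self.mpk6_dependent, self.total)

    def independent_share_percent(self) -> int | None:
        return percent_int(self.mpk6_independent, self.total)


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-timepoint summary of the classifier output.

    One row per timepoint with counts and both percentage styles for:
    responsive/induced/repressed totals, dependent counts per direction, the
    subdivision split of the dependent set (partial residual kept separate,
    per-subcategory shares computed over the two discrete subcategories), and
    the hyper-shifted share of the fully kinase-dependent induced set.
    """
    rows = []
    for t, sub in calls.groupby("timepoint_min"):
        resp = sub[sub["responsive"]]
        induced = resp[resp["direction"] == DIR_INDUCED]
        repressed = resp[resp["direction"] == DIR_REPRESSED]
        dc_ind = DirectionCounts(len(induced), int(induced["mkp1_dependent"].sum()))
        dc_rep = DirectionCounts(len(repressed), int(repressed["mkp1_dependent"].sum()))
        sd = SubdivisionCounts(
            int((resp["category"] == CAT_BOTH).sum()),
            int((resp["category"] == CAT_MPK6_INDEP).sum()),
        )
        both = resp[resp["category"] == CAT_BOTH]
        hyper = int(((both["direction"] == DIR_INDUCED) & (both["mkp1_shift"] > 0)).sum())
        rows.append(
            {
                "timepoint_min": t,
                "n_responsive": len(resp),
                "n_induced": dc_ind.total,
                "n_induced_dependent": dc_ind.dependent,
                "pct_induced_dependent": dc_ind.dependent_percent(),
                "n_repressed": dc_rep.total,
                "n_repressed_dependent": dc_rep.dependent,
                "pct_repressed_dependent": dc_rep.dependent_percent(),
                "n_mpk6_dependent": sd.mpk6_dependent,
                "n_mpk6_independent": sd.mpk6_independent,
                "n_partial": int((resp["category"] == CAT_PARTIAL).sum()),
                "pct_mpk6_dependent": sd.dependent_share_percent(),
                "pct_mpk6_independent": sd.independent_share_percent(),
                "n_hyper_induced_mpk6dep": hyper,
                "pct_hyper_induced_mpk6dep": percent_int(hyper, len(both)),
                "n_baseline_genotype_diff": int(sub["baseline_genotype_diff"].sum()),
            }
        )
    return pd.DataFrame(rows)


def assigned_percent(n_assigned: int, n_total: int) -> int | None:
    """Prose-style share of genes confidently assigned to a single profile."""
    return percent_int(n_assigned, n_total)


def crosstab_cluster_by_category(
    calls: pd.DataFrame,
    assignments: pd.DataFrame,
    timepoint: int,
    categories: tuple[str, ...] = (
        "MKP1_independent",
        CAT_BOTH,
        CAT_MPK6_INDEP,
    ),
) -> pd.DataFrame:
    """Cluster x genetic-category percentage matrix for one timepoint.

    Cells show the share of each category's responsive genes falling in each
    archetype cluster, formatted ``44.58%(1136/2548)``; the Total row shows
    each category's assigned fraction at integer precision. Genes present in
    ``assignments`` but missing from ``calls`` are a fatal consistency error.
    """
    sub = calls[(calls["timepoint_min"] == timepoint) & calls["responsive"]]
    known = set(sub["gene_id"]) | set(calls["gene_id"])
    stray = set(assignments["gene_id"]) - known
    if stray:
        raise ValueError(f"{len(stray)} gene(s) in cluster assignments missing from calls")
    assigned = assignments.dropna(subset=["archetype"])
    merged = sub.merge(assigned[["gene_id", "archetype"]], on="gene_id", how="left")

    clusters = list(range(1, 9))
    data = {}
    totals = {}
    for cat in categories:
        cat_genes = merged[merged["category"] == cat]
        denom = len(cat_genes)
        col = []
        for cl in clusters:
            k = int((cat_genes["archetype"] == cl).sum())
            col.append(format_fraction(k, denom, decimals=2))
        data[cat] = col
        n_assigned = int(cat_genes["archetype"].notna().sum())
        totals[cat] = format_fraction(n_assigned, denom, decimals=0)
    table = pd.DataFrame(data, index=[str(c) for c in clusters])
    table.loc["Total"] = [totals[cat] for cat in categories]
    table.index.name = "cluster"
    return table
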