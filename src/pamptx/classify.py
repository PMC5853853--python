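"""Per-timepoint classification of transcripts into pathway-dependency categories.

Decision rules (all thresholds inclusive):

* responsive at t: |log2FC| >= lfc_min and q <= q_resp in the wild-type
  response contrast (wt_t vs wt_0) OR the single-mutant response contrast,
  union over the two genotypes. Direction follows the qualifying contrast,
  wild type taking precedence.
* dependent at t: responsive, and the wt-vs-single-mutant contrast at t shows
  at least ``dep_fold_min`` linear fold in either direction with q <= q_dep.
  The independent set is the responsive set minus the dependent set.
* subdivision of dependent transcripts (q-only gates): significant
  single-vs-double mutant difference with non-significant wt-vs-double
  difference means the double mutation reverts the change (fully
  kinase-dependent); the reverse pattern means it does not (kinase-
  independent); every other dependent transcript is the partial residual.

The 30- and 90-min labels of a gene are independent; no cross-timepoint
consistency is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pamptx.tables import GENE_CALL_COLUMNS, condition_label

CAT_INDEPENDENT = "MKP1_independent"
CAT_BOTH = "MKP1_MPK6_dependent"
CAT_MPK6_INDEP = "MKP1_dep_MPK6_indep"
CAT_PARTIAL = "MKP1_dep_partial_MPK6"
CAT_NOT_RESPONSIVE = "not_responsive"

CATEGORIES = (CAT_INDEPENDENT, CAT_BOTH, CAT_MPK6_INDEP, CAT_PARTIAL, CAT_NOT_RESPONSIVE)
RESPONSIVE_CATEGORIES = (CAT_INDEPENDENT, CAT_BOTH, CAT_MPK6_INDEP, CAT_PARTIAL)

DIR_INDUCED = "induced"
DIR_REPRESSED = "repressed"
DIR_NONE = "none"


@dataclass(frozen=True)
class Thresholds:
    """Significance gates for the classification rules."""

    lfc_min: float = 1.0  # log2 units, responsiveness gate
    q_resp: float = 0.01
    dep_fold_min: float = 1.5  # linear fold, dependence gate
    q_dep: float = 0.01

    def __post_init__(self) -> None:
        if not (self.lfc_min > 0 and self.dep_fold_min > 0):
            raise ValueError("fold thresholds must be positive")
        if not (0 < self.q_resp < 1 and 0 < self.q_dep < 1):
            raise ValueError("q thresholds must lie in (0, 1)")


@dataclass
class ClassifyStats:
    """Gap/conflict counters accumulated while classifying."""

    missing_contrasts: dict = field(default_factory=dict)
    direction_conflicts: int = 0


def _contrast_lookup(diffs: pd.DataFrame):
    """Pivot a differential frame to per-contrast (lfc, q, ok) gene series."""
    key = diffs["sample_1"].astype(str) + "\t" + diffs["sample_2"].astype(str)
    ok = (diffs["status"] == "OK").to_numpy()
    frame = pd.DataFrame(
        {
            "gene_id": diffs["gene_id"].astype(str),
            "key": key,
            "log2_fc": diffs["log2_fc"].to_numpy(dtype=float),
            "q_value": np.where(ok, diffs["q_value"].to_numpy(dtype=float), np.nan),
        }
    )
    lfc = frame.pivot_table(index="gene_id", columns="key", values="log2_fc", aggfunc="first")
    q = frame.pivot_table(index="gene_id", columns="key", values="q_value", aggfunc="first")
    return lfc, q


def _col(table: pd.DataFrame, a: str, b: str, genes: pd.Index) -> np.ndarray:
    key = f"{a}\t{b}"
    if key in table.columns:
        return table[key].reindex(genes).to_numpy(dtype=float)
    return np.full(genes.size, np.nan)


def classify_calls(
    diffs: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    genotypes: Sequence[str] = ("Ws", "mkp1", "mkp1_mpk6"),
    timepoints: Sequence[int] = (30, 90),
    baseline_timepoint: int = 0,
) -> tuple[pd.DataFrame, ClassifyStats]:
    """Classify every gene at every elicited timepoint.

    Returns a calls frame (one row per gene x timepoint, columns
    :data:`pamptx.tables.GENE_CALL_COLUMNS`) plus gap statistics. Genes whose
    responsiveness contrasts are missing (or not status OK) are called
    not_responsive, with the gap counted rather than raised.
    """
    wt, single, double = genotypes
    lfc_t, q_t = _contrast_lookup(diffs)
    genes = lfc_t.index
    stats = ClassifyStats()

    base_lfc = _col(lfc_t, condition_label(wt, baseline_timepoint), condition_label(single, baseline_timepoint), genes)
    base_q = _col(q_t, condition_label(wt, baseline_timepoint), condition_label(single, baseline_timepoint), genes)
    log_dep_fold = np.log2(thresholds.dep_fold_min)
    with np.errstate(invalid="ignore"):
        baseline_diff = (np.abs(base_lfc) >= log_dep_fold) & (base_q <= thresholds.q_dep)
    baseline_diff = np.where(np.isnan(base_q), False, baseline_diff)

    out_frames = []
    for t in timepoints:
        wt_lfc = _col(lfc_t, condition_label(wt, baseline_timepoint), condition_label(wt, t), genes)
        wt_q = _col(q_t, condition_label(wt, baseline_timepoint), condition_label(wt, t), genes)
        mut_lfc = _col(lfc_t, condition_label(single, baseline_timepoint), condition_label(single, t), genes)
        mut_q = _col(q_t, condition_label(single, baseline_timepoint), condition_label(single, t), genes)
        dep_lfc = _col(lfc_t, condition_label(wt, t), condition_label(single, t), genes)
        dep_q = _col(q_t, condition_label(wt, t), condition_label(single, t), genes)
        sub_sd_q = _col(q_t, condition_label(single, t), condition_label(double, t), genes)
        sub_wd_q = _col(q_t, condition_label(wt, t), condition_label(double, t), genes)

        n_missing_resp = int(np.sum(np.isnan(wt_q) & np.isnan(mut_q)))
        if n_missing_resp:
            stats.missing_contrasts[f"responsiveness_t{t}"] = n_missing_resp

        with np.errstate(invalid="ignore"):
            wt_hit = (np.abs(wt_lfc) >= thresholds.lfc_min) & (wt_q <= thresholds.q_resp)
            mut_hit = (np.abs(mut_lfc) >= thresholds.lfc_min) & (mut_q <= thresholds.q_resp)
        wt_hit = np.where(np.isnan(wt_q), False, wt_hit).astype(bool)
        mut_hit = np.where(np.isnan(mut_q), False, mut_hit).astype(bool)
        responsive = wt_hit | mut_hit

        sign = np.where(wt_hit, np.sign(wt_lfc), np.where(mut_hit, np.sign(mut_lfc), 0.0))
        stats.direction_conflicts += int(np.sum(wt_hit & mut_hit & (np.sign(wt_lfc) != np.sign(mut_lfc))))
        direction = np.where(sign > 0, DIR_INDUCED, np.where(sign < 0, DIR_REPRESSED, DIR_NONE))
        direction = np.where(responsive, direction, DIR_NONE)

        n_missing_dep = int(np.sum(responsive & np.isnan(dep_q)))
        if n_missing_dep:
            stats.missing_contrasts[f"dependence_t{t}"] = n_missing_dep
        with np.errstate(invalid="ignore"):
            dependent = responsive & (np.abs(dep_lfc) >= log_dep_fold) & (dep_q <= thresholds.q_dep)
        dependent = np.where(np.isnan(dep_q), False, dependent).astype(bool)

        n_missing_sub = int(np.sum(dependent & (np.isnan(sub_sd_q) | np.isnan(sub_wd_q))))
        if n_missing_sub:
            stats.missing_contrasts[f"subdivision_t{t}"] = n_missing_sub
        with np.errstate(invalid="ignore"):
            sd_sig = sub_sd_q <= thresholds.q_dep  # single vs double differ
            wd_sig = sub_wd_q <= thresholds.q_dep  # wt vs double differ
        sd_sig = np.where(np.isnan(sub_sd_q), False, sd_sig).astype(bool)
        wd_sig = np.where(np.isnan(sub_wd_q), False, wd_sig).astype(bool)

        category = np.full(genes.size, CAT_NOT_RESPONSIVE, dtype=object)
        category[responsive] = CAT_INDEPENDENT
        category[dependent & sd_sig & ~wd_sig] = CAT_BOTH
        category[dependent & ~sd_sig & wd_sig] = CAT_MPK6_INDEP
        category[dependent & ~((sd_sig & ~wd_sig) | (~sd_sig & wd_sig))] = CAT_PARTIAL

        mkp1_shift = np.where(dependent, np.sign(dep_lfc), 0.0)

        out_frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes.astype(str),
                    "timepoint_min": t,
                    "responsive": responsive,
                    "direction": direction,
                    "category": category,
                    "mkp1_dependent": dependent,
                    "mkp1_shift": mkp1_shift.astype(int),
                    "baseline_genotype_diff": baseline_diff.astype(bool),
                },
                columns=GENE_CALL_COLUMNS,
            )
        )
    calls = pd.concat(out_frames, ignore_index=True)
    return calls, stats
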