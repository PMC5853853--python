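"""Stand-in pairwise differential-expression test.

This deliberately replaces the negative-binomial machinery of alignment-based
DE tools with a transparent test on the expression tables the pipeline
exchanges: Welch's two-sample t on log2(fpkm + pseudocount), fold changes on
pseudocounted means, and Benjamini-Hochberg q-values computed within each
contrast. It honours the same table contract (log2_fc, p, q, status) that the
downstream classifier consumes, but makes no attempt to reproduce any
particular tool's numerics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pamptx.tables import DIFF_COLUMNS, condition_label, split_condition_label

#: smallest p reported for a zero-variance contrast with unequal means
P_FLOOR = 1e-300


@dataclass(frozen=True)
class Contrast:
    """A pairwise condition contrast; conditions are ``<genotype>_<minutes>`` labels."""

    condition_a: str
    condition_b: str

    def __post_init__(self) -> None:
        if self.condition_a == self.condition_b:
            raise ValueError(f"contrast requires two distinct conditions, got {self.condition_a!r} twice")
        # validate label grammar eagerly
        split_condition_label(self.condition_a)
        split_condition_label(self.condition_b)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at 1.
    Order-preserving; NaN input is fatal.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _condition_arrays(matrix: pd.DataFrame, label: str) -> np.ndarray | None:
    """gene x replicate array for one condition; None if condition absent.

    Row order follows the sorted unique gene ids of the matrix.
    """
    genotype, t = split_condition_label(label)
    sub = matrix[(matrix["genotype"] == genotype) & (matrix["timepoint_min"] == t)]
    if sub.empty:
        return None
    wide = sub.pivot_table(index="gene_id", columns="replicate", values="fpkm")
    return wide


def test_contrast(
    matrix: pd.DataFrame,
    contrast: Contrast,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential test of one contrast over all genes in the matrix.

    Returns a differential frame (see :data:`pamptx.tables.DIFF_COLUMNS`) with
    ``log2_fc = log2((mean_b + pc) / (mean_a + pc))`` and Welch-t p-values on
    log2(fpkm + pc). Degenerate zero-variance rows use the convention
    p = 1 for equal means, p = :data:`P_FLOOR` otherwise. Conditions with
    fewer than 2 replicates produce status ``NOTEST`` (p = q = 1), and rows
    where both raw means fall below the pseudocount are flagged ``LOWDATA``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    wide_a = _condition_arrays(matrix, contrast.condition_a)
    wide_b = _condition_arrays(matrix, contrast.condition_b)
    if wide_a is None or wide_b is None:
        missing = contrast.condition_a if wide_a is None else contrast.condition_b
        raise ValueError(f"condition {missing!r} not present in expression matrix")
    genes = wide_a.index.union(wide_b.index)
    a = wide_a.reindex(genes).to_numpy(dtype=float)
    b = wide_b.reindex(genes).to_numpy(dtype=float)

    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    notest = (n_a < 2) | (n_b < 2)

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(lb, la, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)

    var_a = np.nanvar(la, axis=1)
    var_b = np.nanvar(lb, axis=1)
    degenerate = (var_a + var_b) == 0
    equal_means = np.isclose(np.nanmean(la, axis=1), np.nanmean(lb, axis=1), rtol=0, atol=1e-12)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, P_FLOOR, p)
    p = np.where(notest, 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)

    status = np.full(genes.size, "OK", dtype=object)
    status[(mean_a < pseudocount) & (mean_b < pseudocount)] = "LOWDATA"
    status[notest] = "NOTEST"

    q = np.ones(genes.size, dtype=float)
    tested = status != "NOTEST"
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    return pd.DataFrame(
        {
            "gene_id": genes.astype(str),
            "sample_1": contrast.condition_a,
            "sample_2": contrast.condition_b,
            "value_1": mean_a,
            "value_2": mean_b,
            "log2_fc": lfc,
            "p_value": p,
            "q_value": q,
            "status": status,
        },
        columns=DIFF_COLUMNS,
    )


def default_contrasts(
    genotypes: Sequence[str] = ("Ws", "mkp1", "mkp1_mpk6"),
    timepoints: Sequence[int] = (0, 30, 90),
) -> list[Contrast]:
    """The contrast set the classifier consumes.

    Per elicited timepoint t: within-genotype responses (wt and single mutant
    vs their own time 0), wt vs single mutant, single vs double mutant, and wt
    vs double mutant; plus the untreated wt-vs-single-mutant baseline check.
    """
    wt, single, double = genotypes
    t0, *elicited = timepoints
    contrasts: list[Contrast] = []
    for t in elicited:
        contrasts.append(Contrast(condition_label(wt, t0), condition_label(wt, t)))
        contrasts.append(Contrast(condition_label(single, t0), condition_label(single, t)))
        contrasts.append(Contrast(condition_label(wt, t), condition_label(single, t)))
        contrasts.append(Contrast(condition_label(single, t), condition_label(double, t)))
        contrasts.append(Contrast(condition_label(wt, t), condition_label(double, t)))
    contrasts.append(Contrast(condition_label(wt, t0), condition_label(single, t0)))
    return contrasts


def run_contrasts(
    matrix: pd.DataFrame,
    contrasts: Iterable[Contrast],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Run several contrasts and concatenate; q-values stay per-contrast."""
    frames = [test_contrast(matrix, c, pseudocount=pseudocount) for c in contrasts]
    if not frames:
        raise ValueError("no contrasts given")
    return pd.concat(frames, ignore_index=True)
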