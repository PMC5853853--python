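"""qPCR quantification from raw amplification curves.

Implements a window-of-linearity reconstruction of per-reaction efficiency
estimation: baseline subtraction, a sliding fixed-width log-linear window
restricted to a band of the plateau, efficiency from the best-fitting slope,
fractional-cycle threshold crossing for Ct, and the ``E^-dCt`` relative
expression formula with reference-gene and reference-condition
normalization plus equal-variance two-sample t-tests between genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EfficiencyEstimate:
    efficiency: float
    ct: float
    r_squared: float
    window_start: int  # first cycle of the fitted window (1-based)
    baseline: float
    reliable: bool


@dataclass(frozen=True)
class WindowParams:
    """Window-of-linearity settings.

    A fitted window must stay at or below ``band_high`` of the plateau, touch
    the ``band_low``..``band_high`` band with at least one point, and keep all
    points above a small noise-floor guard. Requiring full containment in the
    band would be infeasible: at efficiency ~2 a five-cycle window spans a
    ~16x signal range, more than the band is wide.
    """

    width: int = 5  # cycles per fitted window
    band_low: float = 0.05  # fraction of plateau the window must reach
    band_high: float = 0.60  # fraction of plateau the window must stay below
    floor_frac: float = 0.001  # noise-floor guard, fraction of plateau
    ct_threshold: float = 0.10  # fraction of plateau
    min_r_squared: float = 0.99
    baseline_cycles: tuple[int, int] = (3, 10)  # inclusive, 1-based


def _fit_windows(log_f: np.ndarray, usable: np.ndarray, anchor: np.ndarray, width: int):
    """Best (r2, slope, intercept, start index) over contiguous usable windows."""
    best = None
    n = log_f.size
    x = np.arange(n, dtype=float)
    for start in range(0, n - width + 1):
        sl = slice(start, start + width)
        if not usable[sl].all() or not anchor[sl].any():
            continue
        xs, ys = x[sl], log_f[sl]
        xm, ym = xs.mean(), ys.mean()
        sxx = float(((xs - xm) ** 2).sum())
        sxy = float(((xs - xm) * (ys - ym)).sum())
        syy = float(((ys - ym) ** 2).sum())
        if sxx == 0 or syy == 0:
            continue
        slope = sxy / sxx
        r2 = (sxy * sxy) / (sxx * syy)
        if best is None or r2 > best[0]:
            best = (r2, slope, ym - slope * xm, start)
    return best


def _evaluate_baseline(f: np.ndarray, baseline: float, params: WindowParams):
    g = f - baseline
    positive = g > 0
    if not positive.any():
        return None
    plateau = float(g[positive].max())
    usable = positive & (g >= params.floor_frac * plateau) & (g <= params.band_high * plateau)
    anchor = positive & (g >= params.band_low * plateau)
    if usable.sum() < params.width:
        return None
    log_g = np.where(positive, np.log10(np.where(positive, g, 1.0)), np.nan)
    fit = _fit_windows(log_g, usable, anchor, params.width)
    if fit is None:
        return None
    return fit + (plateau,)


def estimate_efficiency(
    fluorescence,
    params: WindowParams = WindowParams(),
) -> EfficiencyEstimate:
    """Estimate (efficiency, Ct) from one amplification curve.

    ``fluorescence`` is the per-cycle signal for cycles 1..N (N >= 25).
    The baseline is chosen to maximize the best window's R^2 among a
    deterministic candidate grid seeded by the early-cycle mean (a pure
    exponential thus gets a zero baseline and an exact slope). The efficiency
    is 10**slope clamped to (1, 2]; Ct is the log-interpolated crossing of
    the threshold fraction of the plateau. Reactions whose best window fails
    the R^2 gate are flagged unreliable.
    """
    f = np.asarray(fluorescence, dtype=float)
    if f.size < 25:
        raise ValueError("need at least 25 cycles")
    lo, hi = params.baseline_cycles
    b_init = float(f[lo - 1 : hi].mean())
    candidates = [0.0]
    if b_init > 0:
        candidates.append(b_init)
        candidates.extend(np.linspace(0.0, 1.5 * b_init, 25)[1:])
    best = None
    for b in candidates:
        fit = _evaluate_baseline(f, b, params)
        if fit is None:
            continue
        r2, slope, intercept, start, plateau = fit
        if best is None or r2 > best[0]:
            best = (r2, slope, intercept, start, plateau, b)
    if best is None:
        return EfficiencyEstimate(float("nan"), float("nan"), 0.0, -1, b_init, False)
    r2, slope, intercept, start, plateau, baseline = best
    eff = 10.0 ** slope
    eff = min(eff, 2.0)
    reliable = r2 >= params.min_r_squared and eff > 1.0

    ct = _threshold_crossing(f - baseline, params.ct_threshold * plateau)
    return EfficiencyEstimate(eff, ct, r2, start + 1, baseline, reliable)


def _threshold_crossing(g: np.ndarray, threshold: float) -> float:
    """First log-interpolated cycle (1-based, fractional) where g crosses threshold."""
    above = np.flatnonzero(g >= threshold)
    if above.size == 0:
        return float("nan")
    i = int(above[0])
    if i == 0 or g[i - 1] <= 0:
        return float(i + 1)
    lo, hi = np.log10(g[i - 1]), np.log10(g[i])
    if hi == lo:
        return float(i + 1)
    frac = (np.log10(threshold) - lo) / (hi - lo)
    return float(i) + float(frac)  # cycle numbers are 1-based


def estimate_reactions(curves: pd.DataFrame, params: WindowParams = WindowParams()) -> pd.DataFrame:
    """Run :func:`estimate_efficiency` per reaction of a long-format curve table."""
    rows = []
    for rid, sub in curves.groupby("reaction_id", sort=True):
        sub = sub.sort_values("cycle")
        est = estimate_efficiency(sub["fluorescence"].to_numpy(), params)
        rows.append((rid, est.efficiency, est.ct, est.r_squared, est.reliable))
    return pd.DataFrame(rows, columns=["reaction_id", "efficiency", "ct", "r_squared", "reliable"])


def expression_level(ct_target: float, ct_reference: float, efficiency: float) -> float:
    """Relative expression ``E ** -(Ct_target - Ct_reference)``.

    With E = 2 this is exactly the classical 2^-dCt.
    """
    if not np.isfinite(ct_target) or not np.isfinite(ct_reference):
        raise ValueError("Ct values must be finite")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    return float(efficiency ** -(ct_target - ct_reference))


def quantify_samples(
    estimates: pd.DataFrame,
    sample_map: pd.DataFrame,
    reference_gene: str,
    per_amplicon_efficiency: bool = True,
) -> pd.DataFrame:
    """Per-sample relative levels of each target gene vs the reference gene.

    ``sample_map`` maps reaction_id -> (target, genotype, timepoint_min,
    replicate). Unreliable reactions, and samples lacking a reliable
    reference reaction, are excluded. Efficiencies are averaged per amplicon
    (target) before entering the formula.
    """
    merged = sample_map.merge(estimates, on="reaction_id", how="inner")
    merged = merged[merged["reliable"]]
    eff = (
        merged.groupby("target")["efficiency"].mean().to_dict()
        if per_amplicon_efficiency
        else None
    )
    key = ["genotype", "timepoint_min", "replicate"]
    refs = merged[merged["target"] == reference_gene].set_index(key)["ct"]
    rows = []
    for row in merged[merged["target"] != reference_gene].itertuples(index=False):
        sample = (row.genotype, row.timepoint_min, row.replicate)
        if sample not in refs.index:
            continue
        e = eff[row.target] if eff is not None else row.efficiency
        level = expression_level(row.ct, float(refs.loc[sample]), e)
        rows.append((row.target, row.genotype, row.timepoint_min, row.replicate, level))
    return pd.DataFrame(rows, columns=["target", "genotype", "timepoint_min", "replicate", "level"])


def normalize_and_test(
    levels: pd.DataFrame,
    reference_condition: tuple[str, int] = ("Ws", 0),
    contrast_genotypes: tuple[str, str] = ("Ws", "mkp1"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-changes vs the reference condition and genotype-contrast t-tests.

    Folds divide each level by the mean level of the reference condition of
    the same target (so the reference-condition mean fold is exactly 1).
    For each target x timepoint, an equal-variance two-sample unpaired t-test
    compares folds between the two contrast genotypes; significance stars:
    ``*`` for p < 0.05, ``**`` for p < 0.01. Zero variance in both groups
    with equal means yields p = 1.
    """
    ref_geno, ref_t = reference_condition
    folds = levels.copy()
    out_tests = []
    for target, sub in levels.groupby("target", sort=True):
        ref = sub[(sub["genotype"] == ref_geno) & (sub["timepoint_min"] == ref_t)]
        if len(ref) == 0:
            folds = folds[folds["target"] != target]
            continue
        ref_mean = float(ref["level"].mean())
        folds.loc[folds["target"] == target, "fold"] = sub["level"] / ref_mean
        for t, at_t in sub.groupby("timepoint_min", sort=True):
            a = at_t[at_t["genotype"] == contrast_genotypes[0]]["level"].to_numpy() / ref_mean
            b = at_t[at_t["genotype"] == contrast_genotypes[1]]["level"].to_numpy() / ref_mean
            if a.size < 2 or b.size < 2:
                continue
            if np.var(a) == 0 and np.var(b) == 0:
                p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            out_tests.append((target, t, float(a.mean()), float(b.mean()), p, stars))
    tests = pd.DataFrame(
        out_tests,
        columns=["target", "timepoint_min", "mean_fold_a", "mean_fold_b", "p_value", "stars"],
    )
    return folds, tests
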