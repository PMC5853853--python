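"""Short time-series model-profile clustering.

Candidate profiles are integer-valued temporal shapes starting at 0 with
bounded per-step change; genes are assigned to the profile best correlated
with their log2 ratio-to-time-zero vector; profile over-representation is
tested against the exact timepoint-permutation null; and non-flat profiles
are grouped into eight archetypes (induced/repressed x transient, late,
sustained, amplified).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pamptx.differential import bh_adjust

_EPS_VAR = 1e-12
_EPS_TIE = 1e-9


@dataclass(frozen=True)
class ModelProfile:
    """An integer temporal shape; ``levels`` is cumulative, starting at 0."""

    profile_id: int
    levels: tuple[int, ...]

    @property
    def is_flat(self) -> bool:
        return all(v == 0 for v in self.levels)

    @property
    def amplitude(self) -> int:
        return max(self.levels) - min(self.levels)


def _centered_unit(vec: np.ndarray) -> np.ndarray | None:
    """Mean-centered unit vector; None for (near-)constant input.

    Pearson correlation of two vectors equals the dot product of their
    centered unit vectors; a cosine-on-centered fallback therefore coincides
    with this representation whenever it is defined.
    """
    v = np.asarray(vec, dtype=float)
    c = v - v.mean()
    norm = np.linalg.norm(c)
    if norm * norm < _EPS_VAR:
        return None
    return c / norm


def profile_distance(a, b) -> float:
    """1 - Pearson correlation of cumulative vectors; 1.0 when undefined."""
    ua = _centered_unit(np.asarray(a, float))
    ub = _centered_unit(np.asarray(b, float))
    if ua is None or ub is None:
        return 1.0
    return float(1.0 - ua @ ub)


def enumerate_profiles(T: int = 3, c: int = 2, m: int = 50) -> list[ModelProfile]:
    """All (2c+1)^(T-1) candidate profiles, reduced to m by greedy max-min.

    The greedy selection (used only when the candidate count exceeds m)
    starts from the largest-amplitude profile and repeatedly adds the profile
    maximizing its minimum distance to the selected set; all ties break
    lexicographically on the level vectors, so the result is deterministic.
    """
    if T < 2:
        raise ValueError("need at least two timepoints")
    if c < 1 or m < 1:
        raise ValueError("max unit change and max profiles must be >= 1")
    candidates = []
    for steps in itertools.product(range(-c, c + 1), repeat=T - 1):
        levels = (0, *itertools.accumulate(steps))
        candidates.append(tuple(levels))
    candidates.sort()
    if len(candidates) > m:
        chosen = [max(candidates, key=lambda v: (max(v) - min(v), [-x for x in v]))]
        remaining = [v for v in candidates if v != chosen[0]]
        while len(chosen) < m and remaining:
            best = max(
                remaining,
                key=lambda v: (min(profile_distance(v, s) for s in chosen), [-x for x in v]),
            )
            chosen.append(best)
            remaining.remove(best)
        candidates = sorted(chosen)
    return [ModelProfile(i, v) for i, v in enumerate(candidates)]


def group_archetypes(profile: ModelProfile) -> int:
    """Archetype group (1-8) of a non-flat three-timepoint profile.

    Decision table on the first step d1 and the second-segment trend:
    rising first then falling back is transient (1 induced / 5 repressed);
    flat first then moving is late (2 induced / 7 repressed); rising then
    holding is sustained (3; mirrored 6); rising then rising further is
    amplified (4; mirrored 8).
    """
    if len(profile.levels) != 3:
        raise ValueError("archetype grouping is defined for three-timepoint profiles")
    if profile.is_flat:
        raise ValueError("flat profile has no archetype")
    _, v1, v2 = profile.levels
    d1 = v1
    if d1 > 0:
        if v2 > v1:
            return 4
        if v2 == v1:
            return 3
        return 1
    if d1 == 0:
        return 2 if v2 > 0 else 7
    if v2 < v1:
        return 8
    if v2 == v1:
        return 6
    return 5


def ratio_vectors(
    expression: pd.DataFrame,
    genotype: str = "Ws",
    timepoints: tuple[int, ...] = (0, 30, 90),
    pseudocount: float = 1.0,
    genes=None,
) -> pd.DataFrame:
    """Per-gene log2 ratios of replicate-mean expression vs the first timepoint."""
    sub = expression[expression["genotype"] == genotype]
    means = sub.pivot_table(index="gene_id", columns="timepoint_min", values="fpkm", aggfunc="mean")
    means = means.reindex(columns=list(timepoints))
    if genes is not None:
        means = means.reindex([g for g in genes if g in means.index])
    logm = np.log2(means.to_numpy(dtype=float) + pseudocount)
    ratios = logm - logm[:, [0]]
    return pd.DataFrame(ratios, index=means.index, columns=list(timepoints))


def assign_genes(ratios: pd.DataFrame, profiles: list[ModelProfile]) -> pd.DataFrame:
    """Assign each gene to its best-correlated model profile.

    Correlation-equivalent profiles (positive scalar multiples of each other
    have identical Pearson correlation with every gene) are collapsed onto the
    smallest-amplitude representative; a gene whose maximum score is tied
    between genuinely different shapes, or whose ratio vector is flat, or whose
    best profile is flat, stays unassigned. Returns gene_id, profile_id,
    levels, score, archetype (all NA when unassigned).
    """
    non_flat = [p for p in profiles if not p.is_flat]
    if not non_flat:
        raise ValueError("profile set contains no non-flat profile")
    # collapse correlation-equivalent (colinear) profiles onto the
    # smallest-amplitude representative of each direction class
    groups: dict[tuple, ModelProfile] = {}
    for p in non_flat:
        u = _centered_unit(np.array(p.levels, float))
        key = tuple(np.round(u, 9))
        best = groups.get(key)
        if best is None or (p.amplitude, p.levels) < (best.amplitude, best.levels):
            groups[key] = p
    reps = sorted(groups.values(), key=lambda p: (p.amplitude, p.levels))
    U = np.array([_centered_unit(np.array(p.levels, float)) for p in reps])

    mat = ratios.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms * norms < _EPS_VAR
    safe = np.where(flat, 1.0, norms)
    G = centered / safe[:, None]

    S = G @ U.T
    best = S.max(axis=1)
    n_contenders = (S >= best[:, None] - _EPS_TIE).sum(axis=1)
    pick = S.argmax(axis=1)
    assigned = ~flat & (n_contenders == 1)

    rows = []
    for gi, gene in enumerate(ratios.index):
        if not assigned[gi]:
            rows.append((gene, pd.NA, None, np.nan, pd.NA))
        else:
            p = reps[pick[gi]]
            rows.append((gene, p.profile_id, str(list(p.levels)), float(best[gi]), group_archetypes(p)))
    out = pd.DataFrame(rows, columns=["gene_id", "profile_id", "levels", "score", "archetype"])
    out["profile_id"] = out["profile_id"].astype("Int64")
    out["archetype"] = out["archetype"].astype("Int64")
    return out


def profile_significance(
    ratios: pd.DataFrame,
    profiles: list[ModelProfile],
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exact permutation test of per-profile assignment counts.

    The expected count of each profile is the mean of its assignment counts
    when every gene's underlying temporal values are permuted over all T!
    timepoint orderings (ratios re-referenced to the permuted first
    timepoint). p is the upper tail of Binomial(n_genes, expected/n) at the
    observed count; q is BH across profiles.
    """
    if assignments is None:
        assignments = assign_genes(ratios, profiles)
    n_genes = len(ratios)
    observed = assignments["profile_id"].value_counts().to_dict()

    T = ratios.shape[1]
    perm_counts: dict[int, list[int]] = {p.profile_id: [] for p in profiles}
    for perm in itertools.permutations(range(T)):
        permuted = ratios.to_numpy(dtype=float)[:, list(perm)]
        permuted = permuted - permuted[:, [0]]
        perm_ratios = pd.DataFrame(permuted, index=ratios.index, columns=ratios.columns)
        a = assign_genes(perm_ratios, profiles)
        counts = a["profile_id"].value_counts().to_dict()
        for p in profiles:
            perm_counts[p.profile_id].append(counts.get(p.profile_id, 0))

    rows = []
    for p in profiles:
        exp = float(np.mean(perm_counts[p.profile_id])) if perm_counts[p.profile_id] else 0.0
        obs = int(observed.get(p.profile_id, 0))
        rate = min(max(exp / n_genes, 0.0), 1.0) if n_genes else 0.0
        if n_genes == 0:
            pval = 1.0
        else:
            pval = float(stats.binom.sf(obs - 1, n_genes, rate)) if rate > 0 else (1.0 if obs == 0 else 0.0)
        pval = min(max(pval, math.ulp(0.0)), 1.0)
        rows.append((p.profile_id, str(list(p.levels)), obs, exp, pval))
    out = pd.DataFrame(rows, columns=["profile_id", "levels", "observed", "expected", "p_value"])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
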