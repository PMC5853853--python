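"""Synthetic pipeline inputs with known ground truth.

Every downstream stage consumes tables that this module can fabricate with
planted structure: genotype x timepoint expression matrices with planted
dependency categories and temporal archetypes, gene->term maps with planted
enriched terms, and qPCR amplification curves with planted efficiencies and
template quantities. Replicate noise is multiplicative log-normal (expression
values are positive and skewed; count-level simulation is out of scope).
All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pamptx.classify import (
    CAT_BOTH,
    CAT_INDEPENDENT,
    CAT_MPK6_INDEP,
    CAT_NOT_RESPONSIVE,
    CAT_PARTIAL,
    DIR_INDUCED,
    DIR_NONE,
    DIR_REPRESSED,
)

#: archetype id -> shape units at (0, 30, 90); scaled by the responsive effect
ARCHETYPE_SHAPES = {
    1: (0, 1, 0),  # early induced, transient
    2: (0, 0, 1),  # late induced
    3: (0, 1, 1),  # early induced, sustained
    4: (0, 1, 2),  # early induced, amplified
    5: (0, -1, 0),  # early repressed, transient
    6: (0, -1, -1),  # early repressed, sustained
    7: (0, 0, -1),  # late repressed
    8: (0, -1, -2),  # early repressed, amplified
}

#: category-mix key -> classifier category label
MIX_TO_CATEGORY = {
    "nonresponsive": CAT_NOT_RESPONSIVE,
    "MKP1_independent": CAT_INDEPENDENT,
    "MKP1_MPK6_dependent": CAT_BOTH,
    "MKP1_dep_MPK6_indep": CAT_MPK6_INDEP,
    "partial_MPK6": CAT_PARTIAL,
}

_DEPENDENT = (CAT_BOTH, CAT_MPK6_INDEP, CAT_PARTIAL)


def _default_category_mix() -> dict:
    return {
        "nonresponsive": 0.35,
        "MKP1_independent": 0.30,
        "MKP1_MPK6_dependent": 0.15,
        "MKP1_dep_MPK6_indep": 0.10,
        "partial_MPK6": 0.10,
    }


def _default_archetype_mix() -> dict:
    return {k: 0.125 for k in range(1, 9)}


@dataclass
class SimConfig:
    """Parameters of the expression simulator."""

    n_genes: int = 2000
    n_replicates: int = 3
    genotypes: tuple[str, str, str] = ("Ws", "mkp1", "mkp1_mpk6")
    timepoints_min: tuple[int, int, int] = (0, 30, 90)
    category_mix: dict = field(default_factory=_default_category_mix)
    archetype_mix: dict = field(default_factory=_default_archetype_mix)
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.5
    responsive_effect_log2: float = 2.0
    mkp1_effect_log2: float = 1.0
    noise_cv: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.timepoints_min) != 3:
            raise ValueError("archetype planting requires exactly three timepoints")
        unknown = set(self.category_mix) - set(MIX_TO_CATEGORY)
        if unknown:
            raise ValueError(f"unknown category mix key(s): {sorted(unknown)}")
        bad_arch = set(self.archetype_mix) - set(ARCHETYPE_SHAPES)
        if bad_arch:
            raise ValueError(f"unknown archetype id(s): {sorted(bad_arch)}")
        for name, mix in (("category_mix", self.category_mix), ("archetype_mix", self.archetype_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, expected 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} proportions must be non-negative")
        for eff in (self.responsive_effect_log2, self.mkp1_effect_log2, self.noise_cv):
            if not math.isfinite(eff):
                raise ValueError("effect sizes and noise must be finite")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given linear-scale CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the long-format expression matrix and its gene ground truth.

    Planted structure, in log2 space relative to each gene's baseline:
    the wild type follows the planted archetype shape scaled by the
    responsive effect; at timepoints where that shape is non-zero, the single
    mutant is shifted further in the response direction by the genotype
    effect when the gene is planted dependent; the double mutant matches the
    wild type (fully kinase-dependent), matches the single mutant
    (kinase-independent), or sits halfway in log2 (partial).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genotypes = list(config.genotypes)
    timepoints = list(config.timepoints_min)
    reps = config.n_replicates

    cat_keys = sorted(config.category_mix)
    cat_probs = np.array([config.category_mix[k] for k in cat_keys], dtype=float)
    cat_probs = cat_probs / cat_probs.sum()
    planted_mix = rng.choice(len(cat_keys), size=n, p=cat_probs)
    categories = np.array([MIX_TO_CATEGORY[cat_keys[i]] for i in planted_mix], dtype=object)

    arch_keys = sorted(config.archetype_mix)
    arch_probs = np.array([config.archetype_mix[k] for k in arch_keys], dtype=float)
    arch_probs = arch_probs / arch_probs.sum()
    archetypes = np.array([arch_keys[i] for i in rng.choice(len(arch_keys), size=n, p=arch_probs)])
    responsive = categories != CAT_NOT_RESPONSIVE

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)

    shapes = np.zeros((n, len(timepoints)))
    for k, shape in ARCHETYPE_SHAPES.items():
        shapes[responsive & (archetypes == k)] = shape
    ws_log2 = base[:, None] + shapes * config.responsive_effect_log2

    sign = np.sign(shapes)  # response direction at each timepoint; 0 where inactive
    dependent = np.isin(categories, _DEPENDENT)
    delta_single = np.where(dependent[:, None], sign * config.mkp1_effect_log2, 0.0)
    double_factor = np.select(
        [categories == CAT_BOTH, categories == CAT_MPK6_INDEP, categories == CAT_PARTIAL],
        [0.0, 1.0, 0.5],
        default=0.0,
    )
    delta_double = delta_single * double_factor[:, None]

    log2_means = np.stack([ws_log2, ws_log2 + delta_single, ws_log2 + delta_double], axis=1)
    true_fpkm = np.power(2.0, log2_means)  # (gene, genotype, timepoint)

    noise = _lognormal_noise(rng, config.noise_cv, (n, len(genotypes), len(timepoints), reps))
    values = true_fpkm[..., None] * noise

    gene_ids = np.array([f"G{i + 1:06d}" for i in range(n)])
    idx = pd.MultiIndex.from_product(
        [gene_ids, genotypes, timepoints, range(1, reps + 1)],
        names=["gene_id", "genotype", "timepoint_min", "replicate"],
    )
    matrix = idx.to_frame(index=False)
    matrix["fpkm"] = values.reshape(-1)

    direction = np.where(
        responsive,
        np.where(shapes.sum(axis=1) > 0, DIR_INDUCED, DIR_REPRESSED),
        DIR_NONE,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": categories,
            "direction": direction,
            "archetype": pd.array(np.where(responsive, archetypes, -1), dtype="Int64"),
        }
    )
    truth.loc[~responsive, "archetype"] = pd.NA
    return matrix, truth


def active_timepoints(archetype: int, timepoints=(30, 90)) -> tuple[int, ...]:
    """Elicited timepoints at which the planted archetype is non-flat."""
    shape = ARCHETYPE_SHAPES[archetype]
    return tuple(t for t, s in zip(timepoints, shape[1:]) if s != 0)


def simulate_annotations(
    genes,
    study,
    n_terms: int = 50,
    n_enriched: int = 5,
    odds_ratio: float = 8.0,
    base_rate: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a flat gene->term map with planted enriched terms.

    Non-study genes join every term at ``base_rate``. For planted terms,
    study genes join at the rate implied by the requested odds ratio; for the
    remaining terms membership is uniform.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    if n_enriched > n_terms:
        raise ValueError("n_enriched must not exceed n_terms")
    if not 0 < base_rate < 1:
        raise ValueError("base_rate must lie in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    study = set(study)
    missing = study - set(genes)
    if missing:
        raise ValueError(f"{len(missing)} study gene(s) not in gene list")
    rng = np.random.default_rng(seed)
    odds = odds_ratio * base_rate / (1.0 - base_rate)
    enriched_rate = odds / (1.0 + odds)

    is_study = np.array([g in study for g in genes])
    rows = []
    truth_rows = []
    for i in range(n_terms):
        term = f"T{i + 1:04d}"
        enriched = i < n_enriched
        p = np.where(is_study & enriched, enriched_rate, base_rate)
        members = rng.random(len(genes)) < p
        rows.extend((g, term) for g, m in zip(genes, members) if m)
        truth_rows.append((term, bool(enriched)))
    term_map = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    truth = pd.DataFrame(truth_rows, columns=["term_id", "enriched"])
    return term_map, truth


def simulate_qpcr(
    n_reactions: int,
    efficiency,
    true_quantity,
    cycles: int = 40,
    noise_sd: float = 0.0,
    seed: int | None = None,
    baseline: float = 1.0,
    plateau_factor: float = 100.0,
    hill: float = 8.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate amplification curves F(c) = baseline + capped(q0 * E**c).

    The exponential amplicon signal saturates to a plateau at
    ``plateau_factor * baseline`` through a generalized-logistic (Hill) cap,
    which leaves the below-plateau exponential phase essentially undistorted
    while producing a realistic window-of-linearity problem. Noise is
    multiplicative Gaussian on the fluorescence. ``efficiency`` and
    ``true_quantity`` may be scalars or per-reaction arrays.
    """
    if n_reactions <= 0:
        raise ValueError("n_reactions must be positive")
    if cycles < 25:
        raise ValueError("need at least 25 cycles")
    eff = np.broadcast_to(np.asarray(efficiency, dtype=float), (n_reactions,)).copy()
    q0 = np.broadcast_to(np.asarray(true_quantity, dtype=float), (n_reactions,)).copy()
    if np.any(eff <= 1.0):
        raise ValueError("efficiency <= 1 means no amplification")
    if np.any(eff > 2.0):
        raise ValueError("efficiency > 2 is non-physical")
    if np.any(q0 <= 0):
        raise ValueError("true_quantity must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    c = np.arange(1, cycles + 1, dtype=float)
    amp = q0[:, None] * np.power(eff[:, None], c[None, :])
    plateau = plateau_factor * baseline
    capped = amp * np.power(1.0 + np.power(amp / plateau, hill), -1.0 / hill)
    f = baseline + capped
    if noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, noise_sd, size=f.shape))
    reaction_ids = np.array([f"R{i + 1:04d}" for i in range(n_reactions)])
    curves = pd.DataFrame(
        {
            "reaction_id": np.repeat(reaction_ids, cycles),
            "cycle": np.tile(np.arange(1, cycles + 1), n_reactions),
            "fluorescence": f.reshape(-1),
        }
    )
    truth = pd.DataFrame(
        {"reaction_id": reaction_ids, "efficiency": eff, "true_quantity": q0}
    )
    return curves, truth


def simulate_qpcr_panel(
    matrix: pd.DataFrame,
    target_genes,
    reference_gene: str = "REF",
    efficiency_range: tuple[float, float] = (1.80, 1.95),
    quantity_scale: float = 1e-6,
    reference_quantity: float = 1e-4,
    cycles: int = 40,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Curves for a validation panel: target genes plus a constant reference.

    One reaction per (gene, genotype, timepoint, replicate), template quantity
    proportional to the expression value; the reference amplicon has constant
    template in every sample. Per-amplicon efficiencies are drawn uniformly
    from ``efficiency_range``. Returns (curves, sample_map, truth).
    """
    rng = np.random.default_rng(seed)
    sub = matrix[matrix["gene_id"].isin(set(target_genes))].reset_index(drop=True)
    if sub.empty:
        raise ValueError("no target genes found in expression matrix")
    samples = sub[["genotype", "timepoint_min", "replicate"]].drop_duplicates()
    targets = sorted(set(target_genes))
    amplicon_eff = {g: rng.uniform(*efficiency_range) for g in targets}
    amplicon_eff[reference_gene] = rng.uniform(*efficiency_range)

    map_rows = []
    effs = []
    quantities = []
    for row in sub.itertuples(index=False):
        map_rows.append((row.gene_id, row.genotype, row.timepoint_min, row.replicate))
        effs.append(amplicon_eff[row.gene_id])
        quantities.append(max(row.fpkm, 1e-2) * quantity_scale)
    for row in samples.itertuples(index=False):
        map_rows.append((reference_gene, row.genotype, row.timepoint_min, row.replicate))
        effs.append(amplicon_eff[reference_gene])
        quantities.append(reference_quantity)

    curves, truth = simulate_qpcr(
        len(map_rows),
        np.array(effs),
        np.array(quantities),
        cycles=cycles,
        noise_sd=noise_sd,
        seed=rng.integers(0, 2**31),
    )
    sample_map = pd.DataFrame(map_rows, columns=["target", "genotype", "timepoint_min", "replicate"])
    sample_map.insert(0, "reaction_id", truth["reaction_id"].to_numpy())
    return curves, sample_map, truth
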