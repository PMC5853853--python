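"""Singular enrichment analysis against flat gene->term maps.

One-sided (over-representation) Fisher's exact test per term, BH-adjusted
across tested terms. Two background modes are supported by simply passing a
different background set: the responsive-set background or the whole-genome
background. No term-hierarchy propagation is performed; maps are flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pamptx.differential import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study hits
    n: int  # study size
    K: int  # background hits
    N: int  # background size
    odds_ratio: float
    p_value: float
    q_value: float


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b = k, n - k
    c, d = K - k, (N - K) - (n - k)
    if b == 0 or c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_enrich(study, background, term_map: pd.DataFrame) -> pd.DataFrame:
    """Per-term over-representation of ``study`` within ``background``.

    ``term_map`` is a two-column frame (gene_id, term_id). Terms with no
    study hit are not tested. p is the hypergeometric upper tail
    P(X >= k); q is BH across tested terms. Results are sorted by (q, p,
    term_id). A study set not contained in the background is fatal.
    """
    study = set(study)
    background = set(background)
    outside = study - background
    if outside:
        raise ValueError(f"{len(outside)} study gene(s) not in background")
    N = len(background)
    n = len(study)

    rows = []
    if len(term_map):
        in_bg = term_map[term_map["gene_id"].isin(background)]
        for term, genes in in_bg.groupby("term_id")["gene_id"]:
            members = set(genes)
            K = len(members)
            k = len(members & study)
            if k == 0:
                continue
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append((term, k, n, K, N, _odds_ratio(k, n, K, N), min(max(p, 0.0), 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "odds_ratio", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["q_value", "p_value", "term_id"], kind="mergesort", ignore_index=True)
    else:
        out["q_value"] = np.empty(0, dtype=float)
    return out


def significant_terms(results: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    if not len(results):
        return results
    return results[results["q_value"] <= q_cutoff].reset_index(drop=True)
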