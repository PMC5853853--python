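import math

import numpy as np
import pandas as pd
import pytest

from pamptx.classify import (
    CAT_BOTH,
    CAT_INDEPENDENT,
    CAT_MPK6_INDEP,
    CAT_NOT_RESPONSIVE,
    CAT_PARTIAL,
    DIR_INDUCED,
    DIR_NONE,
    DIR_REPRESSED,
    RESPONSIVE_CATEGORIES,
    Thresholds,
    classify_calls,
)
from pamptx.differential import default_contrasts, run_contrasts
from pamptx.simulate import SimConfig, active_timepoints, simulate_expression

from conftest import make_diff_frame


def brute_force_classify(contrast_values, th=Thresholds()):
    """Naive per-gene re-evaluation of every rule predicate.

    ``contrast_values`` maps contrast keys ('ws_resp', 'mut_resp', 'dep',
    'sub_sd', 'sub_wd') to (lfc, q) or None for one gene at one timepoint.
    """
    def get(name):
        return contrast_values.get(name)

    def hit(v, lfc_min, q_max):
        return v is not None and abs(v[0]) >= lfc_min and v[1] <= q_max

    ws, mut = get("ws_resp"), get("mut_resp")
    ws_hit = hit(ws, th.lfc_min, th.q_resp)
    mut_hit = hit(mut, th.lfc_min, th.q_resp)
    responsive = ws_hit or mut_hit
    if not responsive:
        return (False, DIR_NONE, CAT_NOT_RESPONSIVE)
    sign = math.copysign(1, ws[0]) if ws_hit else math.copysign(1, mut[0])
    direction = DIR_INDUCED if sign > 0 else DIR_REPRESSED
    dep = get("dep")
    dependent = hit(dep, math.log2(th.dep_fold_min), th.q_dep)
    if not dependent:
        return (True, direction, CAT_INDEPENDENT)
    sd, wd = get("sub_sd"), get("sub_wd")
    sd_sig = sd is not None and sd[1] <= th.q_dep
    wd_sig = wd is not None and wd[1] <= th.q_dep
    if sd_sig and not wd_sig:
        return (True, direction, CAT_BOTH)
    if wd_sig and not sd_sig:
        return (True, direction, CAT_MPK6_INDEP)
    return (True, direction, CAT_PARTIAL)


def diff_rows_for_gene(gene, t, ws_resp=None, mut_resp=None, dep=None, sub_sd=None, sub_wd=None):
    rows = []
    if ws_resp is not None:
        rows.append((gene, "Ws_0", f"Ws_{t}", 10, 10, *ws_resp))
    if mut_resp is not None:
        rows.append((gene, "mkp1_0", f"mkp1_{t}", 10, 10, *mut_resp))
    if dep is not None:
        rows.append((gene, f"Ws_{t}", f"mkp1_{t}", 10, 10, *dep))
    if sub_sd is not None:
        rows.append((gene, f"mkp1_{t}", f"mkp1_mpk6_{t}", 10, 10, *sub_sd))
    if sub_wd is not None:
        rows.append((gene, f"Ws_{t}", f"mkp1_mpk6_{t}", 10, 10, *sub_wd))
    return rows


def call_for(rows, gene="g", t=30, **kwargs):
    calls, _ = classify_calls(make_diff_frame(rows), **kwargs)
    row = calls[(calls["gene_id"] == gene) & (calls["timepoint_min"] == t)]
    assert len(row) == 1
    return row.iloc[0]


class TestResponsiveness:
    def test_boundary_inclusive(self):
        # |lfc| >= 1 and q <= 0.01 exactly at the boundary qualifies
        row = call_for(diff_rows_for_gene("g", 30, ws_resp=(1.0, 0.001, 0.01)))
        assert row["responsive"]
        assert row["direction"] == DIR_INDUCED

    def test_union_rule_mutant_only(self):
        rows = diff_rows_for_gene("g", 30, ws_resp=(0.2, 0.5, 0.9), mut_resp=(-1.4, 0.0001, 0.001))
        row = call_for(rows)
        assert row["responsive"]
        assert row["direction"] == DIR_REPRESSED

    def test_below_threshold_not_responsive(self):
        row = call_for(diff_rows_for_gene("g", 30, ws_resp=(0.99, 0.001, 0.001)))
        assert not row["responsive"]
        assert row["direction"] == DIR_NONE
        assert row["category"] == CAT_NOT_RESPONSIVE

    def test_wild_type_direction_precedence(self):
        rows = diff_rows_for_gene("g", 30, ws_resp=(1.5, 0.001, 0.001), mut_resp=(-1.5, 0.001, 0.001))
        row = call_for(rows)
        assert row["direction"] == DIR_INDUCED

    def test_direction_conflict_counted(self):
        rows = diff_rows_for_gene("g", 30, ws_resp=(1.5, 0.001, 0.001), mut_resp=(-1.5, 0.001, 0.001))
        _, stats = classify_calls(make_diff_frame(rows))
        assert stats.direction_conflicts == 1

    def test_missing_contrast_counted_not_raised(self):
        rows = diff_rows_for_gene("g", 90, ws_resp=(2.0, 0.001, 0.001))
        calls, stats = classify_calls(make_diff_frame(rows))
        at30 = calls[calls["timepoint_min"] == 30].iloc[0]
        assert at30["category"] == CAT_NOT_RESPONSIVE
        assert stats.missing_contrasts.get("responsiveness_t30") == 1

    def test_non_ok_status_ignored(self):
        rows = [("g", "Ws_0", "Ws_30", 10, 40, 2.0, 0.0001, 0.0001, "NOTEST")]
        row = call_for(rows)
        assert not row["responsive"]


class TestDependence:
    def base_rows(self, dep, sub_sd=(0.5, 0.9, 0.9), sub_wd=(0.5, 0.9, 0.9)):
        return diff_rows_for_gene("g", 30, ws_resp=(2.0, 0.0001, 0.001), dep=dep, sub_sd=sub_sd, sub_wd=sub_wd)

    def test_exact_1p5_fold_inclusive(self):
        row = call_for(self.base_rows(dep=(math.log2(1.5), 0.001, 0.005)))
        assert row["mkp1_dependent"]

    def test_significance_gate(self):
        row = call_for(self.base_rows(dep=(math.log2(3.0), 0.3, 0.5)))
        assert not row["mkp1_dependent"]
        assert row["category"] == CAT_INDEPENDENT

    def test_either_direction_qualifies(self):
        row = call_for(self.base_rows(dep=(-math.log2(2.0), 0.001, 0.005)))
        assert row["mkp1_dependent"]
        assert row["mkp1_shift"] == -1


class TestSubdivision:
    def rows(self, sub_sd, sub_wd):
        return diff_rows_for_gene(
            "g", 30, ws_resp=(2.0, 0.0001, 0.001), dep=(1.0, 0.001, 0.001), sub_sd=sub_sd, sub_wd=sub_wd
        )

    def test_reverted_in_double_mutant(self):
        row = call_for(self.rows(sub_sd=(1.0, 0.0005, 0.001), sub_wd=(0.1, 0.4, 0.5)))
        assert row["category"] == CAT_BOTH

    def test_not_reverted_in_double_mutant(self):
        row = call_for(self.rows(sub_sd=(0.1, 0.4, 0.5), sub_wd=(1.0, 0.0005, 0.001)))
        assert row["category"] == CAT_MPK6_INDEP

    def test_both_significant_is_partial(self):
        row = call_for(self.rows(sub_sd=(1.0, 0.001, 0.001), sub_wd=(0.5, 0.001, 0.001)))
        assert row["category"] == CAT_PARTIAL

    def test_neither_significant_is_partial(self):
        row = call_for(self.rows(sub_sd=(0.5, 0.2, 0.5), sub_wd=(0.5, 0.2, 0.5)))
        assert row["category"] == CAT_PARTIAL

    def test_q_only_gates_ignore_fold(self):
        # subdivision looks at q only; tiny folds with small q still gate
        row = call_for(self.rows(sub_sd=(0.01, 0.001, 0.001), sub_wd=(0.01, 0.4, 0.5)))
        assert row["category"] == CAT_BOTH


def random_fixture_frame(rng, n_genes, timepoints=(30, 90)):
    rows = []
    for i in range(n_genes):
        gene = f"g{i}"
        for t in timepoints:
            for s1, s2 in [
                ("Ws_0", f"Ws_{t}"),
                ("mkp1_0", f"mkp1_{t}"),
                (f"Ws_{t}", f"mkp1_{t}"),
                (f"mkp1_{t}", f"mkp1_mpk6_{t}"),
                (f"Ws_{t}", f"mkp1_mpk6_{t}"),
            ]:
                lfc = float(rng.normal(0, 1.5))
                q = float(rng.uniform()) ** 2  # skew toward small q to hit every branch
                rows.append((gene, s1, s2, 10, 10, lfc, q / 2, q))
    return make_diff_frame(rows)


class TestPartitionAndOracle:
    def test_partition_invariant_random_fixtures(self, rng):
        diffs = random_fixture_frame(rng, 500)
        calls, _ = classify_calls(diffs)
        for _, sub in calls.groupby("timepoint_min"):
            resp = sub[sub["responsive"]]
            assert set(resp["category"]) <= set(RESPONSIVE_CATEGORIES)
            assert (sub.loc[~sub["responsive"], "category"] == CAT_NOT_RESPONSIVE).all()
            counts = resp["category"].value_counts()
            assert counts.sum() == len(resp)

    def test_vectorized_agrees_with_brute_force(self, rng):
        diffs = random_fixture_frame(rng, 400)
        calls, _ = classify_calls(diffs)
        lookup = {}
        for row in diffs.itertuples(index=False):
            lookup[(row.gene_id, row.sample_1, row.sample_2)] = (row.log2_fc, row.q_value)
        for row in calls.itertuples(index=False):
            g, t = row.gene_id, row.timepoint_min
            cv = {
                "ws_resp": lookup.get((g, "Ws_0", f"Ws_{t}")),
                "mut_resp": lookup.get((g, "mkp1_0", f"mkp1_{t}")),
                "dep": lookup.get((g, f"Ws_{t}", f"mkp1_{t}")),
                "sub_sd": lookup.get((g, f"mkp1_{t}", f"mkp1_mpk6_{t}")),
                "sub_wd": lookup.get((g, f"Ws_{t}", f"mkp1_mpk6_{t}")),
            }
            expected = brute_force_classify(cv)
            assert (row.responsive, row.direction, row.category) == expected, (g, t)

    def test_dep_fold_monotonicity(self, rng):
        diffs = random_fixture_frame(rng, 300)
        counts = []
        for fold in (1.2, 1.5, 2.0, 3.0):
            calls, _ = classify_calls(diffs, Thresholds(dep_fold_min=fold))
            counts.append(int(calls["mkp1_dependent"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_timepoints_labelled_independently(self):
        rows = diff_rows_for_gene("g", 30, ws_resp=(2.0, 0.0001, 0.001), dep=(0.1, 0.9, 0.9))
        rows += diff_rows_for_gene(
            "g", 90, ws_resp=(2.0, 0.0001, 0.001), dep=(1.0, 0.001, 0.001), sub_sd=(0.5, 0.9, 0.9), sub_wd=(1.0, 0.001, 0.001)
        )
        calls, _ = classify_calls(make_diff_frame(rows))
        by_t = calls.set_index("timepoint_min")["category"]
        assert by_t[30] == CAT_INDEPENDENT
        assert by_t[90] == CAT_MPK6_INDEP


class TestRecoveryLowNoise:
    def test_planted_categories_recovered_when_powered(self):
        # at low replicate noise the full pipeline recovers the planted labels;
        # the default (higher) noise setting is exercised in the acceptance suite
        config = SimConfig(n_genes=600, noise_cv=0.02, seed=9)
        matrix, truth = simulate_expression(config)
        calls, _ = classify_calls(run_contrasts(matrix, default_contrasts()))
        piv = calls.pivot(index="gene_id", columns="timepoint_min", values="category")
        truth = truth.set_index("gene_id")
        hits = 0
        for gene, row in truth.iterrows():
            if row["category"] == CAT_NOT_RESPONSIVE:
                hits += (piv.loc[gene] == CAT_NOT_RESPONSIVE).all()
            else:
                ts = active_timepoints(int(row["archetype"]))
                hits += all(piv.loc[gene, t] == row["category"] for t in ts)
        assert hits / len(truth) >= 0.90
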