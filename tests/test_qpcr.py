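import numpy as np
import pandas as pd
import pytest

from pamptx.qpcr import (
    WindowParams,
    estimate_efficiency,
    estimate_reactions,
    expression_level,
    normalize_and_test,
    quantify_samples,
)
from pamptx.simulate import simulate_qpcr


def curve_values(curves, rid=None):
    if rid is None:
        rid = curves["reaction_id"].iloc[0]
    sub = curves[curves["reaction_id"] == rid].sort_values("cycle")
    return sub["fluorescence"].to_numpy()


class TestEfficiencyEstimation:
    def test_pure_exponential_exact(self):
        c = np.arange(1, 41)
        est = estimate_efficiency(0.001 * 2.0**c)
        assert est.reliable
        assert est.efficiency == pytest.approx(2.0, abs=1e-9)

    def test_noiseless_simulated_curve(self):
        curves, _ = simulate_qpcr(1, 1.85, 1e-4, cycles=40, noise_sd=0.0, seed=0)
        est = estimate_efficiency(curve_values(curves))
        assert est.reliable
        assert est.efficiency == pytest.approx(1.85, abs=0.01)

    def test_sixteen_fold_dilution_delta_ct(self):
        c1, _ = simulate_qpcr(1, 2.0, 1e-4, cycles=40, noise_sd=0.0)
        c2, _ = simulate_qpcr(1, 2.0, 1e-4 / 16, cycles=40, noise_sd=0.0)
        dct = estimate_efficiency(curve_values(c2)).ct - estimate_efficiency(curve_values(c1)).ct
        assert dct == pytest.approx(4.0, abs=0.05)

    def test_recovery_with_one_percent_noise(self):
        estimates = []
        for seed in range(100):
            curves, _ = simulate_qpcr(1, 1.85, 1e-4, cycles=40, noise_sd=0.01, seed=seed)
            est = estimate_efficiency(curve_values(curves))
            if est.reliable:
                estimates.append(est.efficiency)
        assert len(estimates) >= 95
        assert np.mean(estimates) == pytest.approx(1.85, abs=0.02)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError, match="25"):
            estimate_efficiency(np.ones(10))

    def test_garbage_curve_flagged_unreliable(self, rng):
        est = estimate_efficiency(rng.uniform(0, 1, 40))
        assert not est.reliable

    def test_estimate_reactions_table(self):
        curves, truth = simulate_qpcr(5, 1.9, 1e-4, cycles=40, noise_sd=0.005, seed=3)
        out = estimate_reactions(curves)
        assert len(out) == 5
        assert out["reliable"].all()
        assert out["efficiency"].between(1.85, 1.95).all()


class TestSimulatedCurves:
    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError, match="no amplification"):
            simulate_qpcr(1, 1.0, 1e-4)
        with pytest.raises(ValueError, match="non-physical"):
            simulate_qpcr(1, 2.2, 1e-4)

    def test_cycle_floor(self):
        with pytest.raises(ValueError):
            simulate_qpcr(1, 1.9, 1e-4, cycles=20)

    def test_deterministic_given_seed(self):
        a, _ = simulate_qpcr(3, 1.9, 1e-4, noise_sd=0.02, seed=11)
        b, _ = simulate_qpcr(3, 1.9, 1e-4, noise_sd=0.02, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_plateau_saturates(self):
        curves, _ = simulate_qpcr(1, 2.0, 1e-3, cycles=40, noise_sd=0.0, baseline=1.0, plateau_factor=100.0)
        f = curve_values(curves)
        assert f.max() <= 1.0 + 100.0 + 1e-6
        assert f.max() > 90.0


class TestExpressionLevel:
    def test_classical_two_power(self):
        assert expression_level(24.0, 20.0, 2.0) == pytest.approx(0.0625, abs=1e-15)

    def test_identity_when_cts_equal(self):
        for e in (1.5, 1.8, 2.0):
            assert expression_level(21.3, 21.3, e) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert expression_level(23.0, 20.0, 1.9) == pytest.approx(0.1458, abs=5e-5)

    def test_invalid_efficiency(self):
        with pytest.raises(ValueError):
            expression_level(20.0, 18.0, 1.0)
        with pytest.raises(ValueError):
            expression_level(20.0, 18.0, 2.1)

    def test_invalid_ct(self):
        with pytest.raises(ValueError):
            expression_level(float("nan"), 18.0, 1.9)


def levels_frame(rows):
    return pd.DataFrame(rows, columns=["target", "genotype", "timepoint_min", "replicate", "level"])


class TestNormalizeAndTest:
    def test_reference_condition_fold_is_one(self):
        rows = [("X", "Ws", 0, r, v) for r, v in enumerate([1.0, 1.2, 0.8], 1)]
        rows += [("X", "Ws", 30, r, v) for r, v in enumerate([2.0, 2.2, 1.8], 1)]
        folds, _ = normalize_and_test(levels_frame(rows))
        ref = folds[(folds["genotype"] == "Ws") & (folds["timepoint_min"] == 0)]
        assert ref["fold"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_identical_folds_p_one_no_stars(self):
        rows = []
        for geno in ("Ws", "mkp1"):
            rows += [("X", geno, 0, r, 1.0) for r in (1, 2, 3)]
            rows += [("X", geno, 30, r, 2.0) for r in (1, 2, 3)]
        folds, tests = normalize_and_test(levels_frame(rows))
        assert (tests["p_value"] == 1.0).all()
        assert (tests["stars"] == "").all()

    def test_planted_fourfold_effect_power(self):
        # 4x genotype effect, 10% CV, n=3: detected at p<0.05 in >=90% of seeds
        detected = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            rows = [("X", "Ws", 0, i, v) for i, v in enumerate(1.0 + 0.1 * r.normal(size=3), 1)]
            rows += [("X", "Ws", 30, i, v) for i, v in enumerate(2.0 * (1 + 0.1 * r.normal(size=3)), 1)]
            rows += [("X", "mkp1", 30, i, v) for i, v in enumerate(8.0 * (1 + 0.1 * r.normal(size=3)), 1)]
            _, tests = normalize_and_test(levels_frame(rows))
            at30 = tests[tests["timepoint_min"] == 30]
            detected += bool((at30["p_value"] < 0.05).any())
        assert detected / n_seeds >= 0.90

    def test_stars_thresholds(self):
        rows = [("X", "Ws", 0, r, v) for r, v in enumerate([1.0, 1.01, 0.99], 1)]
        rows += [("X", "mkp1", 0, r, v) for r, v in enumerate([5.0, 5.05, 4.95], 1)]
        _, tests = normalize_and_test(levels_frame(rows))
        assert tests.loc[0, "p_value"] < 0.01
        assert tests.loc[0, "stars"] == "**"


class TestEndToEndQuantities:
    def test_relative_quantities_within_ten_percent(self):
        # planted template ratios recovered with <10% median absolute relative error
        ratios = np.array([1.0, 0.5, 0.25, 4.0, 2.0, 8.0, 1.0 / 8, 1.0 / 3, 3.0, 1.5])
        q0 = 1e-4 * ratios
        curves, _ = simulate_qpcr(len(q0), 1.9, q0, cycles=40, noise_sd=0.01, seed=77)
        est = estimate_reactions(curves)
        assert est["reliable"].all()
        e_mean = est["efficiency"].mean()
        ct0 = est.loc[0, "ct"]
        recovered = np.array([e_mean ** -(ct - ct0) for ct in est["ct"]])
        rel_err = np.abs(recovered - ratios) / ratios
        assert np.median(rel_err) < 0.10

    def test_quantify_samples_excludes_missing_reference(self):
        est = pd.DataFrame(
            {
                "reaction_id": ["r1", "r2", "r3"],
                "efficiency": [1.9, 1.9, 1.9],
                "ct": [20.0, 24.0, 21.0],
                "r_squared": [1.0, 1.0, 1.0],
                "reliable": [True, True, True],
            }
        )
        sample_map = pd.DataFrame(
            {
                "reaction_id": ["r1", "r2", "r3"],
                "target": ["REF", "X", "X"],
                "genotype": ["Ws", "Ws", "Ws"],
                "timepoint_min": [0, 0, 30],
                "replicate": [1, 1, 1],
            }
        )
        out = quantify_samples(est, sample_map, reference_gene="REF")
        # the t=30 sample has no reference reaction -> excluded
        assert len(out) == 1
        assert out.loc[0, "level"] == pytest.approx(1.9**-4)
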