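"""Gate sweep, leave-one-out correlation statistics and advisory selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmorph import build_param_grid, loo_correlations, run_sweep, select_optimal
from lungmorph.paramopt import GateCombo, sweep_results_to_frame, SweepResult


def brute_force_loo(x, y):
    """Independent oracle: Pearson r on every (n-1)-subset via np.corrcoef."""
    n = len(x)
    rs = []
    for keep in itertools.combinations(range(n), n - 1):
        rs.append(float(np.corrcoef(np.asarray(x)[list(keep)], np.asarray(y)[list(keep)])[0, 1]))
    return rs[::-1]  # combinations drop the last index first; reorder to drop 0..n-1


class TestGrid:
    def test_duct_grid_has_eight_combos(self):
        grid = build_param_grid("duct")
        assert len(grid.combos) == 8
        assert GateCombo("duct", 4000.0, (0.0, 0.5)) in grid.combos

    def test_alveolus_grid_has_nine_combos(self):
        grid = build_param_grid("alveolus")
        assert len(grid.combos) == 9
        assert GateCombo("alveolus", 150.0, (0.01, 1.0)) in grid.combos

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown airway kind"):
            build_param_grid("bronchiole")


class TestLooCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        stats = loo_correlations(x, x)
        assert stats["full_r"] == pytest.approx(1.0)
        assert stats["loo_median_r"] == pytest.approx(1.0)
        assert stats["loo_max_r"] - stats["loo_min_r"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 9.0])
        stats = loo_correlations(x, y)
        expected = brute_force_loo(x, y)
        np.testing.assert_allclose(stats["loo_r"], expected, atol=1e-12)
        assert stats["full_r"] == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-12)

    def test_seven_animals_give_seven_iterations(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(7), rng.standard_normal(7)
        assert len(loo_correlations(x, y)["loo_r"]) == 7

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            loo_correlations([1, 2, 3], [1, 2, 3])

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_full_r_invariant_under_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(99)
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        base = loo_correlations(x, y)["full_r"]
        mapped = loo_correlations(a * x + b, y)["full_r"]
        assert mapped == pytest.approx(base, abs=1e-9)


def sweep_table(grid, area_fn, animals):
    rows = []
    for animal in animals:
        for combo in grid.combos:
            rows.append(
                {
                    "animal_id": animal,
                    "kind": combo.kind,
                    "min_area_um2": combo.min_area_um2,
                    "circ_low": combo.circ[0],
                    "circ_high": combo.circ[1],
                    "mean_area_um2": area_fn(animal, combo),
                }
            )
    return pd.DataFrame(rows)


class TestRunSweep:
    def test_area_proportional_to_lm_gives_r_one_everywhere(self):
        grid = build_param_grid("duct")
        animals = [f"m{i}" for i in range(7)]
        lm = pd.Series({a: 40.0 + 5 * i for i, a in enumerate(animals)})
        table = sweep_table(grid, lambda a, c: 100.0 * lm[a], animals)
        results = run_sweep(table, lm, grid)
        assert len(results) == 8
        for s in results:
            assert s.full_r == pytest.approx(1.0)
            assert s.loo_median_r == pytest.approx(1.0)
            assert s.n == 7

    def test_missing_animal_named_in_error(self):
        grid = build_param_grid("duct")
        animals = ["m0", "m1", "m2", "m3"]
        lm = pd.Series({a: 40.0 + i for i, a in enumerate(animals + ["m4"])})
        table = sweep_table(grid, lambda a, c: 1.0, animals)
        with pytest.raises(ValueError, match="m4"):
            run_sweep(table, lm, grid)

    def test_deterministic_ranking(self):
        grid = build_param_grid("alveolus")
        rng = np.random.default_rng(5)
        animals = [f"m{i}" for i in range(7)]
        lm = pd.Series({a: v for a, v in zip(animals, rng.uniform(30, 90, 7))})
        areas = {
            (a, c): float(rng.uniform(100, 1000)) for a in animals for c in grid.combos
        }
        table = sweep_table(grid, lambda a, c: areas[(a, c)], animals)
        f1 = sweep_results_to_frame(run_sweep(table, lm, grid))
        f2 = sweep_results_to_frame(run_sweep(table, lm, grid))
        pd.testing.assert_frame_equal(f1, f2)


def result_from(x, y, combo):
    return SweepResult(combo=combo, **loo_correlations(x, y))


class TestSelection:
    duct = GateCombo("duct", 4000.0, (0.0, 0.5))
    other = GateCombo("duct", 6000.0, (0.0, 0.5))

    def test_single_candidate_selected(self):
        r = result_from(np.arange(5.0), np.arange(5.0), self.duct)
        best, ranking = select_optimal([r])
        assert best is r
        assert len(ranking) == 1

    def test_stability_rule_prefers_narrow_loo_range(self):
        a = SweepResult(self.duct, 0.9, 0.01, [0.8, 0.85, 0.9], 0.85, 0.80, 0.90, 7)
        b = SweepResult(self.other, 0.95, 0.01, [0.6, 0.85, 1.0], 0.85, 0.60, 1.00, 7)
        best, _ = select_optimal([a, b], loo_range_cap=0.25)
        assert best is a  # equal medians; b's range 0.40 exceeds the cap

    def test_outlier_inflated_combo_loses_to_stable_one(self):
        """A single outlier animal can inflate full-sample r while widening
        the LOO range; the stability rule must prefer the consistent gate.
        Verified against exhaustive LOO recomputation."""
        lm = np.array([40.0, 42.0, 44.0, 46.0, 48.0, 50.0, 95.0])
        rng = np.random.default_rng(3)
        noisy = np.concatenate([rng.uniform(4000, 6000, 6), [20000.0]])  # outlier-driven
        stable = 100 * lm + rng.normal(0, 150, 7)  # genuinely linear
        res_noisy = result_from(noisy, lm, self.other)
        res_stable = result_from(stable, lm, self.duct)
        assert res_noisy.full_r > 0.9  # the outlier pair dominates
        assert res_noisy.loo_range > 0.25
        np.testing.assert_allclose(res_noisy.loo_r, brute_force_loo(noisy, lm), atol=1e-12)
        best, _ = select_optimal([res_noisy, res_stable], loo_range_cap=0.25)
        assert best is res_stable

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="empty sweep"):
            select_optimal([])

    def test_cap_relaxed_with_warning_when_nothing_is_stable(self):
        a = SweepResult(self.duct, 0.9, 0.01, [0.2, 0.6, 0.9], 0.6, 0.2, 0.9, 7)
        with pytest.warns(UserWarning, match="relaxing"):
            best, _ = select_optimal([a], loo_range_cap=0.25)
        assert best is a
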