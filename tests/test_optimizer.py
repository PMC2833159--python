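import numpy as np
import pandas as pd
import pytest

from oracles import coverage_by_counting

from orthomir.features import FEATURE_NAMES, SCAN_MAXIMA
from orthomir.optimizer import coverage_curve, grid_search, select_ranges
from orthomir.simulate import plant_features


def _table(**cols):
    n = len(next(iter(cols.values())))
    base = {name: [0] * n for name in FEATURE_NAMES}
    base.update({k: list(v) for k, v in cols.items()})
    return pd.DataFrame(base)


class TestCoverageCurve:
    def test_all_zero_features_give_full_coverage(self):
        df = _table(mm_mrna=[0, 0, 0, 0])
        c = coverage_curve(df, [True, True, False, False], "mm_mrna")
        assert set(c.cov_verified) == {1.0}
        assert set(c.cov_predicted) == {1.0}

    def test_separated_sets_maximal_gap(self):
        df = _table(mm_mrna=[0, 1, 5, 6])
        c = coverage_curve(df, [True, True, False, False], "mm_mrna", range(0, 7))
        i = c.values.index(1)
        assert c.cov_verified[i] == 1.0
        # predicted coverage counts all rows (verified included)
        assert c.cov_predicted[i] == pytest.approx(0.5)
        assert max(c.gap) == pytest.approx(0.5)
        assert np.argmax(c.gap) == i

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 15, size=200)
        flags = rng.random(200) < 0.25
        df = _table(mm_mirna=vals)
        c = coverage_curve(df, flags, "mm_mirna")
        for v, cv, cp in zip(c.values, c.cov_verified, c.cov_predicted):
            assert cv == pytest.approx(coverage_by_counting(vals[flags], v))
            assert cp == pytest.approx(coverage_by_counting(vals, v))

    def test_coverage_is_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        df = _table(gu_whole=rng.integers(0, 11, size=100))
        c = coverage_curve(df, rng.random(100) < 0.3, "gu_whole")
        assert list(c.cov_predicted) == sorted(c.cov_predicted)
        assert list(c.cov_verified) == sorted(c.cov_verified)

    def test_empty_verified_rejected(self):
        with pytest.raises(ValueError, match="verified"):
            coverage_curve(_table(mm_mrna=[1, 2]), [False, False], "mm_mrna")


class TestSelectRanges:
    def test_unique_peak_plateau(self):
        df = _table(mm_mrna=[0, 0, 1, 1, 9, 10, 11, 12])
        flags = [True, True, True, True, False, False, False, False]
        curves = {n: coverage_curve(df, flags, n) for n in FEATURE_NAMES}
        sel = select_ranges(curves, (5, 5, 5, 4))
        # gap peaks on the plateau between the verified max (1) and decoy min (9)
        assert set(sel["mm_mrna"]) <= set(range(1, 9))
        assert len(sel["mm_mrna"]) == 5 and sel["mm_mrna"] == sorted(sel["mm_mrna"])

    def test_uniform_gap_breaks_ties_strict(self):
        df = _table(gu_seed=[0, 0])
        curves = {n: coverage_curve(df, [True, False], n) for n in FEATURE_NAMES}
        sel = select_ranges(curves, (5, 5, 5, 4))
        assert sel["gu_seed"] == [0, 1, 2, 3]  # all gaps equal → smallest values

    def test_k_too_large_rejected(self):
        df = _table(gu_seed=[0, 1])
        curves = {n: coverage_curve(df, [True, False], n) for n in FEATURE_NAMES}
        with pytest.raises(ValueError):
            select_ranges(curves, (5, 5, 5, 40))

    def test_planted_cut_contained(self):
        df, flags, cut = plant_features(cut=(2, 1, 1, 0), seed=5)
        curves = {n: coverage_curve(df, flags, n) for n in FEATURE_NAMES}
        sel = select_ranges(curves, (5, 5, 5, 4))
        for name, c in zip(FEATURE_NAMES, cut):
            assert c in sel[name]

    def test_default_grid_shape_yields_500_combinations(self):
        df, flags, _ = plant_features(seed=1)
        curves = {n: coverage_curve(df, flags, n) for n in FEATURE_NAMES}
        sel = select_ranges(curves, (5, 5, 5, 4))
        n = np.prod([len(v) for v in sel.values()])
        assert n == 500


class TestGridSearch:
    def test_single_combination(self):
        df, flags, _ = plant_features(seed=2, n_verified=20, n_decoys=100)
        ranges = {n: [m] for n, m in zip(FEATURE_NAMES, SCAN_MAXIMA)}
        points, best = grid_search(df, flags, ranges)
        assert len(points) == 1 and best is points[0]
        assert best.coverage_pct == pytest.approx(100.0)
        assert best.enrichment == pytest.approx(1.0)

    def test_dominating_combination_wins(self):
        df = _table(mm_mrna=[0, 0, 9, 9, 9, 9])
        flags = [True, True, False, False, False, False]
        ranges = {"mm_mrna": [0, 9], "mm_mirna": [14], "gu_whole": [10], "gu_seed": [6]}
        points, best = grid_search(df, flags, ranges)
        assert best.params.max_mm_mrna == 0  # same coverage, higher enrichment

    def test_ec_consistency_and_filter_reproducibility(self):
        from orthomir.features import BindingFeatures, apply_filter

        df, flags, _ = plant_features(seed=4, n_verified=30, n_decoys=300)
        curves = {n: coverage_curve(df, flags, n) for n in FEATURE_NAMES}
        points, best = grid_search(df, flags, select_ranges(curves, (5, 5, 5, 4)))
        for p in points:
            assert p.ec == pytest.approx(p.enrichment * p.coverage_pct, abs=1e-9)
        # best point's kept counts reproducible through apply_filter
        kept = sum(
            apply_filter(BindingFeatures(*row), best.params)
            for row in df[list(FEATURE_NAMES)].itertuples(index=False)
        )
        assert kept == best.n_pred_kept

    def test_recovers_planted_cut(self):
        df, flags, cut = plant_features(cut=(2, 1, 1, 0), seed=8)
        curves = {n: coverage_curve(df, flags, n) for n in FEATURE_NAMES}
        points, best = grid_search(df, flags, select_ranges(curves, (5, 5, 5, 4)))
        assert best.params.as_tuple() == cut

    def test_single_feature_grid_reduces_to_gap_optimum(self):
        df, flags, cut = plant_features(cut=(3, 14, 10, 6), seed=12)
        curves = {n: coverage_curve(df, flags, n) for n in FEATURE_NAMES}
        ranges = {
            "mm_mrna": list(select_ranges(curves, (5, 5, 5, 4))["mm_mrna"]),
            "mm_mirna": [14],
            "gu_whole": [10],
            "gu_seed": [6],
        }
        _, best = grid_search(df, flags, ranges)
        gap_opt = max(zip(curves["mm_mrna"].gap, curves["mm_mrna"].values),
                      key=lambda t: (t[0], -t[1]))[1]
        assert best.params.max_mm_mrna == gap_opt
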