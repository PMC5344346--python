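import itertools

import numpy as np
import pandas as pd
import pytest

from ictalwave.estimators import pick_family_best_max, pick_family_best_threshold
from ictalwave.selection import (
    band_feature_search,
    count_combinations,
    dimensionality_reduction,
    wavelet_level_search,
)
from ictalwave.synthetic import SyntheticConfig, generate_dataset


def brute_force_combinations(level, m):
    bands = range(1, level + 2)
    feats = range(m)
    n = 0
    for nb in range(1, level + 2):
        for _ in itertools.combinations(bands, nb):
            for nf in range(1, m + 1):
                n += sum(1 for _ in itertools.combinations(feats, nf))
    return n


class TestCountCombinations:
    @pytest.mark.parametrize("j,m,expected", [(1, 1, 3), (2, 2, 21), (7, 9, 130305)])
    def test_examples(self, j, m, expected):
        assert count_combinations(j, m) == expected

    @pytest.mark.parametrize("j,m", [(j, m) for j in (1, 2, 3, 4) for m in (1, 2, 3, 4)])
    def test_matches_subset_enumeration(self, j, m):
        assert count_combinations(j, m) == brute_force_combinations(j, m)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            count_combinations(0, 5)


class TestDimensionalityReduction:
    @pytest.mark.parametrize(
        "j,nb,nf,expected",
        [
            (8, 8, 3, 70.37),
            (7, 6, 7, 41.67),
            (1, 1, 5, 72.22),
            (2, 2, 5, 62.96),
            (8, 8, 4, 60.49),
            (1, 1, 4, 77.78),
            (7, 6, 8, 33.33),
            (8, 8, 8, 20.99),
            (5, 4, 8, 40.74),
        ],
    )
    def test_published_configurations(self, j, nb, nf, expected):
        assert dimensionality_reduction(j, nb, nf) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dimensionality_reduction(2, 4, 3)
        with pytest.raises(ValueError):
            dimensionality_reduction(2, 1, 10)


def _entries(rows):
    out = []
    for wavelet, family, level, acc in rows:
        out.append({
            "wavelet": wavelet, "family": family, "level": level,
            "TP": 1, "FP": 0, "TN": 1, "FN": 0, "accuracy": acc,
            "sensitivity": 1.0, "specificity": 1.0, "ppv": 1.0, "npv": 1.0,
        })
    return pd.DataFrame(out)


class TestFamilyPicks:
    def test_argmax_picks_highest_accuracy(self):
        table = _entries([("db1", "db", 3, 0.88), ("db2", "db", 5, 0.92)])
        assert pick_family_best_max(table)["db"] == ("db2", 5, 0.92)

    def test_argmax_tie_prefers_lower_level_then_shorter_filter(self):
        table = _entries([("db2", "db", 5, 0.90), ("db1", "db", 3, 0.90)])
        assert pick_family_best_max(table)["db"] == ("db1", 3, 0.90)
        table = _entries([("db2", "db", 3, 0.90), ("db1", "db", 3, 0.90)])
        assert pick_family_best_max(table)["db"][0] == "db1"

    def test_single_member_family(self):
        table = _entries([("haar", "haar", 2, 0.7)])
        assert pick_family_best_max(table)["haar"] == ("haar", 2, 0.7)

    def test_threshold_prefers_smallest_vanishing_moments(self):
        table = _entries([("sym5", "sym", 1, 0.97), ("sym2", "sym", 1, 0.957)])
        assert pick_family_best_threshold(table, 0.95)["sym"][0] == "sym2"

    def test_threshold_prefers_lower_level(self):
        table = _entries([("coif2", "coif", 2, 0.99), ("coif1", "coif", 1, 0.96)])
        assert pick_family_best_threshold(table, 0.95)["coif"] == ("coif1", 1, 0.96)

    def test_threshold_falls_back_to_argmax(self):
        table = _entries([("db1", "db", 2, 0.80), ("db2", "db", 3, 0.85)])
        with pytest.warns(UserWarning, match="falling back"):
            winner = pick_family_best_threshold(table, 0.95)["db"]
        assert winner == ("db2", 3, 0.85)


class TestWaveletLevelSearch:
    def test_single_pair_reduces_to_one_cv_run(self, small_dataset):
        res = wavelet_level_search(small_dataset, ["haar"], "loso", levels=(3, 3))
        assert len(res.entries) == 1
        assert res.best_per_wavelet["haar"][0] == 3
        assert res.best_per_family["haar"][:2] == ("haar", 3)

    def test_entries_cover_requested_level_grid(self, small_dataset):
        res = wavelet_level_search(small_dataset, ["haar", "db2"], "loso", levels=(1, 2))
        assert sorted(map(tuple, res.entries[["wavelet", "level"]].values)) == [
            ("db2", 1), ("db2", 2), ("haar", 1), ("haar", 2)
        ]

    def test_deeper_levels_isolate_a_slow_planted_rhythm(self):
        # moderate 2-5 Hz effect: at level 1 the 0.5-64 Hz approximation
        # dilutes it; by level 5 the (0.5, 4.5) Hz approximation isolates it
        shallow, deep = [], []
        for seed in range(10):
            config = SyntheticConfig(
                n_subjects=4,
                segments_per_class_per_subject=10,
                effect_bands=((2.0, 5.0, 1.0),),
                seed=seed,
            )
            res = wavelet_level_search(
                generate_dataset(config), ["haar"], "loso", levels=(1, 5), seed=seed
            )
            acc = res.entries.set_index("level").accuracy
            shallow.append(acc[1])
            deep.append(acc[5])
        assert sum(d > s for d, s in zip(deep, shallow)) >= 8
        assert np.mean(deep) - np.mean(shallow) > 0.05

    def test_shuffled_labels_stay_near_chance(self):
        config = SyntheticConfig(n_subjects=4, segments_per_class_per_subject=15, seed=0)
        segments = generate_dataset(config)
        labels = np.random.default_rng(0).permutation([s.label for s in segments])
        for seg, label in zip(segments, labels):
            seg.label = label
        res = wavelet_level_search(segments, ["haar"], "kfold:10", levels=(1, 4), seed=0)
        n = len(segments)
        half = 2.576 * np.sqrt(0.25 / n)
        assert abs(res.entries.accuracy.max() - 0.5) < half


class TestBandFeatureSearch:
    def test_exhaustive_over_restricted_candidates(self, small_dataset):
        res = band_feature_search(
            small_dataset, "haar", 3, "loso",
            candidate_bands=[1, 2], candidate_features=["STD", "Energy"],
        )
        assert len(res.entries) == 9  # (2^2-1) x (2^2-1)
        subsets = set(map(tuple, zip(res.entries.bands, res.entries.features)))
        assert ((1,), ("STD",)) in subsets
        assert ((1, 2), ("STD", "Energy")) in subsets

    def test_winner_dominates_every_entry(self, small_dataset):
        res = band_feature_search(
            small_dataset, "haar", 3, "loso",
            candidate_bands=[1, 2, 3], candidate_features=["Mean", "Energy"],
        )
        assert res.best_metrics.accuracy == res.entries.accuracy.max()

    def test_winner_at_least_as_good_as_full_combination(self, small_dataset):
        res = band_feature_search(
            small_dataset, "db2", 2, "loso",
            candidate_features=["Max", "Min", "Energy"],
        )
        full = res.entries[
            (res.entries.bands.map(len) == 3) & (res.entries.features.map(len) == 3)
        ]
        assert len(full) == 1
        assert res.best_metrics.accuracy >= float(full.accuracy.iloc[0])

    def test_determinism_across_runs(self, small_dataset):
        kw = dict(candidate_bands=[1, 2], candidate_features=["STD", "Energy"])
        a = band_feature_search(small_dataset, "haar", 2, "loso", seed=5, **kw)
        b = band_feature_search(small_dataset, "haar", 2, "loso", seed=5, **kw)
        assert a.best_bands == b.best_bands
        assert a.best_features == b.best_features
        assert a.best_metrics == b.best_metrics

    def test_reported_reduction_matches_formula(self, small_dataset):
        res = band_feature_search(
            small_dataset, "haar", 3, "loso",
            candidate_bands=[1, 2], candidate_features=["STD", "Energy"],
        )
        assert res.dimensionality_reduction == dimensionality_reduction(
            3, len(res.best_bands), len(res.best_features)
        )

    def test_empty_candidates_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            band_feature_search(small_dataset, "haar", 2, "loso", candidate_features=[])
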