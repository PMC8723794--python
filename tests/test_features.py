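"""Feature statistics, registry contracts and CFS selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata, spearmanr

import rehabfuse as rf
from rehabfuse.features import (FeatureRegistry, cfs_merit, cfs_select,
                                cross_correlation_features, extract_recording,
                                series_features)
from rehabfuse.signal import TimeSeries

FS = 51.2


def _ts(values):
    return TimeSeries(np.asarray(values, float), FS)


class TestSeriesFeatures:
    def test_constant_series_conventions(self):
        f = series_features(_ts(np.full(64, 2.5)))
        assert f["min"] == f["max"] == f["mean"] == 2.5
        assert f["rms"] == 2.5
        assert f["skewness"] == f["kurtosis"] == f["entropy"] == 0.0
        assert f["domfreq_ratio"] == 0.0

    def test_sinusoid_dominant_frequency(self):
        t = np.arange(512) / FS
        f = series_features(_ts(np.sin(2 * np.pi * 4.0 * t)))
        assert f["domfreq_ratio"] >= 0.9

    def test_uniform_histogram_entropy_is_4_bits(self):
        # samples filling the 16 bins uniformly: entropy = log2(16) = 4
        x = np.repeat(np.arange(16), 8) + 0.5
        f = series_features(_ts(x), entropy_bins=16)
        assert f["entropy"] == pytest.approx(4.0, abs=1e-9)

    def test_skew_kurtosis_match_scipy(self, rng):
        from scipy.stats import kurtosis, skew
        x = rng.gamma(2.0, size=256)
        f = series_features(_ts(x))
        assert f["skewness"] == pytest.approx(skew(x), abs=1e-9)
        assert f["kurtosis"] == pytest.approx(kurtosis(x), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            series_features(_ts(np.zeros(7)))


class TestSpearmanFeatures:
    def test_identical_pair_is_one(self, rng):
        x = rng.normal(size=50)
        f = cross_correlation_features({"a": x, "b": x.copy()})
        assert f["spearman_a_b"] == pytest.approx(1.0)

    def test_opposite_monotone_is_minus_one(self):
        f = cross_correlation_features({"a": np.arange(20.0),
                                        "b": np.arange(20.0)[::-1]})
        assert f["spearman_a_b"] == pytest.approx(-1.0)

    def test_ties_match_brute_force_rank_pearson(self, rng):
        # oracle: average-rank transform then plain Pearson correlation
        a = rng.integers(0, 5, size=60).astype(float)
        b = rng.integers(0, 5, size=60).astype(float)
        f = cross_correlation_features({"a": a, "b": b})
        brute = pearsonr(rankdata(a), rankdata(b)).statistic
        assert f["spearman_a_b"] == pytest.approx(brute, abs=1e-12)
        assert f["spearman_a_b"] == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)

    def test_pair_count(self, rng):
        series = {s: rng.normal(size=30) for s in "abcde"}
        assert len(cross_correlation_features(series)) == 10


class TestExtractRecording:
    def test_reaching_vector_matches_registry_count(self, tiny_dataset):
        reg = FeatureRegistry()
        key = next(k for k in tiny_dataset.recordings if k[2] == "hand_to_table")
        feats = extract_recording(tiny_dataset.recordings[key], reg)
        assert len(feats) == reg.feature_count("reaching")

    def test_manipulation_vector_matches_registry_count(self, tiny_dataset):
        reg = FeatureRegistry()
        key = next(k for k in tiny_dataset.recordings if k[2] == "lift_can")
        feats = extract_recording(tiny_dataset.recordings[key], reg)
        assert len(feats) == reg.feature_count("manipulation")
        assert reg.feature_count("manipulation") == 3 * reg.block_count() + 3

    def test_extraction_deterministic(self, tiny_dataset):
        key = next(iter(tiny_dataset.recordings))
        rec = tiny_dataset.recordings[key]
        f1 = extract_recording(rec)
        f2 = extract_recording(rec)
        assert f1 == f2

    def test_all_features_finite_across_seeds(self):
        # degenerate segments must never produce NaN/inf features
        cfg = rf.CohortConfig(n_subjects=1)
        reg = FeatureRegistry()
        for seed in range(25):
            subj = rf.generate_cohort(cfg, seed=seed)[0]
            for task in ("hand_to_table", "lift_pencil"):
                rec = rf.simulate_recording(subj, task, 1, "post", seed=seed)
                feats = extract_recording(rec, reg)
                assert all(np.isfinite(v) for v in feats.values())


def _random_cfs_instance(rng, n=60, p=10, informative=0):
    X = rng.normal(size=(n, p))
    y = X[:, informative] + 0.05 * rng.normal(size=n)
    return X, y


class TestCfs:
    def test_single_informative_feature_selected(self, rng):
        # one feature with |r| ~ 1, others independent noise: exhaustive
        # search and best-first both pick exactly that feature
        X, y = _random_cfs_instance(rng)
        ex = cfs_select(X, y, search="exhaustive")
        bf = cfs_select(X, y)
        assert ex.subset == ["f0"]
        assert bf.subset == ["f0"]

    def test_duplicated_feature_not_selected_twice(self, rng):
        X, y = _random_cfs_instance(rng, p=6)
        X = np.column_stack([X, X[:, 0]])   # exact duplicate of the signal
        res = cfs_select(X, y, search="exhaustive")
        assert sum(s in ("f0", "f6") for s in res.subset) == 1

    def test_merit_at_k1_is_abs_correlation(self, rng):
        X, y = _random_cfs_instance(rng, p=3)
        r_cf = np.array([abs(pearsonr(X[:, j], y).statistic) for j in range(3)])
        m = cfs_merit(r_cf, np.eye(3), [1])
        assert m == pytest.approx(r_cf[1])

    def test_best_first_near_exhaustive(self, rng):
        # best-first merit >= 0.99 x exhaustive optimum on random instances
        for trial in range(20):
            p = int(rng.integers(4, 13))
            n = int(rng.integers(20, 60))
            X = rng.normal(size=(n, p))
            w = rng.normal(size=p) * (rng.random(p) < 0.5)
            y = X @ w + rng.normal(size=n)
            if y.std() < 1e-9:
                continue
            ex = cfs_select(X, y, search="exhaustive")
            bf = cfs_select(X, y)
            assert bf.merit >= 0.99 * ex.merit

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            cfs_select(rng.normal(size=(20, 4)), np.ones(20))

    def test_dataframe_names_preserved(self, rng):
        X, y = _random_cfs_instance(rng, p=4)
        df = pd.DataFrame(X, columns=["alpha", "beta", "gamma", "delta"])
        res = cfs_select(df, y)
        assert res.subset[0] == "alpha"


class TestFeatureTables:
    def test_tables_rectangular_no_missing(self, tiny_tables):
        for task, df in tiny_tables.items():
            assert not df.isna().any().any()
            assert "target_fas" in df.columns

    def test_row_count(self, tiny_dataset, tiny_tables):
        n_subj = len(tiny_dataset.subjects)
        for df in tiny_tables.values():
            assert len(df) == n_subj * 2 * 3   # visits x repetitions
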