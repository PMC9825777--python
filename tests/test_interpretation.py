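from itertools import combinations
from math import factorial

import numpy as np
import pytest
from sklearn.ensemble import GradientBoostingClassifier

from difftf.interpret.analysis import (
    cross_factor_eval,
    jaccard_distance,
    pearson_signal_correlation,
    summarize_correlation_by_label,
    train_unified,
)
from difftf.interpret.attribution import (
    CompletenessError,
    attribute,
    make_reference,
    rescale_contributions,
)
from difftf.interpret.treeshap import shap_family_summary, tree_shap
from difftf.io_formats import GenomicInterval, SignalTrack
from difftf.models.cnn import BlockSpec, CnnSpec, build_cnn
from difftf.models.nn import ConvNet, Dense


def small_random_model(trial, in_channels=7, length=60):
    spec = CnnSpec(
        blocks=(BlockSpec(6, 5, 2, 0.0), BlockSpec(9, 3, 2, 0.0)),
        hidden_units=12,
        head_dropout=0.0,
    )
    model = build_cnn(spec, in_channels, length, n_classes=2)
    model.initialize(trial)
    return model


class TestAttribution:
    def test_input_equal_to_reference_gives_zero(self, rng):
        model = small_random_model(0)
        x = rng.normal(size=(7, 60))
        contrib, delta = rescale_contributions(model, x, x.copy())
        assert delta == 0.0
        assert np.allclose(contrib, 0.0)

    def test_single_linear_layer_closed_form(self, rng):
        """For one dense layer the contribution is weight * (input - ref)."""
        layer = Dense(5, 1)
        layer.initialize(rng)
        model = ConvNet([layer], n_outputs=1)
        x = rng.normal(size=5)
        ref = rng.normal(size=5)
        contrib, delta = rescale_contributions(model, x, ref)
        expected = layer.W[0] * (x - ref)
        assert np.allclose(contrib, expected)
        assert delta == pytest.approx(expected.sum())

    @pytest.mark.parametrize("trial", range(5))
    @pytest.mark.parametrize("kind", ["sequence_zeroed", "chromatin_zeroed"])
    def test_completeness_on_random_networks(self, trial, kind, rng):
        model = small_random_model(trial)
        x = rng.normal(size=(60, 7))
        profile = attribute(model, x, kind, tol=1e-4)
        assert profile.completeness_gap < 1e-4
        assert profile.contributions.shape == (60,)
        assert np.all(np.isfinite(profile.contributions))

    def test_reference_construction(self, rng):
        x = rng.normal(size=(10, 7))
        seq_ref = make_reference(x, "sequence_zeroed")
        chrom_ref = make_reference(x, "chromatin_zeroed")
        assert np.all(seq_ref[:, :4] == 0) and np.all(seq_ref[:, 4:] == x[:, 4:])
        assert np.all(chrom_ref[:, 4:] == 0) and np.all(chrom_ref[:, :4] == x[:, :4])

    def test_unknown_reference_kind(self, rng):
        model = small_random_model(0)
        with pytest.raises(ValueError, match="reference_kind"):
            attribute(model, rng.normal(size=(60, 7)), "bogus")

    def test_channel_mismatch(self, rng):
        model = small_random_model(0)
        with pytest.raises(ValueError, match="channels"):
            attribute(model, rng.normal(size=(60, 5)), "sequence_zeroed")


def expvalue(tree, x, S):
    """Oracle: conditional expectation by cover-weighted tree traversal."""

    def rec(node):
        if tree.children_left[node] < 0:
            return tree.value[node, 0, 0]
        f = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if f in S:
            return rec(left if x[f] <= tree.threshold[node] else right)
        w = tree.weighted_n_node_samples
        return (w[left] * rec(left) + w[right] * rec(right)) / w[node]

    return rec(0)


def brute_force_shap(model, x):
    """Oracle: exhaustive Shapley enumeration over all feature coalitions."""
    d = x.shape[0]
    phi = np.zeros(d)
    for tree in (e.tree_ for e in model.estimators_[:, 0]):
        for i in range(d):
            others = [j for j in range(d) if j != i]
            for size in range(d):
                for S in combinations(others, size):
                    w = factorial(size) * factorial(d - size - 1) / factorial(d)
                    phi[i] += model.learning_rate * w * (
                        expvalue(tree, x, set(S) | {i}) - expvalue(tree, x, set(S))
                    )
    return phi


class TestTreeShap:
    @pytest.fixture(scope="class")
    @staticmethod
    def toy_model():
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] * X[:, 2] > 0).astype(int)
        model = GradientBoostingClassifier(
            n_estimators=12, max_depth=3, random_state=0
        )
        model.fit(X, y)
        return model, X

    def test_depth_one_stump_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = (X[:, 1] > 0).astype(int)
        model = GradientBoostingClassifier(
            n_estimators=1, max_depth=1, learning_rate=1.0, random_state=0
        )
        model.fit(X, y)
        expl = tree_shap(model, X[:10])
        # only the split feature receives credit
        assert np.allclose(expl.values[:, 0], 0)
        assert np.allclose(expl.values[:, 2], 0)
        margins = model.decision_function(X[:10])
        assert np.allclose(expl.base_value + expl.values[:, 1], margins)

    def test_matches_brute_force_enumeration(self, toy_model):
        model, X = toy_model
        expl = tree_shap(model, X[:6])
        for i in range(6):
            assert np.allclose(expl.values[i], brute_force_shap(model, X[i]),
                               atol=1e-9)

    def test_additivity(self, toy_model):
        model, X = toy_model
        expl = tree_shap(model, X[:20])
        assert np.allclose(expl.margins(), model.decision_function(X[:20]),
                           atol=1e-6)

    def test_out_of_range_row_still_valid(self, toy_model):
        model, X = toy_model
        far = np.full((1, 4), 1e6)
        expl = tree_shap(model, far)
        assert np.allclose(
            expl.margins(), model.decision_function(far), atol=1e-6
        )


class TestShapFamilySummary:
    NAMES = ["motif.a", "motif.b", "chrom.c", "hic.d"]

    def test_all_zero(self):
        out = shap_family_summary(np.zeros((4, 4)), self.NAMES,
                                  np.array([0, 0, 1, 1]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_planted_importance_ranks_first(self, rng):
        values = rng.normal(0, 0.01, (50, 4))
        values[:, 2] = rng.normal(0, 5.0, 50)  # chrom.c carries the signal
        out = shap_family_summary(values, self.NAMES, np.zeros(50, dtype=int))
        assert out.columns[0] == "chrom"

    def test_family_means_partition_overall_mean(self, rng):
        values = rng.normal(size=(30, 4))
        out = shap_family_summary(values, self.NAMES, np.zeros(30, dtype=int))
        widths = {"motif": 2, "chrom": 1, "hic": 1}
        weighted = sum(out.loc[0, f] * w for f, w in widths.items()) / 4
        assert weighted == pytest.approx(np.abs(values).mean())

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            shap_family_summary(np.zeros((1, 1)), ["wat.x"], np.zeros(1))


class TestPearsonCorrelation:
    def make_track(self, values, cell="A"):
        records = [("chr1", i, i + 1, float(v)) for i, v in enumerate(values)]
        return SignalTrack.from_records(cell, "DNase", records)

    def test_identical_tracks(self, rng):
        vals = rng.random(20) + 0.5
        track = self.make_track(vals)
        peaks = [GenomicInterval("chr1", 0, 20)]
        r = pearson_signal_correlation(peaks, track, self.make_track(vals, "B"))
        assert r[0] == pytest.approx(1.0)

    def test_negated_track(self, rng):
        vals = rng.random(20)
        flipped = vals.max() - vals
        r = pearson_signal_correlation(
            [GenomicInterval("chr1", 0, 20)],
            self.make_track(vals), self.make_track(flipped, "B"),
        )
        assert r[0] == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        r = pearson_signal_correlation(
            [GenomicInterval("chr1", 0, 10)],
            self.make_track(np.ones(10)), self.make_track(np.arange(10.0), "B"),
        )
        assert np.isnan(r[0])

    def test_shared_peaks_correlate_higher_than_specific(self, bundle_default):
        b = bundle_default
        r = pearson_signal_correlation(
            b.peaks, b.tracks[("cellA", "DNase")], b.tracks[("cellB", "DNase")]
        )
        summary = summarize_correlation_by_label(
            r, [l.value for l in b.labels]
        )
        assert summary["SHARED"] > summary["A_SPECIFIC"]
        assert summary["SHARED"] > summary["B_SPECIFIC"]
        assert summary["SHARED"] > 0.5


class TestJaccardDistance:
    def test_identical_sets(self):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 5, 50)]
        assert jaccard_distance(ivs, list(ivs)) == 0.0

    def test_disjoint_sets(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300)]
        assert jaccard_distance(a, b) == 1.0

    def test_half_overlap(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        assert jaccard_distance(a, b) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard_distance([], [])

    def test_symmetry_and_triangle_inequality(self, rng):
        sets = []
        for _ in range(4):
            sets.append([
                GenomicInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 900, 10), rng.integers(20, 80, 10))
            ])
        for a in sets:
            for b in sets:
                assert jaccard_distance(a, b) == pytest.approx(
                    jaccard_distance(b, a)
                )
        for a in sets:
            for b in sets:
                for c in sets:
                    assert jaccard_distance(a, c) <= (
                        jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12
                    )


def _factor_dataset(rng, n=150, flip=False):
    """A toy 'factor': one informative feature separating class 1."""
    X = rng.normal(size=(n, 5))
    y = rng.integers(0, 2, n)
    signal = np.where(y == 1, 2.0, -2.0)
    X[:, 0] += -signal if flip else signal
    return X, y


class TestCrossFactor:
    def fit_scorer(self, X, y):
        model = GradientBoostingClassifier(n_estimators=30, max_depth=2,
                                           random_state=0)
        model.fit(X, y)
        return lambda Z: model.predict_proba(Z)[:, 1]

    def test_diagonal_equals_within_factor_eval(self, rng):
        X1, y1 = _factor_dataset(rng)
        X2, y2 = _factor_dataset(rng)
        scorers = {"f1": self.fit_scorer(X1, y1), "f2": self.fit_scorer(X2, y2)}
        tests = {"f1": (X1, y1), "f2": (X2, y2)}
        report = cross_factor_eval(scorers, tests)
        from sklearn.metrics import average_precision_score

        for f in ("f1", "f2"):
            direct = average_precision_score(tests[f][1], scorers[f](tests[f][0]))
            assert report.prauc.loc[f, f] == direct

    def test_shared_pattern_transfers(self, rng):
        X1, y1 = _factor_dataset(rng)
        X2, y2 = _factor_dataset(rng)
        scorers = {"f1": self.fit_scorer(X1, y1), "f2": self.fit_scorer(X2, y2)}
        report = cross_factor_eval(scorers, {"f1": (X1, y1), "f2": (X2, y2)})
        assert report.prauc.loc["f1", "f2"] >= 0.85
        assert report.prauc.loc["f2", "f1"] >= 0.85

    def test_opposite_pattern_fails_to_transfer(self, rng):
        X1, y1 = _factor_dataset(rng)
        X2, y2 = _factor_dataset(rng, flip=True)
        scorers = {"f1": self.fit_scorer(X1, y1), "f2": self.fit_scorer(X2, y2)}
        report = cross_factor_eval(scorers, {"f1": (X1, y1), "f2": (X2, y2)})
        assert report.prauc.loc["f1", "f2"] <= 0.4

    def test_jaccard_matrices_zero_diagonal(self, rng):
        X1, y1 = _factor_dataset(rng)
        scorers = {"f1": self.fit_scorer(X1, y1)}
        peaks = {"f1": [GenomicInterval("chr1", 0, 100)]}
        report = cross_factor_eval(scorers, {"f1": (X1, y1)},
                                   specific_peaks=peaks, shared_peaks=peaks)
        assert report.jaccard_specific.loc["f1", "f1"] == 0.0

    def test_schema_mismatch_mentions_remediation(self, rng):
        X1, y1 = _factor_dataset(rng)
        model = GradientBoostingClassifier(n_estimators=5, random_state=0)
        model.fit(X1, y1)
        scorers = {"f1": lambda Z: model.predict_proba(Z)[:, 1]}
        bad = rng.normal(size=(20, 9)), rng.integers(0, 2, 20)
        with pytest.raises(ValueError, match="pooled PWM panel"):
            cross_factor_eval(scorers, {"f1": bad})


class TestTrainUnified:
    def make_datasets(self, rng, n_factors=3):
        datasets = {}
        for f in range(n_factors):
            X, y = _factor_dataset(rng, n=120)
            ids = [f"f{f}_p{i}" for i in range(120)]
            datasets[f"f{f}"] = {
                "train": (X[:80], y[:80], ids[:80]),
                "val": (X[80:100], y[80:100], ids[80:100]),
                "test": (X[100:], y[100:], ids[100:]),
            }
        return datasets

    def train_fn(self, train, val):
        model = GradientBoostingClassifier(n_estimators=30, max_depth=2,
                                           random_state=0)
        model.fit(*train)
        return model

    def score_fn(self, model, X):
        return model.predict_proba(X)[:, 1]

    def test_pooling_arithmetic(self, rng):
        datasets = self.make_datasets(rng)
        _, metrics = train_unified(datasets, "f0", self.train_fn, self.score_fn)
        assert metrics["n_train"] == 2 * 80

    def test_shared_rules_generalize(self, rng):
        datasets = self.make_datasets(rng)
        _, metrics = train_unified(datasets, "f1", self.train_fn, self.score_fn)
        assert metrics["AUC"] >= 0.85

    def test_held_out_absent(self, rng):
        with pytest.raises(ValueError, match="absent"):
            train_unified(self.make_datasets(rng), "nope",
                          self.train_fn, self.score_fn)

    def test_leakage_detected(self, rng):
        datasets = self.make_datasets(rng)
        X, y, _ = datasets["f0"]["test"]
        leaky_ids = [i for i in datasets["f1"]["train"][2][:20]]
        datasets["f0"]["test"] = (X, y, leaky_ids)
        with pytest.raises(ValueError, match="shared between"):
            train_unified(datasets, "f0", self.train_fn, self.score_fn)
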