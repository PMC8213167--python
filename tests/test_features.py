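"""Feature space construction and the selection cascade."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import autocyto as ac
from autocyto import errors
from autocyto.features import (
    FeatureTable,
    collinearity_filter,
    group_compare,
    holm_adjust,
    l1_path,
    pca_report,
    tree_report,
    variance_filter,
)


def _table(df, endpoint="endpoint"):
    return FeatureTable(df, endpoint)


def _cohort_table(rng, n=50, informative=False):
    df = pd.DataFrame({
        "f1": rng.normal(0, 1, n),
        "f2": rng.normal(0, 1, n),
        "f3": rng.normal(0, 1, n),
        "endpoint": rng.integers(0, 2, n),
    })
    if informative:
        df["f1"] += 5 * df["endpoint"]
    return _table(df)


class TestExtractFeatures:
    def _project(self):
        project = ac.Project("p")
        project.add_subject(ac.Subject("subj0", {"endpoint": "case",
                                                 "age": 55}))
        exp = project.add_experiment(
            ac.Experiment("e", ac.Panel([("A", ""), ("B", "")])))
        em = ac.EventMatrix(np.zeros((1000, 2)), ["A", "B"])
        fg = ac.FileGroup("s0", "subj0", em)
        fg.add_population(ac.Population("child", "root", np.arange(250)))
        exp.add_filegroup(fg)
        return project

    def test_fraction_of_parent(self):
        ft = ac.extract_features(self._project(), "e", ["child"])
        assert ft.data.loc["subj0", "child"] == pytest.approx(0.25)
        assert ft.data.loc["subj0", "endpoint"] == "case"

    def test_cross_method_mean(self):
        project = self._project()
        fg = project.experiments["e"].filegroups["s0"]
        fg.add_population(ac.Population("child_cls", "root", np.arange(300),
                                        source="classifier"))
        fg.add_population(ac.Population("child_clu", "root", np.arange(400),
                                        source="cluster"))
        ft = ac.extract_features(
            project, "e", ["child"],
            aliases={"child": ["child", "child_cls", "child_clu"]})
        # mean of 0.25, 0.30, 0.40
        assert ft.data.loc["subj0", "child"] == pytest.approx(
            np.mean([0.25, 0.30, 0.40]))

    def test_missing_population_recorded_as_nan_with_warning(self):
        project = self._project()
        with pytest.warns(UserWarning):
            ft = ac.extract_features(project, "e", ["ghost"])
        assert np.isnan(ft.data.loc["subj0", "ghost"])
        # complete-case modelling subset excludes the row
        assert ft.complete_cases().data.shape[0] == 0

    def test_metadata_covariates_joined(self):
        ft = ac.extract_features(self._project(), "e", ["child"],
                                 metadata_covariates=("age",))
        assert ft.data.loc["subj0", "age"] == 55


class TestCollinearityFilter:
    def test_duplicated_feature_drops_one_copy(self, rng):
        x = rng.normal(0, 1, 40)
        ft = _table(pd.DataFrame({"a": x, "b": x.copy(),
                                  "endpoint": rng.integers(0, 2, 40)}))
        out, report = collinearity_filter(ft, 0.9)
        assert len(out.feature_names) == 1
        assert report.shape[0] == 1
        assert report.rho.iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_pair_drops_one(self, rng):
        x = rng.normal(0, 1, 40)
        ft = _table(pd.DataFrame({"a": x, "b": -x,
                                  "endpoint": rng.integers(0, 2, 40)}))
        out, _ = collinearity_filter(ft, 0.9)
        assert len(out.feature_names) == 1

    def test_independent_features_untouched(self):
        # at n=50 independent features essentially never reach |rho| 0.9
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ft = _cohort_table(rng)
            out, report = collinearity_filter(ft, 0.9)
            assert out.feature_names == ft.feature_names
            assert report.empty

    def test_lower_variance_member_dropped(self, rng):
        x = rng.normal(0, 1, 60)
        # same ranks (rho = 1) but cubing stretches the extremes, so the
        # bulk of b is compressed relative to its range -> lower
        # min-max-scaled variance
        b = x ** 3
        ft = _table(pd.DataFrame({"a": x, "b": b,
                                  "endpoint": rng.integers(0, 2, 60)}))
        out, report = collinearity_filter(ft, 0.9)
        assert report.dropped.iloc[0] == "b"
        assert out.feature_names == ["a"]

    def test_order_permutation_invariance(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 50),
                           "c": rng.normal(0, 1, 50),
                           "endpoint": rng.integers(0, 2, 50)})
        survivors = set()
        for cols in itertools.permutations(["a", "b", "c"]):
            ft = _table(df[list(cols) + ["endpoint"]])
            out, _ = collinearity_filter(ft, 0.9)
            out, _ = variance_filter(out, 0.0)
            survivors.add(frozenset(out.feature_names))
        assert len(survivors) == 1


class TestVarianceFilter:
    def test_constant_feature_removed(self, rng):
        ft = _table(pd.DataFrame({"a": np.ones(30), "b": rng.normal(0, 1, 30),
                                  "endpoint": rng.integers(0, 2, 30)}))
        out, _ = variance_filter(ft)
        assert out.feature_names == ["b"]

    def test_balanced_binary_retained_at_default_floor(self):
        # scaled variance of a balanced binary feature is exactly 0.25
        b = np.tile([0.0, 1.0], 20)
        ft = _table(pd.DataFrame({"a": b,
                                  "endpoint": np.tile([0, 1], 20)}))
        out, report = variance_filter(ft)
        assert out.feature_names == ["a"]
        assert report.scaled_variance.iloc[0] == pytest.approx(0.25)

    def test_empty_table_passthrough(self):
        ft = _table(pd.DataFrame({"endpoint": [0, 1]}))
        out, report = variance_filter(ft)
        assert out.feature_names == []
        assert report.empty


class TestPcaReport:
    def test_perfectly_correlated_pair_pc1_explains_all(self, rng):
        x = rng.normal(0, 1, 40)
        ft = _table(pd.DataFrame({"a": x, "b": 2 * x + 3,
                                  "endpoint": rng.integers(0, 2, 40)}))
        rep = pca_report(ft, n_components=2)
        assert rep.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_unit_norm(self, rng):
        rep = pca_report(_cohort_table(rng), n_components=3)
        norms = np.linalg.norm(rep.loadings.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_group_difference_axis_dominates_pc1(self):
        """The feature with the strongest group effect has the largest
        |PC1| loading.  Several features carry the group axis with graded
        strength (a single-factor structure, as in a real cohort where an
        infection shifts several populations at once): the leading
        eigenvector of such a spiked correlation matrix is proportional to
        the per-feature effect correlations, so the strongest carrier tops
        the loadings."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 50
            df = pd.DataFrame({f"f{i}": rng.normal(0, 1, n)
                               for i in range(1, 7)})
            df["endpoint"] = rng.integers(0, 2, n)
            shifts = {"f1": 6.0, "f2": 1.5, "f3": 1.5, "f4": 1.5, "f5": 1.0}
            for f, b in shifts.items():
                df[f] += b * df["endpoint"]
            rep = pca_report(_table(df), n_components=2)
            hits += rep.loadings.loc["PC1"].abs().idxmax() == "f1"
        assert hits >= 18

    def test_n_components_beyond_rank_rejected(self, rng):
        with pytest.raises(errors.ParameterError):
            pca_report(_cohort_table(rng), n_components=10)


class TestL1Path:
    def test_separating_feature_persists_longest(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ft = _cohort_table(rng, informative=True)
            rep = l1_path(ft, seed=seed)
            hits += rep.ranking[0] == "f1"
            # f1 stays nonzero down to the smallest C among all features
            assert rep.persistence["f1"] == rep.persistence.min()
        assert hits >= 18

    def test_large_C_approaches_unregularised_fit(self, rng):
        ft = _cohort_table(rng, informative=True)
        from sklearn.svm import LinearSVC
        from autocyto.features import _standardise
        X = _standardise(ft.features().to_numpy(float))
        y = ft.labels().to_numpy()
        rep = l1_path(ft, C_grid=np.array([1e4]), seed=0)
        ref = LinearSVC(C=1e8, penalty="l2", loss="squared_hinge",
                        dual=False, max_iter=50000).fit(X, y)
        np.testing.assert_allclose(rep.coefficients.iloc[0].to_numpy(),
                                   ref.coef_.ravel(), rtol=0.05, atol=0.01)

    def test_all_noise_fully_regularised_to_zero(self, rng):
        ft = _cohort_table(rng, informative=False)
        rep = l1_path(ft, C_grid=np.array([1e-4]), seed=0)
        assert np.all(np.abs(rep.coefficients.to_numpy()) <= 1e-6)

    def test_single_class_endpoint_rejected(self, rng):
        df = _cohort_table(rng).data
        df["endpoint"] = 1
        with pytest.raises(errors.ModellingError):
            l1_path(_table(df))


class TestTreeReport:
    def test_non_overlapping_ranges_depth1_perfect(self):
        df = pd.DataFrame({"a": np.concatenate([np.arange(10),
                                                np.arange(20, 30)]),
                           "endpoint": np.repeat([0, 1], 10)})
        rep = tree_report(_table(df), max_depth=1)
        assert rep.root_feature == "a"
        assert 9 < rep.root_threshold < 20
        assert rep.training_accuracy == 1.0

    def test_root_split_matches_exhaustive_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (30, 3))
            y = (X[:, 1] + 0.3 * r.normal(0, 1, 30) > 0).astype(int)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            df["endpoint"] = y
            rep = tree_report(_table(df), max_depth=1)

            def gini(lbl):
                _, c = np.unique(lbl, return_counts=True)
                p = c / c.sum()
                return 1 - (p ** 2).sum()
            best_dec = -1
            for j, f in enumerate(["a", "b", "c"]):
                xs = np.sort(X[:, j])
                for cut in (xs[:-1] + xs[1:]) / 2:
                    left = X[:, j] <= cut
                    dec = gini(y) - (left.mean() * gini(y[left])
                                     + (1 - left.mean()) * gini(y[~left]))
                    best_dec = max(best_dec, dec)
            # recompute the decrease achieved by the reported split
            left = X[:, ["a", "b", "c"].index(rep.root_feature)] <= rep.root_threshold
            got = gini(y) - (left.mean() * gini(y[left])
                             + (1 - left.mean()) * gini(y[~left]))
            assert got == pytest.approx(best_dec, abs=1e-12)

    def test_depth_zero_majority_stub(self, rng):
        ft = _cohort_table(rng)
        rep = tree_report(ft, max_depth=0)
        assert rep.root_feature is None
        counts = ft.labels().value_counts(normalize=True)
        assert rep.training_accuracy == pytest.approx(counts.max())


class TestGroupCompare:
    def test_holm_worked_example(self):
        adjusted = holm_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adjusted, [0.03, 0.04, 0.04], atol=1e-12)

    def test_exact_p_small_groups_matches_enumeration(self):
        # groups {1,2,3} vs {10,11,12}: complete separation
        df = pd.DataFrame({"f": [1, 2, 3, 10, 11, 12],
                           "endpoint": [0, 0, 0, 1, 1, 1]})
        out = group_compare(_table(df))
        # oracle: all C(6,3)=20 rank arrangements; both extremes have U=0 or 9
        assert out.p.iloc[0] == pytest.approx(2 / 20)
        assert out.U.iloc[0] in (0.0, 9.0)

    def test_null_distribution_uniformish(self):
        # identical group distributions: U centred on mn/2, p roughly uniform
        pvals, us = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"f": rng.normal(0, 1, 16),
                               "endpoint": np.repeat([0, 1], 8)})
            out = group_compare(_table(df))
            pvals.append(out.p.iloc[0])
            us.append(out.U.iloc[0])
        assert np.mean(us) == pytest.approx(32.0, abs=4)  # mn/2 = 32
        assert 0.35 < np.mean(pvals) < 0.65
        assert np.mean(np.array(pvals) < 0.05) < 0.12

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"f": [1.0, 2.0], "endpoint": [0, 0]})
        with pytest.raises(errors.ModellingError):
            group_compare(_table(df))


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=12))
def test_holm_dominance_and_monotonicity(pvals):
    """Holm output >= raw p, <= Bonferroni, monotone in p-value rank."""
    raw = np.array(pvals)
    adj = holm_adjust(raw)
    m = raw.size
    bonf = np.minimum(raw * m, 1.0)
    assert np.all(adj >= raw - 1e-15)
    assert np.all(adj <= bonf + 1e-15)
    order = np.argsort(raw, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCascadeOnCohort:
    def test_elevated_population_identified(self, small_cohort):
        """End-to-end: the case-elevated population tops PC1, persists
        longest on the L1 path and is the depth-1 root split."""
        spec = ac.flagship_cohort(seed=5, events_per_sample=2000)
        samples = ac.generate_cohort(spec)
        project = ac.cohort_to_project(samples, spec)
        exp = next(iter(project.experiments.values()))
        for s in samples:
            fg = exp.filegroups[s.sample_id]
            for p in spec.populations:
                idx = np.flatnonzero(s.true_labels == p.name)
                fg.add_population(ac.Population(p.name, "root", idx,
                                                source="cluster"))
        ft = ac.extract_features(project, "panel_a",
                                 [p.name for p in spec.populations],
                                 statistics=("fraction_of_root",),
                                 metadata_covariates=("age",))
        ft, _ = collinearity_filter(ft, 0.9)
        ft, _ = variance_filter(ft, 0.02)
        rep = pca_report(ft, 2)
        path = l1_path(ft, seed=5)
        tree = tree_report(ft, 1, seed=5)
        assert rep.loadings.loc["PC1"].abs().idxmax() == "neutrophil"
        assert path.ranking[0] == "neutrophil"
        assert tree.root_feature == "neutrophil"
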