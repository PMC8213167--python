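"""Autonomous gates: threshold/ellipse fits, hulls, matching, search, strategy."""
import itertools

import numpy as np
import pytest
from scipy.stats import chi2

import autocyto as ac
from autocyto import errors
from autocyto.gating import _mfi, fit_ellipse_gate, fit_threshold_gate


# ---------------------------------------------------------------------------
# Independent oracles


def _cross2(u, v):
    """Scalar z-component of the 2-D cross product (broadcasts over rows)."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def brute_force_hull(points):
    """O(n^3) hull: a point is a vertex iff it is not strictly inside the
    hull; an edge (i, j) is on the hull iff all other points lie on one side."""
    pts = np.asarray(points, float)
    n = len(pts)
    hull_points = set()
    for i, j in itertools.combinations(range(n), 2):
        cross = _cross2(pts[j] - pts[i], pts - pts[i])
        if np.all(cross >= -1e-12) or np.all(cross <= 1e-12):
            hull_points.add(i)
            hull_points.add(j)
    # drop points strictly interior to the segment set (collinear midpoints)
    verts = []
    for k in sorted(hull_points):
        others = [p for p in hull_points if p != k]
        inside = False
        for i, j in itertools.combinations(others, 2):
            a, b, c = pts[i], pts[j], pts[k]
            if abs(_cross2(b - a, c - a)) < 1e-12 and \
                    min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12 and \
                    min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12:
                inside = True
                break
        if not inside:
            verts.append(k)
    return pts[verts]


def brute_force_hausdorff(a, b):
    da = max(min(np.linalg.norm(p - q) for q in b) for p in a)
    db = max(min(np.linalg.norm(p - q) for q in a) for p in b)
    return max(da, db)


# ---------------------------------------------------------------------------
# Threshold gates


class TestThresholdGate:
    def test_bimodal_valley_near_symmetry_point(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-2, 0.5, 500), rng.normal(2, 0.5, 500)])
        geom, children = fit_threshold_gate(x)
        t = geom.thresholds[0]
        assert -0.5 < t < 0.5  # analytic mixture density minimum is at 0
        assert abs(int(children["+"].sum()) - 500) <= 25
        assert abs(int(children["-"].sum()) - 500) <= 25

    def test_unimodal_fallback_is_quantile(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 2000)
        geom, _ = fit_threshold_gate(x, q_fallback=0.95)
        assert geom.thresholds[0] == pytest.approx(np.quantile(x, 0.95))

    def test_2d_children_partition_parent(self):
        rng = np.random.default_rng(9)
        x = np.column_stack([
            np.concatenate([rng.normal(-2, .4, 600), rng.normal(2, .4, 400)]),
            np.concatenate([rng.normal(2, .4, 500), rng.normal(-2, .4, 500)])])
        _, children = fit_threshold_gate(x)
        assert set(children) == {"++", "+-", "-+", "--"}
        total = sum(int(m.sum()) for m in children.values())
        assert total == 1000
        stacked = np.vstack([children[k] for k in children])
        assert np.all(stacked.sum(axis=0) == 1)  # exact partition

    def test_partition_property_random_inputs(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            x = rng.normal(0, 1, (rng.integers(5, 300), rng.integers(1, 3)))
            _, children = fit_threshold_gate(x)
            assert sum(int(m.sum()) for m in children.values()) == x.shape[0]

    def test_too_few_events(self):
        with pytest.raises(errors.InsufficientDataError):
            fit_threshold_gate(np.array([1.0]))


class TestEllipseGate:
    def test_chi2_coverage_of_own_component(self):
        rng = np.random.default_rng(11)
        a = rng.normal((0, 0), 1, (1000, 2))
        b = rng.normal((10, 10), 1, (1000, 2))
        geoms, masks = fit_ellipse_gate(np.vstack([a, b]), n_components=2,
                                        conf_level=0.95, seed=3)
        for g, m in zip(geoms, masks):
            own = a if np.linalg.norm(g.center) < 5 else b
            offset = 0 if own is a else 1000
            covered = m[offset:offset + 1000].mean()
            assert covered == pytest.approx(0.95, abs=0.02)

    def test_single_component_center_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.normal((3, -1), 0.8, (2000, 2))
        geoms, _ = fit_ellipse_gate(x, n_components=1, seed=0)
        se = 0.8 / np.sqrt(2000)
        assert np.all(np.abs(geoms[0].center - [3, -1]) < 3 * se * 3)

    def test_conf_level_zero_gives_empty_children(self):
        rng = np.random.default_rng(13)
        _, masks = fit_ellipse_gate(rng.normal(0, 1, (100, 2)), 1,
                                    conf_level=0.0, seed=0)
        assert all(int(m.sum()) == 0 for m in masks)

    def test_mahalanobis_cut_matches_direct_computation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, (500, 2))
        geoms, masks = fit_ellipse_gate(x, 1, conf_level=0.9, seed=0)
        g = geoms[0]
        d = x - g.center
        md2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(g.covariance), d)
        np.testing.assert_array_equal(masks[0], md2 <= chi2.ppf(0.9, 2))

    def test_insufficient_events(self):
        with pytest.raises(errors.InsufficientDataError):
            fit_ellipse_gate(np.zeros((8, 2)), n_components=2)


# ---------------------------------------------------------------------------
# Hull and Hausdorff


class TestHull:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        hull = ac.population_hull(square)
        assert set(map(tuple, hull)) == set(map(tuple, square))

    def test_interior_points_ignored(self, rng):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        pts = np.vstack([square, rng.uniform(0.2, 0.8, (50, 2))])
        hull = ac.population_hull(pts)
        assert set(map(tuple, hull)) == set(map(tuple, square))

    def test_ccw_orientation(self, rng):
        hull = ac.population_hull(rng.normal(0, 1, (30, 2)))
        # shoelace area positive for counter-clockwise rings
        x, y = hull[:, 0], hull[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            pts = rng.normal(0, 1, (50, 2))
            fast = set(map(tuple, np.round(ac.population_hull(pts), 9)))
            slow = set(map(tuple, np.round(brute_force_hull(pts), 9)))
            assert fast == slow

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(errors.DegenerateHullError):
            ac.population_hull(pts)


class TestHausdorff:
    def test_identical_hulls_zero(self):
        h = np.array([[0, 0], [1, 0], [1, 1]], float)
        assert ac.hausdorff(h, h) == 0.0

    def test_translated_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert ac.hausdorff(sq, sq + [3, 0]) == pytest.approx(3.0)

    def test_symmetry_and_oracle_on_random_hulls(self, rng):
        for _ in range(5):
            a = ac.population_hull(rng.normal(0, 1, (20, 2)))
            b = ac.population_hull(rng.normal(1, 2, (20, 2)))
            d1, d2 = ac.hausdorff(a, b), ac.hausdorff(b, a)
            assert d1 == d2
            assert d1 == pytest.approx(brute_force_hausdorff(a, b))


# ---------------------------------------------------------------------------
# Matching


class TestMatchPopulations:
    def test_self_match_identity_zero(self):
        refs = [("a", np.array([0.0, 0.0])), ("b", np.array([5.0, 5.0]))]
        cands = [("ca", np.array([0.0, 0.0])), ("cb", np.array([5.0, 5.0]))]
        assignment, scores = ac.match_populations(cands, refs, "mfi")
        assert assignment == {"a": "ca", "b": "cb"}
        assert sum(scores.values()) == 0.0

    def test_nearest_mfi_wins(self):
        refs = [("r", np.array([2.0, 2.0]))]
        cands = [("near", np.array([2.1, 2.0])), ("far", np.array([5.0, 5.0]))]
        assignment, _ = ac.match_populations(cands, refs, "mfi")
        assert assignment["r"] == "near"

    def test_assignment_matches_exhaustive_minimum(self, rng):
        """Greedy matching equals brute force over all injective assignments
        on instances where greedy is optimal (well-separated candidates)."""
        for _ in range(10):
            refs = [(f"r{i}", rng.normal(i * 10, 0.5, 2)) for i in range(3)]
            cands = [(f"c{i}", rng.normal(i * 10, 0.5, 2)) for i in range(3)]
            assignment, scores = ac.match_populations(cands, refs, "mfi")
            best, best_total = None, np.inf
            for perm in itertools.permutations(range(3)):
                total = sum(np.linalg.norm(refs[i][1] - cands[perm[i]][1])
                            for i in range(3))
                if total < best_total:
                    best_total, best = total, {refs[i][0]: cands[perm[i]][0]
                                               for i in range(3)}
            assert assignment == best
            assert sum(scores.values()) == pytest.approx(best_total)

    def test_no_candidates_is_error(self):
        with pytest.raises(errors.NotFoundError):
            ac.match_populations([], [("r", np.zeros(2))])


# ---------------------------------------------------------------------------
# Hyperparameter search


def _bimodal(seed, n=800, sep=2.0, sd=0.4):
    rng = np.random.default_rng(seed)
    return np.concatenate([rng.normal(-sep, sd, n // 2),
                           rng.normal(sep, sd, n // 2)])


class TestHyperparameterSearch:
    def _fitted_gate(self, grid=None):
        gate = ac.Gate("g", "root", ["A"], "threshold",
                       hyperparameter_grid=grid,
                       children={"+": "pos", "-": "neg"})
        gate.fit(_bimodal(0))
        return gate

    def test_grid_of_size_one_equals_plain_fit(self):
        gate = self._fitted_gate(grid={"bandwidth": [None]})
        data = _bimodal(1)
        plain = gate.apply(data, search=False)
        searched = ac.hyperparameter_search(gate, data)
        for name in plain:
            assert np.array_equal(plain[name][0], searched[name][0])

    def test_bandwidth_grid_picks_resolving_bandwidth(self):
        """Only a small bandwidth resolves two close modes; the oracle
        evaluates each grid fit by hand and the search must agree."""
        gate = ac.Gate("g", "root", ["A"], "threshold",
                       hyperparameter_grid={"bandwidth": [0.1, 0.5, 2.0]},
                       children={"+": "pos", "-": "neg"})
        train = _bimodal(2, sep=1.0, sd=0.25)
        gate.fit(train)
        data = _bimodal(3, sep=1.0, sd=0.25)
        result = gate.apply(data, search=True)
        # oracle: evaluate all three fits, choose min MFI distance per ref
        refs = {r["name"]: r["mfi"] for r in gate.references}
        best = {}
        for gi, bw in enumerate([0.1, 0.5, 2.0]):
            _, children = fit_threshold_gate(data, bandwidth=bw)
            for sign, name in [("+", "pos"), ("-", "neg")]:
                if children[sign].sum() == 0:
                    continue
                d = np.linalg.norm(_mfi(data[children[sign], None])
                                   - refs[name])
                if name not in best or d < best[name][0]:
                    best[name] = (d, np.flatnonzero(children[sign]))
        for name in ("pos", "neg"):
            assert np.array_equal(result[name][0], best[name][1])

    def test_tie_break_lowest_grid_index(self):
        # identical grid values produce identical fits; the first must win
        gate = self._fitted_gate(grid={"bandwidth": [0.5, 0.5]})
        data = _bimodal(4)
        r1 = gate.apply(data, search=True)
        r2 = gate.apply(data, search=True)
        for name in r1:
            assert np.array_equal(r1[name][0], r2[name][0])

    def test_grid_cap_exceeded(self):
        gate = ac.Gate("g", "root", ["A"], "threshold",
                       hyperparameter_grid={"bandwidth": list(range(600))})
        gate.fitted = True
        gate.references = [{"name": "pos", "sign": "+",
                            "mfi": np.zeros(1), "hull": None,
                            "geometry": None}]
        with pytest.raises(errors.ConfigurationError) as e:
            gate.apply(_bimodal(5), search=True)
        assert "600" in str(e.value)


# ---------------------------------------------------------------------------
# Strategy application


class TestGatingStrategy:
    def _strategy_and_fg(self, seed=0):
        rng = np.random.default_rng(seed)
        a = np.concatenate([rng.normal(-2, .4, 400), rng.normal(2, .4, 600)])
        b = np.where(a > 0,
                     rng.normal(np.where(rng.random(1000) < 0.5, -2, 2), .4),
                     rng.normal(0, .4, 1000))
        em = ac.EventMatrix(np.column_stack([a, b]), ["A", "B"])
        fg = ac.FileGroup("s", "subj", em)
        strat = ac.GatingStrategy("demo")
        strat.add_gate(ac.Gate("g1", "root", ["A"], "threshold",
                               children={"+": "high", "-": "low"}))
        strat.add_gate(ac.Gate("g2", "high", ["B"], "threshold",
                               children={"+": "highB", "-": "lowB"}))
        return strat, fg

    def test_self_application_reproduces_definition(self):
        strat, fg = self._strategy_and_fg()
        strat.fit(fg, seed=1)
        snapshot = {n: p.index.copy() for n, p in fg.populations.items()}
        strat.apply(fg, search=False, seed=1)
        for n, idx in snapshot.items():
            assert np.array_equal(fg.populations[n].index, idx)

    def test_children_contained_in_parents(self):
        strat, fg = self._strategy_and_fg()
        strat.fit(fg, seed=1)
        for pop in fg.populations.values():
            if pop.parent:
                parent = fg.populations[pop.parent]
                assert np.isin(pop.index, parent.index).all()

    def test_missing_channel_is_schema_error(self):
        strat, fg = self._strategy_and_fg()
        strat.fit(fg, seed=1)
        em = ac.EventMatrix(np.random.default_rng(0).normal(0, 1, (100, 2)),
                            ["A", "C"])
        with pytest.raises(errors.SchemaError):
            strat.apply(ac.FileGroup("s2", None, em))

    def test_unfitted_strategy_rejected(self):
        strat, fg = self._strategy_and_fg()
        with pytest.raises(errors.ConfigurationError):
            strat.apply(fg)

    def test_gate_with_unknown_parent_rejected_at_stack_time(self):
        strat = ac.GatingStrategy("s")
        with pytest.raises(errors.ConfigurationError):
            strat.add_gate(ac.Gate("g", "ghost", ["A"], "threshold"))

    def test_strategy_serialization_round_trip(self):
        strat, fg = self._strategy_and_fg()
        strat.fit(fg, seed=1)
        doc = strat.to_document()
        loaded = ac.GatingStrategy.from_document(doc)
        fg2 = ac.FileGroup("s2", None, fg.primary.copy())
        loaded.apply(fg2, seed=1)
        for name in ("high", "low", "highB", "lowB"):
            assert name in fg2.populations

    def test_deterministic_given_seed(self):
        strat, fg = self._strategy_and_fg()
        strat.fit(fg, seed=1)
        results = []
        for _ in range(2):
            fg2 = ac.FileGroup("s2", None, fg.primary.copy())
            strat.apply(fg2, search=True, register_landmarks=True, seed=9)
            results.append({n: p.index.copy()
                            for n, p in fg2.populations.items()})
        assert set(results[0]) == set(results[1])
        for n in results[0]:
            assert np.array_equal(results[0][n], results[1][n])


class TestEllipseGateInStrategy:
    def test_named_components_by_prototype(self):
        rng = np.random.default_rng(21)
        x = np.vstack([rng.normal((0, 0), .5, (300, 2)),
                       rng.normal((6, 6), .5, (300, 2))])
        gate = ac.Gate("e", "root", ["A", "B"], "ellipse",
                       hyperparameters={"n_components": 2},
                       children={"low": (0.0, 0.0), "high": (6.0, 6.0)})
        result = gate.fit(x, seed=0)
        assert set(result) == {"low", "high"}
        low_members = x[result["low"]]
        assert np.linalg.norm(low_members.mean(axis=0)) < 1.0

    def test_application_matches_by_hull(self):
        rng = np.random.default_rng(22)
        def draw(seed):
            r = np.random.default_rng(seed)
            return np.vstack([r.normal((0, 0), .5, (300, 2)),
                              r.normal((6, 6), .5, (300, 2))])
        gate = ac.Gate("e", "root", ["A", "B"], "ellipse",
                       hyperparameters={"n_components": 2},
                       children={"low": (0.0, 0.0), "high": (6.0, 6.0)})
        gate.fit(draw(1), seed=0)
        data = draw(2)
        result = gate.apply(data, seed=0)
        assert np.linalg.norm(data[result["low"][0]].mean(axis=0)) < 1.0
        assert np.linalg.norm(data[result["high"][0]].mean(axis=0) - 6) < 1.0
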