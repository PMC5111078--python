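"""Coordinate prediction: distances, fixed points, mixtures, accuracy scoring."""

import math

import numpy as np
import pytest

import biogps as bg
from biogps.gps import _move_toward


class TestAdmixtureDistance:
    def test_identical_vectors_zero(self):
        assert bg.admixture_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_opposite_corners_sqrt_two(self):
        assert bg.admixture_distance([1, 0], [0, 1]) == pytest.approx(math.sqrt(2))

    def test_closed_form_quarter_shift(self):
        d = bg.admixture_distance([0.5, 0.5], [0.25, 0.75])
        assert d == pytest.approx(math.sqrt(0.125))

    def test_k_mismatch_raises(self):
        with pytest.raises(bg.ShapeError):
            bg.admixture_distance([1, 0], [1, 0, 0])


class TestGreatCircle:
    def test_zero_at_same_point(self):
        assert bg.great_circle_km((12.5, 40.0), (12.5, 40.0)) == 0.0

    @pytest.mark.parametrize("a,b", [((0, 0), (0, 180)), ((90, 0), (-90, 0))])
    def test_antipodal_half_circumference(self, a, b):
        assert bg.great_circle_km(a, b) == pytest.approx(math.pi * bg.EARTH_RADIUS_KM, rel=1e-6)

    def test_symmetry_and_triangle_inequality(self, rng):
        pts = [(float(rng.uniform(-80, 80)), float(rng.uniform(-170, 170))) for _ in range(12)]
        for a in pts:
            for b in pts:
                dab = bg.great_circle_km(a, b)
                assert dab == pytest.approx(bg.great_circle_km(b, a))
                for c in pts:
                    assert dab <= bg.great_circle_km(a, c) + bg.great_circle_km(c, b) + 1e-6

    @pytest.mark.parametrize("bad", [(95, 0), (-91, 10), (0, 181), (0, -200)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(bg.DomainError):
            bg.great_circle_km(bad, (0, 0))


class TestGpsPredict:
    def test_centroid_exact_match_fixed_point(self, small_world):
        for pop in small_world.panel:
            r = bg.gps_predict(pop.centroid, small_world.panel)
            assert bg.great_circle_km(r.coordinate, pop.location) < 1e-9
            assert r.best_match == pop.label

    def test_small_panel_uses_all_and_flags(self, small_world):
        panel = small_world.panel[:3]
        r = bg.gps_predict(panel[0].members[0], panel, M=10)
        assert len(r.nearest) == 3
        assert "fewer_than_M" in r.flags

    def test_empty_panel_rejected(self):
        with pytest.raises(bg.InputError):
            bg.gps_predict([1.0], [])

    def test_k_mismatch_rejected(self, small_world):
        with pytest.raises(bg.ShapeError):
            bg.gps_predict([0.5, 0.5], small_world.panel)

    def test_fifty_fifty_mixture_lands_near_geographic_midpoint(self, small_world):
        # mutually nearest pair in admixture space
        panel = small_world.panel
        pairs = [
            (bg.admixture_distance(a.centroid, b.centroid), i, j)
            for i, a in enumerate(panel)
            for j, b in enumerate(panel)
            if i < j
        ]
        _, i, j = min(pairs)
        a, b = panel[i], panel[j]
        q = bg.make_admixed_individual(a.centroid, b.centroid, 0.5)
        q /= q.sum()
        r = bg.gps_predict(q, panel)
        ab = bg.great_circle_km(a.location, b.location)
        mid = _move_toward(a.location, b.location, ab / 2)
        assert bg.great_circle_km(r.coordinate, mid) <= 0.15 * ab

    def test_panel_order_invariance(self, small_world, rng):
        q = bg.make_admixed_individual(
            small_world.panel[0].centroid, small_world.panel[5].centroid, 0.3
        )
        q /= q.sum()
        shuffled = list(small_world.panel)
        rng.shuffle(shuffled)
        r1 = bg.gps_predict(q, small_world.panel)
        r2 = bg.gps_predict(q, shuffled)
        assert r1.coordinate == r2.coordinate
        assert r1.nearest == r2.nearest

    def test_continuity_under_small_perturbation(self, small_world):
        panel = small_world.panel
        q = bg.make_admixed_individual(panel[2].centroid, panel[3].centroid, 0.4)
        q /= q.sum()
        base = bg.gps_predict(q, panel).coordinate
        delta = 1e-4
        v = np.zeros_like(q)
        v[0], v[1] = delta, -delta
        moved = bg.gps_predict((q + v) / (q + v).sum(), panel).coordinate
        assert bg.great_circle_km(base, moved) < 50.0

    def test_interpolation_monotone_in_mixing_fraction(self, small_world):
        panel = small_world.panel
        pairs = [
            (bg.admixture_distance(a.centroid, b.centroid), i, j)
            for i, a in enumerate(panel)
            for j, b in enumerate(panel)
            if i < j
        ]
        _, i, j = min(pairs)
        a, b = panel[i], panel[j]
        dist_to_b = []
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            q = bg.make_admixed_individual(a.centroid, b.centroid, lam)
            q /= q.sum()
            r = bg.gps_predict(q, panel)
            dist_to_b.append(bg.great_circle_km(r.coordinate, b.location))
        assert dist_to_b == sorted(dist_to_b)  # larger lam => closer to a, farther from b


class TestGeographicPositioningEstimator:
    def test_fit_from_member_arrays(self, small_world):
        X = np.vstack([p.members for p in small_world.panel])
        y = np.vstack([[p.location] * p.n_members for p in small_world.panel])
        pops = [p.name for p in small_world.panel for _ in range(p.n_members)]
        eng = bg.GeographicPositioning().fit(X, y, populations=pops)
        assert len(eng.panel_) == len(small_world.panel)
        pred = eng.predict([small_world.panel[0].centroid])
        assert pred.shape == (1, 2)

    def test_unfitted_predict_raises(self):
        with pytest.raises(bg.InputError):
            bg.GeographicPositioning().predict([[1.0]])

    def test_sklearn_params_roundtrip(self):
        eng = bg.GeographicPositioning(n_neighbors=5, weight_power=2.0)
        assert bg.GeographicPositioning(**eng.get_params()).n_neighbors == 5


class TestAssignmentAccuracy:
    def _result(self, ind, coord):
        return bg.PredictionResult(ind, coord, [], "")

    def test_perfect_predictions_score_one(self):
        oracle = bg.SiteRegionOracle({"R": [(10.0, 10.0)]})
        preds = [self._result("a", (10.0, 10.0))]
        acc = bg.assignment_accuracy(preds, {"a": "R"}, oracle, [250, 500])
        assert acc == {250.0: 1.0, 500.0: 1.0}

    def test_threshold_semantics_at_300_km(self):
        # ~300 km north of the region's single site
        oracle = bg.SiteRegionOracle({"R": [(10.0, 10.0)]})
        coord = (10.0 + 300.0 / 111.19, 10.0)
        acc = bg.assignment_accuracy([self._result("a", coord)], {"a": "R"}, oracle, [250, 500])
        assert acc[250.0] == 0.0
        assert acc[500.0] == 1.0

    def test_accuracy_monotone_in_threshold(self, small_world):
        eng = bg.GeographicPositioning().fit_panel(small_world.panel)
        results = []
        for pop in small_world.panel:
            results.extend(eng.predict_result(pop.members, ids=pop.member_ids))
        acc = bg.assignment_accuracy(
            results, small_world.truth_regions(), small_world.oracle(), [250, 500]
        )
        assert acc[500.0] >= acc[250.0]

    def test_unknown_region_rejected(self):
        oracle = bg.SiteRegionOracle({"R": [(0.0, 0.0)]})
        with pytest.raises(bg.InputError):
            bg.assignment_accuracy([self._result("a", (0, 0))], {"a": "nope"}, oracle)
        with pytest.raises(bg.InputError):
            bg.assignment_accuracy([self._result("a", (0, 0))], {}, oracle)
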