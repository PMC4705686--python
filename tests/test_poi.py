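import json
import math

import numpy as np
import pytest

from genesetcontext import (
    CutoffSpec,
    FormulaPOI,
    IntervalPOI,
    PolygonPOI,
    UnionIntervalPOI,
    ValidationError,
    default_poi,
    load_poi,
    match_samples,
    resolve_cutoff,
    save_poi,
)
from genesetcontext._errors import FormulaError

from conftest import make_activity, point_in_polygon_raycast, random_simple_polygon


class TestResolveCutoff:
    def setup_method(self):
        self.act = make_activity(["A"], [list(range(1, 11))])  # 1..10

    def test_raw_is_identity(self):
        assert resolve_cutoff(CutoffSpec("raw", 2.5), self.act, "A") == 2.5

    def test_sd_zero_is_the_mean(self):
        assert resolve_cutoff(CutoffSpec("sd", 0.0), self.act, "A") == pytest.approx(5.5)

    def test_sd_one_is_mean_plus_sd(self):
        sd = np.std(np.arange(1, 11), ddof=1)
        assert resolve_cutoff(CutoffSpec("sd", 1.0), self.act, "A") == pytest.approx(
            5.5 + sd
        )

    def test_quantile_linear_interpolation(self):
        assert resolve_cutoff(
            CutoffSpec("quantile", 0.9), self.act, "A"
        ) == pytest.approx(9.1)

    def test_normal_p_half_upper_is_the_mean(self):
        assert resolve_cutoff(
            CutoffSpec("normal_p", 0.5, "upper"), self.act, "A"
        ) == pytest.approx(5.5)

    def test_normal_p_tails_are_symmetric(self):
        up = resolve_cutoff(CutoffSpec("normal_p", 0.05, "upper"), self.act, "A")
        lo = resolve_cutoff(CutoffSpec("normal_p", 0.05, "lower"), self.act, "A")
        assert up > 5.5 > lo
        assert up - 5.5 == pytest.approx(5.5 - lo)

    @pytest.mark.parametrize(
        "mode,value",
        [("bogus", 0.5), ("quantile", 1.5), ("normal_p", 0.0), ("normal_p", 1.0)],
    )
    def test_invalid_specs_rejected(self, mode, value):
        with pytest.raises(ValidationError):
            CutoffSpec(mode, value)


class TestIntervalPOI:
    def test_strict_open_bounds_exclude_ties(self):
        act = make_activity(["A"], [[0.0, 1.0, 2.0]])
        poi = IntervalPOI([("A", 1.0, None)])
        np.testing.assert_array_equal(
            match_samples(poi, act), [False, False, True]
        )

    def test_conjunction_across_sets(self):
        act = make_activity(["A", "B"], [[0.0, 2.0, 2.0], [2.0, 0.0, 2.0]])
        poi = IntervalPOI([("A", 1.0, None), ("B", 1.0, None)])
        np.testing.assert_array_equal(
            match_samples(poi, act), [False, False, True]
        )

    def test_relaxing_a_cutoff_never_deselects(self):
        rng = np.random.default_rng(0)
        act = make_activity(["A", "B"], rng.normal(size=(2, 200)))
        tight = IntervalPOI([("A", 0.5, None), ("B", -0.2, 0.8)])
        loose = IntervalPOI([("A", 0.2, None), ("B", -0.5, 1.1)])
        m_tight = match_samples(tight, act)
        m_loose = match_samples(loose, act)
        assert not np.any(m_tight & ~m_loose)

    def test_empty_resolved_interval_rejected(self):
        act = make_activity(["A"], [[0.0, 1.0]])
        poi = IntervalPOI([("A", 2.0, 1.0)])
        with pytest.raises(ValidationError, match="empty"):
            match_samples(poi, act)

    def test_repeated_set_name_rejected(self):
        with pytest.raises(ValidationError, match="repeats"):
            IntervalPOI([("A", 0.0, None), ("A", 1.0, None)])


class TestDefaultPOI:
    def test_one_sided_sd_constraint_per_set(self):
        poi = default_poi(["A", "B"])
        assert len(poi.constraints) == 2
        for _, lo, hi in poi.constraints:
            assert lo == CutoffSpec("sd", 1.0, "lower")
            assert hi is None

    def test_selects_upper_tail_of_normal_activities(self):
        rng = np.random.default_rng(12)
        act = make_activity(["A"], rng.normal(size=(1, 20_000)))
        frac = match_samples(default_poi(["A"]), act).mean()
        # P(Z > 1) ~ 0.1587
        assert 0.14 < frac < 0.18

    def test_empty_set_list_rejected(self):
        with pytest.raises(ValidationError, match="at least one"):
            default_poi([])


class TestUnionIntervalPOI:
    def test_union_of_two_intervals(self):
        act = make_activity(["A"], [[-3.0, 0.0, 3.0]])
        poi = UnionIntervalPOI("A", [(None, -1.0), (1.0, None)])
        np.testing.assert_array_equal(
            match_samples(poi, act), [True, False, True]
        )

    def test_mask_equals_union_of_per_interval_masks(self):
        rng = np.random.default_rng(5)
        act = make_activity(["A"], rng.normal(size=(1, 300)))
        intervals = [(-0.5, 0.5), (1.0, 2.0)]
        combined = match_samples(UnionIntervalPOI("A", intervals), act)
        parts = [
            match_samples(UnionIntervalPOI("A", [iv]), act) for iv in intervals
        ]
        np.testing.assert_array_equal(combined, parts[0] | parts[1])


class TestPolygonPOI:
    UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]

    def test_inside_outside_and_boundary(self):
        act = make_activity(
            ["X", "Y"], [[0.5, 2.0, 0.0], [0.5, 2.0, 0.5]]
        )
        poi = PolygonPOI("X", "Y", [self.UNIT_SQUARE])
        # (0.5,0.5) inside, (2,2) outside, (0,0.5) on the boundary -> inside
        np.testing.assert_array_equal(match_samples(poi, act), [True, False, True])

    def test_mask_is_union_over_polygons(self):
        square2 = [(2.0, 2.0), (3.0, 2.0), (3.0, 3.0), (2.0, 3.0)]
        act = make_activity(["X", "Y"], [[0.5, 2.5, 5.0], [0.5, 2.5, 5.0]])
        both = PolygonPOI("X", "Y", [self.UNIT_SQUARE, square2])
        np.testing.assert_array_equal(
            match_samples(both, act), [True, True, False]
        )

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValidationError, match="degenerate|3 vertices"):
            PolygonPOI("X", "Y", [[(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]])

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0.0, 0.0), (1.0, 1.0), (1.0, 0.0), (0.0, 1.0)]
        with pytest.raises(ValidationError, match="degenerate"):
            PolygonPOI("X", "Y", [bowtie])

    def test_agrees_with_raycast_oracle(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(-2.5, 2.5, size=(400, 2))
        act = make_activity(["X", "Y"], pts.T)
        for k in range(5):
            poly = random_simple_polygon(rng, n_vertices=int(rng.integers(3, 9)))
            got = match_samples(PolygonPOI("X", "Y", [poly]), act)
            want = np.array(
                [point_in_polygon_raycast(x, y, poly) for x, y in pts]
            )
            np.testing.assert_array_equal(got, want)


class TestFormulaPOI:
    def test_ellipse_formula_center_and_boundary(self):
        act = make_activity(
            ["MYC", "MYC_TG"], [[-2.0, 0.0], [2.0, 2.0]]
        )
        poi = FormulaPOI("(MYC+2)^2+(MYC_TG-2)^2*10 < 4")
        # center (value 0 < 4): selected; (0, 2) gives 4 < 4: not selected
        np.testing.assert_array_equal(match_samples(poi, act), [True, False])

    def test_power_binds_tighter_than_product(self):
        act = make_activity(["A"], [[3.0]])
        # (A-2)^2*10 = 10, not (A-2)^(2*10)
        assert match_samples(FormulaPOI("(A-2)^2*10 > 9"), act)[0]
        assert not match_samples(FormulaPOI("(A-2)^2*10 > 11"), act)[0]

    def test_power_is_right_associative(self):
        act = make_activity(["A"], [[2.0]])
        # 2^3^2 = 2^9 = 512
        assert match_samples(FormulaPOI("A^3^2 > 511"), act)[0]
        assert not match_samples(FormulaPOI("A^3^2 > 513"), act)[0]

    def test_unary_minus_applies_after_power(self):
        act = make_activity(["A"], [[2.0]])
        # -A^2 = -(A^2) = -4
        assert match_samples(FormulaPOI("-A^2 < -3"), act)[0]

    def test_logical_connectives(self):
        act = make_activity(["A", "B"], [[0.0, 2.0, 2.0], [2.0, 0.0, 2.0]])
        conj = match_samples(FormulaPOI("A > 1 & B > 1"), act)
        disj = match_samples(FormulaPOI("A > 1 | B > 1"), act)
        np.testing.assert_array_equal(conj, [False, False, True])
        np.testing.assert_array_equal(disj, [True, True, True])

    def test_one_sided_formula_matches_interval_poi(self):
        rng = np.random.default_rng(8)
        act = make_activity(["A"], rng.normal(size=(1, 500)))
        f_mask = match_samples(FormulaPOI("A > 0.3"), act)
        i_mask = match_samples(IntervalPOI([("A", 0.3, None)]), act)
        np.testing.assert_array_equal(f_mask, i_mask)

    def test_sanitized_set_names_resolve(self):
        act = make_activity(["my set!"], [[5.0]])
        assert match_samples(FormulaPOI("my_set_ > 4"), act)[0]

    def test_unknown_identifier_rejected(self):
        act = make_activity(["A"], [[1.0]])
        with pytest.raises(FormulaError, match="unknown gene set"):
            match_samples(FormulaPOI("B > 0"), act)

    @pytest.mark.parametrize("bad", ["A >", "A ! 3", "(A > 1", "A + > 2", ""])
    def test_syntax_errors_rejected(self, bad):
        with pytest.raises(FormulaError):
            FormulaPOI(bad)

    def test_non_boolean_formula_rejected(self):
        act = make_activity(["A"], [[1.0]])
        with pytest.raises(FormulaError, match="boolean"):
            match_samples(FormulaPOI("A + 1"), act)


class TestSaveLoad:
    def build_all_kinds(self):
        return [
            IntervalPOI([("A", CutoffSpec("sd", 1.0, "lower"), None),
                         ("B", -0.5, CutoffSpec("quantile", 0.9, "upper"))]),
            UnionIntervalPOI("A", [(None, -1.0), (CutoffSpec("raw", 1.0), None)]),
            PolygonPOI("A", "B", [[(0.0, 0.0), (2.0, 0.0), (1.0, 2.0)]]),
            FormulaPOI("(A-1)^2 + B^2 < 2 | A > 1.5"),
        ]

    def test_round_trip_reproduces_masks(self, tmp_path):
        rng = np.random.default_rng(4)
        act = make_activity(["A", "B"], rng.normal(size=(2, 200)))
        for i, poi in enumerate(self.build_all_kinds()):
            p = tmp_path / f"poi{i}.json"
            save_poi(poi, p)
            back = load_poi(p)
            assert type(back) is type(poi)
            np.testing.assert_array_equal(
                match_samples(back, act), match_samples(poi, act)
            )

    def test_resolved_cutoffs_stored(self, tmp_path):
        act = make_activity(["A"], [[0.0, 1.0, 2.0, 3.0]])
        poi = IntervalPOI([("A", CutoffSpec("sd", 1.0, "lower"), None)])
        match_samples(poi, act)
        p = tmp_path / "poi.json"
        save_poi(poi, p)
        doc = json.loads(p.read_text())
        lo, hi = doc["resolved"]["A"]
        assert lo == pytest.approx(1.5 + np.std([0, 1, 2, 3], ddof=1))
        assert hi == math.inf or hi is None or hi == float("inf")

    def test_unknown_type_tag_rejected(self, tmp_path):
        p = tmp_path / "poi.json"
        p.write_text('{"type": "circle", "poi_version": 1}')
        with pytest.raises(ValidationError, match="unknown POI type"):
            load_poi(p)

    def test_whitespace_edits_tolerated(self, tmp_path):
        p = tmp_path / "poi.json"
        save_poi(FormulaPOI("A > 1"), p)
        p.write_text("\n  " + p.read_text().replace("\n", "\n   ") + "\n\n")
        assert isinstance(load_poi(p), FormulaPOI)
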