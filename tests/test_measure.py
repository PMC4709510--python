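"""Measurement registry coverage and evaluation semantics."""

import copy

import numpy as np
import pytest

import craniometry as cm
from craniometry.measure import (FLAG_MISSING, FLAG_PROXY, Midpoint,
                                 parse_key, registry_by_label)

from oracles import angle_extended_precision, \
    plane_construction_ap_distance, random_rigid


class TestRegistry:
    def test_covers_all_46_labels_once(self):
        registry = cm.table1_registry()
        assert len(registry) == 46
        labels = [d.label for d in registry]
        assert len(set(labels)) == 46
        kinds = {d.label: d.kind for d in registry}
        assert all(kinds[l] == "transverse" for l in "ABCDEFGHIJKLM")
        assert all(kinds[l] == "vertical" for l in "NOPQRSTUV")
        for l in ("W", "X", "Y", "Z", "AA", "BB", "CC", "DD", "EE", "FF",
                  "GG", "HH", "II", "MM"):
            assert kinds[l] == "ap_projected", l
        assert all(kinds[l] == "euclidean" for l in ("JJ", "KK", "LL"))
        for l in ("NN", "OO", "PP", "QQ", "RR", "SS", "TT"):
            assert kinds[l] == "angle", l

    def test_key_definitions(self):
        by = registry_by_label()
        assert by["NN"].landmarks == (31, 27, 25)
        assert by["W"].landmarks == (1, 16)
        assert by["A"].landmarks == (29,)
        assert by["E"].landmarks == (Midpoint((10, 11)),)
        assert by["MM"].landmarks == (1, Midpoint((10, 11)))
        assert by["JJ"].landmarks == (35, 36)
        assert by["KK"].landmarks == (35, 38)
        assert by["LL"].landmarks == (36, 37)

    def test_serialization_round_trip(self, tmp_path):
        registry = cm.table1_registry()
        for name in ("registry.yaml", "registry.json"):
            path = tmp_path / name
            cm.save_registry(registry, path)
            assert cm.load_registry(path) == registry

    def test_parse_key_forms(self):
        assert parse_key("29") == 29
        assert parse_key("(10/11)") == Midpoint((10, 11))
        assert parse_key("35:left") == (35, "left")


class TestTransverse:
    def test_axis_aligned_and_coincident(self, schema):
        spec = cm.SpecimenLandmarks("x", 28)
        spec.set(29, "left", (-1.0, 0.0, 0.0))
        spec.set(29, "right", (1.0, 0.0, 0.0))
        assert cm.transverse_width(spec, 29, schema) == pytest.approx(2.0)
        spec.set(29, "left", (1.0, 0.0, 0.0))
        assert cm.transverse_width(spec, 29, schema) == 0.0

    def test_matches_arithmetic_oracle(self, schema):
        rng = np.random.default_rng(1)
        spec = cm.SpecimenLandmarks("x", 28)
        for _ in range(100):
            l, r = rng.normal(size=3), rng.normal(size=3)
            spec.set(30, "left", l)
            spec.set(30, "right", r)
            expect = float(np.sqrt(((l - r) ** 2).sum()))
            assert cm.transverse_width(spec, 30, schema) == pytest.approx(
                expect, abs=1e-12)

    def test_missing_side_flags_missing(self, schema):
        spec = cm.SpecimenLandmarks("x", 28)
        spec.set(29, "left", (0, 0, 0))
        assert cm.transverse_width(spec, 29, schema) is None


class TestApProjected:
    def test_pure_ap_separation(self, template_frame, schema):
        spec = cm.SpecimenLandmarks("x", 28)
        spec.set(1, "mid", (10.0, 0.0, 0.0))
        spec.set(16, "mid", (6.9, 0.5, -0.7))
        spec.coords[(16, "mid")] = np.array([10.0 - 3.1, 0.0, 0.0])
        assert cm.ap_projected_distance(
            spec, template_frame, 1, 16, schema) == pytest.approx(3.1)

    def test_bilateral_averaging(self, template_frame, schema):
        """Left-side distance 10.0 and right-side 10.2 average to 10.1."""
        spec = cm.SpecimenLandmarks("x", 28)
        spec.set(1, "mid", (0.0, 0.0, 0.0))
        spec.set(10, "left", (10.0, -2.0, 1.0))
        spec.set(11, "left", (10.0, -2.0, 3.0))
        spec.set(10, "right", (10.2, 2.0, 1.0))
        spec.set(11, "right", (10.2, 2.0, 3.0))
        d = cm.ap_projected_distance(spec, template_frame, 1,
                                     Midpoint((10, 11)), schema)
        assert d == pytest.approx(10.1)

    def test_matches_plane_construction_oracle(self, template, schema):
        """Equals the distance between explicitly constructed coronal
        planes through the two landmarks, on random rigidly-moved
        specimens."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            R, t = random_rigid(rng)
            moved = template.transformed(R, t)
            frame = cm.build_frame(moved, schema)
            a, b = rng.choice([1, 5, 16, 22, 25, 26], 2, replace=False)
            got = cm.ap_projected_distance(moved, frame, int(a), int(b),
                                           schema)
            expect = plane_construction_ap_distance(
                moved.get(int(a), "mid"), moved.get(int(b), "mid"),
                frame.axis_ap)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_invariant_to_sliding_within_coronal_plane(self, template,
                                                       schema):
        frame = cm.build_frame(template, schema)
        spec = copy.deepcopy(template)
        base = cm.ap_projected_distance(spec, frame, 1, 16, schema)
        spec.coords[(1, "mid")] = (spec.get(1, "mid")
                                   + 2.3 * frame.axis_ml
                                   - 1.1 * frame.axis_dv)
        assert cm.ap_projected_distance(spec, frame, 1, 16,
                                        schema) == pytest.approx(base)


class TestVertical:
    def test_pure_dv_separation_both_modes(self, template_frame, schema):
        spec = cm.SpecimenLandmarks("x", 28)
        spec.set(2, "mid", (5.0, 0.0, 1.0))
        spec.set(3, "mid", (5.0, 0.0, 3.3))
        for mode in ("euclidean", "dv_projected"):
            d = cm.vertical_distance(spec, template_frame, 2, 3, mode,
                                     schema)
            assert d == pytest.approx(2.3)

    def test_euclidean_bounds_projection(self, template_frame, schema):
        spec = cm.SpecimenLandmarks("x", 28)
        rng = np.random.default_rng(3)
        for _ in range(50):
            spec.set(2, "mid", rng.normal(size=3) * 5)
            spec.set(3, "mid", rng.normal(size=3) * 5)
            eucl = cm.vertical_distance(spec, template_frame, 2, 3,
                                        "euclidean", schema)
            proj = cm.vertical_distance(spec, template_frame, 2, 3,
                                        "dv_projected", schema)
            expect = float(np.linalg.norm(spec.get(2, "mid")
                                          - spec.get(3, "mid")))
            assert eucl == pytest.approx(expect, abs=1e-12)
            assert proj <= eucl + 1e-12


class TestMandible:
    def test_values_and_single_side_fallback(self, template, schema):
        full = cm.mandible_measurements(template, schema)
        spec = copy.deepcopy(template)
        for lid in (35, 36):
            del spec.coords[(lid, "left")]
        single = cm.mandible_measurements(spec, schema)
        for label in ("JJ", "KK", "LL"):
            assert single[label] == pytest.approx(full[label])  # symmetric
        table = cm.evaluate_all(spec, cm.build_frame(spec, schema))
        jj = table[table.label == "JJ"].iloc[0]
        assert "single_side" in jj["flags"]

    def test_both_sides_missing_flags(self, template, schema):
        spec = copy.deepcopy(template)
        for side in ("left", "right"):
            del spec.coords[(35, side)]
        assert cm.mandible_measurements(spec, schema)["JJ"] is None

    def test_invariant_to_mandible_displacement(self, template, schema):
        """Rigidly moving the mandible out of occlusion leaves the
        mandibular measurements unchanged (they never use the cranial
        frame)."""
        rng = np.random.default_rng(4)
        base = cm.mandible_measurements(template, schema)
        spec = copy.deepcopy(template)
        R, t = random_rigid(rng)
        for (lid, side) in list(spec.coords):
            if lid in (35, 36, 37, 38):
                spec.coords[(lid, side)] = R @ spec.coords[(lid, side)] + t
        moved = cm.mandible_measurements(spec, schema)
        for label in ("JJ", "KK", "LL"):
            assert moved[label] == pytest.approx(base[label], abs=1e-9)


class TestAngles:
    def test_collinear_and_perpendicular(self):
        assert cm.angle_3pt([(0, 0, 0), (1, 0, 0), (2, 0, 0)]) \
            == pytest.approx(180.0)
        assert cm.angle_3pt([(1, 0, 0), (0, 0, 0), (0, 2, 0)]) \
            == pytest.approx(90.0)

    def test_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p, v, q = rng.normal(size=(3, 3)) * 10
            assert cm.angle_3pt([p, v, q]) == pytest.approx(
                angle_extended_precision(p, v, q), abs=1e-6)

    def test_coincident_vertex_raises(self):
        with pytest.raises(cm.DegenerateGeometryError):
            cm.angle_3pt([(1, 1, 1), (1, 1, 1), (0, 0, 0)])


class TestEvaluateAll:
    def test_complete_specimen_46_values_no_flags(self, template, schema,
                                                  template_frame):
        table = cm.evaluate_all(template, template_frame)
        assert len(table) == 46
        assert (table["flags"] == "ok").all()
        assert np.isfinite(table.value).all()
        assert (table.loc[table.kind == "angle", "units"] == "degrees").all()
        angles = table.loc[table.kind == "angle", "value"]
        assert ((angles >= 0) & (angles <= 180)).all()
        assert (table.loc[table.kind != "angle", "value"] >= 0).all()

    def test_p7_specimen_proxy_flags(self, schema):
        cohort = cm.sample_cohort(cm.CohortSpec(ages=(7,), n_per_age=1,
                                                seed=9))
        spec = cohort[0]
        table = cm.evaluate_all(spec, cm.build_frame(spec, schema))
        flagged = set(table.loc[table["flags"].str.contains(FLAG_PROXY),
                                "label"])
        uses_13_14 = {d.label for d in cm.table1_registry()
                      if d.landmark_ids() & {13, 14}}
        assert flagged == uses_13_14
        assert {"P", "O", "PP", "QQ", "RR", "OO"} <= flagged

    def test_missing_id8_flags_H_and_II(self, template, schema,
                                        template_frame):
        spec = copy.deepcopy(template)
        for side in ("left", "right"):
            del spec.coords[(8, side)]
        table = cm.evaluate_all(spec, template_frame)
        missing = set(table.loc[table["flags"].str.contains(FLAG_MISSING),
                                "label"])
        assert missing == {"H", "II"}

    def test_bilateral_symmetry_of_per_side_values(self, template, schema,
                                                   template_frame):
        """On a mirror-symmetric specimen, left-only and right-only
        evaluations of per-side measurements agree."""
        for sides in (("left",), ("right",)):
            spec = copy.deepcopy(template)
            for lid in (35, 36):
                for side in ("left", "right"):
                    if side not in sides:
                        del spec.coords[(lid, side)]
            vals = cm.mandible_measurements(spec, schema)
            ref = cm.mandible_measurements(template, schema)
            for label in ("JJ", "KK", "LL"):
                assert vals[label] == pytest.approx(ref[label], abs=1e-9)

    def test_all_measurements_rigid_invariant(self, template, schema):
        """Full-battery invariance to global rigid motion (frame refitted),
        to 1e-8 mm / degrees."""
        rng = np.random.default_rng(6)
        base = cm.evaluate_all(template, cm.build_frame(template, schema))
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = template.transformed(R, t)
            table = cm.evaluate_all(moved, cm.build_frame(moved, schema))
            np.testing.assert_allclose(table.value.to_numpy(),
                                       base.value.to_numpy(), atol=1e-8)
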