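"""Object-based and content-agnostic D/I/R classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_force_agnostic_classes,
    brute_force_object_labels,
    make_trial,
    square_mask,
    two_square_scene,
)
from dirfix.dir_classify import (
    DIRLabels,
    FixationLabel,
    HeuristicParams,
    classify_agnostic,
    classify_object_based,
    label_agreement,
)
from dirfix.errors import ContractError
from dirfix.gaze_io import ScreenGeometry
from dirfix.scene_masks import SceneAnnotation, build_hit_tester, hit_test


def classes_of(labels: DIRLabels) -> list[set[str]]:
    return [set(l.classes) for l in labels]


class TestObjectBased:
    def test_forced_sequence_d_i_d_r_unlabelled(self, small_geometry):
        # hits: [a], [a], [b], [a], []
        scene = two_square_scene(small_geometry)
        tester = build_hit_tester(scene)
        trial = make_trial([(8, 8), (10, 10), (48, 48), (8, 8), (30, 2)])
        labels = classify_object_based(trial, tester, margin_px=0.0)
        assert labels[0].detected == {"a"}
        assert labels[1].inspected == {"a"}
        assert labels[2].detected == {"b"}
        assert labels[3].returned == {"a"}
        assert labels[4].is_unlabelled

    def test_margin_overlap_carries_two_class_flags(self):
        # adjacent squares: a in x[0,10), b in x[14,24); gap 4 px
        geom = ScreenGeometry(32, 32, 3.2, 3.2)
        shape = (32, 32)
        scene = SceneAnnotation(
            "img", geom,
            [square_mask("a", 0, 8, 10, shape, 0),
             square_mask("b", 14, 8, 10, shape, 1)],
        )
        tester = build_hit_tester(scene)
        # hits with margin 3: [a] at (5,12); [a,b] at (12,12); [b] at (20,12)
        assert hit_test(tester, 12, 12, 3.0) == {"a", "b"}
        trial = make_trial([(5, 12), (12, 12), (20, 12)])
        labels = classify_object_based(trial, tester, margin_px=3.0)
        assert labels[0].detected == {"a"}
        assert labels[1].inspected == {"a"} and labels[1].detected == {"b"}
        assert labels[2].inspected == {"b"}
        assert classes_of(labels) == [{"D"}, {"D", "I"}, {"I"}]

    @given(seed=st.integers(0, 500))
    @settings(deadline=None, max_examples=60)
    def test_matches_quadratic_prefix_rescan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        geom = ScreenGeometry(48, 48, 4.8, 4.8)
        shape = (48, 48)
        objects = [
            square_mask(f"o{k}", int(rng.integers(0, 36)),
                        int(rng.integers(0, 36)), int(rng.integers(4, 12)),
                        shape, depth_rank=k)
            for k in range(4)
        ]
        from dirfix.scene_masks import resolve_occlusion
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = SceneAnnotation("img", geom, resolve_occlusion(objects))
        tester = build_hit_tester(scene)
        margin = float(rng.uniform(0, 6))
        trial = make_trial(rng.uniform(0, 48, size=(12, 2)))
        labels = classify_object_based(trial, tester, margin)
        hit_sets = [hit_test(tester, f.x, f.y, margin) for f in trial]
        assert labels == brute_force_object_labels(hit_sets)

    def test_prefix_property_appending_never_relabels(self, small_geometry):
        scene = two_square_scene(small_geometry)
        tester = build_hit_tester(scene)
        positions = [(8, 8), (48, 48), (8, 8), (10, 10), (30, 2), (48, 48)]
        full = classify_object_based(make_trial(positions), tester, 0.0)
        for k in range(1, len(positions)):
            partial = classify_object_based(make_trial(positions[:k]), tester, 0.0)
            assert partial.labels == full.labels[:k]

    def test_order_dependence_on_reversal(self, small_geometry):
        scene = two_square_scene(small_geometry)
        tester = build_hit_tester(scene)
        # [a],[a],[b] -> D,I,D ; reversed [b],[a],[a] -> D,D,I
        fwd = classify_object_based(make_trial([(8, 8), (9, 9), (48, 48)]),
                                    tester, 0.0)
        rev = classify_object_based(make_trial([(48, 48), (9, 9), (8, 8)]),
                                    tester, 0.0)
        assert classes_of(fwd) == [{"D"}, {"I"}, {"D"}]
        assert classes_of(rev) == [{"D"}, {"D"}, {"I"}]
        # symmetric case [a],[b],[a] keeps its Return under reversal
        sym = classify_object_based(make_trial([(8, 8), (48, 48), (9, 9)]),
                                    tester, 0.0)
        assert classes_of(sym) == [{"D"}, {"D"}, {"R"}]

    def test_per_object_counting_invariant(self, small_geometry):
        scene = two_square_scene(small_geometry)
        tester = build_hit_tester(scene)
        rng = np.random.default_rng(7)
        trial = make_trial(rng.uniform(0, 64, size=(40, 2)))
        labels = classify_object_based(trial, tester, 2.0)
        for oid in ("a", "b"):
            n_d = sum(oid in l.detected for l in labels)
            n_i = sum(oid in l.inspected for l in labels)
            n_r = sum(oid in l.returned for l in labels)
            n_hits = sum(
                oid in hit_test(tester, f.x, f.y, 2.0) for f in trial
            )
            assert n_d == (1 if n_hits else 0)
            assert n_hits == n_d + n_i + n_r

    def test_object_in_one_class_per_fixation(self):
        with pytest.raises(ContractError):
            FixationLabel(detected=frozenset({"a"}), inspected=frozenset({"a"}))


class TestAgnostic:
    def test_forced_example_d_i_d_r(self):
        geom = ScreenGeometry(1000, 800, 25.0, 20.0)
        trial = make_trial([(0, 0), (5, 0), (500, 0), (3, 1)])
        labels = classify_agnostic(trial, HeuristicParams(0.10), geom)
        assert classes_of(labels) == [{"D"}, {"I"}, {"D"}, {"R"}]

    def test_single_fixation_is_detection(self, study_geometry):
        labels = classify_agnostic(make_trial([(600, 450)]),
                                   HeuristicParams(), study_geometry)
        assert classes_of(labels) == [{"D"}]

    def test_empty_trial_empty_labels(self, study_geometry):
        labels = classify_agnostic(make_trial([]), HeuristicParams(),
                                   study_geometry)
        assert len(labels) == 0

    def test_return_anchors_most_recent_pseudo_object(self):
        geom = ScreenGeometry(1000, 800, 25.0, 20.0)
        # two distinct pseudo-objects at x=0 and x=300, then a return to
        # a point near both earlier fixations 0 and 1 — anchor must be
        # the more recent one within theta
        trial = make_trial([(0, 0), (50, 0), (500, 0), (40, 0)])
        labels = classify_agnostic(trial, HeuristicParams(0.10), geom)
        # fixation 1 inspected pseudo-object p0; fixation 3 returns to it
        # via the most recent in-theta fixation (index 1)
        assert labels[1].inspected == {"p0"}
        assert labels[3].returned == {"p0"}

    def test_strict_inequality_at_threshold(self):
        geom = ScreenGeometry(1000, 800, 25.0, 20.0)
        # distance exactly theta = 100 px: NOT the same pseudo-object
        trial = make_trial([(0, 0), (100, 0)])
        labels = classify_agnostic(trial, HeuristicParams(0.10), geom)
        assert classes_of(labels) == [{"D"}, {"D"}]

    @given(seed=st.integers(0, 500))
    @settings(deadline=None, max_examples=60)
    def test_matches_quadratic_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        geom = ScreenGeometry(200, 160, 20.0, 16.0)
        positions = rng.uniform(0, 160, size=(15, 2))
        trial = make_trial(positions)
        labels = classify_agnostic(trial, HeuristicParams(0.10), geom)
        expected = brute_force_agnostic_classes(positions, theta=20.0)
        got = ["".join(sorted(l.classes)) for l in labels]
        assert got == expected
        # exactly one class per fixation
        assert all(len(l.classes) == 1 for l in labels)


class TestAgreement:
    def test_identical_labels_full_agreement(self, small_geometry):
        scene = two_square_scene(small_geometry)
        tester = build_hit_tester(scene)
        trial = make_trial([(8, 8), (9, 9), (48, 48), (8, 8)])
        labels = classify_object_based(trial, tester, 0.0)
        report = label_agreement(labels, labels)
        for c in ("D", "I", "R"):
            assert report.match_fraction[c] == 1.0

    def test_total_disagreement_zero_fraction(self):
        obj = DIRLabels((FixationLabel(detected=frozenset({"a"})),) * 3)
        agn = DIRLabels((FixationLabel(inspected=frozenset({"p"})),) * 3)
        report = label_agreement(obj, agn)
        assert report.match_fraction["D"] == 0.0
        assert np.isnan(report.match_fraction["I"])  # no object-scheme I
        assert report.labelled_by_object_scheme == {"D": 3, "I": 0, "R": 0}

    def test_pooled_counts_match_flat_recount(self):
        rng = np.random.default_rng(3)
        trials_obj, trials_agn = [], []
        for _ in range(10):
            n = int(rng.integers(1, 10))
            def rand_labels():
                out = []
                for _ in range(n):
                    role = rng.choice(["detected", "inspected", "returned"])
                    out.append(FixationLabel(**{role: frozenset({"x"})}))
                return DIRLabels(tuple(out))
            trials_obj.append(rand_labels())
            trials_agn.append(rand_labels())
        report = label_agreement(trials_obj, trials_agn)
        flat_obj = [l for t in trials_obj for l in t]
        flat_agn = [l for t in trials_agn for l in t]
        for c in ("D", "I", "R"):
            denom = sum(l.has_class(c) for l in flat_obj)
            joint = sum(
                lo.has_class(c) and la.has_class(c)
                for lo, la in zip(flat_obj, flat_agn)
            )
            assert report.labelled_by_object_scheme[c] == denom
            assert report.jointly_labelled[c] == joint
            if denom:
                assert report.match_fraction[c] == joint / denom

    def test_fixation_count_mismatch_rejected(self):
        a = DIRLabels((FixationLabel(detected=frozenset({"a"})),))
        b = DIRLabels((FixationLabel(detected=frozenset({"a"})),) * 2)
        with pytest.raises(ContractError):
            label_agreement(a, b)

    def test_conditioning_direction_flag(self):
        obj = DIRLabels((
            FixationLabel(detected=frozenset({"a"})),
            FixationLabel(detected=frozenset({"b"})),
        ))
        agn = DIRLabels((
            FixationLabel(detected=frozenset({"p"})),
            FixationLabel(inspected=frozenset({"p"})),
        ))
        fwd = label_agreement(obj, agn, condition_on="object")
        rev = label_agreement(obj, agn, condition_on="agnostic")
        assert fwd.match_fraction["D"] == 0.5
        assert rev.match_fraction["D"] == 1.0
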