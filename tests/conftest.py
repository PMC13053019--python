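"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from dirfix.dir_classify import DIRLabels, FixationLabel
from dirfix.gaze_io import Fixation, ScreenGeometry, Trial
from dirfix.scene_masks import HitTester, ObjectMask, SceneAnnotation


@pytest.fixture
def study_geometry() -> ScreenGeometry:
    """The 3 s-condition display: 1200 x 900 px, 29.6 x 22.2 dva."""
    return ScreenGeometry(1200, 900, 29.6, 22.2)


@pytest.fixture
def small_geometry() -> ScreenGeometry:
    """A 64 x 64 px toy image at exactly 10 px per dva."""
    return ScreenGeometry(64, 64, 6.4, 6.4)


def make_trial(positions, onset0=150.0, duration=200.0, observer="obs0",
               image="img0") -> Trial:
    """Trial with the given (x, y) positions and uniform durations."""
    fixations = tuple(
        Fixation(x=float(x), y=float(y), onset=onset0 + i * (duration + 10),
                 duration=duration, index=i)
        for i, (x, y) in enumerate(positions)
    )
    return Trial(observer_id=observer, image_id=image, fixations=fixations)


def square_mask(object_id, x0, y0, size, shape, depth_rank=0, attributes=()):
    """Axis-aligned square object support on an image of the given shape."""
    support = np.zeros(shape, dtype=bool)
    support[y0:y0 + size, x0:x0 + size] = True
    return ObjectMask(object_id=object_id, support=support,
                      depth_rank=depth_rank, attributes=frozenset(attributes))


def two_square_scene(geometry, margin_px=0.0) -> SceneAnnotation:
    """Objects 'a' (top-left) and 'b' (bottom-right), well separated."""
    shape = (geometry.image_height, geometry.image_width)
    return SceneAnnotation(
        image_id="img0", geometry=geometry,
        objects=[
            square_mask("a", 4, 4, 12, shape, depth_rank=0),
            square_mask("b", 44, 44, 12, shape, depth_rank=1),
        ],
        margin_px=margin_px,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_hits(scene: SceneAnnotation, x: float, y: float,
                     margin_px: float) -> frozenset[str]:
    """Hit set by exhaustive min-distance over every support pixel."""
    h, w = scene.geometry.image_height, scene.geometry.image_width
    xi, yi = int(round(x)), int(round(y))
    if not (0 <= xi < w and 0 <= yi < h):
        return frozenset()
    hits = set()
    for obj in scene.objects:
        ys, xs = np.nonzero(obj.support)
        if ys.size == 0:
            continue
        d = np.sqrt((xs - xi) ** 2 + (ys - yi) ** 2).min()
        if d <= margin_px:
            hits.add(obj.object_id)
    return frozenset(hits)


def brute_force_object_labels(hit_sets) -> DIRLabels:
    """Quadratic-time D/I/R reference: rescan the full prefix per object."""
    out = []
    for i, hits in enumerate(hit_sets):
        detected, inspected, returned = set(), set(), set()
        for o in hits:
            earlier = [j for j in range(i) if o in hit_sets[j]]
            if not earlier:
                detected.add(o)
            elif (i - 1) in earlier:
                inspected.add(o)
            else:
                returned.add(o)
        out.append(FixationLabel(detected=frozenset(detected),
                                 inspected=frozenset(inspected),
                                 returned=frozenset(returned)))
    return DIRLabels(labels=tuple(out))


def brute_force_agnostic_classes(positions, theta) -> list[str]:
    """O(n^2) reference for the spatial heuristic's class flags."""
    pos = np.asarray(positions, dtype=float)
    classes = []
    for i in range(len(pos)):
        if i == 0:
            classes.append("D")
            continue
        d = np.hypot(pos[:i, 0] - pos[i, 0], pos[:i, 1] - pos[i, 1])
        if d[i - 1] < theta:
            classes.append("I")
        elif np.any(d[: i - 1] < theta):
            classes.append("R")
        else:
            classes.append("D")
    return classes
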