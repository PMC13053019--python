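"""Seeded generator of synthetic scenes and scanpaths with known labels.

The generator emulates the structure of annotated free-viewing data:
multi-object scenes (optionally with occlusion), per-observer fixation
sequences with onsets and durations, and binary semantic attributes per
object. Scanpaths are drawn from a per-fixation Markov mix over four
moves — fixate a new object, re-fixate the current object, return to a
previously visited object, or fixate the background — so each fixation
carries a ground-truth intended class (D, I, R or background) against
which the classifier can be scored.

Class tokens for a trial are drawn independently from the mix up front and
realised in feasibility order: a token that is impossible in the current
state (an inspection before any object has been fixated, a return before
any object is revisitable) is deferred until it becomes possible rather
than replaced, which keeps the realised class frequencies unbiased
estimates of the configured mix even in short trials. Only when no
remaining token is feasible is one remapped to a feasible move.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import ndimage

from .errors import DataError
from .gaze_io import Fixation, ScreenGeometry, Trial, dva_to_px
from .scene_masks import (
    ATTRIBUTE_VOCABULARY,
    ObjectMask,
    SceneAnnotation,
    resolve_occlusion,
    write_masks,
)

__all__ = [
    "SynthSceneConfig",
    "SynthGazeConfig",
    "GenerationError",
    "generate_scene",
    "generate_scanpath",
    "generate_corpus",
]


class GenerationError(DataError):
    """Scene packing became infeasible within the retry budget."""


@dataclass(frozen=True)
class SynthSceneConfig:
    """Scene-generator settings.

    Defaults mirror a typical annotated free-viewing stimulus set:
    1200 x 900 px spanning 29.6 x 22.2 degrees of visual angle, about
    eight objects per scene, some of them occluding one another, and a
    0.5-dva hit-test margin.
    """

    image_width: int = 1200
    image_height: int = 900
    width_dva: float = 29.6
    height_dva: float = 22.2
    n_objects: int = 8
    shape: str = "rectangle"  # or "ellipse"
    min_separation_px: float = 60.0
    size_range_px: tuple[float, float] = (80.0, 240.0)
    occlusion_fraction: float = 0.2
    margin_dva: float = 0.5
    attribute_probs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def geometry(self) -> ScreenGeometry:
        return ScreenGeometry(
            image_width=self.image_width,
            image_height=self.image_height,
            width_dva=self.width_dva,
            height_dva=self.height_dva,
        )


@dataclass(frozen=True)
class SynthGazeConfig:
    """Scanpath-generator settings.

    ``class_mix`` orders the move probabilities as (new object, same
    object, return, background) and must sum to 1. Durations are
    log-normal (median 250 ms, sigma 0.4 by default — the usual
    scene-viewing fixation-duration regime) and the first onset is
    150 ms so that onset filtering leaves the trial non-trivial. The
    optional ``mix_ramp`` linearly interpolates the mix toward a second
    tuple across the trial, emulating the drift from detections toward
    inspections and returns over viewing time.
    """

    n_observers: int = 10
    fixations_per_trial: int = 10
    class_mix: tuple[float, float, float, float] = (0.4, 0.4, 0.2, 0.0)
    scatter_px: float = 10.0
    duration_log_mu: float = math.log(250.0)
    duration_log_sigma: float = 0.4
    onset_start_ms: float = 150.0
    mix_ramp: tuple[float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise DataError("class_mix must sum to 1")
        if self.mix_ramp is not None and abs(sum(self.mix_ramp) - 1.0) > 1e-9:
            raise DataError("mix_ramp must sum to 1")


def _make_support(
    shape: str, cx: float, cy: float, w: float, h: float, H: int, W: int
) -> np.ndarray:
    x0, x1 = int(round(cx - w / 2)), int(round(cx + w / 2))
    y0, y1 = int(round(cy - h / 2)), int(round(cy + h / 2))
    support = np.zeros((H, W), dtype=bool)
    if shape == "rectangle":
        support[max(y0, 0) : min(y1, H), max(x0, 0) : min(x1, W)] = True
    elif shape == "ellipse":
        yy, xx = np.mgrid[0:H, 0:W]
        support = ((xx - cx) / (w / 2)) ** 2 + ((yy - cy) / (h / 2)) ** 2 <= 1.0
    else:
        raise DataError(f"unknown shape '{shape}'")
    return support


def _bbox_gap(a: tuple[float, float, float, float],
              b: tuple[float, float, float, float]) -> float:
    """Euclidean gap between two axis-aligned boxes (x0, y0, x1, y1)."""
    dx = max(0.0, max(b[0] - a[2], a[0] - b[2]))
    dy = max(0.0, max(b[1] - a[3], a[1] - b[3]))
    return math.hypot(dx, dy)


def generate_scene(
    config: SynthSceneConfig,
    image_id: str = "synth",
    out_dir: str | Path | None = None,
) -> SceneAnnotation:
    """Place objects, resolve occlusion and return the scene annotation.

    Objects are placed with pairwise support separation of at least
    ``min_separation_px``, except that each object after the first
    deliberately overlaps an earlier one with probability
    ``occlusion_fraction``; overlaps are resolved by depth (placement
    order, earlier = nearer). Raises :class:`GenerationError` after 1000
    failed placement attempts for any object.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry()
    H, W = config.image_height, config.image_width
    lo, hi = config.size_range_px
    boxes: list[tuple[float, float, float, float]] = []
    masks: list[ObjectMask] = []
    for k in range(config.n_objects):
        overlap = k > 0 and rng.random() < config.occlusion_fraction
        placed = False
        for _ in range(1000):
            w = rng.uniform(lo, hi)
            h = rng.uniform(lo, hi)
            if overlap:
                bx = boxes[int(rng.integers(len(boxes)))]
                cx = rng.uniform(bx[0], bx[2])
                cy = rng.uniform(bx[1], bx[3])
                if not (0 <= cx - w / 2 and cx + w / 2 < W
                        and 0 <= cy - h / 2 and cy + h / 2 < H):
                    continue
            else:
                cx = rng.uniform(w / 2, W - w / 2)
                cy = rng.uniform(h / 2, H - h / 2)
            box = (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            if not overlap and any(
                _bbox_gap(box, b) < config.min_separation_px for b in boxes
            ):
                continue
            support = _make_support(config.shape, cx, cy, w, h, H, W)
            attrs = frozenset(
                a
                for a in ATTRIBUTE_VOCABULARY
                if rng.random() < config.attribute_probs.get(a, 0.0)
            )
            masks.append(
                ObjectMask(
                    object_id=f"obj{k}", support=support, depth_rank=k,
                    attributes=attrs,
                )
            )
            boxes.append(box)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place object {k} after 1000 attempts"
            )
    scene = SceneAnnotation(
        image_id=image_id,
        geometry=geom,
        objects=resolve_occlusion(masks),
        margin_px=dva_to_px(config.margin_dva, geom),
    )
    if out_dir is not None:
        write_masks(scene, out_dir, dialect="both")
    return scene


def _sample_in_object(
    rng: np.random.Generator, obj: ObjectMask, scatter_px: float
) -> tuple[float, float]:
    """Point near the object's centroid, guaranteed inside its support."""
    ys, xs = np.nonzero(obj.support)
    cy, cx = ys.mean(), xs.mean()
    h, w = obj.support.shape
    for _ in range(50):
        x = cx + rng.normal(0.0, scatter_px)
        y = cy + rng.normal(0.0, scatter_px)
        xi, yi = int(round(x)), int(round(y))
        if 0 <= xi < w and 0 <= yi < h and obj.support[yi, xi]:
            return float(x), float(y)
    k = int(rng.integers(len(ys)))
    return float(xs[k]), float(ys[k])


def _background_pixels(scene: SceneAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Pixels farther than the margin from every object support."""
    shape = (scene.geometry.image_height, scene.geometry.image_width)
    union = np.zeros(shape, dtype=bool)
    for obj in scene.objects:
        union |= obj.support
    if union.any():
        dist = ndimage.distance_transform_edt(~union)
    else:
        dist = np.full(shape, np.inf)
    return np.nonzero(dist > scene.margin_px)


_MOVES = ("new", "same", "return", "background")


def generate_scanpath(
    scene: SceneAnnotation,
    config: SynthGazeConfig,
    rng: np.random.Generator | None = None,
    observer_id: str = "obs0",
) -> tuple[Trial, list[str]]:
    """Draw one trial on *scene* and return it with its intended labels.

    Intended labels are per-fixation strings in {"D", "I", "R",
    "background"} recording the generator's move; they equal the
    object-based classifier's output whenever the within-object scatter
    keeps samples on their object and objects are separated by more than
    twice the margin. Class tokens are pre-drawn from ``class_mix`` and
    realised in feasibility order (see module docstring); a token that
    can never be realised is remapped, e.g. "new" falls back to "return"
    once every object has been visited.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    objects = {o.object_id: o for o in scene.objects}
    if not objects and config.class_mix[3] < 1.0:
        raise DataError("scene has no objects but class_mix allows object moves")
    bg_ys, bg_xs = _background_pixels(scene)
    visited: set[str] = set()
    current: str | None = None  # object of the immediately preceding fixation
    fixations: list[Fixation] = []
    intended: list[str] = []
    onset = config.onset_start_ms
    n = config.fixations_per_trial
    # Pre-draw one class token per fixation from the (possibly ramped) mix,
    # then realise tokens in feasibility order: a token that is infeasible
    # in the current state (an inspection before any object is fixated, a
    # return before any object is revisitable) is deferred, not discarded,
    # so the realised class frequencies stay unbiased for the mix.
    tokens: list[str] = []
    for i in range(n):
        if config.mix_ramp is not None and n > 1:
            t = i / (n - 1)
            mix = tuple(
                (1 - t) * a + t * b
                for a, b in zip(config.class_mix, config.mix_ramp)
            )
        else:
            mix = config.class_mix
        probs = np.asarray(mix, dtype=float)
        tokens.append(_MOVES[int(rng.choice(4, p=probs / probs.sum()))])
    used = [False] * n
    _FALLBACK = {
        "new": ("return", "same", "background"),
        "same": ("new", "return", "background"),
        "return": ("new", "same", "background"),
        "background": ("new", "same", "return"),
    }
    for i in range(n):
        unvisited = [o for o in objects if o not in visited]
        revisitable = [o for o in visited if o != current]
        feasible = {
            "new": bool(unvisited),
            "same": current is not None,
            "return": bool(revisitable),
            "background": bg_ys.size > 0,
        }
        move = None
        for j, tok in enumerate(tokens):
            if not used[j] and feasible[tok]:
                move, used[j] = tok, True
                break
        if move is None:
            # every remaining token is infeasible: remap the oldest one.
            # Within-object remaps are routine warm-up/exhaustion; only a
            # swap between object and background moves distorts the mix
            # enough to warrant a warning.
            j = used.index(False)
            tok = tokens[j]
            for alt in _FALLBACK[tok]:
                if feasible[alt]:
                    if "background" in (tok, alt):
                        warnings.warn(
                            f"move '{tok}' infeasible at fixation {i}; "
                            f"using '{alt}'", stacklevel=2,
                        )
                    move, used[j] = alt, True
                    break
            else:
                raise DataError("no feasible move: empty scene and no background")
        if move == "new":
            oid = unvisited[int(rng.integers(len(unvisited)))]
            x, y = _sample_in_object(rng, objects[oid], config.scatter_px)
            intended.append("D")
            visited.add(oid)
            current = oid
        elif move == "same":
            oid = current
            x, y = _sample_in_object(rng, objects[oid], config.scatter_px)
            intended.append("I")
            current = oid
        elif move == "return":
            oid = revisitable[int(rng.integers(len(revisitable)))]
            x, y = _sample_in_object(rng, objects[oid], config.scatter_px)
            intended.append("R")
            current = oid
        else:
            k = int(rng.integers(bg_ys.size))
            x, y = float(bg_xs[k]), float(bg_ys[k])
            intended.append("background")
            current = None
        duration = float(
            rng.lognormal(config.duration_log_mu, config.duration_log_sigma)
        )
        fixations.append(
            Fixation(x=x, y=y, onset=onset, duration=duration, index=i)
        )
        onset += duration
    trial = Trial(
        observer_id=observer_id,
        image_id=scene.image_id,
        fixations=tuple(fixations),
    )
    return trial, intended


def generate_corpus(
    scene_config: SynthSceneConfig,
    gaze_config: SynthGazeConfig,
    n_images: int = 1,
    seed: int | None = None,
) -> list[tuple[SceneAnnotation, list[tuple[Trial, list[str]]]]]:
    """Generate *n_images* scenes, each viewed by every observer.

    Returns a list of (scene, [(trial, intended labels), ...]) pairs.
    All randomness derives from *seed* (default: the scene config's).
    """
    root = np.random.default_rng(scene_config.seed if seed is None else seed)
    out = []
    for img in range(n_images):
        scfg = SynthSceneConfig(
            **{
                **scene_config.__dict__,
                "seed": int(root.integers(2**31 - 1)),
            }
        )
        scene = generate_scene(scfg, image_id=f"img{img:04d}")
        gaze_rng = np.random.default_rng(int(root.integers(2**31 - 1)))
        trials = [
            generate_scanpath(scene, gaze_config, rng=gaze_rng,
                              observer_id=f"obs{o:03d}")
            for o in range(gaze_config.n_observers)
        ]
        out.append((scene, trials))
    return out
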