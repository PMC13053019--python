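"""Detection / Inspection / Return fixation classification.

The object-based scheme labels each fixation by its temporal relation to
the objects it lands on (within a tolerance margin):

* **Detection (D)** — the first fixation ever landing on a given object
  within the trial;
* **Inspection (I)** — a fixation landing on the same object as the
  immediately preceding fixation;
* **Return (R)** — a fixation landing on an object fixated earlier in
  the trial, after at least one intervening fixation elsewhere.

Because the tolerance margin can place one fixation on several objects,
the three class flags are not mutually exclusive across objects: a
fixation may simultaneously detect one object and inspect another. For a
*given* object, however, each fixation assigns it exactly one of the
three roles, and an object is detected at most once per trial. A fixation
hitting no object is *unlabelled* (background).

A content-agnostic spatial heuristic approximates the same scheme when no
object masks exist: two fixations closer than a fixed fraction of the
image width (default 10%) are treated as landing on the same
pseudo-object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError
from .gaze_io import ScreenGeometry, Trial
from .scene_masks import HitTester, hit_test

__all__ = [
    "CLASSES",
    "FixationLabel",
    "DIRLabels",
    "HeuristicParams",
    "AgreementReport",
    "classify_object_based",
    "classify_agnostic",
    "label_agreement",
]

#: class short-hands used throughout the package
CLASSES: tuple[str, ...] = ("D", "I", "R")


@dataclass(frozen=True)
class FixationLabel:
    """Class assignment of one fixation: object ids per class."""

    detected: frozenset[str] = frozenset()
    inspected: frozenset[str] = frozenset()
    returned: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.detected & self.inspected) or (self.detected & self.returned) or (
            self.inspected & self.returned
        ):
            raise ContractError(
                "an object may appear in at most one class per fixation"
            )

    @property
    def is_detection(self) -> bool:
        return bool(self.detected)

    @property
    def is_inspection(self) -> bool:
        return bool(self.inspected)

    @property
    def is_return(self) -> bool:
        return bool(self.returned)

    @property
    def is_unlabelled(self) -> bool:
        return not (self.detected or self.inspected or self.returned)

    @property
    def classes(self) -> frozenset[str]:
        """Short class flags of this fixation (empty when unlabelled)."""
        out = set()
        if self.detected:
            out.add("D")
        if self.inspected:
            out.add("I")
        if self.returned:
            out.add("R")
        return frozenset(out)

    def has_class(self, c: str) -> bool:
        if c == "unlabelled":
            return self.is_unlabelled
        return c in self.classes

    def objects_of(self, c: str) -> frozenset[str]:
        return {"D": self.detected, "I": self.inspected, "R": self.returned}[c]


@dataclass(frozen=True)
class DIRLabels:
    """Per-fixation labels for one trial."""

    labels: tuple[FixationLabel, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]


def classify_object_based(
    trial: Trial, tester: HitTester, margin_px: float
) -> DIRLabels:
    """Label every fixation of a (filtered) trial as D / I / R per object.

    Single left-to-right pass with a per-object last-hit index: for
    fixation i with hit set H_i, object o in H_i is

    * detected  iff o was never hit before i,
    * inspected iff o was hit by fixation i-1,
    * returned  iff o was hit by some fixation j < i-1 but not by i-1.

    Fixations with an empty hit set are unlabelled.
    """
    last_hit: dict[str, int] = {}
    out = []
    for i, fix in enumerate(trial.fixations):
        hits = hit_test(tester, fix.x, fix.y, margin_px)
        detected, inspected, returned = set(), set(), set()
        for o in hits:
            if o not in last_hit:
                detected.add(o)
            elif last_hit[o] == i - 1:
                inspected.add(o)
            else:
                returned.add(o)
        for o in hits:
            last_hit[o] = i
        out.append(
            FixationLabel(
                detected=frozenset(detected),
                inspected=frozenset(inspected),
                returned=frozenset(returned),
            )
        )
    return DIRLabels(labels=tuple(out))


@dataclass(frozen=True)
class HeuristicParams:
    """Distance threshold of the content-agnostic scheme.

    ``threshold_fraction`` is the fraction of the image width below which
    two fixations count as landing on the same pseudo-object; 0.10 works
    well for diverse complex scenes.
    """

    threshold_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ContractError("threshold_fraction must be in (0, 1]")

    def threshold_px(self, geometry: ScreenGeometry) -> float:
        return self.threshold_fraction * geometry.image_width


def classify_agnostic(
    trial: Trial,
    params: HeuristicParams,
    geometry: ScreenGeometry,
) -> DIRLabels:
    """Label fixations without object masks, by inter-fixation distance.

    With threshold theta = fraction x image width, fixation i is
    Inspection when ||p_i - p_{i-1}|| < theta; otherwise Return when some
    earlier fixation j < i-1 lies within theta (the most recent such j
    anchors the pseudo-object); otherwise Detection (a fresh
    pseudo-object). Exactly one class per fixation; fixation 0 is always
    a Detection. Pseudo-object ids are stringified anchor indices.
    """
    theta = params.threshold_px(geometry)
    xs = np.array([f.x for f in trial.fixations])
    ys = np.array([f.y for f in trial.fixations])
    pseudo: list[str] = []  # pseudo-object id per fixation
    out = []
    for i in range(len(trial.fixations)):
        if i == 0:
            pseudo.append("p0")
            out.append(FixationLabel(detected=frozenset({"p0"})))
            continue
        d = np.hypot(xs[:i] - xs[i], ys[:i] - ys[i])
        if d[i - 1] < theta:
            pid = pseudo[i - 1]
            out.append(FixationLabel(inspected=frozenset({pid})))
        else:
            near = np.nonzero(d[: i - 1] < theta)[0]
            if near.size:
                pid = pseudo[int(near[-1])]
                out.append(FixationLabel(returned=frozenset({pid})))
            else:
                pid = f"p{i}"
                out.append(FixationLabel(detected=frozenset({pid})))
        pseudo.append(pid)
    return DIRLabels(labels=tuple(out))


@dataclass(frozen=True)
class AgreementReport:
    """Per-class match between object-based and heuristic labels.

    ``match_fraction[c]`` is the fraction of fixations carrying class c
    under the object scheme that also carry c under the heuristic; NaN
    when the object scheme assigned no class-c fixation.
    """

    match_fraction: dict[str, float]
    labelled_by_object_scheme: dict[str, int]
    jointly_labelled: dict[str, int]


def label_agreement(
    object_labels: Iterable[DIRLabels] | DIRLabels,
    agnostic_labels: Iterable[DIRLabels] | DIRLabels,
    condition_on: str = "object",
) -> AgreementReport:
    """Per-fixation class agreement between the two labelling schemes.

    Accepts a single trial's labels or parallel sequences over a corpus;
    counts are pooled across trials before dividing. ``condition_on``
    picks the denominator: ``"object"`` (default) conditions on the
    object-scheme flags, ``"agnostic"`` on the heuristic's.
    """
    if isinstance(object_labels, DIRLabels):
        object_labels = [object_labels]
        agnostic_labels = [agnostic_labels]  # type: ignore[list-item]
    denom = {c: 0 for c in CLASSES}
    joint = {c: 0 for c in CLASSES}
    for obj_l, agn_l in zip(object_labels, agnostic_labels, strict=True):
        if len(obj_l) != len(agn_l):
            raise ContractError(
                f"label sets differ in fixation count: {len(obj_l)} vs {len(agn_l)}"
            )
        base, other = (obj_l, agn_l) if condition_on == "object" else (agn_l, obj_l)
        for bl, ol in zip(base, other):
            for c in CLASSES:
                if bl.has_class(c):
                    denom[c] += 1
                    if ol.has_class(c):
                        joint[c] += 1
    frac = {
        c: (joint[c] / denom[c]) if denom[c] else float("nan") for c in CLASSES
    }
    return AgreementReport(
        match_fraction=frac,
        labelled_by_object_scheme=denom,
        jointly_labelled=joint,
    )
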