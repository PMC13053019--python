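"""Semantic dwell-time profiles of D, I and R fixations.

Objects in OSIE-style annotations carry binary semantic attributes
(faces, emotional expression, text, implied motion, ...). Some attribute
pairs nearly coincide; a fixed overlap policy removes the redundant label
of each such pair before analysis. The dwell table then reports, per
fixation class and attribute, the mean across observers of the dwell-time
share spent on objects carrying that attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dir_classify import CLASSES, DIRLabels
from .errors import ConfigError, ContractError
from .gaze_io import Trial
from .scene_masks import ATTRIBUTE_VOCABULARY, ObjectMask, SceneAnnotation

__all__ = [
    "DEFAULT_ATTRIBUTES",
    "OVERLAP_RULES",
    "apply_overlap_policy",
    "SemanticDwellResult",
    "semantic_dwell_table",
]

logger = logging.getLogger(__name__)

#: the eight attributes normally analysed (the strongly salient ones)
DEFAULT_ATTRIBUTES: tuple[str, ...] = (
    "Face", "Emotion", "Touched", "Gazed", "Motion", "Taste", "Text",
    "Watchable",
)

#: (removed, trigger): drop *removed* from any object carrying *trigger*
OVERLAP_RULES: tuple[tuple[str, str], ...] = (
    ("Face", "Emotion"),
    ("Smell", "Taste"),
    ("Operability", "Touched"),
    ("Gazed", "Touched"),
    ("Watchable", "Text"),
)


def apply_overlap_policy(
    objects: Sequence[ObjectMask],
    rules: Sequence[tuple[str, str]] = OVERLAP_RULES,
) -> list[ObjectMask]:
    """Strip near-redundant attribute labels, rule by rule, in order.

    The default rules: *Face* is removed where *Emotion* is present,
    *Smell* where *Taste*, *Operability* and *Gazed* where *Touched*,
    and *Watchable* where *Text*.
    """
    vocab = set(ATTRIBUTE_VOCABULARY)
    for removed, trigger in rules:
        if removed not in vocab or trigger not in vocab:
            raise ConfigError(f"unknown attribute in rule ({removed}, {trigger})")
    out = []
    for obj in objects:
        attrs = set(obj.attributes)
        for removed, trigger in rules:
            if trigger in attrs:
                attrs.discard(removed)
        out.append(replace(obj, attributes=frozenset(attrs)))
    return out


@dataclass
class SemanticDwellResult:
    """Mean attribute x class dwell-share table plus per-observer data.

    ``table`` is attributes x classes (mean across observers);
    ``per_observer`` is the long-format table (observer, class,
    attribute, proportion) that repeated-measures analyses consume.
    """

    table: pd.DataFrame
    ci_lo: pd.DataFrame
    ci_hi: pd.DataFrame
    per_observer: pd.DataFrame
    denominator: str


def semantic_dwell_table(
    corpus: Iterable[tuple[Trial, DIRLabels, SceneAnnotation]],
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
    classes: Sequence[str] = CLASSES,
    denominator: str = "shared",
) -> SemanticDwellResult:
    """Cumulative dwell-time share on attribute-carrying objects per class.

    For observer o, class c and attribute a, the numerator sums the
    durations of o's fixations whose class-c object set contains at least
    one object carrying a (counted once per fixation). With the default
    ``denominator="shared"`` every cell is normalised by o's total
    labelled (D or I or R) dwell, so cells are comparable across classes;
    ``denominator="per_class"`` normalises by o's class-c dwell instead.
    Observers with zero (relevant) labelled dwell are excluded with a
    warning. The scenes' attribute labels are used as given — apply
    :func:`apply_overlap_policy` upstream.
    """
    unknown = set(attributes) - set(ATTRIBUTE_VOCABULARY)
    if unknown:
        raise ConfigError(f"unknown attributes {sorted(unknown)}")
    if denominator not in ("shared", "per_class"):
        raise ContractError(f"unknown denominator '{denominator}'")
    num: dict[str, np.ndarray] = {}
    den: dict[str, np.ndarray] = {}
    for trial, labels, scene in corpus:
        if len(trial) != len(labels):
            raise ContractError("trial/labels length mismatch")
        attr_of = scene.attribute_map()
        o = trial.observer_id
        if o not in num:
            num[o] = np.zeros((len(attributes), len(classes)))
            den[o] = np.zeros(len(classes))
        for fix, lab in zip(trial.fixations, labels):
            if lab.is_unlabelled:
                continue
            for ci, c in enumerate(classes):
                flagged = lab.has_class(c)
                if denominator == "shared":
                    den[o][ci] += fix.duration
                elif flagged:
                    den[o][ci] += fix.duration
                if not flagged:
                    continue
                carried = frozenset().union(
                    *(attr_of.get(obj, frozenset())
                      for obj in lab.objects_of(c))
                ) if lab.objects_of(c) else frozenset()
                for ai, a in enumerate(attributes):
                    if a in carried:
                        num[o][ai, ci] += fix.duration
    rows = []
    for o in sorted(num):
        if not np.any(den[o] > 0):
            logger.warning("observer %s has zero labelled dwell; excluded", o)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(den[o][None, :] > 0, num[o] / den[o][None, :],
                             np.nan)
        for ai, a in enumerate(attributes):
            for ci, c in enumerate(classes):
                rows.append(
                    {"observer": o, "class": c, "attribute": a,
                     "proportion": props[ai, ci]}
                )
    if not rows:
        raise ContractError("no observer with labelled dwell time")
    long = pd.DataFrame(rows)

    def pivot(aggfunc):
        return (
            long.pivot_table(index="attribute", columns="class",
                             values="proportion", aggfunc=aggfunc,
                             dropna=False)
            .reindex(index=list(attributes), columns=list(classes))
            .to_numpy(dtype=float)
        )

    mean = pivot("mean")
    sd = pivot("std")
    n = pivot("count")
    tcrit = stats.t.ppf(0.975, np.maximum(n - 1, 1))
    with np.errstate(invalid="ignore"):
        half = np.where(n > 1, tcrit * sd / np.sqrt(np.maximum(n, 1)), np.nan)
    frame = lambda a: pd.DataFrame(a, index=list(attributes),
                                   columns=list(classes))
    return SemanticDwellResult(
        table=frame(mean), ci_lo=frame(mean - half), ci_hi=frame(mean + half),
        per_observer=long, denominator=denominator,
    )
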