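"""Fixation data model, table IO, unit conversion and filtering.

Coordinates live in image pixel space: origin at the top-left corner,
x rightward, y downward, 0-based; fixation positions are continuous
(sub-pixel values allowed). Onsets and durations are milliseconds from
image onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ContractError, DataError

__all__ = [
    "Fixation",
    "Trial",
    "ScreenGeometry",
    "read_fixation_table",
    "filter_fixations",
    "dva_to_px",
    "write_labels",
    "read_labels",
    "DEFAULT_COLUMNS",
]

#: default column-name map for fixation tables
DEFAULT_COLUMNS: dict[str, str] = {
    "observer": "observer",
    "image": "image",
    "x": "x",
    "y": "y",
    "onset": "onset_ms",
    "duration": "duration_ms",
}


@dataclass(frozen=True)
class Fixation:
    """One fixation event.

    Parameters
    ----------
    x, y
        Position in image pixels (continuous).
    onset
        Milliseconds from image onset, >= 0.
    duration
        Milliseconds, > 0.
    index
        Ordinal position within the trial, consecutive from 0 and
        ordered by onset.
    """

    x: float
    y: float
    onset: float
    duration: float
    index: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DataError(f"fixation duration must be > 0, got {self.duration}")
        if self.onset < 0:
            raise DataError(f"fixation onset must be >= 0, got {self.onset}")

    @property
    def offset(self) -> float:
        """End of the fixation interval [onset, onset + duration)."""
        return self.onset + self.duration


@dataclass(frozen=True)
class Trial:
    """All fixations of one observer on one image, ordered by onset."""

    observer_id: str
    image_id: str
    fixations: tuple[Fixation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        onsets = [f.onset for f in self.fixations]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise DataError(
                f"trial ({self.observer_id}, {self.image_id}): onsets must be "
                "strictly increasing"
            )
        for i, f in enumerate(self.fixations):
            if f.index != i:
                raise DataError(
                    f"trial ({self.observer_id}, {self.image_id}): fixation "
                    f"indices must be consecutive from 0, got {f.index} at {i}"
                )

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)


@dataclass(frozen=True)
class ScreenGeometry:
    """Image size in pixels and in degrees of visual angle (dva).

    The pixel-per-dva scale uses the horizontal extent; displays with an
    anisotropy above 2% between horizontal and vertical px/dva trigger a
    warning (the conversion is still horizontal).
    """

    image_width: int
    image_height: int
    width_dva: float
    height_dva: float

    def __post_init__(self) -> None:
        if min(self.image_width, self.image_height) <= 0 or min(
            self.width_dva, self.height_dva
        ) <= 0:
            raise ConfigError("all geometry fields must be positive")
        h = self.image_width / self.width_dva
        v = self.image_height / self.height_dva
        if abs(h - v) / h > 0.02:
            warnings.warn(
                f"anisotropic pixel pitch: {h:.2f} px/dva horizontal vs "
                f"{v:.2f} vertical; conversions use the horizontal scale",
                stacklevel=2,
            )

    @property
    def px_per_dva(self) -> float:
        return self.image_width / self.width_dva


def dva_to_px(value: float, geometry: ScreenGeometry) -> float:
    """Convert degrees of visual angle to pixels via the horizontal scale."""
    return value * geometry.px_per_dva


def read_fixation_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[Trial]:
    """Read a delimited fixation table into trials.

    The table must have a header row and (possibly renamed via *dialect*)
    columns observer, image, x, y, onset_ms, duration_ms. One trial is
    produced per (observer, image) pair, fixations ordered by onset.

    Raises
    ------
    ConfigError
        A required column is missing.
    DataError
        Non-numeric cell, or two fixations of one trial share an onset.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for key, name in cols.items():
        if name not in df.columns:
            raise ConfigError(f"fixation table is missing column '{name}' ({key})")
    numeric = {}
    for key in ("x", "y", "onset", "duration"):
        series = pd.to_numeric(df[cols[key]], errors="coerce")
        bad = series.isna() & df[cols[key]].notna()
        if bad.any() or series.isna().any():
            row = int(series.index[series.isna()][0]) + 2  # header + 1-based
            raise DataError(f"non-numeric value in column '{cols[key]}' at row {row}")
        numeric[key] = series.to_numpy(float)
    df = pd.DataFrame(
        {
            "observer": df[cols["observer"]].astype(str),
            "image": df[cols["image"]].astype(str),
            "x": numeric["x"],
            "y": numeric["y"],
            "onset": numeric["onset"],
            "duration": numeric["duration"],
        }
    )
    trials = []
    for (obs, img), grp in df.groupby(["observer", "image"], sort=True):
        if grp["onset"].duplicated().any():
            raise DataError(
                f"trial ({obs}, {img}) has fixations with identical onsets"
            )
        grp = grp.sort_values("onset")
        fixations = tuple(
            Fixation(x=r.x, y=r.y, onset=r.onset, duration=r.duration, index=i)
            for i, r in enumerate(grp.itertuples())
        )
        trials.append(Trial(observer_id=obs, image_id=img, fixations=fixations))
    return trials


def filter_fixations(
    trial: Trial, min_onset: float = 100.0, min_duration: float = 100.0
) -> Trial:
    """Drop fixations with onset < *min_onset* or duration < *min_duration*.

    The standard exclusions for free-viewing data: fixations initiated
    before (or at the edge of) image onset and implausibly short events.
    Surviving fixations keep their order and are re-indexed from 0.
    Boundary values survive (onset >= min_onset, duration >= min_duration).
    """
    if min_onset < 0 or min_duration < 0:
        raise ContractError("filter thresholds must be >= 0")
    kept = [
        f for f in trial.fixations if f.onset >= min_onset and f.duration >= min_duration
    ]
    return replace(
        trial,
        fixations=tuple(replace(f, index=i) for i, f in enumerate(kept)),
    )


def _labels_frame(trials: Sequence[Trial], labels: Sequence) -> pd.DataFrame:
    rows = []
    if len(trials) != len(labels):
        raise ContractError(
            f"{len(trials)} trials but {len(labels)} label sets"
        )
    for trial, lab in zip(trials, labels):
        if len(lab) != len(trial):
            raise ContractError(
                f"trial ({trial.observer_id}, {trial.image_id}) has "
                f"{len(trial)} fixations but {len(lab)} labels"
            )
        for fix, fl in zip(trial.fixations, lab):
            rows.append(
                {
                    "observer": trial.observer_id,
                    "image": trial.image_id,
                    "index": fix.index,
                    "x": fix.x,
                    "y": fix.y,
                    "onset_ms": fix.onset,
                    "duration_ms": fix.duration,
                    "is_detection": fl.is_detection,
                    "is_inspection": fl.is_inspection,
                    "is_return": fl.is_return,
                    "is_unlabelled": fl.is_unlabelled,
                    "detected": ";".join(sorted(fl.detected)),
                    "inspected": ";".join(sorted(fl.inspected)),
                    "returned": ";".join(sorted(fl.returned)),
                }
            )
    columns = [
        "observer", "image", "index", "x", "y", "onset_ms", "duration_ms",
        "is_detection", "is_inspection", "is_return", "is_unlabelled",
        "detected", "inspected", "returned",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_labels(trials: Sequence[Trial], labels: Sequence, path: str | Path) -> None:
    """Write per-fixation class labels to CSV, one row per fixation.

    Boolean class flags plus semicolon-joined object-id lists per class;
    the file round-trips bit-exactly through :func:`read_labels`.
    """
    _labels_frame(trials, labels).to_csv(path, index=False)


def read_labels(path: str | Path):
    """Read a labels CSV written by :func:`write_labels`.

    Returns
    -------
    list of (Trial, DIRLabels) pairs, grouped per (observer, image).
    """
    from .dir_classify import DIRLabels, FixationLabel

    df = pd.read_csv(
        path,
        dtype={"observer": str, "image": str},
        keep_default_na=False,
        na_values=[],
    )
    out = []
    for (obs, img), grp in df.groupby(["observer", "image"], sort=True):
        grp = grp.sort_values("index")
        fixations, labs = [], []
        for i, r in enumerate(grp.itertuples()):
            fixations.append(
                Fixation(
                    x=float(r.x), y=float(r.y), onset=float(r.onset_ms),
                    duration=float(r.duration_ms), index=i,
                )
            )
            labs.append(
                FixationLabel(
                    detected=frozenset(str(r.detected).split(";")) - {""},
                    inspected=frozenset(str(r.inspected).split(";")) - {""},
                    returned=frozenset(str(r.returned).split(";")) - {""},
                )
            )
        out.append(
            (
                Trial(observer_id=obs, image_id=img, fixations=tuple(fixations)),
                DIRLabels(labels=tuple(labs)),
            )
        )
    return out
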