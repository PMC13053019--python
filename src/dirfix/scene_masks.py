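"""Object masks, occlusion resolution and margin-tolerant hit testing.

A scene annotation holds one boolean support grid per object plus a depth
order (0 = nearest to viewer). Overlaps between raw masks are resolved in
favour of the nearer object, after which supports are pairwise disjoint.
Point-to-object assignment tolerates a margin: a fixation hits every
object whose support lies within ``margin_px`` of the (pixel-rounded)
fixation position, so a single fixation near a boundary may hit several
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigError, ContractError, DataError
from .gaze_io import ScreenGeometry

__all__ = [
    "ATTRIBUTE_VOCABULARY",
    "ObjectMask",
    "SceneAnnotation",
    "HitTester",
    "read_masks",
    "resolve_occlusion",
    "build_hit_tester",
    "hit_test",
    "write_masks",
]

#: the 12 binary semantic attributes of OSIE-style annotations
ATTRIBUTE_VOCABULARY: tuple[str, ...] = (
    "Face", "Emotion", "Touched", "Gazed", "Motion", "Sound",
    "Smell", "Taste", "Touch", "Text", "Watchable", "Operability",
)


@dataclass
class ObjectMask:
    """One object's pixel support, depth rank and semantic attributes."""

    object_id: str
    support: np.ndarray  # bool, (H, W)
    depth_rank: int
    attributes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)
        unknown = set(self.attributes) - set(ATTRIBUTE_VOCABULARY)
        if unknown:
            raise ConfigError(
                f"object '{self.object_id}': unknown attributes {sorted(unknown)}"
            )
        self.attributes = frozenset(self.attributes)

    @property
    def area(self) -> int:
        return int(self.support.sum())


@dataclass
class SceneAnnotation:
    """Occlusion-resolved object masks for one image."""

    image_id: str
    geometry: ScreenGeometry
    objects: list[ObjectMask]
    margin_px: float = 0.0

    def __post_init__(self) -> None:
        if self.margin_px < 0:
            raise ConfigError("margin_px must be >= 0")
        shape = (self.geometry.image_height, self.geometry.image_width)
        for obj in self.objects:
            if obj.support.shape != shape:
                raise DataError(
                    f"mask '{obj.object_id}' has shape {obj.support.shape}, "
                    f"expected {shape}"
                )

    def attribute_map(self) -> dict[str, frozenset[str]]:
        return {o.object_id: o.attributes for o in self.objects}


def resolve_occlusion(masks: Sequence[ObjectMask]) -> list[ObjectMask]:
    """Assign each contested pixel to the nearest object.

    A pixel claimed by several masks is kept only in the mask with the
    smallest ``depth_rank``; outputs are pairwise disjoint. Objects whose
    support becomes empty are dropped with a warning.
    """
    if not masks:
        return []
    ranks = [m.depth_rank for m in masks]
    if len(set(ranks)) != len(ranks):
        raise ContractError("duplicate depth_rank values in mask list")
    order = sorted(masks, key=lambda m: m.depth_rank)
    claimed = np.zeros(order[0].support.shape, dtype=bool)
    out: list[ObjectMask] = []
    for m in order:
        support = m.support & ~claimed
        claimed |= support
        if not support.any():
            warnings.warn(
                f"object '{m.object_id}' fully occluded; dropped", stacklevel=2
            )
            continue
        out.append(
            ObjectMask(
                object_id=m.object_id,
                support=support,
                depth_rank=m.depth_rank,
                attributes=m.attributes,
            )
        )
    return out


@dataclass
class HitTester:
    """Per-object Euclidean distance fields for fast point queries.

    ``distance[k, y, x]`` is the exact Euclidean pixel distance from
    pixel (y, x) to the nearest support pixel of object k (0 on the
    support itself). Queries never mutate the tester.
    """

    object_ids: tuple[str, ...]
    distance: np.ndarray  # float, (n_objects, H, W)

    @property
    def shape(self) -> tuple[int, int]:
        return self.distance.shape[1:]


def build_hit_tester(scene: SceneAnnotation) -> HitTester:
    """Precompute one exact Euclidean distance transform per object."""
    shape = (scene.geometry.image_height, scene.geometry.image_width)
    if not scene.objects:
        return HitTester(object_ids=(), distance=np.zeros((0, *shape)))
    fields = np.empty((len(scene.objects), *shape), dtype=np.float32)
    for k, obj in enumerate(scene.objects):
        fields[k] = ndimage.distance_transform_edt(~obj.support)
    return HitTester(
        object_ids=tuple(o.object_id for o in scene.objects), distance=fields
    )


def hit_test(
    tester: HitTester, x: float, y: float, margin_px: float
) -> frozenset[str]:
    """Return the ids of all objects within ``margin_px`` of (x, y).

    Continuous coordinates are rounded to the nearest pixel centre before
    the lookup. Out-of-image coordinates yield the empty set (the
    fixation is unlabellable, not an error).
    """
    if tester.distance.shape[0] == 0:
        return frozenset()
    h, w = tester.shape
    xi = int(round(x))
    yi = int(round(y))
    if not (0 <= xi < w and 0 <= yi < h):
        return frozenset()
    d = tester.distance[:, yi, xi]
    return frozenset(
        oid for oid, dist in zip(tester.object_ids, d) if dist <= margin_px
    )


# ---------------------------------------------------------------------------
# mask file IO
#
# Two dialects:
#   (a) one integer label image (0 = background, k > 0 = object k), assumed
#       pre-resolved and disjoint; optional sidecar CSV maps label values
#       to object ids / attributes.
#   (b) a directory of per-object binary PNGs named <object_id>.png plus a
#       sidecar CSV (object_id, depth_rank, one column per attribute).
# ---------------------------------------------------------------------------

def _read_attribute_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"object_id": str})
    if "object_id" not in df.columns:
        raise ConfigError("attribute table must have an 'object_id' column")
    return df.set_index("object_id")


def _attrs_from_row(row: pd.Series) -> frozenset[str]:
    return frozenset(
        a for a in ATTRIBUTE_VOCABULARY if a in row.index and bool(int(row[a]))
    )


def read_masks(
    path: str | Path,
    attribute_table: str | Path | None = None,
    resolve: bool = True,
) -> list[ObjectMask]:
    """Read object masks from a label image or a directory of binary PNGs.

    For the directory dialect, depth ranks come from the sidecar table's
    ``depth_rank`` column; if absent, file order is used with a warning.
    Label images are taken as pre-resolved (disjoint by construction), so
    ``resolve`` only matters for the directory dialect.
    """
    path = Path(path)
    table = None
    if attribute_table is not None:
        table = _read_attribute_table(attribute_table)
    if path.is_dir():
        sidecar = path / "objects.csv"
        if table is None and sidecar.exists():
            table = _read_attribute_table(sidecar)
        masks = []
        png_files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() == ".png" and p.name != "labels.png"
        )
        have_ranks = table is not None and "depth_rank" in table.columns
        if not have_ranks:
            warnings.warn(
                "no depth_rank sidecar; assigning ranks by file order",
                stacklevel=2,
            )
        for k, p in enumerate(png_files):
            oid = p.stem
            support = np.asarray(Image.open(p)) > 0
            if support.ndim == 3:
                support = support[..., 0]
            rank = k
            attrs: frozenset[str] = frozenset()
            if table is not None and oid in table.index:
                row = table.loc[oid]
                if have_ranks:
                    rank = int(row["depth_rank"])
                attrs = _attrs_from_row(row)
            masks.append(
                ObjectMask(object_id=oid, support=support, depth_rank=rank,
                           attributes=attrs)
            )
        if table is not None:
            known = {m.object_id for m in masks}
            for oid in table.index:
                if oid not in known:
                    warnings.warn(
                        f"attribute table names unknown object '{oid}'",
                        stacklevel=2,
                    )
        return resolve_occlusion(masks) if resolve else masks
    # dialect (a): integer label image
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    value_to_id: dict[int, str] = {}
    if table is not None and "label_value" in table.columns:
        value_to_id = {int(v): oid for oid, v in table["label_value"].items()}
    masks = []
    for k in np.unique(arr):
        if k == 0:
            continue
        oid = value_to_id.get(int(k), str(int(k)))
        attrs = frozenset()
        if table is not None and oid in table.index:
            attrs = _attrs_from_row(table.loc[oid])
        masks.append(
            ObjectMask(object_id=oid, support=arr == k, depth_rank=int(k),
                       attributes=attrs)
        )
    return masks


def write_masks(
    scene: SceneAnnotation, out_dir: str | Path, dialect: str = "both"
) -> None:
    """Write a scene's masks as a label PNG and/or per-object binary PNGs.

    A sidecar ``objects.csv`` records object_id, depth_rank, the label
    value used in the label image, and one 0/1 column per attribute.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = (scene.geometry.image_height, scene.geometry.image_width)
    rows = []
    label_img = np.zeros(shape, dtype=np.uint16)
    for value, obj in enumerate(scene.objects, start=1):
        label_img[obj.support] = value
        rows.append(
            {
                "object_id": obj.object_id,
                "depth_rank": obj.depth_rank,
                "label_value": value,
                **{a: int(a in obj.attributes) for a in ATTRIBUTE_VOCABULARY},
            }
        )
        if dialect in ("binary", "both"):
            Image.fromarray(obj.support.astype(np.uint8) * 255).save(
                out_dir / f"{obj.object_id}.png"
            )
    if dialect in ("label", "both"):
        Image.fromarray(label_img).save(out_dir / "labels.png")
    pd.DataFrame(rows).to_csv(out_dir / "objects.csv", index=False)
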