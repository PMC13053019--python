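"""Per-class fixation maps and split-half inter-observer consistency.

For every image and fixation class, the observers are split into two
halves (by parity of their enumeration order, as is conventional), a
smoothed fixation map is built per half, and the two halves' maps are
correlated for every ordered class pair. Per-pair correlations are
Fisher z-transformed, averaged across images, back-transformed and
squared, giving a 3 x 3 shared-variance (R^2) matrix whose diagonal holds
the within-class consistency. The diagonal-vs-everything contrast is
tested by subsampling coefficients from the whole matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .dir_classify import CLASSES, DIRLabels
from .errors import ContractError
from .gaze_io import Fixation, ScreenGeometry, Trial, dva_to_px

__all__ = [
    "FixationMap",
    "ConsistencyResult",
    "BootstrapResult",
    "make_fixation_map",
    "correlate_maps",
    "split_observers",
    "consistency_matrix",
    "bootstrap_diagonal_test",
]

logger = logging.getLogger(__name__)

#: correlations are clipped to +/-(1 - Z_CLIP) before the z-transform
Z_CLIP = 1e-7


@dataclass
class FixationMap:
    """Smoothed spatial density of fixations for one image and class."""

    image_id: str
    class_label: str
    grid: np.ndarray
    smoothing_sigma_dva: float
    downsample: int


def make_fixation_map(
    fixations: Sequence[Fixation] | Sequence[tuple[float, float]],
    geometry: ScreenGeometry,
    sigma_dva: float = 1.0,
    downsample: int = 4,
    weights: Sequence[float] | None = None,
    image_id: str = "",
    class_label: str = "all",
) -> FixationMap:
    """Build a Gaussian-smoothed fixation map on a downsampled grid.

    Each fixation deposits unit mass (or its *weight*, e.g. its duration)
    into its grid cell; the grid is then smoothed with an isotropic
    Gaussian of ``sigma_dva`` (converted to grid cells), truncated at
    3 sigma. Empty input yields an all-zero map.
    """
    if sigma_dva <= 0:
        raise ContractError("sigma_dva must be > 0")
    if downsample < 1:
        raise ContractError("downsample must be >= 1")
    h = geometry.image_height // downsample
    w = geometry.image_width // downsample
    grid = np.zeros((h, w))
    if weights is None:
        weights = [1.0] * len(fixations)
    for fix, wt in zip(fixations, weights):
        x, y = (fix.x, fix.y) if isinstance(fix, Fixation) else fix
        col = min(max(int(x / downsample), 0), w - 1)
        row = min(max(int(y / downsample), 0), h - 1)
        grid[row, col] += wt
    sigma_cells = dva_to_px(sigma_dva, geometry) / downsample
    grid = ndimage.gaussian_filter(grid, sigma=sigma_cells, truncate=3.0,
                                   mode="constant")
    return FixationMap(
        image_id=image_id, class_label=class_label, grid=grid,
        smoothing_sigma_dva=sigma_dva, downsample=downsample,
    )


def correlate_maps(a: FixationMap, b: FixationMap) -> float:
    """Pearson correlation of two maps over grid cells.

    Returns NaN (the undefined marker) when either map is constant;
    callers exclude those pairwise.
    """
    if a.grid.shape != b.grid.shape:
        raise ContractError(
            f"map shapes differ: {a.grid.shape} vs {b.grid.shape}"
        )
    av = a.grid.ravel()
    bv = b.grid.ravel()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return float("nan")
    ac = av - av.mean()
    bc = bv - bv.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def split_observers(
    observer_ids: Sequence[str], scheme: str = "parity"
) -> tuple[set[str], set[str]]:
    """Split observers into two halves (odd/even enumeration order)."""
    if scheme != "parity":
        raise ContractError(f"unknown split scheme '{scheme}'")
    ordered = sorted(set(observer_ids))
    return set(ordered[0::2]), set(ordered[1::2])


@dataclass
class ConsistencyResult:
    """Shared-variance matrix plus the raw per-image z tensor.

    ``r2[i, j]`` is the squared back-transformed mean Fisher z between
    group-A maps of class ``classes[i]`` and group-B maps of class
    ``classes[j]``. ``z`` has shape (n_images, 3, 3) with NaN marking
    undefined correlations (constant maps).
    """

    r2: np.ndarray
    z: np.ndarray
    classes: tuple[str, ...]
    image_ids: tuple[str, ...]
    n_images: int
    n_undefined: int


def consistency_matrix(
    corpus: Iterable[tuple[Trial, DIRLabels]],
    geometry: ScreenGeometry,
    sigma_dva: float = 1.0,
    downsample: int = 4,
    classes: tuple[str, ...] = CLASSES,
    split: tuple[set[str], set[str]] | None = None,
    duration_weighted: bool = False,
) -> ConsistencyResult:
    """Split-half, per-class fixation-map consistency across a corpus.

    For every image and ordered class pair (c_A, c_B), the group-A map of
    c_A is correlated with the group-B map of c_B; z values are averaged
    across images, back-transformed and squared. Images seen by only one
    half are skipped with a warning; undefined correlations (constant
    maps) are excluded pairwise and counted.
    """
    per_image: dict[str, dict[str, list[tuple[Trial, DIRLabels]]]] = {}
    observers = set()
    for trial, labels in corpus:
        if len(trial) != len(labels):
            raise ContractError("trial/labels length mismatch")
        per_image.setdefault(trial.image_id, {}).setdefault(
            trial.observer_id, []
        ).append((trial, labels))
        observers.add(trial.observer_id)
    if len(observers) < 2:
        raise ContractError("consistency needs at least 2 observers")
    group_a, group_b = split if split is not None else split_observers(observers)

    def class_map(items, c):
        pts, wts = [], []
        for trial, labels in items:
            for fix, lab in zip(trial.fixations, labels):
                if lab.has_class(c):
                    pts.append((fix.x, fix.y))
                    wts.append(fix.duration if duration_weighted else 1.0)
        return make_fixation_map(pts, geometry, sigma_dva, downsample,
                                 weights=wts, class_label=c)

    z_rows, kept_ids = [], []
    n_undef = 0
    for image_id in sorted(per_image):
        by_obs = per_image[image_id]
        items_a = [tl for o, ts in by_obs.items() if o in group_a for tl in ts]
        items_b = [tl for o, ts in by_obs.items() if o in group_b for tl in ts]
        if not items_a or not items_b:
            logger.warning("image %s present in only one half; skipped", image_id)
            continue
        maps_a = {c: class_map(items_a, c) for c in classes}
        maps_b = {c: class_map(items_b, c) for c in classes}
        zmat = np.full((len(classes), len(classes)), np.nan)
        for i, ca in enumerate(classes):
            for j, cb in enumerate(classes):
                r = correlate_maps(maps_a[ca], maps_b[cb])
                if np.isnan(r):
                    n_undef += 1
                    continue
                r = float(np.clip(r, -1 + Z_CLIP, 1 - Z_CLIP))
                zmat[i, j] = np.arctanh(r)
        z_rows.append(zmat)
        kept_ids.append(image_id)
    if not z_rows:
        raise ContractError("no image is viewed by members of both halves")
    z = np.stack(z_rows)
    with np.errstate(invalid="ignore"):
        mean_z = np.nanmean(z, axis=0)
    r2 = np.tanh(mean_z) ** 2
    return ConsistencyResult(
        r2=r2, z=z, classes=tuple(classes), image_ids=tuple(kept_ids),
        n_images=len(kept_ids), n_undefined=n_undef,
    )


@dataclass
class BootstrapResult:
    """Outcome of the diagonal-consistency subsampling test."""

    p_value: float
    observed_mean_z: float
    null_mean_z: float
    n_subsample: int
    n_boot: int
    seed: int


def bootstrap_diagonal_test(
    z: np.ndarray,
    n_subsample: int = 2100,
    n_boot: int = 10000,
    seed: int = 0,
) -> BootstrapResult:
    """Test whether within-class map consistency exceeds between-class.

    The observed statistic is the mean z over all diagonal entries
    (every image x every class). The null distribution is built by
    drawing ``n_subsample`` coefficients without replacement from the
    whole tensor (diagonal and off-diagonal alike) per iteration and
    taking their mean; one-sided p with add-one correction, ties counted
    as extreme.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 3 or z.shape[1] != z.shape[2]:
        raise ContractError("z must have shape (n_images, k, k)")
    diag = np.diagonal(z, axis1=1, axis2=2).ravel()
    diag = diag[~np.isnan(diag)]
    pool = z.ravel()
    pool = pool[~np.isnan(pool)]
    if pool.size == 0 or diag.size == 0:
        raise ContractError("z tensor holds no defined coefficients")
    if n_subsample > pool.size:
        raise ContractError(
            f"n_subsample={n_subsample} exceeds the {pool.size} available "
            "coefficients"
        )
    observed = float(diag.mean())
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(pool.size, size=n_subsample, replace=False)
        boot[b] = pool[idx].mean()
    p = (1 + int(np.sum(boot >= observed))) / (n_boot + 1)
    return BootstrapResult(
        p_value=float(p), observed_mean_z=observed,
        null_mean_z=float(boot.mean()), n_subsample=n_subsample,
        n_boot=n_boot, seed=seed,
    )
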