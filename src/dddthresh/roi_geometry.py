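"""Spherical ROIs, ROI grids, and inter-ROI Euclidean distances.

ROIs are spheres in a common millimetre coordinate space (typically a
template space such as MNI).  A :class:`ROISet` fixes an ordering that
defines the row/column order of every matrix downstream.  Distances are
centre-to-centre Euclidean, rounded half-away-from-zero to integer mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from ._round import round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "ROI",
    "ROISet",
    "DistanceMatrix",
    "euclidean_pair_distance",
    "distance_matrix",
    "make_roi_grid",
    "restrict_to_interface",
    "SpaceMismatchError",
]


class SpaceMismatchError(ValueError):
    """Raised when geometry from different coordinate spaces is mixed."""


@dataclass(frozen=True)
class ROI:
    """A spherical region of interest.

    Parameters
    ----------
    id : str
        Short unique identifier within an :class:`ROISet`.
    center : (3,) array-like of float
        Sphere centre in mm, in the set's coordinate space.
    radius : float
        Sphere radius in mm; must be positive.
    label : str, optional
        Free-text description.
    """

    id: str
    center: tuple[float, float, float]
    radius: float
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"ROI {self.id!r}: center must be a finite 3-vector")
        object.__setattr__(self, "center", tuple(float(v) for v in c))
        if not (self.radius > 0):
            raise ValueError(f"ROI {self.id!r}: radius must be > 0, got {self.radius}")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


class ROISet:
    """An ordered collection of ROIs sharing one coordinate space.

    The ordering is fixed at construction and defines the row/column order
    of every distance and connectivity matrix built from the set.
    """

    def __init__(self, rois: Iterable[ROI], space_tag: str = "mni", *, warn_overlap: bool = True):
        self.rois: list[ROI] = list(rois)
        self.space_tag = str(space_tag)
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ROI ids: {dupes}")
        if warn_overlap and self._has_overlap():
            logger.warning("ROISet %s contains overlapping spheres", space_tag)

    def _has_overlap(self) -> bool:
        if len(self.rois) < 2:
            return False
        centers = self.centers
        radii = np.array([r.radius for r in self.rois])
        d = pdist(centers)
        rsum = radii[:, None] + radii[None, :]
        iu = np.triu_indices(len(self.rois), k=1)
        return bool(np.any(d < rsum[iu]))

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rois]

    @property
    def centers(self) -> np.ndarray:
        """(n, 3) array of centres in mm."""
        if not self.rois:
            return np.empty((0, 3))
        return np.stack([r.center_array for r in self.rois])

    @property
    def radii(self) -> np.ndarray:
        return np.array([r.radius for r in self.rois], dtype=float)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.rois:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.rois[key]

    def index(self, roi_id: str) -> int:
        for i, r in enumerate(self.rois):
            if r.id == roi_id:
                return i
        raise KeyError(roi_id)

    def __repr__(self) -> str:
        return f"ROISet(n={len(self)}, space={self.space_tag!r})"


@dataclass
class DistanceMatrix:
    """Symmetric ROI x ROI integer-mm distances.

    ``measure`` is ``"euclidean"`` (centre-to-centre) or ``"streamline"``
    (group-averaged minimum connecting-streamline length).  Missing
    streamline distances are stored as -1.
    """

    values: np.ndarray
    roi_ids: list[str]
    measure: str = "euclidean"

    MISSING: int = field(default=-1, repr=False)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.roi_ids):
            raise ValueError("roi_ids length must match matrix size")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise ValueError("distance entries must be integers")
            v = v.astype(np.int64)
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if self.measure == "euclidean" and np.any(np.diag(v) != 0):
            raise ValueError("euclidean distance matrix must have zero diagonal")
        self.values = v.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.roi_ids)

    def pair(self, a: str, b: str) -> int:
        i, j = self.roi_ids.index(a), self.roi_ids.index(b)
        return int(self.values[i, j])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (unique pairs)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def euclidean_pair_distance(a: ROI, b: ROI, *, space_tags: tuple[str, str] | None = None) -> int:
    """Centre-to-centre Euclidean distance rounded to integer mm.

    Rounding is half-away-from-zero.  If ``space_tags`` is given the two
    tags must match, otherwise a :class:`SpaceMismatchError` is raised.
    """
    if space_tags is not None and space_tags[0] != space_tags[1]:
        raise SpaceMismatchError(
            f"ROIs live in different spaces: {space_tags[0]!r} vs {space_tags[1]!r}"
        )
    d = float(np.linalg.norm(a.center_array - b.center_array))
    return int(round_half_away(d))


def distance_matrix(rois: ROISet) -> DistanceMatrix:
    """Pairwise integer-mm Euclidean distance matrix for an ROI set.

    Requires at least two ROIs; the result is symmetric with a zero
    diagonal and inherits the set's ordering.
    """
    if len(rois) < 2:
        raise ValueError("distance_matrix needs at least 2 ROIs")
    centers = rois.centers
    d = cdist(centers, centers)
    vals = round_half_away(d)
    np.fill_diagonal(vals, 0)
    return DistanceMatrix(values=vals, roi_ids=rois.ids, measure="euclidean")


def _mask_world_points(mask_data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World-mm coordinates of the centres of nonzero voxels."""
    idx = np.argwhere(mask_data > 0)
    if idx.size == 0:
        return np.empty((0, 3))
    homog = np.c_[idx, np.ones(len(idx))]
    return (homog @ affine.T)[:, :3]


def make_roi_grid(
    mask=None,
    *,
    bounding_box: tuple[Sequence[float], Sequence[float]] | None = None,
    radius: float = 8.0,
    spacing: float = 16.0,
    space_tag: str = "mni",
    id_prefix: str = "roi",
) -> ROISet:
    """Regular cubic lattice of spherical ROIs clipped to a mask or box.

    Lattice points start at the lower corner of the mask/box bounding box
    and step by ``spacing`` along each axis.  With a mask (a nibabel
    spatial image or ``(data, affine)`` pair), only lattice points falling
    inside a nonzero voxel are kept.  Ids are deterministic, derived from
    the lattice index, so repeated calls are byte-identical.

    The default spacing of 16 mm gives touching (non-overlapping) spheres
    at the default 8 mm radius.
    """
    if spacing <= 0 or radius <= 0:
        raise ValueError("spacing and radius must be > 0")
    if (mask is None) == (bounding_box is None):
        raise ValueError("provide exactly one of mask or bounding_box")

    if bounding_box is not None:
        lo = np.asarray(bounding_box[0], dtype=float)
        hi = np.asarray(bounding_box[1], dtype=float)
        if lo.shape != (3,) or hi.shape != (3,) or np.any(hi < lo):
            raise ValueError("bounding_box must be (lo, hi) with hi >= lo")
        inside = None
        voxel_half = None
    else:
        if hasattr(mask, "get_fdata"):
            data = np.asarray(mask.get_fdata()) > 0
            affine = mask.affine
        else:
            data, affine = mask
            data = np.asarray(data) > 0
            affine = np.asarray(affine, dtype=float)
        pts = _mask_world_points(data, affine)
        if len(pts) == 0:
            raise ValueError("mask is empty: no ROI grid can be constructed")
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        inside = pts
        # half the largest voxel edge: a lattice point belongs to a voxel
        # if it lies within the voxel's axis-aligned extent
        voxel_half = 0.5 * np.max(np.abs(affine[:3, :3]).sum(axis=1))

    axes = [np.arange(lo[k], hi[k] + 1e-9, spacing) for k in range(3)]
    rois: list[ROI] = []
    for i, x in enumerate(axes[0]):
        for j, y in enumerate(axes[1]):
            for k, z in enumerate(axes[2]):
                p = np.array([x, y, z])
                if inside is not None:
                    if np.min(np.max(np.abs(inside - p), axis=1)) > voxel_half:
                        continue
                rois.append(
                    ROI(
                        id=f"{id_prefix}_{i:02d}_{j:02d}_{k:02d}",
                        center=tuple(p),
                        radius=radius,
                    )
                )
    return ROISet(rois, space_tag=space_tag)


def restrict_to_interface(rois: ROISet, interface_mask) -> ROISet:
    """Drop ROIs whose sphere contains no interface voxel.

    ``interface_mask`` is a binary volume (nibabel spatial image or
    ``(data, affine)``) marking the grey/white-matter interface; only ROIs
    whose sphere covers at least one nonzero voxel centre are kept, so
    that streamline termini assigned to them are anatomically plausible.
    Surviving ROIs keep their ids and order.  May return an empty set.
    """
    if hasattr(interface_mask, "get_fdata"):
        data = np.asarray(interface_mask.get_fdata()) > 0
        affine = interface_mask.affine
    else:
        data, affine = interface_mask
        data = np.asarray(data) > 0
        affine = np.asarray(affine, dtype=float)
    pts = _mask_world_points(data, affine)
    if len(pts) == 0:
        return ROISet([], space_tag=rois.space_tag)
    kept = []
    for r in rois:
        d = np.linalg.norm(pts - r.center_array, axis=1)
        if np.any(d <= r.radius):
            kept.append(r)
    return ROISet(kept, space_tag=rois.space_tag)
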