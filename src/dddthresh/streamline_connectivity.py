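"""Streamline endpoint assignment and ROI-pair connection scores.

A streamline is a 3D polyline; only its two termini take part in
connectivity.  A terminus is assigned to an ROI when it lies within a
radial search distance of the sphere surface (centre distance <= radius +
search), mirroring the capture zone used by tractography toolkits
(default 4 mm).  Streamlines merely passing through an ROI never count.

The connection score between ROIs A and B is the proportion of
streamlines emerging from A that terminate at B, averaged over the two
seeding directions, giving a symmetric score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._round import round_half_away
from .roi_geometry import ROISet, SpaceMismatchError

__all__ = [
    "Streamline",
    "Tractogram",
    "EndpointAssignment",
    "ConnectivityMatrix",
    "assign_endpoints",
    "connection_score",
    "connectivity_matrix",
    "pair_min_streamline_length",
    "streamline_distance_group",
    "streamline_distance_matrix",
    "DEFAULT_SEARCH_MM",
]

#: Radial search distance in mm within which a terminating streamline is
#: captured by an ROI (the MRtrix3 default).
DEFAULT_SEARCH_MM = 4.0


@dataclass(frozen=True)
class Streamline:
    """One fibre trajectory as an ordered polyline of mm points."""

    points: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("a streamline needs >= 2 points of 3 coordinates")
        object.__setattr__(self, "points", p)

    @property
    def length(self) -> float:
        """Arc length in mm (sum of consecutive point distances)."""
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class Tractogram:
    """A subject's collection of streamlines in one coordinate space."""

    subject_id: str
    streamlines: list[Streamline] = field(default_factory=list)
    space_tag: str = "mni"

    def __post_init__(self):
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class EndpointAssignment:
    """Per-streamline (start_roi, end_roi) assignment; None = unassigned."""

    assignments: list[tuple[Optional[str], Optional[str]]]
    roi_ids: list[str]
    search_mm: float

    def __len__(self) -> int:
        return len(self.assignments)

    def touching(self, roi_id: str) -> np.ndarray:
        """Indices of streamlines with >= 1 terminus assigned to roi_id."""
        return np.array(
            [i for i, (s, e) in enumerate(self.assignments) if roi_id in (s, e)],
            dtype=int,
        )

    def connecting(self, a: str, b: str) -> np.ndarray:
        """Indices of streamlines whose termini are assigned to {a, b}."""
        return np.array(
            [
                i
                for i, (s, e) in enumerate(self.assignments)
                if (s == a and e == b) or (s == b and e == a)
            ],
            dtype=int,
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI connection scores in [0, 1], zero diagonal."""

    values: np.ndarray
    roi_ids: list[str]
    subject_id: str = ""
    n_subjects: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.roi_ids):
            raise ValueError("roi_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric")
        v = 0.5 * (v + v.T)
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity diagonal must be zero")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("connection scores must lie in [0, 1]")
        self.values = v
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def n(self) -> int:
        return len(self.roi_ids)

    def pair(self, a: str, b: str) -> float:
        i, j = self.roi_ids.index(a), self.roi_ids.index(b)
        return float(self.values[i, j])

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _assign_terminus(point: np.ndarray, rois: ROISet, search_mm: float) -> Optional[str]:
    if len(rois) == 0:
        return None
    centers = rois.centers
    radii = rois.radii
    d = np.linalg.norm(centers - point, axis=1)
    within = d <= radii + search_mm
    if not np.any(within):
        return None
    # nearest centre wins; exact ties broken by lexicographic ROI id
    cand = np.flatnonzero(within)
    dmin = d[cand].min()
    tied = [rois.ids[i] for i in cand if d[i] == dmin]
    return min(tied)


def assign_endpoints(
    t: Tractogram, rois: ROISet, search_mm: float = DEFAULT_SEARCH_MM
) -> EndpointAssignment:
    """Assign each streamline terminus to at most one ROI.

    A terminus at centre distance d is captured by an ROI of radius r when
    d <= r + search_mm.  Among capturing ROIs the nearest centre wins,
    with exact ties broken by lexicographic id.  Interior streamline
    points are never considered.
    """
    if search_mm < 0:
        raise ValueError("search_mm must be >= 0")
    if t.space_tag != rois.space_tag:
        raise SpaceMismatchError(
            f"tractogram space {t.space_tag!r} != ROI space {rois.space_tag!r}"
        )
    assignments = [
        (_assign_terminus(s.start, rois, search_mm), _assign_terminus(s.end, rois, search_mm))
        for s in t
    ]
    return EndpointAssignment(assignments=assignments, roi_ids=rois.ids, search_mm=search_mm)


def _directed_counts(asg: EndpointAssignment):
    """Per-ROI terminus totals and per-ordered-pair connection counts."""
    touch: dict[str, int] = {rid: 0 for rid in asg.roi_ids}
    conn: dict[tuple[str, str], int] = {}
    for s, e in asg.assignments:
        for rid in {s, e} - {None}:
            touch[rid] += 1
        if s is not None and e is not None and s != e:
            key = (s, e) if s <= e else (e, s)
            conn[key] = conn.get(key, 0) + 1
    return touch, conn


def connection_score(asg: EndpointAssignment, seed: str, target: str) -> float:
    """Bidirectional connection score between two ROIs.

    Directed score(seed -> target) is the number of streamlines with one
    terminus at the seed and the other at the target, divided by the
    number of streamlines with at least one terminus at the seed.  The
    returned value is the mean of the two directed scores; a direction
    with no streamlines at its seed contributes 0.
    """
    if seed == target:
        raise ValueError("self-connections are undefined (diagonal is fixed at 0)")
    touch, conn = _directed_counts(asg)
    key = (seed, target) if seed <= target else (target, seed)
    n_conn = conn.get(key, 0)
    scores = []
    for s in (seed, target):
        denom = touch.get(s, 0)
        scores.append(n_conn / denom if denom > 0 else 0.0)
    return float(np.mean(scores))


def connectivity_matrix(
    t: Tractogram,
    rois: ROISet,
    search_mm: float = DEFAULT_SEARCH_MM,
    *,
    assignment: EndpointAssignment | None = None,
) -> ConnectivityMatrix:
    """Connection scores for every unordered ROI pair of a tractogram.

    The result is symmetric with zero diagonal by construction.  Pass a
    precomputed ``assignment`` to avoid re-assigning endpoints.
    """
    asg = assignment if assignment is not None else assign_endpoints(t, rois, search_mm)
    touch, conn = _directed_counts(asg)
    ids = rois.ids
    n = len(ids)
    vals = np.zeros((n, n))
    for (a, b), n_conn in conn.items():
        i, j = ids.index(a), ids.index(b)
        sc = []
        for s in (a, b):
            denom = touch[s]
            sc.append(n_conn / denom if denom > 0 else 0.0)
        vals[i, j] = vals[j, i] = float(np.mean(sc))
    return ConnectivityMatrix(values=vals, roi_ids=ids, subject_id=t.subject_id)


def pair_min_streamline_length(
    t: Tractogram, asg: EndpointAssignment, a: str, b: str
) -> Optional[float]:
    """Minimum arc length over streamlines connecting ROIs a and b.

    Returns None when no streamline connects the pair.
    """
    if a == b:
        raise ValueError("a and b must differ")
    idx = asg.connecting(a, b)
    if len(idx) == 0:
        return None
    return float(min(t.streamlines[i].length for i in idx))


def streamline_distance_group(
    per_subject_minima: Iterable[Optional[float]],
) -> Optional[int]:
    """Group streamline distance: mean of per-subject minima, integer mm.

    Subjects without a connecting streamline are treated as missing and
    dropped from the average; if every subject is missing the pair's
    streamline distance is missing (None).  The mean is rounded
    half-away-from-zero.
    """
    vals = [v for v in per_subject_minima if v is not None]
    if not vals:
        return None
    return int(round_half_away(float(np.mean(vals))))


def streamline_distance_matrix(
    tractograms: Sequence[Tractogram],
    rois: ROISet,
    search_mm: float = DEFAULT_SEARCH_MM,
):
    """Group streamline-distance matrix over a cohort of tractograms.

    For each subject and ROI pair the minimum connecting-streamline
    length is taken; these minima are averaged across subjects with
    missing pairs dropped, then rounded to integer mm.  Pairs missing in
    every subject carry the sentinel -1.
    """
    from .roi_geometry import DistanceMatrix

    ids = rois.ids
    n = len(ids)
    vals = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(vals, 0)
    per_pair: dict[tuple[int, int], list[Optional[float]]] = {}
    for t in tractograms:
        asg = assign_endpoints(t, rois, search_mm)
        subject_min: dict[tuple[int, int], float] = {}
        for k, (s, e) in enumerate(asg.assignments):
            if s is not None and e is not None and s != e:
                i, j = sorted((ids.index(s), ids.index(e)))
                L = t.streamlines[k].length
                if (i, j) not in subject_min or L < subject_min[(i, j)]:
                    subject_min[(i, j)] = L
        for i in range(n):
            for j in range(i + 1, n):
                per_pair.setdefault((i, j), []).append(subject_min.get((i, j)))
    for (i, j), vals_list in per_pair.items():
        d = streamline_distance_group(vals_list)
        if d is not None:
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(values=vals, roi_ids=ids, measure="streamline")
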