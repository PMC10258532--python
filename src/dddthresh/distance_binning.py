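"""Grouping integer inter-ROI distances into minimum-occupancy bins.

Unique integer distances are scanned in increasing order and pooled into
contiguous bins until each bin holds at least ``min_samples`` ROI-pair
samples, so every bin supports a well-powered empirical null.  The bin
count is emergent; it falls as ``min_samples`` rises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = ["DistanceBin", "DistanceBinning", "build_bins", "locate_bin"]


@dataclass
class DistanceBin:
    """A contiguous range [lo, hi] of integer mm distances."""

    lo: int
    hi: int
    n_samples: int
    member_pairs: list = field(default_factory=list)

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"bin lo {self.lo} > hi {self.hi}")

    def contains(self, d: int) -> bool:
        return self.lo <= d <= self.hi


@dataclass
class DistanceBinning:
    """Ordered, non-overlapping distance bins with an occupancy floor.

    ``underpowered`` is set when the total sample count could not reach
    ``min_samples`` and the single resulting bin falls short.
    """

    bins: list[DistanceBin]
    measure: str
    min_samples: int
    underpowered: bool = False

    def __post_init__(self):
        los = [b.lo for b in self.bins]
        if any(b.lo <= a.hi for a, b in zip(self.bins, self.bins[1:])):
            raise ValueError("bins must be ordered and non-overlapping")
        if los != sorted(los):
            raise ValueError("bins must be ordered by lo")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_samples(self) -> int:
        return sum(b.n_samples for b in self.bins)

    def edges(self) -> list[tuple[int, int]]:
        return [(b.lo, b.hi) for b in self.bins]

    def to_json(self) -> str:
        return json.dumps(
            {
                "measure": self.measure,
                "min_samples": self.min_samples,
                "underpowered": self.underpowered,
                "bins": [
                    {"lo": b.lo, "hi": b.hi, "n_samples": b.n_samples} for b in self.bins
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DistanceBinning":
        obj = json.loads(text)
        return cls(
            bins=[DistanceBin(b["lo"], b["hi"], b["n_samples"]) for b in obj["bins"]],
            measure=obj["measure"],
            min_samples=obj["min_samples"],
            underpowered=obj.get("underpowered", False),
        )


def build_bins(
    samples: Iterable[tuple[Hashable, int]],
    min_samples: int,
    *,
    measure: str = "euclidean",
) -> DistanceBinning:
    """Greedily pool sorted unique distances into minimum-occupancy bins.

    Parameters
    ----------
    samples : iterable of (pair, distance)
        One entry per ROI-pair sample; ``pair`` is an opaque reference
        kept as bin membership, ``distance`` an integer mm value.
    min_samples : int
        Occupancy floor per bin (>= 1).

    The scan accumulates consecutive unique distances until the running
    count reaches ``min_samples``, then closes the bin.  A terminal
    shortfall is merged into the previous bin.  If the total sample count
    is below ``min_samples`` a single flagged bin is returned.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    samples = list(samples)
    if not samples:
        raise ValueError("build_bins needs at least one sample")

    by_distance: dict[int, list] = {}
    for pair, d in samples:
        by_distance.setdefault(int(d), []).append(pair)
    distances = sorted(by_distance)

    bins: list[DistanceBin] = []
    cur_lo = None
    cur_pairs: list = []
    for d in distances:
        if cur_lo is None:
            cur_lo = d
        cur_pairs.extend(by_distance[d])
        if len(cur_pairs) >= min_samples:
            bins.append(DistanceBin(cur_lo, d, len(cur_pairs), cur_pairs))
            cur_lo, cur_pairs = None, []
    if cur_pairs:
        if bins:
            last = bins[-1]
            merged = last.member_pairs + cur_pairs
            bins[-1] = DistanceBin(last.lo, distances[-1], len(merged), merged)
        else:
            bins.append(DistanceBin(distances[0], distances[-1], len(cur_pairs), cur_pairs))

    underpowered = len(bins) == 1 and bins[0].n_samples < min_samples
    return DistanceBinning(
        bins=bins, measure=measure, min_samples=min_samples, underpowered=underpowered
    )


def locate_bin(binning: DistanceBinning, d: int) -> int:
    """Index of the bin containing distance ``d``, clamped at the ends.

    Distances below the first bin map to the first bin and above the last
    to the last; a distance falling in a gap between bins maps to the bin
    with the nearest boundary, the lower bin on ties.
    """
    if not binning.bins:
        raise ValueError("binning has no bins")
    bins = binning.bins
    if d <= bins[0].hi:
        return 0
    if d >= bins[-1].lo:
        return len(bins) - 1
    for i, b in enumerate(bins):
        if b.contains(d):
            return i
        nxt = bins[i + 1]
        if b.hi < d < nxt.lo:
            return i if (d - b.hi) <= (nxt.lo - d) else i + 1
    raise AssertionError("unreachable")  # pragma: no cover
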