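"""Monte-Carlo distance-dependent null distributions and thresholding.

For each distance bin, the empirical null of connection scores is the
multiset of candidate ROI-pair scores falling in that bin; resampling it
with replacement (default 100,000 draws) gives the bin's sampling
distribution.  The threshold at level alpha is the empirical quantile
leaving a fraction alpha of the distribution strictly above it, so small
alpha means a strict threshold.  Because score distributions decay with
distance, thresholds fall with distance: close ROI pairs must beat a high
bar, distant ones a low bar, removing the distance artefact that a single
uniform cutoff introduces.

A uniform-percentile baseline (one distance-blind cutoff for the whole
matrix) is provided for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .distance_binning import DistanceBinning, locate_bin
from .roi_geometry import DistanceMatrix
from .streamline_connectivity import ConnectivityMatrix

__all__ = [
    "SamplingDistribution",
    "DDDModel",
    "ThresholdedNetwork",
    "fit_sampling_distribution",
    "threshold_at_alpha",
    "empirical_upper_quantile",
    "fit_ddd",
    "apply_ddd",
    "group_average",
    "percentile_threshold",
    "matched_count_cutoff",
    "DEFAULT_ALPHAS",
    "DEFAULT_N_DRAWS",
]

#: Alpha levels used throughout: the fraction of a bin's sampling
#: distribution lying above its threshold.
DEFAULT_ALPHAS = (0.1, 0.2, 0.3)

#: Monte-Carlo draws per bin.
DEFAULT_N_DRAWS = 100_000


@dataclass
class SamplingDistribution:
    """Resampled null distribution of connection scores for one bin."""

    bin_index: int
    draws: np.ndarray
    rng_seed: int

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 1 or self.draws.size < 1:
            raise ValueError("draws must be a non-empty 1D array")

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)


def fit_sampling_distribution(
    bin_index: int,
    scores: Sequence[float],
    n_draws: int = DEFAULT_N_DRAWS,
    rng_seed: int = 0,
) -> SamplingDistribution:
    """Draw with replacement from a bin's candidate score multiset.

    Draws are i.i.d. uniform over the candidates and fully determined by
    ``rng_seed``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError(
            f"bin {bin_index}: empty candidate set; rebuild or merge the bin"
        )
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, scores.size, size=n_draws)
    return SamplingDistribution(bin_index=bin_index, draws=scores[idx], rng_seed=rng_seed)


def empirical_upper_quantile(values: Sequence[float], alpha: float) -> float:
    """Smallest value t with fraction(values strictly > t) <= alpha.

    This is the nearest-rank-lower (1 - alpha) empirical quantile: with n
    sorted values it is the order statistic at index n - floor(alpha * n) - 1.
    Under heavy ties (e.g. zero-inflated scores) the realised fraction
    above t can be well below alpha.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty value set")
    k = int(np.floor(alpha * n + 1e-9))
    return float(v[n - k - 1])


def threshold_at_alpha(dist: SamplingDistribution, alpha: float) -> float:
    """Threshold leaving a fraction alpha of the draws strictly above."""
    return empirical_upper_quantile(dist.draws, alpha)


@dataclass
class DDDModel:
    """Per-bin sampling distributions and alpha-level thresholds.

    ``thresholds[(bin_index, alpha)]`` is the connection-score cutoff for
    that bin; for a fixed bin it is non-increasing in alpha.  Raw draws
    are kept in memory for inspection but are not serialized.
    """

    binning: DistanceBinning
    alphas: tuple[float, ...]
    thresholds: dict[tuple[int, float], float]
    n_draws: int
    seed: int
    distributions: list[SamplingDistribution] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.alphas = tuple(sorted(float(a) for a in self.alphas))
        for b in range(self.binning.n_bins):
            ts = [self.thresholds[(b, a)] for a in self.alphas]
            if any(t1 < t2 for t1, t2 in zip(ts, ts[1:])):
                raise ValueError(f"bin {b}: thresholds must be non-increasing in alpha")

    def threshold(self, bin_index: int, alpha: float) -> float:
        return self.thresholds[(bin_index, float(alpha))]

    def to_json(self) -> str:
        obj = {
            "measure": self.binning.measure,
            "min_samples": self.binning.min_samples,
            "alphas": list(self.alphas),
            "n_draws": self.n_draws,
            "seed": self.seed,
            "bins": [
                {
                    "lo": b.lo,
                    "hi": b.hi,
                    "n_samples": b.n_samples,
                    "thresholds": {
                        repr(a): self.thresholds[(i, a)] for a in self.alphas
                    },
                }
                for i, b in enumerate(self.binning.bins)
            ],
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DDDModel":
        obj = json.loads(text)
        from .distance_binning import DistanceBin

        binning = DistanceBinning(
            bins=[DistanceBin(b["lo"], b["hi"], b["n_samples"]) for b in obj["bins"]],
            measure=obj["measure"],
            min_samples=obj["min_samples"],
        )
        alphas = tuple(obj["alphas"])
        thresholds = {
            (i, float(a)): float(b["thresholds"][repr(float(a))])
            for i, b in enumerate(obj["bins"])
            for a in alphas
        }
        return cls(
            binning=binning,
            alphas=alphas,
            thresholds=thresholds,
            n_draws=obj["n_draws"],
            seed=obj["seed"],
        )


def fit_ddd(
    binning: DistanceBinning,
    pair_scores: Iterable[tuple[Hashable, int, float]],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> DDDModel:
    """Fit one sampling distribution and threshold table per distance bin.

    Parameters
    ----------
    binning : DistanceBinning
        Output of :func:`~dddthresh.distance_binning.build_bins`.
    pair_scores : iterable of (pair, distance_mm, score)
        Candidate samples; each is routed to its bin by distance.
    alphas : sequence of float in (0, 1)
        Levels at which thresholds are extracted.
    n_draws : int
        Monte-Carlo draws per bin.
    seed : int
        Master seed; bin b uses ``seed + b`` so results do not depend on
        evaluation order.
    """
    per_bin: dict[int, list[float]] = {i: [] for i in range(binning.n_bins)}
    for _pair, d, score in pair_scores:
        per_bin[locate_bin(binning, int(d))].append(float(score))

    distributions = []
    thresholds: dict[tuple[int, float], float] = {}
    for b in range(binning.n_bins):
        dist = fit_sampling_distribution(b, per_bin[b], n_draws=n_draws, rng_seed=seed + b)
        distributions.append(dist)
        for a in alphas:
            thresholds[(b, float(a))] = threshold_at_alpha(dist, a)
    return DDDModel(
        binning=binning,
        alphas=tuple(alphas),
        thresholds=thresholds,
        n_draws=n_draws,
        seed=seed,
        distributions=distributions,
    )


@dataclass
class ThresholdedNetwork:
    """Edge table with the smallest surviving level per edge.

    ``edges`` has one row per unordered ROI pair with columns
    ``roi_a, roi_b, score, distance_mm, bin, tier``; ``tier`` is the
    smallest level at which the edge survives, or NaN.  Tier nesting
    holds by construction: an edge surviving level a survives every
    level above a.
    """

    roi_ids: list[str]
    alphas: tuple[float, ...]
    edges: pd.DataFrame
    source: str = ""

    def surviving_edges(self, alpha: float) -> set[frozenset]:
        """Unordered ROI-id pairs surviving at level ``alpha``."""
        ok = self.edges["tier"] <= alpha + 1e-12
        return {
            frozenset((a, b))
            for a, b in zip(self.edges.loc[ok, "roi_a"], self.edges.loc[ok, "roi_b"])
        }

    def n_surviving(self, alpha: float) -> int:
        return len(self.surviving_edges(alpha))

    def adjacency(self, alpha: float) -> np.ndarray:
        """Binary adjacency matrix of survivors at level ``alpha``."""
        n = len(self.roi_ids)
        pos = {rid: i for i, rid in enumerate(self.roi_ids)}
        m = np.zeros((n, n), dtype=int)
        for pair in self.surviving_edges(alpha):
            a, b = sorted(pair)
            m[pos[a], pos[b]] = m[pos[b], pos[a]] = 1
        return m

    def to_networkx(self, alpha: float):
        """Survivor graph at level ``alpha`` with score edge weights."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.roi_ids)
        ok = self.edges["tier"] <= alpha + 1e-12
        for _, row in self.edges.loc[ok].iterrows():
            g.add_edge(row["roi_a"], row["roi_b"], weight=row["score"])
        return g

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def apply_ddd(
    model: DDDModel,
    matrix: ConnectivityMatrix,
    distances: DistanceMatrix,
) -> ThresholdedNetwork:
    """Threshold a connectivity matrix with distance-matched null cutoffs.

    Each edge is routed to its distance bin and assigned the smallest
    alpha whose threshold its score strictly exceeds.  The distance
    measure of ``distances`` must match the model's; edges with missing
    distance (sentinel -1) are excluded.
    """
    if distances.measure != model.binning.measure:
        raise ValueError(
            f"distance measure {distances.measure!r} does not match "
            f"model measure {model.binning.measure!r}"
        )
    if distances.roi_ids != matrix.roi_ids:
        raise ValueError("ROI orderings of matrix and distances differ")

    rows = []
    ids = matrix.roi_ids
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(distances.values[i, j])
            if d < 0:
                continue
            b = locate_bin(model.binning, d)
            score = float(matrix.values[i, j])
            tier = np.nan
            for a in model.alphas:  # ascending; smallest surviving level
                if score > model.threshold(b, a):
                    tier = a
                    break
            rows.append((ids[i], ids[j], score, d, b, tier))
    edges = pd.DataFrame(
        rows, columns=["roi_a", "roi_b", "score", "distance_mm", "bin", "tier"]
    )
    return ThresholdedNetwork(
        roi_ids=list(ids), alphas=model.alphas, edges=edges, source="ddd"
    )


def group_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entrywise mean connectivity across subjects (zeros included)."""
    if not matrices:
        raise ValueError("group_average needs at least one matrix")
    ids = matrices[0].roi_ids
    for m in matrices[1:]:
        if m.roi_ids != ids:
            raise ValueError("ROI orderings differ across matrices")
    vals = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        values=vals,
        roi_ids=list(ids),
        subject_id="group",
        n_subjects=sum(m.n_subjects for m in matrices),
    )


def matched_count_cutoff(matrix: ConnectivityMatrix, n_edges: int) -> float:
    """Uniform cutoff admitting at most ``n_edges`` strict survivors.

    Returns the (n_edges + 1)-th largest off-diagonal score (0.0 when
    n_edges exceeds the pair count), so that thresholding strictly above
    the cutoff keeps at most ``n_edges`` edges; ties at the cutoff are
    dropped.
    """
    vals = np.sort(matrix.offdiag())[::-1]
    if n_edges >= vals.size:
        return -np.inf
    return float(vals[n_edges])


def percentile_threshold(
    matrix: ConnectivityMatrix,
    percentile: float,
    distances: Optional[DistanceMatrix] = None,
    *,
    cutoff: Optional[float] = None,
) -> ThresholdedNetwork:
    """Distance-blind baseline: one percentile cutoff for all edges.

    The cutoff is the nearest-rank ``percentile`` quantile of the
    off-diagonal (upper-triangle) scores; edges strictly above it
    survive.  Smaller percentiles are more lenient.  Pass ``cutoff`` to
    override the percentile with an explicit value (used for matching a
    surviving-edge count).  Survivor sets are nested across percentiles.
    """
    if cutoff is None:
        if not (0 < percentile < 1):
            raise ValueError("percentile must lie in (0, 1)")
        vals = np.sort(matrix.offdiag())
        # nearest-rank percentile: ceil(P * n)-th smallest value
        r = int(np.ceil(percentile * vals.size - 1e-9))
        cutoff = float(vals[r - 1]) if r >= 1 else -np.inf

    ids = matrix.roi_ids
    n = len(ids)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            score = float(matrix.values[i, j])
            d = int(distances.values[i, j]) if distances is not None else -1
            tier = percentile if score > cutoff else np.nan
            rows.append((ids[i], ids[j], score, d, -1, tier))
    edges = pd.DataFrame(
        rows, columns=["roi_a", "roi_b", "score", "distance_mm", "bin", "tier"]
    )
    return ThresholdedNetwork(
        roi_ids=list(ids), alphas=(percentile,), edges=edges, source="percentile"
    )
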