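"""Synthetic cohorts with distance-decaying, zero-inflated connectivity.

The generator emulates the statistical structure that distance-dependent
thresholding assumes in real probabilistic-tractography connectomes:

* most ROI pairs are null, with connection scores that are zero-inflated,
  right-skewed and decaying with inter-ROI distance (the probability of
  an exact zero grows with distance, the magnitude scale shrinks);
* a small set of planted "bundles" — true connections — carries scores
  drawn from a log-normal whose median decays more slowly with distance
  than the null scale, so long-range bundles are weak in absolute terms
  yet strong relative to their distance-matched null.

Planted ground truth is recorded before noise, enabling sensitivity and
specificity evaluation of any thresholding rule, stratified into short-
and long-range edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .distance_binning import build_bins
from .ddd_core import (
    DEFAULT_N_DRAWS,
    ThresholdedNetwork,
    apply_ddd,
    fit_ddd,
    group_average,
    matched_count_cutoff,
    percentile_threshold,
)
from .roi_geometry import ROI, ROISet, distance_matrix
from .streamline_connectivity import ConnectivityMatrix, Streamline, Tractogram

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantedEdge",
    "simulate_cohort",
    "simulate_tractogram",
    "evaluate_recovery",
    "run_recovery_replicate",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Distances below are in mm.  The null score for a pair at distance d
    is 0 with probability pi0(d) = pi_max - (pi_max - pi_min) *
    exp(-d / zero_decay_length), otherwise |Normal(0, null_scale *
    exp(-d / decay_length))|.  A planted bundle draws from a log-normal
    with median strength * exp(-d / (2 * decay_length)) and shape
    ``planted_sigma``; the slower decay (half the null rate) makes long
    bundles weak absolutely but strong against their local null.  Scores
    are clipped to [0, 1].
    """

    n_subjects: int = 30
    n_rois: int = 60
    extent_mm: float = 120.0
    roi_radius_mm: float = 8.0

    n_long_planted: int = 20
    long_min_distance_mm: float = 80.0
    n_short_planted: int = 10
    short_max_distance_mm: float = 40.0

    decay_length_mm: float = 40.0
    null_scale: float = 0.5
    zero_pi_min: float = 0.1
    zero_pi_max: float = 0.9
    zero_decay_length_mm: float = 80.0

    long_planted_median: float = 0.1
    short_planted_median: float = 0.6
    planted_sigma: float = 0.4

    seed: int = 0

    def __post_init__(self):
        if self.decay_length_mm <= 0 or self.zero_decay_length_mm <= 0:
            raise ValueError("decay lengths must be > 0")
        for p in (self.zero_pi_min, self.zero_pi_max):
            if not (0 <= p <= 1):
                raise ValueError("zero-inflation probabilities must lie in [0, 1]")
        if self.zero_pi_min > self.zero_pi_max:
            raise ValueError("zero_pi_min must not exceed zero_pi_max")

    def pi0(self, d):
        """Probability of an exact zero for a null pair at distance d."""
        d = np.asarray(d, dtype=float)
        return self.zero_pi_max - (self.zero_pi_max - self.zero_pi_min) * np.exp(
            -d / self.zero_decay_length_mm
        )

    def null_sigma(self, d):
        """Magnitude scale of the null half-normal at distance d."""
        return self.null_scale * np.exp(-np.asarray(d, dtype=float) / self.decay_length_mm)

    def planted_median(self, d, cls: str):
        base = self.long_planted_median if cls == "long_bundle" else self.short_planted_median
        return base * np.exp(-np.asarray(d, dtype=float) / (2 * self.decay_length_mm))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedEdge:
    roi_a: str
    roi_b: str
    cls: str  # "short_bundle" | "long_bundle"
    distance_mm: float
    median: float


@dataclass
class GroundTruth:
    """Planted true edges, recorded before noise is applied."""

    edges: list[PlantedEdge]
    roi_ids: list[str]

    @property
    def pairs(self) -> set[frozenset]:
        return {frozenset((e.roi_a, e.roi_b)) for e in self.edges}

    def pairs_in(self, cls: str) -> set[frozenset]:
        return {frozenset((e.roi_a, e.roi_b)) for e in self.edges if e.cls == cls}


def _place_rois(cfg: GeneratorConfig, rng: np.random.Generator) -> ROISet:
    centers = rng.uniform(0.0, cfg.extent_mm, size=(cfg.n_rois, 3))
    rois = [
        ROI(id=f"roi{i:03d}", center=tuple(c), radius=cfg.roi_radius_mm)
        for i, c in enumerate(centers)
    ]
    # randomly placed spheres overlap by design; scores are simulated,
    # not derived from the geometry, so the overlap warning is moot here
    return ROISet(rois, space_tag="synthetic", warn_overlap=False)


def _plant_edges(
    cfg: GeneratorConfig, rois: ROISet, dists: np.ndarray, rng: np.random.Generator
) -> list[PlantedEdge]:
    ids = rois.ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    pair_d = dists[iu]
    long_ok = np.flatnonzero(pair_d >= cfg.long_min_distance_mm)
    short_ok = np.flatnonzero(pair_d <= cfg.short_max_distance_mm)
    if len(long_ok) < cfg.n_long_planted:
        raise ValueError(
            f"only {len(long_ok)} pairs at >= {cfg.long_min_distance_mm} mm; "
            f"cannot plant {cfg.n_long_planted} long bundles"
        )
    if len(short_ok) < cfg.n_short_planted:
        raise ValueError(
            f"only {len(short_ok)} pairs at <= {cfg.short_max_distance_mm} mm; "
            f"cannot plant {cfg.n_short_planted} short bundles"
        )
    chosen_long = rng.choice(long_ok, size=cfg.n_long_planted, replace=False)
    chosen_short = rng.choice(short_ok, size=cfg.n_short_planted, replace=False)
    edges = []
    for sel, cls in ((chosen_short, "short_bundle"), (chosen_long, "long_bundle")):
        for k in sel:
            i, j = iu[0][k], iu[1][k]
            d = float(pair_d[k])
            edges.append(
                PlantedEdge(
                    roi_a=ids[i],
                    roi_b=ids[j],
                    cls=cls,
                    distance_mm=d,
                    median=float(cfg.planted_median(d, cls)),
                )
            )
    return edges


def simulate_cohort(
    cfg: GeneratorConfig,
) -> tuple[ROISet, list[ConnectivityMatrix], GroundTruth]:
    """Generate ROIs, per-subject connectivity matrices and ground truth.

    Fully deterministic given ``cfg.seed``.  Matrices are symmetric with
    zero diagonal and scores clipped to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    rois = _place_rois(cfg, rng)
    dists = squareform(pdist(rois.centers))
    planted = _plant_edges(cfg, rois, dists, rng)
    truth = GroundTruth(edges=planted, roi_ids=rois.ids)

    ids = rois.ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    pair_d = dists[iu]
    n_pairs = pair_d.size

    planted_idx: dict[int, PlantedEdge] = {}
    pos = {rid: i for i, rid in enumerate(ids)}
    flat = {(i, j): k for k, (i, j) in enumerate(zip(iu[0], iu[1]))}
    for e in planted:
        i, j = sorted((pos[e.roi_a], pos[e.roi_b]))
        planted_idx[flat[(i, j)]] = e

    pi0 = cfg.pi0(pair_d)
    sigma = cfg.null_sigma(pair_d)

    matrices = []
    for s in range(cfg.n_subjects):
        zeros = rng.random(n_pairs) < pi0
        scores = np.abs(rng.normal(0.0, 1.0, size=n_pairs)) * sigma
        scores[zeros] = 0.0
        for k, e in planted_idx.items():
            scores[k] = rng.lognormal(mean=np.log(e.median), sigma=cfg.planted_sigma)
        scores = np.clip(scores, 0.0, 1.0)
        vals = np.zeros((n, n))
        vals[iu] = scores
        vals += vals.T
        matrices.append(
            ConnectivityMatrix(values=vals, roi_ids=list(ids), subject_id=f"sub{s:03d}")
        )
    return rois, matrices, truth


def _point_in_sphere(roi: ROI, rng: np.random.Generator, shrink: float = 0.5) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = roi.radius * shrink * rng.random() ** (1 / 3)
    return roi.center_array + v * r


def simulate_tractogram(
    cfg: GeneratorConfig,
    rois: ROISet,
    pair_streamline_counts: dict[tuple[str, str], int],
    n_background: int = 0,
    subject_id: str = "sim",
    n_waypoints: int = 3,
    jitter_mm: float = 2.0,
    seed: Optional[int] = None,
) -> Tractogram:
    """Emit jittered polylines connecting requested ROI pairs.

    Each requested streamline runs from a point inside ROI a to a point
    inside ROI b through jittered intermediate waypoints, so its arc
    length is at least the terminus separation.  Background streamlines
    are placed far outside the ROI volume and stay unassigned.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    streamlines: list[Streamline] = []
    for (a, b), count in sorted(pair_streamline_counts.items()):
        if count < 0:
            raise ValueError("streamline counts must be >= 0")
        ra, rb = rois[a], rois[b]
        for _ in range(count):
            p0 = _point_in_sphere(ra, rng)
            p1 = _point_in_sphere(rb, rng)
            ts = np.linspace(0, 1, n_waypoints + 2)[1:-1]
            mid = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
            mid = mid + rng.normal(0.0, jitter_mm, size=mid.shape)
            streamlines.append(Streamline(np.vstack([p0, mid, p1])))
    far = cfg.extent_mm + 100.0
    for _ in range(n_background):
        p0 = rng.uniform(far, far + 100.0, size=3)
        p1 = rng.uniform(far, far + 100.0, size=3)
        streamlines.append(Streamline(np.vstack([p0, p1])))
    return Tractogram(subject_id=subject_id, streamlines=streamlines, space_tag=rois.space_tag)


def evaluate_recovery(
    truth: GroundTruth,
    net: ThresholdedNetwork,
    distance_cut_mm: float,
    alpha: Optional[float] = None,
) -> dict:
    """Sensitivity/specificity of a thresholded network vs planted truth.

    Metrics are reported overall and stratified into short (< cut) and
    long (>= cut) edges using the per-edge distances carried by the
    network.  ``alpha`` defaults to the network's most lenient level.
    """
    if alpha is None:
        alpha = max(net.alphas)
    surviving = net.surviving_edges(alpha)
    true_pairs = truth.pairs

    def _rates(edge_rows):
        tp = fp = fn = tn = 0
        for _, row in edge_rows.iterrows():
            pair = frozenset((row["roi_a"], row["roi_b"]))
            pred = pair in surviving
            real = pair in true_pairs
            tp += pred and real
            fp += pred and not real
            fn += (not pred) and real
            tn += (not pred) and (not real)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return sens, spec

    edges = net.edges
    if (edges["distance_mm"] < 0).any():
        raise ValueError("network edges lack distances; cannot stratify")
    short = edges[edges["distance_mm"] < distance_cut_mm]
    long_ = edges[edges["distance_mm"] >= distance_cut_mm]
    sens, spec = _rates(edges)
    s_sens, s_spec = _rates(short)
    l_sens, l_spec = _rates(long_)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "short_sensitivity": s_sens,
        "short_specificity": s_spec,
        "long_sensitivity": l_sens,
        "long_specificity": l_spec,
        "n_surviving": len(surviving),
    }


def run_recovery_replicate(
    cfg: GeneratorConfig,
    alpha: float = 0.1,
    min_samples: int = 100,
    n_draws: int = DEFAULT_N_DRAWS,
) -> dict:
    """One end-to-end recovery comparison: DDD vs matched percentile cutoff.

    Simulates a cohort, fits the distance-dependent null on the group
    average, thresholds at ``alpha``, then applies a uniform cutoff
    matched to the same surviving-edge count, and scores both against
    the planted truth with long/short stratification at the planted
    long-range boundary.
    """
    rois, matrices, truth = simulate_cohort(cfg)
    group = group_average(matrices)
    dmat = distance_matrix(rois)

    iu = np.triu_indices(len(rois), k=1)
    pairs = [
        ((dmat.roi_ids[i], dmat.roi_ids[j]), int(dmat.values[i, j]), float(group.values[i, j]))
        for i, j in zip(*iu)
    ]
    binning = build_bins([(p, d) for p, d, _ in pairs], min_samples=min_samples)
    model = fit_ddd(binning, pairs, alphas=(alpha,), n_draws=n_draws, seed=cfg.seed + 10_000)
    ddd_net = apply_ddd(model, group, dmat)
    k = ddd_net.n_surviving(alpha)

    cutoff = matched_count_cutoff(group, k)
    base_net = percentile_threshold(group, 0.5, distances=dmat, cutoff=cutoff)

    cut = cfg.long_min_distance_mm
    return {
        "ddd": evaluate_recovery(truth, ddd_net, cut, alpha=alpha),
        "baseline": evaluate_recovery(truth, base_net, cut),
        "n_surviving_ddd": k,
        "n_surviving_baseline": base_net.n_surviving(0.5),
        "n_bins": binning.n_bins,
    }
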