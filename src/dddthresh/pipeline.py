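"""End-to-end workflow: scores -> distances -> bins -> null model -> network.

The pipeline mirrors the standard use of distance-dependent thresholds:
per-subject connectivity is computed (or loaded), averaged into a group
matrix, inter-ROI distances are binned, a Monte-Carlo null is fitted per
bin, and the resulting thresholds are applied back to the group matrix.
All intermediates are written to the output directory together with a
manifest recording input checksums, the seed and package version, so a
rerun with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .distance_binning import build_bins
from .ddd_core import (
    DEFAULT_ALPHAS,
    DEFAULT_N_DRAWS,
    apply_ddd,
    fit_ddd,
    group_average,
)
from .io import (
    read_connectivity_matrix,
    read_roi_table,
    read_streamlines_text,
    read_tck,
    write_matrix,
)
from .roi_geometry import distance_matrix
from .streamline_connectivity import (
    DEFAULT_SEARCH_MM,
    connectivity_matrix,
    streamline_distance_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full thresholding run.

    Provide either ``tractogram_paths`` (TCK or plain text; connectivity
    and streamline distances are computed) or ``matrix_paths``
    (per-subject connectivity CSVs; only Euclidean distances are then
    available).
    """

    roi_table: Union[str, Path]
    out_dir: Union[str, Path]
    tractogram_paths: Sequence[Union[str, Path]] = field(default_factory=list)
    matrix_paths: Sequence[Union[str, Path]] = field(default_factory=list)
    measure: str = "euclidean"
    search_mm: float = DEFAULT_SEARCH_MM
    min_samples: int = 100
    alphas: Sequence[float] = DEFAULT_ALPHAS
    n_draws: int = DEFAULT_N_DRAWS
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        alphas = sorted(float(a) for a in self.alphas)
        if any(not (0 < a < 1) for a in alphas):
            raise ValueError("alphas must lie in (0, 1)")
        self.alphas = alphas
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if bool(self.tractogram_paths) == bool(self.matrix_paths):
            raise ValueError("provide exactly one of tractogram_paths or matrix_paths")
        if self.measure not in ("euclidean", "streamline"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.measure == "streamline" and not self.tractogram_paths:
            raise ValueError("streamline distances require tractograms")

    def to_dict(self) -> dict:
        return {
            "roi_table": str(self.roi_table),
            "out_dir": str(self.out_dir),
            "tractogram_paths": [str(p) for p in self.tractogram_paths],
            "matrix_paths": [str(p) for p in self.matrix_paths],
            "measure": self.measure,
            "search_mm": self.search_mm,
            "min_samples": self.min_samples,
            "alphas": list(self.alphas),
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_tractogram(path: Path):
    if path.suffix == ".tck":
        return read_tck(path)
    return read_streamlines_text(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "version": __version__,
        "inputs": {},
        "outputs": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return deco

    @stage("load")
    def loaded():
        rois = read_roi_table(cfg.roi_table)
        manifest["inputs"][str(cfg.roi_table)] = _sha256(cfg.roi_table)
        if cfg.tractogram_paths:
            tracts = []
            for p in cfg.tractogram_paths:
                p = Path(p)
                tracts.append(_load_tractogram(p))
                manifest["inputs"][str(p)] = _sha256(p)
            return rois, tracts, None
        mats = []
        for p in cfg.matrix_paths:
            mats.append(read_connectivity_matrix(p))
            manifest["inputs"][str(p)] = _sha256(p)
        return rois, None, mats

    rois, tracts, mats = loaded

    @stage("connect")
    def matrices():
        if tracts is not None:
            return [connectivity_matrix(t, rois, cfg.search_mm) for t in tracts]
        for m in mats:
            if m.roi_ids != rois.ids:
                raise ValueError(f"matrix {m.subject_id!r} ROI ids differ from ROI table")
        return mats

    group = group_average(matrices)
    write_matrix(group, out / "group_connectivity.csv")
    manifest["outputs"]["group_connectivity"] = "group_connectivity.csv"

    @stage("distances")
    def dmat():
        if cfg.measure == "euclidean":
            return distance_matrix(rois)
        return streamline_distance_matrix(tracts, rois, cfg.search_mm)

    write_matrix(dmat, out / "distances.csv")
    manifest["outputs"]["distances"] = "distances.csv"

    iu = np.triu_indices(len(rois), k=1)
    pair_samples = [
        ((dmat.roi_ids[i], dmat.roi_ids[j]), int(dmat.values[i, j]), float(group.values[i, j]))
        for i, j in zip(*iu)
        if dmat.values[i, j] >= 0
    ]

    @stage("bins")
    def binning():
        return build_bins(
            [(p, d) for p, d, _ in pair_samples],
            min_samples=cfg.min_samples,
            measure=cfg.measure,
        )

    (out / "bins.json").write_text(binning.to_json())
    manifest["outputs"]["bins"] = "bins.json"

    @stage("fit-ddd")
    def model():
        return fit_ddd(
            binning, pair_samples, alphas=cfg.alphas, n_draws=cfg.n_draws, seed=cfg.seed
        )

    (out / "ddd_model.json").write_text(model.to_json())
    manifest["outputs"]["model"] = "ddd_model.json"

    @stage("threshold")
    def net():
        return apply_ddd(model, group, dmat)

    net.to_tsv(out / "thresholded_edges.tsv")
    manifest["outputs"]["thresholded_edges"] = "thresholded_edges.tsv"

    manifest["n_surviving"] = {
        repr(a): net.n_surviving(a) for a in cfg.alphas
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
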