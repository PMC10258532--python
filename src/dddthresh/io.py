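"""File formats: ROI tables, matrices, streamlines, packaged fixtures.

Formats
-------
ROI table
    TSV with header ``id  x  y  z  radius  label``; mm floats.
Matrices
    CSV with ROI ids as first row and column.  Connectivity matrices are
    validated symmetric within 1e-9 and symmetrized by averaging;
    distance matrices must be exactly symmetric integers.
Streamlines
    MRtrix TCK via nibabel, plus a plain-text interchange format (one
    block per streamline: a ``# <id>`` line then ``x y z`` lines) used
    for small fixtures.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .roi_geometry import ROI, ROISet, DistanceMatrix
from .streamline_connectivity import (
    ConnectivityMatrix,
    EndpointAssignment,
    Streamline,
    Tractogram,
)

__all__ = [
    "read_roi_table",
    "write_roi_table",
    "read_connectivity_matrix",
    "read_distance_matrix",
    "write_matrix",
    "read_streamlines_text",
    "write_streamlines_text",
    "read_tck",
    "write_tck",
    "write_assignment",
    "load_language_distances",
]

ROI_COLUMNS = ["id", "x", "y", "z", "radius", "label"]


def read_roi_table(path: Union[str, Path], space_tag: str = "mni") -> ROISet:
    """Read an ROI definition TSV, preserving row order.

    Malformed rows are rejected with their line number; duplicate ids
    are rejected.  A header-only file yields an empty set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ROI_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    rois = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            rois.append(
                ROI(
                    id=row["id"],
                    center=(float(row["x"]), float(row["y"]), float(row["z"])),
                    radius=float(row["radius"]),
                    label=row.get("label", ""),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed ROI at line {line}: {exc}") from exc
    return ROISet(rois, space_tag=space_tag)


def write_roi_table(rois: ROISet, path: Union[str, Path]) -> None:
    rows = [
        {"id": r.id, "x": r.center[0], "y": r.center[1], "z": r.center[2],
         "radius": r.radius, "label": r.label}
        for r in rois
    ]
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_square(path: Union[str, Path]) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if ids_row != ids_col:
        raise ValueError(f"{path}: row and column ROI ids differ")
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return vals, ids_row


def read_connectivity_matrix(
    path: Union[str, Path], subject_id: str = "", n_subjects: int = 1
) -> ConnectivityMatrix:
    """Read a connection-score CSV; asymmetry beyond 1e-9 is rejected."""
    vals, ids = _read_square(path)
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance 1e-9")
    vals = 0.5 * (vals + vals.T)
    return ConnectivityMatrix(
        values=vals, roi_ids=ids, subject_id=subject_id or str(path), n_subjects=n_subjects
    )


def read_distance_matrix(path: Union[str, Path], measure: str = "euclidean") -> DistanceMatrix:
    """Read an integer-mm distance CSV; must be exactly symmetric."""
    vals, ids = _read_square(path)
    if not np.array_equal(vals, vals.T):
        raise ValueError(f"{path}: distance matrix must be exactly symmetric")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError(f"{path}: distance entries must be integers")
    return DistanceMatrix(values=vals.astype(np.int64), roi_ids=ids, measure=measure)


def write_matrix(
    matrix: Union[ConnectivityMatrix, DistanceMatrix], path: Union[str, Path]
) -> None:
    vals = matrix.values
    df = pd.DataFrame(vals, index=matrix.roi_ids, columns=matrix.roi_ids)
    if isinstance(matrix, DistanceMatrix):
        df.to_csv(path)
    else:
        df.to_csv(path, float_format="%.10g")


def read_streamlines_text(
    path: Union[str, Path], subject_id: str = "", space_tag: str = "mni"
) -> Tractogram:
    """Read the plain-text streamline interchange format."""
    path = Path(path)
    streamlines = []
    points: list[list[float]] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if points:
                streamlines.append(Streamline(np.array(points)))
                points = []
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: line {ln}: expected 'x y z'")
        points.append([float(v) for v in parts])
    if points:
        streamlines.append(Streamline(np.array(points)))
    return Tractogram(
        subject_id=subject_id or path.stem, streamlines=streamlines, space_tag=space_tag
    )


def write_streamlines_text(t: Tractogram, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(t.streamlines):
            fh.write(f"# {i}\n")
            for p in s.points:
                fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")


def read_tck(path: Union[str, Path], subject_id: str = "", space_tag: str = "mni") -> Tractogram:
    """Read an MRtrix .tck track file."""
    import nibabel as nib

    tck = nib.streamlines.load(str(path))
    streamlines = [Streamline(np.asarray(s, dtype=float)) for s in tck.streamlines]
    return Tractogram(
        subject_id=subject_id or Path(path).stem, streamlines=streamlines, space_tag=space_tag
    )


def write_tck(t: Tractogram, path: Union[str, Path]) -> None:
    """Write an MRtrix .tck track file."""
    import nibabel as nib

    tractogram = nib.streamlines.Tractogram(
        [s.points for s in t.streamlines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.TckFile(tractogram).save(str(path))


def write_assignment(asg: EndpointAssignment, path: Union[str, Path]) -> None:
    """Export endpoint assignments as TSV with '-' for unassigned."""
    rows = [
        {"streamline_index": i, "start_roi": s or "-", "end_roi": e or "-"}
        for i, (s, e) in enumerate(asg.assignments)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_language_distances() -> DistanceMatrix:
    """Packaged reference distance table for 13 left-hemisphere language ROIs.

    Integer-mm centre-to-centre Euclidean distances between literature
    language/reading ROIs (fusiform, temporal, inferior frontal,
    premotor, supramarginal and anterior temporal regions), used in the
    worked examples and tests.
    """
    ref = resources.files("dddthresh").joinpath("data/language_roi_distances.csv")
    with resources.as_file(ref) as p:
        return read_distance_matrix(p)
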