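"""Reading and writing cell tables, landmark files, transforms and match tables.

Cell tables are delimited-text segmentation exports (one row per cell) in the
style of QuPath measurement exports: centroid x/y columns in pixels plus
arbitrary per-cell feature columns (area, perimeter, solidity, mean stain
intensity, ...). Ingestion converts centroids to micrometers immediately so
that every downstream module works in physical units; feature columns pass
through untouched. This module isolates the file dialects from the math core.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import LandmarkPairs, RigidTransform, pixels_to_microns

logger = logging.getLogger(__name__)

__all__ = [
    "CellTable",
    "SchemaError",
    "EmptyInputError",
    "ReferentialIntegrityError",
    "DIALECTS",
    "read_cell_table",
    "write_cell_table",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "read_match_table",
    "write_match_table",
]


class SchemaError(ValueError):
    """Required columns are missing from an input table."""


class EmptyInputError(ValueError):
    """An input table contains no usable rows."""


class ReferentialIntegrityError(ValueError):
    """A match references a cell id absent from its table."""


#: Known column-name dialects: maps dialect name -> (x column, y column).
DIALECTS: dict[str, tuple[str, str]] = {
    "qupath": ("Centroid X px", "Centroid Y px"),
    "plain": ("x", "y"),
}

# coordinates written with 4 decimals (0.1 nm) -- far below biological noise
_COORD_FMT = "%.4f"


@dataclass
class CellTable:
    """Per-cell records of one modality: ids, centroids (μm) and features.

    ``xy`` is an (n, 2) float array of centroids in micrometers; ``features``
    is a DataFrame aligned row-for-row with ``xy`` (may be empty of columns).
    """

    ids: np.ndarray
    xy: np.ndarray
    features: pd.DataFrame
    modality: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if len(self.ids) != len(self.xy) or len(self.features) != len(self.xy):
            raise ValueError("ids, xy and features must have equal length")
        if not np.isfinite(self.xy).all():
            raise ValueError("centroids must be finite")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cell ids must be unique")
        self.features = self.features.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, index: np.ndarray) -> "CellTable":
        index = np.asarray(index)
        return CellTable(
            ids=self.ids[index],
            xy=self.xy[index],
            features=self.features.iloc[index].reset_index(drop=True),
            modality=self.modality,
        )


def read_cell_table(
    path: str | Path,
    pixel_size: float = 1.0,
    dialect: str | tuple[str, str] = "auto",
    id_column: str | None = None,
    modality: str = "",
) -> CellTable:
    """Read a delimited-text cell table and convert centroids to μm.

    Parameters
    ----------
    path : file path (TSV/CSV; delimiter auto-detected)
    pixel_size : μm per pixel of the source image; centroids are multiplied
        by it on ingestion. Use 1.0 for files already in μm.
    dialect : ``"qupath"`` / ``"plain"`` / ``"auto"``, or an explicit
        ``(x_column, y_column)`` pair.
    id_column : column holding cell ids; defaults to the row number.

    Rows with non-finite coordinates are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    if isinstance(dialect, tuple):
        candidates = [dialect]
    elif dialect == "auto":
        candidates = list(DIALECTS.values())
    else:
        candidates = [DIALECTS[dialect]]
    for x_col, y_col in candidates:
        if x_col in df.columns and y_col in df.columns:
            break
    else:
        raise SchemaError(
            f"{path}: no centroid columns found (tried {candidates}); "
            f"available: {list(df.columns)}"
        )

    xy_px = df[[x_col, y_col]].to_numpy(dtype=float)
    finite = np.isfinite(xy_px).all(axis=1)
    if not finite.all():
        logger.warning("%s: dropped %d rows with non-finite coordinates", path, (~finite).sum())
        df = df.loc[finite].reset_index(drop=True)
        xy_px = xy_px[finite]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: all rows had non-finite coordinates")

    if id_column is not None:
        if id_column not in df.columns:
            raise SchemaError(f"{path}: id column {id_column!r} not found")
        ids = df[id_column].to_numpy()
        feat = df.drop(columns=[x_col, y_col, id_column])
    else:
        ids = np.arange(len(df))
        feat = df.drop(columns=[x_col, y_col])
    return CellTable(
        ids=ids,
        xy=pixels_to_microns(xy_px, pixel_size),
        features=feat,
        modality=modality,
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table as TSV in the plain dialect (x/y already in μm)."""
    df = pd.DataFrame(
        {
            "cell_id": table.ids,
            "x": np.round(table.xy[:, 0], 4),
            "y": np.round(table.xy[:, 1], 4),
        }
    )
    out = pd.concat([df, table.features.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_landmarks(landmarks: LandmarkPairs, path: str | Path, units: str = "um") -> None:
    """Write landmark pairs as TSV with a units header comment."""
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        fh.write("source_x\tsource_y\ttarget_x\ttarget_y\n")
        for (sx, sy), (tx, ty) in zip(landmarks.source, landmarks.target):
            fh.write(
                f"{_COORD_FMT % sx}\t{_COORD_FMT % sy}\t{_COORD_FMT % tx}\t{_COORD_FMT % ty}\n"
            )


def read_landmarks(
    path: str | Path,
    source_pixel_size: float = 1.0,
    target_pixel_size: float = 1.0,
) -> LandmarkPairs:
    """Read a landmark TSV; pixel sizes convert px-unit files to μm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["source_x", "source_y", "target_x", "target_y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing landmark columns {missing}")
    src = pixels_to_microns(df[["source_x", "source_y"]].to_numpy(float), source_pixel_size)
    tgt = pixels_to_microns(df[["target_x", "target_y"]].to_numpy(float), target_pixel_size)
    return LandmarkPairs(source=src, target=tgt)


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    """Serialise a transform to JSON (bit-exact round-trip via repr floats)."""
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)
        fh.write("\n")


def read_transform(path: str | Path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


def write_match_table(
    matches,  # MatchSet; typed loosely to avoid a circular import
    source: CellTable,
    target: CellTable,
    path: str | Path,
) -> None:
    """Write putative/filtered cell pairs as TSV (source_id, target_id, affinity, kept_by_lpm).

    Raises :class:`ReferentialIntegrityError` if a match references an index
    outside either table.
    """
    si = np.asarray(matches.source_index)
    ti = np.asarray(matches.target_index)
    if len(si) and (si.min() < 0 or si.max() >= len(source)):
        raise ReferentialIntegrityError("match references a source index outside the table")
    if len(ti) and (ti.min() < 0 or ti.max() >= len(target)):
        raise ReferentialIntegrityError("match references a target index outside the table")
    df = pd.DataFrame(
        {
            "source_id": source.ids[si] if len(si) else np.array([], dtype=source.ids.dtype),
            "target_id": target.ids[ti] if len(ti) else np.array([], dtype=target.ids.dtype),
            "affinity": np.round(np.asarray(matches.affinity, dtype=float), 6),
            "kept_by_lpm": np.asarray(matches.kept, dtype=bool),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_match_table(path: str | Path, source: CellTable, target: CellTable):
    """Read a match TSV back into a MatchSet (inverse of :func:`write_match_table`)."""
    from .graphmatch import MatchSet

    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return MatchSet(
            source_index=np.array([], dtype=int),
            target_index=np.array([], dtype=int),
            affinity=np.array([], dtype=float),
            kept=np.array([], dtype=bool),
        )
    sid_to_idx = {i: k for k, i in enumerate(source.ids)}
    tid_to_idx = {i: k for k, i in enumerate(target.ids)}
    try:
        si = np.array([sid_to_idx[i] for i in df["source_id"]], dtype=int)
        ti = np.array([tid_to_idx[i] for i in df["target_id"]], dtype=int)
    except KeyError as exc:
        raise ReferentialIntegrityError(f"{path}: unknown cell id {exc.args[0]!r}") from exc
    return MatchSet(
        source_index=si,
        target_index=ti,
        affinity=df["affinity"].to_numpy(float),
        kept=df["kept_by_lpm"].to_numpy(bool),
    )
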