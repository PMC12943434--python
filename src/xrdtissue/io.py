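"""Readers and writers for frames, masks, metadata and result bundles.

The native frame format is delimited text of integers (one detector row per
line), matching how laboratory photon-counting data is archived; TIFF and
``.npy`` arrays are accepted for bulk data.  Masks travel as 0/1 matrices
in the same formats.  Metadata is a CSV with one row per frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import DiffractionFrame

__all__ = [
    "read_frame",
    "write_frame",
    "read_mask",
    "write_mask",
    "read_metadata",
    "write_metadata",
    "write_results",
    "VALID_LABELS",
]

VALID_LABELS = ("cancer", "fibroadenoma")

_TEXT_SUFFIXES = {".txt", ".dat", ".csv", ".tsv", ".asc"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        return "tiff"
    if suffix == ".npy":
        return "portable-array"
    if suffix in _TEXT_SUFFIXES or suffix == "":
        return "delimited-text"
    raise ValueError(f"cannot infer frame format from suffix {suffix!r} ({path})")


def _parse_text_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cells = stripped.replace(",", " ").split()
        values = []
        for colno, cell in enumerate(cells, start=1):
            try:
                values.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {lineno}, column {colno}"
                ) from None
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise ValueError(
                f"{path}: ragged row {lineno} has {len(values)} cells, expected {width}"
            )
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric rows found")
    return np.asarray(rows)


def read_frame(path: str | Path, format: str = "auto") -> DiffractionFrame:
    """Read a 2D count matrix; counts must be non-negative.

    Formats: ``delimited-text`` (whitespace/comma separated),
    ``tiff``, ``portable-array`` (numpy ``.npy``), or ``auto`` by suffix.
    Integer counts are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "delimited-text":
        data = _parse_text_matrix(path)
    elif fmt == "tiff":
        import tifffile

        data = np.asarray(tifffile.imread(path))
    elif fmt == "portable-array":
        data = np.load(path, allow_pickle=False)
    else:
        raise ValueError(f"unknown frame format {fmt!r}")
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D matrix, got shape {data.shape}")
    if np.any(data < 0):
        r, c = map(int, np.argwhere(data < 0)[0])
        raise ValueError(f"{path}: negative count {data[r, c]} at row {r}, column {c}")
    if np.all(np.equal(np.mod(data, 1), 0)):
        data = data.astype(np.int64)
    return DiffractionFrame(data=data, frame_id=path.stem)


def write_frame(frame: DiffractionFrame | np.ndarray, path: str | Path, format: str = "auto") -> None:
    """Write a frame in the format implied by the suffix (or ``format``)."""
    path = Path(path)
    data = frame.data if isinstance(frame, DiffractionFrame) else np.asarray(frame)
    fmt = _detect_format(path, format)
    if fmt == "delimited-text":
        if np.issubdtype(data.dtype, np.integer):
            np.savetxt(path, data, fmt="%d")
        else:
            np.savetxt(path, data)
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, data)
    elif fmt == "portable-array":
        np.save(path, data)
    else:
        raise ValueError(f"unknown frame format {fmt!r}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/1 exclusion mask (True = excluded)."""
    data = read_frame(path).data
    if not np.all(np.isin(data, (0, 1))):
        raise ValueError(f"{path}: mask must contain only 0/1 values")
    return data.astype(bool)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    write_frame(np.asarray(mask, dtype=np.int64), path)


def read_metadata(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Read the study metadata table (frame_id, patient_id, label[, path])."""
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    required = {"frame_id", "patient_id", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if table["frame_id"].duplicated().any():
        dupes = table.loc[table["frame_id"].duplicated(), "frame_id"].tolist()
        raise ValueError(f"{path}: duplicate frame ids {dupes}")
    bad = sorted(set(table["label"]) - set(VALID_LABELS))
    if bad:
        raise ValueError(f"{path}: labels {bad} outside the vocabulary {VALID_LABELS}")
    if check_files and "path" in table.columns:
        for _, row in table.iterrows():
            fp = (path.parent / row["path"]).resolve()
            if not fp.exists():
                raise FileNotFoundError(f"{path}: frame file missing for {row['frame_id']}: {fp}")
    return table


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(results: dict, path: str | Path) -> None:
    """Write a machine-readable results bundle (JSON, sorted keys)."""
    Path(path).write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")
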