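"""Particle-coordinate and micrograph I/O.

One coordinate convention is used everywhere in the package: 0-based pixel
centers, ``x`` = column, ``y`` = row, origin at the image's top-left corner.
Files store coordinates in pixels; distances are always computed in Å as
``px * pixel_size_A``, because curation thresholds are stated in Å.

Pick tables and recentering results are plain :class:`pandas.DataFrame`
objects with fixed column names (see :data:`PICK_COLUMNS`,
:data:`RECENTER_COLUMNS`); unknown columns found in input files are carried
along untouched so external metadata survives a curation round-trip.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from duster._mrc import MrcFormatError, read_mrc, write_mrc
from duster._star import StarFormatError, read_star, write_star

#: canonical pick-table columns (extra columns are preserved as opaque payload)
PICK_COLUMNS = ["pick_id", "micrograph_id", "x_px", "y_px", "set_label"]

#: canonical recentering-result columns
RECENTER_COLUMNS = [
    "pick_id",
    "shift_x_px",
    "shift_y_px",
    "recentered_x_px",
    "recentered_y_px",
    "class_id",
    "class_prob",
]

# STAR tags <-> canonical column names. RELION-compatible tags are used where
# they exist so common SPA tooling can read the files.
_PICK_TAGS = {
    "micrograph_id": "rlnMicrographName",
    "x_px": "rlnCoordinateX",
    "y_px": "rlnCoordinateY",
    "pick_id": "dusterPickId",
    "set_label": "dusterSetLabel",
}
_RECENTER_TAGS = {
    "pick_id": "dusterPickId",
    "shift_x_px": "rlnOriginX",
    "shift_y_px": "rlnOriginY",
    "recentered_x_px": "dusterRecenteredX",
    "recentered_y_px": "dusterRecenteredY",
    "class_id": "rlnClassNumber",
    "class_prob": "rlnMaxValueProbDistribution",
}
_REQUIRED_PICK_TAGS = ("rlnMicrographName", "rlnCoordinateX", "rlnCoordinateY")


class FormatError(ValueError):
    """A file violates the supported dialect (missing column, bad mode...)."""


class ParseError(ValueError):
    """A field within an otherwise well-formed file could not be parsed."""


@dataclass(frozen=True)
class ImageMeta:
    """Micrograph geometry and extraction parameters.

    Parameters
    ----------
    pixel_size_A:
        Å per pixel; strictly positive.
    nx, ny:
        image width (columns) and height (rows) in pixels.
    box_size_A:
        particle-extraction box edge in Å. Must span at least 8 px.
    """

    pixel_size_A: float
    nx: int
    ny: int
    box_size_A: float = 0.0

    def __post_init__(self):
        if self.pixel_size_A <= 0:
            raise ValueError(f"pixel_size_A must be > 0, got {self.pixel_size_A}")
        if self.box_size_A and self.box_size_A / self.pixel_size_A < 8:
            raise ValueError(
                f"box_size_A={self.box_size_A} spans fewer than 8 px at "
                f"{self.pixel_size_A} A/px"
            )

    @property
    def box_px(self) -> int:
        return int(round(self.box_size_A / self.pixel_size_A))


def _stable_ids(path, n: int) -> list[str]:
    """Stable pick ids: (source-path hash, file-order index). Never reused."""
    digest = hashlib.sha1(str(path).encode()).hexdigest()[:8]
    return [f"{digest}:{i:06d}" for i in range(n)]


def read_picks(path, set_label: str) -> pd.DataFrame:
    """Read a pick table from a STAR-dialect file.

    Rows get stable ``pick_id`` values derived from the source path and file
    order (pre-existing ``dusterPickId`` columns are honored). ``set_label``
    tags every row with the picking run ("A" or "B") it belongs to. Unknown
    columns are preserved as opaque string payload.
    """
    path = Path(path)
    try:
        raw = read_star(path)
    except StarFormatError as exc:
        raise FormatError(str(exc)) from exc
    for tag in _REQUIRED_PICK_TAGS:
        if tag not in raw.columns:
            raise FormatError(f"{path}: missing required column _{tag}")
    df = pd.DataFrame()
    df["micrograph_id"] = raw.pop("rlnMicrographName")
    df["x_px"] = _numeric(raw.pop("rlnCoordinateX"), "rlnCoordinateX", path)
    df["y_px"] = _numeric(raw.pop("rlnCoordinateY"), "rlnCoordinateY", path)
    if "dusterPickId" in raw.columns:
        df["pick_id"] = raw.pop("dusterPickId")
    else:
        df["pick_id"] = _stable_ids(path, len(df))
    if "dusterSetLabel" in raw.columns:
        raw.pop("dusterSetLabel")
    df["set_label"] = str(set_label)
    for col in raw.columns:  # opaque payload
        df[col] = raw[col]
    return df[PICK_COLUMNS + [c for c in df.columns if c not in PICK_COLUMNS]]


def write_picks(table: pd.DataFrame, path) -> None:
    """Write a pick table re-readably; canonical columns first, deterministic order."""
    validate_picks(table)
    out = pd.DataFrame()
    for col in PICK_COLUMNS:
        out[_PICK_TAGS.get(col, col)] = table[col]
    for col in table.columns:
        if col not in PICK_COLUMNS:
            out[col] = table[col]
    write_star(out, path)


def read_recenter_results(path) -> pd.DataFrame:
    """Read a RecenterResult table (shifts, recentered coords, class, probability)."""
    path = Path(path)
    try:
        raw = read_star(path)
    except StarFormatError as exc:
        raise FormatError(str(exc)) from exc
    df = pd.DataFrame()
    for col, tag in _RECENTER_TAGS.items():
        if tag not in raw.columns:
            raise FormatError(f"{path}: missing required column _{tag}")
        if col in ("pick_id",):
            df[col] = raw[tag]
        elif col == "class_id":
            df[col] = _numeric(raw[tag], tag, path).astype(int)
        else:
            df[col] = _numeric(raw[tag], tag, path)
    return df


def write_recenter_results(results: pd.DataFrame, path) -> None:
    out = pd.DataFrame()
    for col, tag in _RECENTER_TAGS.items():
        out[tag] = results[col]
    write_star(out, path)


def _numeric(series: pd.Series, tag: str, path) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: column _{tag}, data row {row}: non-numeric value {series.iloc[row]!r}")
    return values.astype(float)


def validate_picks(table: pd.DataFrame, meta: ImageMeta | None = None) -> None:
    """Enforce pick-table invariants; raises ``ValueError`` on violation.

    Checks unique pick ids, finite coordinates, a single set label per row,
    and — when image geometry is supplied — in-bounds coordinates.
    """
    missing = [c for c in PICK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pick table missing columns: {missing}")
    if table["pick_id"].duplicated().any():
        dup = table.loc[table["pick_id"].duplicated(), "pick_id"].iloc[0]
        raise ValueError(f"duplicate pick_id {dup!r}")
    xy = table[["x_px", "y_px"]].to_numpy(dtype=float)
    if len(xy) and not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in pick table")
    if meta is not None and len(xy):
        if (xy < 0).any() or (xy[:, 0] >= meta.nx).any() or (xy[:, 1] >= meta.ny).any():
            raise ValueError("pick coordinates outside image bounds")


def read_micrograph(path, pixel_size_A: float | None = None) -> tuple[np.ndarray, ImageMeta]:
    """Read a single mode-2 MRC micrograph.

    The pixel size comes from the header unless overridden by the caller.
    """
    try:
        data, header_px = read_mrc(path)
    except MrcFormatError as exc:
        raise FormatError(str(exc)) from exc
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single 2D image, got shape {data.shape}")
    px = pixel_size_A if pixel_size_A is not None else header_px
    ny, nx = data.shape
    return data, ImageMeta(pixel_size_A=px, nx=nx, ny=ny)


def write_micrograph(path, image: np.ndarray, meta: ImageMeta) -> None:
    write_mrc(path, image, pixel_size_A=meta.pixel_size_A)
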