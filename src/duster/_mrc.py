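"""Minimal MRC2014 image I/O: single 2D image (or stack), mode 2 (float32).

The 1024-byte header is read/written field-by-field; pixel size is stored in
the cell dimensions (``cella / mx``). Extended headers are skipped on read and
never written.
"""

from __future__ import annotations

import numpy as np

HEADER_BYTES = 1024
_MODE_FLOAT32 = 2


class MrcFormatError(ValueError):
    """Raised for unsupported or malformed MRC files."""


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a mode-2 MRC file.

    Returns ``(data, pixel_size_A)`` with data shaped ``(ny, nx)`` for a single
    image or ``(nz, ny, nx)`` for a stack; ``data[y, x]`` follows the package's
    row=y, col=x convention (x is the fastest axis on disk).
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise MrcFormatError(f"{path}: truncated header ({len(header)} bytes)")
        ints = np.frombuffer(header, dtype="<i4", count=56)
        floats = np.frombuffer(header, dtype="<f4", count=56)
        nx, ny, nz, mode = (int(v) for v in ints[:4])
        if mode != _MODE_FLOAT32:
            raise MrcFormatError(f"{path}: unsupported MRC mode {mode} (only mode 2 supported)")
        if min(nx, ny, nz) < 1:
            raise MrcFormatError(f"{path}: bad dimensions {(nx, ny, nz)}")
        mx = int(ints[7])
        cella_x = float(floats[10])
        pixel_size = cella_x / mx if mx > 0 and cella_x > 0 else 1.0
        nsymbt = int(ints[23])
        fh.seek(HEADER_BYTES + nsymbt)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype="<f4", count=count)
    if data.size != count:
        raise MrcFormatError(f"{path}: truncated data ({data.size} of {count} values)")
    data = data.reshape((nz, ny, nx))
    if nz == 1:
        data = data[0]
    return np.ascontiguousarray(data), pixel_size


def write_mrc(path, data: np.ndarray, pixel_size_A: float = 1.0) -> None:
    """Write a 2D image or 3D stack as a mode-2 MRC file."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected 2D image or 3D stack, got ndim={data.ndim}")
    nz, ny, nx = data.shape
    ints = np.zeros(56, dtype="<i4")
    floats = np.zeros(56, dtype="<f4")
    ints[0:4] = (nx, ny, nz, _MODE_FLOAT32)
    ints[7:10] = (nx, ny, nz)  # mx, my, mz
    floats[10:13] = (nx * pixel_size_A, ny * pixel_size_A, nz * pixel_size_A)  # cella
    floats[13:16] = (90.0, 90.0, 90.0)  # cellb
    ints[16:19] = (1, 2, 3)  # mapc, mapr, maps
    floats[19:22] = (float(data.min()), float(data.max()), float(data.mean()))
    header = bytearray(HEADER_BYTES)
    header[: 4 * 56] = _merge_header_words(ints, floats)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    rms = np.float32(data.std())
    header[216:220] = rms.tobytes()
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        data.tofile(fh)


def _merge_header_words(ints: np.ndarray, floats: np.ndarray) -> bytes:
    """Combine the int-valued and float-valued header words into one 224-byte block."""
    float_words = {10, 11, 12, 13, 14, 15, 19, 20, 21}
    out = bytearray()
    for i in range(56):
        src = floats if i in float_words else ints
        out += src[i].tobytes()
    return bytes(out)
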