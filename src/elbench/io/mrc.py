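"""Minimal MRC2014 stack I/O (mode 2, float32).

Writes image stacks the way cryo-EM tools expect .mrcs files: little-endian
mode-2 data, nx/ny the box and nz the particle count, pixel size encoded in
the cell dimensions, 'MAP ' magic and machine stamp set.  Writers are
deterministic — identical input produces byte-identical files (fixed label,
no timestamps).
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["write_mrcs", "read_mrcs", "MrcFormatError"]

_HEADER_SIZE = 1024
_LABEL = b"elbench synthetic particle stack".ljust(80, b" ")


class MrcFormatError(ValueError):
    """Raised when a file fails MRC2014 validation; message carries the byte offset."""


def write_mrcs(path, images: np.ndarray, pixel_size: float, ispg: int = 0) -> None:
    """Write a (n, ny, nx) float stack as an MRC2014 mode-2 file.

    ``ispg=0`` marks an image stack; pass 1 for a single 3-D volume.
    """
    data = np.ascontiguousarray(np.asarray(images, dtype="<f4"))
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError("images must be 2-D or (n, ny, nx)")
    nz, ny, nx = data.shape
    dmin, dmax = float(data.min()), float(data.max())
    dmean = float(data.mean())
    rms = float(data.std())
    hdr = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", hdr, 0, nx, ny, nz)
    struct.pack_into("<i", hdr, 12, 2)  # mode 2 = float32
    struct.pack_into("<3i", hdr, 16, 0, 0, 0)  # nxstart..
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)  # mx my mz
    struct.pack_into("<3f", hdr, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into("<3f", hdr, 76, dmin, dmax, dmean)
    struct.pack_into("<i", hdr, 88, ispg)
    struct.pack_into("<i", hdr, 92, 0)  # nsymbt
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", hdr, 216, rms)
    struct.pack_into("<i", hdr, 220, 1)  # nlabl
    hdr[224:304] = _LABEL
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(data.tobytes())


def read_mrcs(path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 mode-2 file; returns (images (n, ny, nx) float32, pixel size)."""
    with open(path, "rb") as fh:
        hdr = fh.read(_HEADER_SIZE)
        if len(hdr) < _HEADER_SIZE:
            raise MrcFormatError(f"truncated header at offset {len(hdr)}")
        if hdr[208:212] != b"MAP ":
            raise MrcFormatError("missing 'MAP ' magic at offset 208")
        nx, ny, nz = struct.unpack_from("<3i", hdr, 0)
        (mode,) = struct.unpack_from("<i", hdr, 12)
        if mode != 2:
            raise MrcFormatError(f"unsupported mode {mode} at offset 12 (only mode 2)")
        if min(nx, ny, nz) < 1:
            raise MrcFormatError(f"invalid dimensions {(nx, ny, nz)} at offset 0")
        cella_x = struct.unpack_from("<f", hdr, 40)[0]
        (nsymbt,) = struct.unpack_from("<i", hdr, 92)
        fh.seek(_HEADER_SIZE + nsymbt)
        raw = fh.read(4 * nx * ny * nz)
        if len(raw) < 4 * nx * ny * nz:
            raise MrcFormatError(f"truncated data at offset {_HEADER_SIZE + nsymbt + len(raw)}")
    images = np.frombuffer(raw, dtype="<f4").reshape(nz, ny, nx).copy()
    pixel_size = cella_x / nx if nx else 0.0
    return images, float(pixel_size)
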