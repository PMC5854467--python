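"""Minimal MRC2014 reader/writer for images, stacks and volumes.

Only mode 2 (32-bit float) is written; modes 0, 1, 2 and 6 are read.  The
pixel size is carried in the cell dimensions (``cella / m{x,y,z}``) as the
format prescribes.  Data are stored with the slowest axis last in the file
(section, row, column); we expose arrays as ``(nz, ny, nx)`` or ``(ny, nx)``.
"""

from __future__ import annotations

import struct

import numpy as np

from .image import Image, Volume

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def write_mrc(path, obj, *, pixel_size: float = None) -> None:
    """Write an Image, Volume or ndarray (2-D, or 3-D stack) as mode-2 MRC."""
    if isinstance(obj, Image):
        data, px = obj.pixels[None], obj.pixel_size
    elif isinstance(obj, Volume):
        data, px = obj.voxels, obj.pixel_size
    else:
        data = np.asarray(obj, dtype=np.float64)
        if data.ndim == 2:
            data = data[None]
        px = pixel_size if pixel_size is not None else 1.0
    nz, ny, nx = data.shape
    data32 = np.ascontiguousarray(data, dtype=np.float32)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)                      # mode
    struct.pack_into("<3i", header, 16, 0, 0, 0)               # nstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)            # m
    struct.pack_into("<3f", header, 40, nx * px, ny * px, nz * px)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)      # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)               # mapc/r/s
    struct.pack_into("<3f", header, 76, float(data32.min()),
                     float(data32.max()), float(data32.mean()))
    struct.pack_into("<i", header, 88, 0)                      # ispg
    struct.pack_into("<i", header, 92, 0)                      # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])          # little-endian
    struct.pack_into("<f", header, 216, float(data32.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data32.tobytes())


def read_mrc(path):
    """Read an MRC file -> (ndarray, pixel_size).

    Returns a 2-D array for single images, 3-D ``(nz, ny, nx)`` otherwise.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cax, cay, caz = struct.unpack_from("<3f", header, 40)
        nsymbt, = struct.unpack_from("<i", header, 92)
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"{path}: not an MRC2014 file (missing MAP stamp)")
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 100000:
            raise ValueError(f"{path}: inconsistent header dimensions")
        fh.seek(_HEADER_SIZE + nsymbt)
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        raw = fh.read(count * np.dtype(dtype).itemsize)
        if len(raw) < count * np.dtype(dtype).itemsize:
            raise ValueError(f"{path}: truncated MRC data section")
        data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    pixel_size = cax / mx if mx > 0 and cax > 0 else 1.0
    data = data.astype(np.float64)
    if nz == 1:
        data = data[0]
    return data, pixel_size


def read_image(path) -> Image:
    data, px = read_mrc(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D image")
    return Image(data, px)


def read_volume(path) -> Volume:
    data, px = read_mrc(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume")
    return Volume(data, px)
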