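"""Minimal MRC2014 stack reader/writer.

Covers what a particle-stack tool needs: modes 0 (int8), 1 (int16),
2 (float32) and 6 (uint16), single images and stacks, little-endian files.
Written data is always mode 2 with a valid MAP/machine-stamp header.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC/MRCS file.

    Returns ``(data, pixel_size)`` with ``data`` shaped ``(nz, ny, nx)``
    (``nz = 1`` for a single image) as float32 and the pixel size in
    Angstrom/pixel (0 when the header does not define one).
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise ValueError(f"{path}: truncated MRC header")
        ints = np.frombuffer(header, dtype="<i4", count=256)
        floats = np.frombuffer(header, dtype="<f4", count=256)
        nx, ny, nz, mode = (int(v) for v in ints[:4])
        if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 100_000:
            raise ValueError(f"{path}: corrupt MRC header dimensions {(nx, ny, nz)}")
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        nsymbt = int(ints[23])
        fh.seek(_HEADER_BYTES + nsymbt)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=np.dtype(_MODE_DTYPES[mode]).newbyteorder("<"),
                           count=count)
        if data.size != count:
            raise ValueError(f"{path}: file shorter than header promises")
    cella_x = float(floats[10])
    pixel_size = cella_x / nx if cella_x > 0 else 0.0
    return data.reshape(nz, ny, nx).astype(np.float32), pixel_size


def write_mrc(path, data, pixel_size: float = 1.0) -> None:
    """Write images as a mode-2 (float32) MRC/MRCS file.

    ``data`` may be a single 2-D image or an ``(nz, ny, nx)`` stack.
    """
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D image or 3-D stack, got ndim={arr.ndim}")
    nz, ny, nx = arr.shape

    ints = np.zeros(256, dtype="<i4")
    floats = np.zeros(256, dtype="<f4")
    ints[0:3] = (nx, ny, nz)
    ints[3] = 2  # mode: float32
    ints[7:10] = (nx, ny, nz)  # mx, my, mz
    floats[10:13] = (nx * pixel_size, ny * pixel_size, nz * pixel_size)
    floats[13:16] = 90.0  # cell angles
    ints[16:19] = (1, 2, 3)  # axis order
    floats[19] = float(arr.min())
    floats[20] = float(arr.max())
    floats[21] = float(arr.mean())
    ints[22] = 0 if nz > 1 else 1  # ispg: 0 flags an image stack
    floats[54] = float(arr.std())  # rms
    ints[55] = 1  # nlabl

    header = bytearray(ints.tobytes())
    fb = floats.tobytes()
    # overlay float fields (cella, cell angles, dmin/dmax/dmean, rms)
    header[4 * 10:4 * 16] = fb[4 * 10:4 * 16]
    header[4 * 19:4 * 22] = fb[4 * 19:4 * 22]
    header[4 * 54:4 * 55] = fb[4 * 54:4 * 55]
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    header[224:224 + 16] = b"freqalign stack ".ljust(16)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())
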