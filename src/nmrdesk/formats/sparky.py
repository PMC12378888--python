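"""UCSF Sparky ``.ucsf`` spectra: big-endian, tiled, real data only.

Layout: a 180-byte file header ("UCSF NMR", dimension count, component
count, version 2) followed by one 128-byte axis header per dimension
(slowest-varying axis first) and the float32 data arranged in row-major
tiles, edge tiles zero-padded to the full tile size.
"""

from __future__ import annotations

import logging
import struct

import numpy as np

from ..core import AxisCalibration, Spectrum

__all__ = ["read_ucsf", "write_ucsf", "NotUcsfError", "DEFAULT_TILE"]

log = logging.getLogger(__name__)

DEFAULT_TILE = 128
_FILE_HEADER = 180
_AXIS_HEADER = 128


class NotUcsfError(ValueError):
    """Raised when a file does not carry the UCSF magic string."""


def _center_ppm(ax: AxisCalibration) -> float:
    # ppm of index n/2, the anchor the ucsf header stores
    return float(ax.ppm_of_point(ax.n_points // 2))


def _axis_header(ax: AxisCalibration, nucleus: str, tile: int) -> bytes:
    head = bytearray(_AXIS_HEADER)
    head[0:6] = nucleus.encode("ascii")[:6].ljust(6, b"\x00")
    struct.pack_into(">i", head, 8, ax.n_points)
    struct.pack_into(">i", head, 16, tile)
    struct.pack_into(">f", head, 20, ax.obs_mhz)
    struct.pack_into(">f", head, 24, ax.sw_hz)
    struct.pack_into(">f", head, 28, _center_ppm(ax))
    return bytes(head)


def _tiled(matrix: np.ndarray, tile_r: int, tile_c: int) -> bytes:
    nr, nc = matrix.shape
    ntr = -(-nr // tile_r)
    ntc = -(-nc // tile_c)
    padded = np.zeros((ntr * tile_r, ntc * tile_c), dtype=">f4")
    padded[:nr, :nc] = matrix
    blocks = padded.reshape(ntr, tile_r, ntc, tile_c).transpose(0, 2, 1, 3)
    return blocks.tobytes()


def _untile(raw: np.ndarray, nr: int, nc: int, tile_r: int, tile_c: int) -> np.ndarray:
    ntr = -(-nr // tile_r)
    ntc = -(-nc // tile_c)
    blocks = raw.reshape(ntr, ntc, tile_r, tile_c).transpose(0, 2, 1, 3)
    padded = blocks.reshape(ntr * tile_r, ntc * tile_c)
    return padded[:nr, :nc]


def write_ucsf(spectrum: Spectrum, path: str, tile: int = DEFAULT_TILE,
               nuclei: tuple[str, str] = ("15N", "1H")) -> None:
    """Write the real part of a single-plane spectrum as a 2D ucsf file.

    Imaginary quadrants have no representation in this format and are
    dropped with a warning.
    """
    if spectrum.n_planes != 1:
        raise ValueError("ucsf output supports a single plane; slice first")
    if spectrum.has_imag:
        log.warning("ucsf format is real-only: dropping imaginary quadrants")
    matrix = spectrum.data_real[0]
    ni, nd = matrix.shape
    tile_r = min(tile, ni)
    tile_c = min(tile, nd)

    head = bytearray(_FILE_HEADER)
    head[0:10] = b"UCSF NMR\x00\x00"
    head[10] = 2          # dimensions
    head[11] = 1          # components per point (real)
    head[13] = 2          # format version
    with open(path, "wb") as fh:
        fh.write(bytes(head))
        fh.write(_axis_header(spectrum.axis_indirect, nuclei[0], tile_r))
        fh.write(_axis_header(spectrum.axis_direct, nuclei[1], tile_c))
        fh.write(_tiled(matrix.astype(">f4"), tile_r, tile_c))


def read_ucsf(path: str) -> Spectrum:
    """Read a 2D ucsf file, reassembling tiles in spectral order."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _FILE_HEADER or raw[0:8] != b"UCSF NMR":
        raise NotUcsfError(f"not a ucsf file: {path}")
    ndim = raw[10]
    if ndim != 2:
        raise NotUcsfError(f"only 2D supported: {path} declares {ndim} "
                           "dimensions")

    axes = []
    for d in range(2):
        off = _FILE_HEADER + d * _AXIS_HEADER
        head = raw[off: off + _AXIS_HEADER]
        npts = struct.unpack(">i", head[8:12])[0]
        tile = struct.unpack(">i", head[16:20])[0]
        obs = struct.unpack(">f", head[20:24])[0]
        sw = struct.unpack(">f", head[24:28])[0]
        center = struct.unpack(">f", head[28:32])[0]
        # invert the center anchor: center sits at index n/2
        step = sw / npts
        origin = center * obs - (npts - 1 - npts // 2) * step
        axes.append((AxisCalibration(n_points=npts, sw_hz=sw, obs_mhz=obs,
                                     origin_hz=origin), tile))
    (ax1, tile_r), (ax2, tile_c) = axes

    data_off = _FILE_HEADER + 2 * _AXIS_HEADER
    payload = np.frombuffer(raw[data_off:], dtype=">f4")
    ntr = -(-ax1.n_points // tile_r)
    ntc = -(-ax2.n_points // tile_c)
    expected = ntr * ntc * tile_r * tile_c
    if payload.size != expected:
        raise NotUcsfError(f"not a ucsf file: payload has {payload.size} "
                           f"floats, expected {expected}")
    matrix = _untile(payload, ax1.n_points, ax2.n_points, tile_r, tile_c)
    return Spectrum(data_real=matrix.astype(np.float64)[None, :, :],
                    axis_direct=ax2, axis_indirect=ax1)
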