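"""NMRPipe-style ``.ft2`` files: 512-float32 header + row-major float32 data.

Header words follow the fdatap layout (FDSIZE at word 99, FDF2SW at 100,
...).  ``ORIG`` words carry the frequency in Hz of the *last* point of each
axis, which is also this package's axis anchor, so calibration survives a
round trip exactly.

Quadrant layout on disk:

* real-only: one row of ``FDSIZE`` floats per indirect point;
* direct imaginaries present: each row is ``[re..., im...]`` (2*FDSIZE);
* full hypercomplex: rows alternate (real-indirect, imag-indirect), each
  carrying its direct re/im halves — four quadrants total.

Multi-plane stacks are stored as consecutive planes with the plane count in
word 15 (the F3-size slot).
"""

from __future__ import annotations

import struct

import numpy as np

from ..core import AxisCalibration, Spectrum

__all__ = ["read_ft2", "write_ft2", "NotFt2Error", "FDATA_WORDS"]

HEADER_WORDS = 512
_MAGIC_FLTORDER = 2.345

# fdatap word indices used by this package
FDATA_WORDS = {
    "FDMAGIC": 0, "FDFLTFORMAT": 1, "FDFLTORDER": 2, "FDDIMCOUNT": 9,
    "FDF3SIZE": 15, "FDDIMORDER1": 24, "FDDIMORDER2": 25, "FDDIMORDER3": 26,
    "FDDIMORDER4": 27, "FDF1QUADFLAG": 55, "FDF2QUADFLAG": 56,
    "FDPIPEFLAG": 57, "FDF2CAR": 66, "FDF1CAR": 67, "FDF2CENTER": 79,
    "FDF1CENTER": 80, "FDSIZE": 99, "FDF2SW": 100, "FDF2ORIG": 101,
    "FDQUADFLAG": 106, "FDF2OBS": 119, "FDNOISE": 153, "FDSPECNUM": 219,
    "FDF2FTFLAG": 220, "FDTRANSPOSED": 221, "FDF1FTFLAG": 222,
    "FDF1OBS": 218, "FDF1SW": 229, "FDF1ORIG": 249, "FD2DPHASE": 256,
    "FDFILECOUNT": 442,
}
_W = FDATA_WORDS


class NotFt2Error(ValueError):
    """Raised when a file does not look like an ft2 spectrum."""


def _quad_layout(spectrum: Spectrum) -> str:
    have = (spectrum.data_imag_direct is not None,
            spectrum.data_imag_indirect is not None,
            spectrum.data_imag_both is not None)
    if have == (False, False, False):
        return "real"
    if have == (True, False, False):
        return "direct"
    if have == (True, True, True):
        return "full"
    raise ValueError("unsupported imaginary-quadrant combination; provide "
                     "none, direct-only, or all four quadrants")


def write_ft2(spectrum: Spectrum, path: str) -> None:
    """Write a spectrum as little-endian float32 ft2."""
    layout = _quad_layout(spectrum)
    n_planes, ni, nd = spectrum.shape
    ax2, ax1 = spectrum.axis_direct, spectrum.axis_indirect

    fdata = np.zeros(HEADER_WORDS, dtype="<f4")
    fdata[_W["FDMAGIC"]] = 0.0
    fdata[_W["FDFLTFORMAT"]] = np.float32(
        struct.unpack("<f", struct.pack("<I", 0xEEEEEEEE))[0])
    fdata[_W["FDFLTORDER"]] = _MAGIC_FLTORDER
    fdata[_W["FDDIMCOUNT"]] = 2
    fdata[_W["FDDIMORDER1"]] = 2
    fdata[_W["FDDIMORDER2"]] = 1
    fdata[_W["FDDIMORDER3"]] = 3
    fdata[_W["FDDIMORDER4"]] = 4
    fdata[_W["FDSIZE"]] = nd
    fdata[_W["FDSPECNUM"]] = 2 * ni if layout == "full" else ni
    fdata[_W["FDF3SIZE"]] = n_planes
    fdata[_W["FDFILECOUNT"]] = 1
    fdata[_W["FD2DPHASE"]] = 2  # States-style hypercomplex ordering

    fdata[_W["FDF2QUADFLAG"]] = 1 if layout == "real" else 0
    fdata[_W["FDF1QUADFLAG"]] = 0 if layout == "full" else 1
    fdata[_W["FDQUADFLAG"]] = 1 if layout == "real" else 0
    fdata[_W["FDF2FTFLAG"]] = 1
    fdata[_W["FDF1FTFLAG"]] = 1

    fdata[_W["FDF2SW"]] = ax2.sw_hz
    fdata[_W["FDF2OBS"]] = ax2.obs_mhz
    fdata[_W["FDF2ORIG"]] = ax2.origin_hz
    fdata[_W["FDF2CAR"]] = (ax2.origin_hz + ax2.sw_hz / 2.0) / ax2.obs_mhz
    fdata[_W["FDF2CENTER"]] = nd // 2
    fdata[_W["FDF1SW"]] = ax1.sw_hz
    fdata[_W["FDF1OBS"]] = ax1.obs_mhz
    fdata[_W["FDF1ORIG"]] = ax1.origin_hz
    fdata[_W["FDF1CAR"]] = (ax1.origin_hz + ax1.sw_hz / 2.0) / ax1.obs_mhz
    fdata[_W["FDF1CENTER"]] = ni // 2
    if spectrum.noise_sigma is not None:
        fdata[_W["FDNOISE"]] = spectrum.noise_sigma

    rr = spectrum.data_real.astype("<f4")
    if layout == "real":
        payload = rr
    elif layout == "direct":
        payload = np.concatenate(
            [rr, spectrum.data_imag_direct.astype("<f4")], axis=2)
    else:
        top = np.concatenate(
            [rr, spectrum.data_imag_direct.astype("<f4")], axis=2)
        bot = np.concatenate(
            [spectrum.data_imag_indirect.astype("<f4"),
             spectrum.data_imag_both.astype("<f4")], axis=2)
        payload = np.empty((n_planes, 2 * ni, 2 * nd), dtype="<f4")
        payload[:, 0::2, :] = top
        payload[:, 1::2, :] = bot

    with open(path, "wb") as fh:
        fh.write(fdata.tobytes())
        fh.write(payload.astype("<f4").tobytes())


def read_ft2(path: str) -> Spectrum:
    """Read an ft2 file written by :func:`write_ft2` (or compatible)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4 * HEADER_WORDS:
        raise NotFt2Error(f"not an ft2 file: {path} is shorter than the "
                          "512-float header")
    fdata = np.frombuffer(raw[: 4 * HEADER_WORDS], dtype="<f4")
    swapped = False
    if abs(float(fdata[_W["FDFLTORDER"]]) - _MAGIC_FLTORDER) > 1e-6:
        fdata = fdata.byteswap()
        swapped = True
        if abs(float(fdata[_W["FDFLTORDER"]]) - _MAGIC_FLTORDER) > 1e-6:
            raise NotFt2Error(f"not an ft2 file: bad byte-order word in {path}")
    if float(fdata[_W["FDMAGIC"]]) != 0.0:
        raise NotFt2Error(f"not an ft2 file: bad magic word in {path}")

    nd = int(fdata[_W["FDSIZE"]])
    specnum = int(fdata[_W["FDSPECNUM"]])
    n_planes = max(1, int(fdata[_W["FDF3SIZE"]]))
    f2_complex = int(fdata[_W["FDF2QUADFLAG"]]) == 0
    f1_complex = int(fdata[_W["FDF1QUADFLAG"]]) == 0
    ni = specnum // 2 if f1_complex else specnum
    row_len = 2 * nd if f2_complex else nd

    dtype = ">f4" if swapped else "<f4"
    data = np.frombuffer(raw[4 * HEADER_WORDS:], dtype=dtype)
    expected = n_planes * specnum * row_len
    if data.size != expected:
        raise NotFt2Error(f"not an ft2 file: payload has {data.size} floats, "
                          f"expected {expected}")
    data = data.reshape(n_planes, specnum, row_len).astype(np.float64)

    ax2 = AxisCalibration(n_points=nd, sw_hz=float(fdata[_W["FDF2SW"]]),
                          obs_mhz=float(fdata[_W["FDF2OBS"]]),
                          origin_hz=float(fdata[_W["FDF2ORIG"]]))
    ax1 = AxisCalibration(n_points=ni, sw_hz=float(fdata[_W["FDF1SW"]]),
                          obs_mhz=float(fdata[_W["FDF1OBS"]]),
                          origin_hz=float(fdata[_W["FDF1ORIG"]]))
    noise = float(fdata[_W["FDNOISE"]]) or None

    imag_d = imag_i = imag_b = None
    if not f2_complex and not f1_complex:
        rr = data
    elif f2_complex and not f1_complex:
        rr, imag_d = data[:, :, :nd], data[:, :, nd:]
    else:
        top, bot = data[:, 0::2, :], data[:, 1::2, :]
        rr, imag_d = top[:, :, :nd], top[:, :, nd:]
        imag_i, imag_b = bot[:, :, :nd], bot[:, :, nd:]

    return Spectrum(data_real=rr, axis_direct=ax2, axis_indirect=ax1,
                    data_imag_direct=imag_d, data_imag_indirect=imag_i,
                    data_imag_both=imag_b, noise_sigma=noise)
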