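"""TopSpin ``totxt`` text spectra.

One documented dialect is accepted: comment lines declaring the F1/F2 ppm
ranges and the matrix size, then intensities one per line in row blocks
ordered from the left (downfield) limit.  Anything missing those range
headers is rejected as an unrecognized dialect rather than guessed at.
"""

from __future__ import annotations

import re

import numpy as np

from ..core import AxisCalibration, Spectrum

__all__ = ["read_topspin_txt", "write_topspin_txt", "TotxtDialectError"]


class TotxtDialectError(ValueError):
    """Raised for text files that do not match the supported totxt layout."""


_RANGE_RE = re.compile(r"(F[12])(LEFT|RIGHT)\s*=\s*([-+0-9.eE]+)\s*ppm")
_SIZE_RE = re.compile(r"(NROWS|NCOLS)\s*=\s*(\d+)")
_SF_RE = re.compile(r"(F[12])SF\s*=\s*([-+0-9.eE]+)\s*MHz")


def _axis_from_range(left: float, right: float, n: int, obs: float) -> AxisCalibration:
    if n > 1:
        step_ppm = (left - right) / (n - 1)
    else:
        step_ppm = 1.0
    if step_ppm <= 0:
        raise TotxtDialectError("left ppm limit must exceed right limit")
    return AxisCalibration(n_points=n, sw_hz=step_ppm * n * obs, obs_mhz=obs,
                           origin_hz=right * obs)


def read_topspin_txt(path: str) -> Spectrum:
    """Parse a totxt export into a spectrum with ppm-faithful axes.

    totxt files carry no observe frequency; if ``# F1SF = ... MHz`` /
    ``# F2SF = ... MHz`` comments are absent the axes default to 1 MHz so
    the ppm map still reproduces the declared ranges exactly.
    """
    ranges: dict = {}
    sizes: dict = {}
    obs = {"F1": 1.0, "F2": 1.0}
    values: list[float] = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for m in _RANGE_RE.finditer(line):
                    ranges[m.group(1) + m.group(2)] = float(m.group(3))
                m = _SIZE_RE.search(line)
                if m:
                    sizes[m.group(1)] = int(m.group(2))
                m = _SF_RE.search(line)
                if m:
                    obs[m.group(1)] = float(m.group(2))
                continue
            values.append(float(line))

    needed = {"F1LEFT", "F1RIGHT", "F2LEFT", "F2RIGHT"}
    if not needed <= set(ranges) or not {"NROWS", "NCOLS"} <= set(sizes):
        raise TotxtDialectError(f"unrecognized totxt dialect: {path} lacks "
                                "range/size headers")
    nr, nc = sizes["NROWS"], sizes["NCOLS"]
    if len(values) != nr * nc:
        raise TotxtDialectError(f"unrecognized totxt dialect: {len(values)} "
                                f"values for a {nr}x{nc} matrix")
    matrix = np.asarray(values, dtype=np.float64).reshape(nr, nc)
    ax1 = _axis_from_range(ranges["F1LEFT"], ranges["F1RIGHT"], nr, obs["F1"])
    ax2 = _axis_from_range(ranges["F2LEFT"], ranges["F2RIGHT"], nc, obs["F2"])
    return Spectrum(data_real=matrix[None, :, :], axis_direct=ax2,
                    axis_indirect=ax1)


def write_topspin_txt(spectrum: Spectrum, path: str) -> None:
    """Write the real part of a single-plane spectrum in the totxt dialect."""
    if spectrum.n_planes != 1:
        raise ValueError("totxt output supports a single plane; slice first")
    matrix = spectrum.data_real[0]
    nr, nc = matrix.shape
    ax1, ax2 = spectrum.axis_indirect, spectrum.axis_direct
    with open(path, "w") as fh:
        fh.write("# File created by nmrdesk\n")
        fh.write(f"# F1LEFT = {ax1.ppm_of_point(0):.6f} ppm. "
                 f"F1RIGHT = {ax1.ppm_of_point(nr - 1):.6f} ppm.\n")
        fh.write(f"# F2LEFT = {ax2.ppm_of_point(0):.6f} ppm. "
                 f"F2RIGHT = {ax2.ppm_of_point(nc - 1):.6f} ppm.\n")
        fh.write(f"# F1SF = {ax1.obs_mhz:.6f} MHz\n")
        fh.write(f"# F2SF = {ax2.obs_mhz:.6f} MHz\n")
        fh.write(f"# NROWS = {nr} ( = number of points along the F1 axis)\n")
        fh.write(f"# NCOLS = {nc} ( = number of points along the F2 axis)\n")
        for r in range(nr):
            fh.write(f"# row = {r}\n")
            for v in matrix[r]:
                fh.write(f"{float(v)!r}\n")
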