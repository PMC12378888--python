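"""Bruker time-domain directories: ``ser``/``fid`` + ``acqus``/``acqu2s``.

Only the JCAMP-DX keys this package needs are interpreted (TD, SW_h, SFO1,
O1, BYTORDA, DTYPA, GRPDLY, FnMODE); everything else is carried through
untouched.  TopSpin >= 3 datasets default to float64 ser data (DTYPA=2);
int32 (DTYPA=0) is handled as well, in either byte order.
"""

from __future__ import annotations

import os
import re
from typing import Optional

import numpy as np

from ..core import AcquisitionMeta, AcquisitionMode, TimeDomainData

__all__ = ["read_bruker", "write_bruker", "parse_jcamp", "NotBrukerError",
           "TruncatedDataError"]

_FNMODE_TO_MODE = {
    4: AcquisitionMode.STATES,
    5: AcquisitionMode.STATES_TPPI,
    6: AcquisitionMode.ECHO_ANTIECHO,
}
_MODE_TO_FNMODE = {v: k for k, v in _FNMODE_TO_MODE.items()}


class NotBrukerError(FileNotFoundError):
    """Raised when a directory lacks the minimal Bruker file set."""


class TruncatedDataError(ValueError):
    """Raised when the ser/fid byte count disagrees with TD parameters."""


def parse_jcamp(path: str) -> dict:
    """Parse a JCAMP-DX parameter file into a {key: value} dict.

    Values are converted to int/float where possible; multi-line array
    values are joined.  Only ``##$``-prefixed private keys are kept.
    """
    params: dict = {}
    with open(path, "r", errors="replace") as fh:
        text = fh.read()
    for m in re.finditer(r"^##\$(\w+)=\s*(.*?)(?=^##|\Z)", text,
                         re.MULTILINE | re.DOTALL):
        key, raw = m.group(1), m.group(2).strip()
        raw = " ".join(raw.split())
        if raw.startswith("("):  # array header "(0..n)" — keep payload only
            raw = raw.split(")", 1)[1].strip()
        value: object = raw
        for conv in (int, float):
            try:
                value = conv(raw)
                break
            except ValueError:
                continue
        params[key] = value
    return params


def _decode_ser(raw: bytes, data_type: str, byte_order: str) -> np.ndarray:
    code = {"int32": "i4", "float64": "f8"}[data_type]
    dt = np.dtype(("<" if byte_order == "little" else ">") + code)
    n = len(raw) // dt.itemsize
    if n * dt.itemsize != len(raw):
        raise TruncatedDataError("truncated or inconsistent data: ser size is "
                                 "not a whole number of samples")
    return np.frombuffer(raw[: n * dt.itemsize], dtype=dt).astype(np.float64)


def read_bruker(dir_path: str) -> tuple[TimeDomainData, AcquisitionMeta]:
    """Read a Bruker dataset directory into complex time-domain data.

    The direct dimension is paired into complex samples; indirect rows are
    kept in acquisition order (quadrature not yet combined).  The digital
    filter group delay is recorded in the metadata but not corrected here.
    """
    acqus_path = os.path.join(dir_path, "acqus")
    ser_path = os.path.join(dir_path, "ser")
    if not os.path.isfile(ser_path):
        ser_path = os.path.join(dir_path, "fid")
    if not os.path.isfile(acqus_path) or not os.path.isfile(ser_path):
        raise NotBrukerError(f"not a Bruker dataset: {dir_path} is missing "
                             "ser/fid or acqus")
    acqus = parse_jcamp(acqus_path)
    acqu2s_path = os.path.join(dir_path, "acqu2s")
    if not os.path.isfile(acqu2s_path):
        raise NotBrukerError(f"not a Bruker dataset: {dir_path} is missing "
                             "acqu2s (2D required)")
    acqu2s = parse_jcamp(acqu2s_path)

    td2 = int(acqus["TD"])           # real points, direct
    td1 = int(acqu2s["TD"])          # rows (real increments), indirect
    byte_order = "big" if int(acqus.get("BYTORDA", 0)) == 1 else "little"
    data_type = "float64" if int(acqus.get("DTYPA", 0)) == 2 else "int32"
    fnmode = int(acqu2s.get("FnMODE", 4))
    mode = _FNMODE_TO_MODE.get(fnmode, AcquisitionMode.STATES)

    with open(ser_path, "rb") as fh:
        raw = fh.read()
    flat = _decode_ser(raw, data_type, byte_order)

    plane_size = td1 * td2
    if plane_size == 0 or flat.size % plane_size:
        raise TruncatedDataError(
            f"truncated or inconsistent data: {flat.size} samples is not a "
            f"multiple of TD1*TD2 = {plane_size}")
    n_planes = flat.size // plane_size

    cplx = flat.reshape(n_planes, td1, td2 // 2, 2)
    data = cplx[..., 0] + 1j * cplx[..., 1]

    sfo1 = float(acqus["SFO1"])
    sfo2 = float(acqu2s["SFO1"])
    meta = AcquisitionMeta(
        n_complex_direct=td2 // 2,
        n_complex_indirect=td1 // 2,
        sw_direct_hz=float(acqus["SW_h"]),
        sw_indirect_hz=float(acqu2s["SW_h"]),
        obs_direct_mhz=sfo1,
        obs_indirect_mhz=sfo2,
        car_direct_ppm=float(acqus.get("O1", 0.0)) / sfo1,
        car_indirect_ppm=float(acqu2s.get("O1", 0.0)) / sfo2,
        mode_indirect=mode,
        data_type=data_type,
        byte_order=byte_order,
        group_delay=float(acqus.get("GRPDLY", 0.0)),
        n_planes=n_planes,
    )
    return TimeDomainData(data=data, meta=meta), meta


def _jcamp_text(title: str, params: dict) -> str:
    lines = [f"##TITLE= {title}", "##JCAMPDX= 5.0", "##DATATYPE= Parameter Values"]
    for k, v in params.items():
        lines.append(f"##${k}= {v}")
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def write_bruker(td: TimeDomainData, meta: AcquisitionMeta, dir_path: str,
                 force: bool = False) -> None:
    """Write a readable Bruker-format directory (ser + acqus + acqu2s)."""
    if os.path.isdir(dir_path) and os.listdir(dir_path) and not force:
        raise FileExistsError(f"refusing to overwrite non-empty {dir_path}")
    os.makedirs(dir_path, exist_ok=True)

    data = td.data
    flat = np.empty(data.shape + (2,), dtype=np.float64)
    flat[..., 0] = data.real
    flat[..., 1] = data.imag
    flat = flat.reshape(-1)
    code = {"int32": "i4", "float64": "f8"}[meta.data_type]
    dt = np.dtype(("<" if meta.byte_order == "little" else ">") + code)
    if meta.data_type == "int32":
        flat = np.rint(flat)
    with open(os.path.join(dir_path, "ser"), "wb") as fh:
        fh.write(flat.astype(dt).tobytes())

    acqus = {
        "TD": 2 * meta.n_complex_direct,
        "SW_h": meta.sw_direct_hz,
        "SFO1": meta.obs_direct_mhz,
        "O1": meta.car_direct_ppm * meta.obs_direct_mhz,
        "BYTORDA": 1 if meta.byte_order == "big" else 0,
        "DTYPA": 2 if meta.data_type == "float64" else 0,
        "GRPDLY": meta.group_delay,
    }
    acqu2s = {
        "TD": td.data.shape[1],
        "SW_h": meta.sw_indirect_hz,
        "SFO1": meta.obs_indirect_mhz,
        "O1": meta.car_indirect_ppm * meta.obs_indirect_mhz,
        "FnMODE": _MODE_TO_FNMODE[AcquisitionMode(meta.mode_indirect)],
    }
    with open(os.path.join(dir_path, "acqus"), "w") as fh:
        fh.write(_jcamp_text("nmrdesk fixture acqus", acqus))
    with open(os.path.join(dir_path, "acqu2s"), "w") as fh:
        fh.write(_jcamp_text("nmrdesk fixture acqu2s", acqu2s))
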