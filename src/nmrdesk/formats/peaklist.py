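"""Peak-list I/O in two dialects: NMRPipe ``.tab`` and Sparky ``.list``.

The tab dialect is column-name driven (VARS/FORMAT header); files with
reordered columns parse identically.  Pseudo-3D per-plane heights travel in
``Z_A0``, ``Z_A1``, ... columns.  The Sparky dialect carries assignment,
w1/w2 ppm and optionally a data height; it has no plane-height columns, so
those are dropped with a warning on write.

Positions are written with 4 decimal places, heights in scientific notation
with 6 significant digits.
"""

from __future__ import annotations

import logging
import re

from ..core import Peak, PeakList

__all__ = ["read_peaklist", "write_peaklist", "PeakListFormatError", "DIALECTS"]

log = logging.getLogger(__name__)

DIALECTS = ("nmrpipe_tab", "sparky_list")


class PeakListFormatError(ValueError):
    """Raised for files whose columns cannot be interpreted."""


def _fmt_height(h: float) -> str:
    return f"{h:+.5e}"


def write_peaklist(peaks: PeakList, path: str, dialect: str = "nmrpipe_tab") -> None:
    if dialect == "nmrpipe_tab":
        _write_tab(peaks, path)
    elif dialect == "sparky_list":
        _write_sparky(peaks, path)
    else:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")


def read_peaklist(path: str, dialect: str = "nmrpipe_tab") -> PeakList:
    if dialect == "nmrpipe_tab":
        return _read_tab(path)
    if dialect == "sparky_list":
        return _read_sparky(path)
    raise ValueError(f"unknown peak-list dialect {dialect!r}")


# ---------------------------------------------------------------- tab dialect

_TAB_BASE = ["INDEX", "X_PPM", "Y_PPM", "HEIGHT",
             "SIGMA_X", "SIGMA_Y", "GAMMA_X", "GAMMA_Y", "ASS"]
_TAB_FORMATS = {"INDEX": "%5d", "X_PPM": "%9.4f", "Y_PPM": "%9.4f",
                "HEIGHT": "%+e", "SIGMA_X": "%8.4f", "SIGMA_Y": "%8.4f",
                "GAMMA_X": "%8.4f", "GAMMA_Y": "%8.4f", "ASS": "%s"}


def _write_tab(peaks: PeakList, path: str) -> None:
    n_z = peaks.n_plane_heights
    cols = _TAB_BASE + [f"Z_A{i}" for i in range(n_z)]
    fmts = [_TAB_FORMATS.get(c, "%+e") for c in cols]
    with open(path, "w") as fh:
        fh.write("VARS   " + " ".join(cols) + "\n")
        fh.write("FORMAT " + " ".join(fmts) + "\n")
        for p in peaks:
            row = [f"{p.index:5d}", f"{p.x_ppm:9.4f}", f"{p.y_ppm:9.4f}",
                   _fmt_height(p.height),
                   f"{p.sigma_x:8.4f}", f"{p.sigma_y:8.4f}",
                   f"{p.gamma_x:8.4f}", f"{p.gamma_y:8.4f}",
                   p.label if p.label else "-"]
            heights = list(p.plane_heights) + [0.0] * (n_z - len(p.plane_heights))
            row += [_fmt_height(h) for h in heights]
            fh.write(" ".join(row) + "\n")


def _read_tab(path: str) -> PeakList:
    names: list[str] = []
    rows: list[dict] = []
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "REMARK", "DATA", "FORMAT",
                                            "NULLVALUE", "NULLSTRING")):
                continue
            if line.startswith("VARS"):
                names = line.split()[1:]
                continue
            if not names:
                raise PeakListFormatError(f"unrecognized peak list: {path} "
                                          "has data before a VARS header")
            fields = line.split()
            if len(fields) != len(names):
                raise PeakListFormatError(
                    f"unrecognized peak list: row has {len(fields)} fields "
                    f"for {len(names)} VARS")
            rows.append(dict(zip(names, fields)))
    if not names or not {"X_PPM", "Y_PPM"} <= set(names):
        raise PeakListFormatError(f"unrecognized peak list: {path} lacks "
                                  "X_PPM/Y_PPM columns")
    z_names = sorted((n for n in names if re.fullmatch(r"Z_A\d+", n)),
                     key=lambda n: int(n[3:]))
    peaks = []
    for row in rows:
        peaks.append(Peak(
            x_ppm=float(row["X_PPM"]), y_ppm=float(row["Y_PPM"]),
            height=float(row.get("HEIGHT", 0.0)),
            sigma_x=float(row.get("SIGMA_X", 0.0)),
            sigma_y=float(row.get("SIGMA_Y", 0.0)),
            gamma_x=float(row.get("GAMMA_X", 0.0)),
            gamma_y=float(row.get("GAMMA_Y", 0.0)),
            plane_heights=[float(row[z]) for z in z_names],
            label="" if row.get("ASS", "-") == "-" else row["ASS"],
        ))
    return PeakList(peaks)


# ------------------------------------------------------------- sparky dialect

def _write_sparky(peaks: PeakList, path: str) -> None:
    if peaks.n_plane_heights:
        log.warning("sparky list format has no plane-height columns: "
                    "dropping Z_A values")
    with open(path, "w") as fh:
        fh.write(f"{'Assignment':>17s} {'w1':>10s} {'w2':>10s} "
                 f"{'Data Height':>14s}\n\n")
        for p in peaks:
            label = p.label if p.label else "?-?"
            fh.write(f"{label:>17s} {p.y_ppm:10.4f} {p.x_ppm:10.4f} "
                     f"{_fmt_height(p.height):>14s}\n")


def _read_sparky(path: str) -> PeakList:
    peaks = []
    saw_header = False
    with open(path, "r") as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if fields[0] == "Assignment":
                if "w1" not in fields or "w2" not in fields:
                    raise PeakListFormatError(
                        f"unrecognized peak list: {path} sparky header "
                        "lacks w1/w2")
                saw_header = True
                continue
            if len(fields) < 3:
                raise PeakListFormatError(f"unrecognized peak list: short "
                                          f"row in {path}")
            label, w1, w2 = fields[0], float(fields[1]), float(fields[2])
            height = float(fields[3]) if len(fields) > 3 else 0.0
            peaks.append(Peak(x_ppm=w2, y_ppm=w1, height=height,
                              label="" if label == "?-?" else label))
    if not saw_header and not peaks:
        raise PeakListFormatError(f"unrecognized peak list: {path} is empty")
    return PeakList(peaks)
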