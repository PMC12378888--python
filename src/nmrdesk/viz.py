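"""Contour computation and static rendering.

Contours come from a marching-squares pass with linear interpolation of
level crossings on cell edges; ambiguous (saddle) cells are resolved by the
cell-center average, which keeps the output reproducible and symmetric
under transposition.  Rendering is deterministic: fixed SVG hash salt, no
timestamps.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import LineCollection  # noqa: E402
import numpy as np  # noqa: E402

from .core import PeakList, Spectrum  # noqa: E402
from .peaks import estimate_noise  # noqa: E402

__all__ = ["LevelMode", "ContourLevelSpec", "OverlayItem", "compute_contours",
           "default_levels", "render_overlay", "cross_section", "projection",
           "render_surface"]

log = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "nmrdesk"  # deterministic SVG ids
plt.rcParams["svg.fonttype"] = "none"     # text as <text>, parseable


class LevelMode(str, enum.Enum):
    GEOMETRIC = "geometric"
    LINEAR = "linear"


@dataclass(frozen=True)
class ContourLevelSpec:
    mode: LevelMode = LevelMode.GEOMETRIC
    lowest: float = 1.0
    factor_or_step: float = 1.4
    count: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", LevelMode(self.mode))
        if self.mode is LevelMode.GEOMETRIC and self.factor_or_step <= 1:
            raise ValueError("geometric levels require factor > 1")
        if self.mode is LevelMode.LINEAR and self.factor_or_step <= 0:
            raise ValueError("linear levels require step > 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def levels(self) -> list[float]:
        if self.mode is LevelMode.GEOMETRIC:
            return [self.lowest * self.factor_or_step ** i
                    for i in range(self.count)]
        return [self.lowest + self.factor_or_step * i
                for i in range(self.count)]


# --------------------------------------------------------- marching squares

def _interp(level: float, va: float, vb: float) -> float:
    return (level - va) / (vb - va)


# per-case connected edge pairs; edges named T(top) B(bottom) L(left) R(right)
_CASES = {
    0: [], 15: [],
    1: [("T", "L")], 14: [("T", "L")],
    2: [("T", "R")], 13: [("T", "R")],
    3: [("L", "R")], 12: [("L", "R")],
    4: [("R", "B")], 11: [("R", "B")],
    6: [("T", "B")], 9: [("T", "B")],
    7: [("L", "B")], 8: [("L", "B")],
}


def compute_contours(matrix: np.ndarray, levels) -> dict:
    """Marching-squares polylines for each level.

    Returns ``{level: [polyline, ...]}`` where each polyline is an array of
    ``(row, col)`` vertices in fractional point units.  Levels above the
    matrix maximum simply yield empty lists.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2D matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")
    if np.isscalar(levels) or isinstance(levels, float):
        levels = [float(levels)]
    out = {}
    for level in levels:
        out[float(level)] = _contour_one_level(matrix, float(level))
    return out


def _contour_one_level(m: np.ndarray, level: float) -> list[np.ndarray]:
    nr, nc = m.shape
    inside = m > level
    verts: dict[tuple, tuple[float, float]] = {}
    adj: dict[tuple, list[tuple]] = {}

    def edge_vertex(kind: str, r: int, c: int) -> tuple:
        key = (kind, r, c)
        if key not in verts:
            if kind == "h":
                t = _interp(level, m[r, c], m[r, c + 1])
                verts[key] = (float(r), c + t)
            else:
                t = _interp(level, m[r, c], m[r + 1, c])
                verts[key] = (r + t, float(c))
        return key

    def connect(k1: tuple, k2: tuple) -> None:
        adj.setdefault(k1, []).append(k2)
        adj.setdefault(k2, []).append(k1)

    edge_key = {
        "T": lambda r, c: edge_vertex("h", r, c),
        "B": lambda r, c: edge_vertex("h", r + 1, c),
        "L": lambda r, c: edge_vertex("v", r, c),
        "R": lambda r, c: edge_vertex("v", r, c + 1),
    }

    for r in range(nr - 1):
        for c in range(nc - 1):
            a = inside[r, c]
            b = inside[r, c + 1]
            cc = inside[r + 1, c + 1]
            d = inside[r + 1, c]
            idx = a | (b << 1) | (cc << 2) | (d << 3)
            if idx in (0, 15):
                continue
            if idx in (5, 10):  # saddle: split by the cell-center average
                center_inside = (m[r, c] + m[r, c + 1] + m[r + 1, c]
                                 + m[r + 1, c + 1]) / 4.0 > level
                if idx == 5:
                    pairs = ([("T", "R"), ("B", "L")] if center_inside
                             else [("T", "L"), ("R", "B")])
                else:
                    pairs = ([("T", "L"), ("R", "B")] if center_inside
                             else [("T", "R"), ("B", "L")])
            else:
                pairs = _CASES[idx]
            for e1, e2 in pairs:
                connect(edge_key[e1](r, c), edge_key[e2](r, c))

    return _chain(verts, adj)


def _chain(verts: dict, adj: dict) -> list[np.ndarray]:
    used = set()
    lines = []

    def walk(start: tuple, first: tuple) -> list[tuple]:
        path = [start, first]
        used.add(frozenset((start, first)))
        prev, cur = start, first
        while True:
            nxt = None
            for cand in adj[cur]:
                if frozenset((cur, cand)) not in used:
                    nxt = cand
                    break
            if nxt is None:
                break
            used.add(frozenset((cur, nxt)))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    # open polylines first: start from degree-1 vertices
    for key in adj:
        if len(adj[key]) == 1:
            for nb in adj[key]:
                if frozenset((key, nb)) not in used:
                    path = walk(key, nb)
                    lines.append(np.array([verts[k] for k in path]))
    # remaining are closed loops
    for key in adj:
        for nb in adj[key]:
            if frozenset((key, nb)) not in used:
                path = walk(key, nb)
                lines.append(np.array([verts[k] for k in path]))
    return lines


def default_levels(spectrum: Spectrum) -> ContourLevelSpec:
    """Geometric levels from 5.5 x noise, factor 1.4, at most 20 levels
    capped below the matrix maximum."""
    matrix = spectrum.data_real[0]
    noise = (spectrum.noise_sigma if spectrum.noise_sigma is not None
             else estimate_noise(spectrum))
    peak = float(np.max(matrix)) if matrix.size else 0.0
    if noise <= 0 and peak <= 0:
        warnings.warn("zero noise and zero signal: single level at 1.0")
        return ContourLevelSpec(lowest=1.0, count=1)
    lowest = 5.5 * noise if noise > 0 else peak / 1.4 ** 20
    count = 20
    while count > 1 and lowest * 1.4 ** (count - 1) >= peak:
        count -= 1
    return ContourLevelSpec(lowest=lowest, factor_or_step=1.4, count=count)


# ----------------------------------------------------------------- overlay

@dataclass
class OverlayItem:
    spectrum: Spectrum
    ref_shift_ppm: tuple[float, float] = (0.0, 0.0)  # (direct, indirect)
    color: str = "black"
    z_order: int = 0


def _contour_segments_ppm(item: OverlayItem, levels: Sequence[float]):
    spec = item.spectrum
    matrix = spec.data_real[0]
    dx, dy = item.ref_shift_ppm
    polys = compute_contours(matrix, list(levels))
    segs = []
    for level_lines in polys.values():
        for line in level_lines:
            x = np.asarray(spec.axis_direct.ppm_of_point(line[:, 1])) + dx
            y = np.asarray(spec.axis_indirect.ppm_of_point(line[:, 0])) + dy
            segs.append(np.column_stack([x, y]))
    return segs


def _place_labels(ax, labels: PeakList, placed_boxes: list,
                  xspan: float, yspan: float):
    """Greedy displacement: try offsets of growing radius around each peak,
    minimizing bounding-box overlap with already placed labels."""
    char_w = 0.010 * xspan
    box_h = 0.035 * yspan
    offsets = [(0, 1), (1, 0), (0, -1), (-1, 0), (1, 1), (-1, 1),
               (1, -1), (-1, -1)]
    for p in labels:
        text = p.label or f"{p.index}"
        w = char_w * max(len(text), 1)
        best, best_overlap = None, np.inf
        for radius in (0.5, 1.0, 1.8, 3.0):
            for ox, oy in offsets:
                cx = p.x_ppm + ox * radius * char_w * 2
                cy = p.y_ppm + oy * radius * box_h
                box = (cx - w / 2, cy - box_h / 2, cx + w / 2, cy + box_h / 2)
                overlap = sum(_box_overlap(box, other)
                              for other in placed_boxes)
                if overlap < best_overlap:
                    best_overlap, best = overlap, (cx, cy, box)
            if best_overlap == 0:
                break
        cx, cy, box = best
        placed_boxes.append(box)
        ax.text(cx, cy, text, color="red", fontsize=8,
                ha="center", va="center", zorder=100)


def _box_overlap(a, b) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(w, 0.0) * max(h, 0.0)


def render_overlay(items: Sequence[OverlayItem],
                   levels: Sequence[Sequence[float]],
                   out_path: str,
                   labels: Optional[PeakList] = None,
                   xlim_ppm: Optional[tuple[float, float]] = None,
                   ylim_ppm: Optional[tuple[float, float]] = None,
                   figsize: tuple[float, float] = (7.0, 5.5)) -> None:
    """Draw stacked contour plots (ascending z_order), ppm axes reversed,
    per-item reference shift applied as a pure axis offset."""
    if not items:
        raise ValueError("need at least one overlay item")
    if len({it.z_order for it in items}) != len(items):
        raise ValueError("z_order values must be unique within an overlay")
    fig, ax = plt.subplots(figsize=figsize)
    x_all, y_all = [], []
    for it, lv in sorted(zip(items, levels), key=lambda t: t[0].z_order):
        segs = _contour_segments_ppm(it, lv)
        if segs:
            ax.add_collection(LineCollection(segs, colors=it.color,
                                             linewidths=0.7,
                                             zorder=it.z_order))
            for s in segs:
                x_all += [s[:, 0].min(), s[:, 0].max()]
                y_all += [s[:, 1].min(), s[:, 1].max()]
        hi_x, lo_x = it.spectrum.axis_direct.ppm_limits
        hi_y, lo_y = it.spectrum.axis_indirect.ppm_limits
        x_all += [hi_x + it.ref_shift_ppm[0], lo_x + it.ref_shift_ppm[0]]
        y_all += [hi_y + it.ref_shift_ppm[1], lo_y + it.ref_shift_ppm[1]]
    xlim = xlim_ppm or (max(x_all), min(x_all))
    ylim = ylim_ppm or (max(y_all), min(y_all))
    ax.set_xlim(max(xlim), min(xlim))  # downfield left
    ax.set_ylim(max(ylim), min(ylim))  # downfield bottom-up reversed
    ax.set_xlabel("direct dimension (ppm)")
    ax.set_ylabel("indirect dimension (ppm)")
    if labels:
        xspan = abs(xlim[0] - xlim[1])
        yspan = abs(ylim[0] - ylim[1])
        _place_labels(ax, labels, [], xspan, yspan)
    _save(fig, out_path)


def _save(fig, out_path: str) -> None:
    try:
        if out_path.endswith(".svg"):
            fig.savefig(out_path, metadata={"Date": None})
        else:
            fig.savefig(out_path, dpi=120)
    except OSError as exc:
        raise OSError(f"cannot write image to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)


# ------------------------------------------------- 1D traces and 3D modes

def cross_section(spectrum: Spectrum, axis: str, at_ppm: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest row/column through ``at_ppm`` (no interpolation).

    ``axis`` names the dimension of the returned trace: ``direct`` gives a
    row (at an indirect-dimension ppm), ``indirect`` a column.
    Returns (ppm_scale, values).
    """
    matrix = spectrum.data_real[0]
    if axis == "direct":
        pick = spectrum.axis_indirect
        idx = int(round(float(pick.point_of_ppm(at_ppm))))
        if not 0 <= idx < pick.n_points:
            raise ValueError(f"{at_ppm} ppm outside the indirect axis span")
        return spectrum.axis_direct.ppm_scale, matrix[idx, :].copy()
    if axis == "indirect":
        pick = spectrum.axis_direct
        idx = int(round(float(pick.point_of_ppm(at_ppm))))
        if not 0 <= idx < pick.n_points:
            raise ValueError(f"{at_ppm} ppm outside the direct axis span")
        return spectrum.axis_indirect.ppm_scale, matrix[:, idx].copy()
    raise ValueError("axis must be 'direct' or 'indirect'")


def projection(spectrum: Spectrum, axis: str, method: str = "max"
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column max or sum of the real matrix onto one axis."""
    matrix = spectrum.data_real[0]
    if method not in ("max", "sum"):
        raise ValueError("method must be 'max' or 'sum'")
    red = np.max if method == "max" else np.sum
    if axis == "direct":
        return spectrum.axis_direct.ppm_scale, red(matrix, axis=0)
    if axis == "indirect":
        return spectrum.axis_indirect.ppm_scale, red(matrix, axis=1)
    raise ValueError("axis must be 'direct' or 'indirect'")


def render_surface(spectrum: Spectrum, out_path: str, mode: str = "surface",
                   view: tuple[float, float] = (35.0, -60.0),
                   max_mesh: int = 1024,
                   levels: Optional[Sequence[float]] = None) -> None:
    """Static 3D rendering: height-mapped surface with contour lines, or a
    terrace model of stacked level slabs."""
    if mode not in ("surface", "terrace"):
        raise ValueError("mode must be 'surface' or 'terrace'")
    matrix = spectrum.data_real[0]
    stride = max(1, int(np.ceil(max(matrix.shape) / max_mesh)))
    if stride > 1:
        log.info("downsampling %sx%s matrix by %d for meshing",
                 *matrix.shape, stride)
        matrix = matrix[::stride, ::stride]
    x = np.asarray(spectrum.axis_direct.ppm_of_point(
        np.arange(0, spectrum.axis_direct.n_points, stride)))
    y = np.asarray(spectrum.axis_indirect.ppm_of_point(
        np.arange(0, spectrum.axis_indirect.n_points, stride)))
    xg, yg = np.meshgrid(x, y)
    if levels is None:
        levels = default_levels(spectrum).levels()
    levels = [lv for lv in levels if lv < matrix.max()]

    fig = plt.figure(figsize=(7.0, 5.5))
    ax = fig.add_subplot(111, projection="3d")
    if mode == "terrace":
        z = np.zeros_like(matrix)
        for lv in sorted(levels):
            z = np.where(matrix > lv, lv, z)
        ax.plot_surface(xg, yg, z, cmap="viridis", shade=False,
                        rstride=1, cstride=1)
    else:
        ax.plot_surface(xg, yg, matrix, cmap="viridis", rstride=1, cstride=1,
                        linewidth=0, antialiased=False)
        if levels:
            ax.contour(xg, yg, matrix, levels=sorted(levels), colors="black",
                       linewidths=0.5)
    ax.view_init(elev=view[0], azim=view[1])
    ax.set_xlim(x.max(), x.min())
    ax.set_ylim(y.max(), y.min())
    _save(fig, out_path)
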