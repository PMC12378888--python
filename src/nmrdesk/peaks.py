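"""Noise estimation, peak picking and Voigt-family deconvolution.

Lineshapes are separable products of 1D profiles along each axis.  The 1D
profile is a Voigt computed through the scaled complex error function, with
pure-Gaussian and pure-Lorentzian branches as degenerate limits.  Fitting
is bounded trust-region least squares over clustered regions; pseudo-3D
stacks share all six shape parameters across planes and vary only the
per-plane heights.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import wofz

from .core import AxisCalibration, Peak, PeakList, Spectrum

__all__ = ["Lineshape", "FitOptions", "FitResult", "estimate_noise",
           "pick_peaks", "voigt_value", "fit_region", "fit_peaks",
           "fit_pseudo3d", "edit_peaklist"]

log = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


class Lineshape(str, enum.Enum):
    VOIGT = "voigt"
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"


@dataclass(frozen=True)
class FitOptions:
    lineshape: Lineshape = Lineshape.VOIGT
    max_iterations: int = 100
    cluster_threshold_sigma: float = 5.5
    region_pad_points: int = 3
    min_separation_points: int = 2
    absolute_heights: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineshape", Lineshape(self.lineshape))
        if self.cluster_threshold_sigma <= 0:
            raise ValueError("cluster_threshold_sigma must be positive")


@dataclass
class FitResult:
    peaks: PeakList
    reconstructed: Spectrum
    residual_rms: float
    converged: list = field(default_factory=list)

    @property
    def all_converged(self) -> bool:
        return all(self.converged) if self.converged else True


# ------------------------------------------------------------------- noise

def estimate_noise(spectrum, block: int = 32) -> float:
    """Robust noise sigma: 1.4826 x the median of per-block MADs.

    Block-wise evaluation keeps strong but sparse signals from inflating
    the estimate.
    """
    matrix = spectrum.data_real if isinstance(spectrum, Spectrum) else spectrum
    matrix = np.asarray(matrix, dtype=float)
    matrix = matrix.reshape(-1, matrix.shape[-1]) if matrix.ndim == 3 else matrix
    nr, nc = matrix.shape
    mads = []
    for r0 in range(0, nr, block):
        for c0 in range(0, nc, block):
            sub = matrix[r0:r0 + block, c0:c0 + block]
            mads.append(np.median(np.abs(sub - np.median(sub))))
    return float(1.4826 * np.median(mads))


# ------------------------------------------------------------------ picking

def pick_peaks(spectrum: Spectrum, threshold_sigma: float = 5.5,
               noise_sigma: Optional[float] = None) -> PeakList:
    """Local maxima of the real matrix strictly above all 8 neighbours and
    above ``threshold_sigma * noise``; sub-point refinement by parabolic
    interpolation along each axis independently."""
    matrix = spectrum.data_real[0]
    noise = noise_sigma if noise_sigma is not None else (
        spectrum.noise_sigma if spectrum.noise_sigma is not None
        else estimate_noise(spectrum))
    threshold = threshold_sigma * noise
    interior = matrix[1:-1, 1:-1]
    higher = np.ones_like(interior, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            nb = matrix[1 + dr: matrix.shape[0] - 1 + dr,
                        1 + dc: matrix.shape[1] - 1 + dc]
            higher &= interior > nb
    higher &= interior > threshold
    rows, cols = np.nonzero(higher)
    peaks = []
    for r, c in sorted(zip(rows + 1, cols + 1)):
        dy = _parabolic_offset(matrix[r - 1, c], matrix[r, c], matrix[r + 1, c])
        dx = _parabolic_offset(matrix[r, c - 1], matrix[r, c], matrix[r, c + 1])
        peaks.append(Peak(
            x_ppm=float(spectrum.axis_direct.ppm_of_point(c + dx)),
            y_ppm=float(spectrum.axis_indirect.ppm_of_point(r + dy)),
            height=float(matrix[r, c])))
    return PeakList(peaks)


def _parabolic_offset(left: float, center: float, right: float) -> float:
    denom = left - 2.0 * center + right
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


# ---------------------------------------------------------------- lineshape

def voigt_value(dx, sigma: float, gamma: float):
    """Area-normalized Voigt profile V(dx; sigma, gamma).

    ``V(dx) = Re[w((dx + i*gamma) / (sigma*sqrt(2)))] / (sigma*sqrt(2*pi))``
    with the pure-Lorentzian branch taken when sigma is (near) zero.
    """
    if sigma < 0 or gamma < 0:
        raise ValueError("widths must be non-negative")
    if sigma + gamma <= 0:
        raise ValueError("sigma + gamma must be positive")
    dx = np.asarray(dx, dtype=float)
    if sigma < 1e-12 * max(1.0, gamma):
        out = gamma / (np.pi * (dx ** 2 + gamma ** 2))
    else:
        z = (dx + 1j * gamma) / (sigma * _SQRT2)
        out = wofz(z).real / (sigma * _SQRT2PI)
    return out if out.ndim else float(out)


def _unit_profile(dx: np.ndarray, sigma: float, gamma: float) -> np.ndarray:
    """Voigt scaled to unit height at dx = 0."""
    v0 = voigt_value(0.0, sigma, gamma)
    return np.asarray(voigt_value(dx, sigma, gamma)) / v0


# ------------------------------------------------------------- region fits

_MIN_WIDTH = 0.3


def _shape_params(lineshape: Lineshape) -> list[str]:
    if lineshape is Lineshape.VOIGT:
        return ["sigma_x", "gamma_x", "sigma_y", "gamma_y"]
    if lineshape is Lineshape.GAUSSIAN:
        return ["sigma_x", "sigma_y"]
    return ["gamma_x", "gamma_y"]


def _widths_of(vec: Sequence[float], lineshape: Lineshape
               ) -> tuple[float, float, float, float]:
    """(sigma_x, gamma_x, sigma_y, gamma_y) from the packed shape vector."""
    if lineshape is Lineshape.VOIGT:
        sx, gx, sy, gy = vec
    elif lineshape is Lineshape.GAUSSIAN:
        (sx, sy), gx, gy = vec, 0.0, 0.0
    else:
        (gx, gy), sx, sy = vec, 0.0, 0.0
    return sx, gx, sy, gy


def _eval_peak_patch(xg: np.ndarray, yg: np.ndarray, x: float, y: float,
                     widths: tuple[float, float, float, float]) -> np.ndarray:
    sx, gx, sy, gy = widths
    px = _unit_profile(xg - x, sx, gx)
    py = _unit_profile(yg - y, sy, gy)
    return np.outer(py, px)


def _default_widths(lineshape: Lineshape) -> list[float]:
    if lineshape is Lineshape.VOIGT:
        return [1.5, 1.0, 1.5, 1.0]
    return [1.5, 1.5]


def _merge_close(peaks_pts: list[dict], min_sep: float) -> list[dict]:
    kept: list[dict] = []
    for p in sorted(peaks_pts, key=lambda q: -abs(q["height"])):
        if all(np.hypot(p["x"] - q["x"], p["y"] - q["y"]) >= min_sep
               for q in kept):
            kept.append(p)
    return kept


def _fit_patch(matrix: np.ndarray, peaks_pts: list[dict], options: FitOptions,
               noise: float, planes: Optional[np.ndarray] = None):
    """Core least-squares fit in patch point coordinates.

    ``matrix`` is the 2D patch (plane 0); ``planes`` optionally carries a
    (n_planes, ny, nx) stack for shared-shape pseudo-3D fitting.  Each peak
    dict holds x, y, height and the four widths; returns (peaks_pts,
    converged) with fitted values filled in, plus per-plane heights when
    ``planes`` is given.
    """
    ls = options.lineshape
    ny, nx = matrix.shape
    xg = np.arange(nx, dtype=float)
    yg = np.arange(ny, dtype=float)
    n_shape = len(_shape_params(ls))
    n_planes = 1 if planes is None else planes.shape[0]
    peaks_pts = _merge_close(peaks_pts, options.min_separation_points)

    def pack(plist: list[dict]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x0, lo, hi = [], [], []
        for p in plist:
            x0 += [p["x"], p["y"]]
            lo += [-0.49, -0.49]
            hi += [nx - 0.51, ny - 0.51]
            shp = [max(_MIN_WIDTH, p[k]) for k in _shape_params(ls)]
            if all(p[k] == 0 for k in _shape_params(ls)):
                shp = _default_widths(ls)
            x0 += shp
            lo += [_MIN_WIDTH] * n_shape
            hi += [float(max(nx, ny))] * n_shape
            if planes is None:
                x0 += [p["height"]]
                lo += [-np.inf]
                hi += [np.inf]
            else:
                hts = p.get("plane_heights") or [p["height"]] * n_planes
                x0 += list(hts)
                lo += [-np.inf] * n_planes
                hi += [np.inf] * n_planes
        return (np.asarray(x0), np.asarray(lo), np.asarray(hi))

    stride = 2 + n_shape + (1 if planes is None else n_planes)

    def model(theta: np.ndarray) -> np.ndarray:
        if planes is None:
            out = np.zeros((ny, nx))
            for j in range(len(theta) // stride):
                seg = theta[j * stride:(j + 1) * stride]
                widths = _widths_of(seg[2:2 + n_shape], ls)
                out += seg[2 + n_shape] * _eval_peak_patch(
                    xg, yg, seg[0], seg[1], widths)
            return out
        out = np.zeros((n_planes, ny, nx))
        for j in range(len(theta) // stride):
            seg = theta[j * stride:(j + 1) * stride]
            widths = _widths_of(seg[2:2 + n_shape], ls)
            shape2d = _eval_peak_patch(xg, yg, seg[0], seg[1], widths)
            out += seg[2 + n_shape:][:, None, None] * shape2d
        return out

    target = matrix if planes is None else planes

    def residual(theta: np.ndarray) -> np.ndarray:
        return (model(theta) - target).ravel()

    def run(plist: list[dict]):
        x0, lo, hi = pack(plist)
        x0 = np.clip(x0, lo, hi)
        # trf does not count finite-difference jacobian calls in nfev, so
        # max_nfev effectively caps the iteration count
        res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                            max_nfev=options.max_iterations)
        return res

    res = run(peaks_pts)
    fitted = _unpack(res.x, peaks_pts, ls, n_shape, stride, planes, n_planes)

    # cull insignificant peaks once, then refit the survivors
    cull_level = 3.0 * noise
    survivors = [p for p in fitted if abs(p["height"]) >= cull_level]
    if len(survivors) != len(fitted):
        if not survivors:
            return [], bool(res.success)
        res = run(survivors)
        fitted = _unpack(res.x, survivors, ls, n_shape, stride, planes,
                         n_planes)
    return fitted, bool(res.success)


def _unpack(theta: np.ndarray, plist: list[dict], ls: Lineshape, n_shape: int,
            stride: int, planes, n_planes: int) -> list[dict]:
    out = []
    for j, src in enumerate(plist):
        seg = theta[j * stride:(j + 1) * stride]
        sx, gx, sy, gy = _widths_of(seg[2:2 + n_shape], ls)
        p = dict(src)
        p.update(x=float(seg[0]), y=float(seg[1]), sigma_x=sx, gamma_x=gx,
                 sigma_y=sy, gamma_y=gy)
        if planes is None:
            p["height"] = float(seg[2 + n_shape])
        else:
            hts = [float(h) for h in seg[2 + n_shape:]]
            p["plane_heights"] = hts
            p["height"] = hts[0]
        out.append(p)
    return out


# ----------------------------------------------------------- public fitting

def _peak_to_pts(p: Peak, ax_x: AxisCalibration, ax_y: AxisCalibration,
                 x_off: int = 0, y_off: int = 0) -> dict:
    return {
        "x": float(ax_x.point_of_ppm(p.x_ppm)) - x_off,
        "y": float(ax_y.point_of_ppm(p.y_ppm)) - y_off,
        "height": p.height, "sigma_x": p.sigma_x, "gamma_x": p.gamma_x,
        "sigma_y": p.sigma_y, "gamma_y": p.gamma_y,
        "plane_heights": list(p.plane_heights), "label": p.label,
    }


def _pts_to_peak(d: dict, ax_x: AxisCalibration, ax_y: AxisCalibration,
                 x_off: int = 0, y_off: int = 0) -> Peak:
    return Peak(
        x_ppm=float(ax_x.ppm_of_point(d["x"] + x_off)),
        y_ppm=float(ax_y.ppm_of_point(d["y"] + y_off)),
        height=d["height"], sigma_x=d["sigma_x"], sigma_y=d["sigma_y"],
        gamma_x=d["gamma_x"], gamma_y=d["gamma_y"],
        plane_heights=list(d.get("plane_heights", [])),
        label=d.get("label", ""))


def fit_region(patch: Spectrum, initial_peaks: PeakList,
               options: FitOptions = FitOptions(),
               noise_sigma: Optional[float] = None) -> FitResult:
    """Fit all peaks of one spectral patch jointly (single plane)."""
    if not initial_peaks:
        raise ValueError("fit_region requires at least one initial peak")
    noise = noise_sigma if noise_sigma is not None else (
        patch.noise_sigma or 0.0)
    matrix = patch.data_real[0]
    pts = [_peak_to_pts(p, patch.axis_direct, patch.axis_indirect)
           for p in initial_peaks]
    fitted, ok = _fit_patch(matrix, pts, options, noise)
    peaks = PeakList([_pts_to_peak(d, patch.axis_direct, patch.axis_indirect)
                      for d in fitted])
    recon = _reconstruct(patch, peaks, options)
    rms = float(np.sqrt(np.mean((patch.data_real - recon.data_real) ** 2)))
    return FitResult(peaks=peaks, reconstructed=recon, residual_rms=rms,
                     converged=[ok])


def _reconstruct(spectrum: Spectrum, peaks: PeakList,
                 options: FitOptions) -> Spectrum:
    n_planes, ny, nx = spectrum.shape
    xg = np.arange(nx, dtype=float)
    yg = np.arange(ny, dtype=float)
    out = np.zeros((n_planes, ny, nx))
    for p in peaks:
        x = float(spectrum.axis_direct.point_of_ppm(p.x_ppm))
        y = float(spectrum.axis_indirect.point_of_ppm(p.y_ppm))
        shape2d = _eval_peak_patch(xg, yg, x, y,
                                   (p.sigma_x, p.gamma_x, p.sigma_y, p.gamma_y))
        if n_planes > 1 and len(p.plane_heights) == n_planes:
            hts = np.asarray(p.plane_heights, dtype=float)
            if not options.absolute_heights:
                hts = hts * p.height  # Z_A values are relative to plane 0
            out += hts[:, None, None] * shape2d
        else:
            out[0] += p.height * shape2d
            if n_planes > 1:
                out[1:] += p.height * shape2d
    return Spectrum(data_real=out, axis_direct=spectrum.axis_direct,
                    axis_indirect=spectrum.axis_indirect,
                    noise_sigma=spectrum.noise_sigma)


def _regions(mask: np.ndarray, pad: int) -> list[tuple[int, int, int, int]]:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    boxes = []
    for sl_y, sl_x in ndimage.find_objects(labels):
        boxes.append((max(0, sl_y.start - pad),
                      min(mask.shape[0], sl_y.stop + pad),
                      max(0, sl_x.start - pad),
                      min(mask.shape[1], sl_x.stop + pad)))
    return boxes


def _assign_regions(spectrum: Spectrum, peaks: PeakList, options: FitOptions,
                    noise: float):
    matrix = spectrum.data_real[0]
    threshold = options.cluster_threshold_sigma * noise
    if threshold <= 0:
        threshold = 1e-6 * max(np.max(np.abs(matrix)), 1e-300)
    boxes = _regions(matrix > threshold, options.region_pad_points)

    ny, nx = matrix.shape
    groups: dict[int, list[int]] = {}
    solo: list[int] = []
    for i, p in enumerate(peaks):
        x = float(spectrum.axis_direct.point_of_ppm(p.x_ppm))
        y = float(spectrum.axis_indirect.point_of_ppm(p.y_ppm))
        if not (-0.5 <= x < nx - 0.5 and -0.5 <= y < ny - 0.5):
            warnings.warn(f"peak {i} at ({p.x_ppm:.3f}, {p.y_ppm:.3f}) ppm "
                          "lies outside the spectrum: dropped")
            continue
        for bi, (y0, y1, x0, x1) in enumerate(boxes):
            if y0 <= y < y1 and x0 <= x < x1:
                groups.setdefault(bi, []).append(i)
                break
        else:
            solo.append(i)
    region_list = [(boxes[bi], idxs) for bi, idxs in sorted(groups.items())]
    halo = options.region_pad_points + 4
    for i in solo:
        x = int(round(float(spectrum.axis_direct.point_of_ppm(peaks[i].x_ppm))))
        y = int(round(float(spectrum.axis_indirect.point_of_ppm(peaks[i].y_ppm))))
        box = (max(0, y - halo), min(ny, y + halo + 1),
               max(0, x - halo), min(nx, x + halo + 1))
        region_list.append((box, [i]))
    return region_list


def fit_peaks(spectrum: Spectrum, peaks: PeakList,
              options: FitOptions = FitOptions(),
              noise_sigma: Optional[float] = None) -> FitResult:
    """Cluster the spectrum into regions and deconvolute each independently.

    Returns refined peaks, the reconstruction on the full grid, and the
    residual RMS over the whole matrix.
    """
    if not peaks:
        raise ValueError("fit_peaks requires a non-empty peak list")
    noise = noise_sigma if noise_sigma is not None else (
        spectrum.noise_sigma if spectrum.noise_sigma is not None
        else estimate_noise(spectrum))
    matrix = spectrum.data_real[0]
    fitted_all: list[dict] = []
    converged: list[bool] = []
    for (y0, y1, x0, x1), idxs in _assign_regions(spectrum, peaks, options,
                                                  noise):
        pts = [_peak_to_pts(peaks[i], spectrum.axis_direct,
                            spectrum.axis_indirect, x_off=x0, y_off=y0)
               for i in idxs]
        fitted, ok = _fit_patch(matrix[y0:y1, x0:x1], pts, options, noise)
        converged.append(ok)
        for d in fitted:
            d["x"] += x0
            d["y"] += y0
            fitted_all.append(d)
    out_peaks = PeakList([_pts_to_peak(d, spectrum.axis_direct,
                                       spectrum.axis_indirect)
                          for d in fitted_all])
    recon = _reconstruct(spectrum, out_peaks, options)
    rms = float(np.sqrt(np.mean((spectrum.data_real[0] - recon.data_real[0]) ** 2)))
    return FitResult(peaks=out_peaks, reconstructed=recon, residual_rms=rms,
                     converged=converged)


def fit_pseudo3d(planes: Spectrum, initial_peaks: PeakList,
                 options: FitOptions = FitOptions(),
                 noise_sigma: Optional[float] = None) -> FitResult:
    """Joint fit over all planes: shared positions and widths, per-plane
    heights (reported relative to plane 0 unless ``absolute_heights``)."""
    if planes.n_planes < 2:
        raise ValueError("fit_pseudo3d requires at least 2 planes")
    if not initial_peaks:
        raise ValueError("fit_pseudo3d requires a non-empty peak list")
    noise = noise_sigma if noise_sigma is not None else (
        planes.noise_sigma if planes.noise_sigma is not None
        else estimate_noise(planes.data_real[0]))
    stack = planes.data_real
    fitted_all: list[dict] = []
    converged: list[bool] = []
    for (y0, y1, x0, x1), idxs in _assign_regions(planes, initial_peaks,
                                                  options, noise):
        pts = [_peak_to_pts(initial_peaks[i], planes.axis_direct,
                            planes.axis_indirect, x_off=x0, y_off=y0)
               for i in idxs]
        for d in pts:
            d["plane_heights"] = []
        fitted, ok = _fit_patch(stack[0, y0:y1, x0:x1], pts, options, noise,
                                planes=stack[:, y0:y1, x0:x1])
        converged.append(ok)
        for d in fitted:
            d["x"] += x0
            d["y"] += y0
            fitted_all.append(d)

    out = []
    for d in fitted_all:
        hts = d["plane_heights"]
        if not options.absolute_heights:
            ref = hts[0] if hts[0] != 0 else 1.0
            d = dict(d, plane_heights=[h / ref for h in hts], height=hts[0])
        out.append(_pts_to_peak(d, planes.axis_direct, planes.axis_indirect))
    out_peaks = PeakList(out)
    recon = _reconstruct(planes, out_peaks, options)
    rms = float(np.sqrt(np.mean((planes.data_real - recon.data_real) ** 2)))
    return FitResult(peaks=out_peaks, reconstructed=recon, residual_rms=rms,
                     converged=converged)


# ----------------------------------------------------------------- editing

def edit_peaklist(peaks: PeakList, action: str, payload) -> PeakList:
    """Pure-functional add / move / delete; indices are re-assigned."""
    out = peaks.copy()
    if action == "add":
        if not isinstance(payload, Peak):
            raise TypeError("add payload must be a Peak")
        out.append(replace(payload, plane_heights=list(payload.plane_heights)))
    elif action == "delete":
        idx = int(payload)
        if not 0 <= idx < len(out):
            raise IndexError(f"peak index {idx} out of range")
        del out[idx]
    elif action == "move":
        idx, x_ppm, y_ppm = payload
        idx = int(idx)
        if not 0 <= idx < len(out):
            raise IndexError(f"peak index {idx} out of range")
        out[idx] = replace(out[idx], x_ppm=float(x_ppm), y_ppm=float(y_ppm),
                           plane_heights=list(out[idx].plane_heights))
    else:
        raise ValueError(f"unknown edit action {action!r}")
    return PeakList(out)
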