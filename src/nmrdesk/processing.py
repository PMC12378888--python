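"""Time-domain to frequency-domain conversion for 2D / pseudo-3D data.

Pipeline per dimension: solvent filter (direct only) -> apodization ->
zero-filling -> FFT with quadrature handling -> phase correction ->
region extraction.  The direct-dimension phase can be determined
automatically; the algorithm minimizes a negativity penalty plus the
entropy of the first derivative of the real part over a coarse grid with
Nelder-Mead refinement.

Fixed conventions (documented, not configurable):

* the first time-domain point of each dimension is scaled by 0.5 before its
  transform (half-first-point rule, suppresses the baseline offset);
* after the FFT the spectrum is rotated so the carrier sits at the center
  and reversed so index 0 is the downfield edge;
* first-order phase is the total sweep across the displayed spectrum with
  the pivot at point 0;
* the Bruker group delay is compensated by a first-order phase ramp of
  ``360 * group_delay`` degrees (a circular time shift of the integer part
  is available behind a flag).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize

from .core import (AcquisitionMeta, AcquisitionMode, AxisCalibration,
                   Spectrum, TimeDomainData)

__all__ = [
    "WindowKind", "WindowSpec", "PhaseSpec", "DimensionScheme",
    "ProcessingScheme", "solvent_suppress", "apodize", "zero_fill",
    "transform_direct", "transform_indirect", "combine_quadrature",
    "apply_phase", "autophase", "extract_region", "process_2d",
    "process_pseudo3d",
]

log = logging.getLogger(__name__)


class WindowKind(str, enum.Enum):
    NONE = "none"
    SINE_BELL = "sine_bell"
    EXPONENTIAL = "exponential"
    GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class WindowSpec:
    """Apodization window, NMRPipe-flavoured parameters.

    ``sine_bell``: weight(i) = sin(pi*off + pi*(end-off)*i/(n-1)) ** pow.
    ``exponential``: weight(i) = exp(-pi * lb_hz * t_i).
    ``gaussian``: Lorentz-to-Gauss, exp(pi*lb_hz*t) * exp(-(t/(gb*T))^2).
    """

    kind: WindowKind = WindowKind.SINE_BELL
    off: float = 0.5
    end: float = 0.95
    pow: float = 2.0
    lb_hz: float = 0.0
    gb: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", WindowKind(self.kind))
        if not (0.0 <= self.off <= 1.0 and 0.0 <= self.end <= 1.0):
            raise ValueError("off and end must lie in [0, 1]")
        if self.kind is WindowKind.SINE_BELL and self.off > self.end:
            raise ValueError("sine_bell requires off <= end")
        if self.pow <= 0:
            raise ValueError("pow must be positive")
        if self.lb_hz < 0:
            raise ValueError("lb_hz must be non-negative")

    def weights(self, n: int, dwell_s: float) -> np.ndarray:
        i = np.arange(n, dtype=float)
        if self.kind is WindowKind.NONE:
            return np.ones(n)
        if self.kind is WindowKind.SINE_BELL:
            frac = i / (n - 1) if n > 1 else i
            return np.sin(np.pi * self.off
                          + np.pi * (self.end - self.off) * frac) ** self.pow
        t = i * dwell_s
        if self.kind is WindowKind.EXPONENTIAL:
            return np.exp(-np.pi * self.lb_hz * t)
        t_max = max((n - 1) * dwell_s, dwell_s)
        return np.exp(np.pi * self.lb_hz * t - (t / (self.gb * t_max)) ** 2)


@dataclass(frozen=True)
class PhaseSpec:
    """Zero- and first-order phase; p1 is the total sweep, pivot point 0."""

    p0_deg: float = 0.0
    p1_deg: float = 0.0


AUTO_PHASE = "auto"


@dataclass
class DimensionScheme:
    window: WindowSpec = field(default_factory=WindowSpec)
    zero_fill_folds: int = 1
    solvent_filter: bool = False
    extract_ppm: Optional[tuple[float, float]] = None
    phase: Union[PhaseSpec, str] = field(default_factory=PhaseSpec)

    def __post_init__(self) -> None:
        if self.zero_fill_folds < 0:
            raise ValueError("zero_fill_folds must be >= 0")
        if isinstance(self.phase, str) and self.phase != AUTO_PHASE:
            raise ValueError(f"phase must be a PhaseSpec or {AUTO_PHASE!r}")


@dataclass
class ProcessingScheme:
    direct: DimensionScheme = field(default_factory=DimensionScheme)
    indirect: DimensionScheme = field(
        default_factory=lambda: DimensionScheme(solvent_filter=False))
    first_plane_only: bool = False

    def __post_init__(self) -> None:
        if self.indirect.solvent_filter:
            raise ValueError("solvent filter applies to the direct "
                             "dimension only")


# --------------------------------------------------------------- primitives

def solvent_suppress(fid_row: np.ndarray, half_width: int = 16) -> np.ndarray:
    """Subtract a centered moving average (boxcar lowpass) from the FID.

    Removes the on-carrier (zero-frequency) component; window shrinks at
    the edges so the output has the input's length.
    """
    fid = np.asarray(fid_row)
    n = fid.shape[-1]
    if n < 3:
        warnings.warn("FID shorter than 3 points: solvent filter skipped")
        return fid.copy()
    csum = np.cumsum(fid, axis=-1)
    csum = np.concatenate([np.zeros(fid.shape[:-1] + (1,), dtype=fid.dtype),
                           csum], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width + 1, n)
    baseline = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return fid - baseline


def apodize(fid_row: np.ndarray, window: WindowSpec,
            dwell_s: float = 1.0) -> np.ndarray:
    """Pointwise multiply by the window (no first-point scaling here)."""
    fid = np.asarray(fid_row)
    if window.kind is WindowKind.NONE:
        return fid.copy()
    return fid * window.weights(fid.shape[-1], dwell_s)


def zero_fill(fid_row: np.ndarray, folds: int) -> np.ndarray:
    """Append zeros until the length is ``n * 2**folds``."""
    if folds < 0:
        raise ValueError("folds must be >= 0")
    fid = np.asarray(fid_row)
    n = fid.shape[-1]
    out = np.zeros(fid.shape[:-1] + (n * 2 ** folds,), dtype=fid.dtype)
    out[..., :n] = fid
    return out


def _shift_and_reverse(ft: np.ndarray) -> np.ndarray:
    """Rotate carrier to center and flip so index 0 is downfield."""
    return np.fft.fftshift(ft, axes=-1)[..., ::-1]


def transform_direct(fid_row: np.ndarray, group_delay: float = 0.0,
                     first_point_scale: float = 0.5,
                     group_delay_mode: str = "phase_ramp") -> np.ndarray:
    """Complex FFT of a (windowed, zero-filled) FID row.

    The output is ordered downfield-first with the carrier at the center
    bin ``n/2 - 1``.  A non-zero Bruker group delay is compensated either
    entirely by a first-order phase ramp (default) or by a circular shift
    of its integer part plus a ramp for the remainder.
    """
    fid = np.asarray(fid_row, dtype=np.complex128).copy()
    n = fid.shape[-1]
    delay = float(group_delay)
    if delay and group_delay_mode == "circular_shift":
        k = int(delay)
        fid = np.roll(fid, -k, axis=-1)
        delay -= k
    fid[..., 0] *= first_point_scale
    ft = np.fft.fft(fid, axis=-1)
    if delay:
        freqs = np.fft.fftfreq(n) * n      # signed bin index
        ft = ft * np.exp(2j * np.pi * freqs * delay / n)
    return _shift_and_reverse(ft)


def combine_quadrature(plane: np.ndarray,
                       mode: AcquisitionMode) -> tuple[np.ndarray, np.ndarray]:
    """Combine interleaved cos/sin rows into hypercomplex t1 vectors.

    Returns ``(a, b)``: the complex indirect interferograms built from the
    real and from the imaginary direct parts respectively, each of shape
    ``(..., n_increments, n_direct)``.
    """
    mode = AcquisitionMode(mode)
    plane = np.asarray(plane, dtype=np.complex128)
    if plane.shape[-2] % 2:
        raise ValueError("incomplete quadrature pairs: odd row count")
    cos_rows = plane[..., 0::2, :]
    sin_rows = plane[..., 1::2, :]
    if mode is AcquisitionMode.ECHO_ANTIECHO:
        echo, anti = cos_rows, sin_rows
        cos_rows = (echo + anti) / 2.0
        sin_rows = 1j * (echo - anti) / 2.0
    a = cos_rows.real + 1j * sin_rows.real
    b = cos_rows.imag + 1j * sin_rows.imag
    if mode is AcquisitionMode.STATES_TPPI:
        sign = np.where(np.arange(a.shape[-2]) % 2 == 0, 1.0, -1.0)
        a = a * sign[:, None]
        b = b * sign[:, None]
    return a, b


def transform_indirect(plane: np.ndarray, mode: AcquisitionMode,
                       first_point_scale: float = 0.5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature combination followed by the indirect-dimension FFT.

    ``plane`` holds interleaved quadrature rows (rows x direct points).
    Returns the two complex planes (from the direct real and imaginary
    parts) transformed along the indirect axis, each ordered
    downfield-first, shape ``(n_indirect, n_direct)``.
    """
    a, b = combine_quadrature(plane, mode)
    out = []
    for block in (a, b):
        block = np.swapaxes(block, -1, -2).copy()  # (..., direct, t1)
        block[..., 0] *= first_point_scale
        ft = _shift_and_reverse(np.fft.fft(block, axis=-1))
        out.append(np.swapaxes(ft, -1, -2))
    return out[0], out[1]


def apply_phase(spectrum_row: np.ndarray, phase: PhaseSpec) -> np.ndarray:
    """out[k] = in[k] * exp(i * (p0 + p1 * k/(N-1)) * pi/180), pivot k=0."""
    row = np.asarray(spectrum_row)
    if not np.iscomplexobj(row):
        raise ValueError("imaginary data required for phase correction")
    n = row.shape[-1]
    k = np.arange(n, dtype=float)
    frac = k / (n - 1) if n > 1 else k
    ramp = np.exp(1j * np.deg2rad(phase.p0_deg + phase.p1_deg * frac))
    return row * ramp


# ---------------------------------------------------------------- autophase
#
# Two-stage estimator.  Stage 1 measures the local phase of every strong
# peak via a Gaussian-weighted complex sum centered on the sub-bin peak
# position, after subtracting a local baseline estimated from the flanking
# regions (this removes the dispersive tails of other peaks); a weighted
# linear regression of the unwrapped peak phases against position then
# yields (p0, p1), iterated twice.  Stage 2 selects among sign/wrap
# candidates by a negativity penalty and polishes p0 with Nelder-Mead.


def _phase_penalty(rows: np.ndarray, p0: float, p1: float) -> float:
    """Negativity of the real part after phasing, on normalized rows."""
    n = rows.shape[-1]
    frac = np.arange(n) / (n - 1) if n > 1 else np.zeros(n)
    real = (rows * np.exp(1j * np.deg2rad(p0 + p1 * frac))).real
    scale = np.max(np.abs(real))
    if scale == 0:
        return 0.0
    return float(np.sum(np.minimum(real / scale, 0.0) ** 2))


def _find_row_peaks(mag: np.ndarray, height: float, distance: int) -> list[int]:
    """Indices of local maxima above ``height``, at least ``distance``
    apart (greedy from the strongest)."""
    cand = np.nonzero((mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])
                      & (mag[1:-1] > height))[0] + 1
    picked: list[int] = []
    for k in cand[np.argsort(mag[cand])[::-1]]:
        if all(abs(k - q) >= distance for q in picked):
            picked.append(int(k))
    return sorted(picked)


def _peak_phase_samples(rows: np.ndarray, window: int = 12,
                        rel_height: float = 0.2):
    """(position_fraction, phase, weight) samples for every strong peak in
    every row."""
    n = rows.shape[-1]
    k_all = np.arange(n)
    samples = []
    for row in rows:
        mag = np.abs(row)
        top = mag.max()
        if top <= 0:
            continue
        for k in _find_row_peaks(mag, rel_height * top, 2 * window):
            den = mag[k - 1] - 2 * mag[k] + mag[k + 1]
            eps = 0.5 * (mag[k - 1] - mag[k + 1]) / den if den < 0 else 0.0
            center = k + float(np.clip(eps, -0.5, 0.5))
            left = row[max(0, k - 2 * window): max(1, k - window)]
            right = row[min(n - 1, k + window + 1): min(n, k + 2 * window + 1)]
            base = 0.0
            if left.size and right.size:
                base = (left.mean() + right.mean()) / 2.0
            weight = np.exp(-((k_all - center) / window) ** 2)
            s = np.sum((row - base) * weight)
            if abs(s) > 0:
                samples.append((center / (n - 1), float(np.angle(s)),
                                float(abs(s))))
    return samples


def _regress_phases(samples, unwrap: bool) -> tuple[float, float]:
    fr = np.array([s[0] for s in samples])
    ph = np.array([s[1] for s in samples])
    w = np.array([s[2] for s in samples])
    order = np.argsort(fr)
    fr, w = fr[order], w[order]
    if unwrap:
        ph = np.unwrap(ph[order])
    else:  # residual phases: wrap each into (-pi, pi]
        ph = np.angle(np.exp(1j * ph[order]))
    if len(fr) == 1:
        return -np.degrees(ph[0]), 0.0
    design = np.column_stack([np.ones_like(fr), fr])
    coef, *_ = np.linalg.lstsq(design * w[:, None], ph * w, rcond=None)
    return -np.degrees(coef[0]), -np.degrees(coef[1])


def autophase(data: np.ndarray, max_rows: int = 4, window: int = 12,
              n_iterations: int = 2) -> PhaseSpec:
    """Estimate (p0, p1) that brings the real part into absorption mode.

    Accepts a complex vector or a stack of complex rows (the strongest
    ``max_rows`` rows are pooled).  p0 is reported in [-180, 180); p1 is
    the total first-order sweep with the pivot at point 0.
    """
    arr = np.asarray(data)
    if not np.iscomplexobj(arr):
        raise ValueError("imaginary data required for automatic phasing")
    rows = arr.reshape(-1, arr.shape[-1])
    power = np.max(np.abs(rows), axis=-1)
    if not np.any(power > 0) or float(np.max(power)) < 1e-300:
        warnings.warn("low signal: autophase returning (0, 0)")
        return PhaseSpec(0.0, 0.0)
    keep = np.argsort(power)[::-1][:max_rows]
    rows = rows[keep] / np.max(power)

    # pass 1: strongest row alone, unwrapped regression
    samples = _peak_phase_samples(rows[:1], window=window)
    if not samples:
        warnings.warn("low signal: autophase returning (0, 0)")
        return PhaseSpec(0.0, 0.0)
    p0, p1 = _regress_phases(samples, unwrap=True)

    # resolve sign-flip / unwrap ambiguities with the negativity penalty
    candidates = [(p0 + d0, p1 + d1) for d0 in (0.0, 180.0)
                  for d1 in (0.0, 360.0, -360.0)]
    p0, p1 = min(candidates, key=lambda c: _phase_penalty(rows, *c))

    # refinement passes: all rows, residual (wrapped) phases
    for _ in range(n_iterations):
        cur = apply_phase(rows, PhaseSpec(p0, p1))
        samples = _peak_phase_samples(cur, window=window)
        if not samples:
            break
        d0, d1 = _regress_phases(samples, unwrap=False)
        if abs(d0) > 90.0 or abs(d1) > 180.0:  # refinement went non-local
            break
        p0 += d0
        p1 += d1
    p0 = (p0 + 180.0) % 360.0 - 180.0
    return PhaseSpec(float(p0), float(p1))


# ----------------------------------------------------------------- slicing

def _extract_indices(axis: AxisCalibration, ppm_lo: float,
                     ppm_hi: float) -> tuple[int, int]:
    lo, hi = sorted((ppm_lo, ppm_hi))
    start = int(np.ceil(axis.point_of_ppm(hi) - 0.5))
    stop = int(np.floor(axis.point_of_ppm(lo) + 0.5)) + 1
    start = max(start, 0)
    stop = min(stop, axis.n_points)
    if stop <= start:
        raise ValueError(f"extraction range [{lo}, {hi}] ppm does not "
                         "overlap the axis")
    return start, stop


def _sliced_axis(axis: AxisCalibration, start: int, stop: int) -> AxisCalibration:
    n = stop - start
    return AxisCalibration(n_points=n, sw_hz=axis.step_hz * n,
                           obs_mhz=axis.obs_mhz,
                           origin_hz=float(axis.hz_of_point(stop - 1)))


def extract_region(spectrum: Spectrum, dim: str, ppm_lo: float,
                   ppm_hi: float) -> Spectrum:
    """Slice a ppm window out of one dimension; retained points keep
    their ppm values exactly."""
    if dim not in ("direct", "indirect"):
        raise ValueError("dim must be 'direct' or 'indirect'")
    axis = spectrum.axis_direct if dim == "direct" else spectrum.axis_indirect
    start, stop = _extract_indices(axis, ppm_lo, ppm_hi)
    sl = ((slice(None), slice(None), slice(start, stop)) if dim == "direct"
          else (slice(None), slice(start, stop), slice(None)))

    def cut(m):
        return None if m is None else m[sl]

    new_axis = _sliced_axis(axis, start, stop)
    return Spectrum(
        data_real=spectrum.data_real[sl],
        axis_direct=new_axis if dim == "direct" else spectrum.axis_direct,
        axis_indirect=new_axis if dim == "indirect" else spectrum.axis_indirect,
        data_imag_direct=cut(spectrum.data_imag_direct),
        data_imag_indirect=cut(spectrum.data_imag_indirect),
        data_imag_both=cut(spectrum.data_imag_both),
        noise_sigma=spectrum.noise_sigma,
    )


# ------------------------------------------------------------ full pipeline

def _resolve_phase(phase, data, context: str) -> PhaseSpec:
    if isinstance(phase, PhaseSpec):
        return phase
    log.info("autophasing %s dimension", context)
    return autophase(data)


def process_direct_rows(data: np.ndarray, meta: AcquisitionMeta,
                        dim: DimensionScheme) -> np.ndarray:
    """Direct-dimension stages on a (planes, rows, points) complex stack,
    excluding phase correction."""
    rows = data
    if dim.solvent_filter:
        rows = solvent_suppress(rows)
    dwell = 1.0 / meta.sw_direct_hz
    rows = apodize(rows, dim.window, dwell)
    rows = zero_fill(rows, dim.zero_fill_folds)
    return transform_direct(rows, group_delay=meta.group_delay)


def process_2d(td: TimeDomainData, meta: AcquisitionMeta,
               scheme: ProcessingScheme, drop_imag: bool = False,
               _reconstruct=None) -> Spectrum:
    """Run the full 2D (or pseudo-3D) pipeline.

    ``_reconstruct`` is an internal hook used by the NUS module to insert a
    time-domain reconstruction between the quadrature combination and the
    indirect transform.
    """
    data = td.data
    if scheme.first_plane_only:
        data = data[:1]
    n_planes = data.shape[0]

    # ---- direct dimension
    spec_rows = process_direct_rows(data, meta, scheme.direct)
    phase_d = _resolve_phase(scheme.direct.phase, spec_rows[0], "direct")
    spec_rows = apply_phase(spec_rows, phase_d)

    nd = spec_rows.shape[-1]
    axis_d = AxisCalibration.from_carrier(nd, meta.sw_direct_hz,
                                          meta.obs_direct_mhz,
                                          meta.car_direct_hz)
    if scheme.direct.extract_ppm is not None:
        start, stop = _extract_indices(axis_d, *scheme.direct.extract_ppm)
        spec_rows = spec_rows[..., start:stop]
        axis_d = _sliced_axis(axis_d, start, stop)

    # ---- indirect dimension
    a, b = combine_quadrature(spec_rows, meta.mode_indirect)
    if _reconstruct is not None:
        a, b = _reconstruct(a, b)
    dwell1 = 1.0 / meta.sw_indirect_hz
    planes_sa, planes_sb = [], []
    for p in range(n_planes):
        cols_a = np.swapaxes(a[p], 0, 1)  # (direct, t1)
        cols_b = np.swapaxes(b[p], 0, 1)
        out = []
        for cols in (cols_a, cols_b):
            cols = apodize(cols, scheme.indirect.window, dwell1)
            cols = zero_fill(cols, scheme.indirect.zero_fill_folds)
            cols = cols.copy()
            cols[..., 0] *= 0.5
            out.append(_shift_and_reverse(np.fft.fft(cols, axis=-1)))
        planes_sa.append(np.swapaxes(out[0], 0, 1))
        planes_sb.append(np.swapaxes(out[1], 0, 1))
    sa = np.stack(planes_sa)
    sb = np.stack(planes_sb)

    phase_i = _resolve_phase(scheme.indirect.phase,
                             np.swapaxes(sa[0], 0, 1), "indirect")
    sa = np.swapaxes(apply_phase(np.swapaxes(sa, 1, 2), phase_i), 1, 2)
    sb = np.swapaxes(apply_phase(np.swapaxes(sb, 1, 2), phase_i), 1, 2)

    ni = sa.shape[1]
    axis_i = AxisCalibration.from_carrier(ni, meta.sw_indirect_hz,
                                          meta.obs_indirect_mhz,
                                          meta.car_indirect_hz)
    spec = Spectrum(
        data_real=sa.real.copy(),
        axis_direct=axis_d, axis_indirect=axis_i,
        data_imag_direct=None if drop_imag else sb.real.copy(),
        data_imag_indirect=None if drop_imag else sa.imag.copy(),
        data_imag_both=None if drop_imag else sb.imag.copy(),
    )
    if scheme.indirect.extract_ppm is not None:
        spec = extract_region(spec, "indirect", *scheme.indirect.extract_ppm)
    return spec


def process_pseudo3d(td: TimeDomainData, meta: AcquisitionMeta,
                     scheme: ProcessingScheme, drop_imag: bool = False
                     ) -> Spectrum:
    """Process every plane with the identical scheme, preserving order."""
    if td.n_planes < 2:
        raise ValueError("pseudo-3D processing requires n_planes >= 2")
    if scheme.first_plane_only:
        raise ValueError("first_plane_only must be off for pseudo-3D "
                         "processing")
    # resolve auto phases once, on the first plane, then reuse verbatim
    return process_2d(td, meta, _freeze_phases(td, meta, scheme),
                      drop_imag=drop_imag)


def _freeze_phases(td: TimeDomainData, meta: AcquisitionMeta,
                   scheme: ProcessingScheme) -> ProcessingScheme:
    """Resolve any 'auto' phases on the first plane so all planes share
    identical parameters."""
    import copy

    frozen = copy.deepcopy(scheme)
    if frozen.direct.phase == AUTO_PHASE or frozen.indirect.phase == AUTO_PHASE:
        first = TimeDomainData(data=td.data[:1], meta=meta)
        spec_rows = process_direct_rows(first.data, meta, frozen.direct)
        if frozen.direct.phase == AUTO_PHASE:
            frozen.direct.phase = autophase(spec_rows[0])
        if frozen.indirect.phase == AUTO_PHASE:
            tmp = copy.deepcopy(frozen)
            tmp.indirect.phase = PhaseSpec(0.0, 0.0)
            probe = process_2d(first, meta, tmp)
            cols = probe.data_real[0] + 1j * probe.data_imag_indirect[0]
            frozen.indirect.phase = autophase(np.swapaxes(cols, 0, 1))
    return frozen
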