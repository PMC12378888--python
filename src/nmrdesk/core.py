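"""Core data model: axes, spectra, time-domain containers, peaks, NUS schedules.

Conventions used throughout the package:

* point index 0 is the downfield (highest-ppm) edge of every axis;
* all indices are 0-based and ranges are half-open ``[start, end)``;
* an axis is an affine, invertible map between point index and ppm, anchored
  on the frequency of the *last* point (``origin_hz``), matching the header
  convention of the ft2 ecosystem.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AcquisitionMode",
    "AcquisitionMeta",
    "AxisCalibration",
    "Spectrum",
    "TimeDomainData",
    "Peak",
    "PeakList",
    "NUSSchedule",
]


class AcquisitionMode(str, enum.Enum):
    """Indirect-dimension quadrature scheme."""

    STATES = "states"
    STATES_TPPI = "states_tppi"
    ECHO_ANTIECHO = "echo_antiecho"


@dataclass
class AcquisitionMeta:
    """Per-dataset acquisition metadata (2 dimensions, optional plane stack).

    ``n_complex_direct`` / ``n_complex_indirect`` count complex points, i.e.
    half the number of stored real values along each dimension.
    """

    n_complex_direct: int
    n_complex_indirect: int
    sw_direct_hz: float
    sw_indirect_hz: float
    obs_direct_mhz: float
    obs_indirect_mhz: float
    car_direct_ppm: float
    car_indirect_ppm: float
    mode_indirect: AcquisitionMode = AcquisitionMode.STATES
    data_type: str = "float64"  # or "int32"
    byte_order: str = "little"  # or "big"
    group_delay: float = 0.0
    n_planes: int = 1

    def __post_init__(self) -> None:
        if self.n_complex_direct <= 0 or self.n_complex_indirect <= 0:
            raise ValueError("point counts must be positive")
        if self.sw_direct_hz <= 0 or self.sw_indirect_hz <= 0:
            raise ValueError("spectral widths must be positive")
        if self.obs_direct_mhz <= 0 or self.obs_indirect_mhz <= 0:
            raise ValueError("observe frequencies must be positive")
        if self.group_delay < 0:
            raise ValueError("group delay must be non-negative")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.data_type not in ("int32", "float64"):
            raise ValueError(f"unsupported data type {self.data_type!r}")
        if self.byte_order not in ("little", "big"):
            raise ValueError(f"unsupported byte order {self.byte_order!r}")
        self.mode_indirect = AcquisitionMode(self.mode_indirect)

    @property
    def car_direct_hz(self) -> float:
        return self.car_direct_ppm * self.obs_direct_mhz

    @property
    def car_indirect_hz(self) -> float:
        return self.car_indirect_ppm * self.obs_indirect_mhz


@dataclass(frozen=True)
class AxisCalibration:
    """Affine point-index <-> ppm map for one spectral dimension.

    ``origin_hz`` is the absolute frequency of the last point (index
    ``n_points - 1``); frequencies increase toward index 0 in steps of
    ``sw_hz / n_points``.
    """

    n_points: int
    sw_hz: float
    obs_mhz: float
    origin_hz: float

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.sw_hz <= 0 or self.obs_mhz <= 0:
            raise ValueError("sw_hz and obs_mhz must be positive")

    @property
    def step_hz(self) -> float:
        return self.sw_hz / self.n_points

    def hz_of_point(self, index):
        index = np.asarray(index, dtype=float)
        out = self.origin_hz + (self.n_points - 1 - index) * self.step_hz
        return out if out.ndim else float(out)

    def ppm_of_point(self, index):
        hz = self.hz_of_point(index)
        return hz / self.obs_mhz

    def point_of_ppm(self, ppm):
        ppm = np.asarray(ppm, dtype=float)
        hz = ppm * self.obs_mhz
        out = self.n_points - 1 - (hz - self.origin_hz) / self.step_hz
        return out if out.ndim else float(out)

    @property
    def ppm_scale(self) -> np.ndarray:
        return np.asarray(self.ppm_of_point(np.arange(self.n_points)))

    @property
    def ppm_limits(self) -> tuple[float, float]:
        """(high, low) ppm of the first and last point."""
        return float(self.ppm_of_point(0)), float(self.ppm_of_point(self.n_points - 1))

    @classmethod
    def from_carrier(cls, n_points: int, sw_hz: float, obs_mhz: float,
                     car_hz: float) -> "AxisCalibration":
        """Build an axis with the carrier at the conventional center bin.

        The first point sits at ``car + sw/2 - sw/n`` and the last at
        ``car - sw/2``, i.e. the carrier falls on index ``n/2 - 1`` of the
        (even-length) frequency grid.
        """
        return cls(n_points=n_points, sw_hz=sw_hz, obs_mhz=obs_mhz,
                   origin_hz=car_hz - sw_hz / 2.0)


def _as3d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim == 2:
        a = a[None, :, :]
    if a.ndim != 3:
        raise ValueError("spectrum matrices must be 2D or 3D")
    return a


@dataclass
class Spectrum:
    """Real frequency-domain matrix with optional hypercomplex quadrants.

    ``data_real`` has shape ``(planes, indirect, direct)``.  The optional
    quadrants are: imaginary along the direct dimension only
    (``data_imag_direct``), along the indirect only (``data_imag_indirect``)
    and along both (``data_imag_both``).
    """

    data_real: np.ndarray
    axis_direct: AxisCalibration
    axis_indirect: AxisCalibration
    data_imag_direct: Optional[np.ndarray] = None
    data_imag_indirect: Optional[np.ndarray] = None
    data_imag_both: Optional[np.ndarray] = None
    noise_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.data_real = _as3d(self.data_real).astype(np.float64, copy=False)
        for name in ("data_imag_direct", "data_imag_indirect", "data_imag_both"):
            m = getattr(self, name)
            if m is not None:
                m = _as3d(m).astype(np.float64, copy=False)
                if m.shape != self.data_real.shape:
                    raise ValueError(f"{name} shape {m.shape} != data shape "
                                     f"{self.data_real.shape}")
                setattr(self, name, m)
        np_, ni, nd = self.data_real.shape
        if self.axis_direct.n_points != nd:
            raise ValueError("direct axis length does not match matrix")
        if self.axis_indirect.n_points != ni:
            raise ValueError("indirect axis length does not match matrix")

    @property
    def n_planes(self) -> int:
        return self.data_real.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data_real.shape

    @property
    def has_imag(self) -> bool:
        return self.data_imag_direct is not None

    def plane(self, i: int) -> "Spectrum":
        sel = slice(i, i + 1)
        return Spectrum(
            data_real=self.data_real[sel],
            axis_direct=self.axis_direct,
            axis_indirect=self.axis_indirect,
            data_imag_direct=None if self.data_imag_direct is None else self.data_imag_direct[sel],
            data_imag_indirect=None if self.data_imag_indirect is None else self.data_imag_indirect[sel],
            data_imag_both=None if self.data_imag_both is None else self.data_imag_both[sel],
            noise_sigma=self.noise_sigma,
        )


@dataclass
class TimeDomainData:
    """Raw hypercomplex FID stack.

    ``data`` has shape ``(planes, rows, direct_complex)`` where ``rows``
    counts stored indirect FIDs (two per complex increment for States-type
    quadrature) and the direct dimension is already paired into complex
    samples.
    """

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = _as3d(self.data).astype(np.complex128, copy=False)

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]


@dataclass
class Peak:
    """A single 2D peak: position, separable Voigt shape, per-plane heights."""

    x_ppm: float
    y_ppm: float
    height: float = 0.0
    sigma_x: float = 0.0
    sigma_y: float = 0.0
    gamma_x: float = 0.0
    gamma_y: float = 0.0
    plane_heights: list = field(default_factory=list)
    label: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.gamma_x, self.gamma_y) < 0:
            raise ValueError("widths must be non-negative")


class PeakList(list):
    """An ordered list of :class:`Peak` with sequential re-indexing."""

    def __init__(self, peaks: Sequence[Peak] = ()):  # noqa: D107
        super().__init__(peaks)
        self.reindex()

    def reindex(self) -> "PeakList":
        for i, p in enumerate(self):
            p.index = i
        return self

    def copy(self) -> "PeakList":
        return PeakList([replace(p, plane_heights=list(p.plane_heights))
                         for p in self])

    @property
    def n_plane_heights(self) -> int:
        return max((len(p.plane_heights) for p in self), default=0)


@dataclass(frozen=True)
class NUSSchedule:
    """Sampled complex-increment indices along the indirect dimension."""

    sampled_increments: tuple
    full_size: int

    def __post_init__(self) -> None:
        inc = tuple(sorted(set(int(i) for i in self.sampled_increments)))
        object.__setattr__(self, "sampled_increments", inc)
        if not inc:
            raise ValueError("schedule is empty")
        if inc[0] < 0:
            raise ValueError("increments must be non-negative")
        if 0 not in inc:
            raise ValueError("increment 0 must be sampled")
        if inc[-1] >= self.full_size:
            raise ValueError("schedule exceeds declared grid")

    @property
    def n_sampled(self) -> int:
        return len(self.sampled_increments)

    @property
    def is_complete(self) -> bool:
        return self.n_sampled == self.full_size

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.full_size, dtype=bool)
        m[list(self.sampled_increments)] = True
        return m
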