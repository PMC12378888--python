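"""Ground-truth fixture generation.

Builds genuine Bruker-format directories (and frequency-domain matrices)
from declared peak parameters, so every other module can be tested without
any external data.  Fixtures are reproducible from (GroundTruth, seed)
alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .core import (AcquisitionMeta, AcquisitionMode, AxisCalibration,
                   NUSSchedule, Spectrum, TimeDomainData)
from .formats.bruker import write_bruker
from .peaks import _eval_peak_patch  # unit-height separable Voigt

__all__ = ["TruthPeak", "GroundTruth", "generate_fid", "write_bruker_fixture",
           "subsample_nus", "poisson_gap_schedule", "make_peak_spectrum",
           "save_truth", "load_truth"]


@dataclass(frozen=True)
class TruthPeak:
    x_ppm: float
    y_ppm: float
    amplitude: float
    r2_x_hz: float = 10.0
    r2_y_hz: float = 5.0
    rate_per_s: float = 0.0      # per-plane decay rate, if planes are used


@dataclass
class GroundTruth:
    peaks: list
    acquisition: AcquisitionMeta
    applied_p0_deg: tuple[float, float] = (0.0, 0.0)
    applied_p1_deg: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.0
    plane_delays_s: Optional[tuple] = None
    nus_schedule: Optional[NUSSchedule] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.peaks = [p if isinstance(p, TruthPeak) else TruthPeak(**p)
                      for p in self.peaks]
        if self.plane_delays_s is not None:
            self.plane_delays_s = tuple(float(d) for d in self.plane_delays_s)
            if len(self.plane_delays_s) != self.acquisition.n_planes:
                raise ValueError("plane_delays_s length must equal n_planes")


def generate_fid(truth: GroundTruth) -> TimeDomainData:
    """Synthesize the hypercomplex FID stack for a ground truth.

    Each peak contributes ``A * exp(i*2pi*fx*t2 - R2x*t2)`` along the
    direct dimension, quadrature-encoded indirect evolution
    ``exp(+-i*2pi*fy*t1 - R2y*t1)`` per the acquisition mode, optional
    per-plane decay ``exp(-rate * delay_p)``, the declared dephasing, and
    seeded complex Gaussian noise.  A non-zero group delay shifts the
    direct-dimension signal to later samples, emulating the digital filter.
    """
    meta = truth.acquisition
    nd = meta.n_complex_direct
    ninc = meta.n_complex_indirect
    n_planes = meta.n_planes
    dwell2 = 1.0 / meta.sw_direct_hz
    dwell1 = 1.0 / meta.sw_indirect_hz
    mode = AcquisitionMode(meta.mode_indirect)

    # direct-dimension dephasing: constant phase + time shift
    p0x = np.deg2rad(truth.applied_p0_deg[0])
    shift2 = -truth.applied_p1_deg[0] / (360.0 * meta.sw_direct_hz)
    t2 = (np.arange(nd) - meta.group_delay) * dwell2 + shift2
    alive2 = t2 >= 0

    p0y = np.deg2rad(truth.applied_p0_deg[1])
    shift1 = -truth.applied_p1_deg[1] / (360.0 * meta.sw_indirect_hz)
    t1 = np.arange(ninc) * dwell1 + shift1

    data = np.zeros((n_planes, 2 * ninc, nd), dtype=np.complex128)
    for pk in truth.peaks:
        fx = (pk.x_ppm - meta.car_direct_ppm) * meta.obs_direct_mhz
        fy = (pk.y_ppm - meta.car_indirect_ppm) * meta.obs_indirect_mhz
        if abs(fx) >= meta.sw_direct_hz / 2 or abs(fy) >= meta.sw_indirect_hz / 2:
            raise ValueError(f"peak at ({pk.x_ppm}, {pk.y_ppm}) ppm falls "
                             "outside the spectral window")
        direct = np.where(
            alive2,
            np.exp((2j * np.pi * fx - np.pi * pk.r2_x_hz) * t2 - 1j * p0x),
            0.0)
        decay1 = np.exp(-np.pi * pk.r2_y_hz * np.abs(t1) - 1j * p0y)
        if mode is AcquisitionMode.ECHO_ANTIECHO:
            row_a = np.exp(-2j * np.pi * fy * t1) * decay1   # echo
            row_b = np.exp(+2j * np.pi * fy * t1) * decay1   # anti-echo
        else:
            row_a = np.cos(2 * np.pi * fy * t1) * decay1
            row_b = np.sin(2 * np.pi * fy * t1) * decay1
            if mode is AcquisitionMode.STATES_TPPI:
                sign = np.where(np.arange(ninc) % 2 == 0, 1.0, -1.0)
                row_a = row_a * sign
                row_b = row_b * sign
        block = np.empty((2 * ninc, nd), dtype=np.complex128)
        block[0::2] = row_a[:, None] * direct[None, :]
        block[1::2] = row_b[:, None] * direct[None, :]
        for p in range(n_planes):
            scale = pk.amplitude
            if truth.plane_delays_s is not None and pk.rate_per_s:
                scale *= np.exp(-pk.rate_per_s * truth.plane_delays_s[p])
            data[p] += scale * block

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        noise = rng.normal(scale=truth.noise_sigma, size=data.shape + (2,))
        data = data + noise[..., 0] + 1j * noise[..., 1]
    return TimeDomainData(data=data, meta=meta)


def write_bruker_fixture(td: TimeDomainData, meta: AcquisitionMeta,
                         dir_path: str, force: bool = False) -> None:
    """Write a fixture directory readable by the Bruker reader."""
    write_bruker(td, meta, dir_path, force=force)


def subsample_nus(td: TimeDomainData, schedule: NUSSchedule) -> TimeDomainData:
    """Keep only the scheduled complex increments (two rows each)."""
    if td.n_rows != 2 * schedule.full_size:
        raise ValueError(f"data has {td.n_rows} rows, schedule grid implies "
                         f"{2 * schedule.full_size}")
    rows = []
    for inc in schedule.sampled_increments:
        rows += [2 * inc, 2 * inc + 1]
    return TimeDomainData(data=td.data[:, rows, :], meta=td.meta)


def poisson_gap_schedule(full_size: int, fraction: float,
                         seed: int = 0) -> NUSSchedule:
    """Seeded, Poisson-gap-like random schedule with increment 0 forced."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = max(1, int(round(fraction * full_size)))
    rng = np.random.default_rng(seed)
    if n_keep >= full_size:
        picks = np.arange(full_size)
    else:
        # denser sampling early, gaps growing toward the tail
        weights = np.exp(-np.arange(full_size) / full_size)
        picks = rng.choice(full_size, size=n_keep, replace=False,
                           p=weights / weights.sum())
        picks = np.union1d(picks, [0])[:n_keep] if 0 not in picks else picks
    return NUSSchedule(sampled_increments=tuple(np.union1d(picks, [0])),
                       full_size=full_size)


def make_peak_spectrum(peaks_pts: list[dict], shape: tuple[int, int],
                       noise_sigma: float = 0.0, seed: int = 0,
                       axis_direct: Optional[AxisCalibration] = None,
                       axis_indirect: Optional[AxisCalibration] = None
                       ) -> Spectrum:
    """Build a frequency-domain matrix directly from peak parameters.

    ``peaks_pts`` entries hold x, y (points), height and the four widths
    (points).  Useful for deconvolution tests where no time-domain round
    trip is wanted.
    """
    ny, nx = shape
    xg = np.arange(nx, dtype=float)
    yg = np.arange(ny, dtype=float)
    matrix = np.zeros((ny, nx))
    for p in peaks_pts:
        widths = (p.get("sigma_x", 0.0), p.get("gamma_x", 0.0),
                  p.get("sigma_y", 0.0), p.get("gamma_y", 0.0))
        matrix += p["height"] * _eval_peak_patch(xg, yg, p["x"], p["y"], widths)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        matrix = matrix + rng.normal(scale=noise_sigma, size=matrix.shape)
    ax_d = axis_direct or AxisCalibration.from_carrier(nx, 8000.0, 600.13,
                                                       4.7 * 600.13)
    ax_i = axis_indirect or AxisCalibration.from_carrier(ny, 2000.0, 60.81,
                                                         118.0 * 60.81)
    return Spectrum(data_real=matrix[None, :, :], axis_direct=ax_d,
                    axis_indirect=ax_i,
                    noise_sigma=noise_sigma if noise_sigma > 0 else None)


# ---------------------------------------------------------- serialization

def save_truth(truth: GroundTruth, path: str) -> None:
    doc = {
        "peaks": [asdict(p) for p in truth.peaks],
        "acquisition": {**asdict(truth.acquisition),
                        "mode_indirect": truth.acquisition.mode_indirect.value},
        "applied_p0_deg": list(truth.applied_p0_deg),
        "applied_p1_deg": list(truth.applied_p1_deg),
        "noise_sigma": truth.noise_sigma,
        "plane_delays_s": (None if truth.plane_delays_s is None
                           else list(truth.plane_delays_s)),
        "nus_schedule": (None if truth.nus_schedule is None else {
            "sampled_increments": list(truth.nus_schedule.sampled_increments),
            "full_size": truth.nus_schedule.full_size}),
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_truth(path: str) -> GroundTruth:
    with open(path, "r") as fh:
        doc = json.load(fh)
    sched = doc.get("nus_schedule")
    return GroundTruth(
        peaks=[TruthPeak(**p) for p in doc["peaks"]],
        acquisition=AcquisitionMeta(**doc["acquisition"]),
        applied_p0_deg=tuple(doc.get("applied_p0_deg", (0.0, 0.0))),
        applied_p1_deg=tuple(doc.get("applied_p1_deg", (0.0, 0.0))),
        noise_sigma=doc.get("noise_sigma", 0.0),
        plane_delays_s=doc.get("plane_delays_s"),
        nus_schedule=None if sched is None else NUSSchedule(
            sampled_increments=tuple(sched["sampled_increments"]),
            full_size=sched["full_size"]),
        seed=doc.get("seed", 0),
    )
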