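"""Downstream analysis of pseudo-3D fits: exponential rates and CEST
profiles.

Fits are mono-exponential, ``h(t) = A * exp(-R * t)``; heights may be the
relative Z_A values — the rate is invariant to their overall scale, so no
renormalization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import PeakList

__all__ = ["RelaxationSeries", "RateFit", "fit_exponential", "cest_profile",
           "rates_from_peaklist", "write_rates_table"]


@dataclass(frozen=True)
class RelaxationSeries:
    delays_s: tuple
    heights: tuple
    peak_label: str = ""

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.delays_s)
        h = tuple(float(x) for x in self.heights)
        object.__setattr__(self, "delays_s", d)
        object.__setattr__(self, "heights", h)
        if len(d) != len(h):
            raise ValueError("delays and heights must have the same length")
        if len(d) < 3:
            raise ValueError("a rate fit needs at least 3 points")
        if any(x < 0 for x in d):
            raise ValueError("delays must be non-negative")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("delays must be strictly increasing")


@dataclass(frozen=True)
class RateFit:
    rate_per_s: float
    amplitude: float
    rate_stderr: float
    r_squared: float


def fit_exponential(series: RelaxationSeries) -> RateFit:
    """Least-squares decay fit, initialized from the log-linear regression
    of the positive heights; stderr from the Jacobian at the optimum."""
    t = np.asarray(series.delays_s)
    h = np.asarray(series.heights)
    if np.allclose(h, h[0]):
        raise ValueError("heights are all equal: no decay to fit")
    pos = h > 0
    if pos.sum() < max(2, len(h) - len(h) // 2):
        raise ValueError("decay model inapplicable: too many non-positive "
                         "heights")

    slope, intercept = np.polyfit(t[pos], np.log(h[pos]), 1)
    x0 = np.array([np.exp(intercept), max(-slope, 1e-12)])

    def residual(theta):
        a, r = theta
        return a * np.exp(-r * t) - h

    res = least_squares(residual, x0, method="lm")
    a, r = res.x
    dof = max(len(t) - 2, 1)
    s2 = float(np.sum(res.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        stderr = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        stderr = float("nan")
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res.fun ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return RateFit(rate_per_s=float(r), amplitude=float(a),
                   rate_stderr=stderr, r_squared=r2)


def cest_profile(heights, offsets_hz, reference_index: int = 0):
    """Normalize intensities by the reference (off-resonance) plane and
    order by saturation offset.  Returns a list of (offset_hz, I/I_ref)."""
    h = np.asarray(heights, dtype=float)
    off = np.asarray(offsets_hz, dtype=float)
    if h.shape != off.shape:
        raise ValueError("heights and offsets must have the same length")
    ref = h[reference_index]
    if ref <= 0:
        raise ValueError("reference intensity must be positive")
    order = np.argsort(off)
    return [(float(off[i]), float(h[i] / ref)) for i in order]


def rates_from_peaklist(fitted_peaks: PeakList, delays_s) -> list:
    """One RateFit per peak from its plane heights.

    Returns a list of ``(label_or_index, RateFit)`` tuples in peak order.
    """
    delays_s = tuple(float(d) for d in delays_s)
    out = []
    for p in fitted_peaks:
        if len(p.plane_heights) != len(delays_s):
            name = p.label or f"#{p.index}"
            raise ValueError(f"peak {name}: {len(p.plane_heights)} plane "
                             f"heights for {len(delays_s)} delays")
        series = RelaxationSeries(delays_s=delays_s,
                                  heights=tuple(p.plane_heights),
                                  peak_label=p.label)
        out.append((p.label or str(p.index), fit_exponential(series)))
    return out


def write_rates_table(rates: list, path: str) -> None:
    """Serialize ``rates_from_peaklist`` output as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("peak\trate_per_s\tamplitude\trate_stderr\tr_squared\n")
        for name, rf in rates:
            fh.write(f"{name}\t{rf.rate_per_s:.6g}\t{rf.amplitude:.6g}\t"
                     f"{rf.rate_stderr:.6g}\t{rf.r_squared:.6g}\n")
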