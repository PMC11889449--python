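"""Spectral grid containers.

A 1D spectrum lives on a uniform chemical-shift axis stored in *descending*
ppm order (the NMR display convention, e.g. 10.0 ppm down to -0.5 ppm).
2D spectra pair an F2 chemical-shift axis (ppm) with an F1 axis that is in
Hz for J-resolved spectra and in ppm for COSY spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrumGrid1D",
    "SpectrumGrid2D",
    "make_ppm_axis",
    "DEFAULT_PPM_MAX",
    "DEFAULT_PPM_MIN",
    "DEFAULT_N_POINTS",
]

#: Default common grid: 9.995 -> -0.005 ppm over 2**15 points
#: (~0.000305 ppm per point at the default span).
DEFAULT_PPM_MAX = 9.995
DEFAULT_PPM_MIN = -0.005
DEFAULT_N_POINTS = 2**15

_UNIFORM_TOL = 1e-9


def make_ppm_axis(
    ppm_max: float = DEFAULT_PPM_MAX,
    ppm_min: float = DEFAULT_PPM_MIN,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Uniform descending ppm axis from ``ppm_max`` to ``ppm_min``."""
    if n_points < 2:
        raise ValueError("axis needs at least 2 points")
    if ppm_max <= ppm_min:
        raise ValueError("ppm_max must exceed ppm_min")
    return np.linspace(ppm_max, ppm_min, n_points)


def _check_uniform(axis: np.ndarray, name: str) -> None:
    diffs = np.diff(axis)
    if diffs.size == 0:
        raise ValueError(f"{name}: axis too short")
    if np.any(diffs == 0) or (np.any(diffs > 0) and np.any(diffs < 0)):
        raise ValueError(f"{name}: axis must be strictly monotone")
    if np.max(np.abs(diffs - diffs[0])) >= _UNIFORM_TOL:
        raise ValueError(f"{name}: axis spacing not uniform")


@dataclass
class SpectrumGrid1D:
    """One 1D spectrum: uniform descending ppm axis plus intensities."""

    ppm_axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _check_uniform(self.ppm_axis, "ppm_axis")
        if self.ppm_axis[0] < self.ppm_axis[-1]:
            raise ValueError("ppm_axis must be stored descending")
        if self.intensity.shape != self.ppm_axis.shape:
            raise ValueError("intensity length must equal axis length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def spacing(self) -> float:
        """Grid spacing in ppm (positive)."""
        return float(self.ppm_axis[0] - self.ppm_axis[1])

    def integral(self) -> float:
        """Trapezoidal integral over the full axis, in area units x ppm."""
        # axis is descending; integrate on the ascending view
        return float(np.trapezoid(self.intensity[::-1], self.ppm_axis[::-1]))

    def index_of_ppm(self, ppm: float) -> int:
        """Index of the grid point closest to ``ppm``."""
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))

    def copy(self) -> "SpectrumGrid1D":
        return SpectrumGrid1D(self.ppm_axis, self.intensity.copy())

    def same_axis(self, other: "SpectrumGrid1D", tol: float = 0.0) -> bool:
        if self.ppm_axis.shape != other.ppm_axis.shape:
            return False
        if tol == 0.0:
            return bool(np.array_equal(self.ppm_axis, other.ppm_axis))
        return bool(np.allclose(self.ppm_axis, other.ppm_axis, atol=tol, rtol=0))


@dataclass
class SpectrumGrid2D:
    """One 2D spectrum.

    ``mode='jres'``: F1 in Hz (multiplet structure), F2 in ppm.
    ``mode='cosy'``: both axes in ppm; fixture-built matrices are symmetric.
    Intensity is indexed ``[f1, f2]``.
    """

    f2_axis: np.ndarray
    f1_axis: np.ndarray
    intensity: np.ndarray
    mode: str = "jres"

    def __post_init__(self) -> None:
        if self.mode not in ("jres", "cosy"):
            raise ValueError(f"unknown 2D mode {self.mode!r}")
        self.f2_axis = np.asarray(self.f2_axis, dtype=float)
        self.f1_axis = np.asarray(self.f1_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _check_uniform(self.f2_axis, "f2_axis")
        _check_uniform(self.f1_axis, "f1_axis")
        if self.intensity.shape != (self.f1_axis.size, self.f2_axis.size):
            raise ValueError("intensity matrix dimensions must match axes")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def f2_spacing(self) -> float:
        return float(abs(self.f2_axis[1] - self.f2_axis[0]))

    def copy(self) -> "SpectrumGrid2D":
        return SpectrumGrid2D(self.f2_axis, self.f1_axis, self.intensity.copy(), self.mode)

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        """COSY symmetry about the f1=f2 diagonal (square grids only)."""
        m = self.intensity
        if m.shape[0] != m.shape[1]:
            return False
        return bool(np.max(np.abs(m - m.T)) <= tol)
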