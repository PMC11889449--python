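"""Peak-cluster detection, pH-dependent shift computation and relocation.

Detection uses two thresholds given as fractions of the global maximum:
clusters are maximal runs of consecutive points at or above the cluster
threshold, and a cluster is kept only if it contains at least one local
maximum at or above the main threshold (its apexes).

The pH shift of a peak cluster between a standard spectrum at pH0 and a
sample at pH1 follows from the Henderson-Hasselbalch equation: with
protonated-fraction f(pH) = 1 / (1 + 10^(pH - pKa)), the observed shift
is the acid-basic limit span times the change in protonation,

    delta_shift = (delta_L - delta_HL) * (sigma(pH0 - pKa) - sigma(pH1 - pKa))

where sigma(t) = 10^t / (1 + 10^t). This form is evaluated through the
logistic function, which is overflow-safe at any |pH - pKa|.

Shifts are quantized to whole grid points so relocation conserves the
integral exactly and commutes exactly with 2D projections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .grids import SpectrumGrid1D, SpectrumGrid2D

__all__ = [
    "PeakClusterSet",
    "ShiftContext",
    "PeakError",
    "detect_peaks_1d",
    "skyline_projection",
    "diagonal_projection",
    "compute_delta_shift",
    "sample_pka",
    "sample_limit_difference",
    "apply_shift_1d",
    "apply_shift_2d",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


class PeakError(ValueError):
    """Raised for invalid peak-engine inputs or impossible shifts."""


@dataclass
class PeakClusterSet:
    """Detected peak clusters on one axis.

    ``clusters`` are half-open [start, end) index intervals, disjoint and
    sorted ascending by index (descending ppm); ``apexes[i]`` lists the
    apex indices of cluster i.
    """

    clusters: list[tuple[int, int]]
    apexes: list[list[int]]
    source_axis: np.ndarray

    def __post_init__(self) -> None:
        if len(self.clusters) != len(self.apexes):
            raise PeakError("clusters and apexes must align")
        prev_end = -1
        for (s, e), ap in zip(self.clusters, self.apexes):
            if not (0 <= s < e <= len(self.source_axis)):
                raise PeakError(f"cluster [{s}, {e}) out of bounds")
            if s < prev_end:
                raise PeakError("clusters must be disjoint and sorted")
            if not ap:
                raise PeakError("every cluster needs at least one apex")
            if any(not (s <= i < e) for i in ap):
                raise PeakError("apex indices must lie inside their cluster")
            prev_end = e

    def __len__(self) -> int:
        return len(self.clusters)

    def apex_ppm(self) -> list[float]:
        """Ppm position of the highest-priority (first) apex per cluster."""
        return [float(self.source_axis[ap[0]]) for ap in self.apexes]


def detect_peaks_1d(
    spec: SpectrumGrid1D,
    main_threshold_frac: float = 0.1,
    cluster_threshold_frac: float = 0.02,
) -> PeakClusterSet:
    """Two-threshold run-based peak-cluster detection.

    Both thresholds are fractions of the spectrum's global maximum. A
    point is an apex if it is >= the main threshold, >= its left neighbor
    and > its right neighbor (out-of-range neighbors count as -inf, so a
    flat plateau yields its rightmost point). Runs without an apex are
    dropped.
    """
    if not (0 < cluster_threshold_frac <= main_threshold_frac <= 1):
        raise PeakError("need 0 < cluster_threshold_frac <= main_threshold_frac <= 1")
    y = spec.intensity
    top = float(y.max(initial=0.0))
    if top <= 0:
        return PeakClusterSet([], [], spec.ppm_axis)
    main_abs = main_threshold_frac * top
    cluster_abs = cluster_threshold_frac * top

    clusters: list[tuple[int, int]] = []
    apexes: list[list[int]] = []
    n = len(y)
    i = 0
    while i < n:
        if y[i] < cluster_abs:
            i += 1
            continue
        j = i
        while j < n and y[j] >= cluster_abs:
            j += 1
        run_apexes = []
        for k in range(i, j):
            left = y[k - 1] if k > 0 else -np.inf
            right = y[k + 1] if k + 1 < n else -np.inf
            if y[k] >= main_abs and y[k] >= left and y[k] > right:
                run_apexes.append(k)
        if run_apexes:
            clusters.append((i, j))
            apexes.append(run_apexes)
        i = j
    return PeakClusterSet(clusters, apexes, spec.ppm_axis)


def skyline_projection(spec: SpectrumGrid2D) -> SpectrumGrid1D:
    """Maximum over F1 per F2 column — the J-Res projected 1D profile."""
    if spec.mode != "jres":
        raise PeakError("skyline projection is defined for J-Res spectra")
    return SpectrumGrid1D(spec.f2_axis, spec.intensity.max(axis=0))


def diagonal_projection(spec: SpectrumGrid2D) -> SpectrumGrid1D:
    """Diagonal trace of a square COSY matrix."""
    if spec.mode != "cosy":
        raise PeakError("diagonal projection is defined for COSY spectra")
    if spec.intensity.shape[0] != spec.intensity.shape[1]:
        raise PeakError("COSY grid must be square")
    if not np.array_equal(spec.f1_axis, spec.f2_axis):
        raise PeakError("COSY axes must be identical for the diagonal projection")
    return SpectrumGrid1D(spec.f2_axis, np.diagonal(spec.intensity).copy())


@dataclass
class ShiftContext:
    """Parameters governing pH-dependent peak shifting.

    ``ph0`` is the pH at which the reference spectra were acquired
    (physiological 7.4 by default); ``pka_fallback_mean/sd`` parameterize
    the normal distribution used to impute a missing pKa, and
    ``limitdiff_mean/sd`` the distribution of acid-basic limit span
    imputed when a cluster has no stated (delta_L, delta_HL) pair.
    """

    ph0: float = 7.4
    pka_fallback_mean: float = 7.0
    pka_fallback_sd: float = 2.0
    limitdiff_mean: float = 0.05
    limitdiff_sd: float = 0.02
    impute_missing: bool = True


def compute_delta_shift(
    delta_L: float,
    delta_HL: float,
    pka: float,
    ph0: float,
    ph1: float,
) -> float:
    """Shift in ppm of a peak between the standard pH0 and the sample pH1.

    Equals (delta_L - delta_HL) * (10^(pH0-pKa) - 10^(pH1-pKa)) /
    ((1 + 10^(pH0-pKa)) * (1 + 10^(pH1-pKa))), evaluated via the logistic
    function: the bracket is sigma(pH0-pKa) - sigma(pH1-pKa) with
    sigma(t) = 1 / (1 + 10^-t), which never overflows.
    """
    for v in (delta_L, delta_HL, pka, ph0, ph1):
        if not math.isfinite(v):
            raise PeakError("shift inputs must be finite")
    s0 = expit((ph0 - pka) * _LN10)
    s1 = expit((ph1 - pka) * _LN10)
    return (delta_L - delta_HL) * (s0 - s1)


def sample_pka(ctx: ShiftContext, rng: np.random.Generator | int) -> float:
    """Impute a pKa from the fallback normal, clamped to [0, 14]."""
    if ctx.pka_fallback_mean is None or ctx.pka_fallback_sd is None:
        raise PeakError("pKa fallback parameters are not configured")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    draw = float(rng.normal(ctx.pka_fallback_mean, ctx.pka_fallback_sd))
    return min(14.0, max(0.0, draw))


def sample_limit_difference(ctx: ShiftContext, rng: np.random.Generator | int) -> float:
    """Impute an acid-basic limit span delta_L - delta_HL (ppm)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return float(rng.normal(ctx.limitdiff_mean, ctx.limitdiff_sd))


def _shift_points(delta_ppm: float, spacing: float) -> int:
    """Grid-point displacement for a ppm shift on a descending axis.

    Positive delta (toward higher ppm) decreases the index.
    """
    return -int(round(delta_ppm / spacing))


def _relocate_segments(
    values: np.ndarray,
    clusters: Sequence[tuple[int, int]],
    moves: Sequence[int],
    collision: str,
    axis_len: int,
    what: str,
) -> np.ndarray:
    """Relocate cluster segments by integer index moves along the last axis.

    ``values`` may be 1D or 2D (segments are column blocks). Vacated
    points are zeroed; targets fully off-grid raise; partial off-grid
    columns are truncated. Overlapping targets raise unless
    ``collision='sum'``.
    """
    out = values.copy()
    occupied: list[tuple[int, int]] = []
    segments = []
    for (s, e), m in zip(clusters, moves):
        seg = values[..., s:e].copy()
        out[..., s:e] = 0.0
        ts, te = s + m, e + m
        cs, ce = max(ts, 0), min(te, axis_len)
        if cs >= ce:
            raise PeakError(f"{what}: cluster [{s}, {e}) shifted fully off the grid")
        if collision != "sum":
            for os_, oe in occupied:
                if cs < oe and os_ < ce:
                    raise PeakError(
                        f"{what}: shifted cluster [{s}, {e}) collides with another cluster"
                    )
        occupied.append((cs, ce))
        segments.append((seg[..., cs - ts : seg.shape[-1] - (te - ce)], cs, ce))
    for seg, cs, ce in segments:
        out[..., cs:ce] += seg
    return out


def apply_shift_1d(
    spec: SpectrumGrid1D,
    clusters: PeakClusterSet,
    shifts: Sequence[float],
    collision: str = "error",
) -> SpectrumGrid1D:
    """Relocate each detected cluster by its ppm shift (grid-quantized)."""
    if len(shifts) != len(clusters):
        raise PeakError("one shift per cluster required")
    if not np.array_equal(clusters.source_axis, spec.ppm_axis):
        raise PeakError("cluster set does not refer to this spectrum's axis")
    moves = [_shift_points(d, spec.spacing) for d in shifts]
    out = _relocate_segments(
        spec.intensity, clusters.clusters, moves, collision, len(spec.ppm_axis), "1D shift"
    )
    return SpectrumGrid1D(spec.ppm_axis, out)


def apply_shift_2d(
    spec: SpectrumGrid2D,
    clusters: PeakClusterSet,
    shifts: Sequence[float],
    collision: str = "error",
) -> SpectrumGrid2D:
    """Relocate projected-profile clusters on a 2D grid.

    J-Res: each F2 column block moves along F2 only, all F1 rows together
    (J structure is pH-invariant). COSY: the same relocation is applied
    along F2 and then along F1, so diagonal blocks move diagonally and the
    matrix stays symmetric; cross peaks follow their diagonal blocks.
    """
    if len(shifts) != len(clusters):
        raise PeakError("one shift per cluster required")
    if not np.array_equal(clusters.source_axis, spec.f2_axis):
        raise PeakError("cluster set does not refer to this spectrum's F2 axis")
    spacing = float(abs(spec.f2_axis[0] - spec.f2_axis[1]))
    if spec.f2_axis[0] < spec.f2_axis[-1]:
        spacing = -spacing  # ascending axis: flip the sign convention
    moves = [_shift_points(d, spacing) for d in shifts]
    n2 = len(spec.f2_axis)
    out = _relocate_segments(
        spec.intensity, clusters.clusters, moves, collision, n2, "2D shift (F2)"
    )
    if spec.mode == "cosy":
        out = _relocate_segments(
            out.T, clusters.clusters, moves, collision, n2, "2D shift (F1)"
        ).T
    return SpectrumGrid2D(spec.f2_axis, spec.f1_axis, out, spec.mode)
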