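"""Fully synthetic pure-compound fixtures.

Builds toy metabolite records — Lorentzian multiplets on a ppm grid, the
matching 2D J-Res and COSY grids, and a broad albumin-like protein
envelope — so every pipeline stage can run and be tested without any
experimental reference data.

Lineshapes are Lorentzian (the natural shape of a processed NMR
resonance); 2D peaks are separable Lorentzian x Lorentzian. Multiplet
patterns follow first-order rules: singlet/doublet/triplet/quartet line
positions at 0, +-J/2, {-J, 0, +J}, {+-J/2, +-3J/2} Hz with Pascal-ratio
amplitudes (1 | 1:1 | 1:2:1 | 1:3:3:1). Hz are converted to ppm with the
spectrometer frequency (default 600 MHz, so 1 Hz = 1/600 ppm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grids import SpectrumGrid1D, SpectrumGrid2D, make_ppm_axis
from .library import (
    ConditionStats,
    Library,
    LibraryError,
    PureCompoundRecord,
    normalize_pure_spectrum,
)

__all__ = [
    "MultipletSpec",
    "ToyMetaboliteSpec",
    "make_multiplet",
    "make_pure_jres",
    "make_pure_cosy",
    "make_protein_background",
    "build_record",
    "build_library",
    "make_toy_library",
    "DEFAULT_FIELD_MHZ",
]

DEFAULT_FIELD_MHZ = 600.0

_PATTERNS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    # pattern -> (line offsets in units of J, Pascal weights)
    "s": (np.array([0.0]), np.array([1.0])),
    "d": (np.array([-0.5, 0.5]), np.array([1.0, 1.0])),
    "t": (np.array([-1.0, 0.0, 1.0]), np.array([1.0, 2.0, 1.0])),
    "q": (np.array([-1.5, -0.5, 0.5, 1.5]), np.array([1.0, 3.0, 3.0, 1.0])),
}


@dataclass(frozen=True)
class MultipletSpec:
    """One proton environment: center, splitting pattern, linewidth, area."""

    center: float  # ppm
    pattern: str = "s"
    j_hz: float = 0.0
    linewidth_hz: float = 1.5  # FWHM
    protons_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown multiplet pattern {self.pattern!r}")
        if self.j_hz < 0:
            raise ValueError("j_hz must be >= 0")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be > 0")
        if self.protons_weight <= 0:
            raise ValueError("protons_weight must be > 0")

    def line_offsets_hz(self) -> np.ndarray:
        offsets, _ = _PATTERNS[self.pattern]
        return offsets * self.j_hz

    def line_areas(self) -> np.ndarray:
        _, weights = _PATTERNS[self.pattern]
        return self.protons_weight * weights / weights.sum()


@dataclass(frozen=True)
class ToyMetaboliteSpec:
    """Blueprint for one synthetic metabolite record."""

    id: str
    name: str
    protons: int
    multiplets: tuple[MultipletSpec, ...]
    pka: Optional[float] = None
    # per-multiplet (delta_L, delta_HL) in ppm, parallel to `multiplets`
    shift_limits: Optional[tuple[tuple[float, float], ...]] = None
    stats: tuple[ConditionStats, ...] = ()

    def __post_init__(self) -> None:
        if len(self.multiplets) == 0:
            raise ValueError("need at least one multiplet")
        total = sum(m.protons_weight for m in self.multiplets)
        if abs(total - self.protons) > 1e-9 * max(1.0, self.protons):
            raise ValueError(
                f"{self.id}: multiplet proton weights sum to {total}, expected {self.protons}"
            )


def _lorentzian(x: np.ndarray, x0: float, fwhm: float, area: float) -> np.ndarray:
    """Area-normalized Lorentzian sampled at x."""
    hwhm = fwhm / 2.0
    return (area / np.pi) * hwhm / ((x - x0) ** 2 + hwhm**2)


def _sampled_lorentzian(axis: np.ndarray, x0: float, fwhm: float, area: float) -> np.ndarray:
    """Lorentzian whose *discrete* trapezoidal integral equals ``area``.

    2D grids are much coarser than 1D ones; a line narrower than the grid
    spacing would fall between samples and lose its intensity budget, so
    the width is floored at two grid steps and the sampled profile is
    rescaled to the exact target area.
    """
    spacing = float(abs(axis[1] - axis[0]))
    y = _lorentzian(axis, x0, max(fwhm, 2.0 * spacing), area)
    got = abs(np.trapezoid(y, axis))
    return y * (area / got) if got > 0 else y


def make_multiplet(
    spec: MultipletSpec,
    axis: np.ndarray,
    field_mhz: float = DEFAULT_FIELD_MHZ,
) -> SpectrumGrid1D:
    """Render one multiplet as a sum of Lorentzian lines on a ppm axis."""
    if field_mhz <= 0:
        raise ValueError("field_mhz must be > 0")
    axis = np.asarray(axis, dtype=float)
    fwhm_ppm = spec.linewidth_hz / field_mhz
    intensity = np.zeros_like(axis)
    lo, hi = float(axis.min()), float(axis.max())
    for off_hz, area in zip(spec.line_offsets_hz(), spec.line_areas()):
        x0 = spec.center + off_hz / field_mhz
        if not (lo <= x0 <= hi):
            warnings.warn(
                f"multiplet line at {x0:.4f} ppm falls outside the axis; truncated",
                stacklevel=2,
            )
        intensity += _lorentzian(axis, x0, fwhm_ppm, area)
    return SpectrumGrid1D(axis, intensity)


def render_1d(
    spec: ToyMetaboliteSpec,
    axis: np.ndarray,
    field_mhz: float = DEFAULT_FIELD_MHZ,
) -> SpectrumGrid1D:
    """Sum all multiplets of a metabolite onto one 1D spectrum."""
    total = np.zeros(np.asarray(axis).shape)
    for m in spec.multiplets:
        total += make_multiplet(m, axis, field_mhz).intensity
    return SpectrumGrid1D(axis, total)


def make_pure_jres(
    spec: ToyMetaboliteSpec,
    f2_axis: np.ndarray,
    f1_axis_hz: np.ndarray,
    field_mhz: float = DEFAULT_FIELD_MHZ,
) -> SpectrumGrid2D:
    """Tilted-convention J-Res grid: multiplet structure on F1, shift on F2.

    Each multiplet line becomes a separable 2D peak at (F1 = line offset in
    Hz, F2 = multiplet center in ppm). Rows are scaled so that summing the
    matrix over F1 gives a profile whose F2-integral equals the line area —
    the 2D grid carries the same total intensity budget as the 1D record.
    """
    f2_axis = np.asarray(f2_axis, dtype=float)
    f1_axis_hz = np.asarray(f1_axis_hz, dtype=float)
    if f1_axis_hz.max() < 25.0 or f1_axis_hz.min() > -25.0:
        raise ValueError("f1 axis must span at least +-25 Hz")
    fwhm_f1 = 1.5  # Hz, fixed fixture linewidth along F1
    intensity = np.zeros((f1_axis_hz.size, f2_axis.size))
    for m in spec.multiplets:
        fwhm_f2 = m.linewidth_hz / field_mhz
        for off_hz, area in zip(m.line_offsets_hz(), m.line_areas()):
            u = _lorentzian(f1_axis_hz, off_hz, fwhm_f1, 1.0)
            s = u.sum()
            if s > 0:
                u = u / s  # unit column-sum: F1 summation recovers the area
            v = _sampled_lorentzian(f2_axis, m.center, fwhm_f2, area)
            intensity += np.outer(u, v)
    return SpectrumGrid2D(f2_axis, f1_axis_hz, intensity, mode="jres")


def make_pure_cosy(
    spec: ToyMetaboliteSpec,
    axis: np.ndarray,
    coupled_pairs: Sequence[tuple[int, int]] = (),
    field_mhz: float = DEFAULT_FIELD_MHZ,
    cross_peak_fraction: float = 0.5,
) -> SpectrumGrid2D:
    """COSY grid: diagonal peaks per multiplet, symmetric cross peaks per pair.

    Diagonal peaks sit at (c_i, c_i) with area equal to the multiplet's
    proton weight; each coupled pair (i, j) adds cross peaks at (c_i, c_j)
    and (c_j, c_i) scaled by ``cross_peak_fraction``. The construction is
    exactly symmetric about the diagonal.
    """
    axis = np.asarray(axis, dtype=float)
    n_mult = len(spec.multiplets)
    for i, j in coupled_pairs:
        if not (0 <= i < n_mult and 0 <= j < n_mult):
            raise ValueError(f"coupled pair ({i}, {j}) references a missing multiplet")
    profiles = []
    for m in spec.multiplets:
        fwhm = m.linewidth_hz / field_mhz
        profiles.append(_sampled_lorentzian(axis, m.center, fwhm, 1.0))
    intensity = np.zeros((axis.size, axis.size))
    for m, prof in zip(spec.multiplets, profiles):
        intensity += m.protons_weight * np.outer(prof, prof)
    for i, j in coupled_pairs:
        w = cross_peak_fraction * np.sqrt(
            spec.multiplets[i].protons_weight * spec.multiplets[j].protons_weight
        )
        cross = np.outer(profiles[i], profiles[j])
        intensity += w * (cross + cross.T)
    return SpectrumGrid2D(axis, axis, intensity, mode="cosy")


DEFAULT_ENVELOPE = (
    # (center ppm, sigma ppm, weight) — broad albumin-like humps
    (0.9, 0.20, 1.0),
    (1.3, 0.25, 1.2),
    (2.0, 0.30, 0.8),
    (3.0, 0.40, 0.9),
    (7.3, 0.50, 0.6),
)


def make_protein_background(
    axis: np.ndarray,
    total_area: float = 1.0,
    envelope: Sequence[tuple[float, float, float]] = DEFAULT_ENVELOPE,
) -> SpectrumGrid1D:
    """Broad smooth Gaussian envelope emulating the serum protein baseline."""
    if total_area <= 0:
        raise ValueError("total_area must be > 0")
    axis = np.asarray(axis, dtype=float)
    intensity = np.zeros_like(axis)
    for center, sigma, weight in envelope:
        if sigma <= 0:
            raise ValueError("envelope sigma must be > 0")
        intensity += weight * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
    spec = SpectrumGrid1D(axis, intensity)
    area = spec.integral()
    if area <= 0:
        raise ValueError("envelope has zero area on this axis")
    return SpectrumGrid1D(axis, intensity * (total_area / area))


def build_record(
    spec: ToyMetaboliteSpec,
    axis: np.ndarray,
    field_mhz: float = DEFAULT_FIELD_MHZ,
    with_2d: bool = True,
    axis_2d: Optional[np.ndarray] = None,
    f1_axis_hz: Optional[np.ndarray] = None,
    coupled_pairs: Sequence[tuple[int, int]] = (),
) -> PureCompoundRecord:
    """Render one ToyMetaboliteSpec into a normalized PureCompoundRecord.

    2D grids live on their own (coarser) F2 axis: a square COSY matrix at
    full 1D resolution would be needlessly huge, and 2D acquisitions have
    far fewer points per dimension than 1D ones anyway.
    """
    # same water-window convention as the library loader, so a written
    # fixture library round-trips bit-for-bit through load_library
    raw = render_1d(spec, axis, field_mhz)
    spec_1d = normalize_pure_spectrum(raw, spec.protons)
    jres = cosy = None
    if with_2d:
        if axis_2d is None:
            axis_2d = make_ppm_axis(n_points=1024)
        if f1_axis_hz is None:
            f1_axis_hz = np.linspace(-30.0, 30.0, 121)
        jres = make_pure_jres(spec, axis_2d, f1_axis_hz, field_mhz)
        cosy = make_pure_cosy(spec, axis_2d, coupled_pairs, field_mhz)
    return PureCompoundRecord(
        id=spec.id,
        name=spec.name,
        protons=spec.protons,
        pka=spec.pka,
        shift_limits=list(spec.shift_limits) if spec.shift_limits else None,
        spectrum_1d=spec_1d,
        spectrum_jres=jres,
        spectrum_cosy=cosy,
        stats=list(spec.stats),
    )


def build_library(
    specs: Sequence[ToyMetaboliteSpec],
    axis: Optional[np.ndarray] = None,
    biofluid: str = "urine",
    field_mhz: float = DEFAULT_FIELD_MHZ,
    with_2d: bool = True,
    axis_2d: Optional[np.ndarray] = None,
    f1_axis_hz: Optional[np.ndarray] = None,
    protein_background_area: float = 1.0,
) -> Library:
    """Assemble records from explicit specs; blood gets a protein envelope."""
    if axis is None:
        axis = make_ppm_axis()
    if with_2d and axis_2d is None:
        axis_2d = make_ppm_axis(n_points=1024)
    records = {}
    for spec in specs:
        if spec.id in records:
            raise LibraryError(f"duplicate fixture id {spec.id!r}")
        # couple the first two multiplets when a metabolite has several
        pairs = [(0, 1)] if len(spec.multiplets) >= 2 else []
        records[spec.id] = build_record(
            spec,
            axis,
            field_mhz,
            with_2d=with_2d,
            axis_2d=axis_2d,
            f1_axis_hz=f1_axis_hz,
            coupled_pairs=pairs,
        )
    background = (
        make_protein_background(axis, total_area=protein_background_area)
        if biofluid == "blood"
        else None
    )
    return Library(records=records, common_grid=np.asarray(axis), protein_background=background)


_WATER = (4.5, 5.0)


def _draw_center(rng: np.random.Generator, lo: float = 0.8, hi: float = 9.0) -> float:
    """Uniform draw on [lo, hi] avoiding the residual-water window."""
    while True:
        c = float(rng.uniform(lo, hi))
        if not (_WATER[0] - 0.1 <= c <= _WATER[1] + 0.1):
            return c


def make_toy_library(
    n_metabolites: int,
    seed: int,
    biofluid: str = "urine",
    axis: Optional[np.ndarray] = None,
    field_mhz: float = DEFAULT_FIELD_MHZ,
    with_2d: bool = True,
    axis_2d: Optional[np.ndarray] = None,
    abnormal_condition: str = "heart transplant",
) -> Library:
    """Random but fully deterministic toy library.

    Each metabolite gets 1-3 multiplets with random centers (water window
    avoided), patterns and couplings; at least half the records carry a pKa
    and per-multiplet acid/basic shift limits so the pH-shift path is
    exercised; every record carries "normal" and one abnormal condition's
    concentration statistics. Blood libraries include the protein envelope.
    """
    if n_metabolites < 1:
        raise ValueError("need at least one metabolite")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_metabolites):
        n_mult = int(rng.integers(1, 4))
        weights = rng.integers(1, 4, size=n_mult)  # integer proton counts per multiplet
        protons = int(weights.sum())
        multiplets = []
        limits = []
        for w in weights:
            pattern = str(rng.choice(["s", "d", "t", "q"]))
            center = _draw_center(rng)
            multiplets.append(
                MultipletSpec(
                    center=center,
                    pattern=pattern,
                    j_hz=0.0 if pattern == "s" else float(rng.uniform(3.0, 12.0)),
                    linewidth_hz=float(rng.uniform(1.0, 2.0)),
                    protons_weight=float(w),
                )
            )
            half_span = float(rng.uniform(0.02, 0.10))
            limits.append((center + half_span, center - half_span))
        has_ph = i < (n_metabolites + 1) // 2  # first half: pH-sensitive
        mean = float(rng.uniform(50.0, 500.0))
        sd = mean / 10.0
        fc = float(rng.uniform(0.5, 2.0))
        stats = (
            ConditionStats(mean, sd, condition="normal", biofluid=biofluid),
            ConditionStats(mean * fc, sd, condition=abnormal_condition, biofluid=biofluid),
        )
        specs.append(
            ToyMetaboliteSpec(
                id=f"tm{i:03d}",
                name=f"toy metabolite {i}",
                protons=protons,
                multiplets=tuple(multiplets),
                pka=float(rng.uniform(3.0, 9.0)) if has_ph else None,
                shift_limits=tuple(limits) if has_ph else None,
                stats=stats,
            )
        )
    return build_library(
        specs,
        axis=axis,
        biofluid=biofluid,
        field_mhz=field_mhz,
        with_2d=with_2d,
        axis_2d=axis_2d,
    )
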