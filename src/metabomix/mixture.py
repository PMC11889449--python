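"""Mixture spectrum assembly and cohort simulation.

A mixture spectrum is the concentration-weighted sum of the library's
normalized pure-compound spectra,

    y(ppm) = sum_k c_k * gamma_k(ppm),

with the observable-proton count p_k already folded into gamma_k by the
library normalization (1 area unit per proton at unit concentration).
Optionally each metabolite is pH-shifted before summation (one realized
sample pH per replicate, shared by all metabolites), a broad protein
background is added for blood, and white Gaussian noise is applied.

Seed discipline: a master seed spawns named substreams (concentrations,
pH, noise, pKa imputation), so e.g. turning noise on does not perturb the
concentration draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .concentrations import (
    ConcentrationTable,
    ContinuousDesign,
    DiscreteDesign,
    sample_continuous,
    sample_discrete,
)
from .grids import SpectrumGrid1D, SpectrumGrid2D
from .library import Library, LibraryError, PureCompoundRecord
from .peaks import (
    PeakClusterSet,
    ShiftContext,
    apply_shift_1d,
    apply_shift_2d,
    compute_delta_shift,
    detect_peaks_1d,
    diagonal_projection,
    sample_limit_difference,
    sample_pka,
    skyline_projection,
)

__all__ = [
    "MixtureSpec",
    "SimulatedSpectrum",
    "CohortResult",
    "MixtureError",
    "substream",
    "simulate_mixture_1d",
    "simulate_mixture_2d",
    "add_protein_background",
    "add_noise",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)


class MixtureError(ValueError):
    """Raised for invalid mixture requests."""


_SUBSTREAMS = {"concentrations": 0, "ph": 1, "noise": 2, "pka": 3, "fixtures": 4}


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, index-addressable RNG substream derived from one master seed."""
    try:
        key = _SUBSTREAMS[name]
    except KeyError:
        raise MixtureError(f"unknown substream {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key, index)))


@dataclass
class MixtureSpec:
    """What to simulate: biofluid, metabolites, mode and nuisance settings."""

    biofluid: str = "urine"
    metabolite_ids: Optional[list[str]] = None  # None: all library records
    mode: str = "1d"  # "1d" | "jres" | "cosy"
    shift_enabled: bool = False
    ph_mean: float = 7.4
    ph_sd: float = 0.0
    shift_context: ShiftContext = field(default_factory=ShiftContext)
    main_threshold_frac: float = 0.1
    cluster_threshold_frac: float = 0.02
    noise_sd: float = 0.0  # fraction of the clean maximum
    protein_scale: float = 0.0  # blood background multiplier
    # shifted resonances that land on the same points physically superpose,
    # so cohort simulation sums them; pass "error" to fail instead
    collision: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("1d", "jres", "cosy"):
            raise MixtureError(f"unknown mode {self.mode!r}")
        if self.noise_sd < 0:
            raise MixtureError("noise_sd must be >= 0")
        if self.protein_scale < 0:
            raise MixtureError("protein_scale must be >= 0")


@dataclass
class SimulatedSpectrum:
    """One simulated spectrum plus full generating provenance."""

    grid: Union[SpectrumGrid1D, SpectrumGrid2D]
    concentrations: dict[str, float]
    ph: Optional[float] = None
    shifts: dict[str, list[float]] = field(default_factory=dict)
    noise_seed: Optional[int] = None
    clean_max: float = 0.0


@dataclass
class CohortResult:
    """All spectra of a simulated cohort plus the labels that made them."""

    spectra: list[SimulatedSpectrum]
    table: ConcentrationTable
    spec: MixtureSpec
    seed: int

    def __post_init__(self) -> None:
        if len(self.spectra) != self.table.n:
            raise MixtureError("spectra count must equal table rows")

    def to_matrix(self) -> np.ndarray:
        """Replicates x grid-points intensity matrix (1D cohorts)."""
        return np.vstack([s.grid.intensity.ravel() for s in self.spectra])


def _resolve(library: Library, concentrations: Mapping[str, float]) -> list[tuple[PureCompoundRecord, float]]:
    out = []
    for mid, c in concentrations.items():
        if c < 0:
            raise MixtureError(f"negative concentration for {mid!r}")
        out.append((library[mid], float(c)))
    return out


def _cluster_shifts(
    rec: PureCompoundRecord,
    profile: SpectrumGrid1D,
    spec: MixtureSpec,
    ph1: float,
    pka_rng: np.random.Generator,
) -> tuple[Optional[PeakClusterSet], list[float]]:
    """Detect clusters on a pure profile and compute each one's pH shift.

    Limit pairs are matched to clusters in ppm order; clusters beyond the
    stated list are imputed (if enabled) or left unshifted. Records with
    neither pKa nor shift limits are pH-invariant.
    """
    ctx = spec.shift_context
    if rec.shift_limits is None and rec.pka is None:
        return None, []
    clusters = detect_peaks_1d(profile, spec.main_threshold_frac, spec.cluster_threshold_frac)
    if len(clusters) == 0:
        return None, []
    pka = rec.pka
    if pka is None:
        if not ctx.impute_missing:
            return None, []
        pka = sample_pka(ctx, pka_rng)
    limits = list(rec.shift_limits or [])
    shifts = []
    for i in range(len(clusters)):
        if i < len(limits):
            d_l, d_hl = limits[i]
        elif ctx.impute_missing:
            diff = sample_limit_difference(ctx, pka_rng)
            d_l, d_hl = diff, 0.0
        else:
            logger.info("record %s: cluster %d has no shift limits; left in place", rec.id, i)
            shifts.append(0.0)
            continue
        shifts.append(compute_delta_shift(d_l, d_hl, pka, ctx.ph0, ph1))
    return clusters, shifts


def simulate_mixture_1d(
    library: Library,
    concentrations: Mapping[str, float],
    spec: MixtureSpec,
    ph1: Optional[float] = None,
    pka_rng: Optional[np.random.Generator] = None,
    noise_rng: Optional[np.random.Generator] = None,
    noise_seed: Optional[int] = None,
) -> SimulatedSpectrum:
    """Simulate one 1D mixture spectrum.

    Order of operations: per-metabolite pH shift (single realized sample
    pH), weighted summation, protein background (blood), then noise.
    """
    pairs = _resolve(library, concentrations)
    axis = library.common_grid
    total = np.zeros(axis.shape)
    shift_log: dict[str, list[float]] = {}
    if spec.shift_enabled and ph1 is None:
        ph1 = spec.ph_mean
    if pka_rng is None:
        pka_rng = substream(spec.seed, "pka")
    for rec, c in pairs:
        profile = rec.spectrum_1d
        if spec.shift_enabled and ph1 is not None:
            clusters, shifts = _cluster_shifts(rec, profile, spec, ph1, pka_rng)
            if clusters is not None:
                profile = apply_shift_1d(profile, clusters, shifts, collision=spec.collision)
                shift_log[rec.id] = list(shifts)
        total = total + c * profile.intensity
    if spec.protein_scale > 0:
        if library.protein_background is None:
            raise MixtureError("library has no protein background (blood only)")
        total = total + spec.protein_scale * library.protein_background.intensity
    clean_max = float(np.abs(total).max(initial=0.0))
    grid = SpectrumGrid1D(axis, total)
    if spec.noise_sd > 0:
        if noise_rng is None:
            noise_rng = substream(spec.seed, "noise") if noise_seed is None else np.random.default_rng(noise_seed)
        grid = add_noise(grid, spec.noise_sd, noise_rng)
    return SimulatedSpectrum(
        grid=grid,
        concentrations={mid: float(c) for mid, c in concentrations.items()},
        ph=ph1 if spec.shift_enabled else None,
        shifts=shift_log,
        noise_seed=noise_seed,
        clean_max=clean_max,
    )


def add_protein_background(
    spec_1d: SpectrumGrid1D,
    background: SpectrumGrid1D,
    protein_scale: float,
) -> SpectrumGrid1D:
    """Pointwise addition of the scaled protein envelope."""
    if not np.array_equal(spec_1d.ppm_axis, background.ppm_axis):
        raise MixtureError("background is not on the spectrum's grid")
    if protein_scale < 0:
        raise MixtureError("protein_scale must be >= 0")
    return SpectrumGrid1D(spec_1d.ppm_axis, spec_1d.intensity + protein_scale * background.intensity)


def add_noise(
    grid: Union[SpectrumGrid1D, SpectrumGrid2D],
    noise_sd_frac: float,
    rng: np.random.Generator | int,
) -> Union[SpectrumGrid1D, SpectrumGrid2D]:
    """Add white Gaussian noise with SD = frac x max(|clean intensity|)."""
    if noise_sd_frac < 0:
        raise MixtureError("noise_sd_frac must be >= 0")
    if noise_sd_frac == 0:
        return grid.copy()
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    scale = float(np.abs(grid.intensity).max(initial=0.0))
    noisy = grid.intensity + rng.normal(0.0, noise_sd_frac * scale, size=grid.intensity.shape)
    if isinstance(grid, SpectrumGrid1D):
        return SpectrumGrid1D(grid.ppm_axis, noisy)
    return SpectrumGrid2D(grid.f2_axis, grid.f1_axis, noisy, grid.mode)


def simulate_mixture_2d(
    library: Library,
    concentrations: Mapping[str, float],
    spec: MixtureSpec,
    ph1: Optional[float] = None,
    pka_rng: Optional[np.random.Generator] = None,
    noise_rng: Optional[np.random.Generator] = None,
    noise_seed: Optional[int] = None,
) -> SimulatedSpectrum:
    """Simulate one 2D (J-Res or COSY) mixture spectrum.

    Per-metabolite 2D grids (already on one shared 2D axis pair, with the
    1D-consistent intensity budget) are weighted by c_k; pH shifting uses
    clusters detected on each metabolite's projected profile.
    """
    if spec.mode not in ("jres", "cosy"):
        raise MixtureError("mode must be 'jres' or 'cosy' for 2D simulation")
    pairs = _resolve(library, concentrations)
    missing = [
        rec.id
        for rec, _ in pairs
        if (rec.spectrum_jres if spec.mode == "jres" else rec.spectrum_cosy) is None
    ]
    if missing:
        raise MixtureError(f"records lack {spec.mode} grids: {missing}")
    if spec.shift_enabled and ph1 is None:
        ph1 = spec.ph_mean
    if pka_rng is None:
        pka_rng = substream(spec.seed, "pka")
    total = None
    ref = None
    shift_log: dict[str, list[float]] = {}
    for rec, c in pairs:
        g2 = rec.spectrum_jres if spec.mode == "jres" else rec.spectrum_cosy
        if ref is None:
            ref = g2
        elif not (
            np.array_equal(ref.f2_axis, g2.f2_axis) and np.array_equal(ref.f1_axis, g2.f1_axis)
        ):
            raise MixtureError(f"record {rec.id!r} is not on the shared 2D axes")
        if spec.shift_enabled and ph1 is not None:
            projected = (
                skyline_projection(g2) if spec.mode == "jres" else diagonal_projection(g2)
            )
            clusters, shifts = _cluster_shifts(rec, projected, spec, ph1, pka_rng)
            if clusters is not None:
                g2 = apply_shift_2d(g2, clusters, shifts, collision=spec.collision)
                shift_log[rec.id] = list(shifts)
        total = c * g2.intensity if total is None else total + c * g2.intensity
    assert ref is not None
    clean_max = float(np.abs(total).max(initial=0.0))
    grid = SpectrumGrid2D(ref.f2_axis, ref.f1_axis, total, spec.mode)
    if spec.noise_sd > 0:
        if noise_rng is None:
            noise_rng = substream(spec.seed, "noise") if noise_seed is None else np.random.default_rng(noise_seed)
        grid = add_noise(grid, spec.noise_sd, noise_rng)
    return SimulatedSpectrum(
        grid=grid,
        concentrations={mid: float(c) for mid, c in concentrations.items()},
        ph=ph1 if spec.shift_enabled else None,
        shifts=shift_log,
        noise_seed=noise_seed,
        clean_max=clean_max,
    )


def simulate_cohort(
    library: Library,
    design: Union[DiscreteDesign, ContinuousDesign],
    spec: MixtureSpec,
) -> CohortResult:
    """Simulate a full labeled cohort: concentrations, then one spectrum per row.

    Fully deterministic given the master seed in ``spec.seed``: the
    concentration table, the per-replicate pH draws and the per-replicate
    noise substreams all derive from it.
    """
    for mid in getattr(design, "metabolite_ids"):
        library[mid]  # raises LibraryError for unknown ids
    conc_rng = substream(spec.seed, "concentrations")
    if isinstance(design, DiscreteDesign):
        table = sample_discrete(replace(design, seed=spec.seed), rng=conc_rng)
    else:
        table = sample_continuous(replace(design, seed=spec.seed), rng=conc_rng)
    ph_rng = substream(spec.seed, "ph")
    ph_draws = (
        ph_rng.normal(spec.ph_mean, spec.ph_sd, size=table.n) if spec.shift_enabled else None
    )
    spectra = []
    for i in range(table.n):
        row = table.concentrations.iloc[i]
        conc = {mid: float(row[mid]) for mid in table.metabolite_ids}
        kwargs = dict(
            ph1=float(ph_draws[i]) if ph_draws is not None else None,
            pka_rng=substream(spec.seed, "pka", i),
            noise_rng=substream(spec.seed, "noise", i),
        )
        try:
            if spec.mode == "1d":
                s = simulate_mixture_1d(library, conc, spec, **kwargs)
            else:
                s = simulate_mixture_2d(library, conc, spec, **kwargs)
        except (MixtureError, LibraryError) as err:
            raise MixtureError(f"replicate {i}: {err}") from err
        spectra.append(s)
    return CohortResult(spectra=spectra, table=table, spec=spec, seed=spec.seed)
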