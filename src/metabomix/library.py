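"""Pure-compound reference library: data model, normalization and disk I/O.

A library bundles, per metabolite, a 1D reference spectrum normalized to
unit concentration (and optional 2D J-Res/COSY grids) together with
chemical metadata (observable proton count, pKa, acid/basic-limit peak
positions) and per-biofluid concentration statistics in the style of the
Human Metabolome Database.

Normalization convention: 1 area unit == 1 observable proton at unit
concentration, so a record's 1D trapezoidal integral equals its proton
count and mixture synthesis reduces to a plain weighted sum over
concentrations.

On-disk format: a directory holding ``library.tsv`` (one row per
metabolite/biofluid/condition) plus one 2-column TSV spectrum per record
(``<id>.tsv``: ppm, intensity), optional dense-matrix 2D grids
(``<id>.jres.tsv`` / ``<id>.cosy.tsv``) and an optional
``protein_background.tsv`` envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import SpectrumGrid1D, SpectrumGrid2D, make_ppm_axis

__all__ = [
    "ConditionStats",
    "ConcRange",
    "PureCompoundRecord",
    "Library",
    "LibraryError",
    "range_to_stats",
    "aggregate_entries",
    "normalize_pure_spectrum",
    "resample_to_grid",
    "load_library",
    "write_library",
    "DEFAULT_WATER_WINDOW",
]

BIOFLUIDS = ("urine", "blood", "csf")

#: Residual-water exclusion window in ppm, zeroed before normalization.
DEFAULT_WATER_WINDOW = (4.5, 5.0)


class LibraryError(ValueError):
    """Raised for malformed libraries or records."""


@dataclass(frozen=True)
class ConditionStats:
    """Concentration mean/SD (uM) for one metabolite in one biofluid/condition."""

    mean: float
    sd: float
    condition: str = "normal"
    biofluid: str = "urine"

    def __post_init__(self) -> None:
        if not (self.mean >= 0):
            raise LibraryError(f"concentration mean must be >= 0, got {self.mean}")
        if not (self.sd >= 0):
            raise LibraryError(f"concentration sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ConcRange:
    """A literature concentration range [min, max] in uM."""

    min_uM: float
    max_uM: float

    def to_stats(self, condition: str = "normal", biofluid: str = "urine") -> ConditionStats:
        return range_to_stats(self.min_uM, self.max_uM, condition=condition, biofluid=biofluid)


def range_to_stats(
    min_conc: float,
    max_conc: float,
    condition: str = "normal",
    biofluid: str = "urine",
) -> ConditionStats:
    """Convert a [min, max] concentration range to (mean, SD).

    The range is read as a 99.7% (3-sigma) interval of a normal
    distribution: mean = midpoint, SD = span / 6.
    """
    if min_conc < 0 or max_conc < 0:
        raise LibraryError("concentrations must be non-negative")
    if min_conc > max_conc:
        raise LibraryError(f"range min {min_conc} exceeds max {max_conc}")
    return ConditionStats(
        mean=(min_conc + max_conc) / 2.0,
        sd=(max_conc - min_conc) / 6.0,
        condition=condition,
        biofluid=biofluid,
    )


def aggregate_entries(entries: Sequence[ConditionStats | ConcRange]) -> ConditionStats:
    """Pool several literature entries for one metabolite/condition.

    Ranges are first converted by the 3-sigma rule; the pooled mean is the
    unweighted arithmetic mean of entry means and the pooled SD the
    unweighted arithmetic mean of entry SDs.
    """
    if len(entries) == 0:
        raise LibraryError("cannot aggregate an empty entry list")
    stats: list[ConditionStats] = []
    for e in entries:
        if isinstance(e, ConcRange):
            stats.append(e.to_stats())
        elif isinstance(e, ConditionStats):
            stats.append(e)
        else:
            raise LibraryError(f"unsupported entry type {type(e).__name__}")
    conditions = {s.condition for s in stats}
    biofluids = {s.biofluid for s in stats}
    if len(conditions) > 1 or len(biofluids) > 1:
        raise LibraryError("entries must share one condition and one biofluid")
    return ConditionStats(
        mean=float(np.mean([s.mean for s in stats])),
        sd=float(np.mean([s.sd for s in stats])),
        condition=stats[0].condition,
        biofluid=stats[0].biofluid,
    )


def normalize_pure_spectrum(
    raw: SpectrumGrid1D,
    protons: int,
    water_window: Optional[tuple[float, float]] = DEFAULT_WATER_WINDOW,
) -> SpectrumGrid1D:
    """Scale a pure-compound spectrum so its integral equals the proton count.

    Optionally zeroes the residual-water window first (default
    4.5-5.0 ppm). The shape is otherwise unchanged: a single positive
    scale factor maps raw to normalized intensities.
    """
    if protons < 1:
        raise LibraryError(f"protons must be >= 1, got {protons}")
    intensity = raw.intensity.copy()
    if water_window is not None:
        lo, hi = min(water_window), max(water_window)
        mask = (raw.ppm_axis >= lo) & (raw.ppm_axis <= hi)
        intensity[mask] = 0.0
    spec = SpectrumGrid1D(raw.ppm_axis, intensity)
    area = spec.integral()
    if area <= 0:
        raise LibraryError("cannot normalize a spectrum with non-positive integral")
    return SpectrumGrid1D(raw.ppm_axis, intensity * (protons / area))


def resample_to_grid(spec: SpectrumGrid1D, target_axis: np.ndarray) -> SpectrumGrid1D:
    """Linearly interpolate a spectrum onto a new uniform ppm axis.

    Target points outside the source range are set to zero.
    """
    target_axis = np.asarray(target_axis, dtype=float)
    # constructor validates uniformity/monotonicity of the target
    if np.array_equal(target_axis, spec.ppm_axis):
        return SpectrumGrid1D(target_axis, spec.intensity.copy())
    # np.interp needs ascending x
    src_ppm = spec.ppm_axis[::-1]
    src_int = spec.intensity[::-1]
    out = np.interp(target_axis, src_ppm, src_int, left=0.0, right=0.0)
    # zero anything strictly outside the source span (interp clamps ends)
    out[(target_axis < src_ppm[0]) | (target_axis > src_ppm[-1])] = 0.0
    return SpectrumGrid1D(target_axis, out)


@dataclass
class PureCompoundRecord:
    """One metabolite: normalized spectra + chemical and concentration metadata.

    ``shift_limits`` holds per-cluster (delta_L, delta_HL) acid/basic limit
    positions in ppm, paired with detected peak clusters in ppm order;
    ``None`` marks the compound as pH-invariant.
    """

    id: str
    name: str
    protons: int
    spectrum_1d: SpectrumGrid1D
    pka: Optional[float] = None
    shift_limits: Optional[list[tuple[float, float]]] = None
    spectrum_jres: Optional[SpectrumGrid2D] = None
    spectrum_cosy: Optional[SpectrumGrid2D] = None
    stats: list[ConditionStats] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.protons < 1:
            raise LibraryError(f"record {self.id!r}: protons must be >= 1")
        if self.pka is not None and not math.isfinite(self.pka):
            raise LibraryError(f"record {self.id!r}: pKa must be finite")
        area = self.spectrum_1d.integral()
        if abs(area - self.protons) > 1e-6 * max(1.0, self.protons):
            raise LibraryError(
                f"record {self.id!r}: 1D integral {area:.8g} does not equal "
                f"proton count {self.protons} (spectrum not normalized?)"
            )

    def stats_for(self, condition: str, biofluid: str) -> ConditionStats:
        for s in self.stats:
            if s.condition == condition and s.biofluid == biofluid:
                return s
        raise LibraryError(
            f"record {self.id!r}: no concentration stats for "
            f"condition={condition!r}, biofluid={biofluid!r}"
        )


@dataclass
class Library:
    """A set of pure-compound records sharing one common ppm grid."""

    records: dict[str, PureCompoundRecord]
    common_grid: np.ndarray
    protein_background: Optional[SpectrumGrid1D] = None

    def __post_init__(self) -> None:
        self.common_grid = np.asarray(self.common_grid, dtype=float)
        for rec in self.records.values():
            if not np.array_equal(rec.spectrum_1d.ppm_axis, self.common_grid):
                raise LibraryError(f"record {rec.id!r} is not on the common grid")
        if self.protein_background is not None and not np.array_equal(
            self.protein_background.ppm_axis, self.common_grid
        ):
            raise LibraryError("protein background is not on the common grid")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> PureCompoundRecord:
        try:
            return self.records[rec_id]
        except KeyError:
            raise LibraryError(f"unknown metabolite id {rec_id!r}") from None

    def ids(self) -> list[str]:
        return sorted(self.records)


# ---------------------------------------------------------------------------
# disk I/O

_META_COLUMNS = [
    "id",
    "name",
    "protons",
    "pka",
    "biofluid",
    "condition",
    "conc_mean_uM",
    "conc_sd_uM",
    "conc_min_uM",
    "conc_max_uM",
    "shift_limits",
]


def _format_shift_limits(limits: Optional[list[tuple[float, float]]]) -> str:
    if not limits:
        return ""
    return ";".join(f"{a:.17g}:{b:.17g}" for a, b in limits)


def _parse_shift_limits(text: str) -> Optional[list[tuple[float, float]]]:
    text = text.strip()
    if not text:
        return None
    out = []
    for pair in text.split(";"):
        try:
            a, b = pair.split(":")
            out.append((float(a), float(b)))
        except ValueError:
            raise LibraryError(f"malformed shift_limits entry {pair!r}") from None
    return out


def _write_grid2d(path: Path, grid: SpectrumGrid2D) -> None:
    # first row: mode marker then f2 axis; first column: f1 axis
    with open(path, "w") as fh:
        fh.write("#mode\t" + grid.mode + "\n")
        fh.write("f1\\f2\t" + "\t".join(f"{v:.17g}" for v in grid.f2_axis) + "\n")
        for i, f1 in enumerate(grid.f1_axis):
            row = "\t".join(f"{v:.17g}" for v in grid.intensity[i])
            fh.write(f"{f1:.17g}\t{row}\n")


def _read_grid2d(path: Path) -> SpectrumGrid2D:
    with open(path) as fh:
        header = fh.readline().split("\t")
        if len(header) != 2 or header[0] != "#mode":
            raise LibraryError(f"{path.name}: missing 2D mode header")
        mode = header[1].strip()
        f2 = np.array(fh.readline().split("\t")[1:], dtype=float)
        f1_vals, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            f1_vals.append(float(parts[0]))
            rows.append(np.array(parts[1:], dtype=float))
    return SpectrumGrid2D(f2, np.array(f1_vals), np.vstack(rows), mode)


def write_library(library: Library, path: str | Path) -> None:
    """Write a library directory (metadata TSV + per-record spectra)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec_id in library.ids():
        rec = library[rec_id]
        base = {
            "id": rec.id,
            "name": rec.name,
            "protons": rec.protons,
            "pka": "" if rec.pka is None else f"{rec.pka:.17g}",
            "shift_limits": _format_shift_limits(rec.shift_limits),
        }
        entries = rec.stats or [None]
        for s in entries:
            row = dict(base)
            if s is None:
                row.update(biofluid="", condition="", conc_mean_uM="", conc_sd_uM="")
            else:
                row.update(
                    biofluid=s.biofluid,
                    condition=s.condition,
                    conc_mean_uM=f"{s.mean:.17g}",
                    conc_sd_uM=f"{s.sd:.17g}",
                )
            row.update(conc_min_uM="", conc_max_uM="")
            rows.append(row)
        np.savetxt(
            path / f"{rec.id}.tsv",
            np.column_stack([rec.spectrum_1d.ppm_axis, rec.spectrum_1d.intensity]),
            fmt="%.17g",
            delimiter="\t",
        )
        if rec.spectrum_jres is not None:
            _write_grid2d(path / f"{rec.id}.jres.tsv", rec.spectrum_jres)
        if rec.spectrum_cosy is not None:
            _write_grid2d(path / f"{rec.id}.cosy.tsv", rec.spectrum_cosy)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path / "library.tsv", sep="\t", index=False)
    if library.protein_background is not None:
        bg = library.protein_background
        np.savetxt(
            path / "protein_background.tsv",
            np.column_stack([bg.ppm_axis, bg.intensity]),
            fmt="%.17g",
            delimiter="\t",
        )


def _read_spectrum_tsv(path: Path) -> SpectrumGrid1D:
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2:
        raise LibraryError(f"{path.name}: expected 2 columns (ppm, intensity)")
    ppm, intensity = data[:, 0], data[:, 1]
    if ppm[0] < ppm[-1]:  # accept ascending files, store descending
        ppm, intensity = ppm[::-1], intensity[::-1]
    return SpectrumGrid1D(ppm, intensity)


def load_library(
    path: str | Path,
    common_grid: Optional[np.ndarray] = None,
    renormalize: bool = True,
    water_window: Optional[tuple[float, float]] = DEFAULT_WATER_WINDOW,
) -> Library:
    """Load a library directory, resampling every record to one common grid.

    If ``common_grid`` is None the first record's axis (by id order) is the
    common grid. Spectra are (re)normalized to the proton-count convention
    unless ``renormalize`` is False (set it for round-tripping an already
    normalized library, where re-zeroing the water window would bias areas).
    """
    path = Path(path)
    meta_path = path / "library.tsv"
    if not meta_path.exists():
        raise LibraryError(f"no library.tsv in {path}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    if meta.duplicated().any():
        dup_ids = sorted(meta.loc[meta.duplicated(), "id"].unique())
        raise LibraryError(f"duplicate metadata rows for id(s) {dup_ids}")

    records: dict[str, PureCompoundRecord] = {}
    for rec_id, group in meta.groupby("id", sort=True):
        rec_id = str(rec_id)
        if rec_id in records:
            raise LibraryError(f"duplicate id {rec_id!r} in library.tsv")
        first = group.iloc[0]
        if (group["protons"].nunique() > 1) or (group["pka"].nunique() > 1):
            raise LibraryError(f"record {rec_id!r}: inconsistent metadata across rows")
        try:
            protons = int(first["protons"])
        except ValueError:
            raise LibraryError(f"record {rec_id!r}: bad proton count {first['protons']!r}") from None
        if protons < 1:
            raise LibraryError(f"record {rec_id!r}: protons must be >= 1")
        spec_path = path / f"{rec_id}.tsv"
        if not spec_path.exists():
            raise LibraryError(f"record {rec_id!r}: missing spectrum file {spec_path.name}")
        raw = _read_spectrum_tsv(spec_path)
        if common_grid is None:
            common_grid = raw.ppm_axis.copy()
        spec = resample_to_grid(raw, common_grid)
        if renormalize:
            spec = normalize_pure_spectrum(spec, protons, water_window=water_window)

        stats = []
        for _, row in group.iterrows():
            if not str(row["biofluid"]).strip():
                continue
            if str(row["conc_mean_uM"]).strip():
                s = ConditionStats(
                    float(row["conc_mean_uM"]),
                    float(row["conc_sd_uM"] or 0.0),
                    condition=str(row["condition"]),
                    biofluid=str(row["biofluid"]),
                )
            elif str(row["conc_min_uM"]).strip():
                s = range_to_stats(
                    float(row["conc_min_uM"]),
                    float(row["conc_max_uM"]),
                    condition=str(row["condition"]),
                    biofluid=str(row["biofluid"]),
                )
            else:
                raise LibraryError(
                    f"record {rec_id!r}: row needs conc_mean_uM or conc_min/max_uM"
                )
            stats.append(s)

        jres_path = path / f"{rec_id}.jres.tsv"
        cosy_path = path / f"{rec_id}.cosy.tsv"
        records[rec_id] = PureCompoundRecord(
            id=rec_id,
            name=str(first["name"]),
            protons=protons,
            pka=float(first["pka"]) if str(first["pka"]).strip() else None,
            shift_limits=_parse_shift_limits(str(first["shift_limits"])),
            spectrum_1d=spec,
            spectrum_jres=_read_grid2d(jres_path) if jres_path.exists() else None,
            spectrum_cosy=_read_grid2d(cosy_path) if cosy_path.exists() else None,
            stats=stats,
        )

    if common_grid is None:
        raise LibraryError(f"library at {path} contains no records")
    bg_path = path / "protein_background.tsv"
    background = _read_spectrum_tsv(bg_path) if bg_path.exists() else None
    if background is not None:
        background = resample_to_grid(background, common_grid)
    return Library(records=records, common_grid=np.asarray(common_grid), protein_background=background)
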