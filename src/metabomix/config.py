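"""Run configuration: YAML parsing, validation, defaults and orchestration.

A run config is a small YAML document with sections::

    library:            # exactly one of path / fixture
      path: my_library/
      fixture: {n_metabolites: 5, biofluid: urine, grid_points: 4096}
    mixture:
      mode: 1d          # 1d | jres | cosy
      biofluid: urine
      metabolites: [tm000, tm001]     # optional; default: all records
      shift_enabled: false
      ph_mean: 7.4
      ph_sd: 0.0
      ph0: 7.4
      noise_sd: 0.0
      protein_scale: 0.0
    design:             # exactly one of discrete / continuous
      discrete:
        condition: normal
        groups:
          normal: {n: 10}
          case:   {n: 10, fold_changes: {tm000: 2.0}, sd_ratios: {tm000: 1.0}}
      continuous:
        n: 100
        response_mean: 25.0
        response_sd: 4.0
        metabolites:
          tm000: {x_mean: 200.0, x_sd: 20.0, a: 0.7, eps_sd: 0.714}
    seed: 17
    log_level: INFO

Unknown keys raise; every default that is filled in is logged. The
standard-spectrum pH defaults to the physiological 7.4.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .concentrations import (
    ContinuousDesign,
    DiscreteDesign,
    GroupSpec,
    MetaboliteResponse,
)
from .fixtures import make_toy_library
from .grids import SpectrumGrid1D, make_ppm_axis
from .library import ConditionStats, Library, load_library, write_library
from .mixture import CohortResult, MixtureSpec, simulate_cohort
from .peaks import ShiftContext

__all__ = ["RunConfig", "ConfigError", "parse_config", "run"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configurations."""


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _default(section: dict, key: str, value: Any, where: str) -> Any:
    if key in section:
        return section[key]
    logger.info("config: %s.%s defaulted to %r", where, key, value)
    return value


@dataclass
class RunConfig:
    """Fully validated run configuration."""

    library_path: Optional[str]
    fixture: Optional[dict]
    mixture: MixtureSpec
    design_section: dict  # raw, resolved against the library at run time
    design_kind: str  # "discrete" | "continuous"
    seed: int
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)


def parse_config(path: Union[str, Path], seed_override: Optional[int] = None) -> RunConfig:
    """Parse and validate a YAML run config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")
    return parse_config_dict(doc, seed_override=seed_override)


def parse_config_dict(doc: dict, seed_override: Optional[int] = None) -> RunConfig:
    _check_keys(doc, {"library", "mixture", "design", "seed", "log_level"}, "top level")

    lib = doc.get("library")
    if not isinstance(lib, dict) or ("path" in lib) == ("fixture" in lib):
        raise ConfigError("library section needs exactly one of 'path' or 'fixture'")
    _check_keys(lib, {"path", "fixture"}, "library")
    fixture = lib.get("fixture")
    if fixture is not None:
        _check_keys(
            fixture,
            {"n_metabolites", "biofluid", "grid_points", "with_2d", "grid_points_2d", "seed"},
            "library.fixture",
        )

    mix = dict(doc.get("mixture") or {})
    _check_keys(
        mix,
        {
            "mode",
            "biofluid",
            "metabolites",
            "shift_enabled",
            "ph_mean",
            "ph_sd",
            "ph0",
            "noise_sd",
            "protein_scale",
            "main_threshold_frac",
            "cluster_threshold_frac",
            "pka_fallback_mean",
            "pka_fallback_sd",
            "limitdiff_mean",
            "limitdiff_sd",
        },
        "mixture",
    )
    seed = doc.get("seed", 0) if seed_override is None else seed_override
    if not (isinstance(seed, int) and seed >= 0):
        raise ConfigError("seed must be a non-negative integer")
    ctx = ShiftContext(
        ph0=float(_default(mix, "ph0", 7.4, "mixture")),
        pka_fallback_mean=float(mix.get("pka_fallback_mean", 7.0)),
        pka_fallback_sd=float(mix.get("pka_fallback_sd", 2.0)),
        limitdiff_mean=float(mix.get("limitdiff_mean", 0.05)),
        limitdiff_sd=float(mix.get("limitdiff_sd", 0.02)),
    )
    mixture = MixtureSpec(
        biofluid=str(_default(mix, "biofluid", "urine", "mixture")),
        metabolite_ids=list(mix["metabolites"]) if mix.get("metabolites") else None,
        mode=str(_default(mix, "mode", "1d", "mixture")),
        shift_enabled=bool(_default(mix, "shift_enabled", False, "mixture")),
        ph_mean=float(_default(mix, "ph_mean", 7.4, "mixture")),
        ph_sd=float(_default(mix, "ph_sd", 0.0, "mixture")),
        shift_context=ctx,
        main_threshold_frac=float(mix.get("main_threshold_frac", 0.1)),
        cluster_threshold_frac=float(mix.get("cluster_threshold_frac", 0.02)),
        noise_sd=float(_default(mix, "noise_sd", 0.0, "mixture")),
        protein_scale=float(_default(mix, "protein_scale", 0.0, "mixture")),
        seed=seed,
    )

    design = doc.get("design")
    if not isinstance(design, dict):
        raise ConfigError("a design section is required")
    _check_keys(design, {"discrete", "continuous"}, "design")
    if ("discrete" in design) == ("continuous" in design):
        raise ConfigError("design needs exactly one of 'discrete' or 'continuous'")
    kind = "discrete" if "discrete" in design else "continuous"
    section = design[kind]
    if kind == "discrete":
        _check_keys(section, {"condition", "groups", "stats"}, "design.discrete")
        if not section.get("groups"):
            raise ConfigError("design.discrete.groups is required")
        for label, g in section["groups"].items():
            _check_keys(
                dict(g), {"n", "fold_changes", "sd_ratios", "stats"}, f"design.discrete.groups.{label}"
            )
    else:
        _check_keys(
            section,
            {"n", "response_mean", "response_sd", "response_name", "metabolites"},
            "design.continuous",
        )
        for key in ("n", "response_mean", "response_sd", "metabolites"):
            if key not in section:
                raise ConfigError(f"design.continuous.{key} is required")

    return RunConfig(
        library_path=lib.get("path"),
        fixture=fixture,
        mixture=mixture,
        design_section=section,
        design_kind=kind,
        seed=seed,
        log_level=str(doc.get("log_level", "INFO")),
        raw=doc,
    )


def _build_library(config: RunConfig) -> Library:
    if config.library_path is not None:
        return load_library(config.library_path)
    fx = dict(config.fixture or {})
    n_points = int(fx.get("grid_points", 2**15))
    axis = make_ppm_axis(n_points=n_points)
    axis_2d = make_ppm_axis(n_points=int(fx.get("grid_points_2d", 1024)))
    return make_toy_library(
        n_metabolites=int(fx.get("n_metabolites", 5)),
        seed=int(fx.get("seed", config.seed)),
        biofluid=str(fx.get("biofluid", config.mixture.biofluid)),
        axis=axis,
        with_2d=bool(fx.get("with_2d", True)),
        axis_2d=axis_2d,
    )


def _build_design(
    config: RunConfig, library: Library
) -> Union[DiscreteDesign, ContinuousDesign]:
    section = config.design_section
    ids = config.mixture.metabolite_ids or library.ids()
    if config.design_kind == "continuous":
        metabolites = {}
        for mid, m in section["metabolites"].items():
            _check_keys(dict(m), {"x_mean", "x_sd", "a", "eps_sd"}, f"continuous.{mid}")
            metabolites[mid] = MetaboliteResponse(
                x_mean=float(m["x_mean"]),
                x_sd=float(m["x_sd"]),
                a=float(m.get("a", 0.0)),
                eps_sd=float(m.get("eps_sd", 0.0)),
            )
        return ContinuousDesign(
            n=int(section["n"]),
            response_mean=float(section["response_mean"]),
            response_sd=float(section["response_sd"]),
            metabolites=metabolites,
            seed=config.seed,
            response_name=str(section.get("response_name", "response")),
        )
    condition = str(section.get("condition", "normal"))
    biofluid = config.mixture.biofluid
    if "stats" in section:
        normal_stats = {
            mid: ConditionStats(float(s["mean"]), float(s["sd"]), condition, biofluid)
            for mid, s in section["stats"].items()
        }
    else:
        normal_stats = {mid: library[mid].stats_for(condition, biofluid) for mid in ids}
    groups = {}
    for label, g in section["groups"].items():
        stats = None
        if "stats" in g:
            stats = {
                mid: ConditionStats(float(s["mean"]), float(s["sd"]), label, biofluid)
                for mid, s in g["stats"].items()
            }
        groups[label] = GroupSpec(
            n=int(g["n"]),
            stats=stats,
            fold_changes={k: float(v) for k, v in (g.get("fold_changes") or {}).items()},
            sd_ratios={k: float(v) for k, v in (g.get("sd_ratios") or {}).items()},
        )
    return DiscreteDesign(
        metabolite_ids=list(ids), normal_stats=normal_stats, groups=groups, seed=config.seed
    )


def _write_spectrum(path: Path, spectrum) -> None:
    grid = spectrum.grid
    if isinstance(grid, SpectrumGrid1D):
        np.savetxt(
            path,
            np.column_stack([grid.ppm_axis, grid.intensity]),
            fmt="%.17g",
            delimiter="\t",
            header="ppm\tintensity",
            comments="",
        )
    else:
        with open(path, "w") as fh:
            fh.write("#mode\t" + grid.mode + "\n")
            fh.write("f1\\f2\t" + "\t".join(f"{v:.17g}" for v in grid.f2_axis) + "\n")
            for i, f1 in enumerate(grid.f1_axis):
                fh.write(f"{f1:.17g}\t" + "\t".join(f"{v:.17g}" for v in grid.intensity[i]) + "\n")


def run(config: RunConfig, out_dir: Union[str, Path]) -> CohortResult:
    """Execute a run config end to end and write all artifacts.

    Writes per-replicate spectra, the label/concentration table, a
    provenance sidecar and a manifest whose replay reproduces the outputs
    bit-identically.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = _build_library(config)
    design = _build_design(config, library)
    result = simulate_cohort(library, design, config.mixture)

    for i, spectrum in enumerate(result.spectra):
        _write_spectrum(out / f"replicate_{i:04d}.tsv", spectrum)
    result.table.to_frame().to_csv(out / "labels.tsv", sep="\t", index_label="replicate")
    provenance = {
        "seed": config.seed,
        "mode": config.mixture.mode,
        "replicates": [
            {
                "index": i,
                "concentrations": s.concentrations,
                "ph": s.ph,
                "shifts": s.shifts,
                "clean_max": s.clean_max,
            }
            for i, s in enumerate(result.spectra)
        ],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    # key order is semantic (groups are simulated in declaration order),
    # so the manifest must not sort keys
    manifest = {"config": config.raw, "seed": config.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def checksum_dir(path: Union[str, Path]) -> dict[str, str]:
    """SHA-256 of every file in a run output directory (reproducibility checks)."""
    out = {}
    for p in sorted(Path(path).iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
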