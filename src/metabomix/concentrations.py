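"""Per-replicate metabolite concentration simulation.

Two cohort designs are supported:

* **Discrete (case-control)**: each group's concentrations are truncated
  normals with group-specific (mean, SD), obtained either directly or by
  applying a fold change / SD ratio to the baseline ("normal") group.
  Optional inter-metabolite correlation is imposed with a Gaussian copula.

* **Continuous response**: a response y (e.g. BMI) is drawn
  N(response_mean, response_sd^2); each metabolite's standardized
  concentration is z_x = a * z_y + eps with eps ~ N(0, eps_sd^2), where
  z_y standardizes y by its *sample* mean and SD. With
  eps_sd = sqrt(1 - a^2) the population correlation between x and y is
  exactly a; a user-set eps_sd instead realizes a / sqrt(a^2 + eps_sd^2).

All concentrations are truncated at zero (physical non-negativity) and
every draw is deterministic given the design seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .library import ConditionStats, LibraryError

__all__ = [
    "CorrelationSpec",
    "GroupSpec",
    "DiscreteDesign",
    "MetaboliteResponse",
    "ContinuousDesign",
    "ConcentrationTable",
    "DesignError",
    "sample_truncated_normal",
    "sample_correlated",
    "apply_condition",
    "sample_discrete",
    "sample_continuous",
]

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised for invalid study designs."""


@dataclass
class CorrelationSpec:
    """Target inter-metabolite Pearson correlation matrix."""

    metabolite_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.metabolite_ids)
        if self.matrix.shape != (k, k):
            raise DesignError("correlation matrix shape must match metabolite count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise DesignError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-12):
            raise DesignError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.matrix) > 1.0 + 1e-12):
            raise DesignError("correlation entries must lie in [-1, 1]")


@dataclass
class GroupSpec:
    """One group of a discrete design.

    Either explicit per-metabolite stats, or fold changes / SD ratios
    relative to the baseline group (missing entries default to 1.0).
    """

    n: int
    stats: Optional[dict[str, ConditionStats]] = None
    fold_changes: dict[str, float] = field(default_factory=dict)
    sd_ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DesignError("group size must be >= 1")
        for mid, fc in self.fold_changes.items():
            if not fc > 0:
                raise DesignError(f"fold change for {mid!r} must be > 0")
        for mid, sr in self.sd_ratios.items():
            if not sr >= 0:
                raise DesignError(f"SD ratio for {mid!r} must be >= 0")


@dataclass
class DiscreteDesign:
    """Case-control design: baseline stats plus one spec per group."""

    metabolite_ids: list[str]
    normal_stats: dict[str, ConditionStats]
    groups: dict[str, GroupSpec]
    correlation: Optional[CorrelationSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise DesignError("need at least one group")
        missing = [m for m in self.metabolite_ids if m not in self.normal_stats]
        if missing:
            raise DesignError(f"no baseline stats for metabolites {missing}")
        for label, g in self.groups.items():
            for mid in list(g.fold_changes) + list(g.sd_ratios):
                if mid not in self.metabolite_ids:
                    raise DesignError(
                        f"group {label!r} references unknown metabolite {mid!r}"
                    )
            if g.stats is not None:
                missing = [m for m in self.metabolite_ids if m not in g.stats]
                if missing:
                    raise DesignError(f"group {label!r} lacks stats for {missing}")
        if self.correlation is not None and set(self.correlation.metabolite_ids) != set(
            self.metabolite_ids
        ):
            raise DesignError("correlation spec metabolites do not match design")

    def group_stats(self, label: str) -> dict[str, ConditionStats]:
        g = self.groups[label]
        if g.stats is not None:
            return g.stats
        out = {}
        for mid in self.metabolite_ids:
            out[mid] = apply_condition(
                self.normal_stats[mid],
                g.fold_changes.get(mid, 1.0),
                g.sd_ratios.get(mid, 1.0),
            )
        return out


@dataclass(frozen=True)
class MetaboliteResponse:
    """One metabolite's marginal stats and response association."""

    x_mean: float
    x_sd: float
    a: float = 0.0  # target Pearson correlation with the response
    eps_sd: float = 0.0  # SD of the error on the standardized scale

    def __post_init__(self) -> None:
        if abs(self.a) > 1.0:
            raise DesignError("|a| must be <= 1")
        if self.eps_sd < 0:
            raise DesignError("eps_sd must be >= 0")
        if self.x_sd < 0:
            raise DesignError("x_sd must be >= 0")


@dataclass
class ContinuousDesign:
    """Continuous-outcome design (response y, e.g. BMI)."""

    n: int
    response_mean: float
    response_sd: float
    metabolites: dict[str, MetaboliteResponse]
    seed: int = 0
    response_name: str = "response"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DesignError("continuous designs need n >= 3 (sample-SD standardization)")
        if not self.response_sd > 0:
            raise DesignError("response_sd must be > 0")
        if not self.metabolites:
            raise DesignError("need at least one metabolite")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)


@dataclass
class ConcentrationTable:
    """Replicate x metabolite concentrations plus the supervised labels."""

    concentrations: pd.DataFrame  # rows: replicates; columns: metabolite ids
    labels: pd.Series  # group label per replicate, or response value
    seed: int
    label_kind: str = "group"  # "group" | "response"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.concentrations):
            raise DesignError("labels and concentration rows must align")
        if (self.concentrations.to_numpy() < 0).any():
            raise DesignError("concentrations must be non-negative")

    @property
    def n(self) -> int:
        return len(self.concentrations)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.concentrations.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.concentrations.copy()
        out[self.label_kind] = self.labels.to_numpy()
        return out


def sample_truncated_normal(
    mean: float,
    sd: float,
    n: int,
    rng: np.random.Generator | int,
    lower: float = 0.0,
) -> np.ndarray:
    """Draw n values from N(mean, sd^2) conditioned on being >= lower."""
    if sd < 0:
        raise DesignError("sd must be >= 0")
    if n < 1:
        raise DesignError("n must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if sd == 0:
        if mean < lower:
            raise DesignError(f"degenerate distribution at {mean} has no mass >= {lower}")
        return np.full(n, float(mean))
    alpha = (lower - mean) / sd
    return sps.truncnorm.rvs(alpha, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def apply_condition(normal: ConditionStats, fold_change: float, sd_ratio: float) -> ConditionStats:
    """Map baseline stats to an abnormal condition's stats."""
    if not fold_change > 0:
        raise DesignError("fold_change must be > 0")
    if not sd_ratio >= 0:
        raise DesignError("sd_ratio must be >= 0")
    return ConditionStats(
        mean=normal.mean * fold_change,
        sd=normal.sd * sd_ratio,
        condition=normal.condition,
        biofluid=normal.biofluid,
    )


def repair_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest-ish valid correlation matrix.

    A matrix that is already positive semi-definite is returned unchanged;
    otherwise negative eigenvalues are clipped at ``eps`` and the result is
    rescaled back to unit diagonal (the repair is logged).
    """
    R = np.asarray(R, dtype=float)
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() >= -1e-12:
        return R
    logger.warning(
        "correlation matrix not positive semi-definite (min eigenvalue %.3g); repairing",
        eigvals.min(),
    )
    w, v = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def sample_correlated(
    stats: Mapping[str, ConditionStats],
    correlation: CorrelationSpec,
    n: int,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Correlated concentration draws via a Gaussian copula.

    Draw multivariate normal with the (repaired) target correlation, map
    each marginal to its stated (mean, SD), then clip at zero. Clipping
    perturbs marginals and correlations negligibly when mean/SD >= 3.
    """
    ids = correlation.metabolite_ids
    missing = [m for m in ids if m not in stats]
    if missing:
        raise DesignError(f"stats missing for metabolites {missing}")
    if set(stats) != set(ids):
        extra = sorted(set(stats) - set(ids))
        raise DesignError(f"correlation spec missing metabolites {extra}")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    R = repair_correlation(correlation.matrix)
    z = rng.multivariate_normal(np.zeros(len(ids)), R, size=n, method="cholesky")
    data = {}
    for j, mid in enumerate(ids):
        s = stats[mid]
        data[mid] = np.clip(s.mean + s.sd * z[:, j], 0.0, None)
    return pd.DataFrame(data, columns=list(ids))


def sample_discrete(design: DiscreteDesign, rng: Optional[np.random.Generator] = None) -> ConcentrationTable:
    """Simulate a case-control concentration table.

    Groups are emitted in design order; within a group, metabolites are
    independent truncated normals unless a correlation spec is given.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    frames, labels = [], []
    for label, g in design.groups.items():
        stats = design.group_stats(label)
        if design.correlation is not None:
            frame = sample_correlated(stats, design.correlation, g.n, rng)
            frame = frame[design.metabolite_ids]
        else:
            cols = {
                mid: sample_truncated_normal(stats[mid].mean, stats[mid].sd, g.n, rng)
                for mid in design.metabolite_ids
            }
            frame = pd.DataFrame(cols, columns=design.metabolite_ids)
        frames.append(frame)
        labels.extend([label] * g.n)
    table = pd.concat(frames, ignore_index=True)
    return ConcentrationTable(
        concentrations=table,
        labels=pd.Series(labels, name="group"),
        seed=design.seed,
        label_kind="group",
    )


def sample_continuous(design: ContinuousDesign, rng: Optional[np.random.Generator] = None) -> ConcentrationTable:
    """Simulate concentrations linearly associated with a continuous response."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    n = design.n
    y = rng.normal(design.response_mean, design.response_sd, size=n)
    y_sd = float(np.std(y, ddof=1))
    if y_sd == 0:
        raise DesignError("drawn response has zero sample SD")
    z_y = (y - y.mean()) / y_sd
    data = {}
    for mid, m in design.metabolites.items():
        eps = rng.normal(0.0, m.eps_sd, size=n) if m.eps_sd > 0 else np.zeros(n)
        z_x = m.a * z_y + eps
        if m.a != 0 and m.eps_sd > 0:
            realized = m.a / np.sqrt(m.a**2 + m.eps_sd**2)
            logger.info(
                "metabolite %s: target a=%.3f with eps_sd=%.3f realizes correlation %.3f",
                mid,
                m.a,
                m.eps_sd,
                realized,
            )
        data[mid] = np.clip(m.x_mean + m.x_sd * z_x, 0.0, None)
    return ConcentrationTable(
        concentrations=pd.DataFrame(data, columns=design.metabolite_ids),
        labels=pd.Series(y, name=design.response_name),
        seed=design.seed,
        label_kind="response",
    )
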