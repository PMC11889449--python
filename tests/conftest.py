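import numpy as np
import pytest

from metabomix import (
    ConditionStats,
    MultipletSpec,
    ToyMetaboliteSpec,
    build_library,
    make_ppm_axis,
    make_toy_library,
)

# compact grids keep the suite fast; resolution-sensitive checks scale
# tolerances accordingly
AXIS_N = 4096
AXIS_2D_N = 512


@pytest.fixture(scope="session")
def axis():
    return make_ppm_axis(n_points=AXIS_N)


@pytest.fixture(scope="session")
def axis_2d():
    return make_ppm_axis(n_points=AXIS_2D_N)


@pytest.fixture(scope="session")
def toy_library(axis, axis_2d):
    """5 random toy metabolites, urine, deterministic."""
    return make_toy_library(5, seed=42, biofluid="urine", axis=axis, axis_2d=axis_2d)


@pytest.fixture(scope="session")
def blood_library(axis, axis_2d):
    return make_toy_library(4, seed=7, biofluid="blood", axis=axis, axis_2d=axis_2d)


def separated_specs(n, biofluid="urine", a_values=None):
    """n singlet metabolites with non-overlapping, evenly spaced peaks.

    Centers run from 1.0 to 8.6 ppm avoiding the water window, so each
    metabolite owns an exclusive +-0.2 ppm spectral region.
    """
    centers = [c for c in np.linspace(1.0, 8.6, n + 2) if not (4.3 <= c <= 5.2)][:n]
    assert len(centers) == n, "not enough water-free centers; increase the span"
    specs = []
    for i, c in enumerate(centers):
        stats = (
            ConditionStats(200.0, 20.0, condition="normal", biofluid=biofluid),
            ConditionStats(400.0, 20.0, condition="case", biofluid=biofluid),
        )
        specs.append(
            ToyMetaboliteSpec(
                id=f"sep{i:02d}",
                name=f"separated singlet {i}",
                protons=2,
                multiplets=(MultipletSpec(center=float(c), pattern="s", protons_weight=2.0),),
                stats=stats,
            )
        )
    return specs


@pytest.fixture(scope="session")
def separated_library(axis):
    """5 well-separated singlets (exclusive integration regions)."""
    return build_library(separated_specs(5), axis=axis, with_2d=False)
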