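"""Shared fixtures: canonical geometric outlines, synthetic cohorts and a
small fitted morphospace with its theoretical grid."""

from __future__ import annotations

import numpy as np
import pytest

from wingmorph.efa import efa_forward
from wingmorph.morphospace import build_grid, fit_morphospace
from wingmorph.outline import Outline, canonicalise
from wingmorph.performance import PerformanceSurface
from wingmorph.synthetic import (
    DEFAULT_SDS,
    STYLE_PRESETS,
    CohortSpec,
    generate_cohort,
)


def square(side: float = 1.0) -> Outline:
    return canonicalise([[0, 0], [side, 0], [side, side], [0, side]])


def rectangle(R: float, c: float) -> Outline:
    return canonicalise([[0, 0], [R, 0], [R, c], [0, c]])


def circle(r: float = 1.0, n: int = 360) -> Outline:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return canonicalise(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def ellipse(a: float, b: float, n: int = 720) -> Outline:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return canonicalise(np.column_stack([a * np.cos(th), b * np.sin(th)]))


def star_polygon(rng: np.random.Generator, n: int = 20) -> Outline:
    """Random simple polygon: radial perturbation around sorted angles."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.3, 1.0, n)
    return canonicalise(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def fake_grid(valid: np.ndarray, outlines=None):
    """Hand-built TheoreticalGrid over unit-spaced PC lattices, for testing
    surface arithmetic without a fitted model."""
    from wingmorph.morphospace import TheoreticalGrid

    valid = np.asarray(valid, bool)
    nx, ny = valid.shape
    if outlines is None:
        outlines = np.empty((nx, ny), dtype=object)
    return TheoreticalGrid(
        pc1_values=np.arange(nx, dtype=float),
        pc2_values=np.arange(ny, dtype=float),
        outlines=outlines,
        valid=valid,
        expansion=0.0,
        n_points=0,
        model=None,
    )


def fake_surface(grid, norm: np.ndarray, direction="high_optimal", metric="AR"):
    norm = np.where(grid.valid, np.asarray(norm, float), np.nan)
    best = np.nanmax(norm)
    ix, iy = np.nonzero(grid.valid & (norm == best))
    return PerformanceSurface(
        grid=grid,
        metric_name=metric,
        direction=direction,
        raw=norm.copy(),
        norm=norm,
        peak_idx=(int(ix[0]), int(iy[0])),
    )


@pytest.fixture(scope="session")
def mixed_cohort():
    """Five-style synthetic cohort (n=40) at 300 landmarks."""
    styles = [
        "marine_soaring",
        "hovering",
        "burst_flapping",
        "thermal_soaring",
        "aerial_predation",
    ]
    rng = np.random.default_rng(99)
    cohorts = []
    for st in styles:
        means = STYLE_PRESETS[st].__class__(
            **{**STYLE_PRESETS[st].__dict__, "n_points": 300}
        )
        cohorts += generate_cohort(
            CohortSpec(st, 8, means, dict(DEFAULT_SDS), seed=int(rng.integers(2**31)))
        )
    return cohorts


@pytest.fixture(scope="session")
def fitted_space(mixed_cohort):
    """Morphospace fitted on the mixed cohort (H=5)."""
    hsets = [efa_forward(o, 5) for o, _ in mixed_cohort]
    return hsets, fit_morphospace(hsets)


@pytest.fixture(scope="session")
def small_grid(fitted_space):
    """12x11 theoretical grid at 300 landmarks over the fitted space."""
    _, model = fitted_space
    return build_grid(model, nx=12, ny=11, expansion=0.20, n_points=300)
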