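"""Optimality of labelled shape sets relative to performance surfaces.

A taxon's optimality is read off a surface at its (PC1, PC2) position; its
distance from the functional optimum is measured in performance value (peak
value minus its value), not in Euclidean morphospace distance — two shapes
equidistant from the peak in PC space can differ greatly in performance. On
normalised surfaces distance and "percentage similarity" are complements:
similarity = 1 - distance.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import OutOfBoundsError, ParameterError
from .morphospace import TheoreticalGrid
from .pareto import ParetoSurface, build_pareto_surface
from .performance import AgilityParams, PerformanceSurface, build_surface

__all__ = [
    "TaxonRecord",
    "surface_value_at",
    "group_peak_distance",
    "style_report",
    "load_style_config",
    "default_style_config",
    "style_convex_hulls",
]


@dataclass
class TaxonRecord:
    """One specimen projected into morphospace, with its group labels."""

    taxon_id: str
    pc: np.ndarray  # (>=2,) PC coordinates; only PC1, PC2 are used
    style: str | None = None
    order: str | None = None
    in_impossible_space: bool = field(default=False, compare=False)


def _values_and_valid(surface: PerformanceSurface | ParetoSurface):
    return surface.norm, surface.grid


def surface_value_at(
    surface: PerformanceSurface | ParetoSurface, pc
) -> float:
    """Surface value at a (PC1, PC2) position.

    Bilinear interpolation over the enclosing grid cell; if any corner of
    the cell is invalid (impossible space) the nearest valid node's value is
    used instead. Positions outside the grid bounds raise
    :class:`OutOfBoundsError`.
    """
    values, grid = _values_and_valid(surface)
    p1, p2 = float(pc[0]), float(pc[1])
    g1, g2 = grid.pc1_values, grid.pc2_values
    eps1 = 1e-9 * (g1[-1] - g1[0])
    eps2 = 1e-9 * (g2[-1] - g2[0])
    if not (g1[0] - eps1 <= p1 <= g1[-1] + eps1) or not (
        g2[0] - eps2 <= p2 <= g2[-1] + eps2
    ):
        raise OutOfBoundsError(f"({p1}, {p2}) lies outside the theoretical grid")
    p1 = min(max(p1, g1[0]), g1[-1])
    p2 = min(max(p2, g2[0]), g2[-1])
    ix = min(int(np.searchsorted(g1, p1, side="right") - 1), grid.nx - 2)
    iy = min(int(np.searchsorted(g2, p2, side="right") - 1), grid.ny - 2)
    ix, iy = max(ix, 0), max(iy, 0)
    corners_valid = grid.valid[ix : ix + 2, iy : iy + 2]
    if corners_valid.all():
        t = (p1 - g1[ix]) / (g1[ix + 1] - g1[ix])
        u = (p2 - g2[iy]) / (g2[iy + 1] - g2[iy])
        v = values[ix : ix + 2, iy : iy + 2]
        return float(
            (1 - t) * (1 - u) * v[0, 0]
            + t * (1 - u) * v[1, 0]
            + (1 - t) * u * v[0, 1]
            + t * u * v[1, 1]
        )
    # nearest valid node fallback
    vix, viy = np.nonzero(grid.valid)
    d2 = (g1[vix] - p1) ** 2 + (g2[viy] - p2) ** 2
    k = int(np.argmin(d2))
    return float(values[vix[k], viy[k]])


def group_peak_distance(
    surface: PerformanceSurface | ParetoSurface,
    records: list[TaxonRecord],
    label: str,
) -> tuple[float, float]:
    """Mean performance distance from the surface peak for one labelled
    group, and the complementary mean similarity."""
    members = [r for r in records if r.style == label or r.order == label]
    if not members:
        raise ParameterError(f"no records carry the label {label!r}")
    peak = surface.peak_value
    vals = np.array([surface_value_at(surface, r.pc) for r in members])
    dist = float(np.mean(peak - vals))
    return dist, 1.0 - dist


def default_style_config() -> dict[str, list[tuple[str, str]]]:
    """Table-derived style -> [(metric, direction)] mapping shipped with the
    package."""
    text = resources.files("wingmorph").joinpath("data/flight_styles.toml").read_text()
    return _parse_style_config(tomllib.loads(text))


def load_style_config(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    with open(path, "rb") as fh:
        return _parse_style_config(tomllib.load(fh))


def _parse_style_config(raw: dict) -> dict[str, list[tuple[str, str]]]:
    cfg = {}
    for style, entry in raw.items():
        combo = [(m, d) for m, d in entry["metrics"]]
        if not combo:
            raise ParameterError(f"style {style!r} has an empty metric list")
        cfg[style] = combo
    return cfg


def combination_surface(
    grid: TheoreticalGrid,
    combo: list[tuple[str, str]],
    agility_params: AgilityParams | None = None,
    _cache: dict | None = None,
) -> PerformanceSurface | ParetoSurface:
    """Surface for one metric combination: a single performance surface for
    one metric, a PRR surface for two or more."""

    def base(metric: str, direction: str) -> PerformanceSurface:
        key = (metric, direction)
        if _cache is not None and key in _cache:
            return _cache[key]
        s = build_surface(grid, metric, direction, agility_params)
        if _cache is not None:
            _cache[key] = s
        return s

    if len(combo) == 1:
        return base(*combo[0])
    return build_pareto_surface(grid, [base(m, d) for m, d in combo])


def style_report(
    grid: TheoreticalGrid,
    records: list[TaxonRecord],
    style_config: dict[str, list[tuple[str, str]]] | None = None,
    agility_params: AgilityParams | None = None,
) -> pd.DataFrame:
    """Per-style optimality summary.

    One row per flight style present in the records: member count, mean
    performance distance from the assigned surface's peak, mean similarity,
    and the fraction of members whose value reaches the top decile of the
    surface (90th percentile over valid nodes).
    """
    style_config = style_config or default_style_config()
    styles = sorted({r.style for r in records if r.style is not None})
    missing = [s for s in styles if s not in style_config]
    if missing:
        raise ParameterError(f"styles missing from config: {missing}")
    cache: dict = {}
    rows = []
    for style in styles:
        combo = style_config[style]
        surf = combination_surface(grid, combo, agility_params, _cache=cache)
        members = [r for r in records if r.style == style]
        vals = np.array([surface_value_at(surf, r.pc) for r in members])
        peak = surf.peak_value
        node_vals = surf.norm[grid.valid]
        decile = float(np.percentile(node_vals, 90.0))
        dist = float(np.mean(peak - vals))
        rows.append(
            {
                "style": style,
                "surface": "+".join(
                    f"{m}(LOW)" if (m == "TA" and d == "high_optimal") else m
                    for m, d in combo
                ),
                "n": len(members),
                "mean_distance": dist,
                "mean_similarity": 1.0 - dist,
                "top_decile_fraction": float(np.mean(vals >= decile)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "style",
            "surface",
            "n",
            "mean_distance",
            "mean_similarity",
            "top_decile_fraction",
        ],
    )


def style_convex_hulls(records: list[TaxonRecord]) -> dict[str, np.ndarray]:
    """Convex-hull vertices (PC1, PC2) per flight style, for plotting."""
    from scipy.spatial import ConvexHull

    hulls = {}
    for style in sorted({r.style for r in records if r.style is not None}):
        pts = np.array([r.pc[:2] for r in records if r.style == style])
        if len(pts) < 3:
            hulls[style] = pts
            continue
        hull = ConvexHull(pts)
        hulls[style] = pts[hull.vertices]
    return hulls
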