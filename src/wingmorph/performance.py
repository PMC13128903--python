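"""Flight-performance proxies on planform outlines and performance surfaces.

Four metrics, each computable from the outline alone (no mass or absolute
size, which theoretical shapes do not have):

AR   aspect ratio R^2/S — cost-of-transport proxy (high = cheap flight).
2MA  non-dimensional second moment of area sqrt(r2/(S R^2)) — spanwise area
     distribution about the root; manoeuvrability proxy.
PA   pitch agility — capacity to go pitch-unstable and initiate manoeuvres;
     relative values only (mass held constant).
TA   tip angle — interior angle at the planform tip in degrees; acute tips
     shed tip vortices (drag reduction), broad tips favour lift.

A PerformanceSurface evaluates one metric on every valid node of a
theoretical grid and min–max normalises over valid nodes; for metrics whose
low end is optimal the normalised value is inverted so that 1 is always "most
optimal" and the peak is the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateOutlineError, ParameterError
from .morphospace import TheoreticalGrid
from .outline import Outline

__all__ = [
    "AgilityParams",
    "aspect_ratio",
    "second_moment",
    "second_moment_nondim",
    "pitch_agility",
    "tip_angle",
    "PerformanceSurface",
    "build_surface",
    "METRICS",
]


def aspect_ratio(outline: Outline) -> float:
    """R^2 / S with R the spanwise extent and S the planform area."""
    S = outline.area
    if S <= 0.0:
        raise DegenerateOutlineError("zero-area outline")
    return outline.span ** 2 / S


def second_moment(outline: Outline) -> float:
    """Second moment of area about the chordwise axis through the root.

    Polygon formula r2 = (1/12) sum (x_i y_{i+1} - x_{i+1} y_i)
    (x_i^2 + x_i x_{i+1} + x_{i+1}^2), evaluated after translating the root
    (minimum x) to x = 0 and orienting counterclockwise.
    """
    pts = outline.points
    if outline.signed_area == 0.0:
        raise DegenerateOutlineError("degenerate polygon")
    if outline.signed_area < 0.0:
        pts = pts[::-1]
    x = pts[:, 0] - pts[:, 0].min()
    y = pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    return float(np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0)


def second_moment_nondim(outline: Outline) -> float:
    """sqrt(r2 / (S R^2)); invariant to uniform scaling."""
    S = outline.area
    R = outline.span
    if S <= 0.0 or R <= 0.0:
        raise DegenerateOutlineError("zero area or span")
    return float(np.sqrt(second_moment(outline) / (S * R * R)))


@dataclass(frozen=True)
class AgilityParams:
    """Settings for the pitch-agility metric.

    m is a dimensionless mass constant (theoretical shapes carry no real
    mass; held at 1 so the (m^0.12)^2 factor is neutral). n_strips is the
    number of equidistant strips used for the mean-quarter-chord estimate;
    100 is past convergence (100 vs 200 differ < 0.5% on smooth planforms).
    axis selects the reference frame: "spanwise" (default) takes the x axis
    literally as the strip axis with the rotation point at minimum x;
    "chordwise" is the aerodynamically conventional alternative with the
    roles of the axes swapped.
    """

    m: float = 1.0
    n_strips: int = 100
    axis: str = "spanwise"

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ParameterError("m must be > 0")
        if self.n_strips < 10:
            raise ParameterError("n_strips must be >= 10")
        if self.axis not in ("spanwise", "chordwise"):
            raise ParameterError("axis must be 'spanwise' or 'chordwise'")


def _strip_stats(pts: np.ndarray, n_strips: int):
    """Chord statistics on equidistant strips along the x axis.

    For each strip midline, intersects the vertical line with the polygon
    boundary: chord = extent between outermost crossings, material = summed
    in-polygon crossing intervals (the weight), leading edge = topmost
    crossing. Returns (chords, materials, y_le) for non-empty strips.
    """
    x0, x1 = pts[:, 0].min(), pts[:, 0].max()
    width = (x1 - x0) / n_strips
    mids = x0 + width * (np.arange(n_strips) + 0.5)
    xa, ya = pts[:, 0], pts[:, 1]
    xb, yb = np.roll(xa, -1), np.roll(ya, -1)
    chords, materials, y_les = [], [], []
    for xm in mids:
        # half-open crossing rule: robust when vertices lie on the midline
        hit = ((xa <= xm) & (xb > xm)) | ((xb <= xm) & (xa > xm))
        if hit.sum() < 2:
            continue
        tt = (xm - xa[hit]) / (xb[hit] - xa[hit])
        ys = np.sort(ya[hit] + tt * (yb[hit] - ya[hit]))
        chords.append(ys[-1] - ys[0])
        # crossings alternate outside->inside; pair them up
        inside = ys.reshape(-1, 2) if len(ys) % 2 == 0 else ys[:-1].reshape(-1, 2)
        materials.append(float(np.sum(inside[:, 1] - inside[:, 0])))
        y_les.append(ys[-1])
    if not chords:
        raise DegenerateOutlineError("no strip intersects the planform")
    return np.array(chords), np.array(materials), np.array(y_les)


def pitch_agility(outline: Outline, params: AgilityParams | None = None) -> float:
    """Relative pitch agility of a planform.

    [ ((x_qc / c_rmax)^0.8 * c_rmax) - x_CG ] * (m^0.12)^2 * S / I_yy, where
    x_qc is the area-weighted mean quarter-chord position (strip leading edge
    offset from the global leading edge plus a quarter of the strip chord),
    c_rmax the maximum strip chord, x_CG the rotation point (minimum
    coordinate on the reference axis, 0 after rooting), S the planform area
    and I_yy the second moment of area about the rotation axis.
    """
    params = params or AgilityParams()
    pts = outline.points
    if params.axis == "chordwise":
        pts = pts[:, ::-1]
        work = Outline(pts)
    else:
        work = outline
    pts = pts.copy()
    pts[:, 0] -= pts[:, 0].min()

    chords, materials, y_le = _strip_stats(pts, params.n_strips)
    c_rmax = float(chords.max())
    if c_rmax <= 0.0:
        raise DegenerateOutlineError("zero maximum strip chord")
    # chordwise positions measured aft of the global leading edge
    le_offset = pts[:, 1].max() - y_le
    quarter = le_offset + 0.25 * chords
    w = materials.sum()
    if w <= 0.0:
        raise DegenerateOutlineError("zero material area across strips")
    x_qc = float(np.sum(quarter * materials) / w)
    x_cg = 0.0  # rooted at the minimum reference-axis coordinate

    i_yy = second_moment(Outline(pts))
    if i_yy <= 0.0:
        raise DegenerateOutlineError("zero second moment about the rotation axis")
    s_max = work.area
    bracket = (x_qc / c_rmax) ** 0.8 * c_rmax - x_cg
    return float(bracket * (params.m**0.12) ** 2 * s_max / i_yy)


def tip_angle(outline: Outline, offset: int = 500) -> float:
    """Interior angle at the planform tip, in degrees (0, 180].

    The tip is the rightmost landmark; where several landmarks tie for
    maximum x (bifurcated tips) the leading-edge point — greatest y — is
    chosen. The angle is measured between the vectors from the tip to the
    landmarks ``offset`` index positions away along the loop in each
    direction. The offset is defined against the canonical 1200-landmark
    outline and scales proportionally for other landmark counts.
    """
    pts = outline.points
    n = outline.n
    eff = offset if n == 1200 else max(1, round(offset * n / 1200))
    if n < 2 * eff + 1:
        raise ParameterError(
            f"outline has {n} landmarks; needs >= {2 * eff + 1} for offset {eff}"
        )
    span = outline.span or 1.0
    near = np.nonzero(pts[:, 0] >= pts[:, 0].max() - 1e-9 * span)[0]
    tip = near[np.argmax(pts[near, 1])]
    v1 = pts[(tip - eff) % n] - pts[tip]
    v2 = pts[(tip + eff) % n] - pts[tip]
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateOutlineError("offset landmark coincides with the tip")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    return 180.0 if ang == 0.0 else ang


METRICS = {
    "AR": lambda o, ap: aspect_ratio(o),
    "2MA": lambda o, ap: second_moment_nondim(o),
    "PA": lambda o, ap: pitch_agility(o, ap),
    "TA": lambda o, ap: tip_angle(o),
}

#: default optimality direction per metric (Table-style conventions: acute
#: tips are the default optimum; inverted "TA(LOW)" styles flip it).
DEFAULT_DIRECTIONS = {"AR": "high_optimal", "2MA": "high_optimal",
                      "PA": "high_optimal", "TA": "low_optimal"}


@dataclass
class PerformanceSurface:
    """One metric evaluated over a theoretical grid.

    ``raw`` holds metric values (NaN on invalid nodes); ``norm`` is the
    min–max normalised, optimality-oriented value in [0, 1] (1 = most
    optimal; already inverted for low_optimal metrics). ``peak_idx`` is the
    (ix, iy) of the oriented maximum, ties broken by lowest ix then iy.
    """

    grid: TheoreticalGrid
    metric_name: str
    direction: str
    raw: np.ndarray
    norm: np.ndarray
    peak_idx: tuple[int, int]
    degenerate: bool = False

    @property
    def peak_value(self) -> float:
        return float(self.norm[self.peak_idx])

    @property
    def peak_coords(self) -> tuple[float, float]:
        return self.grid.node_coords(*self.peak_idx)


def _argmax_lex(values: np.ndarray, valid: np.ndarray) -> tuple[int, int]:
    """First (ix, iy) in lexicographic order attaining the max over valid."""
    best = np.nanmax(np.where(valid, values, -np.inf))
    ix, iy = np.nonzero(valid & (values == best))
    return int(ix[0]), int(iy[0])


def build_surface(
    grid: TheoreticalGrid,
    metric_name: str,
    direction: str | None = None,
    agility_params: AgilityParams | None = None,
) -> PerformanceSurface:
    """Evaluate one metric over every valid grid node and normalise.

    direction defaults to the metric's conventional orientation
    (high_optimal for AR/2MA/PA, low_optimal for TA).
    """
    if metric_name not in METRICS:
        raise ParameterError(f"unknown metric {metric_name!r}")
    direction = direction or DEFAULT_DIRECTIONS[metric_name]
    if direction not in ("high_optimal", "low_optimal"):
        raise ParameterError(f"unknown direction {direction!r}")
    if not grid.valid.any():
        raise ParameterError("grid has no valid nodes")
    fn = METRICS[metric_name]
    raw = np.full((grid.nx, grid.ny), np.nan)
    for ix in range(grid.nx):
        for iy in range(grid.ny):
            if grid.valid[ix, iy]:
                raw[ix, iy] = fn(grid.outlines[ix, iy], agility_params)
    vals = raw[grid.valid]
    lo, hi = float(vals.min()), float(vals.max())
    degenerate = hi - lo <= 0.0
    norm = np.full_like(raw, np.nan)
    if degenerate:
        norm[grid.valid] = 0.0
    else:
        norm[grid.valid] = (raw[grid.valid] - lo) / (hi - lo)
        if direction == "low_optimal":
            norm[grid.valid] = 1.0 - norm[grid.valid]
    peak = _argmax_lex(norm, grid.valid)
    return PerformanceSurface(
        grid=grid,
        metric_name=metric_name,
        direction=direction,
        raw=raw,
        norm=norm,
        peak_idx=peak,
        degenerate=degenerate,
    )
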