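"""Closed planform outlines: container, canonicalisation, file I/O, resampling.

Coordinate convention: x is spanwise with the wing root at minimum x and the
tip at maximum x; y is chordwise with the leading edge on the +y side. A
canonical outline is an open list of distinct vertices traversed
counterclockwise (positive signed area); closure from the last vertex back to
the first is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateOutlineError, FormatError, ParameterError

__all__ = [
    "Outline",
    "canonicalise",
    "read_outline",
    "write_outline_csv",
    "write_outline_tps",
    "resample",
    "mirror_if_left",
]


@dataclass(frozen=True)
class Outline:
    """One closed 2D wing-planform outline.

    ``points`` is an (n, 2) float array of ordered landmarks; the loop closes
    implicitly from the last point to the first.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("outline points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise DegenerateOutlineError("an outline needs at least 3 points")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def span(self) -> float:
        """Spanwise (x) extent, the R of the aspect-ratio formula."""
        return float(self.points[:, 0].max() - self.points[:, 0].min())

    @property
    def chord_extent(self) -> float:
        return float(self.points[:, 1].max() - self.points[:, 1].min())

    def closed_points(self) -> np.ndarray:
        """Vertices with the closure point repeated at the end."""
        return np.vstack([self.points, self.points[:1]])


def _dedupe(pts: np.ndarray, tol: float) -> np.ndarray:
    """Drop consecutive duplicates, including a repeated closure point."""
    keep = np.ones(len(pts), dtype=bool)
    d = np.hypot(*(pts - np.roll(pts, 1, axis=0)).T)
    keep[1:] = d[1:] > tol
    out = pts[keep]
    if len(out) > 1 and np.hypot(*(out[-1] - out[0])) <= tol:
        out = out[:-1]
    return out


def canonicalise(points: np.ndarray | Outline) -> Outline:
    """Return the canonical form: deduplicated, counterclockwise outline.

    Raises :class:`DegenerateOutlineError` for fewer than 3 distinct points or
    zero enclosed area.
    """
    pts = points.points if isinstance(points, Outline) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FormatError("expected an (n, 2) coordinate array")
    scale = float(np.ptp(pts, axis=0).max()) or 1.0
    pts = _dedupe(pts, tol=1e-12 * scale)
    if len(pts) < 3:
        raise DegenerateOutlineError("fewer than 3 distinct points")
    o = Outline(pts)
    if o.signed_area == 0.0:
        raise DegenerateOutlineError("outline encloses zero area")
    if o.signed_area < 0.0:
        o = Outline(pts[::-1].copy())
    return o


# ---------------------------------------------------------------------------
# file I/O


def _read_csv_points(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                rows.append([float(parts[0]), float(parts[1])])
            except (ValueError, IndexError):
                if not rows:  # tolerate a single header line
                    continue
                raise FormatError(f"unparseable coordinate line in {path}: {line!r}")
    if not rows:
        raise FormatError(f"no coordinates found in {path}")
    return np.array(rows, dtype=float)


def _read_tps_points(path: Path) -> np.ndarray:
    """Minimal TPS dialect: LM= count, coordinate pairs, optional SCALE=."""
    pts: list[list[float]] = []
    n_expected = None
    scale = 1.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM="):
                n_expected = int(up.split("=", 1)[1])
            elif up.startswith("SCALE="):
                scale = float(up.split("=", 1)[1])
            elif "=" in up and not up[0].isdigit() and not up[0] in "+-.":
                continue  # ID=, IMAGE= and friends are ignored
            else:
                parts = line.split()
                if len(parts) >= 2:
                    try:
                        pts.append([float(parts[0]), float(parts[1])])
                    except ValueError:
                        raise FormatError(f"bad TPS coordinate line: {line!r}")
    if n_expected is None:
        raise FormatError(f"{path} has no LM= record")
    if len(pts) < n_expected:
        raise FormatError(f"{path}: LM={n_expected} but only {len(pts)} coordinates")
    return np.array(pts[:n_expected], dtype=float) * scale


def read_outline(path: str | Path, format: str | None = None) -> Outline:
    """Read one closed outline from a CSV or TPS file and canonicalise it."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv" or fmt == "txt":
        pts = _read_csv_points(path)
    elif fmt == "tps":
        pts = _read_tps_points(path)
    else:
        raise FormatError(f"unknown outline format {fmt!r}")
    return canonicalise(pts)


def write_outline_csv(outline: Outline, path: str | Path) -> None:
    np.savetxt(path, outline.points, delimiter=",", header="x,y", comments="")


def write_outline_tps(outline: Outline, path: str | Path, id: str = "0") -> None:
    with open(path, "w") as fh:
        fh.write(f"LM={outline.n}\n")
        for x, y in outline.points:
            fh.write(f"{x:.10g} {y:.10g}\n")
        fh.write(f"ID={id}\n")


# ---------------------------------------------------------------------------
# geometry operations


def resample(outline: Outline, n_points: int) -> Outline:
    """Resample to ``n_points`` landmarks equally spaced by arc length.

    Linear interpolation between existing landmarks, starting from the
    original first landmark.
    """
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    closed = outline.closed_points()
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0.0:
        raise DegenerateOutlineError("zero-perimeter outline")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return canonicalise(np.column_stack([x, y]))


def mirror_if_left(outline: Outline, is_left: bool) -> Outline:
    """Reflect a left wing about its mid-span so the tip sits at max x."""
    if not is_left:
        return outline
    pts = outline.points.copy()
    lo, hi = pts[:, 0].min(), pts[:, 0].max()
    pts[:, 0] = (hi + lo) - pts[:, 0]
    return canonicalise(pts)
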