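"""Elliptical Fourier analysis (Kuhl–Giardina) of closed planform outlines.

A closed outline is decomposed into ``H`` harmonically related ellipses; four
coefficients (a_n, b_n, c_n, d_n) per harmonic plus the centroid (DC) terms.
The curve parameter is cumulative chord length, the standard convention for
polygonal outlines. No rotation or starting-point normalisation is applied:
wings are assumed to arrive consistently oriented (root left, leading edge
up), and rotation-normalising would erase the anterior–posterior tip position
variation the shape space is meant to capture.

Size standardisation divides every coefficient by the semi-major axis of the
first elliptic (the first-harmonic ellipse), the conventional size proxy, so
all standardised shapes share a first elliptic of unit semi-major axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateOutlineError, ParameterError
from .outline import Outline, canonicalise

__all__ = [
    "HarmonicSet",
    "efa_forward",
    "efa_inverse",
    "standardise_size",
    "first_elliptic_semi_major",
    "to_feature_vector",
    "from_feature_vector",
    "EllipticalFourierTransform",
]


@dataclass(frozen=True)
class HarmonicSet:
    """Elliptical Fourier coefficients for one outline.

    coeffs: (H, 4) array of rows (a_n, b_n, c_n, d_n).
    dc:     (A0, C0) centroid terms.
    scale:  semi-major axis of the first elliptic before standardisation
            (1.0 for a set that was never standardised against anything).
    """

    coeffs: np.ndarray
    dc: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise ParameterError("coeffs must be an (H, 4) array with H >= 1")
        object.__setattr__(self, "coeffs", c)
        object.__setattr__(self, "dc", (float(self.dc[0]), float(self.dc[1])))

    @property
    def H(self) -> int:
        return self.coeffs.shape[0]


def first_elliptic_semi_major(h: HarmonicSet | np.ndarray) -> float:
    """Semi-major axis of the first-harmonic ellipse (largest singular value
    of the 2x2 first-harmonic coefficient matrix)."""
    c = h.coeffs if isinstance(h, HarmonicSet) else np.asarray(h, float)
    m = np.array([[c[0, 0], c[0, 1]], [c[0, 2], c[0, 3]]])
    return float(np.linalg.svd(m, compute_uv=False)[0])


def efa_forward(outline: Outline, H: int = 5, standardize: bool = True) -> HarmonicSet:
    """Elliptical Fourier coefficients of a canonical closed outline.

    With ``standardize`` (the default) the coefficients — DC terms included —
    are divided by the first elliptic's semi-major axis, which is recorded in
    ``scale``; the returned set then has a unit first elliptic.
    """
    if H < 1:
        raise ParameterError("H must be >= 1")
    if outline.n < 2 * H + 1:
        raise ParameterError(f"need at least {2 * H + 1} landmarks for H={H}")
    closed = outline.closed_points()
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if not np.all(dt > 0):
        raise DegenerateOutlineError("outline has zero-length segments")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise DegenerateOutlineError("zero-perimeter outline")

    # DC terms: mean position over arc length of the piecewise-linear curve.
    mid = 0.5 * (closed[:-1] + closed[1:])
    A0, C0 = (mid * dt[:, None]).sum(axis=0) / T

    n = np.arange(1, H + 1)[:, None]  # (H, 1)
    phase = 2.0 * np.pi * n * t[None, :] / T  # (H, n+1)
    dcos = np.diff(np.cos(phase), axis=1)
    dsin = np.diff(np.sin(phase), axis=1)
    const = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    coeffs = np.column_stack(
        [
            const * (dcos @ vx),
            const * (dsin @ vx),
            const * (dcos @ vy),
            const * (dsin @ vy),
        ]
    )
    h = HarmonicSet(coeffs=coeffs, dc=(A0, C0), scale=1.0)
    return standardise_size(h) if standardize else h


def efa_inverse(h: HarmonicSet, n_points: int = 1200) -> Outline:
    """Evaluate the harmonic sum at ``n_points`` equally spaced parameter
    values and return the canonicalised outline."""
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, h.H + 1)[:, None]
    phase = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phase), np.sin(phase)
    a, b, c, d = h.coeffs.T
    x = h.dc[0] + a @ cos + b @ sin
    y = h.dc[1] + c @ cos + d @ sin
    return canonicalise(np.column_stack([x, y]))


def standardise_size(h: HarmonicSet) -> HarmonicSet:
    """Divide all coefficients by the first elliptic's semi-major axis.

    Idempotent; the accumulated factor is kept in ``scale`` so the original
    size can be recovered.
    """
    s = first_elliptic_semi_major(h)
    if s <= 0.0 or not np.isfinite(s):
        raise DegenerateOutlineError("first elliptic has zero semi-major axis")
    if abs(s - 1.0) < 1e-15:
        return h
    return HarmonicSet(
        coeffs=h.coeffs / s,
        dc=(h.dc[0] / s, h.dc[1] / s),
        scale=h.scale * s,
    )


def to_feature_vector(h: HarmonicSet) -> np.ndarray:
    """Flatten the (H, 4) coefficients row-major into a 4H vector.

    DC terms are excluded: translation is not shape.
    """
    return h.coeffs.reshape(-1).copy()


def from_feature_vector(vec: np.ndarray, H: int | None = None) -> HarmonicSet:
    vec = np.asarray(vec, float).reshape(-1)
    if vec.size % 4 != 0:
        raise ParameterError("feature vector length must be a multiple of 4")
    H = H or vec.size // 4
    if vec.size != 4 * H:
        raise ParameterError("feature vector length does not match H")
    return HarmonicSet(coeffs=vec.reshape(H, 4), dc=(0.0, 0.0), scale=1.0)


class EllipticalFourierTransform(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer: outlines -> (n, 4H) coefficient
    matrix (size-standardised, DC terms excluded).

    Parameters
    ----------
    n_harmonics : number of shape harmonics H (default 5).
    standardize : divide by the first elliptic's semi-major axis (default).
    """

    def __init__(self, n_harmonics: int = 5, standardize: bool = True):
        self.n_harmonics = n_harmonics
        self.standardize = standardize

    def fit(self, X, y=None):  # noqa: D102 — nothing to learn
        if self.n_harmonics < 1:
            raise ParameterError("n_harmonics must be >= 1")
        self.n_features_out_ = 4 * self.n_harmonics
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of Outline. Returns the stacked feature matrix."""
        hs = [
            efa_forward(o, H=self.n_harmonics, standardize=self.standardize)
            for o in X
        ]
        return np.vstack([to_feature_vector(h) for h in hs])

    def harmonic_sets(self, X) -> list[HarmonicSet]:
        return [
            efa_forward(o, H=self.n_harmonics, standardize=self.standardize)
            for o in X
        ]
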