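"""Morphospace construction: PCA over harmonic coefficients, projection,
and the expanded even grid of theoretical planform shapes.

The empirical shapes (as size-standardised elliptical Fourier coefficient
vectors) are summarised by a centred, unscaled PCA. A regular lattice over the
first two principal components, expanded beyond the empirical score range, is
inverse-mapped back to coefficient space (higher PCs held at zero) and each
node's outline reconstructed. Nodes whose reconstructed boundary
self-intersects are geometrically impossible for a real planform and are
masked out of all functional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .efa import (
    HarmonicSet,
    efa_inverse,
    from_feature_vector,
    standardise_size,
    to_feature_vector,
)
from .errors import ParameterError
from .outline import Outline

__all__ = [
    "MorphospacePCA",
    "fit_morphospace",
    "project",
    "inverse_map",
    "TheoreticalGrid",
    "build_grid",
    "self_intersects",
]


class MorphospacePCA(BaseEstimator):
    """Centred PCA over 4H-dimensional harmonic coefficient vectors.

    Fitted attributes
    -----------------
    mean_ : (4H,) coefficient-space mean.
    components_ : (k, 4H) orthonormal loadings, variance-ordered.
    explained_variance_ratio_ : per-PC variance fractions (sum <= 1).
    scores_ : (n, k) training scores; mean_ + scores_ @ components_
        reproduces the training matrix.
    n_harmonics_ : H inferred from the feature dimension.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ParameterError("need at least 3 specimens to fit a morphospace")
        if X.shape[1] % 4 != 0:
            raise ParameterError("feature dimension must be 4*H")
        k = self.n_components or min(X.shape[0] - 1, X.shape[1])
        self._pca = PCA(n_components=k, svd_solver="full")
        self.scores_ = self._pca.fit_transform(X)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.n_harmonics_ = X.shape[1] // 4
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.shape[0]:
            raise ParameterError("feature dimension does not match the fitted model")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return self.mean_ + scores @ self.components_

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.scores_


def fit_morphospace(harmonics: list[HarmonicSet]) -> MorphospacePCA:
    """Fit the morphospace PCA from per-specimen harmonic sets (all sharing
    the same H, size-standardised; DC terms excluded)."""
    if len(harmonics) < 3:
        raise ParameterError("need at least 3 specimens")
    Hs = {h.H for h in harmonics}
    if len(Hs) != 1:
        raise ParameterError(f"mixed harmonic counts across specimens: {sorted(Hs)}")
    X = np.vstack([to_feature_vector(h) for h in harmonics])
    return MorphospacePCA().fit(X)


def project(model: MorphospacePCA, h: HarmonicSet) -> np.ndarray:
    """PC coordinates of one harmonic set under a fitted model."""
    if h.H != model.n_harmonics_:
        raise ParameterError("harmonic count does not match the fitted model")
    return model.transform(to_feature_vector(h)[None, :])[0]


def inverse_map(
    model: MorphospacePCA, pc1: float, pc2: float, n_points: int = 1200
) -> Outline:
    """Theoretical outline at (PC1, PC2), higher PCs held at zero.

    The coefficient vector mean_ + pc1*L1 + pc2*L2 is re-standardised to a
    unit first elliptic (keeping every theoretical shape identically size
    scaled) and evaluated at ``n_points`` landmarks.
    """
    vec = model.mean_ + pc1 * model.components_[0] + pc2 * model.components_[1]
    h = standardise_size(from_feature_vector(vec, H=model.n_harmonics_))
    return efa_inverse(h, n_points=n_points)


def self_intersects(outline: Outline) -> bool:
    """True iff any two non-adjacent boundary segments cross or touch.

    A single shared point (pinch) counts as intersecting: it is the limit of
    the split-point morphology and equally impossible for a real planform.
    """
    ring = LineString(outline.closed_points())
    return not ring.is_simple


@dataclass
class TheoreticalGrid:
    """Even lattice of theoretical planform shapes over PC1 x PC2.

    Arrays are indexed [ix, iy] with ix along PC1 and iy along PC2. ``valid``
    is False where the reconstructed outline self-intersects (impossible
    space).
    """

    pc1_values: np.ndarray
    pc2_values: np.ndarray
    outlines: np.ndarray  # (nx, ny) object array of Outline
    valid: np.ndarray  # (nx, ny) bool
    expansion: float
    n_points: int
    model: MorphospacePCA = field(repr=False, default=None)

    @property
    def nx(self) -> int:
        return len(self.pc1_values)

    @property
    def ny(self) -> int:
        return len(self.pc2_values)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def node_coords(self, ix: int, iy: int) -> tuple[float, float]:
        return float(self.pc1_values[ix]), float(self.pc2_values[iy])


def _expanded_bounds(scores: np.ndarray, expansion: float) -> tuple[float, float]:
    lo, hi = float(scores.min()), float(scores.max())
    rng = hi - lo
    if rng <= 0.0:
        raise ParameterError("degenerate (zero-range) principal component axis")
    pad = 0.5 * expansion * rng  # total range grows by `expansion`
    return lo - pad, hi + pad


def build_grid(
    model: MorphospacePCA,
    nx: int = 23,
    ny: int = 22,
    expansion: float = 0.20,
    n_points: int = 1200,
) -> TheoreticalGrid:
    """Construct the expanded even grid of theoretical shapes.

    Per axis the empirical score range is grown symmetrically by
    ``expansion`` (default 20%, i.e. the grid spans 120% of the observed
    variation); nx nodes along PC1, ny along PC2. Every node's outline is
    reconstructed with :func:`inverse_map` and flagged invalid if it
    self-intersects.
    """
    if nx < 2 or ny < 2:
        raise ParameterError("nx and ny must be >= 2")
    if expansion < 0:
        raise ParameterError("expansion must be >= 0")
    lo1, hi1 = _expanded_bounds(model.scores_[:, 0], expansion)
    lo2, hi2 = _expanded_bounds(model.scores_[:, 1], expansion)
    pc1_values = np.linspace(lo1, hi1, nx)
    pc2_values = np.linspace(lo2, hi2, ny)
    outlines = np.empty((nx, ny), dtype=object)
    valid = np.zeros((nx, ny), dtype=bool)
    for ix, p1 in enumerate(pc1_values):
        for iy, p2 in enumerate(pc2_values):
            o = inverse_map(model, p1, p2, n_points=n_points)
            outlines[ix, iy] = o
            valid[ix, iy] = not self_intersects(o)
    return TheoreticalGrid(
        pc1_values=pc1_values,
        pc2_values=pc2_values,
        outlines=outlines,
        valid=valid,
        expansion=expansion,
        n_points=n_points,
        model=model,
    )
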