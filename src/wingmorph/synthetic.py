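"""Parametric generator of wing-like closed outlines and flight-style cohorts.

The base planform is a superellipse-like chord profile

    c(x) = root_chord * [taper + (1 - taper) * (1 - (x/span)^p)]

with p = 2 / (1 + tip_sharpness), so tip_sharpness 0 gives a rounded,
near-elliptic tip, 1 a linear taper, and large values a slender pointed tip.
A tip-weight factor 1 + tip_weight*(x/span - 1/2) shifts area toward the tip
(positive) or the base (negative). The leading edge is smooth; primary
feather emargination is carved as sinusoidal clefts from the trailing side of
the distal quarter of the span only, so the leading-edge tip rule of the
tip-angle metric is always exercised. Boundary noise is radial Gaussian
jitter about the noiseless outline, applied before resampling; jitter that
produces a self-intersecting boundary is redrawn.

These are caricatures of real wings: no allometry, no camber, no feather
microstructure — just the chord-breadth, tip-base weighting, pointedness and
emargination axes of variation the morphospace analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .morphospace import self_intersects
from .outline import Outline, canonicalise, resample, write_outline_csv

__all__ = [
    "PlanformParams",
    "CohortSpec",
    "FLIGHT_STYLES",
    "STYLE_PRESETS",
    "generate_planform",
    "generate_cohort",
    "write_cohort",
]

FLIGHT_STYLES = (
    "marine_soaring",
    "aerial_predation",
    "thermal_soaring",
    "diving",
    "hovering",
    "long_distance_migration",
    "burst_flapping",
)


@dataclass(frozen=True)
class PlanformParams:
    """Constructor variables for one synthetic planform (arbitrary length
    units)."""

    span: float = 5.0
    root_chord: float = 1.5
    taper: float = 0.5
    tip_weight: float = 0.0
    tip_sharpness: float = 1.0
    emargination_depth: float = 0.0
    emargination_count: int = 0
    noise_sd: float = 0.0
    n_points: int = 1200

    def validate(self) -> None:
        if self.span <= 0 or self.root_chord <= 0:
            raise ParameterError("span and root_chord must be > 0")
        if not 0.0 <= self.taper <= 1.0:
            raise ParameterError("taper must be in [0, 1]")
        if not -1.0 <= self.tip_weight <= 1.0:
            raise ParameterError("tip_weight must be in [-1, 1]")
        if self.tip_sharpness < 0:
            raise ParameterError("tip_sharpness must be >= 0")
        if not 0.0 <= self.emargination_depth < 1.0:
            raise ParameterError("emargination_depth must be in [0, 1)")
        if self.emargination_count < 0:
            raise ParameterError("emargination_count must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_points < 3:
            raise ParameterError("n_points must be >= 3")


def _boundary(params: PlanformParams, n_stations: int = 600) -> np.ndarray:
    """Noiseless boundary polygon: leading edge root->tip, trailing edge
    tip->root, root edge closing implicitly."""
    R, cr = params.span, params.root_chord
    p = 2.0 / (1.0 + params.tip_sharpness)
    x = R * (1.0 - np.cos(np.linspace(0.0, np.pi / 2, n_stations)))  # dense at tip
    profile = params.taper + (1.0 - params.taper) * (1.0 - (x / R) ** p)
    weight = 1.0 + params.tip_weight * (x / R - 0.5)
    chord = np.clip(cr * profile * weight, 0.0, None)

    y_le = 0.25 * chord
    carve = np.zeros_like(x)
    if params.emargination_count > 0 and params.emargination_depth > 0:
        distal = x >= 0.75 * R
        phase = (x[distal] - 0.75 * R) / (0.25 * R)
        carve[distal] = params.emargination_depth * np.sin(
            np.pi * params.emargination_count * phase
        ) ** 2
    y_te = y_le - chord * (1.0 - carve)

    le = np.column_stack([x, y_le])
    te = np.column_stack([x[::-1], y_te[::-1]])
    return np.vstack([le, te])


def generate_planform(params: PlanformParams, seed: int | None = None) -> Outline:
    """One synthetic planform outline with exactly ``n_points`` landmarks.

    Deterministic for a given (params, seed); noise_sd = 0 needs no seed.
    """
    params.validate()
    base = _boundary(params)
    if params.noise_sd == 0.0:
        return resample(canonicalise(base), params.n_points)
    rng = np.random.default_rng(seed)
    centroid = base.mean(axis=0)
    radial = base - centroid
    norms = np.hypot(radial[:, 0], radial[:, 1])
    unit = radial / np.where(norms > 0, norms, 1.0)[:, None]
    for _ in range(20):
        jitter = rng.normal(0.0, params.noise_sd, size=len(base))
        noisy = base + unit * jitter[:, None]
        try:
            out = resample(canonicalise(noisy), params.n_points)
        except Exception:
            continue
        if not self_intersects(out):
            return out
    raise ParameterError(
        "noise_sd too large: could not draw a simple outline in 20 attempts"
    )


_PERTURBABLE = (
    "span",
    "root_chord",
    "taper",
    "tip_weight",
    "tip_sharpness",
    "emargination_depth",
    "noise_sd",
)


@dataclass(frozen=True)
class CohortSpec:
    """A flight-style-labelled cohort drawn around mean planform parameters."""

    style_label: str
    n: int
    param_means: PlanformParams
    param_sds: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.style_label not in FLIGHT_STYLES:
            raise ParameterError(f"unknown flight style {self.style_label!r}")
        if self.n < 1:
            raise ParameterError("cohort size n must be >= 1")
        bad = set(self.param_sds) - set(_PERTURBABLE)
        if bad:
            raise ParameterError(f"cannot perturb fields: {sorted(bad)}")
        self.param_means.validate()


def generate_cohort(spec: CohortSpec, max_retries: int = 100):
    """Draw ``n`` labelled outlines by Gaussian perturbation of the mean
    parameters. Invalid draws are resampled up to ``max_retries`` per
    specimen, then error. Identical seed, identical cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        params = None
        for _attempt in range(max_retries):
            draw = {
                name: rng.normal(getattr(spec.param_means, name), sd)
                for name, sd in spec.param_sds.items()
            }
            candidate = replace(spec.param_means, **draw)
            try:
                candidate.validate()
            except ParameterError:
                continue
            params = candidate
            break
        if params is None:
            raise ParameterError(
                f"could not draw valid parameters in {max_retries} tries"
            )
        child_seed = int(rng.integers(0, 2**31 - 1))
        out.append((generate_planform(params, seed=child_seed), spec.style_label))
    return out


def write_cohort(
    cohorts: list, out_dir: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write outlines as per-specimen CSVs plus a manifest table."""
    out_dir = Path(out_dir)
    (out_dir / "outlines").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (outline, label) in enumerate(cohorts):
        rel = f"outlines/wing_{i:04d}.csv"
        write_outline_csv(outline, out_dir / rel)
        rows.append({"outline_path": rel, "taxon_id": f"wing_{i:04d}",
                     "style_label": label, "is_left": 0})
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


#: Per-style mean parameters. The study reports no within-style parameter
#: distributions, so these are the generator's own study conditions: chosen
#: once on morphological grounds (see docs/methods.md) — slender high-span
#: marine soarers, emarginated thermal soarers, broad low-taper burst
#: flappers, short pointed hoverers, and so on.
STYLE_PRESETS: dict[str, PlanformParams] = {
    "marine_soaring": PlanformParams(span=8.0, root_chord=1.1, taper=0.35,
                                     tip_weight=-0.15, tip_sharpness=2.5),
    "aerial_predation": PlanformParams(span=5.5, root_chord=1.5, taper=0.45,
                                       tip_weight=0.05, tip_sharpness=2.0),
    "thermal_soaring": PlanformParams(span=6.0, root_chord=2.0, taper=0.65,
                                      tip_weight=0.10, tip_sharpness=0.5,
                                      emargination_depth=0.25,
                                      emargination_count=4),
    "diving": PlanformParams(span=4.0, root_chord=1.6, taper=0.40,
                             tip_weight=-0.05, tip_sharpness=1.5),
    "hovering": PlanformParams(span=4.5, root_chord=1.3, taper=0.35,
                               tip_weight=0.10, tip_sharpness=2.0),
    "long_distance_migration": PlanformParams(span=6.5, root_chord=1.4,
                                              taper=0.35, tip_weight=-0.10,
                                              tip_sharpness=2.5),
    "burst_flapping": PlanformParams(span=3.5, root_chord=2.2, taper=0.80,
                                     tip_weight=0.10, tip_sharpness=0.3),
}

#: Default within-style spreads (same units as the parameters).
DEFAULT_SDS = {
    "span": 0.30,
    "root_chord": 0.10,
    "taper": 0.05,
    "tip_weight": 0.05,
    "tip_sharpness": 0.20,
    "noise_sd": 0.0,
}
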