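"""End-to-end orchestration: outlines -> EFA -> morphospace -> theoretical
grid -> performance and Pareto surfaces -> projection and style reports.

Every stage reads and writes plain CSV/JSON artifacts inside a workspace
directory, so stages can be run separately (see the command-line interface)
or all at once with :func:`run_pipeline`. A single seed drives all
randomness; identical configuration and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .efa import HarmonicSet, efa_forward
from .errors import ParameterError
from .groups import (
    TaxonRecord,
    combination_surface,
    default_style_config,
    load_style_config,
    style_report,
)
from .morphospace import (
    MorphospacePCA,
    TheoreticalGrid,
    build_grid,
    fit_morphospace,
    project,
)
from .outline import mirror_if_left, read_outline, resample
from .pareto import build_pareto_surface
from .performance import AgilityParams, build_surface
from .synthetic import (
    DEFAULT_SDS,
    FLIGHT_STYLES,
    STYLE_PRESETS,
    CohortSpec,
    generate_cohort,
    write_cohort,
)

log = logging.getLogger("wingmorph")

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_COMBOS"]

#: The four trade-off combinations analysed as Pareto surfaces.
DEFAULT_COMBOS: dict[str, list[tuple[str, str]]] = {
    "2MA+TA": [("2MA", "high_optimal"), ("TA", "low_optimal")],
    "AR+TA": [("AR", "high_optimal"), ("TA", "low_optimal")],
    "2MA+PA": [("2MA", "high_optimal"), ("PA", "high_optimal")],
    "2MA+PA+TA(LOW)": [
        ("2MA", "high_optimal"),
        ("PA", "high_optimal"),
        ("TA", "high_optimal"),
    ],
}


@dataclass
class PipelineConfig:
    """Analysis settings; the defaults reproduce the canonical protocol
    (1200 landmarks, 5 harmonics, 23x22 grid expanded 20%)."""

    landmarks: int = 1200
    harmonics: int = 5
    grid_nx: int = 23
    grid_ny: int = 22
    expansion: float = 0.20
    n_strips: int = 100
    tip_offset: int = 500
    seed: int = 0
    # inputs: an existing manifest, or simulation settings
    manifest: str | None = None
    simulate_n_per_style: int = 10
    simulate_styles: tuple = FLIGHT_STYLES
    style_config_path: str | None = None
    workspace: str = "wingmorph_run"

    def validate(self) -> None:
        if self.landmarks < 3:
            raise ParameterError("landmarks must be >= 3")
        if self.harmonics < 1:
            raise ParameterError("harmonics must be >= 1")
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ParameterError("grid_nx and grid_ny must be >= 2")
        if self.expansion < 0:
            raise ParameterError("expansion must be >= 0")
        if self.n_strips < 10:
            raise ParameterError("n_strips must be >= 10")
        if self.tip_offset < 1:
            raise ParameterError("tip_offset must be >= 1")
        if 2 * round(self.tip_offset * self.landmarks / 1200) + 1 > self.landmarks:
            raise ParameterError("tip_offset too large for the landmark count")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        if "simulate_styles" in raw:
            raw["simulate_styles"] = tuple(raw["simulate_styles"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, ws: Path) -> Path:
    """Emit labelled synthetic cohorts and their manifest into ws."""
    rng = np.random.default_rng(config.seed)
    cohorts = []
    for style in config.simulate_styles:
        spec = CohortSpec(
            style_label=style,
            n=config.simulate_n_per_style,
            param_means=STYLE_PRESETS[style],
            param_sds=dict(DEFAULT_SDS),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohorts.extend(generate_cohort(spec))
    manifest = write_cohort(cohorts, ws)
    log.info("simulate: wrote %d outlines to %s", len(cohorts), ws)
    return manifest


def load_manifest(manifest: str | Path, landmarks: int):
    """Read a manifest (outline_path, taxon_id, style_label, is_left) and
    return canonical outlines resampled to the landmark count."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    if "outline_path" not in table.columns:
        raise ParameterError("manifest needs an outline_path column")
    root = manifest.parent
    out = []
    for _, row in table.iterrows():
        o = read_outline(root / row["outline_path"])
        o = mirror_if_left(o, bool(row.get("is_left", 0)))
        o = resample(o, landmarks)
        out.append(
            (
                o,
                str(row.get("taxon_id", row["outline_path"])),
                row.get("style_label", None),
                row.get("order_label", None),
            )
        )
    return out


def stage_efa(specimens, config: PipelineConfig, ws: Path):
    """Harmonic coefficients per specimen; writes harmonics.csv."""
    H = config.harmonics
    rows = []
    hsets = []
    for outline, taxon_id, style, order in specimens:
        h = efa_forward(outline, H=H, standardize=True)
        hsets.append(h)
        row = {"taxon_id": taxon_id, "style_label": style, "order_label": order}
        for k in range(H):
            for j, name in enumerate("abcd"):
                row[f"{name}{k + 1}"] = h.coeffs[k, j]
        row["scale"] = h.scale
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(ws / "harmonics.csv", index=False)
    return hsets, df


def harmonics_from_table(df: pd.DataFrame, H: int) -> list[HarmonicSet]:
    cols = [f"{name}{k + 1}" for k in range(H) for name in "abcd"]
    return [
        HarmonicSet(
            coeffs=np.array(row[cols], dtype=float).reshape(H, 4),
            scale=float(row.get("scale", 1.0)),
        )
        for _, row in df.iterrows()
    ]


def save_model(model: MorphospacePCA, path: Path) -> None:
    json.dump(
        {
            "mean": model.mean_.tolist(),
            "components": model.components_.tolist(),
            "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
            "scores": model.scores_.tolist(),
            "n_harmonics": model.n_harmonics_,
        },
        open(path, "w"),
    )


def load_model(path: Path) -> MorphospacePCA:
    raw = json.load(open(path))
    m = MorphospacePCA()
    m.mean_ = np.array(raw["mean"])
    m.components_ = np.array(raw["components"])
    m.explained_variance_ratio_ = np.array(raw["explained_variance_ratio"])
    m.scores_ = np.array(raw["scores"])
    m.n_harmonics_ = int(raw["n_harmonics"])
    return m


def stage_build_space(hsets, harm_df, config: PipelineConfig, ws: Path):
    """Fit the morphospace, project specimens, build the theoretical grid."""
    model = fit_morphospace(hsets)
    scores = model.scores_
    sc = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    sc.insert(0, "taxon_id", harm_df["taxon_id"].values)
    sc.insert(1, "style_label", harm_df["style_label"].values)
    sc.to_csv(ws / "scores.csv", index=False)
    save_model(model, ws / "model.json")

    grid = build_grid(
        model,
        nx=config.grid_nx,
        ny=config.grid_ny,
        expansion=config.expansion,
        n_points=config.landmarks,
    )
    nodes = [
        {
            "ix": ix,
            "iy": iy,
            "pc1": grid.pc1_values[ix],
            "pc2": grid.pc2_values[iy],
            "valid": int(grid.valid[ix, iy]),
        }
        for ix in range(grid.nx)
        for iy in range(grid.ny)
    ]
    pd.DataFrame(nodes).to_csv(ws / "grid_nodes.csv", index=False)
    log.info(
        "build-space: %d nodes, %d invalid (impossible space)",
        grid.n_nodes,
        grid.n_invalid,
    )
    return model, grid


def _surface_df(grid: TheoreticalGrid, surf) -> pd.DataFrame:
    rows = []
    values = surf.norm
    for ix in range(grid.nx):
        for iy in range(grid.ny):
            rows.append(
                {
                    "ix": ix,
                    "iy": iy,
                    "pc1": grid.pc1_values[ix],
                    "pc2": grid.pc2_values[iy],
                    "valid": int(grid.valid[ix, iy]),
                    "raw": getattr(surf, "raw", values)[ix, iy],
                    "norm": values[ix, iy],
                }
            )
    return pd.DataFrame(rows)


def stage_metrics(grid, config: PipelineConfig, ws: Path):
    """The four single-metric performance surfaces."""
    ap = AgilityParams(n_strips=config.n_strips)
    (ws / "surfaces").mkdir(exist_ok=True)
    surfaces = {}
    for name in ("AR", "2MA", "PA", "TA"):
        s = build_surface(grid, name, agility_params=ap)
        surfaces[name] = s
        _surface_df(grid, s).to_csv(ws / "surfaces" / f"{name}.csv", index=False)
        meta = {
            "metric": name,
            "direction": s.direction,
            "peak_ix": s.peak_idx[0],
            "peak_iy": s.peak_idx[1],
            "peak_pc": list(s.peak_coords),
            "degenerate": s.degenerate,
        }
        json.dump(meta, open(ws / "surfaces" / f"{name}.json", "w"))
    return surfaces


def stage_pareto(grid, surfaces, config: PipelineConfig, ws: Path):
    """The Pareto-rank-ratio trade-off surfaces for the default combos."""
    (ws / "surfaces").mkdir(exist_ok=True)
    ap = AgilityParams(n_strips=config.n_strips)
    combos = {}
    for name, combo in DEFAULT_COMBOS.items():
        parts = []
        for metric, direction in combo:
            s = surfaces.get(metric)
            if s is None or s.direction != direction:
                s = build_surface(grid, metric, direction, ap)
            parts.append(s)
        ps = build_pareto_surface(grid, parts)
        combos[name] = ps
        fname = name.replace("+", "_").replace("(", "").replace(")", "")
        df = _surface_df(grid, ps)
        df["R_o"] = ps.r_o.reshape(-1)
        df["R_s"] = ps.r_s.reshape(-1)
        df.to_csv(ws / "surfaces" / f"combo_{fname}.csv", index=False)
        json.dump(
            {
                "metrics": ps.metric_names,
                "directions": ps.directions,
                "peak_pc": list(ps.peak_coords),
                "n_fronts_optimal": int(ps.r_o.max() + 1),
            },
            open(ws / "surfaces" / f"combo_{fname}.json", "w"),
        )
        log.info("pareto: %s -> %d optimal fronts", name, int(ps.r_o.max() + 1))
    return combos


def stage_project(model, grid, hsets, harm_df, ws: Path):
    """Project specimens into the fitted space as taxon records."""
    records = []
    for h, (_, row) in zip(hsets, harm_df.iterrows()):
        pc = project(model, h)
        ix = int(np.argmin(np.abs(grid.pc1_values - pc[0])))
        iy = int(np.argmin(np.abs(grid.pc2_values - pc[1])))
        style = row["style_label"]
        records.append(
            TaxonRecord(
                taxon_id=str(row["taxon_id"]),
                pc=pc,
                style=None if pd.isna(style) else str(style),
                order=row.get("order_label", None),
                in_impossible_space=not grid.valid[ix, iy],
            )
        )
    pd.DataFrame(
        {
            "taxon_id": [r.taxon_id for r in records],
            "style_label": [r.style for r in records],
            "pc1": [r.pc[0] for r in records],
            "pc2": [r.pc[1] for r in records],
            "in_impossible_space": [int(r.in_impossible_space) for r in records],
        }
    ).to_csv(ws / "taxa_projection.csv", index=False)
    flagged = sum(r.in_impossible_space for r in records)
    if flagged:
        log.warning("project: %d taxa fall in impossible space", flagged)
    return records


def stage_report(grid, records, config: PipelineConfig, ws: Path) -> pd.DataFrame:
    style_config = (
        load_style_config(config.style_config_path)
        if config.style_config_path
        else default_style_config()
    )
    ap = AgilityParams(n_strips=config.n_strips)
    report = style_report(grid, records, style_config, ap)
    report.to_csv(ws / "style_report.csv", index=False)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory artifacts and writes the
    workspace files. Identical config and inputs give identical outputs."""
    config.validate()
    ws = Path(config.workspace)
    ws.mkdir(parents=True, exist_ok=True)

    manifest = config.manifest or stage_simulate(config, ws)
    specimens = load_manifest(manifest, config.landmarks)
    hsets, harm_df = stage_efa(specimens, config, ws)
    model, grid = stage_build_space(hsets, harm_df, config, ws)
    surfaces = stage_metrics(grid, config, ws)
    combos = stage_pareto(grid, surfaces, config, ws)
    records = stage_project(model, grid, hsets, harm_df, ws)
    report = stage_report(grid, records, config, ws)

    meta = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_specimens": len(specimens),
        "n_grid_nodes": grid.n_nodes,
        "n_invalid_nodes": grid.n_invalid,
        "explained_variance_ratio": model.explained_variance_ratio_[:3].tolist(),
    }
    json.dump(meta, open(ws / "run_meta.json", "w"), indent=2)
    return {
        "model": model,
        "grid": grid,
        "surfaces": surfaces,
        "combos": combos,
        "records": records,
        "report": report,
        "meta": meta,
    }
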