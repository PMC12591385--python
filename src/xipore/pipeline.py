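"""End-to-end pipeline configuration and orchestration.

A :class:`PipelineConfig` (read from a YAML file) drives the full
synthetic workflow: build the membrane, carve pore states over the
window grid, generate surrogate umbrella data over a configurable truth
profile, solve WHAM, and run the trajectory analytics.  Every stage
writes into a run directory together with a manifest carrying the
package version, the config digest and all seeds, so reruns with the
same config reproduce all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from . import __version__
from .analytics import (
    AnalysisFrameSeries,
    area_compressibility,
    area_per_lipid,
    bilayer_thickness,
    metrics_table,
)
from .backmap import backmap_pipeline, bundled_tables
from .core import BeadConfiguration
from .gro import write_gro, write_gro_frames
from .membrane import (
    MembraneSpec,
    ToyTrajectoryParams,
    build_membrane,
    carve_pore,
    simulate_toy_trajectory,
)
from .nucleation import XiSpec, compute_xi
from .protocol import make_window_grid, plan_equilibration
from .wham import sample_surrogate, wham_solve, write_umbrella_dataset

logger = logging.getLogger("xipore")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "default_config"]

_REQUIRED_SECTIONS = ("membrane", "xi", "protocol", "wham", "analytics", "seeds")


class ConfigError(ValueError):
    """Pipeline configuration is missing sections or values."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``default_config``)."""

    membrane: Dict[str, Any]
    xi: Dict[str, Any]
    protocol: Dict[str, Any]
    wham: Dict[str, Any]
    analytics: Dict[str, Any]
    seeds: Dict[str, int]
    raw: Dict[str, Any] = field(repr=False, default_factory=dict)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        missing = [s for s in _REQUIRED_SECTIONS if s not in data]
        if missing:
            raise ConfigError(f"config missing section(s): {missing}")
        seeds = data["seeds"]
        for key in ("build", "carve", "surrogate", "trajectory"):
            if key not in seeds:
                raise ConfigError(f"seeds section missing explicit seed {key!r}")
        return cls(
            membrane=dict(data["membrane"]),
            xi=dict(data["xi"]),
            protocol=dict(data["protocol"]),
            wham=dict(data["wham"]),
            analytics=dict(data["analytics"]),
            seeds={k: int(v) for k, v in seeds.items()},
            raw=data,
        )

    def digest(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def membrane_spec(self) -> MembraneSpec:
        m = self.membrane
        return MembraneSpec(
            upper_composition=m["upper_composition"],
            lower_composition=m["lower_composition"],
            chol_fraction=float(m.get("chol_fraction", 0.0)),
            target_area=float(m.get("target_area", 100.0)),
            upper_count_adjustment=int(m.get("upper_count_adjustment", 0)),
        )

    def xi_spec(self) -> XiSpec:
        x = dict(self.xi)
        mode = x.pop("mode", "cg")
        base = XiSpec.cg_default if mode == "cg" else XiSpec.aa_default
        allowed = {"radius", "slice_thickness", "n_slices", "saturation_count",
                   "center_xy", "z_anchor"}
        overrides = {k: v for k, v in x.items() if k in allowed}
        if "center_xy" in overrides and overrides["center_xy"] is not None:
            overrides["center_xy"] = tuple(overrides["center_xy"])
        return base(**overrides)


def default_config() -> Dict[str, Any]:
    """Demo configuration: a small single-species membrane, desk scale."""
    return {
        "membrane": {
            "upper_composition": {"POPC": 1.0},
            "lower_composition": {"POPC": 1.0},
            "chol_fraction": 0.0,
            "target_area": 64.0,
        },
        "xi": {"mode": "cg", "n_slices": 19},
        "protocol": {"xi_long": 0.7, "mode": "cg"},
        "wham": {"n_bins": 120, "tolerance": 1e-6, "temperature": 323.0,
                 "n_samples": 800,
                 "truth": {"kind": "harmonic", "k": 200.0, "center": 0.6}},
        "analytics": {"n_frames": 120, "flip_species": "POPS",
                      "enrichment_radius": 2.0},
        "seeds": {"build": 1, "carve": 2, "surrogate": 3, "trajectory": 4},
    }


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_dict(data)


def _truth_function(truth: Dict[str, Any]):
    kind = truth.get("kind", "harmonic")
    if kind == "harmonic":
        k = float(truth.get("k", 200.0))
        c = float(truth.get("center", 0.6))
        return lambda xi: k * (xi - c) ** 2
    if kind == "flat":
        return lambda xi: 0.0
    if kind == "double_well":
        k = float(truth.get("k", 400.0))
        a = float(truth.get("well_a", 0.3))
        b = float(truth.get("well_b", 0.9))
        return lambda xi: k * (xi - a) ** 2 * (xi - b) ** 2 / (0.5 * (b - a)) ** 2
    raise ConfigError(f"unknown truth kind {kind!r}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all pipeline stages into ``out_dir`` and write a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    manifest: Dict[str, Any] = {
        "version": __version__,
        "config_digest": digest,
        "seeds": config.seeds,
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s [config %s]", name, digest)
        t0 = time.perf_counter()
        return lambda **extra: manifest["stages"].update(
            {name: {"elapsed_s": round(time.perf_counter() - t0, 3), **extra}}
        )

    try:
        done = stage("build")
        spec = config.membrane_spec()
        flat = build_membrane(spec, seed=config.seeds["build"])
        write_gro(flat, out / "membrane_flat.gro")
        done(n_beads=int(flat.n_beads))

        done = stage("plan")
        schedule = plan_equilibration(float(config.protocol.get("xi_long", 0.7)))
        grid = make_window_grid(config.protocol.get("mode", "cg"))
        (out / "schedule.txt").write_text(schedule.describe() + "\n")
        done(total_time_ns=schedule.total_time, n_windows=int(grid.n_windows))

        done = stage("carve")
        xi_spec = config.xi_spec()
        carve_targets = [0.4, 0.7, 1.0]
        carved_frames = []
        xi_values = {}
        for i, target in enumerate(carve_targets):
            carved = carve_pore(flat, target, xi_spec,
                                seed=config.seeds["carve"] + i)
            carved_frames.append(carved)
            xi_values[str(target)] = compute_xi(carved, xi_spec).xi
        write_gro_frames(carved_frames, out / "pore_states.gro")
        done(xi_achieved=xi_values)

        done = stage("sample")
        truth = _truth_function(config.wham.get("truth", {}))
        dataset = sample_surrogate(
            truth, grid,
            n_samples=int(config.wham.get("n_samples", 800)),
            seed=config.seeds["surrogate"],
            temperature=float(config.wham.get("temperature", 310.0)),
        )
        write_umbrella_dataset(dataset, out / "umbrella")
        done(n_windows=len(dataset.windows))

        done = stage("wham")
        profile = wham_solve(
            dataset,
            n_bins=int(config.wham.get("n_bins", 200)),
            tolerance=float(config.wham.get("tolerance", 1e-6)),
        )
        profile.save(out / "pmf.dat")
        done(converged=bool(profile.converged), iterations=int(profile.n_iterations))

        done = stage("analyze")
        params = ToyTrajectoryParams(
            area_mean=spec.target_area,
            flip_species=config.analytics.get("flip_species", "POPS"),
        )
        traj = simulate_toy_trajectory(
            flat, params, n_frames=int(config.analytics.get("n_frames", 120)),
            seed=config.seeds["trajectory"],
        )
        series = AnalysisFrameSeries.from_trajectory(traj)
        table = metrics_table(
            series,
            species=(config.analytics.get("flip_species", "POPS")
                     if config.analytics.get("flip_species", "POPS")
                     in set(map(str, flat.residue_names)) else "POPC"),
            radius=float(config.analytics.get("enrichment_radius", 2.0)),
        )
        table.to_csv(out / "metrics.csv", index=False)
        done(
            apl_nm2=round(area_per_lipid(series), 4),
            thickness_nm=round(bilayer_thickness(series), 4),
            ka_mn_per_m=round(area_compressibility(series), 2),
        )

        done = stage("backmap")
        tables = bundled_tables()
        lipid_mask = np.isin(flat.residue_names.astype(str),
                             ("POPC", "POPE", "POPS", "POSM", "CHOL"))
        lipid_rids = np.unique(flat.residue_ids[lipid_mask])[:4]
        subset = flat.select(np.isin(flat.residue_ids, lipid_rids))
        structure, report = backmap_pipeline(subset, tables,
                                             seed=config.seeds["build"])
        write_gro(structure.to_bead_configuration(), out / "backmapped.gro")
        done(n_atoms=int(structure.n_atoms), geometry_ok=bool(report.passed),
             audit=report.summary())
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage failed [config {digest}]: {exc}"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
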