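"""End-to-end orchestration: pool -> densities -> sigma calibration ->
weights -> selection -> PCA, with a manifest sufficient to reproduce the
run.

Configuration is a flat TOML document; defaults equal the reference
parameters (spread width 0.11 nm, 5 Å region radius, 500 ns discard,
250 ns interval, 0.01 weight lattice, 5 replicas, 1e-2 convergence).
Any nm-valued key (``sigma_nm``, ``sigma_scan_nm``) is converted to Å
exactly once, here.
"""

from __future__ import annotations

import json
import os
import tomllib
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .density import SpreadParams, calibrate_sigma
from .fitting import SelectionConfig, best_n_curve, optimize_weights
from .geometry import FramePoolSpec, build_structure_pool
from .io_formats import write_map, write_pdb
from .modes import pca_modes, project_frames, projection_histogram
from .synthetic import (
    CHAIN_SELECTION,
    fit_frames_to_scaffold,
    minimal_scenario,
    paper_like_scenario,
    realize,
)
from .density import spread_density

__all__ = ["RunConfig", "run_pipeline"]

_PRESETS = {
    "paper-like": paper_like_scenario,
    "minimal": minimal_scenario,
}


@dataclass
class RunConfig:
    """Flat run configuration; all lengths in Å after parsing."""

    preset: str = "minimal"
    seed: int = 0
    sigma: float = 1.1
    region_radius: float = 5.0
    discard_ns: float = 500.0
    interval_ns: float = 250.0
    weight_step: float = 0.01
    select_n: List[int] = field(default_factory=lambda: [1, 2, 3, 5])
    n_replicas: int = 5
    convergence_tol: float = 1e-2
    max_iterations: int = 10000
    sigma_scan: List[float] = field(
        default_factory=lambda: [round(0.5 + 0.1 * i, 10) for i in range(11)]
    )
    pca_sample_ns: Optional[float] = None
    out_dir: str = "ensemblefit_run"

    def __post_init__(self):
        if self.preset not in _PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(_PRESETS)}"
            )
        if self.sigma <= 0 or self.region_radius <= 0 or self.weight_step <= 0:
            raise ValueError("sigma, region_radius and weight_step must be > 0")

    @classmethod
    def from_toml(cls, path: str, overrides: Optional[Dict] = None) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update(overrides or {})
        # nm -> Å conversion happens exactly once, here
        if "sigma_nm" in raw:
            raw["sigma"] = float(raw.pop("sigma_nm")) * 10.0
        if "sigma_scan_nm" in raw:
            raw["sigma_scan"] = [float(s) * 10.0 for s in raw.pop("sigma_scan_nm")]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full synthetic workflow and write every artifact.

    Returns the manifest (also written as ``manifest.json``).  A stage
    failure writes a FAILED manifest naming the stage, keeps partial
    outputs, and re-raises.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "status": "RUNNING",
    }
    stage = "setup"

    def _checkpoint():
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonify)

    try:
        stage = "synthesize"
        scenario_spec = _PRESETS[config.preset](seed=config.seed)
        scenario_spec = replace(
            scenario_spec,
            sigma=config.sigma,
            region_radius=config.region_radius,
        )
        data = realize(scenario_spec)
        write_pdb(
            data.base_conformations, os.path.join(config.out_dir, "bases.pdb")
        )
        write_map(data.target.map, os.path.join(config.out_dir, "target.mrc"))
        for label, cmap in zip(
            scenario_spec.conformation_labels, data.conformation_maps
        ):
            write_map(cmap, os.path.join(config.out_dir, f"ensemble_{label}.mrc"))
        with open(os.path.join(config.out_dir, "truth.json"), "w") as fh:
            json.dump(data.truth, fh, indent=2)
        manifest["stages"]["synthesize"] = {
            "preset": config.preset,
            "n_ensembles": len(data.ensembles),
            "truth": data.truth,
        }

        stage = "pool"
        pool_spec = FramePoolSpec(
            discard_ns=config.discard_ns, interval_ns=config.interval_ns
        )
        pool = build_structure_pool(data.ensembles, pool_spec)
        pool_df = pd.DataFrame(
            {
                "trajectory": [p.tag for p in pool],
                "time_ns": [p.time_ns for p in pool],
                "source": [f"ensemble:{p.ensemble_index}" for p in pool],
                "frame_index": [p.frame_index for p in pool],
            }
        )
        _write_tsv(pool_df, os.path.join(config.out_dir, "pool_manifest.tsv"))
        manifest["stages"]["pool"] = {
            "n_structures": len(pool),
            "discard_ns": config.discard_ns,
            "interval_ns": config.interval_ns,
        }

        stage = "calibrate_sigma"
        chain_idx = CHAIN_SELECTION.resolve(data.topology)
        base0 = data.base_conformations[0]
        base0_chain = base0.coordinates[chain_idx]
        scan = calibrate_sigma(base0_chain, data.target, config.sigma_scan)
        _write_tsv(
            pd.DataFrame({"sigma_A": scan.sigmas, "rho": scan.rhos}),
            os.path.join(config.out_dir, "sigma_scan.tsv"),
        )
        manifest["stages"]["calibrate_sigma"] = {
            "best_sigma_A": scan.best_sigma,
            "best_sigma_nm": scan.best_sigma / 10.0,
        }

        stage = "weights"
        opt = optimize_weights(data.conformation_maps, data.target, config.weight_step)
        weights_out = {
            "weights": [float(w) for w in opt.weights],
            "labels": scenario_spec.conformation_labels,
            "rho": opt.rho,
            "grid_step": config.weight_step,
        }
        with open(os.path.join(config.out_dir, "weights.json"), "w") as fh:
            json.dump(weights_out, fh, indent=2)
        if opt.surface is not None:
            cols = [f"w{i + 1}" for i in range(len(opt.weights))] + ["rho"]
            _write_tsv(
                pd.DataFrame(opt.surface, columns=cols),
                os.path.join(config.out_dir, "weight_surface.tsv"),
            )
        manifest["stages"]["weights"] = weights_out

        stage = "select"
        params = SpreadParams(sigma=config.sigma)
        fitted = [fit_frames_to_scaffold(e, data.topology) for e in data.ensembles]
        pool_maps = []
        for p in pool:
            coords = fitted[p.ensemble_index].coordinates[p.frame_index][chain_idx]
            pool_maps.append(spread_density(coords, scenario_spec.grid, params))
        n_values = [n for n in config.select_n if n <= len(pool_maps)]
        sel_cfg = SelectionConfig(
            n_structures=max(n_values),
            n_replicas=config.n_replicas,
            convergence_tol=config.convergence_tol,
            max_iterations=config.max_iterations,
            seed=config.seed,
            weight_grid_step=config.weight_step,
        )
        curve = best_n_curve(
            pool_maps,
            data.target,
            n_values,
            sel_cfg,
            initial_maps=[
                spread_density(b.coordinates[chain_idx], scenario_spec.grid, params)
                for b in data.base_conformations
            ],
        )
        selection_out = {
            "n_values": [int(n) for n in curve.n_values],
            "rhos": [float(r) for r in curve.rhos],
            "full_ensemble_rho": curve.full_ensemble_rho,
            "initial_rho": curve.initial_rho,
            "selections": {
                int(n): {
                    "members": [int(i) for i in res.member_indices],
                    "weights": [float(w) for w in res.weights],
                    "rho": res.rho,
                    "iterations": res.iterations,
                    "replica_rhos": res.replica_rhos,
                    "converged": res.converged,
                }
                for n, res in curve.results.items()
            },
        }
        with open(os.path.join(config.out_dir, "selection.json"), "w") as fh:
            json.dump(selection_out, fh, indent=2)
        manifest["stages"]["select"] = selection_out

        stage = "pca"
        sample_ns = config.pca_sample_ns or scenario_spec.timestep_ns
        basis = pca_modes(fitted, selection=chain_idx, sample_interval_ns=sample_ns)
        projections = project_frames(fitted, basis, n_modes=2)
        proj_df = pd.DataFrame(
            {
                "ensemble": projections.origin_conformations,
                "replica": projections.replica_ids,
                "time_ns": projections.times,
                "pc1": projections.projections[:, 0],
                "pc2": projections.projections[:, 1],
            }
        )
        _write_tsv(proj_df, os.path.join(config.out_dir, "projections.tsv"))
        _write_tsv(
            pd.DataFrame(
                {
                    "mode": np.arange(1, basis.eigenvalues.size + 1),
                    "eigenvalue_A2": basis.eigenvalues,
                    "variance_fraction": basis.variance_fractions,
                }
            ),
            os.path.join(config.out_dir, "modes.tsv"),
        )
        projection_histogram(projections, bins=32)  # sanity: histogram is buildable
        manifest["stages"]["pca"] = {
            "two_mode_variance_fraction": float(basis.variance_fractions[:2].sum()),
            "sample_interval_ns": sample_ns,
        }

        manifest["status"] = "OK"
        _checkpoint()
        return manifest
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        _checkpoint()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
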