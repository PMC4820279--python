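"""Table I/O, run configuration, and stage dispatch.

All tables are plain CSV; every run writes a JSON manifest (config, seed,
package version) next to its outputs so identical manifests reproduce
byte-identical tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_table",
    "write_table",
    "write_manifest",
    "run_stage",
    "STAGES",
]


class SchemaError(ValueError):
    """A table does not match its required schema."""


def read_table(path, required: Optional[list] = None) -> pd.DataFrame:
    """Read a CSV table, checking that the required columns are present.

    Extra columns are preserved with a warning.
    """
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"{path}: extra columns preserved: {extra}")
    return df


def write_table(df: pd.DataFrame, path, required: Optional[list] = None) -> None:
    """Write a CSV table at full precision after schema validation."""
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(out_dir, stage: str, params: dict, seed: int) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "params": params,
        "seed": seed,
        "package": "satgrowth",
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


@dataclass
class RunConfig:
    """A validated stage invocation: name, parameters, seed, output dir."""

    stage: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; available: {sorted(STAGES)}"
            )
        allowed = STAGES[self.stage]["params"]
        unknown = set(self.params) - set(allowed)
        if unknown:
            raise ValueError(
                f"unknown parameter key(s) for stage {self.stage!r}: {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# stages


def _stage_phase_diagram(params: dict, seed: int, out_dir: Path) -> None:
    from .meanfield import PathwayParams, phase_diagram

    p = PathwayParams(
        theta=params.get("theta", 100.0),
        vmax_b=params.get("vmax_b", 1.0),
        km_b=params.get("km_b", 0.1),
        g_max=params.get("g_max", 6e-4),
        toxicity_variant=params.get("variant", "substrate"),
        benefit_form=params.get("benefit_form", "piecewise_linear"),
    )
    n = int(params.get("n_grid", 50))
    v_grid = np.linspace(params.get("v_plus_min", 0.02), params.get("v_plus_max", 2.0), n)
    d_grid = np.linspace(params.get("delta_min", 0.05), params.get("delta_max", 1.5), n)
    pm = phase_diagram(v_grid, d_grid, p)
    write_table(pm.to_frame(), out_dir / "phase_diagram.csv",
                required=["v_plus", "delta", "regime", "norm_growth"])


def _stage_ensemble(params: dict, seed: int, out_dir: Path) -> None:
    from .ssa import SPECIES, build_reaction_system, run_ensemble

    spec = build_reaction_system(
        {
            "k_im": params.get("k_im", 0.1),
            "k_ta": params.get("k_ta", 0.05),
            "theta": params.get("theta", 1e4),
        }
    )
    ens = run_ensemble(
        spec,
        n_traj=int(params.get("n", 200)),
        t_end=float(params.get("t_end", 8000.0)),
        seed_base=seed,
    )
    rows = pd.DataFrame(ens.per_traj_species, columns=list(SPECIES))
    rows.insert(0, "seed", ens.seeds)
    rows["growth"] = ens.per_traj_growth
    rows["arrested"] = ens.per_traj_arrested
    write_table(rows, out_dir / "trajectories.csv")
    summary = {
        "n_traj": ens.n_traj,
        "growth_mean": ens.growth_mean,
        "growth_se": ens.growth_se,
        "arrest_fraction": ens.arrest_fraction,
        "correlations": {
            k: (None if np.isnan(v) else v) for k, v in ens.correlations.items()
        },
    }
    (out_dir / "ensemble_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )


def _stage_popmodel_surface(params: dict, seed: int, out_dir: Path) -> None:
    from .population import fitness_surface

    deltas = np.linspace(params.get("delta_min", 0.1), params.get("delta_max", 2.0),
                         int(params.get("n_delta", 30)))
    xs = np.linspace(params.get("x_min", 0.05), params.get("x_max", 2.0),
                     int(params.get("n_x", 30)))
    lam, arrested = fitness_surface(
        deltas, xs,
        g_max=params.get("g_max", 1.0),
        s_max=params.get("s_max", 2.0),
        sigma_x=params.get("sigma_x", 0.1),
    )
    dd, xx = np.meshgrid(deltas, xs, indexing="ij")
    df = pd.DataFrame(
        {
            "delta": dd.ravel(),
            "x": xx.ravel(),
            "lambda_normalized": lam.ravel(),
            "arrested_fraction": arrested.ravel(),
        }
    )
    write_table(df, out_dir / "fitness_surface.csv",
                required=["delta", "x", "lambda_normalized", "arrested_fraction"])


def _stage_synth_dose(params: dict, seed: int, out_dir: Path) -> None:
    from .synth import DoseResponseConfig, gen_dose_response

    cfg = DoseResponseConfig(
        a=params.get("a", 0.3), b=params.get("b", 0.04), c=params.get("c", -0.0008),
        noise_sd=params.get("noise_sd", 0.01),
    )
    df = gen_dose_response(cfg, seed=seed)
    write_table(df, out_dir / "dose_response.csv", required=["dose", "rate", "replicate"])


def _stage_infer_aic(params: dict, seed: int, out_dir: Path) -> None:
    from .inference import compare_polynomial_models

    table = read_table(params["input"], required=["dose", "rate"])
    res = compare_polynomial_models(table["dose"], table["rate"])
    (out_dir / "aic.json").write_text(json.dumps(res, indent=2, sort_keys=True))


STAGES = {
    "phase-diagram": {
        "run": _stage_phase_diagram,
        "params": {"theta", "vmax_b", "km_b", "g_max", "variant", "benefit_form",
                   "n_grid", "v_plus_min", "v_plus_max", "delta_min", "delta_max"},
    },
    "simulate-ensemble": {
        "run": _stage_ensemble,
        "params": {"k_im", "k_ta", "theta", "n", "t_end"},
    },
    "popmodel-surface": {
        "run": _stage_popmodel_surface,
        "params": {"delta_min", "delta_max", "x_min", "x_max", "n_delta", "n_x",
                   "g_max", "s_max", "sigma_x"},
    },
    "synth-dose": {
        "run": _stage_synth_dose,
        "params": {"a", "b", "c", "noise_sd"},
    },
    "infer-aic": {
        "run": _stage_infer_aic,
        "params": {"input"},
    },
}


def run_stage(config: RunConfig) -> Path:
    """Dispatch a configured stage; writes outputs plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    STAGES[config.stage]["run"](config.params, config.seed, out_dir)
    return write_manifest(out_dir, config.stage, config.params, config.seed)
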