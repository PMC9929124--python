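"""Serialization: CSV/JSON artifacts, config files, and run manifests.

Floats are written with 17 significant digits so that a written-then-read
profile or equilibrium reproduces the in-memory values bit for bit, and a
rerun with the same config and seed is byte-identical (checked via the
manifest checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .equilibrium import CommunityParams, EquilibriumState
from .experiments import ScenarioBundle, ScenarioConfig, SweepResult
from .dynamics import Trajectory
from .rad import CommunityComparison, RankAbundance
from .tradeoff import FecundityProfile

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_equilibrium_csv",
    "write_trajectory_csv",
    "write_rad_csv",
    "comparison_to_dict",
    "write_comparison_json",
    "write_sweep_csv",
    "write_scenario_bundle",
    "load_config",
    "scenario_config_from_dict",
]

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_profile_csv(profile: FecundityProfile, path: str | Path) -> Path:
    """Write a fecundity profile as ``species_index,fecundity`` rows."""
    path = Path(path)
    lines = ["species_index,fecundity"]
    lines += [f"{i + 1},{_fmt(v)}" for i, v in enumerate(profile.values)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_profile_csv(path: str | Path) -> FecundityProfile:
    """Read a profile written by :func:`write_profile_csv` (exact round-trip)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"species_index", "fecundity"} <= set(df.columns):
        raise ValueError(f"{path}: need columns species_index, fecundity")
    df = df.sort_values("species_index")
    idx = df["species_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: species_index must be 1..n without gaps")
    return FecundityProfile(
        values=df["fecundity"].to_numpy(dtype=float),
        provenance={"kind": "csv", "path": str(path)},
    )


def write_equilibrium_csv(
    state: EquilibriumState,
    path: str | Path,
    threshold: float = 1e-5,
    convention: str = "relative",
) -> Path:
    """Equilibrium table plus a JSON sidecar with params and provenance."""
    path = Path(path)
    p = state.frequencies
    total = p.sum()
    rel = p / total if total > 0 else p
    detect_base = rel if convention == "relative" else p
    lines = ["species_index,fecundity,frequency,relative_abundance,detectable"]
    for i in range(p.size):
        lines.append(
            f"{i + 1},{_fmt(state.profile.values[i])},{_fmt(p[i])},"
            f"{_fmt(rel[i])},{int(detect_base[i] >= threshold)}"
        )
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "params": asdict(state.params),
        "profile_provenance": dict(state.profile.provenance),
        "threshold": threshold,
        "convention": convention,
        "occupied_fraction": state.occupied_fraction,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Long-format trajectory: time, species_index, frequency."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time,species_index,frequency\n")
        for t, state in zip(traj.times, traj.states):
            ts = _fmt(t)
            for i, v in enumerate(state):
                fh.write(f"{ts},{i + 1},{_fmt(v)}\n")
    return path


def write_rad_csv(rad: RankAbundance, path: str | Path) -> Path:
    path = Path(path)
    lines = ["rank,species_index,abundance,convention,threshold"]
    for r, (s, a) in enumerate(rad.entries, start=1):
        lines.append(f"{r},{s},{_fmt(a)},{rad.convention},{_fmt(rad.threshold)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def comparison_to_dict(comp: CommunityComparison) -> dict[str, Any]:
    def rad_dict(rad: RankAbundance) -> dict:
        return {
            "species": [int(s) for s in rad.species],
            "abundances": [float(a) for a in rad.abundances],
            "richness": rad.richness,
        }
    return {
        "before": rad_dict(comp.before),
        "after": rad_dict(comp.after),
        "new_species": sorted(comp.new),
        "lost_species": sorted(comp.lost),
        "retained_species": sorted(comp.retained),
        "top_k": comp.k,
        "top_k_tracking": {str(k): v for k, v in comp.top_k_tracking.items()},
        "threshold": comp.before.threshold,
        "convention": comp.before.convention,
    }


def write_comparison_json(comp: CommunityComparison, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(comparison_to_dict(comp), indent=2) + "\n")
    return path


def write_sweep_csv(result: SweepResult, path: str | Path) -> Path:
    """Long-format sweep surface: alpha, beta, richness (both), biomass."""
    path = Path(path)
    df = result.to_frame()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_scenario_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> dict:
    """Write every scenario artifact into a directory and return the manifest.

    Emits the equilibrium CSVs, the trajectory, one RAD CSV per transient
    snapshot, the comparison JSON, the richness/biomass time series, the
    fully resolved config, and ``manifest.json`` listing each file with its
    SHA-256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    files: list[Path] = []

    files.append(write_profile_csv(bundle.profile_before,
                                   out / "profile_before.csv"))
    files.append(write_profile_csv(bundle.profile_after,
                                   out / "profile_after.csv"))
    for name, state in (("before", bundle.eq_before),
                        ("after", bundle.eq_after)):
        p = write_equilibrium_csv(state, out / f"equilibrium_{name}.csv",
                                  cfg.threshold, cfg.convention)
        files += [p, p.with_suffix(".json")]
    files.append(write_rad_csv(bundle.rad_before, out / "rad_before.csv"))
    files.append(write_rad_csv(bundle.rad_after, out / "rad_after.csv"))
    files.append(write_comparison_json(bundle.comparison,
                                       out / "comparison.json"))
    files.append(write_trajectory_csv(bundle.trajectory,
                                      out / "trajectory.csv"))
    for t, rad in bundle.snapshots.items():
        files.append(write_rad_csv(rad, out / f"rad_t{int(round(t))}.csv"))
    ts_path = out / "timeseries.csv"
    bundle.timeseries.to_csv(ts_path, index=False, float_format=_FLOAT_FMT)
    files.append(ts_path)
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(cfg.resolved(), indent=2) + "\n")
    files.append(cfg_path)

    manifest = {
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


_SCENARIO_KEYS = set(ScenarioConfig.__dataclass_fields__)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def scenario_config_from_dict(
    data: dict, **overrides: Any
) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig`, rejecting unknown keys.

    ``overrides`` (typically CLI flags) win over file values; ``None``
    overrides are ignored so unset flags fall through to the file/defaults.
    """
    merged = dict(data)
    for k, v in overrides.items():
        if v is not None:
            merged[k] = v
    unknown = set(merged) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return ScenarioConfig(**merged)
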