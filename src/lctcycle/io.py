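"""Config and tabular I/O plumbing.

All tables are plain CSV with documented headers; structured
configuration and results are YAML with explicit units.  Every
stochastic run records its seed, and result directories carry a
manifest with input checksums, the seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose_response import DrugResponseProfile
from .mean_field import PopulationTrajectory
from .structure import PhaseStructure, RateSet
from .synthetic import LINEAGE_COLUMNS, SyntheticDataset

__all__ = [
    "structure_to_dict", "structure_from_dict",
    "rates_to_dict", "rates_from_dict",
    "profile_to_dict", "profile_from_dict",
    "save_config", "load_config",
    "write_trajectory", "read_trajectory",
    "write_population", "read_population",
    "write_lineage", "read_lineage",
    "write_manifest",
]

POPULATION_COLUMNS = ["drug", "concentration_nM", "replicate", "time_h",
                      "count_norm", "frac_g1"]
TRAJECTORY_COLUMNS = ["time_h", "g1", "sg2", "total", "dead_cum"]


def structure_to_dict(s: PhaseStructure) -> dict:
    return {"g1_parts": s.g1_parts, "g1_subphases_per_part": s.g1_subphases_per_part,
            "sg2_parts": s.sg2_parts, "sg2_subphases_per_part": s.sg2_subphases_per_part}


def structure_from_dict(d: dict) -> PhaseStructure:
    return PhaseStructure(**{k: int(v) for k, v in d.items()})


def rates_to_dict(r: RateSet) -> dict:
    return {
        "units": "1/hour",
        "structure": structure_to_dict(r.structure),
        "alpha": [float(v) for v in r.alpha],
        "beta": [float(v) for v in r.beta],
        "gamma1": [float(v) for v in r.gamma1],
        "gamma2": [float(v) for v in r.gamma2],
    }


def rates_from_dict(d: dict) -> RateSet:
    return RateSet(
        alpha=d["alpha"], beta=d["beta"],
        gamma1=d.get("gamma1", 0.0), gamma2=d.get("gamma2", 0.0),
        structure=structure_from_dict(d["structure"]),
    )


def profile_to_dict(p: DrugResponseProfile) -> dict:
    return {
        "drug_name": p.drug_name,
        "control_rates": rates_to_dict(p.control_rates),
        "ec50_nM": float(p.ec50),
        "steepness": float(p.steepness),
        "e_max": {fam: [float(v) for v in vals] for fam, vals in p.e_max.items()},
    }


def profile_from_dict(d: dict) -> DrugResponseProfile:
    return DrugResponseProfile(
        drug_name=d["drug_name"],
        control_rates=rates_from_dict(d["control_rates"]),
        ec50=float(d["ec50_nM"]),
        steepness=float(d["steepness"]),
        e_max=d.get("e_max", {}),
    )


def save_config(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_trajectory(traj: PopulationTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    return df


def write_population(dataset_or_frame, path) -> None:
    df = (dataset_or_frame.population
          if isinstance(dataset_or_frame, SyntheticDataset) else dataset_or_frame)
    df.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    return df


def write_lineage(records: pd.DataFrame, path) -> None:
    records[LINEAGE_COLUMNS].to_csv(path, index=False)


def read_lineage(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LINEAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lineage table missing columns: {sorted(missing)}")
    return df


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, inputs=(), seed=None, extra=None) -> Path:
    """Record inputs' checksums, the seed and the package version."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "lctcycle",
        "version": __version__,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
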