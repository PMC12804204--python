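"""Configuration, file readers/writers and run provenance.

All tables are UTF-8, comma-delimited with a header row. A run manifest
(JSON) snapshotting the configuration, seeds, package version and input
digests accompanies every output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .core import Grid

GRID_COLUMNS = ["cell_id", "x_index", "y_index", "populated"]
COUNTS_COLUMNS = ["zone", "sex", "age_band", "edu_level", "count"]
TRIPS_COLUMNS = [
    "respondent_id",
    "sex",
    "age_band",
    "edu_level",
    "night_cell",
    "stay_cell",
    "start_min",
    "end_min",
]


class ToyRegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width: int = 15
    height: int = 15
    n_agents: int = Field(10_000, gt=0)
    education_segregation: float = Field(0.8, ge=0.0, le=1.0)
    n_hubs: int = Field(4, ge=1)
    hub_attraction: float = Field(1.0, ge=0.0)
    distance_decay: float = Field(0.35, ge=0.0)


class ParameterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    healthy_diet_reward: float = Field(0.153, ge=0.0, le=1.0)
    opinion_inertia: float = Field(0.820, ge=0.0, le=1.0)
    max_proba_to_switch: float = Field(0.890, ge=0.0, le=1.0)
    constraint_strength: float = Field(0.129, ge=0.0, le=1.0)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    scenario: str = "2C"
    mixing_fraction: float = Field(0.0, ge=0.0, le=1.0)
    n_reps: int = Field(1, ge=1)
    n_days: int = Field(6, ge=0)
    seed: int = 0
    toy_region: ToyRegionConfig = ToyRegionConfig()
    parameters: ParameterConfig = ParameterConfig()
    moran_weights: str = "queen"
    # optional external file hooks (used instead of the toy region if set)
    grid_file: str | None = None
    counts_file: str | None = None
    trips_file: str | None = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults are filled in."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        keys = sorted(
            {".".join(str(p) for p in err["loc"]) for err in exc.errors()}
        )
        raise ValueError(
            f"invalid configuration {path}: offending keys {keys}"
        ) from exc


def read_grid(path: str | Path) -> Grid:
    return Grid.from_frame(pd.read_csv(path))


def write_grid(grid: Grid, path: str | Path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COUNTS_COLUMNS, path)
    return df


def read_trips(path: str | Path, presplit: bool = True) -> pd.DataFrame:
    """Read trip stays; by default split them at slice boundaries so the
    presence-probability builder sees only within-slice stays."""
    df = pd.read_csv(path)
    _require_columns(df, TRIPS_COLUMNS, path)
    if presplit:
        from .synthpop import split_stays_at_boundaries

        df = split_stays_at_boundaries(df)
    return df


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """Provenance sidecar: config snapshot, seeds, version, input digests,
    timings."""

    def __init__(self, config: dict, seed: int):
        self.data = {
            "software": "fiveaday",
            "version": __version__,
            "seed": seed,
            "config": config,
            "inputs": {},
            "timings_s": {},
            "created_unix": time.time(),
        }
        self._t0 = time.perf_counter()

    def add_input(self, name: str, path: str | Path) -> None:
        self.data["inputs"][name] = {
            "path": str(path),
            "sha256": file_digest(path),
        }

    def mark(self, label: str) -> None:
        self.data["timings_s"][label] = round(time.perf_counter() - self._t0, 3)

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path


def write_outputs(
    tables: dict[str, pd.DataFrame],
    manifest: RunManifest,
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write named tables as CSV plus the manifest; refuses to overwrite an
    existing output unless force=True. Round-tripping a written table with
    pandas reproduces its values."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        df.to_csv(path, index=False)
        paths[name] = path
    manifest.mark("total")
    paths["manifest"] = manifest.write(out_dir)
    return paths
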