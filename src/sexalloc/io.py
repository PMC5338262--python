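"""Configuration files, tabular output, and run manifests.

Configs are TOML.  A minimal file only needs the community block; every other
key has a documented default that is echoed into the run manifest::

    [community]
    n_individuals = 100000
    n_demes = 1000
    n_species = 10
    generations = 2000

    [species]                   # optional
    resources = "ladder"        # "ladder" | "normal" | explicit list
    hi = 2.0
    lo = 1.1

    [mutation]                  # optional
    rate = 0.001
    model = "uniform"           # "uniform" | "perturbation"
    sigma = 0.05

    [dispersal]                 # optional
    long_distance_prob = 1.0
    seed_neighborhood_capacity = 100

    [environment]               # optional
    types = 1                   # 2 => reversed-ranking secondary type
    fraction_primary = 0.75

    [run]                       # optional
    seed = 0
    record_every = 1

Outputs are tab-separated (TSV): machine files carry floats at full precision
so a rerun from the manifest reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import (
    EnvironmentMap,
    SimulationConfig,
    SimulationResult,
    SpeciesTable,
)

__all__ = ["RunManifest", "load_config", "write_tsv", "write_outputs"]

_FLOAT_FMT = "%.17g"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bit for bit."""

    config: dict
    master_seed: int
    replicate_seeds: list[int]
    software_version: str = __version__
    start_generation: int = 0
    end_generation: int = 0
    output_files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _get(section: dict, key: str, path: str, default=None, required: bool = False):
    if key in section:
        return section[key]
    if required:
        raise ValueError(f"missing required config key: {path}.{key}")
    return default


def load_config(path) -> tuple[SimulationConfig, SpeciesTable, EnvironmentMap]:
    """Parse and validate a TOML config into the three run objects.

    Errors name the offending key path; divisibility violations are caught
    here, before any computation starts.
    """
    raw = tomllib.loads(Path(path).read_text())
    if "community" not in raw:
        raise ValueError("missing required config section: [community]")
    com = raw["community"]
    n = _get(com, "n_individuals", "community", required=True)
    d = _get(com, "n_demes", "community", required=True)
    s = _get(com, "n_species", "community", required=True)
    gens = _get(com, "generations", "community", required=True)
    if n % d != 0:
        raise ValueError(
            f"community.n_individuals={n} is not divisible by community.n_demes={d}"
        )

    mut = raw.get("mutation", {})
    disp = raw.get("dispersal", {})
    run = raw.get("run", {})
    config = SimulationConfig(
        n_individuals=n,
        n_demes=d,
        n_species=s,
        generations=gens,
        mutation_rate=_get(mut, "rate", "mutation", default=1e-3),
        mutation_model=_get(mut, "model", "mutation", default="uniform"),
        mutation_sigma=_get(mut, "sigma", "mutation", default=0.05),
        long_distance_prob=_get(
            disp, "long_distance_prob", "dispersal", default=1.0
        ),
        seed_neighborhood_capacity=_get(
            disp, "seed_neighborhood_capacity", "dispersal", default=None
        ),
        rng_seed=_get(run, "seed", "run", default=0),
    )

    spe = raw.get("species", {})
    env_sec = raw.get("environment", {})
    n_types = _get(env_sec, "types", "environment", default=1)
    resources = _get(spe, "resources", "species", default="ladder")
    if isinstance(resources, str):
        if resources == "ladder":
            hi = _get(spe, "hi", "species", default=2.0)
            lo = _get(spe, "lo", "species", default=1.1)
            if n_types == 2:
                table = SpeciesTable.reversed_pair(s, hi=hi, lo=lo)
            else:
                table = SpeciesTable.ladder(s, hi=hi, lo=lo)
        elif resources == "normal":
            table = SpeciesTable.normal(
                s,
                mean=_get(spe, "mean", "species", default=1.5),
                sd=_get(spe, "sd", "species", default=0.25),
                rng=np.random.default_rng(config.rng_seed),
            )
        else:
            raise ValueError(
                f"species.resources must be 'ladder', 'normal' or a list, "
                f"got {resources!r}"
            )
    else:
        table = SpeciesTable(np.atleast_2d(np.asarray(resources, dtype=float)))
        if table.n_species != s:
            raise ValueError(
                f"species.resources lists {table.n_species} species but "
                f"community.n_species={s}"
            )

    if n_types == 1:
        env = EnvironmentMap.homogeneous(d)
    elif n_types == 2:
        env = EnvironmentMap.two_types(
            d, fraction_primary=_get(env_sec, "fraction_primary", "environment", default=0.75)
        )
    else:
        raise ValueError("environment.types must be 1 or 2")
    if table.n_env_types < n_types:
        raise ValueError(
            "species.resources provides fewer rows than environment.types"
        )
    return config, table, env


def manifest_for(
    config: SimulationConfig,
    replicate_seeds: list[int],
    record_every: int = 1,
) -> RunManifest:
    cfg = dataclasses.asdict(config)
    cfg["record_every"] = record_every
    return RunManifest(
        config=cfg,
        master_seed=config.rng_seed,
        replicate_seeds=list(replicate_seeds),
        end_generation=config.generations,
    )


def write_tsv(frame: pd.DataFrame, path) -> Path:
    """Write a table as TSV with full-precision floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectory_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_outputs(
    result: SimulationResult,
    rad: pd.DataFrame | None,
    manifest: RunManifest,
    out_dir,
    per_individual: bool = False,
) -> list[Path]:
    """Write trajectory, final census, optional RAD and per-individual state,
    plus the manifest, into ``out_dir``.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    written.append(write_tsv(result.trajectory, out_dir / "trajectory.tsv"))
    final_gen = result.trajectory["generation"].max()
    census = result.trajectory[result.trajectory["generation"] == final_gen]
    written.append(write_tsv(census, out_dir / "final_census.tsv"))
    if rad is not None:
        written.append(write_tsv(rad, out_dir / "rad.tsv"))
    if per_individual:
        st = result.final_state
        frame = pd.DataFrame(
            {"slot": np.arange(st.n_individuals), "species_id": st.species,
             "deme": st.deme, "g": st.g}
        )
        written.append(write_tsv(frame, out_dir / "individuals.tsv"))

    manifest.output_files = [p.name for p in written]
    man_path = out_dir / "manifest.json"
    man_path.write_text(manifest.to_json() + "\n")
    written.append(man_path)
    return written
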