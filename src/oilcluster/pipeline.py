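"""Run-configuration handling and pipeline orchestration.

A run configuration names the input structure/trajectory, the species map,
the fraction of leading frames discarded as equilibration, and a set of
analysis blocks.  ``run_pipeline`` executes every enabled analysis, writes
one result table per analysis plus a JSON manifest echoing all parameters
(for provenance), and returns the written paths.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, dynamics, hbonds, structure
from .io import (
    Trajectory,
    load_species_map,
    read_structure,
    read_trajectory,
    write_series,
)
from .pbc import com_series, unwrap

KNOWN_ANALYSES = ("clusters", "swarm", "rdf", "msd", "vanhove", "hbonds")
_TOP_KEYS = {
    "structure",
    "trajectory",
    "species_map",
    "equilibration_discard_fraction",
    "output_dir",
    "seed",
    "analyses",
}


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`load_run_config`)."""

    structure: Path
    trajectory: Path
    output_dir: Path
    species_map: Path | None = None
    equilibration_discard_fraction: float = 0.5
    seed: int = 0
    analyses: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.equilibration_discard_fraction < 1.0):
            raise ValueError(
                "equilibration_discard_fraction: must lie in [0, 1), got "
                f"{self.equilibration_discard_fraction}"
            )
        for name in self.analyses:
            if name not in KNOWN_ANALYSES:
                raise ValueError(
                    f"analyses.{name}: unknown analysis (choose from {KNOWN_ANALYSES})"
                )


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    for key in ("structure", "trajectory", "output_dir"):
        if key not in raw:
            raise ValueError(f"{path}: missing required key '{key}'")
    base = path.parent
    def _p(v):
        p = Path(v)
        return p if p.is_absolute() else base / p
    return RunConfig(
        structure=_p(raw["structure"]),
        trajectory=_p(raw["trajectory"]),
        output_dir=_p(raw["output_dir"]),
        species_map=_p(raw["species_map"]) if raw.get("species_map") else None,
        equilibration_discard_fraction=float(
            raw.get("equilibration_discard_fraction", 0.5)
        ),
        seed=int(raw.get("seed", 0)),
        analyses=dict(raw.get("analyses") or {}),
    )


def _com(cache: dict, traj: Trajectory, species: str):
    if species not in cache:
        cache[species] = com_series(traj, species)
    return cache[species]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled analysis and write its result table.

    Returns a summary dict (also written as ``manifest.json``) recording,
    per analysis, the parameters used and the output file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    species_map = (
        load_species_map(config.species_map) if config.species_map else None
    )
    topology, _frame = read_structure(config.structure, species_map)
    traj = read_trajectory(config.trajectory, topology)
    n_total = traj.n_frames
    traj = traj.discard_equilibration(config.equilibration_discard_fraction)
    summary: dict = {
        "inputs": {
            "structure": str(config.structure),
            "trajectory": str(config.trajectory),
            "species_map": str(config.species_map) if config.species_map else None,
        },
        "equilibration_discard_fraction": config.equilibration_discard_fraction,
        "frames_total": int(n_total),
        "frames_analyzed": int(traj.n_frames),
        "seed": config.seed,
        "analyses": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    cache: dict = {}
    log_lines = [f"frames: {n_total} read, {traj.n_frames} analyzed"]

    for name, params in config.analyses.items():
        params = dict(params or {})
        if name == "clusters":
            sp = params.pop("species")
            cp = clustering.ClusterParams(
                eps=params.pop("eps", 0.65), min_samples=params.pop("min_samples", 2)
            )
            cts = clustering.cluster_time_series(_com(cache, traj, sp), cp)
            dest = out / "clusters.csv"
            write_series(cts.to_frame(), dest)
            used = {"species": sp, "eps": cp.eps, "min_samples": cp.min_samples}
        elif name == "swarm":
            sp = params.pop("species")
            dest = out / "swarm.csv"
            write_series(clustering.swarm_series(_com(cache, traj, sp)), dest)
            used = {"species": sp}
        elif name == "rdf":
            pair = params.pop("pair")
            sa = _com(cache, traj, pair[0])
            sb = None if pair[1] == pair[0] else _com(cache, traj, pair[1])
            res = structure.rdf_com(
                sa,
                sb,
                bin_width=params.pop("bin_width", 0.02),
                r_max=params.pop("r_max", None),
                extended=params.pop("extended", False),
            )
            dest = out / f"rdf_{pair[0]}_{pair[1]}.csv"
            write_series(
                pd.DataFrame({"r_nm": res.centers, "g": res.g, "n_r": res.n_r}), dest
            )
            used = {"pair": list(pair), "extended": res.extended,
                    "r_max": float(res.edges[-1])}
        elif name == "msd":
            sp = params.pop("species")
            series = unwrap(_com(cache, traj, sp))
            res = dynamics.msd(
                series, origin_stride=params.pop("origin_stride", 10)
            )
            fit = dynamics.fit_diffusion(res) if res.lag_times[-1] > 0 else None
            dest = out / f"msd_{sp}.csv"
            write_series(
                pd.DataFrame({"lag_ps": res.lag_times, "msd_nm2": res.msd}), dest
            )
            used = {"species": sp}
            if fit is not None:
                used.update(
                    {"D_nm2_ps": fit.D, "D_cm2_s": fit.D_cm2_s,
                     "fit_window_ps": list(fit.window), "diffusive": fit.diffusive}
                )
        elif name == "vanhove":
            sp = params.pop("species")
            wrapped = _com(cache, traj, sp)
            vh = dynamics.van_hove_distinct(
                wrapped, bin_width=params.pop("bin_width", 0.02)
            )
            decay = dynamics.peak_decay(vh)
            dest = out / f"vanhove_{sp}.csv"
            table = pd.DataFrame(
                vh.gd.T, columns=[f"t={t:g}ps" for t in vh.lag_times]
            )
            table.insert(0, "r_nm", vh.centers)
            write_series(table, dest)
            write_series(
                pd.DataFrame({"lag_ps": decay.lag_times, "peak_ratio": decay.ratio}),
                out / f"vanhove_peak_{sp}.csv",
            )
            used = {"species": sp, "no_peak": decay.no_peak,
                    "window_nm": decay.window_nm}
        elif name == "hbonds":
            crit = hbonds.HBondCriterion(
                d_max=params.pop("d_max", 0.35),
                angle_max=params.pop("angle_max", 30.0),
            )
            cls = params.pop("class", "polymer-compound")
            series = hbonds.hbond_counts(traj, crit)
            acf = hbonds.hbond_acf(series, cls)
            dest = out / "hbond_counts.csv"
            write_series(series.counts, dest)
            used = {"d_max": crit.d_max, "angle_max": crit.angle_max, "class": cls}
            if acf.c.size:
                tau = hbonds.integrate_acf(acf)
                write_series(
                    pd.DataFrame({"lag_ps": acf.lag_times, "C": acf.c}),
                    out / f"hbond_acf_{cls}.csv",
                )
                used.update({"tau_ps": tau.tau, "tau_truncated": tau.truncated})
        else:  # pragma: no cover - guarded by RunConfig validation
            raise ValueError(f"unknown analysis {name!r}")
        if params:
            raise ValueError(f"analyses.{name}: unknown parameters {sorted(params)}")
        summary["analyses"][name] = {"parameters": used, "output": str(dest)}
        log_lines.append(f"{name}: wrote {dest}")

    with open(out / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
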