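"""CSV/YAML/JSON interchange for plates, absorbance, AFM tables and configs.

CSV is the sole tabular format (plate readers export it), YAML carries
run configuration, JSON carries results and run manifests.  Time is in
hours at every file interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import ThTTrajectory
from .kinetics import Schedule, SonicationEvent, StateTrajectory

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_absorbance_csv",
    "read_afm_csv",
    "write_trajectory_csv",
    "write_population_csv",
    "read_population_csv",
    "schedule_from_dict",
    "load_config",
    "write_manifest",
]

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["time_h", "well", "variant", "phase", "fluorescence_au"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_plate_csv(path) -> list[ThTTrajectory]:
    """Load a long-format plate CSV into per-well, per-phase trajectories.

    Rows with non-finite time or fluorescence are dropped with a logged
    count.  Raises on missing columns or an empty file.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    _require_columns(df, PLATE_COLUMNS, path)
    num = df.assign(
        time_h=pd.to_numeric(df["time_h"], errors="coerce"),
        fluorescence_au=pd.to_numeric(df["fluorescence_au"], errors="coerce"),
    )
    bad = ~(np.isfinite(num["time_h"]) & np.isfinite(num["fluorescence_au"]))
    if bad.any():
        logger.warning("%s: dropped %d malformed rows", path, int(bad.sum()))
    num = num[~bad]
    if num.empty:
        raise ValueError(f"{path}: no valid data rows")
    out = []
    for (well, variant, phase), grp in num.groupby(
        ["well", "variant", "phase"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(ThTTrajectory(
            times=grp["time_h"].to_numpy(),
            values=grp["fluorescence_au"].to_numpy(),
            replicate_id=str(well), variant=str(variant),
            phase_label=str(phase),
        ))
    return out


def write_plate_csv(df: pd.DataFrame, path) -> None:
    _require_columns(df, PLATE_COLUMNS, path)
    df.to_csv(path, index=False)


def read_absorbance_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample", "phase", "a280"], path)
    return df


def read_afm_csv(path, min_length_nm: float = 50.0) -> pd.DataFrame:
    """Load an AFM measurement table, filtering lengths below the minimum
    measurable length (default 50 nm, logged)."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample", "phase", "length_nm"], path)
    has_len = df["length_nm"].notna()
    short = has_len & (df["length_nm"] < min_length_nm)
    if short.any():
        logger.info(
            "%s: filtered %d fibrils below %.0f nm", path, int(short.sum()),
            min_length_nm,
        )
    return df[~short].reset_index(drop=True)


def write_trajectory_csv(traj: StateTrajectory, path) -> None:
    pd.DataFrame({
        "time_h": traj.times,
        "phase": traj.phase_labels.astype(str),
        "m_uM": traj.m,
        "M_A_uM": traj.M_A,
        "M_B_uM": traj.M_B,
        "P_M": traj.P,
        "F_au": traj.F,
    }).to_csv(path, index=False)


def write_population_csv(pop, path, rng_seed: int | None = None,
                         rho: float = 2.0 / 0.47) -> None:
    """Snapshot a fibril population (fibril_id, length_monomers,
    length_nm, polymorph); the RNG seed is recorded as a header comment."""
    with open(path, "w") as fh:
        if rng_seed is not None:
            fh.write(f"# rng_seed={rng_seed}\n")
        pd.DataFrame({
            "fibril_id": np.arange(1, pop.n_fibrils + 1),
            "length_monomers": pop.lengths,
            "length_nm": pop.lengths / rho,
            "polymorph": pop.polymorph,
        }).to_csv(fh, index=False)


def read_population_csv(path):
    from .population import FibrilPopulation

    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["length_monomers", "polymorph"], path)
    return FibrilPopulation(
        lengths=df["length_monomers"].to_numpy(dtype=np.int64),
        polymorph=df["polymorph"].to_numpy(dtype=object),
        free_monomer=0,
    )


def schedule_from_dict(d: dict) -> Schedule:
    """Build a Schedule from a config mapping.

    Expected keys: ``phases`` (list of [label, duration_h]), ``events``
    (list of mappings with time/length_divisor/min_mean_length/
    disassembly_fraction/conversion_prob), ``sampling_rate``.
    """
    phases = tuple((str(lbl), float(dur)) for lbl, dur in d["phases"])
    events = tuple(
        SonicationEvent(
            time=float(e["time"]),
            length_divisor=float(e.get("length_divisor", 5.0)),
            min_mean_length=float(e.get("min_mean_length", 150.0)),
            disassembly_fraction=float(e.get("disassembly_fraction", 0.0)),
            conversion_prob=float(e.get("conversion_prob", 0.0)),
        )
        for e in d.get("events", [])
    )
    return Schedule(
        phases=phases, events=events,
        sampling_rate=float(d.get("sampling_rate", 6.0)),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in cfg.get("inputs", {}).values():
        if not Path(key).exists():
            raise FileNotFoundError(f"{path}: referenced input {key} not found")
    return cfg


def write_manifest(path, config: dict, seed: int | None = None) -> dict:
    """Record config hash, seed and package version alongside outputs."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "synkin_version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
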