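"""File formats and run configuration.

PDB reading/writing (ATOM/MODEL/ENDMDL subset; occupancy/B-factor ignored on
read, written as 1.00/0.00) is delegated to biotite behind Frame/Trajectory
converters.  COLVAR and HILLS files use the PLUMED text dialect: a header
line ``#! FIELDS time <names...>`` followed by whitespace-separated columns.
FES grids round-trip through tab-separated files with '#' metadata headers
naming axes, units and the min-shift convention.  Run configurations are
YAML with all defaults materialized on load and unknown keys rejected; every
output file header records the config hash and seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .fes import FESAxis, FESGrid
from .frames import Frame, Trajectory, _element


class ParseError(ValueError):
    """Malformed text input, annotated with the offending line."""


# ---------------------------------------------------------------------------
# PDB


def _to_atom_array(frame: Frame) -> AtomArray:
    n = frame.n_atoms
    arr = AtomArray(n)
    arr.coord = frame.coords.astype(np.float32)
    arr.chain_id = np.array(frame.chain_ids)
    arr.res_id = frame.residue_indices
    arr.res_name = np.array(frame.residue_names)
    arr.atom_name = np.array(frame.atom_names)
    arr.element = np.array([_element(a) for a in frame.atom_names])
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def _from_atom_array(arr: AtomArray) -> Frame:
    return Frame(
        np.asarray(arr.coord, dtype=float),
        [str(a) for a in arr.atom_name],
        np.asarray(arr.res_id, dtype=int),
        [str(r) for r in arr.res_name],
        [str(c) for c in arr.chain_id],
    )


def write_pdb(path: str | Path, obj: Frame | Trajectory) -> None:
    """Write a frame (single model) or trajectory (multi-model) PDB file."""
    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        template = _to_atom_array(obj.topology)
        stack = AtomArrayStack(obj.n_frames, obj.topology.n_atoms)
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = obj.coords.astype(np.float32)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(obj))
    pdb.write(str(path))


def read_pdb(path: str | Path) -> Frame:
    """Read the first model of a PDB file as a Frame."""
    pdb = PDBFile.read(str(path))
    structure = pdb.get_structure(model=1)
    return _from_atom_array(structure)


def read_pdb_trajectory(path: str | Path, dt_ps: float = 1.0) -> Trajectory:
    """Read all models of a PDB file as a Trajectory."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, AtomArray):
        stack = stack[np.newaxis]
    top = _from_atom_array(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    return Trajectory(top, coords, np.arange(len(coords)) * dt_ps)


# ---------------------------------------------------------------------------
# COLVAR / HILLS dialect


def write_colvar(
    path: str | Path, record: pd.DataFrame, header_comments: list[str] | None = None
) -> None:
    """Write a record in the PLUMED COLVAR/HILLS text dialect.

    Field names and order are preserved; values are written at full
    precision.  Extra '#'-prefixed comment lines may precede the FIELDS line.
    """
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("#! FIELDS " + " ".join(record.columns) + "\n")
        for row in record.itertuples(index=False):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_colvar(path: str | Path) -> pd.DataFrame:
    """Read a COLVAR/HILLS-dialect file; lossless for full-precision writes."""
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#!"):
                parts = text.split()
                if len(parts) < 3 or parts[1] != "FIELDS":
                    raise ParseError(
                        f"line {lineno}: malformed header {text!r} "
                        "(expected '#! FIELDS <names...>')"
                    )
                fields = parts[2:]
                continue
            if text.startswith("#"):
                continue
            if fields is None:
                raise ParseError(
                    f"line {lineno}: data before a '#! FIELDS' header"
                )
            values = text.split()
            if len(values) != len(fields):
                raise ParseError(
                    f"line {lineno}: expected {len(fields)} columns, "
                    f"got {len(values)}"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    if fields is None:
        raise ParseError("no '#! FIELDS' header found")
    return pd.DataFrame(rows, columns=fields)


write_hills = write_colvar
read_hills = read_colvar


# ---------------------------------------------------------------------------
# FES grids


def write_fes(path: str | Path, grid: FESGrid, comments: list[str] | None = None) -> None:
    """Write a 1D/2D FES grid as tab-separated text, losslessly re-readable.

    Headers name the axes and units and record the min-shift convention
    (lowest unmasked bin = 0).  Masked bins are written as 'nan'.
    """
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# fes ndim={grid.ndim} convention=min-shifted-to-zero\n")
        for ax in grid.axes:
            edges = ",".join(f"{e:.17g}" for e in ax.edges)
            fh.write(f"# axis name={ax.name} units={ax.units or '-'} edges={edges}\n")
        has_err = grid.error is not None
        has_counts = grid.counts is not None
        cols = [ax.name for ax in grid.axes] + ["F"]
        if has_err:
            cols.append("error")
        if has_counts:
            cols.append("count")
        fh.write("\t".join(cols) + "\n")
        it = np.ndindex(*grid.F.shape)
        for idx in it:
            vals = [f"{grid.axes[d].centers[idx[d]]:.17g}" for d in range(grid.ndim)]
            vals.append(f"{grid.F[idx]:.17g}")
            if has_err:
                vals.append(f"{np.asarray(grid.error)[idx]:.17g}")
            if has_counts:
                vals.append(f"{np.asarray(grid.counts)[idx]:.17g}")
            fh.write("\t".join(vals) + "\n")


def read_fes(path: str | Path) -> FESGrid:
    """Read a FES grid written by :func:`write_fes`."""
    axes: list[FESAxis] = []
    ndim = None
    data_lines: list[str] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.rstrip("\n")
            if not text.strip():
                continue
            if text.startswith("# fes "):
                for tok in text.split():
                    if tok.startswith("ndim="):
                        ndim = int(tok[5:])
                continue
            if text.startswith("# axis "):
                fieldsd = dict(
                    tok.split("=", 1) for tok in text[7:].split() if "=" in tok
                )
                edges = np.array([float(v) for v in fieldsd["edges"].split(",")])
                units = fieldsd.get("units", "-")
                axes.append(
                    FESAxis(fieldsd["name"], edges, "" if units == "-" else units)
                )
                continue
            if text.startswith("#"):
                continue
            if header is None:
                header = text.split("\t")
                continue
            data_lines.append(text)
    if ndim is None or len(axes) != ndim or header is None:
        raise ParseError(f"{path}: not a FES grid file")
    shape = tuple(ax.n_bins for ax in axes)
    f = np.full(shape, np.nan)
    err = np.full(shape, np.nan) if "error" in header else None
    counts = np.zeros(shape) if "count" in header else None
    rows = [line.split("\t") for line in data_lines]
    for idx, row in zip(np.ndindex(*shape), rows):
        vals = dict(zip(header, row))
        f[idx] = float(vals["F"])
        if err is not None:
            err[idx] = float(vals["error"])
        if counts is not None:
            counts[idx] = float(vals["count"])
    mask = ~np.isfinite(f)
    return FESGrid(axes=axes, F=f, error=err, mask=mask, counts=counts)


# ---------------------------------------------------------------------------
# Run configuration


CONFIG_DEFAULTS: dict = {
    "model": {
        "kind": "helix_coil",
        "params": {},
    },
    "sampler": {
        "temperature_K": 310.0,
        "friction_per_ps": 1.0,
        "timestep_ps": 0.002,
        "n_steps": 200_000,
        "hill_interval_ps": 4.0,
        "exchange_interval_ps": 10.0,
        "output_stride": 100,
        "hill_height_kcal": 0.3,
        "hill_sigma": 0.1,
        "bias_factor": 10.0,
        "replica_cvs": None,  # model-dependent default filled on load
        "seed": 0,
    },
    "analysis": {
        "grid": None,  # {"name":..., "lo":..., "hi":..., "n_bins":...}
        "block_size": 100,
        "equilibration_fraction": 0.2,
        "min_count": 5,
        "hbond_distance_A": 3.2,
        "hbond_angle_deg": 30.0,
        "cluster_cutoff_A": 2.0,
        "ss_threshold": 0.5,
    },
    "output_dir": "results/run",
}

_MODEL_DEFAULT_CVS = {
    "helix_coil": [None, "helix_fraction", "neighbor_alignment"],
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and key != "params" and (
            key != "grid"
        ):
            if not isinstance(value, dict):
                raise ValueError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run config, materializing defaults and rejecting unknowns."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    config = _merge(CONFIG_DEFAULTS, raw)
    if overrides:
        config = _merge(config, overrides)
    if config["sampler"]["replica_cvs"] is None:
        kind = config["model"]["kind"]
        config["sampler"]["replica_cvs"] = _MODEL_DEFAULT_CVS.get(kind, ["x"])
    return config


def config_hash(config: dict) -> str:
    """Short stable hash of a config for output-file stamping."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    )
    return digest.hexdigest()[:12]


def header_stamp(config: dict, seed: int | None = None) -> list[str]:
    """Standard output-header comment lines: config echo, hash, seed."""
    seed_val = config["sampler"]["seed"] if seed is None else seed
    echo = json.dumps(config, sort_keys=True, default=str)
    return [
        f"config {echo}",
        f"config_sha256 {config_hash(config)}",
        f"seed {seed_val}",
        "units coordinates=angstrom energy=kcal/mol time=ps",
    ]
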