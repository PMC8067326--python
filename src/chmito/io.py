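"""Configuration, serialization and fixtures: the reproducibility shell.

Run configurations are TOML with [domain], [[granules]], [solver] and
[output] sections; every run echoes its fully-defaulted configuration next
to its outputs so a run is reproducible from its output directory alone.
Snapshots are ASCII .vtu files (ParaView-readable), checkpoints a single
HDF5 file holding mesh, both fields, step/time and the config echo.
"""

from __future__ import annotations

import json
import logging
import os
import tomllib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields as dc_fields

import h5py
import numpy as np

from . import records as rec_mod
from .ch_solver import (SimulationState, SolverConfig, initialize_random,
                        run_simulation)
from .energetics import ChemicalPotentialField, PhaseField
from .geometry import (Domain, GranuleSpec, build_domain, interval_domain,
                       rectangle_domain)
from .linear_analysis import equilibrium_profile

logger = logging.getLogger("chmito")

CHECKPOINT_VERSION = 1


class ConfigError(ValueError):
    """Malformed run configuration."""


class CheckpointError(RuntimeError):
    """Unreadable or corrupt checkpoint file."""


class CheckpointVersionError(CheckpointError):
    """Checkpoint written by an incompatible format version."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class DomainSection:
    shape: str
    size_params: list
    h_target: float = 0.15


@dataclass
class OutputSection:
    directory: str = "out"
    record_every: int = 250
    snapshot_every: int = 0  # 0: only the final snapshot
    formats: tuple = ("csv", "vtu")


@dataclass
class RunConfig:
    domain: DomainSection
    granules: list
    solver: SolverConfig
    n_steps: int
    output: OutputSection
    defaulted: list = field(default_factory=list, compare=False, repr=False)


_DOMAIN_SCHEMA = {"shape": None, "size_params": None, "h_target": 0.15}
_GRANULE_SCHEMA = {"center": None, "radius": None, "pinned_value": 1.0}
_SOLVER_SCHEMA = {"gamma": 1.0, "dt": 1e-3, "theta": 0.5, "mobility": 0.5,
                  "n_steps": 1000, "newton_abs_tol": 1e-10, "newton_rel_tol": 1e-8,
                  "newton_max_iter": 25, "seed": 0, "record_every": 250,
                  "init_mean": 0.0, "init_amplitude": 0.05}
_OUTPUT_SCHEMA = {"directory": "out", "record_every": None, "snapshot_every": 0,
                  "formats": ["csv", "vtu"]}


def _apply_schema(section: dict, schema: dict, path: str, defaulted: list) -> dict:
    unknown = sorted(set(section) - set(schema))
    if unknown:
        raise ConfigError(f"unknown key(s) in [{path}]: {', '.join(unknown)}")
    out = {}
    for key, default in schema.items():
        if key in section:
            out[key] = section[key]
        else:
            if default is None:
                raise ConfigError(f"missing required key {path}.{key}")
            out[key] = default
            defaulted.append(f"{path}.{key}")
    return out


def parse_config(data: dict) -> RunConfig:
    """Validate a parsed TOML mapping into a RunConfig with defaults filled."""
    unknown = sorted(set(data) - {"domain", "granules", "solver", "output"})
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(unknown)}")
    defaulted = []
    if "domain" not in data:
        raise ConfigError("missing required section [domain]")
    dom = _apply_schema(data["domain"], _DOMAIN_SCHEMA, "domain", defaulted)
    try:
        domain = DomainSection(shape=str(dom["shape"]),
                               size_params=[float(s) for s in dom["size_params"]],
                               h_target=float(dom["h_target"]))
    except (TypeError, ValueError) as err:
        raise ConfigError(f"domain section: {err}") from None

    granules = []
    for i, g in enumerate(data.get("granules", [])):
        gr = _apply_schema(g, _GRANULE_SCHEMA, f"granules[{i}]", defaulted)
        try:
            granules.append(GranuleSpec(center=tuple(gr["center"]),
                                        radius=float(gr["radius"]),
                                        pinned_value=float(gr["pinned_value"])))
        except (TypeError, ValueError) as err:
            raise ConfigError(f"granules[{i}]: {err}") from None

    sol = _apply_schema(data.get("solver", {}), _SOLVER_SCHEMA, "solver", defaulted)
    n_steps = int(sol.pop("n_steps"))
    record_every = int(sol["record_every"])
    try:
        solver = SolverConfig(**{k: type(_SOLVER_SCHEMA[k])(v) for k, v in sol.items()})
    except ValueError as err:
        raise ConfigError(f"solver section: {err}") from None
    if n_steps < 1:
        raise ConfigError("solver.n_steps must be ≥ 1")

    out_schema = dict(_OUTPUT_SCHEMA)
    out_schema["record_every"] = record_every
    out = _apply_schema(data.get("output", {}), out_schema, "output", defaulted)
    output = OutputSection(directory=str(out["directory"]),
                           record_every=int(out["record_every"]),
                           snapshot_every=int(out["snapshot_every"]),
                           formats=tuple(out["formats"]))
    if output.record_every != solver.record_every:
        solver = SolverConfig(**{**{f.name: getattr(solver, f.name)
                                    for f in dc_fields(solver)},
                                 "record_every": output.record_every})
    cfg = RunConfig(domain=domain, granules=granules, solver=solver,
                    n_steps=n_steps, output=output, defaulted=defaulted)
    for key in defaulted:
        logger.debug("config default applied: %s", key)
    return cfg


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:
            raise ConfigError(f"{path}: {err}") from None
    return parse_config(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        r = repr(float(v))
        return r if any(c in r for c in ".einf") else r + ".0"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def echo_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to TOML (lossless round trip)."""
    lines = ["[domain]"]
    lines.append(f"shape = {_toml_value(cfg.domain.shape)}")
    lines.append(f"size_params = {_toml_value(cfg.domain.size_params)}")
    lines.append(f"h_target = {_toml_value(cfg.domain.h_target)}")
    for g in cfg.granules:
        lines += ["", "[[granules]]",
                  f"center = {_toml_value(list(g.center))}",
                  f"radius = {_toml_value(g.radius)}",
                  f"pinned_value = {_toml_value(g.pinned_value)}"]
    lines += ["", "[solver]"]
    for f in dc_fields(cfg.solver):
        lines.append(f"{f.name} = {_toml_value(getattr(cfg.solver, f.name))}")
    lines.append(f"n_steps = {_toml_value(cfg.n_steps)}")
    lines += ["", "[output]",
              f"directory = {_toml_value(cfg.output.directory)}",
              f"record_every = {_toml_value(cfg.output.record_every)}",
              f"snapshot_every = {_toml_value(cfg.output.snapshot_every)}",
              f"formats = {_toml_value(list(cfg.output.formats))}"]
    return "\n".join(lines) + "\n"


def build_domain_from_config(cfg: RunConfig) -> Domain:
    return build_domain(cfg.domain.shape, cfg.domain.size_params,
                        cfg.granules, cfg.domain.h_target)


# ---------------------------------------------------------------------------
# VTU snapshots (ASCII XML; ParaView-readable)
# ---------------------------------------------------------------------------

_VTK_CELL = {(1, 2): 3, (2, 3): 5, (3, 4): 10}       # line, triangle, tetra
_VTK_FACET = {1: 1, 2: 3, 3: 5}                       # vertex, line, triangle


def _ascii(arr, fmt="{!r}") -> str:
    flat = np.asarray(arr).ravel()
    return " ".join(fmt.format(v) for v in flat.tolist())


def write_snapshot(state: SimulationState, d: Domain, path) -> None:
    """Write mesh + point arrays "psi"/"mu" + boundary tags as ASCII .vtu.

    Volume elements carry cell tag −1; boundary facets are appended as
    lower-dimensional cells tagged 0 (outer) or 1+granule index.
    """
    pts3 = np.zeros((d.n_nodes, 3))
    pts3[:, : d.dimension] = d.nodes

    cells = [d.elements]
    tags = [np.full(len(d.elements), -1, dtype=int)]
    if d.outer_facets.size:
        cells.append(d.outer_facets)
        tags.append(np.zeros(len(d.outer_facets), dtype=int))
    for gi, facets in sorted(d.granule_facets.items()):
        if facets.size:
            cells.append(facets)
            tags.append(np.full(len(facets), gi + 1, dtype=int))

    conn, offsets, types = [], [], []
    off = 0
    for block in cells:
        nper = block.shape[1]
        ctype = _VTK_CELL[(d.dimension, nper)] if nper == d.dimension + 1 \
            else _VTK_FACET[nper]
        for row in block:
            conn.extend(int(v) for v in row)
            off += nper
            offsets.append(off)
            types.append(ctype)
    tag_arr = np.concatenate(tags)

    meta = {"step": [state.step], "time": [state.time],
            "gamma": [getattr(state, "gamma", float("nan"))]}
    granule_rows = [list(g.center) + [g.radius, g.pinned_value] for g in d.granules]

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="1.0" byte_order="LittleEndian">\n')
        fh.write(f'<!-- chmito snapshot; shape_descriptor={json.dumps(d.shape_descriptor)} -->\n')
        fh.write("<UnstructuredGrid>\n")
        fh.write(f'<FieldData>\n'
                 f'<DataArray type="Float64" Name="step" NumberOfTuples="1" format="ascii">'
                 f'{state.step}</DataArray>\n'
                 f'<DataArray type="Float64" Name="time" NumberOfTuples="1" format="ascii">'
                 f'{state.time!r}</DataArray>\n')
        if granule_rows:
            flat = _ascii(np.asarray(granule_rows, dtype=float))
            fh.write(f'<DataArray type="Float64" Name="granules" '
                     f'NumberOfTuples="{len(granule_rows) * (d.dimension + 2)}" '
                     f'format="ascii">{flat}</DataArray>\n')
        fh.write("</FieldData>\n")
        fh.write(f'<Piece NumberOfPoints="{d.n_nodes}" NumberOfCells="{len(types)}">\n')
        fh.write('<Points>\n<DataArray type="Float64" NumberOfComponents="3" '
                 'format="ascii">\n')
        fh.write(_ascii(pts3))
        fh.write("\n</DataArray>\n</Points>\n<Cells>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n'
                 + " ".join(str(v) for v in conn) + "\n</DataArray>\n")
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n'
                 + " ".join(str(v) for v in offsets) + "\n</DataArray>\n")
        fh.write('<DataArray type="UInt8" Name="types" format="ascii">\n'
                 + " ".join(str(v) for v in types) + "\n</DataArray>\n")
        fh.write("</Cells>\n<PointData>\n")
        fh.write('<DataArray type="Float64" Name="psi" format="ascii">\n'
                 + _ascii(state.psi.values) + "\n</DataArray>\n")
        fh.write('<DataArray type="Float64" Name="mu" format="ascii">\n'
                 + _ascii(state.mu.values) + "\n</DataArray>\n")
        fh.write("</PointData>\n<CellData>\n")
        fh.write('<DataArray type="Int64" Name="boundary_tag" format="ascii">\n'
                 + " ".join(str(int(v)) for v in tag_arr) + "\n</DataArray>\n")
        fh.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def read_snapshot(path):
    """Read back an ASCII .vtu snapshot -> (Domain, SimulationState).

    Reconstructs the Domain from the volume cells and tagged facet cells;
    granule geometry comes from the "granules" field-data array.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise CheckpointError(f"{path}: no <Piece> element")

    def parse_nums(text, dtype=float):
        return np.array(text.split(), dtype=dtype)

    def arr(xpath, dtype=float):
        el = piece.find(xpath) if piece.find(xpath) is not None else root.find(xpath)
        return parse_nums(el.text, dtype)

    pts = arr('Points/DataArray').reshape(-1, 3)
    conn = arr('Cells/DataArray[@Name="connectivity"]', dtype=np.int64)
    offsets = arr('Cells/DataArray[@Name="offsets"]', dtype=np.int64)
    types = arr('Cells/DataArray[@Name="types"]', dtype=np.int64)
    psi = arr('PointData/DataArray[@Name="psi"]')
    mu = arr('PointData/DataArray[@Name="mu"]')
    tag_el = piece.find('CellData/DataArray[@Name="boundary_tag"]')
    tags = parse_nums(tag_el.text, np.int64)

    starts = np.concatenate([[0], offsets[:-1]])
    dim = 3 if 10 in types else 2 if 5 in types and 10 not in types else 1
    vol_type = {1: 3, 2: 5, 3: 10}[dim]
    vol = [conn[s:e] for s, e, t in zip(starts, offsets, types) if t == vol_type]
    # a 2D mesh stores triangles (type 5) as volume cells and lines as facets
    if dim == 3 and 5 in types:
        facet_type = 5
    elif dim >= 2:
        facet_type = 3
    else:
        facet_type = 1
    elements = np.array(vol, dtype=np.int64)

    facets, facet_tags = [], []
    for s, e, t, tag in zip(starts, offsets, types, tags):
        if t == facet_type and t != vol_type:
            facets.append(conn[s:e])
            facet_tags.append(tag)
    facets = np.array(facets, dtype=np.int64) if facets \
        else np.empty((0, dim), dtype=np.int64)
    facet_tags = np.asarray(facet_tags, dtype=np.int64)

    nodes = pts[:, :dim]
    granules = []
    gdata = root.find('.//FieldData/DataArray[@Name="granules"]')
    if gdata is not None:
        rows = parse_nums(gdata.text).reshape(-1, dim + 2)
        granules = [GranuleSpec(tuple(r[:dim]), r[dim], r[dim + 1]) for r in rows]

    descriptor = {"shape": "unknown"}
    outer = facets[facet_tags == 0] if facets.size else facets
    granule_facets = {gi: facets[facet_tags == gi + 1] for gi in range(len(granules))}
    step_el = root.find('.//FieldData/DataArray[@Name="step"]')
    time_el = root.find('.//FieldData/DataArray[@Name="time"]')
    step = int(float(step_el.text)) if step_el is not None else 0
    time = float(time_el.text) if time_el is not None else 0.0

    d = Domain(dimension=dim, nodes=nodes, elements=elements, outer_facets=outer,
               granule_facets=granule_facets, granules=granules,
               h_target=float("nan"), shape_descriptor=descriptor)
    state = SimulationState(step=step, time=time, psi=PhaseField(psi, d),
                            mu=ChemicalPotentialField(mu, d))
    return d, state


# ---------------------------------------------------------------------------
# HDF5 checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: SimulationState, d: Domain, cfg) -> None:
    """Single-file checkpoint: mesh, both fields, step/time, config echo."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = CHECKPOINT_VERSION
        mesh = fh.create_group("mesh")
        mesh.create_dataset("nodes", data=d.nodes)
        mesh.create_dataset("elements", data=d.elements)
        mesh.create_dataset("element_coords", data=d.element_coords)
        mesh.create_dataset("outer_facets", data=d.outer_facets)
        mesh.attrs["dimension"] = d.dimension
        mesh.attrs["periodic"] = d.periodic
        mesh.attrs["h_target"] = d.h_target
        mesh.attrs["shape_descriptor"] = json.dumps(d.shape_descriptor)
        gg = mesh.create_group("granules")
        for i, g in enumerate(d.granules):
            grp = gg.create_group(str(i))
            grp.attrs["center"] = list(g.center)
            grp.attrs["radius"] = g.radius
            grp.attrs["pinned_value"] = g.pinned_value
            grp.create_dataset("facets", data=d.granule_facets.get(
                i, np.empty((0, d.dimension), dtype=np.int64)))
        st = fh.create_group("state")
        st.create_dataset("psi", data=state.psi.values)
        st.create_dataset("mu", data=state.mu.values)
        st.attrs["step"] = state.step
        st.attrs["time"] = state.time
        if isinstance(cfg, RunConfig):
            fh.attrs["config_kind"] = "run"
            fh.attrs["config"] = echo_config(cfg)
        else:
            fh.attrs["config_kind"] = "solver"
            fh.attrs["config"] = json.dumps(
                {f.name: getattr(cfg, f.name) for f in dc_fields(cfg)})


def load_checkpoint(path):
    """Restore (state, domain, cfg) from a checkpoint file."""
    try:
        fh = h5py.File(path, "r")
    except OSError as err:
        raise CheckpointError(f"{path}: unreadable checkpoint ({err})") from None
    with fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != CHECKPOINT_VERSION:
            raise CheckpointVersionError(
                f"{path}: checkpoint format v{version}, expected v{CHECKPOINT_VERSION}")
        mesh = fh["mesh"]
        granules, granule_facets = [], {}
        for key in sorted(mesh["granules"], key=int):
            grp = mesh["granules"][key]
            granules.append(GranuleSpec(tuple(grp.attrs["center"]),
                                        float(grp.attrs["radius"]),
                                        float(grp.attrs["pinned_value"])))
            granule_facets[int(key)] = grp["facets"][()]
        d = Domain(dimension=int(mesh.attrs["dimension"]),
                   nodes=mesh["nodes"][()], elements=mesh["elements"][()],
                   outer_facets=mesh["outer_facets"][()],
                   granule_facets=granule_facets, granules=granules,
                   h_target=float(mesh.attrs["h_target"]),
                   shape_descriptor=json.loads(mesh.attrs["shape_descriptor"]),
                   element_coords=mesh["element_coords"][()],
                   periodic=bool(mesh.attrs["periodic"]))
        st = fh["state"]
        state = SimulationState(step=int(st.attrs["step"]), time=float(st.attrs["time"]),
                                psi=PhaseField(st["psi"][()], d),
                                mu=ChemicalPotentialField(st["mu"][()], d))
        if fh.attrs["config_kind"] == "run":
            cfg = parse_config(tomllib.loads(fh.attrs["config"]))
        else:
            cfg = SolverConfig(**json.loads(fh.attrs["config"]))
    return state, d, cfg


# ---------------------------------------------------------------------------
# the full runner used by the CLI
# ---------------------------------------------------------------------------

def run_from_config(cfg: RunConfig, outdir=None, seed=None, resume=None):
    """Build, run and serialize a configured simulation.

    Returns ``(final_state, records, domain)``.  With ``resume`` pointing at
    a checkpoint, continues that run for the remaining steps; the continued
    trajectory is bit-compatible with an uninterrupted run.
    """
    if seed is not None:
        cfg = RunConfig(domain=cfg.domain, granules=cfg.granules,
                        solver=SolverConfig(**{**{f.name: getattr(cfg.solver, f.name)
                                                  for f in dc_fields(cfg.solver)},
                                               "seed": int(seed)}),
                        n_steps=cfg.n_steps, output=cfg.output,
                        defaulted=cfg.defaulted)
    outdir = outdir or cfg.output.directory
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config_echo.toml"), "w") as fh:
        fh.write(echo_config(cfg))

    if resume is not None:
        state0, d, _ = load_checkpoint(resume)
        start_step = state0.step
        initial = state0.psi
    else:
        d = build_domain_from_config(cfg)
        initial = initialize_random(d, cfg.solver.init_mean,
                                    cfg.solver.init_amplitude, cfg.solver.seed)
        start_step = 0
    remaining = cfg.n_steps - start_step
    if remaining < 1:
        raise ConfigError(f"nothing to do: checkpoint already at step {start_step}")

    sinks = []
    if "vtu" in cfg.output.formats and cfg.output.snapshot_every > 0:
        def vtu_sink(state, dom):
            if state.step % cfg.output.snapshot_every == 0:
                write_snapshot(state, dom,
                               os.path.join(outdir, f"snapshot_{state.step:06d}.vtu"))
        sinks.append(vtu_sink)

    def log_sink(state, dom):
        logger.info("step=%d time=%g", state.step, state.time)
    sinks.append(log_sink)

    final, records = run_simulation(d, initial, cfg.solver, remaining, sinks=sinks)
    # shift recorded step/time for resumed runs
    if start_step:
        for r in records:
            r.step += start_step
            r.time += start_step * cfg.solver.dt
        final.step += start_step
        final.time = final.step * cfg.solver.dt

    if "csv" in cfg.output.formats:
        rec_mod.write_csv(records, os.path.join(outdir, "timeseries.csv"))
    if "vtu" in cfg.output.formats:
        write_snapshot(final, d, os.path.join(outdir, "final.vtu"))
    save_checkpoint(os.path.join(outdir, "checkpoint.h5"), final, d, cfg)
    return final, records, d


# ---------------------------------------------------------------------------
# analytic fixtures shared by the test suite
# ---------------------------------------------------------------------------

def make_fixture(name: str, **params):
    """Deterministic analytic (Domain, PhaseField) pairs.

    tanh_strip         – equilibrium interface Ψ = tanh(x/√(2γ)) on a strip
    circular_interface – radial interface of radius r inside a disk
    two_blobs          – two disjoint membrane blobs in a matrix background
    sinusoid_mode      – single-mode sinusoid of wavenumber k on a square
    """
    if name == "tanh_strip":
        gamma = params.pop("gamma", 1.0)
        width = params.pop("width", 20.0)
        height = params.pop("height", 1.0)
        h = params.pop("h", 0.1)
        _reject_extra(name, params)
        d = rectangle_domain(width, height, h)
        psi = equilibrium_profile(d.nodes[:, 0], gamma)
        return d, PhaseField(psi, d)
    if name == "circular_interface":
        R = params.pop("R", 2.0)
        r = params.pop("r", 1.0)
        gamma = params.pop("gamma", 1.0)
        h = params.pop("h", 0.1)
        _reject_extra(name, params)
        if not 0 < r < R:
            raise ValueError("need 0 < r < R")
        d = build_domain("disk", [R], h_target=h)
        rho = np.linalg.norm(d.nodes, axis=1)
        psi = np.tanh((r - rho) / np.sqrt(2.0 * gamma))
        return d, PhaseField(psi, d)
    if name == "two_blobs":
        h = params.pop("h", 0.2)
        _reject_extra(name, params)
        d = build_domain("disk", [4.0], h_target=h)
        psi = np.ones(d.n_nodes)
        for cx in (-1.5, 1.5):
            r2 = np.sum((d.nodes - [cx, 0.0]) ** 2, axis=1)
            psi -= 2.0 * np.exp(-r2 / 0.5)
        return d, PhaseField(psi, d)
    if name == "sinusoid_mode":
        k = params.pop("k")
        h = params.pop("h", None)
        amplitude = params.pop("amplitude", 0.5)
        _reject_extra(name, params)
        lam = 2.0 * np.pi / k
        side = 4.0 * lam
        h = h or lam / 16.0
        d = rectangle_domain(side, side, h)
        psi = amplitude * np.sin(k * d.nodes[:, 0])
        return d, PhaseField(psi, d)
    raise ValueError(f"unknown fixture {name!r}")


def _reject_extra(name, params):
    if params:
        raise ValueError(f"unknown parameter(s) for fixture {name!r}: {sorted(params)}")
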