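"""File I/O: HDF5 results, probe CSV files and YAML configuration blocks."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import yaml

from .axial import AxialCurrentSet
from .cable import PassiveParams, SimulationResult, StepCurrent, SynapseSpec
from .dipole import DipoleMoment
from .extracellular import (Anisotropic, Homogeneous, MoILayers, OneSphere,
                            ProbeSpec)
from .headmodels import FourSphereModel

__all__ = [
    "save_simulation", "load_simulation", "append_axial", "save_dipole",
    "load_dipole", "read_probe_csv", "write_probe_csv", "medium_from_dict",
    "load_config", "params_from_config", "synapses_from_config",
    "stimuli_from_config", "probe_from_config", "four_sphere_from_config",
]


def save_simulation(path, result: SimulationResult) -> None:
    """Write time/vm/imem datasets with unit attributes."""
    with h5py.File(path, "w") as fh:
        for name, data, unit in (("time", result.time, "ms"),
                                 ("vm", result.v_m, "mV"),
                                 ("imem", result.i_m, "nA")):
            ds = fh.create_dataset(name, data=data)
            ds.attrs["unit"] = unit


def load_simulation(path) -> SimulationResult:
    with h5py.File(path, "r") as fh:
        return SimulationResult(time=fh["time"][()], v_m=fh["vm"][()],
                                i_m=fh["imem"][()])


def append_axial(path, ax: AxialCurrentSet) -> None:
    """Append iaxial/d_vectors/r_mid datasets to a simulation file."""
    with h5py.File(path, "a") as fh:
        for name, data, unit in (("iaxial", ax.i_axial, "nA"),
                                 ("d_vectors", ax.d_vectors, "um"),
                                 ("r_mid", ax.r_mid, "um")):
            if name in fh:
                del fh[name]
            ds = fh.create_dataset(name, data=data)
            ds.attrs["unit"] = unit


def load_axial(path) -> AxialCurrentSet:
    with h5py.File(path, "r") as fh:
        return AxialCurrentSet(fh["iaxial"][()], fh["d_vectors"][()],
                               fh["r_mid"][()])


def save_dipole(path, dip: DipoleMoment) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("dipole", data=dip.p)
        ds.attrs["unit"] = "nAm"
        if dip.location is not None:
            ds.attrs["location"] = dip.location
        if dip.location_rule:
            ds.attrs["location_rule"] = dip.location_rule


def load_dipole(path) -> DipoleMoment:
    with h5py.File(path, "r") as fh:
        ds = fh["dipole"]
        loc = ds.attrs.get("location")
        rule = ds.attrs.get("location_rule", "")
        return DipoleMoment(ds[()], location=loc, location_rule=str(rule))


PROBE_COLUMNS = ["x", "y", "z", "nx", "ny", "nz", "r_contact"]


def read_probe_csv(path, medium=None, m=50, source_model="linesource") -> ProbeSpec:
    """Probe CSV with columns x,y,z,nx,ny,nz,r_contact (um)."""
    df = pd.read_csv(path)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe CSV missing columns {missing}")
    r_contact = float(df["r_contact"].iloc[0])
    return ProbeSpec(df[["x", "y", "z"]].to_numpy(float),
                     normals=df[["nx", "ny", "nz"]].to_numpy(float),
                     r_contact=r_contact, m=m,
                     medium=medium or Homogeneous(),
                     source_model=source_model)


def write_probe_csv(path, probe: ProbeSpec) -> None:
    df = pd.DataFrame(
        np.column_stack([probe.positions, probe.normals,
                         np.full(len(probe.positions), probe.r_contact)]),
        columns=PROBE_COLUMNS)
    df.to_csv(path, index=False)


def medium_from_dict(cfg: dict):
    """Build a medium from a config mapping with a ``kind`` key."""
    kind = cfg.get("kind", "homogeneous")
    if kind == "homogeneous":
        return Homogeneous(sigma=float(cfg.get("sigma", 0.3)))
    if kind == "anisotropic":
        return Anisotropic(float(cfg["sigma_x"]), float(cfg["sigma_y"]),
                           float(cfg["sigma_z"]))
    if kind == "moi":
        return MoILayers(float(cfg["sigma_g"]), float(cfg["sigma_t"]),
                         float(cfg["sigma_s"]), h=float(cfg.get("h", 300.0)),
                         n_images=int(cfg.get("n_images", 20)))
    if kind == "one_sphere":
        return OneSphere(float(cfg["sigma_in"]), float(cfg["sigma_out"]),
                         float(cfg["R"]), n_terms=int(cfg.get("n_terms", 100)))
    raise ValueError(f"unknown medium kind {kind!r}")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def params_from_config(cfg: dict) -> PassiveParams:
    block = cfg.get("passive", {})
    return PassiveParams(**{k: float(v) for k, v in block.items()})


def synapses_from_config(cfg: dict):
    out = []
    for s in cfg.get("synapses", []):
        out.append(SynapseSpec(segment=int(s["segment"]),
                               onsets=tuple(np.atleast_1d(s.get("onsets", []))),
                               tau_r=float(s.get("tau_r", 0.2)),
                               tau_d=float(s.get("tau_d", 1.7)),
                               g_max=float(s.get("g_max", 1.0)),
                               e_syn=float(s.get("e_syn", 0.0))))
    return out


def stimuli_from_config(cfg: dict):
    out = []
    for s in cfg.get("stimuli", []):
        out.append(StepCurrent(segment=int(s["segment"]),
                               amplitude=float(s["amplitude"]),
                               start=float(s.get("start", 0.0)),
                               stop=float(s.get("stop", np.inf))))
    return out


def probe_from_config(cfg: dict, csv_path=None) -> ProbeSpec:
    medium = medium_from_dict(cfg.get("medium", {}))
    m = int(cfg.get("m", 50))
    source_model = cfg.get("source_model", "linesource")
    if csv_path is not None:
        return read_probe_csv(csv_path, medium=medium, m=m,
                              source_model=source_model)
    pr = cfg["probe"]
    return ProbeSpec(np.asarray(pr["positions"], dtype=float),
                     normals=(np.asarray(pr["normals"], dtype=float)
                              if "normals" in pr else None),
                     r_contact=float(pr.get("r_contact", 0.0)), m=m,
                     medium=medium, source_model=source_model)


def four_sphere_from_config(cfg: dict) -> FourSphereModel:
    block = cfg.get("four_sphere", {})
    kwargs = {}
    if "radii" in block:
        kwargs["radii"] = tuple(float(r) for r in block["radii"])
    if "sigmas" in block:
        kwargs["sigmas"] = tuple(float(s) for s in block["sigmas"])
    if "n_max" in block:
        kwargs["n_max"] = int(block["n_max"])
    return FourSphereModel(**kwargs)
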