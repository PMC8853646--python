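"""Persistence (HDF5 + delimited text), fixture presets and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .morphology import GranuleMorphology, LayerStack, MitralMorphology
from .netgen import Network, Synapse, generate_network
from .placement import (
    GranuleCell,
    MitralCell,
    OBSpace,
    PlacementConfig,
    build_space,
    place_mitral_cells,
)

__all__ = [
    "save_network",
    "load_network",
    "export_tables",
    "make_fixture",
    "FIXTURE_PRESETS",
    "RunManifest",
    "network_hash",
]

FORMAT_VERSION = 1

#: (radius um, GC:MC ratio) presets; "full" is the complete-bulb configuration
FIXTURE_PRESETS = {
    "tiny": (150.0, 5.0),
    "small": (300.0, 15.0),
    "full": (600.0, 15.0),
}

_MC_COLS = [
    "id", "glomerulus", "x", "y", "z", "r_max", "gamma_peak", "xi_center",
    "w", "alpha", "k", "m", "mc_type", "n_preexisting",
]
_GC_COLS = [
    "id", "vx", "vy", "fx", "fy", "r_max", "z0", "z_max", "S", "S_available",
]
_SYN_COLS = ["mc_id", "gc_id", "x", "y", "z", "dendritic_distance"]


def _mc_table(net: Network) -> np.ndarray:
    rows = []
    for mc in net.mitral_cells:
        m = mc.morphology
        rows.append(
            [mc.id, mc.glomerulus, mc.xy[0], mc.xy[1], m.z_m, m.r_max,
             m.gamma_peak, m.xi_center, m.w, m.alpha, m.k, m.m, m.mc_type,
             mc.n_preexisting]
        )
    return np.asarray(rows, dtype=float).reshape(-1, len(_MC_COLS))


def _gc_table(net: Network) -> np.ndarray:
    rows = []
    for gc in net.granule_cells:
        g = gc.morphology
        rows.append(
            [gc.id, g.vertex_xy[0], g.vertex_xy[1], g.face_center_xy[0],
             g.face_center_xy[1], g.r_max, g.z0, g.z_max, g.S, g.S_available]
        )
    return np.asarray(rows, dtype=float).reshape(-1, len(_GC_COLS))


def _syn_table(net: Network) -> np.ndarray:
    rows = [
        [s.mc_id, s.gc_id, *s.location, s.dendritic_distance]
        for s in net.synapses
    ]
    return np.asarray(rows, dtype=float).reshape(-1, len(_SYN_COLS))


def save_network(net: Network, path) -> None:
    """Write the network (space, cell tables, synapse table) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        sp = f.create_group("space")
        sp.attrs["radius"] = net.space.radius
        sp.attrs["glomerulus_density"] = net.space.glomerulus_density
        sp.attrs["boundary_mode"] = net.space.boundary_mode
        sp.attrs["epl"] = net.space.layers.epl_thickness
        sp.attrs["mcl"] = net.space.layers.mcl_thickness
        sp.attrs["ipl"] = net.space.layers.ipl_thickness
        sp.create_dataset("glomeruli", data=np.asarray(net.space.glomeruli))
        f.create_dataset("mitral_cells", data=_mc_table(net))
        f.create_dataset("granule_cells", data=_gc_table(net))
        f.create_dataset("synapses", data=_syn_table(net))


def load_network(path) -> Network:
    """Load a network written by :func:`save_network`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported network file version {version}")
        sp = f["space"]
        layers = LayerStack(
            epl_thickness=float(sp.attrs["epl"]),
            mcl_thickness=float(sp.attrs["mcl"]),
            ipl_thickness=float(sp.attrs["ipl"]),
        )
        space = OBSpace(
            radius=float(sp.attrs["radius"]),
            layers=layers,
            glomerulus_density=float(sp.attrs["glomerulus_density"]),
            boundary_mode=str(sp.attrs["boundary_mode"]),
            glomeruli=sp["glomeruli"][()],
        )
        mcs = []
        for row in f["mitral_cells"][()]:
            d = dict(zip(_MC_COLS, row))
            morph = MitralMorphology(
                r_max=d["r_max"], gamma_peak=d["gamma_peak"],
                xi_center=d["xi_center"], w=d["w"], alpha=d["alpha"],
                k=d["k"], m=d["m"], z_m=d["z"], mc_type=int(d["mc_type"]),
            )
            mcs.append(
                MitralCell(
                    id=int(d["id"]), glomerulus=int(d["glomerulus"]),
                    xy=(d["x"], d["y"]), morphology=morph,
                    n_preexisting=int(d["n_preexisting"]),
                )
            )
        gcs = []
        for row in f["granule_cells"][()]:
            d = dict(zip(_GC_COLS, row))
            morph = GranuleMorphology(
                vertex_xy=(d["vx"], d["vy"]),
                face_center_xy=(d["fx"], d["fy"]),
                r_max=d["r_max"], z0=d["z0"], z_max=d["z_max"],
                S=d["S"], S_available=d["S_available"],
            )
            gcs.append(GranuleCell(id=int(d["id"]), morphology=morph))
        syns = [
            Synapse(
                mc_id=int(r[0]), gc_id=int(r[1]),
                location=(r[2], r[3], r[4]), dendritic_distance=r[5],
            )
            for r in f["synapses"][()]
        ]
    return Network(space=space, mitral_cells=mcs, granule_cells=gcs, synapses=syns)


def export_tables(net: Network, directory) -> None:
    """Write the cell and synapse tables as TSV for inspection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(_mc_table(net), columns=_MC_COLS).to_csv(
        directory / "mitral_cells.tsv", sep="\t", index=False
    )
    pd.DataFrame(_gc_table(net), columns=_GC_COLS).to_csv(
        directory / "granule_cells.tsv", sep="\t", index=False
    )
    pd.DataFrame(_syn_table(net), columns=_SYN_COLS).to_csv(
        directory / "synapses.tsv", sep="\t", index=False
    )


def make_fixture(
    scale: str = "tiny",
    seed: int = 0,
    mode: str = "geometric",
    boundary_mode: str = "bounded",
    p_constant: float | None = None,
    progress: bool = False,
) -> Network:
    """Build a preset network: tiny (r=150, 5:1), small (r=300, 15:1), full (r=600, 15:1)."""
    if scale not in FIXTURE_PRESETS:
        raise ValueError(f"unknown scale {scale!r}; choose from {list(FIXTURE_PRESETS)}")
    radius, ratio = FIXTURE_PRESETS[scale]
    rng = np.random.default_rng(seed)
    space = build_space(radius, rng, boundary_mode=boundary_mode)
    mcs = place_mitral_cells(space, rng)
    return generate_network(
        space, mcs, rng, gc_per_mc_ratio=ratio, mode=mode,
        p_constant=p_constant, progress=progress,
    )


def network_hash(net: Network) -> str:
    """Stable content hash of the cell/synapse tables."""
    h = hashlib.sha256()
    for arr in (_mc_table(net), _gc_table(net), _syn_table(net),
                np.asarray(net.space.glomeruli)):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly."""

    seed: int
    config: dict
    network_hash: str
    code_version: str = "0.1.0"
    timestamp: str = ""

    def write(self, path) -> None:
        d = asdict(self)
        d["timestamp"] = d["timestamp"] or time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(d, indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
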