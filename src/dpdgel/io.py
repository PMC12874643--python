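"""Readers and writers: LAMMPS data files, dump/XYZ trajectories, scalar
logs, checkpoints and run manifests.

The bead-spring network is exchanged in the LAMMPS data-file dialect
(``atom_style molecular`` or ``full``), the format of publicly deposited
gel geometries, so externally built networks can be ingested directly.
Atom types map species: 1 = solvent, 2 = gel monomer, 3 = cross-link.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .system import BeadSystem, NetworkTopology

__all__ = [
    "write_lammps_data",
    "read_lammps_data",
    "write_dump",
    "write_xyz",
    "save_checkpoint",
    "load_checkpoint",
    "RunManifest",
]

_TYPE_OF_SPECIES = {0: 1, 1: 2, 2: 3}
_SPECIES_OF_TYPE = {v: k for k, v in _TYPE_OF_SPECIES.items()}


class ParseError(ValueError):
    """Malformed data file; message names the offending line."""


def write_lammps_data(path: str | Path, system: BeadSystem,
                      topology: NetworkTopology | None = None, *,
                      style: str = "molecular",
                      velocities: bool = False) -> None:
    """Write the system (and topology) as a LAMMPS data file."""
    if style not in ("molecular", "full"):
        raise ValueError(f"unsupported atom style {style!r}")
    topo = topology
    n_bonds = 0 if topo is None else len(topo.bonds)
    n_angles = 0 if topo is None else len(topo.angles)
    mol = np.zeros(system.n, np.int64)
    if topo is not None:
        for ci, chain in enumerate(topo.chains, start=1):
            mol[chain] = ci
    lines = ["# dpdgel bead-spring network", "",
             f"{system.n} atoms",
             f"{n_bonds} bonds",
             f"{n_angles} angles", "",
             "3 atom types"]
    if n_bonds:
        lines.append("1 bond types")
    if n_angles:
        lines.append("1 angle types")
    lines += ["",
              f"0.0 {system.box[0]:.8g} xlo xhi",
              f"0.0 {system.box[1]:.8g} ylo yhi",
              f"0.0 {system.box[2]:.8g} zlo zhi", "",
              "Masses", "", "1 1.0", "2 1.0", "3 1.0", "",
              f"Atoms # {style}", ""]
    q = " 0.0" if style == "full" else ""
    for i in range(system.n):
        t = _TYPE_OF_SPECIES[int(system.species[i])]
        x, y, z = system.pos[i]
        lines.append(f"{i + 1} {mol[i]} {t}{q} {x:.10g} {y:.10g} {z:.10g}")
    if velocities:
        lines += ["", "Velocities", ""]
        for i in range(system.n):
            vx, vy, vz = system.vel[i]
            lines.append(f"{i + 1} {vx:.10g} {vy:.10g} {vz:.10g}")
    if n_bonds:
        lines += ["", "Bonds", ""]
        for b, (i, j) in enumerate(topo.bonds, start=1):
            lines.append(f"{b} 1 {i + 1} {j + 1}")
    if n_angles:
        lines += ["", "Angles", ""]
        for a, (i, j, k) in enumerate(topo.angles, start=1):
            lines.append(f"{a} 1 {i + 1} {j + 1} {k + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header_counts(lines):
    counts = {"atoms": 0, "bonds": 0, "angles": 0}
    box = [0.0, 0.0, 0.0]
    body_start = 0
    for ln, raw in enumerate(lines):
        s = raw.split("#")[0].strip()
        toks = s.split()
        if not toks:
            continue
        if len(toks) == 2 and toks[1] in counts:
            counts[toks[1]] = int(toks[0])
        elif len(toks) == 4 and toks[2] in ("xlo", "ylo", "zlo"):
            ax = "xyz".index(toks[2][0])
            box[ax] = float(toks[1]) - float(toks[0])
        elif toks[0] in ("Atoms", "Velocities", "Bonds", "Angles", "Masses"):
            body_start = ln
            break
    return counts, box, body_start


def read_lammps_data(path: str | Path):
    """Read a LAMMPS data file (molecular or full atom style).

    Returns ``(BeadSystem, NetworkTopology)``; chains are reconstructed
    from the bond graph by walking from the junction beads.  Raises
    :class:`ParseError` naming the line for malformed content.
    """
    lines = Path(path).read_text().splitlines()
    counts, box, body_start = _parse_header_counts(lines)
    n = counts["atoms"]
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    species = np.zeros(n, np.int8)
    bonds = np.zeros((counts["bonds"], 2), np.int64)
    angles = np.zeros((counts["angles"], 3), np.int64)
    seen = {"Atoms": False}
    section = None
    style = "molecular"
    for ln in range(body_start, len(lines)):
        raw = lines[ln]
        stripped = raw.split("#")[0].strip()
        head = raw.strip()
        if head.startswith(("Atoms", "Velocities", "Bonds", "Angles",
                            "Masses", "Pair", "Bond Coeffs", "Angle Coeffs")):
            section = head.split("#")[0].strip()
            if head.startswith("Atoms") and "full" in head:
                style = "full"
            continue
        if not stripped:
            continue
        toks = stripped.split()
        try:
            if section == "Atoms":
                i = int(toks[0]) - 1
                if not 0 <= i < n:
                    raise ParseError(f"line {ln + 1}: atom id {i + 1} out of "
                                     f"range 1..{n}")
                if style == "full" or len(toks) >= 7:
                    t, xyz = int(toks[2]), toks[-3:] if len(toks) == 7 else toks[4:7]
                    if len(toks) == 6:
                        t, xyz = int(toks[2]), toks[3:6]
                else:
                    t, xyz = int(toks[2]), toks[3:6]
                species[i] = _SPECIES_OF_TYPE.get(t, 1)
                pos[i] = [float(v) for v in xyz]
                seen["Atoms"] = True
            elif section == "Velocities":
                i = int(toks[0]) - 1
                vel[i] = [float(v) for v in toks[1:4]]
            elif section == "Bonds":
                b = int(toks[0]) - 1
                i, j = int(toks[2]) - 1, int(toks[3]) - 1
                if not (0 <= i < n and 0 <= j < n):
                    raise ParseError(f"line {ln + 1}: bond references "
                                     "missing atom id")
                bonds[b] = (i, j)
            elif section == "Angles":
                a = int(toks[0]) - 1
                ids = [int(t) - 1 for t in toks[2:5]]
                if any(not 0 <= i < n for i in ids):
                    raise ParseError(f"line {ln + 1}: angle references "
                                     "missing atom id")
                angles[a] = ids
        except (ValueError, IndexError) as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"line {ln + 1}: cannot parse {raw!r}") from exc
    if n and not seen["Atoms"]:
        raise ParseError("no Atoms section found")
    system = BeadSystem(pos, vel, species, tuple(box))
    chains = reconstruct_chains(bonds, species)
    xl = np.flatnonzero(species == 2).astype(np.int64)
    topo = NetworkTopology(xl, chains, bonds, angles)
    return system, topo


def reconstruct_chains(bonds: np.ndarray, species: np.ndarray):
    """Rebuild chain records by walking the bond graph from junctions.

    Junctions are cross-link beads (species 2) and any bead of degree != 2.
    """
    from collections import defaultdict

    adj = defaultdict(list)
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    is_junction = {b: (species[b] == 2 or len(nb) != 2)
                   for b, nb in adj.items()}
    chains = []
    visited = set()
    for start, nb in adj.items():
        if not is_junction[start]:
            continue
        for nxt in nb:
            edge = (min(start, nxt), max(start, nxt))
            if edge in visited:
                continue
            chain = [start]
            prev, cur = start, nxt
            visited.add(edge)
            while not is_junction.get(cur, True):
                chain.append(cur)
                nbs = adj[cur]
                nxt2 = nbs[0] if nbs[0] != prev else nbs[1]
                visited.add((min(cur, nxt2), max(cur, nxt2)))
                prev, cur = cur, nxt2
            chain.append(cur)
            chains.append(np.array(chain, np.int64))
    return chains


def write_dump(path: str | Path, system: BeadSystem, step: int = 0, *,
               append: bool = False) -> None:
    """LAMMPS dump frame: id type x y z vx vy vz."""
    lines = ["ITEM: TIMESTEP", str(step),
             "ITEM: NUMBER OF ATOMS", str(system.n),
             "ITEM: BOX BOUNDS pp pp ff",
             f"0.0 {system.box[0]:.8g}",
             f"0.0 {system.box[1]:.8g}",
             f"0.0 {system.box[2]:.8g}",
             "ITEM: ATOMS id type x y z vx vy vz"]
    for i in range(system.n):
        t = _TYPE_OF_SPECIES[int(system.species[i])]
        x, y, z = system.pos[i]
        vx, vy, vz = system.vel[i]
        lines.append(f"{i + 1} {t} {x:.6g} {y:.6g} {z:.6g} "
                     f"{vx:.6g} {vy:.6g} {vz:.6g}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def write_xyz(path: str | Path, system: BeadSystem, comment: str = "", *,
              append: bool = False) -> None:
    names = {0: "S", 1: "M", 2: "X"}
    lines = [str(system.n), comment or "dpdgel frame"]
    for i in range(system.n):
        x, y, z = system.pos[i]
        lines.append(f"{names[int(system.species[i])]} "
                     f"{x:.6g} {y:.6g} {z:.6g}")
    with open(path, "a" if append else "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_checkpoint(path: str | Path, system: BeadSystem,
                    topology: NetworkTopology | None = None,
                    extra: dict | None = None) -> None:
    """Self-describing binary checkpoint (HDF5)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "dpdgel-checkpoint-1"
        h5.attrs["box"] = system.box
        h5.attrs["pbc_z"] = system.pbc_z
        h5.create_dataset("pos", data=system.pos)
        h5.create_dataset("vel", data=system.vel)
        h5.create_dataset("species", data=system.species)
        if topology is not None:
            h5.create_dataset("bonds", data=topology.bonds)
            h5.create_dataset("angles", data=topology.angles)
            h5.create_dataset("crosslink_ids", data=topology.crosslink_ids)
            lens = np.array([len(c) for c in topology.chains])
            h5.create_dataset("chain_lengths", data=lens)
            if len(topology.chains):
                h5.create_dataset("chain_flat",
                                  data=np.concatenate(topology.chains))
        for k, v in (extra or {}).items():
            h5.attrs[k] = v


def load_checkpoint(path: str | Path):
    import h5py

    with h5py.File(path, "r") as h5:
        system = BeadSystem(h5["pos"][:], h5["vel"][:], h5["species"][:],
                            tuple(h5.attrs["box"]), bool(h5.attrs["pbc_z"]))
        topo = None
        if "bonds" in h5:
            chains = []
            if "chain_flat" in h5:
                flat = h5["chain_flat"][:]
                lens = h5["chain_lengths"][:]
                off = 0
                for L in lens:
                    chains.append(flat[off:off + L])
                    off += L
            topo = NetworkTopology(h5["crosslink_ids"][:], chains,
                                   h5["bonds"][:], h5["angles"][:])
    return system, topo


@dataclass
class RunManifest:
    """Immutable provenance record for one run; every artifact points to
    exactly one manifest."""

    config: dict
    seed: int
    start_step: int
    end_step: int
    material_props: dict = field(default_factory=dict)
    code_version: str = "0.1.0"
    created: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S"))

    @property
    def input_hash(self) -> str:
        blob = json.dumps({"config": self.config, "seed": self.seed},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["input_hash"] = self.input_hash
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        d.pop("input_hash", None)
        return cls(**d)
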