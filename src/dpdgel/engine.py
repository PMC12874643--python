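"""DPD engine: pair/bonded forces, thermostated integration, diagnostics.

The public functions mirror the individual force terms (useful for testing
and for composing custom protocols); :class:`Simulation` wires them into a
single compiled step for production runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .params import BondedParams, DPDParams, WallSpec
from .system import BeadSystem, NetworkTopology

__all__ = [
    "weight",
    "pair_forces",
    "bond_forces",
    "angle_forces",
    "integrate_step",
    "kinetic_temperature",
    "build_neighbor_list",
    "Simulation",
]


def weight(r, r_c: float = 1.0):
    """DPD weight function w(r) = max(0, 1 - r/r_c)."""
    return np.maximum(0.0, 1.0 - np.asarray(r, dtype=float) / r_c)


def _empty_topology():
    return (np.empty((0, 2), np.int64), np.empty((0, 3), np.int64))


def _call_step(system: BeadSystem, frc, img, bonds, angles, tether_ids,
               anchors, wall_h, p, flags, step, seed, out):
    box = np.array(system.box, dtype=np.float64)
    K.dpd_step(system.pos, system.vel, frc, system.species.astype(np.int8),
               img, bonds, angles, tether_ids, anchors, box, wall_h,
               p, flags, step, seed, out)


def _base_pvec(dpd: DPDParams, bonded: BondedParams | None = None):
    p = np.zeros(K.NPARAMS)
    p[K.P_RC] = dpd.r_c
    p[K.P_A] = dpd.a
    p[K.P_GAMMA] = dpd.gamma
    p[K.P_SIGMA] = dpd.sigma
    p[K.P_KBT] = dpd.kBT
    p[K.P_DT] = dpd.dt
    if bonded is not None:
        p[K.P_KBOND] = bonded.k_bond
        p[K.P_REQ] = bonded.r_eq
        p[K.P_KBEND] = bonded.k_bend
    return p


def pair_forces(system: BeadSystem, params: DPDParams, *, seed: int = 0,
                step: int = 0, include_random: bool = True,
                include_dissipative: bool = True) -> np.ndarray:
    """Nonbonded DPD forces on every bead for the current state.

    The random term uses the symmetric per-pair draw keyed by
    ``(seed, step, pair)``; disable terms individually for testing.
    """
    frc = np.zeros_like(system.pos)
    box = np.array(system.box)
    gamma = params.gamma if include_dissipative else 0.0
    sigma_dt = params.sigma / np.sqrt(params.dt) if include_random else 0.0
    K._pair_forces_cells(system.pos, system.vel, frc, box[0], box[1], box[2],
                         system.pbc_z, params.a, gamma, sigma_dt,
                         params.r_c, seed, step)
    return frc


def bond_forces(system: BeadSystem, topology: NetworkTopology,
                params: BondedParams):
    """Harmonic-bond forces and total bond energy."""
    frc = np.zeros_like(system.pos)
    box = np.array(system.box)
    e = K._bond_forces(system.pos, frc, topology.bonds, params.k_bond,
                       params.r_eq, box[0], box[1], box[2], system.pbc_z)
    return frc, e


def angle_forces(system: BeadSystem, topology: NetworkTopology,
                 params: BondedParams):
    """Bending forces and total bending energy."""
    frc = np.zeros_like(system.pos)
    box = np.array(system.box)
    e = K._angle_forces(system.pos, frc, topology.angles, params.k_bend,
                        box[0], box[1], box[2], system.pbc_z)
    return frc, e


def integrate_step(system: BeadSystem, frc: np.ndarray, params: DPDParams,
                   topology: NetworkTopology | None = None,
                   bonded: BondedParams | None = None, *, seed: int = 0,
                   step: int = 0) -> np.ndarray:
    """Advance the system by one modified velocity-Verlet step.

    ``frc`` holds the forces at the current positions (as returned by the
    previous call, or primed via the force functions); the updated forces
    are returned for the next call.  Periodic wrap in x, y (and z when
    ``system.pbc_z``); walls are the shear cell's business.
    """
    bonds, angles = _empty_topology()
    if topology is not None:
        bonds, angles = topology.bonds, topology.angles
    p = _base_pvec(params, bonded)
    flags = np.zeros(K.NFLAGS, np.int64)
    flags[K.F_PBCZ] = 1 if system.pbc_z else 0
    img = np.zeros((system.n, 2), np.int64)
    out = np.zeros(K.NOUT)
    wall_h = np.array([system.box[2]])
    _call_step(system, frc, img, bonds, angles,
               np.empty(0, np.int64), np.empty((0, 3)), wall_h,
               p, flags, step, seed, out)
    return frc


def kinetic_temperature(system: BeadSystem, nbins: int = 12) -> float:
    """Kinetic temperature from peculiar velocities.

    The z-binned mean streaming velocity is subtracted before forming
    (1/3) <m v^2>, so imposed flow does not inflate the estimate.
    """
    if system.n < 2:
        raise ValueError("need at least two beads")
    z = system.pos[:, 2]
    edges = np.linspace(z.min(), z.max() + 1e-9, nbins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, nbins - 1)
    v = system.vel.copy()
    for b in range(nbins):
        m = idx == b
        if np.any(m):
            v[m] -= v[m].mean(axis=0)
    return float(np.sum(v * v) / (3.0 * system.n))


def build_neighbor_list(system: BeadSystem, r_c: float = 1.0,
                        skin: float = 0.3) -> np.ndarray:
    """All pairs within r_c + skin, as an (M, 2) id array (i < j)."""
    box = np.array(system.box)
    pairs = K.brute_force_pairs(system.pos, box[0], box[1], box[2],
                                system.pbc_z, r_c + skin)
    if len(pairs) == 0:
        return np.empty((0, 2), np.int64)
    return np.array(pairs, dtype=np.int64)


@dataclass
class StepLog:
    """Per-sample scalar log of a run."""

    step: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    wall_h: list = field(default_factory=list)
    F_f: list = field(default_factory=list)
    F_wall: list = field(default_factory=list)
    e_bond: list = field(default_factory=list)
    e_angle: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({k: getattr(self, k) for k in
                             ("step", "temperature", "wall_h", "F_f",
                              "F_wall", "e_bond", "e_angle")})


class Simulation:
    """A configured DPD run: system + topology + walls in one stepper.

    Flags select the boundary configuration: a fully periodic box (bulk
    fluid), the frictional shear cell (bounce-back bottom wall, solvent
    guard at the top boundary, loaded moving wall with gel tethers), a
    periodic-Poiseuille viscometer, or a wall-driven Couette cell.
    """

    def __init__(self, system: BeadSystem, dpd: DPDParams,
                 topology: NetworkTopology | None = None,
                 bonded: BondedParams | None = None,
                 walls: WallSpec | None = None, *,
                 bottom_wall: bool = False, top_solvent_wall: bool = False,
                 moving_wall: bool = False, tether_ids=None, anchors=None,
                 poiseuille_fx: float = 0.0, couette_vtop: float | None = None,
                 wall_h: float | None = None, seed: int = 0):
        self.system = system
        self.dpd = dpd
        self.bonded = bonded or BondedParams()
        self.walls = walls or WallSpec()
        self.topology = topology
        self.seed = int(seed) & 0x7FFFFFFF
        self.step_count = 0

        self.bonds, self.angles = _empty_topology()
        if topology is not None:
            self.bonds = np.ascontiguousarray(topology.bonds, np.int64)
            self.angles = np.ascontiguousarray(topology.angles, np.int64)

        self.p = _base_pvec(dpd, self.bonded)
        w = self.walls
        self.p[K.P_KW_BOT_SOL] = w.k_bottom_solvent
        self.p[K.P_KW_BOT_GEL] = w.k_bottom_gel
        self.p[K.P_KW_TOP_SOL] = w.k_top_solvent
        self.p[K.P_KW_MOVE_GEL] = w.k_moving_gel
        self.p[K.P_FN] = w.F_n
        self.p[K.P_WALL_MOB] = w.wall_mobility
        self.p[K.P_V_SLIDE] = w.V
        self.p[K.P_K_TETHER] = w.k_tether
        self.p[K.P_BODY_FX] = poiseuille_fx
        self.p[K.P_COUETTE_V] = couette_vtop or 0.0
        self.p[K.P_STANDOFF] = w.standoff

        self.flags = np.zeros(K.NFLAGS, np.int64)
        self.flags[K.F_PBCZ] = 1 if system.pbc_z else 0
        self.flags[K.F_BOTTOM_WALL] = 1 if bottom_wall else 0
        self.flags[K.F_TOP_SOL_WALL] = 1 if top_solvent_wall else 0
        self.flags[K.F_MOVING_WALL] = 1 if moving_wall else 0
        self.flags[K.F_POISEUILLE] = 1 if poiseuille_fx != 0.0 else 0
        self.flags[K.F_COUETTE_TOP] = 1 if couette_vtop is not None else 0

        self.tether_ids = (np.ascontiguousarray(tether_ids, np.int64)
                           if tether_ids is not None else np.empty(0, np.int64))
        self.anchors = (np.ascontiguousarray(anchors, np.float64)
                        if anchors is not None else np.empty((0, 3)))
        self.flags[K.F_TETHERS] = 1 if self.tether_ids.size else 0
        if moving_wall and self.tether_ids.size == 0 and w.V != 0.0:
            raise ValueError("sliding moving wall requires a tether set")

        self.wall_h = np.array([wall_h if wall_h is not None
                                else system.box[2]], dtype=np.float64)
        self.img = np.zeros((system.n, 2), np.int64)
        self.frc = np.zeros_like(system.pos)
        self.out = np.zeros(K.NOUT)
        self._box = np.array(system.box, dtype=np.float64)
        self._acc = np.zeros(K.NOUT)
        self._acc_n = 0
        self._prime()

    def _prime(self) -> None:
        """Compute forces for the current positions without moving."""
        self.flags[K.F_INIT_ONLY] = 1
        K.dpd_step(self.system.pos, self.system.vel, self.frc,
                   self.system.species, self.img, self.bonds, self.angles,
                   self.tether_ids, self.anchors, self._box, self.wall_h,
                   self.p, self.flags, self.step_count, self.seed, self.out)
        self.flags[K.F_INIT_ONLY] = 0

    def step(self, n: int = 1) -> None:
        for _ in range(n):
            self.step_count += 1
            K.dpd_step(self.system.pos, self.system.vel, self.frc,
                       self.system.species, self.img, self.bonds, self.angles,
                       self.tether_ids, self.anchors, self._box, self.wall_h,
                       self.p, self.flags, self.step_count, self.seed, self.out)
            self._acc += self.out
            self._acc_n += 1
        if self.flags[K.F_MOVING_WALL] and self.wall_h[0] < 1.0:
            raise RuntimeError("over-compression: moving wall reached the "
                               "bottom wall")

    def run(self, n_steps: int, sample_stride: int = 100,
            log: StepLog | None = None, callback=None) -> StepLog:
        """Advance ``n_steps``, sampling scalars every ``sample_stride``."""
        log = log if log is not None else StepLog()
        done = 0
        while done < n_steps:
            chunk = min(sample_stride, n_steps - done)
            self.step(chunk)
            done += chunk
            log.step.append(self.step_count)
            log.temperature.append(kinetic_temperature(self.system))
            log.wall_h.append(float(self.wall_h[0]))
            log.F_f.append(float(self.out[K.O_FF]))
            log.F_wall.append(float(self.out[K.O_FWALL]))
            log.e_bond.append(float(self.out[K.O_EBOND]))
            log.e_angle.append(float(self.out[K.O_EANGLE]))
            if callback is not None:
                callback(self)
        return log

    def drain(self) -> dict:
        """Per-step means of the diagnostics accumulated since the last
        drain (friction force, wall reaction, bounce-back momentum...)."""
        n = max(self._acc_n, 1)
        means = self._acc / n
        out = {"F_f": means[K.O_FF], "F_wall": means[K.O_FWALL],
               "bounce_px": means[K.O_BOUNCE_PX], "e_bond": means[K.O_EBOND],
               "e_angle": means[K.O_EANGLE], "n": self._acc_n}
        self._acc[:] = 0.0
        self._acc_n = 0
        return out

    def unwrapped_pos(self) -> np.ndarray:
        """Positions with periodic x/y wraps undone."""
        pos = self.system.pos.copy()
        pos[:, 0] += self.img[:, 0] * self._box[0]
        pos[:, 1] += self.img[:, 1] * self._box[1]
        return pos


def relax(system: BeadSystem, topology: NetworkTopology | None,
          dpd: DPDParams, bonded: BondedParams | None = None, *,
          steps: int = 2000, cap: float = 0.1, seed: int = 1) -> BeadSystem:
    """Short relaxation with capped per-step displacement.

    Removes build-time overlaps before production; soft DPD potentials make
    this a formality rather than a minimization problem.
    """
    sim = Simulation(system, dpd, topology, bonded, seed=seed)
    capped = max(1, steps // 4)
    for _ in range(capped):
        v0 = system.pos.copy()
        sim.step()
        dx = system.pos - v0
        for ax in range(3):
            L = system.box[ax]
            dx[:, ax] -= L * np.rint(dx[:, ax] / L)
        norm = np.linalg.norm(dx, axis=1)
        over = norm > cap
        if np.any(over):
            scale = cap / norm[over]
            system.pos[over] = v0[over] + dx[over] * scale[:, None]
            system.wrap()
    sim.step(steps - capped)
    return system
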