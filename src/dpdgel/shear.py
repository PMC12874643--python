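"""The frictional shear experiment.

A gel slab sits on the stationary bottom wall (bounce-back no-slip for
solvent, harmonic guards for both species), its top layer is tethered to a
rigid wall that is loaded with a constant normal force F_n, slides at
constant velocity V, passes solvent freely and blocks gel.  The friction
force F_f is the time-averaged horizontal force the tethers (i.e. the
moving wall) must exert on the gel to keep it sliding, and mu = <F_f>/F_n.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .params import BondedParams, DPDParams, NetworkParams, ShearCellConfig, WallSpec
from .system import SOLVENT, BeadSystem, NetworkTopology
from .builder import build_gel, fill_solvent
from .engine import Simulation, StepLog
from .characterize import MaterialProps

__all__ = [
    "FrictionRecord",
    "ShearCell",
    "bounce_back_bottom",
    "wall_repulsion",
    "tether_gel_top",
    "measure_friction",
    "nondimensionalize",
    "V_from_Wi",
    "Fn_from_P",
]


def bounce_back_bottom(system: BeadSystem) -> BeadSystem:
    """Reflect solvent beads that crossed z=0, reversing all velocity
    components (no-slip: zero mean in-plane velocity at the plane)."""
    m = (system.species == SOLVENT) & (system.pos[:, 2] < 0.0)
    system.pos[m, 2] *= -1.0
    system.vel[m] *= -1.0
    return system


def wall_repulsion(system: BeadSystem, walls: WallSpec,
                   wall_h: float | None = None) -> np.ndarray:
    """One-sided harmonic wall forces (U = K d^2 inside the repulsion zone).

    The bottom zone spans [0, standoff] above the rigid wall (species-
    dependent strength), the top zone [Lz - standoff, Lz] acts on solvent,
    and the moving wall at ``wall_h`` blocks gel with no standoff (solvent
    exists on both of its sides, so there is no pile-up to counter).
    """
    f = np.zeros_like(system.pos)
    z = system.pos[:, 2]
    sol = system.species == SOLVENT
    zw = walls.standoff
    below = z < zw
    f[below & sol, 2] = 2.0 * walls.k_bottom_solvent * (zw - z[below & sol])
    f[below & ~sol, 2] = 2.0 * walls.k_bottom_gel * (zw - z[below & ~sol])
    Lz = system.box[2]
    above = sol & (z > Lz - zw)
    f[above, 2] = -2.0 * walls.k_top_solvent * (z[above] - (Lz - zw))
    if wall_h is not None:
        over = ~sol & (z > wall_h)
        f[over, 2] = -2.0 * walls.k_moving_gel * (z[over] - wall_h)
    return f


def tether_gel_top(system: BeadSystem, xi0: float,
                   gel_top: float | None = None):
    """Select the tether set: gel beads within one mesh size of the gel top.

    Returns ``(ids, anchors)`` where anchors start at the beads' own
    positions.  Raises if the slab is empty.
    """
    gel = system.species != SOLVENT
    if gel_top is None:
        gel_top = float(system.pos[gel, 2].max())
    m = gel & (system.pos[:, 2] >= gel_top - xi0)
    ids = np.flatnonzero(m).astype(np.int64)
    if ids.size == 0:
        raise ValueError("empty tether set: no gel beads near the top")
    return ids, system.pos[ids].copy()


def measure_friction(F_f: np.ndarray, F_n: float, n_blocks: int = 5):
    """mu = <F_f>/F_n with a block-averaged standard error.

    ``F_f`` must contain production-phase samples only.
    """
    if F_n == 0:
        raise ValueError("mu undefined at zero normal load")
    F_f = np.asarray(F_f, dtype=float)
    mu = float(F_f.mean() / F_n)
    blocks = np.array_split(F_f, n_blocks)
    bm = np.array([b.mean() for b in blocks]) / F_n
    err = float(bm.std(ddof=1) / np.sqrt(n_blocks))
    return mu, err


def nondimensionalize(walls: WallSpec, props: MaterialProps, area: float):
    """(Wi, P) for a run: Wi = V eta xi0^2 / kBT and P = F_n / (A E)."""
    if props is None:
        raise ValueError("material calibration required")
    Wi = walls.V * props.eta * props.xi0 ** 2
    P = walls.F_n / (area * props.E)
    return Wi, P


def V_from_Wi(Wi: float, props: MaterialProps, kBT: float = 1.0) -> float:
    return Wi * kBT / (props.eta * props.xi0 ** 2)


def Fn_from_P(P: float, props: MaterialProps, area: float) -> float:
    return P * area * props.E


@dataclass
class FrictionRecord:
    """Result of one sliding run."""

    steps: np.ndarray
    F_f: np.ndarray
    wall_h: np.ndarray
    F_n: float
    V: float
    P: float
    Wi: float
    seed: int
    mu: float = 0.0
    mu_err: float = 0.0
    meta: dict = field(default_factory=dict)

    def finalize(self, n_blocks: int = 5) -> "FrictionRecord":
        self.mu, self.mu_err = measure_friction(self.F_f, self.F_n, n_blocks)
        return self


@dataclass
class ProfileAccumulator:
    """On-the-fly z-binned gel density and solvent velocity averages."""

    edges: np.ndarray
    gel_count: np.ndarray
    sol_vx: np.ndarray
    sol_count: np.ndarray
    n_frames: int = 0

    @classmethod
    def make(cls, Lz: float, bin_width: float):
        n = int(np.ceil(Lz / bin_width))
        return cls(np.linspace(0, Lz, n + 1), np.zeros(n), np.zeros(n),
                   np.zeros(n))

    def add(self, system: BeadSystem) -> None:
        z = np.clip(system.pos[:, 2], 0, self.edges[-1] - 1e-9)
        nb = len(self.gel_count)
        idx = (z / (self.edges[-1] / nb)).astype(np.int64)
        gel = system.species != SOLVENT
        self.gel_count += np.bincount(idx[gel], minlength=nb)
        self.sol_vx += np.bincount(idx[~gel], weights=system.vel[~gel, 0],
                                   minlength=nb)
        self.sol_count += np.bincount(idx[~gel], minlength=nb)
        self.n_frames += 1


class ShearCell:
    """A built, wired shear cell ready to equilibrate and slide."""

    def __init__(self, sim: Simulation, topology: NetworkTopology,
                 tether_ids: np.ndarray, props: MaterialProps,
                 seed: int):
        self.sim = sim
        self.topology = topology
        self.tether_ids = tether_ids
        self.props = props
        self.seed = seed
        self.ref_pos: np.ndarray | None = None

    @classmethod
    def build(cls, network: NetworkParams, dpd: DPDParams | None = None,
              bonded: BondedParams | None = None,
              walls: WallSpec | None = None, *,
              props: MaterialProps | None = None,
              gel_height_frac: float = 0.8, relax_steps: int = 600,
              seed: int = 0) -> "ShearCell":
        """Construct gel + solvent in the cell geometry.

        The network is generated in the lower ``gel_height_frac`` of the
        box (the head-space above receives solvent expelled under load),
        solvent fills the whole box to total density rho0, the moving wall
        starts at the gel top with the top gel layer tethered to it, and a
        short capped relaxation removes build-time overlaps.
        """
        dpd = dpd or DPDParams()
        bonded = bonded or BondedParams.for_spacing(network.r_eq)
        walls = walls or WallSpec()
        props = props or MaterialProps.reference()
        Lx, Ly, Lz = network.box
        gel_h = gel_height_frac * Lz
        gel_params = dataclasses.replace(network, box=(Lx, Ly, gel_h),
                                         seed=seed)
        gel_sys, topo, _ = build_gel(gel_params, with_solvent=False)
        full = dataclasses.replace(network, seed=seed)
        gel_sys = BeadSystem(gel_sys.pos, gel_sys.vel, gel_sys.species,
                             (Lx, Ly, Lz))
        system = fill_solvent(gel_sys, full,
                              np.random.default_rng(seed + 101),
                              gel_top=gel_h)
        rng = np.random.default_rng(seed + 202)
        system.thermalize(dpd.kBT, rng)

        tether_ids, anchors = tether_gel_top(system, props.xi0, gel_h)

        # overlap-removal phase: no load, no sliding, walls in place
        pre_walls = dataclasses.replace(walls, F_n=0.0, V=0.0)
        pre = Simulation(system, dpd, topo, bonded, pre_walls,
                         bottom_wall=True, top_solvent_wall=True,
                         moving_wall=True, tether_ids=tether_ids,
                         anchors=anchors.copy(), wall_h=gel_h, seed=seed)
        cap = 0.1
        for _ in range(min(relax_steps, 400)):
            p0 = system.pos.copy()
            pre.step()
            dxyz = system.pos - p0
            for ax in range(2):
                L = system.box[ax]
                dxyz[:, ax] -= L * np.rint(dxyz[:, ax] / L)
            nrm = np.linalg.norm(dxyz, axis=1)
            over = nrm > cap
            if np.any(over):
                system.pos[over] = p0[over] + dxyz[over] * (cap / nrm[over])[:, None]
                system.wrap()
        if relax_steps > 400:
            pre.step(relax_steps - 400)

        sim = Simulation(system, dpd, topo, bonded, walls,
                         bottom_wall=True, top_solvent_wall=True,
                         moving_wall=True, tether_ids=tether_ids,
                         anchors=pre.anchors, wall_h=float(pre.wall_h[0]),
                         seed=seed + 1)
        return cls(sim, topo, tether_ids, props, seed)

    @property
    def area(self) -> float:
        return self.sim.system.box[0] * self.sim.system.box[1]

    def equilibrate(self, steps: int, stride: int = 100) -> StepLog:
        """Run the loaded, sliding transient that is discarded from
        friction averages; the reference configuration for strain is taken
        at the end.

        When sliding starts the whole cell is boosted to the wall velocity
        V: in steady state gel and bulk solvent co-move with the wall and
        only the near-wall boundary layer differs, so starting co-moving
        removes the slow whole-box momentum-diffusion transient.
        """
        V = self.sim.walls.V
        if V != 0.0 and not getattr(self, "_boosted", False):
            self.sim.system.vel[:, 0] += V
            self._boosted = True
        log = self.sim.run(steps, stride)
        self.ref_pos = self.sim.unwrapped_pos()
        return log

    def produce(self, steps: int, stride: int = 50,
                bin_width: float | None = None):
        """Production phase: friction time series + profile accumulation.

        Returns ``(FrictionRecord, ProfileAccumulator, displacement)``
        where ``displacement`` is the time-averaged unwrapped displacement
        of every bead relative to the reference configuration (input to
        the shear-strain estimator).
        """
        sys_ = self.sim.system
        if self.ref_pos is None:
            self.ref_pos = self.sim.unwrapped_pos()
        bw = bin_width if bin_width is not None else 0.1 * self.props.xi0
        acc = ProfileAccumulator.make(sys_.box[2], bw)
        disp_sum = np.zeros(sys_.n)
        n_disp = 0
        Ff, hh, ss = [], [], []
        done = 0
        self.sim.drain()
        while done < steps:
            self.sim.step(stride)
            done += stride
            Ff.append(float(self.sim.drain()["F_f"]))
            hh.append(float(self.sim.wall_h[0]))
            ss.append(self.sim.step_count)
            acc.add(sys_)
            disp_sum += self.sim.unwrapped_pos()[:, 0] - self.ref_pos[:, 0]
            n_disp += 1
        walls = self.sim.walls
        Wi, P = nondimensionalize(walls, self.props, self.area)
        rec = FrictionRecord(np.array(ss), np.array(Ff), np.array(hh),
                             walls.F_n, walls.V, P, Wi, self.seed)
        if walls.F_n > 0:
            rec.finalize()
        return rec, acc, disp_sum / max(n_disp, 1)


def run_shear(config: ShearCellConfig, props: MaterialProps | None = None,
              *, gel_height_frac: float = 0.8):
    """One full sliding experiment from a config: build, transient,
    production.  Returns (FrictionRecord, ProfileAccumulator, gamma).
    """
    from .analysis import shear_strain

    props = props or MaterialProps.reference()
    walls = config.walls
    if config.Wi and walls.V == 0.0:
        walls = dataclasses.replace(walls, V=V_from_Wi(config.Wi, props,
                                                       config.dpd.kBT))
    if config.P and walls.F_n == 0.0:
        area = config.network.box[0] * config.network.box[1]
        walls = dataclasses.replace(walls, F_n=Fn_from_P(config.P, props, area))
    cell = ShearCell.build(config.network, config.dpd, config.bonded, walls,
                           props=props, gel_height_frac=gel_height_frac,
                           seed=config.seed)
    cell.equilibrate(config.equilibration_steps)
    rec, acc, disp = cell.produce(config.production_steps,
                                  config.sample_stride)
    gel = cell.sim.system.gel_mask
    gamma = shear_strain(disp[gel], cell.ref_pos[gel, 2],
                         drift_ids=None)
    rec.meta["gamma"] = gamma
    return rec, acc, gamma
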