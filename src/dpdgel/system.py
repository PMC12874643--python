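"""In-memory containers: the particle state and the permanent gel topology."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# species codes
SOLVENT = 0
MONOMER = 1
CROSSLINK = 2


@dataclass
class BeadSystem:
    """Positions, velocities and species of every bead plus box geometry.

    The box is periodic in x and y; z is bounded (walls live there).  A
    fully periodic variant (``pbc_z=True``) is used for bulk-fluid
    calibration runs.  All beads have unit mass.
    """

    pos: np.ndarray                    # (N, 3) float64
    vel: np.ndarray                    # (N, 3) float64
    species: np.ndarray                # (N,) int8
    box: tuple[float, float, float]
    pbc_z: bool = False

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.vel = np.ascontiguousarray(self.vel, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        if self.pos.shape != self.vel.shape or self.pos.shape[0] != self.species.shape[0]:
            raise ValueError("inconsistent array shapes")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def gel_mask(self) -> np.ndarray:
        return self.species != SOLVENT

    @property
    def n_solvent(self) -> int:
        return int(np.count_nonzero(self.species == SOLVENT))

    @property
    def n_gel(self) -> int:
        return int(np.count_nonzero(self.species != SOLVENT))

    def wrap(self) -> None:
        """Wrap coordinates into the box along the periodic directions."""
        for ax in (0, 1) if not self.pbc_z else (0, 1, 2):
            L = self.box[ax]
            self.pos[:, ax] %= L

    def copy(self) -> "BeadSystem":
        return BeadSystem(self.pos.copy(), self.vel.copy(),
                          self.species.copy(), tuple(self.box), self.pbc_z)

    def thermalize(self, kBT: float, rng: np.random.Generator) -> None:
        """Draw Maxwell-Boltzmann velocities with zero total momentum."""
        self.vel[:] = rng.normal(0.0, np.sqrt(kBT), size=self.vel.shape)
        self.vel -= self.vel.mean(axis=0)


@dataclass
class NetworkTopology:
    """Permanent connectivity of the cross-linked network.

    ``chains`` lists, for every polymer chain, the ordered global bead ids
    from one terminal cross-link through the interior monomers to the other
    terminal cross-link (a dangling chain ends on a monomer).
    """

    crosslink_ids: np.ndarray               # (n_x,) int64
    chains: list[np.ndarray] = field(default_factory=list)
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.int64))

    def __post_init__(self) -> None:
        self.crosslink_ids = np.asarray(self.crosslink_ids, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def monomers_per_chain(self) -> np.ndarray:
        """Interior monomer count N for every chain."""
        return np.array([len(c) - 2 for c in self.chains], dtype=np.int64)

    def degrees(self) -> np.ndarray:
        """Number of chains attached to each cross-link."""
        deg = {int(i): 0 for i in self.crosslink_ids}
        xl = set(deg)
        for c in self.chains:
            for end in (int(c[0]), int(c[-1])):
                if end in xl:
                    deg[end] += 1
        return np.array([deg[int(i)] for i in self.crosslink_ids], dtype=np.int64)

    def validate(self, n_beads: int, max_functionality: int = 4) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n_beads):
            raise ValueError("bond references an invalid bead id")
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() >= n_beads):
            raise ValueError("angle references an invalid bead id")
        if np.any(self.degrees() > max_functionality):
            raise ValueError("cross-link functionality cap exceeded")
        bond_set = {(int(min(a, b)), int(max(a, b))) for a, b in self.bonds}
        for c in self.chains:
            for a, b in zip(c[:-1], c[1:]):
                if (int(min(a, b)), int(max(a, b))) not in bond_set:
                    raise ValueError("chain records inconsistent with bond list")
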