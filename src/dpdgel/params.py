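"""Parameter containers for the DPD hydrogel shear-cell model.

All quantities are in reduced DPD units: the interaction cutoff ``r_c`` is
the unit of length, the bead mass the unit of mass, and the thermal energy
``k_B T`` the unit of energy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DPDParams",
    "BondedParams",
    "NetworkParams",
    "WallSpec",
    "ShearCellConfig",
    "load_config",
    "dump_config",
]


@dataclass
class DPDParams:
    """Nonbonded DPD interaction parameters.

    The noise amplitude ``sigma`` is not free: the fluctuation-dissipation
    relation sigma^2 = 2 * gamma * kBT ties it to the dissipative
    coefficient so the pair thermostat samples the target temperature.
    """

    r_c: float = 1.0          # interaction cutoff (unit of length)
    a: float = 25.0           # conservative repulsion amplitude
    gamma: float = 4.5        # dissipative (friction) coefficient
    kBT: float = 1.0          # thermal energy
    dt: float = 0.01          # integration time step

    def __post_init__(self) -> None:
        if self.r_c <= 0 or self.dt <= 0:
            raise ValueError("r_c and dt must be positive")
        if self.gamma < 0 or self.kBT < 0:
            raise ValueError("gamma and kBT must be non-negative")

    @property
    def sigma(self) -> float:
        """Random-force amplitude fixed by fluctuation-dissipation."""
        return math.sqrt(2.0 * self.gamma * self.kBT)


@dataclass
class BondedParams:
    """Bonded (intra-chain) potentials: U_bond = k_bond (r - r_eq)^2 and
    U_bend = k_bend (1 + cos theta); a straight chain is the bending
    minimum.

    ``r_eq`` is the bond rest length.  Bonded neighbours also feel the
    soft conservative repulsion, which pushes them apart, so the actual
    equilibrium separation of a bonded pair is
    (2 k_bond r_eq + a)/(2 k_bond + a) > r_eq.  Use
    :meth:`for_spacing` to pick r_eq such that the pair equilibrates at
    the monomer spacing the network builder uses — otherwise every chain
    is created pre-stressed and the network creeps toward a swollen
    state.
    """

    k_bond: float = 16.0
    r_eq: float = 0.0203
    k_bend: float = 10.0

    def __post_init__(self) -> None:
        if self.k_bond < 0 or self.k_bend < 0:
            raise ValueError("bonded stiffnesses must be non-negative")
        if self.r_eq < 0:
            raise ValueError("r_eq must be non-negative")

    @classmethod
    def for_spacing(cls, spacing: float, a: float = 25.0,
                    k_bond: float = 16.0, k_bend: float = 10.0,
                    r_c: float = 1.0) -> "BondedParams":
        """Rest length such that bond + pair repulsion balance at
        ``spacing``: 2 k (s - r_eq) = a (1 - s/r_c)."""
        r_eq = spacing - a * max(0.0, 1.0 - spacing / r_c) / (2.0 * k_bond)
        return cls(k_bond=k_bond, r_eq=max(r_eq, 0.0), k_bend=k_bend)

    def equilibrium_spacing(self, a: float = 25.0, r_c: float = 1.0) -> float:
        """Bonded-pair separation where bond tension balances repulsion."""
        return (2.0 * self.k_bond * self.r_eq + a) / (2.0 * self.k_bond
                                                      + a / r_c)


# Default generator constants.  crosslink_density, connect_cutoff and r_eq
# were calibrated jointly (scripts in the repository history; see
# docs/methods.md) so the as-built network reproduces the target structural
# statistics: porosity ~0.89, mean chain length ~6.2 monomers, mean mesh
# size ~3.2.
@dataclass
class NetworkParams:
    """Parameters of the random cross-linked bead-spring network generator."""

    box: tuple[float, float, float] = (20.0, 20.0, 20.0)
    rho0: float = 3.0                 # total bead number density
    crosslink_density: float = 0.027  # cross-links per unit volume
    max_functionality: int = 4        # chains per cross-link, hard cap
    connect_cutoff: float = 4.2       # neighbour rule: connect within this distance
    min_spacing: float = 1.5          # minimum cross-link pair separation
    r_eq: float = 0.45                # bead spacing along discretized chains
    periodic_z: bool = False          # wrap connections in z (bulk statistics)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_functionality < 1:
            raise ValueError("max_functionality must be >= 1")
        if any(L <= 0 for L in self.box):
            raise ValueError("box lengths must be positive")
        if not 0 < self.crosslink_density:
            raise ValueError("crosslink_density must be positive")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")

    @property
    def volume(self) -> float:
        return self.box[0] * self.box[1] * self.box[2]

    @property
    def n_crosslinks(self) -> int:
        return int(round(self.crosslink_density * self.volume))

    @property
    def n_total(self) -> int:
        """Total bead count (gel + solvent) at density rho0."""
        return int(round(self.rho0 * self.volume))


@dataclass
class WallSpec:
    """Wall constants of the shear cell.

    The bottom plane (z = 0) is the stationary rigid wall: solvent obeys a
    bounce-back no-slip rule plus a one-sided harmonic guard of strength
    6.57; gel is kept out by a stiffer one-sided harmonic of strength 50.
    The top box boundary repels solvent with strength 50.  The moving top
    wall is permeable to solvent, blocks gel with a one-sided harmonic,
    carries the normal load F_n and slides at velocity V.
    """

    k_bottom_solvent: float = 6.57
    k_bottom_gel: float = 50.0
    k_top_solvent: float = 50.0
    k_moving_gel: float = 50.0
    k_tether: float = 50.0
    standoff: float = 1.0         # wall repulsion-zone thickness (r_c units)
    F_n: float = 0.0              # compressive load on the moving wall
    V: float = 0.0                # sliding velocity of the moving wall
    wall_mobility: float = 1.0    # overdamped wall-height gain (semi-implicit)

    def __post_init__(self) -> None:
        for name in ("k_bottom_solvent", "k_bottom_gel", "k_top_solvent",
                     "k_moving_gel", "k_tether"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ShearCellConfig:
    """Full configuration of one frictional sliding run."""

    dpd: DPDParams = field(default_factory=DPDParams)
    bonded: BondedParams = field(default_factory=BondedParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    walls: WallSpec = field(default_factory=WallSpec)
    P: float = 0.0                # dimensionless load F_n / (A E)
    Wi: float = 0.0               # Weissenberg number V eta xi0^2 / kBT
    equilibration_steps: int = 20_000
    production_steps: int = 30_000
    sample_stride: int = 50
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict):
    return cls(**data)


def load_config(path: str | Path) -> ShearCellConfig:
    """Read a ShearCellConfig from a YAML file with full defaulting."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, sub in (("dpd", DPDParams), ("bonded", BondedParams),
                     ("network", NetworkParams), ("walls", WallSpec)):
        if key in raw:
            d = dict(raw.pop(key))
            if key == "network" and "box" in d:
                d["box"] = tuple(d["box"])
            kwargs[key] = _build(sub, d)
    kwargs.update(raw)
    return ShearCellConfig(**kwargs)


def dump_config(cfg: ShearCellConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["network"]["box"] = list(d["network"]["box"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_hash(cfg: ShearCellConfig) -> str:
    """Host-independent hash of a resolved configuration."""
    import hashlib

    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
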