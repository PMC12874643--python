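"""Random cross-linked bead-spring network generator.

The construction follows the statistically isotropic protocol: cross-link
points are scattered uniformly in the box (with a minimum spacing to avoid
degenerate meshes), neighbouring cross-links are connected pairwise by
polymer chains up to a functionality cap of four, and each chain is
discretized into monomer beads spaced ~r_eq along the straight segment.
The box is periodic in x and y; connections do not wrap in z, which leaves
a naturally sparser gel layer about one mesh size thick at the top and
bottom surfaces, the depletion expected for a swollen gel boundary.

Default generator constants (cross-link density, connection cutoff, r_eq)
are calibrated so the emergent statistics land on porosity ~0.89, mean
chain length ~6.2 monomers and mean mesh size ~3.2; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .params import NetworkParams
from .system import CROSSLINK, MONOMER, SOLVENT, BeadSystem, NetworkTopology

__all__ = [
    "place_crosslinks",
    "connect_network",
    "discretize_chains",
    "fill_solvent",
    "chain_length_distribution",
    "porosity",
    "build_gel",
    "BuildReport",
]


def _min_image(d: np.ndarray, box, periodic_z: bool = False) -> np.ndarray:
    d = d.copy()
    for ax in (0, 1, 2) if periodic_z else (0, 1):
        d[..., ax] -= box[ax] * np.rint(d[..., ax] / box[ax])
    return d


def place_crosslinks(params: NetworkParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random cross-link coordinates with a minimum pair spacing.

    Spacing is enforced by rejection sampling (minimum image in x, y);
    raises if the requested count cannot fit the box at ``min_spacing``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_crosslinks
    if n == 0:
        return np.empty((0, 3))
    box = np.asarray(params.box)
    # sphere-packing feasibility guard (random sequential addition jams
    # near ~0.38 volume fraction; stay well below)
    occupied = n * (4.0 / 3.0) * np.pi * (params.min_spacing / 2.0) ** 3
    if occupied > 0.3 * params.volume:
        raise ValueError(
            f"infeasible geometry: {n} cross-links at minimum spacing "
            f"{params.min_spacing} do not fit a box of volume {params.volume:.1f}")
    pts = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    s2 = params.min_spacing ** 2
    while placed < n:
        if attempts >= max_attempts:
            raise ValueError("infeasible geometry: cross-link placement "
                             "exceeded the attempt budget")
        cand = rng.random(3) * box
        d = _min_image(pts[:placed] - cand, box, params.periodic_z)
        if placed == 0 or np.min(np.einsum("ij,ij->i", d, d)) >= s2:
            pts[placed] = cand
            placed += 1
        attempts += 1
    return pts


def connect_network(crosslinks: np.ndarray, params: NetworkParams,
                    rng: np.random.Generator | None = None):
    """Pair neighbouring cross-links into chains, capped at functionality 4.

    Candidate pairs are all cross-link pairs within ``connect_cutoff``
    (minimum image in x, y; no wrap in z).  They are drawn in random order
    and accepted while both endpoints have spare functionality, which keeps
    the network statistically isotropic.  Returns ``(pairs, report)`` where
    ``pairs`` is an (M, 2) id array and ``report`` carries the degree
    histogram and largest-connected-component fraction.
    """
    if len(crosslinks) < 2:
        raise ValueError("need at least two cross-links")
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    box = np.asarray(params.box)
    n = len(crosslinks)

    # tile periodic images so the tree sees periodic neighbours
    zshifts = (-box[2], 0.0, box[2]) if params.periodic_z else (0.0,)
    shifts = np.array([(ix, iy, iz) for ix in (-box[0], 0, box[0])
                       for iy in (-box[1], 0, box[1]) for iz in zshifts])
    tiled = (crosslinks[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tree = cKDTree(crosslinks)
    cand = tree.query_ball_point(tiled, params.connect_cutoff)
    pairs = set()
    for t, neigh in enumerate(cand):
        i = t % n
        for j in neigh:
            if i != j:
                pairs.add((min(i, j), max(i, j)))
    cand_pairs = np.array(sorted(pairs), dtype=np.int64)
    order = rng.permutation(len(cand_pairs))

    deg = np.zeros(n, np.int64)
    cap = params.max_functionality
    accepted = []
    for k in order:
        i, j = cand_pairs[k]
        if deg[i] < cap and deg[j] < cap:
            accepted.append((i, j))
            deg[i] += 1
            deg[j] += 1
    accepted = np.array(accepted, dtype=np.int64).reshape(-1, 2)

    iso = int(np.count_nonzero(deg == 0))
    if iso:
        warnings.warn(f"{iso} isolated cross-links retained as dangling points")
    adj = sparse.coo_matrix((np.ones(len(accepted)),
                             (accepted[:, 0], accepted[:, 1])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    lcc = float(np.bincount(labels).max()) / n if n else 0.0
    report = {
        "n_crosslinks": n,
        "n_chains": int(len(accepted)),
        "mean_degree": float(deg.mean()),
        "isolated": iso,
        "largest_component_fraction": lcc,
    }
    return accepted, report


def discretize_chains(crosslinks: np.ndarray, pairs: np.ndarray,
                      params: NetworkParams):
    """Replace every straight cross-link--cross-link segment by monomers.

    N = max(round(d / r_eq) - 1, 0) interior beads, evenly spaced so bonds
    start unstrained; bonds join consecutive beads and bending angles act
    on every consecutive triple along the chain, including the triples
    that span the terminal cross-links.  Returns (BeadSystem of gel beads,
    NetworkTopology).
    """
    box = np.asarray(params.box)
    n_x = len(crosslinks)
    positions = [crosslinks]
    chains: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    angles: list[tuple[int, int, int]] = []
    next_id = n_x
    n0_flagged = 0
    wrap_axes = (0, 1, 2) if params.periodic_z else (0, 1)
    for i, j in pairs:
        d = _min_image(crosslinks[j] - crosslinks[i], box, params.periodic_z)
        dist = float(np.linalg.norm(d))
        N = max(int(round(dist / params.r_eq)) - 1, 0)
        if N == 0:
            n0_flagged += 1
        ids = [int(i)]
        if N > 0:
            ts = np.arange(1, N + 1) / (N + 1)
            pts = crosslinks[i] + ts[:, None] * d
            for ax in wrap_axes:
                pts[:, ax] %= box[ax]
            positions.append(pts)
            ids.extend(range(next_id, next_id + N))
            next_id += N
        ids.append(int(j))
        chain = np.array(ids, dtype=np.int64)
        chains.append(chain)
        bonds.extend(zip(chain[:-1], chain[1:]))
        angles.extend(zip(chain[:-2], chain[1:-1], chain[2:]))
    if n0_flagged:
        warnings.warn(f"{n0_flagged} chains shorter than one bond length "
                      "became direct cross-link bonds")
    pos = np.concatenate(positions, axis=0) if positions else np.empty((0, 3))
    species = np.full(len(pos), MONOMER, np.int8)
    species[:n_x] = CROSSLINK
    system = BeadSystem(pos, np.zeros_like(pos), species, tuple(params.box))
    topo = NetworkTopology(np.arange(n_x, dtype=np.int64), chains,
                           np.array(bonds, np.int64).reshape(-1, 2),
                           np.array(angles, np.int64).reshape(-1, 3))
    return system, topo


def fill_solvent(system: BeadSystem, params: NetworkParams,
                 rng: np.random.Generator | None = None,
                 gel_top: float | None = None) -> BeadSystem:
    """Add solvent beads at random positions up to total density rho0.

    When the gel occupies only the slab [0, ``gel_top``] of a taller box,
    solvent is partitioned so the *total* density is uniform: the gel slab
    receives rho0 minus the gel contribution, the head-space receives the
    full rho0 (an imbalance would exert an osmotic pressure far exceeding
    the gel modulus).  Soft DPD potentials tolerate the resulting
    overlaps; a brief capped relaxation removes them.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    n_total = params.n_total
    n_add = n_total - system.n
    if n_add < 0:
        raise ValueError("gel alone already exceeds the target density")
    box = np.asarray(params.box)
    Lz = box[2]
    if gel_top is None or gel_top >= Lz:
        pos = rng.random((n_add, 3)) * box
    else:
        area = box[0] * box[1]
        n_head = int(round(params.rho0 * area * (Lz - gel_top)))
        n_head = min(n_head, n_add)
        n_slab = n_add - n_head
        pos_s = rng.random((n_slab, 3)) * np.array([box[0], box[1], gel_top])
        pos_h = rng.random((n_head, 3)) * box
        pos_h[:, 2] = gel_top + pos_h[:, 2] * (Lz - gel_top) / Lz
        pos = np.concatenate([pos_s, pos_h], axis=0)
    new_pos = np.concatenate([system.pos, pos], axis=0)
    new_species = np.concatenate(
        [system.species, np.full(n_add, SOLVENT, np.int8)])
    return BeadSystem(new_pos, np.zeros_like(new_pos), new_species,
                      tuple(params.box), system.pbc_z)


def chain_length_distribution(topology: NetworkTopology):
    """Normalized probability mass over chain monomer counts N, with mean.

    Returns ``(values, pmf, mean)``.
    """
    if topology.n_chains == 0:
        raise ValueError("empty topology")
    N = topology.monomers_per_chain
    values, counts = np.unique(N, return_counts=True)
    pmf = counts / counts.sum()
    return values, pmf, float(N.mean())


def porosity(system: BeadSystem) -> float:
    """Solvent-filled volume fraction, via the bead-count proxy.

    At uniform total density the solvent bead fraction equals the solvent
    volume fraction, and bead counting is unambiguous for soft particles.
    """
    if system.n == 0:
        raise ValueError("empty system")
    return system.n_solvent / system.n


@dataclass
class BuildReport:
    n_crosslinks: int
    n_chains: int
    mean_degree: float
    isolated: int
    largest_component_fraction: float
    mean_chain_length: float
    porosity: float
    gel_fraction: float


def build_gel(params: NetworkParams, *, with_solvent: bool = True):
    """Build the full gel(+solvent) system from a NetworkParams.

    Returns ``(system, topology, report)``.  Deterministic for a given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    xl = place_crosslinks(params, rng)
    pairs, creport = connect_network(xl, params, rng)
    system, topo = discretize_chains(xl, pairs, params)
    _, _, meanN = chain_length_distribution(topo)
    if with_solvent:
        system = fill_solvent(system, params, rng)
    eps = porosity(system) if with_solvent else float("nan")
    report = BuildReport(
        n_crosslinks=creport["n_crosslinks"],
        n_chains=creport["n_chains"],
        mean_degree=creport["mean_degree"],
        isolated=creport["isolated"],
        largest_component_fraction=creport["largest_component_fraction"],
        mean_chain_length=meanN,
        porosity=eps,
        gel_fraction=1.0 - eps if with_solvent else float("nan"),
    )
    return system, topo, report
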