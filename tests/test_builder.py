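"""Network generator: placement, connectivity, discretization and the
emergent structural statistics."""

import dataclasses

import numpy as np
import pytest

from dpdgel import builder
from dpdgel.params import NetworkParams


def params(**kw):
    base = dict(box=(12.0, 12.0, 12.0), seed=5)
    base.update(kw)
    return NetworkParams(**base)


class TestPlaceCrosslinks:
    def test_zero_count_empty(self):
        p = params(crosslink_density=1e-9)
        assert p.n_crosslinks == 0
        assert builder.place_crosslinks(p).shape == (0, 3)

    def test_all_inside_box(self):
        p = params()
        pts = builder.place_crosslinks(p)
        assert len(pts) == p.n_crosslinks
        assert (pts >= 0).all() and (pts <= 12.0).all()

    def test_deterministic_for_seed(self):
        np.testing.assert_array_equal(builder.place_crosslinks(params()),
                                      builder.place_crosslinks(params()))

    def test_min_spacing_respected(self):
        p = params(min_spacing=2.0)
        pts = builder.place_crosslinks(p)
        from scipy.spatial.distance import pdist
        assert pdist(pts).min() >= 2.0 - 1e-12  # interior pairs

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            builder.place_crosslinks(params(box=(3.0, 3.0, 3.0),
                                            crosslink_density=2.0,
                                            min_spacing=1.5))


class TestConnectNetwork:
    def test_two_crosslinks_one_chain(self):
        p = params()
        xl = np.array([[2.0, 2.0, 2.0], [4.0, 2.0, 2.0]])
        pairs, rep = builder.connect_network(xl, p)
        assert pairs.tolist() == [[0, 1]]
        assert rep["n_chains"] == 1

    def test_degree_cap_on_clique(self):
        """5 mutually neighbouring cross-links: brute-force degree audit."""
        p = params(max_functionality=4)
        xl = 5.0 + np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                             [0, 0, 1], [1, 1, 1]], dtype=float)
        pairs, _ = builder.connect_network(xl, p)
        deg = np.zeros(5, int)
        for i, j in pairs:
            deg[i] += 1
            deg[j] += 1
        assert deg.max() <= 4

    def test_max_degree_never_exceeds_cap(self, small_network):
        _, _, topo, _ = small_network
        assert topo.degrees().max() <= 4

    def test_isolated_crosslink_warns(self):
        p = params(connect_cutoff=1.5)
        xl = np.array([[2.0, 2.0, 2.0], [3.0, 2.0, 2.0], [9.0, 9.0, 9.0]])
        with pytest.warns(UserWarning, match="isolated"):
            pairs, rep = builder.connect_network(xl, p)
        assert rep["isolated"] == 1


class TestDiscretizeChains:
    def test_shortest_chain_direct_bond(self):
        p = params()
        xl = np.array([[2.0, 2.0, 2.0], [2.0 + p.r_eq, 2.0, 2.0]])
        with pytest.warns(UserWarning, match="direct cross-link"):
            system, topo = builder.discretize_chains(
                xl, np.array([[0, 1]]), p)
        assert system.n == 2
        assert len(topo.bonds) == 1
        assert len(topo.angles) == 0

    @pytest.mark.parametrize("nominal_n", [1, 4, 9])
    def test_bond_and_angle_counts(self, nominal_n):
        """A chain of N interior beads carries N+1 bonds and N angles."""
        p = params()
        sep = (nominal_n + 1) * p.r_eq
        xl = np.array([[2.0, 2.0, 2.0], [2.0 + sep, 2.0, 2.0]])
        system, topo = builder.discretize_chains(xl, np.array([[0, 1]]), p)
        N = topo.monomers_per_chain[0]
        assert N == nominal_n
        assert len(topo.bonds) == N + 1
        assert len(topo.angles) == N
        # spacing approximately r_eq, bonds unstrained at creation
        chain = topo.chains[0]
        d = np.diff(system.pos[chain], axis=0)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), p.r_eq,
                                   rtol=1e-9)

    def test_topology_internally_consistent(self, small_network):
        _, system, topo, _ = small_network
        topo.validate(system.n)


class TestFillAndPorosity:
    def test_bead_budget_arithmetic(self, small_network):
        p, system, _, _ = small_network
        assert system.n == round(3.0 * 12.0 ** 3)

    def test_no_gel_limit_pure_solvent(self):
        p = params(crosslink_density=1e-9)
        from dpdgel.system import BeadSystem
        empty = BeadSystem(np.empty((0, 3)), np.empty((0, 3)),
                           np.empty(0, np.int8), p.box)
        full = builder.fill_solvent(empty, p)
        assert builder.porosity(full) == 1.0

    def test_porosity_complement(self, small_network):
        _, system, _, rep = small_network
        assert rep.porosity + rep.gel_fraction == pytest.approx(1.0)

    def test_headspace_fill_density_matched(self):
        """With a gel slab below a head-space, total density is uniform."""
        import dataclasses as dc

        from dpdgel.builder import build_gel, fill_solvent
        from dpdgel.system import BeadSystem

        p = params(box=(10.0, 10.0, 14.0))
        gel_sys, _, _ = build_gel(dc.replace(p, box=(10.0, 10.0, 10.0)),
                                  with_solvent=False)
        gel_sys = BeadSystem(gel_sys.pos, gel_sys.vel, gel_sys.species,
                             p.box)
        full = fill_solvent(gel_sys, p, np.random.default_rng(0),
                            gel_top=10.0)
        z = full.pos[:, 2]
        rho_slab = np.count_nonzero(z < 10.0) / (100.0 * 10.0)
        rho_head = np.count_nonzero(z >= 10.0) / (100.0 * 4.0)
        assert rho_slab == pytest.approx(rho_head, rel=0.03)


class TestChainLengthDistribution:
    def test_degenerate_all_equal(self):
        from dpdgel.system import NetworkTopology

        chains = [np.arange(7) + 7 * k for k in range(3)]  # N=5 each
        topo = NetworkTopology(np.array([c[0] for c in chains]
                                        + [c[-1] for c in chains]), chains)
        vals, pmf, mean = builder.chain_length_distribution(topo)
        assert vals.tolist() == [5]
        assert pmf.tolist() == [1.0]
        assert mean == 5.0

    def test_mean_matches_independent_summation(self, small_network):
        _, _, topo, rep = small_network
        total = sum(len(c) - 2 for c in topo.chains)
        assert rep.mean_chain_length == pytest.approx(
            total / len(topo.chains))

    def test_empty_topology_raises(self):
        from dpdgel.system import NetworkTopology

        with pytest.raises(ValueError):
            builder.chain_length_distribution(
                NetworkTopology(np.empty(0, np.int64), []))


class TestStructuralStatistics:
    def test_reproducible_build(self):
        p = params()
        s1, t1, _ = builder.build_gel(p)
        s2, t2, _ = builder.build_gel(p)
        np.testing.assert_array_equal(s1.pos, s2.pos)
        np.testing.assert_array_equal(t1.bonds, t2.bonds)

    def test_isotropy_of_chain_vectors(self):
        """Mean end-to-end vector ~ 0; x/y/z variances comparable."""
        p = NetworkParams(box=(20.0, 20.0, 20.0), periodic_z=True, seed=8)
        xl = builder.place_crosslinks(p)
        pairs, _ = builder.connect_network(xl, p)
        system, topo = builder.discretize_chains(xl, pairs, p)
        from dpdgel.builder import _min_image

        e2e = np.array([_min_image(system.pos[c[-1]] - system.pos[c[0]],
                                   np.array(p.box), True)
                        for c in topo.chains])
        n = len(e2e)
        mean = e2e.mean(axis=0)
        scale = np.linalg.norm(e2e, axis=1).mean()
        assert np.linalg.norm(mean) < 4 * scale / np.sqrt(n)
        var = e2e.var(axis=0)
        assert var.max() / var.min() < 1.5

    def test_surface_layer_sparser_than_bulk(self):
        """Open-z build leaves a depleted gel layer near both surfaces."""
        p = NetworkParams(box=(16.0, 16.0, 16.0), seed=2)
        system, _, _ = builder.build_gel(p, with_solvent=False)
        z = system.pos[:, 2]
        area = 16.0 * 16.0
        xi0 = 3.2
        surf = (np.count_nonzero(z < xi0)
                + np.count_nonzero(z > 16.0 - xi0)) / (2 * xi0 * area) / 2
        bulk = np.count_nonzero(np.abs(z - 8.0) < 3.0) / (6.0 * area)
        assert surf < bulk

    def test_porosity_and_chain_length_near_targets(self):
        """Calibrated defaults land near porosity 0.89 and N0 6.2."""
        eps, Ns = [], []
        for seed in (0, 1):
            p = NetworkParams(box=(16.0, 16.0, 16.0), seed=seed)
            _, _, rep = builder.build_gel(p)
            eps.append(rep.porosity)
            Ns.append(rep.mean_chain_length)
        assert np.mean(eps) == pytest.approx(0.89, abs=0.02)
        assert np.mean(Ns) == pytest.approx(6.2, rel=0.08)
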