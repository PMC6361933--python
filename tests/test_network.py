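import itertools

import networkx as nx
import numpy as np
import pytest

from critsync import network as nw


class TestConstruction:
    @pytest.mark.parametrize(
        "steps,n_nodes,n_hubs", [(1, 25, 1), (2, 125, 5)]
    )
    def test_node_and_hub_counts(self, steps, n_nodes, n_hubs):
        net = nw.build_base_network(steps)
        assert net.n_nodes == n_nodes
        assert len(net.hubs) == n_hubs

    def test_step1_hub_degree(self):
        # 4 clique neighbours + 4 peripherals from each of 4 replica cliques
        net = nw.build_base_network(1)
        assert net.degree[0] == 20

    def test_step2_degrees(self):
        net = nw.build_base_network(2)
        k = net.degree
        assert k[0] == 84  # global hub: 20 + 4*16 peripheral attachments
        assert all(k[i] == 20 for i in (25, 50, 75, 100))  # local hubs

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            nw.build_base_network(3)

    def test_bidirectional_representation(self):
        net = nw.build_base_network(1)
        pairs = net.undirected_pairs()
        assert len(net.edges) == 2 * len(pairs)
        edge_set = {tuple(e) for e in net.edges}
        for a, b in pairs:
            assert (a, b) in edge_set and (b, a) in edge_set

    def test_assembly_counts(self, net625):
        assert net625.n_nodes == 625
        assert len(net625.hubs) == 25
        assert (net625.hub_class == "global").sum() == 5
        assert (net625.hub_class == "local").sum() == 20
        # hubs are 4% of all nodes
        assert len(net625.hubs) / net625.n_nodes == 0.04

    def test_assembly_is_disjoint_union(self, net625):
        unit = nw.build_base_network(2)
        assert len(net625.edges) == 5 * len(unit.edges)
        # no link crosses a 125-node replica boundary before rich-club wiring
        assert np.all(net625.edges[:, 0] // 125 == net625.edges[:, 1] // 125)

    def test_assembly_rejects_wrong_unit(self):
        with pytest.raises(ValueError):
            nw.assemble_replicas(nw.build_base_network(1))

    def test_local_hub_neighbourhood_single_cluster(self, net625):
        adj = {i: set() for i in range(net625.n_nodes)}
        for a, b in net625.undirected_pairs():
            adj[a].add(b)
            adj[b].add(a)
        hubs = set(net625.hubs.tolist())
        for lh in np.flatnonzero(net625.hub_class == "local"):
            outside = {n for n in adj[lh] if n not in hubs}
            clusters = {net625.cluster25[n] for n in outside}
            assert len(clusters) == 1

    def test_degree_sequence_deterministic(self, net625):
        again = nw.assemble_replicas(nw.build_base_network(2))
        assert np.array_equal(net625.degree, again.degree)


class TestRichClub:
    def test_kappa_zero_adds_nothing(self, net625, rng):
        out = nw.connect_rich_club(net625, 0.0, rng)
        assert len(out.edges) == len(net625.edges)

    def test_kappa_one_adds_all_pairs(self, net625, rng):
        out = nw.connect_rich_club(net625, 1.0, rng)
        # C(25,2)=300 hub pairs, none adjacent in the base construction
        assert len(out.edges) - len(net625.edges) == 2 * 300

    def test_kappa_half_binomial_mean(self, net625):
        added = [
            (len(nw.connect_rich_club(net625, 0.5, np.random.default_rng(s)).edges)
             - len(net625.edges)) // 2
            for s in range(40)
        ]
        # Binomial(300, 0.5): mean 150, sd ~8.7; 40-seed mean sd ~1.4
        assert abs(np.mean(added) - 150) < 6

    def test_invalid_kappa(self, net625, rng):
        with pytest.raises(ValueError):
            nw.connect_rich_club(net625, 1.5, rng)

    def test_rich_club_only_raises_hub_degrees(self, net625, rng):
        out = nw.connect_rich_club(net625, 1.0, rng)
        k0, k1 = net625.degree, out.degree
        non_hub = net625.hub_class == "none"
        assert np.array_equal(k0[non_hub], k1[non_hub])
        assert np.all(k1[~non_hub] >= k0[~non_hub])

    def test_hub_degree_windows_with_full_rich_club(self, net625, rng):
        out = nw.connect_rich_club(net625, 1.0, rng)
        k = out.degree
        assert np.all(k[out.hub_class == "global"] >= 100)
        loc = k[out.hub_class == "local"]
        assert loc.min() >= 20 and loc.max() <= 44

    def test_classify_hubs_matches_construction(self, net625, rng):
        labels = nw.classify_hubs(net625)
        assert np.array_equal(labels, net625.hub_class)
        net125 = nw.build_base_network(2)
        assert net125.degree[nw.classify_hubs(net125) == "global"].min() >= 80


class TestNeuronTypes:
    @pytest.mark.parametrize("case,expected", [(1, "inhibitory"), (2, "excitatory")])
    def test_global_hub_types(self, net625, rng, case, expected):
        out = nw.assign_neuron_types(net625, case, 0.5, rng)
        assert np.all(out.neuron_type[out.hub_class == "global"] == expected)

    @pytest.mark.parametrize("eta,expected", [(0.0, "excitatory"), (1.0, "inhibitory")])
    def test_local_hub_extremes(self, net625, rng, eta, expected):
        out = nw.assign_neuron_types(net625, 1, eta, rng)
        assert np.all(out.neuron_type[out.hub_class == "local"] == expected)

    def test_non_hub_split_exact(self, net625, rng):
        out = nw.assign_neuron_types(net625, 1, 0.5, rng)
        non_hub_types = out.neuron_type[out.hub_class == "none"]
        assert (non_hub_types == "excitatory").sum() == 480
        assert (non_hub_types == "inhibitory").sum() == 120

    def test_local_hub_inhibitory_fraction_converges_to_eta(self, net625):
        eta = 0.3
        fracs = [
            (nw.assign_neuron_types(net625, 1, eta, np.random.default_rng(s))
             .neuron_type[net625.hub_class == "local"] == "inhibitory").mean()
            for s in range(60)
        ]
        # Bernoulli(0.3) over 20 hubs x 60 seeds: se ~ 0.013
        assert abs(np.mean(fracs) - eta) < 0.05

    def test_explicit_local_hub_override(self, rng):
        net = nw.build_base_network(2)
        out = nw.assign_neuron_types(net, 1, 0.0, rng, local_hub_inhibitory=[50, 100])
        assert list(out.neuron_type[[50, 100]]) == ["inhibitory", "inhibitory"]
        assert list(out.neuron_type[[25, 75]]) == ["excitatory", "excitatory"]

    def test_dales_law_link_signs(self, typed625):
        sign = typed625.link_sign()
        src_inh = typed625.neuron_type[typed625.edges[:, 0]] == "inhibitory"
        assert np.all(sign[src_inh] == -1)
        assert np.all(sign[~src_inh] == 1)

    def test_invalid_eta(self, net625, rng):
        with pytest.raises(ValueError):
            nw.assign_neuron_types(net625, 1, -0.1, rng)


class TestRichClubCoefficient:
    def test_identity_null_gives_unity(self, rng):
        net = nw.build_base_network(2)
        phi = nw.normalized_rich_club(net, [4, 5], n_null=2, rng=rng,
                                      swaps_per_edge=0)
        assert phi[4] == pytest.approx(1.0)
        assert phi[5] == pytest.approx(1.0)

    def test_full_rich_club_exceeds_null(self, rng):
        net = nw.assemble_replicas(nw.build_base_network(2))
        net = nw.connect_rich_club(net, 1.0, rng)
        phi = nw.normalized_rich_club(net, [50], n_null=5, rng=rng,
                                      swaps_per_edge=2)
        assert phi[50] > 1.0

    def test_toy_graph_matches_exhaustive_count(self, rng):
        # against an identity null, phi is defined iff the brute-force count
        # of edges among degree->k nodes is nonzero, and then equals one
        net = nw.build_base_network(1)
        g = net.to_networkx()
        deg = dict(g.degree())
        for k in (3, 4, 19):
            rich = [n for n in g if deg[n] > k]
            expected = sum(
                1 for a, b in itertools.combinations(rich, 2) if g.has_edge(a, b)
            )
            phi = nw.normalized_rich_club(net, [k], n_null=1, rng=rng,
                                          swaps_per_edge=0)
            if expected == 0:
                assert np.isnan(phi[k])
            else:
                assert phi[k] == pytest.approx(1.0)

    def test_no_nodes_above_k_is_nan(self, rng):
        net = nw.build_base_network(1)
        phi = nw.normalized_rich_club(net, [1000], n_null=1, rng=rng,
                                      swaps_per_edge=0)
        assert np.isnan(phi[1000])


class TestVariants:
    def test_unidirectional_halves_links(self, net625, rng):
        out = nw.variant_unidirectional(net625, rng)
        assert len(out.edges) == len(net625.edges) // 2
        assert out.undirected_pairs() == net625.undirected_pairs()

    def test_randomized_preserves_indegree(self, net625, rng):
        out = nw.variant_randomize_keep_indegree(net625, rng)
        indeg0 = np.bincount(net625.edges[:, 1], minlength=625)
        indeg1 = np.bincount(out.edges[:, 1], minlength=625)
        assert np.array_equal(indeg0, indeg1)
        assert np.all(out.edges[:, 0] != out.edges[:, 1])

    def test_randomized_destroys_clustering(self, net625, rng):
        out = nw.variant_randomize_keep_indegree(net625, rng)
        c0 = nx.average_clustering(net625.to_networkx())
        c1 = nx.average_clustering(out.to_networkx())
        assert c1 < c0 / 2


class TestDegreeExponent:
    def test_base_network_exponent_near_2_1(self, net625):
        gamma, k_min = nw.degree_exponent(net625.degree)
        assert gamma == pytest.approx(2.1, abs=0.2)
        assert k_min == 20  # hub hierarchy starts at the local-hub degree

    def test_recovers_synthetic_pareto_tail(self):
        r = np.random.default_rng(1)
        samples = np.floor((1 - r.random(20000)) ** (-1 / 1.1)).astype(int)
        gamma, _ = nw.degree_exponent(samples)
        assert gamma == pytest.approx(2.1, abs=0.25)

    def test_discrete_ml_variant_runs(self, net625):
        gamma, k_min = nw.degree_exponent_ml(net625.degree)
        assert np.isfinite(gamma) and gamma > 1.0


class TestSerialization:
    def test_roundtrip(self, typed625, tmp_path):
        nw.write_network(typed625, tmp_path)
        back = nw.read_network(tmp_path)
        assert back.n_nodes == typed625.n_nodes
        assert {tuple(e) for e in back.edges} == {tuple(e) for e in typed625.edges}
        assert np.array_equal(back.neuron_type, typed625.neuron_type)
        assert np.array_equal(back.hub_class, typed625.hub_class)
        assert np.array_equal(back.cluster5, typed625.cluster5)
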