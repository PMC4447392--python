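"""Network expansion: reachability, canonical ordering, reduced-model oracles."""

import dataclasses

import numpy as np
import pytest

from ddrsim.model import _parse_mol_pattern, build_default_model
from ddrsim.network import (
    enumerate_network,
    initial_species,
    simulate_network,
    species_from_pattern,
)


def dna_species(network):
    return [s for s in network.species if any(m[0] == "DNA" for m in s)]


class TestEnumeration:
    def test_one_site_model_counts(self, mrc5_one_site):
        net = enumerate_network(mrc5_one_site)
        assert len(dna_species(net)) == 91
        assert net.n_species - len(dna_species(net)) == 33
        assert net.n_reactions == 446 + 41

    def test_canonicalization_idempotent(self, mrc5_one_site):
        net1 = enumerate_network(mrc5_one_site)
        net2 = enumerate_network(mrc5_one_site)
        assert net1.species == net2.species
        assert [
            (r.rule, r.reactants, r.products) for r in net1.reactions
        ] == [(r.rule, r.reactants, r.products) for r in net2.reactions]

    def test_dna_local_species_scale_linearly_with_site_count(self):
        one = enumerate_network(build_default_model("MRC5", n_dna_sites=1))
        two = enumerate_network(build_default_model("MRC5", n_dna_sites=2))
        assert len(dna_species(two)) == 2 * len(dna_species(one))

    def test_species_bound_error_reports_partial_counts(self, mrc5_one_site):
        from ddrsim.network import NetworkError

        with pytest.raises(NetworkError, match="species bound exceeded"):
            enumerate_network(mrc5_one_site, max_species=10)


# Independent oracle for the repair machinery on one broken site: adjacency
# of the bound-factor state machine, enumerated by hand.  With only
# repair-tagged rules active and the site seeded with a simple break (H2AX
# unphosphorylated, so ligation stays unreachable), the reachable states and
# transitions are exactly these.
ORACLE_EDGES = [
        ("none", "Kr"), ("none", "Ko"), ("none", "PARP"),      # binding
        ("Kr", "none"), ("Ko", "none"),                        # Ku dissociation
        ("Kr", "Ko"), ("Ko", "Kr"),                            # redox on site
        ("Kr", "KrPu"), ("Kr", "KrPp"),                        # DNA-PKcs binding
        ("Ko", "KoPu"), ("Ko", "KoPp"),
        ("KrPu", "Kr"), ("KrPp", "Kr"), ("KoPu", "Ko"), ("KoPp", "Ko"),
        ("KrPu", "KrPp"), ("KoPu", "KoPp"),                    # autophosphorylation
        ("KrPp", "KrPu"), ("KoPp", "KoPu"),                    # on-site dephos
        ("KrPp", "KrPpL"), ("KoPp", "KoPpL"),                  # ligase IV binding
        ("KrPpL", "KrPp"), ("KoPpL", "KoPp"),
        ("KrPu", "KoPu"), ("KrPp", "KoPp"), ("KrPpL", "KoPpL"),  # oxidation
        ("KoPu", "KrPu"), ("KoPp", "KrPp"), ("KoPpL", "KrPpL"),  # reduction
        ("KoPu", "none"), ("KoPp", "none"),                    # oxidized breakup
        ("PARP", "none"), ("PARP", "PARPL"), ("PARPL", "PARP"),
]


@pytest.fixture(scope="module")
def repair_net():
    model = build_default_model("MRC5", n_dna_sites=1)
    repair_only = dataclasses.replace(
        model, rules=tuple(r for r in model.rules if r.tag == "repair")
    )
    seeds = dict(initial_species(model))
    # replace the intact site with a simple break
    intact = species_from_pattern(
        _parse_mol_pattern("DNA(id~1, site~ok, h2ax~u)")
    )
    del seeds[intact]
    broken = species_from_pattern(
        _parse_mol_pattern("DNA(id~1, site~sdsb, h2ax~u)")
    )
    seeds[broken] = 1.0
    return enumerate_network(repair_only, seeds=seeds), seeds


class TestRepairOnlyOracle:
    ORACLE_EDGES = ORACLE_EDGES

    def test_reachable_states_match_brute_force(self, repair_net):
        net, seeds = repair_net
        reachable = {s for s, _ in zip(self.ORACLE_EDGES, ())}
        reachable = {"none"}
        frontier = ["none"]
        while frontier:
            s = frontier.pop()
            for a, b in self.ORACLE_EDGES:
                if a == s and b not in reachable:
                    reachable.add(b)
                    frontier.append(b)
        assert len(reachable) == 11
        # the network's DNA complexes correspond 1:1 to oracle states
        assert len(dna_species(net)) == len(reachable)
        # free oxidized Ku and phosphorylated DNA-PKcs appear as new pools
        n_new_pools = net.n_species - len(seeds) - (len(reachable) - 1)
        assert n_new_pools == 2

    def test_reaction_count_matches_edge_enumeration(self, repair_net):
        net, _ = repair_net
        assert net.n_reactions == len(self.ORACLE_EDGES)

    def test_ligation_unreachable_without_focus(self, repair_net):
        net, _ = repair_net
        assert all(not r.rule.startswith("ligate") for r in net.reactions)
        # the site never returns to the intact state
        ok = species_from_pattern(_parse_mol_pattern("DNA(id~1, site~ok, h2ax~u)"))
        assert ok not in net.species


class TestNetworkVersusEngine:
    def test_network_free_engine_matches_expanded_network_moments(self, mrc5_one_site):
        """Dual-route check on a birth-death submodel (ROS and p53).

        All rules except ROS production/decay and p53 synthesis/degradation
        are silenced; the expanded-network SSA and the network-free engine
        must then agree in distribution (Welch t-test on means).
        """
        from ddrsim.engine import simulate_cell
        from tests.conftest import zeroed_overlay

        keep = {"k_ros_prod_norm", "k_ros_dec", "k_p53_syn", "k_p53_deg"}
        model = mrc5_one_site.with_overrides(
            {
                **zeroed_overlay(mrc5_one_site, keep=keep),
                "k_ros_prod_norm": 1.0,
                "k_ros_dec": 0.02,
                "k_p53_syn": 0.06,
                "k_p53_deg": 2.0e-3,
                "init_ros": 30.0,
                "init_p53": 10.0,
            }
        )
        net = enumerate_network(model)
        idx = net.species_index()
        ros_i = idx[species_from_pattern(_parse_mol_pattern("ROS()"))]
        p53_i = idx[species_from_pattern(_parse_mol_pattern("p53(psite~u)"))]

        n_rep, t_end = 120, 400.0
        net_ros, net_p53 = [], []
        for k in range(n_rep):
            _, counts = simulate_network(net, t_end, seed=1000 + k,
                                         sample_every=t_end)
            net_ros.append(counts[-1, ros_i])
            net_p53.append(counts[-1, p53_i])
        eng_ros, eng_p53 = [], []
        for k in range(n_rep):
            tr = simulate_cell(model, None, t_end, seed=2000 + k,
                               sample_every=t_end)
            eng_ros.append(tr.column("ros")[-1])
            eng_p53.append(tr.p53[-1])

        from scipy import stats

        for a, b in ((net_ros, eng_ros), (net_p53, eng_p53)):
            t, p = stats.ttest_ind(a, b, equal_var=False)
            assert p > 0.01, (np.mean(a), np.mean(b), p)
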