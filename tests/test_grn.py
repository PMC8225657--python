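"""GRN generation: TF sampling, interaction inheritance, reference-network
sampling, target and housekeeping subnetworks."""

import networkx as nx
import numpy as np
import pytest

import stochastix as sx
from stochastix.grn import (
    GeneRegulatoryNetwork,
    generate_grn,
    generate_reference_network,
    generate_tf_interactions,
    sample_housekeeping_subnetwork,
    sample_target_subnetwork,
    sample_tfs,
)


class TestSampleTfs:
    def test_exactly_one_tf_per_module_at_the_bound(self, linear_backbone):
        tfs = sample_tfs(linear_backbone, num_tfs=5, rng=0)
        assert len(tfs) == 5
        assert {t.module for t in tfs} == set(linear_backbone.module_names)

    def test_every_module_covered_with_extra_tfs(self, linear_backbone):
        tfs = sample_tfs(linear_backbone, num_tfs=12, rng=0)
        assert len(tfs) == 12
        counts = {m: 0 for m in linear_backbone.module_names}
        for t in tfs:
            counts[t.module] += 1
        assert min(counts.values()) >= 1

    def test_too_few_tfs_errors(self, linear_backbone):
        with pytest.raises(ValueError, match="too small"):
            sample_tfs(linear_backbone, num_tfs=3)

    def test_tfs_inherit_burn_and_basal_from_module(self, linear_backbone):
        tfs = sample_tfs(linear_backbone, num_tfs=8, rng=1)
        for t in tfs:
            mod = linear_backbone.module(t.module)
            assert t.burn == mod.burn
            assert t.basal == mod.basal


class TestTfInteractions:
    def test_effect_and_strength_inherited(self):
        bb = sx.predefined_backbone("cyclic")
        tfs = sample_tfs(bb, num_tfs=8, rng=2)
        inter = generate_tf_interactions(bb, tfs, rng=3)
        by_module = {t.name: t.module for t in tfs}
        mod_edges = {
            (mi.from_module, mi.to_module): mi for mi in bb.module_interactions
        }
        for i in inter:
            mi = mod_edges[(by_module[i.regulator], by_module[i.target])]
            assert i.effect == mi.effect
            assert i.strength == mi.strength

    def test_every_downstream_tf_gets_a_regulator(self):
        bb = sx.predefined_backbone("bifurcating")
        tfs = sample_tfs(bb, num_tfs=2 * len(bb.modules), rng=4)
        inter = generate_tf_interactions(bb, tfs, rng=5)
        by_module = {t.name: t.module for t in tfs}
        for mi in bb.module_interactions:
            for t in tfs:
                if t.module != mi.to_module:
                    continue
                regs = [
                    i for i in inter
                    if i.target == t.name and by_module[i.regulator] == mi.from_module
                ]
                assert regs, f"{t.name} lacks a regulator from {mi.from_module}"

    def test_no_module_interactions_give_no_tf_interactions(self, linear_backbone):
        from stochastix.backbone import Backbone

        bb = Backbone("empty", linear_backbone.modules, [], linear_backbone.state_network,
                      linear_backbone.start_state)
        tfs = sample_tfs(bb, num_tfs=5, rng=6)
        assert generate_tf_interactions(bb, tfs, rng=7) == []


class TestReferenceNetwork:
    def test_size_and_no_self_loops(self):
        ref = generate_reference_network(100, rng=0)
        assert ref.num_nodes == 100
        assert not list(nx.selfloop_edges(ref.graph))

    def test_seed_determinism(self):
        e1 = sorted(generate_reference_network(80, rng=42).graph.edges())
        e2 = sorted(generate_reference_network(80, rng=42).graph.edges())
        assert e1 == e2

    def test_in_degree_bounded(self):
        ref = generate_reference_network(200, max_in_degree=5, rng=1)
        assert max(d for _, d in ref.graph.in_degree()) <= 5

    def test_out_degree_is_heavy_tailed(self):
        ref = generate_reference_network(500, rng=2)
        out = np.array([d for _, d in ref.graph.out_degree()])
        # hubs: the top regulator covers many times the mean out-degree
        assert out.max() > 5 * out.mean()

    def test_tsv_round_trip(self, tmp_path):
        from stochastix.grn import ReferenceNetwork

        ref = generate_reference_network(30, rng=3)
        p = tmp_path / "ref.tsv"
        ref.to_tsv(p)
        back = ReferenceNetwork.from_tsv(p)
        assert sorted(back.graph.edges()) == sorted(ref.graph.edges())


@pytest.fixture(scope="module")
def grn_with_targets(linear_backbone):
    tfs = sample_tfs(linear_backbone, 5, rng=0)
    inter = generate_tf_interactions(linear_backbone, tfs, rng=1)
    base = GeneRegulatoryNetwork(tfs, inter, linear_backbone)
    ref = generate_reference_network(300, rng=2)
    return sample_target_subnetwork(base, ref, num_targets=50, rng=3)


class TestTargetSubnetwork:

    def test_exact_target_count(self, grn_with_targets):
        assert len(grn_with_targets.genes_of_kind("target")) == 50

    def test_every_target_downstream_of_a_tf(self, grn_with_targets):
        g = grn_with_targets.to_graph()
        tf_names = [t.name for t in grn_with_targets.genes_of_kind("tf")]
        reachable = set()
        for t in tf_names:
            reachable |= nx.descendants(g, t)
        for target in grn_with_targets.genes_of_kind("target"):
            assert target.name in reachable

    def test_in_degree_capped(self, grn_with_targets):
        for target in grn_with_targets.genes_of_kind("target"):
            assert 1 <= len(grn_with_targets.regulators_of(target.name)) <= 5

    def test_max_one_regulator_bound(self, linear_backbone):
        tfs = sample_tfs(linear_backbone, 5, rng=0)
        base = GeneRegulatoryNetwork(tfs, [], linear_backbone)
        ref = generate_reference_network(100, rng=4)
        out = sample_target_subnetwork(base, ref, 20, max_regs_per_target=1, rng=5)
        for target in out.genes_of_kind("target"):
            assert len(out.regulators_of(target.name)) == 1


class TestHousekeeping:
    def test_bfs_sample_is_weakly_connected(self):
        ref = generate_reference_network(50, rng=6)
        genes, inter = sample_housekeeping_subnetwork(ref, 10, rng=7)
        assert len(genes) == 10
        g = nx.Graph()
        g.add_nodes_from(gene.name for gene in genes)
        g.add_edges_from((i.regulator, i.target) for i in inter)
        assert nx.is_connected(g)

    def test_zero_housekeeping_is_empty(self):
        ref = generate_reference_network(20, rng=8)
        assert sample_housekeeping_subnetwork(ref, 0, rng=9) == ([], [])

    def test_housekeeping_isolated_in_full_grn(self, small_grn):
        hk = {g.name for g in small_grn.genes_of_kind("housekeeping")}
        other = {g.name for g in small_grn.genes if g.kind != "housekeeping"}
        for i in small_grn.interactions:
            crosses = (i.regulator in hk) != (i.target in hk)
            assert not crosses


class TestFullPipeline:
    def test_gene_counts_add_up(self, small_grn):
        assert len(small_grn.genes_of_kind("tf")) == 10
        assert len(small_grn.genes_of_kind("target")) == 8
        assert len(small_grn.genes_of_kind("housekeeping")) == 4
        assert len(small_grn.genes) == 22

    def test_fixed_seed_reproducibility(self, linear_backbone):
        a = generate_grn(linear_backbone, 8, 10, 5, rng=99)
        b = generate_grn(linear_backbone, 8, 10, 5, rng=99)
        assert a.genes == b.genes
        assert a.interactions == b.interactions

    def test_tf_in_edges_come_only_from_tfs(self, small_grn):
        kinds = {g.name: g.kind for g in small_grn.genes}
        for i in small_grn.interactions:
            if kinds[i.target] == "tf":
                assert kinds[i.regulator] == "tf"
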