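import networkx as nx
import numpy as np
import pytest

from anatomynet import compare
from anatomynet.community import ModulePartition
from anatomynet.io import BONE, AnatomicalNetwork
from anatomynet.metrics import basic_params

from conftest import net_from_nx
from oracles import brute_nmi


def part(assignment):
    return ModulePartition(assignment=dict(assignment), q=0.0)


class TestPartitionSimilarity:
    def test_identical_partitions_score_one(self):
        p = part({"a": 0, "b": 0, "c": 1})
        res = compare.partition_similarity(p, p)
        assert res.ratio == 1.0 and res.n_common == 3

    def test_one_block_vs_singletons(self):
        labels = list("abcde")
        res = compare.partition_similarity(
            part({l: 0 for l in labels}), part({l: i for i, l in enumerate(labels)})
        )
        assert res.n_coclassified == 1 and res.ratio == pytest.approx(0.2)

    def test_two_of_twenty_reassigned(self):
        a = {f"e{i}": i // 5 for i in range(20)}          # four blocks of five
        b = dict(a)
        b["e0"], b["e5"] = 3, 3                            # move two elements
        res = compare.partition_similarity(part(a), part(b))
        assert res.ratio == pytest.approx(0.9)

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            a = {f"e{i}": int(rng.integers(0, 4)) for i in range(n)}
            b = {f"e{i}": int(rng.integers(0, 4)) for i in range(n)}
            assert (
                compare.partition_similarity(part(a), part(b)).ratio
                == compare.partition_similarity(part(b), part(a)).ratio
            )

    def test_label_map_bridges_namespaces(self):
        ul = part({"humerus": 0, "radius": 0, "carpal": 1})
        ll = part({"femur": 0, "tibia": 0, "tarsal": 1})
        lmap = {"humerus": "femur", "radius": "tibia", "carpal": "tarsal"}
        res = compare.partition_similarity(ul, ll, lmap)
        assert res.ratio == 1.0 and res.n_common == 3

    def test_empty_common_set_is_an_error(self):
        with pytest.raises(ValueError, match="label_map"):
            compare.partition_similarity(part({"a": 0}), part({"b": 0}))


class TestNMI:
    def test_identical_partitions(self):
        p = part({"a": 0, "b": 0, "c": 1, "d": 2})
        res = compare.nmi_similarity(p, p)
        assert res.nmi == pytest.approx(1.0) and res.similarity_percent == pytest.approx(100.0)

    def test_invariant_to_module_relabeling(self):
        a = part({f"e{i}": i % 3 for i in range(12)})
        b = part({f"e{i}": (i % 3 + 1) % 3 for i in range(12)})
        assert compare.nmi_similarity(a, b).nmi == pytest.approx(1.0)

    def test_independent_random_partitions_near_zero(self):
        rng = np.random.default_rng(17)
        a = {f"e{i}": int(rng.integers(0, 5)) for i in range(1000)}
        b = {f"e{i}": int(rng.integers(0, 5)) for i in range(1000)}
        assert compare.nmi_similarity(part(a), part(b)).nmi < 0.05

    def test_coarsening_matches_entropy_oracle(self):
        # 10 modules of 3; merge modules 8 and 9 into one
        a = {f"e{i}": i // 3 for i in range(30)}
        b = {l: (8 if m == 9 else m) for l, m in a.items()}
        ours = compare.nmi_similarity(part(a), part(b)).nmi
        ref = brute_nmi([a[f"e{i}"] for i in range(30)], [b[f"e{i}"] for i in range(30)])
        assert 0.0 < ours < 1.0
        assert ours == pytest.approx(ref)

    def test_degenerate_single_group_both_sides(self):
        a = part({"a": 0, "b": 0})
        assert compare.nmi_similarity(a, a).nmi == 1.0

    def test_extra_elements_trigger_restriction_warning(self):
        a = part({"a": 0, "b": 1, "c": 1})
        b = part({"a": 0, "b": 1})
        with pytest.warns(UserWarning, match="restricting"):
            compare.nmi_similarity(a, b)


def limb_pair():
    """Synthetic UL/LL pair: identical distal digit chains, different proximal hubs."""
    def build(girdle_edges):
        g = nx.Graph()
        g.add_edges_from(girdle_edges)
        g.add_edges_from([("stylo", "zeug"), ("zeug", "wrist")])
        for d in range(3):
            g.add_edges_from([("wrist", f"d{d}_0"), (f"d{d}_0", f"d{d}_1")])
        return net_from_nx(g)

    ul = build([("g1", "g2"), ("g2", "g3"), ("g1", "g3"), ("g1", "stylo"),
                ("g2", "stylo"), ("g3", "stylo")])         # dense girdle hub
    ll = build([("g1", "g2"), ("g1", "stylo")])            # sparse girdle chain
    regions = lambda net: {
        l: ("proximal" if l.startswith(("g", "stylo")) else "distal") for l in net.labels
    }
    return ul, ll, regions(ul), regions(ll)


class TestProximalDistal:
    def test_identical_networks_score_zero(self):
        ul, _, r_ul, _ = limb_pair()
        res = compare.proximal_distal_params(ul, ul, r_ul, r_ul)
        assert res["prox_vs_prox"] == 0.0 and res["dist_vs_dist"] == 0.0

    def test_shared_distal_chains_more_similar_than_proximal_hubs(self):
        ul, ll, r_ul, r_ll = limb_pair()
        res = compare.proximal_distal_params(ul, ll, r_ul, r_ll)
        assert res["dist_vs_dist"] < res["prox_vs_prox"]

    def test_swapping_inputs_leaves_scores_unchanged(self):
        ul, ll, r_ul, r_ll = limb_pair()
        a = compare.proximal_distal_params(ul, ll, r_ul, r_ll)
        b = compare.proximal_distal_params(ll, ul, r_ll, r_ul)
        assert a["prox_vs_prox"] == pytest.approx(b["prox_vs_prox"])
        assert a["dist_vs_dist"] == pytest.approx(b["dist_vs_dist"])

    def test_empty_region_subgraph_not_assessable(self):
        ul, ll, r_ul, r_ll = limb_pair()
        all_prox = {l: "proximal" for l in ll.labels}
        res = compare.proximal_distal_params(ul, ll, r_ul, all_prox)
        assert res["dist_vs_dist"] is None
        assert res["params"]["LL_distal"] is None
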