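from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from oracles import best_trio_reference

from tissuenet import best_trio, compare_networks, expansion_ability, extract_subnetwork, trio_count
from tissuenet.errors import ParameterError, ValidationError
from tissuenet.pcit import StateNetwork


def _net(edges, nodes, state="PRE", tissue_of=None, tfs=()):
    nodes = sorted(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    sig = np.zeros((n, n), dtype=bool)
    corr = np.zeros((n, n))
    for a, b in edges:
        i, j = pos[a], pos[b]
        sig[i, j] = sig[j, i] = True
        corr[i, j] = corr[j, i] = 0.5
    np.fill_diagonal(corr, 1.0)
    attrs = pd.DataFrame(
        {
            "tissue_of_max_expression": [
                (tissue_of or {}).get(g, "T1") for g in nodes
            ],
            "is_TF": [g in set(tfs) for g in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    return StateNetwork(state, nodes, corr, sig, attrs)


class TestCompareNetworks:
    def test_identical_networks(self):
        nodes = ["a", "b", "c"]
        net = _net([("a", "b"), ("b", "c")], nodes)
        post = _net([("a", "b"), ("b", "c")], nodes, state="POST")
        delta = compare_networks(net, post)
        assert delta.disappeared == set() and delta.emerged == set()
        assert len(delta.persistent) == 2

    def test_two_edge_case(self):
        nodes = ["a", "b", "c"]
        delta = compare_networks(_net([("a", "b")], nodes),
                                 _net([("b", "c")], nodes, state="POST"))
        assert delta.disappeared == {frozenset(("a", "b"))}
        assert delta.emerged == {frozenset(("b", "c"))}

    def test_set_identities_random(self, rng):
        nodes = [f"g{i}" for i in range(40)]
        pairs = list(combinations(nodes, 2))
        e_pre = [pairs[i] for i in rng.choice(len(pairs), 100, replace=False)]
        e_post = [pairs[i] for i in rng.choice(len(pairs), 120, replace=False)]
        delta = compare_networks(_net(e_pre, nodes), _net(e_post, nodes, state="POST"))
        assert len(delta.persistent) + len(delta.disappeared) == len(e_pre)
        assert len(delta.persistent) + len(delta.emerged) == len(e_post)

    def test_tissue_percentages_sum_100(self, rng):
        nodes = [f"g{i}" for i in range(30)]
        tissue_of = {g: f"T{i % 4}" for i, g in enumerate(nodes)}
        pairs = list(combinations(nodes, 2))
        e_pre = [pairs[i] for i in rng.choice(len(pairs), 60, replace=False)]
        e_post = [pairs[i] for i in rng.choice(len(pairs), 50, replace=False)]
        delta = compare_networks(
            _net(e_pre, nodes, tissue_of=tissue_of),
            _net(e_post, nodes, state="POST", tissue_of=tissue_of),
        )
        for col in delta.tissue_table.columns:
            total = delta.tissue_table[col].sum()
            if total:  # empty categories stay at 0
                assert total == pytest.approx(100.0, abs=0.1)

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="d"):
            compare_networks(_net([], ["a", "b", "c"]), _net([], ["a", "b", "d"]))


class TestTrioCount:
    def test_exact_values(self):
        assert trio_count(3) == 1
        assert trio_count(10) == 120
        assert trio_count(364) == 7_971_964

    def test_matches_enumeration(self):
        for n in range(3, 31):
            assert trio_count(n) == len(list(combinations(range(n), 3)))

    def test_too_small(self):
        with pytest.raises(ParameterError):
            trio_count(2)


class TestBestTrio:
    def test_oracle_equivalence_toy(self):
        # 6 TFs with hand-built neighbor sets over 12 genes
        genes = [f"n{i}" for i in range(12)]
        neigh = {
            "t0": set(genes[0:5]),
            "t1": set(genes[4:9]),
            "t2": set(genes[8:12]),
            "t3": set(genes[0:3]),
            "t4": set(genes[3:6]),
            "t5": set(genes[2:4]),
        }
        edges = [(t, g) for t, s in neigh.items() for g in s]
        nodes = genes + list(neigh)
        net = _net(edges, nodes, tfs=neigh)
        result = best_trio(net, list(neigh))
        oracle_trio, oracle_cov, oracle_red = best_trio_reference(
            {t: neigh[t] for t in neigh}
        )
        assert set(result.trio) == set(oracle_trio)
        # coverage in the network includes TF-TF adjacency; compare via sets
        assert result.n_trios_examined == trio_count(6)

    def test_coverage_at_least_best_single(self):
        genes = [f"n{i}" for i in range(10)]
        neigh = {"t0": set(genes[:7]), "t1": set(genes[2:4]), "t2": set(genes[5:6]),
                 "t3": set(genes[8:10])}
        edges = [(t, g) for t, s in neigh.items() for g in s]
        net = _net(edges, genes + list(neigh), tfs=neigh)
        result = best_trio(net, list(neigh))
        assert result.coverage >= 7

    def test_isolated_tf_not_selected(self):
        genes = [f"n{i}" for i in range(9)]
        neigh = {"t0": set(genes[0:4]), "t1": set(genes[4:7]), "t2": set(genes[7:9]),
                 "t3": set()}
        edges = [(t, g) for t, s in neigh.items() for g in s]
        net = _net(edges, genes + list(neigh), tfs=neigh)
        result = best_trio(net, list(neigh))
        assert "t3" not in result.trio

    def test_duplicate_neighborhood_redundancy_tiebreak(self):
        genes = [f"n{i}" for i in range(6)]
        neigh = {
            "t0": set(genes[0:3]),
            "t0b": set(genes[0:3]),  # exact duplicate of t0
            "t1": set(genes[3:6]),
            "t2": set(genes[3:4]),  # equal-coverage, lower-redundancy partner
        }
        edges = [(t, g) for t, s in neigh.items() for g in s]
        net = _net(edges, genes + list(neigh), tfs=neigh)
        result = best_trio(net, list(neigh))
        assert not {"t0", "t0b"} <= set(result.trio)

    def test_too_few_tfs(self):
        net = _net([("a", "b")], ["a", "b"])
        with pytest.raises(ValidationError):
            best_trio(net, ["a", "b"])


def test_expansion_ability_upper_bounded_by_best_trio():
    genes = [f"n{i}" for i in range(15)]
    rng = np.random.default_rng(2)
    neigh = {f"t{i}": set(rng.choice(genes, size=5, replace=False)) for i in range(5)}
    edges = [(t, g) for t, s in neigh.items() for g in s]
    net = _net(edges, genes + list(neigh), tfs=neigh)
    exp = expansion_ability(net, list(neigh))
    best = best_trio(net, list(neigh))
    assert exp.max() == best.coverage
    assert (exp <= best.coverage).all()


class TestExtractSubnetwork:
    def _de_calls(self, rows):
        return pd.DataFrame(rows, columns=["gene", "tissue", "is_de", "posterior_null"])

    def test_no_de_genes_empty(self):
        net = _net([("a", "b")], ["a", "b"])
        calls = self._de_calls([("a", "HYP", False, 0.9)])
        sub = extract_subnetwork(net, calls, tissues=("HYP",))
        assert sub.gene_ids == []

    def test_edges_subset_of_parent(self, rng):
        nodes = [f"g{i}" for i in range(20)]
        pairs = list(combinations(nodes, 2))
        edges = [pairs[i] for i in rng.choice(len(pairs), 40, replace=False)]
        net = _net(edges, nodes, tfs=nodes[:5])
        calls = self._de_calls([(g, "HYP", True, 0.01) for g in nodes[10:15]])
        sub = extract_subnetwork(net, calls, tissues=("HYP",))
        parent = {frozenset((a, b)) for a, b, _ in net.edges()}
        child = {frozenset((a, b)) for a, b, _ in sub.edges()}
        assert child <= parent

    def test_membership_audit(self, rng):
        nodes = [f"g{i}" for i in range(20)]
        pairs = list(combinations(nodes, 2))
        edges = [pairs[i] for i in rng.choice(len(pairs), 50, replace=False)]
        tfs = set(nodes[:6])
        net = _net(edges, nodes, tfs=tfs)
        de_genes = nodes[10:14]
        calls = self._de_calls([(g, "PIT", True, 0.01) for g in de_genes])
        sub = extract_subnetwork(net, calls, tissues=("PIT",))
        pos = {g: i for i, g in enumerate(net.gene_ids)}
        for g in sub.gene_ids:
            if g in de_genes:
                continue
            assert g in tfs
            assert any(net.significant[pos[g], pos[d]] for d in de_genes)

    def test_unknown_tissue_rejected(self):
        net = _net([("a", "b")], ["a", "b"])
        calls = self._de_calls([("a", "HYP", True, 0.01)])
        with pytest.raises(ValidationError, match="XXX"):
            extract_subnetwork(net, calls, tissues=("XXX",))
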