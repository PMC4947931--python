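import math

import numpy as np
import pandas as pd
import pytest

from riverpop.diversity import (
    SaturationError,
    Tree,
    UndefinedStatisticError,
    bootstrap_support,
    build_nj_tree,
    diversity_report,
    group_k2p,
    haplotype_diversity,
    k2p,
    k2p_matrix,
    neighbor_joining,
    nucleotide_diversity,
)
from riverpop.seqcore import Alignment, collapse_haplotypes

from .oracles import hd_brute, k2p_brute, pi_k_brute


class TestHaplotypeDiversity:
    def test_monomorphic_zero(self):
        assert haplotype_diversity(np.array([5])) == 0.0

    def test_all_distinct(self):
        assert haplotype_diversity(np.array([1, 1, 1, 1])) == pytest.approx(1.0)

    def test_counts_211(self):
        # (4/3)(1 - (4+1+1)/16) = 0.83333...
        assert haplotype_diversity(np.array([2, 1, 1])) == pytest.approx(
            0.833333, abs=1e-6
        )

    def test_needs_two(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity(np.array([1]))

    def test_matches_brute(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 6, size=rng.integers(2, 6))
            assert haplotype_diversity(counts) == pytest.approx(
                hd_brute(counts), abs=1e-12
            )


class TestNucleotideDiversity:
    def test_identical(self):
        aln = Alignment.from_pairs([("a", "ACGT"), ("b", "ACGT")])
        pi, K = nucleotide_diversity(aln)
        assert pi == 0 and K == 0

    def test_two_seq(self):
        s1 = "A" * 100
        s2 = "A" * 98 + "CC"
        pi, K = nucleotide_diversity(Alignment.from_pairs([("a", s1), ("b", s2)]))
        assert K == 2
        assert pi == pytest.approx(0.02)

    def test_brute_force(self, random_alignment):
        aln = random_alignment(n=4, k=30, seed=7, missing=0.05)
        pi, K = nucleotide_diversity(aln)
        pi_b, K_b = pi_k_brute(aln.seqs)
        assert pi == pytest.approx(pi_b, abs=1e-12)
        assert K == pytest.approx(K_b, abs=1e-12)

    def test_report_invariants(self, random_alignment):
        aln = random_alignment(n=8, k=50, seed=8)
        rep = diversity_report(aln)
        assert 0 <= rep.Hd <= 1
        assert rep.h <= rep.n
        assert rep.S <= aln.length


class TestK2P:
    def test_identical_zero(self):
        assert k2p("ACGT", "ACGT") == 0.0

    def test_transitions_only(self):
        # P = 0.1, Q = 0: d = -0.5 ln(0.8) = 0.111571...
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p(a, b) == pytest.approx(0.11157, abs=1e-5)

    def test_transversions_only(self):
        # P = 0, Q = 0.1: d = -0.5 ln(0.9) - 0.25 ln(0.8) = 0.108462...
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert k2p(a, b) == pytest.approx(0.10846, abs=1e-5)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p("A" * 10, "G" * 10)

    def test_small_divergence_linear(self):
        a = "A" * 1000
        b = "G" * 2 + "C" * 1 + "A" * 997
        assert k2p(a, b) == pytest.approx(0.003, rel=0.01)

    def test_matches_brute(self):
        rng = np.random.default_rng(9)
        base = rng.choice(list("ACGT"), size=200)
        seqs = []
        for _ in range(5):
            s = base.copy()
            for site in rng.choice(200, size=8, replace=False):
                s[site] = rng.choice(list("ACGT"))
            seqs.append("".join(s))
        aln = Alignment.from_pairs((f"s{i}", s) for i, s in enumerate(seqs))
        m = k2p_matrix(aln)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.iloc[i, j] == pytest.approx(
                    k2p_brute(aln.seqs[i], aln.seqs[j]), abs=1e-12
                )

    def test_group_distances(self):
        from riverpop.seqcore import PopulationMap

        aln = Alignment.from_pairs(
            [("a1", "AAAAAAAAAA"), ("a2", "AAAAAAAAAG"),
             ("b1", "GGAAAAAAAA"), ("b2", "GGAAAAAAAG")]
        )
        pm = PopulationMap(
            {"a1": "pop1", "a2": "pop1", "b1": "pop2", "b2": "pop2"}
        )
        raw, net = group_k2p(aln, pm)
        assert raw.loc["pop1", "pop2"] >= 0
        assert net.loc["pop1", "pop2"] == pytest.approx(
            raw.loc["pop1", "pop2"]
            - (raw.loc["pop1", "pop1"] + raw.loc["pop2", "pop2"]) / 2
        )


def _additive_matrix():
    """Distances generated by the tree ((A:1,B:2):1,(C:3,D:4)); additive."""
    d = {
        ("A", "B"): 3,
        ("A", "C"): 5,
        ("A", "D"): 6,
        ("B", "C"): 6,
        ("B", "D"): 7,
        ("C", "D"): 7,
    }
    labels = ["A", "B", "C", "D"]
    m = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in d.items():
        m.loc[a, b] = m.loc[b, a] = v
    return m


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        labels = ["A", "B", "C"]
        m = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=labels, columns=labels, dtype=float
        )
        tree = neighbor_joining(m)
        bl = {tree.labels[c]: b for c, b in tree.children[tree.root]}
        # three-point equations: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        assert bl == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_too_few_taxa(self):
        m = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            neighbor_joining(m)

    def test_additive_recovery(self):
        tree = neighbor_joining(_additive_matrix())
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        # sum of path lengths reproduces the additive distances
        def path_len(t, a, b):
            adj = {}
            for p, kids in t.children.items():
                for c, bl in kids:
                    adj.setdefault(p, []).append((c, bl))
                    adj.setdefault(c, []).append((p, bl))
            node_a = next(i for i, l in t.labels.items() if l == a)
            node_b = next(i for i, l in t.labels.items() if l == b)
            stack = [(node_a, 0.0, None)]
            while stack:
                node, dist, prev = stack.pop()
                if node == node_b:
                    return dist
                for nb, bl in adj[node]:
                    if nb != prev:
                        stack.append((nb, dist + bl, node))

        m = _additive_matrix()
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert path_len(tree, a, b) == pytest.approx(m.loc[a, b])

    def test_taxon_order_invariance(self):
        m = _additive_matrix()
        perm = ["C", "A", "D", "B"]
        t1 = neighbor_joining(m)
        t2 = neighbor_joining(m.loc[perm, perm])
        assert t1.bipartitions() == t2.bipartitions()

    def test_newick_parses(self):
        import dendropy

        tree = neighbor_joining(_additive_matrix())
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set("ABCD")

    def test_outgroup_rooting(self):
        tree = build_nj_tree(_additive_matrix(), outgroup="D")
        top = [c for c, _ in tree.children[tree.root]]
        sides = [set(tree.leaves(c)) for c in top]
        assert {"D"} in sides


class TestBootstrap:
    def _clean_alignment(self):
        # two clades separated by 15 fixed differences over 300 sites
        base = "A" * 300
        div = "G" * 15 + "A" * 285
        return Alignment.from_pairs(
            [
                ("x1", base),
                ("x2", "C" + base[1:]),
                ("y1", div),
                ("y2", div[:-1] + "T"),
            ]
        )

    def test_reproducible_single_rep(self):
        aln = self._clean_alignment()
        s1 = bootstrap_support(aln, B=1, seed=42)
        s2 = bootstrap_support(aln, B=1, seed=42)
        assert s1 == s2
        assert all(v in (0.0, 1.0) for v in s1.values())

    def test_strong_signal_high_support(self):
        aln = self._clean_alignment()
        support = bootstrap_support(aln, B=100, seed=0)
        split = frozenset({"x1", "x2"})
        assert support[split] > 0.95

    def test_taxon_order_invariant(self):
        aln = self._clean_alignment()
        order = ["y2", "x1", "y1", "x2"]
        perm = aln.subset(order)
        s1 = bootstrap_support(aln, B=50, seed=7)
        s2 = bootstrap_support(perm, B=50, seed=7)
        assert set(s1) == set(s2)


class TestQualitativePattern:
    def test_expansion_data_high_hd_low_pi(self):
        from riverpop.simulate import DemographicScenario, simulate_coalescent

        aln, _ = simulate_coalescent(
            DemographicScenario(
                n=40, k=1000, theta0=0.5, theta1=1000.0, tau=6.0, seed=11
            )
        )
        rep = diversity_report(aln)
        assert rep.Hd > 0.8
        assert rep.pi < 0.02
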