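import numpy as np
import pytest

from crocmhc.phylo import (SubstitutionModel, TreeNode, bipartitions,
                           bootstrap_support, build_tree,
                           diagnostic_fixed_differences, distance_matrix,
                           elw_compare, gamma_category_rates, log_likelihood,
                           model_distance, model_select, nj_tree, parse_newick,
                           site_log_likelihoods, transition_matrix)
from crocmhc.seq_model import Alignment


def random_tree(names, rng, scale=0.2) -> TreeNode:
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[(a, float(rng.uniform(0.05, scale))),
                                        (b, float(rng.uniform(0.05, scale)))]))
    return TreeNode(children=[(n, float(rng.uniform(0.05, scale)))
                              for n in nodes])


def tree_distances(tree: TreeNode) -> dict:
    """Leaf-to-leaf path lengths (the additivity oracle)."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: 0.0}
        below = []
        for child, bl in node.children:
            sub = walk(child)
            below.append({k: v + bl for k, v in sub.items()})
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        out[frozenset((a, b))] = da + db
        merged = {}
        for sub in below:
            merged.update(sub)
        return merged

    walk(tree)
    return out


def simulate_nuc(tree, model, L, rng):
    seqs = {}
    root = rng.integers(0, 4, size=L)

    def rec(node, s):
        if node.is_leaf:
            seqs[node.name] = s
            return
        for ch, bl in node.children:
            P = transition_matrix(model, bl)
            cum = np.cumsum(P, axis=1)
            u = rng.random(L)
            rec(ch, (cum[s] < u[:, None]).sum(axis=1))

    rec(tree, root)
    return Alignment([(n, "".join("ACGT"[i] for i in seqs[n]))
                      for n in sorted(seqs)])


class TestModels:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SubstitutionModel(name="HKY85", base_frequencies=(0.5, 0.5, 0.5, 0.5))

    def test_gamma_alpha_positive(self):
        with pytest.raises(ValueError):
            SubstitutionModel(name="JC69", gamma_alpha=0.0)

    def test_rate_matrix_rows_sum_zero(self):
        for name in ("JC69", "K80", "HKY85", "TN93"):
            m = SubstitutionModel(name=name, kappa=3.0, kappa1=4.0, kappa2=2.0,
                                  base_frequencies=(0.3, 0.2, 0.3, 0.2))
            q = m.rate_matrix()
            assert np.allclose(q.sum(axis=1), 0.0)

    def test_transition_matrix_stochastic(self):
        m = SubstitutionModel(name="TN93", kappa1=4.0, kappa2=2.0,
                              base_frequencies=(0.3, 0.2, 0.3, 0.2))
        p = transition_matrix(m, 0.7)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    def test_gamma_rates_mean_one(self):
        for alpha in (0.2, 0.74, 1.23, 5.0):
            rates = gamma_category_rates(alpha)
            assert np.mean(rates) == pytest.approx(1.0, abs=1e-6)
            assert (np.diff(rates) > 0).all()


class TestDistances:
    def test_identical_zero(self):
        m = SubstitutionModel(name="JC69")
        assert model_distance("ACGT", "ACGT", m) == 0.0

    def test_jc_closed_form_p03(self):
        a = "A" * 700 + "C" * 300
        b = "A" * 700 + "T" * 300
        d = model_distance(a, b, SubstitutionModel(name="JC69"))
        assert d == pytest.approx(-0.75 * np.log(1 - 0.4), abs=1e-9)
        assert d == pytest.approx(0.3831, abs=1e-4)

    def test_gamma_corrected_at_least_uncorrected(self, rng):
        tree = random_tree(list("abcdef"), rng)
        aln = simulate_nuc(tree, SubstitutionModel(name="K80", kappa=3.0),
                           600, rng)
        for name in ("JC69", "K80", "TN93"):
            plain = SubstitutionModel(name=name, kappa=3.0, kappa1=3.0,
                                      kappa2=3.0,
                                      base_frequencies=(0.25,) * 4)
            gm = SubstitutionModel(name=name, kappa=3.0, kappa1=3.0,
                                   kappa2=3.0, base_frequencies=(0.25,) * 4,
                                   gamma_alpha=0.8)
            d0 = distance_matrix(aln, plain)
            d1 = distance_matrix(aln, gm)
            mask = ~np.isnan(d0)
            assert (d1[mask] >= d0[mask] - 1e-12).all()

    def test_saturated_pair_gives_nan(self):
        a, b = "A" * 100, "C" * 50 + "G" * 25 + "T" * 25
        assert np.isnan(model_distance(a, b, SubstitutionModel(name="JC69")))

    def test_tn93_matches_consistency(self, rng):
        # distance under the generating model should approximate the
        # simulated branch length between two taxa
        model = SubstitutionModel(name="TN93", kappa1=4.0, kappa2=2.0,
                                  base_frequencies=(0.3, 0.2, 0.3, 0.2))
        t = 0.3
        tree = TreeNode(children=[(TreeNode(name="x"), t / 2),
                                  (TreeNode(name="y"), t / 2)])
        aln = simulate_nuc(tree, model, 60_000, rng)
        d = model_distance(aln.sequence("x"), aln.sequence("y"), model)
        assert d == pytest.approx(t, rel=0.08)


class TestNeighborJoining:
    def test_three_taxa_unique_tree(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        res = nj_tree(d, ["a", "b", "c"])
        assert set(res.tree.leaves()) == {"a", "b", "c"}

    def test_quartet_additive_recovery(self):
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        res = nj_tree(d, list("ABCD"))
        assert bipartitions(res.tree) == {frozenset({"C", "D"})}
        assert res.newick == "(C:3,D:4,(A:1,B:2):1);"

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 10))
            names = [f"t{i}" for i in range(n)]
            tree = random_tree(names, rng)
            dist = tree_distances(tree)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = dist[frozenset((names[i], names[j]))]
            rebuilt = nj_tree(d, names)
            assert bipartitions(rebuilt.tree) == bipartitions(tree)
            back = tree_distances(rebuilt.tree)
            for key, value in dist.items():
                assert back[key] == pytest.approx(value, abs=1e-9)

    def test_taxon_permutation_same_topology(self, rng):
        names = [f"t{i}" for i in range(6)]
        tree = random_tree(names, rng)
        dist = tree_distances(tree)
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                d[i, j] = d[j, i] = dist[frozenset((names[i], names[j]))]
        ref = bipartitions(nj_tree(d, names).tree)
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        names2 = [names[k] for k in perm]
        assert bipartitions(nj_tree(d2, names2).tree) == ref

    def test_missing_distance_errors(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            nj_tree(d, ["a", "b"])


class TestPruning:
    def test_two_taxon_tree_equals_closed_form(self):
        m = SubstitutionModel(name="K80", kappa=3.0)
        t = 0.4
        tree = TreeNode(children=[(TreeNode(name="x"), t / 2),
                                  (TreeNode(name="y"), t / 2)])
        aln = Alignment([("x", "ACGTAC"), ("y", "ACGTTT")])
        P = transition_matrix(m, t)
        idx = {b: i for i, b in enumerate("ACGT")}
        closed = sum(np.log(0.25 * P[idx[a], idx[b]])
                     for a, b in zip("ACGTAC", "ACGTTT"))
        assert log_likelihood(tree, aln, m) == pytest.approx(closed)

    def test_leaf_mismatch_errors(self):
        tree = TreeNode(children=[(TreeNode(name="x"), 0.1),
                                  (TreeNode(name="z"), 0.1)])
        aln = Alignment([("x", "ACGT"), ("y", "ACGT")])
        with pytest.raises(ValueError):
            site_log_likelihoods(tree, aln, SubstitutionModel(name="JC69"))


class TestModelSelect:
    def test_identical_sequences_select_jc(self):
        aln = Alignment([(f"s{i}", "ACGTACGTACGT") for i in range(4)])
        best, table = model_select(aln)
        assert best.name == "JC69"

    def test_k80_data_rejects_jc(self, rng):
        wins = 0
        reps = 8
        for r in range(reps):
            tree = random_tree(list("abcde"), rng)
            aln = simulate_nuc(tree, SubstitutionModel(name="K80", kappa=5.0),
                               1000, rng)
            best, table = model_select(aln)
            rows = {row["model"]: row["BIC"] for row in table}
            if min(rows["K80"], rows["HKY85"], rows["TN93"]) < rows["JC69"]:
                wins += 1
        assert wins >= int(0.9 * reps)


class TestBootstrap:
    def test_two_clades_full_support(self, rng):
        left = "A" * 60 + "C" * 60
        right = "G" * 60 + "C" * 60
        def noisy(base):
            s = list(base)
            pos = int(rng.integers(0, len(s)))
            s[pos] = "T"
            return "".join(s)
        aln = Alignment([("a1", noisy(left)), ("a2", noisy(left)),
                         ("b1", noisy(right)), ("b2", noisy(right))])
        res = bootstrap_support(aln, SubstitutionModel(name="JC69"),
                                reps=200, seed=1)
        split = frozenset({"b1", "b2"})
        assert res.support[split] > 95

    def test_seeded_runs_identical(self, rng):
        tree = random_tree(list("abcde"), rng)
        aln = simulate_nuc(tree, SubstitutionModel(name="JC69"), 300, rng)
        r1 = bootstrap_support(aln, SubstitutionModel(name="JC69"),
                               reps=100, seed=42)
        r2 = bootstrap_support(aln, SubstitutionModel(name="JC69"),
                               reps=100, seed=42)
        assert r1.support == r2.support


class TestElw:
    def test_same_tree_gives_half_half(self, rng):
        tree = random_tree(list("abcd"), rng)
        aln = simulate_nuc(tree, SubstitutionModel(name="JC69"), 200, rng)
        out = elw_compare(aln, SubstitutionModel(name="JC69"), tree, tree,
                          rell_reps=200, seed=1)
        assert out["weight_a"] == pytest.approx(0.5)
        assert out["weight_a"] + out["weight_b"] == pytest.approx(1.0)

    def test_generating_topology_preferred(self, rng):
        wins = 0
        reps = 6
        for _ in range(reps):
            # tree_a: AB|CD with long internal edge; tree_b: AC|BD
            def quartet(pairs):
                (a, b), (c, d) = pairs
                return TreeNode(children=[
                    (TreeNode(children=[(TreeNode(name=a), 0.1),
                                        (TreeNode(name=b), 0.1)]), 0.15),
                    (TreeNode(name=c), 0.1), (TreeNode(name=d), 0.1)])
            tree_a = quartet((("A", "B"), ("C", "D")))
            tree_b = quartet((("A", "C"), ("B", "D")))
            aln = simulate_nuc(tree_a, SubstitutionModel(name="JC69"),
                               2000, rng)
            out = elw_compare(aln, SubstitutionModel(name="JC69"),
                              tree_a, tree_b, rell_reps=500,
                              seed=int(rng.integers(0, 2 ** 31)))
            if out["weight_a"] > 0.95:
                wins += 1
        assert wins >= int(0.9 * reps)

    def test_leaf_mismatch_errors(self, rng):
        t1 = random_tree(list("abcd"), rng)
        t2 = random_tree(list("abce"), rng)
        aln = simulate_nuc(t1, SubstitutionModel(name="JC69"), 100, rng)
        with pytest.raises(ValueError):
            elw_compare(aln, SubstitutionModel(name="JC69"), t1, t2)


class TestDiagnosticSites:
    def test_no_disjoint_columns_empty(self):
        aln = Alignment([("a", "AAAA"), ("b", "AAAA"),
                         ("c", "AAAA"), ("d", "AAAA")])
        clades = {"a": "1", "b": "1", "c": "2", "d": "2"}
        assert diagnostic_fixed_differences(aln, clades) == []

    def test_planted_disjoint_columns_found_exactly(self, rng):
        L = 40
        planted = [3, 11, 25, 38]
        rows = {}
        for name, clade in (("a", 0), ("b", 0), ("c", 1), ("d", 1)):
            seq = ["A"] * L
            for p in planted:
                seq[p - 1] = "C" if clade == 0 else "G"
            rows[name] = "".join(seq)
        aln = Alignment(sorted(rows.items()))
        clades = {"a": "x", "b": "x", "c": "y", "d": "y"}
        assert diagnostic_fixed_differences(aln, clades) == planted

    def test_gaps_excluded(self):
        aln = Alignment([("a", "C-"), ("b", "CA"), ("c", "G-"), ("d", "GA")])
        clades = {"a": "1", "b": "1", "c": "2", "d": "2"}
        assert diagnostic_fixed_differences(aln, clades) == [1]

    def test_singleton_clade_warns(self):
        aln = Alignment([("a", "CC"), ("b", "GG"), ("c", "GG")])
        clades = {"a": "1", "b": "2", "c": "2"}
        with pytest.warns(UserWarning):
            diagnostic_fixed_differences(aln, clades)


def test_parse_newick_roundtrip():
    text = "(C:3,D:4,(A:1,B:2):1);"
    tree = parse_newick(text)
    assert tree.newick() == text
    assert set(tree.leaves()) == set("ABCD")


def test_build_tree_returns_model(rng):
    tree = random_tree(list("abcd"), rng)
    aln = simulate_nuc(tree, SubstitutionModel(name="JC69"), 300, rng)
    res = build_tree(aln, SubstitutionModel(name="JC69"))
    assert res.model.name == "JC69"
    assert set(res.tree.leaves()) == set(aln.names)


def test_newick_output_agrees_with_dendropy(rng):
    # cross-check tree serialisation and splits with an independent library
    import dendropy

    names = [f"t{i}" for i in range(7)]
    tree = random_tree(names, rng)
    dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert sorted(l.taxon.label for l in dt.leaf_node_iter()) == names
    dt.encode_bipartitions()
    ref = sorted(l.taxon.label for l in dt.leaf_node_iter())[0]
    dendropy_splits = set()
    for edge in dt.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node is dt.seed_node:
            continue
        side = frozenset(l.taxon.label
                         for l in edge.head_node.leaf_iter())
        if 1 < len(side) < len(names) - 1:
            if ref in side:
                side = frozenset(set(names) - side)
            dendropy_splits.add(side)
    assert bipartitions(tree) == dendropy_splits
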