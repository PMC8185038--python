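import itertools

import numpy as np
import pandas as pd
import pytest

import phenoprof as pp
from phenoprof.diversity import parse_tree, tip_names, total_branch_length


# -- independent oracles ----------------------------------------------------

def random_newick(rng, labels):
    """Random binary topology with random branch lengths."""
    def build(names):
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(0.1, 2.0):.4f}"
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        return (
            f"({build(left)},{build(right)}):{rng.uniform(0.1, 2.0):.4f}"
        )
    names = list(labels)
    rng.shuffle(names)
    k = max(1, len(names) // 2)
    return f"({build(names[:k])},{build(names[k:])});"


def brute_faith(tree, observed):
    """Union of root-to-tip path lengths (exhaustive)."""
    edges = set()
    for tip in tree.tips():
        if tip.name not in observed:
            continue
        node = tip
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
    total = 0.0
    for node in tree.traverse():
        if id(node) in edges:
            total += node.length or 0.0
    return total


def brute_unifrac(tree, x, y):
    """Branch-sum weighted UniFrac: sum l_b |x_b - y_b|."""
    total = 0.0
    for node in tree.traverse():
        if node.is_root():
            continue
        tips = {t.name for t in node.tips()} or {node.name}
        xb = sum(x.get(t, 0.0) for t in tips)
        yb = sum(y.get(t, 0.0) for t in tips)
        total += (node.length or 0.0) * abs(xb - yb)
    return total


# -- midpoint rooting -------------------------------------------------------

class TestMidpointRoot:
    def test_two_tip_path_split_evenly(self):
        rooted = pp.midpoint_root(parse_tree("(A:1,B:3);"))
        lengths = {t.name: t.length for t in rooted.tips()}
        assert lengths == {"A": 2.0, "B": 2.0}

    def test_total_length_conserved(self):
        rng = np.random.default_rng(3)
        tree = parse_tree(random_newick(rng, [f"t{i}" for i in range(7)]))
        before = total_branch_length(tree)
        after = total_branch_length(pp.midpoint_root(tree))
        assert after == pytest.approx(before)

    def test_idempotent_on_balanced_tree(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = pp.midpoint_root(tree)
        again = pp.midpoint_root(rooted)
        assert again.compare_rfd(rooted) == 0
        assert total_branch_length(again) == pytest.approx(
            total_branch_length(rooted)
        )

    def test_zero_length_tree_rejected(self):
        with pytest.raises(ValueError):
            pp.midpoint_root(parse_tree("(A:0,B:0);"))


# -- Faith PD ---------------------------------------------------------------

class TestFaithPD:
    def test_single_tip_is_root_path(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        assert pp.faith_pd(tree, {"A"}) == pytest.approx(2.0)

    def test_clade_example(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        assert pp.faith_pd(tree, {"A", "B"}) == pytest.approx(3.0)

    def test_all_tips_give_total_length(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        assert pp.faith_pd(tree, {"A", "B", "C"}) == pytest.approx(
            total_branch_length(tree)
        )

    def test_empty_set_warns_and_returns_zero(self):
        tree = parse_tree("(A:1,B:1);")
        with pytest.warns(UserWarning):
            assert pp.faith_pd(tree, set()) == 0.0

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValueError):
            pp.faith_pd(parse_tree("(A:1,B:1);"), {"Z"})

    @pytest.mark.parametrize("n_tips", [2, 4, 6, 8])
    def test_exhaustive_subset_oracle(self, n_tips):
        rng = np.random.default_rng(n_tips)
        labels = [f"t{i}" for i in range(n_tips)]
        for _ in range(3):
            tree = parse_tree(random_newick(rng, labels))
            for r in range(1, n_tips + 1):
                for subset in itertools.combinations(labels, r):
                    assert pp.faith_pd(tree, set(subset)) == pytest.approx(
                        brute_faith(tree, set(subset)), abs=1e-9
                    )


# -- weighted UniFrac -------------------------------------------------------

class TestWeightedUniFrac:
    def test_identical_vectors_zero(self):
        tree = parse_tree("(A:1,B:1);")
        x = {"A": 0.4, "B": 0.6}
        assert pp.weighted_unifrac(tree, x, dict(x)) == pytest.approx(0.0)

    def test_disjoint_two_tip_distance(self):
        tree = parse_tree("(A:1,B:1);")
        d = pp.weighted_unifrac(tree, {"A": 1.0}, {"B": 1.0})
        assert d == pytest.approx(2.0)

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValueError):
            pp.weighted_unifrac(parse_tree("(A:1,B:1);"), {"Z": 1.0}, {"A": 1.0})

    def test_matches_branch_sum_oracle(self):
        rng = np.random.default_rng(8)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            tree = parse_tree(random_newick(rng, labels))
            x = rng.dirichlet(np.ones(6))
            y = rng.dirichlet(np.ones(6))
            xv = dict(zip(labels, x))
            yv = dict(zip(labels, y))
            assert pp.weighted_unifrac(tree, xv, yv) == pytest.approx(
                brute_unifrac(tree, xv, yv), abs=1e-9
            )

    def test_matches_skbio_on_integer_counts(self):
        # cross-check against the scikit-bio implementation (which
        # only accepts integer count vectors)
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            tree = parse_tree(random_newick(rng, labels))
            u = rng.integers(0, 50, size=6)
            v = rng.integers(0, 50, size=6)
            if u.sum() == 0 or v.sum() == 0:
                continue
            for normalized in (False, True):
                mine = pp.weighted_unifrac(
                    tree, dict(zip(labels, map(float, u))),
                    dict(zip(labels, map(float, v))), normalized=normalized,
                )
                ref = skbio_wu(u, v, taxa=labels, tree=tree,
                               normalized=normalized)
                assert mine == pytest.approx(float(ref), abs=1e-9)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(21)
        labels = [f"t{i}" for i in range(5)]
        for _ in range(100):
            tree = parse_tree(random_newick(rng, labels))
            vecs = [dict(zip(labels, rng.dirichlet(np.ones(5))))
                    for _ in range(3)]
            d01 = pp.weighted_unifrac(tree, vecs[0], vecs[1])
            d10 = pp.weighted_unifrac(tree, vecs[1], vecs[0])
            d02 = pp.weighted_unifrac(tree, vecs[0], vecs[2])
            d12 = pp.weighted_unifrac(tree, vecs[1], vecs[2])
            assert d01 == pytest.approx(d10, abs=1e-12)
            assert d01 >= 0.0
            assert d01 <= d02 + d12 + 1e-9


# -- carrier sub-communities, PAD, PBD --------------------------------------

def small_profile_and_table():
    pi = pd.DataFrame(
        {"ph": [0.61, 0.60, 0.2], "full": [1.0, 1.0, 1.0]},
        index=["a", "b", "c"],
    )
    counts = pd.DataFrame(
        {"s1": [20, 30, 50], "s2": [10, 10, 80]}, index=["a", "b", "c"]
    )
    table = pp.ASVTable(counts, {i: "ACGT" for i in counts.index})
    return pp.PhenotypeProfile(pi), table


class TestCarrierSubcommunity:
    def test_strict_threshold_boundary(self):
        prof, table = small_profile_and_table()
        sub = pp.carrier_subcommunity(prof, table, "ph", 0.6)
        assert list(sub.abundances["s1"].index) == ["a"]

    def test_renormalization(self):
        pi = pd.DataFrame({"ph": [0.9, 0.9, 0.1]}, index=["a", "b", "c"])
        counts = pd.DataFrame({"s1": [20, 30, 50]}, index=["a", "b", "c"])
        table = pp.ASVTable(counts, {i: "A" for i in counts.index})
        sub = pp.carrier_subcommunity(pp.PhenotypeProfile(pi), table, "ph")
        assert sub.abundances["s1"].tolist() == pytest.approx([0.4, 0.6])

    def test_all_carriers_whole_sample(self):
        prof, table = small_profile_and_table()
        sub = pp.carrier_subcommunity(prof, table, "full")
        assert np.allclose(
            sub.abundances["s1"].to_numpy(), table.relative["s1"].to_numpy()
        )

    def test_empty_subcommunity_flagged(self):
        pi = pd.DataFrame({"ph": [0.1, 0.2]}, index=["a", "b"])
        counts = pd.DataFrame({"s1": [1, 1]}, index=["a", "b"])
        table = pp.ASVTable(counts, {"a": "A", "b": "C"})
        sub = pp.carrier_subcommunity(pp.PhenotypeProfile(pi), table, "ph")
        assert sub.empty_samples == ["s1"]


class TestPAD:
    def test_saturated_carriers_equal_sample_diversity(self):
        prof, table = small_profile_and_table()
        tree = parse_tree("((a:1,b:1):1,c:2);")
        sub = pp.carrier_subcommunity(prof, table, "full")
        out = pp.pad(sub, tree)
        assert out["s1"] == pytest.approx(pp.faith_pd(tree, {"a", "b", "c"}))

    def test_empty_subcommunity_missing(self):
        pi = pd.DataFrame({"ph": [0.1]}, index=["a"])
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        table = pp.ASVTable(counts, {"a": "A"})
        sub = pp.carrier_subcommunity(pp.PhenotypeProfile(pi), table, "ph")
        out = pp.pad(sub, parse_tree("(a:1,b:1);"))
        assert np.isnan(out["s1"])

    def test_pad_never_exceeds_sample_faith_pd(self):
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(8)]
        tree = parse_tree(random_newick(rng, labels))
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(8, 3)), index=labels,
            columns=["s1", "s2", "s3"],
        )
        table = pp.ASVTable(counts, {i: "A" for i in labels})
        pi = pd.DataFrame({"ph": rng.random(8)}, index=labels)
        sub = pp.carrier_subcommunity(pp.PhenotypeProfile(pi), table, "ph", 0.5)
        out = pp.pad(sub, tree)
        for s in out.index:
            if not np.isnan(out[s]):
                assert out[s] <= pp.faith_pd(tree, set(labels)) + 1e-12

    def test_lower_threshold_never_lowers_pad(self):
        rng = np.random.default_rng(14)
        labels = [f"t{i}" for i in range(8)]
        tree = parse_tree(random_newick(rng, labels))
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(8, 2)), index=labels, columns=["s1", "s2"]
        )
        table = pp.ASVTable(counts, {i: "A" for i in labels})
        pi = pd.DataFrame({"ph": rng.random(8)}, index=labels)
        prof = pp.PhenotypeProfile(pi)
        prev = None
        for thr in (0.8, 0.5, 0.2):
            sub = pp.carrier_subcommunity(prof, table, "ph", thr)
            vals = pp.pad(sub, tree).reindex(["s1", "s2"]).fillna(0.0)
            if prev is not None:
                assert (vals >= prev - 1e-12).all()
            prev = vals


class TestPBD:
    def _setup(self, seed=2, n=5):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        tree = parse_tree(random_newick(rng, labels))
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(6, n)), index=labels,
            columns=[f"s{i}" for i in range(n)],
        )
        table = pp.ASVTable(counts, {i: "A" for i in labels})
        pi = pd.DataFrame({"ph": rng.random(6), "full": np.ones(6)},
                          index=labels)
        return tree, table, pp.PhenotypeProfile(pi)

    def test_matrix_matches_pairwise_calls(self):
        tree, table, prof = self._setup()
        sub = pp.carrier_subcommunity(prof, table, "ph", 0.3)
        dm, excluded = pp.pbd_matrix(sub, tree)
        for a in dm.index:
            for b in dm.columns:
                expected = pp.weighted_unifrac(
                    tree, sub.abundances[a].to_dict(),
                    sub.abundances[b].to_dict(),
                ) if a != b else 0.0
                assert dm.at[a, b] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(dm.to_numpy(), dm.to_numpy().T)
        assert np.allclose(np.diag(dm.to_numpy()), 0.0)

    def test_identical_subcommunities_zero_matrix(self):
        tree = parse_tree("(a:1,b:1);")
        abund = {"s1": pd.Series({"a": 0.5, "b": 0.5}),
                 "s2": pd.Series({"a": 0.5, "b": 0.5})}
        sub = pp.CarrierSubcommunity("ph", 0.6, abund)
        dm, _ = pp.pbd_matrix(sub, tree)
        assert (dm.to_numpy() == 0).all()

    def test_too_few_samples_rejected(self):
        tree = parse_tree("(a:1,b:1);")
        sub = pp.CarrierSubcommunity(
            "ph", 0.6, {"s1": pd.Series({"a": 1.0})}, ["s2"]
        )
        with pytest.raises(ValueError):
            pp.pbd_matrix(sub, tree)


class TestIntragroupAndRPBD:
    def test_all_zero_matrix(self):
        dm = pd.DataFrame(0.0, index=list("abc"), columns=list("abc"))
        out = pp.intragroup_mean_distance(dm, {s: "g" for s in "abc"})
        assert out["g"] == 0.0

    def test_pair_enumeration(self):
        dm = pd.DataFrame(
            [[0, 1, 2], [1, 0, 3], [2, 3, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        out = pp.intragroup_mean_distance(dm, {s: "g" for s in "abc"})
        assert out["g"] == pytest.approx(2.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        names = list("abcd")
        dm = pd.DataFrame(m, index=names, columns=names)
        groups = {"a": "g", "b": "g", "c": "g", "d": "g"}
        perm = ["c", "a", "d", "b"]
        dm2 = dm.loc[perm, perm]
        assert pp.intragroup_mean_distance(dm, groups)["g"] == pytest.approx(
            pp.intragroup_mean_distance(dm2, groups)["g"]
        )

    def test_singleton_group_missing(self):
        dm = pd.DataFrame(0.0, index=["a"], columns=["a"])
        with pytest.warns(UserWarning):
            out = pp.intragroup_mean_distance(dm, {"a": "g"})
        assert np.isnan(out["g"])

    def test_rpbd_ratio(self):
        assert pp.relative_pbd(0.2, 0.4) == pytest.approx(0.5)
        assert pp.relative_pbd(0.4, 0.4) == pytest.approx(1.0)
        assert np.isnan(pp.relative_pbd(0.1, 0.0))

    def test_rpbd_saturation_is_exactly_one(self):
        # carriers = whole community in every sample -> rPBD = 1
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(6)]
        tree = parse_tree(random_newick(rng, labels))
        counts = pd.DataFrame(
            rng.integers(1, 40, size=(6, 4)), index=labels,
            columns=[f"s{i}" for i in range(4)],
        )
        table = pp.ASVTable(counts, {i: "A" for i in labels})
        prof = pp.PhenotypeProfile(
            pd.DataFrame({"full": np.ones(6)}, index=labels)
        )
        sub = pp.carrier_subcommunity(prof, table, "full")
        pbd, _ = pp.pbd_matrix(sub, tree)
        bd = pp.unifrac_matrix(
            {s: table.relative[s] for s in table.samples}, tree
        )
        groups = {s: "g" for s in table.samples}
        rpbd = pp.relative_pbd(
            pp.intragroup_mean_distance(pbd, groups)["g"],
            pp.intragroup_mean_distance(bd, groups)["g"],
        )
        assert rpbd == pytest.approx(1.0, abs=1e-12)
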