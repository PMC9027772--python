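"""Diversity and permutation statistics, with independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd as skbio_faith_pd
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from halosoil import (
    InputError,
    OtuTable,
    anova_tukey,
    bray_curtis,
    domain_fraction,
    faith_pd,
    linear_r2,
    mantel,
    permanova,
    rarefy,
    richness,
    taxonomy_summary,
)
from halosoil.community import _pseudo_f


class TestRarefy:
    def test_totals_conserved_exactly(self):
        t = OtuTable(np.array([[8, 2], [3, 1]]), ["a", "b"], ["x", "y"])
        out = rarefy(t, 4, seed=0)
        assert (out.counts.sum(axis=1) == 4).all()

    def test_sample_at_depth_unchanged(self):
        t = OtuTable(np.array([[3, 1, 2]]), ["a"], ["x", "y", "z"])
        out = rarefy(t, 6, seed=1)
        assert (out.counts == t.counts).all()

    def test_below_depth_dropped_with_warning(self):
        t = OtuTable(np.array([[3000, 2000], [2000, 2499]]), ["keep", "drop"],
                     ["x", "y"])
        with pytest.warns(UserWarning, match="drop"):
            out = rarefy(t, 4500, seed=0)
        assert out.sample_ids == ["keep"]

    def test_seeded_determinism_bit_identical(self):
        rng = np.random.default_rng(2)
        t = OtuTable(rng.integers(0, 200, (4, 30)), [f"s{i}" for i in range(4)],
                     [f"o{j}" for j in range(30)])
        a = rarefy(t, 100, seed=42)
        b = rarefy(t, 100, seed=42)
        assert (a.counts == b.counts).all()

    def test_all_below_depth_rejected(self):
        t = OtuTable(np.array([[1, 1]]), ["a"], ["x", "y"])
        with pytest.raises(InputError):
            rarefy(t, 10)


class TestRichness:
    def test_counts_nonzero_otus(self):
        t = OtuTable(np.array([[3, 0, 1, 0], [1, 1, 1, 1]]), ["a", "b"],
                     list("wxyz"))
        assert list(richness(t)) == [2, 4]


class TestFaithPD:
    def test_star_tree(self):
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        t = OtuTable(np.array([[1, 1, 1, 0]]), ["s"], list("ABCD"))
        assert faith_pd(t, tree).iloc[0] == pytest.approx(3.0)

    def test_caterpillar_hand_sum(self, caterpillar_tree):
        t = OtuTable(np.array([[2, 1, 0]]), ["s"], list("ABC"))
        assert faith_pd(t, caterpillar_tree).iloc[0] == pytest.approx(3.5)

    def test_all_leaves_give_total_length(self, caterpillar_tree):
        t = OtuTable(np.array([[1, 1, 1]]), ["s"], list("ABC"))
        total = sum(n.length for n in caterpillar_tree.traverse(include_self=False))
        assert faith_pd(t, caterpillar_tree).iloc[0] == pytest.approx(total)

    def test_monotone_in_added_leaf(self, small_community):
        table, _, tree = small_community
        base = table.counts.copy()
        base[0, :] = 0
        base[0, :5] = 1
        t0 = OtuTable(base, table.sample_ids, table.otu_ids)
        more = base.copy()
        more[0, 5:10] = 1
        t1 = OtuTable(more, table.sample_ids, table.otu_ids)
        assert faith_pd(t1, tree).iloc[0] >= faith_pd(t0, tree).iloc[0]

    def test_missing_otu_listed(self, caterpillar_tree):
        t = OtuTable(np.array([[1, 1]]), ["s"], ["A", "ZZZ"])
        with pytest.raises(InputError, match="ZZZ"):
            faith_pd(t, caterpillar_tree)

    def test_agrees_with_skbio_oracle(self, small_community):
        table, _, tree = small_community
        sub = rarefy(table, 4500, seed=0)
        mine = faith_pd(sub, tree)
        for i, sid in enumerate(sub.sample_ids[:6]):
            ref = skbio_faith_pd(sub.counts[i], sub.otu_ids, tree)
            assert mine[sid] == pytest.approx(ref, rel=1e-9)


class TestBrayCurtis:
    def test_hand_value_and_extremes(self):
        t = OtuTable(np.array([[6, 2], [2, 2], [6, 2], [0, 0]]),
                     list("abcd"), ["x", "y"])
        d = bray_curtis(t)
        assert d["a", "b"] == pytest.approx(4 / 12)
        assert d["a", "c"] == 0.0
        t2 = OtuTable(np.array([[5, 0], [0, 7]]), ["a", "b"], ["x", "y"])
        assert bray_curtis(t2)["a", "b"] == 1.0

    @given(arrays(np.int64, (4, 6), elements=st.integers(0, 50)))
    @settings(max_examples=50, deadline=None)
    def test_bounds_symmetry_zero_diagonal(self, counts):
        t = OtuTable(counts, [f"s{i}" for i in range(4)],
                     [f"o{j}" for j in range(6)])
        d = bray_curtis(t).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_matches_scipy_on_positive_tables(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 100, (5, 12))
        t = OtuTable(counts, [f"s{i}" for i in range(5)],
                     [f"o{j}" for j in range(12)])
        ref = squareform(pdist(counts.astype(float), metric="braycurtis"))
        assert np.allclose(bray_curtis(t).data, ref, atol=1e-12)


def _euclidean_dm(x):
    return squareform(pdist(x))


class TestPermanova:
    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(9, 4))
        x[:4] += 1.5
        d = DistanceMatrix(_euclidean_dm(x))
        labels = ["a"] * 4 + ["b"] * 5
        mine = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_permanova(d, labels, permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_exhaustive_enumeration_oracle(self):
        """Sampled permutation p agrees with the full label-permutation null."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        x[3:] += 1.0
        d = _euclidean_dm(x)
        d2 = d * d
        codes = np.array([0, 0, 0, 1, 1, 1])
        f_obs, _ = _pseudo_f(d2, codes, 2)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            f_p, _ = _pseudo_f(d2, codes[list(perm)], 2)
            total += 1
            hits += f_p >= f_obs
        p_exact = hits / total
        res = permanova(DistanceMatrix(d), codes, n_perm=999, seed=3)
        assert res.p_value == pytest.approx(p_exact, abs=0.05)

    def test_degenerate_all_equal_distances(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = permanova(DistanceMatrix(d), [0, 0, 0, 1, 1, 1], n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_singleton_group_named(self):
        d = DistanceMatrix(_euclidean_dm(np.random.default_rng(0).normal(size=(5, 2))))
        with pytest.raises(InputError, match="lonely"):
            permanova(d, ["a", "a", "a", "a", "lonely"], n_perm=99)

    def test_pairwise_holm_table(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 3))
        x[4:8] += 3
        x[8:] += 6
        d = DistanceMatrix(_euclidean_dm(x))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        _, pw = permanova(d, labels, n_perm=199, seed=0, pairwise=True)
        assert len(pw) == 3
        assert (pw["p_holm"] >= pw["p"] - 1e-12).all()


class TestMantel:
    def test_identical_matrices_r_one(self):
        d = _euclidean_dm(np.random.default_rng(0).normal(size=(6, 3)))
        res = mantel(d, d.copy(), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(4)
        a = _euclidean_dm(rng.normal(size=(7, 3)))
        b = _euclidean_dm(rng.normal(size=(7, 3)))
        mine = mantel(a, b, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                   permutations=0)
        assert mine.statistic == pytest.approx(r_ref, rel=1e-10)

    def test_exhaustive_permutation_oracle(self):
        """Sampled p agrees with brute force over all 120 relabelings."""
        rng = np.random.default_rng(6)
        a = _euclidean_dm(rng.normal(size=(5, 2)))
        b = _euclidean_dm(rng.normal(size=(5, 2)))
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
        hits = total = 0
        for perm in itertools.permutations(range(5)):
            perm = list(perm)
            r_p = np.corrcoef(a[iu], b[np.ix_(perm, perm)][iu])[0, 1]
            total += 1
            hits += r_p >= r_obs
        p_exact = hits / total
        res = mantel(a, b, n_perm=119, seed=9)
        assert res.p_value == pytest.approx(p_exact, abs=1 / 12)


class TestAnovaTukey:
    def test_obvious_separation(self):
        rng = np.random.default_rng(0)
        v = np.r_[rng.normal(0, 0.01, 5), rng.normal(0, 0.01, 5),
                  rng.normal(10, 0.01, 5)]
        g = np.array(["x"] * 5 + ["y"] * 5 + ["z"] * 5)
        f, p, letters = anova_tukey(v, g)
        assert p < 1e-10
        assert letters["z"] == "a" and letters["x"] == letters["y"] == "b"

    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(1)
        v = rng.normal(5, 1, 15)
        g = np.repeat(["x", "y", "z"], 5)
        _, p, letters = anova_tukey(v, g)
        assert set(letters.values()) == {"a"}

    def test_f_matches_manual_arithmetic(self):
        # balanced 3×5 fixture, F computed from between/within SS by hand
        groups = {"a": [4.1, 5.2, 3.9, 4.8, 5.0], "b": [6.3, 5.9, 6.8, 6.1, 6.4],
                  "c": [5.1, 4.7, 5.5, 5.3, 4.9]}
        v = np.concatenate([groups[g] for g in "abc"])
        labels = np.repeat(list("abc"), 5)
        grand = v.mean()
        ss_between = sum(5 * (np.mean(groups[g]) - grand) ** 2 for g in "abc")
        ss_within = sum(((np.asarray(groups[g]) - np.mean(groups[g])) ** 2).sum()
                        for g in "abc")
        f_manual = (ss_between / 2) / (ss_within / 12)
        f, _, _ = anova_tukey(v, labels)
        assert f == pytest.approx(f_manual, abs=1e-6)

    def test_letters_agree_with_all_pairs_oracle(self):
        """On a balanced design, the letter display reflects exactly the
        pairwise Tukey significance graph."""
        from scipy import stats as ss

        rng = np.random.default_rng(3)
        means = [0.0, 0.5, 3.0, 3.2]
        v = np.concatenate([rng.normal(m, 0.5, 6) for m in means])
        g = np.repeat(list("wxyz"), 6)
        _, _, letters = anova_tukey(v, g)
        # oracle: Tukey-Kramer significance per pair
        k, n = 4, 24
        mse = np.mean([np.var(v[g == gi], ddof=1) for gi in "wxyz"])
        q = ss.studentized_range.ppf(0.95, k, n - k)
        for gi, gj in itertools.combinations("wxyz", 2):
            diff = abs(v[g == gi].mean() - v[g == gj].mean())
            sig = diff / np.sqrt(mse / 2 * (2 / 6)) > q
            share = bool(set(letters[gi]) & set(letters[gj]))
            assert share == (not sig)


class TestLinearR2:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = linear_r2(x, 2 * x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope > 0

    def test_null_expectation_of_r2(self):
        # E[r²] under independence is 1/(n−1)
        rng = np.random.default_rng(0)
        n = 10
        r2s = [linear_r2(rng.normal(size=n), rng.normal(size=n)).r2
               for _ in range(1000)]
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.02)


class TestTaxonomy:
    def test_published_domain_split(self):
        # 3139 OTUs, 16 archaeal → 99.49% bacterial
        n, n_arch = 3139, 16
        otu_ids = [f"o{i}" for i in range(n)]
        tax = {o: ("Archaea;E;H;Hb" if i < n_arch else "Bacteria;P;C;O")
               for i, o in enumerate(otu_ids)}
        counts = np.ones((1, n), dtype=np.int64)
        t = OtuTable(counts, ["s"], otu_ids, tax)
        frac = domain_fraction(t)
        assert frac["Bacteria"] == 99.49
        assert frac["Archaea"] == 0.51

    def test_single_domain_is_100(self, toy_table):
        t = OtuTable(np.array([[1, 1]]), ["s"], ["A", "B"],
                     {"A": "Bacteria;P", "B": "Bacteria;Q"})
        assert domain_fraction(t) == {"Bacteria": 100.0}

    def test_relative_abundances_sum_to_100(self, toy_table):
        summary = taxonomy_summary(toy_table, level=3)
        assert np.allclose(summary.sum(axis=0), 100.0, atol=1e-9)
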