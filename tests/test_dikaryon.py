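"""Within-dikaryon allele-divergence test machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matlink.alignment import Alignment, AlignedSequence
from matlink.dikaryon import (
    AllelePair,
    DikaryonTestError,
    permutation_test,
    run_group_tests,
    similarity_matrix,
    welch_t_test,
    within_across_split,
)
from conftest import make_alignment, random_seq


def allele_world(rng, n_isolates=6, length=120, divergence=0.3):
    """n isolates x 2 alleles drawn from a diffuse allele cloud."""
    base = random_seq(rng, length)
    members, pairs, table = [], [], []
    for i in range(n_isolates):
        iso = f"SL{i}"
        ids = []
        for a in (1, 2):
            s = list(base)
            for p in rng.choice(length, size=int(divergence * length), replace=False):
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            aid = f"{iso}.a{a}"
            members.append(AlignedSequence(aid, "".join(s), isolate_id=iso))
            ids.append(aid)
            table.append({"allele_id": aid, "isolate_id": iso, "group": "g"})
        pairs.append(AllelePair(iso, tuple(ids), "g"))
    return Alignment("marker", members), pairs, pd.DataFrame(table)


class TestSimilarityMatrix:
    def test_identical_alleles(self):
        m = similarity_matrix(make_alignment(["ACGT", "ACGT"], ids=["x", "y"]))
        assert m.loc["x", "y"] == 1.0
        assert (np.diag(m) == 1.0).all()

    def test_symmetry(self, rng):
        aln = make_alignment([random_seq(rng, 50) for _ in range(5)])
        m = similarity_matrix(aln).to_numpy()
        assert np.allclose(m, m.T)

    def test_hand_computed_three_alleles(self):
        aln = make_alignment(["AAAA", "AAAG", "AAGG"], ids=["x", "y", "z"])
        m = similarity_matrix(aln)
        assert m.loc["x", "y"] == 0.75
        assert m.loc["x", "z"] == 0.50
        assert m.loc["y", "z"] == 0.75


class TestWithinAcrossSplit:
    def test_two_isolates_counts(self, rng):
        aln, pairs, table = allele_world(rng, n_isolates=2)
        m = similarity_matrix(aln)
        within, across = within_across_split(m, pairs, table)
        assert len(within) == 2
        assert len(across) == 4  # 2x2 cross-isolate combinations

    def test_single_isolate_group_errors(self, rng):
        aln, pairs, table = allele_world(rng, n_isolates=2)
        m = similarity_matrix(aln)
        with pytest.raises(DikaryonTestError):
            within_across_split(m, [], table)

    def test_matches_brute_force_enumeration(self, rng):
        aln, pairs, table = allele_world(rng, n_isolates=3)
        m = similarity_matrix(aln)
        within, across = within_across_split(m, pairs, table)
        iso = {r.allele_id: r.isolate_id for r in table.itertuples()}
        ids = list(table["allele_id"])
        expected_across = sorted(
            m.loc[a, b]
            for a, b in itertools.combinations(ids, 2)
            if iso[a] != iso[b]
        )
        assert sorted(across) == pytest.approx(expected_across)
        assert len(within) == 3

    def test_singleton_isolates_join_across_only(self, rng):
        aln, pairs, table = allele_world(rng, n_isolates=3)
        extra = pd.DataFrame(
            [{"allele_id": "SL9.a1", "isolate_id": "SL9", "group": "g"}]
        )
        aln2 = Alignment(
            "marker",
            list(aln.members)
            + [AlignedSequence("SL9.a1", aln.members[0].residues, isolate_id="SL9")],
        )
        m = similarity_matrix(aln2)
        w_with, a_with = within_across_split(m, pairs, pd.concat([table, extra]))
        w_wo, a_wo = within_across_split(m, pairs, pd.concat([table, extra]),
                                         include_singletons=False)
        assert len(w_with) == len(w_wo) == 3
        assert len(a_with) == len(a_wo) + 6  # SL9 allele pairs with 6 others


class TestWelch:
    def test_equal_samples(self):
        t, df, p = welch_t_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 3 + vy / 5
        t_expected = (x.mean() - y.mean()) / np.sqrt(se2)
        df_expected = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 5) ** 2 / 4)
        t, df, p = welch_t_test(x, y)
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert df == pytest.approx(df_expected, abs=1e-12)
        sp = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(sp.statistic, abs=1e-12)
        assert p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_scale_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 1, size=10)
        t1, _, _ = welch_t_test(x, y)
        t2, _, _ = welch_t_test(10 * x, 10 * y)
        assert t1 == pytest.approx(t2)

    def test_degenerate_zero_variance(self):
        t, df, p = welch_t_test(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert t is None and p is None

    def test_alternatives(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.5, 0.6, 0.7])
        _, _, p_less = welch_t_test(x, y, "less")
        _, _, p_greater = welch_t_test(x, y, "greater")
        assert p_less < 0.05 < p_greater


class TestPermutation:
    def test_determinism(self, rng):
        aln, pairs, table = allele_world(rng)
        m = similarity_matrix(aln)
        p1 = permutation_test(m, pairs, table, n_perm=99, seed=5)
        p2 = permutation_test(m, pairs, table, n_perm=99, seed=5)
        assert p1 == p2

    def test_null_p_values_roughly_uniform(self, rng):
        """Random pairings: permutation p should be close to uniform."""
        ps = []
        for rep in range(60):
            aln, pairs, table = allele_world(
                np.random.default_rng(1000 + rep), n_isolates=5
            )
            m = similarity_matrix(aln)
            ps.append(permutation_test(m, pairs, table, n_perm=99, seed=rep))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_for_forced_divergent_pairs(self, rng):
        # two tight allele clusters; every isolate pairs one allele from each
        a, b = random_seq(rng, 100), random_seq(rng, 100)
        b = a[:50] + "".join(
            rng.choice([c for c in "ACGT" if c != x]) for x in a[50:]
        )
        members, pairs, rows = [], [], []
        for i in range(10):
            ids = (f"i{i}.a1", f"i{i}.a2")
            members.append(AlignedSequence(ids[0], a, isolate_id=f"i{i}"))
            members.append(AlignedSequence(ids[1], b, isolate_id=f"i{i}"))
            pairs.append(AllelePair(f"i{i}", ids, "g"))
            rows += [
                {"allele_id": ids[0], "isolate_id": f"i{i}", "group": "g"},
                {"allele_id": ids[1], "isolate_id": f"i{i}", "group": "g"},
            ]
        m = similarity_matrix(Alignment("marker", members))
        p_few = permutation_test(m, pairs, pd.DataFrame(rows), n_perm=99, seed=1)
        p_many = permutation_test(m, pairs, pd.DataFrame(rows), n_perm=1999, seed=1)
        assert p_many < 0.05
        assert p_many <= p_few  # resolution improves with more permutations


class TestRunGroupTests:
    def test_direction_convention(self, rng):
        """More divergent within individuals <=> mean_within < mean_across
        <=> negative t under (within - across)."""
        a, b = random_seq(rng, 100), random_seq(rng, 100)
        members, pairs, rows = [], [], []
        for i in range(5):
            ids = (f"i{i}.a1", f"i{i}.a2")
            members.append(AlignedSequence(ids[0], a, isolate_id=f"i{i}"))
            members.append(AlignedSequence(ids[1], b, isolate_id=f"i{i}"))
            pairs.append(AllelePair(f"i{i}", ids, "g"))
            rows += [
                {"allele_id": x, "isolate_id": f"i{i}", "group": "g"} for x in ids
            ]
        m = similarity_matrix(Alignment("marker", members))
        res = run_group_tests(m, pairs, pd.DataFrame(rows), ["g"], n_perm=49, seed=0)
        r = res.iloc[0]
        assert r.mean_within_similarity < r.mean_across_similarity
        assert r.t_statistic < 0

    def test_empty_group_list(self, rng):
        aln, pairs, table = allele_world(rng)
        res = run_group_tests(similarity_matrix(aln), pairs, table, [], n_perm=9)
        assert len(res) == 0
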