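"""Diversity statistics and neutrality tests (summary-table machinery)."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from matlink.diversity import (
    StatsError,
    fu_li_d_star,
    fu_li_d_star_from_counts,
    fu_li_f_star_from_counts,
    locus_stats,
    locus_summary,
    mean_pairwise_k,
    neutrality_constants,
    nucleotide_diversity,
    render_table,
    segregating_sites,
    tajimas_d,
    tajimas_d_from_counts,
    watterson_theta,
    _fu_li_star_constants,
)
from conftest import make_alignment, random_seq


class TestSegregatingSites:
    def test_identical_sequences(self):
        assert segregating_sites(make_alignment(["ACGT"] * 4)) == (0, 0, 0)

    def test_hand_enumerated_columns(self):
        # columns: {A,A,G} biallelic 1 mutation 1 singleton;
        #          {C,C,C} monomorphic; {A,T,G} 2 mutations, 2 singletons
        aln = make_alignment(["ACA", "ACT", "GCG"])
        assert segregating_sites(aln) == (2, 3, 3)

    def test_single_singleton_column(self):
        seqs = ["A" * 10] * 9 + ["G" + "A" * 9]
        aln = make_alignment([s for s in seqs])
        assert segregating_sites(aln) == (1, 1, 1)

    def test_all_columns_excluded_raises(self):
        with pytest.raises(StatsError):
            segregating_sites(make_alignment(["A-", "-A"]))


class TestPairwiseK:
    def test_two_sequences_five_of_hundred(self):
        a = "A" * 100
        b = "G" * 5 + "A" * 95
        aln = make_alignment([a, b])
        assert mean_pairwise_k(aln) == 5.0
        assert nucleotide_diversity(aln) == pytest.approx(0.05)

    def test_identical_zero(self):
        aln = make_alignment(["ACGTACGT"] * 3)
        assert mean_pairwise_k(aln) == 0.0

    def test_matches_brute_force_all_pairs(self, rng):
        seqs = [random_seq(rng, 60) for _ in range(5)]
        aln = make_alignment(seqs)
        pairs = list(itertools.combinations(seqs, 2))
        brute = np.mean([sum(x != y for x, y in zip(a, b)) for a, b in pairs])
        assert mean_pairwise_k(aln) == pytest.approx(brute)


class TestWattersonTheta:
    @pytest.mark.parametrize(
        "n,S,expected",
        [
            (116, 182, 34.17),
            (95, 183, 35.70),
            (21, 170, 47.25),
            (16, 158, 47.62),
            (27, 132, 34.25),
            (51, 213, 47.34),
            (150, 11, 1.97),
        ],
    )
    def test_published_marker_and_its_rows(self, n, S, expected):
        """theta_W = S/a1 reproduces the printed per-locus estimates to 2 dp
        for the mating-type-linked marker groups and the pooled ITS row."""
        assert watterson_theta(n, S) == pytest.approx(expected, abs=0.005)

    def test_two_sequences(self):
        assert watterson_theta(2, 5) == 5.0  # a1(2) = 1

    def test_monotonic_in_S_and_n(self):
        assert watterson_theta(10, 6) > watterson_theta(10, 5)
        assert watterson_theta(11, 5) < watterson_theta(10, 5)

    def test_requires_two_sequences(self):
        with pytest.raises(StatsError):
            watterson_theta(1, 3)


def _hand_constants(n):
    """Independent transcription of the Tajima variance constants using
    exact fractions."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2), a1


class TestTajimasD:
    def test_undefined_when_no_variation(self):
        assert tajimas_d(make_alignment(["ACGT"] * 4)) is None

    def test_small_alignment_matches_hand_formula(self):
        aln = make_alignment(["AAAA", "AAAG", "AAGG", "CAGG"])
        S, _, _ = segregating_sites(aln)
        k = mean_pairwise_k(aln)
        e1, e2, a1 = _hand_constants(4)
        expected = (k - S / float(a1)) / math.sqrt(
            float(e1) * S + float(e2) * S * (S - 1)
        )
        assert tajimas_d(aln) == pytest.approx(expected, abs=1e-12)

    def test_excess_rare_variants_negative(self):
        # star-like data: every mutation private to one sequence
        base = "A" * 50
        seqs = [base[:i] + "G" + base[i + 1:] for i in range(8)]
        aln = make_alignment(seqs)
        assert tajimas_d(aln) < 0


class TestFuLiStar:
    def test_star_like_fixture_negative(self):
        base = "A" * 50
        seqs = [base[:i] + "G" + base[i + 1:] for i in range(8)]
        aln = make_alignment(seqs)
        assert fu_li_d_star(aln) < 0

    def test_undefined_when_no_variation(self):
        assert fu_li_d_star(make_alignment(["ACGT"] * 4)) is None

    @pytest.mark.parametrize("n", [4, 8, 21, 51, 116])
    def test_constants_match_independent_transcription(self, n):
        """u/v constants agree with a second, exact-fraction transcription
        of the published formulas."""
        an = sum(Fraction(1, i) for i in range(1, n))
        bn = sum(Fraction(1, i * i) for i in range(1, n))
        an1 = an + Fraction(1, n)
        cn = Fraction(2 * (n * an - 2 * (n - 1)), (n - 1) * (n - 2))
        dn = (
            cn
            + Fraction(n - 2, (n - 1) ** 2)
            + Fraction(2, n - 1)
            * (Fraction(3, 2) - (2 * an1 - 3) / (n - 2) - Fraction(1, n))
        )
        nn = Fraction(n)
        vD = (
            (nn / (n - 1)) ** 2 * bn
            + an**2 * dn
            - 2 * nn * an * (an + 1) / (n - 1) ** 2
        ) / (an**2 + bn)
        uD = (nn / (n - 1)) * (an - nn / (n - 1)) - vD
        vF = (
            dn
            + Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
            - Fraction(2, n - 1) * (4 * bn - 6 + Fraction(8, n))
        ) / (an**2 + bn)
        uF = (
            nn / (n - 1)
            + Fraction(n + 1, 3 * (n - 1))
            - Fraction(4, n * (n - 1))
            + 2 * (nn + 1) / (n - 1) ** 2 * (an1 - 2 * nn / (n + 1))
        ) / an - vF
        got = _fu_li_star_constants(n)
        for g, e in zip(got, (uD, vD, uF, vF)):
            assert g == pytest.approx(float(e), rel=1e-12)

    def test_d_star_value_from_counts(self):
        # full-statistic check against the same exact-fraction transcription
        n, eta, eta_s, k = 8, 8, 8, 2.0
        an = sum(1.0 / i for i in range(1, n))
        uD, vD, uF, vF = _fu_li_star_constants(n)
        d_expected = ((n / (n - 1)) * eta - an * eta_s) / math.sqrt(
            uD * eta + vD * eta**2
        )
        f_expected = (k - ((n - 1) / n) * eta_s) / math.sqrt(uF * eta + vF * eta**2)
        assert fu_li_d_star_from_counts(n, eta, eta_s) == pytest.approx(d_expected)
        assert fu_li_f_star_from_counts(n, eta, eta_s, k) == pytest.approx(f_expected)


class TestNeutralityConstants:
    def test_small_n_exact(self):
        c = neutrality_constants(4)
        assert c.a1 == pytest.approx(1 + 0.5 + 1 / 3)
        assert c.a2 == pytest.approx(1 + 0.25 + 1 / 9)
        assert c.b1 == pytest.approx(5 / 9)


class TestLocusSummary:
    def _labelled(self):
        members = []
        import itertools as it
        from matlink.alignment import AlignedSequence, Alignment

        rng = np.random.default_rng(5)
        seqs_a = [random_seq(rng, 40) for _ in range(4)]
        seqs_b = [seqs_a[0]] * 3  # group B monomorphic
        members = [
            AlignedSequence(f"a{i}", s, group="Asia", ecology="N")
            for i, s in enumerate(seqs_a)
        ] + [
            AlignedSequence(f"b{i}", s, group="Cosmo", ecology="B")
            for i, s in enumerate(seqs_b)
        ]
        return Alignment("marker", members)

    def test_one_row_per_locus_per_group(self):
        aln = self._labelled()
        df = locus_summary({"marker": aln})
        assert set(df["Group"]) == {"all", "Asia", "Cosmo"}
        assert len(df) == 3

    def test_monomorphic_group_renders_dashes(self):
        df = locus_summary({"marker": self._labelled()})
        tsv = render_table(df)
        row = [l for l in tsv.splitlines() if "\tCosmo\t" in l][0]
        fields = row.split("\t")
        assert fields[4] == "0"  # S
        assert fields[5] == fields[6] == fields[7] == "-"  # k, pi, thetaW

    def test_pooled_row_equals_direct_computation(self):
        aln = self._labelled()
        df = locus_summary({"marker": aln}).set_index("Group")
        direct = locus_stats(aln)
        assert df.loc["all", "S"] == direct.S
        assert df.loc["all", "k"] == pytest.approx(direct.k)
        assert df.loc["all", "TajimaD"] == pytest.approx(direct.tajima_d)

    def test_distinct_count_mode(self):
        df = locus_summary({"marker": self._labelled()}, count_mode="distinct")
        assert df.set_index("Group").loc["Cosmo", "#"] == 1
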