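"""Multilocus HKA test: expectations, fitting, and the bootstrap null."""

import itertools

import numpy as np
import pytest

from matlink.alignment import Alignment, AlignedSequence
from matlink.diversity import neutrality_constants
from matlink.hka import (
    HKAError,
    HKALocusData,
    fit_hka,
    hka_data_from_alignments,
    hka_expectations,
    hka_null_simulate,
    hka_test,
)


def exact_fixture(thetas=(5.0, 2.0, 8.0), T=3.0, f=0.5, n_a=20, n_b=10):
    """Counts placed exactly at their model expectations."""
    data = []
    for i, th in enumerate(thetas):
        e = hka_expectations(th, T, f, n_a, n_b)
        data.append(
            HKALocusData(f"l{i}", n_a, n_b, S_a=e["E_S_a"], S_b=e["E_S_b"],
                         d_ab=e["E_d"])
        )
    return data


class TestExpectations:
    def test_zero_theta_all_zero(self):
        e = hka_expectations(0.0, 2.0, 0.5, 10, 10)
        assert e["E_S_a"] == e["E_S_b"] == e["E_d"] == 0.0

    def test_symmetric_taxa(self):
        e = hka_expectations(3.0, 0.0, 1.0, 12, 12)
        assert e["E_S_a"] == pytest.approx(e["E_S_b"])
        assert e["E_d"] == pytest.approx(3.0)  # theta * (0 + 1)

    def test_worked_two_locus_case_by_hand(self):
        theta, T, f, n = 4.0, 2.0, 0.5, 5
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        e = hka_expectations(theta, T, f, n, n)
        assert e["E_S_a"] == pytest.approx(theta * a1)
        assert e["Var_S_a"] == pytest.approx(theta * a1 + theta**2 * a2)
        assert e["E_S_b"] == pytest.approx(f * theta * a1)
        assert e["E_d"] == pytest.approx(theta * (T + 0.75))
        assert e["Var_d"] == pytest.approx(theta * (T + 0.75) + (theta * 0.75) ** 2)


class TestFit:
    def test_perfect_fit_x2_zero(self):
        for method in ("moment", "minimize"):
            fit = fit_hka(exact_fixture(), method=method)
            assert fit.x2_obs <= 1e-6
            assert fit.T == pytest.approx(3.0, rel=1e-3)
            assert fit.f == pytest.approx(0.5, rel=1e-3)

    def test_single_locus_rejected(self):
        with pytest.raises(HKAError, match="2 loci"):
            fit_hka(exact_fixture()[:1])

    def test_degenerate_all_zero_rejected(self):
        data = [
            HKALocusData("a", 10, 10, 0, 0, 0.0),
            HKALocusData("b", 10, 10, 0, 0, 0.0),
        ]
        with pytest.raises(HKAError, match="degenerate"):
            fit_hka(data)

    def test_minimize_matches_dense_grid_search(self):
        """One-taxon mode (n_b = 0): grid over (theta1, theta2, T)."""
        data = [
            HKALocusData("a", 10, 0, S_a=14, S_b=0, d_ab=20.0),
            HKALocusData("b", 10, 0, S_a=6, S_b=0, d_ab=9.0),
        ]
        fit = fit_hka(data, method="minimize")
        a1 = neutrality_constants(10).a1
        a2 = neutrality_constants(10).a2

        def x2(t1, t2, T):
            tot = 0.0
            for th, S, d in ((t1, 14, 20.0), (t2, 6, 9.0)):
                ES, VS = th * a1, th * a1 + th**2 * a2
                Ed, Vd = th * (T + 1), th * (T + 1) + th**2
                tot += (S - ES) ** 2 / VS + (d - Ed) ** 2 / Vd
            return tot

        grid = min(
            x2(t1, t2, T)
            for t1 in np.linspace(1, 10, 40)
            for t2 in np.linspace(0.5, 6, 40)
            for T in np.linspace(0.5, 8, 40)
        )
        assert fit.x2_obs <= grid + 1e-3

    def test_locus_order_invariance(self):
        data = exact_fixture((3.0, 7.0), T=1.5, f=0.8)
        x2a = fit_hka(data).x2_obs
        x2b = fit_hka(data[::-1]).x2_obs
        assert x2a == pytest.approx(x2b, abs=1e-9)

    def test_taxon_label_swap_symmetry(self):
        rng = np.random.default_rng(11)
        data, swapped = [], []
        for i in range(3):
            Sa, Sb, d = rng.integers(5, 40, 3)
            data.append(HKALocusData(f"l{i}", 14, 10, int(Sa), int(Sb), float(d)))
            swapped.append(HKALocusData(f"l{i}", 10, 14, int(Sb), int(Sa), float(d)))
        x2a = fit_hka(data, method="minimize").x2_obs
        x2b = fit_hka(swapped, method="minimize").x2_obs
        assert x2a == pytest.approx(x2b, rel=1e-3)


class TestNullSimulation:
    def test_determinism_under_seed(self):
        data = exact_fixture()
        p1 = hka_test(data, n_sims=200, seed=42).p_value
        p2 = hka_test(data, n_sims=200, seed=42).p_value
        assert p1 == p2

    def test_n_sims_validated(self):
        fit = fit_hka(exact_fixture())
        with pytest.raises(HKAError):
            hka_null_simulate(fit, exact_fixture(), 0, np.random.default_rng(0))

    def test_simulated_moments_match_model(self):
        """The null simulator reproduces the analytic E and Var of S and d."""
        rng = np.random.default_rng(3)
        fit = fit_hka(exact_fixture((6.0, 6.0), T=2.0, f=0.5))
        data = exact_fixture((6.0, 6.0), T=2.0, f=0.5)
        from matlink.hka import _simulate_S

        th = fit.theta_per_locus["l0"]
        S = _simulate_S(rng, 20, th, 40000)
        e = hka_expectations(th, fit.T, fit.f, 20, 10)
        assert S.mean() == pytest.approx(e["E_S_a"], rel=0.02)
        assert S.var() == pytest.approx(e["Var_S_a"], rel=0.05)
        t_anc = rng.exponential((1 + fit.f) / 2, 40000)
        d = rng.poisson(th * (fit.T + t_anc))
        assert d.mean() == pytest.approx(e["E_d"], rel=0.02)
        assert d.var() == pytest.approx(e["Var_d"], rel=0.05)

    def test_power_against_polymorphism_inflated_in_one_taxon(self):
        """10x inflated polymorphism in taxon A at one locus only breaks the
        shared-f constraint and is detected."""
        T, f, n_a, n_b = 2.0, 1.0, 20, 20
        data = []
        for i in range(4):
            e = hka_expectations(4.0, T, f, n_a, n_b)
            boost = 10.0 if i == 0 else 1.0
            data.append(
                HKALocusData(
                    f"l{i}", n_a, n_b,
                    S_a=round(boost * e["E_S_a"]),
                    S_b=round(e["E_S_b"]),
                    d_ab=e["E_d"],
                )
            )
        res = hka_test(data, n_sims=500, seed=7)
        assert res.p_value < 0.05

    def test_power_against_balanced_locus_in_both_taxa(self):
        """The headline pattern: one locus with excess polymorphism in both
        taxa but ordinary divergence deviates significantly once the taxa
        are well diverged (divergence no longer scales with the locus's
        apparent theta)."""
        T, f, n_a, n_b = 10.0, 1.0, 20, 20
        data = []
        for i in range(4):
            e = hka_expectations(4.0, T, f, n_a, n_b)
            boost = 10.0 if i == 0 else 1.0
            data.append(
                HKALocusData(
                    f"l{i}", n_a, n_b,
                    S_a=round(boost * e["E_S_a"]),
                    S_b=round(boost * e["E_S_b"]),
                    d_ab=e["E_d"],
                )
            )
        res = hka_test(data, n_sims=500, seed=7)
        assert res.p_value < 0.01


class TestFromAlignments:
    def test_hand_fixture_counts(self):
        a = Alignment("loc", [
            AlignedSequence("a1", "AAAACC"),
            AlignedSequence("a2", "AAAGCC"),
        ])
        b = Alignment("loc", [
            AlignedSequence("b1", "TTAACC"),
            AlignedSequence("b2", "TTAACG"),
        ])
        d = hka_data_from_alignments("loc", a, b)
        assert (d.S_a, d.S_b) == (1, 1)
        # cross pairs: a1-b1:2 a1-b2:3 a2-b1:3 a2-b2:4 -> mean 3.0
        assert d.d_ab == pytest.approx(3.0)
        assert d.L_valid == 6
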