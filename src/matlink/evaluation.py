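"""Study-scale evaluation experiments.

Each function runs one of the package's headline checks from scratch at
the study conditions — published worked examples, calibration of the
neutrality statistics on neutral coalescent data, operating
characteristics of the HKA and dikaryon tests, clone-calling accuracy,
phasing minimality, and the simulator's reproduction of the
balancing-selection pattern. The test suite asserts on these numbers and
the reproduction script reports them.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment, AlignedSequence
from .clonecall import CloneSet, call_alleles
from .dikaryon import AllelePair, permutation_test, welch_t_test
from .diversity import (
    fu_li_d_star_from_counts,
    fu_li_f_star_from_counts,
    mean_pairwise_k,
    segregating_sites,
    tajimas_d_from_counts,
    watterson_theta,
)
from .hka import HKALocusData, fit_hka, hka_expectations, hka_test
from .phasing import (
    GenotypeSequence,
    brute_force_min_haplotypes,
    combine_haplotypes,
    phase_all,
)
from .simulate import SimConfig, simulate, summarize_truth

#: published per-locus (n, S) -> theta_W worked examples: the six
#: MAT-linked marker group rows and the pooled ITS row.
WATTERSON_EXAMPLES: dict[str, tuple[int, int, float]] = {
    "t1": (116, 182, 34.17),
    "t2": (95, 183, 35.70),
    "t3": (21, 170, 47.25),
    "t4": (16, 158, 47.62),
    "t5": (27, 132, 34.25),
    "t6": (51, 213, 47.34),
    "t7": (150, 11, 1.97),
}


def watterson_examples() -> dict[str, dict[str, float]]:
    """Recompute theta_W = S/a1(n) for the published worked examples."""
    return {
        key: {"n": n, "S": S, "theta_w": watterson_theta(n, S), "published": pub}
        for key, (n, S, pub) in WATTERSON_EXAMPLES.items()
    }


# ---------------------------------------------------------------------------
# Neutral-coalescent calibration of D, D*, F*
# ---------------------------------------------------------------------------


def _counts_from_genotype_matrix(G: np.ndarray, n: int):
    S = G.shape[0]
    eta = eta_s = 0
    ksum = 0.0
    npairs = n * (n - 1) / 2
    for row in G:
        _, counts = np.unique(row, return_counts=True)
        eta += len(counts) - 1
        eta_s += min(int((counts == 1).sum()), len(counts) - 1)
        ksum += npairs - (counts * (counts - 1) / 2).sum()
    return S, eta, eta_s, ksum / npairs


def neutral_calibration(
    seed: int, n: int = 20, theta: float = 5.0, reps: int = 2000
) -> dict[str, float]:
    """Mean (and variance) of Tajima's D and Fu & Li's D*/F* over neutral
    coalescent replicates simulated with msprime; the statistics
    themselves come from this package."""
    import msprime

    L = 100_000
    mu = theta / 2 / L
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 2, size=2)
    D, Ds, Fs = [], [], []
    replicates = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, sequence_length=L,
        random_seed=int(anc_seed), num_replicates=reps,
    )
    mut_rng = np.random.default_rng(int(mut_seed))
    for ts in replicates:
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(mut_rng.integers(1, 2**31 - 2))
        )
        G = mts.genotype_matrix()
        if G.shape[0] == 0:
            continue
        S, eta, eta_s, k = _counts_from_genotype_matrix(G, n)
        D.append(tajimas_d_from_counts(n, S, k))
        Ds.append(fu_li_d_star_from_counts(n, eta, eta_s))
        Fs.append(fu_li_f_star_from_counts(n, eta, eta_s, k))
    return {
        "reps": len(D),
        "mean_tajima_d": float(np.mean(D)),
        "var_tajima_d": float(np.var(D)),
        "mean_fu_li_d_star": float(np.mean(Ds)),
        "var_fu_li_d_star": float(np.var(Ds)),
        "mean_fu_li_f_star": float(np.mean(Fs)),
    }


# ---------------------------------------------------------------------------
# Phasing: greedy vs exhaustive minimum, recombination invariant
# ---------------------------------------------------------------------------


def _pool_instance(rng, n_haps, n_genos, length, max_total_het=14):
    while True:
        pool = [
            "".join(rng.choice(list("ACGT"), size=length)) for _ in range(n_haps)
        ]
        genos, total_het = [], 0
        for i in range(n_genos):
            h1, h2 = rng.choice(pool, size=2, replace=True)
            g = combine_haplotypes(h1, h2)
            total_het += sum(c in "RYSWKM" for c in g)
            genos.append(GenotypeSequence(f"g{i}", g))
        if 0 < total_het <= max_total_het:
            return genos


def phasing_suite(seed: int, n_fixtures: int = 24, n_random: int = 1000) -> dict:
    """(a) greedy phase_all vs the exhaustive minimum on small pool-derived
    fixtures; (b) the recombination invariant on random genotypes."""
    rng = np.random.default_rng(seed)
    n_equal = 0
    for _ in range(n_fixtures):
        genos = _pool_instance(
            rng, n_haps=int(rng.integers(2, 5)), n_genos=int(rng.integers(3, 7)),
            length=int(rng.integers(8, 16)),
        )
        greedy = phase_all(genos).n_distinct
        minimum, _ = brute_force_min_haplotypes(genos)
        assert greedy >= minimum
        n_equal += greedy == minimum
    n_ok = 0
    for i in range(n_random):
        length = int(rng.integers(5, 40))
        residues = "".join(rng.choice(list("ACGTRYSWKM"), size=length,
                                      p=[0.2] * 4 + [1 / 30] * 6))
        g = GenotypeSequence(f"r{i}", residues)
        if g.n_het > 12:
            g = GenotypeSequence(f"r{i}", residues.translate(
                str.maketrans("RYSWKM", "AACCGG")))
        hs = phase_all([g])
        h1, h2 = hs.assignments[g.seq_id]
        n_ok += combine_haplotypes(h1, h2) == g.residues
    return {
        "n_fixtures": n_fixtures,
        "n_greedy_equals_minimum": n_equal,
        "n_random_genotypes": n_random,
        "n_recombination_ok": n_ok,
    }


# ---------------------------------------------------------------------------
# Clone calling accuracy
# ---------------------------------------------------------------------------


def clone_calling_experiment(
    seed: int,
    n_isolates: int = 500,
    epsilon: float = 0.002,
    length: int = 810,
    clones_per_allele: tuple[int, int] = (5, 8),
    divergence: float = 0.05,
) -> dict:
    """Allele recovery from simulated clone sets.

    Each isolate carries two alleles at the given divergence; every allele
    is covered by at least five clones carrying independent per-base
    errors. Reports the fraction of called alleles differing from truth.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_alleles = n_wrong = n_split_errors = 0
    for i in range(n_isolates):
        a = rng.integers(0, 4, size=length)
        b = a.copy()
        hit = rng.random(length) < divergence
        b[hit] = (b[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        truth = ["".join(bases[a]), "".join(bases[b])]
        clones = []
        for t_idx, t_seq in enumerate((a, b)):
            m = int(rng.integers(clones_per_allele[0], clones_per_allele[1] + 1))
            for c in range(m):
                read = t_seq.copy()
                n_err = rng.binomial(length, epsilon)
                if n_err:
                    cols = rng.integers(0, length, n_err)
                    read[cols] = (read[cols] + rng.integers(1, 4, n_err)) % 4
                clones.append("".join(bases[read]))
        cs = CloneSet(
            f"I{i}",
            Alignment("marker", [
                AlignedSequence(f"I{i}.c{j}", s) for j, s in enumerate(clones)
            ]),
        )
        result = call_alleles(cs)
        called = [c.allele_seq.residues for c in result.calls]
        if len(called) != 2:
            n_split_errors += 1
        n_alleles += len(called)
        n_wrong += sum(c not in truth for c in called)
    return {
        "n_isolates": n_isolates,
        "epsilon": epsilon,
        "n_alleles_called": n_alleles,
        "allele_error_rate": n_wrong / n_alleles,
        "n_cluster_count_errors": n_split_errors,
    }


# ---------------------------------------------------------------------------
# HKA operating characteristics
# ---------------------------------------------------------------------------


def hka_exact_fixture_x2() -> float:
    """x2 at the optimum for counts placed exactly at model expectations."""
    data = []
    for i, th in enumerate((5.0, 2.0, 8.0)):
        e = hka_expectations(th, 3.0, 0.5, 20, 10)
        data.append(
            HKALocusData(f"l{i}", 20, 10, S_a=e["E_S_a"], S_b=e["E_S_b"],
                         d_ab=e["E_d"])
        )
    return fit_hka(data).x2_obs


def hka_type1(
    seed: int,
    n_outer: int = 400,
    n_inner: int = 200,
    thetas=(4.0, 2.0, 6.0, 10.0),
    T: float = 2.0,
    f: float = 0.8,
    n_a: int = 16,
    n_b: int = 12,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the HKA test on data simulated under its own null."""
    from .hka import _simulate_S

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_outer):
        data = []
        for j, th in enumerate(thetas):
            Sa = float(_simulate_S(rng, n_a, th, 1)[0])
            Sb = float(_simulate_S(rng, n_b, f * th, 1)[0])
            t_anc = rng.exponential((1 + f) / 2)
            d = float(rng.poisson(th * (T + t_anc)))
            data.append(HKALocusData(f"l{j}", n_a, n_b, S_a=Sa, S_b=Sb, d_ab=d))
        res = hka_test(data, n_sims=n_inner, seed=int(rng.integers(2**31 - 1)))
        rejections += res.p_value < alpha
    return {
        "n_outer": n_outer,
        "n_inner": n_inner,
        "alpha": alpha,
        "rejection_rate": rejections / n_outer,
    }


# ---------------------------------------------------------------------------
# Dikaryon test operating characteristics
# ---------------------------------------------------------------------------


def _random_allele_world(rng, n_isolates=10, n_extra=6, length=150, divergence=0.2):
    """Allele cloud + random (null) pairing into isolates."""
    base = rng.integers(0, 4, size=length)
    bases = np.array(list("ACGT"))
    n_alleles = 2 * n_isolates + n_extra
    members, rows = [], []
    for i in range(n_alleles):
        s = base.copy()
        hit = rng.random(length) < divergence
        s[hit] = (s[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        members.append("".join(bases[s]))
    order = rng.permutation(n_alleles)
    pairs, table_rows, aln_members = [], [], []
    for i, idx in enumerate(order):
        iso = f"I{i // 2}" if i < 2 * n_isolates else f"X{i}"
        aid = f"{iso}.a{i % 2 + 1}" if i < 2 * n_isolates else f"{iso}.a1"
        aln_members.append(
            AlignedSequence(aid, members[idx], isolate_id=iso)
        )
        table_rows.append({"allele_id": aid, "isolate_id": iso, "group": "g"})
    for k in range(n_isolates):
        pairs.append(AllelePair(f"I{k}", (f"I{k}.a1", f"I{k}.a2"), "g"))
    import pandas as pd

    return Alignment("marker", aln_members), pairs, pd.DataFrame(table_rows)


def _within_across(matrix, pairs, table):
    from .dikaryon import within_across_split

    return within_across_split(matrix, pairs, table)


def dikaryon_type1(seed: int, reps: int = 400, alpha: float = 0.05) -> dict:
    """Welch-test rejection rate when allele pairs are formed at random."""
    from .dikaryon import similarity_matrix

    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        aln, pairs, table = _random_allele_world(rng)
        m = similarity_matrix(aln)
        within, across = _within_across(m, pairs, table)
        _, _, p = welch_t_test(within, across)
        rej += p < alpha
    return {"reps": reps, "alpha": alpha, "rejection_rate": rej / reps}


def welch_fixture_error() -> float:
    """Max abs deviation of the Welch implementation from the closed
    formula on the hand-computable 3-vs-5 fixture."""
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / 3 + vy / 5
    t_exp = (x.mean() - y.mean()) / np.sqrt(se2)
    df_exp = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 5) ** 2 / 4)
    from scipy import stats

    p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
    t, df, p = welch_t_test(x, y)
    return float(max(abs(t - t_exp), abs(df - df_exp), abs(p - p_exp)))


def dikaryon_decision_agreement(
    seed: int, n_fixtures: int = 100, n_perm: int = 399, alpha: float = 0.05
) -> dict:
    """Agreement of Welch and permutation rejection decisions on fixtures
    calibrated to be clearly null or clearly structured (forced pairing of
    alleles from two divergent clusters)."""
    from .dikaryon import similarity_matrix

    rng = np.random.default_rng(seed)
    agree = 0
    bases = np.array(list("ACGT"))
    for rep in range(n_fixtures):
        if rep % 2 == 0:
            aln, pairs, table = _random_allele_world(rng)
        else:
            # strong signal: every isolate pairs one allele from each cluster
            length = 150
            a = rng.integers(0, 4, size=length)
            b = a.copy()
            half = length // 2
            b[half:] = (b[half:] + rng.integers(1, 4, size=length - half)) % 4
            members, rows, pairs = [], [], []
            import pandas as pd

            for i in range(10):
                for j, tmpl in enumerate((a, b)):
                    s = tmpl.copy()
                    hit = rng.random(length) < 0.01
                    s[hit] = (s[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
                    aid = f"I{i}.a{j + 1}"
                    members.append(
                        AlignedSequence(aid, "".join(bases[s]), isolate_id=f"I{i}")
                    )
                    rows.append(
                        {"allele_id": aid, "isolate_id": f"I{i}", "group": "g"}
                    )
                pairs.append(AllelePair(f"I{i}", (f"I{i}.a1", f"I{i}.a2"), "g"))
            aln, table = Alignment("marker", members), pd.DataFrame(rows)
        m = similarity_matrix(aln)
        within, across = _within_across(m, pairs, table)
        _, _, p_w = welch_t_test(within, across)
        p_p = permutation_test(m, pairs, table, n_perm=n_perm,
                               seed=int(rng.integers(2**31 - 1)))
        agree += (p_w < alpha) == (p_p < alpha)
    return {"n_fixtures": n_fixtures, "agreement": agree / n_fixtures}


# ---------------------------------------------------------------------------
# Simulator headline pattern
# ---------------------------------------------------------------------------

#: study conditions for the headline-pattern experiment: equal founder
#: divergence at all loci (so any marker/neutral contrast is caused by the
#: mating-compatibility mechanism) and a severe founder bottleneck.
HEADLINE_CONFIG = dict(
    N=200,
    generations=150,
    L_marker=810,
    L_neutral=500,
    n_neutral_loci=3,
    founder_divergence=0.05,
    founder_divergence_neutral=0.05,
    bottleneck=(80, 8, 12),
    sample_n_dikaryons=30,
)


def simulator_headline(seed: int, reps: int = 100) -> dict:
    """The simulator's reproduction of the study's central claims: marker
    diversity elevated relative to neutral loci through a bottleneck, and
    within-dikaryon marker divergence exceeding the across-isolate
    background when few MAT alleles survive."""
    from scipy import stats

    from .simulate import SimulationError

    rng = np.random.default_rng(seed)
    ratios, elevations, k_sampled = [], [], []
    n_extinct = 0
    for _ in range(reps):
        cfg = SimConfig(seed=int(rng.integers(2**31 - 1)), **HEADLINE_CONFIG)
        try:
            s = summarize_truth(simulate(cfg))["groups"]["founder"]
        except SimulationError:
            # the founder population can lose all MAT diversity in a severe
            # bottleneck; such runs halt by design and are counted here
            n_extinct += 1
            continue
        ratios.append(s["pi_ratio"])
        elevations.append(
            s["within_dikaryon_divergence"] - s["across_isolate_divergence"]
        )
        k_sampled.append(s["mat_alleles_sampled"])
    ratios = np.array(ratios)
    elevations = np.array(elevations)
    k_sampled = np.array(k_sampled)
    few = k_sampled <= 4
    if few.sum() >= 3:
        t_res = stats.ttest_1samp(elevations[few], 0.0, alternative="greater")
        elev_p = float(t_res.pvalue)
    else:
        elev_p = float("nan")
    return {
        "reps": reps,
        "n_extinct": n_extinct,
        "mean_pi_ratio": float(ratios.mean()),
        "frac_ratio_gt_1": float((ratios > 1).mean()),
        "n_reps_mat_le_4": int(few.sum()),
        "mean_within_minus_across_when_mat_le_4": float(elevations[few].mean())
        if few.any()
        else float("nan"),
        "within_divergence_elevation_p": elev_p,
        "mean_mat_alleles_sampled": float(k_sampled.mean()),
    }
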