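"""Within-dikaryon allele-divergence test.

A dikaryotic isolate carries two nuclei, hence up to two alleles of the
mating-type-linked marker. When few compatible mating types circulate in
a founder population, successful matings over-sample divergent allele
pairs, so the two alleles found *within* individuals should be less
similar than allele pairs drawn *across* individuals of the same group.

The test compares the mean pairwise similarity of within-individual
allele pairs against across-individual pairs with a two-sample unequal
variance (Welch) t test, plus a permutation test that re-pairs alleles
into pseudo-isolates as a distribution-free safeguard (across-pair values
share alleles and are not independent, which the t test ignores).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment, pairwise_identity


class DikaryonTestError(ValueError):
    pass


@dataclass
class AllelePair:
    """The two marker alleles recovered from one dikaryotic isolate."""

    isolate_id: str
    allele_ids: tuple[str, str]
    group: str = ""

    def __post_init__(self) -> None:
        if len(set(self.allele_ids)) != 2:
            raise DikaryonTestError(
                f"{self.isolate_id}: allele ids must be two distinct ids"
            )


@dataclass
class DivergenceTestResult:
    group: str
    n_within: int
    n_across: int
    mean_within_similarity: float
    mean_across_similarity: float
    t_statistic: float | None
    df: float | None
    p_value: float | None
    p_permutation: float | None = None
    method: str = "welch_t"


def similarity_matrix(alleles: Alignment) -> pd.DataFrame:
    """Symmetric pairwise-identity matrix (pairwise deletion), diagonal 1."""
    if alleles.n < 2:
        raise DikaryonTestError("need >= 2 alleles")
    ids = alleles.ids()
    m = np.eye(alleles.n)
    for i, j in combinations(range(alleles.n), 2):
        ident, _ = pairwise_identity(alleles.members[i], alleles.members[j])
        m[i, j] = m[j, i] = np.nan if ident is None else ident
    return pd.DataFrame(m, index=ids, columns=ids)


def within_across_split(
    matrix: pd.DataFrame,
    pairs: list[AllelePair],
    allele_table: pd.DataFrame,
    group: str | None = None,
    include_singletons: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Similarity values for within-individual vs across-individual pairs.

    ``allele_table`` maps every allele to its isolate and group (columns
    allele_id, isolate_id, group), including alleles from isolates that
    yielded only one allele; those join only the across set (switch off
    with ``include_singletons=False``). Across pairs span different
    isolates of the requested group; the two alleles of one isolate never
    enter the across set.
    """
    tab = allele_table
    if group is not None:
        tab = tab[tab["group"] == group]
        pairs = [p for p in pairs if p.group == group]
    if not pairs:
        raise DikaryonTestError(f"group {group!r}: no within-individual pairs")
    if not include_singletons:
        paired_isolates = {p.isolate_id for p in pairs}
        tab = tab[tab["isolate_id"].isin(paired_isolates)]
    for p in pairs:
        for a in p.allele_ids:
            if a not in matrix.index:
                raise DikaryonTestError(f"allele {a} missing from similarity matrix")
    within = np.array([matrix.loc[p.allele_ids[0], p.allele_ids[1]] for p in pairs])
    alleles = list(tab["allele_id"])
    isolate_of = dict(zip(tab["allele_id"], tab["isolate_id"]))
    across = [
        matrix.loc[a, b]
        for a, b in combinations(alleles, 2)
        if isolate_of[a] != isolate_of[b]
    ]
    return within, np.asarray(across, float)


def welch_t_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float | None, float | None, float | None]:
    """Two-sample unequal-variance t test; returns (t, df, p).

    t = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y) with
    Welch-Satterthwaite degrees of freedom. Undefined (None) when both
    samples have zero variance and equal means.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise DikaryonTestError("both samples need >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / len(x) + vy / len(y)
    if se2 == 0:
        if x.mean() == y.mean():
            return None, None, None
        raise DikaryonTestError("zero variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    if alternative == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), float(df), float(p)


def permutation_test(
    matrix: pd.DataFrame,
    pairs: list[AllelePair],
    allele_table: pd.DataFrame,
    group: str | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    include_singletons: bool = True,
) -> float:
    """Re-pairing permutation test.

    The null re-partitions the group's allele pool into random
    pseudo-isolates, preserving the number of two-allele isolates; the
    statistic is |mean_within - mean_across|. p is the fraction of
    permuted statistics at or above the observed one (observed included
    in the numerator and denominator).
    """
    if n_perm < 1:
        raise DikaryonTestError("n_perm must be >= 1")
    tab = allele_table
    if group is not None:
        tab = tab[tab["group"] == group]
        pairs = [p for p in pairs if p.group == group]
    if not include_singletons:
        paired_isolates = {p.isolate_id for p in pairs}
        tab = tab[tab["isolate_id"].isin(paired_isolates)]
    alleles = list(tab["allele_id"])
    isolate_of = dict(zip(tab["allele_id"], tab["isolate_id"]))
    idx = {a: i for i, a in enumerate(alleles)}
    sub = matrix.loc[alleles, alleles].to_numpy()
    iu = np.triu_indices(len(alleles), k=1)
    all_vals = sub[iu]
    total_sum = float(np.nansum(all_vals))
    total_pairs = int(np.sum(~np.isnan(all_vals)))
    k = len(pairs)

    def stat(within_vals: np.ndarray) -> float:
        s_within = float(np.nansum(within_vals))
        n_within = int(np.sum(~np.isnan(within_vals)))
        n_across = total_pairs - n_within
        if n_within == 0 or n_across == 0:
            return 0.0
        mean_w = s_within / n_within
        mean_a = (total_sum - s_within) / n_across
        return abs(mean_w - mean_a)

    obs_within = np.array(
        [sub[idx[p.allele_ids[0]], idx[p.allele_ids[1]]] for p in pairs]
    )
    observed = stat(obs_within)
    rng = np.random.default_rng(seed)
    n_ge = 0
    order = np.arange(len(alleles))
    for _ in range(n_perm):
        rng.shuffle(order)
        w = sub[order[0 : 2 * k : 2], order[1 : 2 * k : 2]]
        if stat(w) >= observed - 1e-12:
            n_ge += 1
    return (n_ge + 1) / (n_perm + 1)


def run_group_tests(
    matrix: pd.DataFrame,
    pairs: list[AllelePair],
    allele_table: pd.DataFrame,
    groups: list[str],
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
    include_singletons: bool = True,
) -> pd.DataFrame:
    """One divergence test per requested group (Welch + permutation).

    Direction convention: alleles more divergent within individuals means
    mean_within_similarity < mean_across_similarity, i.e. t < 0 under the
    (within - across) ordering.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for g in groups:
        within, across = within_across_split(
            matrix, pairs, allele_table, group=g,
            include_singletons=include_singletons,
        )
        within = within[~np.isnan(within)]
        across = across[~np.isnan(across)]
        t, df, p = welch_t_test(within, across, alternative)
        p_perm = permutation_test(
            matrix, pairs, allele_table, group=g, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
            include_singletons=include_singletons,
        )
        rows.append(
            DivergenceTestResult(
                group=g,
                n_within=len(within),
                n_across=len(across),
                mean_within_similarity=float(within.mean()),
                mean_across_similarity=float(across.mean()),
                t_statistic=t,
                df=df,
                p_value=p,
                p_permutation=p_perm,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
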