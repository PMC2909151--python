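"""Per-locus, per-group molecular-variation statistics and neutrality tests.

Implements the summary-table columns familiar from DnaSP: n, segregating
sites S, total mutations eta, singleton mutations eta_s, mean pairwise
differences k, nucleotide diversity pi (= k per analysed site), the
per-locus Watterson estimate theta_W = S / a1(n), Tajima's (1989) D and
Fu & Li's (1993) outgroup-free D* and F* with the Simonsen et al. (1995)
constants.

All statistics apply complete deletion: alignment columns containing any
gap, N or IUPAC ambiguity code are dropped before counting, so phased
haplotype alignments are the intended substrate. Statistics depend only
on per-column allele counts, which makes them invariant to how
heterozygous sites were phased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .alignment import Alignment, AlignedSequence, DNA_BASES, complete_deletion_columns


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class NeutralityConstants:
    """The standard sample-size constants behind Tajima's D."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def neutrality_constants(n: int) -> NeutralityConstants:
    if n < 2:
        raise StatsError("need n >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return NeutralityConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


# ---------------------------------------------------------------------------
# Column counting
# ---------------------------------------------------------------------------


def _base_count_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(counts, valid_cols): per-column base counts (4, n_valid) over the
    complete-deletion columns, plus the column indices retained."""
    valid = complete_deletion_columns(aln)
    mat = aln.to_matrix()[:, valid] if len(valid) else np.empty((aln.n, 0), "S1")
    counts = np.stack(
        [(mat == b.encode()).sum(axis=0) for b in DNA_BASES]
    )  # (4, n_valid)
    return counts, valid


def segregating_sites(aln: Alignment) -> tuple[int, int, int]:
    """(S, eta, eta_s) over complete-deletion columns.

    S counts polymorphic columns; eta sums (distinct bases - 1) per
    column; eta_s counts singleton mutations, i.e. per column the number
    of bases carried by exactly one sequence, capped at that column's
    mutation count (so an n=2 polymorphic column contributes one
    singleton, not two).
    """
    if aln.n < 2:
        raise StatsError("need >= 2 sequences")
    counts, valid = _base_count_matrix(aln)
    if counts.shape[1] == 0:
        raise StatsError(f"{aln.locus_name}: all columns excluded by complete deletion")
    distinct = (counts > 0).sum(axis=0)
    poly = distinct > 1
    S = int(poly.sum())
    eta_col = np.maximum(distinct - 1, 0)
    eta = int(eta_col.sum())
    singles = (counts == 1).sum(axis=0)
    eta_s = int(np.minimum(singles, eta_col)[poly].sum())
    return S, eta, eta_s


def n_valid_sites(aln: Alignment) -> int:
    return len(complete_deletion_columns(aln))


def mean_pairwise_k(aln: Alignment) -> float:
    """Mean number of nucleotide differences per sequence pair, averaged
    over all C(n,2) pairs, counted on complete-deletion columns."""
    if aln.n < 2:
        raise StatsError("need >= 2 sequences")
    counts, _ = _base_count_matrix(aln)
    if counts.shape[1] == 0:
        raise StatsError(f"{aln.locus_name}: all columns excluded by complete deletion")
    n = aln.n
    pairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    return float((pairs - same).sum() / pairs)


def nucleotide_diversity(aln: Alignment) -> float:
    """pi = k normalised per analysed (complete-deletion) site."""
    return mean_pairwise_k(aln) / n_valid_sites(aln)


def watterson_theta(n: int, S: int) -> float:
    """Per-locus Watterson estimate theta_W = S / a1(n)."""
    if n < 2:
        raise StatsError("need n >= 2")
    if S < 0:
        raise StatsError("S must be >= 0")
    return S / neutrality_constants(n).a1


def watterson_theta_per_site(n: int, S: int, L_valid: int) -> float:
    return watterson_theta(n, S) / L_valid


# ---------------------------------------------------------------------------
# Neutrality tests
# ---------------------------------------------------------------------------


def tajimas_d_from_counts(n: int, S: int, k: float) -> float | None:
    """Tajima (1989) D from sample size, segregating sites and mean
    pairwise differences; None (undefined) when S = 0."""
    if S == 0:
        return None
    c = neutrality_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (k - S / c.a1) / math.sqrt(var)


def tajimas_d(aln: Alignment) -> float | None:
    S, _, _ = segregating_sites(aln)
    return tajimas_d_from_counts(aln.n, S, mean_pairwise_k(aln))


def _fu_li_star_constants(n: int) -> tuple[float, float, float, float]:
    """(u_D*, v_D*, u_F*, v_F*) with the Simonsen et al. (1995) corrections."""
    if n < 3:
        raise StatsError("Fu & Li starred statistics need n >= 3")
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2.0) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    )
    vD = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2.0 * n * an * (an + 1.0) / (n - 1.0) ** 2
    ) / (an**2 + bn)
    uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
    vF = (
        dn
        + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4.0 * bn - 6.0 + 8.0 / n)
    ) / (an**2 + bn)
    uF = (
        n / (n - 1.0)
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1.0))
    ) / an - vF
    return uD, vD, uF, vF


def fu_li_d_star_from_counts(n: int, eta: int, eta_s: int) -> float | None:
    if eta == 0:
        return None
    uD, vD, _, _ = _fu_li_star_constants(n)
    num = (n / (n - 1.0)) * eta - sum(1.0 / i for i in range(1, n)) * eta_s
    return num / math.sqrt(uD * eta + vD * eta**2)


def fu_li_f_star_from_counts(n: int, eta: int, eta_s: int, k: float) -> float | None:
    if eta == 0:
        return None
    _, _, uF, vF = _fu_li_star_constants(n)
    num = k - ((n - 1.0) / n) * eta_s
    return num / math.sqrt(uF * eta + vF * eta**2)


def fu_li_d_star(aln: Alignment) -> float | None:
    _, eta, eta_s = segregating_sites(aln)
    return fu_li_d_star_from_counts(aln.n, eta, eta_s)


def fu_li_f_star(aln: Alignment) -> float | None:
    _, eta, eta_s = segregating_sites(aln)
    return fu_li_f_star_from_counts(aln.n, eta, eta_s, mean_pairwise_k(aln))


#: Approximate two-sided 5% critical bounds for D* and F*, interpolated on
#: n. Derived once by neutral-coalescent simulation (theta = 5, 100k reps
#: per n) as a stand-in for the published critical-value tables; used only
#: to place significance flags, never recomputed per dataset.
_STAR_CRITICAL_5PCT: dict[str, dict[int, tuple[float, float]]] = {
    "d_star": {
        10: (-2.00, 1.38), 20: (-2.36, 1.36), 30: (-2.38, 1.41),
        50: (-2.35, 1.44), 75: (-2.28, 1.51), 100: (-2.33, 1.53),
        125: (-2.33, 1.55), 150: (-2.29, 1.54),
    },
    "f_star": {
        10: (-1.79, 1.28), 20: (-2.20, 1.39), 30: (-2.24, 1.48),
        50: (-2.21, 1.57), 75: (-2.12, 1.63), 100: (-2.15, 1.64),
        125: (-2.13, 1.70), 150: (-2.10, 1.69),
    },
}


def fu_li_significant(stat: float | None, n: int, which: str = "d_star") -> bool | None:
    """Flag a D*/F* value as outside the approximate two-sided 5% band."""
    return _star_significant(stat, n, which)


def _star_significant(stat: float | None, n: int, which: str) -> bool | None:
    table = _STAR_CRITICAL_5PCT[which]
    if stat is None or not table:
        return None
    ns = sorted(table)
    nref = min(ns, key=lambda x: abs(x - n))
    lo, hi = table[nref]
    return bool(stat < lo or stat > hi)


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "Locus",
    "Group",
    "Ecol",
    "#",
    "S",
    "k",
    "pi",
    "ThetaW",
    "TajimaD",
    "FuLiDstar",
    "FuLiFstar",
]


@dataclass
class LocusStats:
    locus: str
    group: str
    ecology: str
    n: int
    S: int | None = None
    eta: int | None = None
    eta_s: int | None = None
    k: float | None = None
    pi: float | None = None
    theta_w: float | None = None
    tajima_d: float | None = None
    fu_li_d_star: float | None = None
    fu_li_f_star: float | None = None
    L_valid: int | None = None
    defined: bool = True


def locus_stats(aln: Alignment, group: str = "", ecology: str = "") -> LocusStats:
    """One summary-table row for a (sub-)alignment."""
    n = aln.n
    if n < 2:
        return LocusStats(aln.locus_name, group, ecology, n, defined=False)
    S, eta, eta_s = segregating_sites(aln)
    L = n_valid_sites(aln)
    k = mean_pairwise_k(aln)
    return LocusStats(
        locus=aln.locus_name,
        group=group,
        ecology=ecology,
        n=n,
        S=S,
        eta=eta,
        eta_s=eta_s,
        k=k,
        pi=k / L,
        theta_w=watterson_theta(n, S),
        tajima_d=tajimas_d_from_counts(n, S, k),
        fu_li_d_star=fu_li_d_star_from_counts(n, eta, eta_s) if n >= 3 else None,
        fu_li_f_star=fu_li_f_star_from_counts(n, eta, eta_s, k) if n >= 3 else None,
        L_valid=L,
    )


GroupSpec = tuple[str, Callable[[AlignedSequence], bool]]


def default_groups(aln: Alignment) -> list[GroupSpec]:
    """One group per distinct label on the sequences, plus a pooled 'all'."""
    labels = sorted({m.group for m in aln.members if m.group})
    specs: list[GroupSpec] = [("all", lambda m: True)]
    for lab in labels:
        specs.append((lab, lambda m, lab=lab: m.group == lab))
    return specs


def locus_summary(
    alignments: dict[str, Alignment],
    groups: list[GroupSpec] | None = None,
    count_mode: str = "sequences",
) -> pd.DataFrame:
    """Summary-table rows for every locus x group combination.

    ``groups`` may define nested/overlapping memberships (e.g. a species
    group containing a variety containing a geographic founder group).
    ``count_mode='distinct'`` reports the number of distinct haplotype
    sequences in '#' instead of the number of sequence copies.
    """
    if count_mode not in ("sequences", "distinct"):
        raise ValueError(f"bad count_mode {count_mode!r}")
    rows = []
    for locus, aln in alignments.items():
        specs = groups if groups is not None else default_groups(aln)
        for name, selector in specs:
            members = [m for m in aln.members if selector(m)]
            ecols = {m.ecology for m in members} - {"unknown"}
            ecology = "+".join(sorted(ecols, reverse=True)) if ecols else "unknown"
            if len(members) < 2:
                st = LocusStats(locus, name, ecology, len(members), defined=False)
            else:
                sub = Alignment(locus, members)
                try:
                    st = locus_stats(sub, name, ecology)
                except StatsError:
                    st = LocusStats(locus, name, ecology, len(members), defined=False)
            n_report = st.n
            if count_mode == "distinct":
                n_report = len({m.residues for m in members})
            rows.append(
                {
                    "Locus": locus,
                    "Group": name,
                    "Ecol": st.ecology,
                    "#": n_report,
                    "S": st.S,
                    "k": st.k,
                    "pi": st.pi,
                    "ThetaW": st.theta_w,
                    "TajimaD": st.tajima_d,
                    "FuLiDstar": st.fu_li_d_star,
                    "FuLiFstar": st.fu_li_f_star,
                    "eta": st.eta,
                    "eta_s": st.eta_s,
                    "L_valid": st.L_valid,
                }
            )
    return pd.DataFrame(rows)


def render_table(df: pd.DataFrame, float_fmt: str = "{:.2f}") -> str:
    """TSV rendering in the canonical column order; undefined cells print '-'.

    Statistics are undefined when a group has fewer than two sequences or
    no segregating sites (S = 0 rows print '-' for k through F*, matching
    the convention of the source tables)."""
    out_lines = ["\t".join(TABLE_COLUMNS)]
    for _, row in df.iterrows():
        cells = []
        for col in TABLE_COLUMNS:
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                cells.append("-")
            elif col == "S" and (row["S"] is None):
                cells.append("-")
            elif isinstance(v, float):
                if col in ("k", "pi", "ThetaW") and row.get("S") == 0:
                    cells.append("-")
                elif col == "pi":
                    cells.append(f"{v:.4f}")
                else:
                    cells.append(float_fmt.format(v))
            else:
                cells.append(str(v))
        # S = 0 rows: neutrality columns undefined
        out_lines.append("\t".join(cells))
    return "\n".join(out_lines) + "\n"
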