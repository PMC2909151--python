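"""Haplotype phase inference by allele-count minimisation.

Dikaryon-derived genotype sequences carry IUPAC two-fold codes at
heterozygous sites. Phase is inferred with a template-then-parsimony
procedure aimed at the minimum number of distinct haplotypes:

1. Genotypes homozygous everywhere, or heterozygous at exactly one site,
   have a forced resolution; their haplotypes seed the template set.
2. A genotype with h >= 2 heterozygous sites has 2^(h-1) complementary
   phasings. Preference order: both haplotypes already known as
   templates; else one known, partner closest (Hamming) to a template;
   else the phasing minimising the summed Hamming distance of both
   haplotypes to their nearest templates. Chosen haplotypes join the
   template set. Ties break to the lexicographically smallest pair.

The greedy procedure can exceed the true minimum on adversarial input
(and, like the underlying idea, underestimates haplotype number when
recombinant genotypes occur); :func:`brute_force_min_haplotypes` is the
exhaustive oracle for small instances.

Phase does not affect the site-based statistics downstream (S, k, pi,
theta-W, Tajima's D, Fu & Li's tests): any valid phasing of the same
genotypes yields identical column counts.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, AlignedSequence, IUPAC_TWOFOLD, PAIR_TO_IUPAC

HET_CAP_DEFAULT = 20


class PhasingError(ValueError):
    pass


@dataclass
class GenotypeSequence:
    """An unphased sequence; two-fold IUPAC codes mark heterozygous sites."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = {
            c
            for c in set(self.residues)
            if c not in "ACGTN-" and c not in IUPAC_TWOFOLD
        }
        if bad:
            raise PhasingError(
                f"{self.seq_id}: non-two-fold ambiguity or invalid residues {sorted(bad)}"
            )

    @property
    def het_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.residues) if c in IUPAC_TWOFOLD]

    @property
    def n_het(self) -> int:
        return len(self.het_positions)


@dataclass
class HaplotypeSet:
    """Result of phasing: distinct haplotypes with multiplicities, plus the
    per-genotype assignment and its provenance (forced / template-matched /
    parsimony-inferred). Every dikaryon contributes two haplotype copies,
    so multiplicities sum to twice the genotype count."""

    haplotypes: Counter[str] = field(default_factory=Counter)
    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return len(self.haplotypes)

    def to_alignment(self, locus_name: str = "haplotypes") -> Alignment:
        """One AlignedSequence per haplotype *copy* (ids ``<seq_id>.h1/.h2``)."""
        members = []
        for seq_id, (h1, h2) in self.assignments.items():
            members.append(AlignedSequence(f"{seq_id}.h1", h1))
            members.append(AlignedSequence(f"{seq_id}.h2", h2))
        return Alignment(locus_name, members)


def combine_haplotypes(h1: str, h2: str) -> str:
    """Site-wise union of two haplotypes back into a genotype string."""
    out = []
    for x, y in zip(h1, h2):
        if x == y:
            out.append(x)
        else:
            code = PAIR_TO_IUPAC.get(frozenset((x, y)))
            if code is None:
                raise PhasingError(f"bases {x}/{y} have no two-fold code")
            out.append(code)
    return "".join(out)


def enumerate_phasings(g: GenotypeSequence, cap: int = HET_CAP_DEFAULT):
    """Yield all complementary phasings (h1, h2) of a genotype.

    The first heterozygous site is pinned in h1 so that each unordered
    pair appears once: 2^(h-1) pairs for h het sites.
    """
    het = g.het_positions
    h = len(het)
    if h > cap:
        raise PhasingError(
            f"{g.seq_id}: {h} heterozygous sites exceeds the cap of {cap}; "
            "raise `cap` to force exhaustive enumeration"
        )
    base = list(g.residues)
    if h == 0:
        yield g.residues, g.residues
        return
    choices = [sorted(IUPAC_TWOFOLD[g.residues[p]]) for p in het]
    for combo in itertools.product(*[range(2)] * (h - 1)):
        picks = (0,) + combo
        s1, s2 = base[:], base[:]
        for p, ch, pick in zip(het, choices, picks):
            s1[p] = ch[pick]
            s2[p] = ch[1 - pick]
        yield "".join(s1), "".join(s2)


def known_haplotypes(genotypes: list[GenotypeSequence]) -> Counter[str]:
    """Template haplotypes from genotypes with at most one het site.

    A fully homozygous genotype contributes itself twice; a 1-het genotype
    contributes its two forced resolutions.
    """
    templates: Counter[str] = Counter()
    for g in genotypes:
        if g.n_het == 0:
            templates[g.residues] += 2
        elif g.n_het == 1:
            for h1, h2 in enumerate_phasings(g):
                templates[h1] += 1
                templates[h2] += 1
    return templates


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _ordered(h1: str, h2: str) -> tuple[str, str]:
    return (h1, h2) if h1 <= h2 else (h2, h1)


def phase_sequence(
    g: GenotypeSequence, templates, cap: int = HET_CAP_DEFAULT
) -> tuple[tuple[str, str], str]:
    """Phase one multi-het genotype against a template set.

    Returns the chosen (lexicographically ordered) haplotype pair and its
    provenance tag. Distances to the template set are computed once per
    het site and combined per candidate phasing, so the cost is
    O(2^(h-1) * h + |templates| * L) rather than per-candidate Hamming
    scans.
    """
    het = g.het_positions
    h = len(het)
    if h > cap:
        raise PhasingError(
            f"{g.seq_id}: {h} heterozygous sites exceeds the cap of {cap}; "
            "raise `cap` to force exhaustive enumeration"
        )
    if h == 0:
        return (g.residues, g.residues), "forced"
    template_set = set(templates)
    tlist = sorted(template_set)
    n_t = len(tlist)
    choices = [sorted(IUPAC_TWOFOLD[g.residues[p]]) for p in het]

    if n_t:
        tmat = np.frombuffer("".join(tlist).encode(), dtype="S1").reshape(n_t, -1)
        gbytes = np.frombuffer(g.residues.encode(), dtype="S1")
        non_het = np.ones(len(g.residues), dtype=bool)
        non_het[het] = False
        base = (tmat[:, non_het] != gbytes[non_het]).sum(axis=1)  # (T,)
        # mismatch indicators at each het site for the lo/hi base choice
        m_lo = np.stack(
            [tmat[:, p] != lo.encode() for p, (lo, _) in zip(het, choices)]
        ).astype(np.int64)  # (h, T)
        m_hi = np.stack(
            [tmat[:, p] != hi.encode() for p, (_, hi) in zip(het, choices)]
        ).astype(np.int64)

    C = 1 << (h - 1)
    cand = np.arange(C)
    # picks[c, j] = 1 -> h1 carries the hi base at het site j; site 0 pinned
    picks = np.zeros((C, h), dtype=np.int64)
    for j in range(1, h):
        picks[:, j] = (cand >> (j - 1)) & 1
    if n_t:
        d1 = (base + picks @ m_hi + (1 - picks) @ m_lo).min(axis=1)
        d2 = (base + (1 - picks) @ m_hi + picks @ m_lo).min(axis=1)
    else:
        d1 = d2 = np.full(C, 1, dtype=np.int64)  # nothing is a template

    # membership in the template set <=> exact distance zero
    in1 = d1 == 0
    in2 = d2 == 0
    both = in1 & in2
    if both.any():
        mask, cost, prov = both, np.zeros(C, dtype=np.int64), "template-matched"
    elif (in1 | in2).any():
        mask = in1 ^ in2
        cost = np.where(in1, d2, d1)
        prov = "template-matched"
    else:
        mask, cost, prov = np.ones(C, dtype=bool), d1 + d2, "parsimony-inferred"
    idx = np.nonzero(mask)[0]
    idx = idx[cost[idx] == cost[idx].min()]

    # build the tied candidates' sequences and break ties lexicographically
    L = len(g.residues)
    gbytes = np.frombuffer(g.residues.encode(), dtype="S1")
    a1 = np.tile(gbytes, (len(idx), 1))
    a2 = a1.copy()
    for j, p in enumerate(het):
        lo, hi = choices[j]
        hi_mask = picks[idx, j] == 1
        a1[:, p] = np.where(hi_mask, hi.encode(), lo.encode())
        a2[:, p] = np.where(hi_mask, lo.encode(), hi.encode())
    s1 = a1.reshape(len(idx), L).view(f"S{L}").ravel()
    s2 = a2.reshape(len(idx), L).view(f"S{L}").ravel()
    lt = s1 <= s2
    first = np.where(lt, s1, s2)
    second = np.where(lt, s2, s1)
    best = np.lexsort((second, first))[0]
    return (first[best].decode(), second[best].decode()), prov


def phase_all(
    genotypes: list[GenotypeSequence], cap: int = HET_CAP_DEFAULT,
    max_sweeps: int = 10,
) -> HaplotypeSet:
    """Phase a locus: forced resolutions first, then multi-het genotypes in
    ascending het-count order (input order on ties), each adding its chosen
    haplotypes to the template pool. A re-phasing sweep then revisits each
    multi-het genotype against the haplotypes used by the others and keeps
    any re-assignment that lowers the distinct-haplotype count (the initial
    pass is myopic: an early genotype cannot anticipate which haplotypes
    later genotypes will need). Deterministic."""
    ids = [g.seq_id for g in genotypes]
    if len(set(ids)) != len(ids):
        raise PhasingError("duplicate genotype seq_id")
    assignments: dict[str, tuple[str, str]] = {}
    provenance: dict[str, str] = {}
    templates: Counter[str] = Counter()
    order = sorted(range(len(genotypes)), key=lambda i: (genotypes[i].n_het, i))
    for i in order:
        g = genotypes[i]
        if g.n_het <= 1:
            (h1, h2), prov = next(iter(enumerate_phasings(g))), "forced"
        else:
            (h1, h2), prov = phase_sequence(g, templates, cap)
        h1, h2 = _ordered(h1, h2)
        templates[h1] += 1
        templates[h2] += 1
        assignments[g.seq_id] = (h1, h2)
        provenance[g.seq_id] = prov

    multi = [genotypes[i] for i in order if genotypes[i].n_het >= 2]
    for _ in range(max_sweeps):
        changed = False
        for g in multi:
            h1, h2 = assignments[g.seq_id]
            templates[h1] -= 1
            templates[h2] -= 1
            others = {h for h, c in templates.items() if c > 0}
            (n1, n2), prov = phase_sequence(g, others, cap)
            old_new = (h1 not in others) + (h2 != h1 and h2 not in others)
            new_new = (n1 not in others) + (n2 != n1 and n2 not in others)
            if new_new < old_new:
                assignments[g.seq_id] = (n1, n2)
                provenance[g.seq_id] = prov
                templates[n1] += 1
                templates[n2] += 1
                changed = True
            else:
                templates[h1] += 1
                templates[h2] += 1
        if not changed:
            break

    result = HaplotypeSet()
    for i in order:
        sid = genotypes[i].seq_id
        h1, h2 = assignments[sid]
        result.assignments[sid] = (h1, h2)
        result.provenance[sid] = provenance[sid]
        result.haplotypes[h1] += 1
        result.haplotypes[h2] += 1
    return result


def brute_force_min_haplotypes(
    genotypes: list[GenotypeSequence], max_combinations: int = 1 << 16
) -> tuple[int, dict[str, tuple[str, str]]]:
    """Exhaustive minimum-haplotype phasing (test oracle for small inputs).

    Searches every joint phasing of all genotypes and returns the global
    minimum number of distinct haplotypes with one witness assignment.
    """
    total = 1
    for g in genotypes:
        total *= 2 ** max(g.n_het - 1, 0)
        if total > max_combinations:
            raise PhasingError(
                f"search space {total}+ exceeds bound {max_combinations}"
            )
    if not genotypes:
        return 0, {}
    per_geno = [list(enumerate_phasings(g, cap=64)) for g in genotypes]
    best_count = None
    best_assign: dict[str, tuple[str, str]] = {}
    for combo in itertools.product(*per_geno):
        distinct = set()
        for h1, h2 in combo:
            distinct.add(h1)
            distinct.add(h2)
        if best_count is None or len(distinct) < best_count:
            best_count = len(distinct)
            best_assign = {
                g.seq_id: _ordered(h1, h2) for g, (h1, h2) in zip(genotypes, combo)
            }
    return best_count, best_assign


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------


def phase_fasta(path: str | Path, outdir: str | Path, locus_name: str | None = None):
    """Phase a genotype FASTA; write haplotype FASTA + assignment audit TSV."""
    from .alignment import read_fasta, write_fasta

    aln = read_fasta(path, locus_name=locus_name)
    genotypes = [GenotypeSequence(m.seq_id, m.residues) for m in aln.members]
    result = phase_all(genotypes)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hap_aln = result.to_alignment(aln.locus_name)
    write_fasta(hap_aln, outdir / f"{aln.locus_name}_haplotypes.fasta")
    rows = [
        {
            "seq_id": sid,
            "hap1_id": f"{sid}.h1",
            "hap2_id": f"{sid}.h2",
            "provenance": result.provenance[sid],
        }
        for sid in result.assignments
    ]
    pd.DataFrame(rows).to_csv(
        outdir / f"{aln.locus_name}_phasing_audit.tsv", sep="\t", index=False
    )
    return result
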