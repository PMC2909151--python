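"""Clone-based allele calling for dikaryotic isolates.

A dikaryon carries up to two nuclei, so PCR products from a single-copy
locus are a mixture of 1-4 allele sequences (more than two indicates
multikaryons or paralogues). Cloning separates the mixture but introduces
in-vitro errors, filtered here with three rules keyed on the number of
cloned copies per allele group:

* ``m >= 3`` clones: per-column majority consensus; a variant carried by
  exactly one clone ("autapomorphic") is treated as a PCR artifact and
  discarded, with the column recorded.
* ``m == 2`` clones: the isolate is assumed heterozygous at columns where
  the two copies differ; those columns receive the IUPAC two-fold code.
* ``m == 1`` clone: the sequence is accepted verbatim.

Clones are first partitioned into allele groups by single-linkage
clustering at a divergence threshold (default 2%), well below the 5-6%
between-allele divergence typical of the mating-type-linked marker and
well above per-clone PCR error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import (
    Alignment,
    AlignedSequence,
    PAIR_TO_IUPAC,
    DNA_BASES,
    pairwise_identity,
    read_fasta,
    write_fasta,
)


@dataclass
class CloneSet:
    """Cloned amplicon sequences from one isolate at one locus."""

    isolate_id: str
    clones: Alignment
    locus_name: str = ""

    def __post_init__(self) -> None:
        if not self.locus_name:
            self.locus_name = self.clones.locus_name


@dataclass
class AlleleCall:
    allele_seq: AlignedSequence
    support: int
    discarded_singleton_positions: list[int] = field(default_factory=list)
    ambiguity_positions: list[int] = field(default_factory=list)
    tie_positions: list[int] = field(default_factory=list)
    rule_applied: str = "majority-consensus"  # | two-copy-het | single-copy

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("allele support must be >= 1")
        if self.ambiguity_positions and self.rule_applied != "two-copy-het":
            raise ValueError("ambiguity positions only arise under the two-copy rule")


@dataclass
class AlleleCallSet:
    isolate_id: str
    calls: list[AlleleCall]

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValueError(f"{self.isolate_id}: no allele calls")

    @property
    def n_clusters(self) -> int:
        return len(self.calls)


def cluster_clones(cs: CloneSet, threshold: float = 0.02) -> list[list[int]]:
    """Partition clone indices into allele groups by single-linkage.

    Two clones join the same group when a chain of pairwise distances
    (1 - identity, pairwise deletion) of at most ``threshold`` connects
    them; this is the connected-components formulation of single linkage
    cut at the threshold. Groups are ordered by their lowest clone index.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    m = cs.clones.n
    if m == 0:
        raise ValueError(f"{cs.isolate_id}: empty clone set")
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members = cs.clones.members
    for i in range(m):
        for j in range(i + 1, m):
            ident, n_sites = pairwise_identity(members[i], members[j])
            if ident is None:
                continue
            if 1.0 - ident <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def consensus_call(group: Alignment) -> AlleleCall:
    """Collapse one allele group of clones into a single called allele."""
    m = group.n
    if m == 1:
        clone = group.members[0]
        return AlleleCall(
            allele_seq=AlignedSequence(clone.seq_id, clone.residues,
                                       isolate_id=clone.isolate_id),
            support=1,
            rule_applied="single-copy",
        )
    seqs = [c.residues for c in group.members]
    length = group.length
    if m == 2:
        out = []
        ambiguity_positions = []
        for j in range(length):
            x, y = seqs[0][j], seqs[1][j]
            if x == y:
                out.append(x)
            elif x in DNA_BASES and y in DNA_BASES:
                out.append(PAIR_TO_IUPAC[frozenset((x, y))])
                ambiguity_positions.append(j)
            else:
                # gap/N vs base: keep the informative base
                out.append(x if x in DNA_BASES else y)
        return AlleleCall(
            allele_seq=AlignedSequence(group.members[0].seq_id, "".join(out)),
            support=2,
            ambiguity_positions=ambiguity_positions,
            rule_applied="two-copy-het",
        )
    # m >= 3: majority consensus, singletons discarded
    out = []
    discarded = []
    ties = []
    for j in range(length):
        counts = Counter(s[j] for s in seqs)
        top = max(counts.values())
        best = sorted(c for c, k in counts.items() if k == top)
        if len(best) > 1:
            ties.append(j)  # e.g. 2-2 split at m=4; alphabetical tie-break
        out.append(best[0])
        if any(k == 1 for c, k in counts.items() if c != best[0]):
            discarded.append(j)
    return AlleleCall(
        allele_seq=AlignedSequence(group.members[0].seq_id, "".join(out)),
        support=m,
        discarded_singleton_positions=discarded,
        tie_positions=ties,
        rule_applied="majority-consensus",
    )


def call_alleles(cs: CloneSet, threshold: float = 0.02) -> AlleleCallSet:
    """Cluster the clones, run the consensus rules per group, and return
    the isolate's called alleles ordered by descending clone support then
    lexicographic sequence. Allele ids are ``<isolate>.a1``, ``.a2``, ...
    """
    groups = cluster_clones(cs, threshold)
    calls = []
    for idx in groups:
        sub = Alignment(cs.locus_name, [cs.clones.members[i] for i in idx])
        calls.append(consensus_call(sub))
    calls.sort(key=lambda c: (-c.support, c.allele_seq.residues))
    for rank, call in enumerate(calls, start=1):
        call.allele_seq.seq_id = f"{cs.isolate_id}.a{rank}"
        call.allele_seq.isolate_id = cs.isolate_id
    return AlleleCallSet(isolate_id=cs.isolate_id, calls=calls)


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------


def call_alleles_from_dir(
    clones_dir: str | Path, threshold: float = 0.02
) -> tuple[dict[str, Alignment], pd.DataFrame]:
    """Call alleles from a directory of ``<isolate>_<locus>.fasta`` clone files.

    Returns per-locus alignments of called alleles plus an audit table of
    discarded/ambiguous positions (one row per allele call).
    """
    clones_dir = Path(clones_dir)
    per_locus: dict[str, list[AlignedSequence]] = {}
    audit_rows = []
    for path in sorted(clones_dir.glob("*.fasta")):
        isolate_id, _, locus = path.stem.rpartition("_")
        if not isolate_id:
            raise ValueError(f"{path.name}: expected <isolate>_<locus>.fasta")
        cs = CloneSet(isolate_id, read_fasta(path, locus_name=locus), locus)
        result = call_alleles(cs, threshold)
        for call in result.calls:
            per_locus.setdefault(locus, []).append(call.allele_seq)
            audit_rows.append(
                {
                    "isolate_id": isolate_id,
                    "locus": locus,
                    "allele_id": call.allele_seq.seq_id,
                    "support": call.support,
                    "rule": call.rule_applied,
                    "discarded_singletons": ",".join(
                        str(p + 1) for p in call.discarded_singleton_positions
                    ),
                    "het_positions": ",".join(
                        str(p + 1) for p in call.ambiguity_positions
                    ),
                    "tie_positions": ",".join(str(p + 1) for p in call.tie_positions),
                }
            )
    alignments = {
        locus: Alignment(locus, members) for locus, members in per_locus.items()
    }
    return alignments, pd.DataFrame(audit_rows)


def write_allele_calls(
    alignments: dict[str, Alignment], audit: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, aln in alignments.items():
        write_fasta(aln, outdir / f"{locus}_alleles.fasta")
    audit.to_csv(outdir / "allele_call_audit.tsv", sep="\t", index=False)
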