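"""Sequence/alignment data model, FASTA and sample-sheet I/O, site
classification and pairwise distance primitives.

All downstream stages (clone calling, phasing, diversity statistics, the
HKA and dikaryon tests) consume :class:`Alignment` objects built here.

Conventions
-----------
* Column coordinates are 0-based half-open internally; report renderers
  print 1-based inclusive ranges.
* Two deletion modes are supported when scoring columns: *complete*
  deletion drops every column containing a gap, an ``N`` or an IUPAC
  ambiguity code in any sequence (the DnaSP default used for S, k, pi,
  theta-W and the neutrality tests), while *pairwise* deletion scores each
  sequence pair on the columns where both carry an unambiguous base (used
  for the identity matrix feeding the dikaryon test).
* IUPAC two-fold ambiguity codes (R, Y, S, W, K, M) mark unphased
  heterozygous sites in dikaryon-derived genotype sequences; they are
  treated as missing data by every statistic computed before phasing.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = "ACGT"

#: two-fold IUPAC ambiguity codes -> the unordered base pair they encode
IUPAC_TWOFOLD: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

#: unordered base pair -> IUPAC code
PAIR_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TWOFOLD.items()}

GAP_CHARS = frozenset("-")
MISSING_CHARS = frozenset("N")
VALID_RESIDUES = frozenset(DNA_BASES) | GAP_CHARS | MISSING_CHARS | frozenset(IUPAC_TWOFOLD)

SAMPLE_SHEET_COLUMNS = ["seq_id", "isolate_id", "locus", "group", "ecology"]


class AlignmentError(ValueError):
    """Raised when sequences cannot form a rectangular alignment."""


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be parsed or validated."""


@dataclass
class AlignedSequence:
    """One aligned sequence with its sample metadata.

    ``ecology`` follows the habitat coding used for dry-rot isolates:
    ``N`` (nature), ``B`` (building) or ``unknown``.
    """

    seq_id: str
    residues: str
    isolate_id: str = ""
    group: str = ""
    ecology: str = "unknown"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FastaParseError(
                f"record {self.seq_id!r}: invalid residues {sorted(bad)}"
            )
        if self.ecology not in ("N", "B", "unknown"):
            raise ValueError(f"record {self.seq_id!r}: bad ecology {self.ecology!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A rectangular multiple-sequence alignment for one locus."""

    locus_name: str
    members: list[AlignedSequence]

    def __post_init__(self) -> None:
        if not self.members:
            raise AlignmentError(f"{self.locus_name}: alignment needs >=1 sequence")
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            detail = ", ".join(f"{m.seq_id}:{len(m)}" for m in self.members[:5])
            raise AlignmentError(
                f"{self.locus_name}: unequal sequence lengths ({detail} ...)"
            )
        if len(self.members[0]) < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        ids = [m.seq_id for m in self.members]
        dupes = [s for s, c in Counter(ids).items() if c > 1]
        if dupes:
            raise FastaParseError(f"{self.locus_name}: duplicate seq_id {dupes}")

    @property
    def length(self) -> int:
        return len(self.members[0])

    @property
    def n(self) -> int:
        return len(self.members)

    def ids(self) -> list[str]:
        return [m.seq_id for m in self.members]

    def get(self, seq_id: str) -> AlignedSequence:
        for m in self.members:
            if m.seq_id == seq_id:
                return m
        raise KeyError(seq_id)

    def subset(self, seq_ids: Iterable[str]) -> "Alignment":
        wanted = list(seq_ids)
        index = {m.seq_id: m for m in self.members}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"{self.locus_name}: ids not in alignment: {missing}")
        return Alignment(self.locus_name, [index[s] for s in wanted])

    def to_matrix(self) -> np.ndarray:
        """Byte matrix (n, length) of the residues, dtype ``'S1'``."""
        return np.frombuffer(
            "".join(m.residues for m in self.members).encode(), dtype="S1"
        ).reshape(self.n, self.length)


@dataclass
class SiteClassification:
    column_index: int
    state: str  # monomorphic | biallelic | multiallelic
    has_gap: bool
    has_missing: bool
    has_ambiguity: bool
    allele_counts: dict[str, int] = field(default_factory=dict)
    excluded: bool = False  # under complete deletion


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the headered TSV mapping seq_id -> isolate, locus, group, ecology."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    if df["seq_id"].duplicated().any():
        dupes = df.loc[df["seq_id"].duplicated(), "seq_id"].tolist()
        raise ValueError(f"sample sheet {path}: duplicate seq_id {dupes}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SAMPLE_SHEET_COLUMNS)


def read_fasta(
    path: str | Path,
    sample_sheet: pd.DataFrame | None = None,
    locus_name: str | None = None,
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    If a sample sheet is given, every record id must appear in it and the
    isolate/group/ecology labels are attached to the sequences.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    labels: Mapping[str, pd.Series] = {}
    if sample_sheet is not None:
        labels = {row.seq_id: row for row in sample_sheet.itertuples()}
    members = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        kwargs = {}
        if sample_sheet is not None:
            if rec.id not in labels:
                raise FastaParseError(
                    f"{path}: record {rec.id!r} not present in the sample sheet"
                )
            row = labels[rec.id]
            kwargs = dict(
                isolate_id=row.isolate_id,
                group=row.group,
                ecology=row.ecology or "unknown",
            )
        members.append(AlignedSequence(rec.id, str(rec.seq), **kwargs))
    return Alignment(locus_name or path.stem, members)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write the alignment as FASTA, wrapped at ``wrap`` columns."""
    records = [
        SeqRecord(Seq(m.residues), id=m.seq_id, description="") for m in aln.members
    ]
    handle = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
    writer.write_file(records)
    Path(path).write_text(handle.getvalue())


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


def classify_sites(aln: Alignment, deletion: str = "complete") -> list[SiteClassification]:
    """Classify every alignment column.

    Under ``deletion='complete'`` a column containing any gap, ``N`` or
    ambiguity code is flagged ``excluded`` (it will not enter S, k, pi or
    the neutrality tests). Under ``'pairwise-none'`` no column is excluded;
    per-pair scoring is left to the distance primitives.
    """
    if deletion not in ("complete", "pairwise-none"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    mat = aln.to_matrix()
    out = []
    for j in range(aln.length):
        col = mat[:, j]
        counts: Counter[str] = Counter(col.tobytes().decode())
        has_gap = any(c in GAP_CHARS for c in counts)
        has_missing = any(c in MISSING_CHARS for c in counts)
        has_ambig = any(c in IUPAC_TWOFOLD for c in counts)
        base_counts = {b: c for b, c in counts.items() if b in DNA_BASES}
        n_alleles = len(base_counts)
        if n_alleles <= 1:
            state = "monomorphic"
        elif n_alleles == 2:
            state = "biallelic"
        else:
            state = "multiallelic"
        out.append(
            SiteClassification(
                column_index=j,
                state=state,
                has_gap=has_gap,
                has_missing=has_missing,
                has_ambiguity=has_ambig,
                allele_counts=dict(counts),
                excluded=(
                    deletion == "complete" and (has_gap or has_missing or has_ambig)
                ),
            )
        )
    return out


def complete_deletion_columns(aln: Alignment) -> np.ndarray:
    """Indices of columns where every sequence carries an unambiguous base."""
    mat = aln.to_matrix()
    ok = np.ones(aln.length, dtype=bool)
    for ch in GAP_CHARS | MISSING_CHARS | set(IUPAC_TWOFOLD):
        ok &= ~(mat == ch.encode()).any(axis=0)
    return np.nonzero(ok)[0]


# ---------------------------------------------------------------------------
# Pairwise primitives (pairwise deletion)
# ---------------------------------------------------------------------------


def _comparable_mask(a: str, b: str) -> np.ndarray:
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    good_a = np.isin(aa, [c.encode() for c in DNA_BASES])
    good_b = np.isin(bb, [c.encode() for c in DNA_BASES])
    return good_a & good_b


def pairwise_identity(a: AlignedSequence, b: AlignedSequence) -> tuple[float | None, int]:
    """Fraction of matching positions among pairwise-comparable sites.

    Positions where either sequence carries a gap, ``N`` or an ambiguity
    code are skipped (pairwise deletion); gap-vs-gap positions are not
    compared sites. Returns ``(None, 0)`` when no site is comparable.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"length mismatch: {a.seq_id} ({len(a)}) vs {b.seq_id} ({len(b)})"
        )
    mask = _comparable_mask(a.residues, b.residues)
    n = int(mask.sum())
    if n == 0:
        return None, 0
    aa = np.frombuffer(a.residues.encode(), dtype="S1")[mask]
    bb = np.frombuffer(b.residues.encode(), dtype="S1")[mask]
    return float((aa == bb).mean()), n


def pairwise_differences(a: AlignedSequence, b: AlignedSequence) -> tuple[int, int]:
    """Mismatch count over pairwise-comparable sites; returns (diffs, sites)."""
    if len(a) != len(b):
        raise AlignmentError(
            f"length mismatch: {a.seq_id} ({len(a)}) vs {b.seq_id} ({len(b)})"
        )
    mask = _comparable_mask(a.residues, b.residues)
    n = int(mask.sum())
    if n == 0:
        return 0, 0
    aa = np.frombuffer(a.residues.encode(), dtype="S1")[mask]
    bb = np.frombuffer(b.residues.encode(), dtype="S1")[mask]
    return int((aa != bb).sum()), n
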