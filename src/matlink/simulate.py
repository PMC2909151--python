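"""Forward simulator of a mating-type locus under rare-allele advantage
with a linked marker, generating every input the analysis pipeline reads.

Model
-----
Haploid Wright-Fisher individuals carry one MAT allele (infinite-alleles
label), one marker haplotype physically linked to MAT (recombination
fraction ``r`` per meiosis), and unlinked neutral-locus haplotypes. Each
offspring draws two parents; when MAT compatibility is enforced the
parents must carry different MAT alleles (rejection sampling), which is
the entire selection mechanism — rare MAT alleles are over-represented
among successful matings simply because they are compatible with more
partners. Mutation is finite-sites (random base change) at the sequence
loci and infinite-alleles at MAT. A founder bottleneck of configurable
onset, size and duration emulates the recent range expansion of the dry
rot fungus.

The founding population descends from ``K_init`` pre-diverged founder
lineages; founder haplotypes are built for every locus by the same
process (per-lineage substitutions at a configured divergence). Defaults
give the marker deeper founder divergence (5%) than the neutral loci
(1%), reflecting the long coalescence times balancing selection maintains
at a MAT-linked region versus ITS/tub/gpd-like loci. Setting the two
divergences equal and disabling MAT compatibility makes the marker
statistically exchangeable with a neutral locus — the no-selection
control of the whole study design. Marker haplotype i starts perfectly
associated with MAT allele i; neutral founder haplotypes are assigned
independently.

Sampling emulates the field study: dikaryons are formed by drawing
MAT-compatible pairs from the final generation, the marker is "cloned"
(several reads per isolate with per-base PCR error ``epsilon``, a
fraction of isolates yielding only one allele, as an amplification
failure caused by a structural insertion would), and neutral loci are
reported as IUPAC-coded genotype sequences.

Optionally the population can be split into two taxa (e.g. an aggressive
founder lineage and its natural sister variety) that then evolve
independently, which gives the HKA stage genuine two-taxon data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import Alignment, AlignedSequence, PAIR_TO_IUPAC, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Simulation conditions; defaults emulate the study system: ~80
    dikaryotic isolates, one MAT-linked marker of ~800 bp plus three
    ~500 bp neutral loci, a dozen founding MAT alleles, and a recent
    founder bottleneck."""

    N: int = 200
    generations: int = 150
    mu_site: float = 5e-5
    L_marker: int = 810
    L_neutral: int = 500
    n_neutral_loci: int = 3
    mu_mat: float = 5e-4
    r: float = 0.0
    K_init: int = 12
    founder_divergence: float = 0.05
    founder_divergence_neutral: float = 0.01
    bottleneck: tuple[int, int, int] | None = (80, 14, 10)  # (onset, size, duration)
    sample_n_dikaryons: int = 30
    clones_per_isolate: tuple[int, int] = (6, 20)
    epsilon: float = 0.002
    missing_allele_prob: float = 0.47
    mat_compatibility: bool = True
    split_generation: int | None = None
    group_names: tuple[str, str] = ("founder", "natural")
    ecology_by_group: dict | None = None
    marker_segments: tuple[int, int] = (285, 832)  # mip | spacer | HD1 boundaries
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.mu_site, self.mu_mat, self.r, self.epsilon,
                     self.missing_allele_prob, self.founder_divergence):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.founder_divergence_neutral <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.K_init < 2:
            raise ValueError("K_init must be >= 2")
        lo, hi = self.clones_per_isolate
        if not (1 <= lo <= hi <= 50):
            raise ValueError("clones_per_isolate range must lie within [1, 50]")


@dataclass
class Dikaryon:
    isolate_id: str
    group: str
    ecology: str
    mat_ids: tuple[int, int]
    marker_haplotypes: tuple[str, str]
    neutral_haplotypes: dict[str, tuple[str, str]]
    neutral_genotypes: dict[str, str]
    clone_reads: list[str] = field(default_factory=list)
    missing_allele: bool = False
    amplified_haplotype: int = 0  # which haplotype the clones cover if missing


@dataclass
class SimOutput:
    config: SimConfig
    dikaryons: list[Dikaryon]
    mat_count_trajectory: dict[str, list[int]]
    mat_frequencies: dict[str, dict[int, float]]
    neutral_locus_names: list[str]


@dataclass
class _Pop:
    mat: np.ndarray          # (N,) int
    marker: np.ndarray       # (N, L_marker) uint8
    neutral: list[np.ndarray]


def _seq_str(row: np.ndarray) -> str:
    return _BASES[row].tobytes().decode()


def _founder_haplotypes(
    rng: np.random.Generator, K: int, L: int, divergence: float
) -> np.ndarray:
    """K founder haplotypes around a random ancestral sequence; each
    lineage substitutes each site with probability divergence/2, so the
    expected pairwise founder divergence is ~``divergence``."""
    anc = rng.integers(0, 4, size=L, dtype=np.uint8)
    haps = np.tile(anc, (K, 1))
    hit = rng.random((K, L)) < divergence / 2.0
    shift = rng.integers(1, 4, size=hit.sum(), dtype=np.uint8)
    haps[hit] = (haps[hit] + shift) % 4
    return haps


def _mutate_sites(rng: np.random.Generator, arr: np.ndarray, mu: float) -> None:
    n_mut = rng.poisson(arr.shape[0] * arr.shape[1] * mu)
    if n_mut == 0:
        return
    rows = rng.integers(0, arr.shape[0], n_mut)
    cols = rng.integers(0, arr.shape[1], n_mut)
    arr[rows, cols] = (arr[rows, cols] + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4


def _one_generation(
    pop: _Pop, n_next: int, cfg: SimConfig, rng: np.random.Generator,
    next_mat_id: int,
) -> tuple[_Pop, int]:
    n_cur = len(pop.mat)
    mothers = rng.integers(0, n_cur, n_next)
    fathers = rng.integers(0, n_cur, n_next)
    if cfg.mat_compatibility:
        if len(np.unique(pop.mat)) < 2:
            raise SimulationError(
                "population lost all MAT diversity: no compatible matings remain"
            )
        for _ in range(200):
            bad = pop.mat[mothers] == pop.mat[fathers]
            if not bad.any():
                break
            fathers[bad] = rng.integers(0, n_cur, int(bad.sum()))
        else:
            raise SimulationError("could not find MAT-compatible parent pairs")
    from_mother = rng.random(n_next) < 0.5
    recomb = rng.random(n_next) < cfg.r
    marker_from_mother = from_mother ^ recomb
    mat = np.where(from_mother, pop.mat[mothers], pop.mat[fathers])
    marker = np.where(
        marker_from_mother[:, None], pop.marker[mothers], pop.marker[fathers]
    )
    neutral = []
    for arr in pop.neutral:
        pick = rng.random(n_next) < 0.5
        neutral.append(np.where(pick[:, None], arr[mothers], arr[fathers]))
    # mutation
    marker = marker.copy()
    _mutate_sites(rng, marker, cfg.mu_site)
    neutral = [a.copy() for a in neutral]
    for a in neutral:
        _mutate_sites(rng, a, cfg.mu_site)
    mat = mat.copy()
    n_new = rng.poisson(n_next * cfg.mu_mat)
    if n_new:
        rows = rng.integers(0, n_next, n_new)
        for r_i in rows:
            mat[r_i] = next_mat_id
            next_mat_id += 1
    return _Pop(mat, marker, neutral), next_mat_id


def _evolve(
    pop: _Pop, cfg: SimConfig, rng: np.random.Generator, generations: int,
    bottleneck: tuple[int, int, int] | None, next_mat_id: int,
    trajectory: list[int],
) -> tuple[_Pop, int]:
    for t in range(generations):
        n_next = cfg.N
        if bottleneck is not None:
            onset, size, duration = bottleneck
            if onset <= t < onset + duration:
                n_next = size
        pop, next_mat_id = _one_generation(pop, n_next, cfg, rng, next_mat_id)
        trajectory.append(int(len(np.unique(pop.mat))))
    return pop, next_mat_id


def _sample_dikaryon_pairs(
    pop: _Pop, n_pairs: int, compat: bool, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n = len(pop.mat)
    if compat and len(np.unique(pop.mat)) < 2:
        raise SimulationError("cannot sample dikaryons: single MAT allele left")
    pairs = []
    for _ in range(n_pairs):
        for _try in range(1000):
            i, j = rng.integers(0, n, 2)
            if i == j:
                continue
            if compat and pop.mat[i] == pop.mat[j]:
                continue
            pairs.append((int(i), int(j)))
            break
        else:
            raise SimulationError("rejection sampling of dikaryon pairs failed")
    return pairs


def _genotype_iupac(h1: str, h2: str) -> str:
    out = []
    for x, y in zip(h1, h2):
        out.append(x if x == y else PAIR_TO_IUPAC[frozenset((x, y))])
    return "".join(out)


def _make_clone_reads(
    d: Dikaryon, cfg: SimConfig, rng: np.random.Generator
) -> None:
    lo, hi = cfg.clones_per_isolate
    m = int(rng.integers(lo, hi + 1))
    d.missing_allele = bool(rng.random() < cfg.missing_allele_prob)
    d.amplified_haplotype = int(rng.integers(0, 2)) if d.missing_allele else 0
    reads = []
    for _ in range(m):
        src = d.amplified_haplotype if d.missing_allele else int(rng.integers(0, 2))
        seq = np.frombuffer(d.marker_haplotypes[src].encode(), dtype="S1").copy()
        codes = np.searchsorted(_BASES, seq)
        n_err = rng.binomial(len(seq), cfg.epsilon)
        if n_err:
            cols = rng.integers(0, len(seq), n_err)
            codes[cols] = (codes[cols] + rng.integers(1, 4, n_err)) % 4
        reads.append(_seq_str(codes.astype(np.uint8)))
    d.clone_reads = reads


def simulate(config: SimConfig) -> SimOutput:
    """Run the forward model and sample dikaryotic isolates.

    Fully reproducible: the config seed drives every random draw,
    including clone-read errors and the missing-allele mask.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    neutral_names = [f"neutral{i + 1}" for i in range(cfg.n_neutral_loci)]

    founder_marker = _founder_haplotypes(rng, cfg.K_init, cfg.L_marker,
                                         cfg.founder_divergence)
    founder_neutral = [
        _founder_haplotypes(
            rng, cfg.K_init, cfg.L_neutral, cfg.founder_divergence_neutral
        )
        for _ in range(cfg.n_neutral_loci)
    ]
    mat = rng.permutation(np.arange(cfg.N) % cfg.K_init)
    pop = _Pop(
        mat=mat,
        marker=founder_marker[mat].copy(),
        neutral=[f[rng.integers(0, cfg.K_init, cfg.N)].copy() for f in founder_neutral],
    )
    next_mat_id = cfg.K_init

    groups: dict[str, _Pop] = {}
    trajectories: dict[str, list[int]] = {}
    if cfg.split_generation is None:
        name = cfg.group_names[0]
        traj: list[int] = []
        pop, next_mat_id = _evolve(
            pop, cfg, rng, cfg.generations, cfg.bottleneck, next_mat_id, traj
        )
        groups[name] = pop
        trajectories[name] = traj
    else:
        shared = min(cfg.split_generation, cfg.generations)
        traj_shared: list[int] = []
        pop, next_mat_id = _evolve(
            pop, cfg, rng, shared, None, next_mat_id, traj_shared
        )
        remaining = cfg.generations - shared
        for gi, name in enumerate(cfg.group_names):
            sub = _Pop(pop.mat.copy(), pop.marker.copy(),
                       [a.copy() for a in pop.neutral])
            traj = list(traj_shared)
            # the founder lineage (first group) passes through the bottleneck
            bn = cfg.bottleneck if gi == 0 else None
            sub, next_mat_id = _evolve(sub, cfg, rng, remaining, bn, next_mat_id, traj)
            groups[name] = sub
            trajectories[name] = traj

    eco = cfg.ecology_by_group or (
        {cfg.group_names[0]: "B", cfg.group_names[1]: "N"}
        if cfg.split_generation is not None
        else {cfg.group_names[0]: "B"}
    )
    dikaryons = []
    mat_freqs: dict[str, dict[int, float]] = {}
    for name, gpop in groups.items():
        ids, counts = np.unique(gpop.mat, return_counts=True)
        mat_freqs[name] = {int(i): float(c) / len(gpop.mat) for i, c in zip(ids, counts)}
        pairs = _sample_dikaryon_pairs(
            gpop, cfg.sample_n_dikaryons, cfg.mat_compatibility, rng
        )
        for k, (i, j) in enumerate(pairs):
            iso = f"{name[:3].upper()}{k + 1:03d}"
            hap_pairs = {
                locus: (_seq_str(gpop.neutral[li][i]), _seq_str(gpop.neutral[li][j]))
                for li, locus in enumerate(neutral_names)
            }
            d = Dikaryon(
                isolate_id=iso,
                group=name,
                ecology=eco.get(name, "unknown"),
                mat_ids=(int(gpop.mat[i]), int(gpop.mat[j])),
                marker_haplotypes=(_seq_str(gpop.marker[i]), _seq_str(gpop.marker[j])),
                neutral_haplotypes=hap_pairs,
                neutral_genotypes={
                    locus: _genotype_iupac(*hp) for locus, hp in hap_pairs.items()
                },
            )
            _make_clone_reads(d, cfg, rng)
            dikaryons.append(d)
    return SimOutput(
        config=cfg,
        dikaryons=dikaryons,
        mat_count_trajectory=trajectories,
        mat_frequencies=mat_freqs,
        neutral_locus_names=neutral_names,
    )


# ---------------------------------------------------------------------------
# Truth summaries
# ---------------------------------------------------------------------------


def _pi_from_strings(seqs: list[str]) -> float:
    """Mean pairwise per-site difference for equal-length ACGT strings."""
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    n, L = mat.shape
    pairs = n * (n - 1) / 2.0
    mism = 0.0
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    mism = (pairs - same).sum()
    return float(mism / pairs / L)


def summarize_truth(sim: SimOutput) -> dict:
    """Deterministic truth metrics: final/sampled MAT allele counts, marker
    vs neutral nucleotide diversity in the sample, and the within-dikaryon
    marker divergence against the across-isolate background."""
    out: dict = {"groups": {}}
    for name in sim.mat_count_trajectory:
        diks = [d for d in sim.dikaryons if d.group == name]
        marker_seqs = [h for d in diks for h in d.marker_haplotypes]
        pi_marker = _pi_from_strings(marker_seqs)
        pis_neutral = []
        for locus in sim.neutral_locus_names:
            seqs = [h for d in diks for h in d.neutral_haplotypes[locus]]
            pis_neutral.append(_pi_from_strings(seqs))
        pi_neutral = float(np.mean(pis_neutral))
        # within-dikaryon vs across-isolate marker divergence (per site)
        L = len(marker_seqs[0])
        within = [
            np.mean(
                np.frombuffer(d.marker_haplotypes[0].encode(), "S1")
                != np.frombuffer(d.marker_haplotypes[1].encode(), "S1")
            )
            for d in diks
        ]
        mat2 = np.frombuffer("".join(marker_seqs).encode(), "S1").reshape(-1, L)
        iso = np.repeat(np.arange(len(diks)), 2)
        across = []
        for a in range(len(marker_seqs)):
            for b in range(a + 1, len(marker_seqs)):
                if iso[a] != iso[b]:
                    across.append(float((mat2[a] != mat2[b]).mean()))
        sampled_mats = sorted({m for d in diks for m in d.mat_ids})
        out["groups"][name] = {
            "mat_alleles_final": sim.mat_count_trajectory[name][-1],
            "mat_alleles_sampled": len(sampled_mats),
            "pi_marker": pi_marker,
            "pi_neutral": pi_neutral,
            "pi_ratio": pi_marker / pi_neutral if pi_neutral > 0 else float("inf"),
            "within_dikaryon_divergence": float(np.mean(within)),
            "across_isolate_divergence": float(np.mean(across)),
            "two_allele_fraction": float(
                np.mean([not d.missing_allele for d in diks])
            ),
        }
    out["mat_count_trajectory"] = sim.mat_count_trajectory
    return out


# ---------------------------------------------------------------------------
# Input emission
# ---------------------------------------------------------------------------


def emit_inputs(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write the file set the pipeline consumes.

    clones/<isolate>_marker.fasta   cloned marker reads (PCR error applied)
    <locus>.fasta                   IUPAC-coded neutral genotype alignments
    sample_sheet.tsv                seq_id / isolate / locus / group / ecology
    pairs.tsv                       within-dikaryon allele pairs (truth ids)
    truth/marker_true_alleles.fasta true marker alleles (.a1/.a2 per isolate)
    truth.json                      trajectories, MAT ids, missing mask, seed
    """
    outdir = Path(outdir)
    (outdir / "clones").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    sheet_rows = []

    for d in sim.dikaryons:
        members = [
            AlignedSequence(f"{d.isolate_id}.c{c + 1}", read)
            for c, read in enumerate(d.clone_reads)
        ]
        p = outdir / "clones" / f"{d.isolate_id}_marker.fasta"
        write_fasta(Alignment("marker", members), p)

    truth_members = []
    pair_rows = []
    for d in sim.dikaryons:
        if d.missing_allele:
            hap = d.marker_haplotypes[d.amplified_haplotype]
            truth_members.append(
                AlignedSequence(f"{d.isolate_id}.a1", hap, isolate_id=d.isolate_id,
                                group=d.group, ecology=d.ecology)
            )
            sheet_rows.append((f"{d.isolate_id}.a1", d.isolate_id, "marker",
                               d.group, d.ecology))
        else:
            for a, hap in enumerate(d.marker_haplotypes, start=1):
                truth_members.append(
                    AlignedSequence(f"{d.isolate_id}.a{a}", hap,
                                    isolate_id=d.isolate_id, group=d.group,
                                    ecology=d.ecology)
                )
                sheet_rows.append((f"{d.isolate_id}.a{a}", d.isolate_id, "marker",
                                   d.group, d.ecology))
            pair_rows.append(
                (d.isolate_id, f"{d.isolate_id}.a1", f"{d.isolate_id}.a2", d.group)
            )
    paths["marker_truth"] = outdir / "truth" / "marker_true_alleles.fasta"
    write_fasta(Alignment("marker", truth_members), paths["marker_truth"])

    for locus in sim.neutral_locus_names:
        members = [
            AlignedSequence(f"{d.isolate_id}.{locus}", d.neutral_genotypes[locus])
            for d in sim.dikaryons
        ]
        paths[locus] = outdir / f"{locus}.fasta"
        write_fasta(Alignment(locus, members), paths[locus])
        for d in sim.dikaryons:
            sheet_rows.append((f"{d.isolate_id}.{locus}", d.isolate_id, locus,
                               d.group, d.ecology))

    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    with open(paths["sample_sheet"], "w") as fh:
        fh.write("seq_id\tisolate_id\tlocus\tgroup\tecology\n")
        for row in sheet_rows:
            fh.write("\t".join(row) + "\n")

    paths["pairs"] = outdir / "pairs.tsv"
    with open(paths["pairs"], "w") as fh:
        fh.write("isolate_id\tallele1\tallele2\tgroup\n")
        for row in pair_rows:
            fh.write("\t".join(row) + "\n")

    paths["truth_json"] = outdir / "truth.json"
    cfg = asdict(sim.config)
    truth = {
        "config": cfg,
        "mat_count_trajectory": sim.mat_count_trajectory,
        "mat_frequencies": {
            g: {str(k): v for k, v in f.items()} for g, f in sim.mat_frequencies.items()
        },
        "dikaryons": [
            {
                "isolate_id": d.isolate_id,
                "group": d.group,
                "mat_ids": list(d.mat_ids),
                "missing_allele": d.missing_allele,
                "n_clones": len(d.clone_reads),
            }
            for d in sim.dikaryons
        ],
    }
    paths["truth_json"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
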