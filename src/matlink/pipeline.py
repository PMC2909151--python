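"""End-to-end orchestration: simulate -> call alleles -> phase -> summary
statistics -> HKA -> dikaryon divergence test, with seeded determinism and
audit output. Every emitted table carries a header comment recording the
package version, the run seed and a hash of the effective configuration,
so a run can be reproduced from its outputs alone."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import Alignment, read_fasta, read_sample_sheet, write_fasta
from .clonecall import call_alleles_from_dir, write_allele_calls
from .dikaryon import AllelePair, run_group_tests, similarity_matrix
from .diversity import locus_summary, render_table
from .hka import hka_data_from_alignments, hka_test, write_hka_report
from .phasing import GenotypeSequence, phase_all
from .simulate import SimConfig, emit_inputs, simulate

log = logging.getLogger("matlink")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "matlink_run"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "call_alleles", "phase", "stats", "hka", "dikaryon_test",
        ]
    )
    inputs_dir: str | None = None  # when 'simulate' is toggled off
    simulate: dict = field(default_factory=dict)
    clone_threshold: float = 0.02
    count_mode: str = "sequences"
    hka_n_sims: int = 1000
    n_perm: int = 999
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (
        f"# matlink v{__version__} seed={cfg.seed} config={_config_hash(cfg)}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the enabled stages in order; any stage failure aborts with a
    stage-named error. Re-running an identical config reproduces identical
    outputs."""
    if isinstance(config, dict):
        config = RunConfig(**config)
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    results: dict = {"config_hash": _config_hash(cfg)}
    try:
        inputs_dir = Path(cfg.inputs_dir) if cfg.inputs_dir else outdir / "inputs"
        if "simulate" in cfg.stages:
            try:
                sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.simulate})
                sim = simulate(sim_cfg)
                emit_inputs(sim, inputs_dir)
                results["sim"] = sim
                log.info("simulate: %d dikaryons -> %s", len(sim.dikaryons), inputs_dir)
            except Exception as e:  # noqa: BLE001
                raise StageError("simulate", e) from e
        if not inputs_dir.exists():
            raise ConfigError(f"inputs dir {inputs_dir} missing")
        sheet = read_sample_sheet(inputs_dir / "sample_sheet.tsv")
        iso_meta = (
            sheet.drop_duplicates("isolate_id").set_index("isolate_id")
        )

        alignments: dict[str, Alignment] = {}
        if "call_alleles" in cfg.stages:
            try:
                called, audit = call_alleles_from_dir(
                    inputs_dir / "clones", cfg.clone_threshold
                )
                for aln in called.values():
                    for m in aln.members:
                        if m.isolate_id in iso_meta.index:
                            m.group = iso_meta.loc[m.isolate_id, "group"]
                            m.ecology = iso_meta.loc[m.isolate_id, "ecology"]
                write_allele_calls(called, audit, outdir / "alleles")
                alignments.update(called)
                results["allele_audit"] = audit
                log.info("call_alleles: %d loci", len(called))
            except Exception as e:  # noqa: BLE001
                raise StageError("call_alleles", e) from e
        if "phase" in cfg.stages:
            try:
                loci = sorted(
                    set(sheet["locus"]) - set(alignments) - {"marker"}
                )
                for locus in loci:
                    gpath = inputs_dir / f"{locus}.fasta"
                    if not gpath.exists():
                        continue
                    aln = read_fasta(gpath, locus_name=locus)
                    genotypes = [
                        GenotypeSequence(m.seq_id, m.residues) for m in aln.members
                    ]
                    hs = phase_all(genotypes)
                    hap_aln = hs.to_alignment(locus)
                    for m in hap_aln.members:
                        iso = m.seq_id.split(".")[0]
                        m.isolate_id = iso
                        if iso in iso_meta.index:
                            m.group = iso_meta.loc[iso, "group"]
                            m.ecology = iso_meta.loc[iso, "ecology"]
                    alignments[locus] = hap_aln
                    (outdir / "haplotypes").mkdir(exist_ok=True)
                    write_fasta(hap_aln, outdir / "haplotypes" / f"{locus}.fasta")
                log.info("phase: %d neutral loci", len(loci))
            except Exception as e:  # noqa: BLE001
                raise StageError("phase", e) from e
        if "stats" in cfg.stages:
            try:
                table = locus_summary(alignments, count_mode=cfg.count_mode)
                results["stats"] = table
                with open(outdir / "locus_stats.tsv", "w") as f:
                    f.write(_header(cfg))
                    f.write(render_table(table))
                log.info("stats: %d rows", len(table))
            except Exception as e:  # noqa: BLE001
                raise StageError("stats", e) from e
        groups_present = sorted(
            {g for aln in alignments.values() for g in
             {m.group for m in aln.members} if g}
        )
        if "hka" in cfg.stages:
            try:
                if len(groups_present) < 2:
                    log.info("hka: skipped (needs two taxa, found %s)", groups_present)
                else:
                    ga, gb = groups_present[:2]
                    data = []
                    for locus, aln in alignments.items():
                        aa = Alignment(locus, [m for m in aln.members if m.group == ga])
                        ab = Alignment(locus, [m for m in aln.members if m.group == gb])
                        data.append(hka_data_from_alignments(locus, aa, ab))
                    fit = hka_test(data, n_sims=cfg.hka_n_sims, seed=cfg.seed)
                    write_hka_report(fit, data, outdir / "hka_report.json")
                    results["hka"] = fit
                    log.info("hka: x2=%.3f p=%.3f", fit.x2_obs, fit.p_value)
            except Exception as e:  # noqa: BLE001
                raise StageError("hka", e) from e
        if "dikaryon_test" in cfg.stages:
            try:
                marker = alignments.get("marker")
                if marker is None:
                    marker = read_fasta(
                        inputs_dir / "truth" / "marker_true_alleles.fasta",
                        locus_name="marker",
                    )
                audit = results.get("allele_audit")
                if audit is not None and len(audit):
                    maudit = audit[audit["locus"] == "marker"]
                    counts = maudit.groupby("isolate_id").size()
                    pairs = []
                    for iso in counts[counts == 2].index:
                        ids = tuple(maudit.loc[maudit["isolate_id"] == iso, "allele_id"])
                        grp = (
                            iso_meta.loc[iso, "group"] if iso in iso_meta.index else ""
                        )
                        pairs.append(AllelePair(iso, ids, grp))
                    allele_table = pd.DataFrame(
                        {
                            "allele_id": maudit["allele_id"],
                            "isolate_id": maudit["isolate_id"],
                            "group": [
                                iso_meta.loc[i, "group"] if i in iso_meta.index else ""
                                for i in maudit["isolate_id"]
                            ],
                        }
                    )
                else:
                    ptab = pd.read_csv(inputs_dir / "pairs.tsv", sep="\t")
                    pairs = [
                        AllelePair(r.isolate_id, (r.allele1, r.allele2), r.group)
                        for r in ptab.itertuples()
                    ]
                    allele_table = pd.DataFrame(
                        {
                            "allele_id": [m.seq_id for m in marker.members],
                            "isolate_id": [m.seq_id.rsplit(".", 1)[0]
                                           for m in marker.members],
                            "group": [m.group for m in marker.members],
                        }
                    )
                matrix = similarity_matrix(marker)
                pair_counts = pd.Series([p.group for p in pairs]).value_counts()
                test_groups = sorted(pair_counts[pair_counts >= 2].index)
                res = run_group_tests(
                    matrix, pairs, allele_table, test_groups,
                    n_perm=cfg.n_perm, seed=cfg.seed,
                )
                _write_tsv(res, outdir / "dikaryon_test.tsv", cfg)
                results["dikaryon"] = res
                log.info("dikaryon_test: %d groups", len(test_groups))
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001
                raise StageError("dikaryon_test", e) from e
    finally:
        log.removeHandler(fh)
        fh.close()
    return results
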