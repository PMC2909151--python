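"""Forward simulator: mating constraint, linkage, mutation closure,
bottleneck behaviour and input emission."""

import filecmp
import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from matlink.phasing import combine_haplotypes
from matlink.simulate import (
    SimConfig,
    SimulationError,
    _Pop,
    _one_generation,
    emit_inputs,
    simulate,
    summarize_truth,
)

FAST = dict(N=80, generations=40, sample_n_dikaryons=12, L_marker=200,
            L_neutral=150, n_neutral_loci=2, bottleneck=None)


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mu_site=1.5)
        with pytest.raises(ValueError):
            SimConfig(K_init=1)
        with pytest.raises(ValueError):
            SimConfig(clones_per_isolate=(0, 5))


class TestSimulate:
    def test_two_mat_alleles_every_dikaryon_heteroallelic(self):
        sim = simulate(SimConfig(K_init=2, seed=1, **FAST))
        for d in sim.dikaryons:
            assert d.mat_ids[0] != d.mat_ids[1]

    def test_mat_allele_count_never_increases_without_mutation(self):
        sim = simulate(SimConfig(mu_mat=0.0, seed=2, **FAST))
        traj = sim.mat_count_trajectory["founder"]
        assert all(b <= a for a, b in zip(traj, traj[1:]))
        assert max(traj) <= SimConfig(**FAST).K_init

    def test_complete_linkage_marker_tracks_mat(self):
        """With r=0 and no mutation, the marker haplotype is a deterministic
        function of the MAT allele."""
        cfg = SimConfig(r=0.0, mu_site=0.0, mu_mat=0.0, K_init=2, seed=3,
                        epsilon=0.0, **FAST)
        sim = simulate(cfg)
        by_mat = {}
        for d in sim.dikaryons:
            for mat, hap in zip(d.mat_ids, d.marker_haplotypes):
                by_mat.setdefault(mat, set()).add(hap)
        assert all(len(haps) == 1 for haps in by_mat.values())

    def test_mat_loss_halts_with_diagnostic(self):
        pop = _Pop(
            mat=np.zeros(10, dtype=int),
            marker=np.zeros((10, 20), dtype=np.uint8),
            neutral=[np.zeros((10, 20), dtype=np.uint8)],
        )
        cfg = SimConfig(**FAST)
        with pytest.raises(SimulationError, match="MAT"):
            _one_generation(pop, 10, cfg, np.random.default_rng(0), 5)

    def test_genotypes_reconstruct_from_truth_haplotypes(self):
        sim = simulate(SimConfig(seed=4, **FAST))
        for d in sim.dikaryons:
            for locus, (h1, h2) in d.neutral_haplotypes.items():
                assert combine_haplotypes(h1, h2) == d.neutral_genotypes[locus]

    def test_split_produces_two_diverged_groups(self):
        cfg = SimConfig(seed=5, split_generation=20, **FAST)
        sim = simulate(cfg)
        groups = {d.group for d in sim.dikaryons}
        assert groups == set(cfg.group_names)


class TestCloneReads:
    def test_error_free_clones_equal_truth(self):
        sim = simulate(SimConfig(seed=6, epsilon=0.0, **FAST))
        for d in sim.dikaryons:
            for read in d.clone_reads:
                assert read in d.marker_haplotypes

    def test_missing_allele_fraction(self):
        """About 53% of isolates yield both alleles at the default 0.47
        one-allele failure rate."""
        fracs = []
        for seed in range(40):
            sim = simulate(SimConfig(seed=seed, missing_allele_prob=0.47, **FAST))
            fracs.append(np.mean([not d.missing_allele for d in sim.dikaryons]))
        assert np.mean(fracs) == pytest.approx(0.53, abs=0.05)

    def test_clone_count_range_respected(self):
        sim = simulate(SimConfig(seed=7, clones_per_isolate=(3, 5), **FAST))
        counts = {len(d.clone_reads) for d in sim.dikaryons}
        assert counts <= {3, 4, 5}


class TestEmission:
    def test_identical_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            sim = simulate(SimConfig(seed=11, **FAST))
            emit_inputs(sim, tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*.*"))
        for fa in files_a:
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fb.exists()
            assert fa.read_bytes() == fb.read_bytes()

    def test_emitted_inputs_parse_and_cover_sample_sheet(self, tmp_path):
        from matlink.alignment import read_fasta, read_sample_sheet

        sim = simulate(SimConfig(seed=12, **FAST))
        paths = emit_inputs(sim, tmp_path)
        sheet = read_sample_sheet(paths["sample_sheet"])
        marker = read_fasta(paths["marker_truth"], locus_name="marker")
        assert set(marker.ids()) <= set(sheet["seq_id"])
        for locus in sim.neutral_locus_names:
            aln = read_fasta(paths[locus], locus_name=locus)
            assert aln.n == len(sim.dikaryons)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["config"]["seed"] == 12


class TestTruthSummaries:
    def test_selection_with_bottleneck_elevates_marker_diversity(self):
        """The central mechanism: the mating-compatibility constraint
        preserves marker variation through a bottleneck that strips the
        neutral loci."""
        ratios, controls = [], []
        for seed in range(12):
            # equal founder divergence: any pi elevation is due to selection
            base = dict(N=100, generations=80, sample_n_dikaryons=15,
                        L_marker=300, L_neutral=300, n_neutral_loci=2,
                        founder_divergence_neutral=0.05,
                        bottleneck=(40, 10, 10))
            s1 = summarize_truth(simulate(SimConfig(seed=seed, **base)))
            s0 = summarize_truth(
                simulate(SimConfig(seed=seed, mat_compatibility=False, **base))
            )
            ratios.append(s1["groups"]["founder"]["pi_ratio"])
            controls.append(s0["groups"]["founder"]["pi_ratio"])
        assert np.mean(ratios) > 1.2
        assert np.mean(ratios) > np.mean(controls)

    def test_no_selection_control_marker_indistinguishable_from_neutral(self):
        """With equal founder divergence at all loci and the compatibility
        constraint off, marker and neutral diversity are exchangeable."""
        from scipy import stats

        pm, pn = [], []
        for seed in range(100):
            s = summarize_truth(
                simulate(SimConfig(seed=seed, mat_compatibility=False,
                                   founder_divergence_neutral=0.05))
            )["groups"]["founder"]
            pm.append(s["pi_marker"])
            pn.append(s["pi_neutral"])
        p = stats.ttest_rel(pm, pn).pvalue
        assert p > 0.01

    def test_bottleneck_hits_neutral_richness_harder_than_mat(self):
        # mutation off so that distinct sequences = surviving founder lineages
        kept_mat, kept_neutral = [], []
        for seed in range(12):
            cfg = SimConfig(seed=seed, N=100, generations=60,
                            sample_n_dikaryons=15, L_marker=300, L_neutral=300,
                            n_neutral_loci=2, mu_site=0.0, mu_mat=0.0,
                            bottleneck=(30, 10, 10))
            sim = simulate(cfg)
            mats = {m for d in sim.dikaryons for m in d.mat_ids}
            seqs = {
                h
                for d in sim.dikaryons
                for h in d.neutral_haplotypes[sim.neutral_locus_names[0]]
            }
            kept_mat.append(len(mats) / cfg.K_init)
            kept_neutral.append(len(seqs) / cfg.K_init)
        assert np.mean(kept_mat) > np.mean(kept_neutral)
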