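# matlink

Population-genetic analysis of mating-type-linked markers in dikaryotic
fungi.

Fungal mating-type (MAT) loci are textbook targets of negative
frequency-dependent selection: a haploid mycelium carrying a rare MAT
allele can mate with almost anyone, so rare alleles are favoured and
allelic richness is preserved even through severe bottlenecks. Because
MAT alleles themselves are too divergent for universal primers, a common
strategy is to sequence a physically linked, otherwise ordinary marker
(e.g. the *mip* gene region adjacent to MAT A in many Agaricomycetes)
and read the selection signal off the hitch-hiking variation. `matlink`
provides the full analysis chain for that strategy, for anyone working
with dikaryotic isolates — where every individual carries two nuclei and
hence up to two alleles per locus — plus a forward simulator that
generates realistic synthetic datasets with known truth.

The stages, each usable on its own:

1. **Clone calling** — reconstruct an isolate's 1–4 alleles from cloned
   amplicon reads: single-linkage clustering at 2% divergence, then
   per-group consensus with the copy-number rules (majority consensus
   discarding single-clone "autapomorphic" variants at m ≥ 3, IUPAC
   heterozygosity codes at m = 2, verbatim at m = 1).
2. **Phasing** — resolve IUPAC-coded genotype sequences into haplotypes
   with a template-then-parsimony procedure that minimises the number of
   distinct haplotypes, validated against exhaustive search.
3. **Diversity statistics** — per locus and group: n, segregating sites
   S, mutations η and singletons η_s, mean pairwise differences k,
   nucleotide diversity π = k/L, Watterson's θ_W = S/a₁ with
   a₁ = Σ_{i=1}^{n−1} 1/i, Tajima's
   D = (k − S/a₁)/√(e₁S + e₂S(S−1)), and Fu & Li's outgroup-free D*, F*.
4. **HKA test** — two-taxon multilocus polymorphism/divergence contrast
   with per-locus θ_i, shared divergence time T and size ratio f;
   x² = Σ(obs − E)²/Var, significance by parametric bootstrap over
   refitted coalescent replicates.
5. **Dikaryon divergence test** — are the two alleles co-occurring
   within individuals less similar than allele pairs across individuals
   (the signature of mating with few compatible types)? Welch's unequal
   variance t test plus a re-pairing permutation test.
6. **Forward simulator** — haploid Wright–Fisher population whose only
   selective force is the MAT compatibility rule at mating, with a
   linked marker, neutral loci, founder bottlenecks, optional two-taxon
   splits, dikaryon sampling, clone reads with PCR error, and a truth
   record.

See `docs/methods.md` for models, conventions and defaults.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated two-taxon dataset (a bottlenecked "founder" lineage and its
"natural" sister, deeply split, 30 dikaryons each):

```bash
python analysis/01_simulate_population.py
python analysis/02_call_alleles.py
python analysis/03_phase_haplotypes.py
python analysis/04_diversity_table.py
python analysis/05_hka_test.py
python analysis/06_dikaryon_divergence.py
python analysis/07_calibration_experiments.py
```

Step 01 prints the simulation truth:

```
  founder  MAT alleles sampled= 4  pi_marker=0.0466  pi_neutral=0.0100  ratio=4.66  two-allele frac=0.60
  natural  MAT alleles sampled= 5  pi_marker=0.0771  pi_neutral=0.0047  ratio=16.40  two-allele frac=0.50
```

— the marker retains severalfold more diversity than the neutral loci in
both taxa, most strikingly through the founder bottleneck, and only
~half the dikaryons yield both marker alleles (simulated amplification
failure). Step 04 writes the per-locus summary table
(`results/locus_stats.tsv`); its founder-group rows show marker
π = 0.048 against a neutral mean of ~0.010. Step 05 reports

```
x2 = 31.470, p = 0.000 (1000 simulations)
finding: the four-locus configuration deviates from the neutral model.
```

— the marker's polymorphism is far out of proportion to its divergence,
exactly the HKA signature of balancing selection. Step 06 prints

```
  group  n_within  n_across  mean_within_similarity  mean_across_similarity  t_statistic  p_value  p_permutation
founder        15       975                  0.9274                  0.9525      -4.1976   0.0008         0.0080
natural        14       932                  0.9116                  0.9207      -0.6364   0.5351         0.5650
```

— within-dikaryon alleles are significantly more divergent than chance
in the bottlenecked founder group (few mating types force divergent
pairings) but not in the diverse natural group, where mating is
effectively panmictic. Step 07 re-derives the toolkit's operating
characteristics (statistic calibration, type-I errors, clone-calling
accuracy, and the simulator's headline pattern over replicate
populations).

There is also a `matlink` console script exposing the same stages
(`matlink simulate | call-alleles | phase | stats | hka | dikaryon-test |
run`); `matlink run --config cfg.yaml` executes the pipeline end to end
with seeded determinism and provenance headers on every output.

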