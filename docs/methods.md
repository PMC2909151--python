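# Methods

`matlink` analyses allelic variation at a marker linked to a fungal
mating-type (MAT) locus, in species sampled as dikaryons: each isolate
carries two haploid nuclei and therefore up to two alleles per locus.
The package implements the full chain from raw cloned amplicon reads to
population-genetic inference, plus a forward simulator that generates
every input with the statistical structure the analysis assumes. This
note records the models, the defaults and why, the numerical choices,
and what the synthetic data do and do not establish.

## Clone-based allele calling

PCR products amplified from a dikaryon mix 1–4 allele sequences; cloning
separates them but introduces in-vitro point errors and, potentially,
chimeras. Cloned reads from one isolate are partitioned into allele
groups by single-linkage clustering on pairwise distance (1 − identity,
pairwise deletion), implemented as connected components of the graph
whose edges join clones within the threshold. The default threshold is
**0.02**: within-allele clone scatter is PCR error (per-base error
ε ≈ 10⁻³, so clone pairs differ by ≲0.5%), while distinct alleles at a
MAT-linked marker typically diverge by 5–6%. The threshold is a
configurable stand-in for what a human curator does by eye.

Each group is collapsed by copy number *m*:

* *m* ≥ 3 — per-column majority consensus. A variant carried by exactly
  one clone ("autapomorphic") is treated as an in-vitro mutation and
  discarded; the column index is recorded in the audit trail. A tied
  column (e.g. 2–2 at *m* = 4) resolves to the alphabetically first base
  and is logged as a tie.
* *m* = 2 — columns where the two copies differ are taken as genuine
  heterozygosity and emitted as the IUPAC two-fold code (R/Y/S/W/K/M).
* *m* = 1 — the clone is accepted verbatim; single-copy calls retain
  any PCR errors, which is why calling accuracy is validated at *m* ≥ 5
  per allele (allele error rate < 1% at ε = 0.002 over 500 simulated
  isolates; exact recovery at ε = 0).

Chimera detection is out of scope: no procedure is defined for it and
the simulator does not generate chimeric reads.

## Haplotype phasing by allele-count minimisation

Dikaryon-derived genotype sequences carry two-fold IUPAC codes at
heterozygous sites. Phase is inferred to minimise the number of distinct
haplotypes: genotypes that are homozygous or heterozygous at one site
have forced resolutions and seed the template set; a genotype with *h* ≥
2 heterozygous sites has 2^(h−1) complementary phasings, preferred in
the order (1) both haplotypes already templates, (2) one a template and
the partner closest (Hamming) to a template, (3) minimum summed Hamming
distance of both haplotypes to their nearest templates. Chosen
haplotypes join the template pool. Processing order is ascending
het-site count (input order on ties) and every tie breaks to the
lexicographically smallest pair, so the procedure is deterministic.

Because the greedy pass is myopic — an early genotype cannot know which
haplotypes later genotypes will need — a re-phasing sweep revisits each
multi-het genotype against the haplotypes the others use and accepts any
re-assignment that strictly lowers the number of novel haplotypes,
iterating to a fixed point (≤10 sweeps). On a fixed suite of 24 small
instances the result equals the global minimum found by exhaustive
search; the greedy count can still exceed the minimum on adversarial
input, and, like any minimum-allele procedure, the method
*underestimates* haplotype number when recombinant genotypes occur.
That behaviour is retained deliberately, not corrected.

Enumeration is capped at 20 heterozygous sites (2¹⁹ candidate phasings);
beyond the cap the call errs rather than silently truncating. Candidate
distances to the template set are assembled per het site (a candidate's
distance is a base mismatch count plus one indicator per het site), so
cost grows as 2^(h−1)·h rather than 2^(h−1)·|templates|·L.

Phase does not affect the downstream site statistics: S, η, η_s, k, π,
θ_W and the neutrality tests depend only on per-column allele counts,
which every valid phasing of the same genotypes reproduces identically.
This invariant is asserted in the test suite by comparing statistics
across independently obtained phasings.

## Diversity statistics and neutrality tests

All summary statistics use **complete deletion**: columns containing any
gap, `N` or ambiguity code in any sequence are dropped first (ambiguity
codes are treated as missing wherever statistics are computed before
phasing). The per-pair similarity matrix for the dikaryon test instead
uses **pairwise deletion**, scoring each pair on the columns where both
sequences carry an unambiguous base; gap-vs-gap positions are never
compared sites.

Definitions, for *n* sequences and L analysed sites:

* S — polymorphic columns; η — Σ per column (distinct bases − 1);
  η_s — singleton mutations, counted per column as the number of bases
  carried by exactly one sequence, capped at that column's mutation
  count (an *n* = 2 polymorphic column is one singleton, not two).
* k — mean pairwise difference count over all C(n,2) pairs; π = k / L.
* θ_W = S / a₁(n) with a₁ = Σ_{i<n} 1/i, reported per locus (a per-site
  variant is exposed). The per-locus convention is what the printed
  tables this machinery reproduces use.
* Tajima's D = (k − S/a₁) / √(e₁S + e₂S(S−1)), the 1989 constants.
* Fu & Li's D\* and F\* — outgroup-free statistics from (n, η, η_s) and
  (n, η, η_s, k) with the Simonsen-corrected u/v constants. The
  constants are cross-validated in the tests against an independent
  exact-fraction transcription of the published formulas, and the full
  statistics calibrated on msprime neutral coalescent replicates
  (n = 20, θ = 5: mean D and D\* within ±0.1 of 0, variance of order 1).

Statistics are undefined (rendered `-`) for groups with fewer than two
sequences or S = 0. Optional 5% significance flags for D\*/F\* come from
a small built-in table of two-sided critical bounds per sample size,
derived once by neutral-coalescent simulation (20 000 replicates per
*n*, θ = 5) as an approximation to the published critical-value tables;
flags are never recomputed per dataset. Whether the `#` column counts
sequence copies or distinct haplotypes is a config switch
(`count_mode`), since both conventions appear in published tables.

## HKA test

The two-taxon Hudson–Kreitman–Aguadé test contrasts within-taxon
polymorphism with between-taxon divergence over L ≥ 2 loci. Parameters:
θ_i per locus, a shared divergence time T (units of 2N_A generations)
and the taxon-B/taxon-A size ratio f. Expectations per locus:
E[S_a] = θ a₁(n_a), Var[S_a] = E[S_a] + θ² a₂(n_a); the B terms use
f θ; E[d] = θ (T + (1+f)/2) and Var[d] = E[d] + (θ(1+f)/2)², the second
term being ancestral-coalescence variance. Goodness of fit is
x² = Σ (obs − E)²/Var over the 3L (or 2L when n_b = 0) observations;
n_b = 0 selects the classic one-taxon variant with f fixed at 1.

Two fitters are provided. `method="moment"` (default) solves the HKA
moment equations — per-locus totals plus the two global equations for f
and T — by damped fixed-point iteration, vectorised across simulation
replicates; on data placed exactly at model expectations it recovers the
generating parameters and x² = 0. `method="minimize"` polishes the full
x² objective with L-BFGS-B from the moment start and matches a dense
grid search on test fixtures. Significance is a parametric bootstrap:
coalescent replicates (exponential coalescent tree lengths, Poisson
mutations; divergence as Poisson with an exponential ancestral time) are
drawn at the fitted parameters, **refitted with the same method**, and
p is the fraction of simulated x² at or above the observed value.
Using one fitter consistently for observed and null data is what keeps
the test calibrated: type-I error is 0.04 at nominal 0.05 over 400
outer replicates of 200 inner simulations. Loci are assumed internally
non-recombining and mutually freely recombining.

A property worth knowing: elevated polymorphism at a balanced locus in
*both* taxa is largely absorbed into that locus's θ̂ when the taxa split
recently, because the ancestral-polymorphism variance term grows with
θ²; the deviation becomes detectable once divergence time is large
relative to the balanced coalescence depth (T of order several 2N), and
that is also the biologically relevant regime (trans-species
polymorphism). The analysis drivers therefore use a deep split in the
demonstration dataset.

## Within-dikaryon divergence test

For each group, the similarity of the two alleles co-occurring in each
two-allele isolate ("within" values, one per isolate) is compared with
the similarities of all allele pairs spanning different isolates of the
group ("across" values). Alleles from one-allele isolates join only the
across set (switchable, since the convention is ambiguous in published
work). The primary test is the two-sample unequal-variance (Welch)
t test, two-sided by default, with the direction reported separately:
*more divergent within* ⇔ mean within-similarity < mean
across-similarity ⇔ t < 0 under (within − across).

Across-pair values share alleles and are not independent, which the
t test ignores; a permutation test is the safeguard. The null
re-partitions the group's allele pool into random pseudo-isolates
preserving the number of two-allele isolates, with statistic
|mean_within − mean_across| and the add-one convention
p = (1 + #{perm ≥ obs}) / (1 + n_perm). Under random pairing the Welch
procedure's empirical type-I error is ≤ 0.02 at α = 0.05 (400 seeded
replicates — conservative, as expected given the dependence structure),
permutation p-values are near-uniform, and the two tests' rejection
decisions agree on ≥ 95% of calibrated fixtures.

## Forward simulator

Haploid Wright–Fisher individuals carry a MAT allele (infinite-alleles
label), a marker haplotype linked to MAT with recombination fraction
`r`, and unlinked neutral haplotypes. Each offspring draws two parents
uniformly; with the compatibility constraint on, parent pairs sharing a
MAT allele are rejected and redrawn. That constraint is the entire
selection mechanism — rare MAT alleles are compatible with more partners
— so negative frequency-dependent selection emerges mechanically rather
than through a selection coefficient. Sequence mutation is finite-sites
(Poisson number of events, random site, random different base); MAT
mutates to novel labels at rate `mu_mat` per individual. If the
population converges on one MAT allele, mating is impossible and the run
halts with a diagnostic rather than silently continuing.

Initialisation constructs `K_init` founder lineages per locus by
mutating a random ancestral sequence per lineage; marker haplotype i is
initially perfectly associated with MAT allele i, neutral founder
haplotypes are assigned independently. Coalescent machinery is never
used inside the simulator (it serves only as an independent oracle in
the tests).

Defaults and rationale (all configurable):

| parameter | default | why |
|---|---|---|
| N | 200 haploids | small enough for fast replication, large enough that drift does not destroy MAT richness before the bottleneck |
| generations | 150 | founder-pool structure, not mutation-drift equilibrium, dominates on this horizon — matching a recently expanded fungus |
| L_marker / L_neutral | 810 / 500 bp | marker alignments of ~800 bp; ITS/tub/gpd-like partial genes |
| n_neutral_loci | 3 | three comparison loci |
| mu_site | 5×10⁻⁵ /site/gen | keeps within-run mutation visible but subordinate to founder variation |
| K_init | 12 | a source population with many mating types |
| founder_divergence (marker) | 0.05 | marker π ≈ 5% between alleles, the deep coalescence balancing selection maintains |
| founder_divergence_neutral | 0.01 | neutral loci are far less variable than the marker in this system; also keeps genotype het-site counts in the phasing-friendly range real data show |
| r | 0 | complete linkage; the physical distance to MAT is sub-kilobase in reference taxa |
| mu_mat | 5×10⁻⁴ | novel mating types arise but rarely on the simulated horizon |
| bottleneck (onset, size, duration) | (80, 14, 10) | a severe founder event followed by recovery |
| sample_n_dikaryons | 30 per group | a field-survey-sized sample |
| clones_per_isolate | 6–20 | per-isolate clone counts of the emulated protocol |
| epsilon | 0.002 /base/clone | proofreading-polymerase plus cloning error scale |
| missing_allele_prob | 0.47 | models amplification failure of one allele (e.g. a large insertion between marker and primer sites); yields both alleles from ~53% of isolates |

Sampling forms dikaryons by drawing MAT-compatible individual pairs
(hence every dikaryon is MAT-heteroallelic whenever the compatibility
constraint is on; the no-selection control samples unconstrained pairs,
since keeping the constraint there would bias the very comparison the
control exists for). Marker clone reads receive independent per-base
errors; neutral loci are emitted as IUPAC genotypes. An optional
two-taxon split clones the population at a configurable generation and
evolves the copies independently (the founder lineage alone passing
through the bottleneck), which gives the HKA stage genuine divergence
data. Identical seeds give byte-identical output files.

**Headline-pattern experiment** (the validation the simulator exists
for): 100 replicate populations at N = 200, 150 generations, bottleneck
(80, 8, 12), with founder divergence set *equal* (5%) at marker and
neutral loci so that any contrast is attributable to the compatibility
mechanism. Outcomes: mean π_marker/π_neutral ≈ 4 (> 1 in ~98% of
replicates), and in replicates where ≤ 4 MAT alleles survive into the
sample, within-dikaryon marker divergence exceeds the across-isolate
background (one-sided p < 10⁻¹⁰ across replicates). A no-selection
control with the same equal-divergence configuration shows no
marker/neutral difference (paired t-test p ≈ 0.4), and bottlenecks
remove founder lineages from neutral loci faster than from MAT.
Replicates whose population loses all MAT diversity in the bottleneck
halt by design and are counted separately (~3%).

What the synthetic data do **not** establish: real amplicons have
indels, chimeras and alignment error (the simulator emits gap-free,
perfectly aligned reads); the tetrapolar system's second locus (MAT B)
and multikaryotic isolates are not modelled; populations are panmictic
with discrete generations and no geographic structure; dikaryon
formation is instantaneous with no vegetative stage. Passing the
pipeline on simulated inputs therefore validates the inference machinery
and the qualitative selection signatures, not the handling of real-data
artefacts upstream of an alignment.

## Numerical and reproducibility choices

* Every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; derived seeds stay below 2³¹.
* Internal coordinates are 0-based half-open; audit tables print 1-based
  positions.
* HKA θ estimates are floored at 10⁻⁹ to avoid division by zero at
  invariant loci; f is clipped to [10⁻⁴, 10⁴]; T to [0, ∞).
* Fixed-point HKA fitting runs 200 iterations (convergence is
  geometric; the exact-expectation fixture reaches x² < 10⁻²⁹).
* Validation problem sizes: 10 000 coalescent replicates for the
  neutrality-statistic calibration; 400 outer × 200 inner replicates for
  HKA type-I error; 400 replicates for the dikaryon type-I error; 500
  isolates for clone-calling accuracy; 24 fixtures + 1000 random
  genotypes for phasing; 100 simulator replicates for the headline
  pattern. These sizes give Monte-Carlo error comfortably inside each
  assertion band while keeping the whole validation suite in a few
  minutes on one core.

## Known limitations

* The dikaryon test's across set reuses alleles in many pairs; the
  Welch test is therefore conservative here, and the permutation test is
  the inferentially safer instrument.
* The phasing heuristic is not guaranteed optimal off the validated
  envelope, and underestimates haplotype counts under recombination.
* The HKA moment fitter evaluates x² at moment estimates rather than at
  the exact x² minimum; the bootstrap uses the same estimator throughout
  so the p-value remains calibrated, but reported x² values are not
  comparable across fitters.
* Singleton-mutation counting at multiallelic columns follows the
  capped-count convention described above; other programs may differ at
  such columns.
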