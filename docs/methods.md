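# Methods

## Scope and data model

The package implements a two-stage workflow: (1) discovery — low-coverage
whole-genome genotype calls of a small multi-population sample are masked,
filtered, and mined for a compact diagnostic SNP panel; (2) application —
the panel is genotyped on a large cohort and used for sample QC,
mitochondrial haplogroup assignment, supervised clade assignment and
population-genetic summaries. The central container is a sites × samples
matrix of diploid genotype codes {0 hom-ref, 1 het, 2 hom-alt, −1 missing}
with a parallel read-depth matrix; VCF v4.2 (GT + DP) is the interchange
format. Coordinates are 1-based inclusive throughout. Cells masked for low
coverage and cells missing in the input share one missing state; a boolean
flag channel preserves masking provenance.

## Synthetic demography

The generator emulates the statistical structure of a range-wide lion
cohort, not its sequences.

**Allele frequencies.** Hierarchical Balding–Nichols: ancestral frequency
p ~ U(0.05, 0.5) per site; a subspecies frequency is drawn from
Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance F·p(1−p); clade
frequencies are drawn the same way around their subspecies frequency.
F = 0 is the no-drift limit (copy); F = 1 is rejected. Defaults:
F_subspecies = 0.15 for the north/south split, F_clade = 0.05 per clade
with the India clade raised to 0.5 to emulate its serial bottlenecks and
the resulting low heterozygosity. The Balding–Nichols hierarchy was chosen
over coalescent simulation because its closed-form moments make every
generator property testable, and it suffices to encode the
north/south > clade divergence ordering; it omits linkage, recombination
and selection entirely (sites are exchangeable and unlinked).

**Genotypes and admixture.** An individual with admixture vector q has
per-site dosage ~ Binomial(2, Σ_c q_c p_c). Admixed cohort individuals use
q = 0.5/0.5 between East Africa and West & Central Africa, the
Ethiopia/Kenya contact-zone analogue; the proportions are free parameters
of the generator, not estimates.

**Observation model.** Depth d ~ Poisson(λ_i) per cell; d = 0 is missing.
A true heterozygote with d ≥ 1 is observed heterozygous only if both
alleles appear among d uniform allele draws, i.e. with probability
1 − 2^(1−d); otherwise it is called homozygous for the sampled allele, each
direction equally likely. Homozygotes are observed as-is. Conditional on
being called, the observed/true heterozygosity ratio at rate λ is
1 − 2(e^(−λ/2) − e^(−λ))/(1 − e^(−λ)) — 0.124 at λ = 0.5 — which the test
suite verifies empirically. This depth-based missingness (rather than an
abstract missing rate) is deliberate: the panel-design criteria operate on
depth.

**Presets.** The discovery preset has ten individuals across the four
clades at λ = 3.8, one of them (the Benin analogue) at λ = 0.5; after
coverage-<3 masking that sample is ~98% missing — qualitatively the
near-failed sample of a real low-coverage cohort. The cohort preset has
211 individuals (50 West & Central Africa, 20 India, 60 East Africa, 66
Southern Africa, 15 admixed) at λ = 3.0 with a low-quality tail at λ = 0.8
(31 samples, ~45% missing) so the >25%-missing QC rule has work to do.
Cohort and discovery presets simulated at the same seed and site count
share their allele-frequency table, so a panel designed on the discovery
run applies directly to the cohort run. Default problem size for design
and assignment studies is 5,000 sites.

**Mitochondria and numts.** Six haplogroups (West Africa, Central Africa,
North East Africa, East/Southern Africa, South West Africa, India) are
keyed by candidate diagnostic sites on a synthetic 16,756-nt mitogenome:
four candidate sites split the northern lineage (West Africa, Central
Africa, North East Africa, India) from the southern two (East/Southern
Africa, South West Africa), and three private candidate sites mark each
haplogroup.
Haplotypes follow the key exactly; missingness uses each sample's e^(−λ)
zero-depth mass. Numt decoys are genome segments (3 × 800 nt by default)
mutated at a configurable per-site divergence (default 15%).

## Filtering

Masking is per cell: depth < 3 → missing, matching per-individual
ambiguity replacement. Site filtering keeps sites called in at least
{1, 3, 5, 8, all} individuals (configurable ladder). The canonical order
is mask first, then filter; the suite asserts the two orders genuinely
differ and that the pipeline uses the canonical one. Chromosome
attribution maps scaffolds through a scaffold→chromosome table (the tiger
karyotype's 18 autosomes in the synthetic data); unmapped scaffolds become
"unplaced".

## Panel design

Hard criteria per autosomal candidate: (1) summed depth across samples
≥ 20 at every one of the 101 window positions (strictest defensible
reading of "combined coverage across the flanks"); (2) at most one other
variable position in the flanks, totalled across both flanks (the
conservative reading; a per-flank mode is available); (3) a deterministic
mapping-quality proxy on optional per-window statistics (soft-clip
fraction, indel distance) replacing an irreproducible by-eye browser
check — absent statistics pass with an "unassessed" flag; (4) calls in ≥ 8
individuals; (6-hard) sites where every scored call is heterozygous are
excluded as putative collapsed duplications. Score = called-sample count
plus a bonus of 1 when both het and hom genotypes occur (criterion 6's
soft preference). Selection keeps the best candidate per scaffold, then
fills chromosomes round-robin by descending within-chromosome score until
the 125-SNP target; ties break on (chromosome, scaffold, position), making
the output byte-deterministic. The round-robin rule and the exact
score/tie-break are this package's operationalization of "evenly spread
across all chromosomes"; both are isolated in one function and recorded in
the output provenance columns.

The mitochondrial panel takes exactly two numt-clean subspecies-diagnostic
SNPs plus branch-private SNPs allocated round-robin over the six
haplogroups to the 14-SNP target; construction fails loudly if any branch
lacks a numt-clean candidate or if the target cannot cover all branches.
Numt screening locally aligns each candidate's 101-nt flank against every
numt (match +1, mismatch −1, gap −2, same strand); a candidate is at risk
iff an alignment covers the focal position with identity ≥ 0.8 over ≥ 40
aligned columns.

## Assignment

QC excludes samples with autosomal panel missingness strictly above 25%.
Clade assignment is a supervised Hardy–Weinberg likelihood classifier:
per-clade alternate-allele frequencies f are estimated from reference
samples with a pseudocount (default 1, keeping f in (0,1)), and a query's
log-likelihood per clade sums log HWE genotype probabilities over its
called SNPs; the posterior is the normalized likelihood under a uniform
prior. This replaces unsupervised clustering deliberately: the downstream
use — assigning samples to four known clades — is supervised in practice.
A caveat the suite documents: with ~120 informative SNPs the posterior is
an overconfident point-assignment device, and a 50/50 admixed individual
is usually still assigned to one parental clade with posterior > 0.9; the
admixture signal survives in the best-vs-second log-likelihood margin
(median ≈ 7 for F1 hybrids vs ≈ 19 for non-admixed on the cohort preset),
which is the property the tests assert. Detecting admixture reliably needs
a dedicated model, which is out of scope.

Haplogroup calls pick the key row matching the most called mtDNA SNPs.
Grading is a pure function of the call rate r over the 14 panel SNPs:
r < 0.60 → unknown ('?'); 0.60 ≤ r ≤ 0.85 (both ends inclusive) →
qualified; r > 0.85 → confident; an exact tie labels all winners and
forces the qualified grade. Conflicting called SNPs are counted and
reported. On 14 SNPs the r < 0.60 band is exactly the "≥ 40% of SNPs
failed" rule.

PCA mean-imputes missing dosages per SNP, centers, and fixes each
component's sign so its largest-magnitude loading is positive (sample-order
invariant). The dendrogram uses allele-sharing distance
d = mean(|g_i − g_j|)/2 over jointly called SNPs and neighbor joining;
pairs with no joint calls are an error.

## Heterozygosity and the D-statistic

Observed heterozygosity is het/scored per individual (missing excluded),
and at population level the mean over panel SNPs called in ≥ 5 population
members of the per-SNP het fraction. Report comparisons use Pearson and
Spearman correlations; constant vectors are flagged undefined.

The D-statistic uses the allele-frequency form so single diploid
individuals and multi-sample groups share one code path; the outgroup
enters as p4, and an absent outgroup sample is represented as fixed
reference (the ancestral-state proxy: the synthetic reference allele is
ancestral, as the tiger outgroup is in the real analysis). Significance:
sites (default) or fixed-size site blocks are resampled with replacement
1000 times; Z = D/sd(replicates); |Z| ≥ 3 — the usual field convention,
configurable — is flagged significant. A zero denominator yields an
undefined, flagged result.

Calibration studies use the group configuration with an exact null:
P1 = East Africa, P2 = Southern Africa (sister clades, exchangeable under
the hierarchy, so E[D] = 0 without gene flow), P3 = West & Central Africa,
outgroup fixed-reference. A non-sister ingroup (e.g. one northern and one
southern individual) has E[D] ≠ 0 under the hierarchical null through the
p2–p3 covariance and is therefore not usable as a null; the CLI leaves
group membership fully configurable. The power study injects the gene-flow
pulse (donor P3 → recipient P2, migrant fraction 0.3 on 20% of sites) into
the clade frequencies. Because the pulse yields a true D of only ≈ 0.02,
the calibration replicates run at 10^5 sites — the order of the real
analysis' SNP count — where power at |Z| ≥ 3 is ≈ 96% and the null
rejection rate ≈ 0%; at the 5,000-site design-scale preset the same pulse
is essentially undetectable (power < 10%), which is the expected behaviour
of D at small site counts, not a defect. Replicate bootstraps use 50-site
blocks: sites are unlinked, so block sums are iid and the variance
estimand is unchanged while the resampling cost drops by ~50×.

## Numerical choices and degenerate inputs

Beta parameters are guarded by clipping parent frequencies to
[1e−12, 1 − 1e−12]; pseudocount ≥ 1 keeps HWE log-probabilities finite;
posterior normalization subtracts the max log-likelihood before
exponentiation; bootstrap replicates with zero denominator become NaN and
are excluded from the sd; a zero bootstrap sd with nonzero D yields
Z = ±inf (flagged significant), with D = 0 giving Z = 0. Empty datasets,
all-missing samples, min_called above the sample count, unmapped
scaffolds, and non-empty output directories all have defined behaviour
(error, warning + empty result, "unplaced", or refusal, respectively).

## What passing tests do and do not show

The generator matches the analysis assumptions by construction: unlinked
biallelic sites, known clade labels, HWE within clades, depth-independent
genotyping error only through allelic dropout. Passing tests therefore
demonstrate the correctness and calibration of the implementation under
its own model, and the internal consistency of the published filtering and
selection rules — not robustness to linkage, reference bias, batch
effects, contamination or mis-specified reference panels, all of which
real data add. Problem sizes (5,000 sites for design/assignment studies,
10^5 sites × 100–200 replicates for D calibration, 100 seeds for
dichotomy recovery, 20,000 sites for the dropout closed form) are the
package's chosen desk-scale study conditions.
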