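# Methods

`vicariscan` re-implements, as a tested library, the population-genomic
toolchain used to dissect lake–stream divergence of threespine stickleback
under gene flow: haplotype-based RAD consensus genotyping, joint site
frequency spectra, haplotype-diversity F_ST scans, linkage-disequilibrium
(LD) profiles, EHH-family selection statistics, bulk-segregant mapping, and
chromosomal-inversion detection. Because the original raw sequence data are
not required, the package ships a forward-time synthetic-data generator
whose defaults encode the ecological-vicariance scenario the analyses are
designed to resolve; every analysis is validated against that generator's
truth ledger.

## The simulated scenario (simcore)

Four diploid Wright–Fisher populations — one lake, three streams — split
simultaneously from a 20× larger panmictic ancestor and afterwards exchange
migrants across the lake–stream boundary only (no direct stream–stream
migration). Ancestral standing variation at the moment of the split is
drawn from the neutral coalescent (msprime) with the ancestor's effective
size; the post-split phase is an explicit forward Wright–Fisher process so
that positive selection, inversions and migration compose mechanistically.
A purely forward burn-in to ancestral equilibrium would cost O(N_anc)
generations per run for no change in the founding state's distribution, so
the coalescent initialization is the default; a forward `burnin` parameter
exists for users who want it.

Defaults (the "study conditions" used throughout the tests):

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 5 Mb | desk-scale but multi-chromosome |
| RAD loci | 2,000 × 89 bp, in sister pairs flanking a restriction site | RAD stacks are paired flanks; 89 analyzable bp per read |
| N_anc / N_derived | 4,000 / 200 per population | ancestor ≥ 20× larger than each derived population |
| t_split | 100 generations | recent divergence; see rescaling note |
| migration | symmetric lake↔stream, per-stream rates (0.02, 0.01, 0.0025) | ranked gene-flow intensities reproduce ranked baseline F_ST |
| μ | 2.5 × 10⁻⁷ /bp/gen | desk-scale rescale: 4·N_anc·μ ≈ 4 × 10⁻³ per bp, ~2 SNPs per locus |
| r | 1 × 10⁻⁷ /bp/gen | desk-scale rescale: 4·N_anc·r ≈ 1.6 × 10⁻³ per bp |

**Rescaling note.** At desk-scale population sizes the literal per-bp rates
of the study organism would leave 4Nμ and 4Nr per bp ~50× too small:
haplotype homozygosity would barely decay within a chromosome, LD would not
decline over the 1–100 kb range the analyses bin, and every haplotype
statistic would saturate. Mutation and recombination rates are therefore
rescaled so that the population-scaled densities stay in the realistic
range; times (t_split, sweep onsets) are interpreted on the same compressed
scale. This is the standard coalescent-effective-size rescaling and is the
package's own choice of study conditions.

**Sweeps.** A sweep places the selected allele on copies of a single
founder haplotype (a `sweep_tract` of 400 kb around the site is copied from
the founder, representing the allele's single origin) at a configurable
initial frequency, then applies multiplicative per-copy selection
(1 + s)^dosage in the target population each generation. With s = 0.5 the
allele fixes in ≈ 15–25 generations; its hitchhiking footprint spans
roughly 1/(r·T_fix) ≈ 0.5 Mb per side at the default rates, which is the
spatial scale used when tests ask whether a scan "recovered" the sweep.

**Inversions.** An inversion is a single Mendelian karyotype pseudo-site at
the interval midpoint. The inverted arrangement originates once: carrier
chromosomes receive one founder's interior sequence plus fixed divergent
substitutions (rate `divergence`, default 2%, restricted to RAD locus bp).
During meiosis, crossovers falling inside the interval are discarded in
heterokaryotypes (single crossovers there produce unbalanced products);
homokaryotypes recombine freely. Optional double-crossover gene flux
(default rate 0) exchanges a short interior segment whose center is drawn
Beta(3,3) across the interval — biased away from the breakpoints.

**Frequency-restoring selection.** Inversion and plate-locus frequencies
are held near their target values by a per-copy restoring term
w ∝ (1 + g·(p_target − p))^dosage with gain g = 4. Without it, drift at
N = 200 would move a 0.30-frequency polymorphism by ±0.1–0.2 within the
simulated time span, destroying the very signal (a stable MAF class
mirroring the karyotype frequency) the inversion analysis keys on. The
device mirrors the balancing/divergent selection argued to maintain these
polymorphisms in the study system; equilibrium sd of the frequency is
≈ sqrt(1/(4·N·g)) ≈ 0.02.

**Plate phenotype.** A biallelic locus with a dominant C allele (default
map CC/CL → complete, LL → low; a codominant map with partials is
supported). Default frequencies: 0.8 in the lake, 0.3 in the streams. The
C allele is introduced as copies of one founder haplotype, so
completely-plated individuals share an extended haplotype — the signal the
Delta-iHS contrast detects.

**Coverage model.** Per (individual, locus): total depth ~ negative
binomial with mean 38.5 and size 10; the split between the two haplotypes
is beta-binomial with intraclass correlation ρ = 0.1 (the study reports
overdispersion relative to the binomial without a magnitude; 0.1 is this
package's choice); every read is mutated independently at 0.002 per base;
a `repeat_fraction` (default 5%) of loci additionally pool reads from 3–5
diverged paralog copies, which is what the repeat filters are meant to
catch (2-copy duplicates in homozygotes are undetectable in principle by
those filters, so the default emulates the high-copy families the filters
target). Reads from inverted arrangements drop out wholesale at loci whose
restriction site is disrupted by the inter-type divergence — probability
1 − (1 − d)^20 for an effective 20-bp recognition/anchoring footprint — or
whose fixed inter-type differences exceed a 2-mismatch unique-alignment
tolerance. These two attrition routes generate the stream:lake coverage
distortion the inversion scan detects.

**F2 cross.** Two parents homozygous for alternative arrangements found an
F1 pool of heterokaryotypes; F2 offspring (default 282) are produced by
F1 × F1 meioses with the same suppression machinery, and the phased gametes
plus founder genotypes travel with the genotype table so crossovers can be
counted exactly.

## Genotyping (radgeno)

The whole read is the genotyping unit. Per individual, loci are excluded if
their depth exceeds 3× that individual's mean locus depth or, when
polymorphic, if the two dominant read haplotypes account for ≤ 70% of
reads. Effective coverage is the summed count of the two dominant
haplotypes; ≥ 15 gives a diploid call (heterozygous iff c₂/(c₁+c₂) > 0.25,
evaluated in exact integer arithmetic as 3·c₂ > c₁), 2–14 a haploid call
from the dominant haplotype, and single reads are discarded. Ranking ties
break lexicographically by sequence. The SNP matrix pools consensus
genotypes across populations, emits at most six variant columns per locus
(the first six by position — the down-selection rule is unstated in the
source method, and a positional rule is deterministic) and drops SNPs whose
pooled haploid consensus coverage is below 80. Within a locus the two
genotype slots carry the consensus haplotype phase.

Expected accuracy is a property of the overdispersion: with ρ = 0.1 the
probability that a true heterozygote's minor-read fraction falls at or
below 0.25 is ≈ 0.18 (BetaBin(n ≈ 38.5, a = b = 4.5)), capping diploid
genotype concordance near 96%. The het/hom ratio rule is reproduced as
printed; the residual miscall rate is intrinsic to that rule at this
overdispersion, not an implementation artifact, and vanishes as ρ → 0.

## Site frequency spectra (sfsbuild)

Exactly 30 haploid consensus genotypes per RAD locus are drawn per focal
population (a diploid call contributes both copies); loci with fewer
available copies in any population are dropped. Loci with more than two
polymorphisms sharing an identical minor-allele count within the last 30
positions are excluded as micro-indel pseudo-SNP artifacts ("last 30
positions" is read literally as the final 30 bp and is configurable). The
joint spectrum counts the minor allele — defined on the pool of all four
populations — at each of the 89 positions of every retained locus;
monomorphic positions feed the (0,0) cell, and a pooled MAF of exactly 0.5
enters both orientations at weight 0.5. A locus with a tri-allelic column
is excluded entirely so the conservation identity (total weight = 89 ×
retained loci) holds exactly. Loci that never contributed a SNP to the
matrix are not represented (the matrix interface carries no monomorphic
loci); all spectra therefore share one locus panel. The fastsimcoal
observed-SFS writer puts the pair's second population on rows (`d1_*`),
matching the `<A>_<B>_jointMAFpop1_0.obs` convention.

## Differentiation and diversity (popdiv)

F_ST derives from haplotype diversity h = 1 − Σp², an analogue of
heterozygosity with maximum 0.5 for biallelic sites: H_S is the unweighted
mean of the two populations' h, H_T uses the unweighted mean frequencies,
F_ST = (H_T − H_S)/H_T with 0 where H_T = 0. No sample-size correction is
applied by default (negative values are reported as computed, so a null
baseline of ~0 is representable); `corrected=True` switches to the
unbiased n/(n−1) variant. Scans require ≥ 21 called haploid genotypes per
population and MAF ≥ 0.2 in the focal pool, then keep one SNP per locus
(highest F_ST; ties by position). Differentiation extremes are selected
greedily in descending F_ST across pooled pairings, deduplicated by
position, skipping candidates within 200 kb of an accepted SNP on the same
chromosome. The bulk-segregant scan pools stream individuals by phenotype
(24 per group, seeded draw) and applies identical conventions.

## Linkage disequilibrium (ldstats)

R² is the squared Pearson correlation of unphased genotype dosages
(composite LD); haploid calls contribute dosage 0/1 with the same weight as
diploid dosages. SNP selection excludes tri-allelic SNPs, SNPs with > 25%
missing calls and individuals with > 75% missing diploid calls, filters two
MAF ranges (0.05–0.275, 0.275–0.5; the full-range profile pools the two
sub-range pair sets before binning), and keeps one random SNP per
sister-locus pair. Decay profiles average R² in 1-kb distance bins to
100 kb; the windowed track averages pairs > 2 kb and < 50 kb apart by their
physical midpoint in non-overlapping 200-kb windows (width configurable);
Delta R² subtracts the stream track from the lake track window-wise; the
window correlation is tested against 10,000 permutations with the +1
correction, so P is never exactly zero.

## Haplotype statistics (haploscan)

EHH, EHHS, iHH, iES, iHS and Rsb all reduce to pairwise haplotype identity
over intervals, so the implementation precomputes, for every chromosome
pair, the next/previous mismatch index; a core's full decay curve then
follows from one bincount over pairs, which is what makes 20-seed scan
loops affordable. EHHS is normalized to 1 at the core; the Tang-style
unbiased homozygosity and the Sabeti-style C(n,2) ratio give the identical
normalized curve, so the `variant` flag only documents intent. Integrals
are trapezoid sums truncated where the curve drops below 0.05, with
inter-marker gaps capped at 20 kb (both configurable, following the cited
implementation's defaults). iHS uses the major allele as ancestral proxy
(no outgroup polarization) and standardizes within MAF bins of width 0.05
(chosen over per-SNP-frequency bins for small-sample stability); Rsb
median-centers and SD-scales ln(iES₁/iES₂); |Rsb| > 4 (strict) flags
extremes. Delta-iHS is the per-SNP score difference (group 2 − group 1)
averaged in 100-kb windows; calling it with the low-plated pool first makes
a recent sweep of the complete allele appear as a positive plateau.

## Inversions (invscan)

The coverage-ratio track normalizes each population's per-locus read counts
by its library total (so sequencing effort cancels), excludes loci under
200 pooled reads, and averages stream:lake ratios in 20-kb windows.
Candidate regions are maximal runs of ≥ 5 adjacent windows whose |log₂
ratio − genome median| exceeds 3 scaled MADs (the run-length/robust-z rule
is this package's concretization of "multiple adjacent windows"; both
parameters are exposed); a single missing window is bridged, a present
quiet window breaks the run. The MAF-class analysis histograms region MAFs
(one SNP per locus, singletons omitted) in 0.025 bins against the
genome-wide distribution and returns a 0.15-wide class centred on the most
enriched bin. Breakpoints are refined as the outermost members of the
longest contiguous block of class SNPs whose mean pairwise R² ≥ 0.8, after
first discarding class SNPs not linked at that threshold to the most
connected class SNP — without that cleaning round, neutral SNPs whose MAF
happens to fall in the class dilute the block mean so slowly that blocks
overshoot breakpoints by hundreds of kb. Karyotypes are called from
diagnostic class SNPs ≥ 20 kb from the refined breakpoints: majority-het
individuals are SL, otherwise the majority homozygous state votes SS
(minor/inverted) or LL, with "unknown" under 10 callable SNPs. Homozygote
pools (≥ 5 per class) support a per-SNP F_ST profile and a
shared/unique/fixed-difference classification of region loner SNPs.
Hardy–Weinberg uses a 1-df chi-square, or the Levene–Haldane exact test
when an expected class count is below 5; HWE should be tested per
population — pooling demes with different karyotype frequencies produces a
Wahlund heterozygote deficit by construction. F2 crossovers are counted as
parental-origin switches between adjacent informative markers (founders
homozygous for different alleles), with the recombination fraction
count/(2 × offspring).

## What the synthetic data do and do not establish

The generator reproduces the statistical structure the analyses assume:
overdispersed RAD read counts, repeat contamination, ranked gene-flow
intensities, single-origin sweeps and inversions with suppressed
recombination, and a dominant plate locus on a shared haplotype. It does
not model base-quality error profiles, alignment against a real reference
(mapping loss is parametric, not sequence-driven), statistical-phasing
error (haplotypes are phased by construction, standing in for external
phasing), overlapping generations, or linked background selection. Green
tests therefore demonstrate correctness of the statistics and recovery
power under the modeled data structure, not robustness to artifacts absent
from the model.

## Test and acceptance problem sizes

Unit tests run on a 100-locus, 4 × 30-diploid scenario (seconds).
End-to-end checks use the full study conditions: 2,000 loci with 4 × 24
sampled diploids for the genotyper, SFS, calibration and selection-recovery
scenarios (20 seeds for the sweep and bulk-segregant recoveries); the
inversion scenario uses one 5-Mb chromosome at 3,200 loci, matching the
study's marker density of ~13 loci per 20-kb window, on which the
coverage-ratio rule was designed. `scripts/acceptance.py` re-runs the same
scenarios at 6 seeds per recovery loop and writes every measured quantity
as JSON.
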