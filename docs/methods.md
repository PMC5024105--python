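# Methods

`echinopop` implements the complete two-marker population-genetics workflow
used in shallow-phylogeography surveys of low-dispersal marine invertebrates:
a maternally inherited sequence marker (typically a 657-bp COI fragment) and
a panel of diploid microsatellite loci, sampled from populations nested in
geographic regions (ocean basins). This note documents the models, the
estimators, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Markers and carriers

Sequences are held as an aligned panel over {A,C,G,T,-,N}. Sites carrying a
gap or N are handled pairwise-complete: each pairwise comparison uses only
the sites where both sequences carry a base. This mirrors common DNASP-style
behaviour and avoids shrinking the alignment globally because of a single
ragged sequence. Microsatellite genotypes are unordered pairs of allele
sizes in bp with a per-locus repeat-motif length; the GenePop reader accepts
the 3-digit dialect only (alleles under 1000 bp; `000000` = missing), and a
genotype must be fully present or fully missing.

## Diversity

* Haplotype diversity: Nei's unbiased gene diversity
  `h = n/(n-1)(1 - sum p_i^2)`, with the Nei (1987, eq. 8.12) sampling SD.
* Nucleotide diversity: mean pairwise difference per compared site over all
  C(n,2) pairs; SD is the square root of Nei's (1987, eq. 10.7) total
  variance (which includes the stochastic component, matching how sequence
  surveys usually report it).
* Rarefied richness: the exact hypergeometric expectation
  `sum_i [1 - C(N-N_i, g)/C(N, g)]` (Hurlbert rarefaction; El Mousadik &
  Petit allelic richness for microsatellites). Default subsample g = 8
  gene copies for sequences (a typical smallest-population size in such
  surveys); for microsatellites the default is the smallest per-locus
  gene-copy count in the dataset. Because field reports sometimes print a
  diversity under a "richness" heading, the diversity table emits *both*
  Nei's h and the rarefied richness under unambiguous column names.
* Heterozygosities: Ho is the fraction of heterozygous individuals; He is
  Nei's gene diversity with the unbiased 2n/(2n-1) correction (plug-in
  variant available via a flag).
* FIS: the Nei (1977) ratio-of-sums multi-locus form `1 - sum Ho / sum He`,
  with a percentile confidence interval from bootstrap resampling of loci
  (default 100 resamples) and per-locus values alongside.
* Hardy-Weinberg: a permutation test whose statistic is |multi-locus FIS|
  and whose null shuffles gene copies among individuals within the
  population independently per locus (default 1,001 permutations). All
  Monte-Carlo p-values use the (count+1)/(n+1) correction, so p is never 0.

## Haplotype networks and substitutions

The network is an epsilon-zero minimum-spanning network: Kruskal's MST on
pairwise-complete Hamming distances, augmented with every tied-weight edge
that joins two components at the moment its weight class is processed (so
every edge belonging to some MST is kept). This is deliberately simpler
than median-joining: for shallow, loop-free networks dominated by one- and
two-step links, inferred median vectors add no resolution. Multi-step edges
(weight > 1) are flagged, following the usual "hatch marks" plotting
convention. Tie-breaking is deterministic (weight, then node order), so
output is reproducible.

Substitutions are classified against the most frequent haplotype by codon
translation under the invertebrate mitochondrial code (translation table 5).
The reading-frame offset is a required analysis input because an amplicon's
frame is a property of the primer design, not of the alignment; sites in
incomplete trailing codons or codons containing gaps/N are reported as
`untranslated` and excluded from non-synonymous counts.

## Differentiation

**AMOVA.** A single method-of-moments engine decomposes the matrix of
squared inter-unit distances over an arbitrary nested design. Sums of
squared deviations per stratum come from the standard identity
`SSD(cluster) = (1/n_c) sum_{i<j in c} d^2_ij`; expected-mean-square
coefficients for unbalanced designs are computed from sums of squared
cluster sizes (Searle-type nested-ANOVA coefficients), and the triangular
system is solved bottom-up. The haploid design has three strata (among
groups / among populations within groups / within populations) on pairwise
sequence-difference counts; the diploid design adds a within-individual
stratum and operates on gene copies, with the inter-copy distance the count
of loci (complete-case) carrying different alleles. Fixation indices follow
from the variance components; the identity
`(1-Phi_CT)(1-Phi_SC) = (1-Phi_ST)` holds to machine precision on raw
components. Percent-variation columns clamp negative components at zero
(the usual reporting convention); raw components are always retained.
Significance: Phi_ST/F_ST permutes individuals among all populations,
Phi_SC/F_SC permutes individuals among populations within groups, and
Phi_CT/F_CT permutes whole populations among groups. A group containing a
single population makes the SC contrast vacuous; the result is flagged and
the vacuous component set to zero. With few populations per group the CT
permutation space is small and its p-value granular — a property of the
design, not of the implementation.

**Pairwise statistics.** Phi_ST is the two-population AMOVA on pairwise
difference counts (no substitution-model correction: at the within-species
divergences involved, multiple hits are negligible and the model choice is
not identifiable). F_ST is Weir & Cockerham's (1984) theta, summed over
alleles and loci in ratio-of-sums form; monomorphic loci contribute nothing.
Jost's D uses `D = (HT-HS)/(1-HS) * k/(k-1)` with k = 2 for pairs; the
default estimator applies the Nei & Chesser (1983) small-sample corrections
(with the observed-heterozygosity term for diploid data, without it for
haploid haplotype counts, using harmonic-mean sample sizes), and a plug-in
variant is available for didactic examples. Negative estimates are reported
raw and clamped at zero in display columns. For each statistic the p-values
come from permuting individuals between the pair (the permutation scheme is
the configurable choice; a bootstrap alternative was not implemented since
nothing downstream depends on it), and Benjamini-Hochberg step-up adjustment
is applied across all pairs.

**Isolation by distance.** Mantel correlation over lower triangles with
joint row/column permutations; the stratified variant permutes population
labels only within declared strata (basins), which removes between-basin
divergence from the null and is the standard way to ask whether an IBD
signal survives regional structure. Single-member strata stay fixed;
an all-singleton stratification is rejected. For four populations the exact
4! enumeration is available and is used as the test oracle.

**Ordination and clustering summaries.** Non-metric MDS minimises Kruskal
stress-1 via scikit-learn with 20 seeded random restarts (eps 1e-12,
max 2000 iterations), returning centred coordinates; fixed seed gives
bit-identical output. Evanno's DeltaK summarises externally produced
clustering log-likelihood tables: `|L(K+1) - 2L(K) + L(K-1)| / sd(L(K))`
over replicate runs; zero-sd rows are flagged rather than divided through.

## Demography

**Mismatch distribution.** Observed histograms count pairwise differences
over all pairs. The sudden-expansion model is evaluated as the exact
transient (Li-type) distribution of a pair's difference count when the
coalescence hazard is 1/theta1 during the last tau mutational units and the
residual time beyond tau is exponential with mean theta0:

    F_i = Fhat_i(theta1) * P(Gamma(i+1) <= tau(1+theta1)/theta1)
          + e^(-tau/theta1) * sum_j Pois_j(tau) * Fhat_{i-j}(theta0),

with `Fhat_i(theta) = theta^i/(1+theta)^(i+1)`. This is used instead of the
classical large-theta1 approximation because it is exact at all parameter
values, reduces to the equilibrium form at tau = 0 (and for theta0 =
theta1 at any tau), and sums to one by construction — properties the fit
relies on. Fitting minimises the SSE between observed and model
frequencies by bounded least squares from several moment-based starts
(tau_0 ~ mean - theta0_0); fits pinned at tau ~ 0 or from degenerate
histograms are flagged as boundary cases.

**Dating and conversions.** `tau = 2ut` with u = L x (per-site rate per
generation) converts expansion age to generations, evaluated across a rate
range (default 2.3e-8 to 3.6e-8 per site per generation, i.e. 2.3-3.6% per
million generations per lineage — the only reading of that rate convention
consistent with the published effective-size arithmetic for this marker).
For the maternal marker, `Nf = theta/(2 L r)`; integer rounding is applied
for reporting with the raw value retained. Migration is expressed as
`Mt = m/mu` migrants per generation, and exponential growth as
`theta_t = theta1 e^(-G t)` (LAMARC's convention; the superscripted form
sometimes typeset in print is read this way). Genealogy-aware theta
estimation (MCMC) is out of scope; a moment estimator (mean pairwise
differences per sequence) is provided so the conversion chain runs
end-to-end and is labelled as such in outputs.

**Bottleneck tests.** For each polymorphic locus the observed unbiased He
is compared with the equilibrium He expected *given the observed allele
count k*: theta* is solved so that the equilibrium expected allele count
equals k (Ewens' formula for IAM, closed form; deterministic simulation
bisection for SMM/TPM), samples of the same gene-copy count are simulated
at theta* (Hoppe urn for IAM; an internal Kingman coalescent with stepwise
mutation otherwise), and replicates with exactly k alleles are retained
(falling back to all replicates when conditioning acceptance is too low).
Significance comes from a Wilcoxon signed-rank on per-locus (He_obs - Heq)
differences, with an exact null by dynamic programming on doubled midranks
for up to 25 informative loci (valid under ties) and a continuity-corrected
normal approximation beyond; both one-tailed directions and the two-tailed
p are reported. Fewer than four informative loci cannot reach p < 0.05
two-tailed and the result is flagged. "Replicates" (default 1,000) are the
Heq simulations; the Wilcoxon itself is exact.

**M-ratio.** Per locus `M = k/(rho+1)` with rho the allele-size range in
repeat units (an allele-size range not divisible by the motif indicates a
binning error and is rejected). The critical value Mc is the 5th percentile
of M in equilibrium samples simulated under a two-phase model (defaults
ps = 0.9, mean multi-step size 3.5, 10,000 simulations); decline is
inferred when the observed mean M falls below Mc. Theta for the Mc
simulation must be supplied by the analyst — it is not estimable from the
ratio itself and dominates Mc — and is echoed in the result metadata.

## Synthetic data

Genealogies come from msprime (Hudson coalescent): constant size,
exponential growth, sudden size changes, and island-model migration
(symmetric 2Nm, optionally hierarchical with separate within- and
between-basin rates). Time is expressed in coalescent units at the
interface; because mutational age is tau = theta x t (t in coalescent
units, theta per sequence), expansion-dating tests can assert tau recovery
directly. Sequence mutations are infinite-sites (binary, mapped to distinct
integer sites, erroring if S > L) or finite-sites Jukes-Cantor; no rate
heterogeneity, recombination, selection or sequencing error is modelled.
Microsatellite loci get independent single-tree genealogies; allele states
evolve along branches under IAM, SMM or TPM (Poisson mutations per branch;
multi-step sizes geometric with mean 3.5 by default), and diploids are
formed from the simulator's within-deme pairing with an optional
inbreeding knob F (an individual's two copies become identical by descent
with probability F, per locus). All randomness flows from a single seeded
generator per call; file outputs are byte-identical across runs of the
same seed.

`make_study_like_dataset` emulates the survey design this pipeline targets:
15 populations (2 Atlantic, 9 western Mediterranean, 4 eastern
Mediterranean), 8-30 individuals each, 657-bp sequences in the low-pi
regime (theta_site = 0.0009 plus a very recent sudden expansion and
region-diagnostic substitutions), 8 SMM loci, and a coastline-like sea
distance matrix. Passing tests on this generator demonstrates that the
estimators behave correctly under the *assumed* coalescent models; real
data add artefacts deliberately not emulated (null alleles and scoring
error at microsatellites, selection on the mitochondrion, uneven sampling
in space and time), so conclusions about robustness to those do not follow.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to what the
closed-form comparisons need: calibration means use 120-500 replicates
(assertions at 3 SE), expansion-age recovery uses 30-50 replicates of
n = 30 sequences, detection-rate checks use 30-50 replicate panels of 8
loci with 150 equilibrium simulations per locus, and Mc uses 2,000-10,000
simulations. These sizes are statements about the precision the assertions
require, and they keep the whole suite comfortably re-runnable; all heavy
pieces cache nothing across processes and honour the supplied seed.

## Known limitations

* The diploid AMOVA treats missing genotypes complete-case per locus inside
  a summed distance, which slightly down-weights individuals with missing
  data rather than imputing them.
* Jost's D for multi-locus data is the arithmetic mean of per-locus D; the
  multiplicative (effective-number) pooling is not implemented.
* The bottleneck Heq conditioning follows the classical
  simulate-and-condition recipe; for very large k at small n the rejection
  acceptance drops and the flagged fallback (unconditioned mean) is used.
* The CT-level permutation p is granular when groups contain few
  populations (an inherent property of permuting whole populations).
* Mc depends strongly on the supplied theta; the package deliberately
  refuses to guess it.
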