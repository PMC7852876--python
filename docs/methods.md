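# Methods

## The model

A fully inbred line is maintained at two diploid individuals per
generation.  At mutation–drift equilibrium the line still segregates
variation: new mutations enter at rate 4·L·μ per generation (four haploid
genomes over L callable sites, μ per site per generation) and are lost or
fixed by drift within a few generations.  A segregating site is classified
by the joint genotype of the two sampled sibs, A and B, into one of seven
configurations — the unfolded two-sib site frequency spectrum (SFS):
RARR, RRRA (one alternative copy), RARA, AARR, RRAA (two copies), AARA,
RAAA (three copies).  Monomorphic configurations (zero or four copies) are
not part of the spectrum.

Under neutrality and infinite sites each mutation evolves independently,
so a mutation's configuration follows an absorbing Markov chain over the
seven transient states, absorbing at loss and fixation.  A new mutation
arises in one gamete of one of the next generation's two individuals, so
its start distribution is ½ RARR, ½ RRRA.  The fundamental matrix
(I − Q)⁻¹ gives the expected number of generations spent in each state
(sojourn time); the equilibrium SFS is

  E[S_i] = 4·L·μ · t_i,   t_i = sojourn time in element i,

and the expected segregating total is 4·L·μ·T with T = Σt_i the mean
segregating lifetime.  The equilibrium *proportions* t_i/T are independent
of μ and L, which is what makes the spectrum usable for rate estimation.

### Offspring models

Two transition kernels are implemented and a caller must choose one
explicitly:

- `sib_mating` — strict brother–sister mating: each offspring receives
  one allele from parent A and one from parent B.  Mean lifetime
  T = 29/6 ≈ 4.833; equilibrium proportions (8/29, 8/29, 8/29, 1/58,
  1/58, 2/29, 2/29).
- `wf_selfing` — Wright–Fisher with N = 2, selfing permitted: each of an
  offspring's two alleles is an independent draw from the parental allele
  pool (alt with probability q = (g_A+g_B)/4).  T = 107/29 ≈ 3.690;
  proportions (158/535, 158/535, 18/107, 9/214, 9/214, 42/535, 42/535).

The two differ qualitatively: under `wf_selfing` the double-heterozygote
RARA proportion (0.168) is close to the three-copy classes combined
(0.157) and about twice the single-homozygote classes combined (0.084);
under strict `sib_mating` RARA equals the single-heterozygote classes
(8/29 each).  The reference SFS shape that the estimation targets is the
`wf_selfing` one, which is therefore the default throughout; strict sib
mating is retained as the alternative kernel.

The chain is exchange-symmetric in the A/B labels, so the symmetric state
pairs can be lumped into four classes exactly.  The lumped 4×4 solve is
implemented from independently derived class-level offspring
distributions and is used as a cross-check of the authoritative 7-state
solve (they agree to 1e-10).

### Effective size of a full-sib line

Heterozygosity under brother–sister mating follows
H_t = H_{t−1}/2 + H_{t−2}/4.  The dominant root of its companion matrix,
λ = (1+√5)/4 ≈ 0.809, is the asymptotic per-generation retention;
equating to the Wright–Fisher decay 1 − 1/(2N_e) gives
N_e = 1/(2(1−λ)) ≈ 2.618, i.e. 2.6 at two significant figures.  The
classical diversity expectation 4·μ·N_e·L built on this N_e is close to,
but not identical with, the chain's exact segregating-site expectation
4·μ·L·T (for `wf_selfing`, 4μL·2.618 vs 4μL·3.690 — note the former is a
pairwise-diversity quantity while the latter counts sites segregating in
the sample of four genomes; the coalescent sample-of-four analogue
4·N_e·μ·L·(1+½+⅓) with N_e = 2 is within 1% of the exact value).  The
pipeline reports both expectations side by side and asserts neither.

## Forward simulation

The simulator is event-based: each segregating mutation is one
independent realisation of the genotype-pair chain, held as per-state
counts and advanced by multinomial draws; Poisson(4·L·μ) new mutations
enter per generation, split binomially between RARR and RRRA.  This is
exact under neutrality and infinite sites because marginal per-site
dynamics do not depend on linkage; the per-adjacent-site recombination
rate is accepted for interface parity and has no effect in this mode.  A
literal genome-array engine (four haplotype arrays, recombination,
linkage) exists for validation at small L; a contingency chi-square on
pooled SFS counts from the two engines is part of the test suite.

Replicate r uses the documented stable stream
`SeedSequence(master_seed, spawn_key=(r,))`, so ensembles are bit
reproducible and embarrassingly parallel in principle.

Ensemble summaries average per-replicate *proportions* (each replicate's
spectrum normalised first); replicates with zero segregating sites at a
generation are excluded from that generation's proportion average and
counted.  The per-element SEM is the across-replicate standard deviation
divided by √replicates.  The equilibration generation is the smallest
1-based generation from which every element's mean proportion stays
within a tolerance (default 0.02 absolute — "approximately constant"
needs an operational definition and 2 percentage points is well above the
ensemble's Monte-Carlo noise) of its final value; a constant trajectory
returns generation 1.  At the reference configuration (μ = 1e−8,
L = 2,725,521,370, 100 generations, 1000 replicates) the ensemble runs in
a few seconds, reaches ≈402 segregating sites (the renewal expectation),
stabilises around generation 8–10, and has per-element SEMs below 0.1
percentage points.

## Variant filtering

Strain-specific variants are detected in a joint, all-sites,
multi-sample VCF containing the focal pair, the other strains' inbred
individuals, and unrelated wild "bait" genomes.  The automated criteria
(1–6: QUAL ≥ 90; DP ≥ 10 in every inbred sample; ≤ 1 alt-supporting read
summed over baits and, separately, over non-focal inbreds; an otherwise
hom-ref background with 1–3 alternative copies in the focal pair; SNV
only) define the *pre-check* set; the review-stage criteria (7–10:
heterozygous allele balance ≥ 0.25; focal-pair depth ≤ 2× its genomic
mean; no phase/proximity cluster with another candidate; ≤ 2 alleles)
define the *post-check* set.  Mapping quality is deliberately not used:
joint genotypers do not emit it comparably for variant and non-variant
records.  Notable interpretation choices:

- Purity (criteria 3/4) counts reads via AD summed over alt alleles;
  genotype calls are ignored.  The one-read allowance is summed per site
  across all samples of the class, not per sample.  Missing AD where
  alt-read counting is needed marks the criterion not-evaluated and the
  site fails closed, as does a missing focal genotype.
- The copy cap in criterion 5 (≤ 3) excludes fixed strain differences
  (four copies), which are consistent but uninformative about recent
  mutation.
- Criterion 8 compares the focal pair's summed DP with twice the focal
  pair's mean genomic summed DP (estimated from a streamed subsample of
  records, stride configurable, or supplied).  Restricting to the focal
  pair matters: a strain-specific collapsed duplication elevates depth
  only in the carrier strain, and averaging depth over all twenty samples
  would dilute the signal below the 2× threshold.
- Criterion 9 is a VCF-level approximation of "in phase with other
  variants": a site fails if another primary-passing candidate lies
  within a 100 bp window (configurable) or shares a phase-set (PS) value
  with one.  The genotyper's own active-region machinery is not
  reconstructable post hoc.
- Criterion 11 (mate-pair on another chromosome) requires BAM evidence;
  it is recorded as not-evaluated and never gates a decision.  This is a
  documented extension point.
- QUAL on non-variant records: hom-ref blocks typically carry no
  comparable QUAL, so a missing QUAL passes criterion 1 on records with
  no ALT allele (override available).

L, the callable-site count entering all expectations, is the number of
sites — variant or not — passing criteria 1–4; counting it literally
requires an all-sites VCF and the counter refuses variant-only input.

When the pre-check set is large, a random sample (100 by convention) is
review-checked and the post-check total is extrapolated as
round(pass_fraction × pre-check count); the observed spectrum is then the
pre-check spectrum scaled by the pass fraction.  When the pre-check set
is no larger than the sample size, every site is reviewed and the result
is exact.

## Rate estimation

With u the expected SFS computed at a reference rate (1e−8 by default;
from the exact chain, or from a simulation ensemble when mirroring the
original experiment literally) and v the observed spectrum, the estimate
minimises d(μ) = Σ(μ·u_i − v_i)² over included elements.  RARA is
excluded by default: misaligned paralogous duplicates masquerade
specifically as shared heterozygotes, and the double-heterozygote excess
they create inflates only the with-RARA fit (a property the tests
assert).  The minimiser is located by golden-section search over
[0, max(10, 2× the analytic minimiser)] in reference-rate units, stopping
at three-significant-digit stability of the interval midpoint (max 50
iterations; the bracket expands once, with a warning, if the optimum
touches the upper edge).  The objective is an exact quadratic whose
closed-form minimiser Σu_i·v_i / Σu_i² (clamped at zero) serves as the
search's independent cross-check, never its replacement.

The 95% CI resamples the same total number of segregating sites from the
observed element proportions (multinomial over included elements),
re-runs the search per resample (vectorised), and takes empirical
2.5/97.5 percentiles; no bias correction.  Desk-scale default is 1e4
resamples (the analysis-scale convention is 1e6, which the vectorised
search also handles in seconds).

**Known limitation (measured, deliberate):** the fixed-total multinomial
bootstrap quantifies *compositional* uncertainty conditional on the
observed segregating total.  At equilibrium the per-element counts are
independent Poisson, so the estimator's dominant sampling error is the
fluctuation of the total itself — which a fixed-total resample cannot
see.  Analytically Var_boot/Var_true = 1 − (Σu²)²/(Σu·Σu³) ≈ 0.17 at the
`wf_selfing` equilibrium with RARA excluded; empirically, "|μ̂ − μ| ≤
3×bootstrap-SE" holds in ~75–80% of synthetic trials with Poisson totals,
versus ~96% when the total is held fixed.  The CI is therefore a
conditional interval; the coverage test in the suite draws v at fixed
total (the regime the resampling scheme models), and the end-to-end
recovery check documents the unconditional shortfall rather than hiding
it.

## Synthetic data

The generator emulates the target study design — four strains × two
focal individuals plus twelve wild baits — over a reduced genome (default
1 Mb across two chromosomes) with μ scaled up to 1e−5 so per-strain
variant counts land in the low hundreds, the same count regime as a
gigabase genome at 1e−8.  Per strain it draws the segregating total
Poisson(4·L·μ·T), element labels multinomially from the exact equilibrium
proportions, and renders a standards-conformant VCF (GT/AD/DP, QUAL,
contig headers, PS at paralog clusters) with every other sample hom-ref.
Six labelled artifact classes are injected, each designed to fail one
specific criterion: paralog clusters (3–8 double-het sites within ~80 bp,
focal depth 2.3–2.8× mean, shared PS → criteria 8/9), bait impurities
(2 alt reads in a bait → 3), low-QUAL (→ 1), low-depth (→ 2),
multi-allelic (→ 10) and indel sites (→ 6).

True variants are drawn from the *callable* genome, so their nuisance
fields are sampled conditional on callability: QUAL ~ U[200, 2000];
inbred depths NB(mean 30, size 10) truncated to [10, 1.8×mean] (criterion
2 is part of the callability definition, and callable sequence excludes
collapsed repeats); heterozygote AD ~ Binomial(DP, 0.5) conditioned on
balance ≥ 0.25.  Positions are uniform subject to a 200 bp minimum
spacing (clusters placed as units): at the density being emulated
(hundreds of variants over gigabases) chance sub-window proximity is
negligible, and without the spacing the 1000-fold density inflation of
the test-scale genome would cause the proximity filter to reject true
variants — an artefact of the reduction, not of the method.  Consequently
the filter recovers the truth *exactly* on generated data (the round-trip
tests assert equality, not approximation), and every injected artifact is
rejected with its designed criterion recorded.

What the generator does **not** model: read-level errors and alignment
(FASTQ/BAM), genotype-calling noise, shared (non-strain-specific)
paralogy, linked selection or balancing selection, context-dependent
mutation spectra, and the read-mate signature of criterion 11.  Passing
tests therefore demonstrate the correctness of the filtering logic and
estimator on well-formed joint-genotyped input, not robustness to
upstream caller pathologies.

Emitting gigabases of hom-ref records is infeasible, so callable counts
are written as a per-chromosome sidecar (configured L minus emitted
records failing criteria 1–4); an all-sites mode (L ≤ 1e5) emits every
record so the literal counter can be exercised.

## Numerical and interface choices

- All linear solves are direct (7×7); no iterative tolerances.
- Absorption certainty (spectral radius of Q < 1) is asserted before
  inverting I − Q.
- Reported rates carry explicit units: multiples of the reference rate
  and the absolute per-site per-generation rate.
- Every CLI run writes a JSON manifest (settings, seeds, input SHA-256,
  version); report tables are byte-deterministic given config and seed.
- Problem sizes used by the test suite and the analysis scripts (1 Mb
  genomes, 1e4 bootstrap resamples, 1000-replicate ensembles) are the
  package's desk-scale defaults; every size is a parameter and the
  genome-scale values are exercised where cheap (the ensemble and the
  oracle run at L = 2,725,521,370 directly, since the event-based engine
  scales with the variant count, not with L).
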