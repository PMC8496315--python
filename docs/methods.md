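# Methods

## Model

The package simulates the joint dynamics of three proto-sex chromosome
pairs in the house fly: X/Y^M, III/III^M (both derived alleles carry the
male determiner *Mdmd*) and IV/IV^F (the derived allele carries the
epistatically dominant female determiner *Md-tra^D*). Sex is recomputed
from genotype everywhere: any IV^F copy → female; otherwise any Y^M or
III^M copy → male; otherwise female. Because males never carry IV^F, the
IV^F/IV^F homozygote is unreachable and the diploid space has exactly 18
members — 10 female genotypes (f1..f10) and 8 male (m1..m8), ordered
canonically with f1 = X/X; III/III; IV/IV first. Genotypes are unordered
allele multisets per pair (no parental-origin tracking; the model has no
imprinting) and chromosomes carry no internal variation: every copy of a
derived chromosome has identical fitness effects, i.e. complete linkage
between the sex determiner and the selected variation, and no
recombination is modelled within or between the sex-determining loci and
selected alleles.

### Fitness

Selection coefficients s[sex][chromosome] are drawn i.i.d. from
Uniform(−1, 1), six per fitness array (s[male][IV^F] exists for symmetry
but is never consulted). Single-pair fitness follows the dominance table
reproduced in the README; three conventions matter:

* The table's orientation is adopted as printed: for proto-Y pairs a
  positive s gives the derived-homozygote fitness 1 and penalises the
  standard homozygote (1−s), and a negative s mirrors this. Because the
  prior on s is symmetric, screen-level results are invariant to this
  orientation choice.
* The overdominant scheme applies to proto-Y pairs in males only — the
  male heterozygote always has fitness 1 and both homozygotes 1−|s| — and
  females fall back to the additive rows. This encodes proto-Ys carrying
  male-beneficial alleles alongside recessive deleterious alleles of equal
  magnitude, with equal fitness of the two homozygotes.
* The IV^F pair has a single carrier state (IV/IV^F), assigned the full
  effect 1−s for either sign of s. With only one carrier genotype, any
  half-effect scaling would simply be absorbed by the uniform prior; the
  full-effect convention keeps "negative s = female-beneficial" literal
  for the proto-W and fixes the sign convention of the effect–frequency
  correlation (benefit = −s).

Multi-genotype fitness is the product of the three single-pair values
evaluated with the genotype's sex. Coefficients of ±1 give fitness 0;
both engines tolerate zero-fitness genotypes (they simply get zero
parental weight), and a sex whose total parental weight reaches zero
raises an extinction error (deterministic) or flags the replicate
(finite).

### Deterministic recursion

One generation maps zygote genotype frequencies to the next by
(i) parental weights freq·w normalised within each sex — viability and
fertility selection coincide under this multiplicative weighting;
(ii) egg and sperm pools as the weight-averaged Mendelian gamete
distributions (independent assortment of the three pairs, heterozygous
pairs transmitting either allele with probability 1/2); (iii) random
union of gametes; (iv) epistatic sex determination of zygotes. The zygote
sex ratio is emergent, not forced to 1:1, and chromosome frequencies are
computed over zygotes weighted by the realised sex ratio:
freq[d] = Σ_g p(g)·count_d(g)/2.

The engine is vectorised over batches of fitness arrays. All contractions
use `numpy.einsum` rather than BLAS matmul deliberately: einsum's
summation order per output element is fixed, which makes batch results
bitwise independent of batch size (a tested invariant), at a modest
constant-factor cost. Each generation renormalises the frequency vector
(zygote construction is conservative up to rounding; renormalisation
stops drift of the sum over 10^6-generation horizons), and frequencies
below 1e-300 are flushed to zero to avoid denormal slowdown (logged at
debug level).

### Thresholds and classification

A derived chromosome is *lost* below 0.1% of its chromosome pool, *fixed*
above 99.9%, else *polymorphic*; PSD is maintained when all three are
polymorphic. The open interval matters at the 1000-generation screen:
arrays already beyond 99.9% at generation 1000 are not counted as
maintaining. A deterministic recursion cannot reach 0 or 1 exactly in
finite time, so thresholds are the only loss/fixation criteria (the flush
limit is 296 orders of magnitude below the loss threshold and cannot
affect classification).

Long-horizon runs allow early exit once all three derived-allele
frequencies change by less than 1e-14 in one generation. Any remaining
drift over a 10^6-generation horizon is then bounded by 1e-8, negligible
against the thresholds; a test verifies that classifications with early
exit on and off agree, and the full-horizon result is reproducible with
`early_exit=False`. Trajectories that never meet the criterion (e.g.
slow, near-neutral declines) simply run the full horizon.

### Wright–Fisher layer

Finite populations apply one multinomial draw of N zygotes per generation
from the deterministic expectation computed at the realised frequencies —
the simplest sampling scheme that layers drift on the same recursion;
selection is embedded in the expectation. Replicates use independent
spawned substreams of a master `SeedSequence`, so results are independent
of execution order and fully reproducible from (seed, N, generations,
replicates, fitness). Replicates are initialised by a multinomial draw
from the starting distribution (largest-remainder exact counts available
via `exact_init=True`; the choice is a config knob because the historical
initialisation is not documented). Fixation/loss are absorbing copy-count
states (0 or 2N); Pfix of a derived chromosome equals Ploss of its
standard homolog by construction, and extinct replicates are excluded
from the denominators and reported separately. Selection-vs-drift
fixation counts are compared with the two-sided (minimum-likelihood)
Fisher's exact test; the deficiency/excess direction is read from the raw
proportions, not the test.

### Fitting and antagonism summaries

Rejection fitting is plain top-k: among maintaining arrays, rank by the
mean over the three chromosomes of (simulated − observed frequency)² and
keep the k best; ties break by ascending array id so the ranking is total
and order-invariant. No ABC kernels, tolerances or SMC. The intersexual
correlation ρMF is Spearman's rank correlation (average ranks on ties)
of fitness across the eight male–female genotype pairs differing by one
IV^F copy; constant vectors make it undefined and are reported as NaN and
counted separately. The IV^F effect–frequency association reports both
the benefit convention (−s vs frequency) and the raw-s correlation.

## Synthetic inputs and what the tests show

All inputs are generated internally. The coefficient sampler, the four
dominance schemes, the equal-frequency starting state (all 18 genotypes
at 1/18) and the monogenic-ZW state (f10/m8 at 1/2 each) reproduce the
study conditions directly. The observed CA/NC/NY chromosome-frequency
tables are the exception: the exact values live in primary references and
supplementary material not shipped here, so the package carries clearly
labelled synthetic placeholders consistent with the published ranges
(III^M < 3% of third chromosomes, IV^F between 2 and 9% of fourth
chromosomes, Y^M intermediate). Consequently the best-fit-conditioned
analyses (population-specific loss rates, deficiency/excess counts,
distribution shapes) are exercised mechanically but their quantitative
outputs should not be compared against published population-specific
numbers; passing tests demonstrate the pipeline's correctness, not
agreement with the real populations.

## Problem sizes and reproducibility

Screens default to 10,000 arrays per scheme (the original screens used
10^6); binomial sampling error on a maintenance fraction at that size is
under half a percentage point. Long-run reclassification continues
200–400 maintaining arrays per scheme (at least 100) to 10^6 generations
with early exit. A master seed derives named substreams per
(stage, scheme) via `SeedSequence`, and the coefficient draw fills
row-major so enlarging a screen never changes earlier arrays. CLI runs
embed their full plan (including the seed) in `plan.json`.

## Verified behaviour

The vectorised engine matches an explicit 80-cross mating-table oracle to
1e-12 per generation and over 50-generation trajectories; frequency
vectors stay nonnegative and sum to 1 within 1e-12; the monogenic ZW
state is an exact fixed point under neutrality with IV^F at exactly 25%;
from equal frequencies IV^F starts at 9/36 = 25% of fourth chromosomes (9
of the 18 genotypes carry one copy). With the scaled-down screens the
maintenance fractions are roughly 4% (additive), 21% (recessive), 30%
(dominant) and 43% (overdominant), and over the long horizon ~93% of
dominant maintainers fix a proto-Y versus ~0.5–1% of recessive and
overdominant maintainers.

## Known limitations

* Additive-scheme maintainers fix a proto-Y within 10^6 generations in
  about 2–2.5% of cases here (36/1437 at a 40,000-array screen), somewhat
  above the ~1% reported for comparable published screens. The behaviour
  is reproduced exactly by the independent brute-force recursion, so it
  reflects this parameterisation (most plausibly the IV^F full-effect
  convention or sample size) rather than an engine defect.
* No mutation, migration, recombination, overlapping generations or
  effective-size corrections; the model cannot re-introduce a lost
  determiner.
* ρMF is a rank correlation and, as a summary, is uninformative under the
  overdominant scheme by construction (male heterozygotes are defined as
  the most fit, making the male fitness ranking concave in copy number).
* Analytic equilibrium and stability analysis is out of scope; the system
  is characterised only through simulation.
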