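# Methods

`polybreed` simulates breeding programs for diploid and autotetraploid crops
(the reference parameterization emulates potato) with a genotypic-effect
model that generalizes the textbook bi-allelic coding to multi-allelic QTL at
any even ploidy. This note documents the models, the numerical choices, the
synthetic-data conditions the package is validated under, and what those
validations do and do not show.

## Genotypic model

At a QTL with `n_B` defined alleles in a genome of ploidy `p`, an individual
carries raw allele dosages `t = (t_1, ..., t_nB)` with `sum t_i = p`. Scaled
covariates convert dosages to effect loadings:

- additive: `t_a(t) = (t - p/2) * (2/p)`, antisymmetric in `t <-> p - t`,
  range [-1, 1];
- digenic dominance: `t_d(t) = t * (p - t) * (2/p)^2`, symmetric, 0 for
  homozygotes and 1 for the balanced heterozygote.

Locus values are `a = sum_i t_a(t_i) a_i` and `d = sum_i t_d(t_i) d_i` with
per-allele effects `a_i`, `d_i` (each allele has one dominance effect shared
across all partner alleles — digenic dominance). For `n_B = 2` diploids this
reduces exactly to the -a / 0 / +a substitution coding with `a = a2 - a1`,
and `d` the heterozygote value.

Two-locus epistasis is defined for disjoint QTL pairs (k, l). Each of the
four interaction kinds (additive x additive, additive x dominance, dominance
x additive, dominance x dominance) has an effect vector of length `n_B^2`
over ordered allele pairs; the genotypic value is the Kronecker product of
the two loci's covariate vectors dotted with that effect vector. Element
order runs with the locus-k allele index fastest, i.e. entry
`i = i_l * n_B + i_k`; the brute-force oracle in the test suite pins this
convention. The printed two-locus value table in the source literature
contains sign patterns in two mixed-homozygote additive-by-additive cells
and two dominance-by-additive cells that contradict direct evaluation of the
defining equations; the implementation follows the equations and the test
suite checks those cells against an independent loop-based evaluator.

An individual's total genotypic value `g` sums locus values over all QTL and
pair values over all pairs. Phenotypes are `y = mu + g + e`,
`e ~ N(0, sigma_e^2)`.

## Effect generation: sampling, centering, rescaling

Functional (biological) effects are frequency-independent and frozen after
generation on the founder haplotypes:

1. **Additive.** Sample `a* ~ N(0, sigma_A^2)` per allele and locus; rescale
   all effects by one factor so the realized founder additive variance
   equals `sigma_A^2` exactly; record each locus's founder mean as an offset
   so every locus's centered additive value has founder mean zero. A
   constant shift of all allele effects at a locus cannot change the locus
   value when `n_B = 2` (the additive covariates sum to `2 - n_B = 0`
   independent of genotype), so per-locus centering is implemented as this
   offset — an intercept reallocation that is exact for every `n_B`.
2. **Dominance.** Sample dominance degrees `delta ~ N(mu_d, sigma_d^2)`
   (default `(0.19, 0.097)`, i.e. mostly partial dominance with a positive
   mean degree), set `d* = delta * a` — the prior dominance effect is
   proportional to the allele's final additive effect — and rescale to
   `sigma_D^2`. Dominance is not centered per locus. An alternative reading
   takes the magnitude, `d* = delta * |a|`, which makes every heterozygote
   value positive; that variant induces a systematic decline of the total
   genotypic value as selection erodes heterozygosity, and in our replications
   it depresses the non-additive study's gain rates by ~20% relative to the
   reference values, while the proportional form reproduces them — so the
   proportional form is used.
3. **Epistasis.** Sample each interaction vector from
   `N(0, sigma_component^2)` and rescale per component; the additive x
   dominance and dominance x additive vectors are rescaled jointly so that
   the variance of their *summed* value hits `sigma_AD^2`. Pairs are a
   random disjoint matching of QTL (a perfect matching when
   `n_ep = n_qtl / 2`).
4. **Total centering.** The founder mean of the summed non-additive values
   is absorbed into one offset, so the founder mean of `g` is exactly zero.

**Variance reference (`rescale_method`).** The founder variance used in
rescaling can be measured per individual (variance of component totals,
including between-locus LD covariance) or per locus (sum of per-locus
variances — a linkage-equilibrium reference). The default is `by_locus`.
Rationale: with 2,000 QTL on an 888.6 cM genome, founder LD makes the two
references differ by ~25-30%; marker-based REML estimates the
LE-referenced base-population variance, so only `by_locus` rescaling
reproduces the expected identity between the simulated functional additive
variance and the REML statistical variance in a purely additive model. The
`by_individual` alternative remains available in the configuration.

Because rescaling solves for the target exactly, repeating the
centering-and-rescaling step is a no-op, and the realized founder variances
equal their targets to floating-point precision (the acceptance suite checks
1e-6).

## Founder genomes

Linkage disequilibrium is generated forward in time: `Ne` monoecious
individuals mate randomly (two distinct parents per offspring) for a fixed
number of discrete generations, with an optional bottleneck schedule
(default: generations 901-950 at half `Ne` in the full-scale preset). There
is no mutation; allele counts can only shrink, and loci that fix are pruned
from the simulation (they can never change again) and restored at the end.
Initial allele frequencies are exactly balanced per locus.

Meiosis uses strict bivalent pairing at any even ploidy: homologs are
randomly partitioned into pairs per meiosis, each bivalent recombines with a
Poisson(map length in Morgans) crossover count and uniform positions
(Haldane, no interference, no obligate chiasma) and contributes one
recombinant product to the gamete. Double reduction is impossible under this
model, and the recombination fraction between loci converges to Haldane's
`r = (1 - exp(-2d))/2`.

Panels are drawn in a reference founder population of 100 individuals:
markers from the bi-allelic candidate loci with both alleles at frequency >=
0.05; QTL per allelism class, where a class-`c` QTL has exactly `c` alleles
at frequency >= 0.05 (alleles below the floor may persist at trace
frequency and still carry effects; the effect matrices use the defined
allele count `n_B`, shared by all QTL). Shortfalls raise an error naming the
deficient class rather than silently shrinking the panel.

## Genetic evaluation

The mixed model is `y = X b + Z u + ... + e` with generation as the only
fixed effect. Relationship matrices from bi-allelic markers:

- `Gu` (additive): VanRaden's first method at ploidy `p`,
  `W W' / (p * sum_j p_j q_j)`, `W` the counted-allele dosages centered by
  `p * p_j`;
- `Gv` (dominance): Vitezica's heterosis coding `{-2p^2, 2pq, -2q^2}` for
  diploids; for tetraploids a digenic-dominance covariate `t(4 - t)`
  centered by its Hardy-Weinberg expectation and normalized by the exact
  binomial variance, which satisfies the intended contract (zero HWE mean,
  unit expected diagonal);
- epistatic terms: Hadamard products `Guu = Gu o Gu`, `Guv = Gu o Gv`,
  `Gvv = Gv o Gv`.

Solving uses the GLS form of Henderson's equations (dense path, with a 1e-6
diagonal stabilization of G) or, whenever every relationship matrix carries
its marker factor, the exactly equivalent marker-effect ridge system, which
scales as the number of markers rather than individuals. Genotyped
individuals without phenotypes receive BLUPs through their relationships.

REML: average-information iterations in which a proposed AI step is accepted
only if it keeps all components above a floor (1e-8 of the phenotypic
variance) and does not decrease the restricted likelihood; otherwise a
monotone EM step is substituted. Convergence is a relative log-likelihood
change below 1e-8 (default cap 200 iterations; 100 inside the breeding
loop); non-convergence and boundary estimates are reported, never hidden.
For a single factored component the likelihood is instead profiled onto the
variance ratio via the SVD of the marker factor and maximized by bounded
scalar search — algebraically the same REML optimum at a small fraction of
the cost; the two paths agree on shared problems in the test suite.

Within a breeding run, marker allele frequencies for G are computed once
from the REML records (generations 1 to 5) and frozen for later
evaluations. Recomputing frequencies each generation changes the BLUP
ranking only through a common shift and a slight rescaling of G against the
fixed variance components; freezing keeps G on the scale the variances were
estimated at and allows the normal equations to be updated incrementally.

## Breeding scheme

Per generation: 80 parents are crossed pseudo-randomly (no selfing; at most
4 crosses per parent; rejection sampling with a feasibility pre-check) into
80 families of 10 full sibs — 800 offspring, all genotyped and phenotyped.
Generations 1-5 select the next 80 parents at random from the current 800;
from generation 6 the current offspring are truncation-selected on their
additive BLUP (ties broken by id), using variance components estimated once
by REML at generation 6 on the 4,000 records of generations 1-5. Under
non-additive prediction models the additive BLUP still ranks candidates;
dominance and epistatic solutions inform the fit only. If REML for the
configured model does not converge — frequent for the epistatic model, as
expected — the next simpler model is tried and the event logged.

Metrics: *accuracy* is the Pearson correlation between true and predicted
breeding values of the 800 generation-6 candidates (their own phenotypes are
in the evaluation, as selection happens after phenotyping); the *rate of
genetic gain* is (mean at generation 13 - mean at generation 5)/8, computed
on the true additive value in the additive-only study and on the total
genotypic value in the non-additive study.

## Study conditions and problem sizes

The reference studies are provided as presets at two scales. The `paper`
scale carries the full published conditions (50k marker + 10k QTL initial
loci, panels of 10k markers and 2k QTL, Ne = 200 for 1,000 historical
generations). The `desk` scale — used by this package's tests and by
`scripts/acceptance.py` — keeps the breeding scheme, the QTL panel (2,000
QTL, 1,000 pairs) and, for bi-allelic scenarios, the 1,000-generation
history at full size, and reduces two things:

- the marker panel is 2,000 instead of 10,000 (the evaluation cost per
  generation scales with the square to cube of the marker count);
- the initial candidate-locus pools are resized to the measured
  drift-survival fractions (under pure drift at Ne = 200 for 1,000
  generations only ~10% of diploid and ~37% of tetraploid bi-allelic loci
  keep both alleles above frequency 0.05), giving pools of 30k/25k
  (diploid) and 8k/8k (tetraploid).

Scenarios with quad-allelic QTL are the exception: a locus almost never
keeps four alleles above frequency 0.05 through 1,000 generations of pure
drift at Ne = 200 (measured < 0.1%), so the stated full-scale panel is not
drawable under the stated historical model. Their desk history runs 150
generations (bottleneck at generations 101-130), where ~12% of quad loci
survive; a bi-allelic companion preset on the same shortened history
(`example1_bi_short_history`) provides the condition-matched comparator for
the allelism contrast, so that the allelism effect is not confounded with
historical duration. Desk-scale replication is nested: the acceptance script
averages two founder replicates by three scheme replicates per scenario; the
test suite uses one founder replicate by five scheme replicates.

**What the desk runs show — and what they do not.** The simulator's
component contracts (covariate tables, oracle equivalence of the genotypic
model, exact variance rescaling, Haldane recombination, Wright-Fisher drift
rates, REML recovery) are scale-independent and tested exactly or against
closed forms. The scheme-level quantities are scale-sensitive: fewer markers
lower the captured share of additive variance slightly (about 3% of genetic
variance shifts into the residual at 2,000 markers), and gain trajectories
depend on the MAF spectrum the historical phase produces. Desk-scale
accuracies land close to the full-scale reference values; desk-scale gain
rates run up to ~10% below them, consistent with the reduced marker capture
compounding over eight selected generations. The synthetic genomes also
idealize real data: equal founder frequencies, no mutation, no genotyping
error or missingness, a single purely polygenic trait, and random
environmental noise.

## Degenerate inputs and edge rules

Odd ploidy, empty chromosomes, dosages outside [0, ploidy], infeasible cross
designs and panel shortfalls raise errors naming the violated constraint.
Markers fixed in the evaluation set are excluded from G with a warning.
Clonal founders with a positive target variance are an error (nothing to
rescale). Accuracy of a zero-variance vector is NaN with a warning. All
randomness flows from named substreams of one master seed; a (config, seed)
pair reproduces every output bitwise on a given platform.
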