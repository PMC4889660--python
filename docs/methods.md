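# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `sgqtl`, and what its simulations can and cannot say about real
selective-genotyping (SG) surveys.

## The experimental design being modelled

A biparental F2 population is grown from a cross between a high-protein
female parent (allele `B`) and an ordinary-protein, high-yielding male
parent (allele `A`).  Every F2 plant is phenotyped — in the motivating
surveys through the mean of its selfed F2:3 seed family — for seed protein
and oil in g/kg.  Only the plants in the lowest and highest tails of the
*protein* distribution are genotyped.  Oil is never selected on; it is
scanned on the same selected individuals, which is why fewer oil QTL than
protein QTL are expected even under strong negative protein–oil
correlation.

## Simulator (`simdata`)

**Meiosis.**  Crossovers follow a Poisson process on the cM scale (no
interference).  Gametes are generated as a Markov chain over ordered loci:
the parental-origin label switches between loci *x* cM apart with the
Haldane probability r(x) = (1 − e^(−2x/100))/2.  An F2 genotype is the sum
of two independent gametes.  Because the analysis HMM uses the same map
function, simulation and inference share one genetic model; there is no
model mismatch to confound calibration experiments.

**QTL.**  QTL are simulated *jointly* with the markers (their positions are
spliced into the chromosome before meiosis), so QTL–marker linkage is
exact.  Phenotypes are

    y = midparent mean + Σ_q (a_q·x + d_q·z) + ε,

with x ∈ {−1, 0, +1}, z the heterozygote indicator, and z's coefficient
halved under `generation="F2:3-mean"` (a selfed heterozygote family
segregates 1:2:1, so its mean genotypic value is d/2; homozygote families
stay at ±a).  ε is bivariate normal across the two traits.

**Defaults are the survey's study conditions.**
- n_progeny = 224 (the surveys' average population size).
- Genome: 20 chromosomes × 107.8 cM = 2,156 cM; markers every 1.4 cM
  (1,560 loci), emulating a 1,536-SNP chip on this map length.
- bimorphic_fraction = 0.293: the fraction of chip SNPs segregating in a
  given mating.  Non-segregating markers are drawn marker-wise and set to a
  single homozygous code (both parents carried the same allele); 0.293 ×
  1,560 ≈ 457 informative SNPs at ~4.8 cM effective spacing, the density
  the surveys actually worked with.
- residual_correlation = −0.78, the average protein–oil phenotypic
  correlation in such matings.  Whether the real correlation arises from
  pleiotropy, linked loci, or correlated residuals is not identifiable
  here; the simulator exposes both per-QTL dual effects and the residual
  correlation rather than fixing a ratio.
- residual_sd defaults: 3.0 (protein) and 3.1 (oil) g/kg, i.e. σ²e ≈ 9.
  Against a typical F2:3 protein phenotypic variance of ~27 this leaves
  room for a genetic share near the ~2/3 heritability such populations
  show; the QTL list, not the residual, supplies the genetic variance.
- missing_rate = 0.01 applied uniformly after monomorphism masking: array
  genotyping with manual curation loses few calls.
- Parent means: female 505/160, male 415/190 g/kg protein/oil — typical
  extremes of the germplasm-vs-cultivar contrast.

**Parental replicates** are drawn around each (homozygous) parent's mean
with purely environmental dispersion, which is what makes them usable as an
indirect estimate of environmental variance.

**What the generator does not emulate:** epistasis, crossover interference,
mating-specific marker-gap structure (gaps arise only stochastically from
monomorphism masking), seed-coat-colour-based culling, pod-shattering
attrition, NIR calibration drift, or multi-environment effects.
Consequently, passing calibration tests here demonstrates internal
consistency of design + analysis, not robustness to those field realities.

## Cross I/O and QC (`cross_io`)

The csvr dialect: phenotype rows first (name, two empty cells, one value
per individual), then marker rows (name, chromosome, cM, single-character
codes `A H B -`; the en dash also parses as missing).  Parsing errors name
the offending row and column.  Individuals with all-missing genotypes keep
their phenotypes and are flagged ungenotyped — they are data, not noise,
in an SG design.

Two-point recombination fractions are estimated by EM over the 9-cell F2
joint genotype table (the double heterozygote mixes 0- and 2-recombinant
phases with posterior odds (1−r)²:r²), started at r = 0.33 and iterated to
|Δr| < 1e−9.  The estimate lives in [0, 1]: values far above 0.5 signal
phase-flipped or corrupted assays, not loose linkage.

QC removes (i) monomorphic markers and (ii) markers whose rf with *every*
computable adjacent marker exceeds `rf_ceiling` (default 0.55 = 0.5 plus a
margin against sampling noise; configurable).  The all-adjacent rule is
deliberate: a single phase-flipped marker produces rf > 0.5 against both
neighbours, while each innocent neighbour retains one clean flank — a
"≥ 1 bad pair" rule would cascade removals onto the neighbours.
Segregation distortion (χ² against 1:2:1) is reported per marker but never
auto-removes: distortion can be genuine biology.

## Selection (`selection`)

Two-stage tail selection mirrors assay-thrifty practice: one replicate
ranks everyone; the top and bottom `stage1_fraction` (default 20%) are
re-measured with noise `remeasure_sd`; the mean of the two replicates picks
the final `stage2_fraction` (default 10%) tails.  Tail sizes use
floor(fraction·n) — 224 progeny give 22 + 22.  Ties break by stable sort
on original row order, making selection reproducible.  Masking sets
non-selected individuals' genotypes to missing and never touches
phenotypes.

## Genotype probabilities (`linkage`)

Forward–backward over each chromosome's grid (markers plus pseudo-markers
at a fixed step, default 1 cM; markers are always grid points; co-located
markers multiply their emissions).  Transitions are the F2 matrices built
from Haldane r; emissions allow genotyping error at rate `error_rate`
(default 1e−4 — curated array data is clean but not perfect; matching
calls get 1−e, each mismatch e/2).  Scaled linear-space recursions keep
probabilities normalized; every output triple sums to 1 within 1e−9.
Kosambi or other map functions are intentionally not offered: a single map
model keeps the simulator, the HMM, and the brute-force test oracles in
exact agreement.

## EM interval mapping (`scan`)

At each grid position: a 3-component normal mixture with per-individual
weights fixed to the genotype-probability triple, common residual SD.
EM runs at *all* positions of a chromosome in lockstep (vectorized E/M
steps with a per-position convergence mask) — this is what makes
1,900-replicate permutation tests and 100-replicate power runs tractable
on one CPU.  Numerical choices:

- init: genotype-probability-weighted class means; residual variance from
  those means (a class with effective weight < 1e−9 falls back to the
  grand mean);
- convergence: |Δ log-likelihood| < 1e−6, max 4,000 iterations;
  non-converged positions are flagged and report their last iterate;
- residual SD floored at 1e−8 × SD(y) to avoid degenerate spikes;
- null model: single normal with MLE mean/variance on the same phenotyped
  individuals; LOD = (llₐ − ll₀)/ln 10, floored at 0;
- constant phenotypes short-circuit to LOD 0 with a warning;
- peak ties resolve to the lowest cM (first argmax on the ordered grid).

Individuals with missing phenotypes are excluded from both models;
individuals with missing genotypes are *included* via their prior — under
SG the ungenotyped mid-distribution phenotypes sharpen the null variance
estimate and contribute mixture information.

## Thresholds, effects, calling (`inference`)

**Stratified permutation.**  Phenotypes are shuffled independently within
the genotyped and within the ungenotyped stratum; genome-max LOD recorded
per replicate on cached genotype probabilities (genotypes never move, so
caching is exact, not an approximation).  Threshold = order statistic at
rank ⌈(1−α)(n_perm+1)⌉ — the rule that makes "observed > threshold" an
exact level-α test under exchangeability; the empirical-quantile choice is
documented and configurable.  An empty stratum is vacuous (a fully
genotyped population reduces to a plain shuffle); a stratum of exactly one
individual is rejected as degenerate.  The replicate-count rule
n = α(1−α)/SE² gives 1900 for α = 0.05, SE = 0.005.

**Effects.**  Class means are genotype-probability-weighted phenotype means
over the phenotyped *genotyped* individuals; a = (m_BB − m_AA)/2 (positive
= female B allele raises the trait), d = m_AB − midpoint.  Restricting to
genotyped individuals is deliberate: ungenotyped individuals carry only the
1:2:1 prior, and including them would add identical weight to all three
classes, shrinking contrasts toward zero.  With full genotyping the
estimator reduces exactly to raw class means and is unbiased; under SG the
class contrasts among extremes inflate |a| for QTL that clear the
threshold (winner's curse) — a property of the design the package
reproduces rather than hides.  Effect SEs use the weighted-mean variance
formula; a class with total weight < 1 raises an undefined-effect error.

**Calling.**  One record per chromosome at its peak, with significance
(peak LOD > threshold), a, d, and R² = 1 − 10^(−(2/n)·LOD) where n counts
phenotyped progeny.  Sub-threshold chromosomes below a reporting floor
(default LOD 1.0) are suppressed unless requested — survey tables stay
sparse.

## Heritability (`quantgen`)

σ²e = weighted mean of the two parental sample variances (default weights
½, ½); σ²g = σ²p − σ²e; H² = 100·σ²g/σ²p clamped to [0, 100] (a negative
subtraction is a sampling artefact and reports as 0; the pre-clamp value is
preserved in the estimate object).  Sample variances use n−1 throughout.
Normality assessment delegates to the standard Shapiro–Wilk routine and is
reported as a p-value only.

## Surveys, pooling, power (`survey`)

`run_survey` runs QC → selection (on protein only) → probabilities → scans
of both traits → stratified permutations → calls for each mating,
isolating per-population failures.  Determinism: every stochastic step
derives from the per-population seeds.

`pool_populations` concatenates members sharing a map, keeping the
intersection of markers bimorphic in every member.  `center=True` removes
per-population trait means first (rank-preserving within members) for
pools whose male parents differ; the default is raw pooling.

`estimate_power` simulates the design end to end: one QTL at a random map
position with a = sd·√(2r²/(1−r²)) (so the QTL's F2 variance a²/2 is the
requested share of phenotypic variance), SG, scan, threshold (fixed LOD or
per-replicate permutation), and *detection = significant peak on the true
chromosome within 20 cM of the truth* — a significant peak elsewhere is a
false positive, not power.  The fixed-LOD mode (default 4.0, the typical
permutation-threshold magnitude at these designs) keeps power runs at
seconds-to-minutes scale; permutation mode is the full-fidelity option.

Measured with the default conditions (R² = 0.15, n = 224, 10%+10% tails,
5-cM markers, LOD 4.0, 100 replicates), the acceptance script's power
estimate lands near 0.7 with a binomial SE of ~0.045 — the localization
requirement and the two-tail 20% genotyping budget price this design just
below the 0.8 often quoted from approximate power calculators, which is
precisely the kind of gap the simulator exists to expose.

## Problem sizes used in tests

Test and calibration runs scale the genome and replicate counts to keep
the suite fast while preserving the quantities under test: type-I-error
calibration uses a 5-chromosome × 60 cM toy genome, n = 120, 12+12 SG,
100 permutations, 200 independent seeds (the genome-wise error rate is a
property of the stratified-permutation rule, not of genome length);
pooling properties use 8 × n = 224 members on 3 chromosomes; position
recovery uses a 5-chromosome map at 5-cM spacing.  Full-scale defaults
(20 chromosomes, 1,900 permutations) remain the library defaults.

## Known limitations

- Single-QTL scan model only: no composite interval mapping, multi-QTL
  models, covariates, or epistasis; linked QTL in trans show as a
  sign-flipping additive-effect profile, not as two resolved peaks.
- No confidence intervals for QTL location.
- F2 intercross autosomes only; no sex chromosomes or other cross types.
- The environmental-variance estimator assumes parental replicates share
  the progeny's environment; violations bias H² in either direction.
- Pooling assumes a shared female-parent QTL allele across members; the
  marker-intersection rule discards information at loci informative in
  only some members.
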