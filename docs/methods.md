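# Methods

`reefdiverge` re-implements, as a tested and reusable pipeline, the
population-genomic workflow used to dissect a continuum of divergence
among sympatric coral taxa: RAD-seq-style filtering, divergence
statistics, folded joint-SFS demographic inference with heterogeneous
gene flow, conversion of fitted parameters to demographic units, and
genotype–environment association by partial redundancy analysis. A
coalescent generator replaces raw sequencing data, so every downstream
method can be validated against data whose truth is known.

## Divergence models and units

Two populations of relative sizes ν₁ and ν₂ split from an ancestral
population of size N_ref a scaled time T ago. All times are in units of
2·N_ref generations and migration is scaled as M = 2·N_ref·m, where m is
the fraction of a population replaced by migrants each generation — the
same parameterisation the inference engine fits, so simulator truth and
fitted parameters are directly comparable. The model menu:

- **SI** — strict isolation: no gene flow since the split.
- **IM** — constant symmetric migration M since the split.
- **IM2M** — as IM, but a proportion Q of loci migrates at a reduced
  rate M_e ≤ M (genomic semi-permeability; P = 1 − Q is the neutrally
  exchanging fraction).
- **SC** — secondary contact: no migration on the old epoch
  (T_phase, T], migration M on the recent epoch [0, T_phase). Times are
  ages, so T_phase is the age at which contact resumed.
- **AM** — ancient migration: migration M on (T_phase, T], none more
  recently than T_phase.

Internally SC and AM use one total time plus an epoch fraction
(`T_phase = phase_frac · T`), which keeps the T_phase ≤ T constraint
built into the parameter space. Under the age convention the nesting
identities are SC(T_phase = T) = IM, SC(T_phase = 0) = SI,
AM(T_phase = 0) = IM and AM(T_phase = T) = SI; the test suite asserts
all four.

## Coalescent simulator (`simdata`)

Each RAD tag is an independent, non-recombining locus simulated under
the structured coalescent: exponential waiting times for within-deme
coalescence (pair rate 1/ν_d) and symmetric lineage migration (per-
lineage rate M), with deterministic epoch switches at T_phase and the
merge into the ancestral population at T. Mutations follow the infinite
sites model at rate θ_tag/2 per lineage per unit time; positions are
drawn without replacement along the tag. Diploids pair consecutive
haplotypes within a deme — haplotypes are exchangeable, so this equals
random pairing in distribution. For IM2M each tag is independently
assigned to the reduced-migration class with probability Q.

`expected_jafs_mc` accumulates branch length per descendant
configuration instead of dropping mutations, giving the exact
per-genealogy expectation (θ/2 × branch length per frequency class) and
much lower Monte-Carlo variance; per-cell standard errors come from the
replicate spread of folded spectra. The simulator is cross-validated
against msprime's branch-mode joint AFS for an asymmetric IM history,
and against the Watterson/Fu closed form 1/i + 1/(2n − i) for a
panmictic sample.

Artefact injection mimics the laboratory reality the filters exist for:
independent per-genotype missingness at a configurable rate, and clonal
duplicates re-sampled with independent missingness. Environmental
variables are zero-mean unit-variance Gaussian fields over individual
coordinates with exponential covariance exp(−d/range); a configurable
block of SNPs per variable has its alternate-allele probability shifted
by β·env and its genotypes redrawn binomially, so association methods
can be scored against known causal variables. What the generator does
*not* emulate: within-tag recombination, selection other than the
environmental shifts, sequencing-read noise (depth fields are synthetic)
and more than two demes per simulated pair — conclusions about those
aspects of real data are outside what a passing suite demonstrates.

## Filtering cascade (`genio`)

The cascade follows standard reduced-representation practice, in this
order: stage-1 site filters (biallelic, minor-allele count ≥ 3,
per-genotype depth in [5, 100] when depth is present, ≤ 50% missing per
site) → individual filter (> 70% missing removed; the boundary is kept)
→ clone removal (dosage identity ≥ 99% over co-called sites; the
least-missing member of each clonal group is kept) → stage-2 site
filters (≤ 5% missing, minor-allele frequency ≥ 0.01) → linkage pruning
(sliding window of 50 SNPs, step 5, variance inflation factor ≤ 2).
Thresholds are configurable; allele counts are recomputed at each stage
so removing individuals correctly changes downstream counts. VIF pruning
is greedy — the worst site is removed and VIFs recomputed — and sweeps
are repeated to a fixpoint, so no window of the output violates the
threshold even though removals pull new sites into windows. Depth
filtering masks individual genotypes rather than whole sites, which
reproduces the causal order depth → missingness.

## Divergence statistics (`popstats`)

F_ST uses the Weir–Cockerham (1984) diploid three-component estimator
(a: among populations; b: among individuals within; c: within
individuals), genome-wide as the ratio of sums Σa/Σ(a+b+c); negative
per-locus values are retained because truncation would bias the ratio.
Sites need at least two genotyped diploids per population to contribute.

Individual distances are squared Euclidean on dosage vectors over
co-called sites, rescaled by (total sites / co-called sites) so
missingness does not shrink distances. The sympatry heuristic fits a
Gaussian kernel density (Silverman bandwidth) to the within-reef
distance distribution; a gap is a local minimum whose density falls
below 0.1× the smaller flanking peak, and pairs below the first gap are
classified conspecific. Both constants are exposed.

D_XY follows the pixy accounting: per site the difference count is
c₁(a₂ − c₂) + (a₁ − c₁)c₂ and the comparison count a₁·a₂ (cₖ alternate
copies, aₖ called copies in population k); 1000 bp windows tile each tag
and take the ratio of sums, and the genome-wide value is the
count-weighted ratio over windows — never a mean of window values.
Because SNP matrices omit invariant sites, the default assumes
un-listed tag positions are invariant and fully genotyped; an explicit
all-sites matrix can be supplied instead.

Taxon assignment runs K-means over the leading axes (default 10) of a
PCA on mean-imputed centred dosages, with a fixed seed and multiple
restarts.

## Expected-JAFS diffusion engine (`demography`)

The engine solves the two-population diffusion approximation on a
nonuniform [0,1]² grid crowded at the boundaries: the ancestral
equilibrium density (the discrete steady state θ/x of the 1-D operator,
solved directly as a banded linear system) is placed on the diagonal,
then integrated through the model's epochs by alternating-direction
implicit sweeps. Each 1-D operator is a finite-volume flux form with
drift x(1−x)/ν, migration advection M(y−x), and exponential-fitting
upwind weights where advection dominates. New mutations enter as a
constant influx at the low-frequency corner of each axis. The density is
integrated against binomial sampling kernels onto the (n₁+1)×(n₂+1)
spectrum, computed on three grids and Richardson-extrapolated
(quadratically in the first grid point) to zero spacing.

Boundary handling deserves a note, because it is where a naive scheme
fails. A site lost or fixed in one population is still segregating in
the other, so in the 2-D sweeps the boundary lines must act as
conservative traps — mass accumulates there and keeps evolving in the
other direction, and only the (0,0) and (1,1) corners truly leave the
system (they are masked in the sampled spectrum). Two details make this
correct: absorbing boundary terms are used only in the 1-D ancestral
equilibrium (where loss and fixation do end a site's story), and at the
two edge interfaces the boundary node's flux coefficient is clipped to
inward-advection sign — the unconstrained fitted coefficient would let
an accumulated boundary spike unphysically drain its neighbour. With
migration on, trapped boundary mass legitimately re-enters the interior
(migrants re-polymorise lost and fixed alleles), and the scheme captures
that. Sweep order alternates every step to cancel the leading
operator-splitting asymmetry, which keeps the transposition symmetry
(swap populations ↔ transpose spectrum) at the 10⁻³ level.

Time steps are `timescale_factor / max(0.25/ν₁, 0.25/ν₂, m, 0.25)` per
epoch (default 10⁻³; backward-Euler, unconditionally stable), with a
step-count cap so pathological optimiser excursions stay affordable.
Negligible epochs are dropped, so degenerate epoch layouts reduce
exactly to their nested model's integration sequence and the nesting
identities hold to rounding rather than to discretisation error.

IM2M is computed as the mixture (1−Q)·E[JAFS | M] + Q·E[JAFS | M_e] of
two engine runs sharing the grid.

The engine is validated against the package's own Monte-Carlo coalescent
oracle: for all five models the extrapolated spectrum agrees with the
MC expectation within Monte-Carlo error (the acceptance check uses IM at
ν₁=ν₂=1, M=1, T=1 with ten diploids per population and 10⁵ replicate
tags, requiring every unmasked folded cell within three MC standard
errors).

## Spectrum construction and inference

Genotypes are unpolarised, so spectra are built on the arbitrary
ref/alt orientation and folded, which is exact for folded analyses.
Sites with missing genotypes contribute through hypergeometric
projection to a common sample size; sites below the projection size in
either population are dropped and tallied. Folded cells with total minor
count ≤ 2 — (1,0), (0,1), (2,0), (0,2) and, configurably, (1,1) — are
masked, the standard guard against sequencing-error-inflated rare
variants. Bootstrap replicates resample RAD tags (the linkage unit), 100
by default.

Fitting maximises the Poisson composite log-likelihood over jointly
unmasked cells with the scale θ profiled analytically (θ̂ = Σdata/Σmodel).
The search perturbs the incumbent by 2^u per parameter, u ~
Uniform(−fold, +fold), over rounds of decreasing fold (defaults 3, 2, 1
with ≥30 Nelder-Mead runs per round, in log space for positive
parameters and logit space for fractions), and AIC counts θ among the
free parameters (all models share it, so comparisons are unaffected).
Standard deviations come from the observed Fisher information (central
differences, relative step 10⁻³, in log-parameter space; natural-scale
SDs by the delta method), with bound flags and a condition-number
diagnostic. Likelihood-ratio tests between nested models rescale the
raw statistic by a Godambe-information factor estimated from
tag-bootstrap score variance — the correction composite likelihoods
need because linked SNPs are not independent — with a ½χ²_{d−1} + ½χ²_d
boundary mixture when the null lies on a parameter bound.

## Unit conversions (`unitconvert`)

With L = SNP_used × (n_tags × tag_length) / SNP_discovered and defaults
μ = 1.2 × 10⁻⁸ per base per generation and T_gen = 3 years (both
configurable and recorded in output):

    N_ref = θ/(4μL);  νₖ = νₖ_scaled·N_ref;  m = M_scaled/(2·N_ref);
    T = T_scaled·2·N_ref·T_gen;  M21 = m·ν₁;  M12 = m·ν₂.

Internal values keep full precision; reporting rounds to two significant
figures, which is what lets the worked-example gene-flow cells reproduce
exactly. An algebraic inverse (`deconvert`) exists purely so the tests
can assert the round trip to 10⁻¹² relative.

## Genotype–environment association (`nicherda`)

The response is the Hellinger-transformed individual allele-frequency
matrix on complete-case sites (threshold configurable); predictors are
centred, standardised environmental variables screened for collinearity
at |r| < 0.70. Spatial structure is absorbed by conditioning on dbMEM
eigenvectors: Euclidean distances truncated at the longest
minimum-spanning-tree edge (beyond-threshold distances set to 4× the
truncation), Gower-centred, eigen-decomposed, positive-eigenvalue
vectors retained (a fixed-count override is available; duplicates are
jittered infinitesimally with a fixed seed). Note the leading pair of
transect eigenvalues is nearly degenerate, so the first vector is a
low-frequency sinusoid whose exact phase is data-dependent.

The partial RDA residualises response and predictors on the conditioning
matrix, regresses, and takes canonical axes from the SVD of the fitted
values; R² is SS(fitted)/SS(residualised response) and adjusted R² uses
the Ezekiel correction. Significance comes from permuting rows of the
reduced-model residuals (p = (exceedances + 1)/(permutations + 1), so
the smallest attainable p is 1/(n_perm + 1)). Forward selection adds the
best remaining predictor while its marginal permutation p < α, behind a
global pretest, and stops when the cumulative adjusted R² exceeds the
full-model value — enforced from the second variable onward, because a
single true predictor legitimately exceeds a global model diluted by
noise predictors, and vetoing the first pick would defeat the
procedure's purpose. Variance partitioning decomposes adjusted R² into
pure-environment, pure-space, shared and unexplained fractions from the
three nested models; the fractions sum to the joint adjusted R² by
construction. The RDA core is cross-checked against R's vegan (R²,
adjusted R², pseudo-F) in the test suite.

## Validation studies and problem sizes

`reefdiverge.studies` bundles the validation experiments that
`scripts/acceptance.py` and the acceptance tests run; sizes were chosen
to make the full set feasible on one CPU while keeping each check
informative:

- **Worked-example conversions** — the nine internally consistent
  printed gene-flow cells (M = m·ν at two significant figures) from
  their printed inputs. The remaining printed cells disagree with their
  own row's m and ν at printed precision (upstream rounding of m); they
  are documented, not targeted.
- **Engine vs oracle** — IM, ν₁=ν₂=1, M=1, T=1, ten diploids per deme,
  10⁵ MC tag replicates, all unmasked cells within 3 MC SE.
- **Recovery** — per generating model (SI, IM, IM2M): ten seeds, 2×10³
  tags, ten diploids per population projected to 14 allele copies;
  candidates refit with a single perturbation round of two deep
  Nelder-Mead runs (200 iterations; at these data sizes run depth, not
  run count, decides convergence) over a single-grid engine, IM2M
  warm-started from the fitted IM (the standard nested-model strategy). Scored as the AIC-preference rate (≥ 7/10
  required) and the per-parameter median relative error (< 25%). The
  single-class studies use θ_tag = 0.15 — the ~1-SNP-per-tag regime of
  an LD-pruned dataset, where the composite likelihood's independence
  assumption is cleanest (at ~3 linked SNPs per tag, plain AIC
  spuriously prefers the richer model in a sizeable fraction of
  replicates); the two-class study uses θ_tag = 0.4, i.e. the full
  ~5–6k SNP yield of the real data, because detecting the
  reduced-migration mixture needs the high-divergence tail populated.
  Truths sit at the magnitudes of the published fits (IM truth M = 0.5,
  the printed intraspecific range; T = 1, sizes 2 and 1). Identifiable
  sets are judged by the expected Fisher information at the truth
  (relative SD below ~0.35): {ν₁, ν₂, T} for SI, plus M for IM, plus Q
  for IM2M; M_e fails the bar (expected relative SD ≈ 0.8) and is not
  scored. The median (not per-seed maximum) is the summary because the
  composite likelihood of linked tags occasionally walks along the ν–M
  ridge; the full-protocol defaults (three rounds, ≥30 runs) remain
  the package defaults for real analyses.
- **Estimator fixtures and nulls** — exact F_ST and D_XY fixtures;
  panmictic F_ST null within ±0.02 over 20 seeds; sympatric-mixture
  detection (≥2 distance peaks, perfect K-means recovery over 10 seeds)
  with unimodal nulls.
- **pRDA recovery** — one causal variable among four over 20 seeds
  (axis-1 |r| > 0.9 and forward-selection recovery ≥ 90%), plus a
  200-replicate null calibration of the permutation test at α = 0.05.

## Known limitations

- Tags are non-recombining and unlinked; real RAD loci can recombine
  internally and cluster on chromosomes.
- The composite likelihood ignores intra-tag linkage; parameter SDs
  from the FIM are therefore optimistic, which is exactly why the LRT
  uses the Godambe adjustment and the bootstrap resamples tags.
- The diffusion engine shares the usual limits of two-population
  diffusion solvers: accuracy degrades for very recent splits combined
  with large samples unless grids are enlarged, and heterogeneous
  effective size across loci is out of scope.
- dbMEM conditioning uses planar Euclidean distances; great-circle
  handling is not implemented.
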