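# Methods

This note documents the statistical models and procedures implemented in
`polypopgen`, the assumptions behind them, the tunable parameters that
matter, and the design choices made where the design was genuinely open.

## Data model

Tetraploid microsatellite (SSR) genotypes are multisets of up to four allele
sizes (bp). Fragment analysis often shows fewer than four distinct peaks, in
which case the copy number of each allele is unknown (*dosage ambiguity*).
Cells with four recorded sizes are treated as dosage-known; cells with 1–3
distinct sizes are stored as ambiguous and never silently completed. Allele
identity is the size in bp; repeat counts are derived as size differences
divided by the motif length, anchored at the locus minimum (only differences
matter downstream), with a warning when a size is more than 0.2 repeat units
off the motif lattice.

The *dominant matrix* recodes genotypes as binary presence/absence of each
(locus, allele) band, the standard lossy encoding used to feed polyploid SSR
data to software that assumes simple inheritance. A missing genotype masks
all of its locus's bands for that individual.

## Diversity statistics

* **Allele frequencies.** Two dosage policies: `equal-split` (default)
  spreads the four gene copies evenly over the distinct alleles of an
  ambiguous cell, so every non-missing cell contributes exactly four copies;
  `known-only` drops ambiguous cells. Equal-split is the default because the
  emulated survey reported four scorable alleles per cell, yet the pipeline
  must behave sensibly on partial records.
* **Gene diversity** He uses Nei's small-sample-corrected form
  (n/(n−1))(1−Σp²) with n the gene copies behind the estimate; the
  multilocus value is the unweighted mean over loci. Total diversity HT
  applies the same correction to allele frequencies averaged (unweighted)
  over populations.
* **Allelic richness** is hypergeometric rarefaction to a standard number of
  gene copies g, by default the smallest per-(population, locus) copy count
  (4 × the smallest population size when data are complete). The binomial
  ratio C(N−Na, g)/C(N, g) is evaluated as a running product so fractional
  equal-split counts extend continuously.
* **Private alleles.** An allele is private when it segregates in exactly
  one population; the reported percentage divides by the total number of
  distinct alleles over all populations, so per-population values sum to the
  total row. (The alternative denominator — each population's own allele
  count — is not used because it breaks that additivity.)
* **Inbreeding.** Fi = (Q_ind − Q_pop)/(1 − Q_pop), where Q_ind is the mean
  identity-in-state over the six within-individual gene-copy pairs and
  Q_pop the between-individual within-population analogue; the multilocus
  FIS sums numerators and denominators over loci and individuals.
  Monomorphic population×locus combinations contribute nothing. Ambiguous
  cells are resolved once per run by a seeded random dosage completion.
  Significance: gene copies are permuted among individuals within each
  population×locus (999 permutations by default, two-sided p). Negative
  values indicate heterozygote excess, expected under tetrasomic inheritance
  with outcrossing.

## Distances

* **Bruvo distance** handles polyploidy and stepwise mutation: per allele
  pair d = 1 − 2^−|x| with x the repeat-count difference; the genotype
  distance minimises the mean d over all bijective assignments of the four
  copies (exhaustive over 4! = 24 — exact, no Hungarian approximation
  needed). Dosage-ambiguous genotypes are expanded to every completion to
  four copies and the mean over completion pairs is returned
  (genome-addition behaviour). Consequently two *individuals* sharing the
  same ambiguous phenotype can have a positive distance; the matrix diagonal
  is zero by construction. Multilocus distance averages the loci scored in
  both individuals.
* **Nei distance** between populations treats each band as a biallelic locus
  with presence frequency p and computes the standard D = −ln(J12/√(J1·J2))
  with J terms averaged over bands. The 1972 form is the default; the 1978
  unbiased correction of the within-population J terms is a flag. Infinite
  distances (J12 = 0) are capped at a configurable ceiling (default 10) and
  flagged so regressions can exclude them.
* **Geographic distances** are great-circle (haversine) in metres with Earth
  radius 6 371 000 m.

## Ordination

PCoA via Gower double-centering of −D²/2 and an eigendecomposition.
Coordinates are eigenvectors scaled by √λ for positive eigenvalues; axis
inertia percentages are taken over the positive-eigenvalue sum, and the
negative-eigenvalue mass (non-Euclideanity of Bruvo distances) is reported,
not corrected — a Cailliez correction is available behind a flag. Axis signs
are fixed by making the largest-magnitude loading positive.

## Admixture model

A STRUCTURE-style Gibbs sampler on the dominant matrix. Each band is one
haploid biallelic locus (the recessive-allele dominant-marker model is out
of scope; whether the original analyses coded bands as haploid is unknown,
so this is a documented assumption). The model is the admixture model with
correlated frequencies: cluster band frequencies p_kl ~
Beta(p̄_l(1−F_k)/F_k, (1−p̄_l)(1−F_k)/F_k) around ancestral frequencies p̄_l
(fixed at the empirical pooled frequency, clipped to [0.01, 0.99]);
per-individual q_i ~ Dirichlet(α) with one α shared across clusters,
uniform(0, 10) prior, Metropolis updates (normal proposal, sd 0.25); F_k has
a uniform(0, 1) prior with Metropolis updates (sd 0.05). The data
log-likelihood trace is thinned every 10 sweeps.

Each run reports the posterior-mean Q and a model-evidence estimate
`mean_lnP` = trace mean − trace variance/2 over the post-burn-in trace (the
deviance-based estimator STRUCTURE prints). The variance penalty is what
makes the estimate flatten and fall once K exceeds the true cluster number;
the plain trace mean does not, and makes ΔK unstable.

**Model choice** uses Evanno's ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))
over replicate runs; ΔK is undefined at boundary K and where the replicate
sd is zero. **Replicate alignment** follows the CLUMPP Greedy algorithm:
run 1 is the reference and each subsequent run takes the column permutation
(exhaustive for K ≤ 8, assignment-based otherwise) minimising the squared
Frobenius distance to the running mean; the similarity statistic is
G = 1 − ‖Qa − Qb‖_F/√(2N) averaged over aligned pairs.

Default desk-scale settings are 20 000 sweeps, 5 000 burn-in, 3 replicates,
K from 1 to 10 configurable; the survey-scale settings (500 000 / 50 000 /
10 replicates) are a matter of passing larger numbers.

## AMOVA and gene flow

Three-level AMOVA on squared Euclidean distances between binary band
vectors, partitioned among clusters / among populations within clusters /
within populations. Sums of squares come from the standard distance
identities; variance components are solved from expected mean squares with
unbalanced-design coefficients; Φ_CT, Φ_SC, Φ_ST follow. Missing bands are
pairwise-deleted with rescaling by the number of compared bands. Negative
components are truncated at zero for percentage reporting but retained
signed in the raw table. Significance uses the three standard permutation
schemes (individuals anywhere for Φ_ST; individuals within clusters for
Φ_SC; whole populations among clusters for Φ_CT), 999 permutations by
default, seeded.

Pairwise FST is the two-level Φ_ST of each population pair (truncated at
0); the global FST is the all-population two-level Φ_ST. Slatkin's gene
flow uses the diploid form Nm = (1/FST − 1)/4 by default with the haploid
form behind a flag; published dominant-data Nm tables are often not exactly
reproducible from rounded FST values, so the formula choice is documented
rather than reverse-engineered.

## Barrier detection

Populations are triangulated (Delaunay) on a local equirectangular
projection centred on their centroid — adequate for archipelago extents of
a few hundred km; collinear layouts fall back to a seeded 1 m jitter. A
Monmonier barrier starts at the uncrossed edge with the largest genetic
distance and grows across the dual Voronoi diagram in both directions,
repeatedly crossing the adjacent uncrossed Delaunay edge with the largest
distance until it reaches the network boundary or closes a loop; crossed
edges leave candidacy, and the procedure repeats up to `max_barriers`
(default 9). Ties break by lexicographic population-pair order, making the
output deterministic and invariant to uniform rescaling of the distances.
Sea versus land is not modelled; the network is purely geometric.

## Isolation by distance

* **Mantel tests.** r is the Pearson correlation over off-diagonal pairs.
  The standard scheme permutes entity labels of one matrix; the stratified
  scheme restricts permutations to label swaps within strata (the
  conventional reading of "permuted with clusters"; a whole-stratum mode is
  a flag because the phrase is ambiguous); the partial scheme correlates
  residual matrices after regressing each input on the covariate matrix and
  permutes residual labels. One-tailed p = (1 + #{r_perm ≥ r_obs})/(1 +
  permutations); the default 4 999 permutations resolve p ≈ 0.0002.
* **HIM/SSM protocol.** Four tests — genetic~geographic standard, the same
  stratified within clusters, partial genetic~geographic given the
  cluster-indicator matrix, and genetic~clusters given geography — with the
  conventional decision tags: a non-significant stratified test supports a
  hierarchical island model (no within-cluster IBD); a significant partial
  geography test with high r supports stepping-stone structure; a
  significant cluster effect net of geography supports hierarchical
  structure.
* **Beta regression.** Genetic distances are mapped into (0,1) by min-max
  rescaling followed by Smithson–Verkuilen compression y″ = (y′(n−1) +
  0.5)/n (Nei distances are unbounded above and no canonical mapping
  exists; the record is attached to every fit, and AIC ordering within a
  ladder is invariant to it because all fits share the response). The model
  has a logit mean link and constant precision, maximised from a documented
  start (OLS on logit(y); method-of-moments precision); pseudo-R² is the
  squared Pearson correlation between logit(y) and the fitted linear
  predictor (Ferrari–Cribari-Neto). Geographic distance is rescaled by its
  maximum so the optimiser works near unit scale; AIC = −2ℓ + 2(p + 1).
* **Model ladders.** The base model uses geographic distance alone; barrier
  covariates are added one at a time, cumulatively, under two definitions:
  one straddle indicator per genetic cluster boundary, or cumulative
  indicators for separation by Monmonier barriers 1..k (a pair is separated
  when removing the barriers' crossed edges disconnects it in the Delaunay
  graph). Covariate columns identical to one already present are skipped
  (unidentifiable); indicators that perfectly separate response extremes are
  flagged. The best model minimises AIC.

## Synthetic data generator

`simulate_hierarchical` draws ancestral allele frequencies per locus from a
Dirichlet over the allele-size lattice (concentration 0.45, giving the
skewed frequency spectra typical of SSR loci with 10–31 alleles), drifts
them to cluster and then population frequencies through the multi-allele
Balding–Nichols model (Dirichlet with concentration p̄(1−F)/F; defaults
F_CT = 0.12, F_SC = 0.05), and draws four gene copies per individual.
`simulate_stepping_stone` instead runs a Dirichlet drift chain along the
spatial axis, with per-step drift proportional to distance
(`ibd_strength` per 100 km) plus a jump (`barrier_effect`) across planted
barriers, giving a monotone expected genetic-vs-geographic relation.

Heterozygote excess is induced phenomenologically, not by a mating model: a
fraction w of genotype draws is forced to carry four distinct alleles
(weighted sampling without replacement via Gumbel top-k). Forcing
distinctness flattens the marginal copy distribution, so w is calibrated
per population×locus by solving Fi(w) = target exactly against a
Monte-Carlo estimate of the forced-draw marginal; infeasible targets (below
the all-forced bound) raise an error that reports the bound.

The default ("survey-shape") preset reproduces the emulated survey's
structure: 5 clusters over 9 populations of sizes 11/13/17/13/21/13/16/19/6
(129 tetraploid individuals), 8 loci with 10–31 alleles, island-style
coordinates on four island groups, and drift/excess settings planted to
give a dominant-matrix global Φ_ST ≈ 0.45, multilocus FIS ≈ −0.19 and
HT ≈ 0.85. What passing tests on these data show: the estimators recover
planted hierarchical structure, barriers and IBD at realistic sample sizes.
What they do not show: robustness to genotyping artefacts (null alleles,
stutter, size homoplasy), departures from the Dirichlet drift model, or
non-equilibrium demography — none of which the generator emulates.

## Numerical choices and scale

* Permutation p-values use the (1 + count)/(1 + permutations) convention.
* The Gibbs sampler is compiled with numba; a survey-shape run at K = 5
  with 20 000 sweeps takes ~10 s on one CPU. Test-suite and acceptance
  problem sizes (K scans over 3–7 with 3 replicates; 50–500 simulation
  replicates for calibration checks) were chosen to keep each check in the
  minutes range while leaving the statistical conclusions stable.
* Beta-regression fits restart from statsmodels' defaults when the
  documented start fails; remaining non-convergence raises.
* Distance-matrix containers enforce symmetry and a zero diagonal at
  construction.

## Known limitations

* The dominant encoding discards dosage information by design; statistics
  on it (AMOVA, Nei distance, admixture) inherit that loss.
* The admixture sampler fixes ancestral band frequencies at their empirical
  pooled estimates rather than sampling them; with strong drift and few
  bands this slightly understates uncertainty in F_k.
* ΔK with 3 replicates is noisy below the true K when replicate likelihoods
  nearly coincide; the evidence estimator (mean − var/2) mitigates but does
  not remove this.
* Monmonier barriers on a 9-site network can wander along ties; only the
  separation they induce (which population pairs they split) is a stable
  summary, and that is what the model ladder consumes.
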