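# polypopgen

Population-genetic analysis of **polyploid microsatellite (SSR) data**, built
for surveys of the kind used in island plant conservation genetics: a few
hundred tetraploid individuals from a handful of populations scattered over
an archipelago, genotyped at a small panel of SSR loci, with the questions
*how much diversity is there, how is it structured, and do geography and
physical barriers explain it?*

The package implements the full analysis chain as one tested pipeline:

* **Genotype handling** — tetraploid genotypes with explicit dosage
  ambiguity (a cell showing k < 4 distinct alleles has unknown copy
  numbers), codified co-dominant and dominant (band presence/absence)
  encodings, STRUCTURE-format export.
* **Diversity** — allele counts NA, rarefied allelic richness AR, Nei's
  unbiased gene diversity He and total diversity H_T, private alleles, and
  inbreeding coefficients F_i = (Q_ind − Q_pop)/(1 − Q_pop) and multilocus
  F_IS with permutation significance (negative values = heterozygote
  excess).
* **Distances & ordination** — Bruvo distance (per allele pair
  d = 1 − 2^−|Δrepeats|, minimised over the 4! copy assignments, averaged
  over dosage completions), PCoA with inertia percentages; Nei's genetic
  distance D = −ln(J₁₂/√(J₁J₂)) between populations from band frequencies;
  great-circle geographic distances.
* **Admixture** — a STRUCTURE-style Gibbs sampler (admixture model,
  correlated frequencies Beta F-model) on the dominant matrix, Evanno ΔK
  model choice over replicate runs, CLUMPP-style Greedy alignment.
* **AMOVA** — three-level variance partition (among clusters / among
  populations within clusters / within populations) with Φ-statistics and
  the three standard permutation schemes; pairwise Φ_ST as F_ST and
  Slatkin's gene flow Nm = (1/F_ST − 1)/4.
* **Barriers** — Monmonier's maximum-difference algorithm on the Delaunay
  network of population sites.
* **Isolation by distance** — standard / stratified / partial Mantel tests
  (the hierarchical-island vs stepping-stone decision protocol) and beta
  regressions of genetic distance on geographic distance plus barrier
  covariates, compared by AIC and pseudo-R².
* **Synthetic data** — a generator of tetraploid SSR datasets with known
  truth (Balding–Nichols hierarchical drift or a spatial drift chain,
  planted barriers, calibrated heterozygote excess), so every stage is
  verifiable without access to any deposited matrix.

## Worked example

Simulate a survey-shape dataset (9 populations on four island groups,
129 tetraploid individuals, 8 loci) and compute the diversity report:

```bash
polypopgen simulate --seed 1 --out-prefix demo
polypopgen diversity demo_genotypes.csv --seed 1 --out demo_diversity.csv
```

```
           N      NA     AR     He     Fi   Fi_p      Pa
FACA    11.0   6.500  6.024  0.812 -0.192  0.002   0.926
PIAP    13.0   7.500  6.781  0.831 -0.171  0.002   0.926
...
SMMC     6.0   6.125  6.125  0.837 -0.195  0.002   1.852
Total  129.0  13.500  9.062  0.873 -0.190  0.002  11.111
```

Reading the table: each population carries 6–7.5 alleles per locus on
average (NA), 5.9–6.8 after rarefaction to the smallest sample (AR), and
gene diversity He ≈ 0.81–0.84. Every F_i is significantly negative
(heterozygote excess, as planted at F_IS ≈ −0.19 by the generator), the
total gene diversity H_T is 0.873, and private alleles (Pa, % of all
alleles) concentrate in the more isolated populations.

The full pipeline — diversity, Bruvo PCoA, admixture scan with ΔK,
AMOVA/F_ST, Monmonier barriers, the Mantel protocol and both
beta-regression model ladders, plus figures and a machine-readable
`summary.json` — runs with:

```bash
polypopgen run --preset survey-shape --seed 1 --out-dir run1
```

or from Python via `polypopgen.pipeline.run_all(RunConfig(...))`.

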