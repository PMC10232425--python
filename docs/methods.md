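# Methods

## Divergence model

The amino-acid distance is the Grantham physicochemical distance
`D(i,j) = rho * sqrt(alpha*dc^2 + beta*dp^2 + gamma*dv^2)` over side-chain
composition, polarity and volume, with `alpha = 1.833`, `beta = 0.1018`,
`gamma = 0.000399` and `rho = 50.723`, which normalizes the mean of the 190
unordered residue-pair distances to 100 (the packaged values average 99.87).
The package ships an integer matrix obtained by rounding the exact formula;
the historically printed integer table differs by one unit at a handful of
cells because of 1970s intermediate rounding, and no single scale constant
reproduces every printed cell. Packaging the formula-exact rounding keeps the
matrix, the property triples and the normalization mutually consistent, which
the test suite verifies cell by cell against an independent recomputation.

HLA evolutionary divergence (HED) at a locus is the mean distance per aligned
position between the peptide-binding-domain sequences of the subject's two
alleles: exons 2+3 concatenated for class I (A, B, C), exon 2 for class II
(DRB1, DQB1, DPB1), treated as a single ungapped alignment with no
inter-exon weighting. Positions carrying an unknown residue (`X`) in either
sequence are excluded pairwise and the denominator is the number of included
positions, so unknowns do not bias divergence downward; a comparison with no
usable positions is an error rather than a zero. A homozygous locus scores
exactly 0. Class scores are unweighted means of their three loci and the
global score is the unweighted mean of all six (with three loci per class
this equals the mean of the two class scores, so the two readings of
"global" coincide).

Alleles are handled at protein-level (2-field) resolution. Extra nomenclature
fields and expression suffixes are truncated on input; when several
full-resolution alleles in a sequence FASTA reduce to one 2-field key, the
sequence of the lexicographically smallest full name is kept, making the
dictionary independent of file order.

## Dichotomization

Each score slot (six loci, two class means, global) is dichotomized against
the 50th percentile of a healthy-control reference distribution, computed
with the linear-interpolation percentile convention (numpy's default). A
subject is *high* only when strictly above the cutoff; a tie is *low*, so
"high divergence" always means strictly above the reference median. Cutoffs
derived from this package are therefore reproducible to the bit given the
same controls.

## KIR-ligand classification

HLA-C alleles partition by residue 80 of the alpha-1 domain into C1 and C2
KIR-ligand groups. Classification uses allele-group supertypes: C1 =
{01, 03, 07, 08, 09, 10, 12, 14, 16, 17}, C2 = {02, 04, 05, 06, 15}. Rare
2-field-level exceptions within a supertype are knowingly ignored — the rule
is the group-level one used in clinical stratification. An allele group
outside both lists (e.g. C*18) raises rather than defaulting, because a
silent default would corrupt downstream C1/C1 vs C1/C2 vs C2/C2 strata.

## Survival machinery

One record per subject with a single terminal state: relapse, death without
prior relapse (competing event), or censoring; times are months from
transplant and must be positive and finite.

* **Kaplan–Meier**: product-limit estimator with Greenwood pointwise
  variance; censorings tied with events are handled events-first (a subject
  censored at *t* remains at risk for events at *t*).
* **Aalen–Johansen**: cause-specific cumulative incidence
  `CIF_c(t) = sum_{t_i<=t} S(t_i-) d_ci/n_i` with the all-cause Kaplan–Meier
  `S`; with no competing events this reduces exactly to 1 − KM of the cause.
  The pointwise variance is the standard delta-method estimator. KM and CIF
  are computed from one shared risk-set sweep, so the identity
  `sum_c CIF_c(t) + event-free(t) = 1` holds to better than 1e−12 at every
  step time, ties included. (An external competing-risks fitter that jitters
  tied times would break both this identity and run-to-run determinism at
  monthly-scale data; the test suite still cross-checks both curves against
  lifelines on tie-free data.)
* **Log-rank**: k-sample test via lifelines, chi-square with k−1 degrees of
  freedom; calibration of the type-I error at alpha = 0.05 is asserted over
  1,000 null simulations in the tests.
* **Cause-specific Cox**: partial-likelihood maximization via lifelines'
  `CoxPHFitter` with the Efron tie approximation (the only supported method:
  it is standard and accurate at the tie density of monthly data, and the
  moderate-tie regime makes the Breslow/Efron distinction negligible).
  Competing events are censored at their time — the cause-specific hazard
  convention; subdistribution (Fine–Gray) modeling is out of scope.
  Categorical covariates are reference-coded from a declared level order
  (first level = reference), producing `name=level` indicator columns. Wald
  95% intervals are `exp(coef ± 1.96·se)` and p-values are two-sided.
  Monotone likelihood / complete separation surfaces as an error advising
  that penalization is out of scope, never as a silently huge coefficient.

## Somatic lesion tabulation

Lesion tables carry one row per call (patient, timepoint, allele, category
in {missense, nonsense, frameshift, splicing, UTR, intronic, loss}, optional
VAF). Frequencies collapse to the patient level — a patient with three
lesions counts once — while mutation-vs-loss breakdowns count lesions.
Percentages round to the nearest integer, halves away from zero. The
early/late split of post-transplant relapses is strict: late means relapse
time > 6 months, so a relapse at exactly 6.0 months is early.

Co-mutation enrichment builds, per myeloid driver gene, the 2×2 table of
HLA-altered vs wild-type × gene-mutated vs not, tested two-sided by Fisher's
exact test with Benjamini–Hochberg correction across genes. The displayed
odds ratio uses the Haldane–Anscombe 0.5 correction; p-values come from the
uncorrected table. Genes with a degenerate margin are reported with OR 1 and
p 1 and flagged with a warning rather than dropped. The donor
lymphocyte-infusion analysis (exonic/loss vs regulatory-only lesions against
response) is a labeled cross-tab with no test: the subgroup is far too small
for inference.

## Synthetic cohort generator

The generator emulates the study conditions so every stage runs and is
validated without protected data:

* **Genotypes**: per locus, two independent draws from a fixed allele pool
  (Hardy–Weinberg); eight alleles per locus with skewed frequencies
  (0.30 … 0.02). Loci are independent — no linkage disequilibrium, which is
  adequate for pipeline validation but not for population-genetic inference.
* **Sequences**: a deterministic pool ("fixture-1", internal fixed seed);
  class I sequences are 182 residues (exons 2+3 convention), class II 94
  (exon 2). Alleles differ from a per-locus base sequence at ~25% of
  positions, keeping every heterozygous pair at strictly positive divergence
  so the high/low strata are non-degenerate.
* **Covariates**: centered age in decades (standard normal), donor type
  MRD/MUD/Haplo (0.27/0.53/0.20), conditioning MAC/RIC (0.36/0.64), disease
  AML/MDS/MPN (0.59/0.26/0.15), graft source BM/PBSC (0.31/0.69), comorbidity
  index (Poisson(1.5) capped at 6), disease risk 1/2/3 (0.30/0.45/0.25),
  centered transplant year (uniform −5…5) — proportions shaped on a typical
  adult myeloid transplant cohort.
* **Outcomes**: latent exponential times per cause with subject rate
  `lambda_c · exp(x beta_c)`; the earlier of relapse and death is observed,
  administratively censored at 36 months. Baselines default to 0.013
  relapses and 0.007 deaths per month, giving roughly 30% relapse by three
  years. Exponential baselines suffice because the estimand is a hazard
  ratio under proportional hazards, and they admit closed-form checks (the
  event-type proportion test uses `lambda_r/(lambda_r+lambda_d)` exactly).
* **Calibrated configurations**: the multivariable configuration sets the
  relapse log-hazard effect of high class II HED to log 0.54 alongside
  nonzero adjustment-covariate effects and a death hazard with its own
  profile (class II effect log 0.63); the univariable configuration sets a
  single relapse effect of log 0.65; the survival configuration a single
  all-cause death effect of log 0.63. Because the generator and the fitted
  model share the same proportional-hazards specification and design
  encoding, parameter recovery is a sharp correctness check of the whole
  chain (genotypes → divergence → cutoffs → categories → hazards → Cox).
* **Lesions**: Bernoulli indicators per assayed patient per timepoint at
  configured rates with multinomial categories, plus a fully deterministic
  fixture reproducing the reference somatic-landscape marginals: 9/40
  lesion-positive at diagnosis, 0/9 at post-chemotherapy relapse, and at
  post-transplant relapse 10/20 matched-related, 2/8 haploidentical and 5/17
  unrelated donors (17 positive overall), an early/late split of 4/14 vs
  13/31, and 25 DLI recipients with 5 complete responders. The fixture uses
  45 post-transplant specimens because the donor-group denominators
  (20 + 8 + 17) determine the total; the per-group fractions are the
  machine-checked quantities.

All randomness derives from `numpy.random.default_rng([seed, stream])` with
one fixed stream per purpose (genotypes, controls, covariates, event times,
lesions), so a configuration plus a seed reproduces every realization
bit-for-bit, and tests assert byte-identical pipeline outputs across runs.

## Validation scale and what it shows

The acceptance-style checks recover the three calibrated hazard ratios as
means over 25 cohorts of 4,000 subjects (≈75 Cox fits, about a minute on one
CPU) within ±0.05; estimator oracles compare Kaplan–Meier to the empirical
survival function, the cumulative incidence to 1 − KM without competing
events, Cox to a brute-force partial-likelihood grid (1e−4), and Fisher
p-values to exhaustive hypergeometric enumeration. Passing these shows the
pipeline is internally correct and calibrated under the generator's
assumptions — independent loci, exponential baselines, proportional hazards,
exact category labels. It does not show robustness to features of real
cohorts the generator deliberately omits: linkage disequilibrium between HLA
loci, non-proportional or time-varying effects, informative censoring,
misclassified genotypes, or the real IMGT allele pool.

## Known limitations

* Divergence is computed for the six classical loci only; DQA1/DPA1/DRB3-5
  are parsed and carried but not scored.
* Only Efron tie handling is implemented for Cox fits.
* The Grantham matrix intentionally uses formula-exact rounding (see above);
  analyses that require the historically printed integers verbatim should
  supply a custom `GranthamModel`.
* Ambiguity strings (NMDP codes), G/P groups and HLA typing from reads are
  out of scope; genotype inputs must already be 2-field-resolved.
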