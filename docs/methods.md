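# Methods

`gstassoc` analyses an unmatched case-control study of chronic myeloid
leukemia (CML) susceptibility and treatment response as a function of
three glutathione S-transferase polymorphisms — the GSTM1 and GSTT1
whole-gene deletions (assayed only as *present* vs *null*, since the
multiplex PCR cannot distinguish heterozygotes from homozygous
carriers) and the GSTP1 Ile105Val SNP (rs1695, genotypes AA/AG/GG) —
together with smoking as an environmental co-exposure.

## Association model

Every association is built on the 2×2 table of exposure × case status
with cells a, b (exposed cases/controls) and c, d (unexposed). The
odds ratio is the cross product OR = ad/bc with the Woolf confidence
interval

    exp( ln OR ± z_{1-α/2} · sqrt(1/a + 1/b + 1/c + 1/d) ),

α = 0.05 by default. A table with any zero cell yields an
*inestimable* OR: the raw cross product (0, +∞, or undefined 0/0) is
recorded, no CI is attached, and downstream formulas handle the flag
explicitly. Orientation is always explicit: single-locus tables put
the functional (wild-type / gene-present) category on the exposure
margin, so a protective-looking OR < 1 for "GSTM1 present" is the same
finding as an elevated risk for the null genotype; interaction tables
put the susceptibility genotype and smoking on the exposure margins.

Contingency p-values use the Pearson χ² without continuity correction,
falling back to the two-sided Fisher exact test (probability-mass rule:
the p-value sums hypergeometric probabilities of all tables, with the
observed margins, no more probable than the observed one) whenever a
cell is zero or an expected count is below 5. Every reported p carries
the label of the test that produced it. Age means are compared by the
Welch t-test from summary statistics. No multiplicity adjustment is
applied anywhere; all p-values are raw and two-sided.

### Genetic models

For the three-genotype GSTP1 locus the package fits the three standard
penetrance models: *recessive* (GG vs AA+AG), *dominant* (AG+GG vs AA)
— both as collapsed 2×2 tables — and *additive*, a logistic regression
of case status on G-allele dosage (0/1/2) fitted by maximum likelihood
(IRLS) on the grouped genotype counts, with convergence declared when
successive deviances differ by less than 1e-10 (at most 50 iterations)
and a Wald CI on exp(β). Fitting grouped counts rather than expanded
subject rows gives the identical MLE deterministically. Perfect
separation is reported as an inestimable result. An allele-level 2×2
(2N alleles per group) is also provided. For the deletion loci only a
recessive contrast is meaningful because carriers are indistinguishable
from homozygous wild-type.

Hardy-Weinberg equilibrium is checked with the χ² goodness-of-fit test:
allele frequency p̂ = (2n_AA + n_AG)/2N, expected counts
(p̂², 2p̂q̂, q̂²)·N, one degree of freedom. The exact (enumeration)
HWE test is deliberately not used — the GOF form is the classical
companion of these tables and is what the published p-values (0.19
cases, 0.73 controls) correspond to. Monomorphic samples are flagged
degenerate with p = 1.

## Additive-scale interaction

For two binary factors, subjects are cross-classified into four strata
and each stratum's odds of disease is compared with the
doubly-unexposed reference (OR00 ≡ 1):

    RERI = OR11 − OR10 − OR01 + 1
    AP   = RERI / OR11
    SI   = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1))

computed from *unrounded* stratum ORs (rounding first changes the
second decimal of RERI). RERI > 0 / SI > 1 indicate super-additivity.
AP is undefined when OR11 is inestimable; SI is undefined when its
denominator is zero.

**Sparse-stratum convention.** A stratum OR rendered 0 or inestimable
by a zero cell contributes the value 0 to all three formulas. This is
the only single rule consistent with the full set of published
interaction values for the sparse GSTT1 strata (RERI 0.37, −0.749 and
1.26; AP 0.39; SI 2.39), and it is statistically aggressive — one
empty cell can swing RERI by whole units — so every application is
flagged in the result object and logged at warning level.

Because the substitution rule destroys the smoothness that
delta-method standard errors require, optional CIs for RERI/AP/SI come
from a percentile bootstrap that resamples subjects with replacement
within the case and control groups separately (the design fixes the
group sizes), applying the same substitution rule in each resample and
reporting how often it fired. Default 2000 resamples (minimum 100),
deterministic under a fixed seed.

## Response and survival endpoints

Treatment response among cases uses four binary ELN-style endpoints:
MCyR at 3 months, CCyR at 6 months, and BCR-ABL1 transcript categories
≤10% at 3 months / <1% at 6 months. Each endpoint is tabulated by
genotype grouping (GSTM1 null vs present; GSTP1 AA vs AG/GG) and tested
with the same Pearson/Fisher decision rule. Time-to-MMR and
event-free survival use the Kaplan-Meier product-limit estimator (ties:
events before censorings at the same time; Greenwood-based machinery is
available through the underlying survival library but no published
check depends on it) and the two-group log-rank χ² test with per-group
observed and expected event counts. The composite EFS event is
consumed pre-coded, not derived: deriving "loss of CCyR/MMR" would
require per-visit measurement schedules that a flat cohort table does
not carry.

## Synthetic cohorts

### Fixture mode

The published study ships no subject-level data; every count appears
in five marginal tables. `generate_fixture` rebuilds record sets whose
aggregation reproduces a requested table block cell-for-cell, and
`generate_fixture("paper-all")` builds one 208-subject cohort
consistent with the demographic, single-locus, gene-gene and
gene-smoking tables *simultaneously*. That joint reconstruction is a
small integer margin-completion problem: per group, the joint
(GSTM1, GSTT1, GSTP1-carrier, smoking) distribution must satisfy six
pairwise 2×2 margins. The solver first enumerates the tiny GSTT1-null
stratum (≤3 subjects per group) against its three published margins,
then solves the remaining 2×2×2 system, which has exactly one free
parameter; the smallest feasible value is taken, making the fixture
deterministic. GG genotypes are assigned within the variant-carrier
margin to match the genotype table; ages are a deterministic affine
transform of a standardised grid so each group's sample mean and SD
equal the published values exactly.

The two response blocks are mutually inconsistent over the same 104
cases (e.g. 24 MCyR responders by the GSTM1 split vs 22 by the GSTP1
split; 12 vs 30 for BCR-ABL ≤10% at 3 months), so no joint assignment
exists: "paper-all" carries the GSTM1 response block and the GSTP1
block is generated as its own record set, with the manifest recording
the exclusion. Survival *times* are not reconstructable from the
published record at all and are left missing in fixtures.

### Model mode

`generate_cohort` simulates cohorts by **retrospective tilting**:
controls are drawn from configured exposure-profile frequencies
(GSTM1/GSTT1 null indicators, smoking, and GSTP1 genotypes in
Hardy-Weinberg proportions for a configured G-allele frequency), and
cases from P(profile | case) ∝ P(profile | control) · OR(profile),
where OR(profile) is the product of configured main-effect and
pairwise-interaction odds multipliers (GSTP1 optionally per-allele,
multiplying once per G allele). Sampling profiles conditional on case
status matches the case-control design and makes the configured odds
ratios exactly the estimands of the downstream analysis — the basis of
the parameter-recovery tests. Defaults are the study's conditions:
104 subjects per arm; control frequencies GSTM1-null 51/104, GSTT1-null
1/104, G allele 43/208, smoking 31/104; effect ORs from the published
stratified estimates (GSTM1-null 2.0757, smoking 2.6824, their
interaction multiplier 6.5143/(2.0757·2.6824) ≈ 1.17, GSTP1 per-G
1.569). GSTT1-null carries no default effect: with 3/1 carriers its
published estimates are too unstable to define a condition. Cases
inherit departure from HWE through the tilt, mirroring the published
pattern (controls in equilibrium, cases marginal). Sex and age are
filled independently per group from the demographic margins (Bernoulli
sex; normal age clipped at 0) since no analysis conditions on them
beyond the demographics table.

`attach_survival` adds response/survival fields to cases from
exponential event-time processes stratified by GSTM1: a response
process drives both the binary 3/6-month endpoints (responder iff the
response time is ≤3 or ≤6 months) and the censored time-to-MMR, and an
independent process drives EFS; censoring is uniform on (0, horizon].
Defaults — response hazard 0.06/month for GSTM1-present vs 0.02 for
null (qualitatively reproducing the published slower MMR of null
patients), EFS hazard 0.005/month in both strata (the published EFS
comparison is null), horizon 72 months (cohort mean follow-up ≈61) —
are the package's own choices, since no subject-level survival data
exist to calibrate against; the survival machinery is validated by
properties (calibrated log-rank type-I error, hazard-ordered KM
medians), not by value replication.

### What the generator does and does not emulate

It reproduces marginal and pairwise count structure, case-control
tilting, and HWE in controls. It does not model three-way dependence
beyond what the tilt induces, linkage between loci, age/sex-dependent
exposure or risk, non-exponential response kinetics, or informative
censoring. Tests passing on these cohorts therefore validate the
*estimators* and the pipeline plumbing, not the biological realism of
any particular effect size.

## Numerical and reporting choices

- z-quantile at full precision (1.959964 at α = 0.05), never 1.96.
- Interaction measures always computed from unrounded ORs; display
  rounding (ORs/RERI/SI to 2 decimals, AP to 3, p to 3 or "<0.001")
  applies only in the text renderer; JSON output keeps full precision.
- Strata are always reported in the fixed order (1,1), (1,0), (0,1),
  reference (0,0).
- The replication report places computed and published values side by
  side; "match" means agreement within one unit in the last printed
  digit, because the published tables demonstrably mix rounding and
  truncation (0.46738 appears as 0.46; 1.9994 as 1.99).
- Problem sizes in the test suite are chosen for tight Monte-Carlo
  error at desk scale: 1000 null replicates of n = 200 for log-rank
  calibration, 50,000 subjects per arm for simulator parameter
  recovery (5% relative tolerance), 2000 bootstrap resamples.

## Known limitations

- The sparse-stratum zero convention reproduces the published sparse
  RERIs but is not a recommended estimator; treat flagged values as
  descriptive.
- Published Table-5 response p-values are not reproducible from their
  own printed counts under Pearson, Yates-corrected or Fisher tests
  (e.g. 0.017 printed where the counts give 0.002); the package reports
  its computed p-values with method labels and makes no attempt to
  match those entries.
- One published CI bound (6.51's lower limit, printed 2.57) disagrees
  with the Woolf value 2.76 that the package computes; every other
  checked CI reproduces, consistent with a digit transposition in the
  publication.
- No covariate adjustment (none was performed in the study), no
  multiplicative-scale interaction, no Cox regression or competing
  risks, and no exact HWE test.
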