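# Methods

## Quadrivalent model

A reciprocal translocation t(A;B) is represented by two breakpoints on two
distinct autosomes (sex-chromosome, Robertsonian, inversion and complex
rearrangements are out of scope). Four segments define all dosage
arithmetic: the translocated segment TS of each chromosome runs from the
breakpoint to the telomere of the breakpoint arm, and the centric segment
CS is the complementary, centromere-bearing remainder, so TS + CS equals
the chromosome length exactly. The centromere's own extent is not modelled
as a segment; breakpoints are required to lie strictly inside an arm.
Coordinates are 0-based half-open internally; ISCN text and user-facing
reports are 1-based conventions at band resolution.

Covariates derived from this geometry: sizes of the two chromosomes, TS1,
TS2, CS1, CS2, TSR = max(TS)/min(TS), CSR analogous, TAR_i = TS_i / (length
of the breakpoint arm), and acrocentric involvement (chromosome in
{13, 14, 15, 21, 22}). **Index 1 denotes the longer chromosome.** The
source material is internally inconsistent on this point (its methods text
says index 1 is the smaller chromosome, while the table that actually
reports the covariates defines Size 1 as the longer one); the table
convention is followed because it defines the reported estimates, and the
metrics object also carries a per-chromosome mapping so either ordering can
be read off.

## Segregation products and embryo signatures

The quadrivalent members are A, der(A) = CS_A+TS_B, B, der(B) = CS_B+TS_A.
The five disjunction modes give 16 chromosome compositions (2 alternate, 2
adjacent-1, 2 adjacent-2, 8 of mode 3:1 — tertiary and interchange
trisomies/monosomies, pooled as "3:1" for statistics — and the two 4:0
poles). Counting each composition with and without an
interstitial-crossover chromatid yields the classical 32 gamete classes.

A recombinant chromatid is represented by substituting one member with its
pairing partner's exchange product (A ↔ der(A), B ↔ der(B)), canonically
the first member whose partner is absent from the pole. When a pole
contains both members of a pair (adjacent-2, 4:0), the exchange is
internal to the pole and the dosage is left unchanged: chromatid-level
meiosis II sampling, which could produce e.g. double der(A) gametes, is
deliberately outside the model. Under this convention recombination
creates no dosage vector beyond the 16 non-recombinant ones (alternate
with crossover yields adjacent-1-like dosages; adjacent-1 with crossover
yields copy-neutral products), so dosage-level classification over the
non-recombinant table is complete, and the classifier never needs — nor is
able — to call "recombinant".

Embryo signature = gamete dosage + (1,1,1,1) from a presumed balanced
partner gamete. The two alternate products collapse to the single balanced
entry (CCS cannot distinguish a normal from a balanced-carrier embryo);
the remaining 14 signatures are pairwise distinct, which is what makes
CNV-based mode calling unambiguous at segment resolution.

## CNV classification

Each embryo's segment calls are matched against the carrier's segment
intervals (each segment alone, or a whole chromosome = both segments of an
involved chromosome) with a boundary tolerance, default **5 Mb**: the
platform's stated 1–4 Mb detection resolution plus band-midpoint
uncertainty in karyotype-derived breakpoints. Calls below 1 Mb or with
copy number > 4 are dropped with a warning (platform floor). Matched calls
contribute copy-number deviations to the four-segment dosage vector, which
is then looked up exactly in the 15-entry signature table.

Residual (unmatched) calls decide the remaining flags: whole-chromosome
residuals on uninvolved chromosomes set `incidental_aneuploidy` — treated
as mitotic or meiosis-independent errors that do not veto the quadrivalent
mode call (this is the distinction between "alternate" and
"transferable-normal" embryos) — while partial residuals on involved
chromosomes, or a dosage matching no signature, produce ND
(not-determined). Reports pool 4:0 and ND as "4:0/other". A balanced call
is never emitted alongside a partial residual on an involved chromosome.

Breakpoint refinement takes all CNV-call boundaries on the breakpoint arm
within the tolerance across a carrier's unbalanced embryos and reports the
median with the median absolute deviation; when no embryo supports a
boundary, callers fall back to band midpoints.

## Cohort statistics

* 2×2 odds ratios: OR = ad/bc with the Haldane–Anscombe 0.5 correction on
  any zero cell and Woolf (log-normal) 95% CIs; Pearson chi-square p. The
  Woolf CI reproduces the published stratified CIs to 3 decimals from the
  printed counts, which is how the (unstated) upstream CI method was
  identified.
* Stratified analysis: Mantel–Haenszel common OR and CMH chi-square
  (no continuity correction) via statsmodels; the Breslow–Day homogeneity
  statistic is computed in-package because the statsmodels implementation
  is undefined at pooled OR exactly 1 (the quadratic for the expected cell
  degenerates to a linear equation there); an optional Tarone adjustment
  is provided. Verified against statsmodels to 1e-12 away from the
  degenerate point.
* Random-intercept logistic GLMM: one intercept per carrier, marginal
  likelihood by non-adaptive Gauss–Hermite quadrature (25 nodes — ample
  for frailty SD ≲ 1 and cluster sizes ~5), maximised by BFGS on
  (β, log σ) from a deterministic plain-logistic start; no stochastic
  initialisation anywhere. Wald SEs from the inverse numerical Hessian,
  falling back to the β block when σ sits at the boundary and flattens the
  log-σ direction. σ is clamped to [3e-4, 20] on the log scale purely for
  numerical safety. Cross-checked against lme4's `glmer` (nAGQ = 25) to
  ~1e-3 on coefficients and frailty SD. statsmodels offers no frequentist
  binomial GLMM, hence the in-package implementation.
* Covariate selection mirrors the two-stage design: univariate
  random-intercept screens at α = 0.05, survivors enter the multivariable
  fit. Sizes and segment lengths enter in Mb, ratios untransformed; TAR1
  is additionally dichotomised at 0.2 for the stratified descriptive
  report. No multiple-testing correction is applied (matching the source
  design); the number of tests is reported instead.
* The multinomial outcome (adjacent-1 / adjacent-2 / 3:1 / 4:0-or-other,
  each vs alternate) is decomposed into independent binary
  random-intercept contrasts on the corresponding row subsets. For a
  multinomial logit with a shared random intercept the conditional
  two-category model is exactly the binary model with that contrast's
  coefficients, so the approximation enters only through refitting the
  intercept variance per contrast; a joint multinomial random-effects
  likelihood would add little beyond implementation risk. Contrasts with
  fewer than 10 events are skipped with a warning.
* ROC: AUC by the Mann–Whitney rank statistic (equal to the pairwise
  exceedance probability, ties counted half), sensitivity/specificity at
  the Youden-optimal threshold of the fixed-effects linear predictor.

## Synthetic cohort generator

The generator emulates the statistical structure the estimators assume,
at the published cohort's scale and rates:

| parameter | default | basis |
|---|---|---|
| carriers | 2,253 | published cohort size |
| P(female carrier) | 0.544 | 1,225 / 2,253 |
| embryos per carrier | Poisson(4.8) truncated ≥ 1 | 10,846 / 2,253; per-carrier distribution unreported, Poisson is the neutral choice |
| autosome pair | uniform over the 231 pairs | acrocentric involvement then arises at its combinatorial rate 95/231 ≈ 0.41, close to the published split; a weight override can match it exactly |
| breakpoints | uniform within arms, TS ≥ 5 Mb, 1 Mb clear of the centromere; acrocentric p arms excluded (Robertsonian-like) | detectability floor; study population |
| mode model | multinomial logit vs alternate; baseline logits solve to 46.1/31.3/12.4/5.4/4.7% at covariate centres; coefficients log(1.293), log(1.208), log(0.806) on female sex, Acr-ch, TAR1, identically on every contrast | published marginal frequencies and pooled multivariable ORs |
| random intercept | SD 0.5 shared across contrasts (shared frailty) | simplest structure consistent with within-carrier clustering |
| CNV boundary jitter | N(0, 1 Mb) on breakpoint-derived boundaries | platform resolution |
| incidental aneuploidy | 0.25 per embryo, whole-chromosome ±1 on an uninvolved autosome | 1,289 non-transferable of 5,005 alternates |
| ND | "4:0/other" embryos become a spurious mid-arm segment (placed ≥ 6 Mb from every segment boundary) except a 4/510 fraction emitted as true 4:0 | only four genuine 4:0 products were identified in the published category |

Covariate centring (sex at 0.544, Acr-ch at 95/231, TAR1 at 0.5) keeps the
marginal frequencies near their targets when effects are switched on; with
null effects the frequencies are exact by construction. Because the
default applies one coefficient vector to every contrast, the pooled
alternate-vs-rest margin is *exactly* a random-intercept binary logit with
those coefficients — the configuration under which parameter recovery by
`fit_binary_glmm` is well-posed. ND corruption is applied only to
non-alternate embryos (a balanced profile is never uninterpretable), so
pooling ND into "unbalanced" keeps that binary model correctly specified.
An alternative `effects="per_contrast"` preset instead applies the
contrast-specific published estimates (TAR1 0.316 on adjacent-1; TS1 1.014
per Mb and female sex 1.66 on adjacent-2; female sex 2.643 and Acr-ch
1.387 on 3:1).

Randomness: one root seed; per-carrier child streams are spawned from a
`SeedSequence` over counter-based Philox generators, so adding draw sites
for one carrier never shifts another carrier's stream. Output is a pure
function of the config.

What the generator does **not** emulate: raw read counts or log-ratios
(input is segment calls), mosaicism, uniparental disomy, maternal-age
aneuploidy curves, sub-band breakpoint clustering, correlated embryo
counts by carrier age, or ND profiles whose cause is biological rather
than technical. Passing recovery tests therefore show the estimators are
correct under the assumed structure, not that the clinical effect sizes
are externally valid.

## Problem sizes and numerics

Recovery experiments run 20 replicates of 2,000 carriers (~10,000 embryos
each); examples use 400–600 carriers. Quadrature uses 25 Gauss–Hermite
nodes; convergence is judged by the BFGS gradient test (tolerance 1e-6,
max 200 iterations) with an explicit `converged` flag and diagnostics on
every fit — non-convergence is never silent. OR confidence intervals use
z = 1.959964. Ties in ROC scores are handled by midranks; degenerate
inputs (single-class labels, empty cohorts, constant or non-finite
covariates, two-zero-cell margins, single strata) raise typed errors
rather than returning numbers.

## Reference tables and limitations

Packaged autosome lengths are hg19 assembly constants; centromere
intervals are approximate hg19 acen intervals; the cytoband map is
synthetic — real major-band names laid out with uniform widths within each
arm — so band-resolved coordinates are band-level approximations suitable
for segment arithmetic and simulation, not for annotation. Any finer
application should supply real assembly/band tables by file. The upstream
measurements do not state their assembly or band resolution, which is an
irreducible source of covariate uncertainty that the CNV-based breakpoint
refinement partially removes.

The published clinical ROC triple and per-covariate p-values depend on the
unavailable patient-level dataset and are not reproduction targets; the
corresponding machinery is validated by its mathematical properties
(pairwise-count AUC oracle, null AUC, GLMM-vs-logistic nesting, MH common
OR bracketing) and by parameter recovery on synthetic cohorts.
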