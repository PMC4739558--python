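# Methods

`hybridpanel` analyzes hybridization among westslope cutthroat trout
(WCT, *Oncorhynchus clarkii lewisi*), rainbow trout (RT, *O. mykiss*),
and Yellowstone cutthroat trout (YCT, *O. c. bouvieri*) from a panel of
species-diagnostic SNPs: 86 nuclear markers (35 diagnostic for WCT, 18
for YCT, 33 for RT) plus two mitochondrial markers. Each diagnostic
allele is treated as fixed in its taxon and absent elsewhere, so a
fish's genotypes reduce to per-locus dosages of the diagnostic allele
(0/1/2, or missing), and ancestry questions become allele-counting
questions.

## Per-fish admixture and classification

For a fish carrying alleles of at most two taxa A and B, the ancestry
proportion is the closed-form count over the *pair panel* (loci
diagnostic for A or B; 68 for WCT×RT, 53 for WCT×YCT, 51 for RT×YCT):

    q_A = (diagnostic-A alleles at A-loci + alternative alleles at B-loci)
          / (2 × successfully typed pair-panel loci)

Missing calls drop out of numerator and denominator alike, so
proportions are always "of alleles actually genotyped" and per-fish
denominators vary. Alleles rather than loci are the weighting unit when
calls are missing.

For a fish with alleles of all three taxa, q = (q_WCT, q_RT, q_YCT) is
the maximum-likelihood point on the 3-simplex for the model in which,
at a locus diagnostic for taxon T, the diagnostic allele has
probability q_T and the alternative allele 1 − q_T (the alternative
state is shared by the other two taxa). The likelihood is maximized by
EM: each alternative allele observed at a T-locus is fractionally
attributed to taxon U ≠ T with weight q_U / (1 − q_T); the M-step
renormalizes attributed totals by the number of typed alleles.
Initialization is the simplex barycenter — the boundary is absorbing in
this model, so boundary starts are avoided — and iteration stops when
the log-likelihood gain falls below 1e-10 (cap 1000 iterations, with a
`converged` flag). The log-likelihood is checked non-decreasing every
iteration. Tests verify agreement with a 0.001-resolution grid search
over the simplex (log-likelihood within 1e-6, argmax within 0.002 per
component) and with the closed form on two-taxon inputs.

Classification thresholds (all configurable, defaults as used in the
survey): a fish is a **parental** form of taxon T when q_T ≥ 0.99 — a
deliberate 1% allowance for genotyping error and local homoplasy; an
**F1** has both parental proportions within [0.49, 0.51] *and* at least
90% of its typed pair-panel loci heterozygous ("nearly all loci
heterozygous" is not quantified in the source material; 0.90 is this
package's documented operationalization); everything else is
**admixed**, annotated with the set of taxa whose alleles it carries.

## Marker and individual QC

The rescreening rules that produced the final panel are implemented as
reusable operations:

- **Admixture-frequency outliers.** For each locus, the fraction of
  genotyped fish whose call conflicts with their panel-wide majority
  taxon (for a locus diagnostic for the fish's own majority taxon, a
  conflict is carrying ≥1 alternative allele; otherwise it is carrying
  ≥1 diagnostic allele). Loci whose frequency exceeds mean + 2 SD
  (one-sided high, sample SD, single pass over all loci) are flagged as
  disproportionately indicative of introgression — the parsimonious
  reading being ascertainment bias, not selection. The per-locus
  "frequency of admixture" is not precisely defined in the source; the
  per-individual-conflict definition used here is a documented choice,
  as is breaking majority ties toward WCT (the native taxon of the
  study region; configurable).
- **Failure rates**: loci with > 15% missing calls flagged (strict
  inequality; 15/100 passes, 16/100 fails).
- **Call rates**: fish genotyped at < 85% of panel loci excluded.
- **Perfect linkage**: locus pairs with identical dosages across every
  fish where both are called (≥1 such fish required); the later locus
  in panel order is marked droppable.
- **Replicate discordance**: for re-genotyped fish, allele changes per
  alleles compared, |d₁ − d₂| summed over loci called in both runs over
  2 × loci, as a percentage. For a per-allele miscall rate e the
  expected discordance is ≈ 2e(1 − e).

All flagging operations are validated against brute-force recounts and
are idempotent on their own output.

## Site-level swarm diagnostics

A site is a **hybrid swarm** when (1) no parental fish of any taxon was
sampled, (2) diagnostic alleles are randomly distributed among
individuals, and (3) genotypes are in Hardy–Weinberg proportions. A
site whose randomness test is not applicable (fewer than 10 fish, no
admixed fish, or a degenerate pooled proportion of exactly 0 or 1)
cannot be called a swarm.

**Randomness (binomial) test.** Fish i carries k_i nonnative alleles
among 2L_i typed pair-panel alleles ("nonnative" is counted against the
site's majority taxon by pooled allele share; configurable). Under
random mating k_i ~ Binomial(2L_i, p) with a common p. The test
statistic is the dispersion-type quantity

    X = Σ_i (k_i − 2L_i p̂)² / (2L_i p̂ (1 − p̂)),   p̂ = Σk_i / Σ2L_i.

The source material names the comparison but no statistic; this choice
is exact-calibratable at small n via a parametric bootstrap: B = 10 000
replicates draw k*_i ~ Binomial(2L_i, p̂), re-estimate p̂ within each
replicate (accounting for plug-in estimation), and the p-value is the
fraction with X* ≥ X. The generator is seeded; reruns are exact.
Calibration is verified at the nominal 0.05 level over 500 simulated
random-mating sites, and the test rejects parental mixtures
(20 WCT + 5 RT + 5 F1) with power > 0.99.

**Hardy–Weinberg battery.** Per locus, the exact conditional test
(enumeration of all heterozygote counts compatible with the observed
allele counts; cheap for biallelic markers, and preferred over
Markov-chain approximations) yields one-sided deficit and excess
p-values; F_IS uses the Weir–Cockerham small-sample estimator, with the
multilocus value as the ratio of summed variance components over
polymorphic loci (positive = heterozygote deficit). The number of loci
examined is the union pair panel for the taxa observed in the site's
admixed fish (68 / 53 / 86 / 51); monomorphic loci count toward that
denominator but can never be significant. A site is out of HWP when
either the deficit count or the excess count strictly exceeds 5% of
loci examined. No per-site multiple-testing correction is applied *by
design* — the 5%-of-loci criterion is itself the multiplicity control.
Per-test α = 0.05.

## Mito–nuclear concordance and spatial contrasts

The probability that a fish carries the WCT mitotype is modeled as
logistic in its percent WCT nuclear alleles, fitted by maximum
likelihood among WCT×RT hybrids only: parental fish, fish with YCT
alleles, fish with unresolved mitotypes, and a configurable site
exclusion list (default: the one site dominated by putatively stocked
F1s) are removed, with exclusion counts reported. The predictor is on
the 0–100 percent scale: with the reported coefficients (intercept
−2.8496, slope 0.0705 per percent), the predicted probability at x = 50
is 0.66, which fixes the scale convention. Complete separation is
detected and flagged rather than silently reported.

Longitudinal structure is tested by a paired t contrast of percent WCT
alleles at each stream's upstream-most vs downstream-most site, with
site classes ordered Low < PIBO < Middle < Headwater. Streams with two
sites of the same class have no defined extremes and are excluded with
a warning rather than guessed; so are streams in the exclusion list
(default Rock and Overwhich creeks, which have stocked headwater
lakes). Inside/outside-RT-range contrasts use the pooled-variance
two-sample t-test on site-level percentages.

Mitotypes are resolved at ingest from the two mitochondrial SNPs via an
explicit decision table (the joint coding of the two assays varies
between labs, so the table is an argument with a documented default:
WCT-variant only → WCT, RT-variant only → RT, neither → YCT, both or
heteroplasmic/missing → unresolved).

## Packaged survey tables

Transcriptions of the study's literature-review table (29 studies) and
site table (188 site records, 3865 fish) ship with the package,
checksum-verified at load. Percentages printed "<0.1" are stored as
0.05 with a below-detection flag. Site identity is (stream, site class,
optional disambiguator) because the printed table contains duplicate
(stream, class) pairs. One transcription inference was required: the
table lists two "Sawmill PIBO" rows, which must be two distinct
same-named streams (a PIBO site is a stream's single lowermost
monitored reach); the Sawmill headwater row is assigned to the stream
whose PIBO shares its YCT signal.

Two printed statistics are *not* exactly recoverable from the printed
table and are reproduced only approximately: the paired-contrast means
(printed 96.3%/77.7%, fixture-derived ≈96.1%/78.5% over 50 usable
streams) and the headwater range-contrast group sizes (printed 15/57,
fixture-derived 15/58). Exhaustive search over transcription and
analysis variants shows no reading of the printed table reproduces the
printed means at 0.1 precision; they were evidently computed from
unrounded site values. The package reports its own values and flags the
difference instead of forcing agreement.

## The simulator

The generator is a forward-time Mendelian gene-drop over the panel.
Each individual carries two haplotypes recording, per locus, the taxon
of origin of the allele, so true ancestry (q_true) is bookkeeping, not
estimation; the observable dosage at a T-diagnostic locus is the number
of haplotypes with origin T. Generations are discrete and
non-overlapping; mothers are drawn uniformly; fathers uniformly
(random mating) or with weight exp(−Δq²/σ²) (assortative; σ is a free
parameter, not an estimate from data). Each locus transmits one
uniformly chosen allele per parent, independently across loci.
Mitochondria copy from the maternal parent — sex is not modeled, the
first parent of each pair is maternal by convention. Migration appends
parental immigrants after reproduction. Genotyping noise flips each
observed allele independently with probability e and blanks whole locus
calls with probability m. A `SimConfig` seed fully determines the
output (byte-identical reruns).

Two founding modes matter scientifically:

- `found_population`: parental founders (and optional F1s). Starting
  from parental founders, the between-fish variance of nonnative allele
  counts begins at 4L²p₀(1−p₀) and its excess over the binomial
  equilibrium 2Lp₀(1−p₀) halves each generation, leaving a relative
  overdispersion of about 2L/2^g after g generations. With L = 68 loci
  this is still ≈13% at g = 10 — detectable by a dispersion test — and
  reaches the percent level only around g ≈ 14. The common claim that
  binomial allele distributions emerge "within five generations" is
  thus panel-size dependent: true for the handful-of-markers studies it
  came from (L = 7 gives 2L/2⁵ ≈ 0.4, invisible at field sample sizes),
  not for an 86-SNP panel.
- `found_admixed_population`: an established swarm — founder alleles
  drawn iid from a gene pool with the given taxon fractions. This is
  the regime the site-level randomness test takes as its null, and the
  `swarm` scenario uses it (default population 1000, well above the
  30-fish samples, so sib-sampling correlations are negligible).

Scenario archetypes: `pure_parental`, `recent_contact` (parentals plus
F1s), `swarm(g, p0)`, `three_way`, and `longitudinal_gradient`
(upstream-attenuating immigrant pressure). Loci are simulated unlinked;
real salmonid genomes have linkage, selection, and overlapping
generations, none of which are modeled — so passing tests demonstrate
correctness of the statistical machinery under its stated assumptions,
not robustness of the field inferences to those violations.

## Problem sizes and numerical conventions

Test-suite simulation scales are the package's own choices: 500
replicate sites for the nominal-level check (3-SE binomial band), 200
for power, 100 for logistic parameter recovery (2000 fish each), 60–120
replicates for the smaller property checks. Bootstrap B = 10 000 for
reported site analyses, smaller inside quick tests. EM tolerance 1e-10;
q components clipped to [0,1] and renormalized (sum-to-1 within 1e-9);
degenerate t-tests (zero-variance differences) return t = 0, p = 1 when
the mean difference is zero and ±∞, p = 0 otherwise; monomorphic loci
return HWE p-values of (1, 1) and undefined F_IS, excluded from
multilocus sums.
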