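# Methods

## Scope and data model

`sharedrisk` operates entirely on summary-level GWAS data: per-variant
records of (variant id, chromosome, position, effect/other allele, effect
allele frequency, beta or OR, se or CI, p). Records are held on the
log-odds (beta) scale. Studies publishing odds ratios are converted on
read: `beta = ln(OR)`; with a 95% CI, `se = (ln(hi) − ln(lo)) / (2·1.96)`;
with only OR and p, the documented fallback `se = |ln OR| / |Φ⁻¹(p/2)|`
(the field's tables do not state how they recovered se for OR-only
studies, so the fallback is this package's choice and is flagged as such
here). The critical value is the conventional 1.96, not Φ⁻¹(0.975) to
machine precision, because that is how published intervals are produced.

p-values are carried as log₁₀ alongside the linear value. Associations
stronger than the double-precision floor (p < ~1e-308) keep a finite
log₁₀ p and print as `<1e-300`; the genome-wide filter compares on the log
scale so such records are never lost. The strict consistency check between
(beta, se) and the reported p is off by default — published tables round.

## Overlap enrichment

The hypergeometric upper tail `P(X ≥ k)` is inclusive (the standard
over-representation convention) and evaluated by log-gamma summation with
`logsumexp`, never in linear space, so the deepest enrichments seen in
practice (p ~ 1e-40 for causal-gene overlaps of autoimmune-disease pairs)
are nowhere near the method's limits. An exact `Fraction`-based
enumeration oracle in the test suite confirms agreement at relative 1e-9
for every parameter combination with N ≤ 25, and spot-checks large-N
values at relative 1e-10. Expected overlap is `nK/N`; fold enrichment
`k/expected` is reported at full precision (display rounding — expected to
2 decimals, p to 2 significant figures — happens only at the formatting
layer). Note that the tail is monotone non-increasing both in k and in N:
a fixed overlap becomes *more* surprising as the universe grows.

Published overlap tables of this kind can be internally ambiguous (a row's
expected value may imply one list size while its fold implies another
observed count); the API therefore takes (k, n, K, N) explicitly and does
not guess a reconciliation.

## Loci and windows

A locus is a maximal run of same-chromosome associated variants in which
consecutive positions differ by ≤ 250 kb ("within" read as inclusive);
merging is transitive and order-invariant, and the lead is the
lowest-p member. Each locus maps to the half-open window
`[max(0, lead − 250 kb), lead + 250 kb)`. Half-open intervals mean two
leads overlap iff they share a chromosome and their centers are < 500 kb
apart — abutting blocks do not double-count, matching the genome-binning
background `round(3,298,912,062 / 500,000) = 6598` (GRCh38.p14; rounding
is half-away-from-zero). For enrichment, k counts *query* windows hitting
at least one subject window (the hypergeometric draws are query loci), not
intersecting pairs. Chromosome labels are normalized ("chr1" ≡ "1"); the
MHC region receives no special handling — a known consequence is that
window-based overlap can miss shared MHC signals whose lead variants sit
more than half a window apart. BED output is 0-based half-open (closed
1-based locus starts shift by −1; windows pass through).

## Harmonization

Alignment trusts allele labels first: exact match → keep; label swap →
negate the outcome beta and reflect its allele frequency; complement-only
match → strand flip (no sign change); complement + swap → both.
Magnitudes and standard errors never change — only signs and labels — and
re-harmonizing harmonized output is the identity (property-tested over
randomized encodings). Indels and multi-base alleles are retained only on
exact or exact-swapped matches and are never complemented.

Palindromic SNPs (A/T, C/G) are their own complements, so labels cannot
resolve strand. Two policies are exposed, because practice genuinely uses
both: **drop** (default — exclude palindromic variants outright) and
**infer** (keep only when exposure and outcome frequencies are both below
the 0.3 minor-allele cutoff or both above 0.7 *after* label alignment and
agree in orientation; discordant, intermediate, or missing frequencies
drop the variant with a specific reason). No claim is made that either
policy reproduces any particular published analysis.

The join key is variant id only (an optional strict mode could cross-check
position; duplicated outcome ids keep the first with a warning). Output
order is deterministic (chrom, pos, id). Proxy-variant lookup is out of
scope — it requires an external LD reference panel — and missing ids are
simply absent from the join, visible in the report counts.

## LD clumping

Greedy p-value clumping with defaults r² ≥ 0.001 within 10 Mb (the
two-sample-MR convention; primary literature rarely states its clumping
parameters). The lowest-exposure-p unclumped variant becomes an index and
removes unclumped same-chromosome variants within the window at or above
the r² threshold; ties break by (chrom, pos, id), making the result
independent of input order. r² comes from a user-supplied offline square
matrix or long-format pairwise table; pairs absent from the table are
treated as r² = 0 (independent) — computing LD from genotypes is out of
scope.

## MR estimators

Per-variant Wald ratios: `β_j = Γ_j/γ_j`, first-order delta-method
`se_j = se_Γj/|γ_j|`. Instruments with γ_j = 0 are dropped with a
diagnostic.

**IVW** is weighted regression of Γ on γ through the origin with weights
`1/se_Γ²` — algebraically the inverse-variance weighted mean of the Wald
ratios (asserted to 1e-10 in tests). The default model is multiplicative
random effects: the fixed se `1/√(Σ γ²w)` is multiplied by
`max(1, √(Q/(J−1)))` — inflation only, never deflation — because real
cross-disease instrument sets show significant heterogeneity; a fixed
model is available by config. p-values are two-sided normal.

**MR-Egger** first orients every instrument to γ_j > 0 (the estimate is
not invariant to allele coding; this is the method literature's
convention), then fits weighted least squares with an intercept. The
slope is the causal estimate under InSIDE; the intercept estimates mean
directional pleiotropy. Standard errors carry the same max(1, residual
scale) inflation, and both slope and intercept are tested against t with
J − 2 df (small-J robustness rather than normal). A design with no
variation in |γ| is rejected as degenerate rather than inverted.

**Weighted median**: ratios ordered, weights = inverse first-order ratio
variances normalized; standardized cumulative positions
`p_j = (S_j − w_j/2)/S_J`; the estimate interpolates the ordered ratios at
p = 0.5. **Weighted mode**: argmax of the weighted Gaussian KDE over
ratios with modified-Silverman bandwidth
`h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5)` (weighted sd and weighted median
absolute deviation; φ = 1 default), located by a dense 1024-point grid
plus a bounded refinement to xatol 1e-12; identical ratios short-circuit
to the common value. Both take their standard errors from a parametric
bootstrap — resampling (γ_j, Γ_j) from their Gaussian sampling
distributions, 1000 replicates by default — and are bit-reproducible given
a seed; unseeded calls draw a seed from OS entropy and log it.

**Heterogeneity**: Cochran's Q about the fixed-effect IVW fit on the ratio
scale with weights `1/se_j²` (df J − 1), and the Egger analogue Q' about
`slope + intercept/|γ_j|` (df J − 2); Q' ≤ Q always (extra free
parameter), checked numerically. **Sensitivity suite**: leave-one-out IVW
(with a Wald-ratio fallback when one instrument remains), single-variant
rows plus overall IVW/Egger rows, funnel (ratio vs precision 1/se), and
scatter (γ, Γ, se's with per-method fitted lines) — all as plot-ready
tables. `run_all` composes the four methods and diagnostics, reporting
methods that cannot run at the available instrument count as
not-applicable rather than failing the report; one instrument yields the
Wald ratio alone.

## Synthetic data

The generator draws true exposure effects γ_j ~ N(0, 0.15²), observed
effects with se 0.03 (exposure) and 0.05 (outcome) — magnitudes typical of
well-powered autoimmune GWAS (odds ratios mostly 1.1–1.6) — and outcome
effects `θγ_j + α_j + confounder term` with independent noise in each
sample. Pleiotropy α_j ~ N(μ_α, σ_α²) applies to a configurable fraction
of instruments; an `inside_corr` parameter correlates α with instrument
strength to violate InSIDE on demand. Two design choices matter:

* **Effect alleles are labelled exposure-increasing by default**
  (`orient_exposure_increasing`), as GWAS risk-variant tables report.
  Directional pleiotropy is thereby defined relative to the same
  orientation MR-Egger regresses in. Without this, a symmetric γ
  distribution makes any directional pleiotropy vanish in expectation
  under the γ > 0 reorientation — not a bug but a statement about allele
  coding.
* **Winner's-curse selection is modelled by rejection sampling**: (γ_j,
  γ̂_j) pairs are redrawn until the observed exposure association passes
  the genome-wide threshold (5e-8 by default), with a bounded attempt
  count and an explicit error when the threshold is unreachable. Selection
  can be disabled (`selection_threshold=None`) to study estimator sampling
  properties in isolation.

Calibration studies in the test suite use these conditions: IVW 95% CI
coverage and null type-I error are checked over 500 replicates at J = 30
with balanced pleiotropy σ_α = 0.02 and selection off (selection bias
would otherwise be confounded with interval calibration); Egger intercept
recovery (μ_α = 0.05, J = 50, 500 replicates) keeps selection on, since
the γ > 0 orientation presumes sign-identified instruments — with
selection off, near-null instruments whose observed γ flips sign carry
−α and attenuate the intercept, a real property of the estimator worth
knowing. The same selection mildly attenuates the Egger slope (winner's
curse), so "slope near θ" is asserted within an absolute 0.05 band.
Weighted-median robustness is checked at 40% invalid instruments
(μ_α = 0.3 on the invalid subset), where the median lands closer to θ
than IVW in ≥ 90% of replicates.

What the generator does *not* emulate: LD structure between instruments
(LD enters only through the user-supplied r² table for clumping tests),
individual-level genotypes, sample overlap between the two GWAS, allele
frequency mismatch between ancestries, and effect-size heterogeneity
across populations. Passing simulation tests therefore demonstrate
estimator correctness and pipeline bookkeeping under the stated model —
not robustness to the LD-mismatch and cohort-definition issues that
dominate real trans-ancestry analyses.

Overlap-list generators place exactly k_true shared symbols (or exactly
k_true geometrically overlapping lead-variant windows, with all other
leads separated by several window widths) so enrichment code paths can be
verified by construction.

## Numerical and interface choices

* Exact hypergeometric tails via log-gamma; rational enumeration reserved
  for test oracles (N ≤ 100 is instant with integer arithmetic).
* All stochastic operations take explicit seeds; derived seeds stay below
  2³¹. Same config + seed ⇒ byte-identical outputs (tested through the
  CLI).
* Exit codes: 0 success, 1 empty/degenerate data, 2 configuration error.
  Logging to stderr; every TSV carries a provenance comment (version,
  config hash, seed) and has a JSON twin.
* Known limitations: no GWAS-VCF or binary format parsing; no remote
  database or API access; no proxy-variant search; no MR-PRESSO/
  multivariable-MR/Steiger extensions; figures are left to the emitted
  plot-ready tables.
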