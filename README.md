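# sharedrisk

Do two complex diseases share *causal* genetic risk factors? `sharedrisk`
answers that question for pairs of GWAS-characterized phenotypes — the
motivating case being Sjögren's Disease (SjD) and Systemic Lupus
Erythematosus (SLE), two autoimmune diseases with extensive clinical and
molecular overlap — using three complementary analyses over nothing but
published summary-level data:

1. **Gene-list overlap enrichment.** Given two lists of predicted causal
   genes and a gene universe of size *N* (e.g. the 19,303 genes of a
   whole-proteome interaction network), the probability of observing at
   least *k* shared genes when *n* are drawn against *K* marked is the
   upper-tail hypergeometric
   `P(X ≥ k) = Σ_{j≥k} C(K,j) C(N−K, n−j) / C(N,n)`,
   computed in log space so that enrichments far below p = 1e-300 keep a
   finite log₁₀ p. Expected overlap `nK/N` and fold enrichment
   `k / expected` are reported alongside.
2. **Genomic risk-interval overlap enrichment.** Associated variants are
   merged into loci (adjacent variants within 250 kb), each locus is
   represented by the 500 kb window centered on its lead variant, and the
   number of query windows intersecting any subject window is tested with
   the same hypergeometric against a background of
   `round(genome_length / 500 kb) = 6598` genome blocks (GRCh38.p14).
3. **Two-sample Mendelian randomization.** With exposure effects γ_j and
   outcome effects Γ_j for independent genome-wide-significant instruments,
   the package estimates the causal effect β_XY by four methods — IVW
   (multiplicative random effects by default), MR-Egger with its
   directional-pleiotropy intercept, weighted median, and weighted mode —
   after allele harmonization (strand flips, swaps, palindromic-SNP
   policy) and greedy LD clumping, with Cochran's Q, leave-one-out,
   single-variant, funnel and scatter tables as sensitivity output.
   Estimates are reported as β ± se and as odds ratios via
   `OR = e^β, 95% CI = (e^(β−1.96·se), e^(β+1.96·se))`, `p = 2Φ(−|β/se|)`.

A synthetic-data generator produces paired two-sample summary statistics
with a known causal effect, pleiotropy structure, allele/strand/palindrome
encodings and winner's-curse selection — so the entire pipeline runs and is
tested fully offline.

## Worked example

Simulate a 20-instrument two-sample dataset with true causal effect
θ = 0.5, then run the full MR pipeline on the emitted TSVs:

```bash
sharedrisk simulate --seed 7 --n-instruments 20 --theta 0.5 --out-dir sim
sharedrisk mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
              --seed 7 --out-dir mr
```

which prints

```
                 method  n_snps     beta       se            p       or  or_ci_low  or_ci_high
Inverse-variance weight      17 0.429140 0.069043 5.113500e-10 1.535936   1.341538    1.758504
        Weighted median      17 0.455002 0.078378 6.429428e-09 1.576176   1.351723    1.837900
          Weighted mode      17 0.480234 0.126895 1.540250e-04 1.616452   1.260513    2.072900
               MR Egger      17 0.881084 0.284078 7.293921e-03 2.413515   1.383051    4.211741
```

Of the 20 simulated variants, 3 were palindromic and dropped under the
default policy (`mr/manifest.json` lists each dropped variant with its
reason, the harmonization counts — here 17 kept, 1 allele-swapped — and
every setting and seed). All four estimates bracket the true θ = 0.5 within
their confidence intervals; the Egger intercept (−0.107 ± 0.065, p = 0.12)
shows no significant directional pleiotropy, as expected for a simulation
with none.

Gene-list overlap works on plain one-symbol-per-line files:

```bash
sharedrisk overlap-genes sjd_genes.txt sle_genes.txt --out-dir genes
# gene-overlap	expected=0.01	fold=643.4	p=1.8e-11
```

i.e. 4 shared genes between a 10- and a 12-gene list where 0.01 were
expected by chance in a 19,303-gene universe. `overlap-loci` does the same
for association tables, composing locus merging → windows → overlap →
enrichment with the 6598-block genome background.

The same operations are importable as a library
(`sharedrisk.mr_ivw`, `sharedrisk.harmonize_dataset`,
`sharedrisk.hypergeom_enrichment`, ...); see `docs/methods.md` for the
statistical details and design choices.

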