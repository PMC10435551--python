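# Methods

## Single-effect fine-mapping

Each approximately independent LD block is analyzed under a single-effect
regression (SER): exactly one variant is causal, its standardized effect has
a N(0, σ₀²) prior, and every other effect is zero. For summary statistics
the per-variant evidence is the Wakefield-style approximate Bayes factor

    log BF(z) = ½ log(1/(1+σ₀²)) + (z²/2)·σ₀²/(1+σ₀²).

Under the standard summary-statistics likelihood z ~ MVN(λ·R e_c, R), the
full-vector likelihood ratio between "variant j causal" and the null depends
on z only through z_j (matrix-determinant/Sherman–Morrison identity), so the
single-effect posterior over the causal index,

    PIP_j = π_j BF(z_j) / Σ_k π_k BF(z_k),

is exact given the prior, and the LD matrix is needed only for credible-set
purity. Computation uses a log-sum-exp guard. GWAS mode conditions on the
block containing one causal variant (loci are pre-selected at genome-wide
significance, |z| ≥ 5.45 ⇔ P < 5×10⁻⁸); the enrichment EM instead carries an
explicit no-causal configuration.

σ₀² (prior effect variance, z² scale) is profiled on a 21-point log grid
over [10⁻³, 10³] by maximizing the SER marginal likelihood; a boundary
maximum is flagged. Credible sets take variants in decreasing-PIP order
(ties by ascending position) until the requested coverage (default 95%) is
reached; when an LD matrix is available, a set whose minimum pairwise |r|
falls below 0.5 is discarded, following the usual purity convention.

## Enrichment priors

The prior causal probability of SNP j is logistic in its binary annotations,
π_j = logistic(α₀ + Σ_k α_k A_jk). Causal indicators are independent
Bernoulli(π_j) truncated to at most one causal per block, so a block's
marginal likelihood is

    L_b = Π_j (1-π_j) · (1 + Σ_j odds_j BF_j),   odds_j = π_j/(1-π_j).

For small π this no-causal mass is ≈ 1 − Σ_j π_j. We deliberately use the
odds form: parameterizing the no-causal configuration literally as
1 − Σπ_j makes the likelihood degenerate when most blocks carry strong
signal (it is then non-decreasing in every π_j until Σπ_j → 1), whereas the
truncated-Bernoulli form is a proper likelihood at any signal strength.

Estimation is EM over blocks. The E-step computes posterior causal
probabilities q_j (and the no-causal mass q₀ per block); the M-step — a
weighted logistic regression of q on the annotations, solved by L-BFGS-B on
the concave complete-data objective with a |α_k| ≤ 10 box to contain
separation on sparse annotations — is the exact M-step for this model, so
the marginal log-likelihood is non-decreasing (asserted in tests at 1e-8).
σ₀² is profiled on the shared grid at each iteration (coordinate ascent,
monotone). Convergence: max |Δα| < 1e-4 or 200 iterations; non-convergence
is flagged, and the result still returned. Wald standard errors come from
the observed information of the *marginal* likelihood (central finite
differences of the analytic score X'(q−π)), which accounts for E-step
uncertainty that plug-in M-step information would ignore. Annotations
constant across SNPs are dropped with a warning.

Marginal (one-annotation-at-a-time) fits feed the enrichment report —
log2FE = α_k/ln 2, 95% Wald CI, BH adjustment across the declared family —
while a joint fit over all annotations produces the fine-mapping priors,
which are renormalized to sum to one within each block as the L = 1
semantics require.

Known property: when every analyzed block truly contains a causal variant,
the data contradict the model's no-causal configuration and the MLE of α₁
sits slightly above the generative placement log-odds (≈ +0.1 at 100-SNP
blocks with one causal each and a 10% annotation at log-odds ln 8; the
Bernoulli-regression estimand of even the true labels is ln 8.35 there).
Point recovery is well inside ±0.5 on the log2 scale, but 95% CIs centered
on this estimand under-cover the placement parameter; the test suite records
this honestly (one expected failure in the CI-coverage acceptance test).
Genome-wide use with many signal-free blocks — the regime the method is
meant for — does not have this mismatch, and null-simulation CI coverage is
nominal.

## Gene mapping

SNP-to-gene weights follow a staged scheme. Stages 1–3 assign weight 1 and
accumulate (a SNP exonic for gene A and looped to gene B supports both):

1. exon, or active promoter — a strand-aware window [−2000, +500] around the
   TSS that overlaps an open-chromatin region (OCR);
2. enhancer loops: ABC links at score ≥ 0.015, promoter-capture Hi-C links,
   or the SNP lying in an OCR within 20 kb of an active promoter;
3. UTR, only when the SNP is not in any OCR (UTR variants are taken to act
   through RNA stability / polyadenylation on the host gene).

Stage 4 applies only when stages 1–3 produced nothing: w_ig = exp(−d_ig/5·10⁴)
for every gene with TSS within 1 Mb, d_ig being the SNP-to-TSS distance.
With the 50-kb decay, a closed-form area-under-curve gives
1 − e⁻² ≈ 0.865 of the weight mass within 100 kb. A `first-hit` link mode
(stop at the first stage that links) is provided as a switch, since whether
stage-1 and stage-2 links should coexist is a judgment call.

Weights are normalized per SNP (w̃_ig = w_ig/Σ_g w_ig, so each SNP's causal
evidence is counted once), and the gene PIP is Σ_i PIP_i·w̃_ig over all
blocks. A single-block gene PIP is bounded by 1; a gene spanning several
blocks can exceed 1 and is flagged (interpretable as the expected number of
causal variants targeting it). Credible gene sets rank genes by their
within-locus contribution (ties by gene id) and take the smallest prefix
reaching 80% of the locus's gene-mapped PIP; a multi-block gene enters each
locus only with its local contribution. Benchmarking uses precision
(|nominated ∩ plausible| / |nominated|) against a nearest-gene-to-top-SNP
baseline (TSS distance, ties by gene id).

## Annotation categories

OCR sharing classes: within each cell type, peaks at or above the 75th
percentile of normalized accessibility (ties included — deterministic and
order-independent) are "highly accessible". Differentially accessible (DA)
peaks with exactly one DA cell type are cell-type-specific; DA peaks in
several cell types are moved to the shared classes by their DA cell-type
count (2–3 → shared_2_3, ≥4 → shared_4plus). Non-DA peaks go to shared_2_3
/ shared_4plus by their highly-accessible count, and otherwise to non_DA
(which includes peaks highly accessible in just one cell type without DA
support).

SNP annotation matrices are built by precedence (default: coding > UTR >
conserved > cell-type-specific OCR > shared_2_3 > shared_4plus > non-DA OCR
> other) so the disjoint matrix has row sums ≤ 1. eQTL categories: variants
in OCRs overlapping exons/UTRs, or in non-DA OCRs, are ambiguous and
filtered; intronic-OCR variants take the OCR class; exon/UTR variants
outside OCRs are labeled exon/utr (UTR wins over exon since UTRs lie inside
exon intervals); everything else is unassigned.

PIP partitioning sums PIPs per disjoint category — genome-wide (expected
causal-variant counts) and per locus (the probability the locus's causal
variant falls in each category). Locus cell-type attribution keeps loci
with ≥ 0.25 summed PIP in OCR categories and reports both the raw share and
the share renormalized over OCR categories; both views are emitted because
either could reasonably be plotted.

## eQTL tissue sharing and dilution power

Fine-mapped eQTLs are retained at PIP ≥ 0.8. With w_c the proportion of
eQTLs in category c and p_c the within-category probability of being active
in a second tissue, the overall sharing probability decomposes exactly as
p = Σ_c p_c w_c; the identity is asserted, not estimated. Category
enrichment divides eQTL by control category proportions (controls are
caller-supplied, e.g. LD/MAF-matched sets read from TSV, or generated
synthetically); a category absent from controls reports +inf with a flag.

The dilution power simulation models a bulk tissue in which a
cell-type-specific eQTL acting in a fraction-f cell type contributes bulk
slope f·β while a shared eQTL contributes β; genotypes and residuals are
standard normal, and power is the rejection rate of the marginal slope
t-test. Common random numbers are shared between the two arms (variance
reduction; the f = 1 ratio is exactly 1). Defaults: n = 500 individuals,
effects (0.10, 0.15, 0.20), α = 10⁻³, 1000 replicates. The closed-form
normal-approximation oracle uses non-centralities f·β·√n and β·√n; the
simulation is validated against it to 0.05 per grid point.

## Synthetic-data generator

Defaults are the simulation study conditions used throughout: 1000 blocks
× 100 SNPs, AR1 LD with ρ = 0.5 (a generic within-block decay; real LD is
blockier and longer-ranged than AR1, which the pipeline never exploits),
causal effect λ = 5 on the z scale, one 10% annotation with placement
log-odds ln 8 (log2 enrichment 3), exactly one causal per block, z ~
MVN(λ·R e_c, R). Gene landscapes place 4 genes per 1-Mb locus; the causal
SNP sits in a causal-gene exon with probability 0.3 and otherwise in a
distal OCR (50–250 kb from the causal TSS) looped to the causal gene's
promoter by an ABC link, so the nearest gene is a fallible baseline
(~50% accurate here). eQTL generators emit categorized records with chosen
(w_c, p_c) and matched controls with chosen category proportions. All
generators require an explicit seed (numpy Generator streams, platform
stable); every output parses back through the package's readers.

What the generator does not emulate: realistic human LD panels, allele
frequencies and effect-size coupling, multiple causal variants per block,
overlapping genes/isoform structure, and LD/MAF matching of controls.
Passing tests therefore demonstrate correctness of the estimators under
their assumed models and the stated placement laws, not performance on real
GWAS data.

## Numerical and design choices

- Positions are 1-based; BED/BEDPE intervals 0-based half-open; a 1-based
  position p is inside [s, e) iff s < p ≤ e. Conversion only at I/O.
- PIP normalization and Eq.-style weight normalization are asserted at
  1e-12; EM monotonicity at 1e-8.
- Calibration testing draws λ_b ~ N(0, σ₀²) per block and fine-maps at the
  matching σ₀²: with a fixed shared λ the Bayesian model is mis-specified
  and exact decile calibration is not implied.
- Problem sizes in the test suite (e.g. 10⁴ calibration blocks of 30 SNPs,
  150 gene-landscape loci, 1500 power replicates) are chosen so Monte-Carlo
  error sits comfortably inside each asserted tolerance.
- Degenerate inputs: single-SNP blocks get PIP 1; all-zero priors, empty
  eQTL tables, coverage outside (0,1], ρ ≥ 1 raise; zero-weight SNPs are
  dropped from gene mapping with a log entry.

## Limitations

L = 1 only — no multi-causal fine-mapping or conditional analysis; no LD
mismatch diagnostics; enrichment SEs are asymptotic Wald; the active
promoter window and the accumulate link mode are conventions (configurable)
rather than estimated; the eQTL power model is a two-component mixture with
equal baseline expression across cell types.
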