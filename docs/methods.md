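# Methods

This note documents the models and procedures implemented in `deltabind`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Motif models and exact match p-values

A motif arrives as a 4×w position frequency matrix (PFM) of base counts.
The log-odds position weight matrix against a 0-order background b is

    pwm[i,j] = log2( (pfm[i,j] + c·b[i]) / (colsum_j + c) / b[i] )

with pseudocount c = 0.1 distributed proportionally to the background
(configurable). The background defaults to 0-order base frequencies
estimated from the pooled scanned region sequences, both strands (so
freq(A)=freq(T), freq(C)=freq(G)); a uniform background is available by
flag. These defaults mirror common motif-scanner behaviour; since no
single canonical choice exists, both knobs are exposed.

Match p-values are exact, not approximated: each PWM entry is rounded to a
grid of `granularity` bins per column (default 1000; the exactness checks
use 10⁴), and the null distribution of the window score of an i.i.d.
background sequence is computed by per-column convolution on that integer
grid. Scanning computes every window's quantized score by summing the same
integer entries, so a hit's p-value is exact for the quantized matrix —
there is no interpolation, only the bounded perturbation of rounding the
matrix itself (≤ w/2 bins of score). The survival function is normalized
so the minimum achievable score has p-value exactly 1, and is monotone
non-increasing by construction.

Scanning reports both strands at every offset (no per-position maximum:
the binding score deliberately sums *all* hits); windows containing N are
skipped rather than failing the whole region; a sequence shorter than the
motif yields no hits.

## Variant handling

- Genome-wide significance: p ≤ 5×10⁻⁸, inclusive. Linkage disequilibrium
  is deliberately ignored — every significant variant is carried forward.
- Risk recoding: a variant with negative effect size has its alleles
  swapped and β negated, so the "risk" allele always has β ≥ 0. β = 0 has
  no orientation information and is left unrecoded (logged). Recoding is
  idempotent.
- Indel and multi-allelic rows are skipped with a counted warning: the
  allele-substitution step is length-preserving by design.
- Allele pairs: all SNPs of a region are substituted simultaneously into
  its genomic sequence, yielding one non-risk and one risk sequence (the
  per-region analogue of building two whole-genome references). The
  summary-statistics alleles are authoritative: if the genome base equals
  either allele the substitution proceeds; if it matches neither, the SNP
  is dropped with a warning (a coordinate inconsistency, not a judgement
  call). An extended-MHC exclusion (chr6:26–34 Mb) is available for
  sensitivity analyses.
- Positions are 1-based in GWAS/genotype files (VCF convention), 0-based
  internally; the conversion happens exactly once, at read time.

## Per-cell-type motif selection

Marker peaks are tested on donor-level pseudobulks (one "in-type" and one
"out-of-type" sample per donor), CPM-normalized, with a two-sided Wilcoxon
rank-sum test across donors. Testing at donor rather than cell level
avoids pseudoreplication. log2 fold change uses a 1-CPM pseudocount to
avoid division by zero. Markers: log2FC ≥ 1 and BH-FDR ≤ 0.05.

Motif presence for the enrichment stage is annotated at a stringent match
p ≤ 5×10⁻⁵ — a conventional single-hit cutoff, deliberately distinct from
the permissive 0.99 threshold used for binding scores. Enrichment is the
upper-tail hypergeometric probability of the observed count of
motif-bearing marker peaks; motifs with p < 10⁻¹⁰ (strict) survive.

The accessibility-deviation statistic is a simplified bias-matched
deviation: per cell, the relative excess of observed counts in the
motif's peak set over the expectation under the cell's depth and the
set's global accessibility share, standardized against 50 random peak
sets (minimum 10) matched to the motif peaks by nearest neighbour in
standardized (GC content, mean accessibility) space, then averaged over
the cell type's cells. It reproduces the deviation idea — excess
accessibility relative to technically comparable background peaks — but
not any particular package's internal kernels. The activity cutoff
z ≥ 1.0 is configurable; no canonical numeric value exists for "highly
active".

The expression filter requires every component gene of the TF (split on
`::` for dimers/trimers) to have a nonzero raw count in ≥ 5% (inclusive)
of the cell type's cells. Raw nonzero fractions are used; normalization
does not change zero/nonzero status.

## Differential binding

scCREs of a cell type are the union of (1) peaks called in that cell
type's pseudobulk and (2) peaks accessible (count > 0) in ≥ 5% of its
cells — criterion (2) admits peaks called only in other cell types but
open here.

Binding score: S = Σ −log₁₀ p over all hits at scan threshold 0.99; no
hits ⇒ 0. One shared background and p-value table per motif is used for
both allele sequences — otherwise deltas would reflect background drift
rather than alleles. Δ = S(risk) − S(non-risk), so a positive Δ means
binding gained through the risk allele. Both subtraction orders appear in
the field's descriptions of differential binding; the convention in which
a positive score means gain via the risk (alternative) allele is the
default, and `sign="ref-minus-alt"` selects the opposite,
reference-minus-alternate order. |Δ| > 3 (strict) calls gained/lost; elements with SNPs but no
hits on either allele count as unchanged (Δ = 0), preserving the
gained + lost + unchanged = total bookkeeping. A motif is consistently
enhanced/disrupted in a cell type when |gained − lost| ≥ 5 (inclusive).
Both thresholds are fixed global defaults.

Two structural properties are enforced by tests: **locality** (Δ is fully
determined by scan windows overlapping a substituted position — all other
windows cancel exactly) and **antisymmetry** (swapping the allele roles
negates every Δ and swaps gained↔lost).

Per-SNP attribution within multi-SNP elements and per-element significance
are out of scope: the delta score is a regional, exploratory summary.

## Expression link

SNP→gene mapping uses a ±10 kb promoter window around the TSS and,
optionally, interaction pairs (a SNP in one anchor links to genes with
TSS in the other). This is a transparent stand-in for Hi-C-informed gene
assignment; links carry their evidence type so downstream consumers can
distinguish them.

Carriers are donors with risk-allele dosage ≥ 1; NA dosages are excluded
and counted. The DE test is a negative-binomial GLM with log link,
log-library-size offset, a carrier indicator, and six covariates
(case/control status, sex, age, brain pH, RIN, PMI); the Wald test on the
carrier coefficient gives the p-value and log2FC = coefficient / ln 2.
Dispersion is estimated per gene by method of moments on depth-normalized
counts with a floor of 0.01. This is a deliberate, testable stand-in for
moderated-dispersion DE packages: acceptance is parameter recovery and
null calibration, not coefficient-identical output. Genes need ≥ 10
counts in ≥ 75% of pseudobulk samples (both inclusive) and ≥ 3 donors per
arm (below that the result is marked untestable, not an error). BH-FDR is
applied once across all tested (gene, SNP, cell type) tuples per run —
the multiple-testing family is a single global one, the most conservative
unambiguous choice. FDR ≤ 0.1 (inclusive) calls significance.

## Synthetic data

The generator emulates the statistical structure of a single-nucleus
multi-omic risk-variant cohort at desk scale: 3 cell types × 30 donors ×
30 cells, 500 peaks of 200 bp spaced 2 kb apart on a toy contig, 50
marker peaks per type at 8-fold accessibility, Poisson accessibility
counts (baseline mean 0.3/cell), NB expression counts (dispersion 0.2),
Hardy–Weinberg genotypes at MAF 0.3 with a 2% missing rate, and donor
covariates drawn to the cohort moments of a postmortem brain study (age
55.31 ± 13.12 y, PMI 32.77 ± 14.07 h, pH 6.60 ± 0.22, RIN 7.24 ± 1.17,
34% female). These sizes keep the full test suite within minutes on one
core while leaving every stage statistically well-powered.

The packaged toy motif set contains eight 12-bp PFMs with four
high-information columns (97/1/1/1) and eight medium-information columns
(40/20/20/20). This profile is what makes single-base effects detectable
by the |Δ| > 3 rule: one high-information mismatch costs more log-odds
than all medium columns combined, so ~4⁸ windows outrank the broken site
and its hit p-value rises by ≈ 4.6 orders of magnitude. Planted effects
substitute a risk allele that either breaks a planted consensus site
(lost) or restores a deliberately broken one (gained), 8 elements each by
default. Neutral significant SNPs are rejection-sampled so that no toy
motif's local delta exceeds 1 — the emitted "no effect" ground truth is
verified against the emitted sequences, not assumed. Target genes get a
TSS within the promoter window of their SNP and dosage-dependent means
(2× in carriers at the default log2FC = 1).

Each output artifact draws from its own child stream of the master seed
(`numpy.random.SeedSequence.spawn`), so adding an artifact never perturbs
the others and a seed reproduces the bundle byte for byte.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium (planted SNPs are
independent), realistic motif information-content profiles and motif
similarity families, GC/accessibility confounding between marker and
non-marker peaks, Hi-C contact structure, donor-level batch effects
beyond the covariate table, and read-level noise (counts are drawn, not
aligned). Recovery rates on synthetic data are upper bounds on real-data
performance.

## Numerical choices and degenerate inputs

- p-value table: granularity 1000 bins/column by default, 10⁴ in the
  exactness checks; survival function normalized to p(min) = 1; queries
  above the maximum achievable score clamp to the smallest tabulated p.
- Zero-column PFMs, granularity < 10, empty backgrounds, and non-positive
  pseudocounts are rejected at construction.
- Wilcoxon p-values that are NaN (all-tied pseudobulks) are set to 1.
- Deviation: peak sets with zero expected counts contribute 0 raw
  deviation; background s.d. of 0 is replaced by 1 (degenerate only when
  the background sets are identical).
- GLM failures (singular design, non-convergence) mark the result
  untestable rather than aborting the run.
- Ties: both-strand hits at one offset are both reported; BH is applied
  with the standard step-up procedure everywhere "FDR" appears.

## Limitations

- The hypergeometric enrichment treats peaks as exchangeable; it does not
  correct for peak length or GC beyond what the deviation stage captures.
- The NB-GLM Wald test with plug-in method-of-moments dispersion is
  slightly liberal at small n (its empirical type-I error at α = 0.05 is
  verified to lie in (0.02, 0.09) at n = 30 donors); it is not a
  substitute for moderated-dispersion inference at very small cohort
  sizes.
- Binding scores aggregate all hits in an element; a motif with many weak
  background hits dilutes the contribution of a single strong site.
- The scanner supports fixed-width, ungapped motifs and 0-order
  backgrounds only.
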