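# deltabind

**Cell type-specific differential transcription-factor-binding analysis of
GWAS risk variants.**

Most disease-associated variants from genome-wide association studies fall
in non-coding regulatory DNA, where they can strengthen or weaken the short
sequence motifs that transcription factors (TFs) bind. `deltabind`
implements a single-cell-resolution pipeline for asking, per cell type,
*which TF motifs are consistently disrupted or enhanced by risk alleles,
and whether the implicated variants track with target-gene expression
differences between allele carriers and non-carriers*. It is aimed at
regulatory-genomics analysts working with snATAC-seq/snRNA-seq cohorts and
GWAS summary statistics.

## The method

1. **Per-cell-type motif selection.** Marker peaks (uniquely accessible
   peaks; log2FC ≥ 1, BH-FDR ≤ 0.05 on donor pseudobulks) are tested for
   motif enrichment with an upper-tail hypergeometric test (kept at
   *P* < 10⁻¹⁰), motifs must be highly active by a bias-matched
   accessibility-deviation *z* (background peak sets matched on GC content
   and mean accessibility), and the TF's gene(s) — all components for
   dimers such as FOSL2::JUN — must be expressed in ≥ 5% of the cell
   type's cells.
2. **Allele-specific binding scores.** Each genome-wide-significant SNP
   (*P* ≤ 5×10⁻⁸), recoded so the risk allele has β ≥ 0, is substituted
   into its containing single-cell candidate cis-regulatory elements
   (scCREs: peaks called in the cell type's pseudobulk or accessible in
   ≥ 5% of its cells), yielding a non-risk/risk sequence pair. Both
   sequences are scanned on both strands with a log-odds PWM whose match
   p-values are exact (dynamic-programming score distribution under a
   0-order background), at a permissive threshold of 0.99 so essentially
   all windows count. The binding score of an element is

   S = Σ −log₁₀ p(hit) (0 if no hits),

   and the differential binding score Δ = S(risk) − S(non-risk). |Δ| > 3
   calls the element *gained* or *lost*; a motif whose gained and lost
   scCRE counts differ by ≥ 5 within a cell type is *consistently
   enhanced* or *disrupted*.
3. **Expression link.** SNPs in consistently altered motifs are mapped to
   candidate target genes (promoter window, optionally chromatin
   interaction pairs), donors split into risk-allele carriers (dosage ≥ 1)
   and non-carriers, and per-(donor, cell type) pseudobulk counts tested
   with a negative-binomial GLM (log link, library-size offset; case/control
   status, sex, age, brain pH, RIN and PMI as covariates). Genes with ≥ 10
   counts in ≥ 75% of pseudobulk samples are testable; BH-FDR ≤ 0.1 calls
   significance.

A seeded synthetic-data module generates every input with known ground
truth — toy genome, peaks, motifs, GWAS table, Hardy–Weinberg genotypes,
accessibility and expression matrices, cohort-matched covariates — so the
whole pipeline is testable without any download.

## Worked example

```python
from deltabind import SimulationConfig, simulate, run_pipeline_on_bundle

bundle = simulate(SimulationConfig(seed=0))     # 3 cell types, 30 donors, 500 peaks
result = run_pipeline_on_bundle(bundle)

for v in result.verdicts:
    print(v.cell_type, v.motif_id, v.n_gained, v.n_lost, v.verdict)
```

prints

```
Astro M02 0 0 none
Astro M06 0 0 none
Exc   M01 0 8 disrupted
Exc   M05 8 0 enhanced
Exc   M08 0 0 none
```

i.e. in excitatory neurons the EGR-like motif M01 loses binding in 8
scCREs (a *disrupted* verdict: 8 lost − 0 gained ≥ 5) and the CREB-like
motif M05 gains binding in 8 — exactly the effects the simulator planted —
while motifs without planted SNP effects stay at *none*. One of the lost
elements, for instance, scores S(non-risk) = 177.8 vs S(risk) = 171.2
(Δ = −6.6 < −3). Downstream, 16 of 33 tested (gene, SNP, cell type)
combinations are significantly differentially expressed between carriers
and non-carriers, e.g. target gene `TGT_rs00006` in excitatory neurons:
log2FC ≈ 1.0 (the planted effect), FDR ≈ 1e-05, 15 carriers vs 14
non-carriers.

The same analysis is available from the shell:

```bash
deltabind simulate --seed 0 --out bundle/
deltabind run --bundle bundle/ --out results/
deltabind variants --gwas bundle/gwas.tsv --out filtered.tsv   # 5e-8 filter + recoding
```

## Layout

- `src/deltabind/io_formats.py` — FASTA/BED/JASPAR/MEME/GWAS/MTX/dosage readers & writers
- `src/deltabind/motif_engine.py` — PWM construction, exact p-values, two-strand scanning
- `src/deltabind/variants.py` — significance filter, risk recoding, allele-sequence pairs
- `src/deltabind/celltype_select.py` — marker peaks, enrichment, deviation, expression filter
- `src/deltabind/delta_binding.py` — scCREs, binding scores, Δ classification, verdicts
- `src/deltabind/expression_link.py` — SNP→gene mapping, carrier split, NB-GLM pseudobulk DE
- `src/deltabind/synthetic_data.py` — seeded ground-truth simulator
- `src/deltabind/pipeline.py`, `src/deltabind/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, defaults, and limitations
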