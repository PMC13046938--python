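"""End-to-end orchestration of the differential-binding workflow.

Runs, on an in-memory input bundle: motif-model construction against a
background estimated from the peak sequences, the three-stage per-cell-type
motif filter, GWAS filtering/recoding, scCRE definition and allele-pair
construction, delta-binding classification and motif verdicts, and finally
carrier-vs-non-carrier pseudobulk differential expression of the implicated
target genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import celltype_select as cs
from . import delta_binding as db
from . import expression_link as el
from . import variants as var
from .io_formats import CountMatrix, GenomeSource, RawMotif, Region
from .motif_engine import (
    MotifModel,
    build_motif_models,
    estimate_background,
    motif_present,
)

ANNOTATION_P = 5e-5  # stringent motif-presence cutoff for enrichment annotation


@dataclass
class PipelineParams:
    scan_p_threshold: float = db.SCAN_P_THRESHOLD
    annotation_p: float = ANNOTATION_P
    z_min: float = cs.DEVIATION_Z_MIN
    gwas_p: float = var.GENOME_WIDE_P
    n_background: int = 50
    granularity: int = 1000
    pseudocount: float = 0.1
    uniform_background: bool = False
    exclude_mhc: bool = False
    sign: str = "risk-minus-nonrisk"
    window_bp: int = el.PROMOTER_WINDOW_BP
    deviation_seed: int = 0


@dataclass
class PipelineResult:
    models: dict[str, MotifModel]
    markers: dict[str, list[cs.MarkerPeakResult]]
    annotations: dict[str, set[str]]  # region_id -> motifs present
    enrichments: dict[str, list[cs.MotifEnrichment]]
    deviations: dict[str, list[cs.DeviationResult]]
    motif_sets: dict[str, cs.CellTypeMotifSet]
    snps: list[var.SnpRecord]
    sccres: dict[str, list[db.ScCRE]]
    delta_results: list[db.DeltaBindingResult]
    verdicts: list[db.MotifConsistency]
    de_results: list[el.DEResult]

    def verdict_map(self) -> dict[tuple[str, str], str]:
        return {(v.cell_type, v.motif_id): v.verdict for v in self.verdicts}


def annotate_motif_presence(
    models: Sequence[MotifModel],
    genome: GenomeSource,
    regions: Sequence[Region],
    p_threshold: float = ANNOTATION_P,
) -> dict[str, set[str]]:
    """region_id -> set of motif_ids with at least one stringent match."""
    annotations: dict[str, set[str]] = {r.region_id: set() for r in regions}
    for r in regions:
        seq = genome.fetch(r.contig, r.start, r.end)
        for m in models:
            if motif_present(m, seq, p_threshold):
                annotations[r.region_id].add(m.motif_id)
    return annotations


def select_celltype_motifs(
    models: Sequence[MotifModel],
    atac: CountMatrix,
    rna: CountMatrix,
    annotations: Mapping[str, set[str]],
    peak_gc: Mapping[str, float],
    params: PipelineParams,
) -> tuple[dict, dict, dict, dict]:
    """Run the three-stage filter for every cell type of the ATAC matrix."""
    model_by_id = {m.motif_id: m for m in models}
    markers, enrichments, deviations, motif_sets = {}, {}, {}, {}
    for ct in atac.cell_types:
        mk = cs.call_marker_peaks(atac, ct)
        markers[ct] = mk
        enr = cs.enrich_motifs(annotations, cs.marker_region_ids(mk), cell_type=ct)
        enrichments[ct] = enr
        enriched_ids = [e.motif_id for e in enr if e.is_enriched]
        motif_peaks = {
            mid: {rid for rid, mots in annotations.items() if mid in mots}
            for mid in enriched_ids
        }
        dev = (
            cs.motif_deviation(
                atac, motif_peaks, peak_gc, ct,
                n_background=params.n_background, seed=params.deviation_seed,
            )
            if motif_peaks else []
        )
        deviations[ct] = dev
        expression = {
            mid: cs.expression_filter(rna, ct, model_by_id[mid].tf_name)
            for mid in enriched_ids
        }
        motif_sets[ct] = cs.select_motifs(ct, enr, dev, expression, z_min=params.z_min)
    return markers, enrichments, deviations, motif_sets


def run_pipeline(
    genome: GenomeSource,
    regions: Sequence[Region],
    raw_motifs: Sequence[RawMotif],
    gwas_records: Sequence[var.SnpRecord],
    atac: CountMatrix,
    rna: CountMatrix,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: Sequence[el.GeneModel],
    celltype_peak_calls: Mapping[str, set[str]],
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    region_map = {r.region_id: r for r in regions}
    peak_seqs = [genome.fetch(r.contig, r.start, r.end) for r in regions]

    background = None if params.uniform_background else estimate_background(peak_seqs)
    models = build_motif_models(
        raw_motifs, background=background,
        pseudocount=params.pseudocount, granularity=params.granularity,
    )
    model_by_id = {m.motif_id: m for m in models}

    annotations = annotate_motif_presence(models, genome, regions, params.annotation_p)
    peak_gc = cs.peak_gc_content(genome, regions)
    markers, enrichments, deviations, motif_sets = select_celltype_motifs(
        models, atac, rna, annotations, peak_gc, params
    )

    # --- variants ---------------------------------------------------------
    snps = var.filter_genomewide(gwas_records, params.gwas_p)
    if params.exclude_mhc:
        snps = var.exclude_mhc(snps)
    snps = [var.recode_risk(s) for s in snps]
    snps_by_region = var.assign_snps_to_regions(snps, list(regions))

    # --- delta binding ----------------------------------------------------
    sccres: dict[str, list[db.ScCRE]] = {}
    delta_results: list[db.DeltaBindingResult] = []
    verdicts: list[db.MotifConsistency] = []
    implicated: list[tuple[str, var.SnpRecord]] = []  # (cell_type, snp)
    for ct in atac.cell_types:
        ct_sccres = db.define_sccres(
            atac, celltype_peak_calls, ct, region_map, snps_by_region
        )
        sccres[ct] = ct_sccres
        snp_sccres = [s for s in ct_sccres if s.snps]
        for mid in motif_sets[ct].motifs:
            model = model_by_id[mid]
            per_motif: list[db.DeltaBindingResult] = []
            for sc in snp_sccres:
                build = var.build_allele_pair(sc.region, genome, list(sc.snps))
                res = db.delta_score(
                    build.pair, model, cell_type=ct,
                    p_threshold=params.scan_p_threshold, sign=params.sign,
                )
                per_motif.append(res)
            if not per_motif:
                continue
            delta_results.extend(per_motif)
            verdict = db.motif_consistency(per_motif)
            verdicts.append(verdict)
            if verdict.verdict != "none":
                changed = {r.region_id for r in per_motif if r.call != "unchanged"}
                for sc in snp_sccres:
                    if sc.region.region_id in changed:
                        implicated.extend((ct, s) for s in sc.snps)

    # --- expression link --------------------------------------------------
    de_results: list[el.DEResult] = []
    pb_cache: dict[str, pd.DataFrame] = {}
    seen: set[tuple[str, str, str]] = set()
    for ct, snp in implicated:
        if snp.rsid not in genotypes.index:
            continue
        links = el.map_snps_to_genes([snp], list(genes), window_bp=params.window_bp)
        carriers, noncarriers, _ = el.carrier_split(genotypes, snp.rsid)
        if ct not in pb_cache:
            pb_cache[ct] = el.pseudobulk(rna, ct)
        pb = pb_cache[ct]
        for link in links:
            key = (ct, link.gene_id, snp.rsid)
            if key in seen:
                continue
            seen.add(key)
            if not el.filter_testable(pb, link.gene_id):
                continue
            de_results.append(
                el.de_test_gene(
                    pb, link.gene_id, carriers, noncarriers, covariates,
                    cell_type=ct, rsid=snp.rsid,
                )
            )
    de_results = el.apply_fdr(de_results)

    return PipelineResult(
        models=model_by_id,
        markers=markers,
        annotations=annotations,
        enrichments=enrichments,
        deviations=deviations,
        motif_sets=motif_sets,
        snps=snps,
        sccres=sccres,
        delta_results=delta_results,
        verdicts=verdicts,
        de_results=de_results,
    )


def load_inputs(bundle_dir) -> dict:
    """Read a file bundle (as written by synthetic_data.write_bundle) into
    the keyword arguments of :func:`run_pipeline`."""
    from pathlib import Path

    from . import io_formats as io
    from .expression_link import read_genes

    d = Path(bundle_dir)
    genome = io.read_fasta(d / "genome.fa")
    regions = io.read_bed(d / "peaks.bed")
    raw_motifs = io.read_motifs(d / "motifs.jaspar", format="jaspar")
    gwas = io.read_gwas(d / "gwas.tsv")
    genotypes = io.read_genotypes(d / "genotypes.tsv")
    atac = io.read_matrix(d / "atac.mtx", d / "atac_cells.txt",
                          d / "atac_features.txt", d / "atac_annot.tsv")
    rna = io.read_matrix(d / "rna.mtx", d / "rna_cells.txt",
                         d / "rna_features.txt", d / "rna_annot.tsv")
    covariates = pd.read_csv(d / "covariates.tsv", sep="\t", index_col=0)
    genes = read_genes(d / "genes.tsv")
    calls_df = pd.read_csv(d / "peak_calls.tsv", sep="\t")
    calls: dict[str, set[str]] = {}
    for row in calls_df.itertuples(index=False):
        calls.setdefault(row.cell_type, set()).add(row.region_id)
    return dict(
        genome=genome, regions=regions, raw_motifs=raw_motifs,
        gwas_records=gwas.records, atac=atac, rna=rna, genotypes=genotypes,
        covariates=covariates, genes=genes, celltype_peak_calls=calls,
    )


def run_pipeline_on_bundle(bundle, params: PipelineParams | None = None) -> PipelineResult:
    """Convenience entry point for a synthetic bundle."""
    from .expression_link import GeneModel

    gwas_records = []
    from .io_formats import FormatError  # noqa: F401

    # the bundle's GWAS table is in external (1-based) convention; reuse the
    # same row-level validation as the file reader by going through records
    for row in bundle.gwas.itertuples(index=False):
        a_o, a_e = str(row.allele_other), str(row.allele_effect)
        if len(a_o) != 1 or len(a_e) != 1 or a_o == a_e or not set(a_o + a_e) <= set("ACGT"):
            continue
        gwas_records.append(
            var.SnpRecord(
                rsid=str(row.rsid), contig=str(row.chrom), pos0=int(row.pos) - 1,
                allele_nonrisk=a_o, allele_risk=a_e,
                beta=float(row.beta), pvalue=float(row.pvalue),
            )
        )
    genes = [
        GeneModel(
            gene_id=str(r.gene_id), symbol=str(r.symbol), contig=str(r.contig),
            tss_pos0=int(r.tss) - 1, strand=str(r.strand),
        )
        for r in bundle.genes.itertuples(index=False)
    ]
    return run_pipeline(
        genome=bundle.genome,
        regions=bundle.regions,
        raw_motifs=bundle.motifs,
        gwas_records=gwas_records,
        atac=bundle.atac,
        rna=bundle.rna,
        genotypes=bundle.genotypes,
        covariates=bundle.covariates,
        genes=genes,
        celltype_peak_calls=bundle.celltype_peak_calls,
        params=params,
    )
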