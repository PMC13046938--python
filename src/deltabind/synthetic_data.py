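"""Seeded generator for a complete synthetic input bundle with ground truth.

The simulator emulates the statistical structure of a single-nucleus
multi-omic risk-variant study: a toy genome of peak regions, cell
type-specific marker peaks, motif occurrences planted in accessible
chromatin, genome-wide-significant SNPs that strengthen or weaken motif
matches, Hardy-Weinberg donor genotypes, and dosage-dependent target-gene
expression with a realistic donor covariate table. Every artifact is drawn
from its own child stream of the master seed, so adding an output never
perturbs the others, and the same seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import io_formats as io
from .io_formats import CountMatrix, GenomeSource, RawMotif, Region
from .motif_engine import encode

BASES = "ACGT"

# worst-scoring alternative per consensus base in the toy PFMs (any
# non-consensus base scores equally at the high-information positions;
# a fixed choice keeps the bundle deterministic)
_ALT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# toy motif layout: width 12, high-information positions (counts 97/1/1/1)
# at indices 1,4,7,10, medium-information (40/20/20/20) elsewhere. The SNP
# position used for planted effects is index 7. A single high-information
# mismatch then costs more log-odds than all eight medium positions
# together, so the motif-hit p-value rises by about 4.6 orders of magnitude
# (log10 of the 4^8 medium-mismatch windows that outrank the broken site),
# comfortably past what the |delta| > 3 rule needs to detect.
HIGH_POSITIONS = (1, 4, 7, 10)
SNP_SITE_OFFSET = 7
TOY_CONSENSI = {
    "M01": ("EGR4", "GCGTGGGCGTGG"),
    "M02": ("NFIB", "TTGGCAAGTCCA"),
    "M03": ("SOX2", "AACAATGGCAGA"),
    "M04": ("SPI1", "AGAGGAAGTGAC"),
    "M05": ("CREB1", "TGACGTCATCGT"),
    "M06": ("MEF2D", "CTAAAAATAGCC"),
    "M07": ("RORB", "AAAGTAGGTCAT"),
    "M08": ("FOSL2::JUN", "TGAGTCACCGTA"),
}


def toy_motif_counts(consensus: str) -> np.ndarray:
    counts = np.full((4, len(consensus)), 20.0)
    for j, base in enumerate(consensus):
        b = BASES.index(base)
        if j in HIGH_POSITIONS:
            counts[:, j] = 1.0
            counts[b, j] = 97.0
        else:
            counts[:, j] = 20.0
            counts[b, j] = 40.0
    return counts


def packaged_toy_motifs() -> list[RawMotif]:
    """The toy motif set shipped with the package (JASPAR pfm text)."""
    path = importlib.resources.files("deltabind") / "data" / "toy_motifs.jaspar"
    return io.read_motifs(str(path), format="jaspar")


@dataclass
class PlantedEffect:
    motif_id: str
    direction: str  # gained | lost
    n_sccres: int
    cell_type: str


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults: 3 cell types x 30 donors x 30 cells each, 500 peaks of 200 bp,
    50 marker peaks per type at 8-fold accessibility, 40 genome-wide
    significant SNPs of which the planted effects put 16 inside motif sites
    (8 scCREs with lost binding for one motif, 8 gained for another), and
    dosage-dependent target-gene expression at log2 fold change 1 with NB
    dispersion 0.2. Covariates are drawn to match the cohort moments of a
    postmortem brain study (age 55.31 +/- 13.12 y, PMI 32.77 +/- 14.07 h,
    pH 6.60 +/- 0.22, RIN 7.24 +/- 1.17, 34% female).
    """

    seed: int = 0
    n_cell_types: int = 3
    n_donors: int = 30
    cells_per_donor_per_type: int = 30
    n_peaks: int = 500
    peak_length_bp: int = 200
    peak_spacing_bp: int = 2000
    n_marker_peaks_per_type: int = 50
    marker_fold_change: float = 8.0
    baseline_peak_mean: float = 0.3
    effect_peak_fold: float = 3.0
    n_snps: int = 40
    frac_snps_in_motifs: float = 0.4
    n_decoy_snps: int = 20
    maf: float = 0.3
    geno_na_rate: float = 0.02
    expression_effect_log2fc: float = 1.0
    nb_dispersion: float = 0.2
    target_gene_cell_mean: float = 1.0
    filler_gene_cell_mean: float = 0.5
    n_filler_genes: int = 30
    tf_expressed_mean: float = 0.7
    tf_silent_mean: float = 0.02
    markers_with_motif: int = 30
    promoter_offset_max: int = 5000
    planted_effects: list[PlantedEffect] = field(default_factory=lambda: [
        PlantedEffect("M01", "lost", 8, "Exc"),
        PlantedEffect("M05", "gained", 8, "Exc"),
    ])
    # per cell type: motifs planted in marker peaks, and whether the TF
    # gene(s) are expressed above the 5% fraction in that type
    active_motifs: dict = field(default_factory=lambda: {
        "Exc": {"M01": True, "M05": True, "M08": True},
        "Astro": {"M02": True, "M06": True},
        "Micro": {"M04": False},
    })

    def cell_type_names(self) -> list[str]:
        base = ["Exc", "Astro", "Micro", "Oligo", "OPC", "Endo"]
        if self.n_cell_types > len(base):
            base = base + [f"CT{i}" for i in range(len(base), self.n_cell_types)]
        return base[: self.n_cell_types]

    def validate(self) -> None:
        if self.n_marker_peaks_per_type * self.n_cell_types > self.n_peaks:
            raise ValueError("more marker peaks requested than peaks available")
        if not (0.0 <= self.frac_snps_in_motifs <= 1.0):
            raise ValueError("frac_snps_in_motifs must be in [0, 1]")
        if self.markers_with_motif > self.n_marker_peaks_per_type:
            raise ValueError("markers_with_motif exceeds markers per type")
        n_planted = sum(e.n_sccres for e in self.planted_effects)
        if self.frac_snps_in_motifs > 0 and n_planted > self.n_snps:
            raise ValueError("planted SNPs exceed n_snps")
        for e in self.planted_effects:
            if e.direction not in ("gained", "lost"):
                raise ValueError(f"bad direction {e.direction!r}")
            if e.motif_id not in TOY_CONSENSI:
                raise ValueError(f"unknown motif {e.motif_id!r}")


@dataclass
class GroundTruth:
    """What the simulator planted, for assertion against pipeline output."""

    marker_peak_ids: dict[str, list[str]]  # cell type -> planted marker peaks
    motif_plantings: dict[str, dict[str, list[str]]]  # ct -> motif -> peak ids
    snp_plantings: dict[str, tuple[str, str, str, str]]  # rsid -> (motif, direction, ct, region_id)
    snp_gene_effects: dict[str, tuple[str, float]]  # rsid -> (gene, log2fc)
    selected_motifs: dict[str, list[str]]  # ct -> motifs passing all 3 filters
    neutral_snps: list[str]
    expected_verdicts: dict[tuple[str, str], str]  # (ct, motif) -> verdict


@dataclass
class SyntheticBundle:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimulationConfig
    genome: GenomeSource
    regions: list[Region]
    motifs: list[RawMotif]
    gwas: pd.DataFrame  # raw summary-statistics table (1-based positions)
    genotypes: pd.DataFrame  # rsid x donor dosages
    atac: CountMatrix
    rna: CountMatrix
    covariates: pd.DataFrame  # donor-indexed
    genes: pd.DataFrame  # gene_id, symbol, contig, tss (1-based), strand
    celltype_peak_calls: dict[str, set[str]]
    truth: GroundTruth

    @property
    def region_map(self) -> dict[str, Region]:
        return {r.region_id: r for r in self.regions}


def _rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle for the given study conditions."""
    config.validate()
    rngs = _rngs(
        config.seed,
        ["genome", "assign", "gwas", "geno", "atac", "rna", "covar", "genes"],
    )
    cts = config.cell_type_names()
    L, gap = config.peak_length_bp, config.peak_spacing_bp
    n_peaks = config.n_peaks

    # ---- genome & peaks ---------------------------------------------------
    rng = rngs["genome"]
    contig = "chr1"
    genome_len = n_peaks * gap + gap
    seq = rng.choice(list(BASES), size=genome_len)
    peak_starts = np.arange(n_peaks) * gap + (gap - L) // 2
    regions = [
        Region(contig, int(s), int(s) + L, f"peak{i:04d}")
        for i, s in enumerate(peak_starts)
    ]

    # ---- structural assignments ------------------------------------------
    rng = rngs["assign"]
    peak_ids = [r.region_id for r in regions]
    perm = rng.permutation(n_peaks)
    marker_idx = {
        ct: perm[i * config.n_marker_peaks_per_type:(i + 1) * config.n_marker_peaks_per_type]
        for i, ct in enumerate(cts)
    }
    rest = perm[config.n_marker_peaks_per_type * len(cts):]
    # "common" peaks are called in every cell type's pseudobulk
    common_idx = rest

    motifs = packaged_toy_motifs()
    motif_by_id = {m.motif_id: m for m in motifs}

    # plant motif occurrences in marker peaks of active cell types
    used_sites: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_peaks)}

    def _plant(peak_i: int, consensus: str, offset: int | None = None) -> int:
        w = len(consensus)
        start = regions[peak_i].start
        if offset is None:
            for _ in range(100):
                off = int(rng.integers(0, L - w + 1))
                if all(off + w <= a or off >= b for a, b in used_sites[peak_i]):
                    break
            else:
                raise RuntimeError("could not place motif site")
            offset = off
        used_sites[peak_i].append((offset, offset + w))
        seq[start + offset: start + offset + w] = list(consensus)
        return offset

    motif_plantings: dict[str, dict[str, list[str]]] = {ct: {} for ct in cts}
    for ct in cts:
        for mid in config.active_motifs.get(ct, {}):
            consensus = TOY_CONSENSI[mid][1]
            chosen = rng.choice(marker_idx[ct], size=min(config.markers_with_motif,
                                                         len(marker_idx[ct])), replace=False)
            for pi in chosen:
                _plant(int(pi), consensus)
            motif_plantings[ct][mid] = sorted(peak_ids[int(pi)] for pi in chosen)

    # ---- planted SNP effects inside motif sites ---------------------------
    effects_on = config.frac_snps_in_motifs > 0
    snp_rows = []  # (rsid, pos0, allele_other, allele_effect, beta, pvalue)
    snp_plantings: dict[str, tuple[str, str, str, str]] = {}
    effect_peak_boost: dict[int, str] = {}  # peak index -> cell type (co-elevated)
    rng_gwas = rngs["gwas"]
    common_pool = list(common_idx)
    rng_gwas.shuffle(common_pool)
    pool_pos = 0
    snp_counter = 0

    def _beta_pvalue() -> tuple[float, float]:
        beta = abs(rng_gwas.normal(0.05, 0.02))
        pval = 10 ** rng_gwas.uniform(-12, -9)
        return float(beta), float(pval)

    if effects_on:
        for eff in config.planted_effects:
            consensus = TOY_CONSENSI[eff.motif_id][1]
            cons_base = consensus[SNP_SITE_OFFSET]
            broken_base = _ALT[cons_base]
            for _ in range(eff.n_sccres):
                pi = common_pool[pool_pos]
                pool_pos += 1
                # gained: the genome carries the broken site, the risk allele
                # restores the consensus; lost: genome carries the intact
                # site, the risk allele breaks it
                planted = (
                    consensus if eff.direction == "lost"
                    else consensus[:SNP_SITE_OFFSET] + broken_base + consensus[SNP_SITE_OFFSET + 1:]
                )
                off = _plant(int(pi), planted)
                pos0 = regions[int(pi)].start + off + SNP_SITE_OFFSET
                if eff.direction == "lost":
                    nonrisk, risk = cons_base, broken_base
                else:
                    nonrisk, risk = broken_base, cons_base
                rsid = f"rs{snp_counter:05d}"
                snp_counter += 1
                beta, pval = _beta_pvalue()
                # a configurable fraction arrives sign-flipped (effect allele
                # protective) so the recoding step is exercised
                if rng_gwas.random() < 0.3:
                    snp_rows.append((rsid, pos0, risk, nonrisk, -beta, pval))
                else:
                    snp_rows.append((rsid, pos0, nonrisk, risk, beta, pval))
                snp_plantings[rsid] = (
                    eff.motif_id, eff.direction, eff.cell_type, peak_ids[int(pi)]
                )
                effect_peak_boost[int(pi)] = eff.cell_type

    # neutral genome-wide-significant SNPs: verified not to strengthen or
    # weaken any toy motif match (rejection-sampled so the ground truth
    # "no binding effect" is actually true of the emitted sequences)
    from .motif_engine import build_motif_models
    from .delta_binding import delta_over_snp_windows
    from .variants import AlleleSequencePair

    neutral_models = build_motif_models(motifs, granularity=500)
    max_w = max(m.width for m in neutral_models)

    def _max_local_delta(pos0: int, ref: str, alt: str) -> float:
        lo = max(0, pos0 - max_w)
        ctx = "".join(seq[lo: pos0 + max_w + 1])
        off = pos0 - lo
        alt_ctx = ctx[:off] + alt + ctx[off + 1:]
        pair = AlleleSequencePair("ctx", ctx, alt_ctx, ("x",))
        return max(
            abs(delta_over_snp_windows(pair, m, [off])) for m in neutral_models
        )

    n_neutral = config.n_snps - len(snp_plantings)
    neutral_snps: list[str] = []
    for _ in range(max(0, n_neutral)):
        pi = common_pool[pool_pos]
        pool_pos += 1
        for _ in range(100):
            off = int(rng_gwas.integers(0, L))
            if any(a <= off < b for a, b in used_sites[int(pi)]):
                continue
            pos0 = regions[int(pi)].start + off
            ref = seq[pos0]
            alt = BASES[(BASES.index(ref) + int(rng_gwas.integers(1, 4))) % 4]
            if _max_local_delta(pos0, ref, alt) <= 1.0:
                break
        rsid = f"rs{snp_counter:05d}"
        snp_counter += 1
        beta, pval = _beta_pvalue()
        snp_rows.append((rsid, pos0, ref, alt, beta, pval))
        neutral_snps.append(rsid)

    # decoys above the significance threshold, plus two indel rows that the
    # GWAS reader should skip
    decoy_rows = []
    for _ in range(config.n_decoy_snps):
        pos0 = int(rng_gwas.integers(0, genome_len))
        ref = seq[pos0]
        alt = BASES[(BASES.index(ref) + int(rng_gwas.integers(1, 4))) % 4]
        rsid = f"rs{snp_counter:05d}"
        snp_counter += 1
        beta = float(rng_gwas.normal(0.0, 0.03))
        pval = 10 ** rng_gwas.uniform(-6, -2)
        decoy_rows.append((rsid, pos0, ref, alt, beta, pval))
    indel_rows = [
        (f"rs{snp_counter:05d}", 7, "AT", "A", 0.01, 0.5),
        (f"rs{snp_counter + 1:05d}", 13, "C", "CG", 0.01, 0.5),
    ]

    gwas = pd.DataFrame(
        [
            (rsid, contig, pos0 + 1, a_o, a_e, beta, pval)
            for rsid, pos0, a_o, a_e, beta, pval in snp_rows + decoy_rows
        ]
        + [(r, contig, p, a_o, a_e, b, pv) for r, p, a_o, a_e, b, pv in indel_rows],
        columns=io.GWAS_COLUMNS,
    )

    genome = GenomeSource({contig: "".join(seq)})

    # ---- genotypes --------------------------------------------------------
    rng = rngs["geno"]
    donors = [f"donor{i:02d}" for i in range(config.n_donors)]
    sig_rsids = [row[0] for row in snp_rows]
    dosages = rng.binomial(2, config.maf, size=(len(sig_rsids), len(donors))).astype(float)
    na_mask = rng.random(dosages.shape) < config.geno_na_rate
    dosages[na_mask] = np.nan
    genotypes = pd.DataFrame(dosages, index=sig_rsids, columns=donors)
    genotypes.index.name = "rsid"

    # ---- cells ------------------------------------------------------------
    cells, cell_ct, cell_donor = [], [], []
    for ct in cts:
        for d in donors:
            for k in range(config.cells_per_donor_per_type):
                cells.append(f"{ct}_{d}_c{k:03d}")
                cell_ct.append(ct)
                cell_donor.append(d)
    n_cells = len(cells)

    # ---- ATAC matrix ------------------------------------------------------
    rng = rngs["atac"]
    mean_mat = np.full((n_cells, n_peaks), config.baseline_peak_mean)
    ct_arr = np.asarray(cell_ct)
    for ct in cts:
        rows = ct_arr == ct
        mean_mat[np.ix_(rows, marker_idx[ct])] *= config.marker_fold_change
    for pi, ct in effect_peak_boost.items():
        mean_mat[ct_arr == ct, pi] *= config.effect_peak_fold
    atac_counts = rng.poisson(mean_mat)
    atac = CountMatrix(
        sparse.csr_matrix(atac_counts), cells, peak_ids, list(cell_ct), list(cell_donor)
    )

    celltype_peak_calls = {
        ct: {peak_ids[int(i)] for i in marker_idx[ct]}
        | {peak_ids[int(i)] for i in common_idx}
        for ct in cts
    }

    # ---- genes & RNA matrix ----------------------------------------------
    rng_g = rngs["genes"]
    tf_symbols: list[str] = []
    for mid, (tf, _) in TOY_CONSENSI.items():
        for g in tf.split("::"):
            if g not in tf_symbols:
                tf_symbols.append(g)
    target_genes: dict[str, str] = {}  # rsid -> gene symbol
    gene_rows = []
    for sym in tf_symbols:
        tss = int(rng_g.integers(0, genome_len))
        gene_rows.append((sym, sym, contig, tss + 1, "+"))
    if effects_on:
        for rsid in snp_plantings:
            sym = f"TGT_{rsid}"
            pos0 = int(gwas.loc[gwas.rsid == rsid, "pos"].iloc[0]) - 1
            offset = int(rng_g.integers(200, config.promoter_offset_max))
            tss = pos0 + offset if rng_g.random() < 0.5 else max(0, pos0 - offset)
            gene_rows.append((sym, sym, contig, tss + 1, "+"))
            target_genes[rsid] = sym
    filler_syms = [f"FIL{i:03d}" for i in range(config.n_filler_genes)]
    for sym in filler_syms:
        tss = int(rng_g.integers(0, genome_len))
        gene_rows.append((sym, sym, contig, tss + 1, "+"))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "symbol", "contig", "tss", "strand"])

    rng = rngs["rna"]
    gene_ids = list(genes.gene_id)
    n_genes = len(gene_ids)
    gmean = np.zeros((n_cells, n_genes))
    gidx = {g: j for j, g in enumerate(gene_ids)}
    # TF genes: expressed above/below the 5% fraction by design, per cell type
    expressed_by_ct: dict[str, set[str]] = {ct: set() for ct in cts}
    for ct in cts:
        for mid, expressed in config.active_motifs.get(ct, {}).items():
            for g in TOY_CONSENSI[mid][0].split("::"):
                expressed_by_ct[ct].add(g) if expressed else None
    for sym in tf_symbols:
        for ct in cts:
            rows = ct_arr == ct
            mean = config.tf_expressed_mean if sym in expressed_by_ct[ct] else config.tf_silent_mean
            gmean[rows, gidx[sym]] = mean
    for sym in filler_syms:
        gmean[:, gidx[sym]] = config.filler_gene_cell_mean
    # target genes: dosage-dependent mean (carriers of the risk allele get
    # the 2^log2fc multiplier), NB noise at the configured dispersion
    donor_arr = np.asarray(cell_donor)
    fold = 2.0 ** config.expression_effect_log2fc
    for rsid, sym in target_genes.items():
        base = config.target_gene_cell_mean
        gmean[:, gidx[sym]] = base
        dos = genotypes.loc[rsid]
        carriers = {d for d in donors if not pd.isna(dos[d]) and dos[d] >= 1}
        if carriers:
            mask = np.isin(donor_arr, sorted(carriers))
            gmean[mask, gidx[sym]] = base * fold
    # NB draws: gamma-poisson mixture
    alpha = config.nb_dispersion
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=gmean * alpha, size=gmean.shape)
    rna_counts = rng.poisson(lam)
    rna = CountMatrix(
        sparse.csr_matrix(rna_counts), cells, gene_ids, list(cell_ct), list(cell_donor)
    )

    # ---- covariates (cohort-matched moments) ------------------------------
    rng = rngs["covar"]
    covariates = pd.DataFrame(
        {
            "donor": donors,
            "diagnosis": ["case" if rng.random() < 0.5 else "control" for _ in donors],
            "sex": ["F" if rng.random() < 0.34 else "M" for _ in donors],
            "age": rng.normal(55.31, 13.12, len(donors)).round(1),
            "pH": rng.normal(6.60, 0.22, len(donors)).round(2),
            "RIN": rng.normal(7.24, 1.17, len(donors)).round(1),
            "PMI": rng.normal(32.77, 14.07, len(donors)).round(1),
        }
    ).set_index("donor")

    # ---- ground truth -----------------------------------------------------
    selected: dict[str, list[str]] = {}
    for ct in cts:
        sel = []
        for mid, expressed in config.active_motifs.get(ct, {}).items():
            if expressed:
                sel.append(mid)
        selected[ct] = sorted(sel)
    expected_verdicts: dict[tuple[str, str], str] = {}
    for ct in cts:
        for mid in selected[ct]:
            expected_verdicts[(ct, mid)] = "none"
    if effects_on:
        for eff in config.planted_effects:
            verdict = "disrupted" if eff.direction == "lost" else "enhanced"
            expected_verdicts[(eff.cell_type, eff.motif_id)] = verdict

    truth = GroundTruth(
        marker_peak_ids={ct: sorted(peak_ids[int(i)] for i in marker_idx[ct]) for ct in cts},
        motif_plantings=motif_plantings,
        snp_plantings=snp_plantings,
        snp_gene_effects={
            rsid: (sym, config.expression_effect_log2fc) for rsid, sym in target_genes.items()
        },
        selected_motifs=selected,
        neutral_snps=neutral_snps,
        expected_verdicts=expected_verdicts,
    )

    return SyntheticBundle(
        config=config,
        genome=genome,
        regions=regions,
        motifs=motifs,
        gwas=gwas,
        genotypes=genotypes,
        atac=atac,
        rna=rna,
        covariates=covariates,
        genes=genes,
        celltype_peak_calls=celltype_peak_calls,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# File bundle


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of the bundle in its external format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "bed": out / "peaks.bed",
        "motifs": out / "motifs.jaspar",
        "gwas": out / "gwas.tsv",
        "genotypes": out / "genotypes.tsv",
        "atac_mtx": out / "atac.mtx",
        "atac_cells": out / "atac_cells.txt",
        "atac_features": out / "atac_features.txt",
        "atac_annot": out / "atac_annot.tsv",
        "rna_mtx": out / "rna.mtx",
        "rna_cells": out / "rna_cells.txt",
        "rna_features": out / "rna_features.txt",
        "rna_annot": out / "rna_annot.tsv",
        "covariates": out / "covariates.tsv",
        "genes": out / "genes.tsv",
        "peak_calls": out / "peak_calls.tsv",
    }
    io.write_fasta(bundle.genome, paths["fasta"])
    io.write_bed(bundle.regions, paths["bed"])
    io.write_motifs_jaspar(bundle.motifs, paths["motifs"])
    bundle.gwas.to_csv(paths["gwas"], sep="\t", index=False)
    io.write_genotypes(bundle.genotypes, paths["genotypes"])
    io.write_matrix(bundle.atac, paths["atac_mtx"], paths["atac_cells"],
                    paths["atac_features"], paths["atac_annot"])
    io.write_matrix(bundle.rna, paths["rna_mtx"], paths["rna_cells"],
                    paths["rna_features"], paths["rna_annot"])
    bundle.covariates.to_csv(paths["covariates"], sep="\t")
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["peak_calls"], "w") as fh:
        fh.write("cell_type\tregion_id\n")
        for ct, ids in sorted(bundle.celltype_peak_calls.items()):
            for rid in sorted(ids):
                fh.write(f"{ct}\t{rid}\n")
    return paths


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Machine-readable truth tables (TSV) for test assertions."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": out / "truth_markers.tsv",
        "plantings": out / "truth_motif_plantings.tsv",
        "snps": out / "truth_snp_plantings.tsv",
        "effects": out / "truth_snp_gene_effects.tsv",
        "selected": out / "truth_selected_motifs.tsv",
    }
    with open(paths["markers"], "w") as fh:
        fh.write("cell_type\tregion_id\n")
        for ct, ids in sorted(truth.marker_peak_ids.items()):
            for rid in ids:
                fh.write(f"{ct}\t{rid}\n")
    with open(paths["plantings"], "w") as fh:
        fh.write("cell_type\tmotif_id\tregion_id\n")
        for ct, d in sorted(truth.motif_plantings.items()):
            for mid, ids in sorted(d.items()):
                for rid in ids:
                    fh.write(f"{ct}\t{mid}\t{rid}\n")
    with open(paths["snps"], "w") as fh:
        fh.write("rsid\tmotif_id\tdirection\tcell_type\tregion_id\n")
        for rsid, (mid, direction, ct, rid) in sorted(truth.snp_plantings.items()):
            fh.write(f"{rsid}\t{mid}\t{direction}\t{ct}\t{rid}\n")
    with open(paths["effects"], "w") as fh:
        fh.write("rsid\tgene_id\tlog2_fc\n")
        for rsid, (gene, fc) in sorted(truth.snp_gene_effects.items()):
            fh.write(f"{rsid}\t{gene}\t{fc:g}\n")
    with open(paths["selected"], "w") as fh:
        fh.write("cell_type\tmotif_id\n")
        for ct, mids in sorted(truth.selected_motifs.items()):
            for mid in mids:
                fh.write(f"{ct}\t{mid}\n")
    return paths


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    out = Path(outdir)
    markers: dict[str, list[str]] = {}
    for row in pd.read_csv(out / "truth_markers.tsv", sep="\t").itertuples(index=False):
        markers.setdefault(row.cell_type, []).append(row.region_id)
    plantings: dict[str, dict[str, list[str]]] = {}
    for row in pd.read_csv(out / "truth_motif_plantings.tsv", sep="\t").itertuples(index=False):
        plantings.setdefault(row.cell_type, {}).setdefault(row.motif_id, []).append(row.region_id)
    snps = {}
    for row in pd.read_csv(out / "truth_snp_plantings.tsv", sep="\t").itertuples(index=False):
        snps[row.rsid] = (row.motif_id, row.direction, row.cell_type, row.region_id)
    effects = {}
    for row in pd.read_csv(out / "truth_snp_gene_effects.tsv", sep="\t").itertuples(index=False):
        effects[row.rsid] = (row.gene_id, float(row.log2_fc))
    selected: dict[str, list[str]] = {}
    df = pd.read_csv(out / "truth_selected_motifs.tsv", sep="\t")
    for row in df.itertuples(index=False):
        selected.setdefault(row.cell_type, []).append(row.motif_id)
    return GroundTruth(
        marker_peak_ids=markers,
        motif_plantings=plantings,
        snp_plantings=snps,
        snp_gene_effects=effects,
        selected_motifs=selected,
        neutral_snps=[],
        expected_verdicts={},
    )
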