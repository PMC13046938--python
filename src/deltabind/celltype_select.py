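"""Per-cell-type motif selection: the three-stage filter.

A motif is carried into the differential-binding analysis for a cell type
only if (1) it is enriched in that cell type's marker peaks
(hypergeometric, p < 1e-10), (2) its peaks are highly accessible by a
bias-matched accessibility-deviation statistic, and (3) the gene(s)
encoding the TF are expressed in at least 5% of the cell type's cells
(all component genes for dimer/trimer motifs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse, stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, GenomeSource, Region

logger = logging.getLogger(__name__)

MARKER_LOG2FC_MIN = 1.0
MARKER_FDR_MAX = 0.05
ENRICH_P_MAX = 1e-10  # strict '<'
EXPRESSION_FRACTION_MIN = 0.05  # inclusive
DEVIATION_Z_MIN = 1.0


@dataclass(frozen=True)
class MarkerPeakResult:
    cell_type: str
    region_id: str
    log2_fc: float
    pvalue: float
    fdr: float

    @property
    def is_marker(self) -> bool:
        return self.log2_fc >= MARKER_LOG2FC_MIN and self.fdr <= MARKER_FDR_MAX


@dataclass(frozen=True)
class MotifEnrichment:
    cell_type: str
    motif_id: str
    n_universe: int
    n_marker: int
    n_motif_universe: int
    n_motif_marker: int
    pvalue_hypergeom: float

    @property
    def is_enriched(self) -> bool:
        return self.pvalue_hypergeom < ENRICH_P_MAX


@dataclass(frozen=True)
class DeviationResult:
    cell_type: str
    motif_id: str
    deviation_z: float


@dataclass
class CellTypeMotifSet:
    """Motifs surviving all three filters in one cell type, with provenance."""

    cell_type: str
    motifs: list[str]
    provenance: dict[str, dict]  # motif_id -> {enrich_p, deviation_z, expr_fractions}


# ---------------------------------------------------------------------------
# Stage 1: marker peaks


def call_marker_peaks(atac: CountMatrix, cell_type: str) -> list[MarkerPeakResult]:
    """Peaks uniquely accessible in one cell type, tested on donor pseudobulks.

    Per donor, counts are summed separately over that donor's cells of the
    target type ("in") and all its other cells ("out"), CPM-normalized per
    pseudobulk sample, and compared peak-wise with a two-sided Wilcoxon
    rank-sum test across donors. log2 fold change uses a 1-CPM pseudocount.
    FDR is Benjamini-Hochberg across peaks.
    """
    type_mask = np.asarray([c == cell_type for c in atac.cell_type_labels])
    if not type_mask.any():
        raise KeyError(f"cell type {cell_type!r} absent")
    donors = np.asarray(atac.donor_labels)
    counts = atac.values

    in_rows, out_rows = [], []
    for d in atac.donors:
        d_mask = donors == d
        if (d_mask & type_mask).any():
            in_rows.append(np.asarray(counts[d_mask & type_mask].sum(axis=0)).ravel())
        if (d_mask & ~type_mask).any():
            out_rows.append(np.asarray(counts[d_mask & ~type_mask].sum(axis=0)).ravel())
    if len(in_rows) < 2 or len(out_rows) < 2:
        raise ValueError(
            f"need >= 2 donors with cells both in and out of {cell_type!r}"
        )

    def _cpm(rows: list[np.ndarray]) -> np.ndarray:
        mat = np.vstack(rows).astype(float)
        totals = mat.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return mat / totals * 1e6

    cpm_in, cpm_out = _cpm(in_rows), _cpm(out_rows)
    log2_fc = np.log2((cpm_in.mean(axis=0) + 1.0) / (cpm_out.mean(axis=0) + 1.0))
    stat, pvals = stats.ranksums(cpm_in, cpm_out, axis=0)
    pvals = np.nan_to_num(pvals, nan=1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        MarkerPeakResult(cell_type, rid, float(fc), float(p), float(q))
        for rid, fc, p, q in zip(atac.feature_ids, log2_fc, pvals, fdr)
    ]


def marker_region_ids(results: Sequence[MarkerPeakResult]) -> set[str]:
    return {r.region_id for r in results if r.is_marker}


# ---------------------------------------------------------------------------
# Stage 2a: hypergeometric enrichment


def upper_tail_hypergeom(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population M, successes K, draws n)."""
    return float(min(stats.hypergeom.sf(k - 1, M, K, n), 1.0))


def enrich_motifs(
    annotations: Mapping[str, set[str]],
    marker_ids: set[str],
    cell_type: str = "",
) -> list[MotifEnrichment]:
    """Upper-tail hypergeometric enrichment of motif presence in marker peaks.

    ``annotations`` maps region_id -> set of motif_ids present in that peak;
    its keys define the peak universe. P(X >= n_motif_marker) with
    population = universe size, successes = motif-bearing peaks, draws =
    marker peaks.
    """
    universe = list(annotations)
    n_universe = len(universe)
    markers = marker_ids & set(universe)
    n_marker = len(markers)
    if n_marker == 0:
        raise ValueError("no marker peaks in the annotated universe")
    motif_ids = sorted({m for mots in annotations.values() for m in mots})
    results = []
    for mid in motif_ids:
        with_motif = {rid for rid, mots in annotations.items() if mid in mots}
        k = len(with_motif & markers)
        K = len(with_motif)
        p = float(stats.hypergeom.sf(k - 1, n_universe, K, n_marker))
        results.append(
            MotifEnrichment(
                cell_type=cell_type,
                motif_id=mid,
                n_universe=n_universe,
                n_marker=n_marker,
                n_motif_universe=K,
                n_motif_marker=k,
                pvalue_hypergeom=min(p, 1.0),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Stage 2b: bias-matched accessibility deviation


def peak_gc_content(genome: GenomeSource, regions: Sequence[Region]) -> dict[str, float]:
    """GC fraction per region (N bases excluded from the denominator)."""
    out = {}
    for r in regions:
        seq = genome.fetch(r.contig, r.start, r.end)
        acgt = sum(seq.count(b) for b in "ACGT")
        gc = seq.count("G") + seq.count("C")
        out[r.region_id] = gc / acgt if acgt else 0.0
    return out


def _raw_deviations(
    counts: sparse.csr_matrix, membership: sparse.csr_matrix
) -> np.ndarray:
    """(obs - exp) / exp per cell for each peak set (rows of ``membership``).

    exp = cell total x the peak set's global accessibility fraction.
    Returns sets x cells.
    """
    cell_totals = np.asarray(counts.sum(axis=1)).ravel()  # n_cells
    peak_totals = np.asarray(counts.sum(axis=0)).ravel()  # n_peaks
    grand = cell_totals.sum()
    set_frac = membership @ peak_totals / grand  # n_sets
    obs = np.asarray((counts @ membership.T).todense()).T  # n_sets x n_cells
    exp = set_frac[:, None] * cell_totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(exp > 0, (obs - exp) / np.where(exp > 0, exp, 1.0), 0.0)
    return raw


def motif_deviation(
    atac: CountMatrix,
    annotations: Mapping[str, set[str]],
    peak_gc: Mapping[str, float],
    cell_type: str,
    n_background: int = 50,
    seed: int = 0,
    n_neighbors: int = 50,
) -> list[DeviationResult]:
    """Bias-corrected accessibility deviation of each motif's peak set.

    For each cell, the raw deviation of a peak set is the relative excess of
    observed counts in the set over the expectation under the cell's
    sequencing depth and the set's global accessibility share. The deviation
    is standardized against ``n_background`` random peak sets matched to the
    motif's peaks by GC content and mean accessibility (nearest neighbours
    in that standardized 2-D space), then averaged over the cell type's
    cells. Fully seeded.
    """
    if n_background < 10:
        raise ValueError("insufficient background sets (require >= 10)")
    rng = np.random.default_rng(seed)
    cells = atac.cells_of_type(cell_type)
    counts = atac.values
    n_peaks = len(atac.feature_ids)
    peak_pos = {rid: i for i, rid in enumerate(atac.feature_ids)}

    gc = np.asarray([peak_gc.get(rid, 0.0) for rid in atac.feature_ids])
    mean_acc = np.asarray(counts.mean(axis=0)).ravel()

    def _standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    space = np.column_stack([_standardize(gc), _standardize(mean_acc)])
    tree = cKDTree(space)
    k = min(n_neighbors, n_peaks)
    _, neighbor_idx = tree.query(space, k=k)  # n_peaks x k
    if k == 1:
        neighbor_idx = neighbor_idx[:, None]

    motif_ids = sorted(annotations)
    results = []
    for mid in motif_ids:
        idx = np.asarray(sorted(peak_pos[r] for r in annotations[mid] if r in peak_pos))
        if idx.size == 0:
            raise ValueError(f"motif {mid} annotated in 0 peaks of the matrix")
        m = idx.size
        # observed set + n_background GC/accessibility-matched random sets
        rows, cols = [0] * m, list(idx)
        for b in range(1, n_background + 1):
            choice = neighbor_idx[idx, rng.integers(0, k, size=m)]
            rows.extend([b] * m)
            cols.extend(choice.tolist())
        memb = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_background + 1, n_peaks)
        )
        memb.data = np.ones_like(memb.data)  # collapse duplicate picks
        raw = _raw_deviations(counts, memb)  # (1+nb) x n_cells
        bg_mean = raw[1:].mean(axis=0)
        bg_sd = raw[1:].std(axis=0)
        bg_sd[bg_sd == 0] = 1.0
        z = (raw[0] - bg_mean) / bg_sd
        results.append(
            DeviationResult(cell_type=cell_type, motif_id=mid, deviation_z=float(z[cells].mean()))
        )
    return results


# ---------------------------------------------------------------------------
# Stage 3: TF gene expression


def expression_filter(
    rna: CountMatrix, cell_type: str, tf_name: str
) -> tuple[bool, dict[str, float]]:
    """Require every component gene of the TF expressed in >= 5% of the cells.

    ``tf_name`` is split on ``::`` into component gene symbols
    (heterodimers/-trimers need all components). Expression = nonzero raw
    count. Genes absent from the matrix count as 0% expressed (logged).
    """
    cells = rna.cells_of_type(cell_type)
    sub = rna.values[cells]
    fractions: dict[str, float] = {}
    for gene in tf_name.split("::"):
        j = rna.feature_index(gene)
        if j is None:
            logger.warning("gene %s absent from expression matrix; treated as 0%%", gene)
            fractions[gene] = 0.0
            continue
        nonzero = (sub[:, j] > 0).sum()
        fractions[gene] = float(nonzero) / len(cells)
    ok = all(f >= EXPRESSION_FRACTION_MIN for f in fractions.values())
    return ok, fractions


# ---------------------------------------------------------------------------
# Intersection


def select_motifs(
    cell_type: str,
    enrichments: Sequence[MotifEnrichment],
    deviations: Sequence[DeviationResult],
    expression: Mapping[str, tuple[bool, dict[str, float]]],
    z_min: float = DEVIATION_Z_MIN,
) -> CellTypeMotifSet:
    """Intersect the three filters; record provenance per surviving motif.

    ``expression`` maps motif_id -> (pass, per-gene fractions).
    """
    enriched = {e.motif_id: e for e in enrichments if e.is_enriched}
    dev = {d.motif_id: d for d in deviations}
    selected = []
    provenance = {}
    for mid in sorted(enriched):
        d = dev.get(mid)
        if d is None or d.deviation_z < z_min:
            continue
        expr = expression.get(mid)
        if expr is None or not expr[0]:
            continue
        selected.append(mid)
        provenance[mid] = {
            "enrich_p": enriched[mid].pvalue_hypergeom,
            "deviation_z": d.deviation_z,
            "expr_fractions": expr[1],
        }
    return CellTypeMotifSet(cell_type=cell_type, motifs=selected, provenance=provenance)
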