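"""The analysis core: allele-specific binding scores within scCREs.

For each (cell type, motif, SNP-containing scCRE), both allele sequences
are scanned with the same permissive p-value threshold (0.99, so that
essentially all windows count) and summarized as a binding score — the sum
of -log10 motif-hit p-values. The differential binding score
delta = score(risk) - score(non-risk) classifies the element as
gained (> 3), lost (< -3) or unchanged; a motif whose gained and lost
scCRE counts differ by at least 5 within a cell type is called
consistently enhanced or disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import CountMatrix, Region
from .motif_engine import MotifHit, MotifModel, scan_region
from .variants import AlleleSequencePair, SnpRecord

SCAN_P_THRESHOLD = 0.99
DELTA_CUTOFF = 3.0  # strict: |delta| > 3
CONSISTENCY_MIN_DIFF = 5  # inclusive: |gained - lost| >= 5
SCCRE_ACCESSIBLE_FRACTION = 0.05  # inclusive


@dataclass(frozen=True)
class ScCRE:
    """A candidate cis-regulatory element of one cell type.

    Included because it was called as a peak in the cell type's pseudobulk
    ("called-in-celltype"), is accessible in >= 5% of the type's cells
    ("accessible-fraction"), or both.
    """

    cell_type: str
    region: Region
    source: str  # called-in-celltype | accessible-fraction | both
    snps: tuple[SnpRecord, ...] = ()


@dataclass(frozen=True)
class DeltaBindingResult:
    cell_type: str
    motif_id: str
    region_id: str
    score_nonrisk: float
    score_risk: float
    delta: float
    call: str  # gained | lost | unchanged


@dataclass(frozen=True)
class MotifConsistency:
    cell_type: str
    motif_id: str
    n_gained: int
    n_lost: int
    verdict: str  # enhanced | disrupted | none


def define_sccres(
    atac: CountMatrix,
    celltype_peak_calls: Mapping[str, set[str]],
    cell_type: str,
    regions: Mapping[str, Region],
    snps_by_region: Mapping[str, Sequence[SnpRecord]] | None = None,
) -> list[ScCRE]:
    """scCREs of a cell type: union of the pseudobulk-call and 5%-accessibility criteria.

    ``regions`` maps region_id -> Region over the merged peak set (the ATAC
    feature space); accessibility is nonzero count per cell.
    """
    cells = atac.cells_of_type(cell_type)
    sub = atac.values[cells]
    frac_accessible = np.asarray((sub > 0).sum(axis=0)).ravel() / len(cells)
    called = celltype_peak_calls.get(cell_type, set())
    snps_by_region = snps_by_region or {}
    out: list[ScCRE] = []
    for j, rid in enumerate(atac.feature_ids):
        is_called = rid in called
        is_accessible = frac_accessible[j] >= SCCRE_ACCESSIBLE_FRACTION
        if not (is_called or is_accessible):
            continue
        source = (
            "both" if (is_called and is_accessible)
            else "called-in-celltype" if is_called
            else "accessible-fraction"
        )
        out.append(
            ScCRE(
                cell_type=cell_type,
                region=regions[rid],
                source=source,
                snps=tuple(snps_by_region.get(rid, ())),
            )
        )
    return out


def peak_binding_score(hits: Iterable[MotifHit]) -> float:
    """Sum of -log10(p) over all motif hits of one motif on one sequence.

    Both strands, all offsets; an element without hits scores 0.
    """
    score = 0.0
    for h in hits:
        if h.pvalue <= 0:
            raise ValueError(f"non-positive p-value {h.pvalue} in hit at offset {h.offset}")
        score += -np.log10(h.pvalue)
    return float(score)


def classify_delta(delta: float, cutoff: float = DELTA_CUTOFF) -> str:
    if delta > cutoff:
        return "gained"
    if delta < -cutoff:
        return "lost"
    return "unchanged"


def delta_score(
    pair: AlleleSequencePair,
    model: MotifModel,
    cell_type: str = "",
    p_threshold: float = SCAN_P_THRESHOLD,
    sign: str = "risk-minus-nonrisk",
) -> DeltaBindingResult:
    """Differential binding score of one motif on one scCRE's allele pair.

    Both sequences are scanned with identical parameters and the motif's one
    shared background/p-value table, so the delta reflects the alleles
    alone. The default sign makes a positive delta mean binding gained
    through the risk allele; ``sign='ref-minus-alt'`` flips it.
    """
    if len(pair.seq_nonrisk) != len(pair.seq_risk):
        raise ValueError(f"{pair.region_id}: allele sequences differ in length")
    if sign not in ("risk-minus-nonrisk", "ref-minus-alt"):
        raise ValueError(f"unknown sign convention {sign!r}")
    score_non = peak_binding_score(scan_region(model, pair.seq_nonrisk, p_threshold))
    score_ris = peak_binding_score(scan_region(model, pair.seq_risk, p_threshold))
    delta = score_ris - score_non
    if sign == "ref-minus-alt":
        delta = -delta
    return DeltaBindingResult(
        cell_type=cell_type,
        motif_id=model.motif_id,
        region_id=pair.region_id,
        score_nonrisk=score_non,
        score_risk=score_ris,
        delta=float(delta),
        call=classify_delta(delta),
    )


def delta_over_snp_windows(
    pair: AlleleSequencePair,
    model: MotifModel,
    snp_offsets: Sequence[int],
    p_threshold: float = SCAN_P_THRESHOLD,
) -> float:
    """Delta computed only over scan windows that overlap a SNP offset.

    Windows not overlapping any substituted position are identical on both
    allele sequences and cancel exactly, so this equals the full-region
    delta — the locality property of the differential binding score.
    """
    w = model.width
    offs = set(snp_offsets)

    def _local_score(seq: str) -> float:
        total = 0.0
        for h in scan_region(model, seq, p_threshold):
            if any(h.offset <= o < h.offset + w for o in offs):
                total += -np.log10(h.pvalue)
        return total

    return _local_score(pair.seq_risk) - _local_score(pair.seq_nonrisk)


def motif_consistency(
    results: Sequence[DeltaBindingResult],
    min_diff: int = CONSISTENCY_MIN_DIFF,
) -> MotifConsistency:
    """Verdict for one (cell type, motif) from its per-scCRE calls.

    enhanced iff n_gained - n_lost >= min_diff; disrupted iff
    n_lost - n_gained >= min_diff; otherwise none.
    """
    if not results:
        raise ValueError("no delta-binding results supplied")
    cell_types = {r.cell_type for r in results}
    motif_ids = {r.motif_id for r in results}
    if len(cell_types) != 1 or len(motif_ids) != 1:
        raise ValueError("results must belong to a single (cell type, motif)")
    n_gained = sum(r.call == "gained" for r in results)
    n_lost = sum(r.call == "lost" for r in results)
    if n_gained - n_lost >= min_diff:
        verdict = "enhanced"
    elif n_lost - n_gained >= min_diff:
        verdict = "disrupted"
    else:
        verdict = "none"
    return MotifConsistency(
        cell_type=cell_types.pop(),
        motif_id=motif_ids.pop(),
        n_gained=n_gained,
        n_lost=n_lost,
        verdict=verdict,
    )


def write_delta_tsv(results: Sequence[DeltaBindingResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cell_type\tmotif_id\tregion_id\tscore_nonrisk\tscore_risk\tdelta\tcall\n"
        )
        for r in results:
            fh.write(
                f"{r.cell_type}\t{r.motif_id}\t{r.region_id}\t"
                f"{r.score_nonrisk:.10g}\t{r.score_risk:.10g}\t{r.delta:.10g}\t{r.call}\n"
            )


def write_consistency_tsv(rows: Sequence[MotifConsistency], path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_type\tmotif_id\tn_gained\tn_lost\tverdict\n")
        for r in rows:
            fh.write(f"{r.cell_type}\t{r.motif_id}\t{r.n_gained}\t{r.n_lost}\t{r.verdict}\n")
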