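"""GWAS variant filtering, risk-allele recoding, and allele-sequence pairs.

Variants are filtered to genome-wide significance, oriented so that the
"risk" allele always carries a non-negative effect size, assigned to the
regulatory regions that contain them, and used to build, per region, the
pair of sequences carrying all risk alleles vs. all non-risk alleles —
a per-region analogue of building two whole-genome references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import math

from .io_formats import GenomeSource, Region

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8

# extended MHC region on GRCh38, used for the sensitivity analysis that
# drops all significant variants inside it
MHC_REGION = ("chr6", 26_000_000, 34_000_000)


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS variant, optionally recoded to risk orientation.

    Before recoding, ``allele_nonrisk``/``allele_risk`` hold the summary
    statistics' other/effect alleles and ``beta`` may be negative. After
    :func:`recode_risk`, ``beta >= 0`` and ``allele_risk`` is the
    risk-increasing allele.
    """

    rsid: str
    contig: str
    pos0: int  # 0-based
    allele_nonrisk: str
    allele_risk: str
    beta: float
    pvalue: float
    recoded: bool = False

    def __post_init__(self) -> None:
        if self.allele_nonrisk == self.allele_risk:
            raise ValueError(f"{self.rsid}: identical alleles")


@dataclass(frozen=True)
class AlleleSequencePair:
    """Per-region sequence pair: all non-risk alleles vs. all risk alleles."""

    region_id: str
    seq_nonrisk: str
    seq_risk: str
    snps_applied: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.seq_nonrisk) != len(self.seq_risk):
            raise ValueError(f"{self.region_id}: allele sequences differ in length")


def filter_genomewide(
    snps: Iterable[SnpRecord], threshold: float = GENOME_WIDE_P
) -> list[SnpRecord]:
    """Keep variants with GWAS p-value <= threshold (inclusive)."""
    return [s for s in snps if s.pvalue <= threshold]


def exclude_mhc(
    snps: Iterable[SnpRecord],
    region: tuple[str, int, int] = MHC_REGION,
) -> list[SnpRecord]:
    """Drop variants inside the extended MHC region (chr6:26-34 Mb by default)."""
    contig, start, end = region
    contig_plain = contig.removeprefix("chr")
    kept = []
    for s in snps:
        if s.contig.removeprefix("chr") == contig_plain and start <= s.pos0 < end:
            continue
        kept.append(s)
    return kept


def recode_risk(snp: SnpRecord) -> SnpRecord:
    """Orient the variant so the risk allele has beta >= 0.

    A negative effect size means the effect allele is protective: the
    alleles are swapped and beta negated. beta == 0 is left in non-risk
    orientation (no information to orient on). Idempotent.
    """
    if math.isnan(snp.beta):
        raise ValueError(f"{snp.rsid}: beta is NA")
    if snp.beta < 0:
        return replace(
            snp,
            allele_nonrisk=snp.allele_risk,
            allele_risk=snp.allele_nonrisk,
            beta=-snp.beta,
            recoded=True,
        )
    if snp.beta == 0:
        logger.info("%s: beta == 0, kept in non-risk orientation", snp.rsid)
    return replace(snp, recoded=False)


def assign_snps_to_regions(
    snps: Iterable[SnpRecord], regions: Sequence[Region]
) -> dict[str, list[SnpRecord]]:
    """Map region_id -> SNPs inside it (half-open; multi-overlap allowed).

    Regions without SNPs are absent from the mapping.
    """
    by_contig: dict[str, list[Region]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append(r)
    mapping: dict[str, list[SnpRecord]] = {}
    for s in snps:
        for r in by_contig.get(s.contig, ()):
            if r.start <= s.pos0 < r.end:
                mapping.setdefault(r.region_id, []).append(s)
    return mapping


@dataclass
class AllelePairBuild:
    pair: AlleleSequencePair
    n_mismatch_dropped: int


def build_allele_pair(
    region: Region,
    genome: GenomeSource,
    snps: Sequence[SnpRecord],
) -> AllelePairBuild:
    """Substitute all of a region's SNP alleles into its genomic sequence.

    All SNPs are applied simultaneously: ``seq_risk`` carries every risk
    allele, ``seq_nonrisk`` every non-risk allele. The genome base is not
    authoritative — if it matches either stated allele the substitution is
    made from the record's alleles; if it matches neither, the SNP is
    dropped with a warning (summary-statistics alleles define the
    comparison, but two mismatching alleles mean a coordinate problem).
    """
    ref_seq = genome.fetch(region.contig, region.start, region.end)
    non = list(ref_seq)
    ris = list(ref_seq)
    applied: list[str] = []
    n_dropped = 0
    for s in snps:
        off = s.pos0 - region.start
        if not (0 <= off < len(ref_seq)):
            raise ValueError(f"{s.rsid} at {s.contig}:{s.pos0} outside region {region.region_id}")
        base = ref_seq[off]
        if base not in (s.allele_nonrisk, s.allele_risk):
            logger.warning(
                "%s: genome base %s matches neither allele (%s/%s); dropped",
                s.rsid, base, s.allele_nonrisk, s.allele_risk,
            )
            n_dropped += 1
            continue
        non[off] = s.allele_nonrisk
        ris[off] = s.allele_risk
        applied.append(s.rsid)
    pair = AlleleSequencePair(
        region_id=region.region_id,
        seq_nonrisk="".join(non),
        seq_risk="".join(ris),
        snps_applied=tuple(applied),
    )
    return AllelePairBuild(pair=pair, n_mismatch_dropped=n_dropped)


def risk_protective_counts(snps: Iterable[SnpRecord]) -> tuple[int, int]:
    """(n risk: beta > 0, n protective: beta < 0) on un-recoded records."""
    n_risk = n_prot = 0
    for s in snps:
        if s.beta > 0:
            n_risk += 1
        elif s.beta < 0:
            n_prot += 1
    return n_risk, n_prot
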