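"""Linking binding-altering SNPs to target-gene expression differences.

SNPs implicated by the delta-binding stage are mapped to candidate target
genes (promoter window and/or chromatin-interaction pairs — a simplified
stand-in for Hi-C-informed gene mapping), donors are split into carriers
and non-carriers of the risk allele, and pseudobulk expression per
(donor, cell type) is tested with a negative-binomial GLM (log link,
library-size offset) with case/control status, sex, age, brain pH, RIN and
PMI as covariates. Benjamini-Hochberg FDR <= 0.1 calls significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, Region
from .variants import SnpRecord

logger = logging.getLogger(__name__)

PROMOTER_WINDOW_BP = 10_000
MIN_GROUP_SIZE = 3
TESTABLE_MIN_COUNT = 10
TESTABLE_MIN_FRACTION = 0.75
DE_FDR_MAX = 0.1
DISPERSION_FLOOR = 0.01
COVARIATE_COLUMNS = ["diagnosis", "sex", "age", "pH", "RIN", "PMI"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    contig: str
    tss_pos0: int
    strand: str


@dataclass(frozen=True)
class SnpGeneLink:
    rsid: str
    gene_id: str
    evidence: str  # promoter-window | interaction-pair


@dataclass
class DEResult:
    cell_type: str
    gene_id: str
    rsid: str
    log2_fc: float
    pvalue: float
    fdr: float
    n_carriers: int
    n_noncarriers: int
    testable: bool = True

    @property
    def significant(self) -> bool:
        return self.testable and self.fdr <= DE_FDR_MAX


def read_genes(path) -> list[GeneModel]:
    """Gene annotation TSV: gene_id, symbol, contig, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                contig=str(row.contig),
                tss_pos0=int(row.tss) - 1,
                strand=str(row.strand),
            )
        )
    return genes


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneModel],
    window_bp: int = PROMOTER_WINDOW_BP,
    interaction_pairs: Sequence[tuple[Region, Region]] = (),
) -> list[SnpGeneLink]:
    """Candidate target genes per SNP: promoter window or interaction pair.

    A SNP links to a gene if |pos - TSS| <= window_bp on the same contig, or
    if the SNP lies in one anchor of an interaction pair whose other anchor
    contains the TSS. Links are deduplicated (promoter-window evidence wins
    when both apply).
    """
    links: dict[tuple[str, str], str] = {}
    for s in snps:
        for g in genes:
            if g.contig == s.contig and abs(s.pos0 - g.tss_pos0) <= window_bp:
                links[(s.rsid, g.gene_id)] = "promoter-window"
        for a, b in interaction_pairs:
            for anchor_snp, anchor_tss in ((a, b), (b, a)):
                if (
                    anchor_snp.contig == s.contig
                    and anchor_snp.start <= s.pos0 < anchor_snp.end
                ):
                    for g in genes:
                        if (
                            g.contig == anchor_tss.contig
                            and anchor_tss.start <= g.tss_pos0 < anchor_tss.end
                        ):
                            links.setdefault((s.rsid, g.gene_id), "interaction-pair")
    return [SnpGeneLink(rsid=r, gene_id=g, evidence=e) for (r, g), e in sorted(links.items())]


def carrier_split(
    genotypes: pd.DataFrame, rsid: str
) -> tuple[list[str], list[str], int]:
    """Split donors by dosage of the risk allele: carriers (>=1) vs non-carriers (0).

    Returns (carriers, noncarriers, n_excluded_NA).
    """
    if rsid not in genotypes.index:
        raise KeyError(f"rsid {rsid!r} absent from genotype table")
    dosages = genotypes.loc[rsid]
    carriers, noncarriers = [], []
    n_na = 0
    for donor, d in dosages.items():
        if pd.isna(d):
            n_na += 1
        elif d >= 1:
            carriers.append(str(donor))
        else:
            noncarriers.append(str(donor))
    return carriers, noncarriers, n_na


def pseudobulk(rna: CountMatrix, cell_type: str) -> pd.DataFrame:
    """Donor x gene matrix of summed raw counts over the cell type's cells.

    Donors with no cells of the type are omitted.
    """
    cells = rna.cells_of_type(cell_type)
    donors = np.asarray(rna.donor_labels)[cells]
    sub = rna.values[cells]
    rows = {}
    for d in sorted(set(donors)):
        mask = donors == d
        rows[d] = np.asarray(sub[mask].sum(axis=0)).ravel()
    return pd.DataFrame.from_dict(rows, orient="index", columns=rna.feature_ids)


def filter_testable(pb: pd.DataFrame, gene: str) -> bool:
    """Gene testable iff >= 10 counts in >= 75% of pseudobulk samples (inclusive)."""
    if gene not in pb.columns:
        return False
    counts = pb[gene].to_numpy()
    return (counts >= TESTABLE_MIN_COUNT).mean() >= TESTABLE_MIN_FRACTION


def estimate_dispersion(counts: np.ndarray, offset_log: np.ndarray) -> float:
    """Method-of-moments NB dispersion on depth-normalized counts, floored."""
    norm = counts / np.exp(offset_log - offset_log.mean())
    m = norm.mean()
    v = norm.var(ddof=1)
    if m <= 0:
        return DISPERSION_FLOOR
    alpha = (v - m) / (m * m)
    return float(max(alpha, DISPERSION_FLOOR))


def de_test_gene(
    pb: pd.DataFrame,
    gene: str,
    carriers: Sequence[str],
    noncarriers: Sequence[str],
    covariates: pd.DataFrame,
    cell_type: str = "",
    rsid: str = "",
) -> DEResult:
    """NB-GLM Wald test of the carrier effect for one gene.

    Model: counts ~ carrier + diagnosis + sex + age + pH + RIN + PMI with a
    log library-size offset. log2 fold change = carrier coefficient / ln 2.
    Groups below the minimum size are marked untestable rather than raising.
    The per-result ``fdr`` is filled in later across the whole family by
    :func:`apply_fdr`.
    """
    donors = [d for d in pb.index if d in set(carriers) | set(noncarriers)]
    carr = [d for d in donors if d in set(carriers)]
    nonc = [d for d in donors if d in set(noncarriers)]
    if len(carr) < MIN_GROUP_SIZE or len(nonc) < MIN_GROUP_SIZE:
        return DEResult(cell_type, gene, rsid, np.nan, np.nan, np.nan,
                        len(carr), len(nonc), testable=False)
    sub = pb.loc[donors]
    y = sub[gene].to_numpy(dtype=float)
    libsize = sub.sum(axis=1).to_numpy(dtype=float)
    offset_log = np.log(libsize)

    cov = covariates.loc[donors, COVARIATE_COLUMNS].copy()
    for col in ("diagnosis", "sex"):
        cov[col] = pd.Categorical(cov[col]).codes
    X = sm.add_constant(
        np.column_stack(
            [np.asarray([1.0 if d in set(carr) else 0.0 for d in donors])]
            + [cov[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
        )
    )
    alpha = estimate_dispersion(y, offset_log)
    try:
        model = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset_log
        )
        res = model.fit()
    except Exception as exc:  # singular design, failed convergence
        logger.warning("DE fit failed for %s/%s: %s", gene, rsid, exc)
        return DEResult(cell_type, gene, rsid, np.nan, np.nan, np.nan,
                        len(carr), len(nonc), testable=False)
    coef = res.params[1]
    pval = float(res.pvalues[1])
    if not np.isfinite(pval):
        return DEResult(cell_type, gene, rsid, np.nan, np.nan, np.nan,
                        len(carr), len(nonc), testable=False)
    return DEResult(
        cell_type=cell_type,
        gene_id=gene,
        rsid=rsid,
        log2_fc=float(coef / np.log(2)),
        pvalue=pval,
        fdr=np.nan,
        n_carriers=len(carr),
        n_noncarriers=len(nonc),
    )


def apply_fdr(results: Sequence[DEResult]) -> list[DEResult]:
    """Benjamini-Hochberg across all testable (gene, rsid, cell type) tuples."""
    testable = [r for r in results if r.testable]
    if testable:
        fdrs = multipletests([r.pvalue for r in testable], method="fdr_bh")[1]
        for r, q in zip(testable, fdrs):
            r.fdr = float(q)
    return list(results)


def write_de_tsv(results: Sequence[DEResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cell_type\tgene_id\trsid\tlog2_fc\tpvalue\tfdr\t"
            "n_carriers\tn_noncarriers\ttestable\tsignificant\n"
        )
        for r in results:
            fh.write(
                f"{r.cell_type}\t{r.gene_id}\t{r.rsid}\t{r.log2_fc:.6g}\t"
                f"{r.pvalue:.6g}\t{r.fdr:.6g}\t{r.n_carriers}\t{r.n_noncarriers}\t"
                f"{int(r.testable)}\t{int(r.significant)}\n"
            )
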