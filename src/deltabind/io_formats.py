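"""Readers and writers for the external formats the pipeline touches.

Every reader validates its input and converts to in-memory domain types so
downstream modules never touch files. Coordinate conventions: BED input is
0-based half-open; GWAS and genotype tables use 1-based positions (VCF
convention) and are converted to 0-based exactly once, here, at read time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

_DNA_OK = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeSource:
    """Named DNA sequences (contig -> uppercase ACGTN string)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for contig {name!r}")
            bad = set(seq) - _DNA_OK
            if bad:
                raise FormatError(f"non-ACGTN characters {bad} in contig {name!r}")

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.sequences[contig]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"region {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CountMatrix:
    """Sparse cells x features count matrix with cell-type and donor labels."""

    values: sparse.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    cell_type_labels: list[str]
    donor_labels: list[str]

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        n_cells, n_feat = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.feature_ids) != n_feat:
            raise ValueError("feature_ids length does not match matrix columns")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("feature_ids not unique")
        if len(self.cell_type_labels) != n_cells or len(self.donor_labels) != n_cells:
            raise ValueError("label vectors must match the cell axis")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative count in matrix")

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type_labels))

    @property
    def donors(self) -> list[str]:
        return sorted(set(self.donor_labels))

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        mask = np.asarray([c == cell_type for c in self.cell_type_labels])
        if not mask.any():
            raise KeyError(f"cell type {cell_type!r} absent from matrix")
        return np.flatnonzero(mask)

    def feature_index(self, feature_id: str) -> int | None:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            return None


@dataclass
class RawMotif:
    """A motif as read from file: raw 4 x w count/frequency matrix (rows A,C,G,T)."""

    motif_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(
                f"motif {self.motif_id}: matrix must have 4 rows, got shape {self.counts.shape}"
            )
        if self.counts.shape[1] < 1:
            raise FormatError(f"motif {self.motif_id}: zero-width matrix")
        if (self.counts < 0).any():
            raise FormatError(f"motif {self.motif_id}: negative entries")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSource:
    """Read a FASTA file into a :class:`GenomeSource`.

    Sequences are uppercased; characters outside ACGTN are coerced to N with
    a logged warning. Duplicate contig names are a hard error.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "contig %s: %d non-ACGTN characters coerced to N", name, n_bad
            )
            seq = _NON_ACGTN.sub("N", seq)
        if name in sequences:
            raise FormatError(f"duplicate contig {name}")
        if not seq:
            raise FormatError(f"empty sequence for contig {name!r}")
        sequences[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line.strip())
    _flush()
    if not sequences:
        raise FormatError(f"empty FASTA file: {path}")
    return GenomeSource(sequences)


def write_fasta(genome: GenomeSource, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Region]:
    """Read BED3/BED4 (0-based half-open); region_id from column 4 or synthesized."""
    regions: list[Region] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 columns")
            contig, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"line {lineno}: invalid interval {start}-{end} (need 0 <= start < end)"
                )
            region_id = cols[3] if len(cols) >= 4 and cols[3] else f"{contig}:{start}-{end}"
            if region_id in seen:
                raise FormatError(f"line {lineno}: duplicate region_id {region_id!r}")
            seen.add(region_id)
            regions.append(Region(contig, start, end, region_id))
    return regions


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# Motifs (JASPAR pfm text / MEME minimal)

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[\s*([-\d.eE+\s]*)\s*\]\s*$")


def _parse_jaspar(lines: list[str]) -> list[RawMotif]:
    motifs: list[RawMotif] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"expected JASPAR header line, got {line!r}")
        fields = line[1:].split(None, 1)
        motif_id = fields[0]
        tf_name = fields[1].strip() if len(fields) > 1 else motif_id
        rows: dict[str, list[float]] = {}
        i += 1
        for _ in range(4):
            if i >= len(lines):
                raise FormatError(f"motif {motif_id}: matrix must have 4 rows, found {len(rows)}")
            m = _JASPAR_ROW.match(lines[i].strip())
            if not m:
                raise FormatError(
                    f"motif {motif_id}: matrix must have 4 rows (A/C/G/T); bad row {lines[i]!r}"
                )
            base, nums = m.group(1), m.group(2).split()
            rows[base] = [float(x) for x in nums]
            i += 1
        if set(rows) != set("ACGT"):
            raise FormatError(f"motif {motif_id}: rows must be A, C, G, T")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise FormatError(f"motif {motif_id}: ragged matrix rows")
        counts = np.array([rows[b] for b in "ACGT"])
        motifs.append(RawMotif(motif_id, tf_name, counts))
    return motifs


def _parse_meme(lines: list[str]) -> list[RawMotif]:
    motifs: list[RawMotif] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            fields = line.split()
            if len(fields) < 2:
                raise FormatError("MOTIF line without identifier")
            motif_id = fields[1]
            tf_name = fields[2] if len(fields) > 2 else motif_id
            # advance to the letter-probability header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"motif {motif_id}: missing letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"motif {motif_id}: missing letter-probability matrix")
            header = lines[i].strip()
            m = re.search(r"w\s*=\s*(\d+)", header)
            if not m:
                raise FormatError(f"motif {motif_id}: letter-probability header lacks w=")
            w = int(m.group(1))
            rows = []
            i += 1
            for _ in range(w):
                if i >= len(lines):
                    raise FormatError(f"motif {motif_id}: truncated probability matrix")
                vals = lines[i].split()
                if len(vals) != 4:
                    raise FormatError(
                        f"motif {motif_id}: matrix must have 4 columns per position"
                    )
                rows.append([float(x) for x in vals])
                i += 1
            counts = np.array(rows).T  # MEME rows are positions; ours are bases
            motifs.append(RawMotif(motif_id, tf_name, counts))
        else:
            i += 1
    if not motifs:
        raise FormatError("no MOTIF records found in MEME file")
    return motifs


def read_motifs(path: str | Path, format: str = "jaspar") -> list[RawMotif]:
    """Read motifs from JASPAR pfm text or MEME minimal format.

    TF names containing ``::`` (dimers such as FOSL2::JUN) are kept verbatim.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if format == "jaspar":
        return _parse_jaspar(lines)
    if format == "meme":
        return _parse_meme(lines)
    raise ValueError(f"unknown motif format {format!r} (expected 'jaspar' or 'meme')")


def write_motifs_jaspar(motifs: Sequence[RawMotif], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for b, row in zip("ACGT", m.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics

GWAS_COLUMNS = ["rsid", "chrom", "pos", "allele_other", "allele_effect", "beta", "pvalue"]

_SINGLE_BASE = set("ACGT")


@dataclass
class GwasReadResult:
    records: list  # list[variants.SnpRecord]; kept untyped to avoid circular import
    n_skipped: int


def read_gwas(path: str | Path):
    """Read a GWAS summary-statistics TSV into SnpRecords.

    Positions are 1-based in the file and converted to 0-based here.
    Indel / multi-allelic rows (allele longer than one base or identical
    alleles) are skipped with a counted warning, since allele substitution
    downstream is length-preserving.
    """
    from .variants import SnpRecord  # deferred: variants imports this module's types

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"GWAS table missing columns: {missing}")
    records: list[SnpRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        a_other = str(row.allele_other).upper()
        a_eff = str(row.allele_effect).upper()
        if (
            a_other not in _SINGLE_BASE
            or a_eff not in _SINGLE_BASE
            or a_other == a_eff
        ):
            n_skipped += 1
            continue
        pval = float(row.pvalue)
        if not (0.0 < pval <= 1.0):
            raise FormatError(f"rsid {row.rsid}: pvalue {pval} outside (0, 1]")
        records.append(
            SnpRecord(
                rsid=str(row.rsid),
                contig=str(row.chrom),
                pos0=int(row.pos) - 1,
                allele_nonrisk=a_other,
                allele_risk=a_eff,
                beta=float(row.beta),
                pvalue=pval,
            )
        )
    if n_skipped:
        logger.warning("skipped %d indel/multi-allelic GWAS rows", n_skipped)
    return GwasReadResult(records=records, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Count matrices (MatrixMarket + sidecar TSVs)


def read_matrix(
    mtx_path: str | Path,
    cells_path: str | Path,
    features_path: str | Path,
    annot_path: str | Path,
) -> CountMatrix:
    """Read a cells x features MatrixMarket matrix with sidecar annotations.

    ``cells_path`` and ``features_path`` are one-id-per-line text files;
    ``annot_path`` is a TSV with columns cell_id, cell_type, donor.
    """
    mat = mmread(str(mtx_path))
    data = np.asarray(mat.data)
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError("matrix contains non-integer entries")
    if data.size and data.min() < 0:
        raise FormatError("negative count in matrix")
    mat = sparse.csr_matrix(mat, dtype=np.int64)

    cell_ids = [l.strip() for l in open(cells_path) if l.strip()]
    feature_ids = [l.strip() for l in open(features_path) if l.strip()]
    if mat.shape != (len(cell_ids), len(feature_ids)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(cell_ids)} cells x "
            f"{len(feature_ids)} features"
        )
    annot = pd.read_csv(annot_path, sep="\t", dtype=str)
    for col in ("cell_id", "cell_type", "donor"):
        if col not in annot.columns:
            raise FormatError(f"annotation table missing column {col!r}")
    annot = annot.set_index("cell_id")
    missing = [c for c in cell_ids if c not in annot.index]
    if missing:
        raise FormatError(
            f"{len(missing)} cells missing annotation, first 5: {missing[:5]}"
        )
    cell_types = [annot.at[c, "cell_type"] for c in cell_ids]
    donors = [annot.at[c, "donor"] for c in cell_ids]
    return CountMatrix(mat, cell_ids, feature_ids, cell_types, donors)


def write_matrix(
    matrix: CountMatrix,
    mtx_path: str | Path,
    cells_path: str | Path,
    features_path: str | Path,
    annot_path: str | Path,
) -> None:
    mmwrite(str(mtx_path), sparse.coo_matrix(matrix.values))
    Path(cells_path).write_text("".join(c + "\n" for c in matrix.cell_ids))
    Path(features_path).write_text("".join(f + "\n" for f in matrix.feature_ids))
    pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "cell_type": matrix.cell_type_labels,
            "donor": matrix.donor_labels,
        }
    ).to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype dosages


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a dosage TSV (rows = SNPs indexed by rsid, columns = donors, 0/1/2/NA)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0])
    if not ok.all():
        bad = vals[~ok][0]
        raise FormatError(f"dosage value {bad} not in {{0,1,2,NA}}")
    return df


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "rsid"
    out.to_csv(path, sep="\t", na_rep="NA")
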