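"""Log-odds PWM construction, exact score p-values, and two-strand scanning.

The scanner replaces an external motif-search tool: a position frequency
matrix is turned into a log2 log-odds PWM against a 0-order background, the
null distribution of the window score (random i.i.d. background sequence) is
computed exactly by per-column convolution of an integer-quantized copy of
the PWM, and every window on both strands whose match p-value passes a
threshold is reported as a hit.

Quantization: each PWM entry is rounded to a grid of ``granularity`` bins
per column. Both the null distribution and every scanned window score are
evaluated on the same integer grid, so a hit's p-value is *exact* for the
quantized matrix — there is no interpolation error, only the (tiny, bounded)
perturbation from rounding the matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    try:
        return np.fromiter((_CODE[b] for b in sequence), dtype=np.int8, count=len(sequence))
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order base frequencies pooled over both strands of the given sequences.

    Pooling both strands makes the background strand-symmetric
    (freq(A)=freq(T), freq(C)=freq(G)), as is standard for double-stranded
    scanning. N bases are ignored. A pseudo-observation of each base keeps
    all four probabilities strictly positive.
    """
    counts = np.ones(4)
    for seq in sequences:
        codes = encode(seq.upper())
        codes = codes[codes < 4]
        fwd = np.bincount(codes, minlength=4)
        counts += fwd + fwd[::-1]  # reverse strand: A<->T, C<->G
    return counts / counts.sum()


@dataclass
class ScorePvalueTable:
    """Exact survival function of the quantized window score under background.

    ``pvalue_of_k(K)`` returns P(Score_q >= K) where Score_q is the sum of
    quantized column scores of a random background window.
    """

    bin_width: float
    k_min: int
    sf: np.ndarray  # sf[i] = P(Score_q >= k_min + i); sf[0] == 1

    def pvalue_of_k(self, k: int) -> float:
        idx = k - self.k_min
        if idx <= 0:
            return 1.0
        if idx >= len(self.sf):
            # above the maximum achievable score (can only happen for queries
            # not produced by scanning); clamp to the smallest tabulated p
            return float(self.sf[-1])
        return float(self.sf[idx])

    def pvalue_of_score(self, score: float) -> float:
        """p-value for a raw (float) score, via the same rounding as scanning."""
        return self.pvalue_of_k(int(round(score / self.bin_width)))

    @property
    def min_score(self) -> float:
        return self.k_min * self.bin_width

    @property
    def max_score(self) -> float:
        return (self.k_min + len(self.sf) - 1) * self.bin_width


@dataclass
class MotifModel:
    """A TF motif: PFM, log-odds PWM, background, and score p-value table."""

    motif_id: str
    tf_name: str
    pfm: np.ndarray  # 4 x w, raw counts
    pwm: np.ndarray  # 4 x w, log2 odds
    background: np.ndarray  # length-4 base probabilities
    pseudocount: float
    kmat: np.ndarray | None = None  # 4 x w integer-quantized pwm
    pvalue_table: ScorePvalueTable | None = None

    @property
    def width(self) -> int:
        return int(self.pwm.shape[1])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    motif_id: str
    offset: int  # 0-based start within the region
    strand: str  # '+' or '-'
    score: float  # log2-odds sum
    pvalue: float


def build_pwm(
    pfm: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    motif_id: str = "",
    tf_name: str = "",
) -> MotifModel:
    """Build a log2 log-odds PWM from a position frequency matrix.

    The pseudocount is distributed proportionally to the background:
    pwm[b,j] = log2( (pfm[b,j] + pc*bg[b]) / (colsum_j + pc) / bg[b] ).
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4 or pfm.shape[1] < 1:
        raise ValueError(f"pfm must be 4 x w with w >= 1, got shape {pfm.shape}")
    if (pfm < 0).any():
        raise ValueError("pfm has negative entries")
    colsums = pfm.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("pfm has a zero column sum")
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    prob = (pfm + pseudocount * background[:, None]) / (colsums + pseudocount)
    pwm = np.log2(prob / background[:, None])
    return MotifModel(
        motif_id=motif_id,
        tf_name=tf_name or motif_id,
        pfm=pfm,
        pwm=pwm,
        background=background,
        pseudocount=pseudocount,
    )


def score_pvalue_table(model: MotifModel, granularity: int = 1000) -> ScorePvalueTable:
    """Exact null distribution of the quantized window score by convolution.

    granularity = number of quantization bins per PWM column. The table is
    attached to the model (``model.kmat``, ``model.pvalue_table``) and also
    returned. Guarantees: the p-value is non-increasing in score and equals
    1 at the minimum achievable score.
    """
    if granularity < 10:
        raise ValueError("granularity must be >= 10")
    pwm, bg = model.pwm, model.background
    col_ranges = pwm.max(axis=0) - pwm.min(axis=0)
    max_range = float(col_ranges.max())
    bin_width = max_range / granularity if max_range > 0 else 1.0
    kmat = np.round(pwm / bin_width).astype(np.int64)

    k_min = int(kmat.min(axis=0).sum())
    k_max = int(kmat.max(axis=0).sum())
    dist = np.zeros(k_max - k_min + 1)
    # convolve column by column on the integer grid, exact in float arithmetic
    cur_min = 0
    dist[0] = 1.0
    cur_len = 1
    for j in range(model.width):
        kj = kmat[:, j]
        new_min = cur_min + int(kj.min())
        new_len = cur_len + int(kj.max() - kj.min())
        new = np.zeros(new_len)
        for b in range(4):
            off = int(kj[b]) - int(kj.min())
            new[off : off + cur_len] += bg[b] * dist[:cur_len]
        dist[:new_len] = new
        dist[new_len:] = 0.0
        cur_min, cur_len = new_min, new_len
    pmf = dist[:cur_len]
    sf = np.cumsum(pmf[::-1])[::-1]
    sf = np.minimum.accumulate(np.append(sf, 0.0))[:-1]
    sf /= sf[0]  # total mass exactly 1 => p(min achievable) == 1
    table = ScorePvalueTable(bin_width=bin_width, k_min=k_min, sf=sf)
    model.kmat = kmat
    model.pvalue_table = table
    return table


def _window_scores(
    codes: np.ndarray, pwm: np.ndarray, kmat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores (float and quantized) at every offset; mask of N-free windows."""
    w = pwm.shape[1]
    n_win = len(codes) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)  # n_win x w
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    cols = np.arange(w)
    scores = pwm[safe, cols].sum(axis=1)
    ks = kmat[safe, cols].sum(axis=1)
    return scores, ks, valid


def scan_region(
    model: MotifModel,
    sequence: str,
    p_threshold: float = 0.99,
    region_id: str = "",
) -> list[MotifHit]:
    """Scan a sequence on both strands; report windows with p-value <= threshold.

    Windows containing N are skipped. The reverse-strand score at offset o is
    the score of the reverse complement of the window starting at o. Hits are
    ordered by offset, then strand ('+' before '-'). A sequence shorter than
    the motif yields an empty list.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    if model.pvalue_table is None or model.kmat is None:
        raise ValueError("model has no p-value table; call score_pvalue_table first")
    w = model.width
    sequence = sequence.upper()
    if len(sequence) < w:
        return []
    codes = encode(sequence)
    table = model.pvalue_table

    # reverse strand == scanning the forward codes with the reverse-complement
    # of the matrix (rows complemented, columns reversed)
    rc_pwm = model.pwm[::-1, ::-1]
    rc_kmat = model.kmat[::-1, ::-1]

    hits: list[MotifHit] = []
    fwd = _window_scores(codes, model.pwm, model.kmat)
    rev = _window_scores(codes, rc_pwm, rc_kmat)
    n_win = len(codes) - w + 1
    for off in range(n_win):
        for strand, (scores, ks, valid) in (("+", fwd), ("-", rev)):
            if not valid[off]:
                continue
            pval = table.pvalue_of_k(int(ks[off]))
            if pval <= p_threshold:
                hits.append(
                    MotifHit(
                        region_id=region_id,
                        motif_id=model.motif_id,
                        offset=off,
                        strand=strand,
                        score=float(scores[off]),
                        pvalue=pval,
                    )
                )
    return hits


def motif_present(
    model: MotifModel, sequence: str, p_threshold: float = 5e-5
) -> bool:
    """True if the sequence carries at least one match at the given p-value.

    Used for motif-presence annotation of peaks (a stringent match cutoff,
    distinct from the permissive 0.99 scan used for binding scores).
    """
    if model.pvalue_table is None or model.kmat is None:
        raise ValueError("model has no p-value table; call score_pvalue_table first")
    w = model.width
    sequence = sequence.upper()
    if len(sequence) < w:
        return False
    codes = encode(sequence)
    table = model.pvalue_table
    for pwm, kmat in (
        (model.pwm, model.kmat),
        (model.pwm[::-1, ::-1], model.kmat[::-1, ::-1]),
    ):
        _, ks, valid = _window_scores(codes, pwm, kmat)
        ks = ks[valid]
        if ks.size and table.pvalue_of_k(int(ks.max())) <= p_threshold:
            return True
    return False


def build_motif_models(
    raw_motifs: Sequence,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    granularity: int = 1000,
) -> list[MotifModel]:
    """Convenience: PWM + p-value table for each raw motif against one background."""
    models = []
    for rm in raw_motifs:
        m = build_pwm(
            rm.counts,
            background=background,
            pseudocount=pseudocount,
            motif_id=rm.motif_id,
            tf_name=rm.tf_name,
        )
        score_pvalue_table(m, granularity=granularity)
        models.append(m)
    return models


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tmotif_id\toffset\tstrand\tscore\tpvalue\n")
        for h in hits:
            fh.write(
                f"{h.region_id}\t{h.motif_id}\t{h.offset}\t{h.strand}\t"
                f"{h.score:.6g}\t{h.pvalue:.6g}\n"
            )
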