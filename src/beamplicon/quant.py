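"""Per-protospacer-position tabulation of base-editing outcomes.

Substitution counts are tabulated over indel-free reads only, while the indel
frequency is reported over all aligned reads; keeping the two denominators
separate prevents gap columns from deflating conversion rates and matches how
amplicon-editing tools conventionally report the two outcome classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from beamplicon.align import Alignment, ScoringScheme, align_read
from beamplicon.io import Read, TargetSite

BASES = ("A", "C", "G", "T", "N", "del")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: indel quantification window extends this many nt past the protospacer
INDEL_WINDOW_PAD = 5


@dataclass(frozen=True)
class QCParams:
    """Read-level quality filters applied before alignment.

    ``min_read_length`` defaults to the protospacer length when None.
    ``min_alignment_score_fraction`` is relative to the maximum attainable
    score (match score times read length).
    """

    min_mean_quality: float = 20.0
    min_read_length: int | None = None
    min_alignment_score_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.min_mean_quality < 0 or self.min_alignment_score_fraction < 0:
            raise ValueError("QC thresholds must be >= 0")


@dataclass
class EditingMatrix:
    """Per-protospacer-position base counts among indel-free reads.

    ``counts`` has shape (L, 6) with columns A, C, G, T, N, del in
    protospacer orientation.  ``n_aligned = n_indel_free + n_indel``;
    ``n_unusable`` counts reads dropped by QC, alignment score, or
    insufficient protospacer coverage.
    """

    site: TargetSite
    counts: np.ndarray
    n_aligned: int = 0
    n_indel_free: int = 0
    n_indel: int = 0
    n_unusable: int = 0

    @classmethod
    def empty(cls, site: TargetSite) -> "EditingMatrix":
        L = len(site.protospacer)
        return cls(site=site, counts=np.zeros((L, len(BASES)), dtype=np.int64))

    def ref_base(self, position: int) -> str:
        return self.site.protospacer[position - 1]

    def to_frame(self) -> pd.DataFrame:
        L = len(self.site.protospacer)
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(1, L + 1))
        df.insert(1, "ref_base", list(self.site.protospacer))
        df["n_indel_free"] = self.n_indel_free
        return df


def _window(site: TargetSite, pad: int = INDEL_WINDOW_PAD) -> tuple[int, int]:
    lo, hi = site.proto_span
    return max(0, lo - pad), min(len(site.amplicon), hi + pad)


def iter_usable_alignments(
    reads: Iterable[Read],
    site: TargetSite,
    qc: QCParams = QCParams(),
    scoring: ScoringScheme = ScoringScheme(),
    counters: dict | None = None,
) -> Iterator[Alignment]:
    """Yield alignments of reads that pass QC, score, and coverage filters.

    ``counters`` (if given) accumulates 'n_unusable' and 'n_input'.
    """
    min_len = qc.min_read_length
    if min_len is None:
        min_len = len(site.protospacer)
    lo, hi = site.proto_span
    for read in reads:
        if counters is not None:
            counters["n_input"] = counters.get("n_input", 0) + 1
        usable = (
            len(read) >= max(1, min_len)
            and float(np.mean(read.qualities)) >= qc.min_mean_quality
        )
        if usable:
            aln = align_read(read, site, scoring)
            usable = (
                aln.score >= qc.min_alignment_score_fraction * scoring.max_score(len(read))
                and aln.covers(lo, hi)
            )
        if not usable:
            if counters is not None:
                counters["n_unusable"] = counters.get("n_unusable", 0) + 1
            continue
        yield aln


def tabulate(alignments: Iterable[Alignment], site: TargetSite,
             indel_window_pad: int = INDEL_WINDOW_PAD) -> EditingMatrix:
    """Build an EditingMatrix from usable alignments.

    Reads carrying an indel that overlaps the quantification window
    (protospacer +/- ``indel_window_pad``) are counted in ``n_indel`` and
    excluded from base counts; for minus-strand sites observed bases are
    complemented into protospacer orientation.
    """
    matrix = EditingMatrix.empty(site)
    w_lo, w_hi = _window(site, indel_window_pad)
    for aln in alignments:
        matrix.n_aligned += 1
        if aln.has_indel_in(w_lo, w_hi):
            matrix.n_indel += 1
            continue
        matrix.n_indel_free += 1
        for pos, offset in site.positions.items():
            base = aln.aligned_bases.get(offset)
            if base is None:  # deleted column outside the indel window
                matrix.counts[pos - 1, _BASE_IDX["del"]] += 1
                continue
            matrix.counts[pos - 1, _BASE_IDX.get(site.observed_base(base), 4)] += 1
    return matrix


def quantify(
    reads: Iterable[Read],
    site: TargetSite,
    qc: QCParams = QCParams(),
    scoring: ScoringScheme = ScoringScheme(),
    indel_window_pad: int = INDEL_WINDOW_PAD,
) -> EditingMatrix:
    """Align reads to the site and tabulate per-position outcomes.

    Raises ``ValueError("no usable reads")`` when nothing aligns.
    """
    counters: dict = {}
    matrix = tabulate(
        iter_usable_alignments(reads, site, qc, scoring, counters),
        site, indel_window_pad)
    matrix.n_unusable = counters.get("n_unusable", 0)
    if matrix.n_aligned == 0:
        raise ValueError("no usable reads")
    return matrix


def process_reads(
    reads: Iterable[Read],
    site: TargetSite,
    qc: QCParams = QCParams(),
    scoring: ScoringScheme = ScoringScheme(),
    indel_window_pad: int = INDEL_WINDOW_PAD,
):
    """One-pass convenience: returns (EditingMatrix, AlleleTable)."""
    from beamplicon.alleles import build_allele_table

    counters: dict = {}
    alignments = list(iter_usable_alignments(reads, site, qc, scoring, counters))
    matrix = tabulate(alignments, site, indel_window_pad)
    matrix.n_unusable = counters.get("n_unusable", 0)
    if matrix.n_aligned == 0:
        raise ValueError("no usable reads")
    table = build_allele_table(alignments, site, indel_window_pad)
    return matrix, table


def efficiency(matrix: EditingMatrix, from_base: str, to_base: str) -> np.ndarray:
    """Percent conversion ``from_base -> to_base`` at each protospacer
    position whose reference base equals ``from_base``; other positions are
    NaN (undefined, never zero).

    N calls are excluded from both numerator and denominator.
    """
    if matrix.n_indel_free == 0:
        raise ValueError("no indel-free reads to compute efficiency from")
    from_base, to_base = from_base.upper(), to_base.upper()
    L = len(matrix.site.protospacer)
    out = np.full(L, np.nan)
    for pos in range(1, L + 1):
        if matrix.ref_base(pos) != from_base:
            continue
        denom = matrix.n_indel_free - int(matrix.counts[pos - 1, _BASE_IDX["N"]])
        if denom <= 0:
            continue
        out[pos - 1] = 100.0 * matrix.counts[pos - 1, _BASE_IDX[to_base]] / denom
    return out


def indel_frequency(matrix: EditingMatrix) -> float:
    """Percent of aligned reads carrying an indel in the quantification window."""
    if matrix.n_aligned <= 0:
        raise ValueError("no aligned reads")
    return 100.0 * matrix.n_indel / matrix.n_aligned


def matrix_to_tsv(matrix: EditingMatrix, path,
                  conversions: list[tuple[str, str]] = (("A", "G"), ("C", "T"))) -> None:
    """Write the per-position matrix with efficiency columns per conversion."""
    df = matrix.to_frame()
    for from_b, to_b in conversions:
        df[f"eff_{from_b}to{to_b}"] = efficiency(matrix, from_b, to_b).round(4)
    df.to_csv(path, sep="\t", index=False)
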