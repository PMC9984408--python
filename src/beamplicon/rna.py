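"""Control-anchored filtering of RNA-seq variant tables and strand-aware
A-to-I / C-to-U labeling of deaminase off-target editing events.

The filtering chain mirrors standard practice for quantifying guide-
independent RNA off-target editing of TadA-based editors: a candidate locus
in a base-editor overexpression sample is kept only if the matched control
covers it deeply (above the 90th percentile of coverages across the
overexpression sample's variants) and is essentially homozygous reference
(>= 99% reference reads), and loci that also appear as editing events in GFP
control samples (>= 10 reads, > 0% alternate reads) are subtracted as
background.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VariantRecord:
    """One variant call consumed from an upstream RNA-seq pipeline."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_depth: int
    gene_strand: str = "unknown"  # '+', '-', or 'unknown'
    sample_id: str = ""
    group: str = ""  # control | overexpression | gfp_control

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"{self.contig}:{self.position}: alt_depth {self.alt_depth} "
                f"outside [0, depth={self.depth}]")
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.position}: ref == alt")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.contig, self.position)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def alt_fraction(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def ref_fraction(self) -> float:
        return 1.0 - self.alt_fraction if self.depth else 0.0


@dataclass(frozen=True)
class RNAFilterParams:
    """Thresholds of the RNA off-target filtering chain."""

    coverage_percentile: float = 90.0
    control_ref_consensus: float = 0.99
    min_reads_gfp: int = 10
    min_alt_fraction: float = 0.0  # strict lower bound (> 0%)

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_percentile <= 100:
            raise ValueError("coverage_percentile must be in [0, 100]")
        if not 0 < self.control_ref_consensus <= 1:
            raise ValueError("control_ref_consensus must be in (0, 1]")
        if self.min_reads_gfp < 1:
            raise ValueError("min_reads_gfp must be >= 1")


@dataclass
class RNAEditSummary:
    """Retained off-target editing events for one sample."""

    n_sites: int
    editing_fractions: list[float]
    by_type: dict[str, int]
    filter_log: dict[str, int] = field(default_factory=dict)

    @property
    def mean_efficiency(self) -> float:
        if not self.editing_fractions:
            return math.nan
        return float(np.mean(self.editing_fractions))

    def as_dict(self) -> dict:
        mean = self.mean_efficiency
        return {
            "n_sites": self.n_sites,
            "mean_efficiency": None if math.isnan(mean) else mean,
            "editing_fractions": self.editing_fractions,
            "by_type": dict(self.by_type),
            "filter_log": dict(self.filter_log),
        }


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation (type-7) percentile with inclusive endpoints."""
    if len(values) == 0:
        raise ValueError("percentile of empty list")
    return float(np.percentile(np.asarray(values, dtype=float), q))


def control_confidence_filter(
    oe_variants: Sequence[VariantRecord],
    control_variants: Sequence[VariantRecord],
    params: RNAFilterParams = RNAFilterParams(),
) -> list[VariantRecord]:
    """Keep overexpression variants whose locus has a high-confidence
    reference genotype in the control sample.

    A locus is retained iff the control covers it with depth strictly greater
    than the ``coverage_percentile``-th percentile of read coverages across
    all the overexpression sample's variants, and the control reference-allele
    fraction is at least ``control_ref_consensus``.  Loci absent from the
    control table are excluded.
    """
    if not oe_variants:
        return []
    threshold = percentile([v.depth for v in oe_variants],
                           params.coverage_percentile)
    control_by_locus = {v.locus: v for v in control_variants}
    retained = []
    for v in oe_variants:
        ctrl = control_by_locus.get(v.locus)
        if ctrl is None:
            continue
        if ctrl.depth > threshold and ctrl.ref_fraction >= params.control_ref_consensus:
            retained.append(v)
    return retained


def gfp_background_filter(
    variants: Sequence[VariantRecord],
    params: RNAFilterParams = RNAFilterParams(),
) -> list[VariantRecord]:
    """Editing events in GFP control samples that count as background:
    loci with >= ``min_reads_gfp`` reads and > ``min_alt_fraction`` of reads
    supporting the alternate allele."""
    return [v for v in variants
            if v.depth >= params.min_reads_gfp
            and v.alt_fraction > params.min_alt_fraction]


def label_edit_type(v: VariantRecord) -> str:
    """Strand-aware deamination label.

    A-to-I: A>G called on a + strand gene or T>C on a - strand gene.
    C-to-U: C>T on + or G>A on -.  Anything else (including unknown strand)
    is 'other'.
    """
    pair = (v.ref.upper(), v.alt.upper(), v.gene_strand)
    if pair in (("A", "G", "+"), ("T", "C", "-")):
        return "A-to-I"
    if pair in (("C", "T", "+"), ("G", "A", "-")):
        return "C-to-U"
    return "other"


def rna_pipeline(
    oe_table: Sequence[VariantRecord],
    control_table: Sequence[VariantRecord],
    gfp_table: Sequence[VariantRecord],
    params: RNAFilterParams = RNAFilterParams(),
) -> RNAEditSummary:
    """Full filtering chain: control-confidence filter, subtraction of GFP
    background loci (matched by contig, position, ref, alt), then labeling."""
    retained = control_confidence_filter(oe_table, control_table, params)
    background = {v.key for v in gfp_background_filter(gfp_table, params)}
    final = [v for v in retained if v.key not in background]
    by_type = Counter(label_edit_type(v) for v in final)
    return RNAEditSummary(
        n_sites=len(final),
        editing_fractions=[v.alt_fraction for v in final],
        by_type=dict(by_type),
        filter_log={
            "n_input": len(oe_table),
            "n_control_confident": len(retained),
            "n_after_background_subtraction": len(final),
        },
    )


# ---------------------------------------------------------------------------
# table I/O

_TSV_COLUMNS = ["contig", "position", "ref", "alt", "depth", "alt_depth",
                "gene_strand"]


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.contig, v.position, v.ref, v.alt, v.depth, v.alt_depth,
          v.gene_strand, v.sample_id, v.group) for v in variants],
        columns=_TSV_COLUMNS + ["sample_id", "group"])


def write_variant_tsv(variants: Iterable[VariantRecord], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def _load_tsv(path, group: str) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = set(_TSV_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(VariantRecord(
            contig=str(row.contig), position=int(row.position),
            ref=str(row.ref), alt=str(row.alt), depth=int(row.depth),
            alt_depth=int(row.alt_depth),
            gene_strand=str(getattr(row, "gene_strand", "unknown")),
            sample_id=str(getattr(row, "sample_id", "")),
            group=group or str(getattr(row, "group", ""))))
    return records


def _load_vcf(path, group: str) -> list[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            depth = alt_depth = None
            if samples:
                fmt = rec.samples[samples[0]]
                if "AD" in fmt and fmt["AD"] is not None:
                    ad = fmt["AD"]
                    depth = int(sum(a for a in ad if a is not None))
                    alt_depth = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                if "DP" in fmt and fmt["DP"] is not None:
                    depth = int(fmt["DP"])
            if depth is None and "DP" in rec.info:
                depth = int(rec.info["DP"])
            if depth is None or alt_depth is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks "
                                 "DP/AD depth information")
            strand = rec.info.get("GENE_STRAND", "unknown")
            if isinstance(strand, (tuple, list)):
                strand = strand[0]
            records.append(VariantRecord(
                contig=rec.chrom, position=rec.pos, ref=rec.ref, alt=alt,
                depth=depth, alt_depth=min(alt_depth, depth),
                gene_strand=str(strand), group=group))
    return records


def load_variants(path, group: str = "") -> list[VariantRecord]:
    """Load a variant table from TSV or VCF (DP/AD from the first sample)."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _load_vcf(path, group)
    return _load_tsv(path, group)


def annotate_strand_from_bed(variants: Sequence[VariantRecord],
                             bed_path) -> list[VariantRecord]:
    """Assign gene_strand from a BED file (contig, start, end, name, score,
    strand); loci outside every interval keep strand 'unknown'."""
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["contig", "start", "end", "name", "score", "strand"],
                      dtype={"contig": str})
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for row in bed.itertuples(index=False):
        by_contig.setdefault(str(row.contig), []).append(
            (int(row.start), int(row.end), str(row.strand)))
    out = []
    for v in variants:
        strand = "unknown"
        for start, end, s in by_contig.get(v.contig, []):
            if start < v.position <= end:  # BED is 0-based half-open
                strand = s
                break
        out.append(VariantRecord(contig=v.contig, position=v.position,
                                 ref=v.ref, alt=v.alt, depth=v.depth,
                                 alt_depth=v.alt_depth, gene_strand=strand,
                                 sample_id=v.sample_id, group=v.group))
    return out
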