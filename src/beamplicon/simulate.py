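"""Generative models for amplicon reads from an edited cell population and
for paired control/overexpression RNA variant tables with planted edits.

The read simulator emulates a transfected cell pool sequenced by amplicon
HTS: each read draws its edits from per-position conversion probabilities,
with a one-parameter coupling ``rho`` between positions (rho=0: positions
edit independently; rho=1: a single latent draw drives every editable
position, giving comonotone edits whose co-occurrence equals the minimum of
the marginals).  Indels, uniform sequencing errors, and constant library
adapters are overlaid.  Every draw flows from one seeded generator, so a
fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from beamplicon.io import (DEFAULT_ADAPTERS, AdapterPair, Read, TargetSite,
                           revcomp)

_DNA = "ACGT"

#: default indel size distribution: negative sizes delete, positive insert
DEFAULT_INDEL_SIZES = {-1: 0.4, -2: 0.2, -3: 0.1, 1: 0.2, 2: 0.1}

_CONVERSION = {"A": "G", "C": "T"}  # protospacer-orientation base edits


@dataclass
class EditingModel:
    """Parameters of the synthetic edited population.

    ``p_edit`` maps protospacer positions to the marginal conversion
    probability of their designated conversion (A->G at reference-A
    positions, C->T at reference-C positions; anything else is an error).
    """

    site: TargetSite
    p_edit: dict[int, float]
    rho: float = 0.0
    indel_rate: float = 0.0
    indel_size_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_SIZES))
    error_rate: float = 0.0
    n_reads: int = 5000
    seed: int = 0
    phred: int = 37
    adapters: AdapterPair | None = None

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for value in (self.rho, self.indel_rate, self.error_rate,
                      *self.p_edit.values()):
            if not 0.0 <= value <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        proto = self.site.protospacer
        for pos in self.p_edit:
            if not 1 <= pos <= len(proto):
                raise ValueError(f"p_edit position {pos} outside protospacer")
            if proto[pos - 1] not in _CONVERSION:
                raise ValueError(
                    f"p_edit position {pos} has non-editable reference base "
                    f"{proto[pos - 1]!r}")


def _apply_edit(amplicon: list[str], site: TargetSite, pos: int) -> None:
    offset = site.positions[pos]
    new_base = _CONVERSION[site.protospacer[pos - 1]]
    if site.strand == "-":
        new_base = revcomp(new_base)
    amplicon[offset] = new_base


def simulate_reads(model: EditingModel) -> tuple[list[Read], pd.DataFrame]:
    """Draw reads from the editing model.

    Returns the reads and a per-read truth table with columns read_id,
    edited_positions (comma-joined), has_indel, indel (e.g. 'del:3@47' in
    amplicon coordinates), n_errors.
    """
    rng = np.random.default_rng(model.seed)
    site = model.site
    positions = sorted(model.p_edit)
    probs = np.array([model.p_edit[p] for p in positions])
    sizes = list(model.indel_size_dist)
    size_p = np.array([model.indel_size_dist[s] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()
    lo, hi = site.proto_span
    reads: list[Read] = []
    truth_rows = []
    for r in range(model.n_reads):
        if positions and (model.rho > 0 and rng.random() < model.rho):
            u = rng.random()  # one latent draw drives all positions
            edited_mask = u < probs
        elif positions:
            edited_mask = rng.random(len(positions)) < probs
        else:
            edited_mask = np.zeros(0, dtype=bool)
        edited = [p for p, e in zip(positions, edited_mask) if e]

        seq = list(site.amplicon)
        for pos in edited:
            _apply_edit(seq, site, pos)

        indel_desc = ""
        if model.indel_rate and rng.random() < model.indel_rate:
            # placed within the protospacer span itself so that leftmost
            # gap-shifting under alignment ambiguity stays inside the
            # padded quantification window
            size = sizes[rng.choice(len(sizes), p=size_p)]
            if size < 0:  # deletion of |size| bases
                start = int(rng.integers(lo, max(lo + 1, hi + size)))
                del seq[start: start - size]
                indel_desc = f"del:{-size}@{start}"
            else:
                start = int(rng.integers(lo + 1, hi))
                insert = rng.choice(list(_DNA), size=size)
                seq[start:start] = list(insert)
                indel_desc = f"ins:{size}@{start}"

        n_errors = 0
        if model.error_rate:
            err_mask = rng.random(len(seq)) < model.error_rate
            for i in np.flatnonzero(err_mask):
                alternatives = [b for b in _DNA if b != seq[i]]
                seq[i] = alternatives[int(rng.integers(3))]
                n_errors += 1

        sequence = "".join(seq)
        if model.adapters is not None:
            sequence = (model.adapters.forward + sequence
                        + revcomp(model.adapters.backward))
        read_id = f"sim_{r}"
        reads.append(Read(id=read_id, sequence=sequence,
                          qualities=[model.phred] * len(sequence)))
        truth_rows.append((read_id, ",".join(map(str, edited)),
                           bool(indel_desc), indel_desc, n_errors))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "edited_positions",
                                              "has_indel", "indel", "n_errors"])
    return reads, truth


@dataclass
class RNASimParams:
    """Parameters for paired control/overexpression/GFP variant tables.

    Planted true edits follow the strand-aware A-to-I convention (A>G on +
    strand genes, T>C on -); background SNPs are heterozygous in both groups
    so the control-consensus filter removes them; GFP background loci appear
    as editing events in the GFP control so subtraction removes them.
    Control depths at clean loci are drawn above the overexpression coverage
    range, satisfying the percentile gate by construction.
    """

    n_background_snps: int = 30
    n_true_edits: int = 20
    n_gfp_background: int = 10
    edit_fraction_range: tuple[float, float] = (0.05, 0.6)
    oe_depth_range: tuple[int, int] = (20, 200)
    control_depth_range: tuple[int, int] = (500, 1000)
    contig: str = "chr1"
    edit_type: str = "A-to-I"  # or 'C-to-U'
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_background_snps, self.n_true_edits,
                  self.n_gfp_background):
            if n < 0:
                raise ValueError("locus counts must be >= 0")
        if self.edit_type not in ("A-to-I", "C-to-U"):
            raise ValueError("edit_type must be 'A-to-I' or 'C-to-U'")


_EDIT_ALLELES = {  # edit_type -> strand -> (ref, alt)
    "A-to-I": {"+": ("A", "G"), "-": ("T", "C")},
    "C-to-U": {"+": ("C", "T"), "-": ("G", "A")},
}


def simulate_rna_tables(params: RNASimParams
                        ) -> tuple[list, list, list, pd.DataFrame]:
    """Generate (overexpression, control, gfp_control) variant tables plus a
    truth table flagging which loci are planted true edits."""
    from beamplicon.rna import VariantRecord

    rng = np.random.default_rng(params.seed)
    n_loci = params.n_background_snps + params.n_true_edits + params.n_gfp_background
    pos_pool = rng.choice(np.arange(1000, 1000 + 50 * max(1, n_loci)),
                          size=n_loci, replace=False)
    positions = iter(sorted(int(p) for p in pos_pool))

    oe, control, gfp = [], [], []
    truth_rows = []

    def oe_depth() -> int:
        return int(rng.integers(params.oe_depth_range[0],
                                params.oe_depth_range[1] + 1))

    def control_depth() -> int:
        return int(rng.integers(params.control_depth_range[0],
                                params.control_depth_range[1] + 1))

    for _ in range(params.n_true_edits):
        pos = next(positions)
        strand = "+" if rng.random() < 0.5 else "-"
        ref, alt = _EDIT_ALLELES[params.edit_type][strand]
        frac = rng.uniform(*params.edit_fraction_range)
        depth = oe_depth()
        alt_depth = max(1, int(round(frac * depth)))
        oe.append(VariantRecord(params.contig, pos, ref, alt, depth,
                                alt_depth, strand, group="overexpression"))
        control.append(VariantRecord(params.contig, pos, ref, alt,
                                     control_depth(), 0, strand,
                                     group="control"))
        truth_rows.append((params.contig, pos, ref, alt, "true_edit",
                           params.edit_type, alt_depth / depth))

    for _ in range(params.n_background_snps):
        pos = next(positions)
        strand = "+" if rng.random() < 0.5 else "-"
        ref, alt = ("G", "A") if rng.random() < 0.5 else ("T", "A")
        depth = oe_depth()
        alt_depth = max(1, int(round(rng.uniform(0.35, 0.65) * depth)))
        oe.append(VariantRecord(params.contig, pos, ref, alt, depth,
                                alt_depth, strand, group="overexpression"))
        # heterozygous in the control too: fails the 99% consensus gate
        cdepth = control_depth()
        control.append(VariantRecord(params.contig, pos, ref, alt, cdepth,
                                     int(round(0.5 * cdepth)), strand,
                                     group="control"))
        truth_rows.append((params.contig, pos, ref, alt, "background_snp",
                           "other", alt_depth / depth))

    for _ in range(params.n_gfp_background):
        pos = next(positions)
        strand = "+" if rng.random() < 0.5 else "-"
        ref, alt = _EDIT_ALLELES[params.edit_type][strand]
        depth = oe_depth()
        alt_depth = max(1, int(round(rng.uniform(0.05, 0.3) * depth)))
        oe.append(VariantRecord(params.contig, pos, ref, alt, depth,
                                alt_depth, strand, group="overexpression"))
        control.append(VariantRecord(params.contig, pos, ref, alt,
                                     control_depth(), 0, strand,
                                     group="control"))
        gdepth = max(int(rng.integers(10, 60)), 10)
        gfp.append(VariantRecord(params.contig, pos, ref, alt, gdepth,
                                 max(1, int(round(0.1 * gdepth))), strand,
                                 group="gfp_control"))
        truth_rows.append((params.contig, pos, ref, alt, "gfp_background",
                           params.edit_type, alt_depth / depth))

    truth = pd.DataFrame(truth_rows, columns=["contig", "position", "ref",
                                              "alt", "kind", "edit_type",
                                              "oe_fraction"])
    return oe, control, gfp, truth


def make_demo_site(seed: int = 0, name: str = "demo_site",
                   flank: int = 30) -> TargetSite:
    """A random amplicon with an embedded NGG-protospacer, for examples and
    tests.  The protospacer is seeded with editable A and C bases."""
    from beamplicon.io import locate_protospacer

    rng = np.random.default_rng(seed)
    while True:
        proto = "".join(rng.choice(list(_DNA), size=20))
        left = "".join(rng.choice(list(_DNA), size=flank))
        right = "".join(rng.choice(list(_DNA), size=flank))
        amplicon = left + proto + "AGG" + right
        if "A" not in proto or "C" not in proto:
            continue
        try:
            return locate_protospacer(amplicon, proto, "NGG", name=name)
        except ValueError:
            continue  # accidental second occurrence; redraw
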