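"""Sequencing I/O, adapter trimming, and protospacer geometry.

Conventions
-----------
Protospacer positions are numbered 1..L from the PAM-distal 5' end of the
protospacer; the PAM sits immediately 3' of position L and is not numbered.
Amplicon coordinates are 0-based half-open.  For a protospacer found on the
minus strand of the amplicon, position numbering follows the protospacer's own
5'->3' direction, so position 1 maps to the *highest* amplicon offset of the
match and observed amplicon bases must be complemented to read them in
protospacer orientation.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return reverse_complement(seq)


@dataclass
class Read:
    """A single sequencing read with Phred quality scores."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AdapterPair:
    """Constant library adapters flanking the amplicon insert.

    ``forward`` is expected at the 5' end of a read; the reverse complement of
    ``backward`` is expected at the 3' end.  ``min_overlap`` is the minimum
    length of an end-anchored partial adapter match that is still trimmed.
    """

    forward: str
    backward: str
    min_overlap: int = 8

    def __post_init__(self) -> None:
        if not self.forward or not self.backward:
            raise ValueError("adapters must be non-empty")
        if self.min_overlap < 5:
            raise ValueError("min_overlap must be >= 5")


#: Adapter sequences attached by the library's site-specific primers.
DEFAULT_ADAPTERS = AdapterPair(
    forward="GGAGTGAGTACGGTGTGC", backward="GAGTTGGATGCTGGATGG"
)


@dataclass
class TargetSite:
    """An amplicon reference with resolved protospacer/PAM geometry."""

    name: str
    amplicon: str
    protospacer: str
    pam: str
    strand: str  # '+' or '-'
    proto_start: int  # 0-based half-open start of the protospacer match
    positions: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.positions:
            self.positions = self._position_map()

    def _position_map(self) -> dict[int, int]:
        L = len(self.protospacer)
        if self.strand == "+":
            return {i: self.proto_start + i - 1 for i in range(1, L + 1)}
        return {i: self.proto_start + L - i for i in range(1, L + 1)}

    @property
    def proto_span(self) -> tuple[int, int]:
        """Amplicon interval (0-based half-open) covered by the protospacer."""
        offs = self.positions.values()
        return min(offs), max(offs) + 1

    def observed_base(self, amplicon_base: str) -> str:
        """Convert a top-strand amplicon base to protospacer orientation."""
        if self.strand == "+":
            return amplicon_base.upper()
        return amplicon_base.upper().translate(COMPLEMENT)


def _iupac_match(pattern: str, seq: str) -> bool:
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern.upper(), seq.upper()):
        if s not in ambiguous_dna_values.get(p, p):
            return False
    return True


def locate_protospacer(amplicon: str, protospacer: str, pam: str,
                       name: str = "") -> TargetSite:
    """Find a protospacer (with adjacent PAM) on either strand of an amplicon.

    Raises ``ValueError`` if no PAM-flanked occurrence exists or if more than
    one does ("ambiguous target").
    """
    amp = amplicon.upper()
    proto = protospacer.upper()
    hits: list[tuple[str, int]] = []

    # plus strand: protospacer then PAM, left to right
    start = amp.find(proto)
    while start != -1:
        pam_seq = amp[start + len(proto): start + len(proto) + len(pam)]
        if _iupac_match(pam, pam_seq):
            hits.append(("+", start))
        start = amp.find(proto, start + 1)

    # minus strand: revcomp(protospacer) on the top strand, PAM 5' of it
    rc = revcomp(proto)
    start = amp.find(rc)
    while start != -1:
        pam_seq = revcomp(amp[max(0, start - len(pam)): start])
        if start - len(pam) >= 0 and _iupac_match(pam, pam_seq):
            hits.append(("-", start))
        start = amp.find(rc, start + 1)

    if not hits:
        raise ValueError(f"protospacer not found in amplicon {name!r}")
    if len(hits) > 1:
        raise ValueError(f"ambiguous target: protospacer occurs {len(hits)} "
                         f"times in amplicon {name!r}")
    strand, proto_start = hits[0]
    return TargetSite(name=name, amplicon=amp, protospacer=proto, pam=pam.upper(),
                      strand=strand, proto_start=proto_start)


def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Stream reads from a (optionally gzipped) Phred+33 FASTQ file.

    Malformed records raise ``ValueError`` naming the 0-based record index.
    """
    with _open_maybe_gzip(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {index}: sequence and quality "
                    f"lengths differ ({len(seq)} vs {len(qual)})")
            yield Read(id=title.split()[0], sequence=seq.upper(),
                       qualities=[ord(c) - 33 for c in qual])
            index += 1


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written.

    A ``.gz`` suffix selects gzip compression.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(min(q, 93) + 33) for q in read.qualities)
            out.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def _find_forward_cut(seq: str, adapter: str, min_overlap: int) -> int:
    """Return the cut offset after a forward-adapter match, or 0."""
    idx = seq.find(adapter)
    if idx != -1:
        return idx + len(adapter)
    # partial: a 3' suffix of the adapter at the very start of the read
    for ov in range(len(adapter) - 1, min_overlap - 1, -1):
        if seq.startswith(adapter[-ov:]):
            return ov
    return 0


def _find_backward_cut(seq: str, adapter_rc: str, min_overlap: int) -> int:
    """Return the cut offset before a 3'-adapter match, or len(seq)."""
    idx = seq.rfind(adapter_rc)
    if idx != -1:
        return idx
    # partial: a 5' prefix of the rc adapter at the very end of the read
    for ov in range(len(adapter_rc) - 1, min_overlap - 1, -1):
        if seq.endswith(adapter_rc[:ov]):
            return len(seq) - ov
    return len(seq)


def trim_adapters(read: Read, adapters: AdapterPair = DEFAULT_ADAPTERS) -> Read:
    """Remove the forward adapter (and anything 5' of it) and the reverse
    complement of the backward adapter (and anything 3' of it).

    Matching is exact, with end-anchored partial overlaps of at least
    ``adapters.min_overlap`` bases also trimmed.  A read without adapter
    sequence is returned unchanged.
    """
    seq = read.sequence
    start = _find_forward_cut(seq, adapters.forward.upper(), adapters.min_overlap)
    rc_back = revcomp(adapters.backward.upper())
    end = _find_backward_cut(seq[start:], rc_back, adapters.min_overlap) + start
    if start == 0 and end == len(seq):
        return read
    return Read(id=read.id, sequence=seq[start:end],
                qualities=read.qualities[start:end])


def load_target_config(path) -> list[TargetSite]:
    """Load target sites from a TSV (name, amplicon, protospacer, pam) or a
    JSON list of objects with those keys; geometry is resolved on load."""
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        rows = data if isinstance(data, list) else data.get("targets", [])
    else:
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"name", "amplicon", "protospacer", "pam"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"target config missing columns: {sorted(missing)}")
        rows = df.to_dict("records")
    return [
        locate_protospacer(r["amplicon"], r["protospacer"], r["pam"],
                           name=r["name"])
        for r in rows
    ]
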