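"""Allele-level statistics for single and dual base editors.

An allele here is the read's sequence over the protospacer window, read in
protospacer orientation, with deleted columns marked '-'.  Alleles are
classified into the mutually exclusive outcome classes used for dual-editor
reporting: only A-to-G, only C-to-T, simultaneous A-and-C conversion,
unedited, other substitutions, and indel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from beamplicon.align import Alignment
from beamplicon.io import TargetSite
from beamplicon.quant import INDEL_WINDOW_PAD, EditingMatrix, _window, efficiency
from beamplicon.stats import wilcoxon_signed_rank


@dataclass
class AlleleTable:
    """Distinct protospacer-window alleles with read counts.

    Entries are (allele_seq, has_indel, count), sorted by descending count
    then lexicographically.
    """

    site: TargetSite
    entries: list[tuple[str, bool, int]]
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries,
                          columns=["allele", "has_indel", "count"])
        df["frequency"] = df["count"] / self.n_total if self.n_total else 0.0
        return df

    def n_mutant_types(self, min_frequency: float = 0.001) -> int:
        """Number of distinct non-reference allele types at or above a
        minimum frequency floor (default 0.1%, suppressing error singletons)."""
        ref = self.site.protospacer
        floor = min_frequency * self.n_total
        return sum(1 for seq, has_indel, count in self.entries
                   if (has_indel or seq != ref) and count >= floor)


@dataclass
class EditClassCounts:
    """Mutually exclusive allele outcome classes; fields sum to n_total."""

    only_a2g: int = 0
    only_c2t: int = 0
    simultaneous: int = 0
    unedited: int = 0
    other_subst: int = 0
    indel: int = 0

    @property
    def n_total(self) -> int:
        return (self.only_a2g + self.only_c2t + self.simultaneous
                + self.unedited + self.other_subst + self.indel)

    def as_dict(self) -> dict[str, int]:
        return {
            "only_a2g": self.only_a2g, "only_c2t": self.only_c2t,
            "simultaneous": self.simultaneous, "unedited": self.unedited,
            "other_subst": self.other_subst, "indel": self.indel,
            "n_total": self.n_total,
        }


@dataclass(frozen=True)
class WindowSpec:
    """A named set of protospacer positions, e.g. the canonical A2-A9 window."""

    label: str
    positions: frozenset

    def __init__(self, label: str, positions: Iterable[int]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "positions", frozenset(int(p) for p in positions))
        if not self.positions:
            raise ValueError("window positions must be non-empty")

    @classmethod
    def from_range(cls, start: int, end: int, label: str | None = None) -> "WindowSpec":
        return cls(label or f"{start}-{end}", range(start, end + 1))


@dataclass
class WindowSummary:
    window: WindowSpec
    per_site: dict[str, float]
    skipped_sites: list[str]

    @property
    def median(self) -> float:
        return float(np.median(list(self.per_site.values()))) if self.per_site else float("nan")

    @property
    def range(self) -> tuple[float, float]:
        if not self.per_site:
            return (float("nan"), float("nan"))
        vals = list(self.per_site.values())
        return (float(min(vals)), float(max(vals)))


@dataclass
class EditorComparison:
    """Per-position editor-vs-editor comparison plus per-window paired tests."""

    positions: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    fold: np.ndarray  # mean_y / mean_x; NaN where mean_x == 0 or undefined
    t_pvalues: np.ndarray  # two-tailed two-sample t-test per position
    window_pvalues: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions, "mean_x": self.mean_x,
            "mean_y": self.mean_y, "fold": self.fold, "t_p": self.t_pvalues,
        })


def window_sequence(aln: Alignment, site: TargetSite) -> str:
    """Read bases over the protospacer window, protospacer orientation;
    deleted columns are '-'."""
    bases = []
    for pos in sorted(site.positions):
        base = aln.aligned_bases.get(site.positions[pos])
        bases.append("-" if base is None else site.observed_base(base))
    return "".join(bases)


def build_allele_table(alignments: Iterable[Alignment], site: TargetSite,
                       indel_window_pad: int = INDEL_WINDOW_PAD) -> AlleleTable:
    """Tally distinct protospacer-window alleles among usable alignments."""
    w_lo, w_hi = _window(site, indel_window_pad)
    counts: dict[tuple[str, bool], int] = {}
    n_total = 0
    for aln in alignments:
        key = (window_sequence(aln, site), aln.has_indel_in(w_lo, w_hi))
        counts[key] = counts.get(key, 0) + 1
        n_total += 1
    entries = sorted(((seq, flag, n) for (seq, flag), n in counts.items()),
                     key=lambda e: (-e[2], e[0], e[1]))
    return AlleleTable(site=site, entries=entries, n_total=n_total)


def editable_positions(site: TargetSite, base: str) -> set[int]:
    """Protospacer positions whose reference base is ``base``."""
    return {i for i, b in enumerate(site.protospacer, start=1) if b == base.upper()}


def classify_alleles(table: AlleleTable,
                     a_positions: Iterable[int] | None = None,
                     c_positions: Iterable[int] | None = None) -> EditClassCounts:
    """Partition alleles into the six dual-editor outcome classes.

    ``a_positions`` / ``c_positions`` restrict which positions count as
    qualifying A-to-G / C-to-T edits (default: every reference A / C in the
    protospacer).  Indel alleles are classed 'indel' regardless of
    substitutions; qualifying edits take precedence over stray substitutions.
    """
    site = table.site
    ref = site.protospacer
    L = len(ref)
    a_pos = set(a_positions) if a_positions is not None else editable_positions(site, "A")
    c_pos = set(c_positions) if c_positions is not None else editable_positions(site, "C")
    for label, posset in (("a_positions", a_pos), ("c_positions", c_pos)):
        bad = [p for p in posset if not 1 <= p <= L]
        if bad:
            raise ValueError(f"{label} outside protospacer 1..{L}: {bad}")
    counts = EditClassCounts()
    for seq, has_indel, n in table.entries:
        if has_indel:
            counts.indel += n
            continue
        a2g = any(ref[p - 1] == "A" and seq[p - 1] == "G" for p in a_pos)
        c2t = any(ref[p - 1] == "C" and seq[p - 1] == "T" for p in c_pos)
        if a2g and c2t:
            counts.simultaneous += n
        elif a2g:
            counts.only_a2g += n
        elif c2t:
            counts.only_c2t += n
        elif seq != ref:
            counts.other_subst += n
        else:
            counts.unedited += n
    return counts


def simultaneous_fraction(counts: EditClassCounts) -> float:
    """Percent of all classified reads carrying both an A-to-G and a C-to-T
    edit on the same allele (the dual-editor headline statistic)."""
    if counts.n_total <= 0:
        raise ValueError("no classified reads")
    return 100.0 * counts.simultaneous / counts.n_total


def max_position_efficiency(matrix: EditingMatrix,
                            conversion: tuple[str, str] = ("A", "G")
                            ) -> tuple[int, float]:
    """Most efficiently edited position; ties go to the PAM-distal (smaller)
    position.  Returns (position, percent)."""
    eff = efficiency(matrix, *conversion)
    if np.all(np.isnan(eff)):
        raise ValueError(f"no editable {conversion[0]} position in protospacer")
    idx = int(np.nanargmax(eff))  # first (smallest position) maximum
    return idx + 1, float(eff[idx])


def window_summary(per_site_efficiencies: Mapping[str, Mapping[int, float]],
                   window: WindowSpec) -> WindowSummary:
    """Per-site mean efficiency over editable positions inside a window, with
    cross-site median and range.  Sites with no editable position in the
    window are skipped and reported."""
    per_site: dict[str, float] = {}
    skipped: list[str] = []
    for site_name, effs in per_site_efficiencies.items():
        vals = [v for p, v in effs.items()
                if p in window.positions and not np.isnan(v)]
        if not vals:
            skipped.append(site_name)
            continue
        per_site[site_name] = float(np.mean(vals))
    return WindowSummary(window=window, per_site=per_site, skipped_sites=skipped)


def editable_efficiencies(matrix: EditingMatrix,
                          conversion: tuple[str, str] = ("A", "G")
                          ) -> dict[int, float]:
    """Position -> percent efficiency, restricted to editable positions."""
    eff = efficiency(matrix, *conversion)
    return {i + 1: float(v) for i, v in enumerate(eff) if not np.isnan(v)}


def compare_editors(values_x: pd.DataFrame, values_y: pd.DataFrame,
                    windows: Sequence[WindowSpec] = (),
                    paired_by_site: bool = True) -> EditorComparison:
    """Compare two editors measured on the same sites/positions.

    ``values_x`` / ``values_y``: rows are observations (sites or replicates),
    columns are protospacer positions; NaN marks non-editable positions.
    Per position: fold change of cross-row means (NaN where mean_x == 0) and a
    two-tailed two-sample t-test.  Per window: the per-row window means of the
    two editors are compared with a two-sided paired Wilcoxon signed-rank
    test (exact null for n <= 25).
    """
    if list(values_x.columns) != list(values_y.columns):
        raise ValueError("editors measured on different positions")
    if paired_by_site and list(values_x.index) != list(values_y.index):
        raise ValueError("paired comparison requires identical site labels")
    positions = np.asarray(values_x.columns, dtype=int)
    mean_x = values_x.mean(axis=0).to_numpy(dtype=float)
    mean_y = values_y.mean(axis=0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_x > 0, mean_y / mean_x, np.nan)

    t_p = np.full(len(positions), np.nan)
    for j in range(len(positions)):
        xv = values_x.iloc[:, j].dropna()
        yv = values_y.iloc[:, j].dropna()
        if len(xv) >= 2 and len(yv) >= 2:
            t_p[j] = sps.ttest_ind(xv, yv).pvalue

    window_p: dict[str, float] = {}
    for window in windows:
        cols = [c for c in values_x.columns if int(c) in window.positions]
        wx = values_x[cols].mean(axis=1, skipna=True)
        wy = values_y[cols].mean(axis=1, skipna=True)
        if paired_by_site:
            window_p[window.label] = wilcoxon_signed_rank(wy.to_numpy(),
                                                          wx.to_numpy()).pvalue
        else:
            window_p[window.label] = float(
                sps.mannwhitneyu(wx.dropna(), wy.dropna(),
                                 alternative="two-sided").pvalue)
    return EditorComparison(positions=positions, mean_x=mean_x, mean_y=mean_y,
                            fold=fold, t_pvalues=t_p, window_pvalues=window_p)
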