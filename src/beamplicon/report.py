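"""Pipeline orchestration and Markdown reporting.

``run_pipeline`` executes the requested stages from a single config mapping,
writes versioned TSV/JSON outputs plus a MANIFEST, and renders a Markdown
report with per-position efficiency tables, window summaries, and the allele
class breakdown.  Outputs are a pure function of config + seed, so reruns are
hash-identical.

No multiple-testing correction is applied to comparison p-values; reported
statistics are limited to means/SD, median/range, two-sample t-tests and
paired signed-rank tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from beamplicon import __version__
from beamplicon.alleles import (WindowSpec, build_allele_table,
                                classify_alleles, editable_efficiencies,
                                max_position_efficiency, simultaneous_fraction,
                                window_summary)
from beamplicon.io import write_fastq
from beamplicon.quant import (QCParams, efficiency, indel_frequency,
                              matrix_to_tsv, process_reads)
from beamplicon.rna import rna_pipeline, RNAFilterParams, write_variant_tsv
from beamplicon.simulate import (EditingModel, RNASimParams, make_demo_site,
                                 simulate_reads, simulate_rna_tables)


@dataclass
class RunConfig:
    """Configuration for an end-to-end synthetic run."""

    seed: int = 0
    n_reads: int = 2000
    p_edit: dict | None = None  # position -> probability; default demo values
    rho: float = 0.0
    indel_rate: float = 0.02
    error_rate: float = 0.001
    windows: tuple = ((2, 9), (10, 15))
    rna: dict = field(default_factory=dict)  # RNASimParams overrides

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _default_p_edit(site) -> dict[int, float]:
    """Moderate editing at the first two editable As and the first C."""
    a_pos = [i for i, b in enumerate(site.protospacer, 1) if b == "A"][:2]
    c_pos = [i for i, b in enumerate(site.protospacer, 1) if b == "C"][:1]
    p = {pos: 0.3 for pos in a_pos}
    p.update({pos: 0.2 for pos in c_pos})
    return p


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> quantify -> alleles -> rna-filter, with a Markdown report.

    Returns the summary dict that is also written to ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    site = make_demo_site(seed=config.seed)
    p_edit = ({int(k): float(v) for k, v in config.p_edit.items()}
              if config.p_edit else _default_p_edit(site))
    model = EditingModel(site=site, p_edit=p_edit, rho=config.rho,
                         indel_rate=config.indel_rate,
                         error_rate=config.error_rate,
                         n_reads=config.n_reads, seed=config.seed)
    reads, truth = simulate_reads(model)
    write_fastq(reads, outdir / "reads.fastq")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest += ["reads.fastq", "truth.tsv"]

    matrix, table = process_reads(reads, site, QCParams())
    matrix_to_tsv(matrix, outdir / "position_matrix.tsv")
    table.to_frame().to_csv(outdir / "alleles.tsv", sep="\t", index=False)
    manifest += ["position_matrix.tsv", "alleles.tsv"]

    classes = classify_alleles(table)
    effs = editable_efficiencies(matrix, ("A", "G"))
    windows = [WindowSpec.from_range(a, b, f"A{a}-A{b}")
               for a, b in config.windows]
    win_summaries = {
        w.label: window_summary({site.name: effs}, w).per_site.get(site.name)
        for w in windows
    }
    best_pos, best_eff = max_position_efficiency(matrix, ("A", "G"))

    rna_params = RNASimParams(seed=config.seed, **config.rna)
    oe, control, gfp, rna_truth = simulate_rna_tables(rna_params)
    for name, tbl in (("oe", oe), ("control", control), ("gfp", gfp)):
        write_variant_tsv(tbl, outdir / f"rna_{name}.tsv")
        manifest.append(f"rna_{name}.tsv")
    rna_summary = rna_pipeline(oe, control, gfp, RNAFilterParams())

    summary = {
        "version": __version__,
        "seed": config.seed,
        "site": {"name": site.name, "protospacer": site.protospacer,
                 "strand": site.strand},
        "n_reads": config.n_reads,
        "n_aligned": matrix.n_aligned,
        "n_indel_free": matrix.n_indel_free,
        "indel_frequency_pct": indel_frequency(matrix),
        "efficiency_a2g_pct": {str(k): v for k, v in effs.items()},
        "max_position": {"position": best_pos, "efficiency_pct": best_eff},
        "window_means_pct": win_summaries,
        "allele_classes": classes.as_dict(),
        "simultaneous_fraction_pct": simultaneous_fraction(classes),
        "n_allele_types": table.n_mutant_types(),
        "rna": rna_summary.as_dict(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    manifest.append("summary.json")

    _write_report(outdir / "report.md", summary, matrix)
    manifest.append("report.md")
    (outdir / "MANIFEST").write_text("\n".join(["status: ok"] + manifest) + "\n")
    return summary


def _write_report(path, summary: dict, matrix) -> None:
    eff = efficiency(matrix, "A", "G")
    lines = [
        "# beamplicon run report",
        "",
        f"- package version: {summary['version']}",
        f"- seed: {summary['seed']}",
        f"- site: {summary['site']['name']} "
        f"(protospacer {summary['site']['protospacer']}, "
        f"strand {summary['site']['strand']})",
        f"- reads simulated: {summary['n_reads']}, aligned: "
        f"{summary['n_aligned']}, indel-free: {summary['n_indel_free']}",
        "",
        "## Per-position A-to-G efficiency (%)",
        "",
        "| position | ref | efficiency |",
        "|---|---|---|",
    ]
    for i, base in enumerate(matrix.site.protospacer, start=1):
        value = eff[i - 1]
        shown = "-" if pd.isna(value) else f"{value:.2f}"
        lines.append(f"| {i} | {base} | {shown} |")
    lines += [
        "",
        "## Window summaries (mean % over editable As)",
        "",
    ]
    for label, value in summary["window_means_pct"].items():
        shown = "no editable A" if value is None else f"{value:.2f}"
        lines.append(f"- {label}: {shown}")
    classes = summary["allele_classes"]
    lines += [
        "",
        "## Allele class composition",
        "",
        "| class | reads |",
        "|---|---|",
    ] + [f"| {k} | {classes[k]} |" for k in
         ("only_a2g", "only_c2t", "simultaneous", "unedited",
          "other_subst", "indel")] + [
        "",
        f"- simultaneous A/C conversion: "
        f"{summary['simultaneous_fraction_pct']:.2f}%",
        f"- indel frequency: {summary['indel_frequency_pct']:.2f}%",
        f"- distinct mutant allele types (>=0.1% of reads): "
        f"{summary['n_allele_types']}",
        "",
        "## RNA off-target filtering",
        "",
        f"- retained sites: {summary['rna']['n_sites']}",
        f"- mean editing fraction: {summary['rna']['mean_efficiency']}",
        f"- by type: {summary['rna']['by_type']}",
        f"- filter log: {summary['rna']['filter_log']}",
        "",
        "Statistics reported here are limited to means/SD, medians/ranges "
        "and unadjusted test p-values; no multiple-testing correction is "
        "applied.",
        "",
    ]
    Path(path).write_text("\n".join(lines))
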