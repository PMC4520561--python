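"""Plain-text readers and writers for the pipeline's tables and sequences.

Formats: tab-separated tables with a header row and gene_id first column
(annotation, counts, binding, ground truth), a sample-metadata sidecar TSV
next to every count table, comma-separated Ct tables, and FASTA for
sequences (via Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import CountTable, CtTable, TrueParameters


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    return df


def write_counts(counts: CountTable, path: str | Path) -> None:
    """Write counts TSV plus a ``<stem>.samples.tsv`` metadata sidecar."""
    path = Path(path)
    counts.counts.to_csv(path, sep="\t")
    counts.samples.to_csv(path.with_suffix("").with_suffix(".samples.tsv"), sep="\t")


def read_counts(path: str | Path) -> CountTable:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t").set_index("gene_id")
    sidecar = path.with_suffix("").with_suffix(".samples.tsv")
    samples = pd.read_csv(sidecar, sep="\t").set_index("sample_id")
    return CountTable(counts, samples)


def write_ct(ct: CtTable, path: str | Path) -> None:
    path = Path(path)
    ct.records.to_csv(path, index=False)
    ct.samples.to_csv(path.with_suffix("").with_suffix(".samples.csv"))


def read_ct(path: str | Path) -> CtTable:
    path = Path(path)
    records = pd.read_csv(path)
    samples = pd.read_csv(
        path.with_suffix("").with_suffix(".samples.csv")
    ).set_index("sample_id")
    return CtTable(records, samples)


def write_truth(truth: TrueParameters, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_profile(profile, path: str | Path) -> None:
    """Profile TSV (position, u_fraction), ready for plotting."""
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_report(report: dict, outdir: str | Path) -> None:
    """Write a landscape report (one condition) as deterministic TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["landscape"].table.to_csv(outdir / "landscape.tsv", sep="\t")
    report["quota_raw"].to_csv(outdir / "quota_raw.tsv", sep="\t")
    report["quota_smoothed"].to_csv(outdir / "quota_smoothed.tsv", sep="\t")
    report["enrichment"].to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    for name in ("top_set", "bottom_set"):
        (outdir / f"{name}.txt").write_text("\n".join(report[name]) + "\n")
    if report.get("scatter") is not None:
        report["scatter"].to_csv(outdir / "scatter.tsv", sep="\t")
    if report.get("selected_scores") is not None:
        report["selected_scores"].to_csv(outdir / "selected_scores.tsv", sep="\t")
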