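"""RPKM normalization, detection filtering and per-gene binding scores.

The pull-down experiment yields paired libraries: total cell extract and
protein-bound eluate.  Counts are normalized to RPKM (reads per kilobase of
gene length per million mapped reads), poorly detected and non-coding genes
are removed, replicate libraries are pooled, and each gene receives a
binding score

    B = RPKM_pulldown / RPKM_extract,

the ranking variable of the association landscape.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import CountTable

VALID_CATEGORIES = ("MPR", "CPR", "SPR", "CSP", "OTHER", "NONCODING")


class AnnotationJoinError(KeyError):
    """Raised when counted genes are missing from the annotation."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"genes missing from annotation: {self.missing[:10]}"
                         + ("..." if len(self.missing) > 10 else ""))


def _check_annotation(counts: pd.DataFrame, annotation: pd.DataFrame) -> None:
    missing = counts.index.difference(annotation.index)
    if len(missing):
        raise AnnotationJoinError(sorted(missing))
    if (annotation["length_nt"] < 1).any():
        raise ValueError("annotation lengths must be >= 1 nt")


def _mapped_totals(
    counts: pd.DataFrame, annotation: pd.DataFrame, denominator: str
) -> pd.Series:
    """Per-sample mapped-read totals for the 'per million' denominator.

    ``denominator='coding'`` (default pipeline behaviour) excludes
    NONCODING genes — rRNA/tRNA reads are removed before normalization —
    while ``'all'`` uses raw library totals.
    """
    if denominator == "coding":
        cats = annotation.loc[counts.index, "category"]
        totals = counts.loc[cats != "NONCODING"].sum(axis=0)
    elif denominator == "all":
        totals = counts.sum(axis=0)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero mapped reads: {zero}")
    return totals.astype(float)


def compute_rpkm(
    counts: CountTable,
    annotation: pd.DataFrame,
    denominator: str = "coding",
) -> pd.DataFrame:
    """RPKM(g, s) = count / (length_kb) / (mapped_total / 1e6), genes x samples."""
    _check_annotation(counts.counts, annotation)
    totals = _mapped_totals(counts.counts, annotation, denominator)
    length_kb = annotation.loc[counts.counts.index, "length_nt"].astype(float) / 1000.0
    return counts.counts.div(length_kb, axis=0).div(totals / 1e6, axis=1)


def filter_detected(
    rpkm: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    min_rpkm: float = 1.0,
    min_samples: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the detection filter; return (kept gene ids, exclusion report).

    NONCODING genes are always removed.  A coding gene is retained iff its
    RPKM reaches ``min_rpkm`` in at least ``min_samples`` samples of EACH
    fraction (detected in both extract and pull-down).  The report lists
    every removed gene with a reason ('noncoding' or 'poorly_detected').
    """
    if min_rpkm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    cats = annotation.loc[rpkm.index, "category"]
    noncoding = cats == "NONCODING"
    detected = pd.Series(True, index=rpkm.index)
    for fraction in ("extract", "pulldown"):
        cols = samples.index[samples["fraction"] == fraction].tolist()
        cols = [c for c in cols if c in rpkm.columns]
        hits = (rpkm[cols] >= min_rpkm).sum(axis=1)
        detected &= hits >= min_samples
    kept = rpkm.index[(~noncoding) & detected].tolist()
    reasons = []
    for g in rpkm.index[noncoding | ~detected]:
        reasons.append((g, "noncoding" if noncoding.loc[g] else "poorly_detected"))
    report = pd.DataFrame(reasons, columns=["gene_id", "reason"])
    return kept, report


def binding_scores(
    counts: CountTable,
    annotation: pd.DataFrame,
    condition: str | None = None,
    pooling: str = "pooled_counts",
    min_rpkm: float = 1.0,
    min_samples: int = 1,
    denominator: str = "coding",
) -> pd.DataFrame:
    """Compute the per-gene binding table for one condition.

    Replicates are combined per ``pooling``: ``'pooled_counts'`` (default)
    sums counts across replicates and recomputes RPKM from the pooled
    library; ``'mean_rpkm'`` averages replicate-level RPKMs.  Output columns:
    rpkm_extract, rpkm_pulldown, binding_score (NaN when undefined),
    defined (bool), category — restricted to genes passing the detection
    filter.  Genes whose extract RPKM is zero after filtering are flagged
    undefined rather than dropped.
    """
    if pooling not in ("pooled_counts", "mean_rpkm"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    sub = counts.select(condition=condition) if condition is not None else counts
    if sub.samples.empty:
        raise ValueError(f"no samples for condition {condition!r}")
    for fraction in ("extract", "pulldown"):
        if not (sub.samples["fraction"] == fraction).any():
            raise ValueError(f"missing {fraction} samples — cannot pair fractions")

    rpkm = compute_rpkm(sub, annotation, denominator)
    kept, _ = filter_detected(rpkm, annotation, sub.samples, min_rpkm, min_samples)

    per_fraction: dict[str, pd.Series] = {}
    for fraction in ("extract", "pulldown"):
        cols = sub.samples.index[sub.samples["fraction"] == fraction].tolist()
        if pooling == "pooled_counts":
            pooled = sub.counts[cols].sum(axis=1).to_frame("pooled")
            meta = pd.DataFrame(
                {"fraction": [fraction], "condition": ["pooled"], "replicate": [1]},
                index=pd.Index(["pooled"], name="sample_id"),
            )
            pooled_rpkm = compute_rpkm(CountTable(pooled, meta), annotation, denominator)
            per_fraction[fraction] = pooled_rpkm["pooled"]
        else:
            per_fraction[fraction] = rpkm[cols].mean(axis=1)

    out = pd.DataFrame(
        {
            "rpkm_extract": per_fraction["extract"].loc[kept],
            "rpkm_pulldown": per_fraction["pulldown"].loc[kept],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        score = out["rpkm_pulldown"] / out["rpkm_extract"]
    out["defined"] = out["rpkm_extract"] > 0
    out["binding_score"] = score.where(out["defined"], np.nan)
    out["category"] = annotation.loc[kept, "category"]
    out.index.name = "gene_id"
    return out
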