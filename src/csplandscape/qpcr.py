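"""qPCR quantification: fraction ratios, relative quantities, curve QC.

One cycle of threshold (Ct) corresponds to a two-fold difference in
template abundance, so all formulas here are powers of two over Ct
differences:

* fraction/pull-down to extract ratio = 2^(Ct_input - Ct_fraction);
* relative quantity (RQ), a delta-delta-Ct normalized to an endogenous
  control gene and a calibrator transcript whose RQ is 1 by construction;
* standard-curve QC: slope of Ct on log10 input must lie in [-3.6, -3]
  with R^2 > 0.995 for acceptable primer efficiency.

Undetermined Cts (no amplification) are carried as NaN and propagate to
undefined ratios; they are never imputed or replaced by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CtTable


def fraction_ratio(ct_input, ct_fraction):
    """Abundance ratio of a fraction relative to its input extract.

    ratio = 2^input Ct / 2^fraction Ct = 2^(Ct_input - Ct_fraction).
    Accepts scalars or arrays; NaN (not detected) propagates.
    """
    ct_input = np.asarray(ct_input, dtype=float)
    ct_fraction = np.asarray(ct_fraction, dtype=float)
    if ((ct_input <= 0) | (ct_fraction <= 0)).any():
        raise ValueError("Ct values must be positive")
    out = 2.0 ** (ct_input - ct_fraction)
    return float(out) if out.ndim == 0 else out


def _mean_ct(records: pd.DataFrame) -> pd.Series:
    """Replicate Cts are averaged on the Ct (log) scale before any formula."""
    return records.groupby("gene_id")["ct"].mean()


def fraction_ratio_table(
    ct: CtTable,
    input_fraction: str = "extract",
    output_fraction: str = "pulldown",
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-gene fraction/extract ratios from a long-format Ct table.

    Replicate Cts are averaged per (gene, fraction) before applying the
    ratio formula; the SEM column is computed over replicate-paired ratios
    when replicate indices match across fractions (NaN otherwise).
    """
    meta = ct.samples
    if condition is not None:
        meta = meta[meta["condition"] == condition]
    rec = ct.records[ct.records["sample_id"].isin(meta.index)]
    parts = {}
    for frac in (input_fraction, output_fraction):
        sids = meta.index[meta["fraction"] == frac]
        sub = rec[rec["sample_id"].isin(sids)]
        if sub.empty:
            raise ValueError(f"no {frac!r} measurements in Ct table")
        parts[frac] = sub
    mean_in = _mean_ct(parts[input_fraction])
    mean_out = _mean_ct(parts[output_fraction])
    genes = mean_in.index.intersection(mean_out.index)
    ratio = pd.Series(
        fraction_ratio(mean_in.loc[genes], mean_out.loc[genes]), index=genes
    )
    # replicate-paired ratios for the SEM, where pairing is possible
    pin = parts[input_fraction].groupby(["gene_id", "replicate"])["ct"].mean()
    pout = parts[output_fraction].groupby(["gene_id", "replicate"])["ct"].mean()
    paired = 2.0 ** (pin - pout)
    sem = paired.groupby("gene_id").sem().reindex(genes)
    return pd.DataFrame({"ratio": ratio, "sem": sem}).rename_axis("gene_id")


def relative_quantity(
    ct: CtTable | pd.DataFrame,
    target_genes: Sequence[str] | None = None,
    control_gene: str = "rnpB",
    calibrator_gene: str | None = None,
) -> pd.DataFrame:
    """Relative quantities normalized to an endogenous control.

    dCt(g) = mean Ct(g) - mean Ct(control);
    RQ(g) = 2^(dCt(calibrator) - dCt(g)); RQ(calibrator) == 1 by
    construction.  Plate-offset invariant: adding a constant to every Ct
    leaves every RQ unchanged.
    """
    records = ct.records if isinstance(ct, CtTable) else ct
    mean = _mean_ct(records)
    if control_gene not in mean.index:
        raise KeyError(f"control gene {control_gene!r} absent from Ct table")
    if calibrator_gene is None:
        raise KeyError("a calibrator gene must be specified")
    if calibrator_gene not in mean.index:
        raise KeyError(f"calibrator gene {calibrator_gene!r} absent from Ct table")
    genes = list(target_genes) if target_genes is not None else [
        g for g in mean.index if g != control_gene
    ]
    missing = [g for g in genes if g not in mean.index]
    if missing:
        raise KeyError(f"target genes absent from Ct table: {missing}")
    dct = mean.loc[genes] - mean.loc[control_gene]
    dct_cal = mean.loc[calibrator_gene] - mean.loc[control_gene]
    rq = 2.0 ** (dct_cal - dct)
    # SEM over replicate-level RQs, when control/calibrator replicate-pair
    per_rep = records.groupby(["gene_id", "replicate"])["ct"].mean()
    sems = []
    for g in genes:
        try:
            d = per_rep.loc[g] - per_rep.loc[control_gene]
            rq_rep = 2.0 ** (dct_cal - d)
            sems.append(rq_rep.sem() if len(rq_rep) > 1 else np.nan)
        except KeyError:
            sems.append(np.nan)
    return pd.DataFrame(
        {"delta_ct": dct, "rq": rq, "sem": sems}, index=pd.Index(genes, name="gene_id")
    )


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct against log10 relative input for primer QC."""

    slope: float  # cycles per log10 unit of input
    intercept: float  # cycles at input 1
    r_squared: float
    efficiency: float  # 10^(-1/slope) - 1; 1.0 means perfect doubling
    qc_pass: bool
    n_points: int

    SLOPE_RANGE = (-3.6, -3.0)
    MIN_R2 = 0.995


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a qPCR standard curve from (log10 relative input, Ct) pairs.

    Requires >= 3 distinct input levels.  QC passes when the slope lies in
    [-3.6, -3] (PCR efficiency between ~90% and ~115%) and R^2 > 0.995.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len({x for x, _ in pts}) < 3:
        raise ValueError("standard curve requires >= 3 distinct input levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: zero variance in log10 input")
    fit = stats.linregress(x, y)
    ss_res = float(np.sum((y - (fit.intercept + fit.slope * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    slope = float(fit.slope)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else math.inf
    lo, hi = StandardCurve.SLOPE_RANGE
    qc = (lo <= slope <= hi) and (r2 > StandardCurve.MIN_R2)
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency=efficiency,
        qc_pass=qc,
        n_points=len(pts),
    )


def densitometry_normalize(
    values: Mapping[str, float], reference: str
) -> dict[str, float]:
    """Express band signals as percentages of a reference lane."""
    if reference not in values:
        raise KeyError(f"reference lane {reference!r} not among values")
    ref = values[reference]
    if ref <= 0:
        raise ValueError("reference signal must be positive")
    return {lane: 100.0 * v / ref for lane, v in values.items()}
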