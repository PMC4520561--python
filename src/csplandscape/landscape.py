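"""Percentile binding landscape and category enrichment statistics.

Genes are ranked by binding score and cut into near-equal percentile bins
(deciles by default).  The per-bin quota of each functional-location
category, smoothed with a centred moving average, is the landscape curve;
the top and bottom fractions of the ranking are tested for category
enrichment with the hypergeometric tail (and its conservative EASE
variant), Bonferroni-corrected over the tests performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class LandscapeResult:
    """Ranked, binned binding landscape.

    ``table`` is indexed by gene_id (ascending binding score) with columns
    ``binding_score``, ``rank`` (0-based) and ``bin`` (1..n_bins, bin 1 =
    least bound).  ``excluded`` lists genes dropped for undefined scores.
    """

    table: pd.DataFrame
    n_bins: int
    excluded: list[str]

    def bin_sizes(self) -> pd.Series:
        return self.table["bin"].value_counts().sort_index()


def _ranked_defined(binding: pd.DataFrame) -> pd.DataFrame:
    defined = binding.dropna(subset=["binding_score"])
    if "defined" in defined.columns:
        defined = defined[defined["defined"]]
    # ties broken lexicographically by gene_id for cross-platform determinism
    return defined.loc[
        sorted(defined.index, key=lambda g: (defined.at[g, "binding_score"], g))
    ]


def rank_and_bin(binding: pd.DataFrame, n_bins: int = 10) -> LandscapeResult:
    """Sort genes by ascending binding score into contiguous rank bins.

    Bin sizes differ by at most one; when N is not divisible by n_bins the
    remainder goes to the lowest bins (least-bound end).  Undefined-score
    genes are excluded and reported.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ranked = _ranked_defined(binding)
    excluded = sorted(set(binding.index) - set(ranked.index))
    n = len(ranked)
    if n < n_bins:
        raise ValueError(f"{n} defined-score genes < {n_bins} bins")
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if b < extra else 0) for b in range(n_bins)]
    bins = np.repeat(np.arange(1, n_bins + 1), sizes)
    table = pd.DataFrame(
        {
            "binding_score": ranked["binding_score"].to_numpy(),
            "rank": np.arange(n),
            "bin": bins,
        },
        index=ranked.index.rename("gene_id"),
    )
    return LandscapeResult(table=table, n_bins=n_bins, excluded=excluded)


def category_quota(
    landscape: LandscapeResult,
    annotation: pd.DataFrame,
    smooth_window: int = 3,
    categories: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin category quotas and their moving-average curves.

    raw[bin, cat] = (# genes of cat in bin) / (bin size).  The smoothed
    curve is a centred moving average of width ``smooth_window`` (odd),
    shrinking symmetrically at the edges.  Returns (raw, smoothed), both
    bins x categories.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    cats = annotation.loc[landscape.table.index, "category"]
    table = landscape.table.assign(category=cats)
    counts = (
        table.groupby(["bin", "category"], observed=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(range(1, landscape.n_bins + 1), fill_value=0)
    if categories is not None:
        counts = counts.reindex(columns=list(categories), fill_value=0)
    sizes = landscape.bin_sizes().reindex(counts.index, fill_value=0)
    raw = counts.div(sizes, axis=0)
    half = smooth_window // 2
    smoothed = raw.copy()
    vals = raw.to_numpy(float)
    out = np.empty_like(vals)
    n = len(raw)
    for i in range(n):
        # shrink symmetrically so edge windows stay centred
        h = min(half, i, n - 1 - i)
        out[i] = vals[i - h : i + h + 1].mean(axis=0)
    smoothed.loc[:, :] = out
    return raw, smoothed


def top_bottom_sets(
    binding: pd.DataFrame, fraction: float = 0.30
) -> tuple[list[str], list[str]]:
    """The ceil(fraction * N) most- and least-bound genes (disjoint sets)."""
    if not (0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5) so the sets are disjoint")
    ranked = _ranked_defined(binding)
    k = math.ceil(fraction * len(ranked))
    bottom = ranked.index[:k].tolist()
    top = ranked.index[-k:].tolist()
    return top, bottom


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of a category within a selected gene set.

    N: background size; K: category members in background; n: selected-set
    size; k: category members selected.  ``p_enriched`` is the upper tail
    P(X >= k), ``p_depleted`` the lower tail P(X <= k); ``p_hypergeometric``
    is the tail matching ``direction``.  ``p_ease`` is the conservative
    EASE variant (upper tail with k - 1).  ``p_bonferroni`` multiplies the
    method's p by ``n_tests``, capped at 1.
    """

    N: int
    K: int
    n: int
    k: int
    fold_enrichment: float
    p_enriched: float
    p_depleted: float
    p_ease: float
    p_hypergeometric: float
    p_bonferroni: float
    direction: str
    method: str


def enrichment_test(
    selected: Iterable[str],
    category_genes: Iterable[str],
    background: Iterable[str],
    method: str = "hypergeometric",
    n_tests: int = 1,
) -> EnrichmentResult:
    """Test a category for over/under-representation in a selected set.

    ``selected`` must be a subset of ``background``; ``category_genes`` is
    intersected with the background to give K.  Enrichment uses the upper
    hypergeometric tail, depletion the lower tail; the EASE score is the
    upper tail computed with max(k - 1, 0) successes.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown method {method!r}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    bg = set(background)
    sel = set(selected)
    if not sel <= bg:
        raise ValueError("selected set must be a subset of the background")
    cat = set(category_genes) & bg
    N, K, n, k = len(bg), len(cat), len(sel), len(sel & cat)
    if k > K or k > n:
        raise ValueError("inconsistent counts: k exceeds K or n")
    expected = n * K / N if N else float("nan")
    fold = (k / n) / (K / N) if (n and K and N) else float("nan")
    p_enriched = float(hypergeom.sf(k - 1, N, K, n))
    p_depleted = float(hypergeom.cdf(k, N, K, n))
    p_ease = float(hypergeom.sf(max(k - 1, 0) - 1, N, K, n))
    direction = "enriched" if k >= expected else "depleted"
    p_hyper = p_enriched if direction == "enriched" else p_depleted
    p_sel = p_ease if method == "ease" else p_hyper
    return EnrichmentResult(
        N=N,
        K=K,
        n=n,
        k=k,
        fold_enrichment=fold,
        p_enriched=p_enriched,
        p_depleted=p_depleted,
        p_ease=p_ease,
        p_hypergeometric=p_hyper,
        p_bonferroni=min(1.0, p_sel * n_tests),
        direction=direction,
        method=method,
    )


def landscape_report(
    binding: pd.DataFrame | Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    n_bins: int = 10,
    fraction: float = 0.30,
    smooth_window: int = 3,
    method: str = "hypergeometric",
    categories: Sequence[str] | None = None,
    selected_genes: Sequence[str] | None = None,
    n_tests: int | None = None,
) -> dict:
    """Full landscape report, per condition.

    ``binding`` may be one binding table or a mapping condition -> table.
    Each per-condition report carries the extract-vs-pulldown scatter table,
    raw and smoothed quota curves, top/bottom gene sets with enrichment
    statistics for every category, and the binding scores of any
    ``selected_genes`` of interest.  Deterministic for fixed inputs.
    """
    if isinstance(binding, pd.DataFrame):
        return _single_report(
            binding, annotation, n_bins, fraction, smooth_window, method,
            categories, selected_genes, n_tests,
        )
    return {
        cond: _single_report(
            tbl, annotation, n_bins, fraction, smooth_window, method,
            categories, selected_genes, n_tests,
        )
        for cond, tbl in binding.items()
    }


def _single_report(
    binding: pd.DataFrame,
    annotation: pd.DataFrame,
    n_bins: int,
    fraction: float,
    smooth_window: int,
    method: str,
    categories: Sequence[str] | None,
    selected_genes: Sequence[str] | None,
    n_tests: int | None,
) -> dict:
    cats = categories or sorted(annotation.loc[binding.index, "category"].unique())
    scape = rank_and_bin(binding, n_bins)
    raw, smoothed = category_quota(scape, annotation, smooth_window, cats)
    top, bottom = top_bottom_sets(binding, fraction)
    background = scape.table.index.tolist()
    m = n_tests if n_tests is not None else 2 * len(cats)
    rows = []
    for set_name, sel in (("top", top), ("bottom", bottom)):
        for cat in cats:
            members = annotation.index[annotation["category"] == cat]
            res = enrichment_test(sel, members, background, method=method, n_tests=m)
            rows.append(
                {
                    "set": set_name,
                    "category": cat,
                    "N": res.N,
                    "K": res.K,
                    "n": res.n,
                    "k": res.k,
                    "fold_enrichment": res.fold_enrichment,
                    "p_enriched": res.p_enriched,
                    "p_depleted": res.p_depleted,
                    "p_ease": res.p_ease,
                    "p_hypergeometric": res.p_hypergeometric,
                    "p_bonferroni": res.p_bonferroni,
                    "direction": res.direction,
                }
            )
    scatter = binding[["rpkm_extract", "rpkm_pulldown", "category"]].copy() \
        if {"rpkm_extract", "rpkm_pulldown"} <= set(binding.columns) else None
    selected_scores = (
        binding.loc[[g for g in selected_genes if g in binding.index],
                    ["binding_score", "category"]]
        if selected_genes is not None
        else None
    )
    return {
        "landscape": scape,
        "quota_raw": raw,
        "quota_smoothed": smoothed,
        "top_set": top,
        "bottom_set": bottom,
        "enrichment": pd.DataFrame(rows),
        "scatter": scatter,
        "selected_scores": selected_scores,
    }
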