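"""Synthetic data generation for the pull-down analysis pipeline.

Emulates the experimental design of a CspE pull-down RNA-seq study on
*E. coli*: paired total-extract and pull-down libraries in replicate under
two Mg2+ conditions, with a category-dependent binding effect (membrane
protein mRNAs enriched in the eluate, cytosolic ones depleted), plus qPCR
Ct tables consistent with the simulated abundances and ORF-like sequences
carrying U-rich stretches mimicking transmembrane-helix-coding segments.

Ground truth (per-gene abundance and binding propensity) is returned with
every simulated dataset so recovery tests can compare pipeline output with
the generative parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("MPR", "CPR", "SPR", "CSP", "OTHER")

DEFAULT_CATEGORY_FRACTIONS: dict[str, float] = {
    "MPR": 0.20,
    "CPR": 0.50,
    "SPR": 0.20,
    "CSP": 0.005,
    "OTHER": 0.095,
}

# log2 binding-propensity shifts per category and condition.  MPRs bind the
# cold shock protein preferentially and the effect grows with [Mg2+]; CPRs
# and SPRs show the opposite trend; CSP-family mRNAs associate more strongly
# under low Mg2+.  Magnitudes are free parameters of the generator.
DEFAULT_BINDING_EFFECT: dict[str, dict[str, float]] = {
    "MPR": {"Mg2": 1.0, "Mg15": 2.0},
    "CPR": {"Mg2": -0.5, "Mg15": -1.0},
    "SPR": {"Mg2": -0.5, "Mg15": -1.0},
    "CSP": {"Mg2": 1.5, "Mg15": 0.5},
    "OTHER": {"Mg2": 0.0, "Mg15": 0.0},
}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic pull-down experiment.

    Attributes
    ----------
    n_genes:
        Number of genes simulated (>= 10).
    category_fractions:
        Fraction of genes per functional-location category; must sum to 1.
    length_meanlog, length_sdlog:
        Natural-log parameters of the log-normal gene-length distribution
        (nt).  Defaults give a median around 900 nt, typical of bacterial
        ORFs.
    abundance_meanlog, abundance_sdlog:
        Log-normal parameters of the true extract relative abundance.
    binding_effect:
        category -> condition -> log2 binding-propensity shift.
    binding_noise_sd_log2:
        SD of the gene-level log2 noise around the category effect, shared
        across conditions (a gene's intrinsic affinity).
    conditions:
        Condition labels (Mg2+ levels by default).
    n_replicates:
        Libraries per (fraction, condition).
    libsize:
        Expected total mapped reads per library.
    nb_dispersion:
        Overdispersion alpha of the negative binomial, var = mu + alpha*mu^2;
        0 gives Poisson counts.
    seed:
        Base seed; all generators derive deterministic substreams from it.
    """

    n_genes: int = 2000
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    length_meanlog: float = 6.8
    length_sdlog: float = 0.45
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    binding_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_BINDING_EFFECT.items()}
    )
    binding_noise_sd_log2: float = 0.5
    conditions: Sequence[str] = ("Mg2", "Mg15")
    n_replicates: int = 3
    libsize: int = 2_000_000
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.category_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category_fractions must sum to 1, got {total!r}"
            )
        if any(f < 0 for f in self.category_fractions.values()):
            raise ConfigurationError("category_fractions must be non-negative")
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.libsize <= 0:
            raise ConfigurationError("libsize must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not self.conditions:
            raise ConfigurationError("at least one condition label required")


@dataclass(frozen=True)
class TrueParameters:
    """Generative ground truth recorded alongside every simulated dataset.

    ``table`` is indexed by gene_id with columns ``category``, ``length_nt``,
    ``abundance`` (true extract relative abundance) and one
    ``propensity_<condition>`` column per condition (true binding
    propensity, linear scale).
    """

    table: pd.DataFrame
    conditions: tuple[str, ...]

    def propensity(self, condition: str) -> pd.Series:
        return self.table[f"propensity_{condition}"]

    def abundance(self) -> pd.Series:
        return self.table["abundance"]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _largest_remainder_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion n among categories by largest-remainder rounding."""
    cats = sorted(fractions)  # deterministic order
    quotas = {c: fractions[c] * n for c in cats}
    counts = {c: int(np.floor(quotas[c])) for c in cats}
    short = n - sum(counts.values())
    remainders = sorted(cats, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a gene annotation table (gene_id, length_nt, category).

    Category counts follow largest-remainder rounding of
    ``category_fractions``; lengths are log-normal, floored at 90 nt.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, 0)
    counts = _largest_remainder_counts(config.category_fractions, config.n_genes)
    labels = np.concatenate([np.repeat(c, k) for c, k in sorted(counts.items())])
    rng.shuffle(labels)
    lengths = rng.lognormal(config.length_meanlog, config.length_sdlog, config.n_genes)
    lengths = np.maximum(90, np.rint(lengths)).astype(int)
    width = len(str(config.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    return pd.DataFrame(
        {"gene_id": gene_ids, "length_nt": lengths, "category": labels}
    ).set_index("gene_id")


@dataclass(frozen=True)
class CountTable:
    """Genes x samples read counts plus per-sample metadata.

    ``counts`` is indexed by gene_id with one integer column per sample;
    ``samples`` is indexed by sample_id with columns ``fraction``
    (extract|pulldown), ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.samples["fraction"]) - {"extract", "pulldown"}
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(bad)}")

    def select(self, fraction: str | None = None, condition: str | None = None) -> "CountTable":
        meta = self.samples
        if fraction is not None:
            meta = meta[meta["fraction"] == fraction]
        if condition is not None:
            meta = meta[meta["condition"] == condition]
        return CountTable(self.counts[meta.index.tolist()], meta)


def simulate_counts(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[CountTable, TrueParameters]:
    """Simulate extract and pull-down count libraries.

    Expected extract counts are proportional to abundance x length; expected
    pull-down counts to abundance x length x binding propensity, where
    log2(propensity) = binding_effect[category][condition] + gene-level
    Gaussian noise.  Each library is scaled to ``libsize`` expected total
    reads and counts are drawn negative-binomial with dispersion
    ``nb_dispersion`` (Poisson when 0).
    """
    if len(annotation) != config.n_genes:
        raise ConfigurationError(
            f"annotation has {len(annotation)} genes, config expects {config.n_genes}"
        )
    rng = _rng(config.seed, 1)
    n = len(annotation)
    abundance = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, n)
    gene_noise = rng.normal(0.0, config.binding_noise_sd_log2, n)

    truth = annotation.copy()
    truth["abundance"] = abundance
    cat_idx = annotation["category"].to_numpy()
    for cond in config.conditions:
        shift = np.array(
            [config.binding_effect.get(c, {}).get(cond, 0.0) for c in cat_idx]
        )
        truth[f"propensity_{cond}"] = 2.0 ** (shift + gene_noise)

    length = annotation["length_nt"].to_numpy(float)
    extract_mu = abundance * length
    extract_mu = extract_mu / extract_mu.sum() * config.libsize

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in config.conditions:
        prop = truth[f"propensity_{cond}"].to_numpy()
        pull_mu = abundance * length * prop
        pull_mu = pull_mu / pull_mu.sum() * config.libsize
        for fraction, mu in (("extract", extract_mu), ("pulldown", pull_mu)):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{fraction}_{cond}_r{rep}"
                columns[sid] = _draw_counts(rng, mu, config.nb_dispersion)
                meta_rows.append((sid, fraction, cond, rep))

    counts = pd.DataFrame(columns, index=annotation.index)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "fraction", "condition", "replicate"]
    ).set_index("sample_id")
    return CountTable(counts, samples), TrueParameters(truth, tuple(config.conditions))


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR cycle-of-threshold records with sample metadata.

    ``records`` has columns gene_id, sample_id, replicate, ct; ``samples``
    is indexed by sample_id with columns ``fraction`` and ``condition``.
    """

    records: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"CtTable records missing columns: {sorted(missing)}")


def simulate_ct(
    true_params: TrueParameters,
    genes: Sequence[str],
    samples: Sequence[tuple[str, str, str]],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    intercept: float = 35.0,
) -> CtTable:
    """Simulate a qPCR Ct table consistent with the generative abundances.

    Ct = intercept - log2(relative abundance in that sample) + N(0, noise_sd).
    Extract samples see the true abundance; pull-down samples see
    abundance x binding propensity for the sample's condition.  ``samples``
    is a sequence of (sample_id, fraction, condition) triples.
    """
    rng = _rng(seed, 2)
    missing = [g for g in genes if g not in true_params.table.index]
    if missing:
        raise KeyError(f"genes absent from ground truth: {missing}")
    rows = []
    for sid, fraction, cond in samples:
        if fraction not in ("extract", "pulldown"):
            raise ValueError(f"unknown fraction {fraction!r} for sample {sid!r}")
        for g in genes:
            level = true_params.table.at[g, "abundance"]
            if fraction == "pulldown":
                level = level * true_params.table.at[g, f"propensity_{cond}"]
            base_ct = intercept - np.log2(level)
            for rep in range(1, n_replicates + 1):
                ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((g, sid, rep, ct))
    records = pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate", "ct"])
    meta = pd.DataFrame(
        [(sid, fr, cond) for sid, fr, cond in samples],
        columns=["sample_id", "fraction", "condition"],
    ).set_index("sample_id")
    return CtTable(records, meta)


class DesignError(ValueError):
    """Raised for infeasible sequence-design requests."""


def simulate_orf(
    n_codons: int,
    u_rich_segments: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
) -> str:
    """Generate an ORF-like sequence with optional U-rich segments.

    The sequence is 3*n_codons long, starts with ATG and ends with a stop
    codon (TAA).  Each segment is a half-open codon range
    (start_codon, end_codon) whose nucleotides carry a T fraction within
    +-0.05 of the target (placed by exact count); background positions are
    uniform over A/C/G/T.  U-rich segments of ~20 codons at ~0.5 T emulate
    the transmembrane-helix-coding stretches of membrane-protein mRNAs.
    """
    if n_codons < 2:
        raise DesignError("n_codons must be >= 2 (start and stop codons)")
    segs = sorted(u_rich_segments)
    for (s, e, f) in segs:
        if not (0 <= s < e <= n_codons):
            raise DesignError(f"segment ({s}, {e}) outside [0, {n_codons})")
        if not (0.0 < f < 1.0):
            raise DesignError(f"target U fraction {f} outside (0, 1)")
    for (_, e1, _), (s2, _, _) in zip(segs, segs[1:]):
        if s2 < e1:
            raise DesignError("U-rich segments overlap")

    rng = _rng(seed, 3)
    length = 3 * n_codons
    seq = rng.choice(list("ACGT"), size=length)
    for (s, e, f) in segs:
        lo, hi = 3 * s, 3 * e
        span = hi - lo
        n_t = int(round(f * span))
        pos = rng.choice(np.arange(lo, hi), size=span, replace=False)
        seq[pos[:n_t]] = "T"
        seq[pos[n_t:]] = rng.choice(list("ACG"), size=span - n_t)
    seq[0:3] = list("ATG")
    seq[length - 3 : length] = list("TAA")
    return "".join(seq)
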