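# Methods

## Generative model of the pull-down experiment

The simulator emulates a metal-affinity pull-down of a 6His-tagged RNA-binding
protein from *E. coli* extracts, sequenced as paired libraries (total extract
and eluate) in triplicate under two Mg²⁺ conditions.

For gene *g* with length *L_g* and category *c(g)*:

* **Lengths** are log-normal (`length_meanlog=6.8`, `length_sdlog=0.45`;
  median ≈ 900 nt, floored at 90 nt) — typical of bacterial ORFs.
* **Abundances** θ_g are log-normal (`abundance_sdlog=1.5`), spanning the
  few orders of magnitude seen in bacterial RNA-seq.
* **Binding propensity** per condition φ_g = 2^(β_{c(g),cond} + ε_g), with
  ε_g ~ N(0, 0.5) shared across conditions: binding is a continuous landscape
  around the category effect, not two point masses.
* **Expected counts**: extract ∝ θ_g·L_g, pull-down ∝ θ_g·L_g·φ_g, each
  library rescaled to `libsize` (default 2×10⁶) expected reads. Counts are
  negative-binomial with variance μ + αμ² (`nb_dispersion` α = 0.05; α = 0
  gives Poisson). A single shared dispersion is the simplest model with
  RNA-seq-like overdispersion.
* **Default effects** (log2): MPR +1 under "Mg2", +2 under "Mg15"; CPR and
  SPR −0.5/−1; CSP +1.5/+0.5; OTHER 0. These encode the study conditions the
  pipeline targets — preferential MPR binding that sharpens with Mg²⁺, the
  opposite trend for cytosolic/secretory mRNAs, and CSP-family self-association
  strongest at low Mg²⁺. Magnitudes are configuration, not code.
* **Category composition** defaults to MPR 0.20, CPR 0.50, SPR 0.20,
  CSP 0.005, OTHER 0.095, apportioned by largest-remainder rounding so the
  composition is exactly reproducible.
* **Ct tables**: Ct = intercept − log2(level) + N(0, noise_sd), intercept 35
  (abundance 1 → Ct 35; arbitrary but fixed and configurable); pull-down
  samples use θ_g·φ_g. **ORF-like sequences** place an exact count of T within
  each declared U-rich segment (target ±0.05 guaranteed by construction) over
  a uniform A/C/G/T background, starting ATG and ending TAA.

Library sizes and replicate variability of the real deposited data are not
published; the defaults above are free parameters chosen as field-typical and
are exposed in `SimulationConfig`.

What the generator does **not** emulate: positional read coverage, GC or
length bias, batch effects, correlated gene programs, or any mapping
artefacts. Passing tests therefore demonstrate the pipeline's arithmetic and
statistical calibration under its own model assumptions, not robustness to
every artefact of real libraries.

## Quantification choices

* The "per million mapped reads" denominator excludes NONCODING genes
  (rRNA/tRNA reads are removed before analysis); `denominator="all"` restores
  raw totals.
* Detection: a coding gene is retained iff RPKM ≥ `min_rpkm` (default 1) in at
  least `min_samples` (default 1) libraries of **each** fraction. The original
  study's exact "sufficiently detected" rule is unstated; the threshold is
  explicit configuration.
* Replicates are pooled by **summing counts** and recomputing RPKM
  (`pooled_counts`); `mean_rpkm` averaging is offered and agrees exactly when
  replicate library sizes are equal.
* Genes with zero extract RPKM after filtering keep a row with
  `defined=False` rather than being dropped, so the landscape tails are not
  silently biased.

## Landscape and enrichment

* Ranking is ascending in binding score with lexicographic gene-id
  tie-breaks — deterministic across platforms. Bins are contiguous rank
  blocks; when N is not divisible by `n_bins` the remainder goes to the
  lowest (least-bound) bins. Top/bottom sets take ceil(fraction·N) genes.
* Quota curves are smoothed with a centred moving average whose window
  shrinks symmetrically at the edges (window 3 by default, odd required).
* Enrichment reports both hypergeometric tails (upper for enrichment, lower
  for depletion — correct discrete-tail semantics rather than 1−p), the EASE
  variant (upper tail with k−1, always computed since annotation-tool
  pipelines in this field are EASE-based), and a Bonferroni correction whose
  multiplicity defaults to (categories × 2 sets) and is caller-controllable,
  because the appropriate test universe depends on the user's design.
* Published headline p-values for such experiments come from annotation tools
  with unstated backgrounds; this package asserts direction and magnitude
  class on printed counts (tails < 1e−12 and < 1e−6 on the published
  2731/471/1363/820/213/487 configuration, verified against an
  arbitrary-precision enumeration), never the tools' exact values. The
  top/bottom cut is applied per condition.

## Transcript design

* U-content windows are 0-based, half-open, step 1 by default; window 55 nt
  is the classical visualization window for transmembrane-helix-coding
  U-rich stretches.
* Start-codon set defaults to {ATG}; GTG/TTG scanning is opt-in. Either
  frame-0-only or all-frame start removal is supported.
* Stops are written as TAA (strongest stop; identity configurable) in frame 0
  every 15 codons starting at codon 14, so a 138-codon fragment carries ≥ 9
  designed stops.
* An SD-like motif is any ≥ 4-base contiguous match to AGGAGG. During design
  every such motif is disrupted (after start removal no specific start
  remains to anchor a spacer, so all potential RBSs are treated as live);
  `verify_untranslatable` additionally pairs motifs with surviving starts
  4–14 nt downstream.
* Substitution choice is deterministic: candidates are enumerated in a fixed
  (position; T, A, C, G) order and chosen to minimize the net T-count change
  within ±27 nt of the edit, so the 55-nt U profile of the mimic tracks the
  source. Design runs start-removal/SD-disruption passes to a fixpoint
  (stop decoration can expose a start spanning a codon boundary); stop
  positions are protected from later edits.
* Known limitation: stop positions and identity are fixed, so in a maximally
  T-rich window containing two designed stops the windowed U profile can
  shift by up to 4/55 ≈ 0.07; typical deviations on simulated 138-codon
  fragments are ≤ 2/55.

## qPCR arithmetic

Replicate Cts are averaged on the Ct (log) scale before any formula —
standard practice, and consistent with single-Ct ratio definitions; SEM over
replicate-paired quantities is reported alongside. Undetermined Cts are NaN
and propagate; they are never imputed. The extract/fraction and
extract/pull-down ratio statements are one formula with role labels. The
standard curve is ordinary least squares of Ct on log10 input; efficiency is
10^(−1/slope) − 1 and QC requires −3.6 ≤ slope ≤ −3 with R² > 0.995.

## Calibration and recovery checks (problem sizes)

The acceptance suite runs the full chain at these sizes, chosen to give
stable Monte-Carlo behaviour at desk scale:

* **Null calibration**: 200 datasets, 2000 genes, 3 replicates, one condition,
  all binding effects zero. The upper-tail MPR-enrichment p-value of the
  top-30% set is uniform (Kolmogorov–Smirnov, α = 0.01) — the upper tail is
  the calibrated quantity under the null — and every dataset's median binding
  score lies in [0.8, 1.25]. The median sits slightly below 1 because the
  pull-down library is renormalized by the mean (not median) propensity; this
  is a property of ratio normalization, not a bug.
* **Effect recovery**: 100 seeds with a +1 log2 MPR shift, 2000 genes:
  top-30% MPR enrichment at p < 0.01 in ≥ 95 seeds, and the smoothed MPR
  decile quota rises with bin index (Spearman ρ > 0.8 in ≥ 95 seeds and in
  the median).
* One condition label is simulated in these checks; the condition count only
  multiplies runtime, not the statistical content.

## Numerical notes

Hypergeometric tails come from `scipy.stats.hypergeom` and are cross-checked
in the tests against exact `fractions.Fraction` enumeration for all universes
N ≤ 12 and at the published-count scale. RPKM inverts to counts exactly
(relative tolerance 1e−9). All generators derive independent substreams from
a single seed via `numpy.random.SeedSequence`; identical seeds give
byte-identical outputs.
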