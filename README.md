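# csplandscape

Analysis pipeline for RNA pull-down (RIP-seq–style) experiments that ask
whether an RNA-binding protein — here modelled on the *E. coli* cold shock
proteins CspE/CspC — preferentially binds uracil-rich, membrane-protein-encoding
mRNAs (MPRs). The package is aimed at bench scientists and computational
biologists who have paired *total extract* and *pull-down eluate* read-count
tables (plus qPCR Ct tables and candidate sequences) and want the complete
quantitative workflow:

1. **Transcript design** — sliding-window U-content profiles and construction
   of *untranslatable mimics* of ORF segments: same length and U composition,
   but no start codons in any frame, periodic in-frame stop codons, and
   disrupted Shine–Dalgarno-like motifs, so binding can be studied independently
   of translation.
2. **Quantification** — RPKM normalization, removal of non-coding and poorly
   detected genes, replicate pooling, and the per-gene binding score
   **B = RPKM_pulldown / RPKM_extract**.
3. **Landscape** — genes ranked by B and cut into percentile bins; per-bin
   category quotas with moving-average smoothing; top/bottom-30% sets tested
   for category enrichment with the hypergeometric tail (and the conservative
   EASE variant), Bonferroni-corrected.
4. **qPCR** — fraction/extract ratios `2^(Ct_input − Ct_fraction)`, ΔΔCt
   relative quantities normalized to an endogenous control (`rnpB`) with a
   calibrator fixed at RQ = 1, and standard-curve QC
   (−3.6 ≤ slope ≤ −3, R² > 0.995).
5. **Synthetic data** — a negative-binomial generator that emulates the whole
   experiment (triplicates, two Mg²⁺ conditions, category-dependent binding
   effects, matching Ct tables, U-rich ORF-like sequences) with recorded
   ground truth, so every stage is testable without external downloads.

## The statistics in brief

For gene *g* in sample *s* with gene length *L_g* (nt) and *M_s* mapped reads
(after removing non-coding genes):

```
RPKM(g,s) = count(g,s) / (L_g / 1000) / (M_s / 10^6)
B(g)      = RPKM_pulldown(g) / RPKM_extract(g)        (replicates pooled)
```

A category with *K* members in a background of *N* detected genes, *k* of them
in a selected set of size *n*, is scored with the upper hypergeometric tail

```
p = Σ_{i=k}^{min(K,n)}  C(K,i) C(N−K, n−i) / C(N,n)
```

(lower tail for depletion; EASE uses k−1). Enrichment of MPRs at the
most-associated end and of cytosolic-protein mRNAs (CPRs) at the
least-associated end is the pipeline's target signature.

## Worked example

```
python examples/03_binding_landscape.py
```

simulates 2000 genes with the default binding effects and prints, per
condition:

```
[Mg2] 1998 detected mRNAs, top/bottom sets of 600 genes
  MPR in top 30%:    367/400  fold=3.06  p=3.12e-194
  CPR in bottom 30%: 419/999  fold=1.40  p=7.50e-32
  smoothed MPR quota by decile: [0.0, 0.0, 0.0, 0.01, 0.02, 0.05, 0.15, 0.34, 0.61, 0.92]

[Mg15] 1996 detected mRNAs, top/bottom sets of 599 genes
  MPR in top 30%:    400/400  fold=3.33  p=2.08e-269
```

367 of 400 simulated MPRs fall in the 30% most-associated genes under low
Mg²⁺ (3.1-fold over the background proportion), the MPR decile quota rises
monotonically along the landscape, and the separation sharpens under high
Mg²⁺ — the qualitative behaviour the method is built to expose. The other
examples cover dataset simulation (`01`), mimic design and U profiling
(`02`), and qPCR quantification (`04`).

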