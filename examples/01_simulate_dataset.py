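"""Simulate a complete pull-down dataset and write it as plain-text tables.

Builds the annotation, triplicate extract/pull-down count libraries under
two Mg2+ conditions, and the generative ground truth, then saves everything
to ./example_output/.
"""

from pathlib import Path

from csplandscape import SimulationConfig, io, simulate_annotation, simulate_counts

config = SimulationConfig(n_genes=1000, seed=42)
annotation = simulate_annotation(config)
counts, truth = simulate_counts(annotation, config)

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)
io.write_annotation(annotation, outdir / "annotation.tsv")
io.write_counts(counts, outdir / "counts.tsv")
io.write_truth(truth, outdir / "truth.tsv")

print(f"genes per category: {annotation['category'].value_counts().to_dict()}")
print(f"libraries: {list(counts.counts.columns)}")
print(f"total reads per library:\n{counts.counts.sum().to_string()}")
# Each library's total fluctuates around the configured libsize; extract
# and pull-down libraries share the generative abundances, but pull-down
# counts are additionally scaled by each gene's binding propensity.
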