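"""Simulate a genotyping-by-sequencing dataset with a known XY sex chromosome.

Builds a 10-male / 10-female population with 50 sex-linked and 2000
autosomal SNPs (plus presence/absence markers), writes the plain-text
files a real DArT-style analysis would start from, and prints what was
generated.
"""

from pathlib import Path

from sexlink import ScenarioConfig, simulate_population, write_dataset

config = ScenarioConfig(seed=1)
dataset = simulate_population(config)
paths = write_dataset(dataset, Path("scratch") / "example_dataset")

counts = dataset.truth.class_counts()
print(f"individuals: {dataset.snp.n_individuals} "
      f"({config.n_males} males, {config.n_females} females, {config.system})")
print(f"SNP loci: {dataset.snp.n_loci}, PA loci: {dataset.pa.n_loci}")
for key, n in sorted(counts.items()):
    print(f"  {key[0]:>3} {key[1]:<25} {n}")
print(f"files written to {paths['snp'].parent}/")
# The truth table records, per locus, its class (autosomal, sex-linked
# non-recombining, sex-linked recombining), its chromosome of origin and
# its Y-haplotype label — the ground truth the pipeline should recover.
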