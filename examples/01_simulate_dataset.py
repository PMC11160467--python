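"""Generate a synthetic multi-species methylation study and save it.

Builds a 40-species dataset (tree, life-history traits, sample-level
beta values, detection p-values, planted ground truth) and writes it as
plain-text files. The printed numbers summarize what was planted.
"""

import methylspan as ms

config = ms.SimulationConfig(
    n_species=40, n_cpgs=500, n_informative=50, n_unreliable_cpgs=25, seed=1
)
ds = ms.simulate_dataset(config)
ds.save("example_dataset")

print(f"species:            {len(ds.traits)}")
print(f"samples:            {ds.methylation.n_samples}")
print(f"taxonomic orders:   {ds.traits['order'].nunique()}")
print(f"life spans (years): {ds.traits['max_lifespan_years'].min():.1f}"
      f" - {ds.traits['max_lifespan_years'].max():.1f}")
print(f"informative CpGs:   {len(ds.truth.informative_cpgs)} of {config.n_cpgs}")
print(f"unreliable CpGs:    {len(ds.truth.unreliable_cpgs)}")
print(f"dimorphic species:  {len(ds.truth.dimorphic_species)}")
# The informative CpGs carry the planted life-span signal the predictors
# must recover; the unreliable ones should disappear at the filter step.
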