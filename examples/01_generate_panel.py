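"""Generate a synthetic strain panel with a planted genotype->phenotype link.

Produces a strain x enzyme count matrix, a pollutant pathway map, and
per-strain degradation efficiencies for lignin, atrazine and PFAS. The
planted model is the ground truth later examples try to recover.
"""

import syncomdesign as scd

cfg = scd.GeneratorConfig(
    n_strains=20, n_enzymes=24, n_metabolites=9, signal_strength=6.0, noise_sd=0.02, seed=1
)
profiles, pathway_map = scd.generate_profiles(cfg)
planted = scd.PlantedModel.from_pathway_map(
    pathway_map, list(profiles.columns), cfg.signal_strength, seed=2
)
labels = scd.generate_labels(profiles, planted, cfg.noise_sd, seed=3)

print(f"count matrix: {profiles.shape[0]} strains x {profiles.shape[1]} enzyme classes")
print(f"sparsity: {(profiles.to_numpy() == 0).mean():.0%} zero entries")
for pol in pathway_map["pollutants"]:
    print(f"{pol}: {len(pathway_map['pathways'][pol])} pathway enzymes")
print("\ndegradation efficiencies (first 5 strains):")
print(labels.head().round(3))
print(
    "\nEach row is one strain's efficiency in [0, 1] per pollutant; the spread "
    "comes from the planted pathway-coverage link, plus sd=0.02 assay noise."
)
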