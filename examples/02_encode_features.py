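"""Encode strain genomes as spline coefficients + Node2Vec graph embeddings.

Counts pass through a degree-3, 10-knot B-spline basis (2 Greville-moment
coefficients per enzyme) and each graph node gets a biased-random-walk
embedding; the concatenation is the node feature vector the attention
predictor consumes. At full scale (267 enzymes, 128-d embeddings) this is
534 + 128 = 662 dimensions.
"""

import syncomdesign as scd

cfg = scd.GeneratorConfig(n_strains=20, n_enzymes=24, n_metabolites=9, seed=1)
profiles, pathway_map = scd.generate_profiles(cfg)
mg = scd.build_graph(profiles, pathway_map)

encoder = scd.SplineEncoder().fit(profiles.to_numpy())
spline_vec = encoder.encode(profiles.iloc[0].to_numpy())
print(f"spline part: {profiles.shape[1]} counts -> {spline_vec.size} coefficients")

params = scd.Node2VecParams(
    dimensions=16, walk_length=30, walks_per_node=5, context=5, epochs=2, seed=1
)
embeddings = scd.node2vec_embed(mg, params)
print(f"embeddings: {len(embeddings)} nodes x {params.dimensions} dimensions")

features = scd.build_feature_map(mg, encoder, embeddings)
dim = len(next(iter(features.values())))
print(f"combined node features: {dim} dimensions "
      f"({spline_vec.size} spline + {params.dimensions} embedding)")
print("\nStrain nodes carry both blocks; enzyme/metabolite nodes carry only "
      "their embedding (zero spline block).")
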