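"""Train the graph-attention predictor and cross-validate it.

Each strain becomes a community subgraph (strain + its enzymes + their
metabolites) whose label is the 3-vector of degradation efficiencies. The
GAT (3 attention layers, global attention pooling, sigmoid MLP head) is
trained with Adam under a composite loss, then evaluated by
leave-one-strain-out cross-validation. With a planted signal the held-out
Spearman rho should be high; a permutation of the labels destroys it.
"""

import numpy as np

import syncomdesign as scd
from syncomdesign.predictor import PredictorConfig, loocv

cfg = scd.GeneratorConfig(
    n_strains=16, n_enzymes=12, n_metabolites=6, signal_strength=6.0, noise_sd=0.01, seed=21
)
profiles, pathway_map = scd.generate_profiles(cfg)
mg = scd.build_graph(profiles, pathway_map)
encoder = scd.SplineEncoder().fit(profiles.to_numpy())
embeddings = scd.node2vec_embed(
    mg, scd.Node2VecParams(dimensions=8, walk_length=15, walks_per_node=3, context=3, epochs=1, seed=21)
)
features = scd.build_feature_map(mg, encoder, embeddings)
planted = scd.PlantedModel.from_pathway_map(pathway_map, list(profiles.columns), 6.0, seed=22)
labels = scd.generate_labels(profiles, planted, noise_sd=0.01, seed=23)
dataset = scd.build_dataset(mg, features, labels)

pconf = PredictorConfig(
    input_dim=encoder.output_dim + 8, gat_layers=3, heads_per_layer=2,
    layer_dims=(8, 8, 4), mlp_dims=(4, 4, 3), dropout=0.1, learning_rate=0.01, seed=0,
)
model = scd.build_model(pconf)
history = scd.train(model, dataset, epochs=150)
print(f"training loss: {history['loss_trace'][0]:.4f} -> {history['loss_trace'][-1]:.4f}")

pred = scd.predict(model, dataset[0])
print(f"strain {dataset[0].members[0]}: predicted {np.round(pred, 3)}, "
      f"true {np.round(dataset[0].label, 3)}")

metrics = loocv(dataset, pconf, epochs=120, seed=0)
print(f"LOOCV: R2 = {metrics.r2:.3f}, RMSE = {metrics.rmse:.3f}, "
      f"Spearman rho = {metrics.spearman_rho:.3f}")
print("\nrho near 1 means held-out strains are ranked almost perfectly by "
      "predicted degradation ability; the permutation null in the test suite "
      "shows this is signal, not memorization.")
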