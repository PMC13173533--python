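# Methods

This note documents the models, the synthetic study conditions, the numeric
choices, and the limits of what the test suite demonstrates.

## Synthetic study conditions

The generator emulates the data layout of a 45-strain, 3-pollutant
community-design study: a strain × enzyme-class count matrix (default
45 × 267), a pathway map over 38 metabolites, per-strain efficiencies in
[0, 1] for lignin, atrazine and PFAS (135 strain–pollutant combinations),
and replicate-resolved assay time series (n = 6, ±SD reporting).

- **Counts.** Each enzyme family has its own prevalence drawn from
  Beta(2, 3) (mean 0.4, so roughly 60 % of entries are zero, matching the
  presence/absence character of strain–enzyme annotations); conditional on
  presence, copy number is 1 + NegBin(r = 1/dispersion) with dispersion 0.6,
  giving realistic 1–5 copy tails. The empirical copy-number distribution of
  annotated enzyme classes is not published for this kind of panel; these are
  modeling choices, fixed once.
- **Planted genotype→phenotype link.** For each pollutant, positive weights
  on its pathway enzymes define a coverage score: the weighted mean of
  log1p counts. Efficiency is a rescaled logistic of coverage, pinned to
  `floor` = 0.05 at zero coverage and `ceiling` = 0.95 asymptotically —
  bounded in [0, 1] like the sigmoid head's outputs and monotone
  nondecreasing in every weight-positive count. The link slope is the
  planted effect size; `signal_strength = 6` is the "signal on" condition
  used throughout, `signal_strength = 0` zeroes both slope and weights so
  labels are independent of genotype (the permutation-style null).
  Label noise is additive Gaussian (sd 0.02 by default, ≤ 0.05 in every
  recovery experiment) with clipping to [0, 1].
- **Assay series.** First-order, biphasic (two rates with a breakpoint) and
  sigmoid (lag, rate, plateau; logistic midpoint two days past the lag so a
  one-day lag keeps day-1 removal below 5 %) curves; replicate noise is
  additive Gaussian truncated at zero.

What the generator does **not** emulate: phylogenetic correlation between
strains, enzyme–enzyme co-occurrence structure beyond family prevalence,
horizontal transfer, expression-level effects (copy number is taken as
capacity), or compositional sequencing noise in abundance tables. Passing
recovery tests therefore demonstrates that the pipeline can extract a
pathway-mediated genotype→phenotype signal of realistic sparsity and noise —
not that it would achieve the same accuracy on any particular real panel.

## Spline encoding

Counts are log1p-transformed (variance stabilization for overdispersed
copy numbers), min–max normalized per enzyme across the panel (constant
columns map to 0), and evaluated against a shared open-uniform cubic
B-spline basis with 10 interior knots on [0, 1] (14 basis functions). Each
enzyme contributes the first two *Greville-moment projections* of its basis
response, Σᵢ ξᵢᵐ Bᵢ(x) for m = 1, 2 with ξᵢ the Greville abscissae — so 267
counts become 534 coefficients.

This reduction was a genuinely open design point. An earlier candidate —
keeping the two largest basis-function values at x — is near-periodic in x
because interior B-splines on uniform knots are translates of each other;
distinct counts collide and a linear probe on planted data plateaued around
ρ ≈ 0.6. The moment projections are smooth, deterministic, and injective
(by the linear precision of B-splines the first moment reproduces x
exactly), and the same probe reaches ρ ≈ 0.9. The count of coefficients per
enzyme is configurable; higher moments extend the same scheme.

## Node2Vec

Biased second-order random walks (return p = 1, in-out q = 0.5, walk length
80, 10 walks per node, context 10 at full scale) over the full heterogeneous
graph, embedded by skip-gram with negative sampling (5 negatives, unigram^0.75
noise distribution, linearly decayed learning rate, per-position window
subsampling as in word2vec). Walk generation is single-threaded and fully
seeded; isolated nodes receive a self-loop so every node enters the corpus.
Strain nodes concatenate their spline block with their embedding; enzyme and
metabolite nodes have no count profile, so their spline block is zero and
the embedding carries their identity and graph context.

## Metabolic graph

Node count is structural: |strains| + |enzymes| + |metabolites|. Edge counts
are emergent from the data and never asserted. Strain–enzyme edges are
binary (count > 0). Enzyme–substrate edges take catalytic-efficiency
weights from a user-supplied k_cat table keyed by EC number, defaulting to
the pathway map's value or 1.0. Strain–strain complementarity is
α·Jaccard(pathway-enzyme sets) + (1 − α)·exchange score with α = 0.5; the
exchange score is the fraction of chain metabolites producible by one
strain and consumable by the other, symmetrized by averaging, and only the
top 10 % of pairs by weight become edges. Versatility is a saturating proxy
for pathway completeness: 4 × mean over pollutants of
min(1, n_pathway_enzymes/3), clipped to [0, 4]; each strain's role and
score depend only on its own repertoire.

## Redundancy

LZ76 exhaustive-history phrase counting on binarized profiles, serialized
in canonical order (enzymes sorted by identifier, strains by ID) so the
score is invariant to subset ordering. Redundancy =
clip(1 − C(concat)/Σ C(member), 0, 1). A general-purpose compressor could
stand behind the same interface; the phrase count was chosen because it is
deterministic, dependency-free and checkable against a definition-level
reference parser (exhaustively, for all binary strings up to length 12).
Presence/absence (not counts) is serialized, matching the binary
strain–enzyme edge semantics.

## Attention predictor

Each training sample is the subgraph induced by a community's member
strains plus their enzyme neighbors and those enzymes' metabolite
neighbors; single-strain communities are valid samples, and the training
set is one sample per labelled strain. Samples are padded to a common node
count and processed batched.

Architecture: three GAT layers (heads concatenated in layers 1–2, averaged
in layer 3; LeakyReLU(0.2) attention logits, softmax masked to the
adjacency with self-loops), ELU, masked batch normalization over valid
nodes, dropout in training only; global attention pooling (softmax gate
over nodes); MLP head ending in a sigmoid, so predictions are always in
[0, 1]³ and invariant to node ordering. The full-scale configuration is
input 662 → 256 → 128 → 64 with 8 heads and head [64, 32, 16, 3]; the
printed input width of the first layer is configurable because the
534-only and 662-d conventions both occur in practice — the default uses
all 662 assembled features.

Loss: MSE + λ₁·Σ‖W‖² (weight matrices only) + λ₂·stability, where the
stability term is the mean squared deviation between the community
prediction and predictions on its leave-one-member-out subcommunities — a
community-robustness penalty that is identically zero for single-strain
samples. λ₁ = λ₂ = 0 recovers plain MSE exactly. Optimization is full-batch
Adam with a single-cycle cosine-annealed learning rate and optional early
stopping on a validation plateau (patience 20); dropout is disabled and
batch-norm running statistics are used at evaluation.

The engine underneath is a ~300-line reverse-mode autodiff on numpy
(float64), gradient-checked against central finite differences in the test
suite.

LOOCV is strain-wise (one fold per strain, preventing within-strain
leakage across pollutants); metrics are pooled over held-out predictions
flattened across the three outputs: R² = 1 − SS_res/SS_tot (defined as 0
and flagged when SS_tot = 0), RMSE, and Spearman ρ.

## Community selection and activation

GA over k-subsets: tournament selection, uniform crossover, swap mutation,
duplicate repair (replace by random non-members), elitism of 4, fitness
memoized per subset — so the best-so-far trace is monotone and small
instances are effectively enumerated. Hyperparameters (population 200,
generations 300 at full scale; much smaller in tests) are configurable; the
published constraint is only (k = 9, γ = 0.15). γ multiplies the raw
redundancy score directly, and the degradation aggregate is the unweighted
mean over pollutants. The activation simulator is reporting-only by
default (it does not feed back into GA fitness).

Activation (Ψᵃ): each pollutant's pathway is a linear chain of
unit-stoichiometry conversion steps from the pathway map (not a
genome-scale reconstruction). A step is available when any member carries
one of its enzymes. Per time step, engagement is the optimum of a linear
program — maximize terminal-product flux subject to steady-state mass
balance at internal metabolites, an uptake bound scaled by the
environmental multiplier, and per-step capacity bounds — solved with
HiGHS via scipy; mass-balance residuals are checked to 1e−8. Infeasible or
broken chains report zero engagement with a diagnostic instead of raising.

## Assay metrics

Percentages are rounded to one decimal and fold ratios to two (reporting
convention); raw values are always returned. First-order fits are OLS on
ln C vs t (k = −slope); the days-1–3 linear window fit is plain OLS on raw
concentrations. Shannon entropy defaults to natural log with a base option
(no published value is asserted for it). CSI = mean/SD (SD with one delta
degree of freedom) of consecutive Bray–Curtis dissimilarities; zero-spread
or zero-mean cases return a capped sentinel (10⁶) with a degeneracy flag,
since 1/CV is undefined there. Unit conversions (ng/mL ↔ µg/L ↔ mg/L,
mg/L ↔ µM via molar mass) are explicit audited operations.

## Problem sizes

The recovery battery (tests and `scripts/acceptance.py`) runs the full
45-strain × 3-pollutant design with 30 enzyme classes, 12 metabolites,
16-d embeddings and a compact GAT (2 heads, dims 16/16/8, head 8/8/3,
dropout 0.1, lr 0.01, 150 epochs), chosen as desk-scale sizes that keep a
full 45-fold LOOCV × 3 seeds plus a permutation null around 8 minutes on
one CPU. Structural-dimension checks use the full 267-enzyme cardinality.
GA–oracle equivalence uses instances with C(n, k) ≤ 500 so exhaustive
enumeration is the oracle.

## Known limitations

- The GAT is full-batch and CPU-bound; panels beyond a few hundred strains
  would need minibatching and a compiled backend.
- The exchange score and versatility weight are simple proxies; with real
  genome-scale models one would derive both from flux simulations.
- The activation simulator's unit-stoichiometry chains ignore branching
  pathways, cofactor balancing and biomass coupling.
- LZ76 on short profiles (≲ 50 enzymes) is granular; redundancy scores
  stabilize for profile lengths in the hundreds.
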