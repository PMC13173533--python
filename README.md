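# syncomdesign

Model-guided design of pollutant-degrading synthetic microbial communities
(SynComs), plus the assay arithmetic used to validate them.

Given a panel of bacterial strains characterized by genome-annotated enzyme
copy numbers (EC classes) and per-strain degradation efficiencies for a set
of target pollutants (lignin, atrazine, PFAS), the pipeline answers: **which
fixed-size subset of strains should be assembled to maximize community-level
degradation while minimizing functional redundancy?**

## The pipeline

1. **Genomic encoding (φ)** — each strain's enzyme-count vector is passed
   through a shared cubic B-spline basis (degree 3, 10 interior knots) after
   log1p stabilization and per-enzyme min–max normalization; every enzyme
   contributes two Greville-moment coefficients, so 267 counts become 534
   spline coefficients. Node2Vec embeddings (biased second-order walks,
   walk length 80, 10 walks/node, context 10, p = 1, q = 0.5; 128
   dimensions) summarize graph context; the concatenation gives 662-d node
   features.
2. **Network integration (Ψ)** — a heterogeneous graph over strains,
   enzymes and metabolites (45 + 267 + 38 = 350 nodes at full scale) with
   binary strain–enzyme edges, k_cat-weighted enzyme–substrate edges, and
   strain–strain metabolic-complementarity edges (α·Jaccard of pathway
   coverage + (1 − α)·metabolite exchange score; top decile kept). Coverage,
   generalist/specialist roles and 0–4 versatility scores are read off this
   graph.
3. **Degradation prediction** — a multi-head graph attention network (3
   layers, 8 heads, dims [input → 256 → 128 → 64], ELU, batch norm, global
   attention pooling, MLP head [64 → 32 → 16 → 3], sigmoid output
   y ∈ [0, 1]³) trained with Adam (η = 0.001, cosine annealing) under
   L = MSE + λ₁‖W‖² + λ₂·L_stability (λ₁ = 0.001, λ₂ = 0.01), evaluated by
   leave-one-strain-out cross-validation (R², RMSE, Spearman ρ).
4. **Redundancy scoring (Ψʳ)** — LZ76 phrase-count complexity of
   concatenated binary enzyme profiles:
   redundancy = 1 − C(concat)/Σᵢ C(memberᵢ), clipped to [0, 1].
5. **Community selection + activation (Ψᵃ)** — genetic-algorithm search
   over k-subsets (k = 9, γ = 0.15) maximizing
   mean(predicted efficiencies) − γ·redundancy, followed by a
   linear-programming flux model of each pollutant's conversion chain under
   substrate-limited, fluctuating conditions.
6. **Assay metrics** — percent removal, fold improvement, mineralization
   stoichiometry (e.g. complete mineralization of 200 µg/L atrazine with 5
   N atoms, M = 215.68 g/mol, releases 200·5·14.007/215.68 = 64.9 µg N/L),
   first-order kinetic fits, Shannon/Simpson diversity, and the community
   stability index CSI = 1/CV of consecutive Bray–Curtis dissimilarities.

Everything runs on synthetic panels with a *planted* genotype→phenotype
link (a bounded monotone link from pathway-weighted log counts to
efficiency), so prediction quality is measured as parameter recovery against
a known ground truth.

## Worked example

```bash
python examples/05_train_and_validate.py
```

```
training loss: 0.2690 -> 0.0325
strain S001: predicted [0.784 0.769 0.083], true [0.811 0.808 0.049]
LOOCV: R2 = 0.562, RMSE = 0.256, Spearman rho = 0.722
```

A 16-strain toy panel: training reduces the composite loss by ~8×, the
held-out prediction for strain S001 tracks its true (lignin, atrazine,
PFAS) efficiencies, and leave-one-strain-out cross-validation ranks unseen
strains with ρ = 0.72. At the pipeline's study scale (45 strains × 3
pollutants) the recovery battery reaches mean ρ ≈ 0.9 — and collapses to
R² < 0 when labels are permuted, confirming the skill is signal, not
memorization. The other `examples/*.py` scripts walk through generation,
encoding, network statistics, redundancy, GA selection and assay metrics,
one capability each.

A thin CLI mirrors the stages
(`syncomdesign generate|encode|network|redundancy|train|loocv|select|assay`);
run any subcommand with `--help`.

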