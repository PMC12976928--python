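# tcrcontact

Explainable prediction of T-cell receptor (TCR) recognition of peptide-MHC
complexes, built around *contact-prototype layers*: the model's binding score
**is** an aggregate of residue-pair contact estimates, so every prediction
comes with a residue-level contact map that can be read off the architecture
directly — no post-hoc attribution.

The package is aimed at computational immunologists who have paired-chain
TCR data (CDR3α, CDR3β, peptide, binding label) and per-residue embeddings
from any protein language model, and who want both a binding probability and
a mechanistic, structure-comparable explanation for it.

## The model

Inputs are three residue-embedding blocks, `E_a, E_b, E_e ∈ ℝ^{N×d}` for
CDR3α, CDR3β and the peptide (padded to length `N`, masked). Two stages:

**Cross-attention fusion.** Six directed single-head cross-attentions
`A(Q, K=V)` mix the chains and then the peptide:

```
E_{a→b} = A(E_a, E_b)          E_{b→a} = A(E_b, E_a)
E_{e→a→b} = A(E_e, E_{a→b})    E_{a→b→e} = A(E_{a→b}, E_e)
E_{e→b→a} = A(E_e, E_{b→a})    E_{b→a→e} = A(E_{b→a}, E_e)
```

Each block is scaled dot-product attention over valid key positions with a
residual connection and layer normalization.

**Contact prototype.** For a fused pair `(E1, E2)` the similarity
`S[k,j] = clamp(cos(E1_k, E2_j), 0, 1) / max(τ, 1)` (trainable temperature
τ) is pushed through a bank of soft contact filters `M_i = σ((S − t_i)·N)`
at thresholds `T = (t_1 … t_|T|)`, aggregated as
`A′ = (1/|T|) Σ_i softmax(T)_i · M_i`, and summarized as the scalar contact
area `w = Σ_{k,j} A′[k,j] / N²`. The binding score averages the two
chain-side prototypes, `ŷ = (w_{a,e} + w_{b,e}) / 2`, and `A′` is the
explanation: its row/column maxima rank residues by predicted contact, which
the Binding Region Hit Rate (BRHR) compares against the top structurally
closest residues from a crystal structure (hit rate of the top-25% overlap).

Evaluation uses the partial ROC-AUC at a maximum false-positive rate of 0.1
(McClish-standardized: chance = 0.5), the low-FPR regime that matters when
triaging candidate binders.

## Worked example

The built-in benchmark generator plants a ground-truth contact rule — a
residue-compatibility table realized exactly by the embedding geometry, and
a contact patch between the peptide core and each CDR3 — so that both
discrimination and explanation recovery are measurable offline:

```python
import numpy as np
import tcrcontact as tc

world = tc.generate_world(tc.WorldConfig(seed=7))
data  = tc.generate_dataset(world, n_pos=150, neg_ratio=4, seed=70)
test  = tc.generate_dataset(world, n_pos=40, neg_ratio=4, seed=71)

provider = tc.synthetic_provider(world)
seqs = set(tc.unique_sequences(data.records)) | set(tc.unique_sequences(test.records))
store = tc.build_store(seqs, provider, "store.h5")

config = tc.TrainConfig(epochs=25, batch_size=128, learning_rate=3e-3,
                        tied=True, normalize_by_valid=True, seed=0)
result = tc.train(data.records, store, config)

print(f"trained {config.epochs} epochs; best validation epoch "
      f"{result.best_epoch}; pos_weight {result.pos_weight:.1f}")

preds  = tc.predict_dataset(test.records, store, result.head)
y      = np.array([p.record.label for p in preds])
scores = np.array([p.y_hat for p in preds])
print(f"held-out AUC {tc.partial_auc(scores, y, max_fpr=1.0):.3f}, "
      f"pAUC(0.1) {tc.partial_auc(scores, y, max_fpr=0.1):.3f}")

from tcrcontact.evaluation import residue_importance, brhr
rates = []
for p, dmap in zip(preds, test.distance_maps):
    if p.record.label != 1:
        continue
    imp = residue_importance(p.map_b, "pep->cdr3a")
    rates.append(brhr(imp, dmap["pep->cdr3a"], t=0.25).hit_rate)
print(f"mean BRHR(pep->cdr3a, t=0.25) over {len(rates)} binders: "
      f"{np.mean(rates):.3f} (random-ranking null: 0.25)")

one = preds[0]
print(f"example record: peptide {one.record.peptide} label {one.record.label} "
      f"score {one.y_hat:.4f}; contact map axes "
      f"({one.map_b.row_axis} x {one.map_b.col_axis}), "
      f"valid block {one.map_b.row_length}x{one.map_b.col_length}")
```

prints, for this seed:

```
trained 25 epochs; best validation epoch 23; pos_weight 4.1
held-out AUC 0.845, pAUC(0.1) 0.710
mean BRHR(pep->cdr3a, t=0.25) over 40 binders: 0.429 (random-ranking null: 0.25)
example record: peptide YKHPSWQD label 0 score 0.0007; contact map axes
(peptide x cdr3a), valid block 8x13
```

The held-out AUC of 0.845 says the head separates binders from shuffled
non-binders well above chance on epitopes it saw with *new* TCR chains; the
BRHR of 0.429 says that in roughly 43% of cases the residues the model ranks
as contacts are also the structurally closest ones — 1.7× the random-null
rate of 0.25. Per-record scores are small in absolute terms (here 0.0007 for
a non-binder) because `w` is a normalized contact area, not a calibrated
probability; ranking, not scale, carries the signal.

The same workflow is available from the shell:

```
tcrcontact simulate --out-dir sim --n-pos 150 --neg-ratio 4 --seed 7
tcrcontact train   --data sim/triads.csv --store sim/store.h5 --out model
tcrcontact predict --ckpt model --data sim/triads.csv --store sim/store.h5 --out preds.csv
tcrcontact explain --ckpt model --data sim/triads.csv --store sim/store.h5 --out maps.npz
```

For real data, `read_triads` loads delimited text with configurable column
mapping, `generate_negatives` augments positives by cross-epitope shuffling
of paired chains at a chosen ratio, `unseen_epitope_split` builds
edit-distance-guarded novel-epitope test sets, and `residue_distances`
extracts nearest-atom residue distances from PDB structures for BRHR ground
truth. Real protein-language-model embeddings plug in by implementing the
two-method `EmbeddingProvider` interface and building a store once.

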