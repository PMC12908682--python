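# epintlm

Enhancer–promoter interaction (EPI) prediction from paired DNA
sequence and epigenomic features, built around pretrained k-mer
embeddings, a CNN–BiGRU encoder, intra-sequence self-attention,
bidirectional enhancer↔promoter cross-attention with residual
aggregation, and post hoc motif extraction from the learned
cross-attention maps.

## Who this is for

Computational genomics researchers who want a fully inspectable,
dependency-light reimplementation of a dual-attention EPI classifier:
the complete preprocessing protocol of the standard six-cell-line
benchmark (stratified splitting, 20× positive augmentation, grouped
fit/validation splitting, single-container serialization), the model
itself, training with the embedding freeze/unfreeze schedule, AUROC /
AUPR evaluation on the original imbalanced test split, and
TOMTOM-ready motif export. A synthetic data generator with a planted,
learnable enhancer/promoter motif co-occurrence signal makes every
stage runnable and testable with no downloads. The network runs on a
small reverse-mode autodiff core over numpy included in the package —
no deep-learning framework required.

## The model

Given an enhancer `E` (3000 bp), promoter `P` (2000 bp) and genomic
features `G`, the model learns `f : (E, P, G) → [0, 1]`:

```
I_E ∈ N^2995, I_P ∈ N^1995            overlapping 6-mer tokens
X = E[I],  E ∈ R^(4097×1280)          k-mer embedding lookup
C = Dropout(BN(MaxPool20(ReLU(Conv40(X)))))   → L'_E=147, L'_P=97
H = BiGRU2(C) ∈ R^(L'×B×64)           regulatory dependency encoder
S_E = SelfAttn(H_E)   S_P = SelfAttn(H_P)   S_G = SelfAttn(G)
C_E = CrossAttn(H_E, H_P)   C_P = CrossAttn(H_P, H_E)
H*_E = H_E + S_E + C_E    H*_P = H_P + S_P + C_P    G* = S_G
F = Concat(H*_E, H*_P, G*)            flatten → (147+97+1)·64 = 15680
ŷ = σ(MLP(F))                         L = BCE(ŷ, y)
```

Adam (weight decay 1e-3), batch 256; the embedding table is frozen
for two epochs at lr 1e-3, then unfrozen at lr 1e-4. Ablation flags
reproduce the studied variants (without residuals: `H* = C`; without
residuals and cross-attention: `H* = S`).

## Worked example

```python
import epintlm as ep
from epintlm.model import reduced_config

spec = ep.SyntheticSpec(n_pairs=600, seed=5)          # ~5% positives
records = ep.generate_pairs(spec)
tracks = ep.generate_tracks(spec, records)            # five epigenomic marks
feats = ep.normalize_features(ep.features_from_signal_vectors(tracks))
for r, f in zip(records, feats):
    r.genomic_features = f

train, test = ep.stratified_split(records, 0.1, seed=5)
aug = ep.augment_positives(train, factor=20, seed=5, max_shift=300)
fit, val = ep.split_train_val(aug, 0.1, seed=5)

cfg = reduced_config(genomic_dim=100)                  # narrow widths, same wiring
table = ep.build_embedding_table(ep.SyntheticKmerEmbedder(seed=5, dim=cfg.embed_dim))
model = ep.EPINTLM(cfg, table, seed=5)
ep.train(model, ep.build_seqgen_dataset(fit), ep.build_seqgen_dataset(val),
         ep.TrainConfig(batch_size=64, max_epochs=2, freeze_epochs=2, seed=5))
print(ep.evaluate(model, ep.build_seqgen_dataset(test)))
```

prints (numbers from this exact run):

```
{'auroc': 0.8888888888888888, 'aupr': 0.31025641025641026, 'n_pos': 3, 'n_neg': 57}
```

`auroc` is the probability the model ranks an interacting pair above a
non-interacting one on the untouched, imbalanced test split; `aupr`
summarizes retrieval of the rare positive class (chance level equals
the ~5% prevalence, so 0.31 is far above chance even when a
three-positive test split makes single-run numbers noisy). The `examples/` directory
has one short narrative script per capability — tokenization and
embedding, pipeline bookkeeping, end-to-end training, motif
extraction — each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
epintlm simulate --spec cfg.yaml --out sim/
epintlm build-table --embedder synthetic --seed 1 --dim 16 --out table.npz
epintlm preprocess --pairs sim/pairs.tsv --tracks sim/tracks.npz --out ds --seed 1
epintlm train --data ds --table table.npz --out run/
epintlm evaluate --ckpt run/model.ckpt.npz --data ds.test.sgd.npz
epintlm motifs --ckpt run/model.ckpt.npz --data ds.test.sgd.npz --out motifs/
```

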