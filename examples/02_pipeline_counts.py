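"""Reproduce the benchmark's split/augmentation bookkeeping.

The six-cell-line EPI benchmark reports, per cell line, the original
positive/negative counts, the augmented training counts and the test
counts.  Those numbers follow deterministically from a stratified 90/10
split with per-class flooring plus 20x positive augmentation — this
script recomputes all six rows from the original counts alone.
"""

from epintlm import PairRecord, augment_positives, stratified_split

CELL_LINES = {
    "GM12878": (2113, 42200), "HeLa-S3": (1740, 34800),
    "HUVEC": (1524, 30400), "IMR90": (1254, 25000),
    "K562": (1977, 39500), "NHEK": (1291, 25600),
}

print(f"{'cell line':>8}  {'orig+':>6} {'orig-':>6} {'train+':>7} "
      f"{'train-':>7} {'test+':>5} {'test-':>5}")
for name, (n_pos, n_neg) in CELL_LINES.items():
    records = ([PairRecord(f"p{i}", "A" * 6, "C" * 6, 1) for i in range(n_pos)]
               + [PairRecord(f"n{i}", "G" * 6, "T" * 6, 0) for i in range(n_neg)])
    train, test = stratified_split(records, test_fraction=0.1, seed=0)
    aug = augment_positives(train, factor=20, seed=0)
    print(f"{name:>8}  {n_pos:>6} {n_neg:>6} "
          f"{sum(r.label for r in aug):>7} {sum(1 - r.label for r in aug):>7} "
          f"{sum(r.label for r in test):>5} {sum(1 - r.label for r in test):>5}")
# Train+ = 20 x (orig+ - floor(0.1 x orig+)); the test side keeps the
# original <5% prevalence, which is where AUROC/AUPR are measured.
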