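"""Tokenize enhancer/promoter sequences and build the k-mer embedding table.

A 3000-bp enhancer yields 2995 overlapping 6-mer tokens and a 2000-bp
promoter yields 1995; the lookup table has one 1280-wide row per
possible 6-mer plus a special row for ambiguous bases.  Here a reduced
16-wide synthetic embedder keeps the demo instant.
"""

import numpy as np

from epintlm import (SyntheticKmerEmbedder, build_embedding_table, encode_kmer,
                     tokenize)

enhancer = "".join(np.random.default_rng(0).choice(list("ACGT"), 3000))
promoter = "".join(np.random.default_rng(1).choice(list("ACGT"), 2000))

tokens_e = tokenize(enhancer)
tokens_p = tokenize(promoter)
print(f"enhancer: {len(enhancer)} bp -> {len(tokens_e)} tokens")
print(f"promoter: {len(promoter)} bp -> {len(tokens_p)} tokens")
print(f"code('ACGTAC') = {encode_kmer('ACGTAC')}  (base-4 positional code)")
print(f"code('ACGTAN') = {encode_kmer('ACGTAN')}  (ambiguous -> special token)")

table = build_embedding_table(SyntheticKmerEmbedder(seed=0, dim=16))
embedded = table.lookup(tokens_e[None, :])
print(f"table: {table.matrix.shape[0]} rows x {table.matrix.shape[1]} dims")
print(f"embedded enhancer batch: {embedded.shape}")
# Each token row indexes the table; the (1, 2995, 16) tensor is what the
# convolutional front end of the model consumes.
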