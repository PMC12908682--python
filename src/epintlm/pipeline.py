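"""Dataset preparation: splits, positive augmentation, genomic features,
and the single-container serialized dataset.

The protocol mirrors the benchmark preparation used for the six-cell-line
EPI corpus:

1. the imbalanced pair set is split 90/10 into train/test with
   per-class stratification (test keeps the original imbalance);
2. each positive *training* pair is expanded into 20 shifted variants so
   positives and negatives are approximately balanced;
3. the augmented set is split 90/10 into fit/validation subsets at the
   level of original pair identifiers, so no variant of a pair ever
   crosses the boundary;
4. the model is finally evaluated on the untouched, imbalanced test split.

All modalities (token matrices, genomic features, labels, pair ids) are
serialized into one indexable container, :class:`SeqGenDataset`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .tokenization import (ENHANCER_LENGTH_BP, PROMOTER_LENGTH_BP,
                           KmerVocabulary, canonicalize_length, tokenize)

logger = logging.getLogger(__name__)

#: The five epigenomic marks, in canonical order.
GENOMIC_MARKS = ("CTCF", "DNase", "H3K27ac", "H3K4me1", "H3K4me3")

#: Default bins per element per mark (feature width 5 marks x 2 elements x bins).
DEFAULT_N_BINS = 10

_CONTAINER_VERSION = 1


@dataclass
class PairRecord:
    """One enhancer-promoter pair.  Augmented variants keep the ancestor's
    ``pair_id``; ``variant`` distinguishes them."""

    pair_id: str
    enhancer_seq: str
    promoter_seq: str
    label: int
    cell_line: str = ""
    genomic_features: Optional[np.ndarray] = None
    variant: int = 0


@dataclass(frozen=True)
class SplitSpec:
    """Split/augmentation protocol parameters."""

    test_fraction: float = 0.1
    val_fraction: float = 0.1
    augmentation_factor: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.test_fraction < 1 and 0 < self.val_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.augmentation_factor < 1:
            raise ValueError("augmentation factor must be >= 1")


# -- splits and augmentation ----------------------------------------------

def stratified_split(records: Sequence[PairRecord], test_fraction: float = 0.1,
                     seed: int = 0) -> tuple[list[PairRecord], list[PairRecord]]:
    """Per-class stratified train/test split.

    Test size per class is ``floor(test_fraction * class_count)``, so the
    test side retains the original imbalance exactly; membership is
    seeded, counts are not.
    """
    records = list(records)
    by_class: dict[int, list[int]] = {0: [], 1: []}
    for i, r in enumerate(records):
        by_class.setdefault(int(r.label), []).append(i)
    for cls in (0, 1):
        if not by_class.get(cls):
            raise ValueError(f"class {cls} has no members; cannot stratify")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x59]))
    test_idx: set[int] = set()
    for cls, idxs in sorted(by_class.items()):
        n_test = math.floor(test_fraction * len(idxs))
        chosen = rng.choice(len(idxs), size=n_test, replace=False)
        test_idx.update(idxs[j] for j in chosen)
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def _shift_sequence(seq: str, shift: int, rng: np.random.Generator) -> str:
    """Positional jitter: shift the element by ``shift`` bp, filling the
    exposed edge with random bases (as a stand-in for the genome flank a
    coordinate-based pipeline would expose).  Positive shifts move
    content rightwards.

    The fill is deliberately *not* a distinguishable pad symbol: a
    class-correlated edge marker on augmented positives would hand the
    classifier an artifact that original, unshifted test positives lack.
    """
    if shift == 0:
        return seq
    fill = "".join(np.array(list("ACGT"))[rng.integers(0, 4, abs(shift))])
    if shift > 0:
        return fill + seq[:-shift]
    return seq[-shift:] + fill


def augment_positives(train_records: Sequence[PairRecord], factor: int = 20,
                      seed: int = 0, max_shift: int = 100) -> list[PairRecord]:
    """Expand every positive pair into ``factor`` shifted variants.

    Variant 0 is the identity; the remaining ``factor - 1`` variants use
    distinct nonzero shifts drawn from ``[-max_shift, max_shift]``,
    applied independently to enhancer and promoter.  Negatives pass
    through unchanged.  All variants keep the ancestor ``pair_id``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06]))
    out: list[PairRecord] = []
    nonzero = np.concatenate([np.arange(-max_shift, 0), np.arange(1, max_shift + 1)])
    for r in train_records:
        if r.label != 1 or factor == 1:
            out.append(r)
            continue
        shifts_e = rng.choice(nonzero, size=factor - 1, replace=False)
        shifts_p = rng.choice(nonzero, size=factor - 1, replace=False)
        out.append(replace(r, variant=0))
        for v, (se, sp) in enumerate(zip(shifts_e, shifts_p), start=1):
            out.append(replace(
                r, variant=v,
                enhancer_seq=_shift_sequence(r.enhancer_seq, int(se), rng),
                promoter_seq=_shift_sequence(r.promoter_seq, int(sp), rng)))
    return out


def split_train_val(records: Sequence[PairRecord], val_fraction: float = 0.1,
                    seed: int = 0) -> tuple[list[PairRecord], list[PairRecord]]:
    """Group-aware stratified fit/validation split.

    All variants sharing a ``pair_id`` land on the same side; the split
    is stratified by label at the group level.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot split an empty record list")
    groups: dict[str, list[int]] = {}
    group_label: dict[str, int] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.pair_id, []).append(i)
        group_label[r.pair_id] = int(r.label)
    if len(groups) < 2:
        raise ValueError("need at least two pair groups to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A1]))
    val_ids: set[str] = set()
    for cls in (0, 1):
        ids = sorted(g for g, lab in group_label.items() if lab == cls)
        if not ids:
            continue
        n_val = int(round(val_fraction * len(ids)))
        if len(ids) >= 2:
            n_val = min(max(n_val, 1), len(ids) - 1)
        chosen = rng.choice(len(ids), size=n_val, replace=False)
        val_ids.update(ids[j] for j in chosen)
    fit = [r for r in records if r.pair_id not in val_ids]
    val = [r for r in records if r.pair_id in val_ids]
    return fit, val


# -- genomic features ------------------------------------------------------

def bin_signal(signal: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean signal per equal-width bin over a fixed window."""
    signal = np.asarray(signal, dtype=np.float64)
    L = signal.shape[-1]
    if n_bins < 1 or L < n_bins:
        raise ValueError(f"cannot bin length {L} into {n_bins} bins")
    edges = np.linspace(0, L, n_bins + 1).astype(int)
    return np.stack([signal[..., lo:hi].mean(axis=-1)
                     for lo, hi in zip(edges[:-1], edges[1:])], axis=-1)


def window_signal(track: dict[str, np.ndarray], region: tuple[str, int, int]) -> np.ndarray:
    """Signal over a 0-based half-open genomic window; zeros (with a
    warning) where the track has no coverage."""
    chrom, start, end = region
    out = np.zeros(end - start, dtype=np.float64)
    arr = track.get(chrom)
    if arr is None:
        logger.warning("region %s:%d-%d outside track coverage", chrom, start, end)
        return out
    lo, hi = max(start, 0), min(end, len(arr))
    if hi <= lo:
        logger.warning("region %s:%d-%d outside track coverage", chrom, start, end)
        return out
    out[lo - start:hi - start] = arr[lo:hi]
    return out


def extract_genomic_features(tracks: dict[str, dict[str, np.ndarray]],
                             enhancer_region: tuple[str, int, int],
                             promoter_region: tuple[str, int, int],
                             n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Raw binned features for one pair: 5 marks x {enhancer, promoter}
    x ``n_bins`` bin means, concatenated (length ``5 * 2 * n_bins``).

    Normalization (log1p + per-column z-score) is applied across the
    dataset by :func:`normalize_features`.
    """
    missing = set(GENOMIC_MARKS) - set(tracks)
    if missing:
        raise ValueError(f"missing tracks for marks: {sorted(missing)}")
    feats = []
    for mark in GENOMIC_MARKS:
        for region in (enhancer_region, promoter_region):
            feats.append(bin_signal(window_signal(tracks[mark], region), n_bins))
    return np.concatenate(feats)


def features_from_signal_vectors(signals: dict[str, dict[str, np.ndarray]],
                                 n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Raw binned feature matrix from per-element signal vectors
    (the synthetic-track layout of :func:`epintlm.synthetic.generate_tracks`)."""
    cols = []
    for mark in GENOMIC_MARKS:
        for element in ("enhancer", "promoter"):
            cols.append(bin_signal(signals[mark][element], n_bins))
    return np.concatenate(cols, axis=-1)


def normalize_features(raw: np.ndarray) -> np.ndarray:
    """log1p transform then per-column z-score across the dataset.

    Signal tracks are nonnegative by nature; values below zero (possible
    in synthetic noise) are clipped to zero before the log.
    """
    x = np.log1p(np.clip(np.asarray(raw, dtype=np.float64), 0.0, None))
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return ((x - mu) / sd).astype(np.float32)


# -- the serialized single-container dataset -------------------------------

@dataclass
class SeqGenDataset:
    """All modalities of a processed dataset in one indexable container."""

    I_E: np.ndarray
    I_P: np.ndarray
    G: np.ndarray
    y: np.ndarray
    pair_ids: np.ndarray
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.y)
        for name in ("I_E", "I_P", "G", "pair_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"component {name} length != {n}")

    def __len__(self) -> int:
        return len(self.y)

    def __getitem__(self, i: int) -> dict:
        return {"I_E": self.I_E[i], "I_P": self.I_P[i], "G": self.G[i],
                "y": int(self.y[i]), "pair_id": str(self.pair_ids[i])}

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.y))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        manifest = dict(self.manifest)
        manifest.update(container="epintlm-seqgen", version=_CONTAINER_VERSION,
                        n=len(self))
        np.savez(path, I_E=self.I_E, I_P=self.I_P, G=self.G, y=self.y,
                 pair_ids=self.pair_ids.astype("U"),
                 manifest=np.frombuffer(json.dumps(manifest).encode(),
                                        dtype=np.uint8))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SeqGenDataset":
        with np.load(Path(path)) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            if manifest.get("container") != "epintlm-seqgen":
                raise ValueError(f"{path} is not a SeqGenDataset container")
            return cls(I_E=z["I_E"], I_P=z["I_P"], G=z["G"], y=z["y"],
                       pair_ids=z["pair_ids"], manifest=manifest)


def build_seqgen_dataset(records: Sequence[PairRecord],
                         vocab: KmerVocabulary | None = None,
                         out_path: str | Path | None = None,
                         genomic_dim: int = 5 * 2 * DEFAULT_N_BINS,
                         manifest: dict | None = None) -> SeqGenDataset:
    """Tokenize, canonicalize and pack records into one container.

    Sequences are forced to the canonical 3000/2000 bp widths first, so
    token rows are rectangular by construction.  Records lacking
    genomic features get zero vectors of ``genomic_dim``.
    """
    vocab = vocab or KmerVocabulary()
    records = list(records)
    if not records:
        raise ValueError("no records to build a dataset from")
    n = len(records)
    I_E = np.empty((n, ENHANCER_LENGTH_BP - vocab.k + 1), dtype=np.int32)
    I_P = np.empty((n, PROMOTER_LENGTH_BP - vocab.k + 1), dtype=np.int32)
    g_dim = genomic_dim
    for r in records:
        if r.genomic_features is not None:
            g_dim = len(r.genomic_features)
            break
    G = np.zeros((n, g_dim), dtype=np.float32)
    y = np.empty(n, dtype=np.int8)
    pair_ids = np.empty(n, dtype=object)
    for i, r in enumerate(records):
        I_E[i] = tokenize(canonicalize_length(r.enhancer_seq, ENHANCER_LENGTH_BP), vocab.k)
        I_P[i] = tokenize(canonicalize_length(r.promoter_seq, PROMOTER_LENGTH_BP), vocab.k)
        if r.genomic_features is not None:
            G[i] = np.asarray(r.genomic_features, dtype=np.float32)
        y[i] = r.label
        pair_ids[i] = r.pair_id
    ds = SeqGenDataset(I_E=I_E, I_P=I_P, G=G, y=y,
                       pair_ids=pair_ids.astype("U"),
                       manifest=dict(manifest or {}, k=vocab.k,
                                     vocab_size=vocab.size))
    if out_path is not None:
        ds.save(out_path)
    return ds


# -- readers ---------------------------------------------------------------

def read_pairs_table(path: str | Path) -> list[PairRecord]:
    """Read a tabular pair list (TSV or CSV by extension) with columns
    ``enhancer_seq``, ``promoter_seq``, ``label``, ``pair_id`` and
    optionally ``cell_line``."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"pair_id": str})
    required = {"enhancer_seq", "promoter_seq", "label", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    cell = df["cell_line"] if "cell_line" in df.columns else [""] * len(df)
    return [PairRecord(pair_id=str(p), enhancer_seq=str(e), promoter_seq=str(q),
                       label=int(l), cell_line=str(c))
            for p, e, q, l, c in zip(df["pair_id"], df["enhancer_seq"],
                                     df["promoter_seq"], df["label"], cell)]


def write_pairs_table(records: Iterable[PairRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([{"pair_id": r.pair_id, "enhancer_seq": r.enhancer_seq,
                        "promoter_seq": r.promoter_seq, "label": r.label,
                        "cell_line": r.cell_line} for r in records])
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED intervals (0-based half-open) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a bedGraph signal into dense per-base arrays keyed by chromosome."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    tracks: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        length = int(sub["end"].max())
        arr = np.zeros(length, dtype=np.float64)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[int(s):int(e)] = v
        tracks[str(chrom)] = arr
    return tracks


def load_bigwig_window(path: str | Path, region: tuple[str, int, int]) -> np.ndarray:
    """Per-base signal over a window of a BigWig file (requires pyBigWig)."""
    import pyBigWig  # optional dependency
    chrom, start, end = region
    with pyBigWig.open(str(path)) as bw:
        vals = bw.values(chrom, start, end)
    return np.nan_to_num(np.asarray(vals, dtype=np.float64))
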