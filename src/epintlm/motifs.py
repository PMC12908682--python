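"""Motif extraction from enhancer-to-promoter cross-attention.

For each positive sample the enhancer-to-promoter attention map is
reduced to one score per pooled promoter position (mean over heads, sum
over enhancer query positions).  Pooled positions are then mapped back
to base-pair coordinates through the composed receptive field of the
convolution (kernel 40), the max pooling (kernel 20) and the k-mer
width (6): pooled position ``j`` covers promoter bases
``[20j, 20j + 64)``, clipped to the promoter.  Because adjacent
receptive fields overlap by 44 bp, scores are spread uniformly over
their bp intervals and accumulated into a bp-resolution relevance
profile; the reported 12-bp window is the one maximizing total
relevance (ties broken toward the relevance centroid, then leftmost).
Windows are exported as FASTA plus a minimal MEME-format position
frequency matrix ready for TOMTOM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Width of reported motif windows in bp.
MOTIF_WIDTH = 12

_BASE_ORDER = "ACGT"


@dataclass
class AttentionProfile:
    """Per-pooled-promoter-position attention score for one sample."""

    scores: np.ndarray
    sample_id: str
    aggregation: str = "head_mean/query_sum"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1 or (self.scores < -1e-9).any():
            raise ValueError("profile must be a 1-D nonnegative vector")


@dataclass
class MotifWindow:
    """A reported promoter subsequence with its relevance score."""

    sequence: str
    start_bp: int
    score: float
    sample_id: str


def promoter_attention_profile(attn_map: np.ndarray, sample: int,
                               sample_id: str | None = None,
                               head_agg: str = "mean",
                               query_agg: str = "sum") -> AttentionProfile:
    """Reduce an enhancer-to-promoter attention map to a promoter profile.

    Parameters
    ----------
    attn_map
        Per-head weights with shape (H, B, L_q, L_k) — the
        ``enh_to_pro`` map, queries over enhancer positions, keys over
        pooled promoter positions.
    sample
        Batch index.
    head_agg, query_agg
        ``mean`` or ``max`` over heads; ``sum`` or ``max`` over enhancer
        query positions.
    """
    attn_map = np.asarray(attn_map)
    if attn_map.ndim != 4:
        raise ValueError("expected an (H, B, L_q, L_k) attention map")
    w = attn_map[:, sample, :, :]           # (H, L_q, L_k)
    w = w.mean(axis=0) if head_agg == "mean" else w.max(axis=0)
    scores = w.sum(axis=0) if query_agg == "sum" else w.max(axis=0)
    return AttentionProfile(scores=scores,
                            sample_id=sample_id or str(sample),
                            aggregation=f"head_{head_agg}/query_{query_agg}")


def pooled_to_bp(pooled_index: int, promoter_len_bp: int = 2000,
                 pool_kernel: int = 20, conv_kernel: int = 40,
                 k: int = 6) -> tuple[int, int]:
    """Receptive field of a pooled position, as a bp interval [start, end).

    Pooled position j covers conv positions [Pj, Pj+P-1]; conv position
    i covers tokens [i, i+K-1]; token t covers bases [t, t+k-1] — so j
    maps to [Pj, Pj + P + K + k - 2), clipped to the promoter (width 64
    at the canonical P=20, K=40, k=6).  The final pooled position
    absorbs the tail the floored pooling drops, extending to the
    promoter end so every base is covered by at least one interval.
    """
    n_pooled = (promoter_len_bp - k + 1 - conv_kernel + 1) // pool_kernel
    if not 0 <= pooled_index < n_pooled:
        raise IndexError(f"pooled index {pooled_index} outside [0, {n_pooled})")
    start = pool_kernel * pooled_index
    if pooled_index == n_pooled - 1:
        return start, promoter_len_bp
    end = start + pool_kernel + conv_kernel + k - 2
    return start, min(end, promoter_len_bp)


def bp_relevance(profile: AttentionProfile, promoter_len_bp: int = 2000,
                 **field_kwargs) -> np.ndarray:
    """Spread each pooled score uniformly over its receptive field and
    accumulate into a per-bp relevance vector."""
    rel = np.zeros(promoter_len_bp, dtype=np.float64)
    for j, s in enumerate(profile.scores):
        lo, hi = pooled_to_bp(j, promoter_len_bp, **field_kwargs)
        rel[lo:hi] += s / (hi - lo)
    return rel


def extract_motif_windows(profile: AttentionProfile, promoter_seq: str,
                          width: int = MOTIF_WIDTH, top_n: int = 1) -> list[MotifWindow]:
    """The ``top_n`` non-overlapping width-bp windows by summed bp relevance.

    Deterministic: ties go to the window whose center is nearest the
    relevance centroid, then leftmost.
    """
    L = len(promoter_seq)
    if width > L:
        raise ValueError(f"window width {width} exceeds promoter length {L}")
    rel = bp_relevance(profile, promoter_len_bp=L)
    window_scores = np.convolve(rel, np.ones(width), mode="valid")
    total = rel.sum()
    centroid = float((np.arange(L) * rel).sum() / total) if total > 0 else (L - 1) / 2.0

    taken = np.zeros(len(window_scores), dtype=bool)
    out: list[MotifWindow] = []
    for _ in range(top_n):
        avail = np.flatnonzero(~taken)
        if avail.size == 0:
            break
        best_score = window_scores[avail].max()
        cands = avail[np.isclose(window_scores[avail], best_score, rtol=0, atol=1e-12)]
        centers = cands + (width - 1) / 2.0
        cands = cands[np.abs(centers - centroid)
                      == np.abs(centers - centroid).min()]
        start = int(cands.min())
        out.append(MotifWindow(sequence=promoter_seq[start:start + width],
                               start_bp=start, score=float(window_scores[start]),
                               sample_id=profile.sample_id))
        lo, hi = max(0, start - width + 1), min(len(taken), start + width)
        taken[lo:hi] = True
    out.sort(key=lambda w: -w.score)
    return out


# -- export ----------------------------------------------------------------

def position_frequency_matrix(windows: Sequence[MotifWindow],
                              pseudocount: float = 0.25) -> np.ndarray:
    """Column-normalized PFM (width x 4, column order ACGT) from aligned
    windows, with a per-base pseudocount.  Ambiguous bases contribute
    only pseudocount mass."""
    if not windows:
        raise ValueError("need at least one window")
    width = len(windows[0].sequence)
    counts = np.full((width, 4), pseudocount, dtype=np.float64)
    for w in windows:
        if len(w.sequence) != width:
            raise ValueError("windows must share one width")
        for i, ch in enumerate(w.sequence.upper()):
            j = _BASE_ORDER.find(ch)
            if j >= 0:
                counts[i, j] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def write_motif_outputs(windows: Sequence[MotifWindow], out_dir: str | Path,
                        motif_name: str = "attended_promoter_motif") -> dict[str, Path]:
    """Write windows.fasta, windows.tsv and motifs.meme under ``out_dir``."""
    windows = list(windows)
    if not windows:
        raise ValueError("no motif windows to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fasta = out_dir / "windows.fasta"
    with open(fasta, "w") as fh:
        for i, w in enumerate(windows):
            fh.write(f">{w.sample_id}|start={w.start_bp}|score={w.score:.6g}\n")
            fh.write(w.sequence + "\n")

    tsv = out_dir / "windows.tsv"
    with open(tsv, "w") as fh:
        fh.write("sample_id\tstart_bp\tscore\tsequence\n")
        for w in windows:
            fh.write(f"{w.sample_id}\t{w.start_bp}\t{w.score:.6g}\t{w.sequence}\n")

    pfm = position_frequency_matrix(windows)
    meme = out_dir / "motifs.meme"
    with open(meme, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {motif_name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pfm.shape[0]} "
                 f"nsites= {len(windows)} E= 0\n")
        for row in pfm:
            fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
    return {"fasta": fasta, "tsv": tsv, "meme": meme}


def read_meme(path: str | Path) -> dict[str, np.ndarray]:
    """Strict reader for the minimal MEME motif format written above.

    Returns motif name -> (width x 4) probability matrix; validates the
    header, alphabet and per-column normalization.
    """
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, 1))
    motifs: dict[str, np.ndarray] = {}

    def err(lineno, msg):
        raise ValueError(f"{path}:{lineno}: {msg}")

    first = next(it, None)
    if first is None or not first[1].startswith("MEME version"):
        err(1, "missing 'MEME version' header")
    saw_alphabet = False
    for lineno, line in it:
        line = line.strip()
        if not line or line.startswith(("strands:", "Background", "A ")):
            if line.startswith("A "):
                parts = line.split()
                if len(parts) != 8:
                    err(lineno, "malformed background frequencies")
            continue
        if line.startswith("ALPHABET="):
            if line.split("=", 1)[1].strip() != "ACGT":
                err(lineno, "alphabet must be ACGT")
            saw_alphabet = True
            continue
        if line.startswith("MOTIF"):
            name = line.split(maxsplit=1)[1].strip()
            lineno2, header = next(it)
            if not header.strip().startswith("letter-probability matrix:"):
                err(lineno2, "expected letter-probability matrix header")
            fields = dict(zip(header.split()[2::2], header.split()[3::2]))
            width = int(fields["w="]) if "w=" in fields else None
            if width is None:
                err(lineno2, "matrix header missing w=")
            rows = []
            for _ in range(width):
                lineno3, row = next(it)
                vals = [float(v) for v in row.split()]
                if len(vals) != 4:
                    err(lineno3, "matrix row must have 4 probabilities")
                if abs(sum(vals) - 1.0) > 1e-6:
                    err(lineno3, f"matrix row sums to {sum(vals)}, not 1")
                rows.append(vals)
            motifs[name] = np.array(rows)
            continue
        err(lineno, f"unexpected line: {line!r}")
    if not saw_alphabet:
        raise ValueError(f"{path}: missing ALPHABET declaration")
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


# -- end-to-end helper -----------------------------------------------------

def extract_motifs_from_model(model, dataset, threshold: float = 0.5,
                              top_n: int = 1, batch_size: int = 64,
                              use_true_positives: bool = True,
                              head_agg: str = "mean", query_agg: str = "sum",
                              promoter_seqs: dict[str, str] | None = None,
                              ) -> list[MotifWindow]:
    """Run the model over a dataset and extract promoter motif windows
    for positive samples.

    "Positive samples" defaults to true-positive predictions (label 1
    and score >= ``threshold``); with ``use_true_positives=False`` all
    labeled positives are used regardless of the prediction.
    ``promoter_seqs`` maps pair_id to the promoter sequence; when absent
    the sequence is reconstructed from tokens (exact for unambiguous
    bases).
    """
    from .nn import no_grad
    from .tokenization import decode_kmer

    model.eval()
    out: list[MotifWindow] = []
    pos_idx = np.flatnonzero(np.asarray(dataset.y) == 1)
    with no_grad():
        for lo in range(0, len(pos_idx), batch_size):
            chunk = pos_idx[lo:lo + batch_size]
            probs, maps = model(dataset.I_E[chunk], dataset.I_P[chunk],
                                dataset.G[chunk], return_attention=True)
            for b, i in enumerate(chunk):
                if use_true_positives and probs.data[b] < threshold:
                    continue
                pid = str(dataset.pair_ids[i])
                profile = promoter_attention_profile(
                    maps["enh_to_pro"], b, sample_id=pid,
                    head_agg=head_agg, query_agg=query_agg)
                if promoter_seqs is not None and pid in promoter_seqs:
                    pseq = promoter_seqs[pid]
                else:
                    pseq = _sequence_from_tokens(dataset.I_P[i], decode_kmer)
                out.extend(extract_motif_windows(profile, pseq, top_n=top_n))
    return out


def _sequence_from_tokens(tokens: np.ndarray, decode) -> str:
    k = 6
    special = 4 ** k
    chars = []
    for t in tokens:
        chars.append("N" if t >= special else decode(int(t), k)[0])
    last = int(tokens[-1])
    chars.append("N" * (k - 1) if last >= special else decode(last, k)[1:])
    return "".join(chars)
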