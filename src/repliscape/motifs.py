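"""Position-weight-matrix motif scanning (log-odds, both strands).

Motifs are read from MEME minimal format (via Biopython's parser) and
converted to background-relative log-odds; scanning reports every
position on either strand whose summed log-odds meets the threshold.
FIMO-style p-values are out of scope: the threshold is on the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = ["PWM", "read_meme", "pwm_scan"]

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space


@dataclass
class PWM:
    """Log-odds scoring matrix over ACGT.

    ``log_odds`` has one row per motif position; scores are log2 of the
    motif probability (pseudocounted) over the background probability.
    """

    name: str
    log_odds: np.ndarray  # (length, 4)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must be (length, 4)")
        if not np.isfinite(self.log_odds).all():
            raise ValueError("log_odds must be finite")

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_probabilities(
        cls, name: str, probs: np.ndarray, *,
        background: np.ndarray | None = None, pseudo: float = 1e-3
    ) -> "PWM":
        probs = np.asarray(probs, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = probs + pseudo
        p /= p.sum(axis=1, keepdims=True)
        return cls(name=name, log_odds=np.log2(p / bg))


def read_meme(path) -> list[PWM]:
    """Read MEME minimal format into log-odds PWMs."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        probs = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in ALPHABET])
        bg = None
        if m.background:
            bg = np.array([m.background[b] for b in ALPHABET], dtype=float)
        out.append(PWM.from_probabilities(m.name or m.base_id or "motif", probs,
                                          background=bg))
    return out


def _encode_fast(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(len(arr), -1, dtype=int)
    for b, i in _IDX.items():
        code[arr == ord(b)] = i
    return code


def _scan_one_strand(code: np.ndarray, lo: np.ndarray, threshold: float):
    L = lo.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        c = code[j : j + n]
        ok = c >= 0
        valid &= ok
        scores += np.where(ok, lo[j, np.clip(c, 0, 3)], 0.0)
    hits = np.flatnonzero(valid & (scores >= threshold))
    return hits, scores[hits]


def pwm_scan(
    sequences: dict[str, str], pwm: PWM, threshold: float
) -> pd.DataFrame:
    """Scan sequences on both strands for log-odds scores >= threshold.

    Returns a DataFrame with ``chrom, start, end, score, strand``
    (0-based half-open forward-strand coordinates; a minus-strand hit at
    [start, end) means the motif matches the reverse complement there).
    Sequences shorter than the motif yield no hits with a warning.
    """
    L = len(pwm)
    rc_lo = pwm.log_odds[::-1][:, _COMPLEMENT]
    rows = []
    for name, seq in sequences.items():
        if len(seq) < L:
            warnings.warn(f"sequence {name!r} shorter than motif", stacklevel=2)
            continue
        code = _encode_fast(seq)
        for strand, lo in (("+", pwm.log_odds), ("-", rc_lo)):
            hits, scores = _scan_one_strand(code, lo, threshold)
            for h, s in zip(hits, scores):
                rows.append({"chrom": name, "start": int(h), "end": int(h + L),
                             "score": float(s), "strand": strand})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "strand"])
    return df.sort_values(["chrom", "start", "strand"], ignore_index=True)
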