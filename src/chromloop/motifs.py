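"""Position-weight-matrix scanning for CTCF-like motifs.

Scores are sums of per-position log2 likelihood ratios against a background
base composition (FIMO-style log-odds). A motif is considered present when
its best score exceeds a strict threshold (10 by default downstream, matching
the commonly used FIMO cutoff for the CTCF matrix). Windows containing ``N``
are disqualified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# CTCF-like core consensus used by the synthetic genome generator. 16 bp,
# contains a CpG, contains no GATC on either strand (so planted motifs never
# collide with planted restriction sites).
CTCF_CONSENSUS = "CCACCAGGGGGCGCTA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds PWM with explicit background frequencies."""

    probs: np.ndarray  # (width, 4) base probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be (width, 4) with width >= 1")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive")
        if np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be positive and sum to 1")
        object.__setattr__(self, "probs", probs / probs.sum(axis=1, keepdims=True))
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def information_content(self) -> float:
        """Total information content in bits (uniform-background formula)."""
        p = self.probs
        return float(np.sum(p * np.log2(p / self.background)))

    @classmethod
    def from_consensus(cls, consensus: str, match_prob: float = 0.85,
                       background: np.ndarray | None = None) -> "PositionWeightMatrix":
        """Single-consensus PWM: the consensus base gets ``match_prob``, the
        remaining probability is split evenly over the other three bases."""
        if not (0.25 < match_prob < 1.0):
            raise ValueError("match_prob must be in (0.25, 1)")
        probs = np.full((len(consensus), 4), (1 - match_prob) / 3)
        for i, base in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[base]] = match_prob
        bg = np.full(4, 0.25) if background is None else background
        return cls(probs, bg)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(self.probs[::-1, ::-1].copy(),
                                    self.background[::-1].copy())


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    score: float
    contains_cpg: bool

    @property
    def strand(self) -> str:
        return self.interval.strand


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N get -inf."""
    w = log_odds.shape[0]
    n_win = encoded.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    lo = np.hstack([log_odds, np.full((w, 1), -np.inf)])  # column 4 = N
    scores = np.zeros(n_win)
    for j in range(w):
        scores += lo[j, encoded[j : j + n_win]]
    return scores


def scan_pwm(sequence: str, pwm: PositionWeightMatrix, threshold: float,
             chrom: str = "seq", offset: int = 0) -> list[MotifHit]:
    """Scan both strands; report every window whose score strictly exceeds
    ``threshold``, in coordinate order (+ before - at the same position).

    ``offset`` shifts reported coordinates (use when scanning a slice of a
    chromosome). ``contains_cpg`` flags a CG dinucleotide in the matched
    genomic (forward-strand) subsequence.
    """
    w = pwm.width
    if len(sequence) < w:
        return []
    enc = encode(sequence)
    hits: list[tuple[int, int, float]] = []  # (pos, strand_rank, score)
    fwd = _window_scores(enc, pwm.log_odds)
    rev = _window_scores(enc, pwm.reverse_complement().log_odds)
    for pos in np.nonzero(fwd > threshold)[0]:
        hits.append((int(pos), 0, float(fwd[pos])))
    for pos in np.nonzero(rev > threshold)[0]:
        hits.append((int(pos), 1, float(rev[pos])))
    hits.sort()
    out = []
    for pos, srank, score in hits:
        sub = sequence[pos : pos + w].upper()
        out.append(
            MotifHit(
                GenomicInterval(chrom, offset + pos, offset + pos + w,
                                "+" if srank == 0 else "-"),
                score,
                "CG" in sub,
            )
        )
    return out


def best_hit(sequence: str, pwm: PositionWeightMatrix, threshold: float,
             chrom: str = "seq", offset: int = 0) -> MotifHit | None:
    """Best-scoring hit above threshold (ties: leftmost, then + strand)."""
    hits = scan_pwm(sequence, pwm, threshold, chrom=chrom, offset=offset)
    if not hits:
        return None
    return max(hits, key=lambda h: (h.score, -h.interval.start, h.strand == "+"))
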