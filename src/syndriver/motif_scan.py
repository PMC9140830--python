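"""FIMO-style PWM scanning of transcript sequences with exact p-values.

RNA-binding proteins recognise short (3-7 nt) sequence motifs described by
position probability matrices.  This module scores every window of a
transcript against a motif's log-odds matrix and assigns each window an
*exact* p-value: the tail probability of its score under the background
(i.i.d. letters drawn from the background composition), computed by dynamic
programming over the discretized score distribution — the same device FIMO
uses.  Variants can then be intersected with significant motif occurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_LUT = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

#: default pseudocount, as a fraction of the background probability (FIMO convention)
DEFAULT_PSEUDOCOUNT = 0.1
#: default score discretization step, in bits
DEFAULT_GRANULARITY = 1e-3
#: FIMO's default output threshold
DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class MotifPWM:
    """A position probability matrix over (A, C, G, T).

    ``probs`` has one row per motif position; each row sums to 1.
    ``background`` is the letter composition the scores are contrasted
    against.  ``pseudocount`` is the mass (as a fraction of background)
    mixed into each row before taking log-odds, preventing -inf scores.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(
                f"motif {self.motif_id!r}: probability matrix must be (width, 4)"
            )
        if np.any(probs < 0):
            raise ValueError(f"motif {self.motif_id!r}: negative probabilities")
        row_sums = probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError(
                f"motif {self.motif_id!r}: matrix rows must sum to 1 "
                f"(max deviation {np.max(np.abs(row_sums - 1.0)):.3g})"
            )
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError(f"motif {self.motif_id!r}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Highest-probability letter at each position (ties -> first in ACGT)."""
        return "".join(ALPHABET[j] for j in np.argmax(self.probs, axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One significant motif occurrence on a transcript.

    ``start``/``end`` are 1-based, fully closed coordinates on the scanned
    sequence (so ``end - start + 1 == width``), regardless of strand.
    """

    motif_id: str
    transcript: str
    start: int
    end: int
    strand: str  # "sense" | "antisense"
    score: float  # log-odds, bits
    pvalue: float
    matched_sequence: str


def log_odds_matrix(pwm: MotifPWM) -> np.ndarray:
    """Smoothed log2 odds matrix of a PWM against its background.

    Each probability is smoothed as ``(p + c*bg) / (1 + c)`` with
    ``c = pwm.pseudocount`` before taking ``log2(p' / bg)``, so a motif row
    identical to the background scores exactly 0 and no entry is -inf for
    positive pseudocount.
    """
    bg = pwm.background
    if np.any(bg <= 0):
        raise ValueError(f"motif {pwm.motif_id!r}: background entries must be > 0")
    c = pwm.pseudocount
    smoothed = (pwm.probs + c * bg[np.newaxis, :]) / (1.0 + c)
    with np.errstate(divide="ignore"):
        return np.log2(smoothed / bg[np.newaxis, :])


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the discretized window score under background.

    Scores are discretized to integer multiples of ``granularity`` bits.
    ``tail[i]`` is P(S >= offset + i) for the integer score ``offset + i``.
    """

    granularity: float
    scaled: np.ndarray  # (width, 4) integer matrix
    offset: int  # minimum achievable integer score
    tail: np.ndarray

    def pvalue(self, scaled_score: int) -> float:
        i = scaled_score - self.offset
        if i < 0:
            return 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])


def score_pvalues(
    lom: np.ndarray,
    background: np.ndarray,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreDistribution:
    """Exact tail probabilities of the discretized PWM score by DP.

    Convolves, position by position, the distribution of the rounded
    per-position scores of a random background letter.  Total probability
    mass is conserved to within 1e-9.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    lom = np.asarray(lom, dtype=float)
    if not np.all(np.isfinite(lom)):
        raise ValueError("log-odds matrix must be finite")
    scaled = np.rint(lom / granularity).astype(np.int64)
    offset = int(scaled.min(axis=1).sum())
    top = int(scaled.max(axis=1).sum())
    size = top - offset + 1
    pdf = np.zeros(size)
    pdf[0] = 1.0  # relative to current minimum sum
    cur_min = 0
    for row in scaled:
        row_min = int(row.min())
        new = np.zeros(size)
        for letter, s in enumerate(row):
            shift = int(s) - row_min
            new[shift:] += background[letter] * pdf[: size - shift if shift else size]
        pdf = new
        cur_min += row_min
    # cur_min == offset by construction
    tail = np.cumsum(pdf[::-1])[::-1]
    if abs(tail[0] - 1.0) > 1e-9:
        raise AssertionError("score distribution mass not conserved")
    return ScoreDistribution(granularity=granularity, scaled=scaled, offset=offset, tail=tail)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3; other letters -> -1."""
    return _LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return mat[::-1, ::-1]


def scan_transcript(
    sequence: str,
    pwm: MotifPWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    strands: str = "sense_only",
    transcript_id: str = "",
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """All motif occurrences with exact p-value below ``p_threshold``.

    Every window of length ``pwm.width`` is scored (windows containing
    non-ACGT letters are skipped).  ``strands`` is ``sense_only`` (RBPs bind
    the mRNA itself) or ``both`` (FIMO's DNA default; antisense windows are
    scored against the reverse-complemented matrix, coordinates staying on
    the given sequence).  Hits are sorted by (start, motif_id, strand).
    """
    if strands not in ("sense_only", "both"):
        raise ValueError(f"unknown strands mode {strands!r}")
    w = pwm.width
    seq = sequence.upper().replace("U", "T")
    if len(seq) < w:
        return []
    codes = encode_sequence(seq)
    lom = log_odds_matrix(pwm)
    matrices = [("sense", lom)]
    if strands == "both":
        matrices.append(("antisense", _revcomp_matrix(lom)))
    n_win = len(seq) - w + 1
    bad = codes < 0
    clipped = np.where(bad, 0, codes)
    # window validity: no non-ACGT letter inside
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[w:] - bad_cum[:-w]) == 0
    hits: list[MotifHit] = []
    for strand, mat in matrices:
        dist = score_pvalues(mat, pwm.background, granularity)
        scores = np.zeros(n_win, dtype=np.int64)
        for i in range(w):
            scores += dist.scaled[i, clipped[i : i + n_win]]
        idx = np.clip(scores - dist.offset, 0, len(dist.tail) - 1)
        pvals = dist.tail[idx]
        for start0 in np.nonzero(valid & (pvals < p_threshold))[0]:
            s = int(scores[start0])
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    transcript=transcript_id,
                    start=int(start0) + 1,
                    end=int(start0) + w,
                    strand=strand,
                    score=s * granularity,
                    pvalue=dist.pvalue(s),
                    matched_sequence=seq[start0 : start0 + w],
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_id, h.strand))
    return hits


def scan_transcripts(
    sequences: dict[str, str],
    motifs: list[MotifPWM],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    strands: str = "sense_only",
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan every motif against every transcript; hits sorted per transcript."""
    hits: list[MotifHit] = []
    for tx_id in sequences:
        per_tx: list[MotifHit] = []
        for pwm in motifs:
            per_tx.extend(
                scan_transcript(
                    sequences[tx_id], pwm, p_threshold, strands, tx_id, granularity
                )
            )
        per_tx.sort(key=lambda h: (h.start, h.motif_id, h.strand))
        hits.extend(per_tx)
    return hits


def variant_motif_overlap(variants, hits: list[MotifHit]):
    """Intersect variant transcript positions with motif occurrences.

    Returns ``{(chrom, pos, ref, alt, transcript): (flag, motif_ids)}`` where
    ``flag`` is True iff some hit on the same transcript covers the variant's
    ``tx_pos`` (closed interval), and ``motif_ids`` lists the overlapping
    motifs sorted.  Variants without ``tx_pos`` get ``(None, [])`` and are
    counted in the log.
    """
    by_tx: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_tx.setdefault(h.transcript, []).append(h)
    out = {}
    n_indeterminate = 0
    for v in variants:
        key = (v.chrom, v.pos, v.ref, v.alt, v.transcript)
        if v.tx_pos is None:
            n_indeterminate += 1
            out[key] = (None, [])
            continue
        ids = sorted(
            {
                h.motif_id
                for h in by_tx.get(v.transcript, [])
                if h.start <= v.tx_pos <= h.end
            }
        )
        out[key] = (bool(ids), ids)
    if n_indeterminate:
        logger.warning(
            "variant_motif_overlap: %d variants lack tx_pos (indeterminate)",
            n_indeterminate,
        )
    return out
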