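"""Position-specific scoring matrix for the 17-bp sigma54 -24/-12 element.

The sigma54 binding site is a bipartite promoter element: a GG dinucleotide
around the -24 position and a TGC core around -12, separated by a spacer of
low information content.  Within the 17-mer used here the strongly
constrained ("important") columns are 3, 4, 14, 15 and 16 (1-based) and the
low-information ("unimportant") columns are 1, 8, 9, 10 and 12.

Scores are log2 odds against a background base distribution (uniform by
default), summed over the 17 columns.  The scale therefore differs from
scores printed under other PSSM conventions; agreement with such scores is
by rank, not by value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import GenomeRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MOTIF_WIDTH = 17
MOTIF_CENTER_OFFSET = 8  # center = 9th base of the 17-mer (0-based offset 8)
IMPORTANT_POSITIONS = frozenset({3, 4, 14, 15, 16})  # 1-based
UNIMPORTANT_POSITIONS = frozenset({1, 8, 9, 10, 12})


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; N (or any other base) to 4."""
    return np.array([_BASE_INDEX.get(c, 4) for c in seq], dtype=np.int8)


@dataclass
class PSSM:
    """17 x 4 log2-odds matrix with base order A, C, G, T."""

    log_odds: np.ndarray
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float
    n_sites: int

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        # argmax per column; numpy argmax takes the leftmost on ties,
        # which in base order A,C,G,T is the documented tie-break
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def to_meme(self, name: str = "sigma54") -> str:
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "strands: + -",
            "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, self.background)),
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} nsites= {self.n_sites}",
        ]
        for row in self.probs:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring 17-mer in a scanned window."""

    position: int  # top-strand coordinate of the motif center
    strand: str
    score: float
    sequence: str  # as read on the hit strand
    ambiguous: bool = False  # True if an N contributed a zero term


def build_pssm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
) -> PSSM:
    """Build a log2-odds PSSM from the per-column nucleotide frequencies of
    aligned, equal-length binding-site sequences."""
    if not aligned_sites:
        raise ValueError("need at least one aligned site")
    width = len(aligned_sites[0])
    counts = np.zeros((width, 4))
    for seq in aligned_sites:
        if len(seq) != width:
            raise ValueError(f"length mismatch: expected {width}, got {len(seq)}")
        enc = encode(seq.upper())
        if np.any(enc > 3):
            raise ValueError(f"non-ACGT base in {seq!r}")
        counts[np.arange(width), enc] += 1
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    n = len(aligned_sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / background)
    return PSSM(log_odds=log_odds, probs=probs, background=background,
                pseudocount=pseudocount, n_sites=n)


def score_sequence(pssm: PSSM, seq: str) -> float:
    """Sum of per-column log-odds.  N bases contribute zero (with the
    ``ambiguous`` flag surfaced by :func:`score_sequence_checked`)."""
    score, _ = score_sequence_checked(pssm, seq)
    return score


def score_sequence_checked(pssm: PSSM, seq: str) -> tuple[float, bool]:
    if len(seq) != pssm.width:
        raise ValueError(f"sequence length {len(seq)} != PSSM width {pssm.width}")
    enc = encode(seq.upper())
    ambiguous = bool(np.any(enc > 3))
    ok = enc <= 3
    score = float(pssm.log_odds[np.flatnonzero(ok), enc[ok]].sum())
    return score, ambiguous


def _rc_log_odds(pssm: PSSM) -> np.ndarray:
    """Matrix scoring the reverse-complement motif directly on the top strand."""
    return pssm.log_odds[::-1, ::-1]


def _window_scores(
    pssm: PSSM, genome: GenomeRecord, center: int, halfwidth: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score every motif center in [center-halfwidth, center+halfwidth] on
    both strands.  Returns (centers, plus_scores, minus_scores); N bases
    contribute 0 to the score."""
    n = len(genome)
    lo = center - halfwidth - MOTIF_CENTER_OFFSET
    hi = center + halfwidth + MOTIF_CENTER_OFFSET
    if hi - lo + 1 < MOTIF_WIDTH:
        raise ValueError("window smaller than motif width")
    if not genome.circular and (lo < 1 or hi > n):
        lo, hi = max(lo, 1), min(hi, n)
    seq = genome.fetch(lo, hi)
    enc = encode(seq)
    m = len(enc) - MOTIF_WIDTH + 1
    if m < 1:
        raise ValueError("window smaller than motif width")
    # sliding 17-mer view
    windows = np.lib.stride_tricks.sliding_window_view(enc, MOTIF_WIDTH)
    lo_plus = np.vstack([pssm.log_odds, np.zeros((1, 4))])  # row 4 = N -> 0
    lo_minus = np.vstack([_rc_log_odds(pssm), np.zeros((1, 4))])
    cols = np.arange(MOTIF_WIDTH)
    idx = np.clip(windows, 0, 4)  # windows hold 0..4 (4 = N)
    plus = lo_plus[cols[None, :], idx].sum(axis=1)
    minus = lo_minus[cols[None, :], idx].sum(axis=1)
    centers = lo + MOTIF_CENTER_OFFSET + np.arange(m)
    if genome.circular:
        centers = (centers - 1) % n + 1
    mask = np.abs(_signed_offset(centers, center, n, genome.circular)) <= halfwidth
    return centers[mask], plus[mask], minus[mask]


def _signed_offset(positions: np.ndarray, center: int, n: int, circular: bool) -> np.ndarray:
    d = positions.astype(int) - center
    if circular:
        d = (d + n // 2) % n - n // 2
    return d


def scan_window(
    pssm: PSSM, genome: GenomeRecord, center: int, halfwidth: int
) -> MotifHit:
    """Best motif hit whose center lies within ``halfwidth`` of ``center``.

    Both strands are evaluated; ties prefer the smaller top-strand
    coordinate, then the + strand.
    """
    centers, plus, minus = _window_scores(pssm, genome, center, halfwidth)
    best_pos, best_strand, best_score = None, None, -np.inf
    for strand, scores in (("+", plus), ("-", minus)):
        for i in np.flatnonzero(scores == scores.max()):
            s, pos = float(scores[i]), int(centers[i])
            better = s > best_score or (
                s == best_score
                and (pos < best_pos or (pos == best_pos and strand == "+"))
            )
            if better:
                best_pos, best_strand, best_score = pos, strand, s
    top = genome.fetch(best_pos - MOTIF_CENTER_OFFSET, best_pos + MOTIF_CENTER_OFFSET)
    seq = top if best_strand == "+" else reverse_complement(top)
    return MotifHit(position=best_pos, strand=best_strand, score=best_score,
                    sequence=seq, ambiguous="N" in top)


def associate_peaks(
    peaks,
    genome: GenomeRecord,
    pssm: PSSM,
    halfwidth: int = 75,
    min_score: float = 6.5,
) -> list[tuple]:
    """Attach the best in-window motif hit to each peak if it scores at least
    ``min_score``; peaks without a qualifying hit get ``None``.

    The default threshold sits just below the lowest score of the packaged
    reference sites under the packaged PSSM, mirroring how the peak-set
    threshold was originally anchored to the weakest genuine site.
    """
    out = []
    for peak in peaks:
        hit = scan_window(pssm, genome, peak.center, halfwidth)
        out.append((peak, hit if hit is not None and hit.score >= min_score else None))
    return out


def central_enrichment(
    offsets: Sequence[int], bin_width: int = 10, halfrange: int = 75
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of motif-center minus peak-center offsets, and a one-sided
    binomial tail probability that the central three bins are enriched
    relative to a uniform placement of motifs across all bins.

    Returns (bin_edges, densities, p_central).  Offsets outside the range are
    dropped from the histogram and the test.
    """
    offsets = np.asarray(list(offsets), dtype=float)
    if offsets.size == 0:
        raise ValueError("no offsets supplied")
    edges = np.arange(-halfrange, halfrange + bin_width, bin_width, dtype=float)
    inside = offsets[(offsets >= -halfrange) & (offsets <= halfrange)]
    if inside.size == 0:
        raise ValueError("no offsets within the scanned range")
    counts, _ = np.histogram(inside, bins=edges)
    n_bins = len(counts)
    densities = counts / counts.sum() / bin_width
    mid = n_bins // 2
    central = int(counts[mid - 1 : mid + 2].sum())
    n = int(counts.sum())
    p = float(stats.binom.sf(central - 1, n, 3.0 / n_bins))
    return edges, densities, p
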