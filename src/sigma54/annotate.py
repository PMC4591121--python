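"""Classification of binding sites against a gene annotation, predicted
transcription start sites, and the positional / orientation statistics.

Site classes
------------
OS  intergenic, oriented toward the adjacent downstream gene (sense)
OA  intergenic, oriented away from the adjacent gene (antisense)
IS  inside a gene, same strand as the gene
IA  inside a gene, opposite strand

"Intragenic" means the motif center lies within [start, end] of a gene,
boundaries inclusive.  The predicted TSS is 19 bp downstream of the motif
center on the motif strand.  The distance of a site to its target is
measured from the TSS to the strand-aware start of the nearest same-strand
gene downstream; for intragenic sites the overlapping gene is excluded.
A gene whose start lies upstream of the TSS is never "available", even if
its body overlaps the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import Gene, GeneAnnotation

TSS_OFFSET = 19  # bp downstream of the motif center


@dataclass
class ClassifiedSite:
    motif_center: int
    motif_strand: str
    site_class: str  # OS / OA / IS / IA
    tss: int
    overlapping_gene: Optional[Gene]
    downstream_gene: Optional[Gene]
    distance: Optional[int]
    ambiguous_overlap: bool = False

    @property
    def intragenic(self) -> bool:
        return self.site_class in ("IS", "IA")


def predict_tss(motif_center: int, strand: str, genome_length: Optional[int] = None) -> int:
    """TSS = motif center + 19 bp in the direction of the motif (circular)."""
    if strand == "+":
        tss = motif_center + TSS_OFFSET
    elif strand == "-":
        tss = motif_center - TSS_OFFSET
    else:
        raise ValueError(f"bad strand {strand!r}")
    if genome_length is not None:
        tss = (tss - 1) % genome_length + 1
    return tss


def _downstream_distance(
    pos: int, strand: str, starts: np.ndarray, genome_length: int
) -> Optional[int]:
    """Distance from ``pos`` to the nearest strand-aware gene start at or
    downstream of ``pos`` on ``strand``; circular wrap; None if no starts."""
    if starts.size == 0:
        return None
    if strand == "+":
        d = (starts - pos) % genome_length
    else:
        d = (pos - starts) % genome_length
    return int(d.min())


class _Index:
    """Sorted lookup structures for one annotation."""

    def __init__(self, annotation: GeneAnnotation, genome_length: int):
        self.genome_length = genome_length
        self.genes = list(annotation)
        self.starts = np.array([g.start for g in self.genes], dtype=int)
        self.ends = np.array([g.end for g in self.genes], dtype=int)
        self.strands = np.array([g.strand for g in self.genes])
        self.coding_starts = {
            "+": np.array([g.coding_start for g in self.genes if g.strand == "+"], dtype=int),
            "-": np.array([g.coding_start for g in self.genes if g.strand == "-"], dtype=int),
        }
        self.gene_by_strand = {
            "+": [g for g in self.genes if g.strand == "+"],
            "-": [g for g in self.genes if g.strand == "-"],
        }


def classify_site(
    motif_center: int,
    strand: str,
    annotation: GeneAnnotation,
    genome_length: int,
    _index: Optional[_Index] = None,
) -> ClassifiedSite:
    """Classify one site and compute its predicted TSS, target gene and distance."""
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    idx = _index or _Index(annotation, genome_length)
    inside = (idx.starts <= motif_center) & (motif_center <= idx.ends)
    containing = [idx.genes[i] for i in np.flatnonzero(inside)]
    tss = predict_tss(motif_center, strand, genome_length)

    overlapping: Optional[Gene] = None
    ambiguous = False
    if containing:
        overlapping = min(containing, key=lambda g: (g.start, g.end))
        ambiguous = len(containing) > 1
        cls = "IS" if overlapping.strand == strand else "IA"
    else:
        # intergenic: orientation relative to the next annotated gene
        # encountered moving downstream from the site
        nxt = _next_gene_downstream(motif_center, strand, idx)
        cls = "OS" if (nxt is not None and nxt.strand == strand) else "OA"

    genes_s = idx.gene_by_strand[strand]
    starts = idx.coding_starts[strand]
    keep = np.ones(len(genes_s), dtype=bool)
    if overlapping is not None and overlapping.strand == strand:
        for i, g in enumerate(genes_s):  # exclude the host gene by identity
            if g is overlapping:
                keep[i] = False
                break
    dist = None
    downstream = None
    if keep.any():
        if strand == "+":
            d = (starts[keep] - tss) % genome_length
        else:
            d = (tss - starts[keep]) % genome_length
        j = int(np.argmin(d))
        dist = int(d[j])
        downstream = [g for g, k in zip(genes_s, keep) if k][j]
    return ClassifiedSite(
        motif_center=motif_center,
        motif_strand=strand,
        site_class=cls,
        tss=tss,
        overlapping_gene=overlapping,
        downstream_gene=downstream,
        distance=dist,
        ambiguous_overlap=ambiguous,
    )


def _next_gene_downstream(pos: int, strand: str, idx: _Index) -> Optional[Gene]:
    """First gene record (any strand) whose nearest boundary is encountered
    moving downstream from ``pos`` in the direction of ``strand``."""
    if not idx.genes:
        return None
    n = idx.genome_length
    if strand == "+":
        d = (idx.starts - pos) % n
    else:
        d = (pos - idx.ends) % n
    return idx.genes[int(np.argmin(d))]


def classify_sites(
    centers: Sequence[int],
    strands: Sequence[str],
    annotation: GeneAnnotation,
    genome_length: int,
) -> list[ClassifiedSite]:
    idx = _Index(annotation, genome_length)
    return [
        classify_site(c, s, annotation, genome_length, _index=idx)
        for c, s in zip(centers, strands)
    ]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def orientation_bias_test(n_sense: int, n_total: int) -> float:
    """One-sided exact binomial tail P(X >= n_sense | n_total, 1/2)."""
    if n_total == 0:
        raise ValueError("no sites to test")
    if not 0 <= n_sense <= n_total:
        raise ValueError("n_sense out of range")
    return float(stats.binom.sf(n_sense - 1, n_total, 0.5))


def interval_enrichment(
    distances: Sequence[int],
    lo: int = 360,
    hi: int = 760,
    background_fraction: Optional[float] = None,
) -> tuple[float, Optional[float], Optional[float]]:
    """Fraction of distances inside [lo, hi], the background fraction, and
    their ratio (None when no background is supplied)."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances supplied")
    observed = float(((d >= lo) & (d <= hi)).mean())
    ratio = None
    if background_fraction is not None and background_fraction > 0:
        ratio = observed / background_fraction
    return observed, background_fraction, ratio


def genome_background_fraction(
    annotation: GeneAnnotation,
    genome_length: int,
    lo: int,
    hi: int,
    intragenic_only: bool = False,
) -> float:
    """Fraction of genome coordinates whose distance to the next available
    same-strand gene start falls within [lo, hi], averaged over the two
    orientation conventions.  Computed exhaustively over every position.
    """
    positions = np.arange(1, genome_length + 1)
    if intragenic_only:
        mask = annotation.coding_mask(genome_length)
        positions = positions[mask]
        if positions.size == 0:
            return 0.0
    fracs = []
    for strand in "+-":
        starts = np.sort(
            np.array([g.coding_start for g in annotation if g.strand == strand], dtype=int)
        )
        if starts.size == 0:
            continue  # no genes on this strand: the convention is undefined
        if strand == "+":
            j = np.searchsorted(starts, positions, side="left")
            nxt = starts[j % len(starts)]
            d = (nxt - positions) % genome_length
        else:
            j = np.searchsorted(starts, positions, side="right") - 1
            nxt = starts[j % len(starts)]
            d = (positions - nxt) % genome_length
        fracs.append(float(((d >= lo) & (d <= hi)).mean()))
    if not fracs:
        return 0.0
    return float(np.mean(fracs))


def cumulative_distance_curve(
    classified: Sequence[ClassifiedSite],
    annotation: GeneAnnotation,
    genome_length: int,
    n_random: int = 4000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Sorted distance arrays (empirical CDF supports) for intergenic,
    intragenic and all sites, plus ``n_random`` seeded random positions with
    random orientation."""
    if not classified:
        raise ValueError("no sites supplied")
    inter = np.sort([s.distance for s in classified if not s.intragenic and s.distance is not None])
    intra = np.sort([s.distance for s in classified if s.intragenic and s.distance is not None])
    all_d = np.sort([s.distance for s in classified if s.distance is not None])
    rng = np.random.default_rng(seed)
    pos = rng.integers(1, genome_length + 1, size=n_random)
    strands = np.where(rng.random(n_random) < 0.5, "+", "-")
    idx = _Index(annotation, genome_length)
    rand = []
    for p, s in zip(pos, strands):
        starts = idx.coding_starts[s]
        d = _downstream_distance(int(p), s, starts, genome_length)
        if d is not None:
            rand.append(d)
    return {
        "intergenic": inter.astype(float),
        "intragenic": intra.astype(float),
        "all": all_d.astype(float),
        "random": np.sort(np.array(rand, dtype=float)),
    }


def spearman_fat_vs_score(
    fats: Sequence[float], scores: Sequence[float]
) -> float:
    """Spearman rank correlation between ChIP enrichment (FAT) and motif score."""
    fats = np.asarray(list(fats), dtype=float)
    scores = np.asarray(list(scores), dtype=float)
    if fats.size < 3:
        raise ValueError("need at least 3 sites")
    if np.all(fats == fats[0]) or np.all(scores == scores[0]):
        raise ValueError("correlation undefined for a constant column")
    rho = stats.spearmanr(fats, scores).statistic
    return float(rho)
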