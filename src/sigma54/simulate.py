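"""Synthetic genomes, annotations, planted binding sites, ChIP/RNAP
coverage and diverged ortholog genomes with known anchors.

The generator emulates an E. coli-like chromosome: ~88% coding density on
a circular, 1-based coordinate system; 135 planted 17-bp sites split
42/8/58/27 across the OS/OA/IS/IA classes; a roughly two-thirds sense bias
among intragenic sites; intragenic site-to-gene-start distances enriched
in a 360-760 bp band; bimodal ChIP enrichment around each site; and
symmetric RNAP footprints centered on the motif.  Ortholog genomes diverge
by substitutions only (coordinates preserved), with an optional relaxation
of the substitution rate at constrained motif positions.

Every stage draws from its own RNG stream seeded from ``config.seed`` plus
a stage offset, so stages can be re-run independently and everything is a
pure function of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnchorRecord, CoverageTrack, Gene, GeneAnnotation, GenomeRecord, reverse_complement
from .motif import BASES, MOTIF_CENTER_OFFSET, PSSM

_STAGE_GENOME = 1
_STAGE_SITES = 2
_STAGE_COVERAGE = 3
_STAGE_ORTHOLOG = 4


class PlacementError(RuntimeError):
    """Raised when sites cannot be placed without overlap."""


@dataclass
class DistanceMix:
    """Intragenic TSS-to-gene-start distance distribution: a uniform band
    (the empirically enriched 360-760 bp range) mixed with a broad uniform
    background."""

    band_lo: int = 360
    band_hi: int = 760
    band_weight: float = 0.365
    max_distance: int = 2000


@dataclass
class SimConfig:
    genome_length: int = 2_000_000
    coding_fraction: float = 0.88
    n_sites: int = 135
    class_proportions: tuple = (42 / 135, 8 / 135, 58 / 135, 27 / 135)  # OS, OA, IS, IA
    sense_bias: float = 58 / 85  # P(sense | intragenic)
    tss_distance_mix: DistanceMix = field(default_factory=DistanceMix)
    read_depth: float = 50.0
    peak_height: float = 1.8  # unit-strength site peaks near the calling threshold
    peak_halfwidth: int = 100
    mean_gene_length: int = 950
    min_site_separation: int = 1500
    fragment_length: int = 100  # sequenced-fragment span; makes coverage locally correlated
    min_site_score: float = 6.7  # weakest genuine site's PSSM score; see plant_sites
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0.0 < self.coding_fraction <= 0.99:
            raise ValueError("coding_fraction must be in (0, 0.99]")
        if self.genome_length <= 10 * self.peak_halfwidth:
            raise ValueError("genome too short for the configured peak width")
        if self.read_depth <= 0 or self.peak_height <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass(frozen=True)
class PlantedSite:
    site_id: str
    position: int  # motif center, top strand
    strand: str
    site_class: str
    sequence: str  # 17-mer as read on the motif strand
    host_gene: str  # empty for intergenic sites
    downstream_gene: str
    distance: int  # TSS to downstream strand-aware gene start; -1 if none


def truth_frame(truth: list[PlantedSite]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth])


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def generate_genome(config: SimConfig) -> tuple[GenomeRecord, GeneAnnotation]:
    """I.i.d. uniform background sequence with non-overlapping genes tiled
    to approximate the requested coding fraction."""
    rng = np.random.default_rng(config.seed + _STAGE_GENOME)
    n = config.genome_length
    seq_codes = rng.integers(0, 4, size=n)
    sequence = "".join(BASES[c] for c in seq_codes)

    f = config.coding_fraction
    mean_gap = max(20.0, config.mean_gene_length * (1 - f) / f)
    if config.mean_gene_length + mean_gap > n:
        raise ValueError("coding_fraction infeasible for this genome length")
    genes = []
    pos = 1 + int(rng.exponential(mean_gap))
    i = 0
    while True:
        length = int(np.clip(rng.normal(config.mean_gene_length, 200), 300, None))
        if pos + length - 1 > n:
            break
        i += 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"g{i:04d}", f"b{i:04d}", pos, pos + length - 1, strand))
        pos += length + max(1, int(rng.exponential(mean_gap)))
    if not genes:
        raise ValueError("coding_fraction infeasible for this genome length")
    return GenomeRecord("sim", sequence), GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------


def _sample_motif(pwm: PSSM, rng: np.random.Generator,
                  min_score: float = -np.inf, max_tries: int = 100) -> str:
    """Sample a site sequence column-wise from the motif model.

    Independent-column sampling occasionally emits sequences weaker than any
    site observed in vivo (real sites are under selection for binding, which
    correlates columns).  Rejection at ``min_score`` truncates the sampled
    distribution at the weakest genuine site's score; after ``max_tries``
    draws the last sample is accepted so degenerate motif models still work.
    """
    from .motif import score_sequence

    for _ in range(max_tries):
        cols = [rng.choice(4, p=pwm.probs[i] / pwm.probs[i].sum()) for i in range(pwm.width)]
        seq = "".join(BASES[c] for c in cols)
        if score_sequence(pwm, seq) >= min_score:
            return seq
    return seq


def _write_motif(seq_list: list, center: int, strand: str, motif: str) -> None:
    top = motif if strand == "+" else reverse_complement(motif)
    start = center - MOTIF_CENTER_OFFSET - 1  # 0-based
    seq_list[start : start + len(top)] = list(top)


def _next_start_downstream(pos: int, strand: str, starts: np.ndarray, n: int) -> int:
    if strand == "+":
        return int(((starts - pos) % n).min())
    return int(((pos - starts) % n).min())


def plant_sites(
    genome: GenomeRecord,
    annotation: GeneAnnotation,
    pwm: PSSM,
    config: SimConfig,
    max_tries: int = 500,
) -> tuple[GenomeRecord, list[PlantedSite]]:
    """Write ``config.n_sites`` motif instances into the genome.

    Classes are drawn from ``class_proportions`` (intragenic sense with
    probability ``sense_bias``); intragenic placement aims for a
    TSS-to-next-gene-start distance drawn from ``tss_distance_mix``,
    falling back to a uniform position inside the host gene when the local
    gene layout cannot realize the drawn distance.
    """
    if pwm.width != 17:
        raise ValueError("motif model must have 17 positions")
    rng = np.random.default_rng(config.seed + _STAGE_SITES)
    n = config.genome_length
    seq = list(genome.sequence)
    genes = list(annotation)
    p_os, p_oa, p_is, p_ia = config.class_proportions
    p_intra = p_is + p_ia
    starts_by_strand = {
        s: np.array([g.coding_start for g in genes if g.strand == s], dtype=int)
        for s in "+-"
    }
    gaps = []  # (gap_start, gap_end, left_gene, right_gene), linear interior gaps
    for left, right in zip(genes[:-1], genes[1:]):
        if right.start - left.end - 1 >= 60:
            gaps.append((left.end + 1, right.start - 1, left, right))
    if not gaps:
        raise PlacementError("no intergenic gaps wide enough for planting")
    big_genes = [g for g in genes if g.end - g.start + 1 >= 200]
    if not big_genes:
        raise PlacementError("no genes long enough for intragenic planting")

    planted: list[PlantedSite] = []
    taken: list[int] = []
    counters = {"OS": 0, "OA": 0, "IS": 0, "IA": 0}

    def far_enough(center: int) -> bool:
        return all(abs(center - t) >= config.min_site_separation for t in taken)

    for _ in range(config.n_sites):
        intragenic = rng.random() < p_intra
        if intragenic:
            cls = "IS" if rng.random() < config.sense_bias else "IA"
        else:
            cls = "OS" if rng.random() < p_os / (p_os + p_oa) else "OA"
        placed = False
        for _try in range(max_tries):
            if intragenic:
                host = big_genes[rng.integers(len(big_genes))]
                strand = host.strand if cls == "IS" else ("-" if host.strand == "+" else "+")
                mix = config.tss_distance_mix
                if rng.random() < mix.band_weight:
                    d = int(rng.integers(mix.band_lo, mix.band_hi + 1))
                else:
                    d = int(rng.integers(0, mix.max_distance + 1))
                others = starts_by_strand[strand]
                others = others[others != (host.coding_start if host.strand == strand else -1)]
                if others.size == 0:
                    continue
                # center such that TSS + d hits the nearest same-strand start
                if strand == "+":
                    target_d = _next_start_downstream(host.start, "+", others, n)
                    target = (host.start + target_d - 1) % n + 1
                    tss = (target - 1 - d) % n + 1
                    center = (tss - 1 - 19) % n + 1
                else:
                    target_d = _next_start_downstream(host.end, "-", others, n)
                    target = (host.end - target_d - 1) % n + 1
                    tss = (target - 1 + d) % n + 1
                    center = (tss - 1 + 19) % n + 1
                if not (host.start + MOTIF_CENTER_OFFSET <= center <= host.end - MOTIF_CENTER_OFFSET):
                    if _try < max_tries // 2:
                        continue  # try another gene / distance draw first
                    # local gene layout cannot realize the drawn distance:
                    # fall back to a uniform interior position
                    center = int(rng.integers(host.start + MOTIF_CENTER_OFFSET,
                                              host.end - MOTIF_CENTER_OFFSET + 1))
                if not far_enough(center):
                    continue
                host_gene = host
                placed = True
                break
            else:
                gs, ge, left, right = gaps[rng.integers(len(gaps))]
                if ge - gs < 2 * MOTIF_CENTER_OFFSET + 2:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                adjacent = right if strand == "+" else left
                is_os = adjacent.strand == strand
                if is_os != (cls == "OS"):
                    continue
                center = int(rng.integers(gs + MOTIF_CENTER_OFFSET, ge - MOTIF_CENTER_OFFSET + 1))
                if not far_enough(center):
                    continue
                host_gene = None
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {cls} site after {max_tries} tries; "
                "genome too small or too crowded"
            )
        motif = _sample_motif(pwm, rng, min_score=config.min_site_score)
        _write_motif(seq, center, strand, motif)
        taken.append(center)
        counters[cls] += 1
        # truth distance: simple direct scan, strand-aware, excluding the host
        tss = (center - 1 + (19 if strand == "+" else -19)) % n + 1
        starts = starts_by_strand[strand]
        if host_gene is not None and host_gene.strand == strand:
            starts = starts[starts != host_gene.coding_start]
        if starts.size:
            dist = _next_start_downstream(tss, strand, starts, n)
            target = (tss - 1 + (dist if strand == "+" else -dist)) % n + 1
            dn = next((g.gene_id for g in genes
                       if g.strand == strand and g.coding_start == target), "")
        else:
            dist, dn = -1, ""
        planted.append(
            PlantedSite(
                site_id=f"{cls}{counters[cls]:02d}",
                position=center,
                strand=strand,
                site_class=cls,
                sequence=motif,
                host_gene=host_gene.gene_id if host_gene is not None else "",
                downstream_gene=dn,
                distance=dist,
            )
        )
    return GenomeRecord(genome.id, "".join(seq)), planted


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


def _add_gaussian(lam: np.ndarray, center: int, amplitude: float, sigma: float) -> None:
    n = len(lam)
    reach = int(4 * sigma)
    idx = np.arange(center - 1 - reach, center - 1 + reach + 1) % n
    x = np.arange(-reach, reach + 1, dtype=float)
    lam[idx] += amplitude * np.exp(-0.5 * (x / sigma) ** 2)


def _pileup(lam: np.ndarray, frag: int, rng: np.random.Generator) -> np.ndarray:
    """Fragment-pileup coverage: Poisson fragment starts at rate lam/frag per
    base, each fragment covering ``frag`` bases (circular).  The marginal
    mean and variance equal ``lam`` but neighboring positions are correlated,
    as in real short-read coverage."""
    if frag <= 1:
        return rng.poisson(lam).astype(float)
    # a fragment starting at s covers [s, s+frag-1]; drawing its rate from
    # the enrichment at the fragment CENTER keeps the pileup centered on lam
    starts = rng.poisson(np.roll(lam, -(frag // 2)) / frag).astype(float)
    ext = np.concatenate([starts[-(frag - 1):], starts])
    return np.convolve(ext, np.ones(frag), mode="valid")


def simulate_chip_coverage(
    genome: GenomeRecord,
    truth: list[PlantedSite],
    config: SimConfig,
) -> tuple[CoverageTrack, CoverageTrack, CoverageTrack, CoverageTrack, np.ndarray]:
    """Simulated coverage tracks: sigma factor ChIP (two-lobed enrichment at
    each site), RNAP ChIP per strand (symmetric footprint), and an input
    control with no planted enrichment.

    Per-site strength factors are log-uniform over [1, 200], mimicking the
    wide dynamic range of real peak enrichment.  Returns (sigma, rnap_plus,
    rnap_minus, input, strengths); an empty truth list yields pure
    background noise tracks.
    """
    rng = np.random.default_rng(config.seed + _STAGE_COVERAGE)
    n = len(genome)
    depth = config.read_depth
    strengths = np.exp(rng.uniform(np.log(1.0), np.log(200.0), size=len(truth)))
    lam_sigma = np.full(n, depth)
    lam_plus = np.full(n, depth)
    lam_minus = np.full(n, depth)
    lobe_sigma = config.peak_halfwidth / 2.0
    lobe_off = config.peak_halfwidth // 2
    for site, strength in zip(truth, strengths):
        amp = config.peak_height * depth * strength / 2.0  # per lobe
        # bimodal: strand-offset lobes flanking the binding site
        _add_gaussian(lam_sigma, site.position - lobe_off, amp, lobe_sigma)
        _add_gaussian(lam_sigma, site.position + lobe_off, amp, lobe_sigma)
        # symmetric RNAP footprint, both strands alike
        rnap_amp = 5.0 * depth
        _add_gaussian(lam_plus, site.position, rnap_amp, lobe_sigma)
        _add_gaussian(lam_minus, site.position, rnap_amp, lobe_sigma)
    frag = config.fragment_length
    sigma = CoverageTrack(genome.id, _pileup(lam_sigma, frag, rng))
    plus = CoverageTrack(genome.id, _pileup(lam_plus, frag, rng), strand="+")
    minus = CoverageTrack(genome.id, _pileup(lam_minus, frag, rng), strand="-")
    ctrl = CoverageTrack(genome.id, _pileup(np.full(n, depth), frag, rng))
    return sigma, plus, minus, ctrl, strengths


def simulate_background_track(config: SimConfig, seed_offset: int = 0) -> CoverageTrack:
    """Pure Poisson noise track (no planted enrichment)."""
    rng = np.random.default_rng(config.seed + _STAGE_COVERAGE + seed_offset)
    return CoverageTrack("sim", rng.poisson(
        np.full(config.genome_length, config.read_depth)).astype(float))


# ---------------------------------------------------------------------------
# ortholog divergence
# ---------------------------------------------------------------------------


def mutate_ortholog(
    genome: GenomeRecord,
    truth: list[PlantedSite],
    divergence_per_bp: float,
    constrained_positions=frozenset(),
    seed: int = 0,
    relaxation: float = 0.1,
    species: str = "ortholog",
) -> tuple[GenomeRecord, list[AnchorRecord]]:
    """Neutral substitutions at ``divergence_per_bp``, with constrained motif
    positions (1-based within the 17-mer) mutating at the relaxed rate
    ``divergence_per_bp * relaxation``.  Coordinates are preserved, so the
    returned anchors map every site to its own position.
    """
    if not 0.0 <= divergence_per_bp < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(seed + _STAGE_ORTHOLOG)
    n = len(genome)
    rate = np.full(n, divergence_per_bp)
    for site in truth:
        for p in constrained_positions:
            if site.strand == "+":
                top = site.position - (MOTIF_CENTER_OFFSET + 1) + p
            else:
                top = site.position + (MOTIF_CENTER_OFFSET + 1) - p
            rate[(top - 1) % n] = divergence_per_bp * relaxation
    mutate = rng.random(n) < rate
    shifts = rng.integers(1, 4, size=int(mutate.sum()))
    codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}.get(c, 0) for c in genome.sequence],
                     dtype=np.int8)
    codes[mutate] = (codes[mutate] + shifts) % 4
    new_seq = "".join(BASES[c] for c in codes)
    # N bases (never produced by the simulator) would be overwritten above;
    # the generator emits pure ACGT genomes so this is safe.
    anchors = [
        AnchorRecord(site.site_id, species, site.position, site.strand, 1e-30, None)
        for site in truth
    ]
    return GenomeRecord(f"{genome.id}|{species}", new_seq, circular=genome.circular), anchors
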