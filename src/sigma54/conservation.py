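"""Cross-species conservation of binding sites.

Each E. coli site is mapped into a query genome through a homology anchor
(a BLAST-style hit, or the naive matcher for simulated orthologs).  The
motif is then re-scored at the exact anchored coordinate and re-scanned
100 bp up- and downstream on both strands; the best score in the window
measures whether a recognizable site survives near the homologous position.

The substitution statistic contrasts the per-position substitution rate at
the strongly constrained motif columns (3, 4, 14, 15, 16) with the rate at
the low-information columns (1, 8, 9, 10, 12), over (site, species) pairs
whose homolog is perfectly aligned (best hit at offset 0) and still a
strong site.  Important columns where the E. coli base itself deviates
from the consensus are excluded from the count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AnchorRecord, GenomeRecord, SiteRecord, reverse_complement
from .motif import (
    IMPORTANT_POSITIONS,
    MOTIF_CENTER_OFFSET,
    PSSM,
    UNIMPORTANT_POSITIONS,
    score_sequence,
    scan_window,
)


@dataclass
class ConservationCell:
    site_id: str
    species: str
    exact_score: Optional[float]
    best_score: Optional[float]
    best_offset: Optional[int]
    best_strand: Optional[str]
    homolog_found: bool
    exact_sequence: Optional[str] = None  # 17-mer at offset 0, mapped strand


@dataclass
class SubstitutionTally:
    important_substitutions: int = 0
    important_examined: int = 0
    unimportant_substitutions: int = 0
    unimportant_examined: int = 0
    n_pairs: int = 0
    n_skipped: int = 0  # pairs without a usable homolog 17-mer

    def __post_init__(self):
        if self.important_substitutions > self.important_examined:
            raise ValueError("substitutions exceed examined positions")
        if self.unimportant_substitutions > self.unimportant_examined:
            raise ValueError("substitutions exceed examined positions")


def _motif_at(genome: GenomeRecord, center: int, strand: str) -> str:
    top = genome.fetch(center - MOTIF_CENTER_OFFSET, center + MOTIF_CENTER_OFFSET)
    return top if strand == "+" else reverse_complement(top)


def conservation_scan(
    site: SiteRecord,
    query_genome: GenomeRecord,
    anchor: Optional[AnchorRecord],
    pssm: PSSM,
    window: int = 100,
) -> ConservationCell:
    """Re-score the site at its anchored coordinate and within +/-window bp."""
    species = anchor.species if anchor is not None else ""
    if anchor is None or not anchor.found:
        return ConservationCell(site.site_id, species, None, None, None, None, False)
    pos, strand = anchor.mapped_position, anchor.mapped_strand
    n = len(query_genome)
    if not query_genome.circular:
        margin = MOTIF_CENTER_OFFSET
        if pos - margin < 1 or pos + margin > n:
            # clip to what the linear contig allows
            pos = min(max(pos, 1 + margin), n - margin)
    seq = _motif_at(query_genome, pos, strand)
    exact = score_sequence(pssm, seq)
    hit = scan_window(pssm, query_genome, pos, window)
    offset = hit.position - pos
    if query_genome.circular:
        offset = (offset + n // 2) % n - n // 2
    # prefer the anchored coordinate itself when it ties the window best,
    # so "perfectly aligned" (offset 0) is detected whenever it holds
    if hit.score > exact:
        best_score, best_offset, best_strand = float(hit.score), int(offset), hit.strand
    else:
        best_score, best_offset, best_strand = exact, 0, strand
    return ConservationCell(
        site_id=site.site_id,
        species=species,
        exact_score=exact,
        best_score=best_score,
        best_offset=best_offset,
        best_strand=best_strand,
        homolog_found=True,
        exact_sequence=seq,
    )


def build_matrix(
    sites: Sequence[SiteRecord],
    species_genomes: dict[str, GenomeRecord],
    anchors: Sequence[AnchorRecord],
    pssm: PSSM,
    window: int = 100,
) -> pd.DataFrame:
    """Site x species table of best window scores ("NA" = no homolog).

    Rows are ordered by site class (OS, OA, IS, IA) then id, matching the
    canonical / non-canonical split used for display.
    """
    by_key: dict[tuple[str, str], AnchorRecord] = {}
    for a in anchors:
        key = (a.site_id, a.species)
        if key in by_key:
            raise ValueError(f"duplicate anchor for {key}")
        by_key[key] = a
    class_order = {"OS": 0, "OA": 1, "IS": 2, "IA": 3}
    ordered = sorted(sites, key=lambda s: (class_order[s.site_class], s.site_id))
    species = list(species_genomes)
    data = {}
    for sp in species:
        col = []
        for s in ordered:
            cell = conservation_scan(s, species_genomes[sp], by_key.get((s.site_id, sp)), pssm, window)
            col.append(cell.best_score if cell.homolog_found else np.nan)
        data[sp] = col
    return pd.DataFrame(data, index=[s.site_id for s in ordered])


def substitution_stats(
    ecoli_motifs: dict[str, str],
    cells: Sequence[ConservationCell],
    pssm: PSSM,
    min_score: float = 6.0,
) -> SubstitutionTally:
    """Count base substitutions at important vs unimportant motif positions.

    A (site, homolog) pair qualifies when the homolog was found, its best
    hit is perfectly aligned (offset 0) and scores above ``min_score``.
    Important positions where the E. coli base does not match the consensus
    are excluded from the examined count.
    """
    consensus = pssm.consensus
    tally = SubstitutionTally()
    for cell in cells:
        if not cell.homolog_found or cell.exact_sequence is None:
            tally.n_skipped += 1
            continue
        if cell.best_offset != 0 or cell.best_score is None or cell.best_score <= min_score:
            continue
        eco = ecoli_motifs.get(cell.site_id)
        if eco is None:
            tally.n_skipped += 1
            continue
        hom = cell.exact_sequence
        tally.n_pairs += 1
        for p in sorted(IMPORTANT_POSITIONS):
            if eco[p - 1] != consensus[p - 1]:
                continue  # E. coli itself deviates: position not informative
            tally.important_examined += 1
            if hom[p - 1] != eco[p - 1]:
                tally.important_substitutions += 1
        for p in sorted(UNIMPORTANT_POSITIONS):
            tally.unimportant_examined += 1
            if hom[p - 1] != eco[p - 1]:
                tally.unimportant_substitutions += 1
    return tally


def fold_ratio(tally: SubstitutionTally) -> float:
    """(unimportant substitution rate) / (important substitution rate).

    Returns ``inf`` when no substitutions were seen at important positions.
    """
    if tally.important_examined == 0 or tally.unimportant_examined == 0:
        raise ValueError("no examined positions")
    unimp = tally.unimportant_substitutions / tally.unimportant_examined
    if tally.important_substitutions == 0:
        return float("inf")
    imp = tally.important_substitutions / tally.important_examined
    return unimp / imp


# ---------------------------------------------------------------------------
# naive anchoring for substitution-only orthologs
# ---------------------------------------------------------------------------


def anchor_from_alignment(
    site: SiteRecord,
    ecoli_genome: GenomeRecord,
    query_genome: GenomeRecord,
    species: str = "query",
    mode: str = "naive",
    fragment: int = 300,
    seed_length: int = 20,
    min_identity: float = 0.6,
) -> AnchorRecord:
    """Locate the homologous coordinate of a site in a query genome.

    ``naive`` mode assumes a substitution-only ortholog (coordinates
    preserved up to the substitutions): exact ``seed_length``-mers from the
    300-nt fragment centered on the motif are searched in the query, each
    candidate placement is extended to the full fragment and scored by
    Hamming identity, and the best placement above ``min_identity`` wins.
    """
    if mode != "naive":
        raise ValueError("only 'naive' mode is computed here; BLAST anchors are read from file")
    c = site.motif_center
    half = fragment // 2
    frag = ecoli_genome.fetch(c - half, c + half - 1)  # length == fragment
    q = query_genome.sequence
    best_pos, best_ident = None, -1.0
    for off in range(0, fragment - seed_length + 1, seed_length // 2):
        seed = frag[off : off + seed_length]
        start = 0
        while True:
            j = q.find(seed, start)
            if j < 0:
                break
            start = j + 1
            # fragment start in query (0-based)
            fs = j - off
            if fs < 0 or fs + fragment > len(q):
                continue
            cand = q[fs : fs + fragment]
            ident = sum(a == b for a, b in zip(cand, frag)) / fragment
            if ident > best_ident:
                best_ident = ident
                best_pos = fs + half + 1  # 1-based motif center
    if best_pos is None or best_ident < min_identity:
        return AnchorRecord(site.site_id, species, None, site.motif_strand, None, None)
    return AnchorRecord(
        site.site_id, species, int(best_pos), site.motif_strand, None, float(best_ident)
    )


def plot_heatmap(matrix: pd.DataFrame, path, vmax: Optional[float] = None) -> None:
    """Convenience heatmap of the conservation matrix (TSV stays canonical)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * matrix.shape[1] + 2),
                                    max(4, 0.08 * matrix.shape[0] + 1)))
    data = matrix.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0.0, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="best PSSM score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
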