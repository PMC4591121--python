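# sigma54

Genome-wide analysis of σ54 (RpoN) binding sites in bacteria.

σ54 is the archetypal member of the second bacterial sigma-factor family.
Unlike σ70-family factors, RNAP:σ54 holoenzyme binds its −24/−12 promoter
element in a transcriptionally inactive state and waits for an ATP-dependent
activator, so ChIP maps of σ54 reveal the full binding-site repertoire
regardless of growth condition.  A striking feature of that repertoire in
*E. coli* is that roughly two thirds of the 135 high-confidence sites lie
**inside** genes, with a strong bias toward the sense strand of the host
gene and toward positions 360–760 bp upstream of the next usable gene
start — the signature of promoters producing mRNAs with very long 5′ UTRs.

This package implements the complete downstream analysis as a tested,
reusable library:

- **peaks** — coverage normalization, trimmed mean + *k*·SD thresholding,
  peak calling and Fold-Above-Threshold (FAT) scoring (FAT = 1 at the
  calling threshold; a 5-fold reduced threshold gives the low-stringency
  peak set).
- **motif** — a 17-column log₂-odds PSSM of the σ54 element
  (consensus `CTGGCACGAATTTTGCA`; the GG/TGC core occupies the strongly
  constrained columns 3, 4 and 14, 15, 16), strand-aware window scanning,
  peak–motif association, and a central-enrichment binomial statistic for
  motif offsets in 10-bp bins over ±75 bp.
- **annotate** — OS/OA/IS/IA site classification against a gene
  annotation, predicted TSS (motif center + 19 bp), distance to the next
  available same-strand gene start, exact binomial orientation-bias test,
  interval enrichment against an exhaustively computed genomic background,
  cumulative distance curves and FAT-vs-score rank correlations.
- **occupancy** — strand-resolved median RNAP occupancy meta-profiles over
  ±500 bp, each site normalized at offset 0, with seeded random-position
  controls.
- **conservation** — anchored ±100 bp PSSM rescans of each site in other
  genomes, site × species conservation matrices, and the
  important-vs-unimportant-position substitution-rate contrast
  (columns {3,4,14,15,16} vs {1,8,9,10,12}).
- **simulate** — a synthetic-data generator (E. coli-like coding density,
  planted motifs, fragment-pileup ChIP coverage, substitution-only
  ortholog genomes with known anchors) so every stage is testable without
  external data.
- **io** — FASTA / GFF3 / BED6 / bedGraph / wiggle / BLAST-tabular readers
  and the packaged transcription of the 135-site reference table.

## Worked example

```python
from sigma54 import io as gio, motif as mot, peaks as pk, annotate as ann, simulate as sim

# the packaged 135-site table and its PSSM
sites = gio.load_site_fixture()
pssm = mot.build_pssm([s.motif for s in sites])
print("consensus:", pssm.consensus)

df = gio.load_site_fixture_frame()
cls = df.site_id.str[:2]
intra = df[cls.isin(['IS', 'IA'])]
print(f"sites: {len(df)}  intragenic: {len(intra)} ({100*len(intra)/len(df):.0f}%)")
p = ann.orientation_bias_test(int((cls == 'IS').sum()), len(intra))
print(f"sense bias among intragenic: {int((cls=='IS').sum())}/{len(intra)}  binomial p = {p:.1e}")

# a full synthetic round trip: plant sites, simulate ChIP, call peaks
cfg = sim.SimConfig(seed=1)
genome, annotation = sim.generate_genome(cfg)
genome, truth = sim.plant_sites(genome, annotation, pssm, cfg)
chip, rnap_p, rnap_m, ctrl, _ = sim.simulate_chip_coverage(genome, truth, cfg)
norm = pk.normalize_coverage(chip)
thr = pk.compute_threshold(norm)
peaks = pk.call_peaks(norm, thr)
print(f"threshold: {thr:.2f}  peaks called: {len(peaks)}  (135 sites planted)")
```

Output:

```
consensus: CTGGCACGAATTTTGCA
sites: 135  intragenic: 85 (63%)
sense bias among intragenic: 58/85  binomial p = 5.1e-04
threshold: 2.33  peaks called: 121  (135 sites planted)
```

The 135-site table splits 42 OS / 8 OA / 58 IS / 27 IA.  The sense bias
among intragenic sites (58/85, 68%) is far from the fair-coin expectation
(exact binomial p ≈ 5×10⁻⁴), and ChIP enrichment correlates with motif
score much more strongly for canonical intergenic-sense sites (Spearman
ρ = 0.67) than for the rest (ρ = 0.38).  On the synthetic genome, 121
peaks are called from 135 planted sites; the misses are sites whose
log-uniform strength factor left them below the calling threshold, which
mirrors how weak genuine sites behave in real data.

A command-line interface wraps the same functions:

```bash
sigma54 stats                      # fixture statistics as JSON
sigma54 sim --out simdata/         # write a synthetic dataset
sigma54 peaks --chip simdata/sigma54.bedgraph --genome-length 2000000 --out peaks.tsv
sigma54 annotate --gff simdata/genes.gff3 --genome-length 2000000 --out classified.tsv
```

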