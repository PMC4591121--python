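"""Strand-resolved median RNAP occupancy meta-profile around binding sites.

Each site contributes a +/-500 bp window of RNAP ChIP coverage, flipped so
that the motif points downstream (for "-" sites the offset axis is reversed
and the strand tracks are swapped), then normalized to its own value at
offset 0.  The reported profile is the per-offset median across sites, so
the median at offset 0 is 1 by construction and every site contributes
equally regardless of its absolute signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CoverageTrack


@dataclass
class MetaProfile:
    offsets: np.ndarray  # -halfwidth .. +halfwidth
    sense: np.ndarray  # median normalized occupancy, motif-sense strand
    antisense: np.ndarray
    n_sites: int  # sites contributing to at least one strand
    n_dropped_sense: int  # zero coverage at offset 0
    n_dropped_antisense: int
    control: bool = False


def _site_windows(
    track_plus: np.ndarray,
    track_minus: np.ndarray,
    center: int,
    strand: str,
    offsets: np.ndarray,
    genome_length: int,
):
    """(sense, antisense) windows in motif orientation for one site."""
    if strand == "+":
        idx = (center - 1 + offsets) % genome_length
        return track_plus[idx], track_minus[idx]
    idx = (center - 1 - offsets) % genome_length
    return track_minus[idx], track_plus[idx]


def median_profile(
    track_plus: CoverageTrack,
    track_minus: CoverageTrack,
    sites,
    halfwidth: int = 500,
    statistic: str = "median",
    control: bool = False,
) -> MetaProfile:
    """Median (or mean, for diagnostics) normalized occupancy per offset.

    ``sites`` is an iterable of (center, strand) pairs or objects carrying
    ``motif_center`` / ``motif_strand``.  A site whose coverage at offset 0
    is zero on a strand is dropped from that strand's profile.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    n = len(track_plus.values)
    if len(track_minus.values) != n:
        raise ValueError("strand tracks differ in length")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    zero = halfwidth  # index of offset 0
    sense_rows, anti_rows = [], []
    dropped_s = dropped_a = 0
    n_sites = 0
    for site in sites:
        if hasattr(site, "motif_center"):
            center, strand = site.motif_center, site.motif_strand
        else:
            center, strand = site
        w_s, w_a = _site_windows(
            track_plus.values, track_minus.values, int(center), strand, offsets, n
        )
        used = False
        if w_s[zero] > 0:
            sense_rows.append(w_s / w_s[zero])
            used = True
        else:
            dropped_s += 1
        if w_a[zero] > 0:
            anti_rows.append(w_a / w_a[zero])
            used = True
        else:
            dropped_a += 1
        if used:
            n_sites += 1
    if not sense_rows and not anti_rows:
        raise ValueError("all sites dropped (zero coverage at offset 0)")
    agg = np.median if statistic == "median" else np.mean
    empty = np.full(offsets.shape, np.nan)
    return MetaProfile(
        offsets=offsets,
        sense=agg(np.array(sense_rows), axis=0) if sense_rows else empty,
        antisense=agg(np.array(anti_rows), axis=0) if anti_rows else empty,
        n_sites=n_sites,
        n_dropped_sense=dropped_s,
        n_dropped_antisense=dropped_a,
        control=control,
    )


def control_profile(
    track_plus: CoverageTrack,
    track_minus: CoverageTrack,
    n: int,
    genome_length: int,
    seed: int = 0,
    halfwidth: int = 500,
) -> MetaProfile:
    """Meta-profile at ``n`` seeded random positions with random orientation."""
    if n < 1:
        raise ValueError("need at least one control position")
    rng = np.random.default_rng(seed)
    centers = rng.integers(1, genome_length + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    sites = list(zip(centers.tolist(), strands.tolist()))
    return median_profile(track_plus, track_minus, sites, halfwidth=halfwidth, control=True)


def profile_to_frame(profile: MetaProfile):
    import pandas as pd

    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "sense": profile.sense,
            "antisense": profile.antisense,
        }
    )


def plot_profile(profiles: dict, path) -> None:
    """Save a simple meta-profile figure (one line per profile and strand)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof.offsets, prof.sense, label=f"{label} sense")
        ax.plot(prof.offsets, prof.antisense, label=f"{label} antisense", ls="--")
    ax.set_xlabel("position relative to motif center (bp)")
    ax.set_ylabel("median occupancy (offset 0 = 1)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
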