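"""Coverage normalization, peak calling and Fold-Above-Threshold scoring.

A peak's FAT score is its maximum normalized coverage divided by the
high-stringency peak-calling threshold, so FAT = 1 exactly at threshold.
Low-stringency calling divides the threshold by 5 but keeps the FAT
denominator at the high threshold, so low-stringency peaks can have
FAT < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CoverageTrack


@dataclass(frozen=True)
class Peak:
    center: int  # 1-based position of the run maximum (leftmost tie)
    fat: float  # max_height / high-stringency threshold
    max_height: float  # normalized depth at the maximum
    span: tuple[int, int]  # 1-based inclusive run boundaries

    @property
    def fat_rounded(self) -> int:
        """FAT as printed: nearest integer, minimum 1."""
        return max(1, int(round(self.fat)))


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Scale a track so its genome-wide mean is exactly 1."""
    total = track.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero coverage track")
    return CoverageTrack(
        genome_id=track.genome_id,
        values=track.values * (len(track.values) / total),
        strand=track.strand,
    )


def input_corrected(
    chip: CoverageTrack,
    control: CoverageTrack,
    smooth_halfwidth: int = 250,
    floor: float = 0.2,
) -> CoverageTrack:
    """ChIP / smoothed-control ratio track (control floored to avoid blow-ups).

    The control track is mean-normalized, smoothed with a centered moving
    average, floored at ``floor`` and divided into the raw ChIP signal.
    """
    if len(chip) != len(control):
        raise ValueError("ChIP and control tracks differ in length")
    from scipy.ndimage import uniform_filter1d

    ctrl = normalize_coverage(control).values
    smoothed = uniform_filter1d(ctrl, size=2 * smooth_halfwidth + 1, mode="wrap")
    smoothed = np.maximum(smoothed, floor)
    return CoverageTrack(chip.genome_id, chip.values / smoothed, chip.strand)


def compute_threshold(
    normalized: CoverageTrack, k_sd: float = 4.0, trim_q: float = 0.99
) -> float:
    """Peak-calling threshold: trimmed mean + ``k_sd`` standard deviations.

    Positions above the ``trim_q`` quantile are excluded from the mean/SD so
    that the peaks themselves (a tiny fraction of the genome) do not inflate
    the background estimate.
    """
    v = normalized.values
    if v.size == 0:
        raise ValueError("empty track")
    cutoff = np.quantile(v, trim_q)
    kept = v[v <= cutoff]
    if kept.size == 0:
        raise ValueError("trimming removed all positions")
    threshold = float(kept.mean() + k_sd * kept.std())
    if threshold <= 0:
        raise ValueError("degenerate threshold <= 0")
    return threshold


def call_peaks(
    normalized: CoverageTrack,
    threshold: float,
    merge_gap: int = 200,
    stringency: str = "high",
) -> list[Peak]:
    """Call maximal runs of positions above the (possibly reduced) threshold.

    ``stringency='low'`` divides the calling threshold by 5; FAT scores are
    always relative to the high-stringency threshold.  Runs separated by
    fewer than ``merge_gap`` bp are merged into one peak.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if stringency not in ("high", "low"):
        raise ValueError(f"unknown stringency {stringency!r}")
    effective = threshold if stringency == "high" else threshold / 5.0
    v = normalized.values
    above = v > effective
    if not above.any():
        return []
    # run boundaries (0-based, half-open)
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    peaks = []
    for s, e in merged:
        seg = v[s:e]
        i = int(np.argmax(seg))  # leftmost maximum
        peaks.append(
            Peak(
                center=s + i + 1,
                fat=float(seg[i] / threshold),
                max_height=float(seg[i]),
                span=(s + 1, e),
            )
        )
    return peaks


def evaluate_recovery(
    peaks: list[Peak], true_positions, tolerance: int = 50
) -> dict:
    """Sensitivity and positional error of called peaks against planted sites.

    A planted site is recovered if any peak center lies within ``tolerance``
    bp.  Returns sensitivity, number recovered, and the median absolute
    positional error of recovered sites.
    """
    true_positions = np.asarray(list(true_positions), dtype=int)
    if true_positions.size == 0:
        return {"sensitivity": float("nan"), "n_recovered": 0,
                "n_true": 0, "median_abs_error": float("nan")}
    centers = np.array([p.center for p in peaks], dtype=int)
    errors = []
    n_rec = 0
    for pos in true_positions:
        if centers.size == 0:
            continue
        err = np.abs(centers - pos).min()
        if err <= tolerance:
            n_rec += 1
            errors.append(err)
    return {
        "sensitivity": n_rec / len(true_positions),
        "n_recovered": n_rec,
        "n_true": int(len(true_positions)),
        "median_abs_error": float(np.median(errors)) if errors else float("nan"),
    }
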