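"""ChIP-seq peak-list utilities: ranking cutoffs, set overlap, motif profiles.

Peaks are rows of a DataFrame with columns chrom, start, end (half-open)
and height (the tag count, BED column 5).  ``rank_and_cut`` keeps either the
top-n peaks or everything above the knee of the log-height-vs-rank curve;
``peak_set_overlap`` reports the per-peak (>=1 bp) overlap fraction in both
directions; ``motif_center_profile`` averages motif-hit counts in distance
bins around peak centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .pwm import PWM, positional_weights, reverse_complement

PEAK_COLUMNS = ["chrom", "start", "end", "height"]


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED peak list; tag height is taken from the score column (5)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 5:
        raise ValueError("peak BED needs at least 5 columns (score = tag height)")
    out = frame.iloc[:, [0, 1, 2, 4]].copy()
    out.columns = PEAK_COLUMNS
    return validate_peaks(out)


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if (peaks["end"] <= peaks["start"]).any():
        raise ValueError("peaks must satisfy end > start")
    if (peaks["height"] < 0).any():
        raise ValueError("peak heights must be non-negative")
    return peaks.reset_index(drop=True)


def rank_and_cut(
    peaks: pd.DataFrame,
    mode: Literal["top_n", "knee"] = "top_n",
    n: int | None = None,
) -> pd.DataFrame:
    """Keep the strongest peaks, by explicit count or by elbow detection.

    ``top_n`` returns the n tallest peaks with ties broken by genomic order,
    so the result is order-invariant and idempotent.  ``knee`` ranks peaks
    by descending height and keeps those above the elbow of the natural-log
    height vs rank curve, located as the point of maximum perpendicular
    distance to the chord joining the curve's endpoints.
    """
    peaks = validate_peaks(peaks)
    ranked = peaks.sort_values(["height", "chrom", "start", "end"],
                               ascending=[False, True, True, True],
                               kind="mergesort").reset_index(drop=True)
    if mode == "top_n":
        if n is None:
            raise ValueError("top_n mode requires n")
        if n > len(ranked):
            raise ValueError(f"requested {n} peaks but only {len(ranked)} available")
        return ranked.head(n).reset_index(drop=True)
    if mode != "knee":
        raise ValueError(f"unknown mode {mode!r}")
    h = ranked["height"].to_numpy(dtype=float)
    if np.ptp(h) == 0:
        raise ValueError(
            "knee detection is degenerate for constant peak heights; "
            "use mode='top_n' with an explicit n instead")
    y = np.log(np.maximum(h, 1e-9))
    x = np.arange(len(y), dtype=float)
    # perpendicular distance from each point to the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    # the chord endpoints have distance 0, so the argmax is interior; peaks
    # strictly above the elbow point are kept
    knee = int(np.argmax(dist))
    return ranked.head(knee).reset_index(drop=True)


@dataclass
class OverlapResult:
    fraction_a_in_b: float
    fraction_b_in_a: float
    matched_pairs: list[tuple[int, int]]   # (row index in a, row index in b)


def peak_set_overlap(a: pd.DataFrame, b: pd.DataFrame,
                     min_reciprocal_fraction: float = 0.0) -> OverlapResult:
    """Fraction of peaks of each set touching (>= 1 bp) a peak of the other.

    The default counts any 1-bp intersection, matching a plain reading of
    peak-set overlap; ``min_reciprocal_fraction`` > 0 additionally requires
    the intersection to cover that fraction of BOTH peaks.
    """
    a = validate_peaks(a)
    b = validate_peaks(b)
    if len(a) == 0:
        raise ValueError("empty peak set a")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in b.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(row.start), int(row.end), int(row.Index))
            for row in sub.itertuples()
        )
    pairs: list[tuple[int, int]] = []
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for row in a.itertuples():
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        for iv in tree.overlap(int(row.start), int(row.end)):
            inter = min(row.end, iv.end) - max(row.start, iv.begin)
            if min_reciprocal_fraction > 0:
                wa = row.end - row.start
                wb = iv.end - iv.begin
                if inter < min_reciprocal_fraction * max(wa, 1) or \
                   inter < min_reciprocal_fraction * max(wb, 1):
                    continue
            pairs.append((int(row.Index), int(iv.data)))
            hit_a.add(int(row.Index))
            hit_b.add(int(iv.data))
    frac_a = len(hit_a) / len(a)
    frac_b = len(hit_b) / len(b) if len(b) else 0.0
    return OverlapResult(frac_a, frac_b, sorted(pairs))


def _scan_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Vectorised forward-strand scores at every offset of a long sequence."""
    from .pwm import _encode

    L = len(pwm)
    enc = _encode(seq)
    m = pwm.effective_matrix
    w = positional_weights(pwm)
    with np.errstate(divide="ignore"):
        logratio = np.log(m / m.max(axis=1, keepdims=True)) * w[:, None]
    logratio = np.where(np.isneginf(logratio) & (w[:, None] == 0), 0.0, logratio)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    total = logratio[np.arange(L)[None, :], windows].sum(axis=1)
    return np.exp(total)


def motif_center_profile(
    peaks: pd.DataFrame,
    pwm: PWM,
    sequences,
    flank: int = 1000,
    bin_size: int = 50,
    score_min: float = 0.8,
) -> pd.DataFrame:
    """Mean motif-hit count per distance bin around peak centers.

    For each peak the window center +/- flank is scanned on both strands; a
    hit is a placement scoring >= ``score_min``, assigned to the bin of its
    motif midpoint relative to the peak center.  ``sequences`` is any object
    with a ``fetch(chrom, start, end)`` method.  Returns a DataFrame with
    bin_center_bp and mean_count columns of length 2*flank/bin_size.
    """
    peaks = validate_peaks(peaks)
    if len(peaks) == 0:
        raise ValueError("no peaks to profile")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    L = len(pwm)
    n_bins = 2 * flank // bin_size
    counts = np.zeros(n_bins, dtype=float)
    used = 0
    for row in peaks.itertuples():
        center = (int(row.start) + int(row.end)) // 2
        lo, hi = center - flank - L // 2, center + flank + L
        try:
            seq = sequences.fetch(str(row.chrom), max(lo, 0), hi)
        except (KeyError, ValueError):
            continue
        if len(seq) < L:
            continue
        fwd = _scan_scores(pwm, seq)
        rev = _scan_scores(pwm, reverse_complement(seq))[::-1]
        best = np.maximum(fwd, rev)
        offsets = np.arange(len(best)) + max(lo, 0)
        mids = offsets + L // 2
        rel = mids - center
        hits = rel[(best >= score_min) & (rel >= -flank) & (rel < flank)]
        bins = (hits + flank) // bin_size
        np.add.at(counts, bins.astype(int), 1.0)
        used += 1
    if used == 0:
        raise ValueError("no peak had fetchable sequence")
    centers = np.arange(n_bins) * bin_size - flank + bin_size / 2
    return pd.DataFrame({"bin_center_bp": centers, "mean_count": counts / used})
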