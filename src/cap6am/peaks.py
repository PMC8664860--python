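"""Classify external-caller peaks into cap-m6Am versus internal m6A.

A peak whose start lies within 25 nt downstream of its nearest annotated
TSS is cap-m6Am; one starting more than 50 nt away is internal m6A; the
26-50 nt zone between the two published rules is deliberately left
ambiguous and excluded from both classes.  The module also computes the
m6A/m6Am ratio, the cross-condition chi-square on those counts, the
TSS-distance histogram, and the %A-at-TSS versus peak-score relation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .io import PeakRecord, TSSRecord, nearest_tss

__all__ = ["ClassifiedPeak", "classify_peak", "classify_peaks",
           "class_counts", "m6a_m6am_ratio", "compare_ratios_chisq",
           "distance_histogram", "tss_adenosine_vs_score"]


@dataclass
class ClassifiedPeak:
    peak: PeakRecord
    nearest: TSSRecord | None
    distance: int | None       # signed nt in the matched TSS's direction
    cls: str                   # m6am | m6a | ambiguous | unclassified


def _reference_point(peak: PeakRecord, reference: str) -> int:
    if reference == "summit" and peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return peak.start


def classify_peak(peak: PeakRecord, catalog, m6am_max: int = 25,
                  m6a_min: int = 50, upstream_slack: int = 0,
                  reference: str = "start") -> ClassifiedPeak:
    """Assign a peak to m6am / m6a / ambiguous by nearest-TSS distance.

    ``m6am``: 0 - upstream_slack <= distance <= m6am_max (downstream of
    the TSS by default); ``m6a``: |distance| > m6a_min; anything between
    is ``ambiguous``.  Distance is measured from the peak start (or
    summit when ``reference="summit"``) in the matched TSS's
    transcription direction.
    """
    hit = nearest_tss(peak.chrom, _reference_point(peak, reference), catalog)
    if hit is None:
        warnings.warn(f"no TSS on chromosome {peak.chrom}; "
                      f"peak {peak.name} left unclassified")
        return ClassifiedPeak(peak=peak, nearest=None, distance=None,
                              cls="unclassified")
    tss, dist = hit
    if -upstream_slack <= dist <= m6am_max:
        cls = "m6am"
    elif abs(dist) > m6a_min:
        cls = "m6a"
    else:
        cls = "ambiguous"
    return ClassifiedPeak(peak=peak, nearest=tss, distance=dist, cls=cls)


def classify_peaks(peaks, catalog, **kwargs) -> list[ClassifiedPeak]:
    return [classify_peak(p, catalog, **kwargs) for p in peaks]


def class_counts(classified) -> dict[str, int]:
    counts = {"m6am": 0, "m6a": 0, "ambiguous": 0, "unclassified": 0}
    for cp in classified:
        counts[cp.cls] += 1
    return counts


def m6a_m6am_ratio(counts: dict) -> tuple[float, float]:
    """m6A/m6Am peak ratio; returns ``(raw, rounded)`` with the reported
    value rounded half-up to one decimal."""
    m6am = counts.get("m6am", 0)
    m6a = counts.get("m6a", 0)
    if m6am == 0:
        raise ZeroDivisionError("no m6Am peaks: ratio undefined")
    raw = m6a / m6am
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.1"),
                                                rounding=ROUND_HALF_UP))
    return raw, rounded


def compare_ratios_chisq(counts_a: dict, counts_b: dict):
    """Pearson chi-square (no continuity correction) comparing the
    m6A:m6Am split between two conditions; returns ``(chi2, df, p)``."""
    table = np.array([[counts_a.get("m6a", 0), counts_a.get("m6am", 0)],
                      [counts_b.get("m6a", 0), counts_b.get("m6am", 0)]],
                     dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() \
            or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin is zero")
    res = stats.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if (expected <= 0).any():
        raise ValueError("chi-square undefined: zero expected cell")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def distance_histogram(classified, bins=None):
    """Histogram of signed TSS distances plus the fraction within 50 nt.

    Returns ``(edges, counts, fraction_within_50)``; the fraction is NaN
    on empty input.
    """
    dists = np.array([cp.distance for cp in classified
                      if cp.distance is not None], dtype=float)
    if dists.size == 0:
        return np.array([]), np.array([], dtype=int), math.nan
    if bins is None:
        bins = np.arange(-500, 501, 25)
    counts, edges = np.histogram(dists, bins=bins)
    frac = float(np.mean(np.abs(dists) <= 50))
    return edges, counts, frac


def tss_adenosine_vs_score(classified, genome: dict, n_bins: int = 5):
    """%A at the nearest annotated TSS base as a function of peak score.

    Peaks are cut into ``n_bins`` equal-count bins of fold enrichment;
    for each bin the percentage of peaks whose nearest TSS base
    (strand-aware) is adenosine is reported, along with the Pearson r of
    bin mean score versus %A (NaN with fewer than two usable bins).
    Returns ``(bin_mean_scores, pct_a, r)``.
    """
    scored = [(cp.peak.fold_enrichment, cp.nearest)
              for cp in classified if cp.nearest is not None]
    if not scored:
        return np.array([]), np.array([]), math.nan
    is_a = []
    scores = []
    for score, tss in scored:
        seq = genome.get(tss.chrom)
        if seq is None or not 0 <= tss.pos < len(seq):
            continue
        base = seq[tss.pos].upper()
        if tss.strand == "-":
            base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")
        is_a.append(1.0 if base == "A" else 0.0)
        scores.append(score)
    scores = np.asarray(scores)
    is_a = np.asarray(is_a)
    if scores.size == 0:
        return np.array([]), np.array([]), math.nan
    n_bins = min(n_bins, scores.size)
    order = np.argsort(scores, kind="stable")
    splits = np.array_split(order, n_bins)
    mean_scores = np.array([scores[idx].mean() for idx in splits])
    pct_a = np.array([100.0 * is_a[idx].mean() for idx in splits])
    if len(splits) < 2 or np.allclose(mean_scores.std(), 0) \
            or np.allclose(pct_a.std(), 0):
        return mean_scores, pct_a, math.nan
    r = float(stats.pearsonr(mean_scores, pct_a).statistic)
    return mean_scores, pct_a, r
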