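"""The cap-m6Am caller.

For each annotated TSS the caller sums capped read 5'-end counts over the
25 transcribed positions starting at the TSS in IP and input, filters out
TSSs with zero input coverage within 100 nt downstream (the average RNA
fragment length), computes the library-normalized fold change

    fc = (ip_count / input_count) * (input_library / ip_library),

gates on ip_count > 5 and fc > 2, assigns a one-sided Fisher exact
p-value on the 2x2 table of window count versus remainder-of-library per
sample, applies Benjamini-Hochberg across the tested set, excludes TSSs
overlapping a known m1A site, and keeps one best TSS per gene.  A
negative control reruns the identical procedure with IP and input roles
swapped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import EndCountTrack, TSSRecord

__all__ = ["Thresholds", "WindowCount", "M6AmCall", "CallSet",
           "cap_duplicates", "window_count", "fold_change",
           "input_coverage_filter", "fisher_enrichment_test", "bh_adjust",
           "call_sample", "negative_control", "replicate_consensus",
           "fc_track", "calls_to_frame"]


@dataclass(frozen=True)
class Thresholds:
    """Caller gates; defaults mirror the published criteria."""

    window: int = 25        # TSS window width (positions incl. the TSS base)
    cov_span: int = 100     # input-coverage span downstream of the TSS
    dup_cap: int = 5        # max read ends retained per single position
    min_ip: int = 6         # ip_count > 5  <=>  ip_count >= 6
    min_fc: float = 2.0     # strict: fold change must exceed this
    max_fdr: float = 0.05   # BH q-value cutoff (inclusive)
    # BH universe: "all" tests every coverage-passing TSS then gates
    # (matching the published order: a p-value for each TSS, FDR, then the
    # count/fc cuts); "gated" tests only the count/fc gate survivors, which
    # leaves BH almost no correction to do on that pre-selected set.
    fdr_universe: str = "all"


@dataclass
class WindowCount:
    tss: TSSRecord
    ip_count: int
    input_count: int
    ip_library: int
    input_library: int
    input_cov100: int


@dataclass
class M6AmCall:
    window: WindowCount
    fold_change: float = math.nan
    p_value: float = math.nan
    q_value: float = math.nan
    flags: set = field(default_factory=set)
    passed: bool = False


@dataclass
class CallSet:
    sample_id: str
    calls: list
    passed_genes: set


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def cap_duplicates(track: EndCountTrack, cap: int = 5) -> EndCountTrack:
    """Clamp every per-position count at ``cap`` (PCR-duplicate removal).

    ``library_size`` is untouched: the cap is positional cleaning, not a
    library renormalization.  Idempotent.
    """
    if cap < 1:
        raise ValueError(f"duplicate cap must be >= 1, got {cap}")
    counts = {key: (pos, np.minimum(val, cap))
              for key, (pos, val) in track.counts.items()}
    return EndCountTrack(sample_id=track.sample_id, role=track.role,
                         library_size=track.library_size, counts=counts)


def _window_bounds(tss: TSSRecord, width: int) -> tuple[int, int]:
    """Half-open genomic interval covering the ``width`` transcribed
    positions starting at the TSS base."""
    if tss.strand == "+":
        return tss.pos, tss.pos + width
    return tss.pos - width + 1, tss.pos + 1


def window_count(track_ip: EndCountTrack, track_input: EndCountTrack,
                 tss: TSSRecord, window: int = 25,
                 cov_span: int = 100) -> WindowCount:
    """Strand-matched end counts in the TSS window, plus the input
    coverage within ``cov_span`` transcribed positions."""
    w_lo, w_hi = _window_bounds(tss, window)
    c_lo, c_hi = _window_bounds(tss, cov_span)
    return WindowCount(
        tss=tss,
        ip_count=track_ip.window_sum(tss.chrom, tss.strand, w_lo, w_hi),
        input_count=track_input.window_sum(tss.chrom, tss.strand, w_lo, w_hi),
        ip_library=track_ip.library_size,
        input_library=track_input.library_size,
        input_cov100=track_input.window_sum(tss.chrom, tss.strand,
                                            c_lo, c_hi))


def fold_change(wc: WindowCount) -> float:
    """Library-normalized IP/input fold change; NaN when input_count is 0
    (such TSSs must already carry the undefined-fc flag upstream)."""
    if wc.input_count == 0:
        return math.nan
    return (wc.ip_count / wc.input_count) * \
        (wc.input_library / wc.ip_library)


def input_coverage_filter(wc: WindowCount) -> bool:
    """Keep a TSS only if the input sample has any read end within the
    100 nt downstream of it."""
    return wc.input_cov100 > 0


def _fisher_tail(k, N, K, n):
    """One-sided (enrichment) Fisher p = P[X >= k], X ~ Hypergeom(N, K, n).

    Vectorized over arrays; parameters follow the 2x2 table
    [[k, n - k], [K - k, N - n - K + k]] with row sums (n, N - n) and
    column sums (K, N - K).
    """
    k = np.asarray(k, dtype=np.int64)
    return stats.hypergeom.sf(k - 1, N, K, n)


def fisher_enrichment_test(wc: WindowCount) -> float:
    """One-sided Fisher exact test for IP enrichment on the table
    [[ip_count, ip_library - ip_count],
     [input_count, input_library - input_count]].

    Degenerate tables (any zero margin) give p = 1.
    """
    a, b = wc.ip_count, wc.ip_library - wc.ip_count
    c, d = wc.input_count, wc.input_library - wc.input_count
    if min(a, b, c, d) < 0:
        raise ValueError("window count exceeds library size")
    N = a + b + c + d
    if N == 0 or (a + c) == 0 or (a + b) == 0 or (b + d) == 0 \
            or (c + d) == 0:
        return 1.0
    p = float(_fisher_tail(a, N, a + c, a + b))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The full per-sample caller
# ---------------------------------------------------------------------------

def _m1a_overlaps(tss: TSSRecord, m1a_sites, window: int) -> bool:
    lo, hi = _window_bounds(tss, window)
    for site in m1a_sites:
        if site.chrom == tss.chrom and lo <= site.pos < hi:
            return True
    return False


def call_sample(track_ip: EndCountTrack, track_input: EndCountTrack,
                catalog, m1a_sites=(), thresholds: Thresholds = Thresholds(),
                _negative: bool = False) -> CallSet:
    """Run the full caller on one IP/input pair.

    Stages, in order: duplicate cap -> window counting -> input-coverage
    filter -> fold change -> strict count/fc gates -> Fisher test on the
    tested set -> BH across exactly that set -> m1A-overlap exclusion ->
    per-gene best-TSS selection.  Every evaluated TSS is retained in
    ``calls`` with its filter flags.
    """
    t = thresholds
    if t.fdr_universe not in ("gated", "all"):
        raise ValueError(f"fdr_universe must be 'gated' or 'all', "
                         f"got {t.fdr_universe!r}")
    if not catalog:
        warnings.warn("empty TSS catalog: returning an empty call set")
        return CallSet(sample_id=track_ip.sample_id, calls=[],
                       passed_genes=set())
    ip = cap_duplicates(track_ip, t.dup_cap)
    inp = cap_duplicates(track_input, t.dup_cap)

    calls: list[M6AmCall] = []
    for tss in catalog:
        wc = window_count(ip, inp, tss, window=t.window, cov_span=t.cov_span)
        call = M6AmCall(window=wc)
        if _negative:
            call.flags.add("negative_mode")
        if not input_coverage_filter(wc):
            call.flags.add("no_input_cov")
            calls.append(call)
            continue
        if wc.input_count == 0:
            call.flags.add("undefined_fc")
        else:
            call.fold_change = fold_change(wc)
        if wc.ip_count < t.min_ip:
            call.flags.add("low_ip")
        if not (call.fold_change > t.min_fc):   # NaN fails too
            call.flags.add("low_fc")
        calls.append(call)

    if t.fdr_universe == "gated":
        tested = [c for c in calls
                  if not c.flags & {"no_input_cov", "undefined_fc",
                                    "low_ip", "low_fc"}]
    else:
        tested = [c for c in calls
                  if not c.flags & {"no_input_cov", "undefined_fc"}]
    for c in tested:
        c.p_value = fisher_enrichment_test(c.window)
    if tested:
        qs = bh_adjust([c.p_value for c in tested])
        for c, q in zip(tested, qs):
            c.q_value = float(q)

    for c in calls:
        if m1a_sites and _m1a_overlaps(c.window.tss, m1a_sites, t.window):
            c.flags.add("m1a_overlap")
        gates_ok = not (c.flags & {"no_input_cov", "undefined_fc", "low_ip",
                                   "low_fc", "m1a_overlap"})
        c.passed = bool(gates_ok and not math.isnan(c.q_value)
                        and c.q_value <= t.max_fdr)

    # one best TSS per gene: lowest p, then highest fc, then 5'-most
    best: dict[str, M6AmCall] = {}
    for c in calls:
        if not c.passed:
            continue
        gene = c.window.tss.gene_id
        prev = best.get(gene)
        if prev is None or _best_key(c) < _best_key(prev):
            best[gene] = c
    for c in calls:
        if c.passed and best.get(c.window.tss.gene_id) is not c:
            c.passed = False
            c.flags.add("not_best_tss")

    sample_id = track_ip.sample_id or track_input.sample_id
    return CallSet(sample_id=sample_id, calls=calls,
                   passed_genes=set(best))


def _best_key(call: M6AmCall):
    tss = call.window.tss
    five_prime = tss.pos if tss.strand == "+" else -tss.pos
    return (call.p_value, -call.fold_change, five_prime)


def negative_control(track_ip: EndCountTrack, track_input: EndCountTrack,
                     catalog, m1a_sites=(),
                     thresholds: Thresholds = Thresholds()) -> CallSet:
    """The swapped control: rerun the identical caller with the IP track
    as input and vice versa; calls carry the ``negative_mode`` flag."""
    return call_sample(track_input, track_ip, catalog, m1a_sites,
                       thresholds, _negative=True)


def replicate_consensus(callsets, min_reps: int = 2) -> set:
    """Genes passing in at least ``min_reps`` of the given call sets."""
    callsets = list(callsets)
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    if min_reps > len(callsets):
        raise ValueError(f"min_reps={min_reps} exceeds the number of "
                         f"call sets ({len(callsets)})")
    tally: dict[str, int] = {}
    for cs in callsets:
        for gene in cs.passed_genes:
            tally[gene] = tally.get(gene, 0) + 1
    return {g for g, n in tally.items() if n >= min_reps}


def fc_track(track_ip: EndCountTrack, track_input: EndCountTrack,
             tss: TSSRecord, span: int = 100, window: int = 5):
    """Sliding-window IP/input fold-change profile around a TSS.

    For each offset in ``[-span//2, span//2]`` (transcription direction),
    the library-normalized fold change of end counts within the centered
    ``window``-bp window; NaN where the input window is empty.
    Returns ``(offsets, fold_changes)``.
    """
    if span < window:
        raise ValueError("span must be >= window")
    half = window // 2
    offsets = np.arange(-(span // 2), span // 2 + 1)
    out = np.full(offsets.shape, math.nan)
    norm = (track_input.library_size / track_ip.library_size
            if track_ip.library_size else math.nan)
    sign = 1 if tss.strand == "+" else -1
    for i, off in enumerate(offsets):
        center = tss.pos + sign * int(off)
        lo, hi = center - half, center + half + 1
        ip = track_ip.window_sum(tss.chrom, tss.strand, lo, hi)
        inp = track_input.window_sum(tss.chrom, tss.strand, lo, hi)
        if inp > 0:
            out[i] = (ip / inp) * norm
    return offsets, out


def calls_to_frame(callset: CallSet):
    """Flatten a CallSet to the tabular output schema."""
    import pandas as pd
    rows = []
    for c in callset.calls:
        t = c.window.tss
        rows.append({
            "gene": t.gene_id, "tss_id": t.tss_id, "chrom": t.chrom,
            "pos": t.pos, "strand": t.strand,
            "ip_count": c.window.ip_count,
            "input_count": c.window.input_count,
            "ip_lib": c.window.ip_library,
            "input_lib": c.window.input_library,
            "fold_change": c.fold_change, "p": c.p_value, "q": c.q_value,
            "flags": ",".join(sorted(c.flags)), "passed": c.passed})
    return pd.DataFrame(rows)
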