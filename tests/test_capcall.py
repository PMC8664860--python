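"""Unit and property tests for the cap-m6Am caller."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from cap6am import (EndCountTrack, Thresholds, TSSRecord, bh_adjust,
                    call_sample, cap_duplicates, fc_track,
                    fisher_enrichment_test, fold_change,
                    input_coverage_filter, negative_control,
                    replicate_consensus, window_count)
from cap6am.capcall import CallSet, WindowCount


def _tss(pos=100, strand="+", gene="G1", tss="t1"):
    return TSSRecord(chrom="chr1", pos=pos, strand=strand, gene_id=gene,
                     tss_id=tss)


def _track(mapping, lib, sample="s", role="ip"):
    return EndCountTrack.from_mapping(mapping, lib, sample_id=sample,
                                      role=role)


def _wc(ip, inp, ip_lib, inp_lib, cov=1):
    return WindowCount(tss=_tss(), ip_count=ip, input_count=inp,
                       ip_library=ip_lib, input_library=inp_lib,
                       input_cov100=cov)


class TestCapDuplicates:
    def test_caps_above_and_keeps_below(self):
        track = _track({("chr1", "+", 10): 12, ("chr1", "+", 20): 3}, 15)
        capped = cap_duplicates(track, 5)
        got = {p: c for _, p, _, c in capped.iter_entries()}
        assert got == {10: 5, 20: 3}
        assert capped.library_size == 15  # library untouched

    def test_idempotent(self):
        track = _track({("chr1", "+", i): i for i in range(1, 12)}, 66)
        once = cap_duplicates(track, 5)
        twice = cap_duplicates(once, 5)
        assert [e for e in once.iter_entries()] == \
            [e for e in twice.iter_entries()]

    def test_cap_below_one_rejected(self):
        with pytest.raises(ValueError):
            cap_duplicates(_track({}, 0), 0)


class TestWindowCount:
    def test_plus_strand_half_open_boundary(self):
        ip = _track({("chr1", "+", 100): 1, ("chr1", "+", 124): 2,
                     ("chr1", "+", 125): 4}, 100)
        inp = _track({}, 100)
        wc = window_count(ip, inp, _tss(pos=100, strand="+"), window=25)
        assert wc.ip_count == 3  # 100 and 124 in, 125 out

    def test_minus_strand_mirror(self):
        ip = _track({("chr1", "-", 76): 1, ("chr1", "-", 75): 8,
                     ("chr1", "-", 100): 2}, 100)
        inp = _track({}, 100)
        wc = window_count(ip, inp, _tss(pos=100, strand="-"), window=25)
        assert wc.ip_count == 3  # 76 and 100 in, 75 out

    def test_opposite_strand_excluded(self):
        ip = _track({("chr1", "-", 110): 5}, 100)
        inp = _track({}, 100)
        wc = window_count(ip, inp, _tss(pos=100, strand="+"))
        assert wc.ip_count == 0

    def test_input_cov100_spans_beyond_window(self):
        ip = _track({}, 100)
        inp = _track({("chr1", "+", 180): 1}, 100)
        wc = window_count(ip, inp, _tss(pos=100))
        assert wc.input_count == 0 and wc.input_cov100 == 1


class TestFoldChange:
    @pytest.mark.parametrize("ip,inp,ip_lib,inp_lib,expected", [
        (20, 5, 2_000_000, 1_000_000, 2.0),
        (7, 7, 500, 500, 1.0),
        (10, 5, 1_000_000, 2_000_000, 4.0),
    ])
    def test_printed_formula(self, ip, inp, ip_lib, inp_lib, expected):
        assert fold_change(_wc(ip, inp, ip_lib, inp_lib)) == \
            pytest.approx(expected)

    def test_zero_input_is_nan(self):
        assert math.isnan(fold_change(_wc(3, 0, 100, 100)))


class TestCoverageFilter:
    @pytest.mark.parametrize("cov,keep", [(0, False), (1, True)])
    def test_boundary(self, cov, keep):
        assert input_coverage_filter(_wc(5, 5, 100, 100, cov=cov)) is keep


def _fisher_oracle(a, b, c, d):
    """Exhaustive one-sided tail: sum hypergeometric pmf over tables at
    least as IP-enriched, from log-factorial binomial coefficients."""
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi = max(0, m1 - n2), min(m1, n1)

    def log_pmf(k):
        return (gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
                + gammaln(n2 + 1) - gammaln(m1 - k + 1)
                - gammaln(n2 - m1 + k + 1)
                - (gammaln(n1 + n2 + 1) - gammaln(m1 + 1)
                   - gammaln(n1 + n2 - m1 + 1)))
    return sum(math.exp(log_pmf(k)) for k in range(a, hi + 1))


class TestFisher:
    def test_zero_ip_gives_one(self):
        assert fisher_enrichment_test(_wc(0, 5, 100, 100)) == 1.0

    def test_matches_enumeration_oracle(self):
        p = fisher_enrichment_test(_wc(5, 1, 100, 100))
        assert p == pytest.approx(_fisher_oracle(5, 95, 1, 99), abs=1e-12)

    def test_matches_scipy_fisher_exact(self, rng):
        from scipy.stats import fisher_exact
        for _ in range(50):
            lib1, lib2 = rng.integers(20, 500, size=2)
            a = int(rng.integers(0, lib1 // 2))
            c = int(rng.integers(0, lib2 // 2))
            wc = _wc(a, c, int(lib1), int(lib2))
            _, want = fisher_exact([[a, lib1 - a], [c, lib2 - c]],
                                   alternative="greater")
            assert fisher_enrichment_test(wc) == pytest.approx(
                max(want, 5e-324), rel=1e-9)

    def test_one_sidedness_swap_increases_p(self, rng):
        for _ in range(30):
            lib = 200
            c = int(rng.integers(1, 20))
            a = int(c + rng.integers(5, 30))  # ip enriched
            fwd = fisher_enrichment_test(_wc(a, c, lib, lib))
            swapped = fisher_enrichment_test(_wc(c, a, lib, lib))
            assert swapped > fwd

    def test_monotone_in_ip_count(self):
        ps = [fisher_enrichment_test(_wc(k, 10, 1000, 1000))
              for k in range(0, 60, 5)]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))
        fcs = [fold_change(_wc(k, 10, 1000, 1000)) for k in range(1, 60, 5)]
        assert all(f2 >= f1 for f1, f2 in zip(fcs, fcs[1:]))


def _bh_closed_form(p):
    """q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_worked_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0] * 5), 1.0)

    def test_matches_step_up_closed_form(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(bh_adjust(p), _bh_closed_form(p),
                               atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _spread(spec):
    """Expand {(strand, pos): count} so no position exceeds the cap of 5
    (counts above 5 spill onto consecutive positions)."""
    out = {}
    for (strand, pos), count in spec.items():
        offset = 0
        while count > 0:
            out[(strand, pos + offset)] = min(count, 5)
            count -= 5
            offset += 1
    return out


def _study_tracks(ip_spec, inp_spec, lib=10_000):
    """Build IP/input tracks from {(strand, pos): count} specs; counts
    above the duplicate cap are spread over adjacent positions."""
    ip = _track({("chr1", s, p): c
                 for (s, p), c in _spread(ip_spec).items()}, lib,
                sample="ip", role="ip")
    inp = _track({("chr1", s, p): c
                  for (s, p), c in _spread(inp_spec).items()}, lib,
                 sample="in", role="input")
    return ip, inp


class TestCallSample:
    def _base_inp(self, pos=100):
        # 2 input reads in window, more downstream for coverage
        return {("+", pos): 2, ("+", pos + 60): 3}

    def test_low_ip_flag_blocks_huge_enrichment(self):
        ip, inp = _study_tracks({("+", 100): 5}, self._base_inp())
        cs = call_sample(ip, inp, [_tss(pos=100)])
        (call,) = cs.calls
        assert not call.passed and "low_ip" in call.flags

    def test_low_fc_flag(self):
        # fc = (3/2)*(1) = 1.5 < 2
        ip, inp = _study_tracks({("+", 100): 3}, self._base_inp())
        cs = call_sample(ip, inp, [_tss(pos=100)],
                         thresholds=Thresholds(min_ip=1))
        (call,) = cs.calls
        assert not call.passed and "low_fc" in call.flags

    def test_no_input_coverage_filtered(self):
        ip, inp = _study_tracks({("+", 100): 50}, {("+", 500): 5})
        cs = call_sample(ip, inp, [_tss(pos=100)])
        (call,) = cs.calls
        assert not call.passed and "no_input_cov" in call.flags
        assert math.isnan(call.p_value)

    def test_zero_input_count_with_coverage_flagged_not_passed(self):
        ip, inp = _study_tracks({("+", 100): 50}, {("+", 180): 5})
        cs = call_sample(ip, inp, [_tss(pos=100)])
        (call,) = cs.calls
        assert not call.passed and "undefined_fc" in call.flags

    def test_passing_call(self):
        ip, inp = _study_tracks({("+", 100): 40}, self._base_inp())
        cs = call_sample(ip, inp, [_tss(pos=100)])
        (call,) = cs.calls
        assert call.passed and cs.passed_genes == {"G1"}

    def test_best_tss_per_gene(self):
        ip, inp = _study_tracks(
            {("+", 100): 40, ("+", 200): 15},
            {**self._base_inp(100), **self._base_inp(200)})
        cat = [_tss(pos=100, tss="t1"), _tss(pos=200, tss="t2")]
        cs = call_sample(ip, inp, cat)
        passed = [c for c in cs.calls if c.passed]
        assert len(passed) == 1 and passed[0].window.tss.tss_id == "t1"
        other = next(c for c in cs.calls if c.window.tss.tss_id == "t2")
        assert "not_best_tss" in other.flags
        assert cs.passed_genes == {"G1"}

    def test_m1a_overlap_voids_call(self):
        ip, inp = _study_tracks({("+", 100): 40}, self._base_inp())
        m1a = [_tss(pos=110, gene="m1a_site")]
        cs = call_sample(ip, inp, [_tss(pos=100)], m1a_sites=m1a)
        (call,) = cs.calls
        assert not call.passed and "m1a_overlap" in call.flags

    def test_m1a_outside_window_harmless(self):
        ip, inp = _study_tracks({("+", 100): 40}, self._base_inp())
        m1a = [_tss(pos=130, gene="m1a_site")]
        cs = call_sample(ip, inp, [_tss(pos=100)], m1a_sites=m1a)
        assert cs.calls[0].passed

    def test_empty_catalog_warns(self):
        ip, inp = _study_tracks({}, {})
        with pytest.warns(UserWarning):
            cs = call_sample(ip, inp, [])
        assert cs.calls == [] and cs.passed_genes == set()


class TestNegativeControl:
    def test_swap_is_involution(self):
        ip, inp = _study_tracks({("+", 100): 40, ("+", 160): 3},
                                {("+", 100): 2, ("+", 160): 3})
        fwd = call_sample(ip, inp, [_tss(pos=100)])
        double = negative_control(inp, ip, [_tss(pos=100)])
        assert [c.passed for c in fwd.calls] == \
            [c.passed for c in double.calls]
        assert all("negative_mode" in c.flags for c in double.calls)
        assert [c.window.ip_count for c in fwd.calls] == \
            [c.window.ip_count for c in double.calls]


class TestReplicateConsensus:
    def _cs(self, genes):
        return CallSet(sample_id="s", calls=[], passed_genes=set(genes))

    def test_two_of_three_included(self):
        sets = [self._cs({"A", "B"}), self._cs({"A"}), self._cs({"C"})]
        assert replicate_consensus(sets, 2) == {"A"}

    def test_one_of_three_excluded(self):
        sets = [self._cs({"A"}), self._cs({}), self._cs({})]
        assert replicate_consensus(sets, 2) == set()

    def test_min_reps_one_is_union(self):
        sets = [self._cs({"A"}), self._cs({"B"})]
        assert replicate_consensus(sets, 1) == {"A", "B"}

    def test_min_reps_exceeding_count_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus([self._cs({"A"})], 2)


class TestFcTrack:
    def test_uniform_tracks_flat_profile(self):
        spec = {("+", p): 2 for p in range(50, 150)}
        ip, inp = _study_tracks(spec, spec)
        offsets, prof = fc_track(ip, inp, _tss(pos=100), span=40, window=5)
        assert np.allclose(prof, 1.0)

    def test_ip_spike_peaks_at_tss(self):
        inp_spec = {("+", p): 2 for p in range(50, 150)}
        ip_spec = dict(inp_spec)
        ip_spec[("+", 100)] = 50
        ip, inp = _study_tracks(ip_spec, inp_spec)
        offsets, prof = fc_track(ip, inp, _tss(pos=100), span=40, window=5)
        peak_zone = np.abs(offsets) <= 2
        assert prof[peak_zone].min() > prof[~peak_zone].max()

    def test_zero_input_all_undefined(self):
        ip, _ = _study_tracks({("+", 100): 5}, {})
        inp = _track({}, 100, role="input")
        _, prof = fc_track(ip, inp, _tss(pos=100), span=20)
        assert np.all(np.isnan(prof))
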