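"""Detection procedure: form regions, filters, pairing, merging, end to end."""

import numpy as np
import pytest

import triform as tf
from triform.coverage import CoverageTrack
from triform.detect import (FORMS, PeakCall, RegionCandidate, form_z,
                            pair_strand_regions, resolve_forms, score_peak)

Z9 = tf.min_z_from_p(0.1)


def _cluster_reads(chrom, start0, n, strand="+", length=36):
    """n identical stacked reads at one location."""
    return [tf.ReadAlignment(chrom, start0, start0 + length, strand)] * n


def _region(strand="+", form=1, start=100, end=199, er=5.0, nlp=2.0,
            chrom="chr1"):
    return RegionCandidate(
        chrom=chrom, strand=strand, form=form, start=start, end=end,
        center=(start + end) // 2, summit=(start + end) // 2,
        summit_z=3.0, er_center=er, nlp=nlp)


def _peak(start, end, form, nlp=2.0, lag=50, chrom="chr1"):
    return PeakCall(chrom=chrom, start=start, end=end,
                    peak_loc=(start + end) // 2, peak_nlp=nlp, form=form,
                    lag=lag, er=3.0)


class TestFormZ:
    def test_empty_track_all_zero(self):
        empty = CoverageTrack(chrom="chr1", strand="+")
        assert all(form_z(empty, x, f, 150) == 0.0
                   for x in (1, 500) for f in FORMS)

    def test_isolated_spike_reduces_to_z1_of_center(self):
        track = tf.build_track(_cluster_reads("chr1", 1000, 10), "+", 100)
        x = int(track.starts[0])  # inside the cluster; flanks at +-150 empty
        assert form_z(track, x, 1, 150) == pytest.approx(20 / np.sqrt(20))
        assert form_z(track, x, 2, 150) == pytest.approx(10 / np.sqrt(10))

    def test_flat_coverage_is_zero_for_all_forms(self):
        flat = CoverageTrack(chrom="chr1", strand="+",
                             starts=np.array([1], np.int64),
                             ends=np.array([2000], np.int64),
                             values=np.array([7], np.int64))
        assert all(form_z(flat, 1000, f, 150) == 0.0 for f in FORMS)


class TestDetectFormRegions:
    def test_empty_chip_no_regions(self):
        empty = CoverageTrack(chrom="chr1", strand="+")
        params = tf.Parameters(r=1.0)
        assert tf.detect_form_regions(empty, empty, 1, params) == []

    def test_requires_library_ratio(self):
        empty = CoverageTrack(chrom="chr1", strand="+")
        with pytest.raises(ValueError):
            tf.detect_form_regions(empty, empty, 1, tf.Parameters())

    def test_single_planted_cluster_gives_one_form1_region(self):
        """Ten stacked reads, no background, no control: one region whose
        span contains the cluster center, all positions audited."""
        chip = tf.build_track(_cluster_reads("chr1", 5000, 10), "+", 100)
        control = CoverageTrack(chrom="chr1", strand="+")
        params = tf.Parameters(r=1.0)
        regions = tf.detect_form_regions(chip, control, 1, params)
        assert len(regions) == 1
        (reg,) = regions
        cluster_center = (int(chip.starts[0]) + int(chip.ends[-1])) // 2
        assert reg.start <= cluster_center <= reg.end
        assert reg.width == 100  # whole cluster passes, flanks empty
        assert reg.er_center == pytest.approx(11.0)  # (1 + 10)/(1 + 0)
        assert reg.nlp == pytest.approx(tf.nlp_from_z(reg.summit_z))
        # independent pointwise audit of every position in the region
        for x in range(reg.start, reg.end + 1):
            assert form_z(chip, x, 1, params.delta) > params.min_z
            assert tf.z4(chip.coverage_at(x), control.coverage_at(x),
                         1.0) > params.min_z

    def test_constant_plateau_with_matched_control_rejected(self):
        """A wide uniform block over an equal control has z4 = 0 everywhere
        and must produce no regions of any form."""
        reads = [tf.ReadAlignment("chr1", s, s + 36, "+")
                 for s in range(1000, 1600, 10) for _ in range(3)]
        chip = tf.build_track(reads, "+", 100)
        control = tf.build_track(reads, "+", 100)
        params = tf.Parameters(r=1.0)
        for form in FORMS:
            assert tf.detect_form_regions(chip, control, form, params) == []

    def test_min_n_is_strict(self):
        """A passing run of exactly min_n positions is rejected."""
        chip = tf.build_track(_cluster_reads("chr1", 5000, 10), "+", 100)
        control = CoverageTrack(chrom="chr1", strand="+")
        wide = tf.Parameters(r=1.0, min_n=99)
        narrow = tf.Parameters(r=1.0, min_n=100)
        assert len(tf.detect_form_regions(chip, control, 1, wide)) == 1
        assert tf.detect_form_regions(chip, control, 1, narrow) == []


class TestMinEr:
    def test_three_eighths_quantile_linear_interpolation(self):
        regions = [_region(er=v) for v in (1, 2, 3, 4, 5, 6, 7, 8)]
        assert tf.compute_min_er(regions, 0.375) == pytest.approx(3.625)

    def test_single_region_any_quantile(self):
        for q in (0.1, 0.375, 0.9):
            assert tf.compute_min_er([_region(er=5.0)], q) == 5.0

    def test_empty_set_vacuous_filter(self):
        assert tf.compute_min_er([], 0.375) == 0.0

    def test_er_filter_is_strict(self):
        regions = [_region(er=v) for v in (2.0, 3.0, 4.0)]
        kept = tf.apply_er_filter(regions, {"+": 3.0})
        assert [r.er_center for r in kept] == [4.0]
        assert tf.apply_er_filter(regions, {"+": 0.0}) == regions
        assert tf.apply_er_filter([], {"+": 3.0}) == []


class TestReplicateFilter:
    def _setup(self):
        chip = tf.build_track(_cluster_reads("chr1", 5000, 10), "+", 100)
        control = CoverageTrack(chrom="chr1", strand="+")
        params = tf.Parameters(r=1.0)
        (reg,) = tf.detect_form_regions(chip, control, 1, params)
        return chip, control, params, reg

    def test_single_replicate_is_identity(self):
        chip, control, params, reg = self._setup()
        out = tf.apply_replicate_filter(
            [reg], [{("chr1", "+"): chip}], {("chr1", "+"): control},
            [1.0], params)
        assert out == [reg]

    def test_two_supporting_replicates_keep_region(self):
        chip, control, params, reg = self._setup()
        reps = [{("chr1", "+"): chip}, {("chr1", "+"): chip}]
        out = tf.apply_replicate_filter(
            [reg], reps, {("chr1", "+"): control}, [1.0, 1.0], params)
        assert out == [reg]

    def test_zero_coverage_replicate_drops_region(self):
        chip, control, params, reg = self._setup()
        empty = {("chr1", "+"): CoverageTrack(chrom="chr1", strand="+")}
        out = tf.apply_replicate_filter(
            [reg], [{("chr1", "+"): chip}, empty],
            {("chr1", "+"): control}, [1.0, 1.0], params)
        assert out == []


class TestPairing:
    def test_unique_overlap_pairs(self):
        f = _region(strand="+", start=100, end=199)
        g = _region(strand="-", start=150, end=249)
        assert pair_strand_regions([f], [g]) == [(f, g)]

    def test_ambiguous_overlap_rejected(self):
        f = _region(strand="+", start=100, end=300)
        g1 = _region(strand="-", start=120, end=180)
        g2 = _region(strand="-", start=200, end=260)
        assert pair_strand_regions([f], [g1, g2]) == []

    def test_disjoint_regions_unpaired(self):
        f = _region(strand="+", start=100, end=199)
        g = _region(strand="-", start=300, end=399)
        assert pair_strand_regions([f], [g]) == []

    def test_pairing_is_symmetric_under_strand_swap(self):
        fwd = [_region(strand="+", start=s, end=s + 80)
               for s in (100, 400, 900)]
        rev = [_region(strand="-", start=s, end=s + 80)
               for s in (150, 430, 460)]
        pairs = pair_strand_regions(fwd, rev)
        swapped = pair_strand_regions(rev, fwd)
        assert {(f.start, g.start) for f, g in pairs} == \
            {(g.start, f.start) for f, g in swapped}

    def test_form_restriction(self):
        f = _region(strand="+", form=1, start=100, end=199)
        g = _region(strand="-", form=2, start=150, end=249)
        assert pair_strand_regions([f], [g], form=1) == []
        assert pair_strand_regions([f], [g]) == [(f, g)]


class TestLagFilter:
    def _shifted_pair(self, shift):
        """Reverse profile = forward profile translated right by ``shift``."""
        reads = _cluster_reads("chr1", 5000, 20, strand="+")
        fwd = tf.build_track(reads, "+", 100)
        rev = CoverageTrack(chrom="chr1", strand="-",
                            starts=fwd.starts + shift,
                            ends=fwd.ends + shift,
                            values=fwd.values.copy(), n_reads=fwd.n_reads)
        f = _region(strand="+", start=int(fwd.starts[0]),
                    end=int(fwd.ends[-1]))
        g = _region(strand="-", start=int(rev.starts[0]),
                    end=int(rev.ends[-1]))
        return fwd, rev, f, g

    def test_true_shift_recovered_and_kept(self):
        fwd, rev, f, g = self._shifted_pair(80)
        params = tf.Parameters(r=1.0)
        out = tf.lag_filter([(f, g)], fwd, rev, params)
        assert len(out) == 1
        assert out[0][2] == 80

    def test_coincident_profiles_dropped(self):
        fwd, rev, f, g = self._shifted_pair(0)
        out = tf.lag_filter([(f, g)], fwd, rev, tf.Parameters(r=1.0))
        assert out == []

    def test_empty_input(self):
        fwd, rev, _f, _g = self._shifted_pair(80)
        assert tf.lag_filter([], fwd, rev, tf.Parameters(r=1.0)) == []

    def test_zero_profile_pair_dropped(self):
        fwd, _rev, f, g = self._shifted_pair(80)
        empty = CoverageTrack(chrom="chr1", strand="-")
        assert tf.lag_filter([(f, g)], fwd, empty,
                             tf.Parameters(r=1.0)) == []


class TestScorePeak:
    def test_span_and_midpoint(self):
        f = _region(strand="+", start=100, end=199, nlp=1.5)
        g = _region(strand="-", start=150, end=249, nlp=2.5)
        peak = score_peak(f, g, lag=80)
        assert (peak.start, peak.end, peak.peak_loc) == (100, 249, 174)
        assert peak.peak_nlp == pytest.approx(4.0)
        assert peak.lag == 80

    def test_fisher_combination_of_threshold_z(self):
        f = _region(strand="+", nlp=tf.nlp_from_z(Z9))
        g = _region(strand="-", start=150, end=249, nlp=tf.nlp_from_z(Z9))
        assert score_peak(f, g, 20).peak_nlp == pytest.approx(2.0, rel=1e-9)

    def test_commutative_in_strand_arguments(self):
        f = _region(strand="+", start=100, end=199, nlp=1.5, er=2.0)
        g = _region(strand="-", start=150, end=249, nlp=2.5, er=4.0)
        assert score_peak(f, g, 33) == score_peak(g, f, 33)


class TestResolveForms:
    def test_form1_only_passthrough(self):
        p1 = [_peak(100, 200, 1), _peak(500, 600, 1)]
        assert resolve_forms(p1, [], []) == sorted(
            p1, key=lambda p: -p.peak_nlp)

    def test_redundant_partial_form_removed(self):
        p1 = [_peak(100, 200, 1, nlp=5.0)]
        p2 = [_peak(150, 250, 2, nlp=9.0)]  # overlaps Form 1: dropped
        assert resolve_forms(p1, p2, []) == p1

    def test_partial_forms_merge_into_form1(self):
        p2 = [_peak(100, 200, 2, nlp=2.0, lag=15)]
        p3 = [_peak(180, 300, 3, nlp=3.0, lag=40)]
        (merged,) = resolve_forms([], p2, p3)
        assert (merged.start, merged.end, merged.peak_loc) == (100, 300, 200)
        assert merged.form == 1
        assert merged.peak_nlp == pytest.approx(5.0)
        assert merged.lag == 40

    def test_same_form_residual_overlap_keeps_higher_score(self):
        p2 = [_peak(100, 200, 2, nlp=2.0), _peak(150, 260, 2, nlp=7.0)]
        out = resolve_forms([], p2, [])
        assert [p.peak_nlp for p in out] == [7.0]

    def test_output_non_overlapping_per_chromosome(self):
        p1 = [_peak(100, 300, 1, nlp=5.0), _peak(250, 420, 1, nlp=4.0),
              _peak(600, 700, 1, nlp=1.0)]
        out = resolve_forms(p1, [], [])
        for i, p in enumerate(out):
            for q in out[i + 1:]:
                assert not p.overlaps(q)


class TestCallPeaks:
    def test_control_identical_to_chip_silences_everything(
            self, small_experiment):
        chip_bed, _control, _truth, _cfg = small_experiment
        peaks = tf.call_peaks([chip_bed], chip_bed)
        assert peaks == []

    def test_empty_chip_empty_output(self, bed_file):
        chip = bed_file([""])
        control = bed_file(["chr1\t100\t136\tr\t0\t+"])
        peaks, info = tf.call_peaks([chip], control, return_info=True)
        assert peaks == []
        assert info.chip_library_sizes == [0]

    def test_recovers_planted_sites(self, small_experiment):
        chip_bed, control_bed, truth, _cfg = small_experiment
        peaks, info = tf.call_peaks([chip_bed], control_bed,
                                    return_info=True)
        result = tf.evaluate_calls(peaks, truth, tol=100)
        assert result.recall >= 0.85
        assert result.fdp <= 0.3
        assert info.r == pytest.approx(
            info.control_library_size / sum(info.chip_library_sizes))
        assert set(info.min_er) == {"+", "-"}
        assert info.stage_counts["final"] == len(peaks)

    def test_deterministic_outputs(self, small_experiment, tmp_path):
        chip_bed, control_bed, _truth, _cfg = small_experiment
        outs = []
        for name in ("a.txt", "b.txt"):
            peaks = tf.call_peaks([chip_bed], control_bed)
            out = tmp_path / name
            tf.write_peaks(peaks, out)
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_detected_regions_pass_pointwise_audit(self, small_experiment):
        """Dual-route check: every region found by the vectorized scan
        passes the per-position conditions when re-tested with the scalar
        coverage/statistic path."""
        chip_bed, control_bed, _truth, _cfg = small_experiment
        chip_reads = tf.read_bed_reads(chip_bed)
        control_reads = tf.read_bed_reads(control_bed)
        r = tf.library_size_ratio(len(chip_reads), len(control_reads))
        params = tf.Parameters(r=r)
        chip_tracks = tf.build_tracks(chip_reads, params.w)
        control_tracks = tf.build_tracks(control_reads, params.w)
        audited = 0
        for (key, chip) in chip_tracks.items():
            control = control_tracks[key]
            for form in FORMS:
                for reg in tf.detect_form_regions(chip, control, form,
                                                  params):
                    assert reg.width > params.min_n
                    for x in range(reg.start, reg.end + 1):
                        assert form_z(chip, x, form, params.delta) \
                            > params.min_z
                        assert tf.z4(chip.coverage_at(x),
                                     control.coverage_at(x), r) \
                            > params.min_z
                    audited += 1
        assert audited > 0

    def test_mirror_symmetry(self, small_experiment, tmp_path):
        """Reflecting all reads through the chromosome and swapping strands
        yields the mirrored peak set (5'-anchored extension is exact under
        reflection; midpoints may shift by 1 bp)."""
        chip_bed, control_bed, _truth, cfg = small_experiment
        L = cfg.genome[0][1]

        def _mirror(path, name):
            flipped = [
                tf.ReadAlignment(r.chrom, L - r.end, L - r.start,
                                 "-" if r.strand == "+" else "+")
                for r in tf.read_bed_reads(path)]
            out = tmp_path / name
            tf.write_reads_bed(sorted(
                flipped, key=lambda r: (r.chrom, r.strand, r.start)), out)
            return out

        fwd_peaks = tf.call_peaks([chip_bed], control_bed)
        rev_peaks = tf.call_peaks([_mirror(chip_bed, "mc.bed")],
                                  _mirror(control_bed, "mk.bed"))
        assert len(fwd_peaks) == len(rev_peaks)
        spans = sorted((p.start, p.end) for p in fwd_peaks)
        mirrored = sorted((L + 1 - p.end, L + 1 - p.start)
                          for p in rev_peaks)
        assert spans == mirrored

    def test_threshold_monotonicity(self, small_experiment):
        """Tightening any detection threshold never yields more peaks."""
        chip_bed, control_bed, _truth, _cfg = small_experiment

        def n_peaks(**kwargs):
            return len(tf.call_peaks([chip_bed], control_bed,
                                     params=tf.Parameters(**kwargs)))

        for key, values in [
            ("min_z", [Z9, 1.96, 3.0]),
            ("min_n", [10, 40, 80]),
            ("min_lag", [10, 60, 200]),
            ("min_er_quantile", [0.375, 0.7, 0.95]),
        ]:
            ns = [n_peaks(**{key: v}) for v in values]
            assert ns[0] >= ns[1] >= ns[2], (key, ns)

    def test_replicates_pool_and_filter(self, small_experiment, tmp_path):
        """Splitting the sample into two replicate files keeps consistent
        strong peaks; adding an empty second replicate removes everything."""
        chip_bed, control_bed, _truth, _cfg = small_experiment
        reads = tf.read_bed_reads(chip_bed)
        half1 = tmp_path / "rep1.bed"
        half2 = tmp_path / "rep2.bed"
        tf.write_reads_bed(reads[0::2], half1)
        tf.write_reads_bed(reads[1::2], half2)
        pooled = tf.call_peaks([chip_bed], control_bed)
        split = tf.call_peaks([half1, half2], control_bed)
        assert 0 < len(split) <= len(pooled)
        # a replicate with no coverage anywhere near the peaks fails the
        # per-replicate sign tests at every region: everything is dropped
        far = tmp_path / "far.bed"
        tf.write_reads_bed([tf.ReadAlignment("chr1", 299_900, 299_936, "+")],
                           far)
        assert tf.call_peaks([chip_bed, far], control_bed) == []
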