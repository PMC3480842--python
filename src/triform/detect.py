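"""Peak detection: per-strand form regions, filters, strand pairing, merging.

The detection procedure, per chromosome and strand, for each of the three
peak forms (1: center above both flanks; 2: above the left flank; 3: above
the right flank):

1. find maximal runs of positions whose form statistic and enrichment
   statistic both strictly exceed ``min_z`` and whose width strictly
   exceeds ``min_n`` bp;
2. set a per-strand enrichment cut-off ``min.er`` as a quantile of the
   center enrichment ratios of the Form-1 regions, and drop regions (all
   forms) whose center enrichment ratio does not strictly exceed it;
3. if two or more ChIP replicates were given, keep only regions where every
   position has positive form and enrichment statistics in every replicate;
4. pair each surviving forward-strand region with the unique overlapping
   reverse-strand region of the same form (ambiguous or unpaired regions
   are dropped);
5. estimate the inter-strand lag of each pair by cross-correlation over the
   pair's δ-extended span and require it to strictly exceed ``min_lag``;
6. score each pair (peak span = union of the two regions, score = sum of
   the two strand NLPs, i.e. a Fisher combination), then remove Form-2/3
   peaks overlapping a Form-1 peak and merge overlapping Form-2/Form-3
   peaks into Form-1 peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import io as _io
from .coverage import (CoverageTrack, Parameters, UndefinedLagError,
                       best_lag, build_tracks, library_size_ratio)
from .io import FORWARD, REVERSE, ReadAlignment
from .stats import enrichment_ratio, nlp_from_z, z1, z2, z3, z4

__all__ = [
    "RegionCandidate",
    "PeakCall",
    "RunInfo",
    "form_z",
    "detect_form_regions",
    "compute_min_er",
    "apply_er_filter",
    "apply_replicate_filter",
    "pair_strand_regions",
    "lag_filter",
    "score_peak",
    "resolve_forms",
    "call_peaks",
]

logger = logging.getLogger(__name__)

FORMS = (1, 2, 3)


@dataclass(frozen=True, slots=True)
class RegionCandidate:
    """A maximal per-strand run of positions passing one form test.

    Coordinates are 1-based inclusive; ``center`` is the span midpoint,
    ``summit`` the position of maximal form-z (smallest such position on
    ties), ``er_center`` the enrichment ratio at the center and ``nlp`` the
    negative log10 p-value of the summit z.
    """

    chrom: str
    strand: str
    form: int
    start: int
    end: int
    center: int
    summit: int
    summit_z: float
    er_center: float
    nlp: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other) -> bool:
        return (self.chrom == other.chrom and self.start <= other.end
                and other.start <= self.end)


@dataclass(frozen=True, slots=True)
class PeakCall:
    """A final two-strand peak call (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    peak_loc: int
    peak_nlp: float
    form: int
    lag: int
    er: float

    def overlaps(self, other) -> bool:
        return (self.chrom == other.chrom and self.start <= other.end
                and other.start <= self.end)


@dataclass
class RunInfo:
    """Run metadata: parameters, library sizes, cut-offs and stage counts."""

    params: dict
    chip_library_sizes: list
    control_library_size: int
    r: float
    min_er: dict
    stage_counts: dict

    def as_dict(self) -> dict:
        return asdict(self)


def _form_z_values(cl, cc, cr, form):
    if form == 1:
        return z1(cl, cc, cr)
    if form == 2:
        return z2(cl, cc)
    if form == 3:
        return z3(cc, cr)
    raise ValueError(f"form must be 1, 2 or 3, got {form}")


def form_z(track: CoverageTrack, x: int, form: int, delta: int) -> float:
    """Form statistic at position ``x`` from coverage at x-δ, x, x+δ."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    cl = track.coverage_at(x - delta)
    cc = track.coverage_at(x)
    cr = track.coverage_at(x + delta)
    return float(_form_z_values(cl, cc, cr, form))


def _mask_runs(mask: np.ndarray):
    """(start_idx, end_idx) pairs of maximal True runs, inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[brk + 1]))
    ends = np.concatenate((idx[brk], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_form_regions(chip: CoverageTrack, control: CoverageTrack,
                        form: int, params: Parameters
                        ) -> list[RegionCandidate]:
    """All maximal regions passing the form and enrichment conditions.

    A region is a maximal run of consecutive positions ``x`` with
    ``form_z(x) > min_z`` and ``z4(x) > min_z``, of width strictly greater
    than ``min_n``.  ``params.r`` must be set.  The control track is the
    strand-matched control coverage.
    """
    if params.r is None:
        raise ValueError("params.r (library size ratio) must be set")
    r = params.r
    delta = params.delta
    regions: list[RegionCandidate] = []
    if chip.is_empty:
        return regions
    # Any passing position has positive ChIP coverage (all four statistics
    # are <= 0 where the center count is 0), so scanning the coverage
    # support is exact; nearby blocks are merged to cut window overhead.
    for lo, hi in chip.support_blocks(merge_gap=delta):
        xs0 = lo
        cc = chip.dense(lo, hi)
        cl = chip.dense(lo - delta, hi - delta)
        cr = chip.dense(lo + delta, hi + delta)
        b = control.dense(lo, hi)
        zf = np.asarray(_form_z_values(cl, cc, cr, form))
        ze = np.asarray(z4(cc, b, r))
        mask = (zf > params.min_z) & (ze > params.min_z)
        for i0, i1 in _mask_runs(mask):
            start = xs0 + i0
            end = xs0 + i1
            if end - start + 1 <= params.min_n:
                continue
            rel = zf[i0:i1 + 1]
            summit_off = int(np.argmax(rel))  # first max: smallest position
            summit_z = float(rel[summit_off])
            center = (start + end) // 2
            ci = center - xs0
            er_c = enrichment_ratio(int(cc[ci]), int(b[ci]), r)
            regions.append(RegionCandidate(
                chrom=chip.chrom, strand=chip.strand, form=form,
                start=start, end=end, center=center,
                summit=start + summit_off, summit_z=summit_z,
                er_center=er_c, nlp=nlp_from_z(summit_z)))
    return regions


def compute_min_er(form1_regions: Sequence[RegionCandidate],
                   quantile: float) -> float:
    """Per-strand min.er: a quantile of Form-1 center enrichment ratios.

    Uses the linear-interpolation ("type 7") quantile convention.  With no
    Form-1 regions on the strand the filter is vacuous (returns 0).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    ers = [reg.er_center for reg in form1_regions]
    if not ers:
        return 0.0
    return float(np.quantile(np.asarray(ers, dtype=np.float64), quantile,
                             method="linear"))


def apply_er_filter(regions: Iterable[RegionCandidate],
                    min_er_by_strand: Mapping[str, float]
                    ) -> list[RegionCandidate]:
    """Keep regions whose center enrichment ratio strictly exceeds min.er."""
    return [reg for reg in regions
            if reg.er_center > min_er_by_strand.get(reg.strand, 0.0)]


def apply_replicate_filter(regions: Iterable[RegionCandidate],
                           replicate_tracks: Sequence[Mapping],
                           control_tracks: Mapping,
                           replicate_ratios: Sequence[float],
                           params: Parameters) -> list[RegionCandidate]:
    """Replicate consistency: every position, every replicate, z > 0.

    ``replicate_tracks`` holds one ``{(chrom, strand): CoverageTrack}``
    mapping per ChIP replicate and ``replicate_ratios`` the corresponding
    control/replicate library-size ratios against the shared control.
    With fewer than two replicates the condition is inapplicable and the
    input passes through unchanged.
    """
    regions = list(regions)
    if len(replicate_tracks) < 2:
        return regions
    if len(replicate_ratios) != len(replicate_tracks):
        raise ValueError("one library ratio is required per replicate")
    empty_cache: dict[tuple[str, str], CoverageTrack] = {}

    def _track(mapping, chrom, strand):
        track = mapping.get((chrom, strand))
        if track is None:
            key = (chrom, strand)
            if key not in empty_cache:
                empty_cache[key] = CoverageTrack(chrom=chrom, strand=strand)
            track = empty_cache[key]
        return track

    kept = []
    delta = params.delta
    for reg in regions:
        control = _track(control_tracks, reg.chrom, reg.strand)
        b = control.dense(reg.start, reg.end)
        ok = True
        for tracks_k, r_k in zip(replicate_tracks, replicate_ratios):
            chip_k = _track(tracks_k, reg.chrom, reg.strand)
            cc = chip_k.dense(reg.start, reg.end)
            cl = chip_k.dense(reg.start - delta, reg.end - delta)
            cr = chip_k.dense(reg.start + delta, reg.end + delta)
            zf = np.asarray(_form_z_values(cl, cc, cr, reg.form))
            ze = np.asarray(z4(cc, b, r_k))
            if not (np.all(zf > 0.0) and np.all(ze > 0.0)):
                ok = False
                break
        if ok:
            kept.append(reg)
    return kept


def pair_strand_regions(fwd_regions: Sequence[RegionCandidate],
                        rev_regions: Sequence[RegionCandidate],
                        form: Optional[int] = None
                        ) -> list[tuple[RegionCandidate, RegionCandidate]]:
    """Pairs of strand regions that overlap each other and nothing else.

    A pair ``(f, r)`` is emitted iff ``f`` overlaps ``r``, ``f`` overlaps
    no other reverse region in the input, and ``r`` overlaps no other
    forward region.  When ``form`` is given, only regions of that form are
    considered.
    """
    fwd = [g for g in fwd_regions if form is None or g.form == form]
    rev = [g for g in rev_regions if form is None or g.form == form]
    fwd_hits: dict[int, list[int]] = {i: [] for i in range(len(fwd))}
    rev_hits: dict[int, list[int]] = {j: [] for j in range(len(rev))}
    for i, f in enumerate(fwd):
        for j, g in enumerate(rev):
            if f.overlaps(g):
                fwd_hits[i].append(j)
                rev_hits[j].append(i)
    pairs = []
    for i, hits in fwd_hits.items():
        if len(hits) == 1 and len(rev_hits[hits[0]]) == 1:
            pairs.append((fwd[i], rev[hits[0]]))
    pairs.sort(key=lambda p: (p[0].chrom, p[0].start, p[1].start))
    return pairs


def lag_filter(pairs: Sequence[tuple[RegionCandidate, RegionCandidate]],
               fwd_track: CoverageTrack, rev_track: CoverageTrack,
               params: Parameters
               ) -> list[tuple[RegionCandidate, RegionCandidate, int]]:
    """Annotate pairs with their inter-strand lag; keep lag > min_lag.

    The lag range runs from δ before the forward region's start to δ past
    the reverse region's end; the searched lags are capped at 2δ.  Pairs
    with an undefined lag (a zero profile) are dropped.
    """
    kept = []
    delta = params.delta
    for f, g in pairs:
        lo = f.start - delta
        hi = g.end + delta
        if hi < lo:
            lo, hi = min(lo, hi), max(lo, hi)
        try:
            lag = best_lag(fwd_track, rev_track, lo, hi,
                           max_lag=min(hi - lo, 2 * delta))
        except UndefinedLagError:
            logger.debug("dropping pair %s:%d-%d / %d-%d: undefined lag",
                         f.chrom, f.start, f.end, g.start, g.end)
            continue
        if lag > params.min_lag:
            kept.append((f, g, lag))
    return kept


def score_peak(fwd: RegionCandidate, rev: RegionCandidate,
               lag: int) -> PeakCall:
    """Combine a strand-region pair into one scored peak.

    The span is the union of the two regions, the location its midpoint
    and the score the sum of the two strand NLPs — a Fisher combination of
    the two strand tests (2·ln10·ΣNLP is the χ² statistic on 4 df).
    """
    if fwd.chrom != rev.chrom:
        raise ValueError("cannot combine regions on different chromosomes")
    start = min(fwd.start, rev.start)
    end = max(fwd.end, rev.end)
    form = fwd.form if fwd.form == rev.form else 1
    return PeakCall(
        chrom=fwd.chrom, start=start, end=end,
        peak_loc=(start + end) // 2,
        peak_nlp=fwd.nlp + rev.nlp, form=form, lag=int(lag),
        er=0.5 * (fwd.er_center + rev.er_center))


def _merge_peaks(members: Sequence[PeakCall]) -> PeakCall:
    start = min(p.start for p in members)
    end = max(p.end for p in members)
    return PeakCall(
        chrom=members[0].chrom, start=start, end=end,
        peak_loc=(start + end) // 2,
        peak_nlp=sum(p.peak_nlp for p in members),
        form=1,
        lag=max(p.lag for p in members),
        er=float(np.mean([p.er for p in members])))


def resolve_forms(peaks1: Sequence[PeakCall], peaks2: Sequence[PeakCall],
                  peaks3: Sequence[PeakCall]) -> list[PeakCall]:
    """Cross-form redundancy resolution.

    Form-2/3 peaks overlapping any Form-1 peak are removed as redundant;
    surviving Form-2 peaks overlapping Form-3 peaks are merged with them
    into Form-1 peaks (union span, summed score, max lag); any residual
    overlap is resolved by keeping the higher-scoring peak.  The result is
    non-overlapping per chromosome, sorted by descending score.
    """
    peaks1 = list(peaks1)
    survivors = [p for p in list(peaks2) + list(peaks3)
                 if not any(p.overlaps(q) for q in peaks1)]

    # Union-find over cross-form overlaps among the surviving Form-2/3 peaks.
    parent = list(range(len(survivors)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, p in enumerate(survivors):
        for j in range(i + 1, len(survivors)):
            q = survivors[j]
            if p.form != q.form and p.overlaps(q):
                parent[find(i)] = find(j)
    groups: dict[int, list[PeakCall]] = {}
    for i, p in enumerate(survivors):
        groups.setdefault(find(i), []).append(p)

    merged: list[PeakCall] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
        else:
            merged.append(_merge_peaks(members))

    # Final non-overlap sweep: greedy by descending score.
    candidates = sorted(peaks1 + merged, key=_io._peak_sort_key)
    final: list[PeakCall] = []
    for p in candidates:
        if not any(p.overlaps(q) for q in final):
            final.append(p)
    return final


def _detect_all_regions(chip_tracks, control_tracks, params, counts):
    regions: dict[tuple[str, str, int], list[RegionCandidate]] = {}
    for (chrom, strand), chip in chip_tracks.items():
        control = control_tracks.get(
            (chrom, strand), CoverageTrack(chrom=chrom, strand=strand))
        for form in FORMS:
            regs = detect_form_regions(chip, control, form, params)
            regions[(chrom, strand, form)] = regs
            counts[f"detected_form{form}_{strand}"] = (
                counts.get(f"detected_form{form}_{strand}", 0) + len(regs))
    return regions


def call_peaks(chip_read_files: Sequence, control_read_file,
               params: Optional[Parameters] = None,
               chrom_sizes: Optional[Mapping[str, int]] = None,
               return_info: bool = False):
    """End-to-end peak calling from BED read files.

    Replicates are pooled into a single sample for the main statistics; the
    replicate consistency filter additionally applies when two or more ChIP
    files are given.  Returns the scored, score-sorted peak list, plus a
    :class:`RunInfo` when ``return_info`` is true.
    """
    if params is None:
        params = Parameters()
    chip_read_files = list(chip_read_files)
    if not chip_read_files:
        raise ValueError("at least one ChIP read file is required")

    per_file_reads = [_io.read_bed_reads(path) for path in chip_read_files]
    control_reads = _io.read_bed_reads(control_read_file)
    pooled = [read for reads in per_file_reads for read in reads]

    counts: dict[str, int] = {}
    min_er: dict[str, float] = {}

    def _result(peaks, r_value):
        info = RunInfo(
            params={k: v for k, v in asdict(params).items()},
            chip_library_sizes=[len(reads) for reads in per_file_reads],
            control_library_size=len(control_reads),
            r=r_value, min_er=min_er, stage_counts=counts)
        return (peaks, info) if return_info else peaks

    if not pooled:
        return _result([], params.r if params.r is not None else float("nan"))

    r = params.r if params.r is not None else library_size_ratio(
        len(pooled), len(control_reads))
    run_params = Parameters(**{**asdict(params), "r": r})

    anchor = run_params.extension_anchor
    chip_tracks = build_tracks(pooled, run_params.w, chrom_sizes,
                               anchor=anchor)
    control_tracks = build_tracks(control_reads, run_params.w, chrom_sizes,
                                  anchor=anchor)

    regions = _detect_all_regions(chip_tracks, control_tracks, run_params,
                                  counts)

    # Per-strand min.er from the significantly enriched Form-1 regions.
    for strand in (FORWARD, REVERSE):
        form1 = [reg for (_, s, form), regs in regions.items() if
                 s == strand and form == 1 for reg in regs]
        min_er[strand] = compute_min_er(form1, run_params.min_er_quantile)

    filtered = {key: apply_er_filter(regs, min_er)
                for key, regs in regions.items()}
    counts["after_er"] = sum(len(v) for v in filtered.values())

    if len(per_file_reads) >= 2:
        replicate_tracks = [build_tracks(reads, run_params.w, chrom_sizes,
                                         anchor=anchor)
                            for reads in per_file_reads]
        replicate_ratios = [
            library_size_ratio(len(reads), len(control_reads))
            for reads in per_file_reads]
        filtered = {
            key: apply_replicate_filter(regs, replicate_tracks,
                                        control_tracks, replicate_ratios,
                                        run_params)
            for key, regs in filtered.items()}
        counts["after_replicate"] = sum(len(v) for v in filtered.values())

    chroms = sorted({chrom for (chrom, _s) in chip_tracks})
    peaks_by_form: dict[int, list[PeakCall]] = {form: [] for form in FORMS}
    n_pairs = n_lag = 0
    for chrom in chroms:
        fwd_track = chip_tracks.get(
            (chrom, FORWARD), CoverageTrack(chrom=chrom, strand=FORWARD))
        rev_track = chip_tracks.get(
            (chrom, REVERSE), CoverageTrack(chrom=chrom, strand=REVERSE))
        if run_params.same_form_pairing:
            form_pairs = [
                (form,
                 filtered.get((chrom, FORWARD, form), []),
                 filtered.get((chrom, REVERSE, form), []))
                for form in FORMS]
        else:
            all_fwd = [reg for form in FORMS
                       for reg in filtered.get((chrom, FORWARD, form), [])]
            all_rev = [reg for form in FORMS
                       for reg in filtered.get((chrom, REVERSE, form), [])]
            form_pairs = [(None, all_fwd, all_rev)]
        for form, fwd_regs, rev_regs in form_pairs:
            pairs = pair_strand_regions(fwd_regs, rev_regs, form=form)
            n_pairs += len(pairs)
            lagged = lag_filter(pairs, fwd_track, rev_track, run_params)
            n_lag += len(lagged)
            for f, g, lag in lagged:
                peak = score_peak(f, g, lag)
                peaks_by_form[peak.form].append(peak)
    counts["pairs"] = n_pairs
    counts["after_lag"] = n_lag
    counts["peaks_before_merge"] = sum(
        len(v) for v in peaks_by_form.values())

    final = resolve_forms(peaks_by_form[1], peaks_by_form[2],
                          peaks_by_form[3])
    counts["final"] = len(final)
    logger.info("peak calling stages: %s", counts)
    return _result(final, r)
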