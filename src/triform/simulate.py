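"""Synthetic TF ChIP-Seq read simulator and call evaluator.

Emulates the coverage-level structure a strand-aware peak caller relies
on: at each planted binding site, sequenced fragment ends produce a
forward-strand read cluster upstream and a reverse-strand cluster
downstream of the site, separated by roughly the fragment length; both
ChIP and the antibody-free control carry uniform Poisson read background.
No sequence-level realism (mappability, repeats, GC) is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import FORWARD, REVERSE, ReadAlignment

__all__ = [
    "SimConfig",
    "TruthSite",
    "TruthTable",
    "simulate_experiment",
    "evaluate_calls",
    "EvalResult",
    "write_truth",
    "read_truth",
]


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults describe a small but realistic TF ChIP-Seq experiment: a 2 Mb
    genome carrying 50 binding sites, 200 bp fragments sequenced for 36 bp,
    40 reads per site per strand with 20 bp site-position jitter, and a
    background of 0.005 reads/bp/strand in both ChIP and control.
    """

    genome: Sequence[tuple[str, int]] = (("chr1", 2_000_000),)
    n_sites: int = 50
    site_positions: Optional[Sequence[tuple[str, int]]] = None
    fragment_length: int = 200
    reads_per_site: float = 40.0
    position_sd: float = 20.0
    background_rate: float = 0.005
    control_rate: float = 0.005
    read_length: int = 36
    seed: int = 0

    def __post_init__(self):
        if any(length <= 0 for _c, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.fragment_length <= self.read_length:
            raise ValueError("fragment_length must exceed read_length")
        for name in ("reads_per_site", "position_sd", "background_rate",
                     "control_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True, slots=True)
class TruthSite:
    chrom: str
    position: int       # 1-based site position
    strength: int       # realized ChIP reads attributable to the site


@dataclass
class TruthTable:
    """Planted binding sites with realized per-site read counts."""

    sites: list[TruthSite] = field(default_factory=list)

    def __len__(self):
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def _emit_reads(chrom, length, starts0, read_length, strand, out):
    for s0 in np.asarray(starts0, dtype=np.int64):
        s = max(int(s0), 0)
        e = min(int(s0) + read_length, length)
        if s < e:
            out.append(ReadAlignment(chrom, s, e, strand))


def _site_reads(rng, chrom, length, pos1, cfg, out):
    """Strand-shifted read clusters for one site; returns realized count."""
    rl = cfg.read_length
    shift = cfg.fragment_length / 2 - rl / 2
    total = 0
    for strand, mean in ((FORWARD, pos1 - 1 - shift),
                         (REVERSE, pos1 - 1 + shift)):
        n = int(rng.poisson(cfg.reads_per_site))
        centers = rng.normal(mean, cfg.position_sd, size=n)
        starts0 = np.rint(centers - rl / 2).astype(np.int64)
        _emit_reads(chrom, length, starts0, rl, strand, out)
        total += n
    return total


def _uniform_reads(rng, chrom, length, rate, read_length, out):
    for strand in (FORWARD, REVERSE):
        n = int(rng.poisson(rate * length))
        starts0 = rng.integers(0, length, size=n)
        _emit_reads(chrom, length, starts0, read_length, strand, out)


def simulate_experiment(config: SimConfig):
    """Draw one synthetic experiment.

    Returns ``(chip_reads, control_reads, truth)``.  Forward-strand read
    centers at a site are normal around ``site - fragment_length/2 +
    read_length/2`` and reverse-strand centers mirror downstream, so the
    expected inter-strand lag is ``fragment_length - read_length``.  Reads
    crossing a chromosome boundary are truncated at emission.  Fully
    reproducible from ``config.seed``: one seed sequence per chromosome,
    spawned deterministically, plus a master stream for site placement.
    """
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    children = ss.spawn(len(config.genome))

    lengths = {chrom: int(length) for chrom, length in config.genome}
    margin = config.fragment_length
    sites_by_chrom: dict[str, list[int]] = {c: [] for c in lengths}
    if config.site_positions is not None:
        for chrom, pos in config.site_positions:
            if chrom not in lengths:
                raise ValueError(f"site on unknown chromosome {chrom!r}")
            if not 1 <= pos <= lengths[chrom]:
                raise ValueError(
                    f"site {chrom}:{pos} outside chromosome bounds")
            sites_by_chrom[chrom].append(int(pos))
    elif config.n_sites > 0:
        total = sum(lengths.values())
        probs = np.array([length / total for length in lengths.values()])
        alloc = master.multinomial(config.n_sites, probs)
        for (chrom, length), n in zip(lengths.items(), alloc):
            if 2 * margin >= length:
                raise ValueError(
                    f"chromosome {chrom} too short for site placement")
            pos = np.sort(master.integers(margin, length - margin, size=n))
            sites_by_chrom[chrom] = [int(p) + 1 for p in pos]

    chip: list[ReadAlignment] = []
    control: list[ReadAlignment] = []
    truth = TruthTable()
    for child, (chrom, length) in zip(children, config.genome):
        rng = np.random.default_rng(child)
        length = int(length)
        for pos1 in sites_by_chrom[chrom]:
            strength = _site_reads(rng, chrom, length, pos1, config, chip)
            truth.sites.append(TruthSite(chrom, pos1, strength))
        _uniform_reads(rng, chrom, length, config.background_rate,
                       config.read_length, chip)
        _uniform_reads(rng, chrom, length, config.control_rate,
                       config.read_length, control)
    chip.sort(key=lambda r: (r.chrom, r.strand, r.start, r.end))
    control.sort(key=lambda r: (r.chrom, r.strand, r.start, r.end))
    return chip, control, truth


@dataclass
class EvalResult:
    """Recall / false-discovery summary of calls against planted truth."""

    recall: float
    fdp: float
    errors: np.ndarray          # |peak_loc - site| of matched peaks, bp
    n_matched: int
    n_peaks: int
    n_truth: int
    no_peaks: bool              # FDP reported as 0 because nothing was called

    @property
    def median_error(self) -> float:
        if self.errors.size == 0:
            return float("nan")
        return float(np.median(self.errors))


def evaluate_calls(peaks, truth: TruthTable, tol: int) -> EvalResult:
    """Greedy 1-to-1 matching of peaks to planted sites within ``tol`` bp.

    Peaks are processed in order of descending score; each is matched to
    the nearest still-unmatched truth site on its chromosome within the
    tolerance.  Recall is matched truth over total truth; the
    false-discovery proportion is unmatched peaks over total peaks (0,
    flagged, when no peaks were called).
    """
    if tol <= 0:
        raise ValueError(f"matching tolerance must be positive, got {tol}")
    peaks = sorted(peaks, key=lambda p: (-p.peak_nlp, p.chrom, p.start))
    unmatched = {i: site for i, site in enumerate(truth.sites)}
    errors = []
    for peak in peaks:
        best_i, best_d = None, None
        for i, site in unmatched.items():
            if site.chrom != peak.chrom:
                continue
            d = abs(peak.peak_loc - site.position)
            if d <= tol and (best_d is None or d < best_d
                             or (d == best_d and site.position
                                 < unmatched[best_i].position)):
                best_i, best_d = i, d
        if best_i is not None:
            del unmatched[best_i]
            errors.append(best_d)
    n_matched = len(errors)
    n_peaks = len(peaks)
    n_truth = len(truth.sites)
    recall = n_matched / n_truth if n_truth else 1.0
    no_peaks = n_peaks == 0
    fdp = 0.0 if no_peaks else (n_peaks - n_matched) / n_peaks
    return EvalResult(recall=recall, fdp=fdp,
                      errors=np.asarray(errors, dtype=np.float64),
                      n_matched=n_matched, n_peaks=n_peaks,
                      n_truth=n_truth, no_peaks=no_peaks)


def write_truth(truth: TruthTable, path):
    """Write the truth table as tab-delimited chrom, position, strength."""
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrength\n")
        for site in truth.sites:
            fh.write(f"{site.chrom}\t{site.position}\t{site.strength}\n")


def read_truth(path) -> TruthTable:
    truth = TruthTable()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"unexpected truth table header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, strength = line.rstrip("\n").split("\t")
            truth.sites.append(TruthSite(chrom, int(pos), int(strength)))
    return truth
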