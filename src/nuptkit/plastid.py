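"""Plastid genome structure and NUPT donor hotspot/coldspot analysis.

Angiosperm plastid genomes are typically quadripartite: a Large Single Copy
(LSC), Inverted Repeat A (IRa), Small Single Copy (SSC), and Inverted Repeat
B (IRb), with IRb the exact reverse complement of IRa.  NUPT donor sites are
summarised as a per-bp coverage track over the plastid genome; positions
whose coverage exceeds Q3 + 1.5*IQR are hotspots, positions covered by no
NUPT are coldspots.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corestats import RankCorrResult, iqr_threshold, kendall_tau, spearman_rho
from .errors import InputError, StatisticsError

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlastidPartition:
    """Quadripartite structure of a plastid genome.

    Intervals are 0-based half-open; all four are None for genomes without
    the canonical structure (no reverse-complement repeat pair long enough).
    ``lsc``/``ssc`` may additionally be None when an IR pair is found but the
    single-copy regions do not form two contiguous linear segments.
    """

    total_length: int
    lsc: tuple[int, int] | None = None
    ira: tuple[int, int] | None = None
    ssc: tuple[int, int] | None = None
    irb: tuple[int, int] | None = None

    @property
    def is_quadripartite(self) -> bool:
        return all(x is not None for x in (self.lsc, self.ira, self.ssc, self.irb))

    def ir_intervals(self) -> list[tuple[int, int]]:
        return [iv for iv in (self.ira, self.irb) if iv is not None]


@dataclass
class CoverageTrack:
    """Per-bp NUPT donor coverage over the plastid genome."""

    counts: np.ndarray  # non-negative int, one entry per plastid position

    @property
    def total_length(self) -> int:
        return len(self.counts)


@dataclass
class SpotSet:
    """Hotspot/coldspot call over a coverage track.

    A hotspot position has coverage strictly above Q3 + 1.5*IQR; a coldspot
    position has zero coverage.  The two sets are disjoint whenever the
    threshold is non-negative, which it always is for count data.
    """

    hotspot_positions: np.ndarray
    coldspot_positions: np.ndarray
    q1: float
    q3: float
    iqr: float
    threshold: float
    hotspot_fraction: float
    coldspot_fraction: float
    total_length: int


# ---------------------------------------------------------------------------
# inverted repeat detection
# ---------------------------------------------------------------------------

def _maximal_rc_matches(seq: str, min_len: int, k: int = 24):
    """Yield maximal exact matches (i, j, L) between ``seq`` and its reverse
    complement, seeded on left-maximal shared k-mers."""
    n = len(seq)
    if n < 2 * min_len:
        return
    rc = revcomp(seq)
    anchors: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        anchors.setdefault(seq[i:i + k], []).append(i)
    seen = set()
    for j in range(n - k + 1):
        kmer = rc[j:j + k]
        hits = anchors.get(kmer)
        if not hits:
            continue
        for i in hits:
            # only extend left-maximal anchor pairs: each maximal match is
            # then processed once instead of once per internal k-mer
            if i > 0 and j > 0 and seq[i - 1] == rc[j - 1]:
                continue
            li, lj = i, j
            ri, rj = i + k, j + k
            while ri < n and rj < n and seq[ri] == rc[rj]:
                ri += 1
                rj += 1
            length = ri - li
            if length < min_len:
                continue
            key = (li, lj, length)
            if key not in seen:
                seen.add(key)
                yield li, lj, length


def detect_inverted_repeats(sequence: str, min_ir_length: int = 1000) -> PlastidPartition:
    """Locate the longest pair of non-overlapping exact reverse-complement
    repeats and derive the quadripartite partition.

    The partition assigns the longest single-copy segment as LSC and the
    other as SSC.  When no repeat pair of length >= ``min_ir_length`` exists
    the genome is reported as non-quadripartite (all intervals None).
    """
    if len(sequence) == 0:
        raise InputError("empty plastid sequence")
    seq = sequence.upper()
    n = len(seq)
    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    k = min(24, min_ir_length)
    for i, j, length in _maximal_rc_matches(seq, min_ir_length, k=k):
        # match at rc position j maps back to seq interval [n-j-L, n-j)
        a = (i, i + length)
        b = (n - j - length, n - j)
        if a[0] > b[0]:
            a, b = b, a
        if a[1] > b[0]:  # overlapping (palindromic) pair: trim is out of scope
            continue
        if best is None or length > best[0]:
            best = (length, a, b)
    if best is None:
        return PlastidPartition(total_length=n)
    _, ira, irb = best
    left = (0, ira[0])
    mid = (ira[1], irb[0])
    right = (irb[1], n)
    segments = [s for s in (left, mid, right) if s[1] > s[0]]
    if len(segments) > 2 or len(segments) == 0:
        # rotated circular genome (LSC wraps the origin): IRs located but the
        # single-copy regions are not two contiguous linear segments
        return PlastidPartition(total_length=n, ira=ira, irb=irb)
    if len(segments) == 1:
        lsc, ssc = segments[0], None
    else:
        segments.sort(key=lambda s: (s[1] - s[0]), reverse=True)
        lsc, ssc = segments[0], segments[1]
    return PlastidPartition(total_length=n, lsc=lsc, ira=ira, ssc=ssc, irb=irb)


# ---------------------------------------------------------------------------
# coverage and spot calling
# ---------------------------------------------------------------------------

def coverage_track(nupts, total_length: int) -> CoverageTrack:
    """Per-bp donor coverage: counts[i] = number of NUPTs whose plastid
    (donor) interval covers position i."""
    diff = np.zeros(total_length + 1, dtype=np.int64)
    for rec in nupts:
        s, e = rec.plastid_start, rec.plastid_end
        if s < 0 or e > total_length or s >= e:
            raise InputError(
                f"NUPT {rec.id}: donor interval [{s}, {e}) outside plastid "
                f"[0, {total_length})"
            )
        diff[s] += 1
        diff[e] -= 1
    return CoverageTrack(np.cumsum(diff[:-1]))


def call_spots(track: CoverageTrack) -> SpotSet:
    """IQR-rule hotspots (coverage > Q3 + 1.5*IQR) and zero-coverage
    coldspots over a per-bp track."""
    counts = np.asarray(track.counts)
    if counts.size == 0:
        raise InputError("empty coverage track")
    q1, q3, iqr, threshold = iqr_threshold(counts)
    hot = np.flatnonzero(counts > threshold)
    cold = np.flatnonzero(counts == 0)
    n = counts.size
    return SpotSet(
        hotspot_positions=hot,
        coldspot_positions=cold,
        q1=q1, q3=q3, iqr=iqr, threshold=threshold,
        hotspot_fraction=len(hot) / n,
        coldspot_fraction=len(cold) / n,
        total_length=n,
    )


def spot_fraction_correlation(per_species) -> tuple[RankCorrResult, RankCorrResult]:
    """Kendall and Spearman correlation between a per-species spot fraction
    (hotspot or coldspot) and the fraction of plastid DNA in the nucleus.

    ``per_species`` is a sequence of (spot_fraction, nupt_fraction) pairs.
    """
    pairs = list(per_species)
    if len(pairs) < 3:
        raise StatisticsError(f"need at least 3 species, got {len(pairs)}")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    return kendall_tau(x, y), spearman_rho(x, y)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _positions_to_intervals(positions: np.ndarray) -> list[tuple[int, int]]:
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [positions.size - 1]])
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def write_spots_bed(spots: SpotSet, path, chrom: str = "plastid") -> None:
    """Write hotspot/coldspot runs as BED (0-based half-open) intervals."""
    with open(path, "w") as fh:
        for name, positions in (("hotspot", spots.hotspot_positions),
                                ("coldspot", spots.coldspot_positions)):
            for s, e in _positions_to_intervals(np.asarray(positions)):
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_spots_summary(spots: SpotSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("q1\tq3\tiqr\tthreshold\thotspot_fraction\tcoldspot_fraction\n")
        fh.write(f"{spots.q1:g}\t{spots.q3:g}\t{spots.iqr:g}\t{spots.threshold:g}\t"
                 f"{spots.hotspot_fraction:.6g}\t{spots.coldspot_fraction:.6g}\n")
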