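"""NUPT calling from plastid-vs-nuclear alignment hits.

Every alignment hit in the 12-column tabular format (qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore; query =
plastid, subject = nuclear) is one candidate NUPT.  Because the two plastid
inverted repeats are sequence-identical, a NUPT whose donor lies in an IR
aligns to both copies and is reported twice; such duplicated hits are
counted once, keeping one IR copy chosen at random (seeded).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aging
from .errors import InputError, ParseError
from .intervals import reciprocal_overlap
from .plastid import PlastidPartition

#: fraction of a hit's plastid interval that must lie inside an IR for the
#: hit to be treated as IR-redundant candidate
IR_OVERLAP_FRACTION = 0.5
#: reciprocal nuclear-interval overlap grouping the two IR copies of a hit
RECIPROCAL_OVERLAP_MIN = 0.9

LOG10_SIZE_BIN_WIDTH = 0.25


@dataclass(frozen=True)
class TabularHit:
    """One row of 12-column tabular alignment output (1-based inclusive
    coordinates; send < sstart on the nuclear minus strand)."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    row: int = 0  # 1-based row number in the source file


@dataclass
class NuptRecord:
    """A called NUPT: nuclear locus, plastid donor locus, size and age."""

    id: str
    nuclear_chrom: str
    nuclear_start: int  # 0-based half-open
    nuclear_end: int
    plastid_start: int  # 0-based half-open
    plastid_end: int
    size: int
    pident: float
    p_dist: float
    K: float
    in_ir: bool
    source_hit_index: int

    @property
    def nuclear_interval(self) -> tuple[int, int]:
        return (self.nuclear_start, self.nuclear_end)

    @property
    def plastid_interval(self) -> tuple[int, int]:
        return (self.plastid_start, self.plastid_end)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_hits(path) -> list[TabularHit]:
    """Read and validate a 12-column tabular hit file."""
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, found {len(fields)}",
                    line=lineno,
                )
            try:
                hit = TabularHit(
                    qseqid=fields[0], sseqid=fields[1],
                    pident=float(fields[2]), length=int(fields[3]),
                    mismatch=int(fields[4]), gapopen=int(fields[5]),
                    qstart=int(fields[6]), qend=int(fields[7]),
                    sstart=int(fields[8]), send=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                    row=lineno,
                )
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from exc
            if not 0.0 <= hit.pident <= 100.0:
                raise ParseError(f"pident {hit.pident} outside [0, 100]", line=lineno)
            if hit.length < 1 or hit.mismatch > hit.length or hit.mismatch < 0:
                raise ParseError(
                    f"invalid length/mismatch ({hit.length}/{hit.mismatch})",
                    line=lineno,
                )
            if hit.qstart > hit.qend:
                raise ParseError("qstart > qend (query must be plus strand)",
                                 line=lineno)
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# IR deduplication and record construction
# ---------------------------------------------------------------------------

def _plastid_interval(hit: TabularHit) -> tuple[int, int]:
    return (hit.qstart - 1, hit.qend)


def _nuclear_interval(hit: TabularHit) -> tuple[int, int]:
    s, e = hit.sstart, hit.send
    if s > e:
        s, e = e, s
    return (s - 1, e)


def _ir_fraction(interval: tuple[int, int], partition: PlastidPartition) -> float:
    s, e = interval
    span = e - s
    ov = 0
    for ir in partition.ir_intervals():
        ov += max(0, min(e, ir[1]) - max(s, ir[0]))
    return ov / span if span else 0.0


def _ir_side(interval: tuple[int, int], partition: PlastidPartition) -> str:
    """Which IR copy holds more of the interval ('ira' or 'irb')."""
    s, e = interval
    ov_a = ov_b = 0
    if partition.ira:
        ov_a = max(0, min(e, partition.ira[1]) - max(s, partition.ira[0]))
    if partition.irb:
        ov_b = max(0, min(e, partition.irb[1]) - max(s, partition.irb[0]))
    return "ira" if ov_a >= ov_b else "irb"


def _cluster_by_reciprocal_overlap(items: list[tuple[int, tuple[int, int]]]):
    """Greedy single-linkage clustering of (index, interval) pairs by
    reciprocal overlap >= RECIPROCAL_OVERLAP_MIN; input sorted by start."""
    clusters: list[list[tuple[int, tuple[int, int]]]] = []
    for idx, iv in sorted(items, key=lambda t: t[1]):
        placed = False
        for cl in clusters:
            if any(reciprocal_overlap(iv, other) >= RECIPROCAL_OVERLAP_MIN
                   for _, other in cl):
                cl.append((idx, iv))
                placed = True
                break
        if not placed:
            clusters.append([(idx, iv)])
    return clusters


def hits_to_nupts(hits: list[TabularHit], partition: PlastidPartition,
                  seed: int = 0) -> list[NuptRecord]:
    """Turn validated hits into NUPT records, removing IR redundancy.

    Hits with >= 50% of their plastid interval inside an IR are grouped by
    nuclear locus (same chromosome, reciprocal overlap >= 0.9); within each
    group, IRa-side and IRb-side copies are paired off and one member of
    each pair is kept by a seeded uniform draw.  Applying the operation to
    its own output changes nothing (surviving hits have no IR partner).
    """
    rng = np.random.default_rng(seed)
    has_irs = bool(partition.ir_intervals())

    keep = np.ones(len(hits), dtype=bool)
    in_ir_flags = [False] * len(hits)

    if has_irs:
        ir_hits_by_chrom: dict[str, list[tuple[int, tuple[int, int]]]] = {}
        for idx, hit in enumerate(hits):
            if _ir_fraction(_plastid_interval(hit), partition) >= IR_OVERLAP_FRACTION:
                in_ir_flags[idx] = True
                ir_hits_by_chrom.setdefault(hit.sseqid, []).append(
                    (idx, _nuclear_interval(hit))
                )
        for chrom_items in ir_hits_by_chrom.values():
            for cluster in _cluster_by_reciprocal_overlap(chrom_items):
                sides: dict[str, list[int]] = {"ira": [], "irb": []}
                for idx, _ in cluster:
                    sides[_ir_side(_plastid_interval(hits[idx]), partition)].append(idx)
                for a_idx, b_idx in zip(sorted(sides["ira"]), sorted(sides["irb"])):
                    drop = a_idx if rng.integers(2) == 1 else b_idx
                    keep[drop] = False

    records: list[NuptRecord] = []
    for idx, hit in enumerate(hits):
        if not keep[idx]:
            continue
        ns, ne = _nuclear_interval(hit)
        ps, pe = _plastid_interval(hit)
        p = aging.p_distance(hit)
        if p >= aging.P_SATURATION:
            raise InputError(
                f"hit row {hit.row}: p-distance {p:.3f} at or beyond JC69 "
                "saturation (0.75)"
            )
        records.append(NuptRecord(
            id=f"nupt{len(records):05d}",
            nuclear_chrom=hit.sseqid,
            nuclear_start=ns, nuclear_end=ne,
            plastid_start=ps, plastid_end=pe,
            size=ne - ns,
            pident=hit.pident,
            p_dist=p,
            K=aging.jc69(p),
            in_ir=in_ir_flags[idx],
            source_hit_index=idx,
        ))
    return records


# ---------------------------------------------------------------------------
# per-species summary
# ---------------------------------------------------------------------------

def summarize(nupts, nuclear_genome_size: int, plastid_size: int) -> dict:
    """Per-species catalog summary: count, size range, cumulative size, the
    fraction of the nuclear genome of plastid origin, and a log10-size
    histogram with fixed bin width."""
    if nuclear_genome_size <= 0:
        raise InputError("nuclear genome size must be positive")
    sizes = np.array([r.size for r in nupts], dtype=float)
    if sizes.size == 0:
        return {
            "count": 0, "min_size": 0, "max_size": 0, "cumulative_size": 0,
            "mean_size": 0.0, "median_size": 0.0, "genome_fraction": 0.0,
            "nuclear_genome_size": nuclear_genome_size,
            "plastid_size": plastid_size,
            "log10_size_hist": {"bin_edges": [], "counts": []},
        }
    cumulative = int(sizes.sum())
    log10 = np.log10(sizes)
    lo = np.floor(log10.min() / LOG10_SIZE_BIN_WIDTH) * LOG10_SIZE_BIN_WIDTH
    hi = np.ceil(log10.max() / LOG10_SIZE_BIN_WIDTH) * LOG10_SIZE_BIN_WIDTH
    n_bins = max(1, int(round((hi - lo) / LOG10_SIZE_BIN_WIDTH)))
    edges = lo + LOG10_SIZE_BIN_WIDTH * np.arange(n_bins + 1)
    hist, _ = np.histogram(log10, bins=edges)
    return {
        "count": int(sizes.size),
        "min_size": int(sizes.min()),
        "max_size": int(sizes.max()),
        "cumulative_size": cumulative,
        "mean_size": float(sizes.mean()),
        "median_size": float(np.median(sizes)),
        "genome_fraction": cumulative / nuclear_genome_size,
        "nuclear_genome_size": nuclear_genome_size,
        "plastid_size": plastid_size,
        "log10_size_hist": {
            "bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in hist],
        },
    }


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def catalog_frame(nupts) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": r.id, "chrom": r.nuclear_chrom, "start": r.nuclear_start,
         "end": r.nuclear_end, "size": r.size,
         "plastid_start": r.plastid_start, "plastid_end": r.plastid_end,
         "pident": r.pident, "p_dist": r.p_dist, "K": r.K, "in_ir": r.in_ir}
        for r in nupts
    ])


def write_catalog(nupts, tsv_path, bed_path=None) -> None:
    catalog_frame(nupts).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in nupts:
                fh.write(f"{r.nuclear_chrom}\t{r.nuclear_start}\t{r.nuclear_end}"
                         f"\t{r.id}\n")


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
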