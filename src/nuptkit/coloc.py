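"""Spatial association between NUPTs and annotated nuclear features.

Three complementary statistics, all on base-pair interval sets:

* expected-overlap test — observed overlapping bp against the expectation
  proportional to the fraction of the genome each feature occupies, judged
  by a Yates-corrected chi-squared on the 2x2 bp table;
* Jaccard permutation test — intersection/union bp against a null built by
  shuffling NUPTs across the genome while preserving their lengths and the
  multiset of inter-NUPT spacings;
* relative distance test (RDT) — distances between NUPT centers and their
  flanking feature centers, uniform on [0, 0.5] under independence, with a
  signed correlation-like measure C = (0.25 - mean(d))/0.25 (positive =
  NUPTs closer to features than expected).

Permutation p-values are two-sided, centered on the null mean, and computed
as (1 + #extreme)/(n_perm + 1) so they are never zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, StatisticsError
from . import intervals as iv

PROMOTER_TERMINATOR_BP = 1000


@dataclass
class FeatureTrack:
    """A labeled set of genomic intervals (0-based half-open, per chromosome)."""

    label: str
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) sorted by start

    @classmethod
    def from_pairs(cls, label: str, pairs) -> "FeatureTrack":
        by_chrom: dict[str, list] = {}
        for chrom, s, e in pairs:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(label, {c: iv.as_array(sorted(v)) for c, v in by_chrom.items()})

    def total_bp(self) -> int:
        return sum(iv.total_length(iv.merge(a)) for a in self.intervals.values())

    def centers(self) -> dict[str, np.ndarray]:
        return {c: np.sort((a[:, 0] + a[:, 1]) / 2.0)
                for c, a in self.intervals.items() if len(a)}


@dataclass
class GeneModel:
    """One gene reduced to its longest isoform's exon chain."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, 0-based half-open


@dataclass
class OverlapTestResult:
    observed_bp: int
    expected_bp: float
    chi2: float
    p_value: float
    direction: str  # "over" | "under" | "none"
    degenerate: bool = False


@dataclass
class JaccardResult:
    j_obs: float
    null_j: np.ndarray
    p_value: float
    degenerate: bool = False


@dataclass
class RdtResult:
    c_measure: float
    rel_distances: np.ndarray  # in [0, 0.5]
    p_value: float
    n_used: int
    n_dropped: int
    null_c: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SpatialTestResult:
    track_label: str
    test: str  # "overlap_chi2" | "jaccard" | "rdt"
    statistic: float
    p_value: float
    sign: str  # "over"/"under"/"closer"/"farther"/"none"
    n_perm: int
    degenerate: bool
    detail: object = None


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def _open_gff_db(gff3_path):
    import gffutils
    try:
        return gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                                  keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # gffutils raises assorted parse failures
        raise ParseError(f"malformed GFF3 {gff3_path}: {exc}") from exc


def _matches(feature, spec: dict) -> bool:
    if feature.featuretype != spec.get("featuretype"):
        return False
    for key, allowed in spec.get("attributes", {}).items():
        values = feature.attributes.get(key, [])
        if not any(v in allowed for v in values):
            return False
    return True


def load_features(gff3_path, class_map: dict[str, dict]) -> dict[str, FeatureTrack]:
    """Group GFF3 features into labeled tracks.

    ``class_map`` maps a track label to a matcher:
    ``{"featuretype": "transposable_element",
       "attributes": {"te_order": ["LTR"]}}``.
    GFF3 1-based inclusive coordinates become 0-based half-open internally.
    """
    db = _open_gff_db(gff3_path)
    pairs: dict[str, list] = {label: [] for label in class_map}
    for feature in db.all_features():
        for label, spec in class_map.items():
            if _matches(feature, spec):
                pairs[label].append((feature.seqid, feature.start - 1, feature.end))
    return {label: FeatureTrack.from_pairs(label, p) for label, p in pairs.items()}


def class_map_from_labels(labels) -> dict[str, dict]:
    """Matchers for the simulator's GFF3 conventions, from hierarchy-path
    labels such as ``TE/Retrotransposon/LTR`` or ``RNA/regulatory/isrR``."""
    out = {}
    for label in labels:
        parts = label.split("/")
        if parts[0] == "TE":
            names = ["te_class", "te_order", "te_superfamily"]
            out[label] = {"featuretype": "transposable_element",
                          "attributes": {n: [v] for n, v in zip(names, parts[1:])}}
        elif parts[0] == "RNA":
            names = ["rna_class", "rna_subclass"]
            out[label] = {"featuretype": "ncRNA",
                          "attributes": {n: [v] for n, v in zip(names, parts[1:])}}
        else:
            out[label] = {"featuretype": "gene", "attributes": {}}
    return out


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Genes reduced to their longest isoform (greatest summed exon length;
    ties break toward the lexicographically lowest mRNA ID)."""
    db = _open_gff_db(gff3_path)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        isoforms = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")]
            if not exons:
                warnings.warn(f"mRNA {mrna.id} has no exons; skipped")
                continue
            isoforms.append((sum(e - s for s, e in exons), mrna.id, sorted(exons)))
        if not isoforms:
            continue
        isoforms.sort(key=lambda t: (-t[0], t[1]))
        _, _, exons = isoforms[0]
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exons))
    return genes


def derive_gene_parts(genes: list[GeneModel],
                      chromosome_lengths: dict[str, int]) -> dict[str, FeatureTrack]:
    """Promoter/exon/intron/terminator tracks from longest-isoform genes.

    Promoter = 1 kb immediately 5' of the first exon and terminator = 1 kb
    immediately 3' of the last exon, strand-aware and clipped at chromosome
    bounds; introns are the gaps between consecutive exons.
    """
    parts: dict[str, list] = {"promoter": [], "exon": [], "intron": [],
                              "terminator": []}
    for g in genes:
        clen = chromosome_lengths[g.chrom]
        first_s, _ = g.exons[0]
        _, last_e = g.exons[-1]
        for s, e in g.exons:
            if e > clen or s < 0:
                raise ParseError(
                    f"gene {g.gene_id}: exon [{s}, {e}) outside chromosome "
                    f"{g.chrom} of {clen} bp")
            parts["exon"].append((g.chrom, s, e))
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            if s2 > e1:
                parts["intron"].append((g.chrom, e1, s2))
        if g.strand == "-":
            upstream = (last_e, min(clen, last_e + PROMOTER_TERMINATOR_BP))
            downstream = (max(0, first_s - PROMOTER_TERMINATOR_BP), first_s)
        else:
            upstream = (max(0, first_s - PROMOTER_TERMINATOR_BP), first_s)
            downstream = (last_e, min(clen, last_e + PROMOTER_TERMINATOR_BP))
        if upstream[1] > upstream[0]:
            parts["promoter"].append((g.chrom, *upstream))
        if downstream[1] > downstream[0]:
            parts["terminator"].append((g.chrom, *downstream))
    return {name: FeatureTrack.from_pairs(name, p) for name, p in parts.items()}


# ---------------------------------------------------------------------------
# interval bookkeeping
# ---------------------------------------------------------------------------

def nupt_intervals_by_chrom(nupts) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list] = {}
    for r in nupts:
        by_chrom.setdefault(r.nuclear_chrom, []).append(
            (r.nuclear_start, r.nuclear_end))
    return {c: iv.as_array(sorted(v)) for c, v in by_chrom.items()}


def _coerce(nupts) -> dict[str, np.ndarray]:
    if isinstance(nupts, dict):
        return {c: iv.as_array(a) for c, a in nupts.items()}
    return nupt_intervals_by_chrom(nupts)


def _pooled_intersection(a: dict, b: dict) -> int:
    return sum(iv.intersection_length(a[c], b[c]) for c in a.keys() & b.keys())


def _pooled_union(a: dict, b: dict) -> int:
    total = 0
    for c in a.keys() | b.keys():
        total += iv.total_length(iv.merge(np.concatenate(
            [a.get(c, iv.as_array([])), b.get(c, iv.as_array([]))])))
    return total


def _pooled_bp(a: dict) -> int:
    return sum(iv.total_length(iv.merge(arr)) for arr in a.values())


# ---------------------------------------------------------------------------
# expected-overlap chi-squared test
# ---------------------------------------------------------------------------

def expected_overlap_test(nupts, track: FeatureTrack,
                          genome_size_bp: int) -> OverlapTestResult:
    """Observed vs expected overlapping bp, judged by a Yates-corrected
    chi-squared on the 2x2 bp table {NUPT, non-NUPT} x {feature, non-feature}.

    The expectation is proportional to the fraction of the genome the
    feature occupies: E = NUPT_bp * feature_bp / genome_bp.  Zero-bp tracks
    (or NUPT sets) give a degenerate result with direction "none" and p = 1.
    The bp-unit table treats positions as independent draws, which is exact
    only in the limit of 1-bp intervals; see the methods documentation.
    """
    nupt_ivs = _coerce(nupts)
    feat_ivs = track.intervals
    nupt_bp = _pooled_bp(nupt_ivs)
    feat_bp = _pooled_bp(feat_ivs)
    observed = _pooled_intersection(nupt_ivs, feat_ivs)
    if nupt_bp == 0 or feat_bp == 0 or genome_size_bp <= 0:
        return OverlapTestResult(observed, 0.0, 0.0, 1.0, "none", degenerate=True)
    expected = nupt_bp * feat_bp / genome_size_bp
    table = np.array([
        [observed, nupt_bp - observed],
        [feat_bp - observed, genome_size_bp - nupt_bp - feat_bp + observed],
    ], dtype=float)
    if (table < 0).any() or table.sum(axis=1).min() <= 0 or table.sum(axis=0).min() <= 0:
        return OverlapTestResult(observed, expected, 0.0, 1.0, "none",
                                 degenerate=True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    if observed > expected:
        direction = "over"
    elif observed < expected:
        direction = "under"
    else:
        direction = "none"
    return OverlapTestResult(observed, expected, float(chi2), float(p), direction)


# ---------------------------------------------------------------------------
# spacing-preserving permutation
# ---------------------------------------------------------------------------

def permute_nupts(nupts, chromosome_lengths: dict[str, int],
                  rng) -> dict[str, np.ndarray]:
    """Shuffle NUPTs along each chromosome keeping their lengths and the
    multiset of inter-interval spacings (including both flanking gaps).

    Per chromosome the n+1 gaps and the n interval lengths are independently
    re-ordered and laid out left to right; total span is conserved and no
    overlaps are introduced.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out: dict[str, np.ndarray] = {}
    for chrom, arr in _coerce(nupts).items():
        clen = chromosome_lengths[chrom]
        if len(arr) == 0:
            out[chrom] = arr
            continue
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        starts, ends = arr[:, 0], arr[:, 1]
        lengths = ends - starts
        # gaps between consecutive intervals plus the two flanks:
        gaps = np.concatenate([[starts[0]], starts[1:] - ends[:-1],
                               [clen - ends[-1]]])
        perm_lengths = rng.permutation(lengths)
        perm_gaps = rng.permutation(gaps)
        new = np.empty_like(arr)
        pos = 0
        for i, L in enumerate(perm_lengths):
            pos += perm_gaps[i]
            new[i, 0] = pos
            new[i, 1] = pos + L
            pos += L
        out[chrom] = new
    return out


# ---------------------------------------------------------------------------
# Jaccard permutation test
# ---------------------------------------------------------------------------

def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    center = null.mean()
    extreme = np.sum(np.abs(null - center) >= abs(obs - center) - 1e-15)
    return float((1 + extreme) / (len(null) + 1))


def jaccard_test(nupts, track: FeatureTrack, chromosome_lengths: dict[str, int],
                 n_perm: int = 1000, seed: int = 0) -> JaccardResult:
    """Genome-pooled Jaccard index of NUPTs vs a feature track, with a
    spacing-preserving permutation null."""
    nupt_ivs = _coerce(nupts)
    feat_ivs = track.intervals
    union = _pooled_union(nupt_ivs, feat_ivs)
    if union == 0:
        return JaccardResult(0.0, np.empty(0), 1.0, degenerate=True)
    j_obs = _pooled_intersection(nupt_ivs, feat_ivs) / union
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = permute_nupts(nupt_ivs, chromosome_lengths, rng)
        u = _pooled_union(perm, feat_ivs)
        null[i] = _pooled_intersection(perm, feat_ivs) / u if u else 0.0
    return JaccardResult(float(j_obs), null, _perm_pvalue(j_obs, null))


# ---------------------------------------------------------------------------
# relative distance test
# ---------------------------------------------------------------------------

def _relative_distances(nupt_ivs: dict, feat_centers: dict
                        ) -> tuple[np.ndarray, int]:
    ds = []
    dropped = 0
    for chrom, arr in nupt_ivs.items():
        centers = feat_centers.get(chrom)
        x = (arr[:, 0] + arr[:, 1]) / 2.0
        if centers is None or len(centers) < 2:
            dropped += len(arr)
            continue
        inside = (x >= centers[0]) & (x <= centers[-1])
        dropped += int((~inside).sum())
        x = x[inside]
        if len(x) == 0:
            continue
        right = np.searchsorted(centers, x, side="left")
        right = np.clip(right, 1, len(centers) - 1)
        a = centers[right - 1]
        b = centers[right]
        ds.append(np.minimum(x - a, b - x) / (b - a))
    if ds:
        return np.concatenate(ds), dropped
    return np.empty(0), dropped


def relative_distance_test(nupts, track: FeatureTrack,
                           chromosome_lengths: dict[str, int],
                           n_perm: int = 1000, seed: int = 0) -> RdtResult:
    """Relative distances of NUPT centers to flanking feature centers.

    Each usable NUPT center x with flanking feature centers a <= x <= b on
    the same chromosome contributes d = min(x-a, b-x)/(b-a) in [0, 0.5];
    NUPT centers outside the feature span are dropped and counted.  The
    signed measure C = (0.25 - mean(d))/0.25 is positive when NUPTs sit
    closer to features than the uniform null; its p-value comes from the
    spacing-preserving permutation null.
    """
    nupt_ivs = _coerce(nupts)
    centers = track.centers()
    d_obs, dropped = _relative_distances(nupt_ivs, centers)
    if len(d_obs) == 0:
        raise StatisticsError(
            f"no usable NUPT centers within the span of track {track.label!r}")
    c_obs = (0.25 - float(d_obs.mean())) / 0.25
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = permute_nupts(nupt_ivs, chromosome_lengths, rng)
        d_p, _ = _relative_distances(perm, centers)
        null[i] = (0.25 - float(d_p.mean())) / 0.25 if len(d_p) else 0.0
    return RdtResult(c_obs, d_obs, _perm_pvalue(c_obs, null),
                     n_used=len(d_obs), n_dropped=dropped, null_c=null)


# ---------------------------------------------------------------------------
# suite driver
# ---------------------------------------------------------------------------

def run_coloc_suite(nupts, tracks: dict[str, FeatureTrack],
                    chromosome_lengths: dict[str, int],
                    n_perm: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> list[SpatialTestResult]:
    """All three tests for every track; per-track degeneracies are reported
    as flagged rows instead of aborting the suite."""
    genome_size = sum(chromosome_lengths.values())
    results: list[SpatialTestResult] = []
    for ti, (label, track) in enumerate(sorted(tracks.items())):
        ov = expected_overlap_test(nupts, track, genome_size)
        results.append(SpatialTestResult(
            label, "overlap_chi2", ov.chi2, ov.p_value, ov.direction, 0,
            ov.degenerate, ov))
        jc = jaccard_test(nupts, track, chromosome_lengths, n_perm,
                          seed=seed + 1000 * ti)
        j_sign = "none" if jc.degenerate else (
            "over" if len(jc.null_j) and jc.j_obs > jc.null_j.mean() else "under")
        results.append(SpatialTestResult(
            label, "jaccard", jc.j_obs, jc.p_value, j_sign, n_perm,
            jc.degenerate, jc))
        try:
            rd = relative_distance_test(nupts, track, chromosome_lengths,
                                        n_perm, seed=seed + 1000 * ti + 500)
            sign = "closer" if rd.c_measure > 0 else (
                "farther" if rd.c_measure < 0 else "none")
            results.append(SpatialTestResult(
                label, "rdt", rd.c_measure, rd.p_value, sign, n_perm, False, rd))
        except StatisticsError:
            results.append(SpatialTestResult(
                label, "rdt", float("nan"), 1.0, "none", n_perm, True, None))
    return results


def suite_frame(results: list[SpatialTestResult],
                adjust_pvalues: bool = False) -> pd.DataFrame:
    """Tabulate suite results; ``adjust_pvalues`` adds a Benjamini–Hochberg
    column (off by default — raw p-values at 0.05 are the default rule)."""
    frame = pd.DataFrame([
        {"track": r.track_label, "test": r.test, "statistic": r.statistic,
         "p_value": r.p_value, "sign": r.sign, "n_perm": r.n_perm,
         "degenerate": r.degenerate}
        for r in results
    ])
    if adjust_pvalues and len(frame):
        from .corestats import benjamini_hochberg
        frame["p_adjusted"] = benjamini_hochberg(frame["p_value"].to_numpy())
    return frame
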