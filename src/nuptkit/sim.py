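"""Synthetic NUPT datasets with known ground truth.

The generator emulates the study system end to end: a quadripartite plastid
genome (LSC-IRa-SSC-IRb, IRb the exact reverse complement of IRa); NUPT
insertions whose relative ages K follow a mixture of an exponential
component (continuous gain/loss) and a Gaussian component (an episodic
burst); JC69-consistent substitution of the inserted fragments; right-skewed
(log-normal) insert sizes; optional donor-site hotspot/coldspot biases on
the plastid genome; and nuclear feature annotations (TEs, RNA genes,
structural genes with exons) with configurable colocalization bias toward
the insertions.

Alignment hits are emitted directly from the realized substitutions as
gap-free 12-column tabular rows rather than by re-aligning the mutated
fragments, which removes the dependence on an external aligner while
keeping K estimation testable end to end.  Donor intervals are drawn from
the non-redundant plastid representation (LSC + IRa + SSC); a donor inside
IRa also emits the redundant IRb-coordinate row that a real aligner would
report, so IR deduplication is exercised downstream.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aging import jc69_inverse
from .errors import ConfigurationError, GenerationError, InputError
from .plastid import PlastidPartition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b

MAX_PLACEMENT_ATTEMPTS = 1000


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrackConfig:
    """One annotated feature track to simulate.

    ``label`` is a hierarchy path such as ``"TE/Retrotransposon/LTR"``,
    ``"RNA/regulatory/isrR"`` or ``"gene"``; ``kind`` selects the GFF3
    representation.  With probability ``colocalization_prob`` a feature is
    placed within ``colocalization_distance`` bp of a NUPT insertion
    (cycling over insertions, so prob 1 with count >= #NUPTs covers every
    NUPT); otherwise placement is uniform.
    """

    label: str
    kind: str  # "te" | "rna" | "gene"
    count: int
    length_mean: float = 500.0
    length_sd: float = 100.0
    colocalization_prob: float = 0.0
    colocalization_distance: int = 0
    max_exons: int = 4  # genes only

    def validate(self) -> None:
        if self.kind not in ("te", "rna", "gene"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        if not 0.0 <= self.colocalization_prob <= 1.0:
            raise ConfigurationError("colocalization_prob must be in [0, 1]")
        if self.count < 0 or self.length_mean <= 0:
            raise ConfigurationError("feature count/length must be positive")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a typical angiosperm plastid genome (150 kb, 25 kb
    IRs) and the canonical mixed age regime: half the insertions from an
    exponential with rate 20 per unit K (mean age 0.05) and half from an
    episodic burst at K = 0.2 with spread 0.02.
    """

    seed: int = 0
    plastid_length: int = 150_000
    ir_length: int = 25_000
    lsc_length: int = 85_000
    chromosome_lengths: list[int] = field(default_factory=lambda: [2_000_000, 2_000_000])
    n_continuous: int = 500
    lambda_cont: float = 20.0
    n_episodic: int = 500
    mu_epis: float = 0.2
    sigma_epis: float = 0.02
    size_log10_mean: float = 2.5
    size_log10_sd: float = 0.4
    min_size: int = 30
    hotspot_bias: tuple[tuple[int, int], float] | None = None
    coldspot_intervals: list[tuple[int, int]] = field(default_factory=list)
    feature_tracks: list[FeatureTrackConfig] = field(default_factory=list)

    @property
    def ssc_length(self) -> int:
        return self.plastid_length - self.lsc_length - 2 * self.ir_length

    def validate(self) -> None:
        if self.plastid_length <= 0 or self.lsc_length <= 0 or self.ir_length < 0:
            raise ConfigurationError("plastid region lengths must be positive")
        if self.ssc_length <= 0:
            raise ConfigurationError(
                f"lsc_length + 2*ir_length = {self.lsc_length + 2 * self.ir_length}"
                f" leaves non-positive SSC in plastid of {self.plastid_length} bp"
            )
        if self.lambda_cont <= 0:
            raise ConfigurationError("lambda_cont must be > 0")
        if self.sigma_epis <= 0:
            raise ConfigurationError("sigma_epis must be > 0")
        if self.n_continuous + self.n_episodic < 1:
            raise ConfigurationError("at least one insertion required")
        if not self.chromosome_lengths or any(c <= 0 for c in self.chromosome_lengths):
            raise ConfigurationError("at least one chromosome with positive length required")
        for track in self.feature_tracks:
            track.validate()
        if self.hotspot_bias is not None:
            (s, e), mult = self.hotspot_bias
            if not (0 <= s < e <= self.plastid_length) or mult <= 0:
                raise ConfigurationError("invalid hotspot_bias")


@dataclass
class SimulatedDataset:
    """Paths and ground truth of one generated dataset."""

    outdir: Path
    plastid_fasta: Path
    nuclear_fasta: Path
    hits_path: Path
    gff3_path: Path
    truth_path: Path
    truth: pd.DataFrame
    partition: PlastidPartition
    config: SimConfig

    @property
    def nuclear_genome_size(self) -> int:
        return sum(self.config.chromosome_lengths)


# ---------------------------------------------------------------------------
# generative pieces
# ---------------------------------------------------------------------------

def generate_plastid_genome(cfg: SimConfig, rng: np.random.Generator | None = None
                            ) -> tuple[str, PlastidPartition]:
    """Random plastid genome in LSC-IRa-SSC-IRb order with IRb the exact
    reverse complement of IRa; ir_length 0 gives a non-quadripartite genome."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_unique = cfg.lsc_length + cfg.ir_length + cfg.ssc_length
    core = _BASES[rng.integers(0, 4, size=n_unique)]
    lsc = (0, cfg.lsc_length)
    ira = (cfg.lsc_length, cfg.lsc_length + cfg.ir_length)
    ssc = (ira[1], ira[1] + cfg.ssc_length)
    irb = (ssc[1], ssc[1] + cfg.ir_length)
    seq = np.concatenate([core, _revcomp_arr(core[ira[0]:ira[1]])])
    if cfg.ir_length == 0:
        partition = PlastidPartition(total_length=cfg.plastid_length)
    else:
        partition = PlastidPartition(total_length=cfg.plastid_length,
                                     lsc=lsc, ira=ira, ssc=ssc, irb=irb)
    return _to_str(seq), partition


def draw_ages(cfg: SimConfig, rng: np.random.Generator | None = None
              ) -> list[tuple[float, str]]:
    """Ages K of the insertions: ``n_continuous`` ~ Exponential(lambda_cont)
    and ``n_episodic`` ~ Normal(mu_epis, sigma_epis) truncated at 0 by
    resampling, with component labels preserved."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ages: list[tuple[float, str]] = []
    cont = rng.exponential(1.0 / cfg.lambda_cont, size=cfg.n_continuous)
    ages.extend((float(a), "continuous") for a in cont)
    need = cfg.n_episodic
    while need > 0:
        draw = rng.normal(cfg.mu_epis, cfg.sigma_epis, size=need)
        ok = draw[draw >= 0]
        ages.extend((float(a), "episodic") for a in ok)
        need -= len(ok)
    return ages


def mutate_jc69(fragment: str, target_K: float,
                rng: np.random.Generator | None = None) -> tuple[str, float]:
    """Substitute each site independently with probability
    p = (3/4)(1 - exp(-4K/3)) to one of the three other bases uniformly;
    returns the mutated fragment and the realized fraction of changed sites."""
    if target_K < 0:
        raise InputError("target_K must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    arr = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
    p = jc69_inverse(target_K)
    hit = rng.random(len(arr)) < p
    n_hit = int(hit.sum())
    if n_hit:
        idx = np.flatnonzero(hit)
        base_index = np.zeros(256, dtype=np.int64)
        for bi, b in enumerate(_BASES):
            base_index[b] = bi
        current = base_index[arr[idx]]
        shift = rng.integers(1, 4, size=n_hit)
        arr[idx] = _BASES[(current + shift) % 4]
    realized_p = n_hit / len(arr) if len(arr) else 0.0
    return _to_str(arr), realized_p


def place_nonoverlapping(lengths, chromosome_lengths,
                         rng: np.random.Generator) -> list[tuple[int, int]]:
    """Place intervals of the given lengths uniformly and without overlap
    across chromosomes; returns (chromosome index, start) per interval.

    Placement is uniform over feasible positions (chromosome chosen in
    proportion to length, start uniform, resampled on collision), making
    inter-interval gap order exchangeable — the null the spacing-preserving
    permutation test conditions on.
    """
    chrom_lengths = np.asarray(chromosome_lengths, dtype=np.int64)
    weights = chrom_lengths / chrom_lengths.sum()
    occupied: list[list[tuple[int, int]]] = [[] for _ in chrom_lengths]
    out: list[tuple[int, int]] = []
    for i, L in enumerate(lengths):
        L = int(L)
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            c = int(rng.choice(len(chrom_lengths), p=weights))
            if chrom_lengths[c] < L:
                continue
            s = int(rng.integers(0, chrom_lengths[c] - L + 1))
            e = s + L
            if any(s < oe and e > os_ for os_, oe in occupied[c]):
                continue
            occupied[c].append((s, e))
            out.append((c, s))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place interval {i} of {L} bp after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts: insufficient free space "
                f"on chromosomes {list(map(int, chrom_lengths))}"
            )
    return out


def _donor_weights(cfg: SimConfig, partition: PlastidPartition, size: int
                   ) -> np.ndarray:
    """Sampling weights over donor start positions for one insert size.

    Donors live in the non-redundant representation (everything before IRb);
    windows touching a coldspot interval get weight 0 and windows
    intersecting the hotspot interval get the configured multiplier.
    """
    canonical_end = partition.irb[0] if partition.irb else cfg.plastid_length
    n_starts = canonical_end - size + 1
    if n_starts <= 0:
        raise GenerationError(
            f"donor size {size} exceeds the canonical plastid region "
            f"({canonical_end} bp)"
        )
    w = np.ones(n_starts, dtype=float)
    if cfg.coldspot_intervals:
        forbidden = np.zeros(canonical_end + 1, dtype=np.int64)
        for s, e in cfg.coldspot_intervals:
            forbidden[max(0, s):min(canonical_end, e)] = 1
        cum = np.concatenate([[0], np.cumsum(forbidden[:canonical_end])])
        bad = (cum[size:size + n_starts] - cum[:n_starts]) > 0
        w[bad] = 0.0
    if cfg.hotspot_bias is not None:
        (h0, h1), mult = cfg.hotspot_bias
        lo = max(0, h0 - size + 1)
        hi = min(n_starts, h1)
        if hi > lo:
            w[lo:hi] *= mult
    if w.sum() <= 0:
        raise GenerationError(
            f"no feasible donor start for insert of {size} bp given the "
            "configured coldspot intervals"
        )
    return w


def _sample_donor(cfg, partition, size, rng) -> int:
    w = _donor_weights(cfg, partition, size)
    cdf = np.cumsum(w)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path), "fasta",
    )


def _mirror_to_irb(interval: tuple[int, int], partition: PlastidPartition
                   ) -> tuple[int, int]:
    """Map a donor interval inside IRa to its reverse-complement copy in IRb."""
    (a0, a1), (b0, _b1) = partition.ira, partition.irb
    s, e = interval
    return (b0 + (a1 - e), b0 + (a1 - s))


def _track_attributes(track: FeatureTrackConfig, idx: int) -> tuple[str, str]:
    parts = track.label.split("/")
    attrs = [f"ID={track.kind}_{parts[-1]}_{idx}"]
    if track.kind == "te":
        names = ["te_class", "te_order", "te_superfamily"]
        for name, val in zip(names, parts[1:]):
            attrs.append(f"{name}={val}")
        return "transposable_element", ";".join(attrs)
    if track.kind == "rna":
        names = ["rna_class", "rna_subclass"]
        for name, val in zip(names, parts[1:]):
            attrs.append(f"{name}={val}")
        return "ncRNA", ";".join(attrs)
    return "gene", ";".join(attrs)


def build_dataset(cfg: SimConfig, outdir) -> SimulatedDataset:
    """Generate the full dataset on disk: plastid and nuclear FASTA, the
    12-column hit file, GFF3 annotations, and the ground-truth TSV.

    Byte-identical across calls with the same config (one seeded generator
    drives every draw)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    plastid_seq, partition = generate_plastid_genome(cfg, rng)
    plastid_arr = np.frombuffer(plastid_seq.encode("ascii"), dtype=np.uint8)

    ages = draw_ages(cfg, rng)
    rng.shuffle(ages)
    n = len(ages)
    sizes = np.round(10 ** rng.normal(cfg.size_log10_mean, cfg.size_log10_sd,
                                      size=n)).astype(int)
    sizes = np.maximum(sizes, cfg.min_size)

    donors = [(_sample_donor(cfg, partition, int(L), rng), int(L)) for L in sizes]
    placements = place_nonoverlapping(sizes, cfg.chromosome_lengths, rng)
    strands = rng.integers(0, 2, size=n)  # 1 = minus

    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chromosome_lengths))]
    chrom_arrays = [
        _BASES[rng.integers(0, 4, size=L)] for L in cfg.chromosome_lengths
    ]

    truth_rows = []
    hit_rows = []
    redundant_rows = []
    for i, ((age, label), (ds, L), (ci, ns), strand) in enumerate(
            zip(ages, donors, placements, strands)):
        de = ds + L
        fragment = _to_str(plastid_arr[ds:de])
        mutated, realized_p = mutate_jc69(fragment, age, rng)
        mism = int(round(realized_p * L))
        insert = np.frombuffer(mutated.encode("ascii"), dtype=np.uint8)
        if strand:
            insert = _revcomp_arr(insert)
        chrom_arrays[ci][ns:ns + L] = insert
        ne = ns + L
        pident = round(100.0 * (1.0 - mism / L), 3)
        nupt_id = f"truth{i:05d}"
        sstart, send = (ne, ns + 1) if strand else (ns + 1, ne)
        hit_rows.append((
            "plastid", chrom_names[ci], pident, L, mism, 0,
            ds + 1, de, sstart, send, 0.0, round(2.0 * L, 1),
        ))
        in_ira = (partition.ira is not None
                  and ds >= partition.ira[0] and de <= partition.ira[1])
        if in_ira:
            ms, me = _mirror_to_irb((ds, de), partition)
            redundant_rows.append((
                "plastid", chrom_names[ci], pident, L, mism, 0,
                ms + 1, me, send, sstart, 0.0, round(2.0 * L, 1),
            ))
        truth_rows.append({
            "id": nupt_id, "true_age_K": age, "component_label": label,
            "plastid_start": ds, "plastid_end": de,
            "nuclear_chrom": chrom_names[ci], "nuclear_start": ns,
            "nuclear_end": ne, "true_size": L, "strand": "-" if strand else "+",
            "realized_mismatches": mism, "realized_p": realized_p,
            "in_ira": bool(in_ira),
        })

    truth = pd.DataFrame(truth_rows)

    # --- annotation tracks -------------------------------------------------
    gff_lines = ["##gff-version 3"]
    nupt_spans = [(r["nuclear_chrom"], r["nuclear_start"], r["nuclear_end"])
                  for r in truth_rows]
    for track in cfg.feature_tracks:
        coloc_cycle = 0
        for fi in range(track.count):
            flen = max(10, int(round(rng.normal(track.length_mean, track.length_sd))))
            if nupt_spans and rng.random() < track.colocalization_prob:
                chrom, ns, ne = nupt_spans[coloc_cycle % len(nupt_spans)]
                coloc_cycle += 1
                d = track.colocalization_distance
                ci = chrom_names.index(chrom)
                lo = max(0, ns - flen - d)
                hi = min(cfg.chromosome_lengths[ci] - flen, ne + d)
                fs = int(rng.integers(lo, max(lo + 1, hi + 1)))
            else:
                ci = int(rng.choice(len(chrom_names),
                                    p=np.asarray(cfg.chromosome_lengths, float)
                                    / sum(cfg.chromosome_lengths)))
                chrom = chrom_names[ci]
                fs = int(rng.integers(0, cfg.chromosome_lengths[ci] - flen + 1))
            fe = min(fs + flen, cfg.chromosome_lengths[chrom_names.index(chrom)])
            strand_c = "-" if rng.integers(0, 2) else "+"
            ftype, attrs = _track_attributes(track, fi)
            if track.kind == "gene":
                gene_id = f"gene_{fi}"
                n_ex = int(rng.integers(1, track.max_exons + 1))
                gff_lines.append(
                    f"{chrom}\tnuptkit_sim\tgene\t{fs + 1}\t{fe}\t.\t{strand_c}"
                    f"\t.\tID={gene_id}")
                mrna_id = f"{gene_id}.t1"
                gff_lines.append(
                    f"{chrom}\tnuptkit_sim\tmRNA\t{fs + 1}\t{fe}\t.\t{strand_c}"
                    f"\t.\tID={mrna_id};Parent={gene_id}")
                bounds = np.sort(rng.choice(
                    np.arange(1, flen), size=min(2 * n_ex - 2, max(0, flen - 2)),
                    replace=False)) if n_ex > 1 else np.array([], dtype=int)
                cuts = [0, *bounds.tolist(), flen]
                for ei in range(0, len(cuts) - 1, 2):
                    es, ee = fs + cuts[ei], fs + cuts[ei + 1]
                    if ee > es:
                        gff_lines.append(
                            f"{chrom}\tnuptkit_sim\texon\t{es + 1}\t{ee}\t.\t"
                            f"{strand_c}\t.\tID={mrna_id}.e{ei // 2};Parent={mrna_id}")
            else:
                gff_lines.append(
                    f"{chrom}\tnuptkit_sim\t{ftype}\t{fs + 1}\t{fe}\t.\t"
                    f"{strand_c}\t.\t{attrs}")

    # --- files -------------------------------------------------------------
    plastid_fasta = outdir / "plastid.fasta"
    nuclear_fasta = outdir / "nuclear.fasta"
    hits_path = outdir / "hits.tsv"
    gff3_path = outdir / "features.gff3"
    truth_path = outdir / "truth.tsv"

    _write_fasta(plastid_fasta, [("plastid", plastid_seq)])
    _write_fasta(nuclear_fasta,
                 [(name, _to_str(arr)) for name, arr in zip(chrom_names, chrom_arrays)])
    with open(hits_path, "w") as fh:
        for row in hit_rows + redundant_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    truth.to_csv(truth_path, sep="\t", index=False)

    return SimulatedDataset(
        outdir=outdir, plastid_fasta=plastid_fasta, nuclear_fasta=nuclear_fasta,
        hits_path=hits_path, gff3_path=gff3_path, truth_path=truth_path,
        truth=truth, partition=partition, config=dataclasses.replace(cfg),
    )
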