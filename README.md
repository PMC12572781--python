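# nuptkit

Detection, age modeling and spatial statistics of **NUPTs** — nuclear
sequences of plastid origin. Plastid (chloroplast) DNA continually
integrates into plant nuclear genomes; each insertion then decays in place
by substitution. `nuptkit` is for researchers in organellar genome
evolution who have plastid-vs-nuclear alignment hits (12-column tabular
format) and nuclear annotations (GFF3) and want to know:

* **When** NUPTs formed. Each hit's p-distance p = mismatch/length is
  corrected to a relative age K = −(3/4) ln(1 − (4/3)p) (Jukes–Cantor).
  Four models of the K distribution — Exponential(λ), N(μ, σ²), a
  two-Gaussian mixture, and an exponential+Gaussian mixture
  w·Exp(λ) + (1−w)·N(μ, σ²) — are fitted by ML/EM; the lowest
  BIC = ν ln n − 2 lnL over 15 replicated EM starts decides between
  continuous formation (exponential) and episodic bursts (Gaussian).
* **Where on the plastid genome** they come from. Hits redundantly
  matching both inverted repeats are counted once (seeded random copy);
  per-bp donor coverage yields hotspots (coverage > Q3 + 1.5·IQR) and
  coldspots (coverage 0).
* **Where in the nuclear genome** they land. Association with TEs, RNA
  genes and gene parts (promoter/exon/intron/terminator, longest isoform)
  via a Yates-corrected χ² on overlapping bp, a Jaccard permutation test,
  and the relative distance test with signed measure
  C = (0.25 − mean d)/0.25.

A synthetic-data generator (`nuptkit.sim`) produces complete datasets —
quadripartite plastid genome, JC69-mutated insertions with known ages,
hit files with IR-redundant rows, GFF3 annotations with configurable
colocalization bias, and a ground-truth table — so every stage is
verifiable without downloads. See `docs/methods.md` for the full model
description.

## Worked example

```python
import numpy as np
from nuptkit import sim, calling, plastid
from nuptkit.aging import NuptAgeModel

cfg = sim.SimConfig(seed=42, n_continuous=150, n_episodic=150,
                    chromosome_lengths=[1_000_000, 1_000_000])
ds = sim.build_dataset(cfg, "example_data")

hits = calling.parse_hits(ds.hits_path)
nupts = calling.hits_to_nupts(hits, ds.partition, seed=1)
print(f"{len(hits)} hits -> {len(nupts)} NUPTs after IR dedup")

res = NuptAgeModel.from_nupts(nupts).select(n_replicates=15, seed=1)
print(res.summary())
```

prints (trimmed):

```
365 hits -> 300 NUPTs after IR dedup
BIC model selection over replicated EM starts
       EXP: best in 0 replicates
    GAUSS1: best in 0 replicates
    GAUSS2: best in 3 replicates
  EXPGAUSS: best in 12 replicates
  modal best model: EXPGAUSS
NUPT age model: EXPGAUSS
  n = 300, free parameters = 4
  log-likelihood = 444.8104, BIC = -866.8056
  converged = True after 25 EM iterations
         w = 0.473022
       lam = 25.4818
        mu = 0.198732
     sigma = 0.0342262
  Gaussian mass below K=0 (diagnostic): 1.682e-09
```

The 365 hits include one redundant inverted-repeat row per IRa-resident
donor; deduplication restores the true count of 300. The selected
exponential+Gaussian mixture recovers the generating regime: about half
the insertions (w ≈ 0.47) from continuous turnover with rate λ ≈ 25
(mean age K ≈ 0.04; true rate 20), the rest from an episodic burst at
μ ≈ 0.199 (truth 0.2) with spread σ ≈ 0.034 — slightly wider than the
generating 0.02 because finite fragment lengths add estimation noise to
each K.

Hotspot/coldspot calling and the spatial tests follow the same pattern:

```python
track = plastid.coverage_track(nupts, ds.partition.total_length)
spots = plastid.call_spots(track)       # .hotspot_fraction, .threshold, ...
```

The same pipeline is scriptable from the shell:

```sh
nuptkit simulate --config sim.yaml --outdir data/
nuptkit run --hits data/hits.tsv --plastid-fasta data/plastid.fasta \
    --nuclear-fasta data/nuclear.fasta --gff3 data/features.gff3 \
    --seed 1 --outdir out/      # writes out/report.json + TSV artifacts
```

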