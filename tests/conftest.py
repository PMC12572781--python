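"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (O(n^2) pair counting, per-bp
bitmaps, explicit sort-and-interpolate quantiles) so they stay independent
of the implementation paths they check.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from nuptkit import calling, sim


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def kendall_tau_oracle(x, y) -> float:
    """Tau-b by explicit enumeration of all C(n,2) pairs with tie correction."""
    x, y = list(x), list(y)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (nc - nd) / denom


def _tie_term(v) -> float:
    from collections import Counter
    return sum(t * (t - 1) / 2 for t in Counter(v).values())


def midrank(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def spearman_rho_oracle(x, y) -> float:
    """Pearson correlation of midranks."""
    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def quantile_oracle(values, q: float) -> float:
    """Linear interpolation between order statistics at h = (n-1)q."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def spots_oracle(counts):
    """Brute-force IQR hotspot/coldspot caller: explicit sort + interpolate
    + linear scan."""
    q1 = quantile_oracle(counts, 0.25)
    q3 = quantile_oracle(counts, 0.75)
    threshold = q3 + 1.5 * (q3 - q1)
    hot = [i for i, c in enumerate(counts) if c > threshold]
    cold = [i for i, c in enumerate(counts) if c == 0]
    return q1, q3, threshold, hot, cold


def bitmap_intersection_union(a, b, genome_len: int):
    """Per-bp bitmap oracle for intersection/union lengths of interval sets."""
    bm_a = np.zeros(genome_len, dtype=bool)
    bm_b = np.zeros(genome_len, dtype=bool)
    for s, e in a:
        bm_a[s:e] = True
    for s, e in b:
        bm_b[s:e] = True
    return int((bm_a & bm_b).sum()), int((bm_a | bm_b).sum())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cfg() -> sim.SimConfig:
    """Desk-scale study conditions: mixed-age insertions on two 1-Mb
    chromosomes with a colocalized LTR track and annotated genes."""
    return sim.SimConfig(
        seed=42,
        n_continuous=150, n_episodic=150,
        chromosome_lengths=[1_000_000, 1_000_000],
        feature_tracks=[
            sim.FeatureTrackConfig("TE/Retrotransposon/LTR", "te", count=120,
                                   length_mean=400, length_sd=80),
            sim.FeatureTrackConfig("RNA/regulatory/isrR", "rna", count=40,
                                   length_mean=120, length_sd=20),
            sim.FeatureTrackConfig("gene", "gene", count=60,
                                   length_mean=3000, length_sd=500),
        ],
    )


@pytest.fixture(scope="session")
def dataset(small_cfg, tmp_path_factory):
    return sim.build_dataset(small_cfg, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def nupts(dataset):
    hits = calling.parse_hits(dataset.hits_path)
    return calling.hits_to_nupts(hits, dataset.partition, seed=1)
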