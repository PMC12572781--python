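"""Feature loading, gene-part derivation and spatial association tests."""
import numpy as np
import pytest

from conftest import bitmap_intersection_union
from nuptkit import coloc, intervals as iv
from nuptkit.coloc import FeatureTrack, GeneModel
from nuptkit.errors import StatisticsError

CHR = {"chr1": 100_000}


def _track(pairs, label="t"):
    return FeatureTrack.from_pairs(label, pairs)


def _gff(tmp_path, body):
    path = tmp_path / "f.gff3"
    path.write_text("##gff-version 3\n" + body)
    return path


class TestLoadFeatures:
    def test_one_based_inclusive_becomes_half_open(self, tmp_path):
        path = _gff(tmp_path,
                    "chr1\tsrc\tncRNA\t1\t10\t.\t+\t.\tID=r1;rna_class=regulatory\n")
        tracks = coloc.load_features(path, {
            "RNA/regulatory": {"featuretype": "ncRNA",
                               "attributes": {"rna_class": ["regulatory"]}}})
        assert tracks["RNA/regulatory"].intervals["chr1"].tolist() == [[0, 10]]

    def test_attribute_filter_excludes_other_classes(self, tmp_path):
        path = _gff(tmp_path,
                    "chr1\ts\tncRNA\t1\t10\t.\t+\t.\tID=a;rna_class=regulatory\n"
                    "chr1\ts\tncRNA\t21\t30\t.\t+\t.\tID=b;rna_class=rRNA\n")
        tracks = coloc.load_features(path, coloc.class_map_from_labels(
            ["RNA/rRNA"]))
        assert tracks["RNA/rRNA"].intervals["chr1"].tolist() == [[20, 30]]

    def test_sim_gff_round_trip(self, dataset):
        labels = [t.label for t in dataset.config.feature_tracks
                  if t.kind != "gene"]
        tracks = coloc.load_features(dataset.gff3_path,
                                     coloc.class_map_from_labels(labels))
        for cfg_track in dataset.config.feature_tracks:
            if cfg_track.kind == "gene":
                continue
            n = sum(len(a) for a in tracks[cfg_track.label].intervals.values())
            assert n == cfg_track.count


class TestGeneModels:
    def test_longest_isoform_kept(self, tmp_path):
        body = (
            "chr1\ts\tgene\t1001\t9000\t.\t+\t.\tID=g1\n"
            "chr1\ts\tmRNA\t1001\t9000\t.\t+\t.\tID=g1.a;Parent=g1\n"
            "chr1\ts\texon\t1001\t1900\t.\t+\t.\tID=g1.a.e1;Parent=g1.a\n"
            "chr1\ts\tmRNA\t1001\t9000\t.\t+\t.\tID=g1.b;Parent=g1\n"
            "chr1\ts\texon\t1001\t1600\t.\t+\t.\tID=g1.b.e1;Parent=g1.b\n"
            "chr1\ts\texon\t8401\t9000\t.\t+\t.\tID=g1.b.e2;Parent=g1.b\n"
        )
        genes = coloc.load_gene_models(_gff(tmp_path, body))
        assert len(genes) == 1
        # isoform b: 600 + 600 = 1200 beats isoform a: 900
        assert genes[0].exons == [(1000, 1600), (8400, 9000)]

    def test_plus_strand_promoter_and_introns(self):
        g = GeneModel("g", "chr1", "+", [(5000, 5200), (6000, 6400)])
        parts = coloc.derive_gene_parts([g], CHR)
        assert parts["promoter"].intervals["chr1"].tolist() == [[4000, 5000]]
        assert parts["terminator"].intervals["chr1"].tolist() == [[6400, 7400]]
        assert parts["intron"].intervals["chr1"].tolist() == [[5200, 6000]]

    def test_minus_strand_mirrors_promoter_terminator(self):
        g = GeneModel("g", "chr1", "-", [(4000, 4200), (5000, 5200)])
        parts = coloc.derive_gene_parts([g], CHR)
        assert parts["promoter"].intervals["chr1"].tolist() == [[5200, 6200]]
        assert parts["terminator"].intervals["chr1"].tolist() == [[3000, 4000]]

    def test_single_exon_gene_has_no_introns(self):
        g = GeneModel("g", "chr1", "+", [(100, 400)])
        parts = coloc.derive_gene_parts([g], {"chr1": 1000})
        assert "chr1" not in parts["intron"].intervals
        # promoter clipped at the chromosome start
        assert parts["promoter"].intervals["chr1"].tolist() == [[0, 100]]


class TestIntervalArithmetic:
    def test_matches_bitmap_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            glen = int(rng.integers(1000, 100_000))
            def rand_set():
                n = int(rng.integers(1, 40))
                starts = rng.integers(0, glen - 10, size=n)
                return [(int(s), int(s + rng.integers(1, 500))) for s in starts
                        if s + 1 < glen]
            a = [(s, min(e, glen)) for s, e in rand_set()]
            b = [(s, min(e, glen)) for s, e in rand_set()]
            inter, union = bitmap_intersection_union(a, b, glen)
            assert iv.intersection_length(a, b) == inter
            assert iv.union_length(a, b) == union


class TestOverlapTest:
    def test_expected_equals_observed_gives_direction_none(self):
        nupts = {"chr1": iv.as_array([(0, 45), (100, 105)])}  # 50 bp total
        track = _track([("chr1", 40, 45), ("chr1", 200, 295)])  # 100 bp
        res = coloc.expected_overlap_test(nupts, track, 1000)
        assert res.expected_bp == pytest.approx(5.0)
        assert res.observed_bp == 5
        assert res.direction == "none"

    def test_nested_nupts_fully_observed(self):
        nupts = {"chr1": iv.as_array([(10, 20), (30, 40)])}
        track = _track([("chr1", 0, 100)])
        res = coloc.expected_overlap_test(nupts, track, 100_000)
        assert res.observed_bp == 20
        assert res.direction == "over" and res.p_value < 1e-6

    def test_zero_overlap_with_ample_bp_is_under_and_significant(self):
        # spliceosomal-RNA-style outcome: sizeable track, zero intersection
        nupts = {"chr1": iv.as_array([(i * 100, i * 100 + 50) for i in range(100)])}
        track = _track([("chr1", 20_000 + i * 100, 20_050 + i * 100)
                        for i in range(100)])
        res = coloc.expected_overlap_test(nupts, track, 50_000)
        assert res.direction == "under" and res.p_value < 1e-6

    def test_empty_track_degenerate(self):
        nupts = {"chr1": iv.as_array([(0, 10)])}
        res = coloc.expected_overlap_test(nupts, _track([]), 1000)
        assert res.degenerate and res.p_value == 1.0 and res.direction == "none"


class TestPermutation:
    def test_preserves_size_and_gap_multisets(self):
        rng = np.random.default_rng(0)
        arr = iv.as_array([(10, 60), (100, 130), (500, 900)])
        perm = coloc.permute_nupts({"chr1": arr}, {"chr1": 1000}, rng)["chr1"]
        assert sorted(perm[:, 1] - perm[:, 0]) == [30, 50, 400]
        def gaps(a, L):
            return sorted([a[0, 0]] + list(a[1:, 0] - a[:-1, 1]) + [L - a[-1, 1]])
        assert gaps(perm, 1000) == gaps(arr, 1000)
        assert (perm[:, 0] >= 0).all() and (perm[:, 1] <= 1000).all()
        assert (perm[1:, 0] >= perm[:-1, 1]).all()

    def test_two_seeds_differ_same_sizes(self):
        arr = iv.as_array([(i * 50, i * 50 + 20) for i in range(10)])
        a = coloc.permute_nupts({"chr1": arr}, {"chr1": 1000}, 1)["chr1"]
        b = coloc.permute_nupts({"chr1": arr}, {"chr1": 1000}, 2)["chr1"]
        assert not np.array_equal(a, b)
        assert sorted(a[:, 1] - a[:, 0]) == sorted(b[:, 1] - b[:, 0])

    def test_single_nupt_uniform_over_feasible_layouts(self):
        # with one interval the spacing-preserving scheme has exactly two
        # feasible layouts (the flanking gaps swap); both must be equally
        # likely across draws
        arr = iv.as_array([(400, 500)])
        rng = np.random.default_rng(7)
        starts = np.array(
            [coloc.permute_nupts({"c": arr}, {"c": 1000}, rng)["c"][0, 0]
             for _ in range(2000)])
        assert set(starts.tolist()) == {400, 500}
        frac = (starts == 400).mean()
        assert abs(frac - 0.5) <= 3 * 0.5 / np.sqrt(2000)


class TestJaccard:
    def test_identical_sets_give_one(self):
        arr = iv.as_array([(0, 50), (100, 200)])
        res = coloc.jaccard_test({"chr1": arr}, _track(
            [("chr1", 0, 50), ("chr1", 100, 200)]), {"chr1": 1000}, n_perm=20)
        assert res.j_obs == 1.0

    def test_disjoint_sets_give_zero(self):
        res = coloc.jaccard_test({"chr1": iv.as_array([(0, 10)])},
                                 _track([("chr1", 500, 510)]),
                                 {"chr1": 1000}, n_perm=20)
        assert res.j_obs == 0.0 and not res.degenerate

    def test_interval_arithmetic_example(self):
        res = coloc.jaccard_test({"chr1": iv.as_array([(0, 10)])},
                                 _track([("chr1", 5, 15)]),
                                 {"chr1": 1000}, n_perm=20)
        assert res.j_obs == pytest.approx(5 / 15)

    def test_empty_union_degenerate(self):
        res = coloc.jaccard_test({}, _track([]), {"chr1": 100}, n_perm=5)
        assert res.degenerate


class TestRdt:
    def test_center_on_feature_center_d_zero(self):
        nupts = {"chr1": iv.as_array([(1995, 2005)])}  # center 2000
        track = _track([("chr1", 1999, 2001), ("chr1", 2999, 3001)])
        res = coloc.relative_distance_test(nupts, track, {"chr1": 10_000},
                                           n_perm=10)
        assert res.rel_distances[0] == pytest.approx(0.0)

    def test_midpoint_d_half_and_quarter_offset_closed_form(self):
        # features every 1000 bp; NUPT centers at offset 250 -> all d = 0.25
        feats = [("chr1", i * 1000 - 1, i * 1000 + 1) for i in range(1, 20)]
        nupts = {"chr1": iv.as_array([(i * 1000 + 245, i * 1000 + 255)
                                      for i in range(1, 19)])}
        res = coloc.relative_distance_test(nupts, _track(feats),
                                           {"chr1": 30_000}, n_perm=10)
        assert np.allclose(res.rel_distances, 0.25)
        assert res.c_measure == pytest.approx(0.0, abs=1e-12)
        mid = {"chr1": iv.as_array([(1495, 1505)])}  # midpoint of 1000/2000
        res2 = coloc.relative_distance_test(mid, _track(feats),
                                            {"chr1": 30_000}, n_perm=10)
        assert res2.rel_distances[0] == pytest.approx(0.5)

    def test_outside_span_dropped_and_counted(self):
        nupts = {"chr1": iv.as_array([(0, 10), (5000, 5010)])}
        track = _track([("chr1", 4000, 4002), ("chr1", 6000, 6002)])
        res = coloc.relative_distance_test(nupts, track, {"chr1": 10_000},
                                           n_perm=10)
        assert res.n_used == 1 and res.n_dropped == 1

    def test_no_usable_centers_raises(self):
        with pytest.raises(StatisticsError):
            coloc.relative_distance_test({"chr1": iv.as_array([(0, 10)])},
                                         _track([("chr2", 0, 10),
                                                 ("chr2", 50, 60)]),
                                         {"chr1": 100, "chr2": 100}, n_perm=5)

    def test_c_measure_sign_flips_under_mirrored_bias(self):
        rng = np.random.default_rng(13)
        feats = [("chr1", i * 2000, i * 2000 + 10) for i in range(1, 40)]
        near, far = [], []
        for i in range(2, 38):
            c = i * 2000 + 5
            near.append((c + 60, c + 80))     # hugging feature centers
            far.append((c + 960, c + 1040))   # avoiding them (midpoints)
        res_near = coloc.relative_distance_test(
            {"chr1": iv.as_array(near)}, _track(feats), {"chr1": 100_000},
            n_perm=50, seed=3)
        res_far = coloc.relative_distance_test(
            {"chr1": iv.as_array(far)}, _track(feats), {"chr1": 100_000},
            n_perm=50, seed=3)
        assert res_near.c_measure > 0 > res_far.c_measure


class TestSuite:
    def test_forced_colocalization_detected(self, tmp_path):
        from nuptkit import calling, sim
        cfg = sim.SimConfig(
            seed=77, n_continuous=60, n_episodic=0,
            chromosome_lengths=[800_000],
            feature_tracks=[sim.FeatureTrackConfig(
                "TE/Retrotransposon/LTR", "te", count=80, length_mean=300,
                length_sd=50, colocalization_prob=1.0,
                colocalization_distance=0)])
        ds = sim.build_dataset(cfg, tmp_path)
        hits = calling.parse_hits(ds.hits_path)
        nupts = calling.hits_to_nupts(hits, ds.partition, seed=0)
        tracks = coloc.load_features(
            ds.gff3_path, coloc.class_map_from_labels(["TE/Retrotransposon/LTR"]))
        res = coloc.relative_distance_test(
            nupts, tracks["TE/Retrotransposon/LTR"], {"chr1": 800_000},
            n_perm=200, seed=5)
        assert res.c_measure > 0 and res.p_value < 0.05

    def test_suite_completes_with_degenerate_track(self, nupts, dataset):
        tracks = {"empty": _track([]),
                  "one": _track([("chr1", 1000, 2000)])}
        chrom = {f"chr{i+1}": L for i, L in
                 enumerate(dataset.config.chromosome_lengths)}
        results = coloc.run_coloc_suite(nupts, tracks, chrom, n_perm=20, seed=0)
        by = {(r.track_label, r.test): r for r in results}
        assert by[("empty", "overlap_chi2")].degenerate
        assert by[("empty", "rdt")].degenerate
        assert len(results) == 6
        frame = coloc.suite_frame(results)
        assert set(frame["test"]) == {"overlap_chi2", "jaccard", "rdt"}
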