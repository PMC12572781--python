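"""Generator correctness: determinism, age draws, JC69 mutation, layout."""
import filecmp

import numpy as np
import pandas as pd
import pytest

from nuptkit import sim
from nuptkit.errors import ConfigurationError, GenerationError, InputError
from nuptkit.plastid import revcomp


class TestConfig:
    def test_region_lengths_must_close(self):
        with pytest.raises(ConfigurationError):
            sim.SimConfig(plastid_length=1000, ir_length=300, lsc_length=600).validate()

    @pytest.mark.parametrize("field,value", [
        ("lambda_cont", 0.0), ("sigma_epis", -1.0), ("chromosome_lengths", []),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        cfg = sim.SimConfig(**{field: value})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_colocalization_prob_bounds(self):
        track = sim.FeatureTrackConfig("TE/x", "te", 10, colocalization_prob=1.5)
        with pytest.raises(ConfigurationError):
            track.validate()


class TestPlastidGenome:
    def test_irb_is_reverse_complement_of_ira(self):
        cfg = sim.SimConfig(seed=7, plastid_length=1000, ir_length=100,
                            lsc_length=600)
        seq, part = sim.generate_plastid_genome(cfg)
        assert cfg.ssc_length == 200
        # partition covers [0, 1000) in order LSC, IRa, SSC, IRb
        assert (part.lsc, part.ira, part.ssc, part.irb) == (
            (0, 600), (600, 700), (700, 900), (900, 1000))
        assert revcomp(seq[slice(*part.ira)]) == seq[slice(*part.irb)]

    def test_same_seed_same_sequence(self):
        cfg = sim.SimConfig(seed=5, plastid_length=2000, ir_length=200,
                            lsc_length=1200)
        assert sim.generate_plastid_genome(cfg)[0] == sim.generate_plastid_genome(cfg)[0]


class TestAges:
    def test_exponential_mean_at_large_n(self):
        cfg = sim.SimConfig(seed=11, n_continuous=5000, n_episodic=0,
                            lambda_cont=20.0)
        ages = np.array([a for a, _ in sim.draw_ages(cfg)])
        se = (1 / 20.0) / np.sqrt(5000)
        assert abs(ages.mean() - 1 / 20.0) <= 3 * se

    def test_degenerate_burst_concentrates_at_mu(self):
        cfg = sim.SimConfig(seed=2, n_continuous=0, n_episodic=200,
                            mu_epis=0.2, sigma_epis=1e-6)
        ages = np.array([a for a, _ in sim.draw_ages(cfg)])
        assert np.allclose(ages, 0.2, atol=1e-4)

    def test_labeled_components_match_their_generators(self):
        cfg = sim.SimConfig(seed=3, n_continuous=4000, n_episodic=4000,
                            lambda_cont=20.0, mu_epis=0.2, sigma_epis=0.02)
        draws = sim.draw_ages(cfg)
        cont = np.array([a for a, lab in draws if lab == "continuous"])
        epis = np.array([a for a, lab in draws if lab == "episodic"])
        assert len(cont) == 4000 and len(epis) == 4000
        assert abs(cont.mean() - 0.05) <= 3 * 0.05 / np.sqrt(4000)
        assert abs(epis.mean() - 0.2) <= 3 * 0.02 / np.sqrt(4000)
        assert (epis >= 0).all()


class TestMutation:
    def test_zero_age_is_identity(self):
        frag = "ACGTACGTAC" * 10
        out, p = sim.mutate_jc69(frag, 0.0, np.random.default_rng(0))
        assert out == frag and p == 0.0

    def test_realized_p_matches_jc69_expectation(self):
        rng = np.random.default_rng(12)
        frag = "".join(rng.choice(list("ACGT"), 100_000))
        _, p = sim.mutate_jc69(frag, 0.38, rng)
        expect = 0.2981245721  # (3/4)(1 - exp(-4*0.38/3))
        sd = np.sqrt(expect * (1 - expect) / 100_000)
        assert abs(p - expect) <= 4 * sd

    def test_saturation_limit(self):
        rng = np.random.default_rng(1)
        frag = "".join(rng.choice(list("ACGT"), 50_000))
        _, p = sim.mutate_jc69(frag, 50.0, rng)
        assert p == pytest.approx(0.75, abs=0.01)

    def test_negative_age_rejected(self):
        with pytest.raises(InputError):
            sim.mutate_jc69("ACGT", -0.1)

    def test_substituted_sites_actually_change(self):
        rng = np.random.default_rng(4)
        frag = "".join(rng.choice(list("ACGT"), 5000))
        out, p = sim.mutate_jc69(frag, 0.2, rng)
        diff = sum(a != b for a, b in zip(frag, out)) / len(frag)
        assert diff == pytest.approx(p)


class TestDataset:
    def test_same_seed_byte_identical_outputs(self, small_cfg, tmp_path):
        a = sim.build_dataset(small_cfg, tmp_path / "a")
        b = sim.build_dataset(small_cfg, tmp_path / "b")
        for pa, pb in [(a.plastid_fasta, b.plastid_fasta),
                       (a.nuclear_fasta, b.nuclear_fasta),
                       (a.hits_path, b.hits_path),
                       (a.gff3_path, b.gff3_path),
                       (a.truth_path, b.truth_path)]:
            assert filecmp.cmp(pa, pb, shallow=False), pa.name

    def test_hit_rows_count_truth_plus_ira_donors(self, dataset):
        n_rows = sum(1 for _ in open(dataset.hits_path))
        assert n_rows == len(dataset.truth) + int(dataset.truth["in_ira"].sum())

    def test_truth_intervals_disjoint_and_in_bounds(self, dataset):
        for chrom, grp in dataset.truth.groupby("nuclear_chrom"):
            grp = grp.sort_values("nuclear_start")
            assert (grp["nuclear_end"] <= dict(
                zip([f"chr{i+1}" for i in range(2)],
                    dataset.config.chromosome_lengths))[chrom]).all()
            assert (grp["nuclear_start"].values[1:]
                    >= grp["nuclear_end"].values[:-1]).all()

    def test_coldspots_exclude_donor_intervals(self, tmp_path):
        cold = [(10_000, 20_000), (70_000, 75_000)]
        cfg = sim.SimConfig(seed=9, n_continuous=150, n_episodic=0,
                            chromosome_lengths=[800_000],
                            coldspot_intervals=cold)
        ds = sim.build_dataset(cfg, tmp_path)
        for s, e in zip(ds.truth["plastid_start"], ds.truth["plastid_end"]):
            for cs, ce in cold:
                assert e <= cs or s >= ce

    def test_forced_colocalization_covers_every_nupt(self, tmp_path):
        cfg = sim.SimConfig(
            seed=21, n_continuous=40, n_episodic=0,
            chromosome_lengths=[600_000],
            feature_tracks=[sim.FeatureTrackConfig(
                "TE/Retrotransposon/LTR", "te", count=60, length_mean=300,
                length_sd=50, colocalization_prob=1.0,
                colocalization_distance=0)])
        ds = sim.build_dataset(cfg, tmp_path)
        ltr = []
        for line in open(ds.gff3_path):
            if "\ttransposable_element\t" in line:
                f = line.split("\t")
                ltr.append((int(f[3]) - 1, int(f[4])))
        for _, row in ds.truth.iterrows():
            ns, ne = row["nuclear_start"], row["nuclear_end"]
            assert any(s <= ne and e >= ns for s, e in ltr)

    def test_insufficient_space_names_shortfall(self, tmp_path):
        cfg = sim.SimConfig(seed=1, n_continuous=500, n_episodic=0,
                            chromosome_lengths=[10_000],
                            size_log10_mean=3.0, size_log10_sd=0.1)
        with pytest.raises(GenerationError, match="insufficient free space"):
            sim.build_dataset(cfg, tmp_path)

    def test_truth_p_consistent_with_hit_file(self, dataset):
        hits = pd.read_csv(dataset.hits_path, sep="\t", header=None)
        primary = hits.iloc[:len(dataset.truth)]
        assert np.array_equal(primary[4].values,
                              dataset.truth["realized_mismatches"].values)
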