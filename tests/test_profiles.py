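"""Metagene/RdDM/window profiling: flatness, strand symmetry, conservation."""

import numpy as np
import pandas as pd
import pytest

from bsmeth.core import Feature, GenomicInterval
from bsmeth.profiles import (LevelIndex, classify_constitutive_loci,
                             classify_te_lengths,
                             length_methylation_correlation, merge_alignments,
                             metagene_profile, rddm_profile,
                             sirna_length_fractions, subgenome_summary,
                             window_track)
from bsmeth.simulate import (SimulationConfig, generate_genome,
                             generate_methylome, simulate_bisulfite_counts,
                             simulate_dataset)

from conftest import make_sample


@pytest.fixture(scope="module")
def flat_dataset():
    """Constant true level 0.3 in every context, no islands, no DMRs."""
    cfg = SimulationConfig(
        seed=13, chrom_lengths={"A01": 150_000}, genes_per_chrom=10,
        tegs_per_chrom=0, tes_per_chrom=10, chh_island_level=0.0,
        context_means={"CG": 0.3, "CHG": 0.3, "CHH": 0.3},
        context_concentration={"CG": np.inf, "CHG": np.inf, "CHH": np.inf},
        n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
    )
    genome = generate_genome(cfg)
    truth = generate_methylome(genome, cfg)
    sample = simulate_bisulfite_counts(truth, cfg.samples[0], cfg)
    return cfg, genome, sample


def _assert_flat(prof, p_true, r):
    """Every defined bin within 6 binomial SEs of the expected level."""
    p_obs = p_true + (1 - p_true) * r
    defined = prof[prof["reads"] > 0]
    assert len(defined) > 0
    se = np.sqrt(p_obs * (1 - p_obs) / defined["reads"])
    assert (np.abs(defined["level"] - p_obs) <= 6 * se + 1e-12).all()


class TestMetagene:
    def test_flat_methylome_gives_flat_profile(self, flat_dataset):
        cfg, genome, sample = flat_dataset
        for ctx in ("CG", "CHH"):
            prof = metagene_profile(sample, genome.genes(), ctx)
            assert len(prof) == 300
            _assert_flat(prof, 0.3, cfg.nonconversion_rate)

    def test_chh_islands_raise_tss_proximal_upstream_bins(self, dataset):
        sample = dataset.methylomes[dataset.config.samples[0]]
        prof = metagene_profile(sample, dataset.genome.genes(), "CHH")
        # island width 500 = last 25 upstream bins of a 2-kb flank
        near = prof[(prof["bin"] >= 75) & (prof["bin"] < 100)]["level"]
        body = prof[prof["segment"] == "body"]["level"]
        assert near.mean() > body.mean() + 0.02

    def test_minus_strand_profile_equals_mirrored_plus_profile(self):
        L = 10_000
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=400, replace=False))
        m = rng.integers(0, 20, size=len(pos))
        u = rng.integers(0, 20, size=len(pos))
        fwd = make_sample(
            [("A01", int(p), "+", "CHH", int(a), int(b))
             for p, a, b in zip(pos, m, u)])
        mirrored = make_sample(
            [("A01", int(L - p + 1), "+", "CHH", int(a), int(b))
             for p, a, b in zip(pos, m, u)])
        gene_minus = Feature(GenomicInterval("A01", 4000, 6500, "-"), "g", "PCG")
        gene_plus = Feature(
            GenomicInterval("A01", L - 6500, L - 4000, "+"), "g", "PCG")
        p_minus = metagene_profile(fwd, [gene_minus], "CHH", flank=1000, nbins=20)
        p_plus = metagene_profile(mirrored, [gene_plus], "CHH", flank=1000, nbins=20)
        pd.testing.assert_frame_equal(p_minus, p_plus)

    def test_rejects_empty_feature_list(self, sample_first):
        with pytest.raises(ValueError):
            metagene_profile(sample_first, [], "CHH")


class TestRddmProfile:
    def test_flat_methylome_gives_flat_locus_profile(self, flat_dataset):
        cfg, genome, sample = flat_dataset
        loci = pd.DataFrame({"chrom": "A01",
                             "start": [20_000, 60_000, 100_000],
                             "end": [20_300, 60_200, 100_500]})
        prof = rddm_profile(sample, loci, "CHH", flank=5000)
        _assert_flat(prof, 0.3, cfg.nonconversion_rate)

    def test_chh_peaks_in_locus_body(self, dataset):
        name = dataset.config.samples[-1]
        prof = rddm_profile(dataset.methylomes[name],
                            dataset.sirna_loci[name], "CHH")
        body = prof[prof["segment"] == "body"]["level"].mean()
        edges = prof[(prof["bin"] < 20) | (prof["bin"] >= 280)]["level"].mean()
        assert body > edges + 0.05

    def test_locus_at_chromosome_edge_truncates_flank(self):
        sample = make_sample([("A01", p, "+", "CHH", 1, 1)
                              for p in range(1, 300)])
        loci = pd.DataFrame({"chrom": ["A01"], "start": [0], "end": [100]})
        prof = rddm_profile(sample, loci, "CHH", flank=5000)
        upstream = prof[prof["segment"] == "upstream"]
        assert (upstream["reads"] == 0).all()
        assert upstream["level"].isna().all()


class TestWindows:
    def test_uniform_level_everywhere(self, flat_dataset):
        cfg, genome, sample = flat_dataset
        track = window_track(sample, 10_000, 10_000,
                             chrom_lengths=genome.chrom_lengths,
                             contexts="CHH")
        p_obs = 0.3 + 0.7 * cfg.nonconversion_rate
        se = np.sqrt(p_obs * (1 - p_obs) / track["reads_CHH"])
        assert (np.abs(track["level_CHH"] - p_obs) <= 6 * se).all()

    def test_degenerate_single_window_equals_genome_level(self, sample_first):
        lengths = {c: int(g["pos"].max())
                   for c, g in sample_first.sites.groupby("chrom")}
        track = window_track(sample_first, max(lengths.values()),
                             max(lengths.values()), chrom_lengths=lengths)
        for ctx in ("CG", "CHG", "CHH"):
            per_chrom = track.set_index("chrom")[f"level_{ctx}"]
            for chrom in lengths:
                sub = sample_first.subset(context=ctx, chrom=chrom)
                expected = sub["count_m"].sum() / (
                    sub["count_m"].sum() + sub["count_u"].sum())
                assert per_chrom.loc[chrom] == pytest.approx(expected, abs=1e-12)

    def test_tiling_windows_conserve_genome_level_exactly(self, sample_first):
        """Read-weighted mean over a tiling equals the genome-wide level."""
        track = window_track(sample_first, 10_000, 10_000, contexts="CHH")
        total_m = (track["level_CHH"].fillna(0) * track["reads_CHH"]).sum()
        total = track["reads_CHH"].sum()
        assert total_m / total == pytest.approx(sample_first.level("CHH"),
                                                abs=1e-12)

    def test_max_differential_window_overlaps_planted_hyper_region(self, dataset):
        """Planted DMRs are the only sample-specific signal, so the window
        with the largest between-sample CHH gap must overlap one."""
        first, last = dataset.config.samples[0], dataset.config.samples[-1]
        kwargs = dict(chrom_lengths=dataset.genome.chrom_lengths,
                      contexts="CHH")
        t_a = window_track(dataset.methylomes[first], 1000, 1000, **kwargs)
        t_b = window_track(dataset.methylomes[last], 1000, 1000, **kwargs)
        diff = (t_b["level_CHH"] - t_a["level_CHH"]).fillna(0)
        best = t_b.loc[diff.idxmax()]
        planted = dataset.truth.dmrs.query("context == 'CHH' and delta > 0")
        assert ((planted["chrom"] == best["chrom"])
                & (planted["start"] < best["end"])
                & (planted["end"] > best["start"])).any()

    def test_partial_last_window_flagged(self, sample_first):
        track = window_track(sample_first, 100_000, 50_000,
                             chrom_lengths={"A01": 120_000, "D01": 120_000})
        assert track["partial"].any()
        assert not track["partial"].iloc[0]

    def test_invalid_step_rejected(self, sample_first):
        with pytest.raises(ValueError):
            window_track(sample_first, 100, 200)


class TestTELengthClasses:
    @pytest.mark.parametrize(
        "length, expected",
        [(400, "short"), (500, "medium"), (4000, "medium"), (5000, "long")],
    )
    def test_published_thresholds_are_strict(self, length, expected):
        te = Feature(GenomicInterval("A01", 0, length), "te", "TE")
        out = classify_te_lengths([te])
        assert out["class"].iloc[0] == expected

    def test_fractions_partition_te_set(self, dataset):
        out = classify_te_lengths(dataset.genome.tes())
        summary = out.attrs["summary"]
        assert summary["count"].sum() == len(dataset.genome.tes())
        assert summary["fraction"].sum() == pytest.approx(1.0)

    def test_empty_te_set_rejected(self):
        with pytest.raises(ValueError):
            classify_te_lengths([])

    def test_class_levels_computed_with_sample(self, dataset, sample_first):
        out = classify_te_lengths(dataset.genome.tes(), sample_first)
        levels = out.attrs["class_levels"]
        assert ("short", "CG") in levels
        assert 0 <= levels[("short", "CG")] <= 1


class TestSubgenome:
    def test_symmetric_genome_has_equal_subgenomes(self, sample_first):
        out = subgenome_summary(sample_first).set_index("subgenome")
        assert abs(out.loc["A", "level_CHH"] - out.loc["D", "level_CHH"]) < 0.02
        assert abs(out.loc["A", "level_CG"] - out.loc["D", "level_CG"]) < 0.02

    def test_planted_subgenome_boost_recovered(self):
        cfg = SimulationConfig(
            seed=21, chrom_lengths={"A01": 60_000, "D01": 60_000},
            genes_per_chrom=3, tegs_per_chrom=0, tes_per_chrom=5,
            chh_island_level=0.0, subgenome_chh_boost={"D": 0.05},
            n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
        )
        genome = generate_genome(cfg)
        truth = generate_methylome(genome, cfg)
        sample = simulate_bisulfite_counts(truth, cfg.samples[0], cfg)
        out = subgenome_summary(sample).set_index("subgenome")
        diff = out.loc["D", "level_CHH"] - out.loc["A", "level_CHH"]
        assert diff == pytest.approx(0.05, abs=0.01)

    def test_loci_only_on_a_gives_zero_d_count(self, sample_first):
        loci = pd.DataFrame({"chrom": ["A01", "A01"], "start": [0, 500],
                             "end": [100, 600]})
        out = subgenome_summary(sample_first, loci).set_index("subgenome")
        assert out.loc["A", "n_sirna_loci"] == 2
        assert out.loc["D", "n_sirna_loci"] == 0

    def test_unprefixed_chromosomes_grouped_unassigned(self):
        sample = make_sample([("chrX", 10, "+", "CG", 1, 1)])
        out = subgenome_summary(sample)
        assert list(out["subgenome"]) == ["unassigned"]


class TestSirnaHelpers:
    def test_length_fractions(self):
        assert sirna_length_fractions([24, 24, 24]).loc[24] == 1.0
        halves = sirna_length_fractions([21, 24, 21, 24])
        assert halves.loc[21] == halves.loc[24] == 0.5

    def test_length_fractions_reject_nonpositive(self):
        with pytest.raises(ValueError):
            sirna_length_fractions([24, 0])

    def test_merge_alignments(self):
        aln = pd.DataFrame({
            "chrom": ["A01"] * 3 + ["D01"],
            "start": [0, 10, 100, 5],
            "end": [24, 34, 124, 29],
        })
        loci = merge_alignments(aln)
        assert len(loci) == 3
        first = loci.iloc[0]
        assert (first["start"], first["end"], first["n_alignments"]) == (0, 34, 2)

    def test_constitutive_loci_classes(self):
        a = pd.DataFrame({"chrom": ["A01", "A01"], "start": [0, 200],
                          "end": [100, 300]})
        b = pd.DataFrame({"chrom": ["A01"], "start": [50], "end": [150]})
        out = classify_constitutive_loci(a, b)
        classes = out.set_index("start")["class"]
        assert classes.loc[0] == "constitutive"
        assert classes.loc[50] == "constitutive"
        assert classes.loc[200] == "specific_a"
        same = classify_constitutive_loci(a, a)
        assert (same["class"] == "constitutive").all()

    def test_constitutive_loci_in_hyper_regions_have_higher_level(self):
        # constitutive locus sits in a methylated block, specific in a bare one
        rows = [("A01", p, "+", "CHH", 9, 1) for p in range(1, 101)]
        rows += [("A01", p, "+", "CHH", 0, 10) for p in range(201, 301)]
        sample = make_sample(rows)
        a = pd.DataFrame({"chrom": ["A01", "A01"], "start": [0, 200],
                          "end": [100, 300]})
        b = pd.DataFrame({"chrom": ["A01"], "start": [20], "end": [90]})
        out = classify_constitutive_loci(a, b, sample=sample)
        levels = out.attrs["class_levels"]
        assert levels["constitutive"] > levels["specific_a"]


class TestLengthCorrelation:
    def test_exact_linear_relation_gives_r_one(self):
        feats, rows = [], []
        for i, length in enumerate([100, 200, 300, 400]):
            start = 1000 * i
            feats.append(Feature(
                GenomicInterval("A01", start, start + length), f"f{i}", "TE"))
            k = length // 10  # level = length / 1000
            rows.append(("A01", start + 1, "+", "CG", k, 100 - k))
        out = length_methylation_correlation(feats, make_sample(rows), "CG")
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_independent_levels_give_null_r(self):
        rng = np.random.default_rng(3)
        feats, rows = [], []
        for i in range(300):
            length = int(rng.integers(100, 5000))
            start = 6000 * i
            feats.append(Feature(
                GenomicInterval("A01", start, start + length), f"f{i}", "TE"))
            k = int(rng.integers(0, 101))
            rows.append(("A01", start + 1, "+", "CG", k, 100 - k))
        out = length_methylation_correlation(feats, make_sample(rows), "CG")
        assert abs(out["pearson_r"].iloc[0]) < 0.15

    def test_too_few_points_undefined(self, sample_first):
        feats = [Feature(GenomicInterval("Z9", 0, 100), "f", "TE")]
        out = length_methylation_correlation(feats, sample_first, "CG")
        assert np.isnan(out["pearson_r"].iloc[0])
        assert out["n_excluded"].iloc[0] == 1


class TestLevelIndex:
    def test_interval_counts_match_direct_sum(self, sample_first):
        idx = LevelIndex(sample_first)
        sub = sample_first.subset(context="CG", chrom="A01")
        window = (2000, 9000)
        inside = sub[(sub["pos"] - 1 >= window[0]) & (sub["pos"] - 1 < window[1])]
        m, t = idx.counts("A01", *window, "CG")
        assert m == inside["count_m"].sum()
        assert t == (inside["count_m"] + inside["count_u"]).sum()
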