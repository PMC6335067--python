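"""Generator properties: determinism, planted structure, observation model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsmeth.simulate import (Genome, PlantedDMR, SimulationConfig,
                             SyntheticTruth, extract_cytosines,
                             generate_genome, generate_methylome,
                             promoter_levels_from_truth,
                             simulate_bisulfite_counts, simulate_expression,
                             simulate_sirna_loci)


def _flat_truth(levels, samples=("a", "b")):
    """Minimal truth object with explicit per-site true levels."""
    n = len(levels)
    sites = pd.DataFrame({
        "chrom": "A01",
        "pos": np.arange(1, n + 1),
        "strand": "+",
        "context": "CHH",
        "tri": "CAT",
    })
    for s in samples:
        sites[f"level_{s}"] = levels
    return SyntheticTruth(sites, list(samples), pd.DataFrame(), pd.DataFrame())


class TestGenome:
    def test_config_echo_and_subgenome_prefixes(self, dataset):
        genome = dataset.genome
        assert set(genome.sequences) == {"A01", "D01"}
        prefixes = {c[0] for c in genome.chrom_lengths}
        assert prefixes == {"A", "D"}
        kinds = {f.kind for f in genome.features}
        assert kinds == {"PCG", "TEG", "TE"}

    def test_same_seed_identical_output(self, small_config):
        g1 = generate_genome(small_config)
        g2 = generate_genome(small_config)
        assert all(np.array_equal(g1.sequences[c], g2.sequences[c])
                   for c in g1.sequences)
        assert [(f.feature_id, f.interval) for f in g1.features] == \
               [(f.feature_id, f.interval) for f in g2.features]

    def test_no_long_tes_when_long_fraction_zero(self):
        cfg = SimulationConfig(chrom_lengths={"A01": 100_000},
                               genes_per_chrom=2, tegs_per_chrom=0,
                               tes_per_chrom=20,
                               te_length_fracs=(0.6, 0.4, 0.0))
        genome = generate_genome(cfg)
        assert all(te.length <= 4000 for te in genome.tes())

    def test_features_non_overlapping(self, dataset):
        feats = sorted(dataset.genome.features,
                       key=lambda f: (f.interval.chrom, f.interval.start))
        for a, b in zip(feats, feats[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end <= b.interval.start

    def test_capacity_exceeded_rejected(self):
        cfg = SimulationConfig(chrom_lengths={"A01": 30_000},
                               genes_per_chrom=20)
        with pytest.raises(ValueError, match="capacity"):
            generate_genome(cfg)

    def test_extracted_contexts_match_triplets(self, dataset):
        from bsmeth.core import assign_context
        sites = extract_cytosines(dataset.genome).sample(200, random_state=0)
        for row in sites.itertuples(index=False):
            assert assign_context(row.tri) == row.context


class TestMethylomeTruth:
    def test_context_mean_recovered_without_islands(self):
        cfg = SimulationConfig(seed=3, chrom_lengths={"A01": 200_000},
                               genes_per_chrom=0, tegs_per_chrom=0,
                               tes_per_chrom=0, chh_island_level=0.0,
                               n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0})
        genome = generate_genome(cfg)
        truth = generate_methylome(genome, cfg)
        chh = truth.sites[truth.sites["context"] == "CHH"]
        assert len(chh) > 10_000
        assert chh["level_NEC"].mean() == pytest.approx(0.08, abs=0.01)

    def test_zero_variance_config_pins_every_site_to_context_mean(self):
        cfg = SimulationConfig(seed=3, chrom_lengths={"A01": 50_000},
                               genes_per_chrom=0, tegs_per_chrom=0,
                               tes_per_chrom=0, chh_island_level=0.0,
                               context_concentration={"CG": np.inf,
                                                      "CHG": np.inf,
                                                      "CHH": np.inf},
                               n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0})
        truth = generate_methylome(generate_genome(cfg), cfg)
        for ctx, mu in cfg.context_means.items():
            sub = truth.sites[truth.sites["context"] == ctx]
            assert (sub["level_NEC"] == mu).all()

    def test_planted_dmr_shifts_designated_sample_only(self, dataset):
        truth, cfg = dataset.truth, dataset.config
        target = cfg.samples[-1]
        other = cfg.samples[0]
        chh = truth.dmrs[truth.dmrs["context"] == "CHH"]
        assert len(chh) == cfg.n_planted_dmrs["CHH"]
        for d in chh.itertuples(index=False):
            inside = truth.sites[
                (truth.sites["chrom"] == d.chrom)
                & (truth.sites["pos"] - 1 >= d.start)
                & (truth.sites["pos"] - 1 < d.end)
                & (truth.sites["context"] == "CHH")
            ]
            gap = inside[f"level_{target}"].mean() - inside[f"level_{other}"].mean()
            assert gap == pytest.approx(0.4, abs=0.02)
            assert d.n_sites >= cfg.dmr_min_sites

    def test_clamped_deltas_recorded(self, dataset):
        cg = dataset.truth.dmrs[dataset.truth.dmrs["context"] == "CG"]
        # -0.8 from a ~0.75 baseline must clamp at 0 for many sites
        assert cg["clamped"].any()
        assert (cg["realized_delta"] > cg["delta"]).all()

    def test_chh_islands_elevate_upstream_sites(self, dataset):
        truth = dataset.truth
        strong = truth.gene_islands[truth.gene_islands["boost"] > 0.15]
        assert len(strong) > 0
        row = strong.iloc[0]
        sites = truth.sites
        inside = sites[(sites["chrom"] == row["chrom"])
                       & (sites["pos"] - 1 >= row["start"])
                       & (sites["pos"] - 1 < row["end"])
                       & (sites["context"] == "CHH")]
        background = sites[(sites["context"] == "CHH")]
        assert inside["level_NEC"].mean() > background["level_NEC"].mean() + 0.05


class TestCountsModel:
    @pytest.mark.parametrize(
        "true_level, expected",
        [(0.0, 0.006), (1.0, 1.0), (0.5, 0.5 + 0.5 * 0.006)],
    )
    def test_observed_level_matches_m_plus_one_minus_m_r(self, true_level,
                                                         expected):
        cfg = SimulationConfig(seed=11, mean_depth=30.0)
        truth = _flat_truth(np.full(100_000, true_level), samples=("NEC", "EC"))
        sample = simulate_bisulfite_counts(truth, "NEC", cfg)
        m = sample.sites["count_m"].sum()
        t = m + sample.sites["count_u"].sum()
        # binomial SE on the pooled level at 3e6 reads is ~1e-4
        assert m / t == pytest.approx(expected, abs=5e-4)

    def test_coverage_mean_and_determinism(self):
        cfg = SimulationConfig(seed=11, mean_depth=30.0)
        truth = _flat_truth(np.full(20_000, 0.1), samples=("NEC", "EC"))
        s1 = simulate_bisulfite_counts(truth, "NEC", cfg)
        s2 = simulate_bisulfite_counts(truth, "NEC", cfg)
        cov = s1.sites["count_m"] + s1.sites["count_u"]
        assert cov.mean() == pytest.approx(30.0, rel=0.02)
        pd.testing.assert_frame_equal(s1.sites, s2.sites)

    def test_truth_and_counts_mutually_consistent(self, dataset):
        """Pooled observed level tracks the truth-implied expectation."""
        cfg = dataset.config
        name = cfg.samples[0]
        truth_levels = dataset.truth.levels(name)
        r = cfg.nonconversion_rate
        expected = np.mean(truth_levels + (1 - truth_levels) * r)
        sample = dataset.methylomes[name]
        observed = (sample.sites["count_m"].sum()
                    / (sample.sites["count_m"] + sample.sites["count_u"]).sum())
        assert observed == pytest.approx(expected, abs=0.002)


class TestSirnaLoci:
    def test_full_coupling_places_every_locus_inside_hyper_regions(self):
        cfg = SimulationConfig(seed=5, sirna_coupling=1.0, n_sirna_loci=200,
                               chrom_lengths={"A01": 150_000},
                               genes_per_chrom=6, tegs_per_chrom=0,
                               tes_per_chrom=6)
        genome = generate_genome(cfg)
        truth = generate_methylome(genome, cfg)
        loci = simulate_sirna_loci(truth, cfg, genome)
        regions = truth.dmrs[(truth.dmrs["context"] == "CHH")
                             & (truth.dmrs["delta"] > 0)]
        for df in loci.values():
            for row in df.itertuples(index=False):
                hit = ((regions["chrom"] == row.chrom)
                       & (regions["start"] <= row.start)
                       & (regions["end"] >= row.end)).any()
                assert hit

    def test_half_coupling_hits_binomial_fraction(self, dataset):
        cfg = SimulationConfig(seed=9, sirna_coupling=0.5, n_sirna_loci=1000,
                               sirna_shared_fraction=0.0,
                               chrom_lengths={"A01": 200_000},
                               genes_per_chrom=8, tegs_per_chrom=0,
                               tes_per_chrom=8)
        genome = generate_genome(cfg)
        truth = generate_methylome(genome, cfg)
        loci = simulate_sirna_loci(truth, cfg, genome)
        df = loci[cfg.samples[0]]
        inside = int(df["planted_inside"].sum())
        assert inside == pytest.approx(500, abs=50)

    def test_same_seed_identical_bed(self, small_config, dataset):
        again = simulate_sirna_loci(dataset.truth, small_config, dataset.genome)
        for name, df in dataset.sirna_loci.items():
            pd.testing.assert_frame_equal(df, again[name])

    def test_locus_lengths_at_least_one_alignment(self, dataset):
        for df in dataset.sirna_loci.values():
            lengths = df["end"] - df["start"]
            assert (lengths >= 24).all()
            assert (df["abundance"] >= 1).all()


class TestExpression:
    def _x(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"NEC": rng.uniform(0, 1, n), "EC": rng.uniform(0, 1, n)},
            index=[f"g{i}" for i in range(n)],
        )

    def test_zero_noise_gives_exact_linear_relation(self):
        cfg = SimulationConfig(expression_noise_sd=0.0)
        x = self._x(50)
        out = simulate_expression(x, cfg)
        y = np.log2(out["fpkm_NEC"].to_numpy() + 1)
        r = np.corrcoef(x["NEC"], y)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_slope_gives_null_correlation(self):
        cfg = SimulationConfig(seed=2, expression_slope=0.0)
        x = self._x(2000)
        out = simulate_expression(x, cfg)
        y = np.log2(out["fpkm_NEC"].to_numpy() + 1)
        r = np.corrcoef(x["NEC"], y)[0, 1]
        assert abs(r) < 0.05

    def test_ols_recovers_slope(self):
        """slope -4, sd 0.5, 2000 genes: OLS on the truth recovers -4."""
        cfg = SimulationConfig(seed=4, expression_slope=-4.0,
                               expression_noise_sd=0.5)
        x = self._x(2000, seed=4)
        out = simulate_expression(x, cfg)
        y = np.log2(out["fpkm_NEC"].to_numpy() + 1)
        fit = stats.linregress(x["NEC"], y)
        assert fit.slope == pytest.approx(-4.0, abs=0.1)

    def test_promoter_levels_from_truth_reflect_islands(self, dataset):
        levels = promoter_levels_from_truth(dataset.truth, dataset.genome)
        boosts = dataset.truth.gene_islands.set_index("gene_id")["boost"]
        shared = levels.index.intersection(boosts.index)
        r = np.corrcoef(levels.loc[shared].iloc[:, 0], boosts.loc[shared])[0, 1]
        assert r > 0.8
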