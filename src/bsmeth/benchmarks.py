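"""Reproducible validation experiments for the whole pipeline.

Each function runs one self-contained experiment — oracle-equivalence
sweeps for the exact tests, synthetic null / planted-signal studies for
the DMR caller, flatness and conservation checks for the profilers, and
coupling recovery for the methylation-expression integration — and
returns a dict of plain numbers.  The test suite asserts on these; the
reproduction script reports them.

Problem sizes are chosen so the whole battery runs in a few minutes on
one core: a 5.5-Mb featureless genome gives ~55,000 testable CHH bins
for the null study; recovery plants 20 bins per context on a 1-Mb
genome; coupling uses 2,000 genes on a 5.8-Mb genome.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .calling import min_methylated_count
from .core import Parameters
from .differential import call_dmrs, fisher_bin_test_batch
from .integrate import (compare_dmr_vs_nondmr_correlation,
                        methylation_expression_correlation,
                        promoter_methylation)
from .profiles import metagene_profile, rddm_profile, window_track
from .simulate import (SimulationConfig, generate_genome, generate_methylome,
                       promoter_levels_from_truth, simulate_bisulfite_counts,
                       simulate_expression)


def binomial_tail_check(max_n: int = 200, r: float = 0.006,
                        alpha: float = 1e-5) -> dict:
    """Sweep every (n, m) with n <= max_n against plain pmf summation.

    The oracle is an independent enumeration (math.comb, suffix sums);
    also verifies the minimum-significant-count table derived from it.
    """
    max_abs = 0.0
    max_rel = 0.0
    thresholds_agree = True
    thresholds = {}
    for n in range(1, max_n + 1):
        terms = np.array([
            math.comb(n, k) * r**k * (1 - r) ** (n - k) for k in range(n + 1)
        ])
        oracle = np.cumsum(terms[::-1])[::-1]  # oracle[m] = P(X >= m)
        impl = binom.sf(np.arange(n + 1) - 1, n, r)
        diff = np.abs(impl - oracle)
        max_abs = max(max_abs, float(diff.max()))
        big = oracle > 1e-250
        if big.any():
            max_rel = max(max_rel, float((diff[big] / oracle[big]).max()))
        hits = np.flatnonzero(oracle < alpha)
        t_oracle = int(hits[0]) if len(hits) else None
        t_impl = min_methylated_count(n, r, alpha)
        thresholds_agree &= t_oracle == t_impl
        thresholds[n] = t_impl
    return {
        "n_coverages": max_n,
        "max_abs_diff": max_abs,
        "max_rel_diff": max_rel,
        "thresholds_agree": bool(thresholds_agree),
        "threshold_n3": thresholds[3],
        "threshold_n10": thresholds[10],
    }


def _all_tables(max_margin: int) -> np.ndarray:
    rows = []
    for r1 in range(max_margin + 1):
        for a in range(r1 + 1):
            rows.append((a, r1 - a))
    rows = np.array(rows, dtype=np.int64)
    n1 = len(rows)
    a = np.repeat(rows[:, 0], n1)
    b = np.repeat(rows[:, 1], n1)
    c = np.tile(rows[:, 0], n1)
    d = np.tile(rows[:, 1], n1)
    return np.stack([a, b, c, d], axis=1)


def fisher_enumeration_check(max_margin: int = 40) -> dict:
    """Exhaustive two-sided Fisher check against an integer-exact oracle.

    Every 2x2 table with both row margins <= max_margin; the oracle sums
    hypergeometric numerators in exact integer arithmetic (same 1e-7
    relative tie slack as the implementation).
    """
    tables = _all_tables(max_margin)
    p_impl = fisher_bin_test_batch(tables[:, 0], tables[:, 1],
                                   tables[:, 2], tables[:, 3], chunk=20_000)
    comb = [[math.comb(n, k) for k in range(n + 1)]
            for n in range(2 * max_margin + 1)]
    p_oracle = np.empty(len(tables))
    for i, (a, b, c, d) in enumerate(tables):
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2
        if n == 0:
            p_oracle[i] = 1.0
            continue
        obs = comb[r1][a] * comb[r2][c]
        thresh = obs + obs * 1e-7
        lo, hi = max(0, c1 - r2), min(r1, c1)
        total = 0
        row1, row2 = comb[r1], comb[r2]
        for k in range(lo, hi + 1):
            t = row1[k] * row2[c1 - k]
            if t <= thresh:
                total += t
        p_oracle[i] = total / comb[n][c1]
    return {
        "n_tables": len(tables),
        "max_abs_diff": float(np.abs(p_impl - p_oracle).max()),
    }


def null_fdr_experiment(seed: int = 1, chrom_len: int = 2_750_000) -> dict:
    """False-discovery control on a synthetic null comparison.

    Two samples share identical true methylomes (featureless genome, no
    planted signal); counts are drawn independently.  Reports the
    fraction of tested CHH bins called significant and the BH bound
    0.05 + 3 Monte-Carlo standard errors.
    """
    cfg = SimulationConfig(
        seed=seed,
        chrom_lengths={"A01": chrom_len, "D01": chrom_len},
        genes_per_chrom=0, tegs_per_chrom=0, tes_per_chrom=0,
        chh_island_level=0.0,
        n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
        samples=("null_a", "null_b"),
    )
    genome = generate_genome(cfg)
    truth = generate_methylome(genome, cfg)
    a = simulate_bisulfite_counts(truth, "null_a", cfg)
    b = simulate_bisulfite_counts(truth, "null_b", cfg)
    tested = call_dmrs(a, b, "CHH", return_all=True)
    n = len(tested)
    k = int(tested["significant"].sum())
    alpha = Parameters().dmr_fdr
    return {
        "n_tested_bins": n,
        "n_significant": k,
        "fraction": k / n,
        "bound": alpha + 3 * math.sqrt(alpha * (1 - alpha) / n),
    }


def dmr_recovery_experiment(seed: int = 1) -> dict:
    """Sensitivity on planted DMRs: 20 CHH bins (delta +0.4) and 20 CG
    bins (delta -0.8) at 30x depth, >= 15 sites per bin."""
    cfg = SimulationConfig(
        seed=seed,
        chrom_lengths={"A01": 500_000, "D01": 500_000},
        genes_per_chrom=0, tegs_per_chrom=0, tes_per_chrom=0,
        chh_island_level=0.0,
        samples=("WT", "R0"),
        n_planted_dmrs={"CG": 20, "CHG": 0, "CHH": 20},
        planted_delta={"CG": -0.8, "CHG": -0.5, "CHH": 0.4},
        dmr_min_sites=15,
    )
    genome = generate_genome(cfg)
    truth = generate_methylome(genome, cfg)
    wt = simulate_bisulfite_counts(truth, "WT", cfg)
    r0 = simulate_bisulfite_counts(truth, "R0", cfg)
    out = {}
    for ctx, want in (("CHH", "hyper"), ("CG", "hypo")):
        dmrs = call_dmrs(wt, r0, ctx)
        found = dmrs.set_index(["chrom", "start"])
        planted = truth.dmrs[truth.dmrs["context"] == ctx]
        recovered = direction_ok = 0
        for d in planted.itertuples(index=False):
            key = (d.chrom, d.start)
            if key in found.index:
                recovered += 1
                direction_ok += int(found.loc[key, "direction"] == want)
        out[f"{ctx.lower()}_sensitivity"] = recovered / len(planted)
        out[f"{ctx.lower()}_direction_accuracy"] = (
            direction_ok / recovered if recovered else 0.0)
        out[f"{ctx.lower()}_n_planted"] = len(planted)
    return out


def profile_flatness_experiment(seed: int = 1) -> dict:
    """Constant-level methylome: every defined profile bin must sit within
    the analytic binomial bound, and tiling windows must conserve the
    genome-wide level exactly."""
    level = 0.3
    cfg = SimulationConfig(
        seed=seed, chrom_lengths={"A01": 150_000, "D01": 150_000},
        genes_per_chrom=10, tegs_per_chrom=0, tes_per_chrom=10,
        chh_island_level=0.0,
        context_means={"CG": level, "CHG": level, "CHH": level},
        context_concentration={"CG": np.inf, "CHG": np.inf, "CHH": np.inf},
        n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
    )
    genome = generate_genome(cfg)
    truth = generate_methylome(genome, cfg)
    sample = simulate_bisulfite_counts(truth, cfg.samples[0], cfg)
    p_obs = level + (1 - level) * cfg.nonconversion_rate

    def max_z(levels, reads):
        ok = reads > 0
        se = np.sqrt(p_obs * (1 - p_obs) / reads[ok])
        return float((np.abs(levels[ok] - p_obs) / se).max())

    zs = []
    for ctx in ("CG", "CHG", "CHH"):
        prof = metagene_profile(sample, genome.genes(), ctx)
        zs.append(max_z(prof["level"].to_numpy(), prof["reads"].to_numpy()))
    import pandas as pd
    loci = pd.DataFrame({"chrom": ["A01", "A01", "D01"],
                         "start": [30_000, 90_000, 50_000],
                         "end": [30_300, 90_200, 50_400]})
    prof = rddm_profile(sample, loci, "CHH")
    zs.append(max_z(prof["level"].to_numpy(), prof["reads"].to_numpy()))
    track = window_track(sample, 10_000, 10_000,
                         chrom_lengths=genome.chrom_lengths, contexts="CHH")
    zs.append(max_z(track["level_CHH"].to_numpy(),
                    track["reads_CHH"].to_numpy()))
    pooled = (track["level_CHH"].fillna(0) * track["reads_CHH"]).sum()
    conservation_error = abs(
        pooled / track["reads_CHH"].sum() - sample.level("CHH"))
    return {
        "max_abs_z": max(zs),
        "n_bins_checked": 3 * 300 + 300 + len(track),
        "conservation_error": float(conservation_error),
    }


def coupling_experiment(seed: int = 1) -> dict:
    """Expression-coupling recovery at 2,000 genes (slope -4, noise 0.5).

    Measures Pearson r between observed promoter CHH level and
    log2(FPKM+1) against the closed-form population correlation
    s*sd(x) / sqrt(s^2 var(x) + sigma^2), and the DMR-gene vs
    non-DMR-gene contrast (coupling applied to half the genes).
    """
    cfg = SimulationConfig(
        seed=seed,
        chrom_lengths={"A01": 2_900_000, "D01": 2_900_000},
        genes_per_chrom=1000, tegs_per_chrom=0, tes_per_chrom=0,
        gene_length_range=(500, 900), min_feature_gap=2100,
        samples=("NEC", "EC"),
        n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 0},
        expression_slope=-4.0, expression_noise_sd=0.5,
    )
    genome = generate_genome(cfg)
    truth = generate_methylome(genome, cfg)
    sample = simulate_bisulfite_counts(truth, "NEC", cfg)
    x_true = promoter_levels_from_truth(truth, genome)
    expr = simulate_expression(x_true, cfg).set_index("gene_id")
    prom_obs = promoter_methylation(sample, genome.genes(), "CHH")
    res = methylation_expression_correlation(prom_obs, expr["fpkm_NEC"])
    x = x_true["NEC"].to_numpy()
    s, sd = cfg.expression_slope, cfg.expression_noise_sd
    r_expected = s * x.std() / math.sqrt(s**2 * x.var() + sd**2)
    # contrast: same promoters, coupling restricted to half the genes
    cfg_half = SimulationConfig(
        seed=seed + 1, expression_coupled_fraction=0.5,
        expression_slope=s, expression_noise_sd=sd)
    expr_half = simulate_expression(x_true, cfg_half).set_index("gene_id")
    both = compare_dmr_vs_nondmr_correlation(
        prom_obs, expr_half["fpkm_NEC"],
        expr_half.index[expr_half["coupled"]],
        expr_half.index[~expr_half["coupled"]])
    return {
        "n_genes": int(res["n"]),
        "r_measured": res["pearson_r"],
        "r_expected": float(r_expected),
        "r_dmr_genes": both["dmr"]["pearson_r"],
        "r_non_dmr_genes": both["non_dmr"]["pearson_r"],
    }


def determinism_experiment(seed: int = 1) -> dict:
    """Two full pipeline runs with one seed must be byte-identical."""
    from .pipeline import run_all

    cfg = SimulationConfig(
        seed=seed, chrom_lengths={"A01": 60_000, "D01": 60_000},
        genes_per_chrom=4, tegs_per_chrom=1, tes_per_chrom=6,
        n_planted_dmrs={"CG": 1, "CHG": 1, "CHH": 2},
        n_sirna_loci=50,
    )
    with tempfile.TemporaryDirectory() as tmp:
        m1 = run_all(cfg, Path(tmp) / "run1")
        m2 = run_all(cfg, Path(tmp) / "run2")
    return {
        "n_files": len(m1),
        "identical": m1 == m2 and len(m1) > 0,
    }
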