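"""Differential methylation between two methylomes.

DMRs: the genome is tiled into non-overlapping 100-bp bins; per bin and
context, methylated/unmethylated read counts are pooled across sites
and the two samples compared with a two-sided Fisher's exact test.
Only bins with at least 10 *informative* cytosines of the context
(>= 4 reads each) in each compared sample are tested; Benjamini-
Hochberg correction runs across all tested bins of one context within
one comparison, and bins with q < 0.05 are DMRs.  Bins are not merged,
and no minimum delta is imposed (delta is reported for post-filtering).

DMCs: positions covered (>= 3 reads) in both samples whose binomial
call statuses differ (methylated in exactly one sample) and whose
absolute level difference reaches the context threshold
(0.7 / 0.5 / 0.1 for CG / CHG / CHH).

The two-sided Fisher p-value is the sum of hypergeometric point
probabilities not exceeding the observed table's probability (with the
customary 1e-7 relative slack for floating-point ties).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .calling import call_sites
from .core import CONTEXTS, MethylomeSample, Parameters

logger = logging.getLogger(__name__)

_TIE_SLACK = 1e-7  # relative tolerance when comparing point probabilities


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_bin_test_batch(m_a, u_a, m_b, u_b,
                          chunk: int = 4096) -> np.ndarray:
    """Two-sided Fisher's exact test on many 2x2 tables [[m_a,u_a],[m_b,u_b]].

    Vectorized enumeration of the hypergeometric support; all-zero
    tables give p = 1 by convention.
    """
    a = np.asarray(m_a, dtype=np.int64)
    b = np.asarray(u_a, dtype=np.int64)
    c = np.asarray(m_b, dtype=np.int64)
    d = np.asarray(u_b, dtype=np.int64)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("negative counts")
    r1, r2 = a + b, c + d
    n = r1 + r2
    c1 = a + c
    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(r1, c1)
    out = np.ones(len(a), dtype=float)
    nz = np.flatnonzero(n > 0)
    for s in range(0, len(nz), chunk):
        idx = nz[s:s + chunk]
        width = int((hi[idx] - lo[idx]).max()) + 1
        k = lo[idx, None] + np.arange(width)[None, :]
        valid = k <= hi[idx, None]
        kc = np.where(valid, k, lo[idx, None])
        logp = (
            _log_choose(r1[idx, None], kc)
            + _log_choose(r2[idx, None], c1[idx, None] - kc)
            - _log_choose(n[idx, None], c1[idx, None])
        )
        logobs = (
            _log_choose(r1[idx], a[idx])
            + _log_choose(r2[idx], c[idx])
            - _log_choose(n[idx], c1[idx])
        )
        include = valid & (logp <= logobs[:, None] + _TIE_SLACK)
        p = np.where(include, np.exp(logp), 0.0).sum(axis=1)
        out[idx] = np.minimum(p, 1.0)
    return out


def fisher_bin_test(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher's exact p for a single 2x2 table."""
    return float(fisher_bin_test_batch([m_a], [u_a], [m_b], [u_b])[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bin_genome(sample: MethylomeSample, context: str, bin_size: int = 100,
               informative_min_reads: int = 4,
               chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Pooled counts and informative-cytosine tally per 100-bp tile.

    Tiles are [k*bin, (k+1)*bin) in internal 0-based coordinates (the
    1-based report position p falls in bin (p-1)//bin).  An informative
    cytosine carries at least ``informative_min_reads`` reads.  By
    default only non-empty bins are returned; pass ``chrom_lengths`` to
    materialise the full tiling (empty bins have counts (0, 0) and
    informative 0).
    """
    sub = sample.subset(context=context)
    empty = pd.DataFrame(
        columns=["chrom", "bin", "start", "end", "m", "u", "informative"])
    if len(sub) == 0 and chrom_lengths is None:
        return empty
    binned = pd.DataFrame({
        "chrom": sub["chrom"].to_numpy(),
        "bin": (sub["pos"].to_numpy() - 1) // bin_size,
        "m": sub["count_m"].to_numpy(),
        "u": sub["count_u"].to_numpy(),
    })
    binned["informative"] = (
        (binned["m"] + binned["u"]) >= informative_min_reads
    ).astype(np.int64)
    g = binned.groupby(["chrom", "bin"], observed=True).sum().reset_index()
    if chrom_lengths is not None:
        full = pd.concat([
            pd.DataFrame({
                "chrom": chrom,
                "bin": np.arange(-(-length // bin_size), dtype=np.int64),
            })
            for chrom, length in sorted(chrom_lengths.items())
        ], ignore_index=True)
        g = full.merge(g, on=["chrom", "bin"], how="left").fillna(0)
        for col in ("m", "u", "informative"):
            g[col] = g[col].astype(np.int64)
    g["start"] = g["bin"] * bin_size
    g["end"] = g["start"] + bin_size
    return g[["chrom", "bin", "start", "end", "m", "u", "informative"]]


def call_dmrs(sample_a: MethylomeSample, sample_b: MethylomeSample,
              context: str, params: Parameters = Parameters(),
              informative_mode: str = "each",
              return_all: bool = False) -> pd.DataFrame:
    """Fisher-exact binned DMRs between two samples for one context.

    ``informative_mode``: "each" (default, stricter reading) requires
    >= 10 informative cytosines in each sample; "either" in at least
    one.  Direction is relative to sample A: "hyper" means sample B has
    the higher level.  With ``return_all`` every tested bin is returned
    (column ``significant`` flags q < FDR); otherwise only DMRs.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    bins_a = bin_genome(sample_a, context, params.dmr_bin_size,
                        params.informative_min_reads)
    bins_b = bin_genome(sample_b, context, params.dmr_bin_size,
                        params.informative_min_reads)
    merged = bins_a.merge(bins_b, on=["chrom", "bin", "start", "end"],
                          how="outer", suffixes=("_a", "_b")).fillna(0)
    for col in ("m_a", "u_a", "m_b", "u_b", "informative_a", "informative_b"):
        merged[col] = merged[col].astype(np.int64)
    if informative_mode == "each":
        testable = (
            (merged["informative_a"] >= params.dmr_min_informative)
            & (merged["informative_b"] >= params.dmr_min_informative)
        )
    elif informative_mode == "either":
        testable = (
            (merged["informative_a"] >= params.dmr_min_informative)
            | (merged["informative_b"] >= params.dmr_min_informative)
        )
    else:
        raise ValueError("informative_mode must be 'each' or 'either'")
    tested = merged[testable].reset_index(drop=True)
    if len(tested) == 0:
        logger.info("no testable %s bins between %s and %s",
                    context, sample_a.name, sample_b.name)
        cols = ["chrom", "start", "end", "context", "level_a", "level_b",
                "delta", "p_value", "q_value", "direction"]
        return pd.DataFrame(columns=cols)
    p = fisher_bin_test_batch(tested["m_a"], tested["u_a"],
                              tested["m_b"], tested["u_b"])
    q = bh_adjust(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = tested["m_a"] / (tested["m_a"] + tested["u_a"])
        level_b = tested["m_b"] / (tested["m_b"] + tested["u_b"])
    delta = level_b - level_a
    out = pd.DataFrame({
        "chrom": tested["chrom"],
        "start": tested["start"],
        "end": tested["end"],
        "context": context,
        "level_a": level_a,
        "level_b": level_b,
        "delta": delta,
        "p_value": p,
        "q_value": q,
        "direction": np.where(delta > 0, "hyper", "hypo"),
        "m_a": tested["m_a"], "u_a": tested["u_a"],
        "m_b": tested["m_b"], "u_b": tested["u_b"],
        "informative_a": tested["informative_a"],
        "informative_b": tested["informative_b"],
    })
    out["significant"] = out["q_value"] < params.dmr_fdr
    out.attrs["n_tested"] = len(out)
    if return_all:
        return out
    dmrs = out[out["significant"]].drop(columns="significant")
    dmrs = dmrs.reset_index(drop=True)
    dmrs.attrs["n_tested"] = len(out)
    return dmrs


def call_dmcs(sample_a: MethylomeSample, sample_b: MethylomeSample,
              params: Parameters = Parameters(),
              method: str = "status") -> pd.DataFrame:
    """Differentially methylated cytosines between two samples.

    ``method="status"`` (default): both sites covered by >= 3 reads,
    binomial call statuses discordant (methylated in exactly one
    sample), and |level_a - level_b| >= the context delta.
    ``method="fisher"``: replaces the discordant-status requirement with
    a per-site two-sided Fisher test at p < 0.05 (alternative reading).
    """
    keys = ["chrom", "pos", "strand", "context"]
    calls_a = call_sites(sample_a, params)
    calls_b = call_sites(sample_b, params)
    merged = calls_a.merge(calls_b, on=keys, suffixes=("_a", "_b"))
    covered = (
        (merged["coverage_a"] >= params.min_coverage_call)
        & (merged["coverage_b"] >= params.min_coverage_call)
    )
    merged = merged[covered].reset_index(drop=True)
    level_a = merged["ratio_a"].to_numpy()
    level_b = merged["ratio_b"].to_numpy()
    delta = level_b - level_a
    thresh = merged["context"].map(params.dmc_delta).to_numpy(dtype=float)
    big_enough = np.abs(delta) >= thresh
    if method == "status":
        discordant = (
            (merged["status_a"] == "methylated")
            ^ (merged["status_b"] == "methylated")
        ).to_numpy()
        keep = discordant & big_enough
    elif method == "fisher":
        p = fisher_bin_test_batch(merged["count_m_a"], merged["count_u_a"],
                                  merged["count_m_b"], merged["count_u_b"])
        keep = (p < 0.05) & big_enough
    else:
        raise ValueError("method must be 'status' or 'fisher'")
    out = merged.loc[keep, keys + [
        "count_m_a", "count_u_a", "count_m_b", "count_u_b",
        "status_a", "status_b"]].copy()
    out["level_a"] = level_a[keep]
    out["level_b"] = level_b[keep]
    out["delta"] = delta[keep]
    return out.reset_index(drop=True)


def compare_dmr_sets(named_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Overlap classes across >= 2 named DMR collections.

    A DMR is *common* when it overlaps (>= 1 bp, same context) a DMR in
    every other set, *unique* when it overlaps none, *partial*
    otherwise.  Returns per-set class counts; per-DMR labels are in
    ``.attrs['labels']``.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two DMR sets")
    from intervaltree import IntervalTree

    trees: dict[str, dict[tuple, IntervalTree]] = {}
    for name, df in named_sets.items():
        trees[name] = {}
        for row in df.itertuples(index=False):
            key = (row.chrom, row.context)
            trees[name].setdefault(key, IntervalTree()).addi(row.start, row.end)
    labelled = []
    for name, df in named_sets.items():
        others = [o for o in named_sets if o != name]
        rows = []
        for row in df.itertuples(index=False):
            key = (row.chrom, row.context)
            hits = sum(
                1 for o in others
                if key in trees[o] and trees[o][key].overlap(row.start, row.end)
            )
            if hits == len(others):
                cls = "common"
            elif hits == 0:
                cls = "unique"
            else:
                cls = "partial"
            rows.append((name, row.chrom, row.start, row.end, row.context, cls))
        labelled.append(pd.DataFrame(
            rows, columns=["set", "chrom", "start", "end", "context", "class"]))
    labels = (pd.concat(labelled, ignore_index=True) if labelled
              else pd.DataFrame(columns=["set", "chrom", "start", "end",
                                         "context", "class"]))
    summary = (
        labels.groupby(["set", "class"], observed=True).size()
        .unstack(fill_value=0)
        .reindex(columns=["common", "partial", "unique"], fill_value=0)
        .reindex(index=list(named_sets), fill_value=0)
    )
    summary.attrs["labels"] = labels
    return summary
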