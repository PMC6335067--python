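"""Shared domain types and primitives for bisulfite methylome analysis.

The atoms of the pipeline are single cytosines with methylated /
unmethylated read counts, grouped into named methylome samples.  All
internal interval arithmetic is 0-based half-open; on-disk formats keep
their native dialects (cytosine reports and GFF3 are 1-based, BED is
0-based half-open) and conversion happens at the I/O boundary.

The central numeric primitive is the *weighted* methylation level of a
set of sites: summed methylated reads over summed total reads.  Pooling
counts (rather than averaging per-site ratios) makes the statistic
robust to uneven coverage; the mean-of-ratios variant is available via
``method="mean_ratio"`` for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: the three cytosine sequence contexts of plant methylomes (H = A, T or C)
CONTEXTS = ("CG", "CHG", "CHH")

#: canonical column order of a site table
SITE_COLUMNS = ["chrom", "pos", "strand", "context", "count_m", "count_u"]

UNDEFINED = float("nan")


class CytosineSite(NamedTuple):
    """One cytosine: genomic address, strand, context and read counts.

    ``pos`` is the 1-based genomic position of the cytosine on the
    forward reference strand (the cytosine-report convention).
    ``count_m`` counts unconverted (methylated) reads, ``count_u``
    converted (unmethylated) reads.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    count_m: int
    count_u: int

    @property
    def coverage(self) -> int:
        return self.count_m + self.count_u


@dataclass(frozen=True)
class GenomicInterval:
    """Internal 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        return overlap_length(self, other)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class Feature:
    """An annotated genomic feature: protein-coding gene, TE, or TE-gene.

    ``exons`` (PCG/TEG only) must nest inside ``interval``.
    """

    interval: GenomicInterval
    feature_id: str
    kind: str  # {"PCG", "TE", "TEG"}
    exons: list[GenomicInterval] = field(default_factory=list)
    te_family: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("PCG", "TE", "TEG"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        for ex in self.exons:
            if (
                ex.chrom != self.interval.chrom
                or ex.start < self.interval.start
                or ex.end > self.interval.end
            ):
                raise ValueError(
                    f"exon {ex} of {self.feature_id} outside parent span"
                )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        """0-based position of the transcription start (strand-aware)."""
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1

    def promoter(self, length: int = 2000) -> GenomicInterval | None:
        """Strand-aware upstream window of ``length`` bp, clipped at 0."""
        if self.interval.strand == "-":
            return GenomicInterval(
                self.interval.chrom, self.interval.end, self.interval.end + length, "-"
            )
        start = max(0, self.interval.start - length)
        if start >= self.interval.start:
            return None
        return GenomicInterval(self.interval.chrom, start, self.interval.start, "+")


def _default_dmc_delta() -> dict[str, float]:
    return {"CG": 0.7, "CHG": 0.5, "CHH": 0.1}


@dataclass(frozen=True)
class Parameters:
    """Every tunable threshold of the pipeline, with its default.

    Defaults: methylated cytosines need >= 3 reads, binomial upper-tail
    p < 1e-5 against the non-conversion rate, and a methylated ratio
    > 25%.  DMRs are 100-bp bins with >= 10 informative cytosines
    (>= 4 reads each) in each compared sample, Fisher-exact tested and
    kept at BH-FDR < 0.05.  DMCs require per-context absolute level
    differences of 0.7 / 0.5 / 0.1 (CG / CHG / CHH).  Metagene profiles
    use 2-kb flanks in 100 intervals per segment; RdDM-locus profiles
    use 5-kb flanks.  TE length classes: short < 500 bp, long > 4 kb.
    DEGs: p < 0.05 and |log2 ratio| >= 2.  Chromosome tracks: 1-Mb
    windows sliding 200 kb (coarse) and 100-kb windows sliding 1 kb
    (fine).
    """

    min_coverage_call: int = 3
    call_p_threshold: float = 1e-5
    call_ratio_threshold: float = 0.25
    dmr_bin_size: int = 100
    dmr_min_informative: int = 10
    informative_min_reads: int = 4
    dmr_fdr: float = 0.05
    dmc_delta: dict[str, float] = field(default_factory=_default_dmc_delta)
    promoter_len: int = 2000
    metagene_flank: int = 2000
    metagene_nbins: int = 100
    rddm_flank: int = 5000
    te_short_max: int = 500
    te_long_min: int = 4000
    kmeans_k: int = 10
    deg_p: float = 0.05
    deg_min_abs_log2fc: float = 2.0
    circos_window: int = 1_000_000
    circos_step: int = 200_000
    fine_window: int = 100_000
    fine_step: int = 1_000
    sirna_len: int = 24

    def __post_init__(self) -> None:
        for name in (
            "min_coverage_call", "call_p_threshold", "call_ratio_threshold",
            "dmr_bin_size", "dmr_min_informative", "informative_min_reads",
            "dmr_fdr", "promoter_len", "metagene_flank", "metagene_nbins",
            "rddm_flank", "te_short_max", "te_long_min", "kmeans_k",
            "deg_p", "deg_min_abs_log2fc", "circos_window", "circos_step",
            "fine_window", "fine_step", "sirna_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if set(self.dmc_delta) != set(CONTEXTS):
            raise ValueError("dmc_delta must be keyed by exactly CG, CHG, CHH")
        if any(v <= 0 for v in self.dmc_delta.values()):
            raise ValueError("dmc_delta thresholds must be strictly positive")


def assign_context(triplet: str) -> str:
    """Classify the 3-base sequence starting at a cytosine (on its strand).

    CG if the second base is G; CHG if the third base is G (and the
    second is not); CHH otherwise.
    """
    if len(triplet) != 3:
        raise ValueError(f"need a 3-base string, got {triplet!r}")
    t = triplet.upper()
    if any(b not in "ACGT" for b in t):
        raise ValueError(f"non-ACGT base in {triplet!r}")
    if t[0] != "C":
        raise ValueError(f"triplet must start with C, got {triplet!r}")
    if t[1] == "G":
        return "CG"
    if t[2] == "G":
        return "CHG"
    return "CHH"


def pooled_level(m_total: float, u_total: float) -> float:
    """Weighted level from pooled counts; NaN when there are no reads."""
    total = m_total + u_total
    if total <= 0:
        return UNDEFINED
    return float(m_total) / float(total)


def _extract_counts(sites) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sites, pd.DataFrame):
        m = sites["count_m"].to_numpy(dtype=float)
        u = sites["count_u"].to_numpy(dtype=float)
        return m, u
    ms, us = [], []
    for s in sites:
        if hasattr(s, "count_m"):
            ms.append(s.count_m)
            us.append(s.count_u)
        else:
            a, b = s
            ms.append(a)
            us.append(b)
    return np.asarray(ms, dtype=float), np.asarray(us, dtype=float)


def weighted_level(sites, method: str = "pooled") -> float:
    """Methylation level of a site collection.

    ``method="pooled"`` (default): sum(count_m) / sum(count_m+count_u).
    ``method="mean_ratio"``: unweighted mean of per-site ratios over
    covered sites.  Returns NaN when no reads (or, for mean_ratio, no
    covered sites).  Negative counts are rejected.
    """
    m, u = _extract_counts(sites)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("negative read counts")
    if method == "pooled":
        return pooled_level(m.sum(), u.sum())
    if method == "mean_ratio":
        cov = m + u
        ok = cov > 0
        if not ok.any():
            return UNDEFINED
        return float(np.mean(m[ok] / cov[ok]))
    raise ValueError(f"unknown method {method!r}")


def validate_site_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a site table (sort, type-check, dedupe check)."""
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["count_m"] = df["count_m"].astype(np.int64)
    df["count_u"] = df["count_u"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be >= 1 (1-based)")
    if (df["count_m"] < 0).any() or (df["count_u"] < 0).any():
        raise ValueError("negative read counts")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"unknown context token(s): {sorted(df.loc[bad, 'context'].unique())}")
    bad = ~df["strand"].isin(("+", "-"))
    if bad.any():
        raise ValueError(f"invalid strand token(s): {sorted(df.loc[bad, 'strand'].unique())}")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate site at {first['chrom']}:{first['pos']}({first['strand']})"
        )
    return df


@dataclass
class MethylomeSample:
    """A named methylome: a sorted site table plus its non-conversion rate.

    ``sites`` columns: chrom, pos (1-based), strand, context, count_m,
    count_u, and optionally ``tri`` (the reference triplet).
    ``nonconversion_rate`` is the probability that a truly unmethylated
    cytosine escapes bisulfite conversion (estimated upstream from an
    unmethylated spike-in control; 0.006 by default).
    """

    name: str
    sites: pd.DataFrame
    nonconversion_rate: float = 0.006

    def __post_init__(self) -> None:
        if not (0 <= self.nonconversion_rate < 1):
            raise ValueError("nonconversion_rate must be in [0, 1)")
        self.sites = validate_site_frame(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.sites["chrom"]))

    def subset(self, context: str | None = None, chrom: str | None = None) -> pd.DataFrame:
        df = self.sites
        if context is not None:
            df = df[df["context"] == context]
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        return df

    def level(self, context: str | None = None, method: str = "pooled") -> float:
        """Genome-wide weighted level, optionally for one context."""
        return weighted_level(self.subset(context=context), method=method)

    def iter_sites(self) -> Iterable[CytosineSite]:
        for row in self.sites.itertuples(index=False):
            yield CytosineSite(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.count_m), int(row.count_u),
            )
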