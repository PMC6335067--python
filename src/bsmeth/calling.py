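"""Methylated-cytosine identification by a binomial test.

A cytosine with n reads, of which m are unconverted, is tested against
the bisulfite non-conversion rate r: under the null (truly
unmethylated) m ~ Binomial(n, r), and the site is called methylated
when the upper-tail probability P(X >= m) falls below 1e-5, the
methylated ratio m/n exceeds 25%, and coverage is at least 3 reads.
Sites below the coverage floor are *uncallable*.  No multiple-testing
correction is applied to per-site calls; the fixed threshold is the
procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import CONTEXTS, MethylomeSample, Parameters

CALL_STATUSES = ("methylated", "unmethylated", "uncallable")


def site_pvalue(count_m: int, n: int, r: float) -> float:
    """Exact upper-tail binomial probability P(X >= count_m), X ~ Bin(n, r)."""
    if not (0 <= r < 1):
        raise ValueError("non-conversion rate must be in [0, 1)")
    if count_m < 0 or n < 0 or count_m > n:
        raise ValueError(f"need 0 <= count_m <= n, got m={count_m}, n={n}")
    return float(binom.sf(count_m - 1, n, r))


def site_pvalues(count_m: np.ndarray, n: np.ndarray, r: float) -> np.ndarray:
    """Vectorized :func:`site_pvalue`."""
    count_m = np.asarray(count_m)
    n = np.asarray(n)
    if (count_m < 0).any() or (count_m > n).any():
        raise ValueError("need 0 <= count_m <= n")
    return binom.sf(count_m - 1, n, r)


def min_methylated_count(n: int, r: float, alpha: float) -> int | None:
    """Smallest methylated count significant at ``alpha`` for coverage n.

    Returns None when even m = n is not significant.  With a degenerate
    alpha > 1 every count (including 0) is significant.
    """
    if n < 1:
        raise ValueError("coverage must be >= 1")
    p = binom.sf(np.arange(-1, n), n, r)  # p[m] = P(X >= m), m = 0..n
    hits = np.flatnonzero(p < alpha)
    return int(hits[0]) if len(hits) else None


def call_sites(sample: MethylomeSample,
               params: Parameters = Parameters()) -> pd.DataFrame:
    """Per-site methylation calls for one sample.

    Returns the site table plus ``coverage``, ``ratio``, ``p_value`` and
    ``status`` columns; every site receives exactly one status.
    """
    df = sample.sites.copy()
    m = df["count_m"].to_numpy()
    n = m + df["count_u"].to_numpy()
    with np.errstate(invalid="ignore"):
        ratio = np.where(n > 0, m / np.maximum(n, 1), np.nan)
    p = binom.sf(m - 1, n, sample.nonconversion_rate)
    callable_ = n >= params.min_coverage_call
    methylated = (
        callable_
        & (p < params.call_p_threshold)
        & (ratio > params.call_ratio_threshold)
    )
    status = np.where(
        ~callable_, "uncallable", np.where(methylated, "methylated", "unmethylated")
    )
    df["coverage"] = n
    df["ratio"] = ratio
    df["p_value"] = p
    df["status"] = status
    return df


def methylome_composition(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of methylated cytosines per context.

    Fractions are over methylated sites only (they sum to 1); with zero
    methylated sites the fractions are NaN (flagged empty summary).
    """
    meth = calls[calls["status"] == "methylated"]
    counts = meth["context"].value_counts().reindex(CONTEXTS, fill_value=0)
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts})
    out["fraction"] = counts / total if total > 0 else np.nan
    out.index.name = "context"
    out.attrs["n_methylated"] = total
    out.attrs["empty"] = total == 0
    return out


def classify_sharing(callsets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Constitutive / varied / unique labels across k samples.

    A position methylated in all k samples is constitutive, in exactly
    one sample unique, otherwise varied.  Keys are exact
    (chrom, pos, strand, context) tuples — no positional fuzz.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets")
    k = len(callsets)
    keys = ["chrom", "pos", "strand", "context"]
    frames = []
    for name, calls in callsets.items():
        meth = calls.loc[calls["status"] == "methylated", keys].copy()
        meth["sample"] = name
        frames.append(meth)
    union = pd.concat(frames, ignore_index=True)
    counts = union.groupby(keys, observed=True).size().rename("n_samples")
    out = counts.reset_index()
    out["sharing"] = np.select(
        [out["n_samples"] == k, out["n_samples"] == 1],
        ["constitutive", "unique"], default="varied",
    )
    return out
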