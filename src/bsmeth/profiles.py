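"""Aggregate methylation over aligned features, loci and windows.

Metagene (and meta-TE / RdDM-locus) profiles align features at their
5' and 3' ends: each flank is cut into ``nbins`` fixed-width bins
(2000/100 = 20 bp by default) and the body is rescaled into ``nbins``
fractional bins, 3 x nbins bins total.  Minus-strand features are
reversed so bin 0 is always 5'-most.  Bin statistics pool read counts
across features (coverage-weighted); bins receiving zero reads are
undefined (NaN).

Sliding-window chromosome tracks, TE length classes (short < 0.5 kb,
long > 4 kb), subgenome (A/D chromosome prefix) summaries and
siRNA-locus statistics live here too.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core import (CONTEXTS, Feature, GenomicInterval, MethylomeSample,
                   Parameters, pooled_level)

logger = logging.getLogger(__name__)

SEGMENTS = ("upstream", "body", "downstream")


class LevelIndex:
    """Prefix-sum index over a methylome for O(log n) interval pooling.

    Per (chromosome, context): sorted 0-based positions plus cumulative
    methylated/total read counts, so the pooled level of any interval is
    two binary searches.
    """

    def __init__(self, sample: MethylomeSample):
        self.sample = sample
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (chrom, ctx), g in sample.sites.groupby(["chrom", "context"],
                                                    observed=True):
            pos0 = g["pos"].to_numpy() - 1
            m = np.concatenate([[0], np.cumsum(g["count_m"].to_numpy())])
            t = np.concatenate(
                [[0], np.cumsum((g["count_m"] + g["count_u"]).to_numpy())])
            self._idx[(chrom, ctx)] = (pos0, m, t)

    def counts(self, chrom: str, start: int, end: int,
               context: str) -> tuple[int, int]:
        """(methylated, total) reads on [start, end) for one context."""
        entry = self._idx.get((chrom, context))
        if entry is None:
            return 0, 0
        pos0, m, t = entry
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return int(m[hi] - m[lo]), int(t[hi] - t[lo])

    def level(self, chrom: str, start: int, end: int, context: str) -> float:
        m, t = self.counts(chrom, start, end, context)
        return pooled_level(m, t - m)

    def interval_level(self, iv: GenomicInterval, context: str) -> float:
        return self.level(iv.chrom, iv.start, iv.end, context)


def _profile_bins(sample: MethylomeSample, intervals: list[GenomicInterval],
                  context: str, flank: int, nbins: int) -> pd.DataFrame:
    """Pool counts into 3*nbins aligned bins over intervals + flanks."""
    if not intervals:
        raise ValueError("need at least one feature/locus")
    m_bins = np.zeros(3 * nbins, dtype=np.int64)
    t_bins = np.zeros(3 * nbins, dtype=np.int64)
    sub = sample.subset(context=context)
    by_chrom = {
        c: (g["pos"].to_numpy() - 1, g["count_m"].to_numpy(),
            (g["count_m"] + g["count_u"]).to_numpy())
        for c, g in sub.groupby("chrom", observed=True)
    }
    for iv in intervals:
        if iv.length < 1:
            raise ValueError(f"feature shorter than 1 bp: {iv}")
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            continue
        pos0, m, t = entry
        lo = np.searchsorted(pos0, iv.start - flank, side="left")
        hi = np.searchsorted(pos0, iv.end + flank, side="left")
        if hi <= lo:
            continue
        p = pos0[lo:hi]
        # distance from the 5' end along the feature's own orientation
        if iv.strand == "-":
            d = (iv.end - 1) - p
        else:
            d = p - iv.start
        L = iv.length
        body = (d >= 0) & (d < L)
        up = d < 0
        down = d >= L
        idx = np.empty(len(p), dtype=np.int64)
        idx[up] = (d[up] + flank) * nbins // flank
        idx[down] = 2 * nbins + (d[down] - L) * nbins // flank
        idx[body] = nbins + (d[body] * nbins // L).astype(np.int64)
        ok = (idx >= 0) & (idx < 3 * nbins)
        np.add.at(m_bins, idx[ok], m[lo:hi][ok])
        np.add.at(t_bins, idx[ok], t[lo:hi][ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(t_bins > 0, m_bins / np.maximum(t_bins, 1), np.nan)
    return pd.DataFrame({
        "bin": np.arange(3 * nbins),
        "segment": np.repeat(SEGMENTS, nbins),
        "context": context,
        "m": m_bins,
        "reads": t_bins,
        "level": level,
    })


def metagene_profile(sample: MethylomeSample, features: list[Feature],
                     context: str, flank: int = 2000,
                     nbins: int = 100) -> pd.DataFrame:
    """Pooled methylation over aligned feature bodies and 2-kb flanks.

    Returns a tidy frame of 3*nbins rows (upstream / body / downstream),
    with pooled level and contributing read totals per bin.  Flank bins
    have fixed width (flank/nbins bp) so genomic distances stay
    interpretable; body bins are fractional.
    """
    intervals = [f.interval for f in features]
    return _profile_bins(sample, intervals, context, flank, nbins)


def rddm_profile(sample: MethylomeSample, loci: pd.DataFrame, context: str,
                 flank: int = 5000, nbins: int = 100) -> pd.DataFrame:
    """Methylation over 24-nt siRNA (RdDM) loci with 5-kb flanks.

    ``loci`` is a BED-like frame (chrom/start/end); loci are unstranded.
    """
    intervals = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), ".")
        for r in loci.itertuples(index=False)
    ]
    return _profile_bins(sample, intervals, context, flank, nbins)


def merge_alignments(alignments: pd.DataFrame, merge_dist: int = 0) -> pd.DataFrame:
    """Merge overlapping (or within ``merge_dist``) intervals into loci."""
    rows = []
    for chrom, g in alignments.sort_values(["chrom", "start"]).groupby(
            "chrom", observed=True):
        cur_s = cur_e = None
        n = 0
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e, n = s, e, 1
            elif s <= cur_e + merge_dist:
                cur_e = max(cur_e, e)
                n += 1
            else:
                rows.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_alignments"])


def classify_constitutive_loci(loci_a: pd.DataFrame, loci_b: pd.DataFrame,
                               sample: MethylomeSample | None = None,
                               context: str = "CHH") -> pd.DataFrame:
    """Constitutive (overlapping) vs set-specific siRNA loci.

    Overlap is >= 1 bp.  Returns all loci labelled {constitutive,
    specific_a, specific_b}; when a methylome is supplied the per-class
    pooled level over locus intervals is in ``.attrs['class_levels']``.
    """
    from intervaltree import IntervalTree

    def trees(df):
        out: dict[str, IntervalTree] = {}
        for r in df.itertuples(index=False):
            out.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end))
        return out

    ta, tb = trees(loci_a), trees(loci_b)

    def label(df, other, specific):
        rows = []
        for r in df.itertuples(index=False):
            hit = r.chrom in other and bool(other[r.chrom].overlap(
                int(r.start), int(r.end)))
            rows.append((r.chrom, int(r.start), int(r.end),
                         "constitutive" if hit else specific))
        return rows

    out = pd.DataFrame(
        label(loci_a, tb, "specific_a") + label(loci_b, ta, "specific_b"),
        columns=["chrom", "start", "end", "class"],
    )
    if sample is not None:
        idx = LevelIndex(sample)
        levels = {}
        for cls, g in out.groupby("class", observed=True):
            m = t = 0
            for r in g.itertuples(index=False):
                mm, tt = idx.counts(r.chrom, r.start, r.end, context)
                m += mm
                t += tt
            levels[cls] = pooled_level(m, t - m)
        out.attrs["class_levels"] = levels
    return out


def window_track(sample: MethylomeSample, window: int, step: int,
                 chrom_lengths: dict[str, int] | None = None,
                 contexts=CONTEXTS, loci: pd.DataFrame | None = None,
                 features: list[Feature] | None = None) -> pd.DataFrame:
    """Sliding-window chromosome track of pooled levels (and densities).

    A cytosine contributes to every window containing it.  The last
    partial window on each chromosome is kept and flagged.  Optional
    24-nt locus density (overlapping loci per bp) and feature density.
    """
    if step < 1 or window < step:
        raise ValueError("need step >= 1 and window >= step")
    if isinstance(contexts, str):
        contexts = (contexts,)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(g["pos"].max())
            for c, g in sample.sites.groupby("chrom", observed=True)
        }
    idx = LevelIndex(sample)
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        starts = np.arange(0, length, step)
        for s in starts:
            e = min(s + window, length)
            row = {"chrom": chrom, "start": int(s), "end": int(e),
                   "partial": bool(e - s < window)}
            total_reads = 0
            for ctx in contexts:
                m, t = idx.counts(chrom, s, e, ctx)
                row[f"level_{ctx}"] = pooled_level(m, t - m)
                row[f"reads_{ctx}"] = t
                total_reads += t
            if loci is not None:
                sub = loci[loci["chrom"] == chrom]
                n = int(((sub["start"] < e) & (sub["end"] > s)).sum())
                row["sirna_density"] = n / (e - s)
            if features is not None:
                n = sum(
                    1 for f in features
                    if f.interval.chrom == chrom
                    and f.interval.start < e and f.interval.end > s
                )
                row["feature_density"] = n / (e - s)
            rows.append(row)
    return pd.DataFrame(rows)


def classify_te_lengths(tes: list[Feature],
                        sample: MethylomeSample | None = None,
                        params: Parameters = Parameters()) -> pd.DataFrame:
    """Short / medium / long TE classes (< 0.5 kb, otherwise, > 4 kb).

    Thresholds are strict at both ends: a 4000-bp TE is medium.  Returns
    the per-TE table; class counts/fractions in ``.attrs['summary']``
    and (with a methylome) per-class pooled context levels in
    ``.attrs['class_levels']``.
    """
    if not tes:
        raise ValueError("TE set is empty")
    rows = []
    for te in tes:
        length = te.length
        if length <= 0:
            raise ValueError(f"zero-length TE {te.feature_id}")
        if length < params.te_short_max:
            cls = "short"
        elif length > params.te_long_min:
            cls = "long"
        else:
            cls = "medium"
        rows.append((te.feature_id, te.interval.chrom, te.interval.start,
                     te.interval.end, length, te.te_family, cls))
    out = pd.DataFrame(rows, columns=[
        "te_id", "chrom", "start", "end", "length", "family", "class"])
    counts = out["class"].value_counts().reindex(
        ["short", "medium", "long"], fill_value=0)
    summary = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    out.attrs["summary"] = summary
    if sample is not None:
        idx = LevelIndex(sample)
        levels = {}
        for cls, g in out.groupby("class", observed=True):
            for ctx in CONTEXTS:
                m = t = 0
                for r in g.itertuples(index=False):
                    mm, tt = idx.counts(r.chrom, r.start, r.end, ctx)
                    m += mm
                    t += tt
                levels[(cls, ctx)] = pooled_level(m, t - m)
        out.attrs["class_levels"] = levels
    return out


def subgenome_summary(sample: MethylomeSample,
                      loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pooled context levels (and 24-nt locus counts) per subgenome.

    Chromosomes are grouped by their leading letter (A/D); anything
    else lands in an "unassigned" group (logged).
    """
    def group_of(chrom: str) -> str:
        head = chrom[:1].upper()
        if head in ("A", "D"):
            return head
        return "unassigned"

    groups = sample.sites["chrom"].map(group_of)
    if (groups == "unassigned").any():
        logger.warning("chromosomes without A/D prefix grouped as 'unassigned'")
    rows = []
    for grp, g in sample.sites.groupby(groups, observed=True):
        row = {"subgenome": grp}
        for ctx in CONTEXTS:
            sub = g[g["context"] == ctx]
            row[f"level_{ctx}"] = pooled_level(
                sub["count_m"].sum(), sub["count_u"].sum())
        if loci is not None:
            row["n_sirna_loci"] = int(
                loci["chrom"].map(group_of).eq(grp).sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("subgenome").reset_index(drop=True)


def sirna_length_fractions(lengths) -> pd.Series:
    """Fraction of small-RNA reads/loci per length (sums to 1)."""
    lengths = pd.Series(list(lengths), dtype=int)
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    out = lengths.value_counts(normalize=True).sort_index()
    out.index.name = "length"
    out.name = "fraction"
    out.attrs["empty"] = len(lengths) == 0
    return out


def length_methylation_correlation(features: list[Feature],
                                   sample: MethylomeSample,
                                   contexts=CONTEXTS) -> pd.DataFrame:
    """Pearson correlation of feature length vs feature-body level.

    Features with undefined (zero-read) body level are excluded and
    counted; fewer than 3 usable points gives an undefined (NaN) r.
    """
    if isinstance(contexts, str):
        contexts = (contexts,)
    idx = LevelIndex(sample)
    rows = []
    for ctx in contexts:
        lengths, levels = [], []
        excluded = 0
        for f in features:
            lv = idx.interval_level(f.interval, ctx)
            if np.isnan(lv):
                excluded += 1
                continue
            lengths.append(f.length)
            levels.append(lv)
        if len(levels) < 3 or np.std(lengths) == 0 or np.std(levels) == 0:
            rows.append((ctx, np.nan, len(levels), excluded))
            continue
        r, _ = pearsonr(lengths, levels)
        rows.append((ctx, float(r), len(levels), excluded))
    return pd.DataFrame(rows, columns=["context", "pearson_r", "n", "n_excluded"])
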