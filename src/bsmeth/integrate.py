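"""Connect methylation to annotation and expression.

DMRs are assigned to gene-centric categories with precedence
promoter > exon > intron > intergenic (>= 1 bp overlap; promoters are
strand-aware 2-kb upstream windows), with TE overlap flagged
independently.  Promoter methylation is the pooled level over the 2-kb
upstream window.  Methylation-expression association is Pearson's r on
(promoter level, log2(FPKM+1)); a *signed* r-squared (sign(r) * r^2) is
reported alongside plain r.  Expression trajectories across stages are
z-scored per gene and clustered with k-means (k = 10).  Differential
expression is consumed, not computed: the DEG filter keeps p < 0.05 and
|log2 ratio| >= 2.  The TE up/down balance uses a 1-df chi-squared
goodness-of-fit test against equal counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.cluster import KMeans

from .core import Feature, MethylomeSample, Parameters
from .profiles import LevelIndex

GENE_CATEGORIES = ("promoter", "exon", "intron", "intergenic")


def _trees(intervals) -> dict[str, IntervalTree]:
    out: dict[str, IntervalTree] = {}
    for chrom, start, end, payload in intervals:
        if end > start:
            out.setdefault(chrom, IntervalTree()).addi(start, end, payload)
    return out


def _hits(trees: dict[str, IntervalTree], chrom, start, end):
    t = trees.get(chrom)
    if t is None:
        return []
    return list(t.overlap(start, end))


def annotate_dmrs(dmrs: pd.DataFrame, features: list[Feature],
                  promoter_len: int = 2000,
                  params: Parameters = Parameters()) -> pd.DataFrame:
    """Gene-centric category + independent TE-overlap flag per DMR.

    Category percentages (over the four disjoint categories) are in
    ``.attrs['percentages']``.
    """
    genes = [f for f in features if f.kind in ("PCG", "TEG")]
    tes = [f for f in features if f.kind == "TE"]
    promoters = []
    for g in genes:
        win = g.promoter(promoter_len)
        if win is not None:
            promoters.append((win.chrom, win.start, win.end, g.feature_id))
    prom_t = _trees(promoters)
    exon_t = _trees([
        (e.chrom, e.start, e.end, g.feature_id)
        for g in genes for e in e_list(g)
    ])
    body_t = _trees([
        (g.interval.chrom, g.interval.start, g.interval.end, g.feature_id)
        for g in genes
    ])
    te_t = _trees([
        (t.interval.chrom, t.interval.start, t.interval.end, t)
        for t in tes
    ])
    cats, te_flags, te_classes, gene_ids = [], [], [], []
    for row in dmrs.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        prom = _hits(prom_t, row.chrom, s, e)
        if prom:
            cats.append("promoter")
            gene_ids.append(prom[0].data)
        else:
            ex = _hits(exon_t, row.chrom, s, e)
            if ex:
                cats.append("exon")
                gene_ids.append(ex[0].data)
            else:
                body = _hits(body_t, row.chrom, s, e)
                if body:
                    cats.append("intron")
                    gene_ids.append(body[0].data)
                else:
                    cats.append("intergenic")
                    gene_ids.append(None)
        te_hits = _hits(te_t, row.chrom, s, e)
        if te_hits:
            te = max(te_hits, key=lambda h: min(h.end, e) - max(h.begin, s)).data
            te_flags.append(True)
            length = te.length
            te_classes.append(
                "short" if length < params.te_short_max
                else "long" if length > params.te_long_min else "medium")
        else:
            te_flags.append(False)
            te_classes.append(None)
    out = dmrs.copy()
    out["gene_category"] = cats
    out["gene_id"] = gene_ids
    out["te_overlap"] = te_flags
    out["te_length_class"] = te_classes
    counts = out["gene_category"].value_counts().reindex(
        GENE_CATEGORIES, fill_value=0)
    out.attrs["percentages"] = (100 * counts / max(len(out), 1)).to_dict()
    return out


def e_list(gene: Feature) -> list:
    """Exons of a gene; a gene without exon records counts as one exon."""
    return gene.exons if gene.exons else [gene.interval]


def promoter_methylation(sample: MethylomeSample, genes: list[Feature],
                         context: str, promoter_len: int = 2000) -> pd.Series:
    """Pooled level over each gene's strand-aware 2-kb upstream window.

    NaN where the promoter has zero covered cytosines (counted in
    ``.attrs['n_undefined']``).
    """
    idx = LevelIndex(sample)
    out = {}
    for g in genes:
        win = g.promoter(promoter_len)
        out[g.feature_id] = (
            idx.interval_level(win, context) if win is not None else np.nan)
    s = pd.Series(out, name=f"promoter_{context}")
    s.attrs["n_undefined"] = int(s.isna().sum())
    return s


def methylation_expression_correlation(promoter_levels: pd.Series,
                                       expression: pd.Series,
                                       context: str | None = None) -> dict:
    """Pearson r of promoter level vs log2(FPKM + 1) over shared genes.

    Returns pearson_r, signed_r_squared (sign(r) * r^2 — the signed
    convention), p_value and n.  Degenerate variance or n < 3 gives NaN
    (flagged via ``defined``)."""
    df = pd.DataFrame({"x": promoter_levels, "fpkm": expression}).dropna()
    x = df["x"].to_numpy(dtype=float)
    y = np.log2(df["fpkm"].to_numpy(dtype=float) + 1)
    base = {"context": context, "n": len(df)}
    if len(df) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {**base, "pearson_r": np.nan, "signed_r_squared": np.nan,
                "p_value": np.nan, "defined": False}
    r, p = stats.pearsonr(x, y)
    return {**base, "pearson_r": float(r),
            "signed_r_squared": float(np.sign(r) * r ** 2),
            "p_value": float(p), "defined": True}


def compare_dmr_vs_nondmr_correlation(promoter_levels: pd.Series,
                                      expression: pd.Series,
                                      dmr_genes, non_dmr_genes,
                                      context: str | None = None) -> dict:
    """Methylation-expression correlation for DMR vs non-DMR gene sets."""
    dmr_genes = [g for g in dmr_genes if g in promoter_levels.index]
    non_dmr_genes = [g for g in non_dmr_genes if g in promoter_levels.index]
    return {
        "dmr": methylation_expression_correlation(
            promoter_levels.loc[dmr_genes], expression.loc[dmr_genes], context),
        "non_dmr": methylation_expression_correlation(
            promoter_levels.loc[non_dmr_genes], expression.loc[non_dmr_genes],
            context),
    }


@dataclass
class ClusterAssignment:
    """k-means result: per-gene labels (1..k) and per-cluster trajectories."""

    labels: pd.Series
    centroids: pd.DataFrame  # cluster x stage, z-score units
    inertia: float
    promoter_means: pd.DataFrame | None = None


def cluster_expression(expression: pd.DataFrame, k: int = 10, seed: int = 0,
                       n_init: int = 10,
                       promoter_levels: pd.DataFrame | None = None
                       ) -> ClusterAssignment:
    """k-means clustering of per-gene z-scored expression trajectories.

    ``expression``: genes (index) x stages (columns).  Rows are z-scored
    across stages (constant rows map to all-zero).  Lloyd's algorithm
    with ``n_init`` restarts keeps the lowest within-cluster sum of
    squares; clusters are relabelled 1..k by descending first-stage
    centroid so output is stable.  Optional per-gene promoter levels
    (same index, stage columns) are averaged per cluster.
    """
    if expression.shape[0] < k:
        raise ValueError(f"need >= {k} genes, got {expression.shape[0]}")
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 stages")
    x = expression.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1), 0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                algorithm="lloyd").fit(z)
    order = np.argsort(-km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[km.labels_], index=expression.index,
                       name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=np.arange(1, k + 1),
                             columns=expression.columns)
    centroids.index.name = "cluster"
    prom = None
    if promoter_levels is not None:
        prom = promoter_levels.groupby(labels).mean()
        prom.index.name = "cluster"
    return ClusterAssignment(labels, centroids, float(km.inertia_), prom)


def deg_filter(expression: pd.DataFrame, p_threshold: float = 0.05,
               min_abs_log2fc: float = 2.0) -> pd.DataFrame:
    """Differentially expressed genes: p < 0.05 and |log2 ratio| >= 2.

    The log2-fold-change bound is inclusive; direction follows the sign
    of the ratio."""
    for col in ("p_value", "log2_ratio"):
        if col not in expression.columns:
            raise ValueError(f"expression table missing column {col!r}")
    keep = (
        (expression["p_value"] < p_threshold)
        & (expression["log2_ratio"].abs() >= min_abs_log2fc)
    )
    out = expression[keep].copy()
    out["direction"] = np.where(out["log2_ratio"] > 0, "up", "down")
    return out.reset_index(drop=True)


def genes_by_sirna_overlap(genes: list[Feature], loci: pd.DataFrame,
                           sample: MethylomeSample,
                           contexts=("CG", "CHG", "CHH")) -> dict:
    """Gene groups by >= 1 bp gene-body overlap with any 24-nt locus.

    Per context: gene-body levels of overlapping vs non-overlapping
    genes and a two-sided Wilcoxon rank-sum p (NaN when a group is
    empty or degenerate).
    """
    if not genes or loci is None or len(loci) == 0:
        raise ValueError("need non-empty gene and locus sets")
    t = _trees([(r.chrom, int(r.start), int(r.end), None)
                for r in loci.itertuples(index=False)])
    idx = LevelIndex(sample)
    overlap_flag = {
        g.feature_id: bool(_hits(t, g.interval.chrom, g.interval.start,
                                 g.interval.end))
        for g in genes
    }
    result = {"overlap_genes": [g for g, v in overlap_flag.items() if v],
              "non_overlap_genes": [g for g, v in overlap_flag.items() if not v],
              "tests": {}}
    for ctx in contexts:
        levels_in, levels_out = [], []
        for g in genes:
            lv = idx.interval_level(g.interval, ctx)
            if np.isnan(lv):
                continue
            (levels_in if overlap_flag[g.feature_id] else levels_out).append(lv)
        entry = {"n_overlap": len(levels_in), "n_non_overlap": len(levels_out),
                 "mean_overlap": float(np.mean(levels_in)) if levels_in else np.nan,
                 "mean_non_overlap": float(np.mean(levels_out)) if levels_out else np.nan}
        if levels_in and levels_out:
            try:
                stat, p = stats.mannwhitneyu(levels_in, levels_out,
                                             alternative="two-sided")
                entry["p_value"] = float(p)
            except ValueError:
                entry["p_value"] = np.nan
        else:
            entry["p_value"] = np.nan
        result["tests"][ctx] = entry
    return result


def te_balance_test(n_up: int, n_down: int) -> dict:
    """1-df chi-squared goodness-of-fit of up/down counts against 50:50.

    No continuity correction; symmetric in its arguments.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    if n_up + n_down == 0:
        raise ValueError("both counts are zero")
    chi2, p = stats.chisquare([n_up, n_down])
    return {"chi_squared": float(chi2), "df": 1, "p_value": float(p),
            "n_up": int(n_up), "n_down": int(n_down)}
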