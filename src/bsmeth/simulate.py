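"""Synthetic bisulfite-sequencing data with known ground truth.

Generates a miniature two-subgenome plant genome (chromosome names carry
A/D prefixes), gene/TE/TE-gene annotations, per-sample true methylomes
with planted differentially methylated regions, bisulfite read counts,
24-nt siRNA loci coupled to CHH-hypermethylated regions, and expression
tables whose log-expression is linearly (negatively) coupled to promoter
CHH methylation.  Everything is reproducible from a single seed, with
one RNG stream per output so regenerating one artifact does not perturb
the others.

The statistical structure emulated:

* context-stratified site levels (CG high ~0.75, CHG intermediate
  ~0.45, CHH low ~0.08), beta-distributed per site;
* CHH islands: localized CHH elevation in a 500-bp window upstream of
  each gene TSS, with per-gene intensity so promoters vary;
* observed counts: coverage ~ Poisson(depth), methylated reads ~
  Binomial(n, m + (1-m)*r) where r is the bisulfite non-conversion
  rate (0.006) — non-conversion inflates, never deflates, the signal;
* planted DMRs shift the designated sample's true level by a fixed
  delta inside chosen 100-bp bins (clamped to [0, 1], recorded);
* 24-nt siRNA loci fall inside CHH-hyper regions with a configurable
  coupling probability;
* log2(FPKM + 1) = intercept + slope * promoter_CHH + Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CONTEXTS, Feature, GenomicInterval, MethylomeSample

_BASES = np.array(["A", "C", "G", "T"])
_A, _C, _G, _T = 0, 1, 2, 3
_TE_FAMILIES = ("Gypsy", "Copia", "LINE", "DNA")


@dataclass(frozen=True)
class PlantedDMR:
    """A planted differential bin: the designated sample's true level is
    shifted by ``delta`` inside [start, end) for sites of ``context``."""

    chrom: str
    start: int
    end: int
    context: str
    delta: float
    sample: str


def _default_chroms() -> dict[str, int]:
    return {"A01": 500_000, "D01": 500_000}


def _default_means() -> dict[str, float]:
    return {"CG": 0.75, "CHG": 0.45, "CHH": 0.08}


def _default_conc() -> dict[str, float]:
    # beta concentration (a+b); smaller = more dispersed per-site levels
    return {"CG": 2.0, "CHG": 4.0, "CHH": 8.0}


def _default_planted_n() -> dict[str, int]:
    return {"CG": 4, "CHG": 4, "CHH": 8}


def _default_planted_delta() -> dict[str, float]:
    return {"CG": -0.8, "CHG": -0.5, "CHH": 0.4}


@dataclass
class SimulationConfig:
    """All knobs of the generator.  ``seed`` fixes every stream."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    samples: tuple[str, ...] = ("NEC", "EC", "SE")

    # annotation
    genes_per_chrom: int = 30
    tegs_per_chrom: int = 6
    tes_per_chrom: int = 50
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    # short (<0.5 kb) / medium / long (>4 kb) TE class proportions
    te_length_fracs: tuple[float, float, float] = (0.54, 0.45, 0.01)
    min_feature_gap: int = 2_600

    # true methylome
    context_means: dict[str, float] = field(default_factory=_default_means)
    context_concentration: dict[str, float] = field(default_factory=_default_conc)
    chh_island_width: int = 500
    chh_island_level: float = 0.15  # per-gene boost ~ Uniform(0, 2 * level)
    # additive CHH shift per subgenome prefix, e.g. {"D": 0.05}
    subgenome_chh_boost: dict[str, float] = field(default_factory=dict)

    # observation model
    mean_depth: float = 30.0
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    nonconversion_rate: float = 0.006

    # planted DMRs (auto-planned unless dmr_plan given explicitly)
    dmr_plan: list[PlantedDMR] = field(default_factory=list)
    n_planted_dmrs: dict[str, int] = field(default_factory=_default_planted_n)
    planted_delta: dict[str, float] = field(default_factory=_default_planted_delta)
    dmr_min_sites: int = 15

    # 24-nt siRNA loci
    n_sirna_loci: int = 300
    sirna_coupling: float = 0.7
    sirna_shared_fraction: float = 0.5
    sirna_mean_alignments: float = 4.0

    # expression coupling
    expression_slope: float = -4.0
    expression_noise_sd: float = 0.5
    expression_intercept: float = 6.0
    expression_coupled_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("need at least two samples")
        for mu in self.context_means.values():
            if not (0 <= mu <= 1):
                raise ValueError("context means must be in [0, 1]")
        if not (0 <= self.nonconversion_rate < 1):
            raise ValueError("nonconversion_rate must be in [0, 1)")
        for p in (self.sirna_coupling, self.sirna_shared_fraction,
                  self.expression_coupled_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.te_length_fracs) - 1) > 1e-9:
            raise ValueError("te_length_fracs must sum to 1")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = list(self.samples)
        d["gene_length_range"] = list(self.gene_length_range)
        d["te_length_fracs"] = list(self.te_length_fracs)
        d["dmr_plan"] = [dataclasses.asdict(p) for p in self.dmr_plan]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "samples" in d:
            d["samples"] = tuple(d["samples"])
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        if "te_length_fracs" in d:
            d["te_length_fracs"] = tuple(d["te_length_fracs"])
        if "dmr_plan" in d:
            d["dmr_plan"] = [PlantedDMR(**p) for p in d["dmr_plan"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# fixed stream indices: regenerating one artifact never shifts another
_STREAMS = {"genome": 0, "levels": 1, "plan": 2, "counts": 3,
            "sirna": 4, "expression": 5}


def _rng(config: SimulationConfig, stream: str, sub: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence([config.seed, _STREAMS[stream], sub])
    return np.random.default_rng(ss)


@dataclass
class Genome:
    """Simulated chromosome sequences (uint8 codes 0..3 = ACGT) + features."""

    sequences: dict[str, np.ndarray]
    features: list[Feature]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sequence_str(self, chrom: str) -> str:
        return "".join(_BASES[self.sequences[chrom]])

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind in ("PCG", "TEG")]

    def tes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "TE"]


def _te_length(rng: np.random.Generator, fracs) -> int:
    cls = rng.choice(3, p=np.asarray(fracs, dtype=float))
    if cls == 0:
        return int(rng.integers(80, 500))
    if cls == 1:
        return int(rng.integers(500, 4_001))
    return int(rng.integers(4_001, 9_000))


def _make_exons(rng: np.random.Generator, chrom: str, start: int, end: int,
                strand: str) -> list[GenomicInterval]:
    length = end - start
    n_ex = int(rng.integers(1, 5))
    n_ex = min(n_ex, max(1, length // 200))
    if n_ex == 1:
        return [GenomicInterval(chrom, start, end, strand)]
    cuts = np.sort(rng.choice(np.arange(start + 50, end - 50),
                              size=2 * (n_ex - 1), replace=False))
    bounds = [start, *cuts.tolist(), end]
    return [
        GenomicInterval(chrom, bounds[i], bounds[i + 1], strand)
        for i in range(0, len(bounds) - 1, 2)
    ]


def generate_genome(config: SimulationConfig) -> Genome:
    """Random sequences plus non-overlapping PCG/TEG/TE annotations.

    Features are laid out with a minimum inter-feature gap (room for
    promoters and CHH islands); raises if the requested features do not
    fit on a chromosome.
    """
    rng = _rng(config, "genome")
    sequences: dict[str, np.ndarray] = {}
    features: list[Feature] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        sequences[chrom] = rng.integers(0, 4, size=length, dtype=np.uint8)
        items: list[tuple[str, int, str | None]] = []
        lo, hi = config.gene_length_range
        for _ in range(config.genes_per_chrom):
            items.append(("PCG", int(rng.integers(lo, hi + 1)), None))
        for _ in range(config.tegs_per_chrom):
            fam = str(rng.choice(_TE_FAMILIES))
            items.append(("TEG", int(rng.integers(lo, hi + 1)), fam))
        for _ in range(config.tes_per_chrom):
            fam = str(rng.choice(_TE_FAMILIES))
            items.append(("TE", _te_length(rng, config.te_length_fracs), fam))
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        total = sum(it[1] for it in items)
        n = len(items)
        slack = length - total - (n + 1) * config.min_feature_gap
        if slack < 0:
            raise ValueError(
                f"requested features exceed capacity of {chrom} "
                f"({total} bp of features in {length} bp)"
            )
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        cursor = 0
        counters = {"PCG": 0, "TEG": 0, "TE": 0}
        for (kind, flen, fam), gap in zip(items, gaps[:-1]):
            cursor += int(gap) + config.min_feature_gap
            start, end = cursor, cursor + flen
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            counters[kind] += 1
            fid = f"{chrom}_{kind.lower()}{counters[kind]:04d}"
            interval = GenomicInterval(chrom, start, end, strand)
            exons = (
                _make_exons(rng, chrom, start, end, strand)
                if kind in ("PCG", "TEG") else []
            )
            features.append(Feature(interval, fid, kind, exons, fam))
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return Genome(sequences, features)


def extract_cytosines(genome: Genome) -> pd.DataFrame:
    """All cytosines on both strands with context and reference triplet.

    Positions are 1-based.  Cytosines too close to a chromosome end to
    carry a full triplet are skipped (no context is definable).
    """
    frames = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        if len(seq) < 3:
            continue
        # plus strand: C at i with triplet seq[i:i+3]
        i = np.flatnonzero(seq[:-2] == _C)
        second, third = seq[i + 1], seq[i + 2]
        ctx_p = np.where(second == _G, "CG", np.where(third == _G, "CHG", "CHH"))
        tri_p = np.char.add(np.char.add(_BASES[seq[i]], _BASES[second]), _BASES[third])
        # minus strand: G at j >= 2; triplet on the minus strand reads
        # comp(seq[j]), comp(seq[j-1]), comp(seq[j-2])
        j = np.flatnonzero(seq[2:] == _G) + 2
        second_m, third_m = 3 - seq[j - 1], 3 - seq[j - 2]
        ctx_m = np.where(second_m == _G, "CG", np.where(third_m == _G, "CHG", "CHH"))
        tri_m = np.char.add(np.char.add("C", _BASES[second_m]), _BASES[third_m])
        df = pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate([i + 1, j + 1]),
            "strand": np.concatenate([np.full(len(i), "+"), np.full(len(j), "-")]),
            "context": np.concatenate([ctx_p, ctx_m]),
            "tri": np.concatenate([tri_p, tri_m]),
        })
        frames.append(df.sort_values("pos", kind="mergesort"))
    out = pd.concat(frames, ignore_index=True)
    return out


def plan_dmrs(sites: pd.DataFrame, context: str, n: int, delta: float,
              sample: str, rng: np.random.Generator, bin_size: int = 100,
              min_sites: int = 15,
              exclude: list[PlantedDMR] | None = None) -> list[PlantedDMR]:
    """Pick ``n`` distinct 100-bp bins dense enough in ``context`` sites.

    Bins are drawn from those carrying at least ``min_sites`` cytosines
    of the context, so every planted DMR satisfies the informative-
    cytosine precondition of the DMR caller (recovery failures then
    indicate caller faults, not simulation faults).
    """
    sub = sites[sites["context"] == context]
    bins = sub.groupby(["chrom", (sub["pos"] - 1) // bin_size]).size()
    eligible = bins[bins >= min_sites]
    taken = {(d.chrom, d.start // bin_size) for d in (exclude or [])}
    keys = [k for k in eligible.index.tolist() if k not in taken]
    if len(keys) < n:
        raise ValueError(
            f"only {len(keys)} bins with >= {min_sites} {context} sites; "
            f"cannot plant {n} DMRs"
        )
    picks = rng.choice(len(keys), size=n, replace=False)
    plan = [
        PlantedDMR(keys[i][0], int(keys[i][1]) * bin_size,
                   (int(keys[i][1]) + 1) * bin_size, context, delta, sample)
        for i in sorted(picks)
    ]
    return plan


@dataclass
class SyntheticTruth:
    """Ground truth written alongside the simulated data.

    ``sites`` holds one row per cytosine with a ``level_<sample>``
    column per sample; ``dmrs`` the planted-DMR table with realized
    (possibly clamped) deltas; ``gene_islands`` the per-gene CHH-island
    boosts."""

    sites: pd.DataFrame
    samples: list[str]
    dmrs: pd.DataFrame
    gene_islands: pd.DataFrame
    expression_slope: float | None = None

    def levels(self, sample: str) -> np.ndarray:
        return self.sites[f"level_{sample}"].to_numpy()

    def promoter_true_levels(self, genes: list[Feature], sample: str,
                             context: str = "CHH",
                             promoter_len: int = 2000) -> pd.Series:
        """Mean true site level in each gene's 2-kb upstream window."""
        col = f"level_{sample}"
        sub = self.sites[self.sites["context"] == context]
        by_chrom = {c: g for c, g in sub.groupby("chrom")}
        out = {}
        for gene in genes:
            g = by_chrom.get(gene.interval.chrom)
            if g is None:
                out[gene.feature_id] = np.nan
                continue
            win = gene.promoter(promoter_len)
            if win is None:
                out[gene.feature_id] = np.nan
                continue
            pos0 = g["pos"].to_numpy() - 1
            lo = np.searchsorted(pos0, win.start, side="left")
            hi = np.searchsorted(pos0, win.end, side="left")
            out[gene.feature_id] = (
                float(g[col].to_numpy()[lo:hi].mean()) if hi > lo else np.nan
            )
        return pd.Series(out, name=f"promoter_{context}_{sample}")


def generate_methylome(genome: Genome, config: SimulationConfig,
                       dmr_plan: list[PlantedDMR] | None = None,
                       sites: pd.DataFrame | None = None) -> SyntheticTruth:
    """True per-site levels per sample, with CHH islands and planted DMRs.

    The baseline methylome is shared across samples; planted DMRs shift
    the designated sample only.  Deltas that would push a level outside
    [0, 1] are clamped and the realized delta recorded in the truth
    table.
    """
    if sites is None:
        sites = extract_cytosines(genome)
    rng = _rng(config, "levels")
    n = len(sites)
    base = np.empty(n, dtype=float)
    ctx = sites["context"].to_numpy()
    for c in CONTEXTS:
        mask = ctx == c
        mu = config.context_means[c]
        conc = config.context_concentration.get(c)
        if conc is None or not np.isfinite(conc) or mu in (0.0, 1.0):
            base[mask] = mu
        else:
            base[mask] = rng.beta(mu * conc, (1 - mu) * conc, size=int(mask.sum()))

    # per-chromosome slices over the (chrom, pos)-sorted site table, so
    # interval edits are searchsorted lookups rather than full-array scans
    pos0 = sites["pos"].to_numpy() - 1
    chrom_arr = sites["chrom"].to_numpy()
    chrom_slices: dict[str, tuple[int, int]] = {}
    bounds = np.flatnonzero(np.concatenate(
        [[True], chrom_arr[1:] != chrom_arr[:-1], [True]]))
    for i in range(len(bounds) - 1):
        chrom_slices[str(chrom_arr[bounds[i]])] = (bounds[i], bounds[i + 1])

    def _interval_idx(chrom: str, start: int, end: int) -> slice | None:
        span = chrom_slices.get(chrom)
        if span is None:
            return None
        lo, hi = span
        a = lo + np.searchsorted(pos0[lo:hi], start, side="left")
        b = lo + np.searchsorted(pos0[lo:hi], end, side="left")
        return slice(a, b) if b > a else None

    for prefix, boost in sorted(config.subgenome_chh_boost.items()):
        mask = (ctx == "CHH") & np.char.startswith(
            chrom_arr.astype(str), prefix)
        base[mask] = np.clip(base[mask] + boost, 0, 1)
    genes = genome.genes()
    boosts = rng.uniform(0, 2 * config.chh_island_level, size=len(genes))
    island_rows = []
    if config.chh_island_level > 0 and config.chh_island_width > 0:
        for gene, boost in zip(genes, boosts):
            iv = gene.interval
            if iv.strand == "-":
                s, e = iv.end, iv.end + config.chh_island_width
            else:
                s, e = max(0, iv.start - config.chh_island_width), iv.start
            idx = _interval_idx(iv.chrom, s, e)
            if idx is not None:
                seg = base[idx]  # view into base: edits apply in place
                sub = ctx[idx] == "CHH"
                seg[sub] = np.clip(seg[sub] + boost, 0, 1)
            island_rows.append((gene.feature_id, iv.chrom, s, e, float(boost)))
    gene_islands = pd.DataFrame(
        island_rows, columns=["gene_id", "chrom", "start", "end", "boost"]
    )

    if dmr_plan is None:
        dmr_plan = list(config.dmr_plan)
        if not dmr_plan:
            plan_rng = _rng(config, "plan")
            target = config.samples[-1]
            for c in CONTEXTS:
                k = config.n_planted_dmrs.get(c, 0)
                if k > 0:
                    dmr_plan += plan_dmrs(
                        sites, c, k, config.planted_delta[c], target,
                        plan_rng, min_sites=config.dmr_min_sites,
                        exclude=dmr_plan,
                    )

    truth = sites.copy()
    levels = {s: base.copy() for s in config.samples}
    dmr_rows = []
    for d in dmr_plan:
        if d.sample not in levels:
            raise ValueError(f"planted DMR names unknown sample {d.sample!r}")
        idx = _interval_idx(d.chrom, d.start, d.end)
        sub = (ctx[idx] == d.context) if idx is not None else np.array([], bool)
        n_in = int(sub.sum())
        if n_in == 0:
            raise ValueError(f"planted DMR {d} covers no {d.context} site")
        inside = base[idx][sub]
        shifted = np.clip(inside + d.delta, 0, 1)
        clamped = bool(np.any(shifted != inside + d.delta))
        seg = levels[d.sample][idx]
        seg[sub] = shifted
        levels[d.sample][idx] = seg
        others = [s for s in config.samples if s != d.sample]
        realized = float(shifted.mean() - inside.mean())
        dmr_rows.append((d.chrom, d.start, d.end, d.context, d.sample,
                         others[0], d.delta, realized, clamped, n_in))
    for s in config.samples:
        truth[f"level_{s}"] = levels[s]
    dmrs = pd.DataFrame(
        dmr_rows,
        columns=["chrom", "start", "end", "context", "sample", "other",
                 "delta", "realized_delta", "clamped", "n_sites"],
    )
    return SyntheticTruth(truth, list(config.samples), dmrs, gene_islands,
                          expression_slope=config.expression_slope)


def simulate_bisulfite_counts(truth: SyntheticTruth, sample: str,
                              config: SimulationConfig) -> MethylomeSample:
    """Observed counts: coverage ~ Poisson (or NB), methylated reads ~
    Binomial(n, m + (1-m)*r).  Zero-coverage sites are kept (the report
    convention lists every reference cytosine)."""
    idx = truth.samples.index(sample)
    rng = _rng(config, "counts", idx)
    m = truth.levels(sample)
    if config.overdispersion is None:
        n = rng.poisson(config.mean_depth, size=len(m))
    else:
        k = config.overdispersion
        p = k / (k + config.mean_depth)
        n = rng.negative_binomial(k, p, size=len(m))
    r = config.nonconversion_rate
    p_obs = m + (1 - m) * r
    count_m = rng.binomial(n, p_obs)
    df = truth.sites[["chrom", "pos", "strand", "context", "tri"]].copy()
    df["count_m"] = count_m
    df["count_u"] = n - count_m
    df = df[["chrom", "pos", "strand", "context", "count_m", "count_u", "tri"]]
    return MethylomeSample(sample, df, nonconversion_rate=r)


def _hyper_chh_regions(truth: SyntheticTruth) -> pd.DataFrame:
    """Regions of elevated CHH methylation: planted hyper-CHH DMRs if
    any, otherwise the gene CHH-island windows."""
    d = truth.dmrs
    hyper = d[(d["context"] == "CHH") & (d["delta"] > 0)]
    if len(hyper):
        return hyper[["chrom", "start", "end"]].reset_index(drop=True)
    return truth.gene_islands[["chrom", "start", "end"]].reset_index(drop=True)


def _draw_locus(rng, regions, chrom_names, chrom_len_arr, chrom_probs,
                inside: bool, mean_aln: float) -> tuple[str, int, int, int]:
    n_aln = 1 + int(rng.poisson(max(mean_aln - 1, 0)))
    span = 24 + (int(rng.integers(0, 13)) if n_aln > 1 else 0)
    if inside and len(regions):
        row = regions.iloc[int(rng.integers(0, len(regions)))]
        avail = max(int(row["end"]) - int(row["start"]) - span, 0)
        start = int(row["start"]) + int(rng.integers(0, avail + 1))
        return str(row["chrom"]), start, start + span, n_aln
    ci = int(rng.choice(len(chrom_names), p=chrom_probs))
    start = int(rng.integers(0, chrom_len_arr[ci] - span))
    return chrom_names[ci], start, start + span, n_aln


def simulate_sirna_loci(truth: SyntheticTruth, config: SimulationConfig,
                        genome: Genome) -> dict[str, pd.DataFrame]:
    """Per-sample 24-nt siRNA locus tables (BED-style, 0-based half-open).

    Each locus is the merge of >= 1 overlapping 24-nt alignments; with
    probability ``sirna_coupling`` it is placed inside a CHH-hyper
    region, otherwise uniformly on the genome.  A ``sirna_shared_fraction``
    of loci is identical across samples (constitutive loci)."""
    rng = _rng(config, "sirna")
    regions = _hyper_chh_regions(truth)
    chrom_names = sorted(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=float)
    probs = lens / lens.sum()
    n_shared = int(round(config.sirna_shared_fraction * config.n_sirna_loci))

    def draw_set(n: int, tag: str) -> list[tuple]:
        rows = []
        for i in range(n):
            inside = bool(rng.random() < config.sirna_coupling)
            chrom, s, e, ab = _draw_locus(
                rng, regions, chrom_names, lens.astype(int), probs,
                inside, config.sirna_mean_alignments)
            rows.append((chrom, s, e, f"{tag}{i:05d}", ab, ".", inside))
        return rows

    shared = draw_set(n_shared, "sirna_shared_")
    out: dict[str, pd.DataFrame] = {}
    for sample in truth.samples:
        rows = list(shared) + draw_set(
            config.n_sirna_loci - n_shared, f"sirna_{sample}_")
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "abundance",
                           "strand", "planted_inside"],
        ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        out[sample] = df
    return out


def promoter_levels_from_truth(truth: SyntheticTruth, genome: Genome,
                               context: str = "CHH",
                               promoter_len: int = 2000) -> pd.DataFrame:
    """True promoter levels, genes x samples (columns named per sample)."""
    genes = genome.genes()
    cols = {
        s: truth.promoter_true_levels(genes, s, context, promoter_len)
        for s in truth.samples
    }
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    return out


def simulate_expression(promoter_levels: pd.DataFrame,
                        config: SimulationConfig) -> pd.DataFrame:
    """Gene expression coupled to promoter CHH methylation.

    ``promoter_levels``: genes (index) x samples (columns).  Per sample,
    log2(FPKM + 1) = intercept + slope * promoter_CHH + N(0, sd); a
    configurable fraction of genes is coupled (slope applies), the rest
    receive slope 0.  ``log2_ratio`` and ``p_value`` contrast the last
    column against the first."""
    rng = _rng(config, "expression")
    ids = list(promoter_levels.index)
    samples = list(promoter_levels.columns)
    coupled = np.ones(len(ids), dtype=bool)
    if config.expression_coupled_fraction < 1.0:
        k = int(round(config.expression_coupled_fraction * len(ids)))
        coupled[:] = False
        coupled[rng.choice(len(ids), size=k, replace=False)] = True
    out = pd.DataFrame({"gene_id": ids})
    logf = {}
    for s in samples:
        x = promoter_levels[s].fillna(0.0).to_numpy(dtype=float)
        eff = np.where(coupled, config.expression_slope, 0.0)
        noise = (rng.normal(0, config.expression_noise_sd, size=len(ids))
                 if config.expression_noise_sd > 0 else np.zeros(len(ids)))
        lf = config.expression_intercept + eff * x + noise
        logf[s] = lf
        out[f"fpkm_{s}"] = np.maximum(np.exp2(lf) - 1, 0.0)
        out[f"promoter_chh_{s}"] = x
    first, last = samples[0], samples[-1]
    ratio = logf[last] - logf[first]
    out["log2_ratio"] = ratio
    sd = config.expression_noise_sd
    if sd > 0:
        from scipy.stats import norm
        out["p_value"] = 2 * norm.sf(np.abs(ratio) / (np.sqrt(2) * sd))
    else:
        out["p_value"] = np.where(ratio != 0, 0.0, 1.0)
    out["coupled"] = coupled
    return out


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    genome: Genome
    truth: SyntheticTruth
    methylomes: dict[str, MethylomeSample]
    sirna_loci: dict[str, pd.DataFrame]
    expression: pd.DataFrame


def simulate_dataset(config: SimulationConfig,
                     outdir: str | Path | None = None) -> SimulatedDataset:
    """Run the full generator; optionally write every artifact to disk."""
    genome = generate_genome(config)
    truth = generate_methylome(genome, config)
    methylomes = {
        s: simulate_bisulfite_counts(truth, s, config) for s in config.samples
    }
    sirna = simulate_sirna_loci(truth, config, genome)
    expression = simulate_expression(
        promoter_levels_from_truth(truth, genome), config)
    ds = SimulatedDataset(config, genome, truth, methylomes, sirna, expression)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> list[Path]:
    """Write reports, annotations, siRNA BEDs, expression and truth tables."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    ds.config.to_yaml(_w(outdir / "config.yaml"))
    for name, sample in ds.methylomes.items():
        mio.write_cytosine_report(sample, _w(outdir / f"{name}.cx_report.tsv"))
    mio.write_features_gff3(
        [f for f in ds.genome.features if f.kind in ("PCG", "TEG")],
        _w(outdir / "genes.gff3"))
    mio.write_features_bed(ds.genome.tes(), _w(outdir / "tes.bed"))
    for name, loci in ds.sirna_loci.items():
        mio.write_bed6(loci, _w(outdir / f"sirna_{name}.bed"),
                       score_col="abundance")
    mio.write_expression(ds.expression, _w(outdir / "expression.tsv"))
    ds.truth.sites.to_csv(_w(outdir / "truth_sites.tsv"), sep="\t",
                          index=False, float_format="%.6g")
    ds.truth.dmrs.to_csv(_w(outdir / "truth_dmrs.tsv"), sep="\t", index=False,
                         float_format="%.6g")
    ds.truth.gene_islands.to_csv(_w(outdir / "truth_gene_islands.tsv"),
                                 sep="\t", index=False, float_format="%.6g")
    lengths = pd.DataFrame(
        sorted(ds.genome.chrom_lengths.items()), columns=["chrom", "length"])
    lengths.to_csv(_w(outdir / "chrom_lengths.tsv"), sep="\t", index=False)
    return written
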