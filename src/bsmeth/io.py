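"""Readers and writers for the on-disk formats the pipeline touches.

Dialects follow the de facto conventions of each format and are
converted to the internal 0-based half-open model at this boundary:

* cytosine report: tab-separated, no header, 1-based positions, columns
  chrom / pos / strand / count_m / count_u / context / trinucleotide
  (the bismark CX layout);
* GFF3: 1-based inclusive; BED: 0-based half-open;
* derived tables (DMRs, expression) are headered TSVs, optionally with
  ``#``-prefixed metadata lines.

Readers reject rather than silently coerce; gzip is handled
transparently by extension.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONTEXTS, Feature, GenomicInterval, MethylomeSample

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "context", "tri"]
DMR_COLUMNS = ["chrom", "start", "end", "context", "level_a", "level_b",
               "delta", "p_value", "q_value", "direction"]


class FormatError(ValueError):
    """A file does not parse under its declared dialect."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# cytosine reports
# --------------------------------------------------------------------------

def read_cytosine_report(path, nonconversion_rate: float = 0.006,
                         name: str | None = None,
                         header: bool = False) -> MethylomeSample:
    """Parse a per-cytosine bisulfite count report into a methylome sample.

    Malformed lines are reported with their 1-based line number.  The
    trinucleotide column is optional (6- or 7-column files accepted).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=0 if header else None,
                          names=REPORT_COLUMNS, dtype=str, comment=None,
                          skip_blank_lines=False)
    except Exception as exc:  # pragma: no cover - parser internals vary
        raise FormatError(f"{path}: cannot parse as cytosine report: {exc}") from exc
    offset = 2 if header else 1  # data row i sits on file line i + offset

    def _fail(mask: pd.Series, why: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + offset
            raise FormatError(f"{path}, line {line}: {why}")

    _fail(raw[REPORT_COLUMNS[:6]].isna().any(axis=1), "missing field(s)")
    pos = pd.to_numeric(raw["pos"], errors="coerce")
    _fail(pos.isna() | (pos % 1 != 0), "position is not an integer")
    _fail(pos < 1, "position must be >= 1 (1-based)")
    for col in ("count_m", "count_u"):
        v = pd.to_numeric(raw[col], errors="coerce")
        _fail(v.isna() | (v % 1 != 0), f"{col} is not an integer")
        _fail(v < 0, f"{col} is negative")
    _fail(~raw["strand"].isin(("+", "-")), "strand must be + or -")
    _fail(~raw["context"].isin(CONTEXTS), "unknown context token")
    df = pd.DataFrame({
        "chrom": raw["chrom"],
        "pos": pos.astype(np.int64),
        "strand": raw["strand"],
        "context": raw["context"],
        "count_m": pd.to_numeric(raw["count_m"]).astype(np.int64),
        "count_u": pd.to_numeric(raw["count_u"]).astype(np.int64),
    })
    if raw["tri"].notna().any():
        df["tri"] = raw["tri"]
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + offset
        raise FormatError(f"{path}, line {line}: duplicate (chrom, pos, strand)")
    if name is None:
        name = path.name.split(".")[0]
    return MethylomeSample(name, df, nonconversion_rate=nonconversion_rate)


def write_cytosine_report(sample: MethylomeSample, path,
                          header: bool = False) -> None:
    df = sample.sites.copy()
    if "tri" not in df.columns:
        df["tri"] = df["context"]
    df = df[REPORT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, header=header)


# --------------------------------------------------------------------------
# annotations: GFF3 (genes) and BED6 (TEs, siRNA loci)
# --------------------------------------------------------------------------

def write_features_gff3(features: list[Feature], path) -> None:
    """Genes/TEGs as GFF3 (1-based inclusive), exons as child records."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = f"ID={f.feature_id};kind={f.kind}"
            if f.te_family:
                attrs += f";te_family={f.te_family}"
            fh.write(
                f"{iv.chrom}\tbsmeth\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(f.exons, 1):
                fh.write(
                    f"{ex.chrom}\tbsmeth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={f.feature_id}.exon{i};"
                    f"Parent={f.feature_id}\n"
                )


def _read_gff3(path) -> list[Feature]:
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as GFF3: {exc}") from exc

    def _first(feat, key, default=None):
        vals = feat.attributes.get(key, [])
        return vals[0] if vals else default

    genes: dict[str, Feature] = {}
    gene_types = ("gene", "mRNA", "transposable_element_gene")
    for g in db.all_features():
        if g.featuretype not in gene_types:
            continue
        kind = _first(g, "kind")
        if kind not in ("PCG", "TEG"):
            kind = "TEG" if g.featuretype == "transposable_element_gene" else "PCG"
        fid = _first(g, "ID", g.id)
        iv = GenomicInterval(g.seqid, g.start - 1, g.end,
                             g.strand if g.strand in "+-" else ".")
        genes[fid] = Feature(iv, fid, kind, [], _first(g, "te_family"))
    for ex in db.features_of_type("exon"):
        parent = _first(ex, "Parent")
        gene = genes.get(parent) if parent else None
        if gene is None:
            logger.warning("%s: orphan exon %s skipped", path, ex.id)
            continue
        iv = GenomicInterval(ex.seqid, ex.start - 1, ex.end,
                             ex.strand if ex.strand in "+-" else ".")
        if (iv.chrom != gene.interval.chrom or iv.start < gene.interval.start
                or iv.end > gene.interval.end):
            logger.warning("%s: exon %s outside parent %s span, skipped",
                           path, ex.id, parent)
            continue
        gene.exons.append(iv)
    for gene in genes.values():
        gene.exons.sort(key=lambda e: e.start)
    return sorted(genes.values(), key=lambda f: (f.interval.chrom, f.interval.start))


def write_features_bed(features: list[Feature], path) -> None:
    """TEs as BED6 (0-based half-open); name carries id:family."""
    rows = []
    for f in features:
        iv = f.interval
        name = f.feature_id + (f":{f.te_family}" if f.te_family else "")
        rows.append((iv.chrom, iv.start, iv.end, name, iv.length, iv.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _read_bed_features(path) -> list[Feature]:
    df = read_bed(path)
    out = []
    for row in df.itertuples(index=False):
        name = str(row.name)
        fid, _, fam = name.partition(":")
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                             getattr(row, "strand", "."))
        out.append(Feature(iv, fid or name, "TE", [], fam or None))
    return out


def read_features(path) -> list[Feature]:
    """Read an annotation: GFF3 (genes/TEGs with exons) or BED6 (TEs)."""
    suffixes = Path(path).suffixes
    base = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else (
        suffixes[-1] if suffixes else "")
    if base in (".gff", ".gff3"):
        return _read_gff3(path)
    if base == ".bed":
        return _read_bed_features(path)
    raise FormatError(f"{path}: unrecognised annotation extension {base!r}")


def read_bed(path) -> pd.DataFrame:
    """BED with 3-6 columns -> DataFrame (0-based half-open, as on disk)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: invalid BED interval (need 0 <= start < end)")
    return df


def write_bed6(df: pd.DataFrame, path, score_col: str | None = None) -> None:
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "name": df["name"] if "name" in df else ".",
        "score": df[score_col] if score_col and score_col in df else 0,
        "strand": df["strand"] if "strand" in df else ".",
    })
    out.to_csv(path, sep="\t", index=False, header=False)


# --------------------------------------------------------------------------
# derived tables
# --------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with _open_text(path, "wt") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_dmrs(dmrs: pd.DataFrame, path, meta: dict | None = None) -> None:
    """DMRs as a headered BED-like TSV (internal 0-based half-open)."""
    missing = [c for c in DMR_COLUMNS if c not in dmrs.columns]
    if missing:
        raise FormatError(f"DMR table missing column(s): {missing}")
    extra = [c for c in dmrs.columns if c not in DMR_COLUMNS]
    _write_table(dmrs[DMR_COLUMNS + extra], path, meta)


def read_dmrs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in DMR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: DMR table missing column(s): {missing}")
    return df


def write_expression(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_table(df, path, meta)


def read_expression(path) -> pd.DataFrame:
    """Expression table: gene_id, fpkm_<sample> columns, p_value, log2_ratio."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "p_value", "log2_ratio"):
        if col not in df.columns:
            raise FormatError(f"{path}: expression table missing column {col!r}")
    if not [c for c in df.columns if c.startswith("fpkm")]:
        raise FormatError(f"{path}: expression table has no fpkm_* column")
    return df


def read_chrom_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"chrom", "length"} <= set(df.columns):
        raise FormatError(f"{path}: need columns chrom, length")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def validate_file(path) -> dict:
    """Best-effort dialect sniffing for the CLI ``validate`` subcommand."""
    path = Path(path)
    base = path.name[:-3] if path.name.endswith(".gz") else path.name
    if base.endswith((".gff", ".gff3")):
        feats = read_features(path)
        return {"format": "gff3", "records": len(feats)}
    if base.endswith(".bed"):
        df = read_bed(path)
        return {"format": "bed", "records": len(df)}
    try:
        df = read_expression(path)
        return {"format": "expression", "records": len(df)}
    except FormatError:
        pass
    try:
        df = read_dmrs(path)
        return {"format": "dmr", "records": len(df)}
    except Exception:
        pass
    sample = read_cytosine_report(path)
    return {"format": "cytosine_report", "records": sample.n_sites}
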