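"""End-to-end driver: simulate -> call -> DMR -> profile -> integrate.

``run_all`` chains every stage on a synthetic dataset and writes tidy
TSVs with a small ``#`` metadata header (seed, samples).  Output is a
pure function of the configuration: rerunning with the same seed gives
byte-identical files (the returned manifest maps relative paths to
SHA-256 digests so callers can assert this cheaply).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .calling import call_sites, classify_sharing, methylome_composition
from .core import CONTEXTS, Parameters
from .differential import call_dmcs, call_dmrs
from .integrate import (annotate_dmrs, cluster_expression, deg_filter,
                        genes_by_sirna_overlap,
                        methylation_expression_correlation,
                        promoter_methylation)
from .profiles import (classify_constitutive_loci, classify_te_lengths,
                       metagene_profile, rddm_profile, subgenome_summary,
                       window_track)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


def _write(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(config: SimulationConfig, outdir,
            params: Parameters = Parameters(),
            window: int = 100_000, step: int = 10_000) -> dict[str, str]:
    """Run the whole pipeline; returns {relative path: sha256}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "samples": ",".join(config.samples)}

    ds = simulate_dataset(config, outdir / "sim")
    first, last = config.samples[0], config.samples[-1]
    genes = ds.genome.genes()
    tes = ds.genome.tes()

    callsets = {}
    comp_rows = []
    for name, sample in ds.methylomes.items():
        calls = call_sites(sample, params)
        callsets[name] = calls
        _write(calls, outdir / f"calls_{name}.tsv", meta)
        comp = methylome_composition(calls).reset_index()
        comp.insert(0, "sample", name)
        comp_rows.append(comp)
    _write(pd.concat(comp_rows, ignore_index=True),
           outdir / "composition.tsv", meta)

    sharing = classify_sharing(callsets)
    summary = (sharing.groupby(["context", "sharing"], observed=True).size()
               .rename("n").reset_index())
    _write(summary, outdir / "sharing_summary.tsv", meta)

    dmr_tables = {}
    for ctx in CONTEXTS:
        dmrs = call_dmrs(ds.methylomes[first], ds.methylomes[last], ctx, params)
        dmr_tables[ctx] = dmrs
        mio.write_dmrs(dmrs, outdir / f"dmrs_{ctx}_{first}_vs_{last}.tsv",
                       meta={**meta, "context": ctx,
                             "n_tested": dmrs.attrs.get("n_tested", 0)})
    dmcs = call_dmcs(ds.methylomes[first], ds.methylomes[last], params)
    _write(dmcs, outdir / f"dmcs_{first}_vs_{last}.tsv", meta)

    for ctx in CONTEXTS:
        prof = metagene_profile(ds.methylomes[last], genes, ctx,
                                params.metagene_flank, params.metagene_nbins)
        _write(prof, outdir / f"metagene_{ctx}_{last}.tsv", meta)
    rddm = rddm_profile(ds.methylomes[last], ds.sirna_loci[last], "CHH",
                        params.rddm_flank, params.metagene_nbins)
    _write(rddm, outdir / f"rddm_CHH_{last}.tsv", meta)

    track = window_track(ds.methylomes[last], window, step,
                         chrom_lengths=ds.genome.chrom_lengths,
                         loci=ds.sirna_loci[last])
    _write(track, outdir / f"windows_{last}.tsv",
           {**meta, "window": window, "step": step})
    _write(subgenome_summary(ds.methylomes[last], ds.sirna_loci[last]),
           outdir / f"subgenome_{last}.tsv", meta)
    te_tab = classify_te_lengths(tes, ds.methylomes[last], params)
    _write(te_tab, outdir / "te_length_classes.tsv", meta)

    ann = annotate_dmrs(dmr_tables["CHH"], ds.genome.features,
                        params.promoter_len, params)
    _write(ann, outdir / "dmr_annotation_CHH.tsv", meta)

    expr = ds.expression.set_index("gene_id")
    corr_rows = []
    prom_frames = []
    for ctx in CONTEXTS:
        prom = promoter_methylation(ds.methylomes[last], genes, ctx,
                                    params.promoter_len)
        prom_frames.append(prom.rename(f"promoter_{ctx}"))
        res = methylation_expression_correlation(
            prom, expr[f"fpkm_{last}"], ctx)
        corr_rows.append(res)
    prom_df = pd.concat(prom_frames, axis=1)
    prom_df.index.name = "gene_id"
    _write(prom_df.reset_index(), outdir / f"promoter_levels_{last}.tsv", meta)
    _write(pd.DataFrame(corr_rows), outdir / "correlation.tsv", meta)

    stages = [f"fpkm_{s}" for s in config.samples]
    logexpr = np.log2(expr[stages] + 1)
    k = min(params.kmeans_k, len(logexpr))
    clusters = cluster_expression(logexpr, k=k, seed=config.seed)
    ctab = clusters.labels.rename("cluster").reset_index()
    _write(ctab, outdir / "expression_clusters.tsv", {**meta, "k": k})

    degs = deg_filter(ds.expression, params.deg_p, params.deg_min_abs_log2fc)
    _write(degs, outdir / "degs.tsv", meta)

    groups = genes_by_sirna_overlap(genes, ds.sirna_loci[last],
                                    ds.methylomes[last])
    rows = [{"context": ctx, **vals} for ctx, vals in groups["tests"].items()]
    _write(pd.DataFrame(rows), outdir / "sirna_gene_groups.tsv", meta)

    loci_classes = classify_constitutive_loci(
        ds.sirna_loci[first], ds.sirna_loci[last], ds.methylomes[last])
    _write(loci_classes, outdir / "sirna_locus_classes.tsv", meta)

    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = str(path.relative_to(outdir))
            manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
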