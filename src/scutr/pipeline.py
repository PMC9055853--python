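"""End-to-end orchestration: BAM -> coverage -> fits -> APA calls.

The command-line entry points are thin wrappers over these functions; they
are equally usable from Python for notebook-scale analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, coverage, isoform, model

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and knobs of the pipeline, with the documented defaults."""

    cpm_min: float = 10.0
    min_cluster_count: int = 20
    min_two_site_clusters: int = 3
    fdr: float = 0.05
    log2_or_gate: float = 0.25
    fold: float = 2.0
    max_sites: int = 2
    barcode_tag: str = "CB"
    umi_tag: str = "UB"
    flank: int | None = None
    min_minor_fraction: float = 0.01
    min_residual_gain: float = 0.05
    internal_priming_window: int = 10
    exclude_internal_priming: bool = True
    stranded: bool = True
    drop_duplicates: bool = False
    seed: int = 0


@dataclass
class QuantifyResult:
    fits: dict[str, isoform.IsoformFit]
    counts: dict[str, dict[str, isoform.IsoformCounts]]
    depths: dict[str, int]
    ends: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for gene, fit in self.fits.items():
            for k in sorted(fit.w_long):
                c = self.counts.get(gene, {}).get(k)
                rows.append({
                    "gene_id": gene,
                    "cluster": k,
                    "proximal_site": fit.proximal_site,
                    "genomic_site": fit.genomic_site,
                    "utr_length": fit.L,
                    "w_long": fit.w_long[k],
                    "w_short": fit.w_short[k],
                    "pdui": fit.pdui(k),
                    "residual": fit.residual[k],
                    "two_site": fit.two_site_clusters[k],
                    "internal_priming": fit.internal_priming,
                    "long_count": c.long_count if c else 0,
                    "short_count": c.short_count if c else 0,
                    "cpm_long": c.cpm_long if c else 0.0,
                    "cpm_short": c.cpm_short if c else 0.0,
                })
        return pd.DataFrame(rows)


def quantify(
    bam_path: str | Path,
    annotation_path: str | Path,
    clusters_path: str | Path,
    genome_path: str | Path | None = None,
    config: RunConfig | None = None,
) -> QuantifyResult:
    """Pad reads, fit the shared proximal site per gene, count isoforms."""
    cfg = config or RunConfig()
    utrs = {u.gene_id: u for u in annotation.load_utrs(annotation_path)}
    assign = coverage.ClusterAssignment.from_tsv(clusters_path)
    depths = coverage.cluster_depths(bam_path, assign, cfg.barcode_tag)
    if not depths:
        raise ValueError("no reads matched the cluster assignment")
    ends = coverage.collect_padded_ends(
        bam_path, utrs.values(), assign, cfg.barcode_tag,
        stranded=cfg.stranded, drop_duplicates=cfg.drop_duplicates,
        umi_tag=cfg.umi_tag,
    )
    fits: dict[str, isoform.IsoformFit] = {}
    counts: dict[str, dict[str, isoform.IsoformCounts]] = {}
    for per_cluster in coverage.coverage_by_gene(ends, utrs, depths):
        first = next(iter(per_cluster.values()))
        gene = first.gene_id
        utr = utrs[gene]
        cov = {k: pc.coverage for k, pc in per_cluster.items()}
        fit = isoform.fit_two_site(
            cov, gene, cfg.flank, cfg.min_minor_fraction, cfg.min_residual_gain
        )
        if fit is None:
            continue
        fit.genomic_site = utr.to_genomic(fit.proximal_site)
        if genome_path is not None:
            seq = annotation.fetch_downstream(
                genome_path, utr, fit.proximal_site, cfg.internal_priming_window
            )
            fit.internal_priming = isoform.flag_internal_priming(seq)
        fits[gene] = fit
        sub = ends[ends.gene_id == gene]
        counts[gene] = {}
        for k, csub in sub.groupby("cluster"):
            expanded = np.repeat(csub["end"].to_numpy(), csub["count"].to_numpy())
            counts[gene][k] = isoform.assign_isoform_counts(
                expanded, fit.proximal_site, depths[k], gene, k
            )
    log.info("quantified %d genes", len(fits))
    return QuantifyResult(fits, counts, depths, ends)


def test_apa(
    quant: QuantifyResult, config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Filter genes/clusters and run the across- and per-cell-type tests."""
    cfg = config or RunConfig()
    retained = model.filter_genes(
        quant.counts, quant.fits, cfg.min_two_site_clusters,
        cfg.cpm_min, cfg.min_cluster_count,
    )
    log.info("filters: %d of %d genes retained", len(retained), len(quant.counts))
    results = []
    for gene, clusters in retained.items():
        obs = [
            model.Observation(
                k, quant.counts[gene][k].long_count, quant.counts[gene][k].short_count
            )
            for k in clusters
        ]
        res = model.test_gene(obs, gene, log2_or_gate=cfg.log2_or_gate)
        res.internal_priming = quant.fits[gene].internal_priming
        results.append(res)
    model.finalize_results(results, cfg.fdr, cfg.fold, cfg.exclude_internal_priming)
    return model.results_frame(results), retained


def write_sites_bed(quant: QuantifyResult, utrs_path: str | Path, out: str | Path) -> None:
    """Emit called proximal sites as BED6 point intervals."""
    utrs = {u.gene_id: u for u in annotation.load_utrs(utrs_path)}
    with open(out, "w") as fh:
        for gene, fit in sorted(quant.fits.items()):
            u = utrs[gene]
            g = fit.genomic_site if fit.genomic_site is not None else u.to_genomic(fit.proximal_site)
            fh.write(f"{u.chrom}\t{g}\t{g + 1}\t{gene}\t0\t{u.strand}\n")
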