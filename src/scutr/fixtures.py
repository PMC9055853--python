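"""Synthetic ground-truth data: a miniature 3'-biased scRNA-seq experiment.

Generates, from a seed, a small genome (FASTA), a BED12 gene annotation, a
coordinate-sorted barcoded BAM of 3'-biased reads, a barcode->cluster table
and a truth table.  Reads are placed with their 3' ends jittered around the
chosen isoform end (proximal or distal pA site, Bernoulli(PDUI) per read),
which is what a 3' selection library produces after alignment.  One gene can
be given an adenine-rich tract just downstream of its proximal site to
exercise the internal-priming filter end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam


@dataclass
class FixtureGene:
    """Ground truth for one simulated gene."""

    gene_id: str
    strand: str = "+"
    utr_length: int = 1000
    proximal_site: int = 400  # transcript coordinate of the short-isoform end
    pdui: dict[str, float] = field(default_factory=dict)  # per cluster
    a_rich: bool = False  # plant an A8 tract downstream of the proximal site


@dataclass
class Fixture:
    bam: Path
    clusters_tsv: Path
    annotation_bed: Path
    genome_fasta: Path
    truth_tsv: Path
    utr_bounds: dict[str, tuple[str, int, int, str]]


GAP = 2000  # intergenic spacer on the fixture contig
READ_LEN = 90
MAX_JITTER = 10


def make_fixture(
    out_dir: str | Path,
    genes: list[FixtureGene],
    clusters: list[str],
    reads_per_gene_cluster: int = 300,
    cells_per_cluster: int = 20,
    seed: int = 0,
    covariate_of_cluster: dict[str, str] | None = None,
) -> Fixture:
    """Write genome, annotation, BAM, cluster table and truth table.

    Every read carries a CB (cell barcode) and UB (UMI) tag; barcodes are
    drawn uniformly from each cluster's cells.  The cluster table gains a
    covariate column when ``covariate_of_cluster`` is given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for g in genes:
        if not 1 < g.proximal_site < g.utr_length:
            raise ValueError(f"{g.gene_id}: proximal site outside (1, L)")
        missing = set(clusters) - set(g.pdui)
        if missing:
            raise ValueError(f"{g.gene_id}: no PDUI for clusters {sorted(missing)}")

    # --- genome and annotation -------------------------------------------
    chrom = "chr1"
    pos = GAP
    bounds: dict[str, tuple[str, int, int, str]] = {}
    for g in genes:
        bounds[g.gene_id] = (chrom, pos, pos + g.utr_length, g.strand)
        pos += g.utr_length + GAP
    contig_len = pos + GAP
    seq = rng.choice(list("CGT"), size=contig_len)  # A-free background
    for g in genes:
        if g.a_rich:
            # a genomic A stretch spanning the proximal site, so the 10 nt
            # downstream of the (jittered) site estimate stay adenine-rich
            _, s, e, strand = bounds[g.gene_id]
            if strand == "+":
                gpos = s + g.proximal_site
                seq[gpos - 10:gpos + 10] = "A"
            else:
                gpos = e - g.proximal_site
                seq[gpos - 10:gpos + 10] = "T"
    genome_fasta = out / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for i in range(0, contig_len, 60):
            fh.write(s[i:i + 60] + "\n")

    annotation_bed = out / "genes.bed"
    with open(annotation_bed, "w") as fh:
        for g in genes:
            _, s0, e0, strand = bounds[g.gene_id]
            # BED12 with the whole transcript as one UTR block: thick region empty
            thick = s0 if strand == "+" else e0
            fh.write(
                f"{chrom}\t{s0}\t{e0}\t{g.gene_id}\t0\t{strand}\t{thick}\t{thick}"
                f"\t0\t1\t{e0 - s0}\t0\n"
            )

    # --- barcodes ---------------------------------------------------------
    barcodes = {
        k: [f"BC{k}-{i:04d}" for i in range(cells_per_cluster)] for k in clusters
    }
    clusters_tsv = out / "clusters.tsv"
    with open(clusters_tsv, "w") as fh:
        header = "barcode\tcluster"
        if covariate_of_cluster:
            header += "\tregion"
        fh.write(header + "\n")
        for k in clusters:
            for bc in barcodes[k]:
                line = f"{bc}\t{k}"
                if covariate_of_cluster:
                    line += f"\t{covariate_of_cluster[k]}"
                fh.write(line + "\n")

    # --- reads ------------------------------------------------------------
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": contig_len}]}
    reads = []
    truth_rows = []
    umi = 0
    for g in genes:
        _, s0, e0, strand = bounds[g.gene_id]
        L = g.utr_length
        for k in clusters:
            p = g.pdui[k]
            is_long = rng.random(reads_per_gene_cluster) < p
            jitter = rng.integers(0, MAX_JITTER + 1, reads_per_gene_cluster)
            ends = np.where(is_long, L, g.proximal_site) - jitter
            ends = np.clip(ends, READ_LEN, L)  # keep the read inside the UTR
            for e in ends:
                if strand == "+":
                    start = s0 + int(e) - READ_LEN  # 0-based leftmost
                    flag = 0
                else:
                    start = e0 - int(e)
                    flag = 16
                bc = barcodes[k][int(rng.integers(len(barcodes[k])))]
                umi += 1
                reads.append((start, flag, bc, f"UMI{umi:07d}", g.gene_id))
            truth_rows.append((g.gene_id, k, p))

    bam = out / "reads.bam"
    reads.sort(key=lambda r: r[0])
    with pysam.AlignmentFile(str(bam), "wb", header=header) as fh:
        for i, (start, flag, bc, umi_tag, gene) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i:08d}"
            a.flag = flag
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{READ_LEN}M"
            a.query_sequence = "A" * READ_LEN
            a.set_tag("CB", bc)
            a.set_tag("UB", umi_tag)
            fh.write(a)
    pysam.index(str(bam))

    truth_tsv = out / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("gene_id\tcluster\tpdui\tproximal_site\tutr_length\tstrand\n")
        for gene_id, k, p in truth_rows:
            g = next(x for x in genes if x.gene_id == gene_id)
            fh.write(f"{gene_id}\t{k}\t{p}\t{g.proximal_site}\t{g.utr_length}\t{g.strand}\n")

    return Fixture(bam, clusters_tsv, annotation_bed, genome_fasta, truth_tsv, bounds)
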