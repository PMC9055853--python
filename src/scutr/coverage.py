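"""Cluster splitting, read padding, and depth-normalised 3'-UTR coverage.

3'-biased reads only sample the very end of a transcript.  Padding extends
each read from the annotated 3'-UTR start (transcript position 1) to the
read's 3'-most aligned base, so the stacked padded intervals reproduce the
coverage profile a full-length library would show over the 3'-UTR.  Every
padded coverage vector is therefore non-increasing along the transcript.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .annotation import UtrRegion

log = logging.getLogger(__name__)

CPM_SCALE = 1e6


@dataclass
class ClusterAssignment:
    """Barcode -> cluster (and optional categorical covariates) map."""

    cluster_of: dict[str, str]
    covariates: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterAssignment":
        """Read a ``barcode<TAB>cluster[<TAB>covariate...]`` table with header."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("cluster table needs at least barcode and cluster columns")
        bc_col, cl_col = df.columns[0], df.columns[1]
        if df[bc_col].duplicated().any():
            dups = df[bc_col][df[bc_col].duplicated()].iloc[0]
            raise ValueError(f"duplicate barcode in cluster table: {dups}")
        cluster_of = dict(zip(df[bc_col], df[cl_col]))
        covs = {
            name: dict(zip(df[bc_col], df[name])) for name in df.columns[2:]
        }
        return cls(cluster_of, covs)

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.cluster_of.values()))


@dataclass
class PaddedCoverage:
    """Per-gene, per-cluster padded coverage in transcript orientation.

    ``coverage[j-1]`` is the depth-normalised (counts-per-million of cluster
    library size) coverage at transcript position j.  ``n_reads`` is the raw
    number of UTR reads behind the vector and ``depth`` the cluster's total
    read count used for normalisation.
    """

    gene_id: str
    cluster: str
    coverage: np.ndarray
    n_reads: int
    depth: int


def _read_passes(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def split_by_cluster(
    bam_path: str | Path,
    assignment: ClusterAssignment,
    out_dir: str | Path,
    barcode_tag: str = "CB",
) -> dict[str, Path]:
    """Split a barcoded BAM into one BAM per cluster.

    Each primary mapped non-duplicate alignment is routed to exactly one
    cluster by its barcode tag; reads with a missing or unassigned barcode
    are dropped and counted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    src = pysam.AlignmentFile(str(bam_path), "rb")
    writers = {
        k: pysam.AlignmentFile(str(out_dir / f"cluster_{k}.bam"), "wb", template=src)
        for k in assignment.clusters
    }
    n_tagged = n_dropped = n_total = 0
    for read in src.fetch(until_eof=True):
        if not _read_passes(read):
            continue
        n_total += 1
        try:
            bc = read.get_tag(barcode_tag)
        except KeyError:
            n_dropped += 1
            continue
        n_tagged += 1
        cluster = assignment.cluster_of.get(bc)
        if cluster is None:
            n_dropped += 1
            continue
        writers[cluster].write(read)
    src.close()
    for w in writers.values():
        w.close()
    if n_total and n_tagged == 0:
        raise ValueError(
            f"no read carries the barcode tag {barcode_tag!r}; "
            "check --barcode-tag against the aligner's output"
        )
    log.info("split: %d reads routed, %d dropped (untagged/unassigned)", n_total - n_dropped, n_dropped)
    paths = {}
    for k in assignment.clusters:
        p = out_dir / f"cluster_{k}.bam"
        pysam.sort("-o", str(p) + ".sorted", str(p))
        Path(str(p) + ".sorted").rename(p)
        pysam.index(str(p))
        paths[k] = p
    return paths


def pad_read(read_start: int, read_end: int, strand: str, utr: UtrRegion) -> int | None:
    """Padded transcript end ``e`` of a read aligned at [read_start, read_end).

    The padded interval is [1, e] where ``e`` is the transcript coordinate of
    the read's 3'-most aligned base within the UTR, clamped to L.  Returns
    ``None`` when the read does not overlap the UTR on the matching strand.
    """
    if strand != utr.strand:
        return None
    if read_end <= utr.start or read_start >= utr.end:
        return None
    if utr.strand == "+":
        g3 = read_end - 1  # rightmost aligned base
        return min(g3 - utr.start + 1, utr.L)
    g3 = read_start  # leftmost base is 3'-most on the - strand
    return min(utr.end - g3, utr.L)


def compute_coverage(
    padded_ends: Iterable[int], utr_length: int, depth: int,
    gene_id: str = "", cluster: str = "",
) -> PaddedCoverage:
    """Stack padded intervals [1, e] into a CPM-normalised coverage vector.

    Raw coverage at transcript position j is the number of reads with e >= j;
    the vector is scaled by 1e6 / depth.
    """
    if depth <= 0:
        raise ValueError(f"cluster {cluster!r}: zero sequencing depth")
    ends = np.asarray(list(padded_ends), dtype=np.int64)
    raw = np.zeros(utr_length, dtype=np.float64)
    if ends.size:
        if ends.min() < 1 or ends.max() > utr_length:
            raise ValueError("padded end outside [1, L]")
        counts = np.bincount(ends, minlength=utr_length + 1)[1:]
        raw = np.cumsum(counts[::-1])[::-1].astype(np.float64)
    return PaddedCoverage(gene_id, cluster, raw * CPM_SCALE / depth, int(ends.size), depth)


def cluster_depths(
    bam_path: str | Path, assignment: ClusterAssignment, barcode_tag: str = "CB"
) -> dict[str, int]:
    """Total usable (primary, mapped, non-duplicate) reads per cluster."""
    depths: Counter[str] = Counter()
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if not _read_passes(read):
                continue
            try:
                bc = read.get_tag(barcode_tag)
            except KeyError:
                continue
            cluster = assignment.cluster_of.get(bc)
            if cluster is not None:
                depths[cluster] += 1
    return dict(depths)


def collect_padded_ends(
    bam_path: str | Path,
    utrs: Iterable[UtrRegion],
    assignment: ClusterAssignment,
    barcode_tag: str = "CB",
    stranded: bool = True,
    drop_duplicates: bool = False,
    umi_tag: str = "UB",
) -> pd.DataFrame:
    """Assign reads to UTRs and pad them.

    Returns a tidy frame with one row per (gene, cluster, padded end, count).
    Reads overlapping several same-strand UTRs are counted for each (logged).
    With ``drop_duplicates`` an exact (position, barcode, UMI) duplicate is
    kept once — a naive stand-in for an upstream UMI-aware deduplication.
    """
    rows: dict[tuple[str, str, int], int] = defaultdict(int)
    seen: set[tuple] = set()
    n_multi = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for utr in utrs:
            if utr.chrom not in bam.references:
                continue
            for read in bam.fetch(utr.chrom, utr.start, utr.end):
                if not _read_passes(read):
                    continue
                try:
                    bc = read.get_tag(barcode_tag)
                except KeyError:
                    continue
                cluster = assignment.cluster_of.get(bc)
                if cluster is None:
                    continue
                strand = "-" if read.is_reverse else "+"
                if not stranded:
                    strand = utr.strand
                # reference_start/end are soft-clip free by construction
                e = pad_read(read.reference_start, read.reference_end, strand, utr)
                if e is None:
                    continue
                if drop_duplicates:
                    umi = read.get_tag(umi_tag) if read.has_tag(umi_tag) else read.query_name
                    key = (utr.gene_id, read.reference_start, read.reference_end, bc, umi)
                    if key in seen:
                        continue
                    seen.add(key)
                rows[(utr.gene_id, cluster, e)] += 1
    df = pd.DataFrame(
        [(g, k, e, c) for (g, k, e), c in rows.items()],
        columns=["gene_id", "cluster", "end", "count"],
    )
    if n_multi:
        log.info("%d reads assigned to multiple overlapping UTRs", n_multi)
    return df.sort_values(["gene_id", "cluster", "end"]).reset_index(drop=True)


def coverage_by_gene(
    ends: pd.DataFrame,
    utrs: Mapping[str, UtrRegion],
    depths: Mapping[str, int],
) -> Iterator[dict[str, PaddedCoverage]]:
    """Group a padded-end table into per-gene {cluster: PaddedCoverage} dicts."""
    for gene_id, sub in ends.groupby("gene_id", sort=True):
        utr = utrs[gene_id]
        out = {}
        for cluster, csub in sub.groupby("cluster"):
            expanded = np.repeat(csub["end"].to_numpy(), csub["count"].to_numpy())
            out[cluster] = compute_coverage(
                expanded, utr.L, depths[cluster], gene_id, cluster
            )
        yield out
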