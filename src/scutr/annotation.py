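"""3'-UTR annotation model and sequence access.

All internal genomic coordinates are 0-based half-open, BED-style.
Transcript coordinates are 1-based positions 1..L in the 5'->3' direction of
the mRNA, so transcript position 1 is the annotated 3'-UTR start (the base
right after the stop codon) and position L is the distal end of the longest
annotated 3'-UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class UtrRegion:
    """The longest annotated 3'-UTR span of one gene.

    ``start``/``end`` are 0-based half-open genomic bounds.  ``L`` is the UTR
    length in nucleotides.  On the + strand transcript position 1 maps to
    ``start``; on the - strand it maps to ``end - 1``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def L(self) -> int:
        return self.end - self.start

    def to_genomic(self, t: int) -> int:
        """Map transcript coordinate ``t`` (1..L) to a genomic base position."""
        if not 1 <= t <= self.L:
            raise ValueError(f"transcript coordinate {t} outside [1, {self.L}]")
        if self.strand == "+":
            return self.start + t - 1
        return self.end - t

    def to_transcript(self, g: int) -> int:
        """Map genomic base position ``g`` (0-based) to transcript coordinate."""
        if not self.start <= g < self.end:
            raise ValueError(f"genomic position {g} outside UTR")
        if self.strand == "+":
            return g - self.start + 1
        return self.end - g


@dataclass(frozen=True)
class PaSite:
    chrom: str
    position: int
    strand: str


class PaSiteCatalog:
    """Annotated poly(A) sites, one representative base each, sorted."""

    def __init__(self, sites: Iterable[PaSite]):
        uniq = sorted(set(sites), key=lambda s: (s.chrom, s.strand, s.position))
        self.sites = uniq
        self._by_key: dict[tuple[str, str], list[int]] = {}
        for s in uniq:
            self._by_key.setdefault((s.chrom, s.strand), []).append(s.position)

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, chrom: str, strand: str) -> list[int]:
        return self._by_key.get((chrom, strand), [])


def _merge_utr_spans(spans: list[tuple[str, int, int, str]], gene_id: str) -> UtrRegion:
    """Union rule: span from the most 5' UTR start to the most 3' UTR end."""
    chroms = {s[0] for s in spans}
    strands = {s[3] for s in spans}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError(f"{gene_id}: 3'-UTR features on multiple chroms/strands")
    start = min(s[1] for s in spans)
    end = max(s[2] for s in spans)
    return UtrRegion(gene_id, chroms.pop(), start, end, strands.pop())


def _parse_gtf_attr(attr: str, key: str) -> str | None:
    for field in attr.split(";"):
        field = field.strip()
        if field.startswith(key + " ") or field.startswith(key + "="):
            return field.split(None, 1)[1].strip().strip('"')
    return None


def load_utrs(path: str | Path) -> list[UtrRegion]:
    """Load one :class:`UtrRegion` per gene from GTF or BED12.

    GTF: ``three_prime_utr`` (or ``3UTR``) features are collected per
    ``gene_id`` and merged with the union rule, converting 1-based closed
    coordinates to 0-based half-open.  BED12: the UTR span is taken as the
    part of the transcript downstream of ``thickEnd`` (+ strand) or upstream
    of ``thickStart`` (- strand); rows sharing a name are merged.  Genes
    without any 3'-UTR feature are skipped with a log entry.
    """
    path = Path(path)
    spans: dict[str, list[tuple[str, int, int, str]]] = {}
    is_gtf = path.suffix.lower() in (".gtf", ".gff", ".gff3")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if is_gtf:
                    if fields[2].lower() not in ("three_prime_utr", "3utr", "utr3"):
                        continue
                    chrom, s, e, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                    gene = _parse_gtf_attr(fields[8], "gene_id")
                    if gene is None:
                        raise ValueError("no gene_id attribute")
                else:
                    chrom, s, e, gene, strand = (
                        fields[0], int(fields[1]), int(fields[2]), fields[3], fields[5],
                    )
                    if len(fields) >= 12:
                        thick_s, thick_e = int(fields[6]), int(fields[7])
                        # 3'-UTR = transcript part beyond the CDS in the 3' direction
                        if strand == "+":
                            s = max(s, thick_e)
                        else:
                            e = min(e, thick_s)
                        if e <= s:
                            log.info("gene %s: no 3'-UTR block, skipped", gene)
                            continue
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line ({exc})") from exc
            spans.setdefault(gene, []).append((chrom, s, e, strand))
    return [_merge_utr_spans(v, g) for g, v in spans.items()]


def write_utrs_bed(utrs: Sequence[UtrRegion], path: str | Path) -> None:
    """Write the derived UTR model as BED6."""
    with open(path, "w") as fh:
        for u in sorted(utrs, key=lambda u: (u.chrom, u.start)):
            fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{u.gene_id}\t0\t{u.strand}\n")


def fetch_downstream(fasta_path: str | Path, utr: UtrRegion, site: int, window: int = 10) -> str:
    """Sense-strand sequence of ``window`` bases 3' of transcript position ``site``.

    Truncated silently at the contig end; raises ``KeyError`` for a missing
    chromosome.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    fa = Fasta(str(fasta_path), rebuild=False)
    if utr.chrom not in fa:
        raise KeyError(f"chromosome {utr.chrom} missing from FASTA")
    g = utr.to_genomic(site)
    contig_len = len(fa[utr.chrom])
    if utr.strand == "+":
        lo, hi = g + 1, min(g + 1 + window, contig_len)
        seq = str(fa[utr.chrom][lo:hi]) if hi > lo else ""
        return seq.upper()
    lo, hi = max(g - window, 0), g
    seq = str(fa[utr.chrom][lo:hi]) if hi > lo else ""
    return reverse_complement(seq.upper())


def load_pa_catalog(path: str | Path) -> PaSiteCatalog:
    """Load a BED of annotated pA sites; intervals collapse to their midpoint."""
    sites = []
    n_raw = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) > 5 else "+"
                if e <= s:
                    raise ValueError("empty interval")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED ({exc})") from exc
            n_raw += 1
            sites.append(PaSite(chrom, (s + e) // 2, strand))
    cat = PaSiteCatalog(sites)
    if len(cat) < n_raw:
        log.info("pA catalog: %d duplicate positions collapsed", n_raw - len(cat))
    return cat
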