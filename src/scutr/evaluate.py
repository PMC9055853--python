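"""Benchmark statistics: SD_isoprop, annotation support, agreement ratio."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import PaSiteCatalog


def sd_isoprop(pduis: Sequence[float] | np.ndarray) -> float:
    """Across-cluster sample SD (ddof=1) of the long-isoform proportions.

    The dispersion of PDUI across cell types; high values characterise APA
    genes.  NaN entries are ignored; fewer than two defined values -> NaN.
    """
    x = np.asarray(pduis, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


@dataclass(frozen=True)
class Prediction:
    """A predicted pA site: a point (start == end) or an interval."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def is_point(self) -> bool:
        return self.start == self.end


@dataclass
class SupportCurve:
    """Fraction of predictions supported by the catalog per tolerance distance."""

    distances: list[int]
    fractions: list[float]
    n_supported: list[int]
    n_total: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance": self.distances, "fraction": self.fractions,
             "n_supported": self.n_supported, "n_total": self.n_total}
        )


def _supported(pred: Prediction, positions: Sequence[int], d: int) -> bool:
    if not positions:
        return False
    pos = np.asarray(positions)
    if pred.is_point:
        return bool((np.abs(pos - pred.start) <= d).any())
    # >=1 bp overlap between [start, end] and [site-d, site+d]
    return bool(((pos - d <= pred.end) & (pos + d >= pred.start)).any())


def pa_support(
    predictions: Iterable[Prediction],
    catalog: PaSiteCatalog,
    distances: Sequence[int] = tuple(range(10, 151, 10)),
    match_strand: bool = True,
) -> SupportCurve:
    """Fraction of predicted sites within +/- d of an annotated pA site.

    A point prediction is supported at distance ``d`` iff it lies within
    ``d`` bp (inclusive) of an annotated site on the same chromosome (and
    strand unless ``match_strand`` is off); an interval prediction needs at
    least 1 bp of overlap with the widened annotation interval.
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("empty prediction set")
    fractions, supported = [], []
    for d in distances:
        n = 0
        for p in preds:
            if match_strand:
                positions = catalog.positions(p.chrom, p.strand)
            else:
                positions = catalog.positions(p.chrom, "+") + catalog.positions(p.chrom, "-")
            if _supported(p, positions, d):
                n += 1
        supported.append(n)
        fractions.append(n / len(preds))
    return SupportCurve(list(distances), fractions, supported, len(preds))


def apa_agreement_ratio(sample_genes: Iterable[str], total_genes: Iterable[str]) -> float:
    """|sample APA genes ∩ total APA genes| / |total APA genes|.

    A robustness measure under cell subsampling: how much of the full-data
    APA gene set a subsample recovers.
    """
    total = set(total_genes)
    if not total:
        raise ValueError("total APA gene set is empty")
    return len(set(sample_genes) & total) / len(total)
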