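"""Simulation platform for benchmarking cluster-level APA callers.

The generator mirrors how APA manifests in clustered scRNA-seq data at the
cluster level: a gene's expression is split between a long and a short
3'-UTR isoform, and the across-cluster standard deviation of the
long-isoform proportion (SD_isoprop, the SD of PDUI) separates APA genes
(high dispersion) from non-APA genes (low dispersion).  The platform
therefore simulates

1. a genes x clusters total-count matrix (log-normal gene means,
   negative-binomial per-cell counts with log-normal cell size factors,
   summed within clusters),
2. a PDUI matrix whose rows have an *exact* sample SD equal to the target
   dispersion (standard-normal draws centred, rescaled to unit sample SD,
   scaled by the target and shifted by a Uniform(0.05, 0.95) row mean, with
   rejection of rows leaving [0, 1]),
3. long/short splits of the totals by the PDUI matrix,

and scores the logistic-LRT caller against a Pearson chi-square comparator
(which, mirroring its R reference behaviour, returns no p-value whenever a
zero appears in the 2 x K table).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .model import LOG2, bh_adjust

DEFAULT_MEANLOG = 1.0
DEFAULT_SDLOG = 1.2
DEFAULT_DISPERSION = 0.2
DEFAULT_SIZE_FACTOR_SDLOG = 0.25


@dataclass
class SimScenario:
    """One simulation condition.

    Defaults follow the benchmark design: 5,000 genes, 3,000 cells in 5
    clusters, 10% true APA genes with SD_isoprop 0.127 against 0.009 for
    non-APA genes, 100 repetitions.
    """

    n_genes: int = 5000
    n_cells: int = 3000
    cluster_proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    frac_apa: float = 0.10
    sd_apa: float = 0.127
    sd_non: float = 0.009
    reps: int = 100
    seed: int = 0
    mean_range: tuple[float, float] = (0.05, 0.95)
    meanlog: float = DEFAULT_MEANLOG
    sdlog: float = DEFAULT_SDLOG
    dispersion: float = DEFAULT_DISPERSION
    size_factor_sdlog: float = DEFAULT_SIZE_FACTOR_SDLOG

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if not 0.0 <= self.frac_apa < 1.0:
            raise ValueError("frac_apa must be in [0, 1)")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    def cluster_sizes(self) -> np.ndarray:
        sizes = np.floor(np.asarray(self.cluster_proportions) * self.n_cells).astype(int)
        sizes[0] += self.n_cells - sizes.sum()  # remainder to the first cluster
        return sizes


@dataclass
class PduiMatrix:
    """Per-gene, per-cluster long-isoform proportions with APA truth labels."""

    values: np.ndarray  # (G, K) in [0, 1]
    truth: np.ndarray  # (G,) bool, True = APA gene
    sd_apa: float
    sd_non: float


def simulate_cluster_counts(scenario: SimScenario, rng: np.random.Generator | None = None) -> np.ndarray:
    """Genes x clusters matrix of total read counts.

    Per-gene means are log-normal(meanlog, sdlog); each cell draws a
    negative-binomial count (gamma-Poisson with dispersion alpha, mean
    scaled by a log-normal cell size factor) and cells are summed within
    clusters.  Deterministic for a given scenario seed.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    G = scenario.n_genes
    gene_mean = rng.lognormal(scenario.meanlog, scenario.sdlog, G)
    alpha = scenario.dispersion
    totals = np.zeros((G, scenario.n_clusters), dtype=np.int64)
    chunk = 200  # cells per vectorised block, bounds peak memory
    for k, size in enumerate(scenario.cluster_sizes()):
        factors = rng.lognormal(0.0, scenario.size_factor_sdlog, size)
        for lo in range(0, size, chunk):
            s = factors[lo:lo + chunk]
            mu = gene_mean[:, None] * s[None, :]
            lam = rng.gamma(1.0 / alpha, alpha * mu)
            totals[:, k] += rng.poisson(lam).sum(axis=1)
    return totals


def _exact_sd_rows(
    rng: np.random.Generator, n_rows: int, k: int, sd: float,
    mean_range: tuple[float, float], max_tries: int = 1000,
) -> np.ndarray:
    """Rows with exact sample SD ``sd`` and entries in [0, 1], by rejection."""
    out = np.empty((n_rows, k))
    pending = np.arange(n_rows)
    for _ in range(max_tries):
        m = pending.size
        if m == 0:
            return out
        means = rng.uniform(*mean_range, m)
        if sd == 0.0:
            out[pending] = means[:, None]
            return out
        z = rng.standard_normal((m, k))
        z -= z.mean(axis=1, keepdims=True)
        norm = z.std(axis=1, ddof=1, keepdims=True)
        degenerate = norm[:, 0] == 0.0
        norm[degenerate] = 1.0
        rows = means[:, None] + sd * z / norm
        feasible = (~degenerate) & (rows.min(axis=1) >= 0.0) & (rows.max(axis=1) <= 1.0)
        out[pending[feasible]] = rows[feasible]
        pending = pending[~feasible]
    raise RuntimeError(
        f"could not draw rows with SD {sd} and entries in {mean_range} "
        f"after {max_tries} rejection rounds"
    )


def generate_pdui_matrix(scenario: SimScenario, rng: np.random.Generator | None = None) -> PduiMatrix:
    """PDUI matrix with exact per-row SD_isoprop and random APA truth rows."""
    rng = rng or np.random.default_rng(scenario.seed)
    G, K = scenario.n_genes, scenario.n_clusters
    n_apa = int(round(scenario.frac_apa * G))
    truth = np.zeros(G, dtype=bool)
    truth[rng.choice(G, n_apa, replace=False)] = True
    values = np.empty((G, K))
    values[truth] = _exact_sd_rows(rng, n_apa, K, scenario.sd_apa, scenario.mean_range)
    values[~truth] = _exact_sd_rows(rng, G - n_apa, K, scenario.sd_non, scenario.mean_range)
    return PduiMatrix(values, truth, scenario.sd_apa, scenario.sd_non)


def split_counts(totals: np.ndarray, pdui: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split totals into long/short integer matrices: long = round(total*PDUI)."""
    if totals.shape != pdui.shape:
        raise ValueError("shape mismatch between totals and PDUI matrix")
    long = np.rint(totals * pdui).astype(np.int64)
    return long, totals - long


# ---------------------------------------------------------------------------
# callers
# ---------------------------------------------------------------------------

def gtest_pvalues(long: np.ndarray, short: np.ndarray) -> np.ndarray:
    """Vectorised likelihood-ratio (G) test of independence per 2 x K table.

    Equals the cell-type-only logistic LRT on each gene's aggregated counts.
    Clusters with zero total are excluded gene-wise (the df shrinks); genes
    with fewer than two populated clusters get NaN.
    """
    O = np.stack([long, short], axis=1).astype(float)  # (G, 2, K)
    col = O.sum(axis=1)  # (G, K) cluster totals
    pop = col > 0
    npop = pop.sum(axis=1)
    grand = O.sum(axis=(1, 2))
    row = O.sum(axis=2)  # (G, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = row[:, :, None] * col[:, None, :] / grand[:, None, None]
        term = O * np.log(O / E)
    term = np.where(O > 0, term, 0.0)
    stat = 2.0 * np.nansum(term, axis=(1, 2))
    df = npop - 1
    ok = (npop >= 2) & (row > 0).all(axis=1)
    p = np.full(long.shape[0], np.nan)
    p[ok] = stats.chi2.sf(stat[ok], df[ok])
    return p


def effect_gate_vector(long: np.ndarray, short: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Vectorised effect-size gate: any cluster with |log2 OR vs grand mean| > threshold.

    Logits use a Haldane 0.5 correction wherever a zero cell would make them
    infinite; the grand mean is the read-weighted mean logit, matching the
    weighted-effect-coded intercept.
    """
    l = long.astype(float)
    s = short.astype(float)
    zero = (l == 0) | (s == 0)
    l = np.where(zero, l + 0.5, l)
    s = np.where(zero, s + 0.5, s)
    n = l + s
    with np.errstate(divide="ignore", invalid="ignore"):
        logit = np.log(l / s)
        wmean = (n * logit).sum(axis=1) / n.sum(axis=1)
        beta = logit - wmean[:, None]
    gate = np.abs(beta) / LOG2 > threshold
    return np.where(np.isfinite(beta), gate, False).any(axis=1)


def apa_caller(long: np.ndarray, short: np.ndarray, fdr: float = 0.05,
               log2_or_gate: float | None = 0.25) -> np.ndarray:
    """Gene-level APA calls: LRT + BH at ``fdr``, plus the effect-size gate.

    Set ``log2_or_gate=None`` for the bare LRT+BH calls.  NaN p-values count
    as non-significant.
    """
    p = gtest_pvalues(long, short)
    q = bh_adjust(p)
    calls = np.nan_to_num(q, nan=1.0) < fdr
    if log2_or_gate is not None:
        calls &= effect_gate_vector(long, short, log2_or_gate)
    return calls


def chisq_comparator(long: np.ndarray, short: np.ndarray) -> np.ndarray:
    """Pearson chi-square p-values per 2 x K table, NaN when any cell is 0.

    Mirrors a comparator built on R's ``chisq.test`` (no continuity
    correction), which yields NA for tables containing zeros; NaN is scored
    as a non-significant call downstream.
    """
    O = np.stack([long, short], axis=1).astype(float)
    anyzero = (O == 0).any(axis=(1, 2))
    col = O.sum(axis=1)
    row = O.sum(axis=2)
    grand = O.sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        E = row[:, :, None] * col[:, None, :] / grand[:, None, None]
        stat = np.nansum((O - E) ** 2 / E, axis=(1, 2))
    df = O.shape[2] - 1
    p = stats.chi2.sf(stat, df)
    p[anyzero] = np.nan
    return p


# ---------------------------------------------------------------------------
# scoring and scenario sweeps
# ---------------------------------------------------------------------------

def sensitivity_specificity(calls: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    tp = int((calls & truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    fp = int((calls & ~truth).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


@dataclass
class MetricReport:
    """Tidy per-rep, per-method sensitivity/specificity table."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        return self.frame.groupby(["scenario", "method"])[
            ["sensitivity", "specificity"]
        ].mean().reset_index()


def run_scenario(
    scenario: SimScenario,
    methods: Iterable[str] = ("logistic_lrt", "chisq"),
    fdr: float = 0.05,
    log2_or_gate: float | None = 0.25,
    label: str = "",
) -> pd.DataFrame:
    """Run one scenario: fixed count matrix, fresh PDUI matrix per rep.

    The count matrix is drawn once from the scenario seed; every repetition
    regenerates the PDUI matrix (seeded by (seed, rep)), splits the counts,
    and scores each caller against the truth labels at BH q < ``fdr``.
    """
    totals = simulate_cluster_counts(scenario)
    rows = []
    for rep in range(scenario.reps):
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, rep]))
        pm = generate_pdui_matrix(scenario, rng)
        long, short = split_counts(totals, pm.values)
        for method in methods:
            if method == "logistic_lrt":
                calls = apa_caller(long, short, fdr, log2_or_gate)
            elif method == "chisq":
                p = chisq_comparator(long, short)
                q = bh_adjust(p)
                calls = np.nan_to_num(q, nan=1.0) < fdr
            else:
                raise ValueError(f"unknown method {method!r}")
            sens, spec = sensitivity_specificity(calls, pm.truth)
            rows.append(
                {"scenario": label, "rep": rep, "method": method,
                 "sensitivity": sens, "specificity": spec,
                 "n_called": int(calls.sum())}
            )
    return pd.DataFrame(rows)


def run_scenarios(
    scenarios: dict[str, SimScenario],
    methods: Iterable[str] = ("logistic_lrt", "chisq"),
    fdr: float = 0.05,
    log2_or_gate: float | None = 0.25,
) -> MetricReport:
    frames = [
        run_scenario(sc, methods, fdr, log2_or_gate, label)
        for label, sc in scenarios.items()
    ]
    return MetricReport(pd.concat(frames, ignore_index=True))


def sd_sweep_scenarios(
    base: SimScenario, sd_low: float = 0.06, sd_high: float = 0.18, n_levels: int = 15
) -> dict[str, SimScenario]:
    """15 equally spaced APA dispersion levels (the benchmark's SD sweep)."""
    levels = np.linspace(sd_low, sd_high, n_levels)
    return {f"sd={lv:.4f}": replace(base, sd_apa=float(lv)) for lv in levels}
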