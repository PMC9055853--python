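"""Gene-level APA testing with a weighted-effect-coded binomial GLM.

For each gene the long/short isoform counts per cell cluster are modelled by
logistic regression,

    logit p = b0 + sum_i b_i C_i + sum_j b_j V_j,

where p is the probability that a transcript uses the distal pA site (long
isoform), C_i are cell-type codes and V_j optional categorical confounders.
Weighted effect coding is used for the cell types: category i's column is 1
for cluster i, -n_i/n_ref for the designated reference cluster, and 0
otherwise, with n_i the cluster read totals.  Each coefficient then measures
the deviation of a cluster's log-odds from the read-weighted grand mean
rather than from an arbitrary reference level, so unbalanced cluster sizes
do not distort the intercept.  Because the reference level itself carries no
column, the model is fitted twice with two different references so every
cluster receives a coefficient and standard error.

Across-cell-type APA is tested by a likelihood-ratio test of the cell-type
model against the null (or, with confounders, the full model against the
confounder-only model); on saturated cell-type-only fits this LRT equals the
G-test of independence of the long/short x cluster table.  P-values are
Benjamini-Hochberg adjusted, and a gene is called significant APA only if in
addition at least one cluster shows |log2 odds ratio| above an effect-size
gate.  Cluster-specific lengthening/shortening is called from Wald tests on
the per-cluster coefficients plus a fold-change rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .isoform import IsoformCounts, IsoformFit

log = logging.getLogger(__name__)

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_genes(
    counts: Mapping[str, Mapping[str, IsoformCounts]],
    fits: Mapping[str, IsoformFit],
    min_two_site_clusters: int = 3,
    cpm_min: float = 10.0,
    min_cluster_count: int = 20,
) -> dict[str, list[str]]:
    """Gene- and cluster-level filters ahead of model fitting.

    A gene is retained when two pA sites are detected in at least
    ``min_two_site_clusters`` clusters and the across-cluster mean CPM
    exceeds ``cpm_min`` for the long and the short isoform separately.
    Within retained genes, clusters with fewer than ``min_cluster_count``
    raw reads are dropped; genes left with fewer than two clusters are
    dropped.  Returns {gene_id: [retained clusters]}.
    """
    retained: dict[str, list[str]] = {}
    for gene, per_cluster in counts.items():
        fit = fits.get(gene)
        if fit is None or fit.n_two_site() < min_two_site_clusters:
            continue
        cl = list(per_cluster.values())
        if np.mean([c.cpm_long for c in cl]) <= cpm_min:
            continue
        if np.mean([c.cpm_short for c in cl]) <= cpm_min:
            continue
        keep = [c.cluster for c in cl if c.total >= min_cluster_count]
        if len(keep) >= 2:
            retained[gene] = sorted(keep)
    return retained


# ---------------------------------------------------------------------------
# observations and design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Observation:
    """One aggregated binomial row: a cell cluster (x covariate pattern)."""

    cluster: str
    long: float
    short: float
    covariates: tuple[tuple[str, str], ...] = ()

    @property
    def total(self) -> float:
        return self.long + self.short

    def covariate(self, name: str, default: str = "") -> str:
        return dict(self.covariates).get(name, default)


def observations_from_counts(
    long_counts: Mapping[str, float], short_counts: Mapping[str, float]
) -> list[Observation]:
    return [
        Observation(c, float(long_counts[c]), float(short_counts[c]))
        for c in sorted(long_counts)
    ]


@dataclass
class DesignSpec:
    """Weighted-effect-coded design for cluster + optional confounder terms."""

    clusters: list[str]
    weights: dict[str, float]  # cluster read totals n_i
    reference: str
    covariate_levels: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_observations(
        cls, obs: Sequence[Observation], reference: str | None = None,
        with_covariates: bool = True,
    ) -> "DesignSpec":
        clusters = sorted({o.cluster for o in obs})
        weights = {c: 0.0 for c in clusters}
        for o in obs:
            weights[o.cluster] += o.total
        cov_levels: dict[str, list[str]] = {}
        if with_covariates:
            for o in obs:
                for name, level in o.covariates:
                    cov_levels.setdefault(name, [])
                    if level not in cov_levels[name]:
                        cov_levels[name].append(level)
            cov_levels = {k: sorted(v) for k, v in cov_levels.items() if len(v) > 1}
        return cls(clusters, weights, reference or clusters[-1], cov_levels)

    def cluster_columns(self) -> list[str]:
        return [c for c in self.clusters if c != self.reference]

    def matrix(self, obs: Sequence[Observation]) -> np.ndarray:
        """Design matrix (intercept | effect-coded clusters | covariate dummies)."""
        cols = self.cluster_columns()
        n_ref = self.weights[self.reference]
        out = np.zeros((len(obs), 1 + len(cols) + self._n_cov_cols()))
        out[:, 0] = 1.0
        for r, o in enumerate(obs):
            for j, c in enumerate(cols, start=1):
                if o.cluster == c:
                    out[r, j] = 1.0
                elif o.cluster == self.reference:
                    out[r, j] = -self.weights[c] / n_ref
            out[r, 1 + len(cols):] = self._cov_row(o)
        return out

    def _n_cov_cols(self) -> int:
        return sum(len(lv) - 1 for lv in self.covariate_levels.values())

    def _cov_row(self, o: Observation) -> np.ndarray:
        vals: list[float] = []
        for name, levels in self.covariate_levels.items():
            level = o.covariate(name, levels[0])
            vals.extend(1.0 if level == lv else 0.0 for lv in levels[1:])
        return np.asarray(vals)

    def column_names(self) -> list[str]:
        names = ["intercept"] + [f"cluster[{c}]" for c in self.cluster_columns()]
        for name, levels in self.covariate_levels.items():
            names += [f"{name}[{lv}]" for lv in levels[1:]]
        return names


# ---------------------------------------------------------------------------
# binomial GLM
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: dict[str, float]
    bse: dict[str, float]
    llf: float
    df_model: int
    converged: bool
    haldane: bool = False


def _glm_fit(endog: np.ndarray, exog: np.ndarray):
    import warnings

    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # saturated fits (df_resid == 0) trigger benign scale/separation warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.PerfectSeparationWarning)
        return model.fit(maxiter=200, tol=1e-10)


def fit_logistic(obs: Sequence[Observation], design: DesignSpec) -> LogisticFit:
    """Maximum-likelihood binomial GLM on aggregated count rows.

    On separation or non-convergence the fit is retried once with 0.5 added
    to every aggregated cell of the gene's table (Haldane-Anscombe), logged.
    """
    endog = np.array([[o.long, o.short] for o in obs], dtype=float)
    exog = design.matrix(obs)
    names = design.column_names()
    haldane = False
    try:
        res = _glm_fit(endog, exog)
        ok = np.isfinite(res.params).all() and np.isfinite(res.bse).all()
    except Exception:  # PerfectSeparation and friends
        ok = False
    if not ok:
        log.info("logistic fit unstable, retrying with Haldane correction")
        res = _glm_fit(endog + 0.5, exog)
        haldane = True
    return LogisticFit(
        params=dict(zip(names, np.asarray(res.params, float))),
        bse=dict(zip(names, np.asarray(res.bse, float))),
        llf=float(res.llf),
        df_model=exog.shape[1] - 1,
        converged=bool(getattr(res, "converged", True)),
        haldane=haldane,
    )


def fit_logistic_all_clusters(
    obs: Sequence[Observation], with_covariates: bool = True
) -> tuple[dict[str, float], dict[str, float], LogisticFit]:
    """Fit twice with two different reference clusters.

    The reference level of an effect-coded factor carries no column, so a
    single fit leaves one cluster without a coefficient; two fits with
    different references cover every cluster.  Returns per-cluster
    coefficients, their standard errors, and the first fit (intercept,
    confounder terms, likelihood).
    """
    clusters = sorted({o.cluster for o in obs})
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    betas: dict[str, float] = {}
    ses: dict[str, float] = {}
    first: LogisticFit | None = None
    for ref in (clusters[-1], clusters[0]):
        design = DesignSpec.from_observations(obs, ref, with_covariates)
        f = fit_logistic(obs, design)
        if first is None:
            first = f
        for c in clusters:
            key = f"cluster[{c}]"
            if key in f.params and c not in betas:
                betas[c] = f.params[key]
                ses[c] = f.bse[key]
    assert first is not None
    return betas, ses, first


def lrt_across_cell_types(llf_full: float, llf_reduced: float, df_diff: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested binomial GLMs: returns (statistic, p)."""
    if df_diff <= 0:
        raise ValueError("models are not nested (non-positive df difference)")
    stat = max(2.0 * (llf_full - llf_reduced), 0.0)
    return stat, float(stats.chi2.sf(stat, df_diff))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = sm.stats.multipletests(p[ok], method="fdr_bh")[1]
    return q


def effect_size_gate(cluster_betas: Mapping[str, float], threshold: float = 0.25) -> bool:
    """True iff some cluster deviates from the grand mean by |log2 OR| > threshold."""
    return any(abs(b) / LOG2 > threshold for b in cluster_betas.values())


def cell_type_direction(odds_ratio: float, wald_q: float, alpha: float = 0.05,
                        fold: float = 2.0) -> str:
    """Classify a cluster as lengthening / shortening / none."""
    if np.isnan(wald_q) or wald_q >= alpha:
        return "none"
    if odds_ratio >= fold:
        return "lengthening"
    if odds_ratio <= 1.0 / fold:
        return "shortening"
    return "none"


# ---------------------------------------------------------------------------
# gene-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class ApaTestResult:
    gene_id: str
    intercept: float
    betas: dict[str, float]
    ses: dict[str, float]
    confounder_betas: dict[str, float]
    lrt_stat: float
    lrt_p: float
    lrt_q: float = float("nan")
    wald_p: dict[str, float] = field(default_factory=dict)
    wald_q: dict[str, float] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)
    effect_gate: bool = False
    significant: bool = False
    internal_priming: bool = False

    def odds_ratio(self, cluster: str) -> float:
        return float(np.exp(self.betas[cluster]))


def test_gene(
    obs: Sequence[Observation],
    gene_id: str = "",
    adjust_covariates: bool = True,
    log2_or_gate: float = 0.25,
) -> ApaTestResult:
    """Fit the APA model for one gene and compute the across-cluster LRT.

    With covariates present (and ``adjust_covariates``), the LRT compares
    the full model against the confounder-only model; otherwise against the
    intercept-only null.
    """
    betas, ses, full = fit_logistic_all_clusters(obs, adjust_covariates)
    clusters = sorted({o.cluster for o in obs})
    design = DesignSpec.from_observations(obs, with_covariates=adjust_covariates)
    endog = np.array([[o.long, o.short] for o in obs], float)
    if full.haldane:
        endog = endog + 0.5
    if design.covariate_levels:
        exog_full = design.matrix(obs)
        keep = [0] + list(range(len(clusters), exog_full.shape[1]))
        exog_reduced = exog_full[:, keep]
    else:
        exog_reduced = np.ones((len(obs), 1))
    red = _glm_fit(endog, exog_reduced)
    stat, p = lrt_across_cell_types(
        full.llf, float(red.llf), full.df_model - (exog_reduced.shape[1] - 1)
    )
    wald_p = {
        c: float(2 * stats.norm.sf(abs(betas[c] / ses[c]))) if ses[c] > 0 else float("nan")
        for c in clusters
    }
    conf = {
        k: v for k, v in full.params.items()
        if k != "intercept" and not k.startswith("cluster[")
    }
    return ApaTestResult(
        gene_id=gene_id,
        intercept=full.params["intercept"],
        betas=betas,
        ses=ses,
        confounder_betas=conf,
        lrt_stat=stat,
        lrt_p=p,
        wald_p=wald_p,
        effect_gate=effect_size_gate(betas, log2_or_gate),
    )


def finalize_results(
    results: list[ApaTestResult],
    fdr: float = 0.05,
    fold: float = 2.0,
    exclude_internal_priming: bool = True,
) -> list[ApaTestResult]:
    """Across-gene BH adjustment, significance calls, and direction calls.

    LRT q-values are computed over all tested genes.  A gene is significant
    APA iff lrt_q < fdr and the effect-size gate passes (and it is not an
    internal-priming suspect unless that exclusion is disabled).  Wald
    p-values are BH-adjusted within each cell type across the significant
    genes only, then converted to lengthening/shortening calls by the
    fold-change rule.
    """
    if not results:
        return results
    qs = bh_adjust([r.lrt_p for r in results])
    for r, q in zip(results, qs):
        r.lrt_q = float(q)
        r.significant = bool(q < fdr and r.effect_gate)
        if exclude_internal_priming and r.internal_priming:
            r.significant = False
    sig = [r for r in results if r.significant]
    clusters = sorted({c for r in results for c in r.betas})
    for c in clusters:
        members = [r for r in sig if c in r.wald_p]
        if not members:
            continue
        qvals = bh_adjust([r.wald_p[c] for r in members])
        for r, q in zip(members, qvals):
            r.wald_q[c] = float(q)
            r.direction[c] = cell_type_direction(r.odds_ratio(c), float(q), fdr, fold)
    for r in results:
        for c in r.betas:
            r.wald_q.setdefault(c, float("nan"))
            r.direction.setdefault(c, "none")
    return results


def results_frame(results: list[ApaTestResult]) -> pd.DataFrame:
    """Flatten results to a tidy per-gene table (one row per gene)."""
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "intercept": r.intercept,
            "lrt_stat": r.lrt_stat,
            "lrt_p": r.lrt_p,
            "lrt_q": r.lrt_q,
            "effect_gate": r.effect_gate,
            "significant": r.significant,
            "internal_priming": r.internal_priming,
        }
        for c in sorted(r.betas):
            row[f"beta[{c}]"] = r.betas[c]
            row[f"se[{c}]"] = r.ses[c]
            row[f"or[{c}]"] = r.odds_ratio(c)
            row[f"wald_p[{c}]"] = r.wald_p.get(c, float("nan"))
            row[f"wald_q[{c}]"] = r.wald_q.get(c, float("nan"))
            row[f"direction[{c}]"] = r.direction.get(c, "none")
        for k, v in r.confounder_betas.items():
            row[f"beta[{k}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multinomial extension (>2 pA sites)
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    betas: np.ndarray  # (n_sites - 1, n_columns)
    llf: float
    lrt_stat: float
    lrt_p: float
    site_labels: list[str]


def _multinomial_llf(beta: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    # beta: (S-1, p); last category is baseline with eta = 0
    eta = X @ beta.T  # (rows, S-1)
    eta = np.column_stack([eta, np.zeros(len(X))])
    eta -= eta.max(axis=1, keepdims=True)
    logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
    return float((Y * logp).sum())


def fit_multinomial(
    site_counts: Mapping[str, Sequence[float]],
    site_labels: Sequence[str] | None = None,
) -> MultinomialFit:
    """Baseline-category multinomial logit on per-site counts per cluster.

    ``site_counts[cluster]`` holds the read counts of each pA-site isoform
    (ordered 5'->3'); weighted effect coding over clusters matches the
    binomial model, and the LRT compares against the intercept-only model.
    Zero-total site categories are collapsed out with a warning.  With two
    sites this reduces exactly to the binomial fit.
    """
    clusters = sorted(site_counts)
    Y = np.array([site_counts[c] for c in clusters], dtype=float)
    labels = list(site_labels or [f"site{i+1}" for i in range(Y.shape[1])])
    nonzero = Y.sum(axis=0) > 0
    if not nonzero.all():
        log.warning("collapsing %d zero-count pA-site categories", int((~nonzero).sum()))
        Y = Y[:, nonzero]
        labels = [l for l, keep in zip(labels, nonzero) if keep]
    S = Y.shape[1]
    if S < 2:
        raise ValueError("need at least two pA-site categories with counts")
    obs = [Observation(c, 0.0, float(Y[i].sum())) for i, c in enumerate(clusters)]
    design = DesignSpec.from_observations(obs, with_covariates=False)
    X = design.matrix(obs)
    p = X.shape[1]

    def neg(beta_flat: np.ndarray, Xm: np.ndarray) -> float:
        return -_multinomial_llf(beta_flat.reshape(S - 1, Xm.shape[1]), Xm, Y)

    res = optimize.minimize(neg, np.zeros((S - 1) * p), args=(X,), method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-10})
    X0 = np.ones((len(clusters), 1))
    res0 = optimize.minimize(neg, np.zeros(S - 1), args=(X0,), method="BFGS",
                             options={"maxiter": 2000, "gtol": 1e-10})
    llf, llf0 = -res.fun, -res0.fun
    stat, pval = lrt_across_cell_types(llf, llf0, (S - 1) * (p - 1))
    return MultinomialFit(res.x.reshape(S - 1, p), llf, stat, pval, labels)


# ---------------------------------------------------------------------------
# confounder-adjusted vs unadjusted comparison
# ---------------------------------------------------------------------------

def check_collinearity(obs: Sequence[Observation]) -> None:
    """Error when a covariate is a function of cluster (perfect collinearity)."""
    names = sorted({n for o in obs for n, _ in o.covariates})
    for name in names:
        per_cluster: dict[str, set[str]] = {}
        levels = set()
        for o in obs:
            lv = o.covariate(name)
            levels.add(lv)
            per_cluster.setdefault(o.cluster, set()).add(lv)
        if len(levels) > 1 and all(len(v) == 1 for v in per_cluster.values()):
            raise ValueError(
                f"covariate {name!r} is perfectly collinear with the cell-type clusters"
            )


def confounder_adjusted_run(
    gene_observations: Mapping[str, Sequence[Observation]],
    fdr: float = 0.05,
    log2_or_gate: float = 0.25,
) -> tuple[list[ApaTestResult], list[ApaTestResult], list[str]]:
    """Run the model with and without confounder adjustment.

    Returns (adjusted, unadjusted, genes significant only without
    adjustment) — the difference set flags putative covariate-driven calls.
    """
    adjusted, unadjusted = [], []
    for gene, obs in gene_observations.items():
        check_collinearity(obs)
        adjusted.append(test_gene(obs, gene, True, log2_or_gate))
        unadjusted.append(test_gene(obs, gene, False, log2_or_gate))
    finalize_results(adjusted, fdr)
    finalize_results(unadjusted, fdr)
    adj_sig = {r.gene_id for r in adjusted if r.significant}
    unadj_sig = {r.gene_id for r in unadjusted if r.significant}
    return adjusted, unadjusted, sorted(unadj_sig - adj_sig)
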