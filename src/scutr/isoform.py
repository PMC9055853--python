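"""Proximal pA-site estimation and isoform quantification.

A 3'-UTR expressing two isoforms — a short one ending at the proximal pA
site P and a long one running to the distal end L — produces, after read
padding, an expected coverage that is a step function: (w_S + w_L) on
transcript positions 1..P and w_L on P+1..L.  For a candidate P the best
non-negative (w_L, w_S) minimising

    || R - (w_L * 1_L + w_S * 1_P) ||^2

has a closed form, and the change point is found by scanning integer
candidates for P and keeping the one with the smallest residual summed over
cell clusters (one shared proximal site per gene).  PDUI — the percentage of
distal pA-site usage, equivalently the long-isoform proportion — is
w_L / (w_L + w_S).

The >2-site extension models coverage as C = M W with M the upper-triangular
matrix of ones (an isoform of 3'-UTR length l covers positions 1..l) and
recovers a sparse non-negative W by an L1-penalised (LASSO) fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# two-site fit
# ---------------------------------------------------------------------------

def nnls_weights(coverage: np.ndarray, p: int) -> tuple[float, float, float]:
    """Exact non-negative least squares for the two-step model at site ``p``.

    Returns ``(w_long, w_short, residual)`` where residual is the objective
    value at the optimum.  The unconstrained solution is w_long = mean
    coverage on the tail (p, L], w_short = mean head - mean tail; each active
    constraint case is evaluated explicitly and the feasible minimum kept.
    """
    r = np.asarray(coverage, dtype=np.float64)
    L = r.size
    if not 1 < p < L:
        raise ValueError(f"candidate site {p} must satisfy 1 < P < L={L}")
    ss = float(r @ r)
    s_head = float(r[:p].sum())
    s_all = float(r.sum())

    def objective(wl: float, ws: float) -> float:
        # ||r||^2 - 2 wl S_L - 2 ws S_P + wl^2 L + 2 wl ws P + ws^2 P
        return ss - 2 * wl * s_all - 2 * ws * s_head + wl * wl * L + 2 * wl * ws * p + ws * ws * p

    candidates = []
    wl_u = (s_all - s_head) / (L - p)
    ws_u = s_head / p - wl_u
    if wl_u >= 0 and ws_u >= 0:
        candidates.append((wl_u, ws_u))
    candidates.append((max(s_all / L, 0.0), 0.0))
    candidates.append((0.0, max(s_head / p, 0.0)))
    best = min(candidates, key=lambda c: objective(*c))
    return best[0], best[1], max(objective(*best), 0.0)


def _nnls_profile(r: np.ndarray, cand: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`nnls_weights` over all candidate sites ``cand``."""
    L = r.size
    cs = np.concatenate([[0.0], np.cumsum(r)])
    ss = float(r @ r)
    s_all = cs[-1]
    s_head = cs[cand]
    p = cand.astype(np.float64)

    def obj(wl, ws):
        return ss - 2 * wl * s_all - 2 * ws * s_head + wl**2 * L + 2 * wl * ws * p + ws**2 * p

    wl_u = (s_all - s_head) / (L - p)
    ws_u = s_head / p - wl_u
    wl1, ws1 = np.maximum(wl_u, 0), np.maximum(ws_u, 0)
    feas = (wl_u >= 0) & (ws_u >= 0)
    o1 = np.where(feas, obj(wl_u, ws_u), np.inf)
    wl2 = np.full_like(p, max(s_all / L, 0.0))
    o2 = obj(wl2, np.zeros_like(p))
    ws3 = np.maximum(s_head / p, 0.0)
    o3 = obj(np.zeros_like(p), ws3)
    stack_o = np.stack([o1, o2, o3])
    stack_wl = np.stack([wl1, wl2, np.zeros_like(p)])
    stack_ws = np.stack([ws1, np.zeros_like(p), ws3])
    pick = stack_o.argmin(axis=0)
    idx = np.arange(p.size)
    return (
        stack_wl[pick, idx],
        stack_ws[pick, idx],
        np.maximum(stack_o[pick, idx], 0.0),
    )


@dataclass
class IsoformFit:
    """Shared proximal site and per-cluster isoform abundances for one gene."""

    gene_id: str
    proximal_site: int  # transcript coordinate, 1 < P < L
    L: int
    w_long: dict[str, float]
    w_short: dict[str, float]
    residual: dict[str, float]
    two_site_clusters: dict[str, bool]
    internal_priming: bool = False
    genomic_site: int | None = None

    @property
    def two_site(self) -> bool:
        return any(self.two_site_clusters.values())

    def pdui(self, cluster: str) -> float:
        return pdui(self.w_long[cluster], self.w_short[cluster])

    def n_two_site(self) -> int:
        return sum(self.two_site_clusters.values())


def pdui(w_long: float, w_short: float) -> float:
    """Long-isoform proportion w_L / (w_L + w_S); NaN when both are zero."""
    total = w_long + w_short
    if total <= 0:
        return float("nan")
    return w_long / total


def candidate_sites(L: int, flank: float | int | None = None) -> np.ndarray:
    """Integer candidate proximal sites, excluding a flank at each UTR end.

    The default flank is max(50 nt, 5% of L), capped so at least one
    candidate always remains for short UTRs.
    """
    if flank is None:
        flank = max(50, int(round(0.05 * L)))
    flank = int(flank)
    lo, hi = flank + 1, L - flank - 1
    if lo > hi:  # degenerate short UTR: fall back to the full interior
        lo, hi = 2, L - 1
    return np.arange(lo, hi + 1)


def fit_two_site(
    coverages: Mapping[str, np.ndarray],
    gene_id: str = "",
    flank: float | int | None = None,
    min_minor_fraction: float = 0.01,
    min_residual_gain: float = 0.05,
) -> IsoformFit | None:
    """Estimate the shared proximal site P* of a gene across clusters.

    P* minimises the summed per-cluster NNLS residual over all candidate
    sites (ties broken toward the smallest P).  A cluster is flagged
    ``two_site`` when the minor isoform carries at least
    ``min_minor_fraction`` of the abundance *and* the two-isoform fit
    reduces the residual by at least ``min_residual_gain`` relative to the
    best single-isoform (constant) fit.  Returns ``None`` for an all-zero
    gene.
    """
    items = list(coverages.items())
    if not items:
        return None
    L = items[0][1].size
    if any(v.size != L for _, v in items):
        raise ValueError(f"{gene_id}: coverage vectors differ in length")
    if all(float(np.abs(v).sum()) == 0.0 for _, v in items):
        log.info("gene %s: no coverage in any cluster, dropped", gene_id)
        return None
    cand = candidate_sites(L, flank)
    total = np.zeros(cand.size)
    per_cluster = {}
    for k, r in items:
        wl, ws, res = _nnls_profile(np.asarray(r, float), cand)
        per_cluster[k] = (wl, ws, res)
        total += res
    best = int(np.argmin(total))  # argmin returns the first (smallest P) tie
    p_star = int(cand[best])
    fit = IsoformFit(gene_id, p_star, L, {}, {}, {}, {})
    for k, r in items:
        wl, ws, res = per_cluster[k]
        fit.w_long[k] = float(wl[best])
        fit.w_short[k] = float(ws[best])
        fit.residual[k] = float(res[best])
        fit.two_site_clusters[k] = _is_two_site(
            np.asarray(r, float), fit.w_long[k], fit.w_short[k], fit.residual[k],
            min_minor_fraction, min_residual_gain,
        )
    return fit


def _is_two_site(
    r: np.ndarray, wl: float, ws: float, res2: float,
    min_minor_fraction: float, min_residual_gain: float,
) -> bool:
    total = wl + ws
    if total <= 0:
        return False
    if min(wl, ws) / total < min_minor_fraction:
        return False
    mean = max(float(r.mean()), 0.0)
    res1 = float(((r - mean) ** 2).sum())
    if res1 <= 0:
        return False
    return (res1 - res2) / res1 >= min_residual_gain


# ---------------------------------------------------------------------------
# read-level isoform counts
# ---------------------------------------------------------------------------

@dataclass
class IsoformCounts:
    """Raw and CPM long/short isoform counts for one gene and cluster."""

    gene_id: str
    cluster: str
    long_count: int
    short_count: int
    cpm_long: float
    cpm_short: float

    @property
    def total(self) -> int:
        return self.long_count + self.short_count


def assign_isoform_counts(
    padded_ends: Sequence[int] | np.ndarray,
    proximal_site: int,
    depth: int,
    gene_id: str = "",
    cluster: str = "",
) -> IsoformCounts:
    """Classify each padded read end against P: e > P is a long-isoform read."""
    ends = np.asarray(padded_ends)
    long_n = int((ends > proximal_site).sum())
    short_n = int(ends.size - long_n)
    scale = 1e6 / depth
    return IsoformCounts(gene_id, cluster, long_n, short_n, long_n * scale, short_n * scale)


# ---------------------------------------------------------------------------
# internal-priming filter
# ---------------------------------------------------------------------------

def flag_internal_priming(downstream_seq: str) -> bool:
    """Internal-priming heuristic on the 10 nt downstream of the called site.

    True iff the sequence contains a run of >7 consecutive adenines allowing
    up to 1 mismatch — i.e. some window of 8 bases holds at least 7 'A'.
    'N' never counts as adenine.
    """
    s = downstream_seq.upper()
    if len(s) < 8:
        return False
    is_a = np.frombuffer(s.encode(), dtype=np.uint8) == ord("A")
    window = np.convolve(is_a.astype(int), np.ones(8, int), mode="valid")
    return bool((window >= 7).any())


# ---------------------------------------------------------------------------
# >2-site LASSO extension
# ---------------------------------------------------------------------------

@dataclass
class MultiSiteFit:
    """Sparse non-negative solution of C = M W + L1 penalty."""

    gene_id: str
    weights: np.ndarray  # (L, n_clusters)
    lam: float
    active_sites: list[int] = field(default_factory=list)


def _nn_lasso_column(c: np.ndarray, lam: float, w0: np.ndarray,
                     max_iter: int = 20000, tol: float = 1e-10) -> np.ndarray:
    """Coordinate descent for 0.5||c - M w||^2 + lam ||w||_1, w >= 0.

    M is upper-triangular ones: column l is 1 on rows 0..l, so M w is the
    reversed cumulative sum of w and the inner products reduce to prefix
    sums of the residual — each sweep is O(L).
    """
    L = c.size
    w = w0.copy()
    fitted = np.cumsum(w[::-1])[::-1]  # M @ w
    norms = np.arange(1, L + 1, dtype=float)
    delta = np.inf
    for _ in range(max_iter):
        delta = 0.0
        prefix0 = np.cumsum(c - fitted)
        shift = 0.0  # running sum of (l+1)*d over coordinates updated this sweep
        for l in range(L):
            rho = (prefix0[l] - shift) + norms[l] * w[l]
            new = max(0.0, (rho - lam) / norms[l])
            d = new - w[l]
            if d != 0.0:
                shift += norms[l] * d
                w[l] = new
                delta = max(delta, abs(d))
        fitted = np.cumsum(w[::-1])[::-1]
        if delta < tol:
            return w
    raise RuntimeError(
        f"non-negative LASSO did not converge in {max_iter} sweeps "
        f"(lam={lam}, last delta={delta:.3g})"
    )


def fit_multi_site(
    coverage_matrix: np.ndarray,
    lam: float | str = "auto",
    max_sites: int = 4,
    gene_id: str = "",
    active_tol: float = 1e-6,
) -> MultiSiteFit:
    """Detect up to ``max_sites`` pA sites from an L x n coverage matrix.

    Rows are transcript positions, columns cell clusters.  ``lam`` may be a
    number, or ``"auto"`` to pick the value minimising BIC along a
    logarithmic path.  If more than ``max_sites`` rows stay active, the
    penalty is increased along the path until the budget is met.
    """
    C = np.asarray(coverage_matrix, dtype=np.float64)
    if C.ndim != 2:
        raise ValueError("coverage matrix must be 2-D (positions x clusters)")
    L, n = C.shape
    scale = max(np.abs(C).max(), 1e-12)
    lam_max = scale * L  # above this every coordinate soft-thresholds to 0
    path = lam_max * np.logspace(-8, 0, 25)

    def solve(lam_value: float) -> np.ndarray:
        W = np.zeros_like(C)
        for j in range(n):
            W[:, j] = _nn_lasso_column(C[:, j], lam_value, W[:, j])
        return W

    def active(W: np.ndarray) -> np.ndarray:
        return np.where(np.linalg.norm(W, axis=1) > active_tol * scale)[0]

    if lam == "auto":
        best = None
        for lam_value in path:
            W = solve(lam_value)
            act = active(W)
            rss = float(((C - _design_apply(W)) ** 2).sum())
            nobs = C.size
            bic = nobs * math.log(max(rss / nobs, 1e-300)) + act.size * math.log(nobs)
            if (best is None or bic < best[0]) and act.size <= max_sites:
                best = (bic, lam_value, W, act)
        if best is None:  # fall back to the strongest penalty
            lam_value = path[-1]
            W = solve(lam_value)
            best = (0.0, lam_value, W, active(W))
        _, lam_value, W, act = best
    else:
        lam_value = float(lam)
        W = solve(lam_value)
        act = active(W)
        while act.size > max_sites:
            lam_value *= 2.0
            W = solve(lam_value)
            act = active(W)
    sites = [int(i) + 1 for i in act]  # transcript coordinates are 1-based
    return MultiSiteFit(gene_id, W, float(lam_value), sites)


def _design_apply(W: np.ndarray) -> np.ndarray:
    """M @ W for the upper-triangular all-ones design."""
    return np.cumsum(W[::-1], axis=0)[::-1]
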