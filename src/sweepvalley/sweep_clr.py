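"""SFS-based composite-likelihood-ratio sweep scan.

The scan contrasts, at each candidate position x on a grid, the composite
likelihood of the observed per-site derived-allele classes under a neutral
background spectrum against a sweep model in which each lineage escapes the
sweep independently with probability ``p_e = 1 - exp(-alpha * d)`` at
distance ``d`` from x.  Lineages that do not escape descend from the single
sweeping haplotype, so the post-sweep spectrum at distance d is a mixture
over the binomial number of escapees of a hypergeometric down-projection of
the background spectrum.  The statistic is ``2 * (max_alpha log CL_sweep -
log CL_neutral)``, floored at zero, maximized over a log-spaced alpha grid
with golden-section refinement.

Invariant columns participate: every column that is not a polymorphic site
of the focal sample is scored as class 0.  Because the null thresholds are
calibrated on simulations of the focal (European) sample only, columns fixed
for the derived allele are deliberately scored the same way, keeping the
null and the observed data processing identical (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .alignment_io import NUCLEOTIDES, SiteTable
from .popgen_stats import SFS

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ScanResult:
    """Per-grid-position values of a sweep statistic."""

    grid: np.ndarray
    values: np.ndarray
    nuisance: np.ndarray  # optimizing alpha (CLR) or (window, split) packed (omega)
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def argmax_position(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])

    @property
    def max_value(self) -> float:
        return float(np.max(self.values))

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.max_value > self.threshold

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(dict(position=self.grid, value=self.values))


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _escape_transfer_tensor(n: int) -> np.ndarray:
    """M[E, i, j]: P(final class i | background class j, E escapees), E=0..n.

    For E < n the n-E swept lineages collapse into one founder among
    m = E+1; the founders are a hypergeometric subsample of size m of the
    background sample of size n.  If j of the m founders are derived, the
    final derived count is (n-E)+(j-1) with probability j/m (the swept
    founder is derived) and j otherwise.  E = n leaves the sample untouched.
    """
    M = np.zeros((n + 1, n + 1, n + 1))
    ks = np.arange(n + 1)
    for E in range(n):
        m = E + 1
        # hypergeometric projection P[j, k] = P(j derived among m | k among n)
        P = np.zeros((m + 1, n + 1))
        for k in range(n + 1):
            j = np.arange(max(0, m - (n - k)), min(m, k) + 1)
            P[j, k] = np.exp(
                _log_binom(k, j) + _log_binom(n - k, m - j) - _log_binom(n, np.array([m]))
            )
        A = np.zeros((n + 1, m + 1))
        for j in range(m + 1):
            pj = j / m
            A[(n - E) + (j - 1) if j > 0 else 0, j] += pj
            A[j, j] += 1.0 - pj
        M[E] = A @ P
    M[n] = np.eye(n + 1)
    return M


def post_sweep_sfs(background: SFS, alpha: float, d: float, n: int) -> SFS:
    """Expected sample spectrum at distance ``d`` from a sweep of strength ``alpha``."""
    if not background.normalized:
        raise ValueError("background spectrum must be normalized")
    if background.n != n:
        raise ValueError("background sample size mismatch")
    if alpha < 0 or d < 0:
        raise ValueError("alpha and d must be non-negative")
    pe = -math.expm1(-alpha * d)
    M = _escape_transfer_tensor(n)
    E = np.arange(n + 1)
    w = np.zeros(n + 1)
    if pe <= 0.0:
        w[0] = 1.0
    elif pe >= 1.0:
        w[n] = 1.0
    else:
        logw = (_log_binom(n, E) + E * math.log(pe)
                + (n - E) * math.log1p(-pe))
        w = np.exp(logw)
        w /= w.sum()
    q = np.einsum("e,eij,j->i", w, M, background.counts)
    q = np.maximum(q, 0.0)
    return SFS(n, q / q.sum(), normalized=True)


class SweepSpectrumTable:
    """log q_k(p_e) tabulated on a fine escape-probability grid."""

    def __init__(self, background: SFS, n_pe: int = 2048, floor: float = 1e-300):
        if not background.normalized:
            raise ValueError("background spectrum must be normalized")
        n = background.n
        self.n = n
        M = _escape_transfer_tensor(n)
        C = np.einsum("eij,j->ei", M, background.counts)  # (E, class)
        self.pe_grid = np.linspace(0.0, 1.0, n_pe)
        E = np.arange(n + 1)
        lb = _log_binom(n, E)
        with np.errstate(divide="ignore", invalid="ignore"):
            logw = (lb[None, :] + E[None, :] * np.log(self.pe_grid[:, None])
                    + (n - E)[None, :] * np.log1p(-self.pe_grid[:, None]))
        logw[0] = -np.inf
        logw[0, 0] = 0.0
        logw[-1] = -np.inf
        logw[-1, -1] = 0.0
        W = np.exp(logw - logw.max(axis=1, keepdims=True))
        W /= W.sum(axis=1, keepdims=True)
        q = W @ C  # (n_pe, class)
        self.logq = np.log(np.maximum(q, floor))  # (n_pe, n+1)
        self.log_background = np.log(np.maximum(background.counts, floor))

    def lookup(self, classes: np.ndarray, pe: np.ndarray) -> np.ndarray:
        """log q_{class}(pe), nearest-grid-point interpolation."""
        idx = np.clip(
            np.rint(pe * (len(self.pe_grid) - 1)).astype(np.int64),
            0, len(self.pe_grid) - 1,
        )
        return self.logq[idx, classes]


def default_alpha_grid(L: int, n_alpha: int = 64) -> np.ndarray:
    """Log-spaced alphas spanning edge escape probabilities ~1e-4 .. ~0.9999."""
    lo = -math.log1p(-1e-4) / L
    hi = -math.log1p(-0.9999) / L
    return np.geomspace(lo, hi, n_alpha)


def regularize_background(background: SFS, pseudocount: float = 0.5,
                          effective_sites: float = 20011.0) -> SFS:
    """Give zero-mass classes a pseudocount of ``pseudocount`` sites.

    The spectrum is interpreted as proportions of ``effective_sites``
    columns; classes with zero mass receive pseudocount/effective_sites
    before renormalization, so no observed class has -inf log-likelihood.
    """
    counts = background.counts.copy()
    tot = counts.sum()
    if tot <= 0:
        raise ValueError("empty background spectrum")
    counts = counts / tot
    zero = counts <= 0
    if zero.any():
        counts[zero] = pseudocount / effective_sites
    return SFS(background.n, counts).normalize()


@dataclass
class _PreparedSites:
    positions: np.ndarray  # polymorphic site positions (bp)
    classes: np.ndarray    # derived classes, 1..n-1
    L: int
    n: int
    n_invariant: int       # columns scored as class 0


def prepare_clr_sites(table: SiteTable, population: str) -> _PreparedSites:
    """Site classes for the scan: focal-sample polymorphisms, rest invariant."""
    n = table.sample_sizes[population]
    pos, cls = [], []
    for rec in table:
        if rec.kind in ("indel", "masked") or rec.derived_allele is None:
            continue
        counts = rec.allele_counts[population]
        alleles = [a for a in counts if a in NUCLEOTIDES]
        if len(alleles) < 2:
            continue
        k = rec.derived_count_per_pop[population]
        if 0 < k < n:
            pos.append(rec.column)
            cls.append(k)
    positions = np.asarray(pos, dtype=float)
    classes = np.asarray(cls, dtype=np.int64)
    return _PreparedSites(positions, classes, table.L, n,
                          table.L - len(positions))


def sites_from_replicate(rep, population: str) -> _PreparedSites:
    """Scan input from a simulated replicate (0 = ancestral)."""
    h = rep.haplotypes[population]
    n = h.shape[0]
    k = h.sum(axis=0).astype(np.int64)
    seg = (k > 0) & (k < n)
    positions = rep.positions[seg].astype(float)
    return _PreparedSites(positions, k[seg], rep.L, n, rep.L - int(seg.sum()))


def _distance_bins(L: int, n_bins: int = 96) -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate([[0.0], np.geomspace(1.0, float(L), n_bins)])
    centers = np.sqrt(np.maximum(edges[:-1], 0.25) * edges[1:])
    return edges, centers


def clr_scan_sites(sites: _PreparedSites, background: SFS,
                   grid_size: int = 1000, alpha_grid: np.ndarray | None = None,
                   refine: bool = True, refine_tol: float = 1e-6,
                   ) -> ScanResult:
    """CLR over a positional grid for prepared site classes."""
    n, L = sites.n, sites.L
    bg = regularize_background(
        background if background.normalized else background.normalize()
    )
    table = SweepSpectrumTable(bg)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(L)
    grid = np.linspace(1.0, float(L), grid_size)

    # invariant columns: distance histogram per grid point (geometric bins)
    edges, centers = _distance_bins(L)
    all_cols = np.arange(1, L + 1, dtype=float)
    inv_cols = np.setdiff1d(all_cols, sites.positions)
    lo = grid[:, None] - edges[None, :]
    hi = grid[:, None] + edges[None, :]
    left = np.searchsorted(inv_cols, lo[:, ::-1])     # descending -> ascending
    right = np.searchsorted(inv_cols, hi, side="right")
    cnt_left = np.diff(left, axis=1)[:, ::-1]
    cnt_right = np.diff(right, axis=1)
    counts0 = (cnt_left + cnt_right).astype(float)    # (grid, bins)

    D = np.abs(sites.positions[None, :] - grid[:, None])  # (grid, S)

    ll_neutral = (sites.n_invariant * table.log_background[0]
                  + table.log_background[sites.classes].sum())

    npe = len(table.pe_grid)
    logq_by_site = table.logq[:, sites.classes] if sites.positions.size else None
    site_idx = np.arange(sites.positions.size)[None, :]

    def ll_for_alpha(alpha: np.ndarray) -> np.ndarray:
        """Composite log-likelihood per grid point; alpha per grid point."""
        a = np.asarray(alpha, dtype=float).reshape(-1, 1)
        pe0 = -np.expm1(-a * centers[None, :])        # (grid, bins)
        idx0 = np.clip(np.rint(pe0 * (npe - 1)).astype(np.int64), 0, npe - 1)
        ll = np.sum(counts0 * table.logq[idx0, 0], axis=1)
        if logq_by_site is not None:
            pe = -np.expm1(-a * D)
            idx = np.clip(np.rint(pe * (npe - 1)).astype(np.int64), 0, npe - 1)
            ll = ll + logq_by_site[idx, site_idx].sum(axis=1)
        return ll

    best_ll = np.full(grid_size, -np.inf)
    best_alpha = np.zeros(grid_size)
    for a in alpha_grid:
        ll = ll_for_alpha(np.full(grid_size, a))
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_alpha[better] = a

    if refine and len(alpha_grid) > 2:
        ia = np.searchsorted(alpha_grid, best_alpha)
        lo_a = alpha_grid[np.maximum(ia - 1, 0)]
        hi_a = alpha_grid[np.minimum(ia + 1, len(alpha_grid) - 1)]
        a1 = hi_a - GOLDEN * (hi_a - lo_a)
        a2 = lo_a + GOLDEN * (hi_a - lo_a)
        f1 = ll_for_alpha(a1)
        f2 = ll_for_alpha(a2)
        for _ in range(40):
            if np.max((hi_a - lo_a) / np.maximum(lo_a, 1e-300)) < refine_tol:
                break
            take1 = f1 >= f2
            hi_a = np.where(take1, a2, hi_a)
            lo_a = np.where(take1, lo_a, a1)
            a1n = hi_a - GOLDEN * (hi_a - lo_a)
            a2n = lo_a + GOLDEN * (hi_a - lo_a)
            fmid = ll_for_alpha(np.where(take1, a1n, a2n))
            f2 = np.where(take1, f1, fmid)
            f1 = np.where(take1, fmid, f1)
            a2 = np.where(take1, a1, a2n)
            a1 = np.where(take1, a1n, a1)
        mid = 0.5 * (lo_a + hi_a)
        fm = ll_for_alpha(mid)
        better = fm > best_ll
        best_ll[better] = fm[better]
        best_alpha[better] = mid[better]

    values = np.maximum(2.0 * (best_ll - ll_neutral), 0.0)
    return ScanResult(grid=grid, values=values, nuisance=best_alpha)


def clr_scan(table: SiteTable, background: SFS, population: str,
             grid_size: int = 1000, alpha_grid: np.ndarray | None = None,
             refine: bool = True) -> ScanResult:
    """CLR scan of a classified alignment for one population."""
    sites = prepare_clr_sites(table, population)
    bad = (sites.classes < 0) | (sites.classes > sites.n)
    if bad.any():
        raise ValueError("derived count outside 0..n")
    return clr_scan_sites(sites, background, grid_size, alpha_grid, refine)


def background_from_simulations(sims, n: int, population: str = "EU") -> SFS:
    """Pooled neutral spectrum (classes 0..n) from simulated replicates."""
    counts = np.zeros(n + 1)
    total = 0
    for rep in sims:
        h = rep.haplotypes[population]
        if h.shape[0] != n:
            raise ValueError("sample-size mismatch with background n")
        k = h.sum(axis=0).astype(np.int64)
        hist = np.bincount(k[k > 0], minlength=n + 1)
        counts += hist
        counts[0] += rep.L - int((k > 0).sum())
        total += rep.L
    if total == 0:
        raise ValueError("no sites in simulations")
    return SFS(n, counts).normalize()


def clr_max_statistic(background: SFS, population: str = "EU",
                      grid_size: int = 1000, refine: bool = True):
    """Evaluator mapping a simulated replicate to its CLR_max (for calibration)."""

    def stat(rep) -> float:
        res = clr_scan_sites(sites_from_replicate(rep, population), background,
                             grid_size=grid_size, refine=refine)
        return res.max_value

    return stat
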