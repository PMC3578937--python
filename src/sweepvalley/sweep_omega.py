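"""Linkage-disequilibrium omega statistic and its positional scan.

A completed sweep leaves strong LD within each flank of the selected site
but little LD across it.  For S biallelic sites split after site l, omega is
the ratio of the average r-squared within the two blocks to the average
r-squared between them:

    omega = [ (C(l,2) + C(S-l,2))^-1 (sum_{i<j<=l} r2_ij + sum_{l<i<j} r2_ij) ]
            / [ (l (S-l))^-1 sum_{i<=l<j} r2_ij ]

The scan maximizes omega jointly over a ladder of window sizes
(2-10 kb by default) and the split point within each window, for each
position of a regular grid.  A zero between-block sum with a positive
numerator yields an infinite sentinel; threshold calibration caps such
values at a high finite percentile of the null.

Singleton sites carry no linkage information and are excluded by default
(minor allele count >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import NUCLEOTIDES, SiteTable
from .sweep_clr import ScanResult

WINDOW_LADDER = (2000.0, 2830.0, 4000.0, 5660.0, 8000.0, 10000.0)


@dataclass
class HaplotypeMatrix:
    """0/1 haplotypes (rows) at biallelic sites (columns) with bp positions."""

    matrix: np.ndarray    # (n_hap, S) int8; -1 for missing
    positions: np.ndarray  # strictly increasing bp
    L: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions/columns mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    def filtered(self, min_mac: int = 2) -> "HaplotypeMatrix":
        """Keep sites with both alleles at count >= min_mac (missing ignored)."""
        m = self.matrix
        valid = m >= 0
        ones = np.where(valid, m, 0).sum(axis=0)
        called = valid.sum(axis=0)
        mac = np.minimum(ones, called - ones)
        keep = mac >= min_mac
        return HaplotypeMatrix(m[:, keep], self.positions[keep], self.L)


def haplotypes_from_alignment(aln, population: str, table: SiteTable | None = None,
                              min_mac: int = 2) -> HaplotypeMatrix:
    """Biallelic 0/1 haplotype matrix for one population of an alignment."""
    from .alignment_io import classify_sites

    if table is None:
        table = classify_sites(aln)
    idx = aln.population_indices(population)
    n = len(idx)
    cols, pos = [], []
    for rec in table:
        if rec.kind in ("indel", "masked"):
            continue
        symbols = [aln.sequences[i][rec.column - 1] for i in idx]
        alleles = sorted(set(symbols) & NUCLEOTIDES)
        if len(alleles) != 2 or any(s not in NUCLEOTIDES for s in symbols):
            continue
        counts = {a: symbols.count(a) for a in alleles}
        if rec.derived_allele in alleles:
            one = rec.derived_allele
        else:
            one = min(alleles, key=lambda a: counts[a])
        cols.append(np.array([1 if s == one else 0 for s in symbols], dtype=np.int8))
        pos.append(rec.column)
    mat = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    return HaplotypeMatrix(mat, np.asarray(pos, dtype=float), aln.L).filtered(min_mac)


def haplotypes_from_replicate(rep, population: str, min_mac: int = 2
                              ) -> HaplotypeMatrix:
    h = rep.haplotypes[population]
    k = h.sum(axis=0)
    seg = (k > 0) & (k < h.shape[0])
    return HaplotypeMatrix(h[:, seg], rep.positions[seg].astype(float),
                           rep.L).filtered(min_mac)


def r2_pair(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """r-squared between two 0/1 columns on their shared non-missing rows.

    Returns NaN when either column is monomorphic on the shared rows
    (the pair is then dropped from omega sums).
    """
    x = np.asarray(col_i, dtype=float)
    y = np.asarray(col_j, dtype=float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return float("nan")
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (x * y).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def r2_matrix(hap: HaplotypeMatrix) -> np.ndarray:
    """Full S x S r-squared matrix (NaN diagonal-excluded pairs as NaN)."""
    m = hap.matrix.astype(float)
    if np.any(hap.matrix < 0):
        S = hap.S
        out = np.full((S, S), np.nan)
        for i in range(S):
            for j in range(i + 1, S):
                out[i, j] = out[j, i] = r2_pair(hap.matrix[:, i], hap.matrix[:, j])
        np.fill_diagonal(out, 1.0)
        return out
    n = m.shape[0]
    p = m.mean(axis=0)
    pab = (m.T @ m) / n
    num = (pab - np.outer(p, p)) ** 2
    den = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def omega_at_split(r2: np.ndarray, l: int) -> float:
    """Omega for the split after site ``l`` (1-based count of left-block sites)."""
    S = r2.shape[0]
    if not (2 <= l <= S - 2):
        raise ValueError("split must leave >= 2 sites in each block")
    iu = np.triu_indices(S, k=1)
    vals = r2[iu]
    left = (iu[0] < l) & (iu[1] < l)
    right = (iu[0] >= l) & (iu[1] >= l)
    between = ~(left | right)

    def _nanmean(v):
        v = v[np.isfinite(v)]
        return (v.mean(), len(v)) if len(v) else (np.nan, 0)

    mw_l, _ = _nanmean(vals[left])
    mw_r, _ = _nanmean(vals[right])
    within = np.concatenate([vals[left], vals[right]])
    mw, nw = _nanmean(within)
    mb, nb = _nanmean(vals[between])
    if nw == 0 or nb == 0:
        return float("nan")
    if mb == 0.0:
        return float("inf") if mw > 0 else float("nan")
    return float(mw / mb)


def _prefix(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2D prefix sums of values (NaN as 0) and of finite-indicator."""
    finite = np.isfinite(mat)
    vals = np.where(finite, mat, 0.0)
    P = np.zeros((mat.shape[0] + 1, mat.shape[1] + 1))
    C = np.zeros_like(P)
    P[1:, 1:] = vals.cumsum(0).cumsum(1)
    C[1:, 1:] = finite.astype(float).cumsum(0).cumsum(1)
    return P, C


def _block(P: np.ndarray, r0: int, r1: np.ndarray, c0, c1) -> np.ndarray:
    """Sum of P-source over rows [r0, r1) x cols [c0, c1) (vectorized)."""
    return P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]


def _omega_from_blocks(P, C, a, ls, b):
    """Vectorized omega for left blocks [a, ls) and right blocks [ls, b)."""
    wl = _block(P, a, ls, a, ls)
    cl = _block(C, a, ls, a, ls)
    wr = _block(P, ls, b, ls, b)
    cr = _block(C, ls, b, ls, b)
    bt = _block(P, a, ls, ls, b)
    cb = _block(C, a, ls, ls, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (wl + wr) / (cl + cr)
        den = bt / cb
        om = num / den
    om = np.where((cl + cr > 0) & (cb > 0), om, np.nan)
    om = np.where(np.asarray(den == 0) & (num > 0) & (cb > 0), np.inf, om)
    return om


def omega_scan(hap: HaplotypeMatrix, min_window: float = 2000.0,
               max_window: float = 10000.0, grid: int = 1000,
               window_ladder: tuple = WINDOW_LADDER,
               split: str = "center",
               L: float | None = None) -> ScanResult:
    """Max omega per grid position over flanking-window sizes.

    With ``split="center"`` (default) the split between the two LD blocks is
    the grid position itself -- the assumed selected site -- and the outer
    borders of the flanks vary over the window ladder, each flank requiring
    at least two sites.  With ``split="free"`` the split point is also
    maximized over within each centered window.  Ties go to the smaller
    window, then the leftmost center.
    """
    if L is None:
        L = hap.L if hap.L else (hap.positions[-1] if hap.S else 1.0)
    ladder = [w for w in window_ladder if min_window <= w <= max_window]
    if not ladder:
        ladder = [min_window, max_window]
    grid_pos = np.linspace(1.0, float(L), grid)
    values = np.zeros(grid)
    nuisance = np.zeros((grid, 2))  # chosen (window, split-position)
    if hap.S < 4:
        return ScanResult(grid=grid_pos, values=values, nuisance=nuisance)
    R = r2_matrix(hap)
    upper = np.triu(np.ones_like(R, dtype=bool), k=1)
    P, C = _prefix(np.where(upper, R, np.nan))
    pos = hap.positions

    if split == "center":
        ls = np.searchsorted(pos, grid_pos)  # first site right of center
        for w in ladder:
            a = np.searchsorted(pos, grid_pos - w / 2.0)
            b = np.searchsorted(pos, grid_pos + w / 2.0, side="right")
            ok = (ls - a >= 2) & (b - ls >= 2)
            om = np.where(ok, _omega_from_blocks(P, C, a, ls, b), np.nan)
            om = np.where(np.isnan(om), -np.inf, om)
            better = om > values
            values[better] = om[better]
            nuisance[better, 0] = w
            nuisance[better, 1] = grid_pos[better]
        return ScanResult(grid=grid_pos, values=values, nuisance=nuisance)

    if split != "free":
        raise ValueError("split must be 'center' or 'free'")
    for gi, x in enumerate(grid_pos):
        best, best_w, best_split = 0.0, 0.0, 0.0
        for w in ladder:
            a = int(np.searchsorted(pos, x - w / 2.0))
            b = int(np.searchsorted(pos, x + w / 2.0, side="right"))
            if b - a < 4:
                continue
            lss = np.arange(a + 2, b - 1)
            om = _omega_from_blocks(P, C, a, lss, np.full_like(lss, b))
            om_clean = np.where(np.isnan(om), -np.inf, om)
            k = int(np.argmax(om_clean))
            if om_clean[k] > best:
                best = float(om_clean[k])
                best_w = w
                best_split = float(pos[lss[k] - 1])
        values[gi] = best
        nuisance[gi] = (best_w, best_split)
    return ScanResult(grid=grid_pos, values=values, nuisance=nuisance)


def omega_max_statistic(population: str = "EU", min_window: float = 2000.0,
                        max_window: float = 10000.0, grid: int = 1000,
                        min_mac: int = 2):
    """Evaluator mapping a simulated replicate to its omega_max (for calibration)."""

    def stat(rep) -> float:
        hap = haplotypes_from_replicate(rep, population, min_mac=min_mac)
        res = omega_scan(hap, min_window, max_window, grid)
        return res.max_value

    return stat
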