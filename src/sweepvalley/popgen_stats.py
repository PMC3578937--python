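"""Classical population-genetic summary statistics on classified sites.

Implements Watterson's theta, nucleotide diversity (pi), Tajima's D, sliding
windows, unfolded site-frequency spectra with invariant classes, per-site
divergence to the outgroup, a Wilcoxon rank-sum comparison of window
diversities and an upper-tail binomial test for the clustering of derived
alleles in a sub-segment.

Conventions (matching the usual DnaSP behaviour): columns containing gaps
are excluded from S, pi, theta_W and divergence, with the effective number
of sites reduced accordingly; Tajima's D is undefined (None) when S = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .alignment_io import NUCLEOTIDES, SiteTable


@lru_cache(maxsize=None)
def stat_constants(n: int) -> "StatConstants":
    return StatConstants(n)


class StatConstants:
    """The n-dependent constants of Tajima's D (a1, a2, b1, b2, c1, c2, e1, e2)."""

    def __init__(self, n: int):
        if n < 2:
            raise ValueError("sample size must be >= 2")
        self.n = n
        i = np.arange(1, n)
        self.a1 = float(np.sum(1.0 / i))
        self.a2 = float(np.sum(1.0 / i**2))
        self.b1 = (n + 1) / (3.0 * (n - 1))
        self.b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        self.c1 = self.b1 - 1.0 / self.a1
        self.c2 = self.b2 - (n + 2) / (self.a1 * n) + self.a2 / self.a1**2
        self.e1 = self.c1 / self.a1
        self.e2 = self.c2 / (self.a1**2 + self.a2)


def watterson_theta(S: int, n: int, L: int) -> float:
    """Per-site Watterson estimator S / (a1 * L)."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if L < 1:
        raise ValueError("number of sites must be >= 1")
    if S < 0:
        raise ValueError("negative segregating-site count")
    return S / (stat_constants(n).a1 * L)


def _site_heterozygosity(counts: dict[str, int]) -> tuple[float, int]:
    """Unbiased per-site pairwise diversity and the called sample size."""
    ns = sum(c for a, c in counts.items() if a in NUCLEOTIDES)
    if ns < 2:
        return 0.0, ns
    h = 1.0 - sum((c / ns) ** 2 for a, c in counts.items() if a in NUCLEOTIDES)
    return ns / (ns - 1) * h, ns


def pairwise_diversity_total(table: SiteTable, population: str) -> float:
    """Sum over usable sites of unbiased pairwise heterozygosity (pi * L_eff)."""
    tot = 0.0
    for rec in table:
        if rec.kind in ("indel", "masked"):
            continue
        h, _ = _site_heterozygosity(rec.allele_counts[population])
        tot += h
    return tot


def nucleotide_diversity(table: SiteTable, population: str, L: int) -> float:
    """Per-site nucleotide diversity pi for one population."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if population not in table.populations:
        raise ValueError(f"unknown population {population!r}")
    return pairwise_diversity_total(table, population) / L


def segregating_sites(table: SiteTable, population: str) -> int:
    """Columns with >= 2 nucleotide alleles in the population (gap columns excluded)."""
    S = 0
    for rec in table:
        if rec.kind in ("indel", "masked"):
            continue
        alleles = [a for a in rec.allele_counts[population] if a in NUCLEOTIDES]
        if len(alleles) > 1:
            S += 1
    return S


def tajimas_d(S: int, pi_total: float, n: int) -> float | None:
    """Tajima's D from S and the summed pairwise diversity; None when S = 0."""
    if S == 0:
        return None
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    c = stat_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi_total - S / c.a1) / np.sqrt(var)


@dataclass
class WindowStats:
    start: int
    end: int
    n_sites: int  # gap-free columns in the window
    S: int
    pi: float
    theta_w: float
    tajima_d: float | None
    divergence: float | None


def _window_bounds(L: int, window: int, step: int, min_tail_frac: float = 0.5
                   ) -> list[tuple[int, int]]:
    if window > L:
        return [(1, L)]
    bounds = []
    start = 1
    while start <= L:
        end = min(start + window - 1, L)
        bounds.append((start, end))
        if end == L:
            break
        start += step
    # merge a short final partial window into the previous one
    if len(bounds) > 1:
        s, e = bounds[-1]
        if e - s + 1 < min_tail_frac * window:
            bounds[-2] = (bounds[-2][0], e)
            bounds.pop()
    return bounds


def sliding_windows(table: SiteTable, population: str, window: int = 1000,
                    step: int = 500, with_divergence: bool = None,
                    ) -> list[WindowStats]:
    """Per-window S, pi, theta_W, Tajima's D (and divergence when an outgroup exists).

    Windows start at columns 1, 1+step, ...; a final partial window shorter
    than half a window is merged into the previous one.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    n = table.sample_sizes[population]
    has_out = any(r.outgroup_allele in NUCLEOTIDES for r in table)
    if with_divergence is None:
        with_divergence = has_out
    out = []
    for (s, e) in _window_bounds(table.L, window, step):
        recs = [r for r in table.records[s - 1:e] if r.kind not in ("indel", "masked")]
        n_sites = len(recs)
        S = 0
        pi_tot = 0.0
        div_tot, div_sites = 0.0, 0
        for rec in recs:
            counts = rec.allele_counts[population]
            alleles = [a for a in counts if a in NUCLEOTIDES]
            if len(alleles) > 1:
                S += 1
            h, _ = _site_heterozygosity(counts)
            pi_tot += h
            if with_divergence and rec.outgroup_allele in NUCLEOTIDES:
                ns = sum(counts.values())
                if ns > 0:
                    div_tot += (ns - counts.get(rec.outgroup_allele, 0)) / ns
                    div_sites += 1
        if n_sites == 0:
            out.append(WindowStats(s, e, 0, 0, 0.0, 0.0, None, None))
            continue
        out.append(
            WindowStats(
                start=s, end=e, n_sites=n_sites, S=S,
                pi=pi_tot / n_sites,
                theta_w=watterson_theta(S, n, n_sites),
                tajima_d=tajimas_d(S, pi_tot, n),
                divergence=(div_tot / div_sites) if (with_divergence and div_sites) else None,
            )
        )
    return out


def windows_to_dataframe(windows: list[WindowStats]):
    import pandas as pd

    return pd.DataFrame(
        dict(start=w.start, end=w.end, n_sites=w.n_sites, S=w.S, pi=w.pi,
             theta_w=w.theta_w, tajima_d=w.tajima_d, divergence=w.divergence)
        for w in windows
    )


@dataclass
class SFS:
    """Unfolded site-frequency spectrum over derived-allele classes 0..n."""

    n: int
    counts: np.ndarray  # length n+1
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n + 1:
            raise ValueError("counts must have length n+1 (classes 0..n)")
        if np.any(self.counts < 0):
            raise ValueError("negative SFS entries")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-12:
            raise ValueError("normalized SFS must sum to 1")

    def normalize(self) -> "SFS":
        tot = self.counts.sum()
        if tot <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return SFS(self.n, self.counts / tot, normalized=True)

    def drop_invariant(self) -> np.ndarray:
        return self.counts[1:-1].copy()

    def fold(self) -> np.ndarray:
        """Minor-allele-class spectrum (classes 0..n//2)."""
        c = self.counts
        folded = np.zeros(self.n // 2 + 1)
        for k in range(self.n + 1):
            m = min(k, self.n - k)
            folded[m] += c[k] if (k != self.n - k) else c[k]
        return folded


def sfs_from_table(table: SiteTable, population: str,
                   include_invariant: bool = True,
                   polarize_via_joint: bool = True) -> SFS:
    """Unfolded SFS of one population from a polarized SiteTable.

    Segregating sites with a determined derived allele contribute their
    derived count k.  With ``polarize_via_joint``, columns monomorphic in
    the focal population are assigned to class 0 (population carries the
    ancestral allele) or class n (population fixed for the derived allele,
    as determined from the combined sample and the outgroup).  Columns that
    cannot be polarized, contain gaps, or are masked are skipped.
    """
    n = table.sample_sizes[population]
    counts = np.zeros(n + 1)
    for rec in table:
        if rec.kind in ("indel", "masked"):
            continue
        pop_counts = rec.allele_counts[population]
        alleles = [a for a in pop_counts if a in NUCLEOTIDES]
        ns = sum(pop_counts[a] for a in alleles)
        if ns != n:
            continue  # incomplete call; class ambiguous
        seg_in_pop = len(alleles) > 1
        if rec.derived_allele is not None:
            k = rec.derived_count_per_pop[population]
            if seg_in_pop or polarize_via_joint:
                counts[k] += 1
        elif not seg_in_pop and polarize_via_joint \
                and rec.outgroup_allele in NUCLEOTIDES:
            counts[0] += 1  # monomorphic, allele shared with the outgroup
    if not include_invariant:
        counts[0] = 0.0
        counts[n] = 0.0
    return SFS(n, counts)


def divergence(table: SiteTable, population: str, L: int | None = None) -> float:
    """Mean per-site divergence of a population sample to the outgroup.

    Averaged over non-gap, non-missing columns where the outgroup is called;
    ``L`` overrides the denominator (defaults to the usable column count).
    """
    tot, used = 0.0, 0
    for rec in table:
        if rec.kind in ("indel", "masked"):
            continue
        if rec.outgroup_allele not in NUCLEOTIDES:
            continue
        counts = rec.allele_counts[population]
        ns = sum(c for a, c in counts.items() if a in NUCLEOTIDES)
        if ns == 0:
            continue
        tot += (ns - counts.get(rec.outgroup_allele, 0)) / ns
        used += 1
    if used == 0:
        raise ValueError("no outgroup-called columns: is an outgroup present?")
    return tot / (L if L else used)


def wilcoxon_window_test(region_values, baseline_values) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two window sets.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise.  Returns (U statistic, two-sided p).
    """
    x = np.asarray(region_values, dtype=float)
    y = np.asarray(baseline_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.size == 1 and y.size == 1 and x[0] == y[0]:
        return 0.5, 1.0  # degenerate tie: no evidence either way
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def binomial_cluster_test(m: int, observed_in_segment: int, f: float) -> float:
    """Upper-tail binomial probability P(X >= observed), X ~ Binomial(m, f).

    Tests whether ``observed_in_segment`` of ``m`` derived alleles clustering
    in a segment covering fraction ``f`` of the region is surprising.
    """
    if not (0 <= observed_in_segment <= m):
        raise ValueError("need 0 <= observed <= m")
    if not (0 < f <= 1):
        raise ValueError("segment fraction must be in (0, 1]")
    return float(sps.binom.sf(observed_in_segment - 1, m, f))
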