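"""Rejection-ABC inference of the nine demographic parameters.

The data are a genome scan of short sequenced fragments in three population
samples, summarized per population by moments of nucleotide diversity,
Tajima's D and the segregating-site count across fragments -- plus the
number of fragments that are entirely monomorphic in each population.
Monomorphic fragments are usually discarded (D is undefined at S = 0), but
their frequency carries drift information: a bottlenecked population shows
many of them, so including their counts forces the fitted model to explain
variation-free regions by drift before selection is invoked.

Inference is plain rejection ABC: draw parameters from the priors, simulate
a fragment dataset per draw, keep the draws whose summaries are closest to
the observed ones (Euclidean distance on MAD-standardized coordinates), and
report per-parameter posterior modes with 2.5/97.5% quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .coalsim import DemographicModel
from .popgen_stats import tajimas_d

#: Table-ordered parameter names (times in years, sizes in individuals)
PARAM_ORDER = [
    "N_afr_cur", "N_eur_cur", "N_asia_cur",
    "N_eur_bot", "N_asia_bot",
    "T_exit", "T_asia", "T_afr_exp",
    "N_afr_anc",
]

PARAM_LABELS = {
    "N_afr_cur": "Current African population size",
    "N_eur_cur": "Current European population size",
    "N_asia_cur": "Current Asian population size",
    "N_eur_bot": "Bottleneck size of the European population",
    "N_asia_bot": "Bottleneck size of the Asian population",
    "T_exit": "Exit out of Africa",
    "T_asia": "Colonization time of the South-Asian continent",
    "T_afr_exp": "Time of the expansion of the African population",
    "N_afr_anc": "Size of the ancestral African population",
}


@dataclass
class FragmentDataset:
    """Per-fragment, per-population summaries of a multi-locus genome scan."""

    populations: list[str]
    sample_sizes: dict[str, int]
    frag_len: int
    S: np.ndarray         # (n_fragments, K) segregating sites
    pi_total: np.ndarray  # (n_fragments, K) summed pairwise diversity

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.pi_total = np.asarray(self.pi_total, dtype=float)
        if self.S.shape != self.pi_total.shape:
            raise ValueError("S and pi_total shapes differ")
        if self.S.shape[0] < 1:
            raise ValueError("need at least one fragment")

    @property
    def n_fragments(self) -> int:
        return self.S.shape[0]

    def tajima_d(self) -> np.ndarray:
        """(n_fragments, K) Tajima's D; NaN where S = 0."""
        out = np.full(self.S.shape, np.nan)
        for k, pop in enumerate(self.populations):
            n = self.sample_sizes[pop]
            for i in range(self.n_fragments):
                d = tajimas_d(int(self.S[i, k]), self.pi_total[i, k], n)
                out[i, k] = np.nan if d is None else d
        return out

    def monomorphic_counts(self) -> dict[str, int]:
        return {p: int((self.S[:, k] == 0).sum())
                for k, p in enumerate(self.populations)}


@dataclass
class SummaryVector:
    """Fixed-order ABC summaries: per population the across-fragment mean and
    variance of per-site pi, mean and variance of Tajima's D (over fragments
    with S >= 1), mean S -- followed by per-population monomorphic-fragment
    counts."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("names/values mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite summary entries")


def summarize(data: FragmentDataset) -> SummaryVector:
    """Deterministic, fragment-order-invariant ABC summary of a dataset."""
    if data.n_fragments == 0:
        raise ValueError("empty dataset")
    D = data.tajima_d()
    vals, names = [], []
    L = data.frag_len
    for k, pop in enumerate(data.populations):
        pi = data.pi_total[:, k] / L
        dcol = D[:, k]
        dd = dcol[np.isfinite(dcol)]
        mean_d = float(dd.mean()) if dd.size else 0.0
        var_d = float(dd.var(ddof=1)) if dd.size > 1 else 0.0
        vals += [pi.mean(), pi.var(ddof=1) if len(pi) > 1 else 0.0,
                 mean_d, var_d, data.S[:, k].mean()]
        names += [f"{pop}_pi_mean", f"{pop}_pi_var", f"{pop}_D_mean",
                  f"{pop}_D_var", f"{pop}_S_mean"]
    mono = data.monomorphic_counts()
    for pop in data.populations:
        vals.append(float(mono[pop]))
        names.append(f"{pop}_monomorphic")
    return SummaryVector(np.asarray(vals), names)


@dataclass
class Prior:
    """A uniform or log-uniform prior on one parameter."""

    dist: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high) and self.dist == "loguniform":
            raise ValueError("loguniform needs 0 < low < high")
        if self.low >= self.high:
            raise ValueError("need low < high")
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior {self.dist!r}")

    def sample(self, rng, size=None):
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size))


def default_priors(widen: float = 3.0) -> dict[str, Prior]:
    """Log-uniform priors spanning the X-chromosome 95% credible ranges,
    widened by the given factor on each side."""
    ci = {
        "N_afr_cur": (2_392_436, 28_700_928),
        "N_eur_cur": (760_318, 4_866_692),
        "N_asia_cur": (91_417, 4_540_468),
        "N_eur_bot": (10_898, 87_811),
        "N_asia_bot": (3_554, 90_142),
        "T_exit": (7_700, 36_616),
        "T_asia": (1_194, 7_518),
        "T_afr_exp": (2_383, 369_569),
        "N_afr_anc": (580_795, 2_457_912),
    }
    return {k: Prior("loguniform", lo / widen, hi * widen)
            for k, (lo, hi) in ci.items()}


@dataclass
class AbcPosterior:
    """Accepted draws with distances (sorted non-decreasing)."""

    params: dict[str, np.ndarray]  # accepted values per parameter
    distances: np.ndarray
    tolerance: float
    n_sims: int
    param_order: list[str] = field(default_factory=lambda: list(PARAM_ORDER))

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be sorted non-decreasing")

    @property
    def n_accepted(self) -> int:
        return len(self.distances)

    def mode(self, name: str) -> float:
        x = self.params[name]
        if len(np.unique(x)) == 1:
            return float(x[0])
        kde = gaussian_kde(x)  # Silverman-style bandwidth (scipy default)
        grid = np.linspace(x.min(), x.max(), 512)
        return float(grid[int(np.argmax(kde(grid)))])

    def quantiles(self, name: str, qs=(0.025, 0.975)) -> tuple[float, ...]:
        return tuple(float(v) for v in np.quantile(self.params[name], qs))

    def credible_interval(self, name: str) -> tuple[float, float]:
        return self.quantiles(name)


def _draw_parameters(priors: dict[str, Prior], rng) -> dict[str, float]:
    for _ in range(1000):
        draw = {k: float(priors[k].sample(rng)) for k in PARAM_ORDER}
        if draw["T_exit"] > draw["T_asia"]:  # the colonisation order constraint
            return draw
    raise RuntimeError("priors incompatible with T_exit > T_asia")


def abc_reject(observed: SummaryVector, priors: dict[str, Prior],
               n_sims: int, accept_fraction: float = 0.005, seed=None,
               n_fragments: int = 250, frag_len: int = 500,
               samples: dict[str, int] | None = None,
               base_model: DemographicModel | None = None,
               ) -> AbcPosterior:
    """Plain rejection ABC against simulated fragment datasets.

    Each prior draw replaces the nine demographic parameters of
    ``base_model`` (other rates are kept), a fragment dataset of
    ``n_fragments`` x ``frag_len`` bp is simulated and summarized, and the
    ``accept_fraction`` draws with the smallest MAD-standardized Euclidean
    distance to ``observed`` are kept.
    """
    from .synthetic_data import generate_genome_scan

    if n_sims < 1.0 / accept_fraction:
        raise ValueError("n_sims too small for the acceptance fraction")
    if samples is None:
        samples = {"AF": 12, "EU": 12, "AS": 12}
    if base_model is None:
        base_model = DemographicModel()
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(n_sims + 1)[1:]

    draws = np.zeros((n_sims, len(PARAM_ORDER)))
    sums = np.zeros((n_sims, len(observed.values)))
    for i in range(n_sims):
        pars = _draw_parameters(priors, rng)
        draws[i] = [pars[k] for k in PARAM_ORDER]
        model = base_model.with_params(**pars)
        data = generate_genome_scan(model, n_fragments=n_fragments,
                                    frag_len=frag_len, samples=samples,
                                    seed=int(seeds[i]))
        sums[i] = summarize(data).values

    med = np.median(sums, axis=0)
    mad = np.median(np.abs(sums - med), axis=0)
    keep_coord = mad > 0
    if not keep_coord.all():
        dropped = [observed.names[j] for j in np.nonzero(~keep_coord)[0]]
        warnings.warn(f"degenerate summaries dropped: {dropped}")
    if not keep_coord.any():
        raise ValueError("all summary coordinates degenerate")
    z_sims = (sums[:, keep_coord] - med[keep_coord]) / mad[keep_coord]
    z_obs = (observed.values[keep_coord] - med[keep_coord]) / mad[keep_coord]
    dist = np.sqrt(((z_sims - z_obs) ** 2).sum(axis=1))

    n_acc = max(1, int(round(n_sims * accept_fraction)))
    order = np.argsort(dist, kind="stable")[:n_acc]
    order = order[np.argsort(dist[order], kind="stable")]
    return AbcPosterior(
        params={k: draws[order, j] for j, k in enumerate(PARAM_ORDER)},
        distances=dist[order],
        tolerance=float(dist[order][-1]),
        n_sims=n_sims,
    )


def posterior_report(post: AbcPosterior, min_accepted: int = 50):
    """Table of (parameter, mode, Q2.5, Q97.5) in the canonical row order.

    Times are in years, sizes in effective individuals (the units the
    parameters are sampled in).
    """
    import pandas as pd

    if post.n_accepted < min_accepted:
        raise ValueError(
            f"only {post.n_accepted} accepted draws; need >= {min_accepted}"
        )
    rows = []
    for name in post.param_order:
        lo, hi = post.credible_interval(name)
        rows.append(dict(parameter=PARAM_LABELS.get(name, name),
                         key=name, mode=post.mode(name), q2_5=lo, q97_5=hi))
    return pd.DataFrame(rows)
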