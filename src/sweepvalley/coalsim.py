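"""Coalescent simulation under a three-population bottleneck model.

The demographic model describes the out-of-Africa history of *D.
melanogaster*: an ancestral African population that expanded to its current
size, a European population founded through a bottleneck at the exit out of
Africa, and an Asian population founded from Europe through a second
bottleneck.  There is no migration after the splits.  All parameters are
expressed in natural units (effective diploid individuals; times in years,
converted internally with a fixed number of generations per year).

Genealogies are generated backward in time with the structured coalescent
(pairwise coalescence rate ``1/(2N)`` per generation within a population).
Recombination along the sequence uses the sequential SMC' construction: the
genealogy at the left end of the region is evolved rightward, with
breakpoints arising at rate ``r x total branch length`` per bp; at each
breakpoint a uniformly chosen lineage segment is detached and re-coalesced
into the remaining genealogy under the same demography.  Mutations are
Poisson with rate ``mu`` per bp per branch-generation on each marginal
genealogy, so theta is fixed by (N, mu) and never by the observed number of
segregating sites.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

AFR, EUR, ASIA = "AF", "EU", "AS"


class ModelError(ValueError):
    """Invalid demographic parameters."""


@dataclass
class Schedule:
    """A generic backward-time demography.

    size_steps maps population name to a list of ``(t_start_generations, N)``
    pairs (first entry at t=0); merges is a list of
    ``(t_generations, source, destination)`` lineage moves, sorted in time.
    """

    pop_names: list[str]
    size_steps: dict[str, list[tuple[float, float]]]
    merges: list[tuple[float, str, str]] = field(default_factory=list)
    mu: float = 1.5e-9
    r: float = 3.64e-8

    def __post_init__(self) -> None:
        for p, steps in self.size_steps.items():
            if steps[0][0] != 0:
                raise ModelError(f"size steps for {p} must start at t=0")
            for _, N in steps:
                if N <= 0:
                    raise ModelError("population sizes must be positive")
        self.merges = sorted(self.merges)

    def schedule(self) -> "Schedule":
        return self


@dataclass
class DemographicModel:
    """The nine-parameter African/European/Asian bottleneck-expansion model.

    Defaults are the X-chromosome posterior modes of the demographic
    inference (sizes in effective diploid individuals, times in years before
    present, ten generations per year).  The bottleneck of each founded
    population lasts from its founding time until a recovery event; by
    default recovery happens at half the founding time (duration = T/2
    generations), configurable via ``bottleneck_duration_*`` (generations).

    mu is a divergence-based per-bp per-generation mutation rate; r is the
    local crossover rate of the studied X-linked region.
    """

    N_afr_cur: float = 4_635_114.0
    N_eur_cur: float = 1_586_481.0
    N_asia_cur: float = 338_810.0
    N_eur_bot: float = 22_975.0
    N_asia_bot: float = 10_741.0
    N_afr_anc: float = 1_890_641.0
    T_exit: float = 15_628.0       # years
    T_asia: float = 3_264.0        # years
    T_afr_exp: float = 27_643.0    # years
    gen_per_year: float = 10.0
    mu: float = 1.5e-9
    r: float = 3.64e-8
    bottleneck_duration_eur: float | None = None   # generations
    bottleneck_duration_asia: float | None = None  # generations

    def __post_init__(self) -> None:
        for name in ("N_afr_cur", "N_eur_cur", "N_asia_cur", "N_eur_bot",
                     "N_asia_bot", "N_afr_anc"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if not (self.T_exit > self.T_asia > 0):
            raise ModelError("need T_exit > T_asia > 0")
        if self.T_afr_exp <= 0:
            raise ModelError("T_afr_exp must be positive")

    def schedule(self) -> Schedule:
        g = self.gen_per_year
        t_exit = self.T_exit * g
        t_asia = self.T_asia * g
        t_afr = self.T_afr_exp * g
        dur_eur = self.bottleneck_duration_eur
        dur_asia = self.bottleneck_duration_asia
        if dur_eur is None:
            dur_eur = t_exit / 2
        if dur_asia is None:
            dur_asia = t_asia / 2
        dur_eur = min(dur_eur, t_exit)
        dur_asia = min(dur_asia, t_asia)
        return Schedule(
            pop_names=[AFR, EUR, ASIA],
            size_steps={
                AFR: [(0.0, self.N_afr_cur), (t_afr, self.N_afr_anc)],
                EUR: [(0.0, self.N_eur_cur), (t_exit - dur_eur, self.N_eur_bot)],
                ASIA: [(0.0, self.N_asia_cur), (t_asia - dur_asia, self.N_asia_bot)],
            },
            merges=[(t_asia, ASIA, EUR), (t_exit, EUR, AFR)],
            mu=self.mu,
            r=self.r,
        )

    def with_params(self, **kwargs) -> "DemographicModel":
        from dataclasses import replace

        return replace(self, **kwargs)


class _Demography:
    """Query layer over a Schedule: sizes, lineage relabeling, boundaries."""

    def __init__(self, sched: Schedule):
        self.pop_index = {p: i for i, p in enumerate(sched.pop_names)}
        self.step_times = []
        self.step_sizes = []
        for p in sched.pop_names:
            steps = sched.size_steps[p]
            self.step_times.append([t for t, _ in steps])
            self.step_sizes.append([N for _, N in steps])
        self.merges = [(t, self.pop_index[a], self.pop_index[b])
                       for t, a, b in sched.merges]
        bounds = {t for times in self.step_times for t in times if t > 0}
        bounds.update(t for t, _, _ in self.merges)
        self.boundaries = sorted(bounds)

    def size(self, pop: int, t: float) -> float:
        i = bisect.bisect_right(self.step_times[pop], t) - 1
        return self.step_sizes[pop][i]

    def resolve(self, pop: int, t: float) -> int:
        for tm, src, dst in self.merges:
            if tm > t:
                break
            if pop == src:
                pop = dst
        return pop

    def next_boundary(self, t: float) -> float:
        i = bisect.bisect_right(self.boundaries, t)
        return self.boundaries[i] if i < len(self.boundaries) else math.inf


@dataclass
class SimReplicate:
    """One simulated replicate: 0/1 haplotypes (0 = ancestral), positions in bp."""

    haplotypes: dict[str, np.ndarray]  # pop -> (n_pop, S) int8
    positions: np.ndarray              # int bp, strictly increasing, in [1, L]
    L: int
    seed: int | None = None

    @property
    def S(self) -> int:
        return len(self.positions)

    def pop_segregating(self, pop: str) -> int:
        h = self.haplotypes[pop]
        if h.shape[1] == 0:
            return 0
        c = h.sum(axis=0)
        return int(np.sum((c > 0) & (c < h.shape[0])))

    def pop_pi_total(self, pop: str) -> float:
        """Summed pairwise diversity over sites (pi per site = this / L)."""
        h = self.haplotypes[pop]
        n = h.shape[0]
        if n < 2 or h.shape[1] == 0:
            return 0.0
        k = h.sum(axis=0)
        return float(np.sum(2.0 * k * (n - k)) / (n * (n - 1)))


def _first_tree(dem: _Demography, leaf_pops: Sequence[int], rng) -> tuple:
    """Structured-coalescent genealogy at the left region edge.

    Returns (parent, lchild, rchild, time, pop0, root) arrays for
    2n-1 nodes (leaves 0..n-1).
    """
    n = len(leaf_pops)
    size = 2 * n  # one spare slot for splice cycles
    parent = np.full(size, -1, dtype=np.int64)
    lchild = np.full(size, -1, dtype=np.int64)
    rchild = np.full(size, -1, dtype=np.int64)
    time = np.zeros(size)
    pop0 = np.zeros(size, dtype=np.int64)

    t = 0.0
    lineages = list(range(n))
    lpop = [dem.resolve(p, 0.0) for p in leaf_pops]
    for i, p in enumerate(lpop):
        pop0[i] = p
    nxt = n
    while len(lineages) > 1:
        pops = sorted(set(lpop))
        rates = []
        for p in pops:
            k = lpop.count(p)
            rates.append(k * (k - 1) / 2.0 / (2.0 * dem.size(p, t)))
        lam = sum(rates)
        tb = dem.next_boundary(t)
        if lam <= 0:
            if math.isinf(tb):
                raise ModelError("lineages in distinct populations that never merge")
            t = tb
        else:
            dt = rng.exponential(1.0 / lam)
            if t + dt >= tb:
                t = tb
            else:
                t = t + dt
                u = rng.random() * lam
                acc = 0.0
                for p, rt in zip(pops, rates):
                    acc += rt
                    if u <= acc:
                        pop = p
                        break
                idx = [i for i, q in enumerate(lpop) if q == pop]
                i1, i2 = rng.choice(len(idx), size=2, replace=False)
                a, b = lineages[idx[i1]], lineages[idx[i2]]
                node = nxt
                nxt += 1
                time[node] = t
                lchild[node], rchild[node] = a, b
                parent[a] = parent[b] = node
                pop0[node] = pop
                keep = [j for j in range(len(lineages))
                        if lineages[j] not in (a, b)]
                lineages = [lineages[j] for j in keep] + [node]
                lpop = [lpop[j] for j in keep] + [pop]
                continue
        # crossed a boundary: relabel lineages through any merges
        lpop = [dem.resolve(p, t) for p in lpop]
    root = lineages[0]
    return parent, lchild, rchild, time, pop0, root


def _leaves_under(node: int, lchild, rchild, n: int) -> list[int]:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.append(lchild[v])
            stack.append(rchild[v])
    return out


def _subtree_nodes(node: int, lchild, rchild) -> list[int]:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        out.append(v)
        if lchild[v] >= 0:
            stack.append(lchild[v])
            stack.append(rchild[v])
    return out


def _recoalesce(b: int, t_d: float, spare: int, in_tree, root: int,
                parent, lchild, rchild, time, pop0, dem: _Demography,
                rng) -> int:
    """Re-attach the floating lineage rooted at ``b`` from time ``t_d``.

    Reuses node id ``spare`` for the new coalescence node; returns the new
    root of the updated tree.
    """
    node_times = sorted(
        {time[v] for v in np.nonzero(in_tree)[0]} | {t_d}
    )
    t = t_d
    pop_b = pop0[b]
    while True:
        pf = dem.resolve(pop_b, t)
        cands = []
        for v in np.nonzero(in_tree)[0]:
            if time[v] <= t and (v == root or time[parent[v]] > t):
                if dem.resolve(pop0[v], t) == pf:
                    cands.append(v)
        i = bisect.bisect_right(node_times, t)
        t_node = node_times[i] if i < len(node_times) else math.inf
        t_next = min(t_node, dem.next_boundary(t))
        if cands:
            lam = len(cands) / (2.0 * dem.size(pf, t))
            dt = rng.exponential(1.0 / lam)
            if t + dt < t_next:
                t_star = t + dt
                c = cands[int(rng.integers(len(cands)))]
                q = spare
                time[q] = t_star
                lchild[q], rchild[q] = b, c
                pop0[q] = pf
                gp = parent[c]
                parent[q] = gp
                parent[b] = q
                parent[c] = q
                in_tree[q] = True
                if c == root:
                    return q
                if lchild[gp] == c:
                    lchild[gp] = q
                else:
                    rchild[gp] = q
                return root
        if math.isinf(t_next):
            raise ModelError("floating lineage can never re-coalesce")
        t = t_next


def _simulate_arg(dem: _Demography, leaf_pops: Sequence[int], L: int,
                  mu: float, r: float, rng) -> list[tuple[float, list[int]]]:
    """SMC' pass over [0, L); returns (position, derived leaf ids) mutations."""
    n = len(leaf_pops)
    parent, lchild, rchild, time, pop0, root = _first_tree(dem, leaf_pops, rng)
    in_tree = np.zeros(2 * n, dtype=bool)
    in_tree[: 2 * n - 1] = True
    nodes_all = np.arange(2 * n)

    mutations: list[tuple[float, list[int]]] = []
    pos = 0.0
    while pos < L:
        live = nodes_all[in_tree]
        live = live[live != root]
        blen = time[parent[live]] - time[live]
        lam_tot = float(blen.sum())
        seg_end = L if (r <= 0 or lam_tot <= 0) else min(
            L, pos + rng.exponential(1.0 / (r * lam_tot))
        )
        # mutations on the current marginal genealogy
        if mu > 0 and lam_tot > 0 and seg_end > pos:
            nmut = rng.poisson(mu * (seg_end - pos) * lam_tot)
            if nmut:
                cum = np.cumsum(blen)
                picks = rng.random(nmut) * lam_tot
                where = np.searchsorted(cum, picks)
                for w in where:
                    node = int(live[w])
                    p = pos + rng.random() * (seg_end - pos)
                    mutations.append(
                        (p, _leaves_under(node, lchild, rchild, n))
                    )
        if seg_end >= L:
            break
        pos = seg_end
        # recombination: detach a uniform point on the tree, re-coalesce
        u = rng.random() * lam_tot
        cum = np.cumsum(blen)
        w = int(np.searchsorted(cum, u))
        b = int(live[w])
        t_d = time[b] + (u - (cum[w - 1] if w else 0.0))
        P = parent[b]
        sib = rchild[P] if lchild[P] == b else lchild[P]
        G = parent[P]
        parent[sib] = G
        if G >= 0:
            if lchild[G] == P:
                lchild[G] = sib
            else:
                rchild[G] = sib
        else:
            root = sib
        parent[b] = -1
        in_tree[P] = False
        for v in _subtree_nodes(b, lchild, rchild):
            in_tree[v] = False
        root = _recoalesce(b, t_d, P, in_tree, root, parent, lchild, rchild,
                           time, pop0, dem, rng)
        for v in _subtree_nodes(b, lchild, rchild):
            in_tree[v] = True
    return mutations


def _single_tree_mutations(dem: _Demography, leaf_pops: Sequence[int], L: int,
                           mu: float, rng) -> list[tuple[float, list[int]]]:
    """Mutations under a single genealogy (no recombination)."""
    n = len(leaf_pops)
    parent, lchild, rchild, time, pop0, root = _first_tree(dem, leaf_pops, rng)
    live = [v for v in range(2 * n - 1) if v != root]
    blen = np.array([time[parent[v]] - time[v] for v in live])
    lam_tot = float(blen.sum())
    nmut = rng.poisson(mu * L * lam_tot)
    out = []
    if nmut:
        cum = np.cumsum(blen)
        picks = rng.random(nmut) * lam_tot
        where = np.searchsorted(cum, picks)
        ppos = rng.random(nmut) * L
        for p, w in zip(ppos, where):
            node = live[int(w)]
            out.append((float(p), _leaves_under(node, lchild, rchild, n)))
    return out


def _discretize_positions(raw: list[float], L: int) -> np.ndarray:
    """Continuous [0, L) positions -> unique integer bp in [1, L].

    Collisions are resolved by moving to the nearest free integer, which
    preserves locality (an infinite-sites approximation at bp resolution).
    """
    used: set[int] = set()
    out = []
    for p in raw:
        q = min(L, max(1, int(math.floor(p)) + 1))
        if q in used:
            step = 1
            while True:
                if q - step >= 1 and (q - step) not in used:
                    q = q - step
                    break
                if q + step <= L and (q + step) not in used:
                    q = q + step
                    break
                step += 1
                if step > L:
                    raise ValueError("more mutations than sites")
        used.add(q)
        out.append(q)
    return np.asarray(out, dtype=np.int64)


def simulate(model, samples: Mapping[str, int], L: int, seed=None,
             mu: float | None = None, r: float | None = None,
             recombination: bool = True) -> SimReplicate:
    """Simulate one replicate of ``L`` bp for the given per-population sample sizes.

    ``model`` is a :class:`DemographicModel` or a raw :class:`Schedule`.
    ``mu``/``r`` override the model's rates; ``recombination=False`` forces a
    single genealogy for the whole fragment.
    """
    sched = model.schedule()
    if L < 1:
        raise ModelError("L must be >= 1")
    ns = {p: int(k) for p, k in samples.items() if int(k) > 0}
    if sum(ns.values()) < 2:
        raise ModelError("need at least 2 sampled lineages")
    for p in ns:
        if p not in sched.pop_names:
            raise ModelError(f"unknown population {p!r}")
    mu = sched.mu if mu is None else mu
    r = sched.r if r is None else r
    dem = _Demography(sched)
    rng = np.random.default_rng(seed)
    pops_in_order = [p for p in sched.pop_names if p in ns]
    leaf_pops = []
    for p in pops_in_order:
        leaf_pops.extend([dem.pop_index[p]] * ns[p])

    if recombination and r > 0:
        muts = _simulate_arg(dem, leaf_pops, L, mu, r, rng)
    else:
        muts = _single_tree_mutations(dem, leaf_pops, L, mu, rng)

    muts.sort(key=lambda m: m[0])
    positions = _discretize_positions([m[0] for m in muts], L) if muts else \
        np.empty(0, dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    ntot = len(leaf_pops)
    mat = np.zeros((ntot, len(muts)), dtype=np.int8)
    for j, oi in enumerate(order):
        mat[muts[oi][1], j] = 1

    haps = {}
    row = 0
    for p in pops_in_order:
        haps[p] = mat[row:row + ns[p]]
        row += ns[p]
    return SimReplicate(haplotypes=haps, positions=positions, L=int(L),
                        seed=seed if isinstance(seed, int) else None)


def calibrate_thresholds(model, samples: Mapping[str, int], L: int,
                         statistics: Mapping[str, Callable[[SimReplicate], float]],
                         reps: int = 10000, q: float = 0.95, seed=None,
                         recombination: bool = True,
                         inf_cap_quantile: float = 0.999,
                         ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Empirical null q-quantiles of region-maximum statistics.

    Each replicate is simulated under ``model`` and every statistic evaluator
    is applied to it (evaluators restrict themselves to the population subset
    they need, e.g. the European sample).  A statistic that is undefined on a
    replicate contributes its defined minimum, 0.  Infinite values (the omega
    sentinel for a zero between-block LD sum) are capped at the
    ``inf_cap_quantile`` of the finite null values before the threshold
    quantile is taken.

    Returns (thresholds, full null samples).
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates for a stable quantile")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(reps)
    null = {name: np.zeros(reps) for name in statistics}
    for i in range(reps):
        rep = simulate(model, samples, L, seed=int(child_seeds[i]),
                       recombination=recombination)
        for name, fn in statistics.items():
            v = fn(rep)
            null[name][i] = 0.0 if (v is None or np.isnan(v)) else v
    thresholds = {}
    for name, vals in null.items():
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            thresholds[name] = math.inf
            continue
        cap = np.quantile(finite, inf_cap_quantile)
        capped = np.minimum(vals, max(cap, finite.max()))
        capped[~np.isfinite(vals)] = max(cap, finite.max())
        thresholds[name] = float(np.quantile(capped, q))
        null[name] = capped
    return thresholds, null
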