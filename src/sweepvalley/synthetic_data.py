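"""Generators for every input the pipeline needs, without downloads.

Three generators:

* ``generate_genome_scan`` -- a multi-fragment polymorphism survey in three
  populations under the demographic model (the ABC input), including
  realistic monomorphic-fragment counts.
* ``generate_sweep_region`` -- a contiguous multi-kb region with a synthetic
  outgroup at a given divergence, optionally with a completed selective
  sweep injected into one population.  Sweep injection uses the same
  exponential escape model the CLR detector assumes: each haplotype of the
  swept population draws left/right escape breakpoints at Exponential(alpha)
  distances from the sweep position and is replaced by a single shared
  founder haplotype inside them.
* ``table2_fixture`` -- a deterministic two-population alignment carrying a
  known configuration of fixed differences (11 substitutions, 8 of them
  derived in the first population, 3 in the second, plus one fixed
  single-column insertion), for end-to-end tests of the classification
  pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import OUTGROUP, RegionAlignment
from .abc_demography import FragmentDataset
from .coalsim import DemographicModel, simulate

BASES = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    """A completed hard sweep: position (bp), escape-rate alpha (per bp),
    and the population it happened in.  The default alpha gives a mean
    escape distance of 5 kb on each side (a ~10 kb valley)."""

    position: float | None = None  # None -> region midpoint
    alpha: float = 2e-4
    population: str = "EU"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def generate_genome_scan(model: DemographicModel, n_fragments: int = 250,
                         frag_len: int = 500,
                         samples: dict[str, int] | None = None,
                         seed=None, recombination: bool = False,
                         ) -> FragmentDataset:
    """Independent coalescent fragments summarized per population.

    Fragments are simulated without intra-fragment recombination by default:
    the across-fragment means of S, pi and Tajima's D are unaffected by
    intra-locus recombination, and fragments are short (500 bp).
    """
    if samples is None:
        samples = {"AF": 12, "EU": 12, "AS": 12}
    pops = [p for p in ("AF", "EU", "AS") if p in samples] or list(samples)
    seeds = np.random.SeedSequence(seed).generate_state(n_fragments)
    S = np.zeros((n_fragments, len(pops)))
    pi = np.zeros((n_fragments, len(pops)))
    for i in range(n_fragments):
        rep = simulate(model, samples, frag_len, seed=int(seeds[i]),
                       recombination=recombination)
        for k, p in enumerate(pops):
            S[i, k] = rep.pop_segregating(p)
            pi[i, k] = rep.pop_pi_total(p)
    return FragmentDataset(populations=pops,
                           sample_sizes={p: samples[p] for p in pops},
                           frag_len=frag_len, S=S, pi_total=pi)


def _inject_sweep(matrix: np.ndarray, positions: np.ndarray, spec: SweepSpec,
                  L: int, rng) -> np.ndarray:
    """Replace each haplotype inside its escape interval by a shared founder."""
    x = spec.position if spec.position is not None else (L + 1) / 2.0
    n = matrix.shape[0]
    out = matrix.copy()
    founder = matrix[0].copy()
    for i in range(n):
        d_left = rng.exponential(1.0 / spec.alpha)
        d_right = rng.exponential(1.0 / spec.alpha)
        inside = (positions > x - d_left) & (positions < x + d_right)
        out[i, inside] = founder[inside]
    return out


def generate_sweep_region(model: DemographicModel, L: int = 20011,
                          samples: dict[str, int] | None = None,
                          outgroup_divergence: float = 0.06,
                          sweep: SweepSpec | None = None,
                          seed=None, region_offset: int = 0,
                          ) -> RegionAlignment:
    """A neutral (or swept) region alignment with a synthetic outgroup.

    Ingroup haplotypes come from the coalescent simulator with
    recombination; the outgroup is the ancestral sequence with independent
    substitutions at rate ``outgroup_divergence`` per column, placed only at
    columns where the ingroup is monomorphic so that outgroup polarization
    of the polymorphic sites remains exact.
    """
    if not (0.0 < outgroup_divergence < 0.25):
        raise ValueError("outgroup divergence must be in (0, 0.25)")
    if samples is None:
        samples = {"EU": 12, "AF": 12}
    ss = np.random.SeedSequence(seed)
    sim_seed, sweep_seed, synth_seed = ss.generate_state(3)
    rep = simulate(model, samples, L, seed=int(sim_seed))
    rng = np.random.default_rng(int(synth_seed))

    pops = list(rep.haplotypes)
    if sweep is not None:
        if sweep.population not in pops:
            raise ValueError(f"sweep population {sweep.population!r} not sampled")
        # dedicated stream: injecting a sweep must not perturb the letters
        # synthesized for the other populations
        rep.haplotypes[sweep.population] = _inject_sweep(
            rep.haplotypes[sweep.population], rep.positions, sweep, L,
            np.random.default_rng(int(sweep_seed)))

    # nucleotide states: ancestral uniform, derived uniform over the rest
    anc_idx = rng.integers(0, 4, size=L)
    der_idx = (anc_idx[rep.positions - 1] + rng.integers(1, 4, size=rep.S)) % 4
    anc = BASES[anc_idx]

    seqs, labels, poptags = [], [], []
    for p in pops:
        mat = rep.haplotypes[p]
        for i in range(mat.shape[0]):
            row = anc.copy()
            derived_here = rep.positions[mat[i] == 1] - 1
            row[derived_here] = BASES[der_idx[mat[i] == 1]]
            seqs.append("".join(row))
            labels.append(f"{p}{i + 1:02d}")
            poptags.append(p)

    out_row = anc.copy()
    mono = np.ones(L, dtype=bool)
    mono[rep.positions - 1] = False
    sub = mono & (rng.random(L) < outgroup_divergence)
    out_row[sub] = BASES[(anc_idx[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4]
    seqs.append("".join(out_row))
    labels.append("outgroup_sp")
    poptags.append(OUTGROUP)

    return RegionAlignment(seqs, labels, poptags, region_offset)


#: (outgroup, population-A a.k.a. African, population-B a.k.a. European)
#: allele per fixed difference; None marks a gap (the fixed insertion).
TABLE2_CONFIGS: list[tuple[str | None, str | None, str | None]] = [
    ("G", "G", "A"),
    ("T", "C", "T"),
    ("C", "T", "C"),
    ("G", "G", "A"),
    ("A", "A", "G"),
    ("A", "A", "C"),
    ("G", "G", "T"),
    ("G", "G", "A"),
    ("C", "T", "C"),
    ("C", "C", "T"),
    ("C", "C", "A"),
    (None, None, "T"),  # insertion private to population B
]


def table2_fixture(L: int = 400, region_offset: int = 14_810_552,
                   n_per_pop: int = 12) -> RegionAlignment:
    """Deterministic alignment reproducing the canonical fixed-difference set.

    Two ingroup populations (AF, EU) of ``n_per_pop`` haplotypes plus one
    outgroup; the 12 configurations of :data:`TABLE2_CONFIGS` are placed at
    evenly spaced columns, everything else is monomorphic and identical to
    the outgroup.  The first eleven are nucleotide substitutions (8 derived
    in EU, 3 derived in AF), the last is a one-column insertion present only
    in EU.
    """
    rng = np.random.default_rng(20011)
    backbone = BASES[rng.integers(0, 4, size=L)]
    cols = np.linspace(30, L - 30, len(TABLE2_CONFIGS)).astype(int)
    af = backbone.copy().astype(object)
    eu = backbone.copy().astype(object)
    og = backbone.copy().astype(object)
    for c, (o, a, e) in zip(cols, TABLE2_CONFIGS):
        og[c - 1] = o if o is not None else "-"
        af[c - 1] = a if a is not None else "-"
        eu[c - 1] = e if e is not None else "-"
    seqs = ["".join(af)] * n_per_pop + ["".join(eu)] * n_per_pop + ["".join(og)]
    labels = [f"A{i + 1:02d}" for i in range(n_per_pop)] + \
             [f"E{i + 1:02d}" for i in range(n_per_pop)] + ["D_sim_outgroup"]
    pops = ["AF"] * n_per_pop + ["EU"] * n_per_pop + [OUTGROUP]
    return RegionAlignment(seqs, labels, pops, region_offset)


def table2_columns(L: int = 400) -> np.ndarray:
    """The fixture columns carrying the placed fixed differences."""
    return np.linspace(30, L - 30, len(TABLE2_CONFIGS)).astype(int)
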