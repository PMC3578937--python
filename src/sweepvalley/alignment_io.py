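"""Population-labeled alignment I/O and per-column site classification.

The central object is a :class:`RegionAlignment`: equal-length haplotype
sequences from one or more ingroup populations plus (optionally) a single
outgroup sequence used to polarize allelic states.  ``classify_sites`` turns
an alignment into a :class:`SiteTable` with one record per column, from which
fixed differences between two population samples, derived-private allele
counts and open-reading-frame integrity are computed.

Polarization follows the parsimony rule for a single outgroup: the allele
shared with the outgroup is ancestral, an allele absent from the outgroup is
derived.  Columns where the outgroup is missing, gapped, or carries a third
allele are left unpolarized.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

OUTGROUP = "outgroup"
NUCLEOTIDES = frozenset("ACGT")
GAP = "-"
#: symbols treated as missing data (IUPAC ambiguity codes and N)
MISSING = frozenset("NRYSWKMBDHVX?")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AlignmentShapeError(ValueError):
    """Sequences of unequal length (not an alignment)."""


class AlignmentFormatError(ValueError):
    """Empty or malformed input."""


class AlignmentConfigError(ValueError):
    """Inconsistent population configuration (e.g. two outgroups)."""


@dataclass
class RegionAlignment:
    """An aligned set of haplotypes with population labels.

    Parameters
    ----------
    sequences : list of str
        Equal-length uppercase strings over ``A,C,G,T,-`` plus missing codes.
    labels : list of str
        Per-sequence sample identifiers.
    populations : list of str
        Per-sequence population tag; the tag ``"outgroup"`` marks the
        (at most one) outgroup sequence.
    region_offset : int
        Absolute genomic coordinate of alignment column 1.
    """

    sequences: list[str]
    labels: list[str]
    populations: list[str]
    region_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError("alignment contains no sequences")
        if not (len(self.sequences) == len(self.labels) == len(self.populations)):
            raise AlignmentConfigError("sequences, labels, populations differ in length")
        L = len(self.sequences[0])
        if L < 1:
            raise AlignmentShapeError("alignment length must be >= 1")
        for lab, s in zip(self.labels, self.sequences):
            if len(s) != L:
                raise AlignmentShapeError(
                    f"sequence {lab!r} has length {len(s)}, expected {L}"
                )
        if self.populations.count(OUTGROUP) > 1:
            raise AlignmentConfigError("more than one outgroup sequence")
        if self.region_offset < 0:
            raise AlignmentConfigError("region_offset must be non-negative")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    @property
    def ingroup_populations(self) -> list[str]:
        """Ingroup population tags in first-appearance order."""
        seen: list[str] = []
        for p in self.populations:
            if p != OUTGROUP and p not in seen:
                seen.append(p)
        return seen

    @property
    def outgroup_index(self) -> int | None:
        try:
            return self.populations.index(OUTGROUP)
        except ValueError:
            return None

    def population_indices(self, pop: str) -> list[int]:
        return [i for i, p in enumerate(self.populations) if p == pop]

    def sample_sizes(self) -> dict[str, int]:
        return {p: len(self.population_indices(p)) for p in self.ingroup_populations}


def read_alignment(
    path: str | Path | io.TextIOBase,
    population_map: Mapping[str, str],
    region_offset: int = 0,
) -> RegionAlignment:
    """Read a multi-FASTA alignment and attach population tags.

    ``population_map`` maps each FASTA record id to a population tag
    (``"outgroup"`` for the outgroup).  All records must be present in the
    map and of equal length.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path!r}")
    seqs, labels, pops = [], [], []
    for rec in records:
        if rec.id not in population_map:
            raise AlignmentConfigError(f"record {rec.id!r} missing from population map")
        labels.append(rec.id)
        pops.append(population_map[rec.id])
        seqs.append(str(rec.seq).upper())
    return RegionAlignment(seqs, labels, pops, region_offset)


def write_alignment(aln: RegionAlignment, path: str | Path | io.TextIOBase) -> None:
    """Write the alignment as multi-FASTA (round-trips with read_alignment)."""
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for s, lab in zip(aln.sequences, aln.labels)
    ]
    SeqIO.write(records, path, "fasta")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (label, population tag)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, tag = line.split("\t")[:2]
            out[label] = tag
    return out


@dataclass
class SiteRecord:
    """Classification of one alignment column."""

    column: int  # 1-based
    kind: str  # monomorphic | segregating | fixed_difference | indel | masked
    allele_counts: dict[str, Counter]  # per ingroup population
    outgroup_allele: str | None
    derived_allele: str | None
    derived_count_per_pop: dict[str, int]


@dataclass
class SiteTable:
    """Ordered per-column classification of a RegionAlignment."""

    records: list[SiteRecord]
    populations: list[str]
    sample_sizes: dict[str, int]
    region_offset: int = 0
    L: int = 0

    def __post_init__(self) -> None:
        if self.L == 0:
            self.L = len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def kind_counts(self) -> Counter:
        return Counter(r.kind for r in self.records)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            alleles = ";".join(
                f"{p}={'/'.join(f'{a}:{c}' for a, c in sorted(r.allele_counts[p].items()))}"
                for p in self.populations
            )
            rows.append(
                dict(
                    column=r.column,
                    abs_position=self.region_offset + r.column - 1,
                    kind=r.kind,
                    alleles=alleles,
                    outgroup=r.outgroup_allele or ".",
                    derived=r.derived_allele or ".",
                    **{f"derived_count_{p}": r.derived_count_per_pop.get(p, 0)
                       for p in self.populations},
                )
            )
        return pd.DataFrame(rows)


@dataclass
class FixedDifference:
    """A column (or merged indel run) fixed for different alleles in two populations."""

    column: int
    abs_position: int
    alleles: dict[str, str]  # population -> fixed allele
    outgroup_allele: str | None
    status: str  # derived_private_<pop> | unpolarized
    is_indel: bool = False


def _classify_column(
    col: int,
    symbols: Sequence[str],
    pops: Sequence[str],
    ingroup_pops: Sequence[str],
    outgroup_symbol: str | None,
    min_call_rate: float,
    sample_sizes: Mapping[str, int],
) -> SiteRecord:
    per_pop: dict[str, Counter] = {p: Counter() for p in ingroup_pops}
    any_gap = outgroup_symbol == GAP
    n_called = 0
    for sym, pop in zip(symbols, pops):
        if pop == OUTGROUP:
            continue
        if sym == GAP:
            any_gap = True
            per_pop[pop][GAP] += 1
            n_called += 1
        elif sym in NUCLEOTIDES:
            per_pop[pop][sym] += 1
            n_called += 1
        # missing symbols contribute nothing

    out_allele = None
    if outgroup_symbol is not None and outgroup_symbol in NUCLEOTIDES | {GAP}:
        out_allele = outgroup_symbol

    ingroup_alleles = set()
    for c in per_pop.values():
        ingroup_alleles.update(c.keys())

    if n_called == 0:
        return SiteRecord(col, "masked", per_pop, out_allele, None,
                          {p: 0 for p in ingroup_pops})

    if GAP in ingroup_alleles or out_allele == GAP:
        kind = "indel"
    else:
        kind = None

    # fixed difference: both (all) populations internally monomorphic,
    # fully called (min_call_rate), and not all carrying the same allele
    fixed_alleles: dict[str, str] = {}
    all_fixed = len(ingroup_pops) >= 2
    for p in ingroup_pops:
        c = per_pop[p]
        called = sum(c.values())
        if len(c) == 1 and called >= min_call_rate * sample_sizes[p]:
            fixed_alleles[p] = next(iter(c))
        else:
            all_fixed = False
    is_fixed_diff = all_fixed and len(set(fixed_alleles.values())) > 1

    if kind != "indel":
        if is_fixed_diff:
            kind = "fixed_difference"
        elif len(ingroup_alleles) > 1:
            kind = "segregating"
        else:
            kind = "monomorphic"
    elif is_fixed_diff:
        # indel column that is also fixed-different; keep 'indel' as the kind,
        # fixed_differences() re-detects fixed indels from allele counts
        pass

    # polarization (substitutions only; gap columns are left unpolarized)
    derived = None
    derived_counts = {p: 0 for p in ingroup_pops}
    nuc_alleles = ingroup_alleles - {GAP}
    if out_allele in NUCLEOTIDES and kind != "indel":
        non_out = nuc_alleles - {out_allele}
        if len(non_out) == 1 and len(nuc_alleles) <= 2:
            derived = next(iter(non_out))
        elif len(non_out) == 0:
            derived = None  # all ancestral; counts stay 0
        # outgroup carries a third allele or >2 ingroup alleles: unpolarized
        if derived is not None:
            for p in ingroup_pops:
                derived_counts[p] = per_pop[p].get(derived, 0)

    return SiteRecord(col, kind, per_pop, out_allele, derived, derived_counts)


def classify_sites(aln: RegionAlignment, min_call_rate: float = 1.0) -> SiteTable:
    """Classify every alignment column into a :class:`SiteTable`.

    ``min_call_rate`` gates fixed-difference calls: a population counts as
    internally fixed only if at least this fraction of its sample is called
    at the column (default 1.0: no missing data tolerated for fixed calls).
    """
    ingroup = aln.ingroup_populations
    if not ingroup:
        raise AlignmentConfigError("no ingroup populations")
    sizes = aln.sample_sizes()
    og = aln.outgroup_index
    records = []
    for col in range(1, aln.L + 1):
        symbols = [s[col - 1] for s in aln.sequences]
        out_sym = symbols[og] if og is not None else None
        records.append(
            _classify_column(col, symbols, aln.populations, ingroup, out_sym,
                             min_call_rate, sizes)
        )
    return SiteTable(records, ingroup, sizes, aln.region_offset, aln.L)


def _fixed_alleles_at(rec: SiteRecord, populations: Sequence[str],
                      sizes: Mapping[str, int], min_call_rate: float
                      ) -> dict[str, str] | None:
    """Alleles (incl. '-') if every population is internally fixed, else None."""
    out = {}
    for p in populations:
        c = rec.allele_counts[p]
        called = sum(c.values())
        if len(c) != 1 or called < min_call_rate * sizes[p]:
            return None
        out[p] = next(iter(c))
    if len(set(out.values())) < 2:
        return None
    return out


def fixed_differences(table: SiteTable, min_call_rate: float = 1.0,
                      merge_indel_runs: bool = True) -> list[FixedDifference]:
    """All fixed differences between the two ingroup populations.

    Substitutions are reported per column; runs of consecutive fixed-indel
    columns are merged into a single indel event (an insertion/deletion of
    several bases is one mutational event).
    """
    if len(table.populations) != 2:
        raise AlignmentConfigError(
            f"fixed differences are defined for exactly 2 populations, got {len(table.populations)}"
        )
    popA, popB = table.populations
    out: list[FixedDifference] = []
    prev_indel_col = -10

    for rec in table.records:
        fixed = _fixed_alleles_at(rec, table.populations, table.sample_sizes,
                                  min_call_rate)
        if fixed is None:
            prev_indel_col = -10
            continue
        is_indel = GAP in fixed.values() or rec.outgroup_allele == GAP
        if is_indel and GAP not in fixed.values():
            # both populations carry bases; outgroup gap alone is not a
            # fixed indel between the ingroup samples -> substitution
            is_indel = False

        status = "unpolarized"
        og = rec.outgroup_allele
        if og is not None:
            if og == fixed[popA] and og != fixed[popB]:
                status = f"derived_private_{popB}"
            elif og == fixed[popB] and og != fixed[popA]:
                status = f"derived_private_{popA}"

        if is_indel and merge_indel_runs and rec.column == prev_indel_col + 1:
            prev_indel_col = rec.column  # extend current indel event
            continue
        if is_indel:
            prev_indel_col = rec.column
        else:
            prev_indel_col = -10
        out.append(
            FixedDifference(
                column=rec.column,
                abs_position=table.region_offset + rec.column - 1,
                alleles=fixed,
                outgroup_allele=og,
                status=status,
                is_indel=is_indel,
            )
        )
    return out


def count_derived_private(diffs: Iterable[FixedDifference], population: str) -> int:
    """Number of fixed nucleotide substitutions derived-private to ``population``."""
    tag = f"derived_private_{population}"
    return sum(1 for d in diffs if not d.is_indel and d.status == tag)


@dataclass
class OrfStatus:
    """Open-reading-frame integrity of one sequence."""

    label: str
    status: str  # intact | premature_stop | frameshift | no_start
    first_defect_position: int | None = None  # codon index (1-based)


def orf_check(coding_aln: RegionAlignment, frame_start: int = 1,
              reference_length: int | None = None) -> list[OrfStatus]:
    """Check each sequence for an intact ORF in the declared reading frame.

    Each sequence is gap-stripped from alignment column ``frame_start``
    onward.  A sequence is ``intact`` iff it starts with ATG, its length is a
    multiple of 3, it matches ``reference_length`` modulo 3 (frameshift
    check; default reference is the outgroup-free modal length), and no
    in-frame stop codon occurs before the final codon.
    """
    if not (1 <= frame_start <= coding_aln.L):
        raise ValueError("frame_start outside alignment")
    stripped = []
    for lab, s in zip(coding_aln.labels, coding_aln.sequences):
        sub = s[frame_start - 1:].replace(GAP, "")
        bad = set(sub) - NUCLEOTIDES - MISSING
        if bad:
            raise AlignmentFormatError(f"non-nucleotide symbols {bad} in {lab!r}")
        stripped.append(sub)
    if reference_length is None:
        lengths = Counter(len(s) for s in stripped)
        reference_length = lengths.most_common(1)[0][0]

    out = []
    for lab, seq in zip(coding_aln.labels, stripped):
        if not seq.startswith("ATG"):
            out.append(OrfStatus(lab, "no_start", 1))
            continue
        if (len(seq) - reference_length) % 3 != 0 or len(seq) % 3 != 0:
            out.append(OrfStatus(lab, "frameshift", None))
            continue
        status = "intact"
        defect = None
        n_codons = len(seq) // 3
        for i in range(n_codons - 1):  # stops before the final codon
            if seq[3 * i:3 * i + 3] in STOP_CODONS:
                status, defect = "premature_stop", i + 1
                break
        out.append(OrfStatus(lab, status, defect))
    return out
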