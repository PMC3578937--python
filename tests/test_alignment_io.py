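"""Alignment reading, per-column classification, fixed differences, ORFs."""

import io

import numpy as np
import pytest

from sweepvalley.alignment_io import (
    AlignmentConfigError,
    AlignmentFormatError,
    AlignmentShapeError,
    OUTGROUP,
    RegionAlignment,
    classify_sites,
    count_derived_private,
    fixed_differences,
    orf_check,
    read_alignment,
    write_alignment,
)


def _aln(seq_by_pop: dict[str, list[str]], offset: int = 0) -> RegionAlignment:
    seqs, labels, pops = [], [], []
    for pop, ss in seq_by_pop.items():
        for i, s in enumerate(ss):
            seqs.append(s)
            labels.append(f"{pop}{i}")
            pops.append(pop)
    return RegionAlignment(seqs, labels, pops, offset)


class TestReadWrite:
    def test_fasta_round_trip_is_identity(self, tmp_path):
        aln = _aln({"pop1": ["ACGTACGTAC", "ACGTACGTAC"],
                    "pop2": ["ACGTACGAAC"],
                    OUTGROUP: ["ACGTACGTAC"]}, offset=100)
        path = tmp_path / "aln.fasta"
        write_alignment(aln, str(path))
        back = read_alignment(str(path),
                              dict(zip(aln.labels, aln.populations)), 100)
        assert back.sequences == aln.sequences
        assert back.labels == aln.labels
        assert back.populations == aln.populations
        assert back.region_offset == aln.region_offset

    def test_three_records_two_pops(self):
        fh = io.StringIO(">A\nACGTACGTAC\n>B\nACGTACGTAC\n>C\nACGTACGTAC\n")
        aln = read_alignment(fh, {"A": "pop1", "B": "pop2", "C": OUTGROUP})
        assert aln.L == 10
        assert aln.ingroup_populations == ["pop1", "pop2"]

    def test_unequal_lengths_rejected(self):
        fh = io.StringIO(">A\nACGTACGTAC\n>B\nACGTACGTA\n")
        with pytest.raises(AlignmentShapeError):
            read_alignment(fh, {"A": "pop1", "B": "pop1"})

    def test_empty_file_rejected(self):
        with pytest.raises(AlignmentFormatError):
            read_alignment(io.StringIO(""), {})

    def test_two_outgroups_rejected(self):
        with pytest.raises(AlignmentConfigError):
            _aln({OUTGROUP: ["ACGT", "ACGT"], "pop1": ["ACGT"]})

    def test_unmapped_label_rejected(self):
        fh = io.StringIO(">A\nACGT\n>B\nACGT\n")
        with pytest.raises(AlignmentConfigError):
            read_alignment(fh, {"A": "pop1"})


class TestClassification:
    def test_fixed_difference_derived_in_second_population(self):
        # outgroup shares the first population's allele -> second is derived
        aln = _aln({"AF": ["G"] * 3, "EU": ["A"] * 3, OUTGROUP: ["G"]})
        rec = classify_sites(aln).records[0]
        assert rec.kind == "fixed_difference"
        assert rec.derived_allele == "A"
        assert rec.derived_count_per_pop == {"AF": 0, "EU": 3}

    def test_fixed_difference_derived_in_first_population(self):
        aln = _aln({"AF": ["C"] * 3, "EU": ["T"] * 3, OUTGROUP: ["T"]})
        rec = classify_sites(aln).records[0]
        assert rec.kind == "fixed_difference"
        assert rec.derived_allele == "C"
        assert rec.derived_count_per_pop == {"AF": 3, "EU": 0}

    def test_monomorphic_shared_with_outgroup(self):
        aln = _aln({"AF": ["A"] * 2, "EU": ["A"] * 2, OUTGROUP: ["A"]})
        rec = classify_sites(aln).records[0]
        assert rec.kind == "monomorphic"
        assert rec.derived_count_per_pop == {"AF": 0, "EU": 0}

    def test_every_column_classified_once(self):
        rng = np.random.default_rng(0)
        L = 200
        seqs = ["".join(rng.choice(list("ACGT-"), L)) for _ in range(6)]
        aln = RegionAlignment(seqs, [f"s{i}" for i in range(6)],
                              ["p1"] * 3 + ["p2"] * 2 + [OUTGROUP])
        table = classify_sites(aln)
        assert len(table) == L
        assert sum(table.kind_counts().values()) == L
        assert [r.column for r in table] == list(range(1, L + 1))

    def test_permutation_within_population_is_invariant(self):
        rng = np.random.default_rng(1)
        L = 80
        seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(7)]
        labels = [f"s{i}" for i in range(7)]
        pops = ["p1"] * 4 + ["p2"] * 2 + [OUTGROUP]
        a = RegionAlignment(list(seqs), list(labels), list(pops))
        perm = [2, 0, 3, 1]  # shuffle pop1 members only
        seqs2 = [seqs[perm[i]] if i < 4 else seqs[i] for i in range(7)]
        b = RegionAlignment(seqs2, labels, pops)
        ta, tb = classify_sites(a), classify_sites(b)
        for ra, rb in zip(ta, tb):
            assert ra.kind == rb.kind
            assert ra.derived_count_per_pop == rb.derived_count_per_pop

    def test_never_derived_private_in_both_populations(self):
        rng = np.random.default_rng(2)
        L = 300
        seqs = ["".join(rng.choice(list("ACGT"), L, p=[0.7, 0.1, 0.1, 0.1]))
                for _ in range(9)]
        aln = RegionAlignment(seqs, [f"s{i}" for i in range(9)],
                              ["p1"] * 4 + ["p2"] * 4 + [OUTGROUP])
        diffs = fixed_differences(classify_sites(aln))
        for d in diffs:
            assert not (d.status.startswith("derived_private")
                        and "p1" in d.status and "p2" in d.status)


class TestFixedDifferences:
    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        L = 1000
        base = rng.choice(list("ACGT"), L)
        seqs = []
        for _ in range(9):
            s = base.copy()
            mut = rng.random(L) < 0.05
            s[mut] = rng.choice(list("ACGT"), int(mut.sum()))
            seqs.append("".join(s))
        pops = ["p1"] * 4 + ["p2"] * 4 + [OUTGROUP]
        aln = RegionAlignment(seqs, [f"s{i}" for i in range(9)], pops)
        got = {d.column for d in fixed_differences(classify_sites(aln))}

        expect = set()
        for col in range(L):
            a1 = {s[col] for s in seqs[:4]}
            a2 = {s[col] for s in seqs[4:8]}
            if len(a1) == 1 == len(a2) and a1 != a2:
                expect.add(col + 1)
        assert got == expect

    def test_all_monomorphic_alignment_has_none(self):
        aln = _aln({"p1": ["ACGT"] * 3, "p2": ["ACGT"] * 3, OUTGROUP: ["ACGT"]})
        assert fixed_differences(classify_sites(aln)) == []

    def test_requires_exactly_two_populations(self):
        aln = _aln({"p1": ["ACGT"] * 2, "p2": ["ACGT"] * 2, "p3": ["ACGT"]})
        with pytest.raises(AlignmentConfigError):
            fixed_differences(classify_sites(aln))

    def test_consecutive_gap_columns_merge_to_one_indel(self):
        aln = _aln({"p1": ["AC---GT"] * 3, "p2": ["ACTTAGT"] * 3,
                    OUTGROUP: ["AC---GT"]})
        diffs = fixed_differences(classify_sites(aln))
        indels = [d for d in diffs if d.is_indel]
        assert len(indels) == 1
        assert indels[0].column == 3
        assert indels[0].status == "derived_private_p2"

    def test_count_derived_private_empty(self):
        assert count_derived_private([], "p1") == 0

    def test_abs_position_uses_region_offset(self):
        aln = _aln({"p1": ["A"], "p2": ["G"], OUTGROUP: ["A"]}, offset=500)
        d = fixed_differences(classify_sites(aln))[0]
        assert d.abs_position == 500


class TestOrfCheck:
    @pytest.mark.parametrize("seq,status,defect", [
        ("ATGAAATAA", "intact", None),
        ("ATGTGATAA", "premature_stop", 2),
        ("TTGAAATAA", "no_start", 1),
    ])
    def test_single_sequence_statuses(self, seq, status, defect):
        aln = _aln({"p1": [seq, "ATGAAATAA"]})
        res = orf_check(aln, frame_start=1)
        assert res[0].status == status
        assert res[0].first_defect_position == defect

    def test_one_bp_gap_is_a_frameshift(self):
        aln = _aln({"p1": ["ATGAA-AAATAA", "ATGAACAAATAA"]})
        res = orf_check(aln, frame_start=1, reference_length=12)
        assert res[0].status == "frameshift"
        assert res[1].status == "intact"

    def test_non_nucleotide_symbols_rejected(self):
        aln = _aln({"p1": ["AT!AAATAA"]})
        with pytest.raises(AlignmentFormatError):
            orf_check(aln, frame_start=1, reference_length=9)
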