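"""Alignment I/O, coordinate parsing, haplotype collapsing, site classes."""

import numpy as np
import pandas as pd
import pytest

from haplostat.seqio import (
    AlignmentError,
    PopulationMap,
    classify_sites,
    collapse_haplotypes,
    parse_coordinate,
    read_alignment,
    read_population_map,
    usable_sites,
    write_alignment,
)

from conftest import make_alignment, make_popmap, random_alignment


class TestReadAlignment:
    def test_round_trip_preserves_order_and_content(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">s1\nacgtacgtaa\n>s2\nACGTACGTAA\n>s3\nACGTACGTAC\n")
        aln = read_alignment(p)
        assert aln.length == 10
        assert aln.sample_ids == ("s1", "s2", "s3")
        assert aln.sequences[0] == "ACGTACGTAA"  # upper-cased
        out = tmp_path / "rt.fasta"
        write_alignment(aln, out)
        assert read_alignment(out).sequences == aln.sequences

    def test_ragged_lengths_rejected(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nACGTACGTAA\n>b\nACGTACGTA\n")
        with pytest.raises(AlignmentError, match="unaligned"):
            read_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(AlignmentError, match="no FASTA records"):
            read_alignment(p)

    def test_illegal_character_named(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACGT\n>b\nAC!T\n")
        with pytest.raises(AlignmentError, match=r"'b'.*position 3"):
            read_alignment(p)


class TestCoordinates:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("23'31''N", 23 + 31 / 60),
            ("120'49E", 120 + 49 / 60),
            ("23°31′N", 23 + 31 / 60),
            ("24°08\"N", 24 + 8 / 60),
            ("12.5", 12.5),
            ("45°30′S", -(45.5)),
            ("10°W", -10.0),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_coordinate(text) == pytest.approx(expected, abs=1e-9)

    def test_unparseable(self):
        with pytest.raises(AlignmentError, match="coordinate"):
            parse_coordinate("north of the river")


class TestPopulationMap:
    def test_read_and_sizes(self, tmp_path):
        rows = ["sample_id\tpopulation\tgroup\tlat_dd\tlon_dd"]
        sizes = {"YT": 9, "SC": 1, "AA": 4}
        groups = {"YT": "Yushan", "SC": "Sheishan", "AA": "Alishan"}
        for pop, n in sizes.items():
            for i in range(n):
                rows.append(f"{pop}{i}\t{pop}\t{groups[pop]}\t23'31''N\t120'49E")
        p = tmp_path / "popmap.tsv"
        p.write_text("\n".join(rows) + "\n")
        pm = read_population_map(p)
        assert pm.population_sizes() == sizes
        assert pm.coordinates()["YT"] == pytest.approx((23 + 31 / 60, 120 + 49 / 60))

    def test_duplicate_sample_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "a"],
                "population": ["P1", "P1"],
                "group": ["G1", "G1"],
                "lat_dd": [0.0, 0.0],
                "lon_dd": [0.0, 0.0],
            }
        )
        with pytest.raises(AlignmentError, match="duplicate"):
            PopulationMap(df)

    def test_population_in_two_groups_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "population": ["P1", "P1"],
                "group": ["G1", "G2"],
                "lat_dd": [0.0, 0.0],
                "lon_dd": [0.0, 0.0],
            }
        )
        with pytest.raises(AlignmentError, match="multiple groups"):
            PopulationMap(df)


class TestUsableSites:
    def test_no_gaps_keeps_all(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        assert usable_sites(aln) == [0, 1, 2, 3]

    def test_gap_column_excluded(self):
        aln = make_alignment({"a": "AC-T", "b": "ACGA"})
        assert usable_sites(aln) == [0, 1, 3]

    def test_five_site_toy_with_n_and_gap(self):
        # one N column (idx 1), one gap column (idx 3) -> 3 retained
        aln = make_alignment({"a": "ANGTC", "b": "ACG-C", "c": "ACGTC"})
        assert usable_sites(aln) == [0, 2, 4]


class TestCollapse:
    def test_identical_sequences_single_haplotype(self):
        aln = make_alignment({f"s{i}": "ACGT" for i in range(4)})
        pm = make_popmap({f"s{i}": ("P1", "G1") for i in range(4)})
        table = collapse_haplotypes(aln, pm)
        assert table.n_haplotypes == 1
        assert table.counts.tolist() == [[4]]

    def test_manual_tally_three_states_two_pops(self):
        seqs = {
            "a1": "AAAA", "a2": "AAAT", "a3": "AAAA",
            "b1": "AAAT", "b2": "TTTT", "b3": "AAAT",
        }
        pm = make_popmap(
            {s: ("P1" if s.startswith("a") else "P2", "G1") for s in seqs}
        )
        table = collapse_haplotypes(make_alignment(seqs), pm)
        assert table.n_haplotypes == 3
        # rows in order of first appearance: AAAA, AAAT, TTTT
        assert table.counts.tolist() == [[2, 0], [1, 2], [0, 1]]

    def test_unmapped_sample_rejected(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        pm = make_popmap({"a": ("P1", "G1")})
        with pytest.raises(AlignmentError, match="missing from population map"):
            collapse_haplotypes(aln, pm)

    def test_expand_round_trip_and_permutation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n, L = int(rng.integers(2, 12)), int(rng.integers(4, 30))
            aln = random_alignment(rng, n, L, with_gaps=True)
            pm = make_popmap(
                {sid: (f"P{rng.integers(3)}", "G1") for sid in aln.sample_ids}
            )
            table = collapse_haplotypes(aln, pm)
            sites = list(table.usable_sites)
            want = sorted("".join(s[i] for i in sites) for s in aln.sequences)
            assert sorted(table.expand()) == want
            # permuting record order preserves the haplotype classes
            perm = rng.permutation(n)
            aln2 = make_alignment(
                {aln.sample_ids[i]: aln.sequences[i] for i in perm}
            )
            table2 = collapse_haplotypes(aln2, pm)
            assert sorted(table2.expand()) == want
            assert table2.n_haplotypes == table.n_haplotypes


class TestSiteClasses:
    def test_monomorphic_alignment(self):
        sc = classify_sites(make_alignment({"a": "AAAA", "b": "AAAA", "c": "AAAA"}))
        assert sc.polymorphic == 0 and sc.parsimony_informative == 0
        assert sc.monomorphic == 4

    def test_manual_classification(self):
        # site 0: {A,A,G,G} informative; site 1: {A,A,A,T} singleton
        aln = make_alignment({"a": "AA", "b": "AA", "c": "GA", "d": "GT"})
        sc = classify_sites(aln)
        assert sc.polymorphic == 2
        assert sc.parsimony_informative == 1
        assert sc.singleton == 1

    def test_partition_identities_on_random_alignments(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n, L = int(rng.integers(2, 10)), int(rng.integers(3, 40))
            aln = random_alignment(rng, n, L, with_gaps=bool(rng.integers(2)))
            sc = classify_sites(aln)
            assert sc.monomorphic + sc.polymorphic + sc.excluded == aln.length
            assert sc.singleton + sc.parsimony_informative == sc.polymorphic
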