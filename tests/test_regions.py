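"""Region extraction, identity collapse and supraspecies training sets."""

import numpy as np
import pytest

from ampliref.refdb import RefSeqEntry
from ampliref.regions import (
    BUILTIN_REGIONS,
    PRIMERS,
    RegionDef,
    build_training_set,
    collapse,
    extract_region,
    find_primer,
    region_identity_matrix,
)
from ampliref.alignment import reverse_complement

from conftest import make_refset, mutate, random_dna

V13 = BUILTIN_REGIONS["V1-V3"]


def synth_ref(insert, seed=50):
    """Full plus-strand sequence: pad + 27F site + insert + 534R site + tail."""
    fwd_site = "AGAGTTTGATCATGGCTCAG"  # 27F with M resolved to A
    rev_site = reverse_complement(PRIMERS["534R"])
    return random_dna(10, seed) + fwd_site + insert + rev_site + random_dna(40, seed + 1)


class TestFindPrimer:
    def test_exact_site_at_offset_zero(self):
        seq = "AGAGTTTGATCATGGCTCAG" + random_dna(50, 51)
        assert find_primer(seq, PRIMERS["27F"], max_mm=0, orientation="fwd") == 0

    def test_mismatch_budget_boundary(self):
        site = "AGAGTTTGATCATGGCTCAG"
        seq = random_dna(20, 52) + mutate(site, [5]) + random_dna(20, 53)
        assert find_primer(seq, PRIMERS["27F"], max_mm=1) == 20
        assert find_primer(seq, PRIMERS["27F"], max_mm=0) is None

    def test_iupac_degenerate_position_matches_both_bases(self):
        # 27F has M (A or C) at position 11
        for base in "AC":
            site = "AGAGTTTGATC" + base + "TGGCTCAG"
            assert find_primer(site, PRIMERS["27F"], max_mm=0) == 0
        site_g = "AGAGTTTGATC" + "G" + "TGGCTCAG"
        assert find_primer(site_g, PRIMERS["27F"], max_mm=0) is None

    def test_reverse_primer_matched_as_revcomp_rightmost(self):
        site = reverse_complement(PRIMERS["534R"])
        seq = site + random_dna(30, 54) + site
        assert find_primer(seq, PRIMERS["534R"], max_mm=0, orientation="rev") == len(site) + 30

    def test_primer_longer_than_sequence(self):
        assert find_primer("ACGT", PRIMERS["27F"]) is None


class TestExtractRegion:
    def test_planted_insert_recovered_exactly(self):
        insert = random_dna(300, 55)
        entry = RefSeqEntry("100A", "X", synth_ref(insert))
        t = extract_region(entry, V13, hmt=100)
        assert t.extraction_status == "ok"
        assert t.sequence == insert

    def test_missing_reverse_site_reported(self):
        insert = random_dna(100, 56)
        seq = random_dna(10, 57) + "AGAGTTTGATCATGGCTCAG" + insert
        t = extract_region(RefSeqEntry("100A", "X", seq), V13)
        assert t.extraction_status == "rev_missing"
        assert t.sequence == ""

    def test_extraction_is_local_to_the_region(self):
        insert = random_dna(200, 58)
        a = RefSeqEntry("100A", "X", synth_ref(insert, seed=60))
        b = RefSeqEntry("101A", "X", synth_ref(insert, seed=70))
        assert extract_region(a, V13).sequence == extract_region(b, V13).sequence


class TestIdentityMatrix:
    def test_identical_regions_score_100(self):
        insert = random_dna(200, 59)
        refset = make_refset({100: synth_ref(insert, 61), 101: synth_ref(insert, 62)})
        ids, mat, _ = region_identity_matrix(refset, V13)
        assert mat[0, 1] == 100.0

    def test_five_diffs_in_500nt_region_gives_99(self):
        insert = random_dna(500, 63)
        refset = make_refset({
            100: synth_ref(insert, 64),
            101: synth_ref(mutate(insert, [50, 150, 250, 350, 450]), 65),
        })
        _, mat, _ = region_identity_matrix(refset, V13)
        assert mat[0, 1] == pytest.approx(99.0)

    def test_symmetry_and_diagonal(self, sim_refset):
        _, refset, _ = sim_refset
        ids, mat, excluded = region_identity_matrix(refset, V13)
        assert excluded == []
        np.testing.assert_array_equal(mat, mat.T)
        np.testing.assert_array_equal(np.diag(mat), 100.0)

    def test_multi_ref_taxon_uses_max_identity(self):
        insert = random_dna(200, 66)
        far = mutate(insert, range(0, 200, 10))
        refset = make_refset({
            100: [synth_ref(insert, 67), synth_ref(far, 68)],
            101: synth_ref(insert, 69),
        })
        _, mat, _ = region_identity_matrix(refset, V13)
        assert mat[0, 1] == 100.0  # any reference pair suffices

    def test_unextractable_taxon_excluded_and_listed(self):
        insert = random_dna(200, 71)
        refset = make_refset({
            100: synth_ref(insert, 72),
            101: synth_ref(mutate(insert, [5]), 73),
            102: random_dna(300, 74),  # no primer sites at all
        })
        ids, _, excluded = region_identity_matrix(refset, V13)
        assert excluded == [102]
        assert ids == [100, 101]


class TestCollapse:
    def test_distinct_taxa_no_groups(self):
        mat = np.full((5, 5), 90.0)
        np.fill_diagonal(mat, 100.0)
        rep = collapse(mat, [1, 2, 3, 4, 5], 100.0)
        assert rep.groups == []
        assert rep.n_indistinguishable == 0

    def test_single_linkage_chains_transitively(self):
        # A-B and B-C at 99.2, A-C at 98.4: one group of 3 at t=99
        mat = np.array([
            [100.0, 99.2, 98.4],
            [99.2, 100.0, 99.2],
            [98.4, 99.2, 100.0],
        ])
        rep = collapse(mat, ["A", "B", "C"], 99.0, "single")
        assert rep.groups == [frozenset({"A", "B", "C"})]
        assert rep.n_indistinguishable == 3

    def test_collapse_at_100_equals_exact_string_classes(self, sim_refset):
        from collections import defaultdict

        from ampliref.regions import _taxon_regions

        _, refset, _ = sim_refset
        ids, mat, _ = region_identity_matrix(refset, V13)
        rep = collapse(mat, ids, 100.0)
        # hashing oracle: group extracted region strings exactly
        by_seq = defaultdict(set)
        for hmt, seqs in _taxon_regions(refset, V13).items():
            for _rid, s in seqs:
                by_seq[s].add(hmt)
        expected = sorted(
            (frozenset(g) for g in by_seq.values() if len(g) >= 2),
            key=lambda g: sorted(g),
        )
        assert rep.groups == expected

    def test_indistinguishable_count_monotone_in_threshold(self, sim_refset):
        _, refset, _ = sim_refset
        ids, mat, _ = region_identity_matrix(refset, V13)
        counts = [collapse(mat, ids, t).n_indistinguishable for t in (100.0, 99.5, 99.0, 98.0)]
        assert counts == sorted(counts)


class TestTrainingSet:
    def test_planted_identical_pair_gets_supraspecies_label(self):
        insert = random_dna(300, 80)
        refset = make_refset(
            {100: synth_ref(insert, 81), 101: synth_ref(insert, 82)},
            genus="Staphylococcus",
        )
        refset.taxa[100].species_epithet = "capitis"
        refset.taxa[101].species_epithet = "caprae"
        ts = build_training_set(refset, V13)
        assert ts.labels[100] == "Staphylococcus_capitis_caprae"
        assert ts.labels[101] == "Staphylococcus_capitis_caprae"
        assert ts.supraspecies == {"Staphylococcus_capitis_caprae": frozenset({100, 101})}

    def test_three_way_group_alphabetical_epithets(self):
        insert = random_dna(300, 83)
        refset = make_refset(
            {100: synth_ref(insert, 84), 101: synth_ref(insert, 85),
             102: synth_ref(insert, 86)},
            genus="Corynebacterium",
        )
        for hmt, ep in [(100, "tuberculostearicum"), (101, "accolens"), (102, "macginleyi")]:
            refset.taxa[hmt].species_epithet = ep
        ts = build_training_set(refset, V13)
        assert set(ts.supraspecies) == {
            "Corynebacterium_accolens_macginleyi_tuberculostearicum"
        }

    def test_no_groups_means_plain_species_labels(self):
        insert = random_dna(300, 87)
        refset = make_refset({
            100: synth_ref(insert, 88),
            101: synth_ref(mutate(insert, [10, 20]), 89),
        })
        ts = build_training_set(refset, V13)
        assert ts.supraspecies == {}
        assert ts.labels == {h: refset.taxa[h].species_label for h in refset.taxa}

    def test_cross_genus_group_flagged_not_merged(self):
        insert = random_dna(300, 90)
        refset = make_refset({100: synth_ref(insert, 91)}, genus="Staphylococcus")
        other = make_refset({101: synth_ref(insert, 92)}, genus="Moraxella")
        refset.add(other.taxa[101])
        ts = build_training_set(refset, V13)
        assert ts.supraspecies == {}
        assert ts.flagged_cross_genus == [frozenset({100, 101})]
        assert ts.labels[100] == refset.taxa[100].species_label

    def test_planted_supraspecies_recovered_with_perfect_precision(self, sim_refset):
        _, refset, truth = sim_refset
        ts = build_training_set(refset, V13)
        assert ts.supraspecies == truth.expected_supraspecies


def test_region_definitions_validated():
    with pytest.raises(ValueError):
        RegionDef("bad", "", "ACGT")
    with pytest.raises(ValueError):
        RegionDef("bad", "ACGT", "ACGT", max_mismatches=-1)
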