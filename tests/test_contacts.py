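import numpy as np
import pytest

from tcrforge import contacts as ct
from tcrforge import synthetic_data as sd


def brute_force_pairs(structure, cdr3_chain, cdr3_range, peptide_chain):
    """Independent O(N^2) all-atom scan used as the oracle."""
    lo, hi = cdr3_range
    out = []
    for cres in structure.chain(cdr3_chain).residues:
        if not lo <= cres.position <= hi:
            continue
        for pres in structure.chain(peptide_chain).residues:
            best = (np.inf, None, None)
            for a in cres.heavy_atoms():
                for b in pres.heavy_atoms():
                    d = float(np.linalg.norm(a.coord - b.coord))
                    if d < best[0]:
                        best = (d, a, b)
            if best[0] < 5.0:
                out.append((cres, pres, best))
    return out


class TestFindContacts:
    def test_matches_generator_manifest(self, toy_complex):
        pairs = ct.find_contacts(
            toy_complex.structure, "C",
            (1, len(toy_complex.cdr3_sequence)), "P",
        )
        got = {
            (p.cdr3_position, p.peptide_position): (
                p.interaction_type.value, p.cdr3_part.value, p.peptide_part.value,
                round(p.min_distance, 6),
            )
            for p in pairs
        }
        want = {
            (e.cdr3_position, e.peptide_position): (
                e.interaction_type, e.cdr3_part, e.peptide_part,
                round(e.min_distance, 6),
            )
            for e in toy_complex.expected_contacts
        }
        assert got == want

    def test_matches_brute_force_scan(self, toy_complex):
        rng = (1, len(toy_complex.cdr3_sequence))
        pairs = ct.find_contacts(toy_complex.structure, "C", rng, "P")
        oracle = brute_force_pairs(toy_complex.structure, "C", rng, "P")
        assert len(pairs) == len(oracle)
        for p, (cres, pres, (d, a, b)) in zip(pairs, oracle):
            assert (p.cdr3_position, p.peptide_position) == (
                cres.position, pres.position
            )
            assert p.min_distance == pytest.approx(d)
            assert (p.cdr3_part is ct.Part.MAIN_CHAIN) == a.is_backbone
            assert (p.peptide_part is ct.Part.MAIN_CHAIN) == b.is_backbone

    def test_residues_beyond_cutoff_yield_no_pair(self):
        res_a = ct.Residue(1, "A", [ct.Atom("CA", "C", [0.0, 0.0, 0.0])])
        res_b = ct.Residue(1, "A", [ct.Atom("CA", "C", [6.2, 0.0, 0.0])])
        structure = ct.Structure(
            chains={"C": ct.Chain("C", [res_a]), "P": ct.Chain("P", [res_b])}
        )
        assert ct.find_contacts(structure, "C", (1, 1), "P") == []

    def test_one_cdr3_residue_two_peptide_partners_single_closest_flag(self):
        cdr3 = ct.Residue(1, "A", [ct.Atom("CB", "C", [0.0, 0.0, 0.0])])
        pep1 = ct.Residue(1, "A", [ct.Atom("CB", "C", [4.0, 0.0, 0.0])])
        pep2 = ct.Residue(2, "A", [ct.Atom("CB", "C", [0.0, 4.0, 0.0])])
        pep3 = ct.Residue(3, "A", [ct.Atom("CB", "C", [0.0, 0.0, 9.0])])
        structure = ct.Structure(
            chains={"C": ct.Chain("C", [cdr3]), "P": ct.Chain("P", [pep1, pep2, pep3])}
        )
        pairs = ct.find_contacts(structure, "C", (1, 1), "P")
        assert len(pairs) == 2
        flags = [p for p in pairs if p.closest_flag]
        assert len(flags) == 1
        # equal distances: tie broken by lower peptide position
        assert flags[0].peptide_position == 1

    def test_empty_cdr3_range_is_an_error(self, toy_complex):
        with pytest.raises(ValueError, match="empty CDR3 range"):
            ct.find_contacts(toy_complex.structure, "C", (50, 60), "P")

    def test_exactly_one_closest_flag_per_contacting_residue(self, toy_complex):
        pairs = ct.find_contacts(
            toy_complex.structure, "C", (1, len(toy_complex.cdr3_sequence)), "P"
        )
        by_res = {}
        for p in pairs:
            by_res.setdefault(p.cdr3_position, []).append(p.closest_flag)
        assert all(sum(flags) == 1 for flags in by_res.values())


def make_pair(cpos, ppos, dist, cpart, ppart, closest=False, itype="VDW"):
    return ct.ContactPair(
        cdr3_position=cpos, cdr3_residue="A", peptide_position=ppos,
        peptide_residue="G", min_distance=dist,
        cdr3_part=ct.Part(cpart), peptide_part=ct.Part(ppart),
        interaction_type=ct.InteractionType(itype), closest_flag=closest,
    )


class TestContactGroups:
    def test_empty_input_gives_four_empty_groups(self):
        assert ct.contact_groups([]) == ([], [], [], [])

    def test_all_main_chain_pairs_leave_groups_3_and_4_empty(self):
        pairs = [
            make_pair(1, 1, 3.0, "main_chain", "main_chain", closest=True),
            make_pair(1, 2, 4.0, "main_chain", "main_chain"),
        ]
        g1, g2, g3, g4 = ct.contact_groups(pairs)
        assert len(g1) == 2 and len(g2) == 1 and g3 == [] and g4 == []

    def test_mixed_set_matches_hand_classification(self):
        pairs = [
            make_pair(1, 1, 2.9, "side_chain", "side_chain", closest=True),
            make_pair(1, 2, 4.5, "side_chain", "main_chain"),
            make_pair(2, 3, 3.2, "main_chain", "main_chain", closest=True),
            make_pair(3, 1, 3.8, "main_chain", "side_chain", closest=True),
            make_pair(3, 2, 4.8, "main_chain", "main_chain"),
        ]
        g1, g2, g3, g4 = ct.contact_groups(pairs)
        assert [len(g) for g in (g1, g2, g3, g4)] == [5, 3, 3, 2]

    def test_group_containment(self, toy_complex):
        pairs = ct.find_contacts(
            toy_complex.structure, "C", (1, len(toy_complex.cdr3_sequence)), "P"
        )
        g1, g2, g3, g4 = (set(map(id, g)) for g in ct.contact_groups(pairs))
        assert g2 <= g1 and g3 <= g1 and g4 <= g2 and g4 <= g3


class TestTypingRules:
    @pytest.mark.parametrize("seed", range(8))
    def test_ionic_pairs_are_oppositely_charged(self, seed):
        plan = ((2, 2, 3.0, "IONIC"), (6, 6, 3.3, "HBOND"))
        data = sd.generate_toy_complex(sd.ToyComplexSpec(contacts=plan, seed=seed))
        pairs = ct.find_contacts(
            data.structure, "C", (1, len(data.cdr3_sequence)), "P"
        )
        for p in pairs:
            if p.interaction_type is ct.InteractionType.IONIC:
                assert (
                    p.cdr3_residue in ct.NEGATIVE_GROUP
                    and p.peptide_residue in ct.POSITIVE_GROUP
                ) or (
                    p.peptide_residue in ct.NEGATIVE_GROUP
                    and p.cdr3_residue in ct.POSITIVE_GROUP
                )
            if p.interaction_type is ct.InteractionType.HBOND:
                cres = data.structure.chain("C").residue_at(p.cdr3_position)
                pres = data.structure.chain("P").residue_at(p.peptide_position)
                from tcrforge.contacts import _acceptor_names, _donor_names

                assert (
                    (_donor_names(cres) and _acceptor_names(pres))
                    or (_donor_names(pres) and _acceptor_names(cres))
                )


class TestSubstitutionContactStatus:
    def test_contacting_and_non_contacting(self):
        pairs = [make_pair(3, 1, 3.0, "side_chain", "side_chain", closest=True)]
        assert ct.substitution_contact_status(3, pairs) == "contacting"
        assert ct.substitution_contact_status(5, pairs) == "non_contacting"


class TestCountContactPairTypes:
    def test_single_pair_counts_in_all_groups(self):
        pair = ct.ContactPair(
            cdr3_position=1, cdr3_residue="D", peptide_position=1,
            peptide_residue="R", min_distance=2.9,
            cdr3_part=ct.Part.SIDE_CHAIN, peptide_part=ct.Part.SIDE_CHAIN,
            interaction_type=ct.InteractionType.IONIC, closest_flag=True,
        )
        tables = ct.count_contact_pair_types([[pair]], [])
        for g in range(1, 5):
            assert tables[g]["modeled"].loc["D", "R"] == 1
            assert ("D", "R") in tables[g]["novel"]

    def test_identical_model_and_original_sets_have_no_novel_pairs(self, toy_complex):
        pairs = ct.find_contacts(
            toy_complex.structure, "C", (1, len(toy_complex.cdr3_sequence)), "P"
        )
        tables = ct.count_contact_pair_types([pairs], [pairs])
        for g in range(1, 5):
            assert tables[g]["novel"] == set()
            assert tables[g]["modeled"].equals(tables[g]["original"])

    def test_counts_equal_brute_force_tallies(self):
        rng_specs = [
            sd.ToyComplexSpec(contacts=((2, 2, 3.0, "IONIC"),), seed=s)
            for s in range(3)
        ]
        models = []
        for spec in rng_specs:
            data = sd.generate_toy_complex(spec)
            models.append(
                ct.find_contacts(data.structure, "C", (1, len(data.cdr3_sequence)), "P")
            )
        tables = ct.count_contact_pair_types(models, models[:1])
        total = sum(len(m) for m in models)
        assert tables[1]["modeled"].values.sum() == total


def test_any_pair_attribution_is_at_least_as_side_chain_as_min_pair(toy_complex):
    rng = (1, len(toy_complex.cdr3_sequence))
    min_pairs = ct.find_contacts(toy_complex.structure, "C", rng, "P")
    any_pairs = ct.find_contacts(
        toy_complex.structure, "C", rng, "P", part_attribution="any_pair"
    )
    assert len(min_pairs) == len(any_pairs)
    for a, b in zip(min_pairs, any_pairs):
        # any_pair can only widen main_chain -> side_chain, never the reverse
        if a.cdr3_part is ct.Part.SIDE_CHAIN:
            assert b.cdr3_part is ct.Part.SIDE_CHAIN
        if a.peptide_part is ct.Part.SIDE_CHAIN:
            assert b.peptide_part is ct.Part.SIDE_CHAIN
    with pytest.raises(ValueError, match="attribution"):
        ct.find_contacts(
            toy_complex.structure, "C", rng, "P", part_attribution="nope"
        )
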