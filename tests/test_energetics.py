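import numpy as np
import pytest

from tcrforge import energetics as en
from tcrforge import modeling as md
from tcrforge import synthetic_data as sd


@pytest.fixture(scope="module")
def toy_structures():
    specs = [
        sd.ToyComplexSpec(
            contacts=((3, 2, 2.9, "IONIC"), (5, 5, 3.2, "HBOND"), (7, 8, 4.2, "VDW")),
            seed=1,
        ),
        sd.ToyComplexSpec(contacts=((2, 2, 3.0, "IONIC"),), seed=5),
        sd.ToyComplexSpec(contacts=((4, 4, 3.4, "HBOND"), (8, 7, 4.5, "VDW")), seed=9),
        sd.ToyComplexSpec(contacts=(), seed=2),
    ]
    return [sd.generate_toy_complex(s) for s in specs]


class TestInterfaceEnergy:
    def test_per_residue_sums_to_total(self, toy_structures):
        for data in toy_structures:
            for preset in en.PRESETS:
                e = en.interface_energy(
                    data.structure, "C", (1, len(data.cdr3_sequence)), "P", preset
                )
                assert abs(e.total - sum(e.per_residue.values())) < 1e-9

    def test_small_patch_equals_large_minus_bb_terms(self, toy_structures):
        for data in toy_structures:
            rng = (1, len(data.cdr3_sequence))
            large = en.interface_energy(data.structure, "C", rng, "P", "large_patch")
            small = en.interface_energy(data.structure, "C", rng, "P", "small_patch")
            removed = large.per_term["hbond_sr_bb"] + large.per_term["hbond_bb_sc"]
            assert small.total == pytest.approx(large.total - removed, abs=1e-9)

    def test_preset_nesting(self):
        assert set(en.SMALL_PATCH_TERMS) < set(en.LARGE_PATCH_TERMS)
        assert set(en.LARGE_PATCH_TERMS) < set(en.FULL_TERMS)
        assert set(en.LARGE_PATCH_TERMS) - set(en.SMALL_PATCH_TERMS) == {
            "hbond_sr_bb", "hbond_bb_sc",
        }

    def test_distant_residues_contribute_zero(self, toy_structures):
        empty = toy_structures[-1]  # no planned contacts; strands far apart
        e = en.interface_energy(
            empty.structure, "C", (1, len(empty.cdr3_sequence)), "P", "small_patch"
        )
        assert e.total == 0.0

    def test_salt_bridge_is_negative_and_stronger_than_ala_pose(self, toy_structures):
        data = toy_structures[1]
        rng = (1, len(data.cdr3_sequence))
        e = en.interface_energy(data.structure, "C", rng, "P", "small_patch")
        assert e.total < 0
        pos = [p for p in data.structure.chain("P").residues if p.aa in "RKH"][0]
        ala = md.surrogate_mutate(data.structure, "P", pos.position, "A")
        e_ala = en.interface_energy(ala, "C", rng, "P", "small_patch")
        assert abs(e.total) > abs(e_ala.total)

    def test_unknown_preset_rejected(self, toy_structures):
        data = toy_structures[0]
        with pytest.raises(ValueError, match="preset"):
            en.interface_energy(data.structure, "C", (1, 11), "P", "medium_patch")


class TestDEnergy:
    def test_identity_substitution_gives_zero(self, toy_structures):
        data = toy_structures[0]
        rng = (1, len(data.cdr3_sequence))
        aa = data.structure.chain("C").residue_at(4).aa
        child = md.surrogate_mutate(data.structure, "C", 4, aa)
        e_par = en.interface_energy(data.structure, "C", rng, "P", "full", "p")
        e_ch = en.interface_energy(child, "C", rng, "P", "full", "c")
        de = en.denergy(e_par, e_ch, (4, aa, aa), 10.0)
        assert de.value == 0.0

    def test_antisymmetry_of_forward_and_reverse(self, toy_structures):
        data = toy_structures[0]
        rng = (1, len(data.cdr3_sequence))
        fwd = md.surrogate_mutate(data.structure, "C", 3, "A")
        e0 = en.interface_energy(data.structure, "C", rng, "P", "full", "0")
        e1 = en.interface_energy(fwd, "C", rng, "P", "full", "1")
        de_fwd = en.denergy(e0, e1, (3, "X", "A"), 3.0)
        de_rev = en.denergy(e1, e0, (3, "A", "X"), 3.0)
        assert de_fwd.value == pytest.approx(-de_rev.value, abs=1e-12)

    def test_removing_the_only_hbond_costs_its_contribution(self):
        data = sd.generate_toy_complex(
            sd.ToyComplexSpec(contacts=((4, 4, 3.0, "HBOND"),), seed=13)
        )
        rng = (1, len(data.cdr3_sequence))
        parent = en.interface_energy(data.structure, "C", rng, "P", "small_patch", "p")
        assert parent.per_term["hbond_sc"] < 0  # the planned bond is there
        # mutate the hydrogen-bonding CDR3 residue to alanine
        child_structure = md.surrogate_mutate(data.structure, "C", 4, "A")
        child = en.interface_energy(child_structure, "C", rng, "P", "small_patch", "c")
        assert child.per_term["hbond_sc"] == 0.0  # and now it is gone
        de = en.denergy(parent, child, (4, data.cdr3_sequence[3], "A"), 3.0)
        # term bookkeeping: dE decomposes into per-term changes, and the
        # hydrogen-bond part of dE is exactly minus the parent's well
        per_term_change = {
            t: child.per_term[t] - parent.per_term[t] for t in child.per_term
        }
        assert de.value == pytest.approx(sum(per_term_change.values()), abs=1e-12)
        assert per_term_change["hbond_sc"] == pytest.approx(
            -parent.per_term["hbond_sc"], abs=1e-12
        )

    def test_preset_mismatch_rejected(self, toy_structures):
        data = toy_structures[0]
        rng = (1, len(data.cdr3_sequence))
        e1 = en.interface_energy(data.structure, "C", rng, "P", "full", "a")
        e2 = en.interface_energy(data.structure, "C", rng, "P", "small_patch", "b")
        with pytest.raises(ValueError, match="preset"):
            en.denergy(e1, e2, (1, "A", "G"), 1.0)

    def test_substitution_beyond_10A_changes_nothing(self, toy_structures):
        data = toy_structures[0]
        rng = (1, len(data.cdr3_sequence))
        # position 10 sits 70 A along the strand from the nearest contact
        d = en.min_residue_distance(data.structure, "C", 10, "P")
        assert d > 10.0
        child = md.surrogate_mutate(data.structure, "C", 10, "W")
        for preset in en.PRESETS:
            e0 = en.interface_energy(data.structure, "C", rng, "P", preset)
            e1 = en.interface_energy(child, "C", rng, "P", preset)
            assert abs(e1.total - e0.total) < 1e-9


class TestValuablePositions:
    def make_energy(self, per_residue, preset="full"):
        return en.InterfaceEnergy(
            model_id="m", preset=preset, total=sum(per_residue.values()),
            per_residue=per_residue,
        )

    def test_unanimous_presets_give_single_position(self):
        e = {p: self.make_energy({5: -1.0, 6: -3.0, 7: -0.5}, p) for p in en.PRESETS}
        assert en.valuable_positions(e) == {6}

    def test_disagreeing_presets_union_their_candidates(self):
        e = {
            "full": self.make_energy({6: -3.0, 7: -1.0}, "full"),
            "large_patch": self.make_energy({6: -2.0, 7: -1.0}, "large_patch"),
            "small_patch": self.make_energy({6: -1.0, 7: -2.0}, "small_patch"),
        }
        assert en.valuable_positions(e) == {6, 7}

    def test_flat_profile_returns_every_position(self):
        e = {"full": self.make_energy({1: -1.0, 2: -1.0, 3: -1.0})}
        assert en.valuable_positions(e) == {1, 2, 3}


class TestValuableSubstitutionRate:
    def test_no_valuable_substitutions(self):
        subs = [(1, "contacting"), (2, "non_contacting")]
        assert en.valuable_substitution_rate(subs, {9}) == (0.0, 0.0)

    def test_hand_tally(self):
        subs = (
            [(6, "contacting")]
            + [(1, "non_contacting")] * 7
            + [(6, "non_contacting")]
            + [(2, "contacting")]
        )
        all_rate, contact_rate = en.valuable_substitution_rate(subs, {6})
        assert all_rate == pytest.approx(0.2)
        assert contact_rate == pytest.approx(0.5)

    def test_empty_input_gives_nan(self):
        all_rate, contact_rate = en.valuable_substitution_rate([], {1})
        assert np.isnan(all_rate) and np.isnan(contact_rate)


def test_planted_distance_effect_gives_negative_correlation():
    """Closer substitutions have larger |dEnergy| by construction; the
    distance / |dEnergy| Pearson correlation must come out negative."""
    from tcrforge import stats_analysis as sa

    df = sd.generate_planted_denergy(
        n=200, index_slope=0.0, distance_slope=-0.3, noise_sigma=0.2, seed=3
    )
    results = sa.distance_energy_correlations(df)
    pooled = [r for r in results if r.stratum == "all"]
    assert pooled and all(r.r < 0 for r in pooled)


class TestPrecomputedEnergies:
    def test_round_trip_and_invariant_check(self, tmp_path):
        import pandas as pd

        rows = [
            {"model_id": "m1", "preset": "full", "total": -3.0,
             "position": 1, "per_residue": -1.0},
            {"model_id": "m1", "preset": "full", "total": -3.0,
             "position": 2, "per_residue": -2.0},
        ]
        p = tmp_path / "pre.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        energies = en.read_precomputed_energies(p)
        e = energies[("m1", "full")]
        assert e.total == -3.0
        assert e.per_residue == {1: -1.0, 2: -2.0}
        # valuable positions work on precomputed profiles too
        assert en.valuable_positions({"full": e}) == {2}

        rows[0]["per_residue"] = 5.0
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="does not match total"):
            en.read_precomputed_energies(p)

    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd

        p = tmp_path / "bad.tsv"
        pd.DataFrame({"model_id": ["m"], "total": [1.0]}).to_csv(
            p, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="missing column"):
            en.read_precomputed_energies(p)
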