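import numpy as np
import pytest

from tcrforge import modeling as md
from tcrforge.clustering import BuildOrder, build_cluster, enumerate_pathways
from tcrforge.io_repertoire import TcrChain


def backbone_coords(structure, chain_id):
    out = {}
    for res in structure.chain(chain_id).residues:
        for atom in res.atoms:
            if atom.is_backbone:
                out[(res.position, atom.name)] = atom.coord.copy()
    return out


class TestSurrogateMutate:
    def test_backbone_heavy_atoms_identical_bitwise(self, toy_complex):
        parent = toy_complex.structure
        child = md.surrogate_mutate(parent, "C", 4, "W")
        pb, cb = backbone_coords(parent, "C"), backbone_coords(child, "C")
        assert pb.keys() == cb.keys()
        assert all(np.array_equal(pb[k], cb[k]) for k in pb)

    def test_only_the_named_residue_changes(self, toy_complex):
        parent = toy_complex.structure
        child = md.surrogate_mutate(parent, "C", 4, "W")
        for res_p, res_c in zip(
            parent.chain("C").residues, child.chain("C").residues
        ):
            if res_p.position == 4:
                continue
            assert res_p.aa == res_c.aa
            assert [a.name for a in res_p.atoms] == [a.name for a in res_c.atoms]
            for ap, ac in zip(res_p.atoms, res_c.atoms):
                assert np.array_equal(ap.coord, ac.coord)

    def test_asp_to_glu_adds_one_heavy_atom(self, toy_complex):
        parent = md.surrogate_mutate(toy_complex.structure, "C", 4, "D")
        child = md.surrogate_mutate(parent, "C", 4, "E")
        n_parent = len(parent.chain("C").residue_at(4).heavy_atoms())
        n_child = len(child.chain("C").residue_at(4).heavy_atoms())
        assert n_child == n_parent + 1
        # CB kept in place
        assert np.array_equal(
            parent.chain("C").residue_at(4).atom("CB").coord,
            child.chain("C").residue_at(4).atom("CB").coord,
        )

    def test_mutation_to_glycine_leaves_backbone_only(self, toy_complex):
        child = md.surrogate_mutate(toy_complex.structure, "C", 4, "G")
        names = {a.name for a in child.chain("C").residue_at(4).atoms}
        assert names == {"N", "CA", "C", "O"}

    def test_glycine_to_alanine_places_ideal_cb(self, toy_complex):
        gly = md.surrogate_mutate(toy_complex.structure, "C", 4, "G")
        ala = md.surrogate_mutate(gly, "C", 4, "A")
        res = ala.chain("C").residue_at(4)
        d = np.linalg.norm(res.atom("CB").coord - res.atom("CA").coord)
        assert 1.5 <= d <= 1.6

    def test_identity_mutation_returns_atom_for_atom_copy(self, toy_complex):
        parent = toy_complex.structure
        aa = parent.chain("C").residue_at(4).aa
        child = md.surrogate_mutate(parent, "C", 4, aa)
        for rp, rc in zip(parent.chain("C").residues, child.chain("C").residues):
            for ap, ac in zip(rp.atoms, rc.atoms):
                assert ap.name == ac.name and np.array_equal(ap.coord, ac.coord)

    def test_chi_angles_copied_where_names_coincide(self, toy_complex):
        # Q -> E keeps CG and CD names, so chi1/chi2 carry over
        parent = md.surrogate_mutate(toy_complex.structure, "C", 4, "Q")
        child = md.surrogate_mutate(parent, "C", 4, "E")
        pres = parent.chain("C").residue_at(4)
        cres = child.chain("C").residue_at(4)
        chi1_p = md.measure_dihedral(
            pres.atom("N").coord, pres.atom("CA").coord,
            pres.atom("CB").coord, pres.atom("CG").coord,
        )
        chi1_c = md.measure_dihedral(
            cres.atom("N").coord, cres.atom("CA").coord,
            cres.atom("CB").coord, cres.atom("CG").coord,
        )
        assert chi1_c == pytest.approx(chi1_p, abs=1e-6)

    def test_missing_backbone_atom_raises(self, toy_complex):
        broken = toy_complex.structure.copy()
        res = broken.chain("C").residue_at(4)
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(md.BuildError, match="CA"):
            md.surrogate_mutate(broken, "C", 4, "W")


def _three_step_orders(template, core):
    s1 = "G" + core[1:] if core[0] != "G" else "L" + core[1:]
    s2 = s1[:1] + ("G" if s1[1] != "G" else "L") + s1[2:]
    s3 = s2[:10] + ("G" if s2[10] != "G" else "L")
    return [
        BuildOrder(template=template, chain=TcrChain.ALPHA, prefix=(core, s1)),
        BuildOrder(template=template, chain=TcrChain.ALPHA, prefix=(core, s1, s2)),
        BuildOrder(template=template, chain=TcrChain.ALPHA, prefix=(core, s1, s2, s3)),
    ]


class TestRunBuilds:
    def test_three_step_pathway_chains_parent_to_child(self, toy_template):
        core = toy_template.core_records[TcrChain.ALPHA].cdr3
        orders = _three_step_orders(toy_template, core)
        builds = md.run_builds(orders)
        assert [b.status for b in builds] == ["ok", "ok", "ok"]
        assert builds[0].parent_structure is toy_template.structure
        assert builds[1].parent_structure is builds[0].child_structure
        assert builds[2].parent_structure is builds[1].child_structure
        # sequence bookkeeping: the child structure carries the child CDR3
        for b in builds:
            seq = b.child_structure.subsequence("C", toy_template.cdr3_alpha_range)
            assert seq == b.order.child_cdr3

    def test_failed_build_skips_descendants_and_continues(self, toy_template):
        core = toy_template.core_records[TcrChain.ALPHA].cdr3
        orders = _three_step_orders(toy_template, core)

        class FailingBackend(md.SurrogateBackend):
            name = "failing"

            def mutate(self, parent, chain_id, position, to_aa):
                if position == 2:  # the second step mutates position 2
                    raise md.BuildError("boom")
                return super().mutate(parent, chain_id, position, to_aa)

        builds = md.run_builds(orders, backend=FailingBackend())
        assert [b.status for b in builds] == ["ok", "failed", "skipped"]
        with pytest.raises(md.BuildError):
            md.run_builds(orders, backend=FailingBackend(), fail_fast=True)

    def test_determinism_across_runs(self, toy_template):
        core = toy_template.core_records[TcrChain.ALPHA].cdr3
        orders = _three_step_orders(toy_template, core)
        for optimization in ("minimized", "repacked"):
            runs = [md.run_builds(orders, optimization=optimization) for _ in range(2)]
            for b1, b2 in zip(*runs):
                r1 = b1.child_structure.chain("C").residues
                r2 = b2.child_structure.chain("C").residues
                for res1, res2 in zip(r1, r2):
                    for a1, a2 in zip(res1.atoms, res2.atoms):
                        assert np.array_equal(a1.coord, a2.coord)

    def test_sequence_bookkeeping_over_enumerated_pathways(
        self, toy_template, record_factory
    ):
        core_rec = toy_template.core_records[TcrChain.ALPHA]
        core = core_rec.cdr3
        m1 = "G" + core[1:] if core[0] != "G" else "L" + core[1:]
        m2 = m1[:5] + ("G" if m1[5] != "G" else "L") + m1[6:]
        cluster = build_cluster(
            core_rec, toy_template,
            [record_factory(s, v=core_rec.v_gene, j=core_rec.j_gene,
                            epitope=core_rec.epitope) for s in (m1, m2)],
        )
        for pathway in enumerate_pathways(cluster):
            seq = list(pathway.steps[0])
            for pos, _, to_aa in pathway.substitutions:
                seq[pos - 1] = to_aa
            assert "".join(seq) == pathway.final


class TestGroupNonredundant:
    def test_same_chains_and_final_cdr3_group_together(self, toy_template):
        import copy

        other = copy.deepcopy(toy_template)
        other.pdb_id = "toy2"
        core = toy_template.core_records[TcrChain.ALPHA].cdr3
        target = "G" + core[1:] if core[0] != "G" else "L" + core[1:]
        builds = []
        for template in (toy_template, other):
            orders = [BuildOrder(template=template, chain=TcrChain.ALPHA,
                                 prefix=(core, target))]
            builds.extend(md.run_builds(orders))
        groups = md.group_nonredundant(builds)
        assert len(groups) == 1
        assert len(next(iter(groups.values()))) == 2

    def test_different_final_cdr3_stay_separate(self, toy_template):
        core = toy_template.core_records[TcrChain.ALPHA].cdr3
        t1 = "G" + core[1:] if core[0] != "G" else "L" + core[1:]
        t2 = core[:3] + ("G" if core[3] != "G" else "L") + core[4:]
        orders = [
            BuildOrder(template=toy_template, chain=TcrChain.ALPHA, prefix=(core, t1)),
            BuildOrder(template=toy_template, chain=TcrChain.ALPHA, prefix=(core, t2)),
        ]
        groups = md.group_nonredundant(md.run_builds(orders))
        assert len(groups) == 2
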