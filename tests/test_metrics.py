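"""Superposition, LRMSD, normalized target, DockQ and buried surface."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepscore import (
    capri_class,
    contact_surface,
    dockq,
    lrmsd,
    lrmsd_norm,
    make_fixture_complex,
    superpose,
)
from pepscore.metrics import total_sasa


def translate_peptide(cplx, vec):
    out = cplx.copy()
    for res in out.peptide:
        for atom in res.atoms.values():
            atom.coord = atom.coord + np.asarray(vec, float)
    return out


def rigid_transform(cplx, rot, shift):
    out = cplx.copy()
    for chain in (out.receptor, out.peptide):
        for res in chain:
            for atom in res.atoms.values():
                atom.coord = rot @ atom.coord + shift
    return out


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(12, 3))
        applied = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ applied.T
        res = superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.rotation, applied.T, atol=1e-6)

    def test_mirror_gives_proper_rotation(self):
        chiral = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 2.0]])
        mirrored = chiral * np.array([1, 1, -1.0])
        res = superpose(mirrored, chiral)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1

    def test_optimality_against_random_transforms(self, rng):
        target = rng.normal(size=(8, 3)) * 5
        mobile = rng.normal(size=(8, 3)) * 5
        best = superpose(mobile, target).rmsd
        for _ in range(1000):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3) * 3
            moved = mobile @ R.T + t
            rmsd = np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))
            assert rmsd >= best - 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLrmsd:
    def test_self_is_zero(self, fixture_complex):
        assert lrmsd(fixture_complex, fixture_complex) == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_closed_form(self, fixture_complex):
        moved = translate_peptide(fixture_complex, [0, 0, 3.0])
        assert lrmsd(moved, fixture_complex) == pytest.approx(3.0, abs=1e-6)

    def test_global_rigid_transform_invariance(self, fixture_complex, rng):
        moved = translate_peptide(fixture_complex, [1.0, 2.0, 0.5])
        base = lrmsd(moved, fixture_complex)
        rot = Rotation.random(rng=rng).as_matrix()
        transformed = rigid_transform(moved, rot, rng.normal(size=3) * 30)
        assert lrmsd(transformed, fixture_complex) == pytest.approx(base, abs=1e-6)

    def test_correspondence_mismatch_reported(self, fixture_complex):
        other = make_fixture_complex(seed=5)
        with pytest.raises(ValueError, match="differing|mismatch"):
            lrmsd(other, fixture_complex)

    def test_ca_only_atom_set(self, fixture_complex):
        moved = translate_peptide(fixture_complex, [2.0, 0, 0])
        assert lrmsd(moved, fixture_complex, atom_names=("CA",)) == pytest.approx(
            2.0, abs=1e-6
        )


class TestLrmsdNorm:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 1.0), (8.0, 0.5), (24.0, 0.1)],
    )
    def test_printed_formula_values(self, value, expected):
        assert lrmsd_norm(value) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing(self):
        xs = np.linspace(0, 60, 200)
        ys = [lrmsd_norm(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))
        assert 0 < ys[-1] < 0.02

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lrmsd_norm(-0.1)


class TestDockq:
    def test_self_comparison(self, fixture_complex):
        rep = dockq(fixture_complex, fixture_complex)
        assert rep.fnat == 1.0
        assert rep.irmsd == pytest.approx(0.0, abs=1e-9)
        assert rep.lrmsd == pytest.approx(0.0, abs=1e-9)
        assert rep.dockq == pytest.approx(1.0, abs=1e-9)
        assert rep.capri_class == "High"

    def test_displaced_peptide_scores_near_zero(self, fixture_complex):
        far = translate_peptide(fixture_complex, [0, 100.0, 0])
        rep = dockq(far, fixture_complex)
        assert rep.fnat == 0.0
        assert rep.dockq < 0.05
        assert rep.capri_class == "Incorrect"

    def test_fnat_counts_preserved_contacts(self, fixture_complex):
        """fnat equals the brute-force contact-preservation fraction."""
        from scipy.spatial.distance import cdist

        moved = translate_peptide(fixture_complex, [0, 2.5, 0.0])
        rep = dockq(moved, fixture_complex)

        def contacts(cplx):
            out = set()
            for i, rr in enumerate(cplx.receptor):
                for j, pr in enumerate(cplx.peptide):
                    if cdist(rr.heavy_coords(), pr.heavy_coords()).min() < 5.0:
                        out.add((i, j))
            return out

        native = contacts(fixture_complex)
        preserved = native & contacts(moved)
        assert rep.fnat == pytest.approx(len(preserved) / len(native), abs=1e-12)
        assert 0.0 < rep.fnat < 1.0

    def test_rigid_transform_invariance(self, fixture_complex, rng):
        moved = translate_peptide(fixture_complex, [0.5, 1.0, 0.2])
        base = dockq(moved, fixture_complex)
        rot = Rotation.random(rng=rng).as_matrix()
        transformed = rigid_transform(moved, rot, rng.normal(size=3) * 10)
        again = dockq(transformed, fixture_complex)
        assert again.dockq == pytest.approx(base.dockq, abs=1e-6)
        assert again.fnat == base.fnat


class TestCapriClass:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.10, "Incorrect"), (0.229, "Incorrect"),
            (0.23, "Acceptable"), (0.48, "Acceptable"),
            (0.49, "Medium"), (0.50, "Medium"), (0.79, "Medium"),
            (0.80, "High"), (1.0, "High"),
        ],
    )
    def test_boundaries(self, value, label):
        assert capri_class(value) == label

    def test_monotone_in_dockq(self):
        order = ["Incorrect", "Acceptable", "Medium", "High"]
        ranks = [order.index(capri_class(v)) for v in np.linspace(0, 1, 101)]
        assert ranks == sorted(ranks)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            capri_class(1.2)


class TestContactSurface:
    def test_distant_chains_bury_nothing(self, fixture_complex):
        far = translate_peptide(fixture_complex, [0, 1000.0, 0])
        assert contact_surface(far.receptor, far.peptide) == pytest.approx(
            0.0, abs=1.0
        )

    def test_fixture_exceeds_eligibility_threshold(self, fixture_complex):
        assert contact_surface(fixture_complex.receptor, fixture_complex.peptide) > 200.0

    def test_symmetric_in_chain_order(self, fixture_complex):
        a = contact_surface(fixture_complex.receptor, fixture_complex.peptide)
        b = contact_surface(fixture_complex.peptide, fixture_complex.receptor)
        assert a == pytest.approx(b, abs=1e-6)

    def test_single_atom_sasa_matches_analytic_sphere(self):
        """Isolated carbon SASA equals 4 pi (r_vdw + probe)^2 within sampling error."""
        from pepscore.structure import Atom, Chain, Residue

        res = Residue(name3="GLY", one_letter="G", chain_id="X", author_seq=1,
                      index=0, atoms={"CA": Atom("CA", "C", [0.0, 0.0, 0.0])})
        chain = Chain(id="X", residues=[res])
        import biotite.structure.info as info

        r_vdw = info.vdw_radius_single("C")
        analytic = 4.0 * np.pi * (r_vdw + 1.4) ** 2
        assert total_sasa([chain]) == pytest.approx(analytic, rel=0.05)

    def test_against_independent_sasa_implementation(self, fixture_complex):
        """Buried area agrees with mdtraj's Shrake-Rupley within 10%."""
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as elem
        from mdtraj.core.topology import Topology

        def md_sasa(chains):
            top = Topology()
            coords = []
            for chain in chains:
                ch = top.add_chain()
                for res in chain:
                    r = top.add_residue("GLY", ch)
                    for atom in res.atoms.values():
                        if atom.element == "H":
                            continue
                        top.add_atom(atom.name, elem.get_by_symbol(atom.element), r)
                        coords.append(atom.coord / 10.0)  # nm
            traj = mdtraj.Trajectory(np.array(coords)[None], top)
            return float(mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum()) * 100.0

        rec, pep = fixture_complex.receptor, fixture_complex.peptide
        ours = contact_surface(rec, pep)
        theirs = (md_sasa([rec]) + md_sasa([pep]) - md_sasa([rec, pep])) / 2.0
        assert ours == pytest.approx(theirs, rel=0.10)
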