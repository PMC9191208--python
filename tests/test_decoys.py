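"""Fixture generation, perturbation moves, salvageability, balanced sets."""

import numpy as np
import pytest

from pepscore import (
    PerturbationParams,
    assemble_balanced_set,
    is_salvageable,
    lrmsd,
    make_fixture_complex,
    perturb_native,
    select_peptide_complexes,
)
from pepscore.decoys import SALVAGE_MIN_WINDOW, propose_move
from pepscore.metrics import BACKBONE_ATOMS, receptor_superposition


def brute_force_salvageable(decoy, native):
    """Independent reference: naive RMSD over every window, no shortcuts."""
    sup = receptor_superposition(decoy, native)
    n = len(decoy.peptide)
    coords = []
    for rm, rn in zip(decoy.peptide, native.peptide):
        pairs = [
            (sup.apply(rm.atoms[a].coord), rn.atoms[a].coord)
            for a in BACKBONE_ATOMS if a in rm.atoms and a in rn.atoms
        ]
        coords.append(pairs)
    def rmsd(pairs):
        d = np.array([m - t for m, t in pairs])
        return np.sqrt((d ** 2).sum(axis=1).mean())
    full = rmsd([p for res in coords for p in res])
    if full < 5.5:
        return True
    min_len = max(int(np.ceil(n / 2)), SALVAGE_MIN_WINDOW)
    for length in range(min_len, n + 1):
        for start in range(n - length + 1):
            window = [p for res in coords[start:start + length] for p in res]
            if rmsd(window) < 4.0:
                return True
    return False


class TestMakeFixtureComplex:
    def test_passes_eligibility_filters(self, fixture_complex):
        found = select_peptide_complexes(
            [fixture_complex.receptor, fixture_complex.peptide]
        )
        assert len(found) == 1

    def test_ca_trace_spacing(self):
        for seed in range(3):
            cplx = make_fixture_complex(seed=seed)
            for chain in (cplx.receptor, cplx.peptide):
                ca = np.array([r.ca for r in chain])
                gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
                assert gaps.min() >= 3.7 and gaps.max() <= 3.9

    def test_deterministic_per_seed(self):
        a = make_fixture_complex(seed=7)
        b = make_fixture_complex(seed=7)
        for ca, cb in ((a.receptor, b.receptor), (a.peptide, b.peptide)):
            for ra, rb in zip(ca, cb):
                assert ra.name3 == rb.name3
                for name, atom in ra.atoms.items():
                    np.testing.assert_array_equal(atom.coord, rb.atoms[name].coord)

    def test_seeds_differ(self):
        a = make_fixture_complex(seed=0)
        b = make_fixture_complex(seed=1)
        assert a.receptor.sequence() != b.receptor.sequence()

    @pytest.mark.parametrize(
        "kwargs", [{"receptor_len": 49}, {"peptide_len": 1}, {"peptide_len": 26}]
    )
    def test_parameter_bounds(self, kwargs):
        with pytest.raises(ValueError):
            make_fixture_complex(seed=0, **kwargs)


class TestPerturbNative:
    def test_tiny_scales_give_tiny_lrmsd(self, fixture_complex, rng):
        params = PerturbationParams(
            translation_scale=1e-6, rotation_scale=1e-6, internal_scale=1e-6
        )
        rec = perturb_native(fixture_complex, params, rng)
        assert rec.lrmsd_to_native < 1e-4
        assert rec.target == pytest.approx(1.0, abs=1e-6)

    def test_pure_translation_closed_form(self, fixture_complex, rng):
        params = PerturbationParams(
            translation_scale=3.0, rotation_scale=1e-9, internal_scale=1e-9
        )
        rec = perturb_native(fixture_complex, params, rng)
        assert rec.lrmsd_to_native == pytest.approx(3.0, abs=1e-4)

    def test_receptor_never_moves(self, fixture_complex, rng):
        params = PerturbationParams()
        rec = perturb_native(fixture_complex, params, rng)
        for orig, new in zip(fixture_complex.receptor, rec.complex.receptor):
            for name, atom in orig.atoms.items():
                np.testing.assert_array_equal(new.atoms[name].coord, atom.coord)

    def test_distribution_sane(self, fixture_complex, rng):
        values = [
            lrmsd(propose_move(fixture_complex, PerturbationParams(), rng),
                  fixture_complex)
            for _ in range(300)
        ]
        values = np.array(values)
        assert np.all(np.isfinite(values))
        assert values.std() > 0.5
        assert values.min() > 0

    def test_target_consistent_with_lrmsd(self, fixture_complex, rng):
        from pepscore import lrmsd_norm

        rec = perturb_native(fixture_complex, PerturbationParams(), rng)
        assert rec.target == pytest.approx(lrmsd_norm(rec.lrmsd_to_native), abs=1e-12)


class TestIsSalvageable:
    def test_global_threshold(self, fixture_complex, rng):
        params = PerturbationParams(
            translation_scale=5.4, rotation_scale=1e-9, internal_scale=1e-9
        )
        rec = perturb_native(fixture_complex, params, rng)
        assert rec.lrmsd_to_native == pytest.approx(5.4, abs=1e-3)
        assert rec.salvageable

    def test_window_rescues_global_failure(self, fixture_complex):
        # keep the first 6 residues native, swing the rest far away
        decoy = fixture_complex.copy()
        for res in decoy.peptide.residues[6:]:
            for atom in res.atoms.values():
                atom.coord = atom.coord + np.array([0.0, 0.0, 12.0])
        flag, diag = is_salvageable(decoy, fixture_complex)
        assert diag["lrmsd"] >= 5.5
        assert flag
        assert diag["window_lrmsd"] < 4.0
        assert diag["length"] >= 6

    def test_all_windows_bad(self, fixture_complex):
        decoy = fixture_complex.copy()
        for res in decoy.peptide:
            for atom in res.atoms.values():
                atom.coord = atom.coord + np.array([0.0, 0.0, 8.0])
        flag, diag = is_salvageable(decoy, fixture_complex)
        assert not flag

    @pytest.mark.parametrize("seed", [0, 1])
    def test_agrees_with_brute_force(self, seed):
        native = make_fixture_complex(seed=seed)
        rng = np.random.default_rng(seed + 100)
        agree = 0
        for _ in range(60):
            decoy = propose_move(native, PerturbationParams(), rng)
            flag, _ = is_salvageable(decoy, native)
            assert flag == brute_force_salvageable(decoy, native)
            agree += 1
        assert agree == 60

    def test_short_peptide_rejected(self, fixture_complex):
        from pepscore.structure import Chain, PepComplex

        stub = PepComplex(
            receptor=fixture_complex.receptor,
            peptide=Chain(id="P", residues=fixture_complex.peptide.residues[:1]),
        )
        with pytest.raises(ValueError):
            is_salvageable(stub, stub)


class TestAssembleBalancedSet:
    def test_exact_half_split(self, fixture_complex):
        records = assemble_balanced_set(
            fixture_complex, 20, rng=np.random.default_rng(0)
        )
        assert len(records) == 20
        assert sum(r.salvageable for r in records) == 10

    def test_extreme_start_scales_adapt(self, fixture_complex):
        params = PerturbationParams(translation_scale=100.0, adapt_factor=1.5)
        records = assemble_balanced_set(
            fixture_complex, 2, params, np.random.default_rng(1)
        )
        assert sum(r.salvageable for r in records) == 1

    def test_odd_n_rejected(self, fixture_complex):
        with pytest.raises(ValueError):
            assemble_balanced_set(fixture_complex, 7, rng=np.random.default_rng(0))

    def test_adaptive_fraction_near_half(self, fixture_complex):
        """The adaptive schedule hovers around the salvageability boundary."""
        rng = np.random.default_rng(2)
        params = PerturbationParams()
        flags = []
        for _ in range(800):
            rec = perturb_native(fixture_complex, params, rng)
            flags.append(rec.salvageable)
            factor = params.adapt_factor if rec.salvageable else 1 / params.adapt_factor
            params = params.scaled(factor)
        frac = np.mean(flags[100:])
        assert abs(frac - 0.5) < 0.1

    def test_manifest_round_trip(self, fixture_complex, tmp_path):
        from pepscore.decoys import write_decoy_set

        records = assemble_balanced_set(
            fixture_complex, 4, rng=np.random.default_rng(3)
        )
        manifest = write_decoy_set(records, tmp_path / "set")
        lines = open(manifest).read().strip().splitlines()
        assert lines[0].split("\t") == ["file", "scheme", "lrmsd", "target", "salvageable"]
        assert len(lines) == 5
        assert sum(int(l.split("\t")[-1]) for l in lines[1:]) == 2
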