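import numpy as np
import pytest

from fieldqsar import (Atom, AlignedMolecule, FieldConfig, Lattice,
                       assemble_fields, build_lattice, column_filter,
                       comfa_electrostatic, comfa_probe, comfa_steric,
                       comsia_field, comsia_probe, write_dx)
from fieldqsar.fields import FieldMatrix, load_field_matrix, save_field_matrix


def _mol(positions, charges=None, element="C", mol_id="m"):
    positions = np.atleast_2d(positions)
    charges = charges if charges is not None else [0.0] * len(positions)
    return AlignedMolecule(mol_id, [
        Atom(element=element, position=np.asarray(p, float), partial_charge=q,
             vdw_radius=1.7, hydrophobicity_weight=1.0)
        for p, q in zip(positions, charges)])


def _point_lattice(position=(0.0, 0.0, 0.0)):
    return Lattice(origin=tuple(position), spacing=1.0, dims=(1, 1, 1))


CFG = FieldConfig()


class TestLattice:
    def test_single_atom_margin_four_gives_125_points(self):
        lat = build_lattice([_mol([0, 0, 0])], spacing=2.0, margin=4.0)
        assert lat.dims == (5, 5, 5)
        assert lat.n_points == 125
        pts = lat.points()
        assert pts.min() == -4.0 and pts.max() == 4.0

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_lattice([_mol([0, 0, 0])], spacing=0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_lattice([], spacing=2.0)

    def test_all_atoms_contained(self):
        mols = [_mol([[0, 0, 0], [3, -2, 1]]), _mol([[-5, 1, 2]], mol_id="m2")]
        lat = build_lattice(mols, spacing=2.0, margin=4.0)
        for m in mols:
            assert lat.contains(m.coords)


class TestComfaSteric:
    def test_far_field_vanishes(self):
        e = comfa_steric(_mol([50.0, 0, 0]), _point_lattice(), comfa_probe(), CFG)
        assert abs(e[0]) < 1e-6

    def test_energy_minimum_at_contact_distance(self):
        # at r = R_vdw + R_probe the 6-12 form hits exactly -eps
        rstar = 1.7 + 1.52
        e = comfa_steric(_mol([rstar, 0, 0]), _point_lattice(), comfa_probe(), CFG)
        eps = np.sqrt(0.1 * 0.1)
        assert e[0] == pytest.approx(-eps, abs=1e-10)

    def test_overlap_capped_at_cutoff(self):
        e = comfa_steric(_mol([0, 0, 0]), _point_lattice(), comfa_probe(), CFG)
        assert e[0] == 30.0

    def test_additive_below_cap(self):
        m1 = _mol([4.0, 0, 0])
        m2 = _mol([0, 4.0, 0])
        both = _mol([[4.0, 0, 0], [0, 4.0, 0]])
        probe = comfa_probe()
        e = comfa_steric(both, _point_lattice(), probe, CFG)
        e1 = comfa_steric(m1, _point_lattice(), probe, CFG)
        e2 = comfa_steric(m2, _point_lattice(), probe, CFG)
        assert e[0] == pytest.approx(e1[0] + e2[0], abs=1e-12)


class TestComfaElectrostatic:
    def test_coulomb_form_then_cap(self):
        # 332.0636 * (+1)(+1) / (D(r) r) with D(r)=r at r=2 is 83.016,
        # far beyond the 30 kcal/mol clamp
        e = comfa_electrostatic(_mol([2.0, 0, 0], charges=[1.0]),
                                _point_lattice(), comfa_probe(), CFG)
        assert e[0] == 30.0
        loose = FieldConfig(energy_cutoff=100.0)
        e = comfa_electrostatic(_mol([2.0, 0, 0], charges=[1.0]),
                                _point_lattice(), comfa_probe(), loose)
        assert e[0] == pytest.approx(332.0636 / 4.0, abs=1e-3)

    def test_zero_charges_zero_field(self):
        e = comfa_electrostatic(_mol([[1, 2, 3], [0, 1, 0]]),
                                _point_lattice(), comfa_probe(), CFG)
        assert np.all(e == 0.0)

    def test_antisymmetric_in_charge(self):
        lat = _point_lattice()
        ep = comfa_electrostatic(_mol([3.0, 0, 0], charges=[0.4]),
                                 lat, comfa_probe(), CFG)
        em = comfa_electrostatic(_mol([3.0, 0, 0], charges=[-0.4]),
                                 lat, comfa_probe(), CFG)
        assert np.allclose(ep, -em)


class TestComsia:
    def test_unit_weight_at_probe_gives_minus_one(self):
        m = _mol([0, 0, 0])
        m.atoms[0].vdw_radius = 1.0  # steric weight r^3 = 1
        a = comsia_field(m, _point_lattice(), "S", comsia_probe(), CFG)
        assert a[0] == pytest.approx(-1.0, abs=1e-12)

    def test_gaussian_attenuation_closed_form(self):
        m = _mol([1.0, 0, 0])
        m.atoms[0].vdw_radius = 1.0
        a = comsia_field(m, _point_lattice(), "S", comsia_probe(), CFG)
        assert a[0] == pytest.approx(-np.exp(-0.3), abs=1e-10)

    def test_additivity_over_atoms(self):
        one = _mol([1.5, 0.5, 0])
        two = _mol([[1.5, 0.5, 0], [1.5, 0.5, 0]])
        a1 = comsia_field(one, _point_lattice(), "H", comsia_probe(), CFG)
        a2 = comsia_field(two, _point_lattice(), "H", comsia_probe(), CFG)
        assert a2[0] == pytest.approx(2 * a1[0], abs=1e-12)

    def test_unknown_property_rejected(self):
        with pytest.raises(ValueError):
            comsia_field(_mol([0, 0, 0]), _point_lattice(), "X",
                         comsia_probe(), CFG)

    def test_nonpositive_for_positive_weights(self, small_set):
        mols, _, _ = small_set
        lat = build_lattice(mols[:3])
        for prop in ("S",):
            vals = comsia_field(mols[0], lat, prop, comsia_probe(), CFG)
            assert np.all(vals <= 1e-12)
            assert np.all(np.isfinite(vals))


def test_translation_equivariance(small_set):
    mols, _, _ = small_set
    m = mols[0]
    lat = build_lattice([m], spacing=2.0, margin=4.0)
    shift = np.array([13.7, -4.2, 8.9])
    m2 = AlignedMolecule(m.id, [
        Atom(a.element, a.position + shift, a.partial_charge, a.vdw_radius,
             a.hydrophobicity_weight, a.hbd_weight, a.hba_weight)
        for a in m.atoms])
    lat2 = Lattice(origin=tuple(np.asarray(lat.origin) + shift),
                   spacing=lat.spacing, dims=lat.dims)
    cfg = FieldConfig()
    for fn, probe in ((comfa_steric, comfa_probe()),
                      (comfa_electrostatic, comfa_probe())):
        assert np.allclose(fn(m, lat, probe, cfg), fn(m2, lat2, probe, cfg),
                           atol=1e-8)
    for prop in ("S", "E", "H"):
        assert np.allclose(comsia_field(m, lat, prop, comsia_probe(), cfg),
                           comsia_field(m2, lat2, prop, comsia_probe(), cfg),
                           atol=1e-8)


def test_comfa_values_bounded_by_cutoff(small_set):
    mols, _, truth = small_set
    fm = assemble_fields(mols, truth.lattice, FieldConfig(), method="comfa")
    assert fm.values.max() <= 30.0 + 1e-9
    assert fm.values.min() >= -30.0 - 1e-9


class TestAssemble:
    def test_shape_and_identical_rows(self, small_set):
        mols, _, truth = small_set
        cfg = FieldConfig(fields_enabled=("S", "E"))
        fm = assemble_fields([mols[0], mols[0]], truth.lattice, cfg, "comfa")
        assert fm.values.shape == (2, 2 * truth.lattice.n_points)
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_dropping_a_block_shrinks_by_one_block(self, small_set):
        mols, _, truth = small_set
        n = truth.lattice.n_points
        fm2 = assemble_fields(mols, truth.lattice,
                              FieldConfig(fields_enabled=("S", "E")), "comfa")
        fm1 = assemble_fields(mols, truth.lattice,
                              FieldConfig(fields_enabled=("S",)), "comfa")
        assert fm2.values.shape[1] - fm1.values.shape[1] == n

    def test_molecule_outside_lattice_named(self, small_set):
        mols, _, truth = small_set
        far = AlignedMolecule("runaway", [
            Atom("C", np.array([500.0, 0, 0]))])
        with pytest.raises(ValueError, match="runaway"):
            assemble_fields(mols + [far], truth.lattice, FieldConfig(), "comfa")

    def test_comsia_five_blocks(self, small_set):
        mols, _, truth = small_set
        cfg = FieldConfig(fields_enabled=("S", "E", "H", "D", "A"))
        fm = assemble_fields(mols, truth.lattice, cfg, "comsia")
        assert len(fm.blocks) == 5
        assert fm.values.shape[1] == 5 * truth.lattice.n_points


class TestColumnFilter:
    def _fm(self, values):
        values = np.asarray(values, float)
        return FieldMatrix(values=values,
                           compound_ids=[f"c{i}" for i in range(len(values))],
                           field_labels=np.array(["comfa:S"] * values.shape[1]),
                           point_indices=np.arange(values.shape[1]),
                           lattice=Lattice((0, 0, 0), 1.0, (values.shape[1], 1, 1)),
                           method="comfa")

    def test_constant_column_always_masked(self):
        fm = self._fm([[1.0, 5.0], [1.0, 9.0], [1.0, 1.0]])
        out = column_filter(fm, 2.0)
        assert not out.column_mask[0]

    def test_sigma_zero_keeps_everything(self):
        fm = self._fm([[1.0, 5.0], [1.0, 9.0]])
        assert column_filter(fm, 0.0).column_mask.all()

    def test_hand_built_sds_threshold(self):
        # column sds (sample) are 0.5 and 3.0; sigma 2.0 keeps only one
        fm = self._fm([[0.0, 0.0], [0.5, 3.0], [1.0, 6.0]])
        sds = np.std(fm.values, axis=0, ddof=1)
        assert sds == pytest.approx([0.5, 3.0])
        out = column_filter(fm, 2.0)
        assert list(out.column_mask) == [False, True]

    def test_masked_columns_stay_in_matrix(self):
        fm = self._fm([[1.0, 5.0], [1.0, 9.0], [1.0, 1.0]])
        out = column_filter(fm, 2.0)
        assert out.values.shape == fm.values.shape
        assert out.modeling_matrix().shape[1] == int(out.column_mask.sum())


def test_margin_extension_preserves_shared_points(small_set):
    mols, _, _ = small_set
    cfg = FieldConfig(fields_enabled=("S",))
    lat1 = build_lattice(mols, spacing=2.0, margin=4.0)
    lat2 = Lattice(origin=tuple(np.asarray(lat1.origin) - 2.0),
                   spacing=2.0, dims=tuple(d + 2 for d in lat1.dims))
    f1 = comfa_steric(mols[0], lat1, comfa_probe(), cfg)
    f2 = comfa_steric(mols[0], lat2, comfa_probe(), cfg)
    pts1 = {tuple(np.round(p, 6)): v for p, v in zip(lat1.points(), f1)}
    pts2 = {tuple(np.round(p, 6)): v for p, v in zip(lat2.points(), f2)}
    shared = set(pts1) & set(pts2)
    assert len(shared) == lat1.n_points
    for key in shared:
        assert pts1[key] == pytest.approx(pts2[key], abs=1e-10)


def test_field_matrix_round_trip(small_fm, tmp_path):
    save_field_matrix(small_fm, tmp_path / "fm")
    back = load_field_matrix(tmp_path / "fm")
    assert np.array_equal(back.values, small_fm.values)
    assert np.array_equal(back.column_mask, small_fm.column_mask)
    assert back.lattice == small_fm.lattice
    assert back.block_scale == small_fm.block_scale


def test_dx_export_writes_grid(small_set, tmp_path):
    _, _, truth = small_set
    lat = truth.lattice
    path = tmp_path / "grid.dx"
    write_dx(path, lat, np.arange(lat.n_points, dtype=float))
    text = path.read_text()
    assert f"counts {lat.dims[0]} {lat.dims[1]} {lat.dims[2]}" in text
    assert f"items {lat.n_points}" in text
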