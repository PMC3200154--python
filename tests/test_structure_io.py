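import numpy as np
import pytest

from enscon.errors import FormatError, StructureError
from enscon.structure_io import (
    DomainDefinition,
    StructureModel,
    ResidueRecord,
    load_ensemble,
    load_model,
    parse_domain,
    write_model_pdb,
)
from enscon.synthetic import make_reference

from helpers import atom_line, write_pdb


def test_representative_atom_is_cb_and_ca_for_glycine(tmp_path):
    """ALA uses its CB coordinate, GLY its CA coordinate."""
    p = tmp_path / "m.pdb"
    write_pdb(p, [
        atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CB", "ALA", 1, 1.0, 0.0, 0.0),
        atom_line(3, "CA", "GLY", 2, 2.0, 0.0, 0.0),
        atom_line(4, "CA", "ALA", 3, 3.0, 0.0, 0.0),
        atom_line(5, "CB", "ALA", 3, 4.0, 0.0, 0.0),
    ])
    model = load_model(p)
    assert [r.index for r in model.residues] == [1, 2, 3]
    assert [r.coord[0] for r in model.residues] == [1.0, 2.0, 4.0]


def test_missing_cb_skipped_unless_fallback(tmp_path):
    p = tmp_path / "m.pdb"
    write_pdb(p, [
        atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "ALA", 2, 3.8, 0.0, 0.0),
        atom_line(3, "CB", "ALA", 2, 4.8, 0.0, 0.0),
    ])
    model = load_model(p)
    assert [r.index for r in model.residues] == [2]
    model_fb = load_model(p, fallback_to_ca=True)
    assert [r.index for r in model_fb.residues] == [1, 2]
    assert model_fb.residues[0].coord[0] == 0.0


def test_first_listed_altloc_wins(tmp_path):
    p = tmp_path / "m.pdb"
    write_pdb(p, [
        atom_line(1, "CB", "ALA", 1, 1.0, 0.0, 0.0, altloc="A"),
        atom_line(2, "CB", "ALA", 1, 9.0, 0.0, 0.0, altloc="B"),
        atom_line(3, "CA", "GLY", 2, 2.0, 0.0, 0.0),
    ])
    model = load_model(p)
    assert model.residues[0].coord[0] == 1.0


def test_insertion_codes_rejected(tmp_path):
    p = tmp_path / "m.pdb"
    write_pdb(p, [
        atom_line(1, "CA", "GLY", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "GLY", 1, 3.8, 0.0, 0.0, icode="A"),
    ])
    with pytest.raises(StructureError, match="insertion code"):
        load_model(p)


def test_hetatm_only_file_has_zero_usable_residues(tmp_path):
    p = tmp_path / "m.pdb"
    write_pdb(p, [atom_line(1, "O", "HOH", 1, 0.0, 0.0, 0.0, record="HETATM")])
    with pytest.raises(StructureError, match="zero usable residues|no ATOM"):
        load_model(p)


def test_multiple_chains_require_selection(tmp_path):
    p = tmp_path / "m.pdb"
    write_pdb(p, [
        atom_line(1, "CA", "GLY", 1, 0.0, 0.0, 0.0, chain="A"),
        atom_line(2, "CA", "GLY", 2, 3.8, 0.0, 0.0, chain="A"),
        "TER",
        atom_line(3, "CA", "GLY", 1, 20.0, 0.0, 0.0, chain="B"),
    ])
    with pytest.raises(StructureError, match="multiple chains"):
        load_model(p)
    model = load_model(p, chain="B")
    assert model.residues[0].coord[0] == 20.0
    with pytest.raises(StructureError, match="not found"):
        load_model(p, chain="C")


@pytest.mark.parametrize(
    "text,n_segments,length",
    [("31-80,257-384", 2, 178), ("1-135", 1, 135), ("1-10, 20-29", 2, 20)],
)
def test_parse_domain_valid(text, n_segments, length):
    dom = parse_domain(text, target_id="T")
    assert len(dom.segments) == n_segments
    assert dom.length == length


@pytest.mark.parametrize("text", ["10-5", "5-10,8-20", "abc", "", "5--10", "10-20,1-3"])
def test_parse_domain_invalid(text):
    with pytest.raises(FormatError):
        parse_domain(text)


def test_domain_membership():
    dom = parse_domain("31-80,257-384")
    assert 31 in dom and 80 in dom and 257 in dom and 384 in dom
    assert 30 not in dom and 81 not in dom and 256 not in dom


def test_model_requires_strictly_increasing_indices():
    rec = lambda i: ResidueRecord(index=i, aa="GLY", coord=np.zeros(3))
    with pytest.raises(ValueError, match="strictly increasing"):
        StructureModel(model_id="m", residues=(rec(3), rec(2)))
    with pytest.raises(ValueError, match="strictly increasing"):
        StructureModel(model_id="m", residues=(rec(2), rec(2)))


def test_pdb_write_load_round_trip(tmp_path):
    """Written coordinates survive the PDB fixed-width format to 3 decimals."""
    ref = make_reference(40, motif="random_coil", seed=11)
    p = tmp_path / "ref.pdb"
    write_model_pdb(ref, p)
    loaded = load_model(p)
    assert [r.index for r in loaded.residues] == [r.index for r in ref.residues]
    assert [r.aa for r in loaded.residues] == [r.aa for r in ref.residues]
    np.testing.assert_allclose(loaded.coords, ref.coords, atol=5e-4)


def test_load_ensemble_sorted_and_skips_bad_files(tmp_path, caplog):
    for name in ["b", "a", "c", "e", "d"]:
        write_model_pdb(make_reference(30, seed=1), tmp_path / f"{name}.pdb")
    (tmp_path / "broken.pdb").write_text("ATOM truncated garbage\n")
    with caplog.at_level("WARNING"):
        models = load_ensemble(tmp_path)
    assert [m.model_id for m in models] == ["a", "b", "c", "d", "e"]


def test_load_ensemble_empty_directory_errors(tmp_path):
    with pytest.raises(StructureError):
        load_ensemble(tmp_path)


def test_load_ensemble_scales_to_many_models(tmp_path):
    ref = make_reference(25, seed=2)
    for k in range(301):
        write_model_pdb(ref, tmp_path / f"m{k:03d}.pdb")
    assert len(load_ensemble(tmp_path)) == 301
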