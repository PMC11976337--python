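"""Structure-based descriptors, pLDDT gating and the assembled 14-vector."""

import numpy as np
import pytest

from qafi import (
    FeatureConfig,
    FeatureVector,
    LaarMatrices,
    MJTable,
    MSA,
    MaxContactTable,
    SubstitutionMatrix20,
    Variant,
    acc_volume,
    colasi,
    count_contacts,
    fanc_fbnc,
    frac_conserved_3d,
    laar_score,
    mj_delta,
    plddt_bin,
)
from qafi.model_io import AMINO_ACIDS, AA_INDEX, Atom, Residue, StructureModel
from qafi.sequence_features import FeatureError
from qafi.structure_features import FEATURE_NAMES, GATED_FEATURES

from conftest import brute_force_contacts


def _structure(atom_spec, sequence, plddt=90.0):
    """atom_spec: list per residue of [(name, x, y, z), ...]."""
    residues = [
        Residue(
            position=i + 1,
            aa=aa,
            atoms=[Atom(name, "C", x, y, z) for name, x, y, z in atoms],
            plddt=plddt,
        )
        for i, (aa, atoms) in enumerate(zip(sequence, atom_spec))
    ]
    return StructureModel(residues=residues)


def _maxnc(**overrides):
    table = {aa: 8 for aa in AMINO_ACIDS}
    table.update(overrides)
    return MaxContactTable(maxnc=table)


# ---------------------------------------------------------------------------
# pLDDT gate
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,expected", [(70.0, 1), (69.999, 0), (100.0, 1), (0.0, 0), (89.9, 1)]
)
def test_plddt_bin_threshold(value, expected):
    assert plddt_bin(value) == expected


def test_plddt_bin_rejects_out_of_range():
    with pytest.raises(FeatureError):
        plddt_bin(101.0)


# ---------------------------------------------------------------------------
# colasi
# ---------------------------------------------------------------------------


def test_colasi_isolated_residue_is_zero():
    s = _structure([[("CA", 0, 0, 0)], [("CA", 100, 0, 0)]], "AC")
    assert colasi(s, 1, _maxnc()) == 0.0


def test_colasi_reaches_one_at_type_maximum():
    s = _structure([[("CA", 0, 0, 0)], [("CA", 4, 0, 0)]], "AC")
    assert colasi(s, 1, _maxnc(A=1)) == 1.0
    # not clamped: dense environments may exceed 1
    assert colasi(s, 1, _maxnc(A=1)) * 2 == colasi(s, 1, _maxnc(A=1)) + 1


def test_colasi_matches_oracle_composition(helix_structure, assets, cfg):
    for position in (5, 20, 40):
        total, _ = brute_force_contacts(helix_structure, position, cfg.contact_radius)
        aa = helix_structure.residue(position).aa
        expected = total / assets.maxnc[aa]
        assert colasi(helix_structure, position, assets.maxnc, cfg) == pytest.approx(
            expected
        )


# ---------------------------------------------------------------------------
# conserved-neighbor fractions
# ---------------------------------------------------------------------------


def _cons3d_fixture():
    """Native res 1 with 4 contacts: neighbor 2 contributes 2 (conserved),
    neighbor 3 contributes 1 (variable), neighbor 4 contributes 1 (conserved)."""
    atoms = [
        [("CA", 0, 0, 0)],
        [("CA", 4, 0, 0), ("CB", 0, 4, 0)],
        [("CA", 0, 0, 4)],
        [("CA", 0, 0, -4)],
        [("CA", 1000, 0, 0)],
    ]
    s = _structure(atoms, "ACDEF")
    # columns 1, 2, 4, 5 conserved; column 3 maximally variable (D/A/W/Y)
    rows = ["ACDEF", "ACAEF", "ACWEF", "ACYEF"]
    msa = MSA(ids=["q", "h1", "h2", "h3"], rows=rows, query_index=0)
    return s, msa


def test_frac_conserved_3d_hand_value():
    s, msa = _cons3d_fixture()
    report = count_contacts(s, 1, 5.0)
    assert report.per_neighbor == {2: 2, 3: 1, 4: 1}
    # neighbor 3 (column entropy 2.0) fails the 1.37 cutoff; 2 and 4 pass
    assert frac_conserved_3d(s, msa, 1) == pytest.approx(3 / 4)


def test_frac_conserved_3d_extremes():
    s, _ = _cons3d_fixture()
    conserved = MSA(ids=["q", "h"], rows=["ACDEF", "ACDEF"], query_index=0)
    assert frac_conserved_3d(s, conserved, 1) == 1.0
    assert frac_conserved_3d(s, conserved, 5) == 0.0  # no contacts


def test_fanc_fbnc_hand_value():
    """4 native contacts: accessible neighbor 2 (2 contacts, entropy below
    m_acc) and buried neighbor 3 (2 contacts, entropy at/above m_bur) give
    (0.5, 0.0)."""
    atoms = [
        [("CA", 0, 0, 0)],
        [("CA", 4, 0, 0), ("CB", 0, 4, 0)],
        [("CA", 0, 0, 4), ("CB", 0, 0, -4)],
        [("CA", 1000, 100, 0)],
        [("CA", 1000, 200, 0)],
        [("CA", 1000, 300, 0)],
    ]
    s = _structure(atoms, "ACDEFG")
    # columns 1-2 conserved; 3-6 maximally variable -> m_acc = 2, m_bur = 1
    rows = ["ACDEFG", "ACACAA", "ACWWWW", "ACYYYY"]
    msa = MSA(ids=["q", "h1", "h2", "h3"], rows=rows, query_index=0)
    maxnc = _maxnc(A=4, C=8, D=2)
    # colasi: res2 = 2/8 (accessible), res3 = 2/2 (buried); res4-6 = 0
    result = fanc_fbnc(s, msa, 1, maxnc)
    assert result == (pytest.approx(0.5), pytest.approx(0.0))


def test_fanc_fbnc_no_contacts():
    s, msa = _cons3d_fixture()
    assert fanc_fbnc(s, msa, 5, _maxnc()) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# contact-potential difference
# ---------------------------------------------------------------------------


def _custom_mj(entries):
    values = np.zeros((20, 20))
    for (a, b), e in entries.items():
        values[AA_INDEX[a], AA_INDEX[b]] = e
        values[AA_INDEX[b], AA_INDEX[a]] = e
    return MJTable(values=values)


def test_mj_delta_hand_value():
    s = _structure(
        [[("CA", 0, 0, 0)], [("CA", 4, 0, 0)], [("CA", 0, 4, 0)]], "ACD"
    )
    mj = _custom_mj({("W", "C"): -1.2, ("A", "C"): -0.5, ("W", "D"): 0.1, ("A", "D"): 0.4})
    assert mj_delta(s, 1, "W", mj) == pytest.approx(-1.0)


def test_mj_delta_identity_and_empty_neighborhood():
    s = _structure([[("CA", 0, 0, 0)], [("CA", 4, 0, 0)]], "AC")
    mj = MJTable.synthetic_default()
    assert mj_delta(s, 1, "A", mj) == 0.0  # mutant == native cancels termwise
    lonely = _structure([[("CA", 0, 0, 0)], [("CA", 100, 0, 0)]], "AC")
    assert mj_delta(lonely, 1, "W", mj) == 0.0


def test_mj_delta_antisymmetric_in_same_environment(helix_structure):
    mj = MJTable.synthetic_default()
    position, mutant = 10, "W"
    native = helix_structure.residue(position).aa
    forward = mj_delta(helix_structure, position, mutant, mj)
    swapped = StructureModel(
        residues=[
            Residue(r.position, mutant if r.position == position else r.aa,
                    r.atoms, r.plddt)
            for r in helix_structure.residues
        ]
    )
    backward = mj_delta(swapped, position, native, mj)
    assert forward == pytest.approx(-backward)


def test_mj_table_validation():
    bad = np.zeros((20, 20))
    bad[0, 1] = 1.0
    with pytest.raises(FeatureError, match="symmetric"):
        MJTable(values=bad)


# ---------------------------------------------------------------------------
# volume term and laar lookup
# ---------------------------------------------------------------------------


def test_acc_volume_arithmetic():
    table = _maxnc(G=20, W=60)
    v = Variant("p", 1, "G", "W")
    assert acc_volume(v, 0.5, table) == pytest.approx(20.0)
    assert acc_volume(v, 0.0, table) == 0.0
    same = _maxnc(G=30, W=30)
    assert acc_volume(v, 0.7, same) == 0.0


def test_laar_score_state_selection():
    buried = SubstitutionMatrix20(values=np.full((20, 20), 2.0))
    exposed = SubstitutionMatrix20(values=np.full((20, 20), -3.0))
    matrices = LaarMatrices(buried=buried, exposed=exposed)
    v = Variant("p", 1, "A", "W")
    assert laar_score(matrices, v, 0.8) == 2.0
    assert laar_score(matrices, v, 0.5) == -3.0  # boundary goes to exposed
    assert laar_score(matrices, v, 0.2) == -3.0
    zeros = LaarMatrices(
        buried=SubstitutionMatrix20.zeros(), exposed=SubstitutionMatrix20.zeros()
    )
    assert laar_score(zeros, v, 0.9) == 0.0


# ---------------------------------------------------------------------------
# the assembled vector
# ---------------------------------------------------------------------------


def test_feature_vector_gating_invariant_enforced():
    with pytest.raises(FeatureError, match="low-confidence"):
        FeatureVector(
            blosum62=1, shannon=1, pssm=0, neigh_entropy=1, neco=0,
            plddt=40, plddt_bin=0, colasi=0.5, frac_cons_3d=0, fanc=0,
            fbnc=0, mj_delta=0, acc_volume=0, laar=0,
        )


def test_featurize_gates_low_confidence_residues(
    helix_computer, helix_structure, helix_protein, cfg
):
    low = [
        r.position for r in helix_structure.residues if r.plddt < cfg.plddt_cutoff
    ]
    assert len(low) == 5  # the configured low-confidence tail
    for pos in low:
        native = helix_protein.sequence[pos - 1]
        mutant = "W" if native != "W" else "Y"
        vec = helix_computer.featurize(Variant(helix_protein.id, pos, native, mutant))
        assert vec.plddt_bin == 0
        assert all(getattr(vec, name) == 0.0 for name in GATED_FEATURES)
        assert vec.plddt == helix_structure.residue(pos).plddt  # still reported
        assert vec.blosum62 != 0 or vec.shannon != 0  # sequence side untouched


def test_featurize_matches_component_oracles(helix_computer, helix_protein, assets, cfg):
    from qafi import blosum62_element, neighbor_entropy, pssm_value, shannon_entropy
    from qafi.sequence_features import ColumnProfile

    pos = 10
    native = helix_protein.sequence[pos - 1]
    mutant = "W" if native != "W" else "Y"
    v = Variant(helix_protein.id, pos, native, mutant)
    vec = helix_computer.featurize(v)
    msa = helix_computer.msa
    structure = helix_computer.structure
    profile = ColumnProfile.from_msa_column(msa, pos)
    assert vec.blosum62 == blosum62_element(native, mutant)
    assert vec.shannon == pytest.approx(shannon_entropy(profile))
    assert vec.pssm == pytest.approx(pssm_value(profile, mutant))
    assert vec.neigh_entropy == pytest.approx(neighbor_entropy(msa, pos, 3))
    assert vec.neco == assets.neco[native, mutant]
    cv = colasi(structure, pos, assets.maxnc, cfg)
    assert vec.colasi == pytest.approx(cv)
    assert vec.frac_cons_3d == pytest.approx(frac_conserved_3d(structure, msa, pos, cfg))
    assert vec.mj_delta == pytest.approx(mj_delta(structure, pos, mutant, assets.mj, cfg))
    assert vec.acc_volume == pytest.approx(acc_volume(v, cv, assets.maxnc))
    assert vec.laar == laar_score(assets.laar, v, cv, cfg)
    assert (vec.fanc, vec.fbnc) == pytest.approx(
        fanc_fbnc(structure, msa, pos, assets.maxnc, cfg)
    )


def test_position_only_features_shared_across_mutants(helix_computer, helix_protein):
    pos = 12
    native = helix_protein.sequence[pos - 1]
    mutants = [aa for aa in "WYG" if aa != native][:2]
    vecs = [
        helix_computer.featurize(Variant(helix_protein.id, pos, native, m))
        for m in mutants
    ]
    for name in ("plddt", "shannon", "neigh_entropy", "colasi", "frac_cons_3d",
                 "fanc", "fbnc"):
        assert getattr(vecs[0], name) == getattr(vecs[1], name)


def test_features_invariant_under_rigid_motion(
    helix_protein, helix_msa, helix_structure, assets, cfg
):
    from scipy.spatial.transform import Rotation

    from qafi import FeatureComputer

    rng = np.random.default_rng(4)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    moved = StructureModel(
        residues=[
            Residue(
                r.position, r.aa,
                [Atom(a.name, a.element, *(R @ a.coords + t)) for a in r.atoms],
                r.plddt,
            )
            for r in helix_structure.residues
        ]
    )
    base = FeatureComputer(helix_protein, helix_msa, helix_structure, assets, cfg)
    rotated = FeatureComputer(helix_protein, helix_msa, moved, assets, cfg)
    for pos in (3, 25, 50):
        native = helix_protein.sequence[pos - 1]
        mutant = "W" if native != "W" else "Y"
        v = Variant(helix_protein.id, pos, native, mutant)
        np.testing.assert_allclose(
            base.featurize(v).as_array(), rotated.featurize(v).as_array(), atol=1e-9
        )


def test_feature_frame_shape_and_ranges(helix_features):
    assert list(helix_features.columns) == FEATURE_NAMES
    assert helix_features.notna().all().all()
    for name in ("frac_cons_3d", "fanc", "fbnc"):
        assert helix_features[name].between(0, 1).all()
    assert (helix_features["colasi"] >= 0).all()
    assert set(helix_features["plddt_bin"].unique()) <= {0.0, 1.0}
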