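"""Contact counting and derivation of the context-dependent matrices."""

import math

import numpy as np
import pytest

from qafi import (
    FixtureSpec,
    MSA,
    MaxContactTable,
    ProteinRecord,
    ReferenceSet,
    SubstitutionMatrix20,
    count_contacts,
    derive_laar,
    derive_max_contacts,
    derive_neco,
    synth_compact_structure,
    synth_msa,
    synth_sequence,
    synth_two_state_structure,
)
from qafi.fixtures import _anti_mutant, _coupled_mutant
from qafi.model_io import AMINO_ACIDS, Atom, Residue, StructureModel
from qafi.reference_matrices import DerivationError, colasi_profile

from conftest import brute_force_contacts


def _ca_structure(points, sequence):
    residues = [
        Residue(position=i + 1, aa=aa, atoms=[Atom("CA", "C", *p)], plddt=90.0)
        for i, (p, aa) in enumerate(zip(points, sequence))
    ]
    return StructureModel(residues=residues)


# ---------------------------------------------------------------------------
# contact counting
# ---------------------------------------------------------------------------


def test_count_contacts_two_residues():
    near = _ca_structure([(0, 0, 0), (4, 0, 0)], "AC")
    far = _ca_structure([(0, 0, 0), (10, 0, 0)], "AC")
    report = count_contacts(near, 1, radius=5.0)
    assert report.total == 1 and report.per_neighbor == {2: 1}
    assert count_contacts(far, 1, radius=5.0).total == 0


def test_count_contacts_missing_position_errors():
    structure = _ca_structure([(0, 0, 0)], "A")
    with pytest.raises(Exception, match="no residue"):
        count_contacts(structure, 99)


@pytest.mark.parametrize("seed", [7, 8, 9])
def test_count_contacts_matches_brute_force(seed):
    structure = synth_compact_structure(30, seed=seed)
    for position in structure.positions:
        report = count_contacts(structure, position, radius=5.0)
        total, per_neighbor = brute_force_contacts(structure, position, 5.0)
        assert report.total == total
        assert report.per_neighbor == per_neighbor


def test_count_contacts_exclude_adjacent_flag():
    structure = _ca_structure([(0, 0, 0), (3.8, 0, 0), (3.8, 3.8, 0)], "ACD")
    with_adj = count_contacts(structure, 2, radius=5.0)
    without = count_contacts(structure, 2, radius=5.0, exclude_adjacent=True)
    assert with_adj.total == 2 and without.total == 0


# ---------------------------------------------------------------------------
# maxnc
# ---------------------------------------------------------------------------


def test_derive_max_contacts_matches_brute_force_maxima():
    structures = [synth_compact_structure(40, seed=11), synth_compact_structure(40, seed=12)]
    table = derive_max_contacts(structures)
    expected: dict[str, int] = {}
    for s in structures:
        for r in s.residues:
            total, _ = brute_force_contacts(s, r.position, 5.0)
            expected[r.aa] = max(expected.get(r.aa, 0), total)
    assert table.maxnc == expected


def test_derive_max_contacts_missing_type_errors():
    seq = "".join(aa for aa in AMINO_ACIDS if aa != "W") + "A"
    structure = synth_two_state_structure(ProteinRecord(id="x", sequence=seq))
    with pytest.raises(DerivationError, match="W"):
        derive_max_contacts([structure])


def test_max_contact_table_requires_all_types():
    with pytest.raises(DerivationError, match="missing"):
        MaxContactTable(maxnc={"A": 3})


# ---------------------------------------------------------------------------
# neco derivation
# ---------------------------------------------------------------------------


def _hand_msa():
    return MSA(
        ids=["q", "h1", "h2", "h3"],
        rows=["ACD", "ACD", "AMD", "TMD"],
        query_index=0,
    )


def test_derive_neco_hand_tallied_counts():
    """Query ACD vs homologs ACD/AMD/TMD: only position 2 is interior.

    Baseline counts (C,C)=1, (C,M)=2; flank-matched counts (C,C)=1, (C,M)=1
    (the TMD homolog fails the left-flank match). With pseudocount 1 the
    entries are exact count-ratio logs.
    """
    matrix = derive_neco([_hand_msa()], pseudocount=1.0)
    assert matrix["C", "M"] == pytest.approx(math.log((2 / 22) / (3 / 23)))
    assert matrix["C", "C"] == pytest.approx(math.log((2 / 22) / (2 / 23)))
    assert matrix["C", "W"] == pytest.approx(math.log((1 / 22) / (1 / 23)))
    # rows never observed stay exactly at the pseudo-count ratio of 1
    assert matrix["A", "G"] == 0.0
    assert "C" not in matrix.metadata["pseudocount_only_rows"]
    assert "A" in matrix.metadata["pseudocount_only_rows"]


def test_derive_neco_row_order_invariance():
    msa = _hand_msa()
    shuffled = MSA(
        ids=["h3", "q", "h1", "h2"],
        rows=["TMD", "ACD", "ACD", "AMD"],
        query_index=1,
    )
    a = derive_neco([msa]).values
    b = derive_neco([shuffled]).values
    np.testing.assert_allclose(a, b)


def test_derive_neco_context_free_entries_near_zero():
    # 400 homologs x 20 positions per residue type at flat entropy 2.5 gives
    # >50 flank-matched counts per cell; 4.5 sigma of the log-ratio ~ 0.5
    spec = FixtureSpec(
        n_residues=400,
        n_homologs=400,
        conservation=tuple([2.5] * 400),
        seed=21,
    )
    protein = synth_sequence(spec)
    matrix = derive_neco([synth_msa(spec, protein)])
    assert np.abs(matrix.values).max() < 0.5


def test_derive_neco_coupled_signs():
    spec = FixtureSpec(
        n_residues=300,
        n_homologs=1000,
        conservation=tuple([3.0] * 300),
        neighbor_coupling=True,
        coupling_strength=0.8,
        seed=3,
    )
    protein = synth_sequence(spec)
    matrix = derive_neco([synth_msa(spec, protein)])
    for native in AMINO_ACIDS:
        assert matrix[native, _coupled_mutant(native)] > 0, native
        assert matrix[native, _anti_mutant(native)] < 0, native


def test_neco_finite_for_any_positive_pseudocount():
    for pc in (1e-6, 0.5, 1.0, 10.0):
        matrix = derive_neco([_hand_msa()], pseudocount=pc)
        assert np.all(np.isfinite(matrix.values))
    with pytest.raises(DerivationError):
        derive_neco([_hand_msa()], pseudocount=0.0)


def test_substitution_matrix_tsv_round_trip(tmp_path):
    matrix = derive_neco([_hand_msa()])
    path = tmp_path / "neco.tsv"
    matrix.to_tsv(path)
    back = SubstitutionMatrix20.from_tsv(path)
    np.testing.assert_allclose(back.values, matrix.values)


# ---------------------------------------------------------------------------
# laar derivation
# ---------------------------------------------------------------------------


def _uniform_maxnc(value=1):
    return MaxContactTable(maxnc={aa: value for aa in AMINO_ACIDS})


def _hand_laar_refset():
    """Residues 1-2 in contact (buried, colasi 1), residue 3 isolated
    (exposed, colasi 0); 4 homologs of query ACD."""
    structure = _ca_structure([(0, 0, 0), (4, 0, 0), (50, 0, 0)], "ACD")
    msa = MSA(
        ids=["q", "h1", "h2", "h3", "h4"],
        rows=["ACD", "ACD", "AMD", "GCE", "WMD"],
        query_index=0,
    )
    return ReferenceSet(pairs=[(structure, msa)])


def test_derive_laar_hand_tallied_counts():
    """Buried counts come from positions 1-2 only, exposed from position 3;
    the baseline pools all three. Entries are exact pseudo-counted ratios."""
    laar = derive_laar(_hand_laar_refset(), _uniform_maxnc())
    # A and C rows were observed only buried: buried matrix matches baseline
    assert laar.buried["A", "A"] == pytest.approx(0.0)
    assert laar.buried["C", "M"] == pytest.approx(0.0)
    # D row observed only exposed
    assert laar.buried["D", "D"] == pytest.approx(math.log((1 / 20) / (4 / 24)))
    assert laar.buried["D", "E"] == pytest.approx(math.log((1 / 20) / (2 / 24)))
    assert laar.buried["D", "W"] == pytest.approx(math.log((1 / 20) / (1 / 24)))
    assert laar.exposed["D", "D"] == pytest.approx(0.0)
    assert laar.exposed["A", "A"] == pytest.approx(math.log((1 / 20) / (3 / 24)))
    assert laar.exposed["C", "C"] == pytest.approx(math.log((1 / 20) / (3 / 24)))
    # rows absent from the query are flat zero in both states
    assert laar.buried["K", "R"] == 0.0 and laar.exposed["K", "R"] == 0.0


def test_derive_laar_burial_independent_entries_near_zero():
    # burial-independent substitutions at flat entropy 2.5; per-state cell
    # counts ~50, so entries stay within ~4.5 sigma ~ 0.5 of zero
    spec = FixtureSpec(
        n_residues=400,
        n_homologs=400,
        conservation=tuple([2.5] * 400),
        seed=23,
    )
    protein = synth_sequence(spec)
    structure = synth_two_state_structure(protein)
    maxnc = derive_max_contacts([structure])
    msa = synth_msa(spec, protein)
    laar = derive_laar(ReferenceSet(pairs=[(structure, msa)]), maxnc)
    assert np.abs(laar.buried.values).max() < 0.5
    assert np.abs(laar.exposed.values).max() < 0.5


def test_derive_laar_buried_only_substitution_signs():
    spec = FixtureSpec(
        n_residues=300,
        n_homologs=600,
        conservation=tuple([3.0] * 300),
        burial_coupling=True,
        seed=5,
    )
    protein = synth_sequence(spec)
    structure = synth_two_state_structure(protein)
    maxnc = derive_max_contacts([structure])
    buried = colasi_profile(structure, maxnc) > 0.5
    msa = synth_msa(spec, protein, buried=buried)
    laar = derive_laar(ReferenceSet(pairs=[(structure, msa)]), maxnc)
    for native in AMINO_ACIDS:
        permitted = _coupled_mutant(native, 2)
        if permitted == native or _anti_mutant(native, 2) == native:
            continue
        assert laar.buried[native, permitted] > 0, native
        assert laar.exposed[native, permitted] < 0, native


def test_derive_laar_rejects_mismatched_pair():
    structure = _ca_structure([(0, 0, 0)], "A")
    msa = MSA(ids=["q"], rows=["C"], query_index=0)
    with pytest.raises(DerivationError, match="does not match"):
        ReferenceSet(pairs=[(structure, msa)])
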