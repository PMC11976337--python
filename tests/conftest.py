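"""Shared synthetic fixtures: one fully featurized toy protein plus the
matrix assets derived from a synthetic reference set."""

from __future__ import annotations

import numpy as np
import pytest

from qafi import (
    FeatureAssets,
    FeatureComputer,
    FeatureConfig,
    FixtureSpec,
    ReferenceSet,
    derive_laar,
    derive_max_contacts,
    derive_neco,
    enumerate_variants,
    synth_msa,
    synth_sequence,
    synth_structure,
    synth_two_state_structure,
)


@pytest.fixture(scope="session")
def cfg() -> FeatureConfig:
    return FeatureConfig()


@pytest.fixture(scope="session")
def refset():
    """Synthetic reference set (two-state fold + alignment) for matrix
    derivation; couplings off, so matrix entries carry no designed signal."""
    spec = FixtureSpec(n_residues=200, n_homologs=150, seed=7)
    protein = synth_sequence(spec)
    structure = synth_two_state_structure(protein)
    msa = synth_msa(spec, protein)
    return ReferenceSet(pairs=[(structure, msa)])


@pytest.fixture(scope="session")
def assets(refset) -> FeatureAssets:
    structures = [s for s, _ in refset.pairs]
    maxnc = derive_max_contacts(structures)
    neco = derive_neco([m for _, m in refset.pairs])
    laar = derive_laar(refset, maxnc)
    return FeatureAssets(neco=neco, laar=laar, maxnc=maxnc)


@pytest.fixture(scope="session")
def helix_spec() -> FixtureSpec:
    return FixtureSpec(n_residues=60, n_homologs=300, seed=11, low_conf_tail=5)


@pytest.fixture(scope="session")
def helix_protein(helix_spec):
    return synth_sequence(helix_spec)


@pytest.fixture(scope="session")
def helix_structure(helix_spec, helix_protein):
    return synth_structure(helix_spec, helix_protein)


@pytest.fixture(scope="session")
def helix_msa(helix_spec, helix_protein):
    return synth_msa(helix_spec, helix_protein)


@pytest.fixture(scope="session")
def helix_computer(helix_protein, helix_msa, helix_structure, assets, cfg):
    return FeatureComputer(helix_protein, helix_msa, helix_structure, assets, cfg)


@pytest.fixture(scope="session")
def helix_variants(helix_protein):
    return enumerate_variants(helix_protein)


@pytest.fixture(scope="session")
def helix_features(helix_computer, helix_variants):
    return helix_computer.featurize_all(helix_variants)


def brute_force_contacts(structure, position, radius, exclude_adjacent=False):
    """Independent O(n^2) all-pairs oracle for heavy-atom contact counting."""
    res = structure.residue(position)
    per_neighbor: dict[int, int] = {}
    for other in structure.residues:
        if other.position == position:
            continue
        if exclude_adjacent and abs(other.position - position) <= 1:
            continue
        n = 0
        for a in res.atoms:
            for b in other.atoms:
                d = np.sqrt(
                    (a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2
                )
                if d <= radius:
                    n += 1
        if n:
            per_neighbor[other.position] = n
    return sum(per_neighbor.values()), per_neighbor
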