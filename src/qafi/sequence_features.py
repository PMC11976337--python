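"""The five sequence-based descriptors of a missense variant.

All conservation measures are computed from the alignment column holding the
query position, over the 20-residue alphabet with gaps excluded; entropy uses
base-2 logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model_io import AA_INDEX, AMINO_ACIDS, GAP, MSA, Variant
from .reference_matrices import SubstitutionMatrix20


class FeatureError(ValueError):
    pass


@dataclass
class ColumnProfile:
    """Residue counts of one alignment column (gaps excluded)."""

    counts: dict[str, int]
    depth: int

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(AMINO_ACIDS)
        if bad:
            raise FeatureError(f"non-canonical residues in profile: {sorted(bad)}")
        if self.depth != sum(self.counts.values()):
            raise FeatureError("profile depth inconsistent with counts")

    @classmethod
    def from_msa_column(cls, msa: MSA, position: int) -> "ColumnProfile":
        column = msa.column(position)
        counts: dict[str, int] = {}
        for ch in column:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        return cls(counts=counts, depth=sum(counts.values()))

    def frequencies(self) -> np.ndarray:
        freq = np.zeros(20)
        for aa, n in self.counts.items():
            freq[AA_INDEX[aa]] = n
        return freq / self.depth


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def blosum62_element(native: str, mutant: str) -> float:
    """The standard BLOSUM62 entry for a residue pair (symmetric)."""
    if native not in AA_INDEX or mutant not in AA_INDEX:
        raise FeatureError(f"non-canonical residue pair ({native}, {mutant})")
    return float(_blosum62()[native, mutant])


def shannon_entropy(profile: ColumnProfile) -> float:
    """H = -sum f_a log2 f_a over the 20 residues; 0 log 0 == 0."""
    if profile.depth < 1:
        raise FeatureError("all-gap column: entropy undefined")
    f = profile.frequencies()
    f = f[f > 0]
    return float(-(f * np.log2(f)).sum())


def pssm_value(
    profile: ColumnProfile,
    mutant: str,
    pseudocount: float = 1.0,
    background: float = 1.0 / 20.0,
) -> float:
    """Pseudo-counted log2-odds of the mutant at the column vs background."""
    if profile.depth < 1:
        raise FeatureError("all-gap column: PSSM undefined")
    if mutant not in AA_INDEX:
        raise FeatureError(f"non-canonical residue {mutant!r}")
    fg = (profile.counts.get(mutant, 0) + pseudocount) / (
        profile.depth + 20 * pseudocount
    )
    return float(np.log2(fg / background))


def neighbor_entropy(msa: MSA, position: int, window: int = 3) -> float:
    """Mean column entropy over sequence neighbors position±1..±window.

    The queried position itself is excluded and the window truncates at the
    protein termini.
    """
    length = len(msa.query_sequence)
    if not 1 <= position <= length:
        raise FeatureError(f"position {position} outside query (length {length})")
    neighbors = [
        p
        for p in range(position - window, position + window + 1)
        if p != position and 1 <= p <= length
    ]
    if not neighbors:
        raise FeatureError("protein too short: no sequence neighbors")
    values = [
        shannon_entropy(ColumnProfile.from_msa_column(msa, p)) for p in neighbors
    ]
    return float(np.mean(values))


def neco_score(matrix: SubstitutionMatrix20, variant: Variant) -> float:
    """Look up the neighbor-compatibility entry (native, mutant)."""
    return matrix[variant.native, variant.mutant]
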