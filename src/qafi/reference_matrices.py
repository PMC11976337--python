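"""Derivation of the context-dependent substitution matrices and contact assets.

Two log-ratio substitution statistics are derived from a reference set of
(structure, alignment) pairs:

* **neco** (neighbor compatibility) measures how the probability of seeing a
  homolog residue M opposite a query residue N changes when the homolog also
  matches the query at both flanking positions i-1 and i+1:

      neco(N, M) = ln p(Hom=M | Hs=N, flanks match) / p(Hom=M | Hs=N)

* **laar** (likelihood of the accessibility state for a replacement) is the
  analogous statistic conditioned on the burial state of the query position
  (buried: colasi > 0.5; exposed: colasi <= 0.5), giving one 20x20 matrix per
  state.

Both use additive pseudo-counts so every ln is finite. The contact-counting
primitive (heavy-atom pairs within a radius) and the per-amino-acid maximum
contact table (the colasi denominator) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import (
    AA_INDEX,
    AMINO_ACIDS,
    MSA,
    ModelIOError,
    StructureModel,
    _GAP_CODE,
)

DEFAULT_CONTACT_RADIUS = 5.0
DEFAULT_PSEUDOCOUNT = 1.0
BURIAL_COLASI_CUTOFF = 0.5


class DerivationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionMatrix20:
    """A 20x20 real-valued table indexed (native/query, mutant/homolog)."""

    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise DerivationError(f"matrix shape {self.values.shape}, expected (20, 20)")
        if not np.all(np.isfinite(self.values)):
            raise DerivationError("non-finite matrix entries")

    def __getitem__(self, key: tuple[str, str]) -> float:
        native, mutant = key
        return float(self.values[AA_INDEX[native], AA_INDEX[mutant]])

    def to_frame(self) -> pd.DataFrame:
        letters = list(AMINO_ACIDS)
        return pd.DataFrame(self.values, index=letters, columns=letters)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="native")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstitutionMatrix20":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
        return cls(values=df.to_numpy(dtype=float))

    @classmethod
    def zeros(cls) -> "SubstitutionMatrix20":
        return cls(values=np.zeros((20, 20)))


@dataclass
class LaarMatrices:
    buried: SubstitutionMatrix20
    exposed: SubstitutionMatrix20


@dataclass
class MaxContactTable:
    """Maximum heavy-atom contact count observed per residue type."""

    maxnc: dict[str, int]

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.maxnc))
        if missing:
            raise DerivationError(f"residue types missing from maxnc table: {missing}")
        bad = {aa: n for aa, n in self.maxnc.items() if n < 1}
        if bad:
            raise DerivationError(f"non-positive maxnc values: {bad}")

    def __getitem__(self, aa: str) -> int:
        return self.maxnc[aa]

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(self.maxnc, name="maxnc").rename_axis("residue").to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaxContactTable":
        s = pd.read_csv(path, sep="\t", index_col=0)["maxnc"]
        return cls(maxnc={str(k): int(v) for k, v in s.items()})


@dataclass
class ReferenceSet:
    """Structure + alignment pairs for distinct proteins."""

    pairs: list[tuple[StructureModel, MSA]]

    def __post_init__(self) -> None:
        for structure, msa in self.pairs:
            if structure.sequence != msa.query_sequence:
                raise DerivationError(
                    f"{structure.id}: alignment query does not match structure sequence"
                )


@dataclass
class ContactReport:
    total: int
    per_neighbor: dict[int, int]

    def __post_init__(self) -> None:
        if self.total != sum(self.per_neighbor.values()):
            raise DerivationError("contact total inconsistent with per-neighbor counts")


# ---------------------------------------------------------------------------
# contact counting
# ---------------------------------------------------------------------------


def count_contacts(
    structure: StructureModel,
    position: int,
    radius: float = DEFAULT_CONTACT_RADIUS,
    exclude_adjacent: bool = False,
) -> ContactReport:
    """Count heavy-atom pairs between one residue and all other residues.

    A contact is an unordered atom pair (a, b) with a in the residue at
    ``position``, b in any other residue, and dist(a, b) <= radius.
    Sequence-adjacent residues are included unless ``exclude_adjacent``.
    """
    if radius <= 0:
        raise DerivationError("radius must be positive")
    structure.residue(position)  # raises if absent
    coords, owner = structure.atom_arrays()
    mask_self = owner == position
    self_coords = coords[mask_self]
    other_coords = coords[~mask_self]
    other_owner = owner[~mask_self]
    if exclude_adjacent:
        keep = np.abs(other_owner - position) > 1
        other_coords, other_owner = other_coords[keep], other_owner[keep]
    per_neighbor: dict[int, int] = {}
    if len(other_coords):
        tree = cKDTree(other_coords)
        for sc in self_coords:
            for j in tree.query_ball_point(sc, radius):
                pos_j = int(other_owner[j])
                per_neighbor[pos_j] = per_neighbor.get(pos_j, 0) + 1
    return ContactReport(total=sum(per_neighbor.values()), per_neighbor=per_neighbor)


def contact_totals(
    structure: StructureModel,
    radius: float = DEFAULT_CONTACT_RADIUS,
    exclude_adjacent: bool = False,
) -> dict[int, int]:
    """Total contact count for every residue in one pass (pairwise KD-tree)."""
    coords, owner = structure.atom_arrays()
    totals = {pos: 0 for pos in structure.positions}
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(radius):
        pi, pj = int(owner[i]), int(owner[j])
        if pi == pj:
            continue
        if exclude_adjacent and abs(pi - pj) <= 1:
            continue
        totals[pi] += 1
        totals[pj] += 1
    return totals


def derive_max_contacts(
    structures: Sequence[StructureModel],
    radius: float = DEFAULT_CONTACT_RADIUS,
    exclude_adjacent: bool = False,
) -> MaxContactTable:
    """Per-type maxima of residue contact counts over a reference set."""
    best: dict[str, int] = {}
    for structure in structures:
        totals = contact_totals(structure, radius, exclude_adjacent)
        for res in structure.residues:
            n = totals[res.position]
            if n > best.get(res.aa, 0):
                best[res.aa] = n
    missing = sorted(set(AMINO_ACIDS) - set(best))
    if missing:
        raise DerivationError(
            f"residue types absent from the reference set: {missing}"
        )
    return MaxContactTable(maxnc=best)


def colasi_profile(
    structure: StructureModel,
    maxnc: MaxContactTable,
    radius: float = DEFAULT_CONTACT_RADIUS,
    exclude_adjacent: bool = False,
) -> np.ndarray:
    """colasi (contact count / per-type maximum) for every residue, in order."""
    totals = contact_totals(structure, radius, exclude_adjacent)
    return np.array(
        [totals[r.position] / maxnc[r.aa] for r in structure.residues]
    )


# ---------------------------------------------------------------------------
# count accumulation shared by neco / laar
# ---------------------------------------------------------------------------


def _log_ratio(
    context: np.ndarray, baseline: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """ln of pseudo-counted conditional over baseline row-normalized ratios."""
    pc = pseudocount
    ctx = (context + pc) / (context.sum(axis=1, keepdims=True) + 20 * pc)
    base = (baseline + pc) / (baseline.sum(axis=1, keepdims=True) + 20 * pc)
    empty_rows = context.sum(axis=1) == 0
    return np.log(ctx / base), empty_rows


def _pair_iter(msa: MSA):
    """Yield (query_codes, homolog_codes, query_columns) for one alignment.

    ``query_columns`` are the 0-based alignment columns of the query's
    residues, in residue order; homolog rows exclude the query itself.
    """
    enc = msa.encoded()
    q = enc[msa.query_index]
    hom = np.delete(enc, msa.query_index, axis=0)
    qcols = np.flatnonzero(q != _GAP_CODE)
    return q, hom, qcols


def derive_neco(
    msas: Iterable[MSA],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    chunk_rows: int = 200,
) -> SubstitutionMatrix20:
    """Derive the neighbor-compatibility matrix from alignments.

    For every (query, homolog) row pair and every interior query position i
    (positions with a query residue at both i-1 and i+1), the baseline table
    counts (N = query residue, M = homolog residue, both non-gap); the context
    table additionally requires the homolog to carry the query's residues at
    the alignment columns of i-1 and i+1.
    """
    if pseudocount <= 0:
        raise DerivationError("pseudocount must be positive")
    baseline = np.zeros((20, 20))
    context = np.zeros((20, 20))
    n_msas = 0
    for msa in msas:
        n_msas += 1
        q, hom, qcols = _pair_iter(msa)
        if len(qcols) < 3 or hom.shape[0] == 0:
            continue
        cm, c0, cp = qcols[:-2], qcols[1:-1], qcols[2:]
        n_codes = q[c0]
        for start in range(0, hom.shape[0], chunk_rows):
            block = hom[start : start + chunk_rows]
            m_codes = block[:, c0]
            valid = m_codes != _GAP_CODE
            nn = np.broadcast_to(n_codes, m_codes.shape)
            np.add.at(baseline, (nn[valid], m_codes[valid]), 1)
            match = (
                valid
                & (block[:, cm] == q[cm])
                & (block[:, cp] == q[cp])
            )
            np.add.at(context, (nn[match], m_codes[match]), 1)
    if n_msas == 0:
        raise DerivationError("no alignments supplied")
    values, empty = _log_ratio(context, baseline, pseudocount)
    return SubstitutionMatrix20(
        values=values,
        metadata={
            "statistic": "neco",
            "pseudocount": pseudocount,
            "n_alignments": n_msas,
            "baseline_total": float(baseline.sum()),
            "context_total": float(context.sum()),
            "pseudocount_only_rows": [AMINO_ACIDS[i] for i in np.flatnonzero(empty)],
        },
    )


def derive_laar(
    refset: ReferenceSet,
    maxnc: MaxContactTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    radius: float = DEFAULT_CONTACT_RADIUS,
    burial_cutoff: float = BURIAL_COLASI_CUTOFF,
    chunk_rows: int = 200,
) -> LaarMatrices:
    """Derive the burial-conditioned substitution matrices.

    Each query position is assigned a state by its colasi (buried if
    colasi > cutoff), computed with the same maxnc table being shipped; counts
    accumulate per state against the common unconditioned baseline.
    """
    if pseudocount <= 0:
        raise DerivationError("pseudocount must be positive")
    baseline = np.zeros((20, 20))
    per_state = {True: np.zeros((20, 20)), False: np.zeros((20, 20))}
    for structure, msa in refset.pairs:
        buried = colasi_profile(structure, maxnc, radius) > burial_cutoff
        q, hom, qcols = _pair_iter(msa)
        if hom.shape[0] == 0:
            continue
        n_codes = q[qcols]
        for start in range(0, hom.shape[0], chunk_rows):
            block = hom[start : start + chunk_rows]
            m_codes = block[:, qcols]
            valid = m_codes != _GAP_CODE
            nn = np.broadcast_to(n_codes, m_codes.shape)
            np.add.at(baseline, (nn[valid], m_codes[valid]), 1)
            for state in (True, False):
                mask = valid & np.broadcast_to(buried == state, m_codes.shape)
                np.add.at(per_state[state], (nn[mask], m_codes[mask]), 1)
    out = {}
    for state, name in ((True, "buried"), (False, "exposed")):
        values, empty = _log_ratio(per_state[state], baseline, pseudocount)
        out[name] = SubstitutionMatrix20(
            values=values,
            metadata={
                "statistic": f"laar_{name}",
                "pseudocount": pseudocount,
                "burial_cutoff": burial_cutoff,
                "pseudocount_only_rows": [
                    AMINO_ACIDS[i] for i in np.flatnonzero(empty)
                ],
            },
        )
    return LaarMatrices(buried=out["buried"], exposed=out["exposed"])
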