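"""The nine structure-based descriptors and the 14-feature variant vector.

All structural descriptors are gated by AlphaFold confidence: residues with
pLDDT below the cutoff (default 70) get a binary confidence of 0 and the seven
downstream structural features (colasi, fraction of conserved 3D neighbors,
Fanc, Fbnc, the contact-potential difference, the accessibility-dependent
volume term and laar) are set to 0 for variants at those residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import (
    AA_INDEX,
    AMINO_ACIDS,
    MSA,
    ProteinRecord,
    StructureModel,
    Variant,
)
from .reference_matrices import (
    ContactReport,
    LaarMatrices,
    MaxContactTable,
    SubstitutionMatrix20,
    count_contacts,
)
from .sequence_features import (
    ColumnProfile,
    FeatureError,
    blosum62_element,
    neco_score,
    neighbor_entropy,
    pssm_value,
    shannon_entropy,
)

FEATURE_NAMES = [
    "blosum62",
    "shannon",
    "pssm",
    "neigh_entropy",
    "neco",
    "plddt",
    "plddt_bin",
    "colasi",
    "frac_cons_3d",
    "fanc",
    "fbnc",
    "mj_delta",
    "acc_volume",
    "laar",
]

#: structural features zeroed when the binary confidence is 0
GATED_FEATURES = [
    "colasi",
    "frac_cons_3d",
    "fanc",
    "fbnc",
    "mj_delta",
    "acc_volume",
    "laar",
]

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class FeatureConfig:
    """Operational constants of the feature set and classifier.

    ``entropy_max`` (4.12) and ``conserved_cutoff`` (1.37, one third of the
    maximum) are the published operational constants of the conserved-neighbor
    features and are kept as explicit configuration, decoupled from the
    base-2 entropy computation (whose own maximum is log2 20 ≈ 4.32).
    """

    contact_radius: float = 5.0
    mj_radius: float = 6.5
    plddt_cutoff: float = 70.0
    entropy_max: float = 4.12
    conserved_cutoff: float = 1.37
    burial_colasi_cutoff: float = 0.5
    neighbor_window: int = 3
    threshold_grid: tuple[float, float] = (0.0, 1.5)
    threshold_step: float = 0.01
    classification_threshold: float = 0.82
    exclude_adjacent_contacts: bool = False

    def __post_init__(self) -> None:
        for name in (
            "contact_radius",
            "mj_radius",
            "plddt_cutoff",
            "entropy_max",
            "conserved_cutoff",
            "burial_colasi_cutoff",
            "neighbor_window",
            "threshold_step",
            "classification_threshold",
        ):
            if getattr(self, name) <= 0:
                raise FeatureError(f"{name} must be positive")


@dataclass
class MJTable:
    """Symmetric 20x20 residue-residue contact-energy table e(a, b)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise FeatureError("contact-energy table must be 20x20")
        if not np.allclose(self.values, self.values.T):
            raise FeatureError("contact-energy table must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("non-finite contact energies")

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[AA_INDEX[a], AA_INDEX[b]])

    def to_tsv(self, path: str | Path) -> None:
        letters = list(AMINO_ACIDS)
        pd.DataFrame(self.values, index=letters, columns=letters).to_csv(
            path, sep="\t", index_label="residue"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MJTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
        return cls(values=df.to_numpy(dtype=float))

    @classmethod
    def synthetic_default(cls) -> "MJTable":
        """A synthetic stand-in for the Miyazawa–Jernigan contact potential.

        Statistical contact-energy tables are dominated by an additive
        hydrophobicity component, so this stand-in sets
        e(a, b) = -(h_a + h_b) with h a per-residue hydrophobic contact scale
        (RT units). It reproduces the qualitative structure of the published
        potential (strongly favourable aromatic/aliphatic pairs, weak charged
        pairs) without transcribing it; any real 20x20 symmetric table can be
        supplied via ``from_tsv`` instead.
        """
        h = {
            "A": 1.4, "C": 2.7, "D": 0.6, "E": 0.5, "F": 3.6,
            "G": 1.1, "H": 1.5, "I": 3.3, "K": 0.3, "L": 3.6,
            "M": 2.7, "N": 0.8, "P": 0.9, "Q": 0.8, "R": 0.8,
            "S": 0.9, "T": 1.1, "V": 3.1, "W": 2.5, "Y": 2.1,
        }
        vec = np.array([h[aa] for aa in AMINO_ACIDS])
        return cls(values=-(vec[:, None] + vec[None, :]))


@dataclass
class FeatureVector:
    """The 14 named descriptors of one variant, in canonical order."""

    blosum62: float
    shannon: float
    pssm: float
    neigh_entropy: float
    neco: float
    plddt: float
    plddt_bin: float
    colasi: float
    frac_cons_3d: float
    fanc: float
    fbnc: float
    mj_delta: float
    acc_volume: float
    laar: float

    def __post_init__(self) -> None:
        if self.plddt_bin == 0:
            gated = [getattr(self, name) for name in GATED_FEATURES]
            if any(v != 0 for v in gated):
                raise FeatureError(
                    "low-confidence residue with non-zero structural features"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# individual descriptors
# ---------------------------------------------------------------------------


def plddt_bin(plddt: float, cfg: FeatureConfig = FeatureConfig()) -> int:
    """Binary confidence: 1 if pLDDT >= cutoff (default 70), else 0."""
    if not 0 <= plddt <= 100:
        raise FeatureError(f"pLDDT {plddt} outside [0, 100]")
    return 1 if plddt >= cfg.plddt_cutoff else 0


def colasi(
    structure: StructureModel,
    position: int,
    maxnc: MaxContactTable,
    cfg: FeatureConfig = FeatureConfig(),
    report: ContactReport | None = None,
) -> float:
    """Contact layer size: contact count over the type maximum (not clamped)."""
    res = structure.residue(position)
    if report is None:
        report = count_contacts(
            structure, position, cfg.contact_radius, cfg.exclude_adjacent_contacts
        )
    return report.total / maxnc[res.aa]


def frac_conserved_3d(
    structure: StructureModel,
    msa: MSA,
    position: int,
    cfg: FeatureConfig = FeatureConfig(),
    report: ContactReport | None = None,
    entropies: dict[int, float] | None = None,
) -> float:
    """Fraction of the residue's contacts contributed by conserved neighbors.

    A neighbor is conserved when its column entropy is below the configured
    cutoff; neighbors without alignment coverage count as non-conserved.
    """
    if report is None:
        report = count_contacts(
            structure, position, cfg.contact_radius, cfg.exclude_adjacent_contacts
        )
    if report.total == 0:
        return 0.0
    conserved = 0
    for neighbor, n in report.per_neighbor.items():
        h = _neighbor_entropy(msa, neighbor, entropies)
        if h is not None and h < cfg.conserved_cutoff:
            conserved += n
    return conserved / report.total


def _neighbor_entropy(
    msa: MSA, position: int, cache: dict[int, float] | None
) -> float | None:
    if cache is not None:
        return cache.get(position)
    if position not in msa.column_map:
        return None
    return shannon_entropy(ColumnProfile.from_msa_column(msa, position))


def accessibility_medians(
    colasi_values: np.ndarray,
    entropies: np.ndarray,
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[float | None, float | None]:
    """Per-protein median entropies of accessible and buried residues.

    Returns (m_acc, m_bur); a median is None when the protein has no residue
    in that accessibility class.
    """
    acc = entropies[colasi_values <= cfg.burial_colasi_cutoff]
    bur = entropies[colasi_values > cfg.burial_colasi_cutoff]
    m_acc = float(np.median(acc)) if len(acc) else None
    m_bur = float(np.median(bur)) if len(bur) else None
    return m_acc, m_bur


def fanc_fbnc(
    structure: StructureModel,
    msa: MSA,
    position: int,
    maxnc: MaxContactTable,
    cfg: FeatureConfig = FeatureConfig(),
    report: ContactReport | None = None,
    colasi_by_position: dict[int, float] | None = None,
    entropies: dict[int, float] | None = None,
    medians: tuple[float | None, float | None] | None = None,
) -> tuple[float, float]:
    """Fractions of contacts from conserved accessible / buried neighbors.

    Conservation of a neighbor is judged against the per-protein median
    entropy of its own accessibility class (m_acc for accessible, m_bur for
    buried residues, colasi threshold 0.5).
    """
    from .reference_matrices import colasi_profile

    if colasi_by_position is None:
        values = colasi_profile(
            structure, maxnc, cfg.contact_radius, cfg.exclude_adjacent_contacts
        )
        colasi_by_position = dict(zip(structure.positions, values))
    if entropies is None:
        entropies = {
            p: shannon_entropy(ColumnProfile.from_msa_column(msa, p))
            for p in msa.column_map
        }
    if medians is None:
        order = structure.positions
        medians = accessibility_medians(
            np.array([colasi_by_position[p] for p in order]),
            np.array([entropies.get(p, np.nan) for p in order]),
            cfg,
        )
    m_acc, m_bur = medians
    if report is None:
        report = count_contacts(
            structure, position, cfg.contact_radius, cfg.exclude_adjacent_contacts
        )
    if report.total == 0:
        return 0.0, 0.0
    acc_conserved = 0
    bur_conserved = 0
    for neighbor, n in report.per_neighbor.items():
        h = entropies.get(neighbor)
        if h is None or np.isnan(h):
            continue
        if colasi_by_position[neighbor] > cfg.burial_colasi_cutoff:
            if m_bur is not None and h < m_bur:
                bur_conserved += n
        else:
            if m_acc is not None and h < m_acc:
                acc_conserved += n
    return acc_conserved / report.total, bur_conserved / report.total


def sidechain_centroid(structure: StructureModel, position: int) -> np.ndarray:
    """Mean of the side-chain heavy atoms; CA for glycine.

    Falls back to CA (then to the first atom) when no side-chain atoms are
    present in the model.
    """
    res = structure.residue(position)
    by_name = {a.name: a for a in res.atoms}
    if res.aa != "G":
        side = [a.coords for a in res.atoms if a.name not in _BACKBONE_ATOMS]
        if side:
            return np.mean(side, axis=0)
    if "CA" in by_name:
        return by_name["CA"].coords
    return res.atoms[0].coords


def mj_neighbors(
    structure: StructureModel, position: int, cfg: FeatureConfig = FeatureConfig()
) -> list[int]:
    """Residues whose side-chain centroid lies within mj_radius of the native's."""
    center = sidechain_centroid(structure, position)
    out = []
    for r in structure.residues:
        if r.position == position:
            continue
        d = np.linalg.norm(sidechain_centroid(structure, r.position) - center)
        if d < cfg.mj_radius:
            out.append(r.position)
    return out


def mj_delta(
    structure: StructureModel,
    position: int,
    mutant: str,
    mj: MJTable,
    cfg: FeatureConfig = FeatureConfig(),
    neighbors: Sequence[int] | None = None,
) -> float:
    """Contact-energy change sum_j e(mut, j) - e(nat, j) over the native's
    spatial neighbors; the neighbor list is fixed from the native structure."""
    res = structure.residue(position)
    if neighbors is None:
        neighbors = mj_neighbors(structure, position, cfg)
    total = 0.0
    for j in neighbors:
        aa_j = structure.residue(j).aa
        total += mj[mutant, aa_j] - mj[res.aa, aa_j]
    return total


def acc_volume(
    variant: Variant, colasi_value: float, maxnc: MaxContactTable
) -> float:
    """Accessibility-dependent volume term: (maxnc_mut - maxnc_nat) * colasi."""
    return (maxnc[variant.mutant] - maxnc[variant.native]) * colasi_value


def laar_score(
    matrices: LaarMatrices,
    variant: Variant,
    colasi_value: float,
    cfg: FeatureConfig = FeatureConfig(),
) -> float:
    """Burial-conditioned substitution score: buried matrix iff colasi > 0.5."""
    table = (
        matrices.buried
        if colasi_value > cfg.burial_colasi_cutoff
        else matrices.exposed
    )
    return table[variant.native, variant.mutant]


# ---------------------------------------------------------------------------
# assembled pipeline
# ---------------------------------------------------------------------------


@dataclass
class FeatureAssets:
    """Derived data assets shared by all proteins."""

    neco: SubstitutionMatrix20
    laar: LaarMatrices
    maxnc: MaxContactTable
    mj: MJTable = field(default_factory=MJTable.synthetic_default)


class FeatureComputer:
    """Featurizes variants of one protein with per-protein pre-computation.

    Pre-computes, once per protein: column entropies, per-residue contact
    reports and colasi values, the accessible/buried median entropies and the
    side-chain-centroid neighbor lists, so that featurizing all ~19L variants
    of a protein costs only table lookups.
    """

    def __init__(
        self,
        protein: ProteinRecord,
        msa: MSA,
        structure: StructureModel,
        assets: FeatureAssets,
        cfg: FeatureConfig = FeatureConfig(),
    ):
        if msa.query_sequence != protein.sequence:
            raise FeatureError("alignment query does not match the protein sequence")
        if structure.sequence != protein.sequence:
            raise FeatureError("structure sequence does not match the protein sequence")
        self.protein = protein
        self.msa = msa
        self.structure = structure
        self.assets = assets
        self.cfg = cfg

        self.entropies = {
            p: shannon_entropy(ColumnProfile.from_msa_column(msa, p))
            for p in msa.column_map
        }
        self.reports = {
            p: count_contacts(
                structure, p, cfg.contact_radius, cfg.exclude_adjacent_contacts
            )
            for p in structure.positions
        }
        self.colasi = {
            p: self.reports[p].total / assets.maxnc[structure.residue(p).aa]
            for p in structure.positions
        }
        order = structure.positions
        self.medians = accessibility_medians(
            np.array([self.colasi[p] for p in order]),
            np.array([self.entropies[p] for p in order]),
            cfg,
        )
        self._centroids = {
            p: sidechain_centroid(structure, p) for p in structure.positions
        }
        self._mj_neighbors: dict[int, list[int]] = {}

    def _neighbor_entropy(self, position: int) -> float:
        w = self.cfg.neighbor_window
        length = len(self.protein)
        values = [
            self.entropies[p]
            for p in range(position - w, position + w + 1)
            if p != position and 1 <= p <= length
        ]
        if not values:
            raise FeatureError("protein too short: no sequence neighbors")
        return float(np.mean(values))

    def _neighbors(self, position: int) -> list[int]:
        if position not in self._mj_neighbors:
            center = self._centroids[position]
            self._mj_neighbors[position] = [
                p
                for p, c in self._centroids.items()
                if p != position
                and np.linalg.norm(c - center) < self.cfg.mj_radius
            ]
        return self._mj_neighbors[position]

    def featurize(self, variant: Variant) -> FeatureVector:
        variant.check_against(self.protein)
        cfg = self.cfg
        pos = variant.position
        res = self.structure.residue(pos)
        profile = ColumnProfile.from_msa_column(self.msa, pos)
        gate = plddt_bin(res.plddt, cfg)
        if gate:
            cv = self.colasi[pos]
            structural = dict(
                colasi=cv,
                frac_cons_3d=frac_conserved_3d(
                    self.structure, self.msa, pos, cfg,
                    report=self.reports[pos], entropies=self.entropies,
                ),
                mj_delta=mj_delta(
                    self.structure, pos, variant.mutant, self.assets.mj, cfg,
                    neighbors=self._neighbors(pos),
                ),
                acc_volume=acc_volume(variant, cv, self.assets.maxnc),
                laar=laar_score(self.assets.laar, variant, cv, cfg),
            )
            structural["fanc"], structural["fbnc"] = fanc_fbnc(
                self.structure, self.msa, pos, self.assets.maxnc, cfg,
                report=self.reports[pos], colasi_by_position=self.colasi,
                entropies=self.entropies, medians=self.medians,
            )
        else:
            structural = {name: 0.0 for name in GATED_FEATURES}
        return FeatureVector(
            blosum62=blosum62_element(variant.native, variant.mutant),
            shannon=shannon_entropy(profile),
            pssm=pssm_value(profile, variant.mutant),
            neigh_entropy=self._neighbor_entropy(pos),
            neco=neco_score(self.assets.neco, variant),
            plddt=res.plddt,
            plddt_bin=float(gate),
            **structural,
        )

    def featurize_all(self, variants: Sequence[Variant]) -> pd.DataFrame:
        rows = [self.featurize(v).as_dict() for v in variants]
        index = pd.MultiIndex.from_tuples(
            [(v.position, v.mutant) for v in variants], names=["position", "mutant"]
        )
        return pd.DataFrame(rows, index=index, columns=FEATURE_NAMES)


def featurize_variant(
    variant: Variant,
    protein: ProteinRecord,
    msa: MSA,
    structure: StructureModel,
    assets: FeatureAssets,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """One-shot featurization of a single variant (see FeatureComputer)."""
    return FeatureComputer(protein, msa, structure, assets, cfg).featurize(variant)
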