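"""Readers, writers and validated domain types.

All residue numbering in this package is 1-based and must agree between the
reference sequence (FASTA), the alignment (aligned FASTA), the structure model
(PDB/mmCIF, pLDDT stored in the B-factor field following the AlphaFold
convention) and the variant table (TSV). Structures are re-indexed 1..N on
load; the author numbering is preserved as metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
_GAP_CODE = 20

BUNDLE_FORMAT_VERSION = 1


class ModelIOError(ValueError):
    """Raised when an input file violates the format contracts."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein sequence over the 20-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelIOError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ModelIOError(
                f"{self.id}: non-canonical residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MSA:
    """A gapped multiple sequence alignment containing the query protein.

    ``column_map`` maps each 1-based query residue position to the 1-based
    alignment column holding it.
    """

    ids: list[str]
    rows: list[str]
    query_index: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise ModelIOError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ModelIOError("alignment rows differ in length")
        alphabet = set(AMINO_ACIDS) | {GAP}
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - alphabet
            if bad:
                raise ModelIOError(f"{rid}: invalid alignment characters {sorted(bad)}")
        if not 0 <= self.query_index < len(self.rows):
            raise ModelIOError("query_index out of range")
        self._column_map = {}
        pos = 0
        for col, ch in enumerate(self.rows[self.query_index], start=1):
            if ch != GAP:
                pos += 1
                self._column_map[pos] = col

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    @property
    def query_sequence(self) -> str:
        return self.query_row.replace(GAP, "")

    @property
    def column_map(self) -> dict[int, int]:
        return dict(self._column_map)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column(self, position: int) -> str:
        """Alignment column (one char per row) for a 1-based query position."""
        col = self._column_map[position] - 1
        return "".join(row[col] for row in self.rows)

    def encoded(self) -> np.ndarray:
        """Rows as an int8 matrix: residue index 0..19, gap = 20."""
        lut = np.full(128, -1, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            lut[ord(aa)] = i
        lut[ord(GAP)] = _GAP_CODE
        flat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return lut[flat].reshape(len(self.rows), self.width)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    position: int
    aa: str
    atoms: list[Atom]
    plddt: float
    author_number: int | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ModelIOError(f"residue {self.position}: no heavy atoms")
        if not 0.0 <= self.plddt <= 100.0:
            raise ModelIOError(
                f"residue {self.position}: pLDDT {self.plddt} outside [0, 100]"
            )


@dataclass
class StructureModel:
    """Per-residue heavy-atom coordinates plus AlphaFold-style pLDDT."""

    residues: list[Residue]
    id: str = "structure"

    def __post_init__(self) -> None:
        pos = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ModelIOError("residue positions not strictly increasing")
        self._by_position = {r.position: r for r in self.residues}
        self._atom_cache: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def residue(self, position: int) -> Residue:
        try:
            return self._by_position[position]
        except KeyError:
            raise ModelIOError(f"no residue at position {position}") from None

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and their residue positions.

        Returns ``(coords, residue_positions)`` with shapes (n_atoms, 3) and
        (n_atoms,); cached after the first call.
        """
        if self._atom_cache is None:
            coords = []
            owner = []
            for r in self.residues:
                for a in r.atoms:
                    coords.append((a.x, a.y, a.z))
                    owner.append(r.position)
            self._atom_cache = (
                np.asarray(coords, dtype=float),
                np.asarray(owner, dtype=int),
            )
        return self._atom_cache

    def plddt_array(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues])


@dataclass(frozen=True)
class Variant:
    """A missense variant in 1-based protein coordinates."""

    protein_id: str
    position: int
    native: str
    mutant: str

    def __post_init__(self) -> None:
        for aa in (self.native, self.mutant):
            if aa not in AA_INDEX:
                raise ModelIOError(f"{self}: non-canonical residue {aa!r}")
        if self.native == self.mutant:
            raise ModelIOError(
                f"{self.protein_id} position {self.position}: synonymous "
                f"substitution {self.native}->{self.mutant}"
            )
        if self.position < 1:
            raise ModelIOError(f"{self}: position must be 1-based")

    def __str__(self) -> str:  # e.g. PTEN:R130G
        return f"{self.protein_id}:{self.native}{self.position}{self.mutant}"

    def check_against(self, protein: ProteinRecord) -> None:
        if self.position > len(protein):
            raise ModelIOError(
                f"{self}: position beyond sequence length {len(protein)}"
            )
        found = protein.sequence[self.position - 1]
        if found != self.native:
            raise ModelIOError(
                f"{self}: native residue mismatch at position {self.position} "
                f"(sequence has {found})"
            )


@dataclass
class DMSDataset:
    """Normalized deep-mutational-scanning scores for one protein.

    Scores follow the wild-type-anchored convention: 1 means no detectable
    functional impact, below 1 decreased activity, above 1 enhanced activity.
    """

    protein_id: str
    variants: list[Variant]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.variants) != len(self.scores):
            raise ModelIOError("variants and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ModelIOError("non-finite DMS scores")
        seen = set()
        for v in self.variants:
            if v.protein_id != self.protein_id:
                raise ModelIOError(f"{v}: foreign protein id in {self.protein_id}")
            key = (v.position, v.mutant)
            if key in seen:
                raise ModelIOError(f"duplicate variant {v}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.variants])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.protein_id,
                "position": [v.position for v in self.variants],
                "native": [v.native for v in self.variants],
                "mutant": [v.mutant for v in self.variants],
                "score": self.scores,
            }
        )


# ---------------------------------------------------------------------------
# FASTA / alignment
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, record_id: str | None = None) -> ProteinRecord:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ModelIOError(f"{path}: no FASTA records")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ModelIOError(f"{path}: no record with id {record_id!r}")
        rec = matches[0]
    return ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(protein: ProteinRecord, path: str | Path) -> None:
    Path(path).write_text(f">{protein.id}\n{protein.sequence}\n")


def read_msa(path: str | Path, query_id: str) -> MSA:
    """Read an aligned FASTA file and locate the query row."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ModelIOError(f"{path}: no alignment records")
    ids = [r.id for r in records]
    if query_id not in ids:
        raise ModelIOError(f"{path}: query id {query_id!r} not in alignment")
    rows = [str(r.seq).upper() for r in records]
    return MSA(ids=ids, rows=rows, query_index=ids.index(query_id))


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# structures (gemmi)
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read a single-chain PDB or mmCIF model.

    Per-residue pLDDT is taken from the CA atom's B-factor (the AlphaFold
    convention writes an identical value on every atom of the residue); if CA
    is absent, the first heavy atom's value is used. Residues are re-indexed
    1..N, the author numbering kept in ``author_number``.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ModelIOError(f"{path}: no models")
    model = st[0]
    chains = [ch for ch in model]
    if chain is not None:
        chains = [ch for ch in chains if ch.name == chain]
        if not chains:
            raise ModelIOError(f"{path}: no chain {chain!r}")
    if len(chains) != 1:
        raise ModelIOError(
            f"{path}: {len(chains)} chains present; pass an explicit chain selector"
        )
    residues: list[Residue] = []
    for idx, res in enumerate(chains[0], start=1):
        if res.name not in _THREE_TO_ONE:
            raise ModelIOError(f"{path}: non-standard residue {res.name}")
        atoms = [
            Atom(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
            for a in res
            if a.element.name != "H"
        ]
        if not atoms:
            raise ModelIOError(f"{path}: residue {res.seqid.num} has no coordinates")
        b_by_name = {a.name: a.b_iso for a in res}
        plddt = b_by_name.get("CA", next(iter(b_by_name.values())))
        residues.append(
            Residue(
                position=idx,
                aa=_THREE_TO_ONE[res.name],
                atoms=atoms,
                plddt=float(plddt),
                author_number=res.seqid.num,
            )
        )
    return StructureModel(residues=residues, id=Path(path).stem)


def write_structure(
    structure: StructureModel, path: str | Path, fmt: str | None = None
) -> None:
    """Write a structure as PDB or mmCIF; pLDDT goes to every B-factor."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for r in structure.residues:
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[r.aa]
        res.seqid = gemmi.SeqId(r.author_number or r.position, " ")
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(a.x, a.y, a.z)
            atom.b_iso = r.plddt
            atom.occ = 1.0
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# variant / DMS tables
# ---------------------------------------------------------------------------

DMS_COLUMNS = ["protein", "position", "native", "mutant", "score"]


def read_dms_table(
    path: str | Path, protein: ProteinRecord | None = None
) -> DMSDataset:
    """Read a TSV of (protein, position, native, mutant, score) rows."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    missing = [c for c in DMS_COLUMNS if c not in df.columns]
    if missing:
        raise ModelIOError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ModelIOError(f"{path}: empty variant table")
    if not pd.api.types.is_numeric_dtype(df["score"]):
        raise ModelIOError(f"{path}: non-numeric scores")
    protein_ids = df["protein"].unique()
    if len(protein_ids) != 1:
        raise ModelIOError(f"{path}: multiple protein ids {list(protein_ids)}")
    variants = [
        Variant(row.protein, int(row.position), row.native, row.mutant)
        for row in df.itertuples()
    ]
    if protein is not None:
        for v in variants:
            v.check_against(protein)
    return DMSDataset(
        protein_id=str(protein_ids[0]),
        variants=variants,
        scores=df["score"].to_numpy(dtype=float),
    )


def write_dms_table(dataset: DMSDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def normalize_scores(
    raw: Sequence[float] | np.ndarray,
    wildtype: float,
    null: float | None = None,
) -> np.ndarray:
    """Rescale raw assay readouts to the wild-type-anchored convention.

    A readout equal to ``wildtype`` maps to exactly 1 (no detectable impact);
    if a ``null`` (fully non-functional) readout is supplied it maps to 0,
    otherwise scores are a simple ratio to wild type. Readouts below the null
    or above the wild type remain meaningful (negative and >1 respectively,
    the latter indicating enhanced activity).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(wildtype):
        raise ModelIOError("non-finite wild-type readout")
    if null is None:
        if wildtype == 0:
            raise ModelIOError("wild-type readout is 0; supply a null readout")
        return raw / wildtype
    if wildtype == null:
        raise ModelIOError("wild-type and null readouts coincide")
    return (raw - null) / (wildtype - null)


# ---------------------------------------------------------------------------
# model bundles (JSON)
# ---------------------------------------------------------------------------


def write_model_bundle(model, path: str | Path) -> None:
    """Serialize a PSPModel or EnsembleModel to a versioned JSON document."""
    payload = model.to_dict()
    payload["format_version"] = BUNDLE_FORMAT_VERSION
    _check_finite(payload)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_bundle(path: str | Path):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"{path}: truncated or invalid bundle ({exc})") from exc
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: bundle format version {version!r}, expected {BUNDLE_FORMAT_VERSION}"
        )
    kind = payload.get("kind")
    if kind == "psp":
        from .psp_regression import PSPModel

        return PSPModel.from_dict(payload)
    if kind == "ensemble":
        from .ensemble import EnsembleModel

        return EnsembleModel.from_dict(payload)
    raise ModelIOError(f"{path}: unknown bundle kind {kind!r}")


def _check_finite(obj) -> None:
    if isinstance(obj, dict):
        for v in obj.values():
            _check_finite(v)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _check_finite(v)
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ModelIOError("non-finite value in model bundle")
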