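"""Synthetic inputs: toy structures, conservation-profiled alignments,
linear-model DMS scores with a bimodal mixture, and labeled clinical-style
score sets.

Every generator is a pure function of its spec and seed. The fixtures emulate
the statistical shape of the real inputs — entropy-profiled alignment columns,
a deterministic helical fold with a burial gradient, bimodal and imbalanced
assay scores — not their biophysical realism; generators emit the generative
ground truth alongside each dataset so recovery tests can read it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_io import (
    AA_INDEX,
    AMINO_ACIDS,
    MSA,
    Atom,
    DMSDataset,
    ProteinRecord,
    Residue,
    StructureModel,
    Variant,
)
from .structure_features import FEATURE_NAMES

LOG2_20 = math.log2(20)

#: default true feature weights of the linear DMS generative model; moderate
#: mixed-sign effects so the linear signal neither dominates nor vanishes
#: against the bimodal peak structure.
DEFAULT_TRUE_WEIGHTS = (
    0.15, -0.20, 0.10, -0.12, 0.08, 0.05, 0.10,
    -0.25, -0.15, 0.12, -0.10, 0.20, -0.08, 0.10,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic protein.

    Defaults give >1000 possible missense variants per protein (n_residues
    60), an alignment depth of 500 homologs, a smoothly varying conservation
    profile, a bimodal score mixture with 70% of variants in the
    wild-type-like peak at 1.0 and 30% in the damaged peak at 0.2, and assay
    noise sigma 0.1.
    """

    n_residues: int = 60
    n_homologs: int = 500
    conservation: tuple[float, ...] | None = None  # per-position entropy targets
    neighbor_coupling: bool = False
    burial_coupling: bool = False
    coupling_strength: float = 0.8
    true_weights: tuple[float, ...] = DEFAULT_TRUE_WEIGHTS
    intercept: float = 0.0
    noise_sigma: float = 0.1
    peak_means: tuple[float, float] = (0.2, 1.0)
    peak_weight: float = 0.7  # probability of the second (wild-type-like) peak
    low_conf_tail: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be at least 5")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 < self.peak_weight < 1:
            raise ValueError("peak_weight must lie in (0, 1)")
        if len(self.true_weights) != len(FEATURE_NAMES):
            raise ValueError(f"true_weights must have {len(FEATURE_NAMES)} entries")
        if self.conservation is not None:
            if len(self.conservation) != self.n_residues:
                raise ValueError("conservation profile length != n_residues")
            if any(h < 0 or h > LOG2_20 for h in self.conservation):
                raise ValueError(f"entropy targets must lie in [0, {LOG2_20:.4f}]")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")

    def entropy_targets(self) -> np.ndarray:
        if self.conservation is not None:
            return np.asarray(self.conservation, dtype=float)
        i = np.arange(self.n_residues)
        return 1.5 + 1.0 * np.sin(2 * np.pi * i / 17.0)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def synth_sequence(spec: FixtureSpec) -> ProteinRecord:
    """Deterministic query sequence: shuffled 20-letter blocks, so every
    residue type occurs once per block of 20 positions."""
    rng = spec.rng(1)
    letters: list[str] = []
    while len(letters) < spec.n_residues:
        block = list(AMINO_ACIDS)
        rng.shuffle(block)
        letters.extend(block)
    return ProteinRecord(id=f"synth{spec.seed}", sequence="".join(letters[: spec.n_residues]))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

# pseudo side-chain radial extension (Å) per residue type, a volume proxy
_SIDECHAIN_EXT = {
    "G": 0.0, "A": 1.5, "S": 1.9, "C": 2.3, "T": 2.1, "P": 1.9, "V": 2.5,
    "D": 2.5, "N": 2.6, "I": 3.1, "L": 3.1, "E": 3.1, "Q": 3.2, "M": 3.4,
    "H": 3.3, "K": 3.9, "F": 3.7, "R": 4.3, "Y": 4.1, "W": 4.4,
}

#: small/medium/large size class per type; drives the pseudo-atom count so
#: that derived per-type contact maxima differ (as real residue volumes do)
def _size_class(aa: str) -> int:
    ext = _SIDECHAIN_EXT[aa]
    return 1 + (ext > 1.6) + (ext > 3.0)


_CLUSTER_OFFSETS = np.array([(0.3, 0.0, 0.0), (0.0, 0.3, 0.0), (0.0, 0.0, 0.3)])


def _atom_cluster(aa: str, center: np.ndarray) -> list[Atom]:
    """CA plus size-class-many pseudo side-chain atoms within 0.3 Å."""
    atoms = [Atom("CA", "C", *center)]
    names = ("CB", "CG", "CD")
    for k in range(_size_class(aa)):
        atoms.append(Atom(names[k], "C", *(center + _CLUSTER_OFFSETS[k])))
    return atoms


_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
# radius giving the canonical 3.8 Å consecutive-CA distance
_HELIX_RADIUS = math.sqrt(3.8**2 - _HELIX_RISE**2) / (
    2 * math.sin(math.radians(_HELIX_TWIST_DEG / 2))
)


def synth_structure(spec: FixtureSpec, sequence: ProteinRecord | None = None) -> StructureModel:
    """Ideal α-helix (rise 1.5 Å, 100° twist) with pseudo side-chain atoms.

    Each residue carries a CA on the helix, one "CB" at a type-dependent
    radial extension, and a small size-class-dependent atom cluster near the
    CA, so contact counts (and hence colasi, the volume term and the burial
    split) vary along the helix and across residue types. The pLDDT profile
    ripples around 85 in the core (always confident) and around 50 on the
    final ``low_conf_tail`` residues (always below the 70 gate); the ripple
    keeps pLDDT continuous-valued rather than binary.
    """
    if sequence is None:
        sequence = synth_sequence(spec)
    residues = []
    n = len(sequence.sequence)
    for i, aa in enumerate(sequence.sequence):
        theta = math.radians(_HELIX_TWIST_DEG) * i
        ca = np.array(
            [
                _HELIX_RADIUS * math.cos(theta),
                _HELIX_RADIUS * math.sin(theta),
                _HELIX_RISE * i,
            ]
        )
        atoms = _atom_cluster(aa, ca)
        ext = _SIDECHAIN_EXT[aa]
        if ext > 0:
            r = _HELIX_RADIUS + ext
            atoms.append(
                Atom("CE", "C", r * math.cos(theta), r * math.sin(theta), _HELIX_RISE * i)
            )
        if i >= n - spec.low_conf_tail:
            plddt = 50.0 + 8.0 * math.sin(1.7 * i)
        else:
            plddt = 85.0 + 6.0 * math.cos(2 * math.pi * i / 9.0)
        residues.append(Residue(position=i + 1, aa=aa, atoms=atoms, plddt=plddt))
    return StructureModel(residues=residues, id=sequence.id)


def synth_compact_structure(
    n_residues: int, seed: int, radius: float | None = None
) -> StructureModel:
    """Random CA-only globule: residues uniform in a sphere (oracle fixtures)."""
    rng = np.random.default_rng(seed)
    if radius is None:
        radius = 2.2 * n_residues ** (1 / 3) * 1.6
    pts = []
    while len(pts) < n_residues:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            pts.append(p)
    seq = [AMINO_ACIDS[i % 20] for i in range(n_residues)]
    rng.shuffle(seq)
    residues = [
        Residue(position=i + 1, aa=seq[i], atoms=[Atom("CA", "C", *pts[i])], plddt=90.0)
        for i in range(n_residues)
    ]
    return StructureModel(residues=residues, id=f"compact{seed}")


def synth_two_state_structure(
    sequence: ProteinRecord, spacing: float = 4.0
) -> StructureModel:
    """Two-cluster fold with a type-balanced burial split.

    Residues in even 20-residue blocks are "buried": their atom clusters are
    packed four at a time onto regular tetrahedra of edge ``spacing``, so
    every member contacts its three clique partners (contact counts scale
    with the size-class atom counts, making the derived per-type maxima
    type-dependent). Residues in odd blocks are "exposed": placed on a remote
    strand with 10 Å spacing (zero contacts, colasi 0). Because
    block-shuffled sequences put every residue type once per block, each type
    populates both burial states near-equally — which the burial-conditioned
    matrix derivation requires.
    """
    a = spacing
    tetra = np.array(
        [
            (0.0, 0.0, 0.0),
            (a, 0.0, 0.0),
            (a / 2, a * math.sqrt(3) / 2, 0.0),
            (a / 2, a * math.sqrt(3) / 6, a * math.sqrt(2.0 / 3.0)),
        ]
    )
    residues = []
    buried_i = exposed_i = 0
    for i, aa in enumerate(sequence.sequence):
        if (i // 20) % 2 == 0:
            clique, vertex = divmod(buried_i, 4)
            center = tetra[vertex] + np.array([100.0 * (clique + 1), 0.0, 0.0])
            buried_i += 1
        else:
            center = np.array([10.0 * exposed_i, 5000.0, 0.0])
            exposed_i += 1
        residues.append(
            Residue(position=i + 1, aa=aa, atoms=_atom_cluster(aa, center), plddt=90.0)
        )
    return StructureModel(residues=residues, id=sequence.id)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _substitution_prob(entropy_target: float) -> float:
    """Solve H(q) = target for the per-column substitution probability q,
    where the column distribution is (1-q) on the query residue and q/19 on
    each alternative."""
    if entropy_target <= 0:
        return 0.0

    def H(q: float) -> float:
        if q <= 0:
            return 0.0
        h = -q * math.log2(q / 19)
        if q < 1:
            h -= (1 - q) * math.log2(1 - q)
        return h

    hi = 19.0 / 20.0
    if entropy_target >= LOG2_20:
        return hi
    return brentq(lambda q: H(q) - entropy_target, 1e-12, hi)


def _coupled_mutant(native: str, offset: int = 1) -> str:
    return AMINO_ACIDS[(AA_INDEX[native] + offset) % 20]


def _anti_mutant(native: str, offset: int = 1) -> str:
    return AMINO_ACIDS[(AA_INDEX[native] - offset) % 20]


def synth_msa(
    spec: FixtureSpec,
    sequence: ProteinRecord | None = None,
    buried: np.ndarray | None = None,
) -> MSA:
    """Homolog rows drawn per column to hit the target entropies.

    With ``neighbor_coupling``, a designated substitution (native -> next
    residue letter) is boosted — and its anti-partner suppressed — whenever
    the homolog matches the query at the preceding position, giving the
    neighbor-compatibility statistic a recoverable signed signal. With
    ``burial_coupling`` (requires ``buried`` states), a second designated
    substitution is permitted only at buried columns, giving the
    burial-conditioned statistic its signal.
    """
    if sequence is None:
        sequence = synth_sequence(spec)
    n, L = spec.n_homologs, len(sequence.sequence)
    if spec.burial_coupling and buried is None:
        raise ValueError("burial_coupling requires per-position buried states")
    rng = spec.rng(2)
    targets = spec.entropy_targets()
    if len(targets) != L:
        raise ValueError("entropy profile length != sequence length")
    qsub = np.array([_substitution_prob(h) for h in targets])
    seq_idx = np.array([AA_INDEX[aa] for aa in sequence.sequence])

    def column_dist(i: int, state_buried: bool | None) -> np.ndarray:
        native = seq_idx[i]
        p = np.full(20, qsub[i] / 19.0)
        p[native] = 1.0 - qsub[i]
        if spec.burial_coupling and qsub[i] > 0:
            mb = AA_INDEX[_coupled_mutant(sequence.sequence[i], 2)]
            me = AA_INDEX[_anti_mutant(sequence.sequence[i], 2)]
            if mb != native and me != native and mb != me:
                if state_buried:
                    p[mb] += p[me]
                    p[me] = 0.0
                else:
                    p[me] += p[mb]
                    p[mb] = 0.0
        return p

    def boosted(p: np.ndarray, i: int) -> np.ndarray:
        # flank matches the query: enrich the designated coupled mutant at the
        # expense of its anti-partner and of part of the conservation mass
        native = seq_idx[i]
        mc = AA_INDEX[_coupled_mutant(sequence.sequence[i])]
        ma = AA_INDEX[_anti_mutant(sequence.sequence[i])]
        if mc == native or ma == native or mc == ma:
            return p
        out = p.copy()
        delta = spec.coupling_strength * (out[ma] + 0.25 * out[native])
        out[mc] += delta
        out[ma] -= spec.coupling_strength * out[ma]
        out[native] -= spec.coupling_strength * 0.25 * out[native]
        return out

    rows = np.empty((n, L), dtype=np.int8)
    for i in range(L):
        state = bool(buried[i]) if buried is not None else None
        p = column_dist(i, state)
        if spec.neighbor_coupling and i > 0 and qsub[i] > 0:
            pb = boosted(p, i)
            match = rows[:, i - 1] == seq_idx[i - 1]
            rows[:, i] = np.where(
                match,
                _sample_categorical(pb, n, rng),
                _sample_categorical(p, n, rng),
            )
        else:
            rows[:, i] = _sample_categorical(p, n, rng)
    decode = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    row_strings = [bytes(decode[r]).decode() for r in rows]
    return MSA(
        ids=[sequence.id] + [f"hom{j}" for j in range(n)],
        rows=[sequence.sequence] + row_strings,
        query_index=0,
    )


def _sample_categorical(
    p: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int8)


# ---------------------------------------------------------------------------
# DMS scores and clinical-style sets
# ---------------------------------------------------------------------------


def enumerate_variants(protein: ProteinRecord) -> list[Variant]:
    """All 19·L possible missense variants of a protein, position-major."""
    out = []
    for pos, native in enumerate(protein.sequence, start=1):
        for mutant in AMINO_ACIDS:
            if mutant != native:
                out.append(Variant(protein.id, pos, native, mutant))
    return out


def synth_dms(
    spec: FixtureSpec,
    variants: Sequence[Variant],
    features: pd.DataFrame,
) -> tuple[DMSDataset, dict]:
    """Scores from a linear model over min-max-scaled features plus a
    two-peak mixture offset and Gaussian noise.

    score = intercept + w · scaled_features + mu_k + N(0, sigma), with mu_k
    drawn from ``peak_means`` (probability ``peak_weight`` on the second
    peak). Returns the dataset and the generative truth (weights, intercept,
    scaler bounds, peak assignments, signal variance) for recovery tests.
    """
    if len(variants) != len(features):
        raise ValueError("variants and features length mismatch")
    rng = spec.rng(3)
    X = features[FEATURE_NAMES].to_numpy(dtype=float)
    mins, maxs = X.min(axis=0), X.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    Xs = np.where(maxs > mins, (X - mins) / span, 0.0)
    w = np.asarray(spec.true_weights)
    signal = Xs @ w
    peaks = np.asarray(spec.peak_means)
    assignment = (rng.random(len(signal)) < spec.peak_weight).astype(int)
    noise = rng.normal(0.0, spec.noise_sigma, size=len(signal)) if spec.noise_sigma else 0.0
    scores = spec.intercept + signal + peaks[assignment] + noise
    dataset = DMSDataset(
        protein_id=variants[0].protein_id,
        variants=list(variants),
        scores=scores,
    )
    truth = {
        "weights": w.tolist(),
        "intercept": spec.intercept,
        "scaler_mins": mins.tolist(),
        "scaler_maxs": maxs.tolist(),
        "peak_means": list(spec.peak_means),
        "peak_weight": spec.peak_weight,
        "peak_assignment": assignment.tolist(),
        "noise_sigma": spec.noise_sigma,
        "signal_variance": float(np.var(signal)),
        "seed": spec.seed,
    }
    return dataset, truth


def synth_clinical_set(
    n_proteins: int = 5,
    per_protein: int = 200,
    true_boundary: float = 0.65,
    label_noise: float = 0.0,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Labeled clinical-style score sets for threshold calibration.

    Scores come from two overlapping Gaussians around the true boundary;
    labels are the thresholded latent score (1 = pathogenic, score <=
    boundary) with flip probability ``label_noise``. Returns
    protein id -> (scores, labels).
    """
    if not 0 < true_boundary < 1.5:
        raise ValueError("true_boundary must lie in (0, 1.5)")
    rng = np.random.default_rng(seed)
    out = {}
    for p in range(n_proteins):
        n_low = per_protein // 2
        n_high = per_protein - n_low
        scores = np.concatenate(
            [
                rng.normal(true_boundary - 0.35, 0.2, n_low),
                rng.normal(true_boundary + 0.35, 0.2, n_high),
            ]
        )
        scores = np.clip(scores, 0.0, 1.5)
        labels = (scores <= true_boundary).astype(int)
        flips = rng.random(per_protein) < label_noise
        labels[flips] = 1 - labels[flips]
        out[f"clin{p}"] = (scores, labels)
    return out


# ---------------------------------------------------------------------------
# model-collection fixture for selection experiments
# ---------------------------------------------------------------------------


def _whitened_features(rng: np.random.Generator, n: int) -> np.ndarray:
    """Feature matrix with exactly decorrelated columns inside (0.05, 0.95).

    QR of centered uniform draws, rescaled so every entry stays well inside
    the unit interval: predictions through any unit-interval min-max scaler
    then remain linear (no clipping), preserving the exact decorrelation.
    """
    p = len(FEATURE_NAMES)
    X = rng.random((n, p))
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    return Q * (0.45 / np.abs(Q).max()) + 0.5


def synth_psp_collection(
    n_signal: int = 3,
    n_noise: int = 2,
    n_variants: int = 300,
    noise_sigma: float = 0.1,
    seed: int = 0,
):
    """Fitted predictors for several synthetic proteins sharing one true
    linear model, plus "noise" proteins with no transferable signal.

    Three design elements make the no-signal members fail selection by
    construction rather than by chance (a lone random fit direction in 14
    dimensions aligns with the shared weights in a sizeable fraction of
    seeds):

    * noise scores are exactly linear in a weight vector orthogonalized
      against the shared one, so the fitted direction carries no
      transferable component (score noise would leak a random aligned
      component into the fit);
    * signal proteins' feature matrices are empirically decorrelated
      (whitened), so a noise predictor's sample correlation with signal
      scores is exactly the (null) population value instead of a ±1/sqrt(n)
      fluctuation;
    * noise proteins come in mirrored pairs (same features, complementary
      scores), so anti-correlated partners never prop up each other's round
      medians while signal models keep a strictly positive median against
      the pair.

    Returns (models, datasets) ready for cross-prediction / selection.
    """
    from .psp_regression import fit_psp

    rng = np.random.default_rng(seed)
    w = np.asarray(DEFAULT_TRUE_WEIGHTS) * 3.0  # strong shared signal
    models, datasets = [], []
    non_a = [aa for aa in AMINO_ACIDS if aa != "A"]
    pending_mirror: tuple[np.ndarray, np.ndarray] | None = None
    for j in range(n_signal + n_noise):
        pid = f"p{j}"
        if j < n_signal:
            X = _whitened_features(rng, n_variants)
            y = X @ w + rng.normal(0, noise_sigma, n_variants)
        elif pending_mirror is None:
            raw = rng.normal(size=len(FEATURE_NAMES))
            w_perp = raw - (raw @ w) / (w @ w) * w
            w_perp *= np.linalg.norm(w) / np.linalg.norm(w_perp)
            X = rng.random((n_variants, len(FEATURE_NAMES)))
            y = X @ w_perp
            pending_mirror = (X, y)
        else:
            X, y_prev = pending_mirror
            X = X.copy()
            y = 1.0 - y_prev
            pending_mirror = None
        variants = [
            Variant(pid, i // 19 + 1, "A", non_a[i % 19]) for i in range(n_variants)
        ]
        ds = DMSDataset(protein_id=pid, variants=variants, scores=y)
        feats = pd.DataFrame(X, columns=FEATURE_NAMES)
        models.append(fit_psp(ds, feats, balance=False, seed=seed))
        datasets.append((ds, feats))
    return models, datasets
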