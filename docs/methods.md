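# Methods

This note records the model, its operational constants, the numerical and
design choices made where the procedure was genuinely open, and what the
synthetic fixtures do and do not establish.

## The regression model

Each protein-specific predictor (PSP) is an ordinary least-squares fit of
normalized DMS scores on 14 descriptors min–max scaled to [0, 1] using the
training split's extremes. At prediction time, feature values outside the
training range are clipped to [0, 1]: this keeps predictions bounded under
the trained scale at the cost of flattening extrapolation. Rank-deficient
designs are resolved by the pseudo-inverse and flagged (`collinear` in the
model metadata) rather than rejected.

Normalized scores are anchored at 1 = wild-type-like function. The
normalization `normalize_scores(raw, wildtype, null=None)` is a ratio to the
wild-type readout, or an affine map sending (null, wildtype) → (0, 1) when a
non-functional baseline readout is available. Scores above 1 are preserved —
they are the hypermorphic (gain-of-function) signal — and predictions are
never clamped.

### Balancing

DMS score distributions are typically bimodal (a damaged peak and a
wild-type-like peak) and imbalanced. Before fitting, a two-component
univariate Gaussian mixture is fit to the scores and the boundary between the
peaks is taken as the **equal-posterior decision boundary** — the root of
w₁·N(x; μ₁, σ₁) = w₂·N(x; μ₂, σ₂) between the component means nearest their
midpoint — rather than the midpoint of the means, because the Bayes boundary
is what "optimal threshold separating the two peaks" means when the
components have unequal spreads. Degenerate fits (collapsed components, or a
vanishing mixture weight) fall back to the median and are flagged. The larger
group is then undersampled uniformly at random to the size of the smaller.
One integer seed governs both the mixture initialization and the
undersampling draw, and is recorded in the model metadata.

### Cross-validation

Variant effects at the same position are not independent, so the
cross-validation groups by position: one fold per distinct position, all of
its variants held out together. Balancing and the min–max scaler are re-fit
inside each training fold only; the held-out rows are never balanced. A fold
whose training scores lose one peak entirely is fit unbalanced and flagged.
Whether the scaler should have been fit once globally instead is unstated in
the field's practice; the per-fold choice is leakage-safe and is the one
implemented.

## The 14 descriptors

Operational constants, with defaults as shipped in `FeatureConfig`:

| constant | default | meaning |
|---|---|---|
| `contact_radius` | 5.0 Å | heavy-atom contact distance for colasi / conserved-neighbor features |
| `mj_radius` | 6.5 Å | side-chain-centroid distance for contact-energy neighbors |
| `plddt_cutoff` | 70 | confidence gate; below it all 7 structural features are 0 |
| `entropy_max` | 4.12 | published operational maximum for conservation cutoffs |
| `conserved_cutoff` | 1.37 | "conserved" column threshold (one third of 4.12) |
| `burial_colasi_cutoff` | 0.5 | buried (>) vs exposed (≤) |
| `neighbor_window` | 3 | ±window for the neighbor-entropy feature |
| `classification_threshold` | 0.82 | pathogenic iff score ≤ threshold |

Notes on the open points:

* Entropy is computed in base 2 over the 20-residue alphabet with gaps
  excluded, whose true maximum is log₂ 20 ≈ 4.32. The conserved-neighbor
  features nevertheless use the published constants 4.12 / 1.37 verbatim, as
  explicit configuration decoupled from the entropy base: the provenance of
  4.12 (alphabet and base) is not derivable, so it is treated as an opaque
  operational constant rather than re-derived.
* The PSSM is a pseudo-counted log₂-odds against a uniform 1/20 background —
  the simplest defensible choice where the cited practice gives no formula;
  the background is configurable.
* The side-chain centroid is the mean of heavy atoms outside
  {N, CA, C, O, OXT}; glycine uses CA; a residue with no side-chain atoms in
  the model falls back to CA. Contacts to sequence-adjacent residues (i±1)
  are included (the contact definition says only "other residues"); a flag
  can exclude them.
* Per-protein median entropies m_acc/m_bur (for Fanc/Fbnc) are computed over
  all residues regardless of pLDDT.
* colasi is deliberately not clamped above 1 (densely packed residues may
  exceed their reference maximum).
* Burial at exactly colasi = 0.5 is exposed (≤ convention); classification at
  exactly the threshold is pathogenic (≤ convention).

### The Miyazawa–Jernigan table

The contact-energy feature is defined against the published 20×20
residue–residue contact potential. That table is not shipped by any library
this package may depend on, so the default asset
(`MJTable.synthetic_default()`) is a clearly labelled synthetic stand-in
built from an additive hydrophobic-contact model, e(a,b) = −(h_a + h_b) —
additivity is the dominant component of statistical contact potentials, so
the stand-in reproduces the qualitative structure (strong aromatic/aliphatic
pairs, weak charged pairs). Any real symmetric 20×20 table can be supplied
via TSV (`MJTable.from_tsv`, or `mj.tsv` next to the other matrix assets) and
flows through unchanged. No test asserts specific energy values.

## The derived matrices (neco, laar, maxnc)

Both substitution statistics are pseudo-counted log-ratios of a conditional
substitution distribution to its unconditioned baseline, accumulated over
(query, homolog) row pairs of reference alignments: the query row is the
conditioning sequence, every other row is a homolog, and columns where either
member of a pair is gapped are skipped for that pair. neco conditions on the
homolog matching the query at *both* flanking positions; query positions
without both flanks (termini) are skipped. laar conditions on the burial
state of the query position, computed with the same maxnc table that is
shipped (derived first from the same structures, for internal consistency).
The additive pseudo-count (default 1 per cell) guarantees every logarithm is
finite for any positive value; rows never observed in the data are exactly
the pseudo-count ratio (zero) and are listed in the matrix metadata. The
derivations are invariant to alignment row order and to structure file
format.

The gap symbol is `-` only; `.` and `X` are rejected, so entropy counts are
deterministic. Structures are re-indexed 1..N on load (complete, gap-free
models are assumed, as AlphaFold produces); the author numbering is kept as
metadata. pLDDT is read from the CA B-factor, falling back to the first heavy
atom.

## Ensemble and calibration

Cross-prediction applies model m (with m's scaler) to protein t's features
and correlates with t's observed scores; constant predictions give a missing
entry. Selection runs one round per left-out protein: every candidate not
trained on the left-out protein is scored by the **median** of its
cross-prediction Pearsons over the remaining proteins (never its own), and
candidates are ranked. The published rule — "most frequently showed the
highest performance" — does not fully specify an aggregation; this package
uses the **mean rank across the rounds in which a model was a candidate**,
with ties broken by the higher overall median Pearson, then lexicographic
protein id, because frequency-of-top-rank alone ties badly at small n. The
ensemble score is the median of the members' predictions, excluding any
member trained on the queried protein; for an even member count, the mean of
the two central order statistics.

Threshold calibration sweeps 0 to 1.5 in steps of 0.01 (the published range;
the step is chosen to match the resolution of the published optimum 0.82),
computes the per-protein MCC of "pathogenic iff score ≤ t" at each grid
point, takes the median across proteins, and picks the argmax (lowest
threshold on ties). Proteins with a single label class are skipped and
reported.

## Synthetic fixtures: what they emulate, and what passing means

The generators produce every input the tool consumes, deterministically from
a spec and seed:

* **Helical toy fold** — an ideal α-helix (rise 1.5 Å, twist 100°, radius set
  for the canonical 3.8 Å CA–CA distance) with pseudo side-chain atoms whose
  count follows a 3-level size class per residue type, so contact counts,
  burial and the volume term vary by type and position. pLDDT ripples around
  85 in the core and around 50 on a configurable low-confidence tail, keeping
  the pLDDT feature continuous-valued (a two-valued profile would make it
  exactly collinear with its own binarization and the regression
  unidentifiable). A helix was chosen over random coils because its contact
  structure is deterministic and analytically checkable.
* **Two-state reference fold** — buried residues packed four at a time onto
  regular tetrahedra, exposed residues on a remote sparse strand, alternating
  by 20-residue block so every residue type populates both burial states
  near-equally. This fold exists to give the burial-conditioned matrix
  derivation clean, type-balanced states; earlier lattice-ball designs leak
  surface residues into the exposed class unevenly across types.
* **Entropy-profiled alignments** — homolog residues drawn i.i.d. per column
  from a (1−q, q/19-uniform) distribution with q solved so the column's
  expected entropy hits the target. Optional neighbor coupling boosts a
  designated substitution when the homolog matches the query at the preceding
  position (and suppresses its anti-partner); optional burial coupling
  permits a designated substitution only at buried columns. These give the
  matrix derivations recoverable signed signal.
* **Linear DMS scores** — score = intercept + w·(min–max-scaled features) +
  μ_k + N(0, σ), with μ_k drawn from two peak means (defaults 0.2 and 1.0,
  70% weight on the wild-type-like peak, σ = 0.1) to emulate the bimodal,
  imbalanced shape of real assays. Defaults give ≥1000 variants per protein
  (60 residues × 19 substitutions). Recovery tests use a single peak at 0 so
  the linear truth is exact.
* **Clinical-style sets** — scores from two overlapping Gaussians around a
  true boundary, labels = thresholded latent score with a configurable flip
  probability.

Problem sizes used by the deeper tests, chosen as the package's own study
conditions: the matrix-null check uses 1000 homologs over a 10000-column
context-free alignment, because the per-cell sampling error of the log-ratio
is ≈ √((1−f)/C) for C conditional counts at conditional fraction f, and
~500 occurrences per residue type are needed for the maximum over all 380
off-diagonal cells to sit inside a ±0.05 band. Weight recovery uses 2014
variants (106 residues), the attenuation check 3002 variants (158 residues)
against the closed form r = s/√(s² + σ²).

The predictor-selection fixture deserves its own note. With five proteins,
each selection round's median is over at most three targets, so a predictor
fitted on unstructured noise — whose 14-dimensional fit direction aligns with
the shared true weights by pure chance in a sizeable fraction of seeds —
would be excluded only ~60% of the time. The fixture therefore makes the
no-signal members fail *by construction*: their scores are exactly linear in
a direction orthogonalized against the shared weights (score noise would leak
a random aligned component into the fit); the signal proteins' feature
matrices are empirically decorrelated (QR-whitened, bounded inside the unit
interval so min–max clipping never bends the linearity), making a noise
predictor's sample correlation with signal scores exactly its null population
value; and the noise proteins come as a mirrored pair (same features,
complementary scores) so the anti-correlated partners never prop up each
other's round medians while every signal model keeps a strictly positive
median against them.

Passing these tests shows the machinery is correct — counting, derivation,
fitting, grouping, aggregation, calibration — under conditions where the
truth is known. It does not show that the features capture real mutational
biophysics, that real DMS assays meet the linear-model assumptions, or that
the shipped synthetic contact-energy table matches the published potential;
those claims require real alignments, structures and assay data, which the
package deliberately does not fetch.

## Known limitations

* Single-chain, single-model structures only; no multimeric contacts.
* MSA construction (homolog search, filtering, alignment) is out of scope:
  the package consumes an existing aligned FASTA containing the query.
* The MJ-style table is a synthetic stand-in unless a real table is supplied.
* The exact published reference matrices cannot be reproduced without the
  published 593-structure reference set; the derivation machinery is fully
  implemented and oracle-tested on synthetic reference sets instead.
* Whether the original contact counting excluded covalently bonded neighbor
  atoms is unstated; this implementation counts all heavy-atom pairs within
  the radius, with an optional flag to exclude sequence-adjacent residues.
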