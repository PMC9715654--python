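# Methods

This note records the models, conventions, parameter choices and known
limitations behind `threadarch`. It states no empirical result that the
test suite or `scripts/acceptance.py` do not themselves compute.

## Residue-class observation model

At 3.0–3.5 Å a density map does not reveal most side chains, but some are
unambiguous. The package encodes nine observation classes with fixed
member sets:

| class | members | evidence |
|---|---|---|
| ARO | F, Y, W | large flat ring density |
| PRO | P | backbone kink, ring |
| GLY | G | absent side-chain density |
| SEQ_N / SEQ_X / SEQ_ST | N / all−{P} / S, T | glycan protrusion marks an N-x-S/T sequon |
| ALI_IN | L, I, V | medium density pointing into the β-core |
| SML_SURF | N, S, D | short surface stubs |
| UNK | all 20 | no evidence (scores zero) |

Histidine is excluded from ARO: its ring is not uniquely shaped at this
resolution. The sequon X position excludes proline, the standard
N-glycosylation consensus; the source text writes the motif as NXT/S
without stating the exclusion, so it is a package decision.

`build_query` assembles per-position observations into a degenerate query
(gap positions become UNK on request); `concretize_query` collapses it to
one representative letter per class (ARO→F, SEQ_X/UNK→A, ALI_IN→L,
SML_SURF→S, SEQ_ST→T, …) for export to external search engines. The
class-consistency of that policy is property-tested.

## Class-aware proteome search

Rather than searching a concretized sequence — which forces false
mismatches wherever UNK→A is wrong — the query is aligned directly in
class space. Scores are log-odds in bits with `P(a|C)` uniform over the
class members against a background composition `p_a` (default uniform
0.05), a mismatch floor of −4 bits, and an identically-zero UNK row so
uninformative positions neither help nor hurt. Alignment is affine-gap
Smith–Waterman (Gotoh; a gap of length *g* costs `open + g·extend`,
default 11 + g·1 bits, the common protein-search convention since the
source specifies none). Tie-breaking is deterministic: the reported
endpoint is the first maximum in row-major order and the traceback
prefers match over deletion over insertion. The DP kernel is
numba-compiled; correctness is pinned to an exhaustive enumeration of all
gapped local pairings (tiny instances), a memoised top-down recursion
(12×30 instances), and biotite's general-alphabet aligner.

Significance follows the Karlin–Altschul form `E(S) = K·m·n·e^(−λS)`.
(K, λ) are fitted empirically: maxima of local scores against
within-sequence shuffles of the database (composition- and
length-preserving nulls, ≥30 required) are fitted to a Gumbel by maximum
likelihood; λ = 1/scale, `K = e^(λ·loc)/(m·n̄)`. Reported E-values use the
total database length (the per-subject expectations summed over the
database), and the default report threshold is E ≤ 0.01. On decoy-only
proteomes the expected number of hits with E ≤ x must be ≈ x; this
calibration property is asserted at x ∈ {0.1, 1, 5} over 50 seeded
proteomes. Identity is defined over non-UNK query columns only (UNK
columns carry no evidence); coverage is aligned query positions over
query length. No iterative profile refinement is attempted, and no
heuristic seeding — every subject gets a full DP, which is fine at the
≤10⁴-sequence scale this targets.

The published search used an external engine on an unpublished
concretized sequence; its printed E-value and identity are engine- and
version-specific. The package therefore targets the qualitative outcome —
a unique significant hit — plus the calibration and planted-recovery
properties above.

## Helical geometry

A screw operator is (twist in degrees, rise in Å, axis). Sign convention,
stated because depositions rarely state theirs: positive twist is
right-handed about the axis direction, and the axis is oriented so the
rise is non-negative — the thread is then left-handed with twist
−103.234°. Estimation superposes one chain onto another (Kabsch over the
shared (residue, atom) set) and decomposes the rigid transform: the
rotation axis and angle give the twist, the translation component along
the axis the rise, and the perpendicular component locates the axis by
least squares. Degenerate pure translations return twist 0 with the axis
along the translation. Superposition RMSD above 5 Å only warns — the
operator is still returned, but is probably meaningless.

The filament axis is estimated from chain centroids. Centroids of a
helical stack lie on a helix, so their second differences are exactly
radial: the axis direction is the null direction of the stacked second
differences (SVD), and the axis point comes from an algebraic circle fit
in the perpendicular plane. The direction is accepted only when the mean
centroid step is mostly axial (≥ 0.8 of its norm along the candidate),
otherwise the estimator falls back to the centroid principal axis — exact
for twist-free stacks, adequate for very short ones. An optional
refinement minimises the self-match score over two axis-tilt parameters.

Symmetry search scores each candidate (twist, rise) on a grid by
self-match: transform all polymer CA atoms, exclude those that land above
the top of the model (no partner subunit exists there; a candidate
keeping fewer than 20% of atoms scores ∞), and take the mean
nearest-atom distance. Grid defaults 1° × 0.5 Å, refined once around the
best local minimum at 10× finer steps — finer than the 0.5°/0.1 Å
agreement the estimators are held to. Peak reduction tries candidates
`((twist + 360m)/k, rise/k)` for k = 2..k_max, m = −k..k and returns the
smallest-rise candidate whose self-match is within 0.5 Å of the peak's
own score (ties: smaller |twist|); this resolves the characteristic
ambiguity where a coarse peak (here ~95 Å / ~50°) corresponds to several
subunits, and is idempotent by construction.

## Architecture detectors

**Subunit indexing.** Chains are ordered by centroid projection onto the
axis; offsets are reported as signed index differences. Filament polarity
is unknowable from coordinates alone, so no "toward the cell" direction
is ever claimed.

**DSC.** The donor tail is the first `tail_length` residues (default 10 —
the true tail boundary is not printed anywhere; this is a free
parameter). Tail heavy-atom contacts within 4.5 Å are binned by acceptor
offset; an offset is called at ≥ 20% of inter-chain tail contacts.
β-pairing evidence is counted as backbone N–O pairs ≤ 3.5 Å (a
hydrogen-bond proxy; no DSSP dependency, since strand counts are
assignment-method-dependent). Contact fractions are rigid-motion
invariant by construction and tested as such.

**Isopeptide bonds.** Donors are the side-chain amide/carboxylate carbons
of Asn/Asp/Gln/Glu (CG/CD; a coarse model's single SC pseudo-atom is
accepted as fallback). Acceptors are the α-amino nitrogen of each chain's
first modelled residue plus lysine NZ. A candidate needs distance ≤ 1.8 Å
(covalent, as modelled; `survey=True` widens to 2.5 Å for unrefined
models) and an amide-plane dihedral within 30° of planarity when the
flanking atoms exist. Same-chain pairs are excluded: the bond of interest
is intermolecular.

**Sequons and glycans.** The sequon scanner matches N-x(≠P)-S/T with
overlaps allowed and respects the supplied numbering offset (mature
thread numbering starts at Asp24, the signal peptidase I product).
Sequence may come from FASTA or be read off residue names; the source is
recorded per hit, and sequence-scan counts are reported separately from
modelled-glycan counts. Glycan trees are traversed strictly through
explicit linkage records (LINK/struct_conn) — connectivity is parsed,
never inferred from distances — rooted at each glycosylated Asn;
completeness means exactly 2 GlcNAc + 2 Man + 1 Glc + 1 sulfoquinovose,
with the branch at the second GlcNAc.

**Diameter.** Twice the 99th percentile of radial atom distances from the
axis, so a single stray atom cannot inflate the width; protein-only by
default.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (spec, seed); every plantable feature is
recorded in a manifest so detector tests have exact ground truth.

The canonical synthetic target is a deterministic 206-residue mature
subunit numbered from Asp24 carrying exactly the five sequons
N56/N80/N83/N121/N146, Asn57 (the isopeptide donor) at the X position of
the first sequon, an early YYY motif, and a protein-like background
composition. It is a constructed stand-in, not the real subunit sequence.

Decoy proteomes draw i.i.d. sequences (uniform composition, lengths
100–300) with the target inserted at a seeded random rank. The
observation noise model emits each readable feature with a per-class
probability (defaults: ARO/PRO 0.9, GLY 0.8, sequon triplets 0.9 as a
unit, inward aliphatics 0.8 on a 30% inward mask, surface N/S/D 0.7) and
then corrupts each position to a wrong class with probability 0.05.
No error model for manual map interpretation exists in the source; these
rates are plausible placeholders chosen once, and retrieval is
additionally checked across misassignment rates 0–0.30.

Synthetic filaments are coarse three-pseudo-atom-per-residue models
(N, CA, SC — detectors only use distances and directions): a head ring of
radius 14 Å displaced 6 Å from the axis (protein-only width ≈ 40 Å), a
10-residue tail routed toward the subunits at the planted contact offsets
with the N-terminus reaching deepest (offset 2, then offset 1), stacked
by the deposited operator so that at σ=0 all chains are exact rigid
transforms. The planted isopeptide donor SC is placed exactly 1.33 Å from
the acceptor nitrogen, coplanar with the flanking CAs. Per-atom Gaussian
noise is added last, except that the isopeptide placement is re-imposed
afterwards: a covalent bond is a constraint, not a fluctuating contact,
and letting independent noise stretch a 1.33 Å bond past the 1.8 Å
detection cutoff would test the noise model, not the detector. Not
emulated: real β-sheet hydrogen bonding, rotamers, glycan coordinates
(`attach_reference_glycans` decorates connectivity only, with placeholder
coordinates), density maps. Passing tests therefore demonstrate the
correctness of the geometry and inference machinery under controlled
conditions, not robustness to experimental model-building error.

## Problem sizes

The suite and the acceptance script run everything at desk scale, chosen
as the package's own defaults: 6–8 subunit filaments (206-residue
subunits for detectors, 60-residue subunits for grid symmetry searches),
1000-decoy proteomes for retrieval, 200-decoy proteomes × 50 seeds for
E-value calibration checks, 100 seeded filaments for isopeptide
sensitivity/specificity, and 100 shuffles per E-value fit.

## Known limitations

* Coordinate-space only: no density-map handling, no layer-line indexing,
  no map-space symmetry refinement.
* The aligner is O(m·n) per subject with no seeding; fine for ≤10⁴
  sequences, not for large databases.
* E-value calibration assumes the Gumbel regime holds for the class
  alphabet and the given gap penalties; the uniformity tests check the
  regime actually used, nothing beyond it.
* Axis estimation needs ≥4 chains for the helix-aware path and degrades
  gracefully (principal axis) below that.
* Glycan validation trusts the deposition's linkage records; missing
  struct_conn rows yield orphan warnings, not inferred bonds.
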