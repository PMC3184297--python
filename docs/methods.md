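# Methods

## Scoring model

A chain is reduced to its main-chain N, Cα and C atoms.  For an
observing residue *i* the local frame is: origin at Cα; ŷ the unit
vector toward N; x̂ the component of (C − Cα) orthogonal to ŷ,
oriented so C has positive x; ẑ = x̂ × ŷ.  The rotation matrix whose
rows are (x̂, ŷ, ẑ) is orthonormal with determinant +1 by
construction, so the frame is right-handed and every local coordinate
is rigid-motion invariant but chirality-sensitive — a mirrored
structure produces different local coordinates and therefore a
different score, which is essential for a backbone potential.

Partner eligibility: Cα–Cα distance ≤ cutoff and chain separation
> `exclude_neighbors`, where separation is the difference of author
residue numbers.  The numbering rule implements the chain-break policy:
residues flanking a gap (missing residues, or a residue dropped for an
incomplete main chain) are not peptide-bonded neighbours and are
therefore mutually eligible.  Each unordered pair is counted and scored
twice, once from each residue's frame, identically in training and
scoring.

Binning: each axis coordinate c maps to bin ⌊c⌋+1 for c ≥ 0 and ⌊c⌋
otherwise, so bin +k covers [k−1, k), bin −k covers [−k, −k+1), and no
bin 0 exists.  The convention is identified by a string constant that
is stamped into every database header; the scorer refuses a database
with a different stamp, so trainer and scorer can never disagree
silently.  Published figures of this family of potentials show only
that bins carry signed nonzero labels; the half-open orientation is
this package's declared, versioned choice.

Scores: `score(i, j, b) = −ln(n_obs / n_exp(b))` with
`n_exp(b) = total_count(b) / 400`, the mean over all ordered type
pairs, zero-count pairs included.  Unobserved (pair, bin) combinations
are charged `penalty_mult ×` the pair's worst (most positive) observed
score.  When a pair's worst observed score is not positive, or the pair
was never observed at all, the base falls back to the global worst
positive score; if the whole table has no positive score (possible only
for degenerate, tiny corpora) the base is ln 400 — the score of a bin
observed once by a single pair — so a penalty is never favourable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 14 Å | partner eligibility radius (Cα–Cα) |
| `exclude_neighbors` | 1 | sequence neighbours per side never scored |
| `penalty_mult` | 3.0 | zero-count penalty as a multiple of the pair's worst score |

The defaults are the winners of the 84-version grid (cutoffs 8–20 Å
step 2; exclusions 1–4; multipliers 1–3×) under repeated tenfold
cross-validation.  `eligibility` is applied identically during counting
and scoring; each grid version gets its own counting pass.

## Evaluation measures

Ranks are competition ("minimum") ranks; ties in float scores are
broken deterministically by index.  Z-scores use the sample (n−1)
standard deviation and are oriented `(mean − score_of_interest)/sd`, so
better-than-mean structures give positive values.  CC is the raw
Pearson r between score and Cα RMSD (positive for a well-behaved
ascending-is-better function).  Fraction enrichment uses
k = ⌈0.1 N⌉ in both the numerator's intersection and the denominator.
R_B10 uses the 10 best-scoring decoys, or all of them when a set has
fewer.  Undefined measures (zero score variance, constant RMSD, too few
members) are NaN and are excluded pairwise from aggregation, with
counts reported.

Cα RMSD is the least-squares optimal-superposition RMSD over all Cα
atoms (rotation + translation, reflections excluded), computed via
`scipy.spatial.transform.Rotation.align_vectors`; the residual is
measured by explicitly applying the fitted rotation rather than from
the eigenvalue shortcut, which loses ~1e-7 Å to cancellation on
near-identical inputs.

Wilcoxon comparison: paired signed-rank by default (all functions score
the same sets), one-tailed for "A's R_B1 distribution is lower than
B's", zeros handled by Pratt's method, exact null distribution when
n ≤ 25 with no zeros and no tied |differences|, otherwise the normal
approximation with continuity correction.  All-zero differences return
p = 1 with a degeneracy flag.  An unpaired rank-sum mode is available
behind a flag.

Cross-validation: the decoy sets are partitioned into near-equal folds
(sizes differ by at most 1).  Per fold, the version minimizing mean
RMSD_decoy over the held-in sets is selected and charged with its mean
over the held-out fold; the repeat's winner is the selected version
with the lowest mean held-out RMSD_decoy.  The procedure repeats with
fresh random partitions (deterministic given the seed), and the final
winner is the modal repeat winner, ties broken by mean held-out
performance.  A full per-fold report is returned.

## ω-angle baseline

ω_k = dihedral(Cα_k, C_k, N_{k+1}, Cα_{k+1}) in the standard sign
convention (verified against an independent dihedral implementation).
The baseline computes each structure's sample standard deviation σ of
the ω angles within 15° of planar 180° (angles unwrapped around 180°
first, so −178° and +178° are 4° apart) and scores each structure
|σ − mean σ over the set|.  Structures with fewer than two qualifying ω
have an undefined sample SD; they are excluded from the mean and
flagged NaN.  The ranking direction is not forced by the construction;
the evaluation drivers default to descending (largest deviation ranks
first), which is the direction that recognizes planar-ω natives among
ω-noisy decoys, and expose it as a flag.

## Synthetic data

The generator emulates the two inputs the method needs — a training
corpus of "correct" structures and labelled decoy sets — without any
external downloads.  Backbones are built by sequential
internal-coordinate (NeRF) placement with ideal bond lengths
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å) and angles (N–Cα–C 111.2°,
Cα–C–N 116.2°, C–N–Cα 121.7°), so a structure is exactly its sequence
plus per-residue (φ, ψ, ω); recomputing the dihedrals from the
coordinates reproduces the spec to < 1e-6°.  Corpora are random
helix/strand/coil segment mixtures (default 50/25/25) with Gaussian
φ/ψ jitter (sd 3°) and coil drawn from a declared four-basin
Ramachandran-like mixture; ω is planar.  Decoys rebuild a native's
dihedrals with Gaussian φ/ψ noise of chosen sd (ω noise optional, for
exercising the ω baseline), which gives a smooth, tunable RMSD
spectrum from near-native to non-native.

What the synthetic data does *not* emulate: real packing density,
sterics (self-intersection is not prevented), side chains, sequence–
structure correlation, or the error statistics of any particular decoy
generator.  Passing tests therefore demonstrate the correctness and
internal consistency of the machinery and its discrimination behaviour
under controlled perturbations — not benchmark performance on community
decoy archives, which requires external corpora and decoy downloads via
the CLI.

Problem sizes used by the test suite and the acceptance script (corpora
of 40–200 chains of 20–80 residues, 20 decoy sets of 50 decoys, 20
discrimination trials) were chosen as the smallest sizes at which the
measured quantities are stable across seeds.

## Numerical and design choices

- Coordinates are kept in Å exactly as read; no recentering at parse
  time.  PDB parsing is delegated to gemmi; altlocs resolve to highest
  occupancy (ties: first listed), MODRES and tabulated modified
  residues (e.g. MSE) map to their standard parents, unmappable or
  incomplete residues are dropped with a warning and a recorded chain
  break.  Only the first MODEL and (by default) the first chain are
  read — the method scores interactions within a single polypeptide
  chain.
- Observers with degenerate geometry (N/Cα/C collinear within 1e-6)
  are skipped as observers but remain eligible partners (a partner
  contributes only its Cα).
- The database is a checksummed JSON container (format version, bin
  convention, params, provenance, dense 20×20 penalty, sparse score
  records).  JSON float text round-trips IEEE doubles bit-exactly, so
  serialization is lossless; unknown versions and checksum mismatches
  are refused.  A lossless TSV export exists for inspection.
- Bins whose components exceed ⌈cutoff⌉ are unreachable (eligibility is
  distance-gated before binning) and the lookup treats a request for
  one as a contract violation rather than a penalty case.
- Corner bins inside the cube but outside the cutoff sphere are simply
  never populated or requested; they need no special handling.

## Known limitations

- Single-chain scoring only; no mmCIF; first MODEL only; insertion
  codes are honoured for ordering but not for arithmetic.
- The potential is only as good as its training corpus; the bundled
  generator produces idealized geometry, and a database trained on it
  is not transferable to real proteins.
- The ω baseline is set-relative by construction: scores change when
  the composition of the decoy set changes, and it cannot score a
  single structure in isolation.
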