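# Methods

## The problem

A homo-oligomer with cyclic C*n* symmetry that is *pseudo*-symmetric — its
subunits can individually occupy distinct conformational states — poses a
bookkeeping problem for single-particle analysis. Consensus refinement under
C*n* returns, for each particle, a ZYZ Euler triple (rot, tilt, psi) that is
correct only up to an unknown element of the symmetry group (the *anchor*).
Focused classification after symmetry expansion assigns each subunit copy a
state label, but because of the anchor those labels are observed only up to a
cyclic rotation of the whole label string. `symcensus` turns this ambiguity
into usable structure: the rotation-invariant identity of a particle is its
*necklace class*, and composing the orientation with the canonicalizing
rotation puts all particles of one class into a single reference frame.

## Conventions and the orientation model

- The rotation matrix of a triple is `R = Rz(psi) @ Ry(tilt) @ Rz(rot)`
  (degrees). Cyclic operators about the symmetry z-axis act on the
  reference-frame side — right multiplication by `Rz(k*360/n)` — which in
  Euler space is simply `rot += k*360/n`. This is why subunit identity can be
  read from the first Euler angle alone.
- Subunit copy index k increases with +360/*n* increments of rot; copy 0 is
  the untouched parent record. The copy index is stored in a tool-specific
  column (`_symcensusSubunitIndex`); when absent (externally expanded
  tables), it is recovered from rot offsets relative to the first record of
  each parent group, relying on expansion emitting the parent record first.
- Angles are normalized to rot, psi ∈ (−180, 180], tilt ∈ [0, 180] whenever
  they are rewritten, to avoid drift in the modular arithmetic.
- Parent identity is the exact tuple (micrograph name, image name,
  coordinate X, coordinate Y) as read; expanded copies duplicate these
  fields verbatim.

## Canonicalization

The canonical form of a label string is its lexicographically smallest
cyclic rotation (plain string order, so `i < o`); the *shift* is the
smallest rotation index achieving it, with `rotate(s, r)[j] = s[(j+r) mod n]`.
Rotations only, never reflections: particle handedness is physically fixed
in cryo-EM, so mirror-related arrangements such as `iioio` and `ioioo` are
distinct configurations. For prime *n* the minimizing rotation of a
non-uniform string is unique; for uniform strings and general *n*, the
smallest minimizing shift is chosen. All eight two-state pentamer
configuration names in common use are already canonical under this order.

Oligomers containing any subunit whose class maps to the `excluded` sentinel
are dropped whole from the census rather than partially counted — partial
counting would bias configuration frequencies toward classes with fewer
resolved subunits.

## Supervised reorientation

Reorientation composes the parent orientation with the operator equal to the
configuration shift. Two equivalent implementations exist — compose the
shift into rot, or select the expanded copy whose subunit index equals the
shift — and the package tests their identity. The defining contract: after
reorientation, reading the particle's labels in slot order yields the
canonical string, so all particles of one configuration agree slot-by-slot.
Uniform configurations have shift 0 and pass through unchanged. Origin-shift
columns are copied untouched: a rotation about the projection normal in the
reference frame does not alter in-plane shifts under this convention. Only
metadata is modified; downstream reconstruction interprets the updated
angles.

## Synthetic generator

The generator emulates the statistical structure of a focused-classification
experiment:

- **Configurations** are drawn i.i.d. from stated frequencies. The default
  frequency vector populates all eight pentamer classes with values between
  5.2% and 23.6% (iiiii 23.6, iiiio 20.0, iiioo 15.0, iiooo 10.0, ioooo 8.0,
  ooooo 13.0, iioio 5.2, ioioo 5.2), the per-configuration range reported
  for pseudo-C5 channel particles under subactivating conditions.
- **Anchors** are uniform on [0, n): the observed orientation is the true
  one composed with the anchor operator, and the label observed in slot j is
  the true label at position (j + anchor) mod n. This is exactly the
  consensus-refinement ambiguity.
- **Label noise** is an i.i.d. symmetric flip per subunit with probability
  ε (for alphabets larger than two, a uniform resample among the other
  symbols). No systematic confusion structure is modelled.
- **Orientations** are uniform over SO(3) via normalized Gaussian
  quaternions, converted to ZYZ — avoiding the density bias of uniform
  Euler sampling.

What the generator does *not* emulate: CTF, projection to 2D, detector
noise statistics, per-particle defocus, orientation estimation error, or
class-dependent misclassification. Passing tests therefore demonstrate the
correctness of the metadata bookkeeping under the stated ambiguity model,
not robustness to all pathologies of experimental data.

## Toy scene and averaging validator

Toy "particles" are 3D volumes, not 2D projections: the method under test
manipulates orientation metadata, and 3D particles exercise the full C*n*
ambiguity without requiring a Fourier-space reconstructor. Each state volume
is a sum of n unit-peak isotropic Gaussian blobs; blob k sits at azimuth
k·360/n in the xy-plane at radius R0, displaced outward by δ when subunit k
is in the `o` state. Defaults: 64³ grid, 2 Å voxels, R0 = 34 Å, δ = 10 Å,
σ_b = 6 Å, per-voxel Gaussian noise with σ equal to the blob peak. R0 is
chosen so the entire outer blob envelope (R0 + δ + 3σ_b = 62 Å) fits inside
the 64 Å half-edge of the grid, keeping rotations free of edge clipping.

Volumes are rotated with trilinear interpolation (`output(x) =
vol(R⁻¹(x−c)+c)`), so rotating by R1 then R2 equals rotating by R2·R1, and
aligned averaging is the mean of each particle rotated by the inverse of its
assigned orientation — real-space averaging stands in for reconstruction.

The asymmetry readout is the **slot contrast**: mean density in a spherical
probe (radius σ_b) at (R0+δ, azimuth s·360/n) minus the mean in a probe at
(R0, same azimuth), per slot s, measured on the averaged volume. The
**separation statistic** is the maximum slot contrast minus the mean of the
remaining slots — more robust than a single-slot threshold when noise moves
the argmax.

## Numerical choices

- Matrix contracts are tested at 1e-10 elementwise; the Euler↔matrix
  decomposition handles the gimbal-degenerate tilt ∈ {0, 180} by folding the
  free angle into psi.
- STAR numeric values are written with full round-trip precision (`repr`);
  the format contract is the token sequence, not spacing. Numeric-looking
  columns parse to int64/float64; anything else (including non-finite
  tokens) stays text.
- Correlation checks between averaged and reference volumes are evaluated on
  the signal support (voxels above 5% of the reference maximum): the 64³
  grid is ~99.7% empty, so whole-grid correlation is dominated by noise in
  signal-free voxels and says little about feature recovery. Pilot runs at
  the default scene give support-masked correlations ≈ 0.96 for 100-particle
  symmetric averages (frozen threshold 0.95) and supervised/naive separation
  ratios ≈ 20 for 200 singly-activated particles (frozen factor 5).
- Stochastic tests run at fixed seeds; binomial checks use 3σ bounds at the
  stated sample sizes (e.g. 50,000 subunit labels for the flip-rate check).

## Problem sizes

The test and acceptance runs use 2,000–10,000 synthetic oligomers for census
and anchor-recovery checks, the full 511,578-record table for expansion
accounting, and 200 particles at 64³ for the averaging comparison — sizes at
which every statistical bound above is comfortably resolved on a single CPU.

## Known limitations

- Only cyclic point groups; dihedral and higher groups would need
  two-parameter operator bookkeeping.
- One label column per subunit; no multi-feature label vectors.
- The STAR layer supports the single-loop-per-block dialect with
  whitespace-delimited tokens (no quoted strings, no multi-loop blocks
  beyond optics+particles).
- The validator's additive-Gaussian, CTF-free image model makes the
  supervised-vs-naive comparison a demonstration of the alignment logic,
  not a prediction of attainable reconstruction quality on micrographs.
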