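# symcensus

Tools for resolving **asymmetric conformations of cyclic pseudo-symmetric
homo-oligomers** from single-particle cryo-EM metadata.

Homo-oligomeric complexes such as pentameric ligand-gated ion channels are
usually refined with their point-group symmetry imposed, which averages all
subunits together. Focused classification after symmetry expansion can assign
each subunit an individual conformational state (for example an inward *i* or
outward *o* position of a gating loop), but two obstacles remain before
asymmetric particles can be reconstructed:

1. **Anchor ambiguity.** After consensus refinement under C*n*, each particle's
   stored orientation is correct only up to an unknown symmetry operator, so
   the per-subunit labels of one particle are observed only up to cyclic
   rotation.
2. **Averaging washout.** Particles sharing the same arrangement of subunit
   states still sit in arbitrary symmetry-related frames; averaging them
   directly destroys exactly the asymmetric features one wants to see.

`symcensus` implements the metadata bookkeeping that solves both:

- **Symmetry expansion** of ZYZ Euler-angle particle tables under C*n*
  (operators act purely on the first Euler angle, `rot`, by +*k*·360/*n*).
- **Backtracking** of expanded records to their parent particles and readout
  of an ordered per-subunit label vector from focused-classification class
  numbers.
- **Necklace canonicalization**: the rotation-invariant identity of a
  particle is the lexicographically smallest cyclic rotation of its label
  string. For a pentamer with two states there are exactly 8 such
  configurations — `iiiii`, `iiiio`, `iiioo`, `iiooo`, `ioooo`, `ooooo`,
  `iioio`, `ioioo` — matching the Burnside count
  (1/*n*)·Σ<sub>d|n</sub> φ(d)·a<sup>n/d</sup>.
- **Configuration census**: counts, per-configuration frequencies and
  subunit-level state fractions over a particle set, with oligomers
  containing unresolved subunits excluded whole.
- **Supervised reorientation**: composing each particle's orientation with
  the cyclic operator given by its canonicalizing shift, so that all
  particles of one configuration share a reference frame and can be
  refined/reconstructed *without further alignment*.
- A fully ground-truthed **synthetic generator** (hidden configurations,
  random anchors, label noise) and a **toy 3D averaging validator** that
  measures, per subunit slot, whether the asymmetric feature survives
  averaging — so every stage is testable without any experimental data.

STAR particle tables in both the legacy single-block and the
optics+particles two-block dialect are read and written with column order
and unknown columns preserved.

## Worked example

Generate 1,000 synthetic pentamers with hidden configurations, random C5
anchors and perfect labels, then take the census:

```bash
$ symcensus simulate --n-particles 1000 --seed 42 --out-prefix scratch/wt
wrote scratch/wt.star (5000 records, 1000 parents) and scratch/wt_truth.tsv

$ symcensus census scratch/wt.star --class-map i=1,o=2
configuration   count   frequency
iiiii   246     0.246
iiiio   189     0.189
iiioo   147     0.147
ooooo   138     0.138
iiooo   103     0.103
ioooo   73      0.073
iioio   53      0.053
ioioo   51      0.051
# included parents: 1000
# excluded parents: 0
# subunit fraction i: 0.5934
# subunit fraction o: 0.4066
```

Every one of the 1,000 hidden configurations is recovered despite the random
symmetry anchors — cyclic rotation cannot change a necklace class. The
census reports each configuration's particle count and frequency plus the
overall fraction of subunits in each state.

The toy validator shows why reorientation matters. 20 noisy particles of the
singly-activated `iiiio` configuration are averaged twice — once in their
anchored (ambiguous) frames, once after supervised reorientation:

```bash
$ symcensus toyrecon --n-particles 20 --seed 2 --out-prefix scratch/demo
configuration iiiio
supervised separation: 0.928971
naive separation:      0.066612
max-contrast slot (supervised): 4 (o slots: (4,))
```

The *separation* is the outward-minus-inward density contrast of the
strongest subunit slot minus the mean of the remaining slots, measured on
the averaged volume. Supervised averaging recovers the single outward
subunit at its canonical slot (slot 4 of `iiiio`) with ~14× the separation
of naive averaging, which smears the feature over all five slots.

`symcensus reorient --class-map i=1,o=2 --out-dir configs/ input.star`
writes one refinement-ready STAR file per configuration, plus a summary
census.

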