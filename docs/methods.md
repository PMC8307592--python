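# Methods

## The belt as a hollow cylinder

The detergent corona around a solubilized membrane protein is modelled as a
hollow cylinder coaxial with the membrane normal. The choice is deliberate:
neutron diffraction and cryo-EM show a roughly toroidal time-average, while
molecular dynamics shows a fluid, locally deforming monolayer; any smooth
shape is an idealization, and the cylinder is the one whose three parameters
(h, r, R) follow from the inputs by closed forms. The model answers "how
much amphiphile, occupying how much space, at what distance from the axis"
— not where individual monomers sit.

Inputs are (i) a structure already positioned in an implicit bilayer
(z normal to the membrane, origin at the membrane centre; the convention of
the OPM database and PPM server) and (ii) an ordered list of
(amphiphile, monomer count) pairs.

### Height

`h = 2 × half-thickness`. The half-thickness is taken from the first REMARK
line matching either the PPM output dialect ("1/2 of bilayer thickness:")
or a generic "half-thickness" keyword, case-insensitively. If no REMARK
matches, the two planes of membrane dummy atoms (residue `DUM`) provide a
fallback: they sit at z = ±half-thickness, so max |z| over dummies is used.
A matching REMARK with a non-numeric or non-positive value is an error, not
a silent fallback — a corrupted header should not quietly change the belt.
An explicit `--thickness` override wins over both.

### Inner radius

1. **SASA.** Shrake–Rupley areas are computed for *all* protein heavy atoms
   (not just transmembrane ones), so burial by extramembranous domains is
   respected. Van der Waals radii are Bondi values (C 1.70, N 1.55, O 1.52,
   S 1.80, P 1.80 Å; 1.70 Å default for unlisted elements), probe 1.4 Å.
   Test points are a deterministic Fibonacci (golden-angle) lattice,
   default 960 points per sphere; neighbour candidates come from a k-d tree
   whose cutoff (twice the largest inflated radius) guarantees results
   identical to the all-pairs computation. At 960 points an isolated sphere
   is exact (no point is ever occluded) and partially buried atoms carry a
   lattice discretization error of a few percent — far below what the 3 Å²
   threshold below can feel.
2. **Transmembrane selection.** Heavy atoms with |z| ≤ half-thickness
   (atom-centre rule, boundary inclusive) and SASA strictly greater than
   3 Å² are kept. The strict inequality is intentional: 3.0 Å² is excluded.
3. **Radial density.** The kept atoms' distances to the z axis feed a
   Gaussian KDE (Silverman bandwidth by default, explicit bandwidth in Å
   accepted), evaluated on a 512-point uniform grid spanning
   [max(0, min − 3·bw), max + 3·bw]. If all distances coincide (spread
   < 1e-9 Å, as on noiseless synthetic shells) the profile is flagged as a
   point mass and peak extraction short-circuits to that value.
4. **Rightmost peak.** Among local maxima of the density whose height is at
   least 10% of the global maximum, the largest-radius one wins. The 10%
   guard (configurable) exists so that a handful of stray outermost atoms
   cannot drag the belt outward; with no qualifying maximum the global
   argmax is used with a warning.
5. **Offset.** `r = peak + 1.66 Å`, the average van der Waals radius of
   protein heavy atoms, so the inner wall touches atom surfaces rather than
   centres. A user-supplied inner radius replaces the computed value
   (`r_source = "override"`), with all downstream metrics recomputed and
   the total volume untouched — the intended workflow for grooved oligomers
   and large complexes that a cylinder fits poorly.

### Outer radius and mixtures

Total volume `V = Σ nᵢ·vᵢ` over the spec entries. The outer radius is the
unique solution of `V = π·h·(R² − r²)`:

    R = sqrt(V / (π·h) + r²)

Mixtures become stacked slabs tiling [−h/2, +h/2] bottom-up in input order,
slab i of height `h·Vᵢ/V`, so each slab's hollow-cylinder volume equals its
detergent's volume exactly and conservation holds per slab and in total
(relative error ≤ 1e-6 asserted in tests; the last slab edge is pinned to
+h/2 against accumulated rounding). Stacking is a bookkeeping device for
volumes, not a claim about where each detergent sits.

## Monomer volumes

Nominal monomer volumes in the shipped database are additive van der Waals
estimates: atomic increments (C 20.58, H 7.24, N 15.60, O 14.71, S 24.43,
P 24.87 Å³, plus halogens) minus 5.92 Å³ per bond, 14.7 Å³ per aromatic
ring and 3.8 Å³ per non-aromatic ring. Each entry's volume was computed
from its SMILES during curation and frozen into the TSV with
`volume_source = additive_estimate`; the database never needs a
cheminformatics backend at load time. The amphipol A8-35 entry uses an
average chain composition (13 acrylate, 9 octylamide, 15 isopropylamide
units, ≈ 4.3 kDa) since a statistical copolymer has no single SMILES.

The estimator is a scheme choice, not ground truth: grid- or
conformer-based volumes differ by several percent. Because `R` grows with
`√V`, a 5% volume bias moves the belt thickness by ~2.5% — visible but not
qualitative. Any volume can be replaced per run (`--volume ID=VALUE_A3`),
which is also the recommended route when a measured partial specific
volume is available.

Database format: TSV, one row per entry (id, full name, family, formula,
MW, CMC in mM at the cited condition — empty for amphipols and lipids,
which have no classical CMC — SMILES, monomer volume, volume source,
reference, pipe-separated aliases, RGB display colour). Lookup is
case-insensitive over id, then aliases, then full name; near-miss queries
get edit-distance-≤2 suggestions.

## Synthetic fixtures

Test structures are cylindrical shells of carbon pseudo-atoms: `n_rings`
circles of `atoms_per_ring` carbons at radius ρ, stacked over a z-span
inside the membrane slab, with optional Gaussian radial jitter (σ) and an
optional smaller decoy shell (emulating a grooved oligomer whose inner
surfaces also face solvent). Jitter is purely radial so the target density
stays one-dimensional; a 2.5 Å minimum-spacing rule guarantees every shell
atom stays well above the 3 Å² exposure cutoff. The default shell (5 × 36
atoms, ρ = 20 Å, half-thickness 15 Å, z-span 24 Å) is the reference
condition used throughout the tests and the acceptance script.

What the fixtures do *not* emulate: real side-chain packing, buried cores,
tilted helices, rough or elliptical cross-sections. Passing tests therefore
demonstrate that the geometry pipeline is correct and noise-robust, not
that a cylinder fits any particular protein well — for that judgement the
inner-radius override exists.

## Numerical choices

- KDE grid: 512 points; on the default fixture one grid step is ≈ 0.05 Å,
  which bounds the peak-location quantization.
- Degenerate (all-equal) radial distances short-circuit the KDE entirely.
- Slab membership is by atom centre and inclusive at |z| = half-thickness;
  the exposure cutoff is strict at 3 Å².
- Stack tiling pins the final edge to +h/2 exactly.
- All sampling randomness (fixture jitter, pseudo-atom shells) flows
  through explicit integer seeds; the belt computation itself is
  deterministic, and identical inputs produce byte-identical metrics JSON,
  viewer scripts and pseudo-atom PDB streams.
- SASA validation uses two independent oracles: closed forms (isolated
  sphere; two-sphere spherical cap; the two-occluder equatorial band of
  area 2πρd used to construct atoms with prescribed analytic SASA) and
  1e5-point Monte-Carlo surface sampling on random clusters. For the
  Monte-Carlo comparison the clusters use a 2.5 Å minimum separation
  (closest nonbonded heavy-atom approach) in a 9 Å box and the lattice is
  run at 1e4 points, keeping every per-atom area large enough that the 2%
  relative band is well-conditioned against the oracle's own sampling
  noise; the 960-point default is checked separately against the isolated
  sphere (exact) and for 960-vs-4000-point convergence (< 1%).

## Rendering

PyMOL has no hollow-cylinder primitive, so each slab is emitted as two
coaxial CGO cylinders: outer at R in the detergent's display colour,
semi-transparent; inner at r in neutral grey. The embedded python block is
valid Python (asserted by parsing in tests) and all numeric literals carry
the geometry to 3 decimals. The pseudo-atom writer samples each slab's
annulus uniformly (radius² uniform in [r², R²], angle and z uniform),
apportioning points to slabs by volume with largest-remainder rounding, and
emits neon HETATM records (residue `BLT`) so viewers draw unbonded spheres.

## Limitations

- The belt is a rigid, axially symmetric idealization; no torus, no local
  deformation, no per-monomer placement.
- Monomer volumes are estimator-based; absolute belt thickness inherits
  that bias (see above).
- Proteins that do not span the slab, or whose transmembrane atoms are all
  buried, correctly fail with a stage-labelled error rather than producing
  a meaningless radius.
- Only MODEL 1 of multi-model files is read; mmCIF is not supported; no
  membrane orientation is performed.
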