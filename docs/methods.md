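# Methods

This note records the models, conventions and numerical choices behind
`glucangel`, and what the synthetic generators do and do not emulate.

## Coordinate model and periodic geometry

All coordinates are stored in angstroms in orthorhombic periodic boxes;
GRO files (nm) are converted at I/O and triclinic cells are rejected
explicitly.  The topology is a per-atom sidecar table (TSV) carrying
element, atom role name, species (cellulose/callose/water), unit kind and
id (a *unit* is a nanofiber, a single chain, or a water molecule), chain id
within the unit, ring index along the chain, and donor/acceptor flags;
covalent O–H pairs are reconstructed from the role names on load.  The
minimum-image convention maps every displacement component into
(−L/2, L/2]; tests require exact agreement with a 27-image brute force.
Chain unwrapping walks ring centroids sequentially, adding the
minimum-image step between consecutive rings; a step reaching half the
shortest box side is refused as ambiguous.  Link analysis defaults to
minimum-image distances on wrapped coordinates; unwrapped coordinates are
available through `unwrap_chain` where continuity matters (end-to-end,
MSD).

## Sample construction

Chains are assembled from a schematic per-residue template: the six ring
atoms (C1–C5, O5) on a hexagon whose centroid is the ring position, the
hydroxyl oxygens O2/O3/O6 with hydrogens, the exocyclic C6, and the
glycosidic O4 half a repeat up the axis; finite chains are capped with
complementary −OH/−H (O1/HO1 and HO4).  The geometry is deliberately not
force-field grade: downstream analyses consume atom roles, ring indices
and distances.  The extended cellulose repeat is exactly 5.2 Å per ring,
so the ideal chain length is n_rings × 5.2 Å (47 rings → 24.4 nm) and
terminal ring centroids of an extended chain sit (n−1) × 5.2 Å apart.
Callose is built helically with a default rise of 3.0 Å/residue and 6
residues per turn (radius 4 Å), all configurable — only the helical
character is prescribed by the biology; the parameters are package
choices.

Nanofibers pack extended chains in cross-sections of 10 (rows 2,3,3,2),
18 (rows 2,3,4,4,3,2 — the 10-chain layout is its core) or 61 chains
(11 rows alternating 6/5, a four-faced block), with 8.2 Å spacing within
a row and 3.9 Å between rows; the 61-chain block then measures roughly
4.4 × 4.6 nm across including atom extents.

Hydrogel assembly follows the three-axis protocol: per axis direction a
group of nanofibers and single chains is aligned with that axis, each unit
gets a small random tilt (default ≤ 5°, uniform about two axes), a random
cross-sectional position, and a uniform random axial shift.  Clearance
(default 10 Å) is enforced between units sharing an axis direction, by
nearest-neighbour queries on the already-placed atoms; placement retries
up to 1000 times per unit and fails loudly.  Crossing-direction pairs are
deliberately exempt from the clearance constraint: with ~36 near-box-length
rods per direction in a 25 nm box, any two orthogonal rods pass within
roughly their transverse offset of one another, and keeping *all* pairs
1 nm apart would require far more transverse room than the box offers.
Those crossings are physical — they are where interchain links form.

The standard compositions place 4 fibers + 32 single cellulose chains per
direction (100:0); each callose substitution step converts one fiber and
8 cellulose singles of one direction into 18 callose chains (92:8, 84:16,
76:24; the x direction is substituted first by default, configurable).
Water is recorded in the composition report (the standard molecule counts)
but never given coordinates — solvation requires an MD engine, which is
out of scope.  The report prints both the recorded water count and the
polysaccharide weight fraction computed from residue masses; for the
standard counts the naive mass balance gives ≈ 16 wt %, above the nominal
10 wt %, and the report intentionally shows both without reconciling them.
The crystallinity degree is the fraction of cellulose chains grouped in
nanofibers: 120/216 = 56 % for the 100:0 sample.

Bundles place seven 18-chain fibers (one central, six on a ring of radius
42 Å) with nanometre interstices, periodic (uncapped) 16-ring chains along
the axis — the axial box length is exactly 16 × 5.2 Å — and callose chains
dropped at random interstitial positions.  End-to-end analysis refuses
bundle samples: periodic chains have no termini.

## Hydrogen bonds, contacts and links

Hydrogen bonds are geometric and strict: O–O distance < 3.2 Å *and*
O–H–O deviation from linearity < 40°, evaluated per covalent O–H donor
group against all oxygen acceptors under minimum image.  Tallies classify
bonds into eight exhaustive component-pair classes (cellulose–cellulose
intra/inter, callose–callose intra/inter, cellulose–callose,
cellulose–water, callose–water, water–water); *intra* means donor and
acceptor on the same chain.

Short contacts are heavy-atom pairs (< 3.6 Å, strict) on *different*
polysaccharide units; hydrogens are excluded because including them would
inflate contact counts well beyond the tens-per-crossing scale that makes
links meaningful, and intrafiber chain–chain pairs never count.  Contacts
of one unit pair merge into a link when their ring indices differ by at
most `ring_window` (default 2) on both sides, under transitive closure —
the clustering rule is our parameterisation of "one or a few consecutive
rings" and is exposed in the API.  Neighbour searches use periodic
KD-trees with cell edge equal to the cutoff; tests pin them to the O(N²)
brute force.  Network statistics (links per chain by species, fiber–fiber
link count, isolated units, connected components) are computed on the unit
multigraph via networkx.

## End-to-end statistics and diffusion

The end-to-end separation is measured between the first and last ring
*centroids* of an unwrapped chain (robust to template details and
consistent with the ring-level coarse-graining used for S(k)).  P(l) uses
the radial normalisation 4π Σ P(l) l² Δl = N_α, exact by construction at
the bin centres; the default bin width is 5 Å.  Freely-jointed-chain
samples (⟨l²⟩ = N b²) serve as the statistical oracle.

MSD is averaged over particles and all time origins; D = slope/6 from a
least-squares fit over a lag window defaulting to [20 %, 80 %] of the
maximum lag, avoiding the poorly-averaged long-lag tail (and any ballistic
regime in data that has one).  Diffusion constants are reported in the
unit system of the input trajectory; planted-truth random walks use
internal units throughout.

## Structure factors

S(k) = ⟨|ρ(k)|²⟩/N is evaluated on the exact reciprocal lattice of the
box (half space, k = 0 excluded), spherically binned with default bin
width 2π/min(L).  Shells holding more than 2000 vectors are uniformly
subsampled — exactness at low k, where the interesting mesoscopic peak
lives, tractability at high k.  Particles are points (water oxygens or
pyranose-ring centroids, cellulose and callose pooled); no atomic form
factors.  Peak position is refined parabolically over three bins, the
FWHM by linear interpolation of the half-height crossings measured above
zero (a constant background can be supplied); the correlation length
convention is ξ = 2π/Δk and the real-space spacing d = 2π/k₀.  For Bragg
conditions the unbinned per-vector S(k) is exposed separately, since
spherical bins dilute a resonant vector among its shell.

## Elasticity

Bulk modulus: B = k_BT⟨V⟩/Var(V) with variance over the series and a
drift check (first/second half means differing by more than half a
standard deviation flag the estimate).  Strain route: diagonal strains
ε_ii = (L_i − ⟨L_i⟩)/⟨L_i⟩; compliance covariances
⟨ε_iε_j⟩ = k_BT S_ij/V₀ are symmetry-averaged over the equivalent cubic
index pairs, then inverted:
C₁₁ = (S₁₁+S₁₂)/[(S₁₁−S₁₂)(S₁₁+2S₁₂)], C₁₂ = −S₁₂/[same], and
Y = (C₁₁−C₁₂)(C₁₁+2C₁₂)/(C₁₁+C₁₂), identically 1/S₁₁ (unit-tested to
1e-10 on noiseless compliances).  S₁₁ = S₁₂ raises a "vanishing shear
response" error.  All fluctuation standard errors use block averaging
with 10 blocks.  Temperature defaults to 300 K.

Finite deformation: a Padé [1/1] fit f(σ) = aσ/(1 + cσ) (weighted when
standard errors are given) is differentiated analytically,
Y(σ) = (1 + cσ)²/a.  A least-squares Padé cannot place its pole strictly
inside positive data, so divergence "within the sampled range" manifests
as a pole at or just beyond the largest stress; the breakdown flag fires
when the pole lies within 20 % beyond the data range.  The order [1/1] is
a package default; higher orders were not needed for the planted curves.

With the planted constants C₁₁ = 1.9966 GPa and C₁₂ = 1.9417 GPa the
cubic algebra gives (C₁₁+2C₁₂)/3 = 1.960 GPa and Y = 82.0 MPa; the
planted stress–strain constants a = 0.014381 MPa⁻¹, b = 0.50677 MPa⁻¹
give Y(0.3 MPa) = 50 MPa and Y(1.5 MPa) = 4 MPa analytically.  A unit
audit: at V₀ = (25 nm)³ and 300 K, GPa-scale constants correspond to
strain variances of order 10⁻⁶, which the generator reproduces.

## XRD crystallinity

Diffractograms on a 2θ ∈ [10°, 40°] grid at 0.10° steps are fitted as a
sum of Gaussian peaks (pseudo-Voigt optional) on a linear background.
The default cellulose template holds three crystalline reflections near
14.9°, 16.5° and 22.5° plus one broad amorphous hump near 21.5°; an
optional (1,3)-β-glucan peak near 12° serves callose-rich samples.
Centers are constrained to ±1.5° of the template; crystalline FWHMs are
capped at 3° while the amorphous width floats, encoding the assumption
that amorphous content drives peak broadening.  CrI = 100 × crystalline
area / total area, invariant under intensity rescaling.

## Synthetic data: what it does and does not show

Every generator is seed-deterministic and ships a report with its planted
parameters and the ground truth the analysis should recover:

* Hydrogel boxes at configurable scale (1 = the full 12-fiber/96-chain
  protocol), plus a short pseudo-dynamics trajectory (per-atom Gaussian
  jitter, default σ = 0.3 Å/frame, plus slow per-chain drift).  This
  provides frames with known composition and bookkeeping — it makes no
  claim of emulating molecular dynamics.
* Crossing fixtures: chains numerically tuned to skim nanofibers at a
  target heavy-atom distance (default 3.0 Å), giving an exactly known
  link network (one link per chain–fiber pair, no fiber–fiber links).
* Gaussian volume/strain fluctuations of a cubic elastic medium at 300 K
  with planted B or (C₁₁, C₁₂).
* Random walks with planted D (per-step variance 2DΔt per dimension).
* Point configurations (uniform/ideal gas, simple cubic lattice, Gaussian
  clusters) with known S(k) features.
* Diffractograms with a planted crystalline/total area ratio and
  multiplicative noise.
* H-bond fixtures: isolated O–H···O triples either satisfying both
  criteria or violating exactly one, placed away from the strict-inequality
  boundaries.

Passing tests therefore demonstrate that the *estimators* are correct and
unbiased under their stated statistical models — they do not show that
real hydrogel trajectories satisfy those models.  In particular the
pseudo-dynamics has no thermodynamics, the built geometries have no
energetics, and observables that require hundreds of nanoseconds of
1.6M-atom dynamics (equilibrium H-bond tallies, equilibrium link counts,
relaxed end-to-end averages) are validated only structurally, by oracle
equivalence and conservation identities.

## Problem sizes and numerical tolerances

Fluctuation estimators are exercised at n = 10⁵ samples (recovery within
2 % for B, 5 % for Y), diffusion at 10³ particles × 10³ steps (3 %),
Padé recovery on 15 points with 2 % multiplicative noise (10 %),
crystallinity with 1 % noise (±2 points), FJC statistics at 10⁴ chains
(2 %).  These sizes make the whole validation suite runnable on one CPU
in about two minutes while keeping Monte-Carlo error comfortably inside
each tolerance.

## Known limitations

* No MD engine, force field, solvation or energy minimisation; built
  configurations are starting geometries and statistical fixtures only.
* Orthorhombic boxes only; no velocities; no compressed trajectory
  formats.
* The contact/link clustering window and the helical callose parameters
  are package conventions, exposed in the API, not measured properties.
* H-bond lifetime analysis, persistence lengths, cross partial structure
  factors and frequency-dependent viscoelasticity are out of scope.
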