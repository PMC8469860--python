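# Methods

## The system and what the model is for

Gelatin hydrogels doped with polyvinyl alcohol (PVA) change their
porosity, sorption behavior and mechanical resistance as the PVA
fraction increases. The package characterizes those changes on two
levels: exact data reductions of laboratory measurements (weights,
load–displacement curves, micrographs) and a deliberately small
molecular model whose purpose is *directional* insight — how free
volume, hydrogen-bonding site density and stiffness move with
composition — not absolute property prediction.

## Molecular representation

Gelatin is modelled as three identical 15-residue fibers
(H₂N-Pro-Gly-Hyp-Hyp-Gly-Hyp-Pro-Gly-Glu-Gln-Gly-Pro-Ala-Gly-Lys-COOH),
a simplified sequence that conserves collagen-like composition
(glycine-rich, proline/hydroxyproline-heavy) while staying desk-sized.
The three fibers are grown independently and carry no inter-fiber
bonds; their mutual arrangement is left to packing and annealing
rather than imposed as a triple helix. PVA chains are linear runs of
–CH₂–CH(OH)– units, 20 units per chain by default: the degree of
polymerization is a free parameter of the model and 20 is small enough
for desk-scale cells while long enough to behave polymerically.

Atoms are united-atom heavy sites — aliphatic hydrogens are folded
into their carbon's mass — except that every polar hydrogen on N or O
is explicit, because donor counting needs it. Partial charges are a
coarse template set (amide, carboxyl, hydroxyl, amine groups sum to
zero per residue); after assembly each cell's tiny residual net charge
is removed by subtracting the mean, since shifted-force cutoff
electrostatics assume neutral systems.

Blend compositions are specified as PVA **mass** percent (the percent
convention is recorded in every manifest; a monomer-count convention
would differ). Integer chain counts quantize the achievable percent;
compositions validate that the achieved value is within 2.5 points of
the target. The modelled contents 0/40/62/70 % are realized as
0/3/8/11 twenty-unit chains against one gelatin molecule
(38.8/62.8/69.9 % achieved).

## Force field and engine

The potential is class-I: harmonic bonds (k = 300 kcal/mol/Å² between
heavy atoms, 250 for X–H, equilibrium lengths from the templates),
harmonic angles (k = 60 kcal/mol/rad², θ₀ = 120° at carbonyl carbons
and 109.47° elsewhere), threefold cosine dihedrals
(k = 0.25 kcal/mol), Lennard-Jones per element (C: 0.10/3.8, N:
0.17/3.3, O: 0.17/3.1, polar H: 0.01/1.0 kcal/mol / Å;
Lorentz–Berthelot mixing, potential-shifted at the cutoff) and
shifted-force Coulomb, both truncated at a global 7 Å cutoff under the
minimum-image convention. The magnitudes are a generic organic set
chosen for realistic cohesion and stiffness *trends*; no attempt is
made to reproduce any published force field's absolute values, and the
engine refuses cells narrower than twice the cutoff.

Forces are the exact analytic negative gradient of the implemented
energy (verified against central differences to ~1e-10 relative), and
the position-space virial matches energy–strain finite differences to
~1e-9 relative on relaxed structures. Internal units are
Å/fs/amu/kcal·mol⁻¹; the only conversions to GPa, bar and g/cm³ live
in `constants.py`.

Dynamics is velocity Verlet at 1 fs (default). NVT uses a single
Nosé–Hoover friction variable (τ_T = 50 fs); NPT adds an isotropic
weak-coupling volume rescale toward the target pressure with a
water-like compressibility and τ_P = 50 fs, capped at 0.5 % box change
per step. The coupling times are deliberately tight: desk-scale
anneals last ~1 ps, and looser couplings would leave temperature and
volume unrelaxed within a stage. A temperature above 10× target
aborts with the offending step and stage named.

Minimization is L-BFGS on the flattened coordinates with a total
iteration budget. On rugged amorphous landscapes the requested force
tolerance is often unreachable in that budget; `strict=True` raises in
that case, while pipeline calls use `strict=False` and record the
achieved maximum force in the cell's metadata.

## Packing and equilibration

Cells are grown unit by unit as a self-avoiding random walk: each
residue/monomer is placed by sampling up to 25 random torsion
orientations, rejecting any with a non-bonded heavy-atom contact below
1 Å and keeping the best candidate (a placement worse than 0.35 Å
aborts as a packing failure). `pack_amorphous_cell` defaults to a
0.5 g/cm³ growth density; the trend workflow grows at 0.8 g/cm³
because its strongly scaled-down anneals leave the barostat too little
time to densify from 0.5, and starting near the expected amorphous
density lets the NPT stages relax volume in either direction instead.

The equilibration protocol heats to 600 K in NPT, holds 300 ps, cools
in 50 K steps (50 ps holds) to 298 K, then holds 500 ps NPT and 500 ps
NVT — with every duration multiplied by a `scale` factor. Production
runs here use scale = 5e-4 (≈0.8 ps, ~825 steps), which is the
package's chosen desk-scale problem size; the stage *sequence* is
always executed in full and logged. After the protocol the cell is
re-minimized before static properties are measured.

## Observables

**Stiffness (static method).** Six Voigt strain modes ±0.003 are
applied as affine maps of cell and coordinates; each strained cell is
re-minimized and its virial stress read; column j of C is the central
difference of the Voigt stress over 2ε, converted to GPa. C is
symmetrized before extracting λ (mean of the six off-diagonal normal
couplings) and μ (mean shear diagonal); E = μ(3λ+2μ)/(λ+μ) and
K = λ+2μ/3 (the standard isotropic relation, adopted because the
tensor-to-modulus step needs one). On a periodic harmonic simple-cubic
lattice the method reproduces the closed-form C₁₁ = k/a exactly; on
~350–1200-atom amorphous cells the entries are noisy at the
±0.5–1 GPa level, which is why trend statements average three seeds.

**Energy density** is the frame average of E_i/V_i per term (bonded,
van der Waals, electrostatic), taken over the last quarter of the
protocol's frames.

**Interaction decomposition** sums the engine's own pairwise
nonbonded energies (same cutoff, same shifts) over species pairs;
gelatin–gelatin + gelatin–PVA + PVA–PVA equals the total nonbonded
energy exactly, and the cross term is identically zero without PVA.

**FFV** overlays a grid (0.5–0.6 Å spacing); a point is occupied when
within r_vdW + probe of any atom under minimum image, with Bondi
radii. The default probe is 0 Å (geometric free volume); 1.3 Å
approximates a water-sized probe. Halving the grid spacing moves FFV
by well under 1 % on fixture systems.

**Donor–acceptor density**: donors are O/N heavy atoms bearing at
least one H; acceptors are all O and N; the reported count is
donors + acceptors, so each PVA hydroxyl contributes two sites. The
chemical rule is a convention — the counted quantity is a site
density, not a hydrogen-bond count.

**Model pores**: free grid points are grouped into periodically
connected 6-neighbor components; a component's diameter is twice its
maximum distance-to-occupied (periodic Euclidean distance transform,
computed on a 3×3×3 tiling) plus the probe diameter. An atom-free cell
reports one box-spanning pore.

## Experimental track

The sorption formulas are exact arithmetic on the four masses;
replicate statistics use the sample (n−1) standard deviation — the
convention under which the pure-gelatin failure-strength row
reproduces its printed sd exactly, while the printed sd of the two
blend rows is ambiguous at printed precision and is not used as an
exact target. Tangent moduli differentiate a cubic smoothing spline
(penalty by generalized cross-validation unless given) fitted to the
pre-failure curve; strains at or past failure are reported as NaN
rather than extrapolated. The failure point is the running-maximum
sample preceding the first post-peak drop exceeding 20 % of the
running maximum — scale-invariant in stress, so curves in different
units fail at the same strain.

Pore histograms binarize with Otsu's threshold (manual override
available; the laboratory procedure is interactive). The second,
darker pass that recovers pores nested inside larger pores only fires
when the pore-interior intensity is genuinely bimodal (mode separation
above three within-class standard deviations); otherwise unimodal
noise would be split and pores double-counted. Pore size is the
equivalent circular diameter 2√(A/π) — a definition choice; Feret or
inscribed-circle diameters would bin borderline pores differently.
Default bins 0–0.5/0.5–1/1–5/>5 µm; the default pixel size assumes a
20 µm field of view.

## Synthetic data: what it emulates, what it does not

`gen_sem_image` draws non-overlapping dark disks (lognormal diameters,
median 0.3 µm, σ_log 0.6 — right-skewed with most pores below 0.5 µm,
as dried-gel micrographs show) on a bright background, optionally with
one darker disk nested inside larger pores, plus Gaussian noise. The
truth records the *realized* pixel-area diameters of the drawn disks,
which is exactly what a perfect analysis of that image returns. Real
micrographs have irregular pore shapes, uneven illumination and
texture — none of which is emulated, so exact recovery here validates
the measurement chain, not robustness to real SEM artifacts.

`gen_stress_strain` uses σ(ε) = a(e^{bε}−1) (a = 0.024 MPa, b = 5 —
convex and of hydrogel magnitude) truncated by a three-point collapse
at a failure strain drawn uniformly from [0.55, 0.70], the window in
which such hydrogel cylinders fail. The exponential is a fixture
shape, not a constitutive claim.

`gen_weight_records` inverts the sorption formulas into consistent
weight quadruples. The three sorption percentages obey one identity,
(1+SD/100) = (1+WA/100)(1−HD/100), so the generator takes the water
content plus any two of SD/WA/HD and derives the third (supplying all
three inconsistently is an error). Replicates get independent
multiplicative Gaussian noise on each weight, 2.5 % relative by
default — chosen so triplicate swelling-degree scatter lands in the
±2.1–5.3 % relative band typical of these assays.

`gen_toy_lattice` is the elasticity oracle: nearest-neighbor harmonic
springs at natural length a on a periodic simple-cubic lattice give
C₁₁ = C₂₂ = C₃₃ = k/a and all other entries zero, in closed form.

## Trend study and what passing means

The composition trend study builds cells at 0/18/40/62/70 % PVA
(three seeds each), anneals at scale 5e-4 and measures all
observables. At these conditions, seed-averaged donor–acceptor density
rises monotonically from 0 to 40 % PVA, FFV falls over the same range,
and Young's modulus has an interior maximum over the composition range
— the directions expected when low-molecular-weight PVA fills
inter-fiber voids (adding nonbonded stiffness and OH sites) before
dilution of the bonded network takes over. In this implementation the
modulus maximum sits at 62 % rather than 40 %; with ~600-atom cells
and ±0.5 GPa stiffness noise the position of the maximum is not
resolved, only its interiority.

Passing these tests shows the pipeline reproduces the *directional*
composition physics under the model's assumptions. It does not show
quantitative agreement with experiments: the cells are ~10³ atoms,
anneals are ~1 ps, there is no solvent water, no borate or enzymatic
cross-linking chemistry, and the force field is generic — absolute
moduli (GPa-scale here versus MPa-scale for wet gels, which are
mostly water), densities (~0.82 g/cm³ final) and energy magnitudes are
force-field- and size-limited and are reported as trend quantities
only.

## Numerical choices and degenerate inputs

- Minimum image via fractional-coordinate rounding; orthorhombic
  cells take a fast diagonal path, sheared cells (during stiffness
  evaluation) the general 3×3 path.
- Neighbor lists: KDTree pair search with a 2 Å skin,
  displacement-triggered rebuilds; brute-force fallback for
  non-orthorhombic cells.
- Angle forces clamp sin θ at 1e-8 and dihedrals clamp |n|² at 1e-12;
  degenerate (collinear) bonded geometry occurs transiently in raw
  grown chains and is removed by the first minimization.
- Blank or all-white micrographs return an empty histogram with a
  warning rather than an error; zero-length or single replicate lists
  are data errors.
- Ties in failure detection: the failure sample is the *first*
  running-maximum index before the detected drop.

## Known limitations

- No explicit water, no cross-link chemistry, no Ewald electrostatics,
  no constraint algorithms; 1 fs steps with soft X–H springs instead.
- One gelatin molecule per cell: composition resolution is quantized
  by whole PVA chains, and self-interactions through the periodic
  boundary are non-negligible at this size.
- The Nosé–Hoover single-variable thermostat oscillates visibly over
  sub-picosecond stages; temperature statements are stage averages.
- Pore diameters from coarse grids are resolution-limited to about one
  grid spacing.
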