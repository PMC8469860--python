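# gelblend

Desk-scale characterization of gelatin/polyvinyl-alcohol (PVA) hydrogel
blends, for materials scientists and bioprocess engineers who tune
hydrogel carriers (e.g. for enzyme immobilization) by varying the PVA
content.

Gelatin hydrogels doped with PVA change in porosity, sorption and
mechanical strength as the PVA fraction grows. `gelblend` implements
both halves of that characterization:

**Experimental track** — the standard laboratory data reductions:

- gravimetric sorption formulas on the four sample masses
  (W_initial,wet, W_initial,dry, W_swollen,wet, W_swollen,dry):

  - water content (%) = 100 · (W_iw − W_id) / W_iw
  - swelling degree SD (%) = 100 · (W_sw − W_id) / W_id
  - water absorption WA (%) = 100 · (W_sw − W_sd) / W_sd
  - hydrolytic degradation HD (%) = 100 · (W_id − W_sd) / W_id

- compression curves: σ = load/area, ε = displacement/height, tangent
  modulus dσ/dε at chosen strains (smoothing spline), failure point at
  the first >20 % post-peak stress drop, replicate mean ± sample sd;
- SEM-style micrographs: Otsu binarization (with a second, darker pass
  for pores nested inside larger pores), 8-connected labeling,
  equivalent circular diameter d = 2√(A/π), histograms over the
  0–0.5/0.5–1/1–5 µm size classes, aggregated over image series.

**Molecular track** — a self-contained periodic molecular-mechanics
model of the blend:

- amorphous cells built from a simplified gelatin model (three
  identical fibers, H₂N-Pro-Gly-Hyp-Hyp-Gly-Hyp-Pro-Gly-Glu-Gln-Gly-
  Pro-Ala-Gly-Lys-COOH) and linear –CH₂–CH(OH)– PVA chains, grown as
  self-avoiding random walks with Monte Carlo torsion selection;
- a class-I force field (harmonic bonds/angles, cosine dihedrals,
  Lennard-Jones, shifted-force Coulomb), L-BFGS minimization, velocity
  Verlet NVE/NVT/NPT dynamics (Nosé–Hoover thermostat, weak-coupling
  barostat), and the heat-to-600 K / cool-in-50 K-steps / NPT+NVT
  equilibration protocol;
- observables: the static-method stiffness matrix C (6 Voigt strain
  modes, ±0.003, virial stress by central differences), Lamé
  coefficients λ = (C₁₂+C₁₃+C₂₁+C₂₃+C₃₁+C₃₂)/6 and
  μ = (C₄₄+C₅₅+C₆₆)/3, Young's modulus E = μ(3λ+2μ)/(λ+μ), bulk
  modulus K = λ+2μ/3, per-frame energy density E_d = ⟨E_i/V_i⟩,
  gelatin–gelatin / gelatin–PVA interaction decomposition, fractional
  free volume (FFV), hydrogen-bond donor–acceptor density, and a
  grid-based pore-size distribution of the model cell.

A synthetic-data module generates every fixture with known ground
truth: SEM-like pore images, nonlinear compression curves with a
planted failure point, weight records inverted from target sorption
percentages, and a harmonic simple-cubic lattice whose stiffness matrix
is known in closed form (the oracle for the static method).

## Worked example

```python
>>> from gelblend import WeightRecord, water_content, replicate_stats
>>> water_content(WeightRecord(initial_wet=15.022, initial_dry=1.609))
89.2890427373186
>>> replicate_stats([0.629, 0.763, 0.604, 0.594, 0.440])
(0.606, 0.11498043311798752)
```

The first number is the water content (%) of a pure-gelatin hydrogel
from its wet and dry weights — 89.3 % of the sample mass is water. The
second pair is the mean and sample standard deviation of five
compressive failure strengths (MPa): the gel fails at 0.61 ± 0.11 MPa.

On the molecular side:

```python
>>> from gelblend import stiffness_static, lame_from_stiffness, young_modulus
>>> from gelblend.synth import gen_toy_lattice, lattice_forcefield
>>> system, truth = gen_toy_lattice(lattice_constant=2.0, spring_constant=10.0)
>>> C = stiffness_static(system, lattice_forcefield(2.0))
>>> float(C.C[0, 0])
34.73847422799215
```

The static method recovers the analytic stiffness k/a = 34.74 GPa of
the harmonic lattice exactly (all off-diagonal entries are zero for
nearest-neighbor springs).

The full blend study — pack, anneal, measure across PVA contents —
runs from the CLI:

```sh
gelblend build --pva-percent 40 --seed 0 --out cell40
gelblend equilibrate --system cell40/system.json --scale 1e-3 --out eq40
gelblend props --system eq40/system.json --out props40.json
gelblend synth --what sem --nesting-fraction 0.3 --out fixtures
gelblend expanalyze --images fixtures/sem.png --out analysis
```

## Layout

- `src/gelblend/templates.py`, `builder.py` — monomer templates, chain
  growth, blend compositions, amorphous packing
- `src/gelblend/forcefield.py`, `engine.py` — potentials, forces,
  virial, minimization, dynamics, equilibration protocol
- `src/gelblend/elasticity.py`, `observables.py` — stiffness/moduli,
  energy density, interactions, FFV, donor–acceptor, model pores
- `src/gelblend/sorption.py`, `mechanics.py`, `porosimetry.py` — the
  experimental track
- `src/gelblend/synth.py` — synthetic-data generators with truths
- `src/gelblend/workflows.py` — the composition trend study
- `src/gelblend/io.py`, `cli.py` — formats and the `gelblend` CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
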