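# nanoqnar

Atomistic nanodescriptors and kNN read-across modelling of metal-oxide
nanoparticle cytotoxicity.

Metal-oxide nanoparticles (MeₓOᵧ NPs) are screened for hazard with cell
viability assays (ATP, LDH), but wet-lab coverage of the size × dose ×
material space is sparse. Quantitative nanostructure–activity relationship
(QNAR) models fill the gaps by predicting % cell viability from descriptors
of the particle. `nanoqnar` implements that workflow end to end for
computational chemists and nano-safety modellers:

1. **Particle construction** (`crystal_builder`) — replicate a bulk crystal
   unit cell (CIF) into a supercell, carve a sphere of the requested radius,
   remove outermost ions of the over-represented sign until electroneutral,
   and relax with Polak–Ribière conjugate-gradient minimization.
2. **Energetics** (`forcefield`) — Buckingham pair potentials
   `A·exp(−r/ρ) − C/r⁶` plus Coulomb interactions under the damped,
   energy-shifted Wolf summation, with analytic forces. The Wolf parameters
   (α, cutoff) are calibrated so a 2×2×2-cell cluster reproduces the
   infinite-crystal electrostatic energy (Ewald reference).
3. **Nanodescriptors** (`nanodescriptors`) — partition the particle into a
   1 nm surface *shell* and interior *core* and emit 62 descriptors over the
   {all, metal, oxygen} × {whole, core, shell} grid: composition (9),
   potential energy (9), topology/coordination (9), lattice energy (5),
   size (3) and force vectors (27). The coordination cutoff is
   `R = 1.2(R_M + R_O)` from the ionic radii; the surface-normal force
   component of an atom at distance d from the center of mass is
   `V = (x·f_x + y·f_y + z·f_z)/d`.
4. **Read-across model** (`qnar_pipeline`) — redundancy filter (drop a
   descriptor when ≥ 20 % of its values equal an earlier one), z-score
   normalization with train-set statistics, 70/30 split, correlation-based
   feature-subset selection (CFS merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` under
   forward best-first search), and a k-nearest-neighbours regressor whose
   distance is Euclidean on numeric features with a 0/1 term per nominal
   feature (e.g. assay type).
5. **Validation** (`validation`) — Tropsha external-validation statistics
   (R²_cvext, through-origin R₀², slopes k and k′ with their acceptance
   thresholds), Y-randomization, and the applicability domain
   `APD = ⟨d⟩ + Z·σ` (Z = 0.5) over training-set distances.
6. **Batch prediction** (`service_io`) — the published JSON request/response
   schema (`id, coreSize, hydroSize, ecEv, assay, exposureDose, des306,
   des606` in; normalized inputs, 4 nearest neighbours, distances, kNN
   prediction and APD flag out).

Everything is testable offline: `fixtures` generates toy rock-salt oxides,
synthetic force fields and planted-signal modelling tables.

## Worked example

Build a relaxed MgO-like particle and train a model on a synthetic table:

```sh
$ nanoqnar fixtures --make rocksalt --out mgo.cif
$ nanoqnar fixtures --make forcefield --out toy.ff
$ nanoqnar build --cif mgo.cif --radius 8 --ff toy.ff --out mgo_particle.xyz
wrote 208 atoms to mgo_particle.xyz
```

The XYZ comment line records the relaxed total energy (−3584.49 eV for the
208-atom particle): 8 Å of rock-salt MgO at a = 4.2 Å contains 208 ions after
carving and neutralization.

```sh
$ nanoqnar fixtures --make table --out table.csv --seed 3
$ nanoqnar train --table table.csv --schema table.schema.json --seed 1 --out model.json
selected features: ['f00', 'f01', 'f02']
test R2=0.899 R2_cvext=0.873 k=1.163 k'=0.765 passes_all=False
APD threshold: 1.7927
```

The synthetic table plants a linear signal on features f00–f02; best-first
CFS recovers exactly those three. The test-set R² of 0.899 and R²_cvext of
0.873 clear their acceptance thresholds (0.6 and 0.5), while the
through-origin slope k = 1.163 narrowly misses the 0.85–1.15 band on this
small noisy table, so the model is flagged `passes_all=False` — the
validation suite doing its job.

Batch predictions use the published tuple schema:

```sh
$ nanoqnar predict --model model.json --in requests.json
```

where `requests.json` holds tuples such as
`{"id": "CuO", "coreSize": 25, "hydroSize": 45, "ecEv": -5.17,
"assay": "ATP", "exposureDose": 3.2, "des306": 3.579, "des606": -0.243}`.
Each response record reports the normalized inputs, the four nearest
training neighbours and distances, `knnprediction` (normalized endpoint
scale), `viabilityPercent` (denormalized) and the APD reliability flag.

As a library:

```python
from nanoqnar.fixtures import toy_materials, material_descriptor_block
block = material_descriptor_block(toy_materials(24, seed=0))  # 24 x 62
```

## Scope notes

Hydrodynamic size, band energies (E_V, E_C, E_g), electronegativities and
formation enthalpies are *inputs* taken from experimental tables or external
property libraries — the package never computes them. Real force-field
parameters for specific oxides must be supplied by the user via the
plain-text force-field format; the shipped parameters are synthetic toys
for testing.
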