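# Methods

This note records the models implemented in `nanoqnar`, the choices made
where the procedure was genuinely open, and what the synthetic test
conditions do and do not demonstrate.

## Particle construction

A bulk unit cell (lattice vectors, fractional coordinates, integer formal
charges summing to zero) is tiled `n×n×n`, a sphere of radius R is carved
about the supercell's geometric center (configurable to a lattice site —
the center choice changes the surface termination, and nothing in the
workflow pins it down), and electroneutrality is restored by deleting ions
of the over-represented charge sign, outermost first. Ties are broken
deterministically: larger distance from the carve center, then species
symbol, then input order. Removal is greedy on integer charges; if no
sequence of single-ion removals reaches exactly zero (e.g. a +3 imbalance
in a ±2 lattice) the operation fails rather than approximating.

The particle is treated as an isolated cluster with open boundaries. For
strictly pairwise potentials this is identical to the common
molecular-statics setup of a periodic box padded far beyond every cutoff,
so no periodic code path exists.

### Energy model

* Short range: Buckingham `A·exp(−r/ρ) − C/r⁶`, truncated (not shifted) at
  a per-pair cutoff, exactly as specified by its contract; the resulting
  energy discontinuity at the cutoff is the user's responsibility when
  choosing cutoffs (the toy sets place cutoffs beyond all relevant pairs).
* Electrostatics: damped, energy-shifted Wolf summation with self term,

  `E = k_e Σ_{i<j, r<R_c} q_i q_j [erfc(αr)/r − erfc(αR_c)/R_c]
     − k_e (erfc(αR_c)/2R_c + α/√π) Σ_i q_i²`,

  with `k_e = 14.399645 eV·Å/e²`. Forces are the exact analytic gradient of
  the implemented energy (so Newton's third law and zero net force hold to
  machine precision); the small force discontinuity at `R_c` inherent to
  the energy-shifted variant is accepted.
* Per-atom energies: each pair term is split 50/50 between its partners and
  each atom owns its self term, so per-atom energies sum to the total
  exactly. This attribution is needed for the core/shell energy
  descriptors and is a convention, not physics.

### Wolf calibration

α and `R_c` are chosen on a grid so that the Wolf energy of a free-standing
2×2×2-cell cluster, per cell, best matches the infinite-crystal
electrostatic energy per cell. The reference is a classic Ewald sum
(η = 3.5/r_cut, reciprocal cutoff 8η), verified to 10⁻⁶ relative against
the analytic rock-salt Madelung energy. On the rock-salt toy cell the
crossing sits near α ≈ 0.63 Å⁻¹, so the default α grid spans
0.10–0.80 Å⁻¹ (step 0.01) with cutoffs 6–14 Å (step 2; the cluster is
smaller than every cutoff, so the dependence on `R_c` is weak). The
calibrated residual on the toy cell is ≈ 0.3 %; calibration fails loudly
above 1 %.

### Minimization

Polak–Ribière (PR+) conjugate gradients with Armijo backtracking
(c₁ = 10⁻⁴), steepest-descent restart whenever the search direction is not
a descent direction. Stopping: relative energy change < 10⁻⁸ per accepted
step, or maximum force component < 10⁻⁴ eV/Å, or 10⁵ iterations. A
trust-radius-style cap limits any atom's displacement to 0.1 Å per line
search — without it a long trial step can carry a surface ion over the
finite Buckingham barrier into the Coulomb singularity ("ion fusion");
fusion (separation < 0.3 Å) or a non-finite energy aborts with a
diagnostic rather than returning garbage.

## Nanodescriptors

Atoms within 1 nm (default) of the nominal surface — i.e. at distance
≥ R − 10 Å from the carve center — form the shell; the rest the core. A
particle smaller than the shell depth is all shell (warned, not an error).
The 62 descriptors are scalar statistics over the 3×3 grid of scopes
{all, metal, oxygen} × regions {whole, core, shell}:

| category          | n  | definition |
|-------------------|----|------------|
| composition       | 9  | atom counts per cell |
| potential energy  | 9  | mean per-atom energy (eV) |
| topology          | 9  | mean coordination number |
| lattice energy    | 5  | total E, E/atom, core total, shell total, shell/total ratio |
| size              | 3  | diameter 2R, volume 4πR³/3, area 4πR² from the nominal radius |
| force vectors     | 27 | mean radial V, mean tangential magnitude, mean total magnitude per cell |

The coordination cutoff is the single global radius `R = 1.2(R_M + R_O)`
from the ionic radii (supplied per species; particles with more than one
metal species are rejected since the cutoff is defined for a single
oxide). The radial force component uses coordinates relative to the
particle's mass-weighted center of mass, with outward positive. A
statistic over an empty scope×region cell is reported as 0 with a log
message so that tiny particles remain processable; downstream consumers
should treat those zeros together with the corresponding count columns.
The service aliases `des306` and `des606` map to `cn_mean_me_shell` and
`fnormal_mean_me_shell` respectively.

## Read-across pipeline

* **Redundancy filter**: scanning numeric columns in order, a later column
  is dropped when ≥ 20 % of its rows equal an earlier retained column
  (within 10⁻¹²); zero-variance columns are dropped too.
* **Normalization**: z-scores with training-set mean and *population*
  standard deviation; the endpoint is z-scored alongside the descriptors
  (predictions are therefore on the normalized endpoint scale and are
  denormalized for reporting). The divide-by-n convention is documented
  because it is absorbed entirely by the train-only fit.
* **Split**: uniform random 70/30, `|train| = round(0.7 n)`, seeded.
* **Feature selection**: CFS merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` with
  Pearson correlations (nominal features 0/1-encoded, constant features
  contribute correlation 0), maximized by forward best-first search that
  stops after 5 consecutive non-improving expansions. Entropy-based
  discretization used by some CFS implementations is deliberately not
  replicated: the endpoint is continuous.
* **kNN**: squared distance = Σ numeric (Δz)² + Σ nominal mismatch
  indicators; prediction is the unweighted mean endpoint of the
  `n_neighbors` nearest training rows (default 3 — the neighbour count is
  defined literally, and the 4 nearest neighbours are always reported for
  diagnostics regardless of it). Ties break by training-row order, making
  predictions invariant under row permutation up to that documented rule.

## Validation

Tropsha statistics on the test set: `R²_cvext = 1 − Σ(y−ŷ)²/Σ(y−ȳ_tr)²`;
through-origin slopes `k = Σyŷ/Σŷ²`, `k′ = Σyŷ/Σy²`; `R₀²` from the
through-origin fit `ŷ_ro = k·y` (and symmetrically for `R₀′²`); `R²_pred`
as the squared Pearson correlation. Acceptance: R²_cvext > 0.5,
R²_pred > 0.6, |R²_pred − R₀²|/R²_pred < 0.1 in at least one direction,
and 0.85 ≤ k, k′ ≤ 1.15. When predictions are constant the through-origin
R₀² degenerates and is reported as 0 (the report is still produced, and
fails). Y-randomization permutes the endpoint only, refits the entire
pipeline per round (10 by default) and counts rounds whose R²_pred falls
below the original.

Applicability domain: `APD = ⟨d⟩ + Z·σ` with Z = 0.5, where ⟨d⟩ and σ are
taken — following the Enalos-style convention — over the training-set
pairwise distances that lie below their grand mean (falling back to all
pairs when that subset is empty; a flag switches to the plain all-pairs
reading). A query is reliable when the mean distance to the `n_neighbors`
training rows used for its prediction does not exceed the threshold.

## Synthetic study conditions

The fixture generators define the conditions every test and the acceptance
script run under:

* **Toy oxides**: 24 rock-salt MeO cells with lattice constants spread over
  4.0–5.1 Å, charges ±2, carved at radii 7–9 Å (1.4–1.8 nm diameter,
  140–300 atoms — desk-scale). The Buckingham repulsion prefactor scales as
  `A = 1822.6·exp((a/2 − 2.1)/0.32)` so the repulsive wall tracks the bond
  length a/2 across the family, and the toy ionic radii scale linearly
  with a for the same reason. These parameters are synthetic and chosen
  for a bound, well-conditioned minimum; they are not literature force
  fields.
* **Planted-signal tables**: 200 rows × 40 standard-normal features,
  endpoint = 10·f₀ − 9·f₁ + 8·f₂ + N(0, 1) plus a +5 offset for the LDH
  assay level; optional exact duplicate columns feed the redundancy
  filter. Balanced weights keep all three informative features above the
  CFS selection threshold at this noise level.
* **Modelling table**: each of the 24 materials contributes rows for
  ATP/LDH assays on two cell lines at log-spaced doses; the 15
  experimental/molecular columns are drawn from plausible physical ranges,
  and viability is a planted linear function of conduction-band energy,
  core size, log-dose, assay and the two atomistic surface descriptors
  plus N(0, 3) noise, clipped to [0, 120] %.

What passing under these conditions shows: the machinery is correct —
statistics match independent term-by-term transcriptions, kNN matches an
O(n²) brute force, the selection matches exhaustive search, forces match
finite differences, calibrated Wolf electrostatics match Ewald. What it
does not show: predictive performance on real nanoparticle data, which
depends on a curated experimental dataset, real force fields and measured
descriptors none of which ship with the package. Published headline
statistics from any particular dataset (e.g. specific R² values) are not
reproducible without that dataset and the exact random split behind them.

## Numerical conventions and limitations

* Energies in eV, lengths in Å, charges in elementary charges, forces in
  eV/Å; Coulomb constant 14.399645 eV·Å/e².
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); same seed, same output, bit for bit.
* The particle pair machinery is dense O(N²) — appropriate for the
  ≤ few-thousand-atom particles the workflow targets, wasteful beyond.
* No polarizable/shell-model potentials, no finite-temperature dynamics,
  no non-spherical shapes, no computation of band energies or
  hydrodynamic size (inputs by design).
* The CIF reader applies symmetry operations (P1 expansion) and reads
  formal charges from oxidation-state type symbols (`Mg2+`), falling back
  to an explicit per-species mapping — CIF itself has no mandatory charge
  field.
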