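"""Deterministic toy generators: crystals, force fields and modelling tables.

Everything here is synthetic and self-contained so the whole toolkit can be
exercised without downloads.  The rock-salt oxide family stands in for the
bulk metal-oxide structures; the Buckingham parameters are toy values chosen
to give a bound, well-conditioned minimum, not literature force fields.  The
synthetic modelling tables plant a known linear signal in a sea of noise
descriptors so that feature selection and validation have a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crystal_builder import Particle, UnitCell, carve_sphere, minimize_energy, neutralize, replicate_cell
from .forcefield import ForceFieldSpec

__all__ = [
    "make_rocksalt",
    "toy_forcefield",
    "toy_radii",
    "build_particle",
    "SyntheticTableSpec",
    "make_synthetic_table",
    "toy_materials",
    "make_modeling_table",
]

# 24 metal symbols for the toy oxide family (one per fixture material).
_METALS = [
    "Mg", "Ca", "Sr", "Ba", "Zn", "Cd", "Cu", "Ni", "Co", "Fe", "Mn", "Ti",
    "V", "Cr", "Sn", "Pb", "Al", "Ga", "In", "Y", "La", "Ce", "Zr", "Hf",
]


def make_rocksalt(a: float = 4.2, metal: str = "Mg", charge: float = 2.0) -> UnitCell:
    """Conventional 8-site rock-salt MeO cell: 4 cations, 4 anions, net 0."""
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    me = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    ox = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    species = [metal] * 4 + ["O"] * 4
    coords = np.array(me + ox, dtype=float)
    charges = [charge] * 4 + [-charge] * 4
    return UnitCell(lattice=np.eye(3) * a, species=species, frac_coords=coords, charges=charges)


def toy_forcefield(
    metal: str = "Mg",
    charge: float = 2.0,
    A: float = 1822.6,
    rho: float = 0.32,
    cutoff: float = 10.0,
    wolf_alpha: float = 0.3,
    wolf_cutoff: float = 10.0,
) -> ForceFieldSpec:
    """Synthetic Buckingham + charges set for a rock-salt MeO toy oxide.

    Me-O carries the repulsive wall; Me-Me and O-O are electrostatic-only
    (zero Buckingham), the common convention for simple oxide force fields.
    """
    pair_params = {
        frozenset((metal, "O")): (A, rho, 0.0, cutoff),
        frozenset((metal,)): (0.0, 1.0, 0.0, cutoff),
        frozenset(("O",)): (0.0, 1.0, 0.0, cutoff),
    }
    return ForceFieldSpec(pair_params, {metal: charge, "O": -charge}, wolf_alpha, wolf_cutoff)


def toy_radii(metal: str = "Mg", a: float = 4.2) -> dict:
    """Shannon-like ionic radii (A) for the toy oxides.

    The MgO-like reference uses cation 0.74 and oxide 1.40 A; both scale
    linearly with the lattice constant so that, across the toy family, the
    ionic sizes stay consistent with the Me-O bond length a/2.
    """
    s = a / 4.2
    return {metal: 0.74 * s, "O": 1.40 * s}


def build_particle(
    a: float = 4.2,
    metal: str = "Mg",
    charge: float = 2.0,
    radius: float = 8.0,
    ff: ForceFieldSpec | None = None,
    minimize: bool = True,
    tol=None,
) -> Particle:
    """Replicate, carve, neutralize and (optionally) relax a toy particle."""
    cell = make_rocksalt(a, metal, charge)
    counts = int(np.ceil(2 * radius / a)) + 1
    super_ = replicate_cell(cell, (counts, counts, counts))
    particle = neutralize(carve_sphere(super_, radius))
    if minimize:
        ff = ff or toy_forcefield(metal, charge)
        particle = minimize_energy(particle, ff, tol)
    return particle


def material_descriptor_block(
    materials=None, shell_depth: float = 10.0, tol=None
) -> pd.DataFrame:
    """Run the full descriptor engine over a toy materials set.

    Builds, relaxes and tags one particle per material and returns the
    62-column descriptor table (index = material name).  The default
    relaxation budget (1000 CG iterations) is ample for these desk-scale
    particles, which converge on the energy criterion well before it.
    """
    from .crystal_builder import ConvergenceSpec
    from .nanodescriptors import assign_regions, compute_descriptors, descriptor_table

    if materials is None:
        materials = toy_materials()
    if tol is None:
        tol = ConvergenceSpec(max_iter=1000)
    block = {}
    for name, a, metal, charge, radius in materials:
        # shift the repulsive wall with the bond length a/2 so every oxide
        # in the family has a comparable barrier against ion fusion
        A = 1822.6 * float(np.exp((a / 2 - 2.1) / 0.32))
        ff = toy_forcefield(metal, charge, A=A)
        particle = build_particle(a=a, metal=metal, charge=charge, radius=radius, ff=ff, tol=tol)
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")  # small particles may be all shell
                particle = assign_regions(particle, shell_depth)
        block[name] = compute_descriptors(particle, ff, toy_radii(metal, a))
    return descriptor_table(block)


# ---------------------------------------------------------------------------
# Synthetic modelling tables


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a planted-signal regression table.

    The endpoint is a linear combination of the informative features plus
    Gaussian noise and an additive offset for one assay level, mimicking a
    viability table where only a few descriptors carry signal.
    """

    n_rows: int = 200
    n_features: int = 40
    informative: tuple = (0, 1, 2)
    weights: tuple = (10.0, -9.0, 8.0)
    noise_sigma: float = 1.0
    duplicate_pairs: int = 0
    with_assay: bool = True
    assay_offset: float = 5.0
    seed: int = 0


def make_synthetic_table(spec: SyntheticTableSpec) -> tuple[pd.DataFrame, dict]:
    """Generate the planted-signal table and its column-role schema.

    Returns ``(table, schema)`` where schema maps column name to one of
    ``numeric | nominal | endpoint``.  Duplicate columns (exact copies of
    earlier features) are appended per the duplicate plan so the redundancy
    filter has known prey.  Pure function of the spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.normal(size=(spec.n_rows, spec.n_features))
    y = np.zeros(spec.n_rows)
    for idx, w in zip(spec.informative, spec.weights):
        y += w * X[:, idx]
    y += rng.normal(scale=spec.noise_sigma, size=spec.n_rows)
    cols = {f"f{i:02d}": X[:, i] for i in range(spec.n_features)}
    schema = {name: "numeric" for name in cols}
    for d in range(spec.duplicate_pairs):
        src = f"f{d % spec.n_features:02d}"
        name = f"dup{d:02d}"
        cols[name] = cols[src].copy()
        schema[name] = "numeric"
    if spec.with_assay:
        assay = rng.choice(["ATP", "LDH"], size=spec.n_rows)
        y = y + np.where(assay == "LDH", spec.assay_offset, 0.0)
        cols["assay"] = assay
        schema["assay"] = "nominal"
    cols["viability"] = y
    schema["viability"] = "endpoint"
    return pd.DataFrame(cols), schema


def make_service_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Project a full modelling table onto the 7-descriptor service schema.

    Renames the internal column names to the published request field names
    (coreSize, hydroSize, ecEv, assay, exposureDose, des306, des606).
    """
    renames = {
        "core_size": "coreSize",
        "hydro_size": "hydroSize",
        "e_c": "ecEv",
        "exposure_dose": "exposureDose",
        "cn_mean_me_shell": "des306",
        "fnormal_mean_me_shell": "des606",
    }
    cols = ["material"] + list(renames) + ["assay", "viability"]
    out = table[cols].rename(columns=renames)
    schema = {
        "material": "id",
        "assay": "nominal",
        "viability": "endpoint",
    }
    for c in renames.values():
        schema[c] = "numeric"
    return out, schema


# ---------------------------------------------------------------------------
# Toy materials set (descriptor-engine inputs)


def toy_materials(n: int = 24, seed: int = 0):
    """Deterministic family of ``n`` toy rock-salt oxides.

    Yields ``(name, lattice_constant, metal, charge, radius)`` tuples with
    lattice constants spread over 4.0-5.1 A and particle radii over
    7-9 A (diameters 1.4-1.8 nm, desk-scale particles).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        metal = _METALS[i % len(_METALS)]
        a = 4.0 + 1.1 * (i / max(n - 1, 1)) + 0.02 * rng.standard_normal()
        radius = 7.0 + 2.0 * rng.random()
        out.append((f"{metal}O", round(float(a), 3), metal, 2.0, round(float(radius), 3)))
    return out


def make_modeling_table(
    descriptor_block: pd.DataFrame,
    rows_per_material: int = 4,
    noise_sigma: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Assemble a full modelling table around a computed descriptor block.

    ``descriptor_block`` is the per-material output of the descriptor
    engine (index = material id, 62 columns).  Each material contributes
    ``rows_per_material`` experiment rows (ATP/LDH assays on two cell
    lines at varying doses).  The 15 experimental/molecular columns are
    synthetic but physically plausible; viability is a planted linear
    function of conduction-band energy, core size, dose, assay and two
    atomistic surface descriptors, plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    assays = ["ATP", "LDH"]
    cells = ["BEAS-2B", "RAW 264.7"]
    records = []
    for mat_id, desc in descriptor_block.iterrows():
        core = rng.uniform(10, 80)          # nm
        hydro = core * rng.uniform(1.2, 4)  # nm
        ssa = rng.uniform(5, 120)           # m^2/g
        tsa = ssa * rng.uniform(0.5, 2)
        zeta = rng.uniform(-40, 40)         # mV
        e_v = rng.uniform(-9, -5)
        e_c = rng.uniform(-5, -1)
        e_g = e_c - e_v
        chi_cat = rng.uniform(1.0, 2.2)
        chi_ox = rng.uniform(4.5, 7.0)
        e_dh = rng.uniform(-12, -2)
        for k in range(rows_per_material):
            assay = assays[k % 2]
            cell_sp = cells[(k // 2) % 2]
            dose = float(rng.choice([0.4, 0.8, 1.6, 3.2, 6.4, 12.8, 25.6]))
            viability = (
                80.0
                + 6.0 * e_c
                - 0.15 * core
                - 1.2 * np.log1p(dose) * 4.0
                + 2.0 * desc["cn_mean_me_shell"]
                + 15.0 * desc["fnormal_mean_me_shell"]
                + (8.0 if assay == "LDH" else 0.0)
                + rng.normal(scale=noise_sigma)
            )
            row = {
                "material": mat_id,
                "formula": mat_id,
                "core_size": core,
                "specific_surface_area": ssa,
                "total_surface_area": tsa,
                "hydro_size": hydro,
                "zeta_potential": zeta,
                "e_v": e_v,
                "e_c": e_c,
                "e_g": e_g,
                "chi_cation": chi_cat,
                "chi_oxide": chi_ox,
                "e_dh": e_dh,
                "assay": assay,
                "cell_species": cell_sp,
                "exposure_dose": dose,
            }
            row.update(desc.to_dict())
            row["viability"] = float(np.clip(viability, 0, 120))
            records.append(row)
    table = pd.DataFrame(records)
    schema = {"material": "id", "formula": "nominal", "assay": "nominal", "cell_species": "nominal", "viability": "endpoint"}
    for col in table.columns:
        schema.setdefault(col, "numeric")
    return table, schema
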