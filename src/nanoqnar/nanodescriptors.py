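"""Core/shell partitioning and the 62 atomistic nanodescriptors.

A relaxed spherical particle is split into a *shell* (atoms within a set
depth, default 1 nm, of the nominal surface) and a *core* (the rest).
Scalar statistics are then taken over the 3x3 grid of atom scopes
{all, metal, oxygen} x regions {whole, core, shell}, yielding six
descriptor categories with fixed cardinalities:

    composition        9   atom counts per scope x region
    potential_energy   9   mean per-atom potential energy (eV)
    topology           9   mean coordination number
    lattice_energy     5   total / per-atom / core / shell energies + ratio
    size               3   diameter, volume, surface area from the radius
    force_vectors     27   mean radial (outward-normal), tangential and
                           total force magnitudes per scope x region

for 62 descriptors in total.  The coordination cutoff is
``R = 1.2 (R_M + R_O)`` from the ionic radii; the surface-normal force
component of an atom at distance d from the particle center of mass is
``V = (x f_x + y f_y + z f_z) / d`` (outward positive).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .crystal_builder import Particle
from .errors import ConfigurationError, UndefinedGeometryError

__all__ = [
    "CATEGORY_SIZES",
    "DESCRIPTOR_NAMES",
    "SCOPES",
    "REGIONS",
    "assign_regions",
    "coordination_cutoff",
    "coordination_number",
    "normal_force_component",
    "compute_descriptors",
    "descriptor_table",
    "write_descriptor_csv",
]

logger = logging.getLogger(__name__)

SCOPES = ("all", "me", "ox")
REGIONS = ("whole", "core", "shell")

CATEGORY_SIZES = {
    "composition": 9,
    "potential_energy": 9,
    "topology": 9,
    "lattice_energy": 5,
    "size": 3,
    "force_vectors": 27,
}

DEFAULT_SHELL_DEPTH = 10.0  # A (1 nm)


def _grid(prefix: str) -> list[str]:
    return [f"{prefix}_{s}_{r}" for s in SCOPES for r in REGIONS]


#: Canonical descriptor order: grouped by category, scope-major inside.
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    _grid("n")
    + _grid("epot_mean")
    + _grid("cn_mean")
    + ["e_total", "e_per_atom", "e_core_total", "e_shell_total", "e_shell_fraction"]
    + ["diameter", "volume", "surface_area"]
    + _grid("fnormal_mean")
    + _grid("ftangential_mean")
    + _grid("fmag_mean")
)

DESCRIPTOR_CATEGORIES: dict[str, str] = {}
for _n in _grid("n"):
    DESCRIPTOR_CATEGORIES[_n] = "composition"
for _n in _grid("epot_mean"):
    DESCRIPTOR_CATEGORIES[_n] = "potential_energy"
for _n in _grid("cn_mean"):
    DESCRIPTOR_CATEGORIES[_n] = "topology"
for _n in ["e_total", "e_per_atom", "e_core_total", "e_shell_total", "e_shell_fraction"]:
    DESCRIPTOR_CATEGORIES[_n] = "lattice_energy"
for _n in ["diameter", "volume", "surface_area"]:
    DESCRIPTOR_CATEGORIES[_n] = "size"
for _n in _grid("fnormal_mean") + _grid("ftangential_mean") + _grid("fmag_mean"):
    DESCRIPTOR_CATEGORIES[_n] = "force_vectors"


def assign_regions(atoms: Particle, shell_depth: float = DEFAULT_SHELL_DEPTH) -> Particle:
    """Tag every atom core or shell by depth below the nominal surface.

    An atom is *shell* iff its distance from the carve center is at least
    ``nominal_radius - shell_depth``; otherwise *core*.  When the depth
    reaches the radius, the whole particle is shell (warned, not an error).
    """
    if atoms.nominal_radius is None:
        raise ConfigurationError("particle has no nominal radius; carve it first")
    if shell_depth <= 0:
        raise ConfigurationError("shell_depth must be positive")
    if shell_depth >= atoms.nominal_radius:
        warnings.warn(
            f"shell depth {shell_depth} A >= nominal radius "
            f"{atoms.nominal_radius} A: entire particle is shell",
            stacklevel=2,
        )
    center = (
        atoms.carve_center
        if atoms.carve_center is not None
        else atoms.geometric_center()
    )
    dist = np.linalg.norm(atoms.positions - center, axis=1)
    out = atoms.copy()
    out.regions = np.where(
        dist >= atoms.nominal_radius - shell_depth, "shell", "core"
    ).astype(object)
    return out


def coordination_cutoff(radii: dict, species) -> float:
    """Coordination radius ``R = 1.2 (R_M + R_O)`` from the ionic radii."""
    metals = sorted({s for s in species if s != "O"})
    if not metals or "O" not in set(species):
        raise ConfigurationError("particle must contain a metal and oxygen")
    if len(metals) > 1:
        raise ConfigurationError(
            f"multiple metal species {metals}: coordination cutoff is defined "
            "for single-oxide particles"
        )
    for sp in metals + ["O"]:
        if sp not in radii:
            raise ConfigurationError(f"no ionic radius for species {sp!r}")
        if radii[sp] <= 0:
            raise ConfigurationError(f"ionic radius for {sp!r} must be positive")
    return 1.2 * (radii[metals[0]] + radii["O"])


def coordination_number(atoms: Particle, radii: dict) -> np.ndarray:
    """Per-atom count of other atoms within the coordination cutoff."""
    R = coordination_cutoff(radii, atoms.species)
    if atoms.n_atoms == 1:
        return np.zeros(1, dtype=int)
    diff = atoms.positions[:, None, :] - atoms.positions[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(r, np.inf)
    return (r <= R).sum(axis=1)


def normal_force_component(position, force, center) -> float:
    """Outward radial force component ``V = r.f / |r|`` about ``center``.

    ``position`` is taken relative to the particle's center of mass in the
    descriptor pipeline; positive V points away from the center.
    """
    rel = np.asarray(position, dtype=float) - np.asarray(center, dtype=float)
    d = np.linalg.norm(rel)
    if d == 0:
        raise UndefinedGeometryError("atom coincides with the reference center")
    return float(rel @ np.asarray(force, dtype=float) / d)


def _scope_masks(atoms: Particle) -> dict:
    is_ox = np.array([s == "O" for s in atoms.species])
    return {"all": np.ones(atoms.n_atoms, bool), "me": ~is_ox, "ox": is_ox}


def _region_masks(atoms: Particle) -> dict:
    shell = atoms.regions == "shell"
    return {"whole": np.ones(atoms.n_atoms, bool), "core": ~shell, "shell": shell}


def _mean(values: np.ndarray, mask: np.ndarray, name: str) -> float:
    # Empty scope x region cells yield 0 by convention (logged), so small
    # particles (e.g. all-shell) remain processable.
    if not mask.any():
        logger.info("empty atom set for descriptor %s; reporting 0", name)
        return 0.0
    return float(values[mask].mean())


def compute_descriptors(atoms: Particle, ff, radii: dict) -> dict:
    """Compute the full 62-descriptor vector for a prepared particle.

    The particle must be relaxed (per-atom energies and forces present)
    and region-tagged.  Returns an ordered mapping following
    :data:`DESCRIPTOR_NAMES`.
    """
    if atoms.energies is None or atoms.forces is None:
        raise ConfigurationError("particle lacks energies/forces; minimize it first")
    if atoms.regions is None:
        raise ConfigurationError("particle lacks region tags; assign regions first")
    if atoms.nominal_radius is None:
        raise ConfigurationError("particle has no nominal radius")

    scopes = _scope_masks(atoms)
    regions = _region_masks(atoms)
    cells = {
        (s, r): scopes[s] & regions[r] for s in SCOPES for r in REGIONS
    }

    cn = coordination_number(atoms, radii).astype(float)

    com = atoms.center_of_mass()
    rel = atoms.positions - com
    d = np.linalg.norm(rel, axis=1)
    if np.any(d == 0):
        raise UndefinedGeometryError("an atom sits exactly at the center of mass")
    v_normal = (rel * atoms.forces).sum(axis=1) / d
    f_mag = np.linalg.norm(atoms.forces, axis=1)
    v_tang = np.sqrt(np.maximum(f_mag**2 - v_normal**2, 0.0))

    out: dict[str, float] = {}
    for s in SCOPES:
        for r in REGIONS:
            out[f"n_{s}_{r}"] = float(cells[s, r].sum())
    for s in SCOPES:
        for r in REGIONS:
            out[f"epot_mean_{s}_{r}"] = _mean(atoms.energies, cells[s, r], f"epot_mean_{s}_{r}")
    for s in SCOPES:
        for r in REGIONS:
            out[f"cn_mean_{s}_{r}"] = _mean(cn, cells[s, r], f"cn_mean_{s}_{r}")

    e_total = float(atoms.energies.sum())
    shell_mask = regions["shell"]
    e_shell = float(atoms.energies[shell_mask].sum())
    e_core = e_total - e_shell
    out["e_total"] = e_total
    out["e_per_atom"] = e_total / atoms.n_atoms
    out["e_core_total"] = e_core
    out["e_shell_total"] = e_shell
    out["e_shell_fraction"] = e_shell / e_total if e_total != 0 else 0.0

    R = atoms.nominal_radius
    out["diameter"] = 2.0 * R
    out["volume"] = 4.0 / 3.0 * np.pi * R**3
    out["surface_area"] = 4.0 * np.pi * R**2

    for s in SCOPES:
        for r in REGIONS:
            out[f"fnormal_mean_{s}_{r}"] = _mean(v_normal, cells[s, r], f"fnormal_mean_{s}_{r}")
    for s in SCOPES:
        for r in REGIONS:
            out[f"ftangential_mean_{s}_{r}"] = _mean(v_tang, cells[s, r], f"ftangential_mean_{s}_{r}")
    for s in SCOPES:
        for r in REGIONS:
            out[f"fmag_mean_{s}_{r}"] = _mean(f_mag, cells[s, r], f"fmag_mean_{s}_{r}")

    assert tuple(out) == DESCRIPTOR_NAMES
    return out


def descriptor_table(per_material: dict) -> pd.DataFrame:
    """Stack per-material descriptor dicts into a 62-column DataFrame."""
    df = pd.DataFrame.from_dict(per_material, orient="index")
    df.index.name = "material"
    return df[list(DESCRIPTOR_NAMES)]


def write_descriptor_csv(per_material: dict, path) -> None:
    """Write the canonical one-row-per-particle descriptor CSV."""
    descriptor_table(per_material).to_csv(path)
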