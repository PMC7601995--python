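"""Build relaxed spherical nanoparticles from bulk crystal unit cells.

The construction pipeline is: replicate the unit cell into a supercell,
carve a sphere of the requested radius, remove outermost ions of the
over-represented charge sign until the particle is electroneutral, and
relax the geometry with Polak-Ribiere conjugate-gradient minimization
under a Buckingham + Wolf-summed Coulomb force field.  The particle is
treated as an isolated (open-boundary) cluster throughout: for strictly
pairwise potentials this is equivalent to the large-padded periodic box
often used in molecular-statics codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyParticleError,
    InfeasibleError,
    InvalidArgumentError,
    MinimizationError,
)

__all__ = [
    "UnitCell",
    "Particle",
    "ConvergenceSpec",
    "replicate_cell",
    "carve_sphere",
    "neutralize",
    "minimize_energy",
    "read_cif",
    "write_cif",
    "write_xyz",
]

#: Atoms closer than this are considered fused (unphysical overlap), in A.
FUSION_DISTANCE = 0.3


@dataclass(frozen=True)
class UnitCell:
    """A bulk crystal unit cell with formal ionic charges.

    Parameters
    ----------
    lattice : (3, 3) array
        Row lattice vectors in Angstrom.
    species : sequence of str
        Element symbol per site.
    frac_coords : (n, 3) array
        Fractional coordinates in [0, 1).
    charges : sequence of float
        Formal charge per site in elementary charges; must sum to zero.
    """

    lattice: np.ndarray
    species: tuple
    frac_coords: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        frac = np.asarray(self.frac_coords, dtype=float).reshape(-1, 3)
        q = np.asarray(self.charges, dtype=float).ravel()
        object.__setattr__(self, "lattice", lat)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "frac_coords", frac)
        object.__setattr__(self, "charges", q)
        if abs(np.linalg.det(lat)) < 1e-9:
            raise InvalidArgumentError("lattice vectors are linearly dependent")
        if len(self.species) != len(frac) or len(frac) != len(q):
            raise InvalidArgumentError("species/coords/charges length mismatch")
        if abs(q.sum()) > 1e-9:
            raise InvalidArgumentError(
                f"unit cell is not electroneutral (net charge {q.sum():g})"
            )
        if "O" not in self.species or all(s == "O" for s in self.species):
            raise InvalidArgumentError("cell must contain a metal and oxygen")

    @property
    def n_sites(self) -> int:
        return len(self.species)


@dataclass
class Particle:
    """A finite cluster of point ions.

    Positions are Cartesian (Angstrom), charges in elementary charges.
    ``energies`` (eV/atom), ``forces`` (eV/A) and ``regions`` ("core" /
    "shell") are filled in by later pipeline stages.  ``carve_center`` is
    the point the sphere was carved about and is the reference for the
    neutralization and core/shell geometry.
    """

    species: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    nominal_radius: float | None = None
    carve_center: np.ndarray | None = None
    energies: np.ndarray | None = None
    forces: np.ndarray | None = None
    regions: np.ndarray | None = None

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if self.carve_center is not None:
            self.carve_center = np.asarray(self.carve_center, dtype=float).ravel()

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def center_of_mass(self) -> np.ndarray:
        masses = np.array([gemmi.Element(s).weight for s in self.species])
        return masses @ self.positions / masses.sum()

    def geometric_center(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def copy(self) -> "Particle":
        return Particle(
            species=self.species.copy(),
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            nominal_radius=self.nominal_radius,
            carve_center=None if self.carve_center is None else self.carve_center.copy(),
            energies=None if self.energies is None else self.energies.copy(),
            forces=None if self.forces is None else self.forces.copy(),
            regions=None if self.regions is None else self.regions.copy(),
        )


@dataclass(frozen=True)
class ConvergenceSpec:
    """Stopping criteria for the conjugate-gradient minimizer.

    ``energy`` is the relative total-energy change per accepted step,
    ``force`` the maximum force component in eV/A, ``max_iter`` the
    iteration cap.  ``max_step`` caps the displacement of any atom within
    one line search (A); it keeps the search from hopping over the finite
    short-range barrier into the Coulomb singularity (ion fusion).
    """

    energy: float = 1e-8
    force: float = 1e-4
    max_iter: int = 100_000
    max_step: float = 0.1


def replicate_cell(cell: UnitCell, counts: Sequence[int]) -> Particle:
    """Tile the unit cell ``counts = (na, nb, nc)`` times along its vectors.

    Returns a particle whose positions are the Cartesian images of every
    site under all lattice translations; atom count is
    ``cell.n_sites * na * nb * nc``.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 1 for c in counts):
        raise InvalidArgumentError(f"replication counts must be >= 1, got {counts}")
    shifts = np.array(
        [[i, j, k] for i in range(counts[0]) for j in range(counts[1]) for k in range(counts[2])],
        dtype=float,
    )
    frac = cell.frac_coords[None, :, :] + shifts[:, None, :]
    cart = frac.reshape(-1, 3) @ cell.lattice
    n_img = len(shifts)
    return Particle(
        species=np.array(list(cell.species) * n_img, dtype=object),
        positions=cart,
        charges=np.tile(cell.charges, n_img),
    )


def carve_sphere(
    atoms: Particle, radius: float, center: Sequence[float] | None = None
) -> Particle:
    """Keep only atoms within ``radius`` of ``center``.

    ``center`` defaults to the geometric center of the input atoms.
    Idempotent at a fixed radius and center.
    """
    if radius <= 0:
        raise InvalidArgumentError("carve radius must be positive")
    center = (
        atoms.geometric_center() if center is None else np.asarray(center, dtype=float)
    )
    dist = np.linalg.norm(atoms.positions - center, axis=1)
    keep = dist <= radius
    if not keep.any():
        raise EmptyParticleError(
            f"no atoms within radius {radius} A of {np.round(center, 3)}"
        )
    return Particle(
        species=atoms.species[keep],
        positions=atoms.positions[keep],
        charges=atoms.charges[keep],
        nominal_radius=float(radius),
        carve_center=center,
    )


def neutralize(atoms: Particle) -> Particle:
    """Remove outermost over-represented ions until the net charge is zero.

    Only atoms whose charge shares the sign of the net charge are removed,
    outermost first (ties: species symbol, then input order).  Raises
    :class:`InfeasibleError` when no sequence of such removals reaches
    exactly zero (e.g. the imbalance is not a multiple of the ionic charge).
    """
    total = atoms.charges.sum()
    if abs(total) < 1e-9:
        return atoms
    center = (
        atoms.carve_center if atoms.carve_center is not None else atoms.geometric_center()
    )
    dist = np.linalg.norm(atoms.positions - center, axis=1)
    # Outermost-first ordering of candidate removals, deterministic ties.
    order = sorted(
        range(atoms.n_atoms),
        key=lambda i: (-dist[i], str(atoms.species[i]), i),
    )
    removed: list[int] = []
    q = total
    for i in order:
        if q == 0:
            break
        qi = atoms.charges[i]
        if np.sign(qi) == np.sign(q) and abs(qi) <= abs(q) + 1e-9:
            removed.append(i)
            q -= qi
    if abs(q) > 1e-9:
        raise InfeasibleError(
            f"cannot neutralize: residual charge {q:g} after greedy removal"
        )
    keep = np.ones(atoms.n_atoms, dtype=bool)
    keep[removed] = False
    return Particle(
        species=atoms.species[keep],
        positions=atoms.positions[keep],
        charges=atoms.charges[keep],
        nominal_radius=atoms.nominal_radius,
        carve_center=atoms.carve_center,
    )


def minimize_energy(
    atoms: Particle, ff, tol: ConvergenceSpec | None = None
) -> Particle:
    """Relax the particle with Polak-Ribiere (PR+) conjugate gradients.

    A backtracking Armijo line search guarantees monotone energy descent.
    Terminates when the relative energy change drops below ``tol.energy``,
    the maximum force component drops below ``tol.force``, or ``tol.max_iter``
    is hit.  The returned particle carries per-atom energies and forces at
    the final geometry.
    """
    from .forcefield import total_energy_and_forces

    tol = tol or ConvergenceSpec()
    work = atoms.copy()
    x = work.positions.copy()

    def ef(pos):
        work.positions = pos
        e_tot, per_atom, forces = total_energy_and_forces(work, ff)
        return e_tot, per_atom, forces

    energy, per_atom, forces = ef(x)
    if not np.isfinite(energy):
        raise MinimizationError("non-finite energy at the starting geometry")
    g = -forces
    d = -g
    step = 1.0
    for _ in range(tol.max_iter):
        if np.abs(g).max() < tol.force:
            break
        gd = float((g * d).sum())
        if gd >= 0:  # not a descent direction: steepest-descent restart
            d = -g
            gd = float((g * d).sum())
        # Armijo backtracking from the previous accepted step size, capped
        # so no atom moves more than max_step in a single line search.
        d_max = np.abs(d).max()
        alpha_cap = tol.max_step / d_max if d_max > 0 else 1.0
        alpha = min(step * 2.0, 1.0, alpha_cap)
        e_new = None
        for _ls in range(60):
            x_try = x + alpha * d
            e_try, pa_try, f_try = ef(x_try)
            if np.isfinite(e_try) and e_try <= energy + 1e-4 * alpha * gd:
                e_new, pa_new, f_new, x_new = e_try, pa_try, f_try, x_try
                break
            alpha *= 0.5
        if e_new is None:
            break  # line search failed: already at numerical resolution
        _check_fusion(x_new)
        step = alpha
        g_new = -f_new
        denom = float((g * g).sum())
        beta = max(0.0, float((g_new * (g_new - g)).sum()) / denom) if denom > 0 else 0.0
        d = -g_new + beta * d
        converged = abs(energy - e_new) < tol.energy * max(abs(energy), 1.0)
        x, energy, per_atom, forces, g = x_new, e_new, pa_new, f_new, g_new
        if converged:
            break
    if not np.isfinite(energy):
        raise MinimizationError("energy diverged during minimization")
    work.positions = x
    work.energies = per_atom
    work.forces = forces
    return work


def _check_fusion(positions: np.ndarray) -> None:
    if len(positions) < 2:
        return
    diff = positions[:, None, :] - positions[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(r, np.inf)
    rmin = r.min()
    if rmin < FUSION_DISTANCE:
        raise MinimizationError(
            f"atom fusion detected: minimum separation {rmin:.3f} A"
        )


# ---------------------------------------------------------------------------
# File I/O


def read_cif(path: str | Path, charges: dict[str, float] | None = None) -> UnitCell:
    """Read a bulk structure CIF into a :class:`UnitCell`.

    Symmetry operations are applied (P1 expansion) before use.  Formal
    charges are taken from oxidation-state suffixes on the type symbols
    ("Mg2+", "O2-") when present, otherwise from the ``charges`` mapping.
    """
    st = gemmi.read_small_structure(str(path))
    sites = st.get_all_unit_cell_sites()
    if not sites:
        raise InvalidArgumentError(f"no atom sites found in {path}")
    lattice = np.array(st.cell.orth.mat.tolist()).T  # rows = lattice vectors
    symbols, fracs, qs = [], [], []
    for site in sites:
        elem = site.element.name
        frac = np.array([site.fract.x, site.fract.y, site.fract.z]) % 1.0
        q = _charge_from_type_symbol(site.type_symbol)
        if q is None:
            if charges is None or elem not in charges:
                raise InvalidArgumentError(
                    f"no formal charge for species {elem!r}: CIF carries no "
                    "oxidation state and no charges mapping was given"
                )
            q = charges[elem]
        symbols.append(elem)
        fracs.append(frac)
        qs.append(q)
    return UnitCell(lattice=lattice, species=symbols, frac_coords=np.array(fracs), charges=qs)


def _charge_from_type_symbol(type_symbol: str) -> float | None:
    s = type_symbol.strip()
    if not s or (s[-1] not in "+-"):
        return None
    sign = 1.0 if s[-1] == "+" else -1.0
    digits = ""
    for ch in reversed(s[:-1]):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    return sign * (float(digits) if digits else 1.0)


def write_cif(cell: UnitCell, path: str | Path, name: str = "structure") -> None:
    """Write a P1 CIF with oxidation-state type symbols carrying the charges."""
    a, b, c = (np.linalg.norm(v) for v in cell.lattice)

    def angle(u, v):
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

    alpha = angle(cell.lattice[1], cell.lattice[2])
    beta = angle(cell.lattice[0], cell.lattice[2])
    gamma = angle(cell.lattice[0], cell.lattice[1])
    lines = [
        f"data_{name}",
        "_symmetry_space_group_name_H-M 'P 1'",
        f"_cell_length_a {a:.6f}",
        f"_cell_length_b {b:.6f}",
        f"_cell_length_c {c:.6f}",
        f"_cell_angle_alpha {alpha:.6f}",
        f"_cell_angle_beta {beta:.6f}",
        f"_cell_angle_gamma {gamma:.6f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, (sym, frac, q) in enumerate(
        zip(cell.species, cell.frac_coords, cell.charges)
    ):
        qint = int(round(abs(q)))
        suffix = ("" if qint == 0 else f"{qint}") + ("+" if q > 0 else "-" if q < 0 else "")
        lines.append(
            f"{sym}{i + 1} {sym}{suffix} {frac[0]:.6f} {frac[1]:.6f} {frac[2]:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(particle: Particle, path: str | Path, comment: str = "") -> None:
    """Write an extended XYZ file (species, x, y, z, charge)."""
    lines = [str(particle.n_atoms), comment or "nanoqnar particle"]
    for s, p, q in zip(particle.species, particle.positions, particle.charges):
        lines.append(f"{s} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {q:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
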