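"""Potential-energy terms, particle state, neighbor search and exact
reference energy evaluation.

Everything here is plain numpy and serves as the ground truth the fast
Monte Carlo kernel (:mod:`brushsim._kernels`) is tested against.

Conventions: positions are stored unwrapped; the minimum-image convention
applies in x and y only, z is bounded by the two walls at 0 and ``h``.
The pair, bond and wall potentials are all non-negative, so the total
energy is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model import BrushArchitecture, InteractionTable, chain_counts

__all__ = [
    "GRAFT_FREE", "GRAFT_LIQUID", "GRAFT_SOLID",
    "ParticleSystem", "EnergyBreakdown",
    "Displacement", "Insertion", "Deletion",
    "pair_potential", "bond_potential", "wall_potential",
    "total_energy", "delta_energy", "build_cell_list",
]

GRAFT_FREE = 0
GRAFT_LIQUID = 1   # z frozen at the surface plane, free to move in xy
GRAFT_SOLID = 2    # fully frozen

SOLVENT = 0        # species label of the solvent


class ContractViolation(RuntimeError):
    """A move was proposed that the engine contract forbids."""


@dataclass
class ParticleSystem:
    """Mutable simulator state.

    positions : (n, 3) float array in rc, unwrapped.
    species   : (n,) int array; 0 = solvent, p >= 1 = brush population p.
    bonds     : (nb, 2) int array of bonded index pairs (consecutive beads).
    bond_kappa, bond_r0 : per-bond spring constant (kBT/rc^2) and rest length.
    graft     : (n,) int array of GRAFT_* flags.
    chain_id  : (n,) int array, -1 for solvent.
    box_xy    : lateral periodic box lengths (rc).
    h         : wall separation (rc).
    """

    positions: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    bond_kappa: np.ndarray
    bond_r0: np.ndarray
    graft: np.ndarray
    chain_id: np.ndarray
    box_xy: tuple[float, float]
    h: float

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_kappa = np.ascontiguousarray(self.bond_kappa, dtype=np.float64)
        self.bond_r0 = np.ascontiguousarray(self.bond_r0, dtype=np.float64)
        self.graft = np.ascontiguousarray(self.graft, dtype=np.int64)
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def n_solvent(self) -> int:
        return int(np.count_nonzero(self.species == SOLVENT))

    @property
    def n_brush(self) -> int:
        return self.n - self.n_solvent

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(), species=self.species.copy(),
            bonds=self.bonds.copy(), bond_kappa=self.bond_kappa.copy(),
            bond_r0=self.bond_r0.copy(), graft=self.graft.copy(),
            chain_id=self.chain_id.copy(), box_xy=self.box_xy, h=self.h,
        )

    @classmethod
    def empty(cls, box_xy=(7.0, 7.0), h=10.0) -> "ParticleSystem":
        return cls(positions=np.zeros((0, 3)), species=np.zeros(0, dtype=int),
                   bonds=np.zeros((0, 2), dtype=int), bond_kappa=np.zeros(0),
                   bond_r0=np.zeros(0), graft=np.zeros(0, dtype=int),
                   chain_id=np.full(0, -1, dtype=int), box_xy=box_xy, h=h)

    @classmethod
    def solvent_only(cls, positions, box_xy, h) -> "ParticleSystem":
        n = len(positions)
        return cls(positions=np.asarray(positions, dtype=float),
                   species=np.zeros(n, dtype=int),
                   bonds=np.zeros((0, 2), dtype=int), bond_kappa=np.zeros(0),
                   bond_r0=np.zeros(0), graft=np.zeros(n, dtype=int),
                   chain_id=np.full(n, -1, dtype=int), box_xy=box_xy, h=h)

    # -- invariants -------------------------------------------------------
    def check(self, architecture: BrushArchitecture | None = None,
              area_nm2: float | None = None) -> list[str]:
        """Structural invariant check; returns the list of violations."""
        errors = []
        z = self.positions[:, 2]
        if self.n and (z.min() < -1e-12 or z.max() > self.h + 1e-12):
            errors.append("particle z-coordinates must lie in [0, h]")
        if np.any((self.graft != GRAFT_FREE) & (np.abs(z) > 1e-12)):
            errors.append("graft beads must sit on the surface plane z = 0")
        if np.any((self.species == SOLVENT) & (self.graft != GRAFT_FREE)):
            errors.append("solvent particles cannot be grafted")
        for i, j in self.bonds:
            if self.chain_id[i] != self.chain_id[j] or self.chain_id[i] < 0:
                errors.append(f"bond ({i},{j}) must connect beads of one chain")
                break
            if abs(i - j) != 1:
                errors.append(f"bond ({i},{j}) must connect consecutive beads")
                break
        chains = np.unique(self.chain_id[self.chain_id >= 0])
        for c in chains:
            idx = np.flatnonzero(self.chain_id == c)
            ngraft = np.count_nonzero(self.graft[idx] != GRAFT_FREE)
            if ngraft != 1:
                errors.append(f"chain {c} has {ngraft} graft beads, expected 1")
        if architecture is not None and area_nm2 is not None:
            counts = chain_counts(architecture, area_nm2)
            for p, (pop, cnt) in enumerate(zip(architecture.populations, counts)):
                mask = self.species == p + 1
                if int(mask.sum()) != cnt * pop.N:
                    errors.append(
                        f"population {p}: expected {cnt} chains x {pop.N} beads, "
                        f"found {int(mask.sum())} beads"
                    )
        return errors

    def validate(self, architecture=None, area_nm2=None) -> "ParticleSystem":
        errors = self.check(architecture, area_nm2)
        if errors:
            raise ValueError("; ".join(errors))
        return self


@dataclass(frozen=True)
class EnergyBreakdown:
    pair: float
    bond: float
    wall_surface: float
    wall_tip: float

    @property
    def total(self) -> float:
        return self.pair + self.bond + self.wall_surface + self.wall_tip


# -- proposed moves -------------------------------------------------------

@dataclass(frozen=True)
class Displacement:
    index: int
    new_position: np.ndarray


@dataclass(frozen=True)
class Insertion:
    position: np.ndarray
    species: int = SOLVENT


@dataclass(frozen=True)
class Deletion:
    index: int


# -- potentials -----------------------------------------------------------

def pair_potential(r, a):
    """Soft conservative repulsion: U = (a/2)(1 - r)^2 for r < 1 (rc), else 0.

    Continuous and once-differentiable at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pair distance must be non-negative")
    u = np.where(r < 1.0, 0.5 * a * (1.0 - r) ** 2, 0.0)
    return u if u.ndim else float(u)

def bond_potential(r, kappa, r0=0.0):
    """Harmonic spring: U = (kappa/2)(r - r0)^2."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    u = 0.5 * kappa * (r - r0) ** 2
    return u if u.ndim else float(u)


def wall_potential(gap, a_w):
    """Soft wall: U = (a_w/2)(1 - gap)^2 for gap < 1, else 0.

    Negative gaps (penetration past the nominal plane) are allowed and give
    the quadratic continuation -- this is the 'soft, deformable' surface.
    """
    gap = np.asarray(gap, dtype=float)
    u = np.where(gap < 1.0, 0.5 * a_w * (1.0 - gap) ** 2, 0.0)
    return u if u.ndim else float(u)


# -- energy evaluation ----------------------------------------------------

def _min_image_dr(dr, box_xy, h=None, periodic_z=False):
    dr = np.asarray(dr, dtype=float)
    dr[..., 0] -= box_xy[0] * np.rint(dr[..., 0] / box_xy[0])
    dr[..., 1] -= box_xy[1] * np.rint(dr[..., 1] / box_xy[1])
    if periodic_z:
        dr[..., 2] -= h * np.rint(dr[..., 2] / h)
    return dr


def _bonded_pair_set(system: ParticleSystem) -> set[tuple[int, int]]:
    return {(min(i, j), max(i, j)) for i, j in system.bonds}


def total_energy(system: ParticleSystem, table: InteractionTable,
                 exclude_bonded: bool = False,
                 periodic_z: bool = False) -> EnergyBreakdown:
    """Exact O(n^2) reference energy: all pair terms under the xy minimum-image
    convention, all bonds, and both wall planes (skipped when periodic_z)."""
    pos = system.positions
    n = system.n
    e_pair = 0.0
    if n > 1:
        dr = pos[None, :, :] - pos[:, None, :]
        dr = _min_image_dr(dr, system.box_xy, system.h, periodic_z)
        r = np.sqrt((dr ** 2).sum(axis=-1))
        iu, ju = np.triu_indices(n, k=1)
        rij = r[iu, ju]
        aij = table.a[system.species[iu], system.species[ju]]
        mask = rij < 1.0
        if exclude_bonded and len(system.bonds):
            bonded = _bonded_pair_set(system)
            nb_mask = np.array([(min(i, j), max(i, j)) not in bonded
                                for i, j in zip(iu, ju)])
            mask = mask & nb_mask
        e_pair = float(np.sum(0.5 * aij[mask] * (1.0 - rij[mask]) ** 2))
    e_bond = 0.0
    if len(system.bonds):
        dr = pos[system.bonds[:, 0]] - pos[system.bonds[:, 1]]
        dr = _min_image_dr(dr, system.box_xy, system.h, periodic_z)
        r = np.sqrt((dr ** 2).sum(axis=-1))
        e_bond = float(np.sum(0.5 * system.bond_kappa * (r - system.bond_r0) ** 2))
    e_ws = e_wt = 0.0
    if not periodic_z and n:
        z = pos[:, 2]
        e_ws = float(np.sum(wall_potential(z, table.a_wall_surface)))
        e_wt = float(np.sum(wall_potential(system.h - z, table.a_wall_tip)))
    return EnergyBreakdown(pair=e_pair, bond=e_bond,
                           wall_surface=e_ws, wall_tip=e_wt)


def _particle_energy(system: ParticleSystem, table: InteractionTable,
                     pos_i: np.ndarray, species_i: int, skip: int,
                     bonded_partners: Iterable[int] = (),
                     exclude_bonded: bool = False,
                     periodic_z: bool = False) -> float:
    """Interaction energy of one (possibly trial) particle with the rest:
    pair terms within the cutoff plus both wall terms. Bond terms excluded."""
    pos = system.positions
    e = 0.0
    if system.n:
        dr = pos - pos_i[None, :]
        dr = _min_image_dr(dr, system.box_xy, system.h, periodic_z)
        r = np.sqrt((dr ** 2).sum(axis=-1))
        mask = r < 1.0
        if skip >= 0:
            mask[skip] = False
        if exclude_bonded:
            for j in bonded_partners:
                mask[j] = False
        aij = table.a[species_i, system.species[mask]]
        e += float(np.sum(0.5 * aij * (1.0 - r[mask]) ** 2))
    if not periodic_z:
        e += float(wall_potential(pos_i[2], table.a_wall_surface))
        e += float(wall_potential(system.h - pos_i[2], table.a_wall_tip))
    return e


def _bond_energy_of(system: ParticleSystem, i: int,
                    pos_i: np.ndarray) -> float:
    e = 0.0
    for b, (p, q) in enumerate(system.bonds):
        if p == i or q == i:
            j = q if p == i else p
            dr = pos_i - system.positions[j]
            dr = _min_image_dr(dr.copy(), system.box_xy)
            r = float(np.sqrt((dr ** 2).sum()))
            e += 0.5 * system.bond_kappa[b] * (r - system.bond_r0[b]) ** 2
    return e


def _bond_partners_of(system: ParticleSystem, i: int) -> list[int]:
    out = []
    for p, q in system.bonds:
        if p == i:
            out.append(int(q))
        elif q == i:
            out.append(int(p))
    return out


def delta_energy(system: ParticleSystem, move, table: InteractionTable,
                 exclude_bonded: bool = False,
                 periodic_z: bool = False) -> float:
    """Energy change of a proposed move, computed incrementally from the
    neighborhood of the affected particle.

    Agrees with ``total_energy(after) - total_energy(before)`` to 1e-10.
    """
    if isinstance(move, Displacement):
        i = int(move.index)
        if system.graft[i] == GRAFT_SOLID:
            raise ContractViolation("graft_solid particles must never be moved")
        partners = _bond_partners_of(system, i)
        new = np.asarray(move.new_position, dtype=float)
        old = system.positions[i].copy()
        e_old = _particle_energy(system, table, old, int(system.species[i]), i,
                                 partners, exclude_bonded, periodic_z)
        e_old += _bond_energy_of(system, i, old)
        e_new = _particle_energy(system, table, new, int(system.species[i]), i,
                                 partners, exclude_bonded, periodic_z)
        e_new += _bond_energy_of(system, i, new)
        return e_new - e_old
    if isinstance(move, Insertion):
        p = np.asarray(move.position, dtype=float)
        return _particle_energy(system, table, p, int(move.species), -1,
                                (), exclude_bonded, periodic_z)
    if isinstance(move, Deletion):
        i = int(move.index)
        if system.species[i] != SOLVENT:
            raise ContractViolation("only solvent particles may be deleted")
        e = _particle_energy(system, table, system.positions[i].copy(),
                             int(system.species[i]), i, (), exclude_bonded,
                             periodic_z)
        return -e
    raise TypeError(f"unknown move type {type(move)!r}")


def apply_move(system: ParticleSystem, move) -> ParticleSystem:
    """Return a new system with the move applied (reference path, not fast)."""
    s = system.copy()
    if isinstance(move, Displacement):
        s.positions[move.index] = np.asarray(move.new_position, dtype=float)
        return s
    if isinstance(move, Insertion):
        s.positions = np.vstack([s.positions, np.asarray(move.position)[None, :]])
        s.species = np.append(s.species, move.species)
        s.graft = np.append(s.graft, GRAFT_FREE)
        s.chain_id = np.append(s.chain_id, -1)
        return s
    if isinstance(move, Deletion):
        keep = np.ones(s.n, dtype=bool)
        keep[move.index] = False
        if np.any((s.bonds == move.index)):
            raise ContractViolation("cannot delete a bonded particle")
        remap = np.cumsum(keep) - 1
        s.positions = s.positions[keep]
        s.species = s.species[keep]
        s.graft = s.graft[keep]
        s.chain_id = s.chain_id[keep]
        s.bonds = remap[s.bonds]
        return s
    raise TypeError(f"unknown move type {type(move)!r}")


# -- neighbor search ------------------------------------------------------

@dataclass
class CellList:
    """Lateral-periodic cell decomposition with cells of size >= 1 rc.

    Falls back to a single cell per dimension when fewer than three cells
    fit, which degenerates to the all-pairs enumeration in that dimension.
    """

    ncx: int
    ncy: int
    ncz: int
    box_xy: tuple[float, float]
    h: float
    cells: dict = field(default_factory=dict)

    def pairs(self, positions: np.ndarray) -> set[tuple[int, int]]:
        """Every unordered pair with minimum-image distance < 1 rc, exactly once."""
        out = set()
        Lx, Ly = self.box_xy
        for (cx, cy, cz), members in self.cells.items():
            neigh = []
            for dz in (-1, 0, 1):
                cz2 = cz + dz
                if cz2 < 0 or cz2 >= self.ncz:
                    continue
                for dy in ((0,) if self.ncy == 1 else (-1, 0, 1)):
                    cy2 = (cy + dy) % self.ncy
                    for dx in ((0,) if self.ncx == 1 else (-1, 0, 1)):
                        cx2 = (cx + dx) % self.ncx
                        neigh.append((cx2, cy2, cz2))
            cand = set()
            for c in neigh:
                cand.update(self.cells.get(c, ()))
            for i in members:
                for j in cand:
                    if j <= i:
                        continue
                    dr = positions[j] - positions[i]
                    dx = dr[0] - Lx * np.rint(dr[0] / Lx)
                    dy = dr[1] - Ly * np.rint(dr[1] / Ly)
                    dzz = dr[2]
                    if dx * dx + dy * dy + dzz * dzz < 1.0:
                        out.add((i, j))
        return out


def build_cell_list(system: ParticleSystem) -> CellList:
    """Assign particles to cells of edge >= 1 rc (periodic in x, y only)."""
    Lx, Ly = system.box_xy
    ncx = int(Lx) if int(Lx) >= 3 else 1
    ncy = int(Ly) if int(Ly) >= 3 else 1
    ncz = max(1, int(system.h))
    cl = CellList(ncx=ncx, ncy=ncy, ncz=ncz, box_xy=system.box_xy, h=system.h)
    for i, p in enumerate(system.positions):
        xr = p[0] % Lx
        yr = p[1] % Ly
        cx = min(int(xr * ncx / Lx), ncx - 1)
        cy = min(int(yr * ncy / Ly), ncy - 1)
        cz = min(max(int(p[2] * ncz / system.h), 0), ncz - 1)
        cl.cells.setdefault((cx, cy, cz), []).append(i)
    return cl


def all_pairs_within_cutoff(system: ParticleSystem) -> set[tuple[int, int]]:
    """O(n^2) oracle for the cell-list pair enumeration."""
    pos = system.positions
    n = system.n
    out = set()
    for i in range(n):
        dr = pos[i + 1:] - pos[i]
        dr = _min_image_dr(dr.copy(), system.box_xy)
        r2 = (dr ** 2).sum(axis=1)
        for k in np.flatnonzero(r2 < 1.0):
            out.add((i, i + 1 + int(k)))
    return out
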