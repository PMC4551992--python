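"""System construction and synthetic data.

Builds the preset brush/solvent systems (uniform "normal" brush; the
three-population brush with soft or stiff springs), a catalogue of
deterministic micro-fixtures with hand-computed energies, and synthetic
noisy theory force curves for exercising the fitting layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import (GRAFT_FREE, GRAFT_LIQUID, GRAFT_SOLID,
                         EnergyBreakdown, ParticleSystem)
from .model import (BrushArchitecture, ParameterError, SimulationParameters,
                    cancer_architecture, chain_counts, normal_architecture)

__all__ = [
    "FixtureSpec", "SyntheticCurveSpec",
    "build_system", "build_normal_system", "build_cancer_system",
    "make_micro_fixture", "micro_fixture_names", "synth_force_curve",
]

#: Initial bead spacing along a freshly built chain when r0 = 0.
INIT_BOND_SPACING = 0.5


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    description: str
    expected: EnergyBreakdown


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for a noisy multi-population theory force curve."""

    populations: list          # list of (L, Gamma) with Gamma in rc^-2
    h_grid: np.ndarray         # separations in rc, strictly increasing
    noise_sd: float = 0.0      # relative (multiplicative) Gaussian noise
    seed: int = 0

    def __post_init__(self):
        h = np.asarray(self.h_grid, dtype=float)
        if np.any(h <= 0):
            raise ParameterError(["all separations must be positive"])
        if np.any(np.diff(h) <= 0):
            raise ParameterError(["h_grid must be strictly increasing"])
        if self.noise_sd < 0:
            raise ParameterError(["noise_sd must be non-negative"])
        object.__setattr__(self, "h_grid", h)


# -- graft lattice --------------------------------------------------------

def _triangular_lattice(n_sites: int, box_xy) -> np.ndarray:
    """At least ``n_sites`` points of a triangular lattice filling the box."""
    Lx, Ly = box_xy
    aspect = Ly / Lx * 2.0 / math.sqrt(3.0)
    nx = max(1, int(math.ceil(math.sqrt(n_sites / aspect))))
    ny = max(1, int(math.ceil(n_sites / nx)))
    while nx * ny < n_sites:
        ny += 1
    pts = np.empty((nx * ny, 2))
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            x = (ix + 0.5 * (iy % 2)) * Lx / nx
            y = (iy + 0.5) * Ly / ny
            pts[k, 0] = x % Lx
            pts[k, 1] = y
            k += 1
    return pts


def build_system(params: SimulationParameters,
                 segregate_populations: bool = False) -> ParticleSystem:
    """Construct the brush + solvent system described by ``params``.

    Graft ends sit on a jittered triangular lattice at z = 0, one graft
    bead per chain (mobility per the architecture); chains point straight
    up with the initial bead spacing; solvent fills the remaining volume
    uniformly at the target density. Deterministic given ``params.seed``.
    """
    arch = params.architecture
    rng = np.random.default_rng(params.seed)
    counts = chain_counts(arch, params.area_nm2)
    n_chains = sum(counts)
    Lx, Ly = params.box_xy
    h = params.h

    sites = _triangular_lattice(n_chains, params.box_xy)
    jitter = rng.uniform(-0.1, 0.1, size=(len(sites), 2))
    sites = sites + jitter
    order = np.arange(len(sites)) if segregate_populations \
        else rng.permutation(len(sites))
    sites = sites[order][:n_chains]

    graft_flag = GRAFT_SOLID if arch.mobility == "solid" else GRAFT_LIQUID

    positions, species, graft, chain_id = [], [], [], []
    bonds, bond_kappa, bond_r0 = [], [], []
    chain = 0
    site_i = 0
    for p, (pop, cnt) in enumerate(zip(arch.populations, counts)):
        # start near the spring's thermal bond length so stiff chains do
        # not have to relax across a huge initial stretch, and keep the
        # initial chain top clear of the tip wall
        if params.bond_rest_length == 0:
            spacing = min(INIT_BOND_SPACING, 2.0 / math.sqrt(pop.kappa))
        else:
            spacing = params.bond_rest_length
        if pop.N > 1 and pop.N * spacing >= h:
            warnings.warn(
                f"population {p}: chains of {pop.N} beads do not fit below "
                f"the tip at spacing {spacing:g}; compressing initialization",
                stacklevel=2)
        spacing = min(spacing, 0.8 * h / pop.N)
        for _c in range(cnt):
            x0, y0 = sites[site_i]
            site_i += 1
            base = len(positions)
            for k in range(pop.N):
                positions.append((x0, y0, min(k * spacing, h)))
                species.append(p + 1)
                graft.append(graft_flag if k == 0 else GRAFT_FREE)
                chain_id.append(chain)
                if k > 0:
                    bonds.append((base + k - 1, base + k))
                    bond_kappa.append(pop.kappa)
                    bond_r0.append(params.bond_rest_length)
            chain += 1
    n_brush = len(positions)

    n_solvent = max(0, int(round(params.target_density * Lx * Ly * h)) - n_brush)
    sp = rng.random((n_solvent, 3))
    sp[:, 0] *= Lx
    sp[:, 1] *= Ly
    sp[:, 2] *= h
    positions = np.asarray(positions + [tuple(q) for q in sp], dtype=float)
    species = np.asarray(species + [0] * n_solvent, dtype=np.int64)
    graft = np.asarray(graft + [GRAFT_FREE] * n_solvent, dtype=np.int64)
    chain_id = np.asarray(chain_id + [-1] * n_solvent, dtype=np.int64)

    system = ParticleSystem(
        positions=positions, species=species,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_kappa=np.asarray(bond_kappa), bond_r0=np.asarray(bond_r0),
        graft=graft, chain_id=chain_id, box_xy=params.box_xy, h=h,
    )
    return system.validate(arch, params.area_nm2)


def build_normal_system(params: SimulationParameters) -> ParticleSystem:
    """Uniform-brush preset (16 chains of N = 27 at the default area)."""
    if params.architecture.n_populations != 1:
        params = params.replace(
            architecture=normal_architecture(params.architecture.mobility),
            interactions=None)
        params.__post_init__()
    return build_system(params)


def build_cancer_system(params: SimulationParameters,
                        stiffness: str = "soft") -> ParticleSystem:
    """Three-population preset (36/10/4 chains of N = 5/30/42), with soft
    (kappa = 100) or stiff (kappa = 2000) springs on every bond."""
    arch = cancer_architecture(stiffness=stiffness,
                               mobility=params.architecture.mobility)
    params = params.replace(architecture=arch, interactions=None)
    params.__post_init__()
    return build_system(params)


# -- micro-fixtures with hand-computed energies ---------------------------

def _fixture_system(positions, species, bonds=(), kappa=(), r0=(),
                    box_xy=(7.0, 7.0), h=10.0):
    n = len(positions)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    chain_id = np.full(n, -1, dtype=np.int64)
    # assign chain ids along bonded runs so topology checks pass
    if len(bonds):
        cid = 0
        seen = {}
        for i, j in bonds:
            c = seen.get(i, seen.get(j))
            if c is None:
                c = cid
                cid += 1
            seen[i] = seen[j] = c
        for i, c in seen.items():
            chain_id[i] = c
    return ParticleSystem(
        positions=np.asarray(positions, dtype=float),
        species=np.asarray(species, dtype=np.int64),
        bonds=bonds, bond_kappa=np.asarray(kappa, dtype=float),
        bond_r0=np.asarray(r0, dtype=float),
        graft=np.zeros(n, dtype=np.int64), chain_id=chain_id,
        box_xy=box_xy, h=h)


def _micro_catalogue() -> dict:
    cat = {}

    # two solvent beads 0.5 rc apart, far from both walls (a = 25)
    cat["single-pair"] = (
        "two solvent beads at r = 0.5 rc mid-box; pair term only",
        _fixture_system([(2.0, 2.0, 5.0), (2.5, 2.0, 5.0)], [0, 0]),
        # U = (25/2)(1 - 0.5)^2 = 3.125
        EnergyBreakdown(pair=3.125, bond=0.0, wall_surface=0.0, wall_tip=0.0),
    )

    # one bead touching the lower wall (gap 0, a_w = 25)
    cat["wall-contact"] = (
        "single bead at z = 0; surface-wall contact value a_w/2",
        _fixture_system([(3.0, 3.0, 0.0)], [0]),
        EnergyBreakdown(pair=0.0, bond=0.0, wall_surface=12.5, wall_tip=0.0),
    )

    # 3-bead chain, consecutive spacing 0.1 rc from r0 = 0, kappa = 100
    # bonds: 2 x (100/2)(0.1)^2 = 1.0
    # pairs (a = 25, bonded pairs not excluded):
    #   r=0.1 twice: 2 x 12.5 x 0.81 = 20.25 ; r=0.2 once: 12.5 x 0.64 = 8.0
    cat["single-chain-3"] = (
        "three-bead chain spaced 0.1 rc, kappa = 100, mid-box",
        _fixture_system([(3.0, 3.0, 5.0), (3.1, 3.0, 5.0), (3.2, 3.0, 5.0)],
                        [1, 1, 1], bonds=[(0, 1), (1, 2)],
                        kappa=[100.0, 100.0], r0=[0.0, 0.0]),
        EnergyBreakdown(pair=20.25 + 8.0, bond=1.0,
                        wall_surface=0.0, wall_tip=0.0),
    )

    # pair straddling the periodic x boundary: x = 0.05 and 6.75, Lx = 7
    # minimum-image distance 0.3 rc -> U = 12.5 x 0.49 = 6.125
    cat["cross-boundary-pair"] = (
        "two beads separated by 0.3 rc across the periodic x boundary",
        _fixture_system([(0.05, 3.0, 5.0), (6.75, 3.0, 5.0)], [0, 0]),
        EnergyBreakdown(pair=6.125, bond=0.0, wall_surface=0.0, wall_tip=0.0),
    )

    # two interdigitated 2-bead chains on a line, alternating spacing 0.25 rc
    # beads A0 x=3.00, B0 x=3.25, A1 x=3.50, B1 x=3.75 (all same y, z)
    # bonds: A0-A1 r=0.5, B0-B1 r=0.5, kappa=100, r0=0 -> 2 x 12.5 = 25.0
    # pairs within cutoff (a = 25): distances 0.25 x3, 0.50 x2, 0.75 x1
    #   3 x 12.5(0.75)^2 = 21.09375 ; 2 x 12.5(0.5)^2 = 6.25
    #   1 x 12.5(0.25)^2 = 0.78125  -> pair total 28.125
    cat["two-chain-interdigitated"] = (
        "two 2-bead chains interleaved on a line at 0.25 rc spacing",
        _fixture_system([(3.0, 3.0, 5.0), (3.25, 3.0, 5.0),
                         (3.5, 3.0, 5.0), (3.75, 3.0, 5.0)],
                        [1, 1, 1, 1], bonds=[(0, 2), (1, 3)],
                        kappa=[100.0, 100.0], r0=[0.0, 0.0]),
        EnergyBreakdown(pair=28.125, bond=25.0,
                        wall_surface=0.0, wall_tip=0.0),
    )
    return cat


def micro_fixture_names() -> list[str]:
    return sorted(_micro_catalogue())


def make_micro_fixture(name: str) -> tuple[FixtureSpec, ParticleSystem]:
    """Return a deterministic micro-fixture and its hand-computed energy."""
    cat = _micro_catalogue()
    if name not in cat:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(cat)}")
    desc, system, expected = cat[name]
    return FixtureSpec(name=name, description=desc, expected=expected), system


# -- synthetic force curves -----------------------------------------------

def synth_force_curve(spec: SyntheticCurveSpec) -> pd.DataFrame:
    """Noisy multi-population Alexander-de Gennes F/R curve on a grid.

    Noise is multiplicative Gaussian with relative standard deviation
    ``noise_sd``, seeded. The noiseless truth and the generating
    populations are attached in ``DataFrame.attrs``.
    """
    from .theory import BrushPopulationTheory, multi_brush_force

    pops = [BrushPopulationTheory(L=float(L), s=float(g) ** -0.5)
            for L, g in spec.populations]
    h = spec.h_grid
    truth = multi_brush_force(h, pops)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=h.shape) if spec.noise_sd \
        else np.zeros_like(h)
    f = truth * (1.0 + noise)
    df = pd.DataFrame({"h": h, "F_over_R": f})
    df.attrs["truth"] = truth
    df.attrs["populations"] = [(float(L), float(g)) for L, g in spec.populations]
    df.attrs["noise_sd"] = spec.noise_sd
    df.attrs["seed"] = spec.seed
    return df
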