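"""Grand-canonical Metropolis Monte Carlo driver.

Wraps the numba kernel with the user-facing state (:class:`ParticleSystem`),
run scheduling, move statistics, and activity calibration against a target
bulk solvent density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .energetics import (GRAFT_LIQUID, GRAFT_SOLID, SOLVENT, ParticleSystem)
from .model import ParameterError, SimulationParameters

__all__ = [
    "RunSchedule", "MoveStatistics", "RunResult", "CalibrationResult",
    "run_chain", "calibrate_activity", "widom_excess_mu",
]


@dataclass(frozen=True)
class RunSchedule:
    """Sweep counts and move mix for one chain.

    A sweep is one attempted displacement per mobile particle followed by
    insertion/deletion attempts numbering ``gc_fraction`` of the current
    solvent count (insert and delete proposed with equal probability 1/2,
    a symmetric proposal). ``displacement_attempts`` / ``gc_attempts``
    override the per-sweep counts when set.
    """

    n_equilibration: int = 200
    n_production: int = 500
    sample_interval: int = 5
    seed: int = 0
    gc_fraction: float = 0.1
    displacement_attempts: int | None = None
    gc_attempts: int | None = None
    tune_displacement: bool = True
    store_frames: bool = False
    widom_per_sample: int = 0

    def __post_init__(self):
        if self.n_equilibration < 0 or self.n_production < 0:
            raise ParameterError(["sweep counts must be non-negative"])
        if self.sample_interval < 1:
            raise ParameterError(["sample_interval must be >= 1"])
        if not (0.0 <= self.gc_fraction):
            raise ParameterError(["gc_fraction must be non-negative"])

    @property
    def move_mix(self) -> tuple[float, float, float]:
        """(p_displacement, p_insertion, p_deletion) implied by the sweep
        recipe; insertion and deletion are equal by construction and the
        three sum to one."""
        d = 1.0
        g = self.gc_fraction
        tot = d + g
        return (d / tot, 0.5 * g / tot, 0.5 * g / tot)

    @property
    def n_samples(self) -> int:
        return self.n_production // self.sample_interval


@dataclass(frozen=True)
class MoveStatistics:
    attempted: dict
    accepted: dict

    @property
    def acceptance(self) -> dict:
        return {k: (self.accepted[k] / self.attempted[k]
                    if self.attempted[k] else math.nan)
                for k in self.attempted}

    @classmethod
    def from_kernel(cls, stats: np.ndarray) -> "MoveStatistics":
        names = ["displace_free", "displace_graft_liquid", "insert", "delete"]
        return cls(attempted={n: int(stats[i, 0]) for i, n in enumerate(names)},
                   accepted={n: int(stats[i, 1]) for i, n in enumerate(names)})


@dataclass
class RunResult:
    """Everything sampled from one chain."""

    samples: pd.DataFrame           # sweep, n_solvent, energy, tip_force
    hist: np.ndarray                # (n_species, nbins) accumulated counts
    bin_width: float
    graft_trace: np.ndarray         # (n_samples, n_graft, 2) unwrapped xy
    graft_index: np.ndarray         # particle index of each graft bead
    graft_chain: np.ndarray         # chain id of each graft bead
    final_system: ParticleSystem
    stats: MoveStatistics
    schedule: RunSchedule
    h: float
    box_xy: tuple[float, float]
    seed: int
    max_displacement_final: np.ndarray  # tuned per species class
    widom_mean: float               # <exp(-dU)> over test insertions (nan if off)
    frames: list | None = None      # optional list of (n, 3) position arrays
    config: dict = field(default_factory=dict)

    @property
    def area(self) -> float:
        return self.box_xy[0] * self.box_xy[1]

    @property
    def mean_density(self) -> float:
        """Mean solvent number density over the accessible volume."""
        v = self.area * self.h
        return float(self.samples["n_solvent"].mean()) / v


def _adjacency(system: ParticleSystem, capacity: int):
    bnb = np.full((capacity, 2), -1, dtype=np.int64)
    bkap = np.zeros((capacity, 2), dtype=np.float64)
    br0 = np.zeros((capacity, 2), dtype=np.float64)
    bdeg = np.zeros(capacity, dtype=np.int64)
    for b, (i, j) in enumerate(system.bonds):
        for p, q in ((i, j), (j, i)):
            k = bdeg[p]
            if k >= 2:
                raise ParameterError([f"particle {p} has more than two bonds"])
            bnb[p, k] = q
            bkap[p, k] = system.bond_kappa[b]
            br0[p, k] = system.bond_r0[b]
            bdeg[p] = k + 1
    return bnb, bkap, br0, bdeg


def run_chain(system: ParticleSystem, schedule: RunSchedule,
              params: SimulationParameters,
              periodic_z: bool = False) -> RunResult:
    """Run one grand-canonical Metropolis chain. Deterministic per seed.

    The input system is not modified; brush beads must precede solvent in
    the particle ordering (the builder guarantees this).
    """
    n_brush = system.n_brush
    if n_brush and np.any(system.species[:n_brush] == SOLVENT):
        raise ParameterError(["brush beads must precede solvent particles"])
    n0 = system.n
    volume = system.box_xy[0] * system.box_xy[1] * system.h
    expected = params.target_density * volume
    capacity = int(max(n0 + 64, n_brush + 2.0 * expected + 256))

    pos = np.zeros((capacity, 3), dtype=np.float64)
    pos[:n0] = system.positions
    species = np.zeros(capacity, dtype=np.int64)
    species[:n0] = system.species
    graft = np.zeros(capacity, dtype=np.int64)
    graft[:n0] = system.graft
    bnb, bkap, br0, bdeg = _adjacency(system, capacity)

    mobile_brush = np.flatnonzero(
        (np.arange(n0) < n_brush) & (system.graft != GRAFT_SOLID)
    ).astype(np.int64)

    # per-class displacement amplitudes: stiff-bonded beads need smaller
    # trial steps than the solvent or they freeze at high rejection
    n_species = params.interactions.a.shape[0]
    max_disp0 = np.full(n_species, float(params.max_displacement))
    for p, pop in enumerate(params.architecture.populations):
        if p + 1 < n_species:
            max_disp0[p + 1] = min(params.max_displacement,
                                   1.5 / math.sqrt(pop.kappa))
    graft_idx = np.flatnonzero(system.graft != 0).astype(np.int64)
    graft_chain = system.chain_id[graft_idx].copy()

    out = _kernels.run_mc_kernel(
        pos, species, graft, bnb, bkap, br0, bdeg,
        mobile_brush, graft_idx,
        n_brush, n0,
        params.interactions.a, params.interactions.a_wall_surface,
        params.interactions.a_wall_tip,
        float(system.box_xy[0]), float(system.box_xy[1]), float(system.h),
        periodic_z,
        float(params.activity), max_disp0,
        schedule.tune_displacement,
        schedule.n_equilibration, schedule.n_production,
        schedule.sample_interval,
        -1 if schedule.displacement_attempts is None
        else int(schedule.displacement_attempts),
        -1 if schedule.gc_attempts is None else int(schedule.gc_attempts),
        float(schedule.gc_fraction),
        max(1, int(schedule.gc_fraction * params.target_density * volume)),
        params.exclude_bonded_pairs,
        max(1, int(math.ceil(system.h / params.bin_width))),
        float(params.bin_width),
        int(schedule.widom_per_sample),
        schedule.store_frames, int(schedule.seed),
    )
    (samp_sweep, samp_nsolv, samp_energy, samp_tip, hist, graft_xy,
     frames, frames_n, stats, n_final, max_disp, widom_sum, widom_cnt,
     overflow) = out
    if overflow:
        raise RuntimeError(
            "particle capacity or cell occupancy exceeded during the run; "
            "increase capacity margins or check the activity"
        )

    final = ParticleSystem(
        positions=pos[:n_final].copy(),
        species=species[:n_final].copy(),
        bonds=system.bonds.copy(), bond_kappa=system.bond_kappa.copy(),
        bond_r0=system.bond_r0.copy(),
        graft=graft[:n_final].copy(),
        chain_id=np.concatenate([system.chain_id[:n_brush],
                                 np.full(n_final - n_brush, -1, dtype=np.int64)]),
        box_xy=system.box_xy, h=system.h,
    )
    samples = pd.DataFrame({
        "sweep": samp_sweep, "n_solvent": samp_nsolv,
        "energy": samp_energy, "tip_force": samp_tip,
    })
    frame_list = None
    if schedule.store_frames:
        frame_list = [frames[i, :frames_n[i]].copy()
                      for i in range(len(frames_n))]
    return RunResult(
        samples=samples, hist=np.asarray(hist), bin_width=params.bin_width,
        graft_trace=np.asarray(graft_xy), graft_index=graft_idx,
        graft_chain=graft_chain, final_system=final,
        stats=MoveStatistics.from_kernel(np.asarray(stats)),
        schedule=schedule, h=float(system.h), box_xy=system.box_xy,
        seed=int(schedule.seed), max_displacement_final=np.asarray(max_disp),
        widom_mean=(widom_sum / widom_cnt if widom_cnt else math.nan),
        frames=frame_list, config=params.to_dict(),
    )


# -- activity calibration -------------------------------------------------

@dataclass
class CalibrationResult:
    activity: float
    target_density: float
    achieved_density: float
    trace: list  # list of (activity, measured density)

    @property
    def mu_excess(self) -> float:
        """Excess chemical potential implied by z = rho * exp(beta mu_ex)."""
        return math.log(self.activity / self.achieved_density)


class CalibrationError(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


def _uniform_solvent_box(n, box, rng):
    p = rng.random((n, 3))
    p[:, 0] *= box[0]
    p[:, 1] *= box[1]
    p[:, 2] *= box[2]
    return ParticleSystem.solvent_only(p, (box[0], box[1]), box[2])


def widom_excess_mu(params: SimulationParameters, density: float,
                    box=(5.0, 5.0, 5.0), seed: int = 0,
                    n_sweeps: int = 400, widom_per_sample: int = 50) -> float:
    """Widom test-particle estimate of the solvent excess chemical potential
    at the given density, from a canonical (no insert/delete) periodic run."""
    rng = np.random.default_rng(seed)
    n = int(round(density * box[0] * box[1] * box[2]))
    system = _uniform_solvent_box(n, box, rng)
    sched = RunSchedule(n_equilibration=n_sweeps // 2, n_production=n_sweeps,
                        sample_interval=5, seed=seed, gc_attempts=0,
                        widom_per_sample=widom_per_sample)
    res = run_chain(system, sched, params, periodic_z=True)
    if not (res.widom_mean > 0):
        raise CalibrationError("Widom estimate degenerate (no accepted overlap)",
                               [])
    return -math.log(res.widom_mean)


def _measure_density(activity, params, box, seed, n_sweeps):
    rng = np.random.default_rng(seed)
    n = int(round(params.target_density * box[0] * box[1] * box[2]))
    system = _uniform_solvent_box(max(n, 1), box, rng)
    p = params.replace(activity=float(activity))
    sched = RunSchedule(n_equilibration=max(50, n_sweeps // 3),
                        n_production=n_sweeps, sample_interval=5, seed=seed)
    res = run_chain(system, sched, p, periodic_z=True)
    return res.mean_density


def calibrate_activity(target_density: float, params: SimulationParameters,
                       box=(5.0, 5.0, 5.0), seed: int = 0,
                       tol: float = 0.01, max_iter: int = 12,
                       n_sweeps: int = 600) -> CalibrationResult:
    """Find the solvent activity that yields the target bulk density.

    Brush-free, fully periodic GCMC runs; secant iteration on log(z) vs
    log(rho), started from a Widom test-particle estimate. The ideal gas
    (all amplitudes zero) short-circuits to z = rho exactly.
    """
    if target_density < 0:
        raise ParameterError(["target density must be non-negative"])
    if target_density == 0:
        return CalibrationResult(0.0, 0.0, 0.0, [])
    a_ss = float(params.interactions.a[SOLVENT, SOLVENT])
    if a_ss == 0.0:
        return CalibrationResult(target_density, target_density,
                                 target_density, [])
    p = params.replace(target_density=float(target_density))
    trace: list[tuple[float, float]] = []

    mu_ex = widom_excess_mu(p, target_density, box=box, seed=seed)
    z = target_density * math.exp(mu_ex)
    lnz = math.log(z)
    rho = _measure_density(math.exp(lnz), p, box, seed + 1, n_sweeps)
    trace.append((math.exp(lnz), rho))
    if abs(rho - target_density) / target_density <= tol:
        return CalibrationResult(math.exp(lnz), target_density, rho, trace)

    # second point for the secant, stepped against the observed error
    lnz_prev, rho_prev = lnz, rho
    lnz = lnz + 3.0 * (math.log(target_density) - math.log(rho))
    for it in range(max_iter):
        rho = _measure_density(math.exp(lnz), p, box, seed + 2 + it, n_sweeps)
        trace.append((math.exp(lnz), rho))
        if abs(rho - target_density) / target_density <= tol:
            return CalibrationResult(math.exp(lnz), target_density, rho, trace)
        d = math.log(rho) - math.log(rho_prev)
        if abs(d) < 1e-12:
            lnz_new = lnz + 1.0 * (math.log(target_density) - math.log(rho))
        else:
            slope = (lnz - lnz_prev) / d
            lnz_new = lnz + slope * (math.log(target_density) - math.log(rho))
        lnz_prev, rho_prev = lnz, rho
        lnz = lnz_new
    raise CalibrationError(
        f"activity calibration did not converge to {tol:.1%} in "
        f"{max_iter} iterations", trace)
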