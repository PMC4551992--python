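"""Observables computed from runs: tip force, force-distance profiles,
Derjaguin transform, density profiles, brush height, graft meandering and
solvent penetration.

Force-profile conventions
-------------------------
The instantaneous force on the tip wall includes the contribution of the
bulk solvent pressing on the wall, which does not vanish at large
separation. Reported profiles therefore carry both the raw wall pressure
and a net (baseline-subtracted) pressure, the baseline being the value at
the largest separation of the sweep (assumed uncompressed); the Derjaguin
transform integrates the net pressure. Uncertainties are standard errors
from block averaging (10 blocks by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import GRAFT_SOLID, SOLVENT, ParticleSystem
from .gcmc import RunResult

__all__ = [
    "ForceProfile", "DensityProfile", "MeanderTrace", "BrushHeight",
    "tip_force", "block_average", "force_profile", "derjaguin_transform",
    "density_profile", "brush_height", "graft_trace", "solvent_penetration",
    "normalize_profile",
]


# -- instantaneous tip force ----------------------------------------------

def tip_force(system: ParticleSystem, a_wall_tip: float = 25.0) -> float:
    """Force on the tip wall: sum of a_w (1 - gap) over particles within
    1 rc of the plane at z = h (the wall-normal derivative of the soft
    wall potential). Non-negative."""
    gap = system.h - system.positions[:, 2]
    mask = gap < 1.0
    return float(np.sum(a_wall_tip * (1.0 - gap[mask])))


def block_average(x: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and standard error of the mean from block averaging."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("block averaging requires at least 2 samples")
    nb = min(n_blocks, x.size)
    blocks = np.array_split(x, nb)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / math.sqrt(nb) if nb > 1 else 0.0
    return float(x.mean()), float(se)


# -- force-distance profile -----------------------------------------------

@dataclass
class ForceProfile:
    """Mean tip force versus tip-surface separation."""

    h: np.ndarray                 # separations in rc, strictly increasing
    h_nm: np.ndarray
    pressure: np.ndarray          # raw mean wall force per area, kBT/rc^3
    pressure_se: np.ndarray
    force: np.ndarray             # raw mean total wall force, kBT/rc
    force_se: np.ndarray
    net_pressure: np.ndarray      # baseline-subtracted pressure
    baseline: float               # pressure at the largest separation
    n_samples: np.ndarray
    area: float                   # lateral box area, rc^2
    f_over_r: np.ndarray | None = None   # Derjaguin transform, kBT/rc^2
    meta: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        d = {"h_rc": self.h, "h_nm": self.h_nm,
             "pressure_kBT_rc3": self.pressure,
             "pressure_se_kBT_rc3": self.pressure_se,
             "net_pressure_kBT_rc3": self.net_pressure,
             "force_kBT_rc": self.force, "force_se_kBT_rc": self.force_se,
             "n_samples": self.n_samples}
        if self.f_over_r is not None:
            d["F_over_R_kBT_rc2"] = self.f_over_r
        return pd.DataFrame(d)


def force_profile(runs: list[RunResult], rc_nm: float = 0.646,
                  n_blocks: int = 10, baseline: str = "tail") -> ForceProfile:
    """Aggregate per-separation runs into a force-distance profile.

    ``runs`` must hold >= 2 distinct separations, each with >= 2 samples.
    ``baseline='tail'`` subtracts the raw pressure measured at the largest
    separation; ``baseline='none'`` keeps the raw values.
    """
    if len(runs) < 2:
        raise ValueError("force profile needs runs at >= 2 separations")
    runs = sorted(runs, key=lambda r: r.h)
    hs, p, pse, f, fse, ns = [], [], [], [], [], []
    for r in runs:
        x = r.samples["tip_force"].to_numpy()
        if x.size < 2:
            raise ValueError(
                f"run at h={r.h:g} has {x.size} samples; need >= 2 for an "
                "uncertainty estimate")
        m, se = block_average(x, n_blocks)
        hs.append(r.h)
        f.append(m)
        fse.append(se)
        p.append(m / r.area)
        pse.append(se / r.area)
        ns.append(x.size)
    hs = np.asarray(hs)
    p = np.asarray(p)
    base = float(p[-1]) if baseline == "tail" else 0.0
    return ForceProfile(
        h=hs, h_nm=hs * rc_nm, pressure=p, pressure_se=np.asarray(pse),
        force=np.asarray(f), force_se=np.asarray(fse),
        net_pressure=p - base, baseline=base,
        n_samples=np.asarray(ns, dtype=int), area=runs[0].area,
        meta={"n_blocks": n_blocks, "baseline": baseline,
              "seeds": [r.seed for r in runs]},
    )


def derjaguin_transform(profile, R: float | None = None) -> np.ndarray:
    """Derjaguin sphere force F(h)/R = 2 pi * int_h^{hmax} P(u) du.

    Accepts a :class:`ForceProfile` (integrates the net pressure on its
    own grid, trapezoid rule, stores the result on the profile) or a pair
    of arrays ``(h, P)``. ``R`` is unused in reduced units and retained
    for call-site clarity. Warns when the grid does not reach a
    zero-force tail and attaches a truncation bound.
    """
    if isinstance(profile, ForceProfile):
        h, pnet = profile.h, profile.net_pressure
    else:
        h, pnet = (np.asarray(v, dtype=float) for v in profile)
    if h.size < 2:
        raise ValueError("Derjaguin transform needs >= 2 grid points")
    # cumulative trapezoid from the far end toward contact
    seg = 0.5 * (pnet[1:] + pnet[:-1]) * np.diff(h)
    tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    fr = 2.0 * math.pi * tail
    p_end = abs(pnet[-1])
    if isinstance(profile, ForceProfile):
        scale = max(abs(pnet).max(), 1e-300)
        if p_end > 0.05 * scale:
            bound = 2.0 * math.pi * p_end * (h[-1] - h[0])
            profile.meta["truncation_bound"] = float(bound)
            warnings.warn(
                "force grid does not reach a zero-force tail; Derjaguin "
                f"transform truncated (bound {bound:.3g} kBT/rc^2)",
                stacklevel=2)
        profile.f_over_r = fr
    return fr


def normalize_profile(h: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each axis by its maximum (the overlay normalization)."""
    h = np.asarray(h, dtype=float)
    f = np.asarray(f, dtype=float)
    if h.max() <= 0 or f.max() <= 0:
        raise ValueError("normalization requires positive maxima on both axes")
    return h / h.max(), f / f.max()


# -- density profiles -----------------------------------------------------

@dataclass
class DensityProfile:
    z: np.ndarray                  # bin centers, rc
    rho_solvent: np.ndarray        # rc^-3
    rho_brush: np.ndarray          # all brush populations summed, rc^-3
    rho_per_population: np.ndarray  # (n_pops, nbins)
    bin_width: float
    h: float
    area: float
    n_samples: int

    def as_frame(self) -> pd.DataFrame:
        d = {"z_rc": self.z, "rho_solvent": self.rho_solvent,
             "rho_brush": self.rho_brush}
        for p in range(self.rho_per_population.shape[0]):
            d[f"rho_brush_pop{p + 1}"] = self.rho_per_population[p]
        return pd.DataFrame(d)


def density_profile(run: RunResult, bin_width: float | None = None) -> DensityProfile:
    """z-binned number densities from the accumulated run histograms."""
    if bin_width is None:
        bin_width = run.bin_width
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not math.isclose(bin_width, run.bin_width):
        raise ValueError(
            "bin width is fixed at run time; re-run with the desired width")
    n_samples = len(run.samples)
    if n_samples < 10:
        raise ValueError("density profile needs >= 10 samples")
    hist = run.hist
    nbins = hist.shape[1]
    z = (np.arange(nbins) + 0.5) * bin_width
    norm = n_samples * run.area * bin_width
    rho = hist / norm
    return DensityProfile(
        z=z, rho_solvent=rho[SOLVENT],
        rho_brush=rho[1:].sum(axis=0), rho_per_population=rho[1:],
        bin_width=bin_width, h=run.h, area=run.area, n_samples=n_samples)


@dataclass
class BrushHeight:
    L_cumulative: float   # z below which 98% of the brush beads sit
    L_moment: float       # first-moment estimator 2 <z>

    def __iter__(self):
        return iter((self.L_cumulative, self.L_moment))


def brush_height(profile: DensityProfile, quantile: float = 0.98) -> BrushHeight:
    """Uncompressed brush length from the brush density profile.

    Primary estimator: the z at which the cumulative brush density reaches
    ``quantile`` of its total (linearly interpolated inside the bin).
    Secondary: 2 <z>, exact for an ideal step profile.
    """
    rho = profile.rho_brush
    total = rho.sum()
    if total <= 0:
        raise ValueError("empty brush profile")
    cum = np.cumsum(rho)
    target = quantile * total
    i = int(np.searchsorted(cum, target))
    below = cum[i - 1] if i > 0 else 0.0
    frac = (target - below) / rho[i] if rho[i] > 0 else 0.0
    L98 = (i + frac) * profile.bin_width
    zmean = float((profile.z * rho).sum() / total)
    return BrushHeight(L_cumulative=float(L98), L_moment=2.0 * zmean)


# -- graft meandering -----------------------------------------------------

@dataclass
class MeanderTrace:
    xy: np.ndarray           # (n_samples, 2) unwrapped graft positions
    sample_interval: int
    chain_id: int

    @property
    def n_samples(self) -> int:
        return self.xy.shape[0]

    def msd(self) -> np.ndarray:
        """Mean-square displacement versus lag (in samples)."""
        xy = self.xy
        n = xy.shape[0]
        out = np.zeros(n)
        for lag in range(1, n):
            d = xy[lag:] - xy[:-lag]
            out[lag] = float((d ** 2).sum(axis=1).mean())
        return out


def graft_trace(run: RunResult, chain_id: int) -> MeanderTrace:
    """Sampled xy positions of one chain's graft bead (already unwrapped)."""
    where = np.flatnonzero(run.graft_chain == chain_id)
    if where.size != 1:
        raise KeyError(f"chain {chain_id} not found among grafted chains")
    g = int(where[0])
    return MeanderTrace(xy=run.graft_trace[:, g, :].copy(),
                        sample_interval=run.schedule.sample_interval,
                        chain_id=chain_id)


# -- solvent penetration --------------------------------------------------

def solvent_penetration(profile: DensityProfile,
                        window: tuple[float, float]) -> float:
    """Mean number of solvent particles inside a z-interval:
    area * integral of rho_solvent over the window (partial bins weighted)."""
    lo, hi = float(window[0]), float(window[1])
    if not (hi > lo):
        raise ValueError("window must have positive length")
    if lo < 0 or hi > profile.h + 1e-9:
        raise ValueError("window must lie within [0, h]")
    edges = np.arange(profile.z.size + 1) * profile.bin_width
    overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo),
                      0.0, None)
    return float(profile.area * np.sum(profile.rho_solvent * overlap))
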