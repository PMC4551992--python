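"""Experiment orchestration: h sweeps, observable aggregation, theory fits
and condition contrasts."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import observables
from .builder import build_system
from .gcmc import RunResult, RunSchedule, run_chain
from .model import (H_MAX_NM, H_MIN_NM, SimulationParameters, load_config,
                    params_from_config, validate_parameters)
from .observables import (DensityProfile, ForceProfile, density_profile,
                          derjaguin_transform, force_profile)
from .theory import AdGFitResult, fit_force_profile

log = logging.getLogger("brushsim")

__all__ = ["ExperimentBundle", "default_h_grid", "run_sweep",
           "run_experiment", "compare_conditions"]


def default_h_grid(params: SimulationParameters, n: int = 8) -> np.ndarray:
    """Geometric grid of separations spanning 2.8-17.5 nm, in rc."""
    lo = params.units.to_reduced(H_MIN_NM)
    hi = params.units.to_reduced(H_MAX_NM)
    return np.geomspace(lo, hi, n)


@dataclass
class ExperimentBundle:
    """All artifacts of one h-sweep experiment, traceable to (config, seed)."""

    config: dict
    h_grid: np.ndarray
    runs: list                      # RunResult per h
    profile: ForceProfile
    density: DensityProfile         # at the largest separation
    fit: AdGFitResult | None
    seed: int
    label: str = ""

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps({"config": self.config, "seed": self.seed,
                        "label": self.label,
                        "h_grid": self.h_grid.tolist()}, indent=2))
        self.profile.as_frame().to_csv(outdir / "force_profile.tsv",
                                       sep="\t", index=False)
        self.density.as_frame().to_csv(outdir / "density_profile.tsv",
                                       sep="\t", index=False)
        clipped = np.maximum(self.profile.net_pressure, 0.0)
        if clipped.max() > 0:  # flat curves have no overlay normalization
            hn, fn = observables.normalize_profile(self.profile.h, clipped)
            pd.DataFrame({"h_norm": hn, "F_norm": fn}).to_csv(
                outdir / "force_profile_normalized.tsv", sep="\t", index=False)
        if self.fit is not None:
            (outdir / "adg_fit.json").write_text(
                json.dumps(self.fit.to_dict(), indent=2))
        obs = pd.concat(
            [r.samples.assign(h=r.h, seed=r.seed) for r in self.runs],
            ignore_index=True)
        obs.to_csv(outdir / "observables.tsv", sep="\t", index=False)


def run_sweep(params: SimulationParameters, h_grid, seed: int | None = None,
              schedule: RunSchedule | None = None) -> list[RunResult]:
    """Run one chain per separation; the same seed is used at every h so
    matched-seed contrasts share their random streams."""
    seed = params.seed if seed is None else seed
    runs = []
    for h in np.asarray(h_grid, dtype=float):
        p = params.replace(h=float(h), seed=seed)
        validate_parameters(p)
        system = build_system(p)
        sched = schedule or RunSchedule(
            n_equilibration=p.n_equilibration, n_production=p.n_production,
            sample_interval=p.sample_interval, seed=seed)
        if schedule is not None and schedule.seed != seed:
            sched = dataclasses.replace(schedule, seed=seed)
        log.info("run: h=%.3f rc, seed=%d, n=%d particles",
                 h, seed, system.n)
        runs.append(run_chain(system, sched, p))
    return runs


def run_experiment(config, outdir=None, seed: int | None = None,
                   label: str = "") -> ExperimentBundle:
    """Full study for one condition: build, sweep h, aggregate, fit.

    ``config`` is a path to a TOML/JSON file or a mapping; see
    :func:`brushsim.model.params_from_config` for the schema. Extra keys
    ``h_grid`` (list, rc) and ``n_h`` control the sweep grid.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = dict(config)
    params = params_from_config(cfg)
    if seed is not None:
        params = params.replace(seed=int(seed))
    h_grid = np.asarray(cfg.get("h_grid", ()), dtype=float)
    if h_grid.size == 0:
        h_grid = default_h_grid(params, int(cfg.get("n_h", 8)))

    runs = run_sweep(params, h_grid)
    profile = force_profile(runs, rc_nm=params.units.rc_nm)
    derjaguin_transform(profile, params.tip.R_um)
    density = density_profile(runs[-1])

    fit = None
    try:
        fr = np.maximum(profile.f_over_r, 0.0)
        fit = fit_force_profile(
            (profile.h, fr), n_populations=params.architecture.n_populations,
            seed=params.seed)
    except Exception as exc:  # fits may fail legitimately on flat curves
        log.warning("AdG fit skipped: %s", exc)

    bundle = ExperimentBundle(config=params.to_dict(), h_grid=h_grid,
                              runs=runs, profile=profile, density=density,
                              fit=fit, seed=params.seed, label=label)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _pooled_profiles(bundles: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-averaged net pressure and pooled SE on the common h grid."""
    h = bundles[0].profile.h
    for b in bundles[1:]:
        if not np.allclose(b.profile.h, h):
            raise ValueError("bundles must share the same h grid")
    vals = np.stack([b.profile.net_pressure for b in bundles])
    ses = np.stack([b.profile.pressure_se for b in bundles])
    mean = vals.mean(axis=0)
    if len(bundles) > 1:
        # combine between-seed scatter with within-run blocking error
        between = vals.std(axis=0, ddof=1) / math.sqrt(len(bundles))
        within = np.sqrt((ses ** 2).sum(axis=0)) / len(bundles)
        se = np.sqrt(between ** 2 + within ** 2)
    else:
        se = ses[0]
    return h, mean, se


def paired_contrast(profiles_a: list, profiles_b: list) -> pd.DataFrame:
    """Matched-seed contrast between two lists of ForceProfile replicates.

    The per-h difference is averaged over seed pairs; its uncertainty
    combines the between-seed scatter of the paired differences with the
    within-run blocking errors (the between-seed term alone is unreliable
    at a handful of seeds).
    """
    if len(profiles_a) != len(profiles_b) or not profiles_a:
        raise ValueError("need equal, non-empty replicate lists")
    h = profiles_a[0].h
    for p in (*profiles_a, *profiles_b):
        if not np.allclose(p.h, h):
            raise ValueError("profiles must share the h grid")
    n = len(profiles_a)
    diffs = np.stack([pa.net_pressure - pb.net_pressure
                      for pa, pb in zip(profiles_a, profiles_b)])
    within = np.stack([pa.pressure_se ** 2 + pb.pressure_se ** 2
                       for pa, pb in zip(profiles_a, profiles_b)])
    mean = diffs.mean(axis=0)
    between = diffs.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 \
        else np.zeros_like(mean)
    se = np.sqrt(between ** 2 + within.mean(axis=0) / n)
    verdict = np.where(mean > 2 * se, "greater",
                       np.where(mean < -2 * se, "lesser", "indistinguishable"))
    return pd.DataFrame({"h": h, "difference": mean, "se": se,
                         "verdict": verdict})


def compare_conditions(bundles_a: list, bundles_b: list,
                       contrast: str = "") -> pd.DataFrame:
    """Per-separation contrast between two conditions (seed-replicated).

    Returns a table with the difference a - b, its pooled uncertainty and
    a verdict at 2 SE: 'greater', 'indistinguishable' or 'lesser'.
    """
    ha, ma, sa = _pooled_profiles(bundles_a)
    hb, mb, sb = _pooled_profiles(bundles_b)
    if not np.allclose(ha, hb):
        raise ValueError("contrast requires matching h grids")
    if not math.isclose(bundles_a[0].profile.area, bundles_b[0].profile.area):
        raise ValueError("contrast requires matching areas")
    diff = ma - mb
    se = np.sqrt(sa ** 2 + sb ** 2)
    verdict = np.where(diff > 2 * se, "greater",
                       np.where(diff < -2 * se, "lesser", "indistinguishable"))
    return pd.DataFrame({"h": ha, "mean_a": ma, "mean_b": mb,
                         "difference": diff, "se": se, "verdict": verdict,
                         "contrast": contrast})
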