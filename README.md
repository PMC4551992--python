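# brushsim

Grand-canonical Metropolis Monte Carlo simulation of coarse-grained
polymer brushes on a soft surface compressed by an AFM-style planar tip,
with explicit solvent, plus the Alexander–de Gennes theory layer used to
analyse force–distance curves.

The package models "normal" epithelial cell surfaces as a uniform brush
(16 chains of 27 beads at 0.78 chains/nm²) and "cancerous" surfaces as a
three-population brush (36/10/4 chains of 5/30/42 beads), each either
*soft* (bond spring constant κ = 100 kBT/rc²) or *stiff* (κ = 2000,
a 20× ratio), and either *liquid* (graft ends diffuse on the surface) or
*solid* (graft ends frozen). Solvent particles are exchanged with a
reservoir at fixed activity (grand-canonical ensemble); all interactions
are soft DPD-style conservative repulsions, sampled with the Metropolis
algorithm. Lengths are in units of the bead radius rc = 0.646 nm,
energies in kBT.

## Layout

| module | contents |
| --- | --- |
| `brushsim.model` | unit system, interaction table, brush architectures, parameter validation, config I/O |
| `brushsim.energetics` | pair/bond/wall potentials, particle state, exact reference energies, cell-list neighbor search |
| `brushsim.gcmc` | the Metropolis engine (numba kernels in `brushsim._kernels`), run scheduling, move statistics, activity calibration (Widom + secant) |
| `brushsim.builder` | system construction, deterministic micro-fixtures with hand-computed energies, synthetic noisy theory curves |
| `brushsim.observables` | tip force, force–distance profiles with block-averaged errors, Derjaguin transform, density profiles, brush height, graft meandering, solvent penetration |
| `brushsim.theory` | Alexander–de Gennes pressure/sphere force (closed form + quadrature), multi-population fitting with validity-window iteration and AICc model comparison |
| `brushsim.pipeline` | h-sweep experiments, bundles, condition contrasts |
| `brushsim.cli` | `brushsim` command-line interface |

## CLI

```sh
brushsim --config exp.toml --seed 1 --outdir out sweep     # full h sweep
brushsim --config exp.toml --outdir out build              # initial system (XYZ)
brushsim --config exp.toml --outdir out run --frames       # single separation
brushsim --outdir out fit force.tsv --populations 3        # AdG fit of a TSV table
brushsim --outdir out compare out/soft out/stiff           # 2-SE contrast
brushsim --outdir out fixtures                             # micro-fixture catalogue
```

A configuration is TOML or JSON; lengths carry explicit unit tags:

```toml
preset = "cancer"        # or "normal"
stiffness = "soft"       # or "stiff"
mobility = "liquid"      # or "solid"
h = "8.2 nm"             # or "12.7 rc"
seed = 1
```

All outputs embed the resolved configuration and the seed; identical
(config, seed) pairs reproduce every artifact bit-for-bit.

## Notes on conventions

- Solvent bulk density is ρ rc³ = 3 with same-species repulsion
  a = 25 kBT/rc and solvent–brush a = 28 (slightly more repulsive); the
  default activity is pre-calibrated for these values and
  `gcmc.calibrate_activity` recomputes it for any interaction table.
- Bond springs have zero rest length by default (stiff springs pull
  consecutive beads closer, which is what makes stiff brushes shorter);
  `bond_rest_length` is configurable.
- The tip is a planar soft wall (the probe contact area exceeds the box);
  the raw wall pressure includes the bulk solvent contribution, so
  profiles also carry a net pressure with the large-separation baseline
  subtracted, and F/R follows by Derjaguin integration of the net
  pressure.
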