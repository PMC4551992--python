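"""Extended-XYZ snapshot export/import.

Format: particle count; a comment line carrying box, separation, seed and
sweep index as key=value pairs; then one line per particle with a species
label (``W`` solvent, ``B<p>`` brush population p) and x, y, z in rc.
Topology (bonds, graft flags) is not part of the format; readers that
need it must rebuild the system from its parameters.
"""

from __future__ import annotations

import numpy as np

from .energetics import ParticleSystem

__all__ = ["write_xyz", "read_xyz"]


def _label(sp: int) -> str:
    return "W" if sp == 0 else f"B{sp}"


def write_xyz(path, system: ParticleSystem, seed: int = 0, sweep: int = 0,
              mode: str = "w") -> None:
    with open(path, mode) as fh:
        fh.write(f"{system.n}\n")
        fh.write(
            f"box_xy={system.box_xy[0]:.12g},{system.box_xy[1]:.12g} "
            f"h={system.h:.12g} seed={seed} sweep={sweep}\n")
        for sp, p in zip(system.species, system.positions):
            fh.write(f"{_label(int(sp))} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")


def read_xyz(path):
    """Read every frame; returns a list of (positions, species, meta)."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            meta = {}
            for tok in fh.readline().split():
                k, v = tok.split("=", 1)
                meta[k] = v
            pos = np.empty((n, 3))
            species = np.empty(n, dtype=np.int64)
            for i in range(n):
                parts = fh.readline().split()
                species[i] = 0 if parts[0] == "W" else int(parts[0][1:])
                pos[i] = [float(x) for x in parts[1:4]]
            meta["box_xy"] = tuple(float(x) for x in meta["box_xy"].split(","))
            meta["h"] = float(meta["h"])
            frames.append((pos, species, meta))
    return frames
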