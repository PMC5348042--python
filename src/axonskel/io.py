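"""Plain-text trajectory and topology export (XYZ + JSON sidecar)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import KIND_TAGS, ParticleSystem, Topology


def write_xyz(
    path: str | Path,
    system: ParticleSystem,
    frames=None,
    sigma_nm: float = 4.45,
    comment: str = "",
    append: bool = False,
) -> None:
    """Write one frame (or a list of position arrays) in XYZ, coordinates in nm.

    Element tags: A = actin, S = spectrin, K = ankyrin.
    """
    tags = [KIND_TAGS[k] for k in system.kind]
    frames = [system.pos] if frames is None else frames
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for frame in frames:
            fh.write(f"{len(tags)}\n{comment}\n")
            for tag, (x, y, z) in zip(tags, np.asarray(frame) * sigma_nm):
                fh.write(f"{tag} {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz(path: str | Path) -> list[np.ndarray]:
    """Read all frames of an XYZ file; returns positions in nm."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        frames.append(np.array([[float(v) for v in ln.split()[1:4]] for ln in block]))
        i += 2 + n
    return frames


def write_topology_json(path: str | Path, topology: Topology) -> None:
    Path(path).write_text(json.dumps(topology.to_json_dict()))
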