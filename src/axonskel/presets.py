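"""Seeded generators of ready-to-run systems and synthetic AFM data.

Presets freeze the model's reference parameters so tests and measurement
scripts all start from the same documented configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afm import ForceCurve, predict_force
from .config import ModelConfig
from .model import (
    ParticleSystem,
    Topology,
    build_axon,
    build_free_ring_filament,
    build_free_spectrin,
)

PRESET_NAMES = (
    "free_spectrin",
    "free_actin_13",
    "axon_2ring",
    "axon_3ring",
    "axon_3ring_110nm",
    "axon_full_11ring",
)


@dataclass
class Preset:
    name: str
    config: ModelConfig
    system: ParticleSystem
    topology: Topology


def make_preset(name: str, seed: int = 0) -> Preset:
    """Build one of the documented small systems, deterministically."""
    if name == "free_spectrin":
        config = ModelConfig(seed=seed)
        system, topo = build_free_spectrin(config)
    elif name == "free_actin_13":
        config = ModelConfig(seed=seed)
        system, topo = build_free_ring_filament(13, config=config)
    elif name == "axon_2ring":
        config = ModelConfig(n_rings=2, seed=seed)
        system, topo = build_axon(config)
    elif name == "axon_3ring":
        config = ModelConfig(n_rings=3, seed=seed)
        system, topo = build_axon(config)
    elif name == "axon_3ring_110nm":
        config = ModelConfig(n_rings=3, ring_spacing_nm=110.0, seed=seed)
        system, topo = build_axon(config)
    elif name == "axon_full_11ring":
        config = ModelConfig(n_rings=11, seed=seed)
        system, topo = build_axon(config)
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    return Preset(name, config, system, topo)


def make_afm_dataset(
    E_true: float,
    n_curves: int = 256,
    noise_frac: float = 0.05,
    geometry: str = "thin_cylinder",
    seed: int = 0,
    d_max_nm: float = 100.0,
    n_points: int = 50,
) -> list[ForceCurve]:
    """Synthetic indentation grid: power-law curves with multiplicative noise.

    Emulates a force-map of ``n_curves`` indentations over a patch of known
    modulus ``E_true`` (kPa); each force value gets independent Gaussian
    multiplicative noise of relative width ``noise_frac``.
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    rng = np.random.default_rng(seed)
    d = np.linspace(d_max_nm / n_points, d_max_nm, n_points)
    clean = predict_force(E_true, d, geometry)
    curves = []
    for _ in range(n_curves):
        noise = 1.0 + noise_frac * rng.standard_normal(n_points)
        curves.append(ForceCurve(d.copy(), clean * noise, geometry=geometry))
    return curves
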