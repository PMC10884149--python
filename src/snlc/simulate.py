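"""Synthetic ground-truth chromosome pairs and labelled datasets.

Two generators are provided, matching the benchmark conditions used
throughout the package: a pair of fixed-step random walks ("Brownian
motion with fixed step length") and a pair of parallel circular helices.
``make_dataset`` turns either into a complete labelled dataset — structure,
loci partition, and the three contact matrices with multiplicative noise.

The default conditions are 60 loci, half of them ambiguous at uniformly
random positions, step length 1, and homolog centroids separated by five
step lengths (so that the spatial-separation assumption behind the final
symmetry-breaking stage holds for generated fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ContactData, LociPartition, Structure3D, add_noise, contacts_from_structure

__all__ = ["SimulationConfig", "brownian_pair", "helix_pair", "make_dataset"]


@dataclass
class SimulationConfig:
    n: int = 60
    mode: str = "brownian"  # {"brownian", "helix"}
    step: float = 1.0
    helix_radius: float = 1.0
    helix_pitch: float = 0.3  # axial rise per full turn
    offset: Sequence[float] | None = None  # homolog-2 translation; default 5*step along x
    ambiguous_fraction: float = 0.5
    ambiguous_loci: Sequence[int] | None = None  # explicit placement overrides the fraction
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ValueError("ambiguous_fraction must be in [0, 1]")
        if self.mode not in ("brownian", "helix"):
            raise ValueError("mode must be 'brownian' or 'helix'")
        if self.step <= 0 or self.helix_radius <= 0:
            raise ValueError("step and helix_radius must be positive")

    def offset_vector(self) -> np.ndarray:
        if self.offset is None:
            return np.array([5.0 * self.step, 0.0, 0.0])
        v = np.asarray(self.offset, dtype=float)
        if v.shape != (3,):
            raise ValueError("offset must be a 3-vector")
        return v


def _unit_sphere(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform directions: Gaussian draws normalized to unit length."""
    v = rng.standard_normal((size, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample the (measure-zero) degenerate draws
    while (norms < 1e-12).any():
        bad = norms[:, 0] < 1e-12
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


def brownian_pair(config: SimulationConfig) -> Structure3D:
    """Two independent fixed-step random walks; homolog 2 translated by the offset."""
    if config.mode != "brownian":
        raise ValueError("config.mode must be 'brownian'")
    rng = np.random.default_rng(config.seed)
    chains = []
    for _ in range(2):
        steps = config.step * _unit_sphere(rng, config.n - 1) if config.n > 1 else np.zeros((0, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        chains.append(pos)
    return Structure3D(chains[0], chains[1] + config.offset_vector())


def helix_pair(config: SimulationConfig) -> Structure3D:
    """Beads on a circular helix at equal arc length ``step``; homolog 2 is a
    parallel translated copy."""
    if config.mode != "helix":
        raise ValueError("config.mode must be 'helix'")
    r, pitch = config.helix_radius, config.helix_pitch
    # arc length per radian of turn
    ds_dt = np.hypot(r, pitch / (2.0 * np.pi))
    t = (config.step / ds_dt) * np.arange(config.n)
    pos = np.column_stack([r * np.cos(t), r * np.sin(t), (pitch / (2.0 * np.pi)) * t])
    return Structure3D(pos, pos + config.offset_vector())


def make_dataset(config: SimulationConfig) -> tuple[Structure3D, LociPartition, ContactData]:
    """Simulate a structure, partition its loci, and produce noisy counts.

    ``ceil(ambiguous_fraction * n)`` loci are marked ambiguous, drawn
    uniformly without replacement (or taken verbatim from
    ``config.ambiguous_loci``).  Sub-seeds for the structure, the placement
    and the noise are derived from ``config.seed`` so that the full dataset
    is reproducible from the config alone.
    """
    ss = np.random.SeedSequence(config.seed)
    s_struct, s_part, s_noise = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    cfg = SimulationConfig(**{**config.__dict__, "seed": s_struct})
    structure = brownian_pair(cfg) if config.mode == "brownian" else helix_pair(cfg)

    n = config.n
    if config.ambiguous_loci is not None:
        A = np.asarray(sorted(set(int(i) for i in config.ambiguous_loci)), dtype=int)
    else:
        k = int(np.ceil(config.ambiguous_fraction * n))
        A = np.sort(np.random.default_rng(s_part).choice(n, size=k, replace=False))
    U = np.setdiff1d(np.arange(n), A)
    partition = LociPartition(n, U, A)

    contacts = contacts_from_structure(structure, partition)
    if config.epsilon > 0:
        contacts = add_noise(contacts, config.epsilon, s_noise)
    return structure, partition, contacts
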