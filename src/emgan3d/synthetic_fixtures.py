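"""Toy protein-like structures and paired low/high-resolution maps.

Stands in for an experimental/simulated map corpus: the "experimental"
member of each pair is a lower-resolution simulation with additive seeded
Gaussian noise, re-normalized to [0, 1], on the exact grid frame of its
high-resolution partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube_pipeline import CubePair, make_pairs
from .density_io import DensityMap, normalize_density
from .map_simulation import Atom, AtomModel, SimulationConfig, simulate_map

__all__ = [
    "FixtureSpec",
    "make_toy_structure",
    "make_training_pair",
    "make_fixture_dataset",
]

_RISE_HELIX = 1.5  # A per residue along the axis
_TWIST_HELIX = np.deg2rad(100.0)
_RADIUS_HELIX = 2.3
_RISE_STRAND = 3.3
_STEP_COIL = 3.8
_MIN_SEPARATION = 2.0  # self-avoidance distance for coil CA atoms


@dataclass
class FixtureSpec:
    n_structures: int = 20
    residues_min: int = 30
    residues_max: int = 80
    motif_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # helix, strand, coil
    low_resolution: float = 5.0
    high_resolution: float = 2.0
    noise_sd: float = 0.05
    voxel_spacing: float = 1.0
    padding: float = 5.0
    cube_size: int = 25
    stride: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.motif_mix) - 1.0) > 1e-9:
            raise ValueError(f"motif_mix must sum to 1, got {self.motif_mix}")
        if self.low_resolution <= 0 or self.high_resolution <= 0:
            raise ValueError("resolutions must be positive")
        if self.low_resolution <= self.high_resolution:
            raise ValueError("low_resolution must exceed high_resolution")
        if self.n_structures < 1 or self.residues_min < 2:
            raise ValueError("need >= 1 structure with >= 2 residues")
        if self.residues_max < self.residues_min:
            raise ValueError("residues_max must be >= residues_min")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ca_positions(kind: str, n_residues: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "helix":
        i = np.arange(n_residues)
        theta = i * _TWIST_HELIX
        return np.stack(
            [_RADIUS_HELIX * np.cos(theta), _RADIUS_HELIX * np.sin(theta), i * _RISE_HELIX],
            axis=1,
        )
    if kind == "strand":
        i = np.arange(n_residues)
        lateral = np.where(i % 2 == 0, 1.0, -1.0)
        return np.stack([i * _RISE_STRAND, lateral, np.zeros(n_residues)], axis=1)
    if kind == "coil":
        pos = [np.zeros(3)]
        while len(pos) < n_residues:
            placed = False
            for _ in range(200):
                step = rng.normal(size=3)
                step *= _STEP_COIL / np.linalg.norm(step)
                cand = pos[-1] + step
                prior = np.array(pos[:-1]) if len(pos) > 1 else None
                if prior is None or np.min(np.linalg.norm(prior - cand, axis=1)) >= _MIN_SEPARATION:
                    pos.append(cand)
                    placed = True
                    break
            if not placed:  # dead end: back up one residue and retry
                if len(pos) > 1:
                    pos.pop()
                else:
                    raise RuntimeError("self-avoiding walk failed to start")
        return np.array(pos)
    raise ValueError(f"unknown structure kind {kind!r}")


def make_toy_structure(kind: str, n_residues: int, seed: int = 0) -> AtomModel:
    """A backbone-like chain with ideal helix/strand geometry or a coil walk.

    One CA pseudo-atom per residue plus 1-3 side-chain pseudo-atoms placed
    ~1.5 A from the CA.  Deterministic under ``seed``.
    """
    if n_residues < 2:
        raise ValueError(f"need at least 2 residues, got {n_residues}")
    kind_tag = {"helix": 1, "strand": 2, "coil": 3, "mixed": 4}.get(kind)
    if kind_tag is None:
        raise ValueError(f"unknown structure kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence((kind_tag, seed)))
    if kind == "mixed":
        kinds = ["helix", "strand", "coil"]
        n_seg = max(2, n_residues // 15)
        sizes = np.full(n_seg, n_residues // n_seg)
        sizes[: n_residues % n_seg] += 1
        segments = []
        cursor = np.zeros(3)
        for s in sizes:
            seg_kind = kinds[rng.integers(len(kinds))]
            seg = _ca_positions(seg_kind, int(s), rng)
            direction = rng.normal(size=3)
            direction *= _STEP_COIL / np.linalg.norm(direction)
            seg = seg - seg[0] + cursor + direction
            segments.append(seg)
            cursor = seg[-1]
        ca = np.concatenate(segments)[:n_residues]
    else:
        ca = _ca_positions(kind, n_residues, rng)

    side_names = ("CB", "CG", "CD")
    atoms: list[Atom] = []
    for i, p in enumerate(ca):
        atoms.append(
            Atom("C", "A", i + 1, "ALA", tuple(float(c) for c in p), name="CA")
        )
        for j in range(int(rng.integers(1, 4))):
            offset = rng.normal(size=3)
            offset *= 1.5 / np.linalg.norm(offset)
            q = p + offset * (1.0 + 0.3 * j)
            atoms.append(
                Atom("C", "A", i + 1, "ALA", tuple(float(c) for c in q), name=side_names[j])
            )
    return AtomModel(atoms)


def make_training_pair(
    model: AtomModel, spec: FixtureSpec, seed: int | None = None
) -> tuple[DensityMap, DensityMap]:
    """(low-resolution noisy map, high-resolution target) on one grid frame."""
    if len(model) == 0:
        raise ValueError("model is empty")
    high = simulate_map(
        model,
        SimulationConfig(
            resolution=spec.high_resolution,
            voxel_spacing=spec.voxel_spacing,
            padding=spec.padding,
        ),
    )
    low = simulate_map(
        model,
        SimulationConfig(resolution=spec.low_resolution, voxel_spacing=spec.voxel_spacing),
        grid=high,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        noisy = low.data + rng.normal(0.0, spec.noise_sd, low.shape).astype(np.float32)
        low = DensityMap(noisy, low.origin, low.voxel_size, low.label)
        low = normalize_density(low)
    return low, high


@dataclass
class FixtureRecord:
    index: int
    kind: str
    n_residues: int
    model: AtomModel
    low: DensityMap
    high: DensityMap
    cube_pairs: list[CubePair]


@dataclass
class FixtureDataset:
    spec: FixtureSpec
    records: list[FixtureRecord] = field(default_factory=list)

    @property
    def manifest(self) -> dict:
        return {
            "seed": self.spec.seed,
            "n_structures": self.spec.n_structures,
            "low_resolution": self.spec.low_resolution,
            "high_resolution": self.spec.high_resolution,
            "noise_sd": self.spec.noise_sd,
            "structures": [
                {
                    "index": r.index,
                    "kind": r.kind,
                    "n_residues": r.n_residues,
                    "n_atoms": len(r.model),
                    "map_shape": list(r.low.shape),
                    "n_cube_pairs": len(r.cube_pairs),
                }
                for r in self.records
            ],
        }

    def pairs_by_map(self) -> dict[str, list[CubePair]]:
        return {f"structure_{r.index:03d}": r.cube_pairs for r in self.records}

    def all_pairs(self) -> list[CubePair]:
        return [p for r in self.records for p in r.cube_pairs]


def make_fixture_dataset(spec: FixtureSpec) -> FixtureDataset:
    """Generate ``spec.n_structures`` toy structures with map and cube pairs."""
    master = np.random.SeedSequence(spec.seed)
    kinds = ("helix", "strand", "coil")
    probs = np.asarray(spec.motif_mix, dtype=np.float64)
    dataset = FixtureDataset(spec)
    for index, child in enumerate(master.spawn(spec.n_structures)):
        rng = np.random.default_rng(child)
        kind = kinds[rng.choice(3, p=probs)]
        n_res = int(rng.integers(spec.residues_min, spec.residues_max + 1))
        structure_seed = int(rng.integers(2**31))
        model = make_toy_structure(kind, n_res, seed=structure_seed)
        low, high = make_training_pair(model, spec, seed=int(rng.integers(2**31)))
        cube_pairs = make_pairs(
            low, high, spec.cube_size, spec.stride, source_map=f"structure_{index:03d}"
        )
        dataset.records.append(
            FixtureRecord(index, kind, n_res, model, low, high, cube_pairs)
        )
    return dataset
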