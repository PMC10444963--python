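"""Map-change metrics: cube cross-correlation and per-residue RSCC.

The per-residue score correlates a map against a model-derived reference
density inside a mask of voxels within ``mask_radius`` of the residue's
atoms.  The reference density comes from :func:`emgan3d.map_simulation.simulate_map`
on the map's own grid, so the score is internally consistent for
before/after comparisons rather than identical to any external program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cube_pipeline import DEFAULT_CUBE_SIZE, DEFAULT_STRIDE, extract_cubes
from .density_io import DensityMap
from .map_simulation import AtomModel, SimulationConfig, simulate_map

__all__ = [
    "RSCCEntry",
    "RSCCProfile",
    "cross_correlation",
    "cubewise_improvement",
    "rscc_per_residue",
    "improvement_report",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for degenerate inputs."""


def cross_correlation(a: np.ndarray, b: np.ndarray, about_mean: bool = True) -> float:
    """Normalized similarity of two equal-shape density arrays.

    ``about_mean=True`` is the Pearson correlation over voxels;
    ``about_mean=False`` is the about-zero overlap  sum(ab) / (|a| |b|).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if about_mean:
        a = a - a.mean()
        b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        kind = "constant" if about_mean else "zero-norm"
        raise UndefinedCorrelationError(f"correlation undefined for {kind} input")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def cubewise_improvement(
    exp: DensityMap,
    mod: DensityMap,
    sim: DensityMap,
    cube_size: int = DEFAULT_CUBE_SIZE,
    stride: int = DEFAULT_STRIDE,
    about_mean: bool = True,
) -> tuple[float, float, float]:
    """Fraction of valid cubes where CC(mod, sim) >= CC(exp, sim), plus means.

    Valid cubes are those where neither the experimental nor the simulated
    cube is all-zero; cubes where any correlation is undefined (constant
    arrays) are skipped.
    """
    for name, other in (("mod", mod), ("sim", sim)):
        if not exp.same_frame(other):
            raise ValueError(
                f"{name} map frame differs from exp: shapes {other.shape} vs {exp.shape}"
            )
    grid, exp_cubes = extract_cubes(exp, cube_size, stride)
    _, mod_cubes = extract_cubes(mod, cube_size, stride)
    _, sim_cubes = extract_cubes(sim, cube_size, stride)

    improved = 0
    total = 0
    cc_exp_sum = 0.0
    cc_mod_sum = 0.0
    for ec, mc, sc in zip(exp_cubes, mod_cubes, sim_cubes):
        if not (np.any(ec != 0) and np.any(sc != 0)):
            continue
        try:
            cc_exp = cross_correlation(ec, sc, about_mean)
            cc_mod = cross_correlation(mc, sc, about_mean)
        except UndefinedCorrelationError:
            continue
        total += 1
        cc_exp_sum += cc_exp
        cc_mod_sum += cc_mod
        if cc_mod >= cc_exp - 1e-12:
            improved += 1
    if total == 0:
        raise ValueError("no valid cubes to compare")
    return improved / total, cc_exp_sum / total, cc_mod_sum / total


@dataclass
class RSCCEntry:
    chain_id: str
    residue_index: int
    residue_name: str
    rscc: float
    n_voxels: int
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.icode)


@dataclass
class RSCCProfile:
    entries: list[RSCCEntry] = field(default_factory=list)

    @property
    def mean_rscc(self) -> float:
        if not self.entries:
            raise ValueError("empty RSCC profile")
        return float(np.mean([e.rscc for e in self.entries]))

    def by_key(self) -> dict[tuple[str, int, str], RSCCEntry]:
        return {e.key: e for e in self.entries}

    def to_rows(self) -> list[dict]:
        return [
            {
                "chain": e.chain_id,
                "residue_index": e.residue_index,
                "residue_name": e.residue_name,
                "rscc": e.rscc,
                "n_voxels": e.n_voxels,
            }
            for e in self.entries
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresi\tresname\trscc\tn_voxels\n")
            for e in self.entries:
                fh.write(
                    f"{e.chain_id}\t{e.residue_index}{e.icode}\t{e.residue_name}"
                    f"\t{e.rscc:.6f}\t{e.n_voxels}\n"
                )


def _mask_indices(
    positions: np.ndarray, origin: np.ndarray, voxel: np.ndarray,
    shape: tuple[int, int, int], radius: float,
) -> np.ndarray:
    """Flat voxel indices within ``radius`` of any position."""
    nz, ny, nx = shape
    flat: set[int] = set()
    r2 = radius * radius
    for p in positions:
        lo = np.maximum(np.floor((p - radius - origin) / voxel).astype(int), 0)
        hi = np.minimum(
            np.ceil((p + radius - origin) / voxel).astype(int), [nx - 1, ny - 1, nz - 1]
        )
        if np.any(hi < lo):
            continue
        ax = origin[0] + np.arange(lo[0], hi[0] + 1) * voxel[0] - p[0]
        ay = origin[1] + np.arange(lo[1], hi[1] + 1) * voxel[1] - p[1]
        az = origin[2] + np.arange(lo[2], hi[2] + 1) * voxel[2] - p[2]
        d2 = az[:, None, None] ** 2 + ay[None, :, None] ** 2 + ax[None, None, :] ** 2
        zz, yy, xx = np.nonzero(d2 <= r2)
        flat.update(
            ((zz + lo[2]) * ny + (yy + lo[1])) * nx + (xx + lo[0])
        )
    return np.fromiter(flat, dtype=np.int64)


def rscc_per_residue(
    map: DensityMap,
    model: AtomModel,
    sim_cfg: SimulationConfig,
    mask_radius: float = 2.5,
    reference: DensityMap | None = None,
) -> RSCCProfile:
    """Per-residue real-space correlation of a map against a model.

    A reference map is simulated from the full model on the map's grid;
    each residue is scored by the Pearson correlation between map and
    reference over voxels within ``mask_radius`` of the residue's atoms.
    Residues whose mask is empty (or falls on constant density) are skipped
    with a warning.
    """
    if reference is None:
        reference = simulate_map(model, sim_cfg, grid=map)
    ref = reference.data.astype(np.float64).ravel()
    dat = map.data.astype(np.float64).ravel()

    entries: list[RSCCEntry] = []
    for (chain, resi, icode), atoms in model.residues().items():
        positions = np.array([a.position for a in atoms], dtype=np.float64)
        idx = _mask_indices(positions, map.origin, map.voxel_size, map.shape, mask_radius)
        if idx.size < 2:
            logger.warning(
                "residue %s%s%s: mask has %d voxels inside the map; skipped",
                chain, resi, icode, idx.size,
            )
            continue
        try:
            cc = cross_correlation(dat[idx], ref[idx], about_mean=True)
        except UndefinedCorrelationError:
            logger.warning("residue %s%s%s: constant density in mask; skipped", chain, resi, icode)
            continue
        entries.append(RSCCEntry(chain, resi, atoms[0].residue_name, cc, int(idx.size), icode))
    if not entries:
        raise ValueError("no residue produced a non-empty mask inside the map")
    return RSCCProfile(entries)


def improvement_report(profile_a: RSCCProfile, profile_b: RSCCProfile) -> dict:
    """Residue-aligned RSCC deltas of profile_b relative to profile_a."""
    a = profile_a.by_key()
    b = profile_b.by_key()
    missing = sorted(set(a) ^ set(b))
    if missing:
        raise ValueError(f"residue keys differ between profiles: {missing}")
    deltas = {k: b[k].rscc - a[k].rscc for k in a}
    n = len(deltas)
    improved = sum(1 for d in deltas.values() if d >= 0)
    return {
        "n_residues": n,
        "fraction_improved": improved / n,
        "mean_before": profile_a.mean_rscc,
        "mean_after": profile_b.mean_rscc,
        "mean_delta": float(np.mean(list(deltas.values()))),
        "deltas": deltas,
    }
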