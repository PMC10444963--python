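"""Simulated density maps from atomic models (the pdb2vol role).

Each atom contributes an isotropic Gaussian whose full width at half
maximum equals the nominal resolution (sigma = R / (2*sqrt(2*ln 2))),
truncated at a configurable multiple of sigma.  Absolute amplitudes are
convention-dependent; the pipeline only ever consumes min-max-normalized
maps, so only the kernel shape matters downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .density_io import DensityMap, normalize_density

__all__ = [
    "Atom",
    "AtomModel",
    "SimulationConfig",
    "read_pdb",
    "write_pdb",
    "simulate_map",
    "target_resolution_for",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # ~= 1/2.355

# small table for the optional atomic-number weighting scheme
_ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "MG": 12, "CA": 20, "MN": 25, "FE": 26, "ZN": 30, "SE": 34,
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    position: tuple[float, float, float]
    name: str = ""
    icode: str = ""
    weight: float = 1.0

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.icode)


@dataclass
class AtomModel:
    """An ordered collection of atoms in Angstrom coordinates."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite position for atom {a}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=np.float64)

    def weights(self, scheme: str = "unit") -> np.ndarray:
        if scheme == "unit":
            return np.array([a.weight for a in self.atoms], dtype=np.float64)
        if scheme == "atomic-number":
            return np.array(
                [_ATOMIC_NUMBERS.get(a.element.upper(), 6) * a.weight for a in self.atoms],
                dtype=np.float64,
            )
        raise ValueError(f"unknown weight scheme {scheme!r}")

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by (chain, residue index, insertion code), file order."""
        groups: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups


@dataclass
class SimulationConfig:
    resolution: float
    voxel_spacing: float = 1.0
    padding: float = 5.0
    kernel_truncation: float = 3.0
    weight_scheme: str = "unit"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.voxel_spacing <= 0:
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0, got {self.padding}")
        if self.kernel_truncation < 2:
            raise ValueError(f"kernel_truncation must be >= 2, got {self.kernel_truncation}")


def read_pdb(path, include_waters: bool = False) -> AtomModel:
    """Parse ATOM/HETATM records from a PDB file.

    Alternate locations keep the highest-occupancy conformer (ties broken by
    altloc identifier); insertion codes are kept as part of the residue key;
    waters are dropped unless requested.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("model", str(path))

    atoms: list[Atom] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            resname = residue.get_resname().strip()
            if not include_waters and resname in _WATER_RESNAMES:
                continue
            for atom in residue:  # disordered atoms yield the top-occupancy child
                element = (atom.element or atom.get_name()[:1]).strip() or "C"
                atoms.append(
                    Atom(
                        element=element,
                        chain_id=chain.get_id(),
                        residue_index=int(resseq),
                        residue_name=resname,
                        position=tuple(float(c) for c in atom.get_coord()),
                        name=atom.get_name(),
                        icode=icode.strip(),
                    )
                )
    return AtomModel(atoms)


def write_pdb(model: AtomModel, path) -> None:
    """Write a minimal PDB file (ATOM records + TER/END)."""
    lines = []
    for serial, a in enumerate(model.atoms, start=1):
        x, y, z = a.position
        name = a.name or a.element
        lines.append(
            f"ATOM  {serial % 100000:5d} {name:<4.4s}{a.residue_name:>4.3s} "
            f"{a.chain_id:1.1s}{a.residue_index % 10000:4d}{a.icode:1.1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2.2s}"
        )
    lines += ["TER", "END", ""]
    Path(path).write_text("\n".join(lines))


def simulate_map(
    model: AtomModel,
    cfg: SimulationConfig,
    grid: DensityMap | None = None,
    normalize: bool = True,
) -> DensityMap:
    """Rasterize a model as a sum of truncated Gaussians on a regular grid.

    If ``grid`` is given, its frame (origin, shape, spacing) is reused so the
    result is voxel-aligned with an existing map; otherwise the grid covers
    the model's bounding box plus ``cfg.padding``.
    """
    if len(model) == 0:
        raise ValueError("cannot simulate a map from an empty model")

    sigma = cfg.resolution * FWHM_TO_SIGMA
    trunc = cfg.kernel_truncation * sigma
    pos = model.positions
    w = model.weights(cfg.weight_scheme)

    if grid is not None:
        origin = grid.origin.copy()
        shape = grid.shape
        spacing = grid.voxel_size.copy()
    else:
        spacing = np.full(3, cfg.voxel_spacing)
        lo = pos.min(axis=0) - cfg.padding
        hi = pos.max(axis=0) + cfg.padding
        origin = np.floor(lo)
        n_xyz = np.ceil((hi - origin) / spacing).astype(int) + 1
        shape = (int(n_xyz[2]), int(n_xyz[1]), int(n_xyz[0]))

    data = np.zeros(shape, dtype=np.float64)
    nz, ny, nx = shape
    inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
    for p, wt in zip(pos, w):
        # local box of voxels within the truncation radius
        idx_lo = np.maximum(
            np.ceil((p - trunc - origin) / spacing).astype(int), 0
        )
        idx_hi = np.minimum(
            np.floor((p + trunc - origin) / spacing).astype(int), [nx - 1, ny - 1, nz - 1]
        )
        if np.any(idx_hi < idx_lo):
            continue
        ax = origin[0] + np.arange(idx_lo[0], idx_hi[0] + 1) * spacing[0] - p[0]
        ay = origin[1] + np.arange(idx_lo[1], idx_hi[1] + 1) * spacing[1] - p[1]
        az = origin[2] + np.arange(idx_lo[2], idx_hi[2] + 1) * spacing[2] - p[2]
        d2 = (
            az[:, None, None] ** 2 + ay[None, :, None] ** 2 + ax[None, None, :] ** 2
        )
        kernel = np.exp(-d2 * inv_two_sigma2)
        kernel[d2 > trunc * trunc] = 0.0
        data[
            idx_lo[2] : idx_hi[2] + 1,
            idx_lo[1] : idx_hi[1] + 1,
            idx_lo[0] : idx_hi[0] + 1,
        ] += wt * kernel

    out = DensityMap(data.astype(np.float32), origin=origin, voxel_size=spacing)
    if normalize:
        out = normalize_density(out)
    return out


def target_resolution_for(experimental_resolution: float) -> float:
    """Map an experimental map resolution to the simulated-map target.

    Maps at [3.0, 3.5) A are paired with 1.8 A simulations, maps at
    [3.5, 6.0] A with 3.0 A simulations.  Inputs outside [3.0, 6.0] warn and
    use the nearest branch.
    """
    r = float(experimental_resolution)
    if r <= 0:
        raise ValueError(f"resolution must be positive, got {r}")
    if not 3.0 <= r <= 6.0:
        warnings.warn(
            f"experimental resolution {r} A is outside the supported 3.0-6.0 A range",
            stacklevel=2,
        )
    return 1.8 if r < 3.5 else 3.0
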