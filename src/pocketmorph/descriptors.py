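"""Gyration-tensor shape descriptors for pocket point clouds.

The gyration tensor of an N-atom pocket with centered coordinates r_i is

    T = (1/N) sum_i r_i r_i^T        (3x3, symmetric PSD, units A^2)

with all atoms weighted uniformly (no masses, no atom types).  Its ordered
eigenvalues lambda1 >= lambda2 >= lambda3 measure dispersion along the
principal axes, and the three scale-invariant ratios

    rEV21 = lambda2/lambda1   (global elongation)
    rEV32 = lambda3/lambda2   (symmetry within the minor plane)
    rEV31 = lambda3/lambda1   (overall anisotropy; = rEV21 * rEV32)

lie in [0, 1], where 1 is perfect isotropy.  The radius of gyration
Rg = sqrt(lambda1 + lambda2 + lambda3) equals the root-mean-square distance
of the atoms to their centroid and carries the size information that the
ratios deliberately discard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegeneratePocketError
from .structure import PocketAtomCloud

_EIG_CLAMP = 1e-12  # negative round-off below this magnitude is clamped to 0

DESCRIPTOR_COLUMNS = [
    "pocket_id",
    "structure_id",
    "ligand_id",
    "lambda1",
    "lambda2",
    "lambda3",
    "rEV21",
    "rEV32",
    "rEV31",
    "Rg",
    "n_atoms",
    "n_residues",
]


@dataclass(frozen=True)
class EigenSpectrum:
    """Ordered gyration-tensor eigenvalues, in A^2."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self):
        if not (self.lambda1 >= self.lambda2 >= self.lambda3 >= 0):
            raise ValueError(
                f"eigenvalues must satisfy l1 >= l2 >= l3 >= 0, got "
                f"({self.lambda1}, {self.lambda2}, {self.lambda3})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)


@dataclass(frozen=True)
class ShapeDescriptors:
    """The per-pocket morphometric record."""

    pocket_id: str
    rEV21: float
    rEV32: float
    rEV31: float
    Rg: float
    n_atoms: int
    n_residues: int
    spectrum: EigenSpectrum
    structure_id: str = ""
    ligand_id: str = ""
    collinear: bool = False  # lambda2 == 0; rEV32 set to 0 by convention

    def as_dict(self) -> dict:
        return {
            "pocket_id": self.pocket_id,
            "structure_id": self.structure_id,
            "ligand_id": self.ligand_id,
            "lambda1": self.spectrum.lambda1,
            "lambda2": self.spectrum.lambda2,
            "lambda3": self.spectrum.lambda3,
            "rEV21": self.rEV21,
            "rEV32": self.rEV32,
            "rEV31": self.rEV31,
            "Rg": self.Rg,
            "n_atoms": self.n_atoms,
            "n_residues": self.n_residues,
        }


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    """Unweighted gyration tensor (1/N normalization) of an (N, 3) cloud.

    Raises :class:`DegeneratePocketError` for N < 4.  Rank-deficient clouds
    (coplanar or collinear points) are computed normally; the deficiency
    shows up downstream as zero eigenvalues.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"expected (N, 3) coordinates, got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    n = coords.shape[0]
    if n < 4:
        raise DegeneratePocketError(f"{n} atoms cannot define a 3-D shape (need >= 4)")
    centered = coords - coords.mean(axis=0)
    return centered.T @ centered / n


def eigen_spectrum(tensor: np.ndarray, sym_tol: float = 1e-9) -> EigenSpectrum:
    """Descending eigenvalues of a symmetric 3x3 tensor.

    Negative values from floating-point round-off (magnitude below 1e-12
    relative to the largest eigenvalue) are clamped to zero.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValueError(f"expected 3x3 tensor, got shape {tensor.shape}")
    scale = max(np.abs(tensor).max(), 1.0)
    if np.abs(tensor - tensor.T).max() > sym_tol * scale:
        raise ValueError("tensor is not symmetric")
    vals = np.linalg.eigvalsh(tensor)[::-1]
    clamp = _EIG_CLAMP * max(abs(vals[0]), 1.0)
    vals = np.where(np.abs(vals) < clamp, 0.0, vals)
    vals = np.maximum.accumulate(vals[::-1])[::-1]  # enforce exact descending order
    return EigenSpectrum(float(vals[0]), float(vals[1]), float(vals[2]))


def shape_descriptors(
    cloud: PocketAtomCloud | np.ndarray,
    pocket_id: str | None = None,
) -> ShapeDescriptors:
    """Compute the full morphometric record for one pocket.

    Accepts either a :class:`~pocketmorph.structure.PocketAtomCloud` or a
    bare (N, 3) coordinate array.  All points coincident (lambda1 = 0) is an
    error; a collinear cloud (lambda2 = 0) gets rEV32 = 0 by convention and
    is flagged.
    """
    if isinstance(cloud, PocketAtomCloud):
        coords = cloud.coords
        pid = pocket_id or f"{cloud.structure_id}_{cloud.ligand_id}"
        structure_id, ligand_id = cloud.structure_id, cloud.ligand_id
        n_residues = cloud.n_residues
    else:
        coords = np.asarray(cloud, dtype=float)
        pid = pocket_id or "pocket"
        structure_id = ligand_id = ""
        n_residues = 0

    spectrum = eigen_spectrum(gyration_tensor(coords))
    l1, l2, l3 = spectrum.as_tuple()
    if l1 == 0:
        raise DegeneratePocketError("all points coincident (lambda1 = 0)")
    collinear = l2 == 0
    r21 = l2 / l1
    r32 = 0.0 if collinear else l3 / l2
    r31 = l3 / l1
    return ShapeDescriptors(
        pocket_id=pid,
        rEV21=r21,
        rEV32=r32,
        rEV31=r31,
        Rg=float(np.sqrt(l1 + l2 + l3)),
        n_atoms=int(coords.shape[0]),
        n_residues=n_residues,
        spectrum=spectrum,
        structure_id=structure_id,
        ligand_id=ligand_id,
        collinear=collinear,
    )


def describe_pockets(clouds: Iterable[PocketAtomCloud]) -> pd.DataFrame:
    """Descriptor table (one row per pocket) for a batch of clouds."""
    rows = [shape_descriptors(c).as_dict() for c in clouds]
    return pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)
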