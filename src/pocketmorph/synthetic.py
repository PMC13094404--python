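"""Synthetic pockets, toy structure fixtures, and descriptor cohorts.

Everything here is geometry-only: point clouds with controlled anisotropy,
minimal PDB complexes that each encode one extraction/preprocessing rule,
and descriptor tables that emulate the structure of a two-cohort
(RNA vs protein) pocket study.  No attempt is made to simulate realistic
chemistry, sequences, or secondary structure.

The cohort generator's defaults reproduce the study conditions of the
300 + 300 RNA/protein pocket benchmark this package is built around:
per-archetype ratio centroids and spreads, per-group size-descriptor
distributions, and per-group archetype counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

from .structure import AtomRecord, PocketAtomCloud, records_to_gemmi

TOY_PRESETS = (
    "shell",
    "two_residue_threshold",
    "altloc_case",
    "hydrogen_case",
    "multimodel_case",
)


@dataclass(frozen=True)
class CloudSpec:
    """Recipe for one anisotropic point cloud.

    ``sigma`` is the target population-covariance eigenvalue triple
    (sigma1^2 >= sigma2^2 >= sigma3^2, A^2); the cloud is drawn in the
    eigenbasis, rotated by a fixed or random orthonormal matrix, and
    translated.
    """

    n_points: int
    sigma: tuple[float, float, float]
    rotation: np.ndarray | None = None  # None -> random rotation from the seed
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_model: str = "gaussian"  # or "uniform_ellipsoid"
    seed: int = 0

    def __post_init__(self):
        s1, s2, s3 = self.sigma
        if not (s1 >= s2 >= s3 > 0):
            raise ValueError(f"sigma must satisfy s1 >= s2 >= s3 > 0, got {self.sigma}")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.noise_model not in ("gaussian", "uniform_ellipsoid"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def sample_cloud(spec: CloudSpec) -> PocketAtomCloud:
    """Draw a point cloud with population covariance R diag(sigma) R^T.

    For the uniform-ellipsoid model the semi-axes are sqrt(5 * sigma_i), so
    that the population covariance eigenvalues (and hence the eigenvalue
    ratios) match the Gaussian case.  Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.asarray(spec.sigma, dtype=float)
    if spec.noise_model == "gaussian":
        pts = rng.standard_normal((spec.n_points, 3)) * np.sqrt(sigma)
    else:
        # uniform in the unit ball, then scaled: Cov(ball) = I/5
        direction = rng.standard_normal((spec.n_points, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = rng.random(spec.n_points) ** (1.0 / 3.0)
        pts = direction * radius[:, None] * np.sqrt(5.0 * sigma)
    if spec.rotation is None:
        rot = special_ortho_group.rvs(3, random_state=rng)
    else:
        rot = np.asarray(spec.rotation, dtype=float)
    pts = pts @ rot.T + np.asarray(spec.translation, dtype=float)
    return PocketAtomCloud(
        structure_id=f"synthetic_seed{spec.seed}",
        ligand_id="SYN",
        level="atom",
        cutoff=0.0,
        member_residues=[],
        coords=pts,
    )


def _atom(chain, resname, seq, name, element, xyz, het=False, altloc=""):
    return AtomRecord(
        chain_id=chain,
        residue_name=resname,
        residue_seq=seq,
        insertion_code="",
        atom_name=name,
        element=element,
        coords=tuple(float(v) for v in xyz),
        is_hetero=het,
        altloc=altloc,
    )


def _preset_records(preset: str, seed: int) -> list[list[AtomRecord]]:
    rng = np.random.default_rng(seed)
    lig = [_atom("A", "LIG", 100, "C1", "C", (0, 0, 0), het=True)]

    if preset == "two_residue_threshold":
        # R1: one atom inside the 6 A cutoff, one outside; R2: just outside.
        r1 = [
            _atom("A", "ALA", 1, "CA", "C", (5.9, 0, 0)),
            _atom("A", "ALA", 1, "CB", "C", (9.0, 0, 0)),
        ]
        r2 = [_atom("A", "GLY", 2, "CA", "C", (0, 6.1, 0))]
        return [lig + r1 + r2]

    if preset == "shell":
        # one single-atom residue per shell radius, several directions
        records = list(lig)
        seq = 1
        for radius in (3.5, 4.5, 5.5, 6.5, 7.5):
            for direction in np.eye(3):
                records.append(
                    _atom("A", "GLY", seq, "CA", "C", direction * radius)
                )
                seq += 1
        return [records]

    if preset == "altloc_case":
        res = [
            _atom("A", "SER", 1, "CA", "C", (3.0, 0, 0), altloc="A"),
            _atom("A", "SER", 1, "CA", "C", (3.5, 0, 0), altloc="B"),
            _atom("A", "SER", 1, "CB", "C", (4.0, 0, 0)),
        ]
        return [lig + res]

    if preset == "hydrogen_case":
        # anisotropic heavy-atom pocket; each hydrogen is bonded ~1 A from
        # its parent heavy atom, as in real structures
        semi = np.sort(rng.uniform(1.5, 6.0, size=3))[::-1]
        records = list(lig)
        for seq in range(1, 31):  # ~180 atoms with H, the size of a real pocket
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            center = direction * semi * rng.random() ** (1 / 3)
            if np.linalg.norm(center) > 5.0:
                center *= 5.0 / np.linalg.norm(center)
            heavy = [center]
            heavy += [center + off for off in rng.standard_normal((2, 3)) * 0.8]
            atoms = [
                _atom("A", "VAL", seq, name, "C", xyz)
                for name, xyz in zip(("CA", "C1", "C2"), heavy)
            ]
            for k, parent in enumerate(heavy):
                bond = rng.standard_normal(3)
                bond *= 1.0 / np.linalg.norm(bond)
                atoms.append(_atom("A", "VAL", seq, f"H{k+1}", "H", parent + bond))
            records.extend(atoms)
        return [records]

    if preset == "multimodel_case":
        res1 = [
            _atom("A", "GLY", s, "CA", "C", (3.0 + 0.2 * s, 0, 0)) for s in range(1, 4)
        ]
        res2 = [
            _atom("A", "GLY", s, "CA", "C", (0, 3.0 + 0.2 * s, 0)) for s in range(1, 4)
        ]
        return [lig + res1, lig + res2]

    raise ValueError(f"unknown preset {preset!r}; choose from {TOY_PRESETS}")


def write_toy_complex(preset: str, path: str | Path, seed: int = 0) -> Path:
    """Write a minimal, valid PDB complex encoding one extraction rule.

    Presets: ``shell`` (cutoff sweep), ``two_residue_threshold`` (complete-
    residue rule at the 6 A boundary), ``altloc_case`` (first-conformer
    rule), ``hydrogen_case`` (H-sensitivity fixtures; vary ``seed`` for a
    batch), ``multimodel_case`` (first-model rule).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st = records_to_gemmi(_preset_records(preset, seed), name=preset)
    st.write_pdb(str(path))
    return path


# --- cohort generation -------------------------------------------------------

#: Study conditions of the 300 + 300 RNA/protein benchmark: per-archetype
#: (rEV21, rEV32) centroids and SDs of the combined cohort, per-group size
#: distributions (atom count and radius of gyration, mean/SD), and
#: per-group archetype counts.
DEFAULT_CENTROIDS = {
    "sphere": (0.72, 0.71),
    "disk": (0.73, 0.43),
    "strongly_anisotropic": (0.44, 0.42),
    "rod": (0.46, 0.74),
}
DEFAULT_SPREADS = {
    "sphere": (0.09, 0.09),
    "disk": (0.09, 0.11),
    "strongly_anisotropic": (0.12, 0.11),
    "rod": (0.10, 0.10),
}
DEFAULT_COUNTS = {
    "RNA": {"sphere": 49, "disk": 91, "strongly_anisotropic": 75, "rod": 85},
    "protein": {"sphere": 86, "disk": 74, "strongly_anisotropic": 60, "rod": 80},
}
DEFAULT_SIZES = {
    "RNA": {
        "sphere": (288.33, 72.69, 9.49, 0.93),
        "disk": (234.03, 68.84, 9.04, 0.94),
        "strongly_anisotropic": (209.60, 103.97, 8.97, 1.59),
        "rod": (251.99, 98.55, 9.57, 1.46),
    },
    "protein": {
        "sphere": (202.63, 44.04, 8.86, 0.80),
        "disk": (164.66, 51.73, 8.48, 1.01),
        "strongly_anisotropic": (150.07, 60.99, 8.74, 1.37),
        "rod": (178.64, 60.19, 8.93, 1.05),
    },
}


@dataclass
class CohortSpec:
    """Recipe for a synthetic two-group descriptor cohort."""

    counts: dict = field(default_factory=lambda: {g: dict(d) for g, d in DEFAULT_COUNTS.items()})
    centroids: dict = field(default_factory=lambda: dict(DEFAULT_CENTROIDS))
    spreads: dict = field(default_factory=lambda: dict(DEFAULT_SPREADS))
    sizes: dict = field(default_factory=lambda: {g: dict(d) for g, d in DEFAULT_SIZES.items()})
    seed: int = 0
    truncation: str = "clip"  # or "resample"

    def __post_init__(self):
        for group, per_arch in self.counts.items():
            for arch, n in per_arch.items():
                if n < 0:
                    raise ValueError(f"negative count for ({group}, {arch})")
        for arch, (c21, c32) in self.centroids.items():
            if not (0 <= c21 <= 1 and 0 <= c32 <= 1):
                raise ValueError(f"centroid for {arch} outside [0, 1]^2")
        if self.truncation not in ("clip", "resample"):
            raise ValueError("truncation must be 'clip' or 'resample'")


def _draw_truncated(rng, mean, sd, n, mode):
    if mode == "clip":
        return np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n)
        ok = draw[(draw >= 0) & (draw <= 1)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Synthetic descriptor table with group labels.

    Each pocket's (rEV21, rEV32) pair is drawn around its archetype centroid
    (Gaussian, truncated to [0, 1] by clipping by default), rEV31 is set to
    the product, and size descriptors are drawn from the per-group
    distributions.  Columns: pocket_id, group, archetype_true, rEV21, rEV32,
    rEV31, n_atoms, Rg.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for group, per_arch in spec.counts.items():
        for arch, n in per_arch.items():
            if n == 0:
                continue
            c21, c32 = spec.centroids[arch]
            s21, s32 = spec.spreads[arch]
            r21 = _draw_truncated(rng, c21, s21, n, spec.truncation)
            r32 = _draw_truncated(rng, c32, s32, n, spec.truncation)
            atoms_mu, atoms_sd, rg_mu, rg_sd = spec.sizes[group][arch]
            n_atoms = np.maximum(np.round(rng.normal(atoms_mu, atoms_sd, n)), 4).astype(int)
            rg = np.maximum(rng.normal(rg_mu, rg_sd, n), 0.1)
            for i in range(n):
                rows.append(
                    {
                        "pocket_id": f"{group}_{arch}_{i}",
                        "group": group,
                        "archetype_true": arch,
                        "rEV21": r21[i],
                        "rEV32": r32[i],
                        "rEV31": r21[i] * r32[i],
                        "n_atoms": n_atoms[i],
                        "Rg": rg[i],
                    }
                )
    return pd.DataFrame(rows)


def sample_two_blob_cohort(
    n_per_group: int = 300,
    low: tuple[float, float] = (0.3, 0.3),
    high: tuple[float, float] = (0.8, 0.8),
    spread: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Gap-separated fixture: one group per blob, so every stratified
    resample pools equal blob counts and the refitted medians always fall in
    the wide gap between blobs.  Every pocket then sits far from every
    achievable threshold, making the partition perfectly bootstrap-stable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, center in (("RNA", low), ("protein", high)):
        r21 = np.clip(rng.normal(center[0], spread, n_per_group), 0, 1)
        r32 = np.clip(rng.normal(center[1], spread, n_per_group), 0, 1)
        for i in range(n_per_group):
            rows.append(
                {
                    "pocket_id": f"{group}_{i}",
                    "group": group,
                    "rEV21": r21[i],
                    "rEV32": r32[i],
                    "rEV31": r21[i] * r32[i],
                }
            )
    return pd.DataFrame(rows)
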