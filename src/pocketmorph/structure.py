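"""Reading macromolecular structures and extracting ligand-centered pockets.

A binding pocket is defined by proximity to a bound small-molecule ligand:
every residue (or, in atom mode, every individual atom) of the macromolecule
with at least one heavy atom within a distance cutoff of any ligand heavy
atom belongs to the pocket.  The default cutoff of 6 Angstroms captures the
immediate interaction shell while preserving the global geometry of the site.

Structures are read with gemmi (PDB and mmCIF).  Preprocessing removes
solvent, monoatomic ions and hydrogens, and keeps only the first listed
alternate conformation of each atom, so that RNA and protein complexes are
represented homogeneously before any geometry is computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import DegeneratePocketError, LigandSelectionError, StructureParseError

logger = logging.getLogger(__name__)

#: Residue names treated as solvent.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Residue names treated as monoatomic ions and removed during preprocessing.
#: Polyatomic hetero groups (PO4, SO4, ...) are retained; pass a custom list
#: to :func:`preprocess` to change this.
DEFAULT_ION_NAMES = frozenset(
    {"NA", "K", "MG", "CA", "ZN", "CL", "MN", "FE", "NI", "CU", "CO", "CD", "BR", "IOD"}
)

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, with enough provenance to re-serialize it."""

    chain_id: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    is_hetero: bool
    altloc: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        """(chain, seq, icode, name) identifying the residue this atom belongs to."""
        return (self.chain_id, self.residue_seq, self.insertion_code, self.residue_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class StructureModel:
    """A single-model structure as a flat list of atoms."""

    structure_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def residues(self) -> dict[tuple, list[AtomRecord]]:
        """Atoms grouped by residue, preserving file order."""
        out: dict[tuple, list[AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault(atom.residue_key, []).append(atom)
        return out


@dataclass(frozen=True)
class LigandSelector:
    """Identifies one ligand instance by residue name, optionally chain and number."""

    residue_name: str
    chain_id: str | None = None
    residue_seq: int | None = None

    def matches(self, key: tuple[str, int, str, str]) -> bool:
        chain, seq, _icode, name = key
        if name != self.residue_name:
            return False
        if self.chain_id is not None and chain != self.chain_id:
            return False
        if self.residue_seq is not None and seq != self.residue_seq:
            return False
        return True

    @classmethod
    def parse(cls, spec: str) -> "LigandSelector":
        """Parse ``NAME``, ``NAME:CHAIN`` or ``NAME:CHAIN:SEQ``."""
        parts = spec.split(":")
        name = parts[0]
        chain = parts[1] if len(parts) > 1 and parts[1] else None
        seq = int(parts[2]) if len(parts) > 2 and parts[2] else None
        return cls(name, chain, seq)


@dataclass
class PocketAtomCloud:
    """Heavy-atom point cloud of one ligand-proximal binding pocket."""

    structure_id: str
    ligand_id: str
    level: str  # "residue" or "atom"
    cutoff: float
    member_residues: list[tuple[str, int, str, str]]
    coords: np.ndarray  # (N, 3) in Angstroms
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_residues(self) -> int:
        return len(self.member_residues)

    @property
    def is_degenerate(self) -> bool:
        """Fewer than 4 atoms cannot define a 3-D shape."""
        return self.n_atoms < 4

    def provenance(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "ligand": self.ligand_id,
            "cutoff": self.cutoff,
            "level": self.level,
            "n_atoms": self.n_atoms,
            "n_residues": self.n_residues,
        }


def _structure_to_model(st: gemmi.Structure, structure_id: str) -> StructureModel:
    if len(st) == 0:
        raise StructureParseError(f"{structure_id}: structure contains no models")
    model = st[0]  # first model only; NMR ensembles are truncated here
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                pos = atom.pos
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        atom_name=atom.name,
                        element=atom.element.name,
                        coords=(pos.x, pos.y, pos.z),
                        is_hetero=het,
                        altloc=atom.altloc or "",
                    )
                )
    if not atoms:
        raise StructureParseError(f"{structure_id}: structure contains no atoms")
    return StructureModel(structure_id=structure_id, atoms=atoms)


def load_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is kept.  Coordinates are taken
    verbatim from the coordinate records.

    Parameters
    ----------
    path : str or Path
        Structure file.
    format : {"auto", "pdb", "mmcif"}
        File format; "auto" dispatches on content/extension via gemmi.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and format not in ("pdb", "mmcif", "auto"):
            raise
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    structure_id = st.name.strip() or path.stem
    return _structure_to_model(st, structure_id)


def preprocess(
    model: StructureModel,
    keep_hydrogens: bool = False,
    ion_names: Iterable[str] = DEFAULT_ION_NAMES,
) -> StructureModel:
    """Apply the standard cleanup rules before pocket extraction.

    Removes water, monoatomic ions, hydrogen/deuterium atoms (unless
    ``keep_hydrogens``), and for atoms with alternate conformations keeps only
    the first listed one.  The number of removed atoms is logged.
    """
    ion_set = {n.upper() for n in ion_names}
    kept: list[AtomRecord] = []
    seen_altloc: set[tuple] = set()
    for atom in model.atoms:
        resname = atom.residue_name.upper()
        if resname in WATER_NAMES or resname in ion_set:
            continue
        if atom.is_hydrogen and not keep_hydrogens:
            continue
        key = (atom.chain_id, atom.residue_seq, atom.insertion_code, atom.atom_name)
        if atom.altloc:
            if key in seen_altloc:
                continue
            seen_altloc.add(key)
        kept.append(atom)
    removed = len(model.atoms) - len(kept)
    logger.info("preprocess(%s): removed %d of %d atoms", model.structure_id, removed, len(model.atoms))
    if not kept:
        logger.warning("preprocess(%s): empty structure after cleanup", model.structure_id)
    return StructureModel(structure_id=model.structure_id, atoms=kept)


def find_ligand_instances(
    model: StructureModel, ligand: LigandSelector
) -> list[tuple[str, int, str, str]]:
    """All residue keys matching the selector, in file order."""
    seen: list[tuple] = []
    for atom in model.atoms:
        key = atom.residue_key
        if ligand.matches(key) and key not in seen:
            seen.append(key)
    return seen


def extract_pocket(
    model: StructureModel,
    ligand: LigandSelector,
    cutoff: float = 6.0,
    level: str = "residue",
) -> PocketAtomCloud:
    """Extract the binding pocket around one ligand instance.

    The probe set is always the ligand's *heavy* atoms.  In residue mode, if
    any heavy atom of a residue lies within ``cutoff`` (inclusive) of any
    ligand heavy atom, every atom of that residue joins the pocket; in atom
    mode only the individual heavy atoms within the cutoff are returned.
    Pocket membership is decided on heavy atoms in both hydrogen modes, so a
    model preprocessed with ``keep_hydrogens=True`` yields the same member
    residues, with hydrogens added to the returned cloud in residue mode.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if level not in ("residue", "atom"):
        raise ValueError(f"level must be 'residue' or 'atom', got {level!r}")

    instances = find_ligand_instances(model, ligand)
    if len(instances) == 0:
        raise LigandSelectionError(
            f"no residue matches {ligand} in {model.structure_id}"
        )
    if len(instances) > 1:
        raise LigandSelectionError(
            f"ambiguous ligand {ligand} in {model.structure_id}: candidates "
            + ", ".join(f"{c}/{s}{ic}/{n}" for c, s, ic, n in instances)
        )
    ligand_key = instances[0]

    ligand_xyz = np.array(
        [a.coords for a in model.atoms if a.residue_key == ligand_key and not a.is_hydrogen],
        dtype=float,
    )
    if ligand_xyz.size == 0:
        raise LigandSelectionError(f"ligand {ligand_key} has no heavy atoms")

    candidates = [a for a in model.atoms if a.residue_key != ligand_key]
    heavy = [a for a in candidates if not a.is_hydrogen]
    if not heavy:
        raise DegeneratePocketError("structure has no non-ligand heavy atoms")

    tree = cKDTree(ligand_xyz)
    heavy_xyz = np.array([a.coords for a in heavy], dtype=float)
    dmin = tree.query(heavy_xyz, k=1)[0]
    within = dmin <= cutoff  # inclusive by convention

    if level == "atom":
        members = [a for a, w in zip(heavy, within) if w]
        residue_keys = []
        for a in members:
            if a.residue_key not in residue_keys:
                residue_keys.append(a.residue_key)
    else:
        hit_residues = {a.residue_key for a, w in zip(heavy, within) if w}
        residue_keys = []
        members = []
        for a in candidates:
            if a.residue_key in hit_residues:
                members.append(a)
                if a.residue_key not in residue_keys:
                    residue_keys.append(a.residue_key)

    if not members:
        raise DegeneratePocketError(
            f"no pocket atoms within {cutoff} A of {ligand_key} in {model.structure_id}"
        )

    cloud = PocketAtomCloud(
        structure_id=model.structure_id,
        ligand_id=ligand_key[3],
        level=level,
        cutoff=float(cutoff),
        member_residues=residue_keys,
        coords=np.array([a.coords for a in members], dtype=float),
        atoms=members,
    )
    if cloud.is_degenerate:
        logger.warning(
            "pocket %s/%s is degenerate (%d atoms)",
            model.structure_id,
            cloud.ligand_id,
            cloud.n_atoms,
        )
    return cloud


def records_to_gemmi(
    model_records: Sequence[Sequence[AtomRecord]], name: str = "structure"
) -> gemmi.Structure:
    """Build a gemmi Structure from one or more lists of atom records.

    Each inner sequence becomes one MODEL block (multi-model files are used
    by the synthetic fixtures to exercise the first-model rule).
    """
    st = gemmi.Structure()
    st.name = name
    for m, records in enumerate(model_records, start=1):
        gmodel = gemmi.Model(m)
        chains: dict[str, gemmi.Chain] = {}
        current_res: dict[tuple, gemmi.Residue] = {}
        for atom in records:
            if atom.chain_id not in chains:
                chains[atom.chain_id] = gemmi.Chain(atom.chain_id)
            key = atom.residue_key
            if key not in current_res:
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_seq, atom.insertion_code or " ")
                res.het_flag = "H" if atom.is_hetero else "A"
                chains[atom.chain_id].add_residue(res)
                current_res[key] = chains[atom.chain_id][-1]
            a = gemmi.Atom()
            a.name = atom.atom_name
            a.element = gemmi.Element(atom.element)
            a.pos = gemmi.Position(*atom.coords)
            a.altloc = "\0" if not atom.altloc else atom.altloc
            current_res[key].add_atom(a)
        for chain in chains.values():
            gmodel.add_chain(chain)
        st.add_model(gmodel)
    st.setup_entities()
    return st


def write_pocket(cloud: PocketAtomCloud, out_dir: str | Path, stem: str | None = None) -> tuple[Path, Path]:
    """Write a pocket as a PDB subset file plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{cloud.structure_id}_{cloud.ligand_id}_pocket"
    pdb_path = out_dir / f"{stem}.pdb"
    json_path = out_dir / f"{stem}.json"

    st = records_to_gemmi([cloud.atoms], name=cloud.structure_id)
    st.write_pdb(str(pdb_path))
    json_path.write_text(json.dumps(cloud.provenance(), indent=2) + "\n")
    return pdb_path, json_path


def batch_extract(
    model: StructureModel,
    ligand_name: str,
    cutoff: float = 6.0,
    level: str = "residue",
) -> list[PocketAtomCloud]:
    """One pocket per instance of a (possibly multi-copy) ligand."""
    instances = find_ligand_instances(model, LigandSelector(ligand_name))
    clouds = []
    for chain, seq, _icode, name in instances:
        sel = LigandSelector(name, chain, seq)
        clouds.append(extract_pocket(model, sel, cutoff=cutoff, level=level))
    return clouds
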