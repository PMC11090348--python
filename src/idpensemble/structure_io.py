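"""Reading, validating and writing structure ensembles.

The unit of analysis everywhere in this package is a :class:`StructureEnsemble`:
an ordered collection of structure models (AlphaFold2 predictions or MD
snapshots exported as PDB frames) that share one residue layout.  This module
parses PDB files (via Biopython), strips hydrogens and non-amino-acid
heteroatoms, enforces layout consistency across members, and reads AlphaFold
PAE matrices from their JSON dialects.

AF2 models store the per-residue pLDDT confidence in the B-factor column;
MD frames carry meaningless B-factors, which callers flag with
``plddt_in_bfactor=False`` so confidence-based statistics refuse to run on
them instead of producing nonsense.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "ResidueKey",
    "StructureModel",
    "StructureEnsemble",
    "PAEMap",
    "StructureFormatError",
    "EnsembleConsistencyError",
    "read_structure",
    "read_structures",
    "load_ensemble",
    "write_pdb",
    "read_pae",
]

#: Three-letter codes accepted as amino-acid residues (the 20 standard ones
#: plus selenomethionine, which AF2 never emits but MD post-processing can).
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE".split()
)

#: Histidine protonation-state names some MD packages write instead of HIS.
_HIS_ALIASES = {"HSE": "HIS", "HSD": "HIS", "HSP": "HIS", "HIE": "HIS",
                "HID": "HIS", "HIP": "HIS"}


class StructureFormatError(ValueError):
    """A file could not be interpreted as the expected structure format."""


class EnsembleConsistencyError(ValueError):
    """Ensemble members do not share a single residue layout."""


class ResidueKey(NamedTuple):
    """Identity of one residue: (chain, author index, insertion code, name)."""

    chain_id: str
    residue_index: int
    insertion_code: str
    residue_name: str


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its residue identity and confidence value."""

    chain_id: str
    residue_index: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    confidence: float

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_index,
                          self.insertion_code, self.residue_name)


def _is_hydrogen(element: str, atom_name: str) -> bool:
    # Element column preferred; MD tools often omit it, so fall back to the
    # first alphabetic character of the atom name (handles "1HB" etc.).
    el = element.strip().upper()
    if el:
        return el in ("H", "D")
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper() in ("H", "D")
    return False


class StructureModel:
    """A single structure: heavy atoms grouped by residue, in file order.

    Parameters
    ----------
    model_id : str
        Label for this model (file stem, or stem#k for multi-MODEL files).
    atoms : sequence of Atom
        Heavy atoms only; atoms of one residue must be contiguous.
    plddt_valid : bool
        Whether the confidence values are interpretable as pLDDT in [0, 100].
    """

    def __init__(self, model_id: str, atoms: Sequence[Atom],
                 plddt_valid: bool = True):
        if not atoms:
            raise StructureFormatError(
                f"model {model_id!r} contains no amino-acid heavy atoms")
        self.model_id = model_id
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.plddt_valid = plddt_valid

        residues: list[ResidueKey] = []
        atom_residue: list[int] = []
        for atom in self.atoms:
            key = atom.residue_key
            if not residues or residues[-1] != key:
                if key in residues:
                    raise StructureFormatError(
                        f"model {model_id!r}: atoms of residue {key} are not "
                        "contiguous")
                residues.append(key)
            atom_residue.append(len(residues) - 1)
        self.residues: tuple[ResidueKey, ...] = tuple(residues)
        self.atom_residue = np.asarray(atom_residue, dtype=np.intp)

        self.coords = np.array([a.position for a in self.atoms], dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureFormatError(
                f"model {model_id!r} has non-finite coordinates")
        self.confidences = np.array([a.confidence for a in self.atoms],
                                    dtype=float)
        if plddt_valid:
            bad = (self.confidences < 0.0) | (self.confidences > 100.0)
            if np.any(bad):
                raise StructureFormatError(
                    f"model {model_id!r}: confidence values outside [0, 100]; "
                    "pass plddt_in_bfactor=False for MD frames")

        # Strict ordering of residues within each chain.
        per_chain: dict[str, list[tuple[int, str]]] = {}
        for key in residues:
            per_chain.setdefault(key.chain_id, []).append(
                (key.residue_index, key.insertion_code))
        for chain_id, order in per_chain.items():
            if any(a >= b for a, b in zip(order, order[1:])):
                raise StructureFormatError(
                    f"model {model_id!r}: residues of chain {chain_id!r} are "
                    "not strictly ordered")

        # Contiguous residue blocks enable reduceat-style aggregation.
        boundaries = np.flatnonzero(np.diff(self.atom_residue)) + 1
        self.residue_starts = np.concatenate(([0], boundaries))

    # -- derived views -----------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for key in self.residues:
            if key.chain_id not in seen:
                seen.append(key.chain_id)
        return tuple(seen)

    def chain_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for key in self.residues:
            out[key.chain_id] = out.get(key.chain_id, 0) + 1
        return out

    def ca_indices(self) -> np.ndarray:
        """Index of the CA atom of each residue (error if one is missing)."""
        idx = np.full(self.n_residues, -1, dtype=np.intp)
        for i, atom in enumerate(self.atoms):
            if atom.atom_name == "CA" and idx[self.atom_residue[i]] < 0:
                idx[self.atom_residue[i]] = i
        if np.any(idx < 0):
            missing = self.residues[int(np.argmax(idx < 0))]
            raise StructureFormatError(
                f"model {self.model_id!r}: residue {missing} has no CA atom")
        return idx

    def layout(self) -> tuple[ResidueKey, ...]:
        return self.residues

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    model_id: str | None = None) -> "StructureModel":
        """Copy of the model under the rigid motion x -> R x + t."""
        new_coords = self.coords @ np.asarray(rotation, dtype=float).T \
            + np.asarray(translation, dtype=float)
        return self.with_coords(new_coords, model_id=model_id)

    def with_coords(self, coords: np.ndarray,
                    model_id: str | None = None) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.chain_id, a.residue_index, a.insertion_code,
                 a.residue_name, a.atom_name, a.element,
                 tuple(coords[i]), a.confidence)
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(model_id or self.model_id, atoms,
                              plddt_valid=self.plddt_valid)

    def with_confidences(self, values: np.ndarray,
                         model_id: str | None = None) -> "StructureModel":
        values = np.asarray(values, dtype=float)
        if values.shape != self.confidences.shape:
            raise ValueError("confidence array shape mismatch")
        atoms = [
            Atom(a.chain_id, a.residue_index, a.insertion_code,
                 a.residue_name, a.atom_name, a.element, a.position,
                 float(values[i]))
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(model_id or self.model_id, atoms,
                              plddt_valid=True)

    def residue_letters(self) -> list[str]:
        """One-letter code per residue ('X' for anything non-standard)."""
        return [seq1(k.residue_name.capitalize(), undef_code="X")
                for k in self.residues]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<StructureModel {self.model_id!r}: {len(self.atoms)} atoms, "
                f"{self.n_residues} residues, {len(self.chains)} chain(s)>")


@dataclass
class StructureEnsemble:
    """Ordered collection of models sharing one residue layout."""

    members: list[StructureModel]
    source_tag: str = ""
    layout: tuple[ResidueKey, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise EnsembleConsistencyError("ensemble has no members")
        self.layout = self.members[0].layout()
        for m in self.members[1:]:
            if m.layout() != self.layout:
                raise EnsembleConsistencyError(
                    f"model {m.model_id!r} does not match the layout of "
                    f"{self.members[0].model_id!r} "
                    f"({m.n_residues} vs {len(self.layout)} residues)")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> StructureModel:
        return self.members[i]

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.members]

    @property
    def n_residues(self) -> int:
        return len(self.layout)

    def require_size(self, n: int, what: str) -> None:
        if len(self) < n:
            raise EnsembleConsistencyError(
                f"{what} requires an ensemble of at least {n} members, "
                f"got {len(self)}")


@dataclass(frozen=True)
class PAEMap:
    """AlphaFold predicted-aligned-error matrix in Å (may be asymmetric)."""

    matrix: np.ndarray
    n_residues: int

    def symmetrized(self) -> np.ndarray:
        return 0.5 * (self.matrix + self.matrix.T)


# ---------------------------------------------------------------------------
# PDB reading

def _convert_biopdb_model(bio_model, model_id: str,
                          plddt_in_bfactor: bool) -> StructureModel:
    atoms: list[Atom] = []
    degenerate: list[ResidueKey] = []
    for chain in bio_model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            resname = residue.get_resname().strip()
            resname = _HIS_ALIASES.get(resname, resname)
            if resname not in STANDARD_RESIDUES:
                continue  # waters, ions, ligands
            heavy_here = 0
            for atom in residue:  # selected altloc only (highest occupancy)
                if _is_hydrogen(atom.element or "", atom.get_name()):
                    continue
                heavy_here += 1
                x, y, z = atom.get_coord()
                atoms.append(Atom(
                    chain_id=chain.get_id().strip() or "A",
                    residue_index=int(resseq),
                    insertion_code=icode.strip(),
                    residue_name=resname,
                    atom_name=atom.get_name(),
                    element=(atom.element or "").strip().upper(),
                    position=(float(x), float(y), float(z)),
                    confidence=float(atom.get_bfactor()),
                ))
            if heavy_here == 0:
                degenerate.append(ResidueKey(chain.get_id(), int(resseq),
                                             icode.strip(), resname))
    if degenerate:
        raise StructureFormatError(
            f"model {model_id!r}: residue(s) {degenerate} contain no heavy "
            "atoms")
    return StructureModel(model_id, atoms, plddt_valid=plddt_in_bfactor)


def read_structures(path: str | os.PathLike,
                    plddt_in_bfactor: bool = True) -> list[StructureModel]:
    """Read every MODEL of a PDB file as a separate :class:`StructureModel`.

    Hydrogens, waters and non-amino-acid HETATM records are dropped.  For
    disordered atoms the highest-occupancy altloc is kept (first seen wins
    ties).  With ``plddt_in_bfactor`` the B-factor column is validated and
    stored as per-atom pLDDT; otherwise confidences are kept but flagged
    unusable for pLDDT statistics.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise StructureFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    bio_models = list(structure)
    if not bio_models:
        raise StructureFormatError(f"{path} contains no MODEL records or atoms")
    out = []
    for k, bio_model in enumerate(bio_models):
        mid = path.stem if len(bio_models) == 1 else f"{path.stem}#{k}"
        out.append(_convert_biopdb_model(bio_model, mid, plddt_in_bfactor))
    return out


def read_structure(path: str | os.PathLike,
                   plddt_in_bfactor: bool = True) -> StructureModel:
    """Read a single-model PDB file (first MODEL if several are present)."""
    return read_structures(path, plddt_in_bfactor=plddt_in_bfactor)[0]


def load_ensemble(source: str | os.PathLike | Iterable[str | os.PathLike],
                  source_tag: str = "",
                  plddt_in_bfactor: bool = True) -> StructureEnsemble:
    """Assemble a :class:`StructureEnsemble` from PDB files.

    ``source`` may be a directory (all ``*.pdb`` files, sorted by name), a
    single multi-MODEL file, or an explicit collection of paths (sorted by
    name).  The layout of the first model is the reference; any member that
    deviates raises :class:`EnsembleConsistencyError` naming the file.
    """
    if isinstance(source, (str, os.PathLike)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("*.pdb"))
    elif isinstance(source, (str, os.PathLike)):
        paths = [Path(source)]
    else:
        paths = sorted(Path(p) for p in source)
    if not paths:
        raise StructureFormatError("no PDB files found")

    members: list[StructureModel] = []
    for p in paths:
        for model in read_structures(p, plddt_in_bfactor=plddt_in_bfactor):
            if members and model.layout() != members[0].layout():
                raise EnsembleConsistencyError(
                    f"{p} (model {model.model_id!r}) does not match the "
                    f"residue layout of {members[0].model_id!r}")
            members.append(model)
    if len(members) < 2:
        raise EnsembleConsistencyError(
            "an ensemble needs at least 2 models; provide a directory, "
            "multiple files, or a multi-MODEL file")
    return StructureEnsemble(members, source_tag=source_tag)


# ---------------------------------------------------------------------------
# PDB writing (normalized fixed-width output; confidence -> B-factor)

def _pdb_atom_line(serial: int, atom: Atom) -> str:
    name = atom.atom_name
    # Standard alignment: 1-3 char names start in column 14.
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = atom.position
    return (f"ATOM  {serial:>5d} {name_field} {atom.residue_name:<3s} "
            f"{atom.chain_id[:1]:1s}{atom.residue_index:>4d}"
            f"{atom.insertion_code[:1] or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{atom.confidence:6.2f}"
            f"          {atom.element:>2s}")


def write_pdb(obj: StructureModel | StructureEnsemble,
              path: str | os.PathLike) -> None:
    """Write a model, or an ensemble as a multi-MODEL file."""
    models = obj.members if isinstance(obj, StructureEnsemble) else [obj]
    lines: list[str] = []
    multi = len(models) > 1
    for k, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4d}")
        serial = 0
        prev_chain = None
        for atom in model.atoms:
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain_id
            serial += 1
            lines.append(_pdb_atom_line(serial, atom))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PAE matrices

def read_pae(path: str | os.PathLike) -> PAEMap:
    """Read an AF2-style PAE JSON file.

    Accepts ``{"predicted_aligned_error": [[...]]}``, the list-wrapped scores
    dialect ``[{"predicted_aligned_error": [[...]]}]``, and a bare nested
    array.  The matrix must be square with non-negative entries; asymmetry is
    legal (PAE is conditional on the aligned residue).
    """
    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StructureFormatError(f"cannot read PAE JSON {path}: {exc}") from exc
    if isinstance(data, list) and data and isinstance(data[0], dict):
        data = data[0]
    if isinstance(data, dict):
        try:
            data = data["predicted_aligned_error"]
        except KeyError:
            raise StructureFormatError(
                f"{path}: no 'predicted_aligned_error' key in PAE JSON")
    matrix = np.asarray(data, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise StructureFormatError(
            f"{path}: PAE matrix must be square, got shape {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise StructureFormatError(f"{path}: PAE matrix has non-finite entries")
    if np.any(matrix < 0):
        raise ValueError(f"{path}: PAE matrix has negative entries")
    return PAEMap(matrix=matrix, n_residues=matrix.shape[0])
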