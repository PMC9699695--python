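"""Core data model: atoms, frames, molecular systems, leaflet/subunit labels.

The model is deliberately lightweight: analysis operators in this package
only need atom names, residue bookkeeping, species classes, heavy-atom
flags and coordinates.  No topology (bonds) is stored.

Conventions
-----------
* lengths in nm, times in ns
* frame indices are 0-based; intervals are half-open [start, end)
* species classes: ``protein``, ``lipid``, ``sterol``, ``water``, ``ion``
* leaflet labels: ``inner`` (below midplane), ``outer`` (above), or
  ``unassigned``
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Species classification tables (overridable per system)
# ---------------------------------------------------------------------------

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
    # pseudo-residues emitted by the synthetic generators: globular body
    # beads and hairpin (base/tip) beads of a protein subunit
    "GBD", "HPN",
}

_WATER_RESIDUES = {"SOL", "TIP3", "TIP4", "WAT", "HOH", "SPC"}

_ION_RESIDUES = {"NA", "CL", "SOD", "CLA", "K", "POT", "CA", "CAL", "MG"}

_STEROL_RESIDUES = {"CHOL", "CHL1", "ERG"}

# phospholipid and sphingolipid residue names of the asymmetric
# plasma-membrane mimetic, plus common single-component names
_LIPID_RESIDUES = {
    "PSM", "NSM", "LSM", "PLPC", "SOPC", "PAPC", "POPC", "DPPC", "DOPC",
    "PLA20", "PLAPE", "PDOPE", "PDPE", "SAPE", "POPE", "DOPE",
    "PAPS", "SAPS", "POPS", "PIP2", "POP2", "SAPI24", "PI45P2",
}

DEFAULT_SPECIES_CLASSES: dict[str, str] = {}
DEFAULT_SPECIES_CLASSES.update({r: "protein" for r in _AMINO_ACIDS})
DEFAULT_SPECIES_CLASSES.update({r: "water" for r in _WATER_RESIDUES})
DEFAULT_SPECIES_CLASSES.update({r: "ion" for r in _ION_RESIDUES})
DEFAULT_SPECIES_CLASSES.update({r: "sterol" for r in _STEROL_RESIDUES})
DEFAULT_SPECIES_CLASSES.update({r: "lipid" for r in _LIPID_RESIDUES})

#: Headgroup atom names per lipid species.  The default phospholipid set is
#: the phosphate group plus its linked polar oxygens; PI(4,5)P2 additionally
#: carries the inositol ring and ring phosphates; sterols the hydroxyl.
#: The synthetic generators emit single-bead headgroups named "P" (lipids)
#: and "O3" (sterols), which these sets cover.
_PHOSPHATE_SET = frozenset({"P", "O11", "O12", "O13", "O14", "O21", "O22"})
_PIP2_SET = _PHOSPHATE_SET | frozenset(
    {"C11", "C12", "C13", "C14", "C15", "C16",
     "P4", "P5", "OP42", "OP43", "OP44", "OP52", "OP53", "OP54"})
_STEROL_SET = frozenset({"O3", "H3'"})

DEFAULT_HEADGROUP_ATOMS: dict[str, frozenset[str]] = {
    **{r: _PHOSPHATE_SET for r in _LIPID_RESIDUES},
    **{r: _STEROL_SET for r in _STEROL_RESIDUES},
    "PIP2": _PIP2_SET, "POP2": _PIP2_SET, "PI45P2": _PIP2_SET,
}

#: Atom used as a lipid's reference position for leaflet bookkeeping and
#: slab boundaries: the phosphorus for phospholipids, the hydroxyl oxygen
#: for sterols.  Overridable per species via MolecularSystem.
DEFAULT_HEADGROUP_REFERENCE: dict[str, str] = {
    **{r: "P" for r in _LIPID_RESIDUES},
    **{r: "O3" for r in _STEROL_RESIDUES},
}

# element inference exceptions: ion atom names that would otherwise be
# read as C/N/... from their first letter
_ELEMENT_EXCEPTIONS = {
    "NA": "Na", "SOD": "Na", "CL": "Cl", "CLA": "Cl", "CAL": "Ca",
    "POT": "K", "MG": "Mg", "OW": "O", "HW1": "H", "HW2": "H",
}


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer an element symbol from a GRO/PDB atom name.

    GRO files carry no element field; the convention is that the first
    alphabetic character of the atom name is the element, with a small
    exception table for monatomic ions whose names collide with C/N
    prefixes (NA, CL, ...).
    """
    key = atom_name.strip().upper()
    if key in _ELEMENT_EXCEPTIONS:
        # only treat as an ion when the residue agrees (an "NA" atom inside
        # a lipid would be nitrogen); bare ions have residue == atom name
        if residue_name.strip().upper() in _ION_RESIDUES or not residue_name:
            return _ELEMENT_EXCEPTIONS[key]
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Atom:
    """A single atom: name, residue bookkeeping and inferred element."""

    name: str
    residue_name: str
    residue_id: int
    chain: str = ""
    element: str = ""

    def __post_init__(self) -> None:
        if self.residue_id < 0:
            raise ValueError(f"residue_id must be >= 0, got {self.residue_id}")
        if not self.element:
            self.element = infer_element(self.name, self.residue_name)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Frame:
    """Coordinates of one trajectory frame.

    Attributes
    ----------
    time : float
        Frame time in ns.
    positions : (n_atoms, 3) ndarray
        Cartesian coordinates in nm.
    box : (3,) ndarray
        Orthorhombic box lengths (Lx, Ly, Lz) in nm.
    """

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError(f"box components must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


class MolecularSystem:
    """Atoms plus per-residue species, leaflet and subunit labels.

    Residues are identified by contiguous runs of (residue_id,
    residue_name) in atom order and indexed 0..n_residues-1 internally.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        species_classes: Mapping[str, str] | None = None,
        headgroup_atoms: Mapping[str, Iterable[str]] | None = None,
        headgroup_reference: Mapping[str, str] | None = None,
    ) -> None:
        self.atoms = list(atoms)
        self.species_table = dict(DEFAULT_SPECIES_CLASSES)
        if species_classes:
            self.species_table.update(species_classes)
        self.headgroup_atoms = {k: frozenset(v) for k, v in DEFAULT_HEADGROUP_ATOMS.items()}
        if headgroup_atoms:
            self.headgroup_atoms.update({k: frozenset(v) for k, v in headgroup_atoms.items()})
        self.headgroup_reference = dict(DEFAULT_HEADGROUP_REFERENCE)
        if headgroup_reference:
            self.headgroup_reference.update(headgroup_reference)

        self._build_residue_index()
        self.species_class = np.array(
            [self.species_table.get(name, "lipid" if name in self.headgroup_atoms else "unknown")
             for name in self.residue_names], dtype=object)
        unknown = set(self.residue_names[self.species_class == "unknown"])
        if unknown:
            logger.warning("unclassified residue names treated as 'unknown': %s",
                           sorted(unknown))
        self.leaflet = np.array(["unassigned"] * self.n_residues, dtype=object)
        self.subunit = np.full(self.n_residues, -1, dtype=int)

        for ridx in self.lipid_residues():
            if not self._headgroup_set(ridx):
                raise ValueError(
                    f"lipid residue {self.residue_names[ridx]} has no headgroup "
                    f"atoms defined; extend headgroup_atoms")

    # -- residue bookkeeping ------------------------------------------------

    def _build_residue_index(self) -> None:
        res_of_atom = []
        names, ids, chains = [], [], []
        prev = None
        for atom in self.atoms:
            key = (atom.residue_id, atom.residue_name)
            if key != prev:
                names.append(atom.residue_name)
                ids.append(atom.residue_id)
                chains.append(atom.chain)
                prev = key
            res_of_atom.append(len(names) - 1)
        self.residue_of_atom = np.array(res_of_atom, dtype=int)
        self.residue_names = np.array(names, dtype=object)
        self.residue_ids = np.array(ids, dtype=int)
        self.residue_chains = np.array(chains, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def atoms_of_residue(self, ridx: int) -> np.ndarray:
        return np.flatnonzero(self.residue_of_atom == ridx)

    def residues_of_class(self, *classes: str) -> np.ndarray:
        mask = np.isin(self.species_class, classes)
        return np.flatnonzero(mask)

    def protein_residues(self) -> np.ndarray:
        return self.residues_of_class("protein")

    def lipid_residues(self) -> np.ndarray:
        """Lipids including sterols."""
        return self.residues_of_class("lipid", "sterol")

    # -- selections ---------------------------------------------------------

    def _headgroup_set(self, ridx: int) -> frozenset[str]:
        return self.headgroup_atoms.get(self.residue_names[ridx], frozenset())

    def heavy_atom_indices(self, ridx: int) -> np.ndarray:
        idx = self.atoms_of_residue(ridx)
        return idx[[self.atoms[i].is_heavy for i in idx]]

    def headgroup_heavy_indices(self, ridx: int) -> np.ndarray:
        """Heavy atoms of a lipid residue belonging to its headgroup."""
        hg = self._headgroup_set(ridx)
        idx = self.atoms_of_residue(ridx)
        return idx[[self.atoms[i].name in hg and self.atoms[i].is_heavy for i in idx]]

    def headgroup_reference_index(self, ridx: int) -> int:
        """Atom index of the lipid's reference atom (phosphorus by default,
        hydroxyl oxygen for sterols); falls back to the first headgroup
        heavy atom, then to the first atom of the residue."""
        ref_name = self.headgroup_reference.get(self.residue_names[ridx])
        idx = self.atoms_of_residue(ridx)
        if ref_name is not None:
            for i in idx:
                if self.atoms[i].name == ref_name:
                    return int(i)
        hg = self.headgroup_heavy_indices(ridx)
        if len(hg):
            return int(hg[0])
        return int(idx[0])

    def water_oxygen_indices(self) -> np.ndarray:
        out = []
        for ridx in self.residues_of_class("water"):
            for i in self.atoms_of_residue(ridx):
                if self.atoms[i].element == "O":
                    out.append(i)
        return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# Leaflet and subunit assignment
# ---------------------------------------------------------------------------

def assign_leaflets(system: MolecularSystem, frame: Frame) -> np.ndarray:
    """Label each lipid residue ``inner``/``outer`` by headgroup height.

    The membrane midplane is the mean z of all lipid headgroup reference
    atoms (phosphorus for phospholipids, hydroxyl oxygen for sterols);
    lipids above it are ``outer``, at or below it ``inner``.  The labels
    are stored on the system and returned.  Assumes the membrane normal
    is z; invariant under rigid z-translation by construction.
    """
    lipids = system.lipid_residues()
    if len(lipids) == 0:
        raise ValueError("no lipid residues present; cannot assign leaflets")
    ref_z = np.array([frame.positions[system.headgroup_reference_index(r), 2]
                      for r in lipids])
    midplane = ref_z.mean()
    labels = np.where(ref_z > midplane, "outer", "inner")
    system.leaflet[lipids] = labels
    if len(set(labels)) == 1:
        warnings.warn("all lipids fall in a single leaflet; membrane may be "
                      "a monolayer or mis-oriented", stacklevel=2)
    return system.leaflet


def assign_subunits(system: MolecularSystem, n_subunits: int | None = None) -> np.ndarray:
    """Label protein residues with 0-based subunit indices.

    Chain identifiers are used when present (subunit order = order of
    first appearance).  Without chains, the protein residues are split
    into ``n_subunits`` equal contiguous blocks; an indivisible residue
    count is an error.
    """
    prot = system.protein_residues()
    if len(prot) == 0:
        raise ValueError("no protein residues present")
    chains = system.residue_chains[prot]
    distinct = [c for c in dict.fromkeys(chains) if c]
    if len(distinct) > 1:
        chain_index = {c: k for k, c in enumerate(distinct)}
        system.subunit[prot] = [chain_index[c] for c in chains]
        return system.subunit
    if n_subunits is None:
        raise ValueError("no chain identifiers present; n_subunits required")
    if len(prot) % n_subunits != 0:
        raise ValueError(
            f"{len(prot)} protein residues not divisible into {n_subunits} "
            f"equal contiguous blocks and no chain identifiers are present")
    block = len(prot) // n_subunits
    system.subunit[prot] = np.repeat(np.arange(n_subunits), block)
    return system.subunit


def subunit_residues(system: MolecularSystem, subunit: int) -> np.ndarray:
    return np.flatnonzero(system.subunit == subunit)


def n_subunits(system: MolecularSystem) -> int:
    labels = system.subunit[system.subunit >= 0]
    return int(labels.max()) + 1 if len(labels) else 0
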