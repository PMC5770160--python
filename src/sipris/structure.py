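"""Residue-level structure model: PDB parsing, distances, contacts and
hydrogen bonds.

Coordinates are read with gemmi and reduced to a light-weight residue model:
ordered polymer residues (ATOM records) plus ligand groups (HETATM records,
including waters, ions and nucleic-acid chains).  Author (file) residue
numbering is authoritative throughout; no renumbering is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np

logger = logging.getLogger("sipris.structure")

__all__ = [
    "ResidueKey",
    "Residue",
    "StructureModel",
    "HydrogenBond",
    "HBondCriteria",
    "StructureParseError",
    "EmptySelectionError",
    "parse_structure",
    "residue_distance",
    "contacts_with",
    "detect_hbonds",
    "nearest_residue_to_focal",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
BACKBONE_H = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

# Chemically valid hydrogen-bond donor / acceptor heavy atoms for the 20
# standard residues.  Backbone N donates and backbone O/OXT accepts for all.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
STANDARD_RESIDUES = set(THREE_TO_ONE) - {"MSE"}


class StructureParseError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ResidueKey:
    """(chain, author seqnum, insertion code); lexicographic total order."""

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self):
        return f"{self.chain}:{self.seqnum}{self.icode}"


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: Dict[str, np.ndarray]
    elements: Dict[str, str]
    is_polymer: bool = True

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")
        for aname, xyz in self.atoms.items():
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates for {self.key} {aname}")

    def heavy_atoms(self) -> Dict[str, np.ndarray]:
        return {a: c for a, c in self.atoms.items()
                if self.elements.get(a, "") != "H"}

    def heavy_coords(self) -> np.ndarray:
        return np.array([c for a, c in self.atoms.items()
                         if self.elements.get(a, "") != "H"])

    def has_hydrogens(self) -> bool:
        return any(e == "H" for e in self.elements.values())


@dataclass
class StructureModel:
    """Ordered polymer residues plus ligand groups from one coordinate file."""

    residues: List[Residue]
    ligands: List[Residue]
    source_id: str = ""

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate polymer residue keys")
        self.residues = sorted(self.residues, key=lambda r: r.key)
        self._index = {r.key: r for r in self.residues}

    def __len__(self):
        return len(self.residues)

    def __contains__(self, key: ResidueKey):
        return key in self._index

    def __getitem__(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def keys(self) -> List[ResidueKey]:
        return [r.key for r in self.residues]

    def sequence(self) -> str:
        """One-letter sequence of the polymer residues (X for non-standard)."""
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def ligand_group(self, chain: str, seqnum: int, icode: str = "") -> Residue:
        key = ResidueKey(chain, seqnum, icode)
        for lig in self.ligands:
            if lig.key == key:
                return lig
        raise KeyError(f"no ligand {key} in {self.source_id}")


@dataclass(frozen=True)
class HydrogenBond:
    donor: Tuple[ResidueKey, str]
    acceptor: Tuple[ResidueKey, str]
    da_distance: float
    klass: str  # sc-sc | sc-bb | bb-bb

    def __post_init__(self):
        if self.donor[0] == self.acceptor[0]:
            raise ValueError("donor and acceptor residues must differ")
        if self.da_distance <= 0:
            raise ValueError("donor-acceptor distance must be positive")
        if self.klass not in ("sc-sc", "sc-bb", "bb-bb"):
            raise ValueError(f"unknown hydrogen-bond class {self.klass!r}")

    def residues(self) -> Tuple[ResidueKey, ResidueKey]:
        return self.donor[0], self.acceptor[0]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric thresholds for hydrogen-bond detection.

    With explicit hydrogens: H...A <= ``ha_max`` (Angstrom) and the
    D-H...A angle >= ``dha_min_deg``.  Without hydrogens the fallback is
    a plain donor...acceptor heavy-atom cutoff ``da_max``.
    """

    ha_max: float = 2.5
    dha_min_deg: float = 120.0
    da_max: float = 3.5


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _validate_coordinate_lines(text: str):
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise StructureParseError(
                    f"malformed coordinate fields on line {i}: {line.rstrip()!r}")


def _pick_altloc(res: gemmi.Residue):
    """Resolve altLocs to the highest-occupancy conformer (ties -> 'A')."""
    by_name: Dict[str, List[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    for name, group in by_name.items():
        yield name, min(group, key=lambda a: (-a.occ, a.altloc or "A"))


def parse_structure(text: str, model_index: int = 0,
                    chains: Optional[Sequence[str]] = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    The first model is used by default (``model_index`` selects others, e.g.
    for NMR ensembles).  altLoc is resolved to the highest-occupancy
    conformer; HETATM groups (including waters) are routed to ligands.
    """
    _validate_coordinate_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise StructureParseError("no models in structure")
    if model_index >= len(st):
        raise StructureParseError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    chain_names = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in chain_names]
        if missing:
            raise EmptySelectionError(
                f"chain(s) {missing} not present; available: {chain_names}")
    polymers: List[Residue] = []
    ligands: List[Residue] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for gres in chain:
            atoms, elements = {}, {}
            for name, atom in _pick_altloc(gres):
                atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                is_h = atom.element.is_hydrogen
                if callable(is_h):  # gemmi < 0.7 exposes a method
                    is_h = is_h()
                elements[name] = "H" if is_h else atom.element.name
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            key = ResidueKey(chain.name, gres.seqid.num, icode)
            is_het = gres.het_flag == "H" or gres.name in WATER_NAMES
            residue = Residue(key=key, name=gres.name, atoms=atoms,
                              elements=elements, is_polymer=not is_het)
            (ligands if is_het else polymers).append(residue)
    if not polymers:
        raise EmptySelectionError("selection contains no polymer (ATOM) residues")
    sel = "" if chains is None else ":" + "".join(chains)
    return StructureModel(residues=polymers, ligands=ligands,
                          source_id=(st.name or "structure") + sel)


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------

def _min_atom_distance(a: Residue, b: Residue) -> float:
    ca, cb = a.heavy_coords(), b.heavy_coords()
    if ca.size == 0 or cb.size == 0:
        raise ValueError(f"no heavy atoms for {a.key} or {b.key}")
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float(d.min())


def _cb_coord(r: Residue) -> np.ndarray:
    if "CB" in r.atoms:
        return r.atoms["CB"]
    if "CA" in r.atoms:
        return r.atoms["CA"]
    raise ValueError(f"residue {r.key} ({r.name}) has neither CB nor CA")


def residue_distance(a: Residue, b: Residue, metric: str = "min-atom") -> float:
    """Distance between two residues in Angstrom.

    ``min-atom``: minimum over heavy-atom pairs (default).  ``cb``: between
    CB atoms (CA for glycine).
    """
    if a.key == b.key:
        return 0.0
    if metric == "min-atom":
        return _min_atom_distance(a, b)
    if metric == "cb":
        return float(np.linalg.norm(_cb_coord(a) - _cb_coord(b)))
    raise ValueError(f"unknown metric {metric!r}")


def distance_matrix(model: StructureModel, metric: str = "min-atom") -> np.ndarray:
    """Symmetric residue-residue distance matrix over polymer residues."""
    n = len(model)
    if metric == "cb":
        coords = np.array([_cb_coord(r) for r in model.residues])
        diff = coords[:, None, :] - coords[None, :, :]
        return np.linalg.norm(diff, axis=-1)
    coords = [r.heavy_coords() for r in model.residues]
    flat = np.concatenate(coords)
    counts = np.array([len(c) for c in coords])
    owner = np.repeat(np.arange(n), counts)
    d_at = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=-1)
    out = np.full((n, n), np.inf)
    # reduce atom-level distances to residue-level minima
    np.minimum.at(out, (owner[:, None].repeat(len(flat), 1),
                        owner[None, :].repeat(len(flat), 0)), d_at)
    np.fill_diagonal(out, 0.0)
    return out


def contacts_with(model: StructureModel, target: Sequence[Residue],
                  cutoff: float = 4.0) -> Set[ResidueKey]:
    """Polymer residues with any heavy atom within ``cutoff`` of any target
    heavy atom.  Target residues themselves are excluded from the result."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    target = list(target)
    if not target:
        raise EmptySelectionError("contact target is empty")
    tcoords = np.concatenate([t.heavy_coords() for t in target])
    tkeys = {t.key for t in target}
    hits: Set[ResidueKey] = set()
    for r in model.residues:
        if r.key in tkeys:
            continue
        rc = r.heavy_coords()
        if rc.size == 0:
            continue
        d = np.linalg.norm(rc[:, None, :] - tcoords[None, :, :], axis=-1)
        if d.min() <= cutoff:
            hits.add(r.key)
    return hits


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _donor_atoms(r: Residue) -> List[str]:
    out = []
    if "N" in r.atoms and r.name != "PRO":
        out.append("N")
    out.extend(a for a in SIDECHAIN_DONORS.get(r.name, ()) if a in r.atoms)
    return out


def _acceptor_atoms(r: Residue) -> List[str]:
    out = [a for a in ("O", "OXT") if a in r.atoms]
    out.extend(a for a in SIDECHAIN_ACCEPTORS.get(r.name, ()) if a in r.atoms)
    return out


def _attached_hydrogens(r: Residue, heavy: str) -> List[str]:
    hpos = r.atoms[heavy]
    return [a for a, e in r.elements.items()
            if e == "H" and np.linalg.norm(r.atoms[a] - hpos) <= 1.25]


def _atom_class(atom: str) -> str:
    return "bb" if atom in BACKBONE_ATOMS or atom in BACKBONE_H else "sc"


def _bond_klass(donor_atom: str, acceptor_atom: str) -> str:
    pair = sorted((_atom_class(donor_atom), _atom_class(acceptor_atom)),
                  reverse=True)  # sc before bb
    return f"{pair[0]}-{pair[1]}"


def detect_hbonds(model: StructureModel,
                  criteria: HBondCriteria = HBondCriteria(),
                  include_bb_bb: bool = False) -> List[HydrogenBond]:
    """Detect hydrogen bonds between polymer residues.

    If the model carries explicit hydrogens the geometric rule is applied
    (H...A distance plus D-H...A angle); otherwise a heavy-atom
    donor...acceptor cutoff restricted to chemically valid donor/acceptor
    types.  Backbone-to-backbone bonds are emitted only when
    ``include_bb_bb`` is set.  Residues with names outside the 20 standard
    amino acids are skipped with a logged warning.
    """
    use_h = any(r.has_hydrogens() for r in model.residues)
    usable = []
    for r in model.residues:
        if r.name not in STANDARD_RESIDUES and r.name not in THREE_TO_ONE:
            logger.warning("skipping unknown residue %s (%s) in H-bond scan",
                           r.key, r.name)
            continue
        usable.append(r)
    bonds: List[HydrogenBond] = []
    for rd in usable:
        for ra in usable:
            if rd.key == ra.key:
                continue
            for d_at in _donor_atoms(rd):
                for a_at in _acceptor_atoms(ra):
                    da = float(np.linalg.norm(rd.atoms[d_at] - ra.atoms[a_at]))
                    if da > max(criteria.da_max, criteria.ha_max + 1.2):
                        continue
                    if use_h:
                        ok = False
                        for h in _attached_hydrogens(rd, d_at):
                            ha = np.linalg.norm(rd.atoms[h] - ra.atoms[a_at])
                            if ha > criteria.ha_max:
                                continue
                            v1 = rd.atoms[d_at] - rd.atoms[h]
                            v2 = ra.atoms[a_at] - rd.atoms[h]
                            cosang = np.dot(v1, v2) / (
                                np.linalg.norm(v1) * np.linalg.norm(v2))
                            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                            if ang >= criteria.dha_min_deg:
                                ok = True
                                break
                        if not ok:
                            continue
                    elif da > criteria.da_max:
                        continue
                    klass = _bond_klass(d_at, a_at)
                    if klass == "bb-bb" and not include_bb_bb:
                        continue
                    bonds.append(HydrogenBond(donor=(rd.key, d_at),
                                              acceptor=(ra.key, a_at),
                                              da_distance=da, klass=klass))
    return bonds


# ---------------------------------------------------------------------------
# focal points
# ---------------------------------------------------------------------------

def nearest_residue_to_focal(model: StructureModel,
                             focal) -> ResidueKey:
    """Polymer residue with minimum heavy-atom distance to the focal
    selection (a Residue, an iterable of Residues, or an (n, 3) coordinate
    array).  Exact ties go to the smaller residue key."""
    if isinstance(focal, Residue):
        fcoords = focal.heavy_coords()
    elif isinstance(focal, np.ndarray):
        fcoords = np.atleast_2d(focal)
    else:
        focal = list(focal)
        if not focal:
            raise EmptySelectionError("focal selection is empty")
        fcoords = np.concatenate([f.heavy_coords() for f in focal])
    if fcoords.size == 0:
        raise EmptySelectionError("focal selection has no atoms")
    best: Optional[Tuple[float, ResidueKey]] = None
    for r in model.residues:
        rc = r.heavy_coords()
        d = float(np.linalg.norm(rc[:, None, :] - fcoords[None, :, :],
                                 axis=-1).min())
        cand = (d, r.key)
        if best is None or cand < best:
            best = cand
    return best[1]
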