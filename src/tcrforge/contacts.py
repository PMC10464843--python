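"""Residue-level CDR3-peptide contact detection and classification.

This module owns the lightweight in-memory structure container used across
the package (chains of residues of heavy atoms, with 1-based substructure
numbering) and the contact analysis performed on modeled and crystallographic
TCR-peptide-MHC complexes: all CDR3-peptide residue pairs closer than 5 A
(heavy-atom minimum distance) are collected, attributed to main-chain or
side-chain groups, and typed as ionic, hydrogen-bond or van der Waals
interactions with RING-style distance rules.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ContactPair",
    "Part",
    "InteractionType",
    "find_contacts",
    "contact_groups",
    "substitution_contact_status",
    "count_contact_pair_types",
    "read_pdb",
    "write_pdb",
    "CONTACT_CUTOFF",
    "IONIC_CUTOFF",
    "HBOND_CUTOFF",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# analysis thresholds (A); heavy atoms only, hydrogens ignored
CONTACT_CUTOFF = 5.0
IONIC_CUTOFF = 4.0
HBOND_CUTOFF = 3.5

# charged side-chain groups considered for ionic bonds
NEGATIVE_GROUP = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
POSITIVE_GROUP = {
    "K": ("NZ",),
    "R": ("NE", "NH1", "NH2", "CZ"),
    "H": ("ND1", "NE2"),
}

# heavy-atom hydrogen-bond donors/acceptors; backbone N donates, O accepts
SIDECHAIN_DONORS = {
    "R": ("NE", "NH1", "NH2"),
    "K": ("NZ",),
    "H": ("ND1", "NE2"),
    "N": ("ND2",),
    "Q": ("NE2",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "W": ("NE1",),
}
SIDECHAIN_ACCEPTORS = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "N": ("OD1",),
    "Q": ("OE1",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "H": ("ND1", "NE2"),
}


class Part(str, Enum):
    MAIN_CHAIN = "main_chain"
    SIDE_CHAIN = "side_chain"


class InteractionType(str, Enum):
    VDW = "VDW"
    HBOND = "HBOND"
    IONIC = "IONIC"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite values")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    """One residue; ``position`` is 1-based from the start of its substructure."""

    position: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.aa}{self.position} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue_at(self, position: int) -> Residue:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue at position {position}")


@dataclass
class Structure:
    """A complex as a mapping of chain id to :class:`Chain`."""

    chains: dict[str, Chain] = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"structure has no chain {chain_id!r}") from None

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def subsequence(self, chain_id: str, rng: tuple[int, int]) -> str:
        chain = self.chain(chain_id)
        return "".join(r.aa for r in chain.residues if rng[0] <= r.position <= rng[1])


@dataclass
class ContactPair:
    """One CDR3-residue / peptide-residue interaction under the 5 A cutoff."""

    cdr3_position: int
    cdr3_residue: str
    peptide_position: int
    peptide_residue: str
    min_distance: float
    cdr3_part: Part
    peptide_part: Part
    interaction_type: InteractionType
    closest_flag: bool = False


# ---------------------------------------------------------------------------
# PDB round trip (biotite AtomArray is the exchange format)
# ---------------------------------------------------------------------------

def _to_structure(array) -> Structure:
    """Convert a biotite AtomArray to the package container.

    Residues are renumbered 1..n per chain in order of appearance; author
    numbering is dropped from analysis outputs on purpose.
    """
    import biotite.structure as struc

    array = array[struc.filter_amino_acids(array)]
    array = array[array.element != "H"]
    chains: dict[str, Chain] = {}
    for chain_id in np.unique(array.chain_id):
        sub = array[array.chain_id == chain_id]
        chain = Chain(chain_id=str(chain_id))
        starts = struc.get_residue_starts(sub, add_exclusive_stop=True)
        for pos, (lo, hi) in enumerate(zip(starts[:-1], starts[1:]), start=1):
            res = sub[lo:hi]
            res_name = str(res.res_name[0])
            aa = THREE_TO_ONE.get(res_name)
            if aa is None:
                continue
            residue = Residue(position=pos, aa=aa)
            for i in range(res.array_length()):
                residue.atoms.append(
                    Atom(
                        name=str(res.atom_name[i]),
                        element=str(res.element[i]) or str(res.atom_name[i])[0],
                        coord=np.array(res.coord[i], dtype=float),
                    )
                )
            chain.residues.append(residue)
        chains[str(chain_id)] = chain
    return Structure(chains=chains)


def _to_atomarray(structure: Structure):
    import biotite.structure as struc

    n = sum(
        len(r.heavy_atoms()) for c in structure.chains.values() for r in c.residues
    )
    array = struc.AtomArray(n)
    i = 0
    for chain_id in sorted(structure.chains):
        chain = structure.chains[chain_id]
        for res in chain.residues:
            for atom in res.heavy_atoms():
                array.chain_id[i] = chain_id
                array.res_id[i] = res.position
                array.res_name[i] = ONE_TO_THREE[res.aa]
                array.atom_name[i] = atom.name
                array.element[i] = atom.element
                array.coord[i] = atom.coord
                array.hetero[i] = False
                i += 1
    return array


def read_pdb(path) -> Structure:
    """Read a PDB file (standard ATOM records, heavy atoms) into a Structure."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    array = pdb_file.get_structure(model=1)
    return _to_structure(array)


def write_pdb(structure: Structure, path) -> None:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_to_atomarray(structure))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _group_min_distance(
    res_a: Residue, names_a: Iterable[str], res_b: Residue, names_b: Iterable[str]
) -> float:
    best = np.inf
    for na in names_a:
        if not res_a.has_atom(na):
            continue
        ca = res_a.atom(na).coord
        for nb in names_b:
            if not res_b.has_atom(nb):
                continue
            d = float(np.linalg.norm(ca - res_b.atom(nb).coord))
            best = min(best, d)
    return best


def _is_ionic(cdr3_res: Residue, pep_res: Residue) -> bool:
    for neg, pos in ((cdr3_res, pep_res), (pep_res, cdr3_res)):
        if neg.aa in NEGATIVE_GROUP and pos.aa in POSITIVE_GROUP:
            d = _group_min_distance(
                neg, NEGATIVE_GROUP[neg.aa], pos, POSITIVE_GROUP[pos.aa]
            )
            if d <= IONIC_CUTOFF:
                return True
    return False


def _donor_names(res: Residue) -> list[str]:
    names = ["N"] if res.has_atom("N") else []
    names += [n for n in SIDECHAIN_DONORS.get(res.aa, ()) if res.has_atom(n)]
    return names


def _acceptor_names(res: Residue) -> list[str]:
    names = [n for n in ("O", "OXT") if res.has_atom(n)]
    names += [n for n in SIDECHAIN_ACCEPTORS.get(res.aa, ()) if res.has_atom(n)]
    return names


def _is_hbond(res_a: Residue, res_b: Residue) -> bool:
    d1 = _group_min_distance(res_a, _donor_names(res_a), res_b, _acceptor_names(res_b))
    d2 = _group_min_distance(res_b, _donor_names(res_b), res_a, _acceptor_names(res_a))
    return min(d1, d2) <= HBOND_CUTOFF


def _classify(cdr3_res: Residue, pep_res: Residue) -> InteractionType:
    # precedence: IONIC > HBOND > VDW
    if _is_ionic(cdr3_res, pep_res):
        return InteractionType.IONIC
    if _is_hbond(cdr3_res, pep_res):
        return InteractionType.HBOND
    return InteractionType.VDW


def find_contacts(
    model: Structure,
    cdr3_chain: str,
    cdr3_range: tuple[int, int],
    peptide_chain: str,
    cutoff: float = CONTACT_CUTOFF,
    part_attribution: str = "min_pair",
) -> list[ContactPair]:
    """All CDR3-peptide residue pairs with heavy-atom minimum distance < cutoff.

    Positions in the returned pairs are 1-based from the start of the CDR3
    substructure and of the peptide.  With the default ``min_pair``
    attribution the main/side-chain parts come from the atom pair achieving
    the minimum distance; ``any_pair`` (a sensitivity-analysis mode) marks a
    side as side_chain when any of its side-chain atoms participates in any
    atom pair under the cutoff.  Exactly one pair per contacting CDR3
    residue carries ``closest_flag`` (smallest distance, ties broken by
    lower peptide position).
    """
    if part_attribution not in ("min_pair", "any_pair"):
        raise ValueError(f"unknown part attribution {part_attribution!r}")
    lo, hi = cdr3_range
    cdr3_residues = [
        r for r in model.chain(cdr3_chain).residues if lo <= r.position <= hi
    ]
    if not cdr3_residues:
        raise ValueError(f"empty CDR3 range {cdr3_range} on chain {cdr3_chain!r}")
    pep_residues = model.chain(peptide_chain).residues

    pairs: list[ContactPair] = []
    for cres in cdr3_residues:
        ccoords = cres.coords()
        catoms = cres.heavy_atoms()
        for pres in pep_residues:
            pcoords = pres.coords()
            dmat = np.linalg.norm(
                ccoords[:, None, :] - pcoords[None, :, :], axis=-1
            )
            i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
            dmin = float(dmat[i, j])
            if dmin >= cutoff:
                continue
            patoms = pres.heavy_atoms()
            if part_attribution == "min_pair":
                cdr3_side = not catoms[i].is_backbone
                pep_side = not patoms[j].is_backbone
            else:
                under = dmat < cutoff
                cdr3_side = any(
                    not catoms[a].is_backbone for a in np.where(under.any(axis=1))[0]
                )
                pep_side = any(
                    not patoms[b].is_backbone for b in np.where(under.any(axis=0))[0]
                )
            pairs.append(
                ContactPair(
                    cdr3_position=cres.position - lo + 1,
                    cdr3_residue=cres.aa,
                    peptide_position=pres.position,
                    peptide_residue=pres.aa,
                    min_distance=dmin,
                    cdr3_part=Part.SIDE_CHAIN if cdr3_side else Part.MAIN_CHAIN,
                    peptide_part=Part.SIDE_CHAIN if pep_side else Part.MAIN_CHAIN,
                    interaction_type=_classify(cres, pres),
                )
            )

    by_cdr3: dict[int, list[ContactPair]] = {}
    for p in pairs:
        by_cdr3.setdefault(p.cdr3_position, []).append(p)
    for plist in by_cdr3.values():
        winner = min(plist, key=lambda p: (p.min_distance, p.peptide_position))
        winner.closest_flag = True
    pairs.sort(key=lambda p: (p.cdr3_position, p.peptide_position))
    return pairs


def contact_groups(
    pairs: Sequence[ContactPair],
) -> tuple[list[ContactPair], list[ContactPair], list[ContactPair], list[ContactPair]]:
    """The four analysis groups of contact pairs.

    (1) all pairs, (2) closest pairs per CDR3 residue, (3) pairs with at
    least one side-chain part, (4) intersection of (2) and (3).
    """
    group1 = list(pairs)
    group2 = [p for p in pairs if p.closest_flag]
    group3 = [
        p
        for p in pairs
        if p.cdr3_part is Part.SIDE_CHAIN or p.peptide_part is Part.SIDE_CHAIN
    ]
    in3 = set(map(id, group3))
    group4 = [p for p in group2 if id(p) in in3]
    return group1, group2, group3, group4


def substitution_contact_status(
    substitution_position: int, pairs: Sequence[ContactPair]
) -> str:
    """``"contacting"`` iff the substituted CDR3 position appears in any pair."""
    return (
        "contacting"
        if any(p.cdr3_position == substitution_position for p in pairs)
        else "non_contacting"
    )


def count_contact_pair_types(
    model_pairs: Iterable[Sequence[ContactPair]],
    original_pairs: Iterable[Sequence[ContactPair]],
):
    """Per contact group, 20x20 amino-acid pair count tables and novel pairs.

    Returns a dict group index (1-4) -> dict with keys ``modeled``,
    ``original`` (pandas DataFrames indexed CDR3 residue x peptide residue)
    and ``novel`` (set of (cdr3_aa, pep_aa) types seen only in models).
    """
    import pandas as pd

    aa = list(AMINO_ACIDS)

    def tally(pair_lists):
        tables = {
            g: pd.DataFrame(0, index=aa, columns=aa, dtype=int) for g in range(1, 5)
        }
        for pairs in pair_lists:
            for g, plist in enumerate(contact_groups(pairs), start=1):
                for p in plist:
                    tables[g].loc[p.cdr3_residue, p.peptide_residue] += 1
        return tables

    modeled = tally(model_pairs)
    original = tally(original_pairs)
    out = {}
    for g in range(1, 5):
        m, o = modeled[g], original[g]
        novel = {
            (r, c)
            for r in aa
            for c in aa
            if m.loc[r, c] > 0 and o.loc[r, c] == 0
        }
        out[g] = {"modeled": m, "original": o, "novel": novel}
    return out
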