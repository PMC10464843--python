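"""Turning build orders into child structures through a mutation backend.

The modeling protocol mirrors template-based CDR3 engineering: a single
residue is substituted while all main-chain heavy atoms keep their template
positions, then the structure is optionally optimized.  The default
``surrogate`` backend rebuilds the side chain from an internal ideal-geometry
table on the parent's N-CA-CB frame, copying side-chain dihedrals from the
parent where atom names coincide; ``minimized`` optimization is a no-op
(coordinate-restrained minimization leaves the backbone essentially fixed)
and ``repacked`` runs a greedy chi1 grid sweep relieving clashes between
CDR3 and peptide residues closer than 10 A.  An external Rosetta-style
backend can be plugged in through the same contract; a ``precomputed``
backend short-circuits structure building when per-model energy tables are
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np

from .contacts import (
    Atom,
    ONE_TO_THREE,
    Residue,
    Structure,
)
from .io_repertoire import ModelGroupKey, TcrChain, TemplateComplex
from .clustering import BuildOrder

__all__ = [
    "ModelBuild",
    "Backend",
    "SurrogateBackend",
    "surrogate_mutate",
    "run_builds",
    "group_nonredundant",
    "BuildError",
    "REPACK_RADIUS",
]

REPACK_RADIUS = 10.0  # A; CDR3/peptide residues closer than this are repacked
CHI_GRID = np.arange(-180.0, 180.0, 30.0)


class BuildError(RuntimeError):
    """A backend failed to produce a child structure."""


# ---------------------------------------------------------------------------
# Ideal side-chain geometry
# ---------------------------------------------------------------------------
# Each entry places one heavy atom by internal coordinates: bonded reference
# r1, angle reference r2, dihedral reference r3, bond length (A), bond angle
# (deg, atom-r1-r2) and default dihedral (deg, atom-r1-r2-r3).  Defaults give
# extended chi angles; actual chis are copied from the parent residue when
# the four atoms exist there under the same names.  Aromatic rings built this
# way close only approximately, which is irrelevant for the distance-based
# analyses downstream.

_T = lambda name, r1, r2, r3, b, a, d: (name, r1, r2, r3, b, a, d)

SIDE_CHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "A": [],
    "R": [
        _T("CG", "CB", "CA", "N", 1.52, 114.0, 180.0),
        _T("CD", "CG", "CB", "CA", 1.52, 111.0, 180.0),
        _T("NE", "CD", "CG", "CB", 1.46, 112.0, 180.0),
        _T("CZ", "NE", "CD", "CG", 1.33, 124.0, 180.0),
        _T("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
        _T("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0),
    ],
    "N": [
        _T("CG", "CB", "CA", "N", 1.52, 113.0, 180.0),
        _T("OD1", "CG", "CB", "CA", 1.23, 121.0, -60.0),
        _T("ND2", "CG", "CB", "CA", 1.33, 117.0, 120.0),
    ],
    "D": [
        _T("CG", "CB", "CA", "N", 1.52, 113.0, 180.0),
        _T("OD1", "CG", "CB", "CA", 1.25, 118.0, -60.0),
        _T("OD2", "CG", "CB", "CA", 1.25, 118.0, 120.0),
    ],
    "C": [_T("SG", "CB", "CA", "N", 1.81, 114.0, 180.0)],
    "Q": [
        _T("CG", "CB", "CA", "N", 1.52, 114.0, 180.0),
        _T("CD", "CG", "CB", "CA", 1.52, 112.0, 180.0),
        _T("OE1", "CD", "CG", "CB", 1.23, 121.0, -60.0),
        _T("NE2", "CD", "CG", "CB", 1.33, 117.0, 120.0),
    ],
    "E": [
        _T("CG", "CB", "CA", "N", 1.52, 114.0, 180.0),
        _T("CD", "CG", "CB", "CA", 1.52, 112.0, 180.0),
        _T("OE1", "CD", "CG", "CB", 1.25, 118.0, -60.0),
        _T("OE2", "CD", "CG", "CB", 1.25, 118.0, 120.0),
    ],
    "G": [],
    "H": [
        _T("CG", "CB", "CA", "N", 1.50, 113.0, 180.0),
        _T("ND1", "CG", "CB", "CA", 1.38, 122.0, -60.0),
        _T("CD2", "CG", "CB", "CA", 1.36, 129.0, 120.0),
        _T("CE1", "ND1", "CG", "CB", 1.32, 109.0, 180.0),
        _T("NE2", "CD2", "CG", "CB", 1.37, 107.0, 180.0),
    ],
    "I": [
        _T("CG1", "CB", "CA", "N", 1.53, 110.0, 180.0),
        _T("CG2", "CB", "CA", "N", 1.53, 110.0, -60.0),
        _T("CD1", "CG1", "CB", "CA", 1.52, 114.0, 180.0),
    ],
    "L": [
        _T("CG", "CB", "CA", "N", 1.53, 116.0, 180.0),
        _T("CD1", "CG", "CB", "CA", 1.52, 110.0, 60.0),
        _T("CD2", "CG", "CB", "CA", 1.52, 110.0, 180.0),
    ],
    "K": [
        _T("CG", "CB", "CA", "N", 1.52, 114.0, 180.0),
        _T("CD", "CG", "CB", "CA", 1.52, 111.0, 180.0),
        _T("CE", "CD", "CG", "CB", 1.52, 111.0, 180.0),
        _T("NZ", "CE", "CD", "CG", 1.49, 112.0, 180.0),
    ],
    "M": [
        _T("CG", "CB", "CA", "N", 1.52, 114.0, 180.0),
        _T("SD", "CG", "CB", "CA", 1.80, 112.0, 180.0),
        _T("CE", "SD", "CG", "CB", 1.79, 100.0, 180.0),
    ],
    "F": [
        _T("CG", "CB", "CA", "N", 1.50, 114.0, 180.0),
        _T("CD1", "CG", "CB", "CA", 1.39, 120.0, 90.0),
        _T("CD2", "CG", "CB", "CA", 1.39, 120.0, -90.0),
        _T("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
        _T("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
        _T("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
    ],
    "P": [
        _T("CG", "CB", "CA", "N", 1.49, 104.0, 30.0),
        _T("CD", "CG", "CB", "CA", 1.50, 106.0, -35.0),
    ],
    "S": [_T("OG", "CB", "CA", "N", 1.41, 111.0, 180.0)],
    "T": [
        _T("OG1", "CB", "CA", "N", 1.43, 110.0, 180.0),
        _T("CG2", "CB", "CA", "N", 1.52, 111.0, -60.0),
    ],
    "W": [
        _T("CG", "CB", "CA", "N", 1.50, 114.0, 180.0),
        _T("CD1", "CG", "CB", "CA", 1.37, 127.0, 90.0),
        _T("CD2", "CG", "CB", "CA", 1.43, 126.0, -90.0),
        _T("NE1", "CD1", "CG", "CB", 1.38, 110.0, 180.0),
        _T("CE2", "CD2", "CG", "CB", 1.41, 107.0, 180.0),
        _T("CE3", "CD2", "CG", "CB", 1.40, 133.0, 0.0),
        _T("CZ2", "CE2", "CD2", "CG", 1.40, 122.0, 180.0),
        _T("CZ3", "CE3", "CD2", "CG", 1.39, 118.0, 180.0),
        _T("CH2", "CZ2", "CE2", "CD2", 1.37, 117.0, 0.0),
    ],
    "Y": [
        _T("CG", "CB", "CA", "N", 1.50, 114.0, 180.0),
        _T("CD1", "CG", "CB", "CA", 1.39, 120.0, 90.0),
        _T("CD2", "CG", "CB", "CA", 1.39, 120.0, -90.0),
        _T("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
        _T("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
        _T("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
        _T("OH", "CZ", "CE1", "CD1", 1.38, 120.0, 180.0),
    ],
    "V": [
        _T("CG1", "CB", "CA", "N", 1.53, 111.0, 180.0),
        _T("CG2", "CB", "CA", "N", 1.53, 111.0, -60.0),
    ],
}

# CB placement on the backbone frame (used only when the parent lacks CB)
_CB_INTERNAL = ("CA", "N", "C", 1.53, 110.5, -122.6)


def _element_of(atom_name: str) -> str:
    return atom_name[0] if atom_name[0] in ("N", "O", "S") else "C"


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """NeRF placement of atom d bonded to c with angle d-c-b, dihedral d-c-b-a."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-8:  # collinear references; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d2


def measure_dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Dihedral p0-p1-p2-p3 in degrees (IUPAC sign convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rebuild_side_chain(residue: Residue, parent: Residue, to_aa: str) -> None:
    """Replace the side chain of ``residue`` (in place) with ideal ``to_aa``
    geometry, copying dihedrals from ``parent`` where atom names coincide."""
    backbone = [a for a in residue.atoms if a.is_backbone]
    placed: dict[str, np.ndarray] = {a.name: a.coord for a in backbone}
    new_atoms = list(backbone)

    if to_aa != "G":
        if parent.has_atom("CB"):
            cb = parent.atom("CB").coord.copy()
        else:
            r1, r2, r3, b, ang, dih = _CB_INTERNAL
            cb = place_atom(placed[r3], placed[r2], placed[r1], b, ang, dih)
        placed["CB"] = cb
        new_atoms.append(Atom(name="CB", element="C", coord=cb))

        for name, r1, r2, r3, bond, angle, dihedral in SIDE_CHAIN_TOPOLOGY[to_aa]:
            if all(parent.has_atom(x) for x in (name, r1, r2, r3)):
                dihedral = measure_dihedral(
                    parent.atom(r3).coord,
                    parent.atom(r2).coord,
                    parent.atom(r1).coord,
                    parent.atom(name).coord,
                )
            coord = place_atom(
                placed[r3], placed[r2], placed[r1], bond, angle, dihedral
            )
            placed[name] = coord
            new_atoms.append(Atom(name=name, element=_element_of(name), coord=coord))

    residue.aa = to_aa
    residue.atoms = new_atoms


def surrogate_mutate(
    parent: Structure, chain_id: str, position: int, to_aa: str
) -> Structure:
    """Substitute one residue, keeping every main-chain heavy atom fixed.

    Returns a new structure; the parent is untouched.  An identity
    substitution returns an atom-for-atom copy.
    """
    if to_aa not in ONE_TO_THREE:
        raise ValueError(f"unknown target residue {to_aa!r}")
    child = parent.copy()
    residue = child.chain(chain_id).residue_at(position)
    for name in ("N", "CA", "C", "O"):
        if not residue.has_atom(name):
            raise BuildError(
                f"residue {residue.aa}{position} lacks backbone atom {name}"
            )
    if residue.aa == to_aa:
        return child
    parent_res = parent.chain(chain_id).residue_at(position)
    _rebuild_side_chain(residue, parent_res, to_aa)
    return child


# ---------------------------------------------------------------------------
# Optimization (surrogate arms)
# ---------------------------------------------------------------------------

def _rotate_side_chain(residue: Residue, delta_deg: float) -> None:
    """Rotate all atoms beyond CB about the CA-CB axis by delta_deg."""
    if not (residue.has_atom("CA") and residue.has_atom("CB")):
        return
    ca = residue.atom("CA").coord
    cb = residue.atom("CB").coord
    axis = cb - ca
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(delta_deg)
    k = axis
    for atom in residue.atoms:
        if atom.is_backbone or atom.name == "CB":
            continue
        v = atom.coord - cb
        # Rodrigues rotation
        atom.coord = (
            cb
            + v * np.cos(theta)
            + np.cross(k, v) * np.sin(theta)
            + k * np.dot(k, v) * (1 - np.cos(theta))
        )


def _clash_score(residue: Residue, others: Sequence[Residue]) -> float:
    """Soft steric score of one residue's side chain against other residues."""
    side = [a for a in residue.heavy_atoms() if not a.is_backbone and a.name != "CB"]
    if not side:
        return 0.0
    score = 0.0
    sc = np.array([a.coord for a in side])
    for other in others:
        oc = other.coords()
        d = np.linalg.norm(sc[:, None, :] - oc[None, :, :], axis=-1)
        close = d[d < 6.0]
        if close.size:
            # repulsive wall below 3.2 A plus mild attraction
            score += float(np.sum(np.clip(3.2 - close, 0.0, None) ** 2))
            score -= 0.01 * close.size
    return score


def _repack(
    structure: Structure,
    cdr3_chain: str,
    cdr3_range: tuple[int, int],
    peptide_chain: str,
) -> None:
    """Greedy chi1 grid sweep for CDR3 residues near the peptide (in place)."""
    lo, hi = cdr3_range
    pep = structure.chain(peptide_chain).residues
    for residue in structure.chain(cdr3_chain).residues:
        if not (lo <= residue.position <= hi):
            continue
        if not residue.has_atom("CB"):
            continue
        coords = residue.coords()
        dmin = min(
            float(np.min(np.linalg.norm(coords[:, None, :] - p.coords()[None, :, :], axis=-1)))
            for p in pep
        )
        if dmin > REPACK_RADIUS:
            continue
        best_delta, best_score = 0.0, _clash_score(residue, pep)
        for delta in CHI_GRID:
            if delta == 0.0:
                continue
            trial = Residue(
                position=residue.position,
                aa=residue.aa,
                atoms=[Atom(a.name, a.element, a.coord.copy()) for a in residue.atoms],
            )
            _rotate_side_chain(trial, float(delta))
            score = _clash_score(trial, pep)
            if score < best_score - 1e-12:
                best_delta, best_score = float(delta), score
        if best_delta != 0.0:
            _rotate_side_chain(residue, best_delta)


class Backend(Protocol):
    """Contract every mutation backend implements."""

    def mutate(
        self, parent: Structure, chain_id: str, position: int, to_aa: str
    ) -> Structure: ...

    def optimize(
        self,
        structure: Structure,
        mode: str,
        cdr3_chain: str,
        cdr3_range: tuple[int, int],
        peptide_chain: str,
    ) -> Structure: ...


class SurrogateBackend:
    """Deterministic in-process backend (the default).

    ``optimize`` is the identity for ``minimized`` and ``none`` and the chi1
    sweep described in the module docstring for ``repacked``.
    """

    name = "surrogate"

    def mutate(self, parent, chain_id, position, to_aa):
        return surrogate_mutate(parent, chain_id, position, to_aa)

    def optimize(self, structure, mode, cdr3_chain, cdr3_range, peptide_chain):
        if mode in ("minimized", "none"):
            return structure
        if mode == "repacked":
            out = structure.copy()
            _repack(out, cdr3_chain, cdr3_range, peptide_chain)
            return out
        raise ValueError(f"unknown optimization mode {mode!r}")


@dataclass(eq=False)
class ModelBuild:
    """Provenance and result of one executed build order."""

    build_id: str
    order: BuildOrder
    parent_structure: Structure | None
    child_structure: Structure | None
    optimization: str
    backend: str
    status: str = "ok"  # ok | failed | skipped
    error: str = ""

    @property
    def template(self) -> TemplateComplex | None:
        return self.order.template

    @property
    def chain(self) -> TcrChain:
        return self.order.chain

    @property
    def substitution(self) -> tuple[int, str, str]:
        return self.order.substitution

    @property
    def final_cdr3(self) -> str:
        return self.order.child_cdr3

    def group_key(self) -> ModelGroupKey:
        return self.order.group_key()


def run_builds(
    orders: Sequence[BuildOrder],
    backend: Backend | None = None,
    optimization: str = "minimized",
    fail_fast: bool = False,
) -> list[ModelBuild]:
    """Execute build orders in prefix order (parents before children).

    A failed build marks its descendants ``skipped`` and the run continues
    (``fail_fast`` raises instead).  Deterministic for fixed inputs.
    """
    backend = backend or SurrogateBackend()
    orders = sorted(
        orders, key=lambda o: (o.template_id, o.chain.value, len(o.prefix), o.prefix)
    )
    built: dict[tuple, Structure] = {}
    failed_prefixes: set[tuple] = set()
    builds: list[ModelBuild] = []
    for order in orders:
        template = order.template
        if template is None:
            raise ValueError("build orders must reference a template")
        key = (template.pdb_id, order.chain, order.prefix)
        parent_key = (template.pdb_id, order.chain, order.prefix[:-1])
        chain_id = template.tcr_chain_id(order.chain)
        rng = template.cdr3_range(order.chain)
        pep_chain = template.chain_map["peptide"]
        build_id = f"{template.pdb_id}_{order.chain.value}_" + "-".join(order.prefix)

        if parent_key in failed_prefixes:
            failed_prefixes.add(key)
            builds.append(
                ModelBuild(
                    build_id=build_id, order=order, parent_structure=None,
                    child_structure=None, optimization=optimization,
                    backend=getattr(backend, "name", "custom"),
                    status="skipped", error="ancestor failed",
                )
            )
            continue

        if len(order.prefix) == 2:
            parent_structure = template.structure
        else:
            parent_structure = built.get(parent_key)
            if parent_structure is None:
                raise ValueError(
                    f"parent prefix missing for {build_id}; orders form a gap or cycle"
                )

        pos, from_aa, to_aa = order.substitution
        chain_pos = rng[0] + pos - 1
        expect = parent_structure.chain(chain_id).residue_at(chain_pos).aa
        try:
            if expect != from_aa:
                raise BuildError(
                    f"parent residue {expect} at CDR3 position {pos} does not "
                    f"match substitution source {from_aa}"
                )
            child = backend.mutate(parent_structure, chain_id, chain_pos, to_aa)
            child = backend.optimize(child, optimization, chain_id, rng, pep_chain)
        except Exception as err:  # noqa: BLE001 - backend failures are data
            if fail_fast:
                raise
            failed_prefixes.add(key)
            builds.append(
                ModelBuild(
                    build_id=build_id, order=order, parent_structure=parent_structure,
                    child_structure=None, optimization=optimization,
                    backend=getattr(backend, "name", "custom"),
                    status="failed", error=str(err),
                )
            )
            continue
        built[key] = child
        builds.append(
            ModelBuild(
                build_id=build_id, order=order, parent_structure=parent_structure,
                child_structure=child, optimization=optimization,
                backend=getattr(backend, "name", "custom"),
            )
        )
    return builds


def group_nonredundant(
    builds: Iterable[ModelBuild],
) -> dict[ModelGroupKey, list[ModelBuild]]:
    """Group builds sharing template TCR chain sequences, final CDR3 and chain.

    Downstream numeric properties (energies, distances) are averaged within
    each group when the non-redundant view is requested.
    """
    groups: dict[ModelGroupKey, list[ModelBuild]] = {}
    for build in builds:
        if build.status != "ok":
            continue
        groups.setdefault(build.group_key(), []).append(build)
    return groups
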