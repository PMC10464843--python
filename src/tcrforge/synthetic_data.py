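"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end without any download:

* planted repertoires: clusters of CDR3 sequences that satisfy the
  clustering rules by construction (shared chain/V/J/epitope/length,
  Hamming distance <= 3, single-substitution connectivity) plus decoys each
  violating exactly one named rule;
* toy 3D complexes: a CDR3 strand and free-standing peptide residues with a
  controllable contact plan (which residue pairs touch, at what distance,
  with which interaction type);
* descriptor-energy tables with planted linear relationships and noise.

Every ground-truth manifest is computed by brute force inside this module,
independently of the modules under test.  All generators are reproducible:
identical spec and seed give identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import AMINO_ACIDS, Atom, Chain, Residue, Structure
from .descriptors import adjusted_blosum, default_table, get_matrix
from .io_repertoire import SpecificityRecord, TcrChain
from .modeling import SIDE_CHAIN_TOPOLOGY, _CB_INTERNAL, place_atom

__all__ = [
    "RepertoireSpec",
    "RepertoireData",
    "ToyComplexSpec",
    "ToyComplexData",
    "PlantedEnergySpec",
    "GenerationError",
    "generate_repertoire",
    "generate_toy_complex",
    "generate_planted_energies",
    "generate_planted_denergy",
]


class GenerationError(RuntimeError):
    """A spec cannot be realized (invalid parameters or unsatisfiable plan)."""


# ---------------------------------------------------------------------------
# Planted repertoires
# ---------------------------------------------------------------------------

DECOY_KINDS = (
    "wrong_v", "wrong_j", "wrong_length", "wrong_epitope",
    "too_distant", "disconnected",
)


@dataclass(frozen=True)
class RepertoireSpec:
    n_clusters: int = 1
    members_per_cluster: int = 6
    max_distance: int = 3
    decoys: dict = field(default_factory=dict)  # kind -> count
    cdr3_length: int = 12
    alphabet: str = AMINO_ACIDS
    seed: int = 0
    # optional explicit cores: tuples of (cdr3, chain value, epitope); when
    # given they override n_clusters/cdr3_length so clusters anchor on the
    # CDR3 sequences of known template structures
    cores: tuple = ()

    def __post_init__(self) -> None:
        if self.max_distance > 3:
            raise GenerationError("max_distance must not exceed 3")
        for kind in self.decoys:
            if kind not in DECOY_KINDS:
                raise GenerationError(f"unknown decoy kind {kind!r}")


@dataclass
class ClusterManifest:
    core: SpecificityRecord
    member_cdr3s: set[str]
    pathways: list[tuple[str, ...]]  # all monotone chains, intermediates observed


@dataclass
class RepertoireData:
    records: list[SpecificityRecord]
    manifests: list[ClusterManifest]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _brute_force_members(core: str, candidates: set[str], max_d: int) -> set[str]:
    """Reachable-from-core set over single-substitution edges (naive BFS)."""
    pool = {c for c in candidates if 0 < _hamming(c, core) <= max_d}
    reached: set[str] = set()
    frontier = {core}
    while frontier:
        nxt = {
            c for c in pool - reached
            if any(_hamming(c, f) == 1 for f in frontier)
        }
        reached |= nxt
        frontier = nxt
    return reached


def _brute_force_pathways(core: str, members: set[str]) -> list[tuple[str, ...]]:
    """All monotone single-substitution chains core -> member with observed
    intermediates, by exhaustive permutation of the differing positions."""
    paths = set()
    for target in members:
        positions = [i for i, (x, y) in enumerate(zip(core, target)) if x != y]
        for order in itertools.permutations(positions):
            seq = list(core)
            steps = [core]
            ok = True
            for k, pos in enumerate(order):
                seq[pos] = target[pos]
                s = "".join(seq)
                if k < len(order) - 1 and s not in members:
                    ok = False
                    break
                steps.append(s)
            if ok:
                paths.add(tuple(steps))
    return sorted(paths)


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate_at(rng, seq: str, pos: int, alphabet: str) -> str:
    choices = [a for a in alphabet if a != seq[pos]]
    return seq[:pos] + str(rng.choice(choices)) + seq[pos + 1:]


def generate_repertoire(spec: RepertoireSpec) -> RepertoireData:
    """Planted clusters plus rule-violating decoys, with brute-force manifests.

    Members are planted by sampling mutation chains from the core, adding
    every intermediate, so at least one monotone pathway exists for each
    member by construction.  Decoys violate exactly the rule their kind
    names and are verified (by the internal brute-force enumerator) to stay
    outside the cluster.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SpecificityRecord] = []
    manifests: list[ClusterManifest] = []
    rid = itertools.count(1)

    n_clusters = len(spec.cores) or spec.n_clusters
    for ci in range(n_clusters):
        if spec.cores:
            core_cdr3, chain_value, epitope = spec.cores[ci]
            chain = TcrChain(chain_value)
            cdr3_length = len(core_cdr3)
        else:
            chain = TcrChain.ALPHA if ci % 2 == 0 else TcrChain.BETA
            epitope = _random_seq(rng, 9, spec.alphabet)
            cdr3_length = spec.cdr3_length
            core_cdr3 = _random_seq(rng, cdr3_length, spec.alphabet)
        prefix = "TRAV" if chain is TcrChain.ALPHA else "TRBV"
        jprefix = "TRAJ" if chain is TcrChain.ALPHA else "TRBJ"
        v_gene = f"{prefix}{ci + 1}-1*01"
        j_gene = f"{jprefix}{ci + 1}*01"

        members: set[str] = set()
        attempts = 0
        while len(members) < spec.members_per_cluster and attempts < 200:
            attempts += 1
            d = int(rng.integers(1, spec.max_distance + 1))
            positions = rng.choice(cdr3_length, size=d, replace=False)
            seq = core_cdr3
            for pos in positions:
                seq = _mutate_at(rng, seq, int(pos), spec.alphabet)
                if seq != core_cdr3:
                    members.add(seq)
        members.discard(core_cdr3)

        def make_record(cdr3, v=v_gene, j=j_gene, ep=epitope):
            return SpecificityRecord(
                cdr3=cdr3, chain=chain, v_gene=v, j_gene=j, epitope=ep,
                mhc_allele="HLA-A*02:01", record_id=f"syn{next(rid)}",
            )

        core_record = make_record(core_cdr3)
        member_records = [make_record(m) for m in sorted(members)]

        decoy_records = []
        for kind, count in spec.decoys.items():
            for _ in range(count):
                base = _mutate_at(
                    rng, core_cdr3, int(rng.integers(cdr3_length)), spec.alphabet
                )
                if kind == "wrong_v":
                    decoy_records.append(make_record(base, v=v_gene + "alt"))
                elif kind == "wrong_j":
                    decoy_records.append(make_record(base, j=j_gene + "alt"))
                elif kind == "wrong_length":
                    decoy_records.append(make_record(base + base[-1]))
                elif kind == "wrong_epitope":
                    decoy_records.append(
                        make_record(base, ep=_random_seq(rng, 9, spec.alphabet))
                    )
                elif kind == "too_distant":
                    seq = core_cdr3
                    positions = rng.choice(
                        cdr3_length, size=spec.max_distance + 1, replace=False
                    )
                    for pos in positions:
                        seq = _mutate_at(rng, seq, int(pos), spec.alphabet)
                    decoy_records.append(make_record(seq))
                elif kind == "disconnected":
                    decoy_records.append(
                        make_record(
                            _disconnected_decoy(rng, core_cdr3, members, spec, cdr3_length)
                        )
                    )

        # verify by brute force that planted members are exactly the
        # reachable set once decoys with matching metadata are pooled in
        same_meta = {
            r.cdr3 for r in decoy_records
            if (r.v_gene, r.j_gene, r.epitope) == (v_gene, j_gene, epitope)
            and len(r.cdr3) == cdr3_length
        }
        reached = _brute_force_members(
            core_cdr3, members | same_meta, spec.max_distance
        )
        if reached != members:
            raise GenerationError(
                "planted cluster check failed; decoys leaked into the cluster"
            )

        records.append(core_record)
        records.extend(member_records)
        records.extend(decoy_records)
        manifests.append(
            ClusterManifest(
                core=core_record,
                member_cdr3s=set(members),
                pathways=_brute_force_pathways(core_cdr3, members),
            )
        )
    return RepertoireData(records=records, manifests=manifests)


def _disconnected_decoy(
    rng, core: str, members: set[str], spec: RepertoireSpec, cdr3_length: int
) -> str:
    """A sequence within distance 2-3 of the core whose every single-step
    neighborhood misses the member set (so accretion can never reach it)."""
    for _ in range(500):
        d = int(rng.integers(2, spec.max_distance + 1))
        positions = rng.choice(cdr3_length, size=d, replace=False)
        seq = core
        for pos in positions:
            seq = _mutate_at(rng, seq, int(pos), spec.alphabet)
        if seq in members or seq == core:
            continue
        pool = members | {core}
        if all(_hamming(seq, m) > 1 for m in pool):
            return seq
    raise GenerationError("could not place a disconnected decoy")


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------

# residue pairs whose side-chain tips realize each interaction type,
# given an admissible tip-tip distance
_TYPE_CHOICES = {
    "IONIC": [("D", "R"), ("E", "K"), ("D", "K"), ("E", "R")],
    # hydroxyl-tipped residues only: the side-chain tip is simultaneously
    # donor and acceptor, so the tuned minimum-distance pair carries the bond
    "HBOND": [("S", "S"), ("Y", "S"), ("S", "Y"), ("Y", "Y")],
    "VDW": [("L", "L"), ("V", "I"), ("F", "L"), ("I", "V")],
}
_TYPE_MAX_DIST = {"IONIC": 4.0, "HBOND": 3.5, "VDW": 4.9}
_FILLER = "AGLVSTPF"

# independent copies of the published classification tables (kept local so
# the manifest never depends on the module under test)
_NEG = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
_POS = {"K": ("NZ",), "R": ("NE", "NH1", "NH2", "CZ"), "H": ("ND1", "NE2")}
_SC_DON = {
    "R": ("NE", "NH1", "NH2"), "K": ("NZ",), "H": ("ND1", "NE2"),
    "N": ("ND2",), "Q": ("NE2",), "S": ("OG",), "T": ("OG1",),
    "Y": ("OH",), "W": ("NE1",),
}
_SC_ACC = {
    "D": ("OD1", "OD2"), "E": ("OE1", "OE2"), "N": ("OD1",), "Q": ("OE1",),
    "S": ("OG",), "T": ("OG1",), "Y": ("OH",), "H": ("ND1", "NE2"),
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ToyComplexSpec:
    peptide_length: int = 9
    cdr3_length: int = 11
    # (cdr3 position, peptide position, target distance A, intended type)
    contacts: tuple = ()
    seed: int = 0


@dataclass
class ExpectedContact:
    cdr3_position: int
    cdr3_residue: str
    peptide_position: int
    peptide_residue: str
    min_distance: float
    cdr3_part: str
    peptide_part: str
    interaction_type: str


@dataclass
class ToyComplexData:
    structure: Structure
    cdr3_chain: str
    peptide_chain: str
    cdr3_sequence: str
    peptide_sequence: str
    expected_contacts: list[ExpectedContact]


def _canonical_residue(aa: str, position: int) -> Residue:
    """One residue in a canonical frame: CA at origin, side chain along +y."""
    n = 1.458 * np.array([-np.sin(np.deg2rad(55.5)), -np.cos(np.deg2rad(55.5)), 0.0])
    c = 1.525 * np.array([np.sin(np.deg2rad(55.5)), -np.cos(np.deg2rad(55.5)), 0.0])
    ca = np.zeros(3)
    o = place_atom(n, ca, c, 1.23, 121.0, 180.0)
    res = Residue(position=position, aa=aa)
    res.atoms = [
        Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c), Atom("O", "O", o)
    ]
    placed = {"N": n, "CA": ca, "C": c, "O": o}
    if aa != "G":
        r1, r2, r3, b, ang, dih = _CB_INTERNAL
        cb = place_atom(placed[r3], placed[r2], placed[r1], b, ang, dih)
        placed["CB"] = cb
        res.atoms.append(Atom("CB", "C", cb))
        for name, a1, a2, a3, bond, angle, dihedral in SIDE_CHAIN_TOPOLOGY[aa]:
            coord = place_atom(placed[a3], placed[a2], placed[a1], bond, angle, dihedral)
            placed[name] = coord
            res.atoms.append(
                Atom(name, name[0] if name[0] in "NOS" else "C", coord)
            )
    # rotate so the side-chain tip (or O for glycine) points along +y
    tip = max(res.atoms, key=lambda a: np.linalg.norm(a.coord))
    v = tip.coord / np.linalg.norm(tip.coord)
    target = np.array([0.0, 1.0, 0.0])
    axis = np.cross(v, target)
    s = np.linalg.norm(axis)
    if s > 1e-9:
        axis /= s
        angle = np.arctan2(s, np.dot(v, target))
        k = axis
        for atom in res.atoms:
            vv = atom.coord
            atom.coord = (
                vv * np.cos(angle)
                + np.cross(k, vv) * np.sin(angle)
                + k * np.dot(k, vv) * (1 - np.cos(angle))
            )
    return res


def _translate(res: Residue, offset: np.ndarray) -> None:
    for atom in res.atoms:
        atom.coord = atom.coord + offset


def _mirror_y(res: Residue) -> None:
    for atom in res.atoms:
        atom.coord = atom.coord * np.array([1.0, -1.0, 1.0])


def _min_dist(res_a: Residue, res_b: Residue) -> float:
    da = res_a.coords()
    db = res_b.coords()
    return float(np.min(np.linalg.norm(da[:, None, :] - db[None, :, :], axis=-1)))


def _argmin_atoms(res_a: Residue, res_b: Residue) -> tuple[str, str, float]:
    atoms_a = res_a.heavy_atoms()
    atoms_b = res_b.heavy_atoms()
    da = np.array([a.coord for a in atoms_a])
    db = np.array([a.coord for a in atoms_b])
    d = np.linalg.norm(da[:, None, :] - db[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return atoms_a[i].name, atoms_b[j].name, float(d[i, j])


def _expected_type(cres: Residue, pres: Residue) -> str:
    def group_min(res_x, names_x, res_y, names_y):
        best = np.inf
        for nx in names_x:
            if not res_x.has_atom(nx):
                continue
            for ny in names_y:
                if not res_y.has_atom(ny):
                    continue
                best = min(
                    best,
                    float(np.linalg.norm(res_x.atom(nx).coord - res_y.atom(ny).coord)),
                )
        return best

    for neg, pos in ((cres, pres), (pres, cres)):
        if neg.aa in _NEG and pos.aa in _POS:
            if group_min(neg, _NEG[neg.aa], pos, _POS[pos.aa]) <= 4.0:
                return "IONIC"
    don_c = ["N"] + list(_SC_DON.get(cres.aa, ()))
    acc_c = ["O", "OXT"] + list(_SC_ACC.get(cres.aa, ()))
    don_p = ["N"] + list(_SC_DON.get(pres.aa, ()))
    acc_p = ["O", "OXT"] + list(_SC_ACC.get(pres.aa, ()))
    if min(
        group_min(cres, don_c, pres, acc_p), group_min(pres, don_p, cres, acc_c)
    ) <= 3.5:
        return "HBOND"
    return "VDW"


def generate_toy_complex(spec: ToyComplexSpec) -> ToyComplexData:
    """Realize a contact plan as coordinates, with the expected contact list.

    CDR3 residues sit on a widely spaced strand (10 A pitch) with side
    chains pointing at the peptide; planned peptide residues float opposite
    their partner at a tuned separation, unplanned ones far away.  Each
    planned pair is realized within +-0.2 A of its target distance and all
    unplanned pairs stay beyond 6 A; violations raise GenerationError.
    """
    rng = np.random.default_rng(spec.seed)
    plan = list(spec.contacts)
    for cpos, ppos, dist, itype in plan:
        if not (1 <= cpos <= spec.cdr3_length) or not (1 <= ppos <= spec.peptide_length):
            raise GenerationError(f"contact ({cpos},{ppos}) outside the sequences")
        if itype not in _TYPE_CHOICES:
            raise GenerationError(f"unknown interaction type {itype!r}")
        if not 2.5 <= dist <= _TYPE_MAX_DIST[itype]:
            raise GenerationError(
                f"{itype} contact must have target distance in "
                f"[2.5, {_TYPE_MAX_DIST[itype]}], got {dist}"
            )
    if len({c[0] for c in plan}) < len(plan) or len({c[1] for c in plan}) < len(plan):
        raise GenerationError(
            "greedy placement needs distinct CDR3 and peptide positions per contact"
        )

    cdr3_aa = {}
    pep_aa = {}
    for cpos, ppos, dist, itype in plan:
        pair = _TYPE_CHOICES[itype][int(rng.integers(len(_TYPE_CHOICES[itype])))]
        cdr3_aa[cpos], pep_aa[ppos] = pair
    cdr3_seq = "".join(
        cdr3_aa.get(i, _FILLER[i % len(_FILLER)]) for i in range(1, spec.cdr3_length + 1)
    )
    pep_seq = "".join(
        pep_aa.get(i, _FILLER[(i + 3) % len(_FILLER)])
        for i in range(1, spec.peptide_length + 1)
    )

    pitch = 10.0
    cdr3_chain = Chain(chain_id="C")
    for i, aa in enumerate(cdr3_seq, start=1):
        res = _canonical_residue(aa, i)
        _translate(res, np.array([pitch * i, 0.0, 0.0]))
        cdr3_chain.residues.append(res)

    planned_by_pep = {ppos: (cpos, dist) for cpos, ppos, dist, _ in plan}
    pep_chain = Chain(chain_id="P")
    for j, aa in enumerate(pep_seq, start=1):
        res = _canonical_residue(aa, j)
        _mirror_y(res)  # side chain now points along -y
        if j in planned_by_pep:
            cpos, target = planned_by_pep[j]
            partner = cdr3_chain.residues[cpos - 1]
            lo, hi = 0.0, 40.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                trial = Residue(
                    position=j, aa=aa,
                    atoms=[Atom(a.name, a.element, a.coord.copy()) for a in res.atoms],
                )
                _translate(trial, np.array([pitch * cpos, mid, 0.0]))
                if _min_dist(trial, partner) < target:
                    lo = mid
                else:
                    hi = mid
            _translate(res, np.array([pitch * cpos, 0.5 * (lo + hi), 0.0]))
        else:
            _translate(res, np.array([pitch * j + 3.0, 40.0, 0.0]))
        pep_chain.residues.append(res)

    structure = Structure(chains={"C": cdr3_chain, "P": pep_chain})

    # brute-force verification and expected-contact manifest
    expected: list[ExpectedContact] = []
    planned_set = {(c, p) for c, p, _, _ in plan}
    for cres in cdr3_chain.residues:
        for pres in pep_chain.residues:
            d = _min_dist(cres, pres)
            if (cres.position, pres.position) in planned_set:
                target = next(
                    t for c, p, t, _ in plan
                    if (c, p) == (cres.position, pres.position)
                )
                if abs(d - target) > 0.2:
                    raise GenerationError(
                        f"contact ({cres.position},{pres.position}) realized at "
                        f"{d:.2f} A, wanted {target:.2f} A"
                    )
            elif d <= 6.0:
                raise GenerationError(
                    f"unplanned pair ({cres.position},{pres.position}) at {d:.2f} A"
                )
            if d < 5.0:
                an, bn, dmin = _argmin_atoms(cres, pres)
                expected.append(
                    ExpectedContact(
                        cdr3_position=cres.position, cdr3_residue=cres.aa,
                        peptide_position=pres.position, peptide_residue=pres.aa,
                        min_distance=dmin,
                        cdr3_part="main_chain" if an in _BACKBONE else "side_chain",
                        peptide_part="main_chain" if bn in _BACKBONE else "side_chain",
                        interaction_type=_expected_type(cres, pres),
                    )
                )
    for cpos, ppos, dist, itype in plan:
        realized = next(
            e for e in expected
            if (e.cdr3_position, e.peptide_position) == (cpos, ppos)
        )
        if realized.interaction_type != itype:
            raise GenerationError(
                f"contact ({cpos},{ppos}) realized as {realized.interaction_type}, "
                f"intended {itype}"
            )
    return ToyComplexData(
        structure=structure, cdr3_chain="C", peptide_chain="P",
        cdr3_sequence=cdr3_seq, peptide_sequence=pep_seq,
        expected_contacts=expected,
    )


# ---------------------------------------------------------------------------
# Planted descriptor-energy tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEnergySpec:
    n_rows: int = 500
    # feature name (e.g. "cdr3.VHSE1") -> linear effect size.  The default
    # plants five hydrophobicity-group scales chosen to be mutually
    # non-collinear over the 20 residues (pairwise |r| < 0.7): recovery of a
    # planted feature is only well-posed when no other scale aliases it.
    informative: tuple = (
        ("cdr3.Z1", 1.0), ("cdr3.VHSE2", 1.0), ("cdr3.KF10", 1.0),
        ("p.F1", 1.0), ("p.KF10", 1.0),
    )
    noise_sigma: float = 0.25
    feature_noise_sigma: float = 0.1
    distance_slope: float = 0.0
    seed: int = 0


def generate_planted_energies(
    spec: PlantedEnergySpec,
) -> tuple[pd.DataFrame, dict]:
    """Feature/target table with a planted linear descriptor-energy law.

    Rows are random residue pairs; the target is a linear combination of the
    named informative scales plus an optional distance term and Gaussian
    noise.  Effects apply to standardized scale values (z-scored over the 20
    residues) so an effect size of 1 means one target unit per scale SD for
    every family, regardless of the family's native units.  Small Gaussian
    feature noise emulates measurement scatter so no two features are
    exactly collinear.  Returns the table and the ground-truth coefficients.
    """
    table = default_table()
    mu = table.scales.mean()
    sd_ = table.scales.std(ddof=0)
    for name, _ in spec.informative:
        bare = name.split(".", 1)[1] if name.startswith(("cdr3.", "p.")) else name
        if bare not in table.scales.columns:
            raise GenerationError(f"unknown scale {name!r}")
    rng = np.random.default_rng(spec.seed)
    aas = list(AMINO_ACIDS)
    rows = []
    for _ in range(spec.n_rows):
        c = aas[int(rng.integers(20))]
        p = aas[int(rng.integers(20))]
        feats = table.describe_pair(c, p)
        dist = float(rng.uniform(2.5, 5.0))
        energy = sum(
            eff * (feats[name] - mu[name.split(".", 1)[1]]) / sd_[name.split(".", 1)[1]]
            for name, eff in spec.informative
        )
        energy += spec.distance_slope * dist
        energy += float(rng.normal(0.0, spec.noise_sigma))
        row = dict(feats)
        if spec.feature_noise_sigma > 0:
            noise = rng.normal(0.0, spec.feature_noise_sigma, size=len(row))
            row = {k: v + n for (k, v), n in zip(row.items(), noise)}
        row["distance"] = dist
        row["energy"] = energy
        row["cdr3_residue"] = c
        row["peptide_residue"] = p
        rows.append(row)
    truth = {
        "informative": dict(spec.informative),
        "distance_slope": spec.distance_slope,
        "noise_sigma": spec.noise_sigma,
    }
    return pd.DataFrame(rows), truth


def generate_planted_denergy(
    n: int = 200,
    index_name: str = "BLA.62.v2",
    index_slope: float = -0.5,
    distance_slope: float = 0.0,
    noise_sigma: float = 0.1,
    intercept: float = 5.0,
    preset: str = "small_patch",
    optimization: str = "minimized",
    seed: int = 0,
) -> pd.DataFrame:
    """A dEnergy-shaped table with planted index and/or distance effects.

    ``value`` plays the role of dEnergy; the intercept keeps it positive so
    the |dEnergy| used by the correlation analyses preserves the planted
    slopes (a negative ``index_slope`` is recovered as a negative Pearson
    correlation between the adjusted index and |dEnergy|).
    """
    kind, num, _ = index_name.split(".")
    matrix = get_matrix(f"BLOSUM{num}", kind)
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    rows = []
    for _ in range(n):
        a, b = rng.choice(aas, size=2, replace=False)
        adj = adjusted_blosum((str(a), str(b)), matrix)
        dist = float(rng.uniform(2.5, 10.0))
        y = intercept + index_slope * adj + distance_slope * dist
        y += float(rng.normal(0.0, noise_sigma))
        rows.append(
            {
                "from_aa": str(a), "to_aa": str(b),
                "preset": preset, "optimization": optimization,
                "chain": "alpha" if rng.random() < 0.5 else "beta",
                "contact_status": "contacting",
                "min_substitution_distance": dist,
                "value": y,
            }
        )
    return pd.DataFrame(rows)
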