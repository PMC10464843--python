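"""Amino-acid descriptor scales and adjusted substitution-matrix indices.

The compendium holds 47 scales per residue, 94 per contacting residue pair
(``cdr3.`` and ``p.`` prefixes):

* ``KF1``-``KF10``   Kidera factors (Kidera et al., J Protein Chem 1985)
* ``VHSE1``-``VHSE8`` principal-component scores of hydrophobic, steric and
  electronic properties (Mei et al., Biopolymers 2005)
* ``PP1``-``PP3``    Cruciani properties (Cruciani et al., J Chemometrics 2004)
* ``Z1``-``Z5``      extended z-scales (Sandberg et al., J Med Chem 1998)
* ``a.pah``, ``a.pss``, ``a.ms``, ``a.cc``, ``a.ec`` Atchley factors
  (Atchley et al., PNAS 2005): polarity/accessibility/hydrophobicity,
  propensity for secondary structure, molecular size, codon composition,
  electrostatic charge
* ``Blos1``-``Blos10`` substitution-profile components.  SYNTHETIC STAND-IN:
  the original BLOSUM-indices scale set could not be sourced here, so these
  are eigenvector scores of the BLOSUM62 matrix computed at import time;
  they play the same structural role (ten orthogonal axes of the BLOSUM62
  substitution profile, the first tracking hydropathy).
* ``F1``-``F6``      six-factor summary scales.  SYNTHETIC STAND-IN for the
  published factor-analysis scales: principal-component scores of the 31
  embedded scales above, sign-aligned so that F1 tracks hydrophobicity,
  F2 secondary structure, F3 bulk and F6 electronic properties.

Both stand-in families can be overridden by supplying a replacement table.

Substitution statistics use BLOSUM62 and BLOSUM100 in three index kinds:
half-bit scores (BLA, from the NCBI matrices bundled with biotite), bit-unit
scores (SIJ = BLA/2) and target frequencies (QIJ, reconstructed as
q_ij = p_i p_j 2^{s_ij} with Robinson-Robinson backgrounds, renormalised).
The adjusted index of a substitution a->b is
``M[a][b] - (M[a][a] + M[b][b]) / 2``, zero for every identity substitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .contacts import AMINO_ACIDS

__all__ = [
    "DescriptorTable",
    "SubstitutionMatrix",
    "default_table",
    "describe_residue",
    "describe_pair",
    "adjusted_blosum",
    "adjusted_index_table",
    "get_matrix",
    "ADJUSTED_INDEX_NAMES",
    "SCALE_NAMES",
    "PROPERTY_GROUPS",
]

AA = list(AMINO_ACIDS)  # alphabetical one-letter order

# ---------------------------------------------------------------------------
# Published tables (rows in the order A C D E F G H I K L M N P Q R S T V W Y)
# ---------------------------------------------------------------------------

_KIDERA = {
    "A": [-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48],
    "R": [0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93],
    "N": [1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73],
    "D": [0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70],
    "C": [0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10],
    "Q": [-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33],
    "E": [-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12],
    "G": [1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46],
    "H": [-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63],
    "I": [-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78],
    "L": [-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93],
    "K": [-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60],
    "M": [-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27],
    "F": [-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44],
    "P": [2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28],
    "S": [0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23],
    "T": [0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19],
    "W": [0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60],
    "Y": [1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53],
    "V": [-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65],
}

_ZSCALES = {
    "A": [0.24, -2.32, 0.60, -0.14, 1.30],
    "R": [3.52, 2.50, -3.50, 1.99, -0.17],
    "N": [3.05, 1.62, 1.04, -1.15, 1.61],
    "D": [3.98, 0.93, 1.93, -2.46, 0.75],
    "C": [0.84, -1.67, 3.71, 0.18, -2.65],
    "Q": [1.75, 0.50, -1.44, -1.34, 0.66],
    "E": [3.11, 0.26, -0.11, -3.04, -0.25],
    "G": [2.05, -4.06, 0.36, -0.82, -0.38],
    "H": [2.47, 1.95, 0.26, 3.90, 0.09],
    "I": [-3.89, -1.73, -1.71, -0.84, 0.26],
    "L": [-4.28, -1.30, -1.49, -0.72, 0.84],
    "K": [2.29, 0.89, -2.49, 1.49, 0.31],
    "M": [-2.85, -0.22, 0.47, 1.94, -0.98],
    "F": [-4.22, 1.94, 1.06, 0.54, -0.62],
    "P": [-1.66, 0.27, 1.84, 0.70, 2.00],
    "S": [2.39, -1.07, 1.15, -1.39, 0.67],
    "T": [0.75, -2.18, -1.12, -1.46, -0.40],
    "W": [-4.36, 3.94, 0.59, 3.44, -1.59],
    "Y": [-2.54, 2.44, 0.43, 0.04, -1.47],
    "V": [-2.59, -2.64, -1.54, -0.85, -0.02],
}

_VHSE = {
    "A": [0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48],
    "R": [-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83],
    "N": [-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80],
    "D": [-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56],
    "C": [0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19],
    "Q": [-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41],
    "E": [-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02],
    "G": [-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34],
    "H": [-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65],
    "I": [1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13],
    "L": [1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62],
    "K": [-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13],
    "M": [1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68],
    "F": [1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20],
    "P": [0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56],
    "S": [-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11],
    "T": [-0.34, -0.51, -0.55, -1.06, -0.06, -0.01, -0.79, 0.39],
    "W": [1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.01, -0.85],
    "Y": [0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52],
    "V": [0.76, -0.92, -0.17, -1.91, 0.22, -1.40, -0.24, -0.03],
}

_CRUCIANI = {
    "A": [-0.96, -0.76, 0.31],
    "R": [0.80, 0.63, 0.99],
    "N": [0.82, -0.57, 0.02],
    "D": [1.00, -0.89, -1.00],
    "C": [-0.55, -0.47, 0.19],
    "Q": [0.78, -0.30, -0.38],
    "E": [0.94, -0.54, -0.99],
    "G": [-0.88, -1.00, 0.49],
    "H": [0.67, -0.11, 0.37],
    "I": [-0.94, -0.05, -0.18],
    "L": [-0.90, 0.03, -0.24],
    "K": [0.60, 0.10, 1.00],
    "M": [-0.82, 0.03, -0.08],
    "F": [-0.85, 0.48, -0.58],
    "P": [-0.81, -0.41, -0.07],
    "S": [0.41, -0.82, 0.57],
    "T": [0.40, -0.64, 0.37],
    "W": [-0.60, 1.00, -0.47],
    "Y": [-0.41, 0.77, -0.64],
    "V": [-1.00, -0.40, -0.07],
}

_ATCHLEY = {
    "A": [-0.591, -1.302, -0.733, 1.570, -0.146],
    "C": [-1.343, 0.465, -0.862, -1.020, -0.255],
    "D": [1.050, 0.302, -3.656, -0.259, -3.242],
    "E": [1.357, -1.453, 1.477, 0.113, -0.837],
    "F": [-1.006, -0.590, 1.891, -0.397, 0.412],
    "G": [-0.384, 1.652, 1.330, 1.045, 2.064],
    "H": [0.336, -0.417, -1.673, -1.474, -0.078],
    "I": [-1.239, -0.547, 2.131, 0.393, 0.816],
    "K": [1.831, -0.561, 0.533, -0.277, 1.648],
    "L": [-1.019, -0.987, -1.505, 1.266, -0.912],
    "M": [-0.663, -1.524, 2.219, -1.005, 1.212],
    "N": [0.945, 0.828, 1.299, -0.169, 0.933],
    "P": [0.189, 2.081, -1.628, 0.421, -1.392],
    "Q": [0.931, -0.179, -3.005, -0.503, -1.853],
    "R": [1.538, -0.055, 1.502, 0.440, 2.897],
    "S": [-0.228, 1.399, -4.760, 0.670, -2.647],
    "T": [-0.032, 0.326, 2.213, 0.908, 1.313],
    "V": [-1.337, -0.279, -0.544, 1.242, -1.262],
    "W": [-0.595, 0.009, 0.672, -2.128, -0.184],
    "Y": [0.260, 0.830, 3.097, -0.838, 1.512],
}

_ATCHLEY_NAMES = ["a.pah", "a.pss", "a.ms", "a.cc", "a.ec"]

# Robinson & Robinson (1991) background frequencies, used to reconstruct
# target frequencies from bit scores
_BACKGROUND = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def _frame(table: Mapping[str, list[float]], names: list[str]) -> pd.DataFrame:
    df = pd.DataFrame({aa: table[aa] for aa in AA}, index=names).T
    return df.loc[AA]


def _align_sign(col: pd.Series, reference: pd.Series | None) -> pd.Series:
    if reference is not None:
        r = np.corrcoef(col.values, reference.values)[0, 1]
        if r < 0:
            return -col
        return col
    # deterministic fallback: largest-magnitude entry made positive
    idx = col.abs().idxmax()
    return -col if col[idx] < 0 else col


def _blosum_components(bla62: pd.DataFrame, reference: pd.Series) -> pd.DataFrame:
    """Ten eigenvector score columns of the BLOSUM62 matrix (Blos1-Blos10)."""
    m = bla62.loc[AA, AA].values.astype(float)
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(-np.abs(vals))[:10]
    scores = vecs[:, order] * np.sqrt(np.abs(vals[order]))
    df = pd.DataFrame(scores, index=AA, columns=[f"Blos{i}" for i in range(1, 11)])
    df["Blos1"] = _align_sign(df["Blos1"], reference)
    for c in df.columns[1:]:
        df[c] = _align_sign(df[c], None)
    return df


def _factor_scales(base: pd.DataFrame, refs: dict[str, pd.Series]) -> pd.DataFrame:
    """Six principal-component factor columns (F1-F6) of the scale compendium."""
    x = (base - base.mean()) / base.std(ddof=0)
    u, s, _ = np.linalg.svd(x.values, full_matrices=False)
    scores = u[:, :6] * s[:6] / np.sqrt(len(AA))
    df = pd.DataFrame(scores, index=AA, columns=[f"F{i}" for i in range(1, 7)])
    for name, ref in refs.items():
        df[name] = _align_sign(df[name], ref)
    for c in df.columns:
        if c not in refs:
            df[c] = _align_sign(df[c], None)
    return df


# groups of scales by the physicochemical property they represent; a scale
# may appear in several groups (multi-membership view)
PROPERTY_GROUPS: dict[str, tuple[str, ...]] = {
    "hydrophobicity": ("Z1", "PP2", "F1", "VHSE1", "VHSE2", "Blos1", "KF4", "KF10"),
    "steric": ("a.ms", "Z2", "F3", "VHSE3", "VHSE4", "Blos1", "Blos2", "Blos3", "KF2"),
    "electronic": (
        "a.pah", "a.ec", "Z3", "PP1", "F6", "VHSE5", "VHSE6", "VHSE7", "VHSE8",
    ),
    "secondary_structure": ("a.pss", "F2", "Blos1", "Blos3", "KF1", "KF3", "KF5", "KF8"),
}

SCALE_NAMES: list[str] = (
    [f"Blos{i}" for i in range(1, 11)]
    + [f"KF{i}" for i in range(1, 11)]
    + [f"VHSE{i}" for i in range(1, 9)]
    + [f"PP{i}" for i in range(1, 4)]
    + [f"Z{i}" for i in range(1, 6)]
    + [f"F{i}" for i in range(1, 7)]
    + _ATCHLEY_NAMES
)


@dataclass
class DescriptorTable:
    """47 named scales over the 20 canonical residues, with property groups."""

    scales: pd.DataFrame  # 20 x 47, index = residues, columns = scale names

    def describe_residue(self, residue: str) -> dict[str, float]:
        if residue not in AMINO_ACIDS:
            raise KeyError(f"non-canonical residue {residue!r}")
        return self.scales.loc[residue].to_dict()

    def describe_pair(self, cdr3_res: str, pep_res: str) -> dict[str, float]:
        c = self.describe_residue(cdr3_res)
        p = self.describe_residue(pep_res)
        out = {f"cdr3.{k}": v for k, v in c.items()}
        out.update({f"p.{k}": v for k, v in p.items()})
        return out

    def group_memberships(self, scale: str) -> set[str]:
        """All property groups listing the scale (may be several or none)."""
        return {g for g, names in PROPERTY_GROUPS.items() if scale in names}

    def primary_group(self, scale: str) -> str:
        """Single-group view: first listing group, else ``unassigned``."""
        for g, names in PROPERTY_GROUPS.items():
            if scale in names:
                return g
        return "unassigned"

    def group_scales(self, group: str) -> list[str]:
        return [s for s in self.scales.columns if s in PROPERTY_GROUPS.get(group, ())]


@lru_cache(maxsize=1)
def default_table() -> DescriptorTable:
    kf = _frame(_KIDERA, [f"KF{i}" for i in range(1, 11)])
    z = _frame(_ZSCALES, [f"Z{i}" for i in range(1, 6)])
    vhse = _frame(_VHSE, [f"VHSE{i}" for i in range(1, 9)])
    pp = _frame(_CRUCIANI, [f"PP{i}" for i in range(1, 4)])
    atch = _frame(_ATCHLEY, _ATCHLEY_NAMES)
    base = pd.concat([kf, vhse, pp, z, atch], axis=1)

    bla62 = get_matrix("BLOSUM62", "BLA").values
    blos = _blosum_components(bla62, reference=vhse["VHSE1"])
    factors = _factor_scales(
        base,
        refs={
            "F1": vhse["VHSE1"],
            "F2": atch["a.pss"],
            "F3": vhse["VHSE3"],
            "F6": z["Z3"],
        },
    )
    scales = pd.concat([blos, kf, vhse, pp, z, factors, atch], axis=1)
    scales = scales[SCALE_NAMES]
    return DescriptorTable(scales=scales)


def describe_residue(residue: str) -> dict[str, float]:
    """47 named descriptor values for one canonical residue."""
    return default_table().describe_residue(residue)


def describe_pair(cdr3_res: str, pep_res: str) -> dict[str, float]:
    """94 named values for a contacting pair (``cdr3.`` / ``p.`` prefixes)."""
    return default_table().describe_pair(cdr3_res, pep_res)


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

ADJUSTED_INDEX_NAMES = [
    "BLA.62.v2", "SIJ.62.v2", "QIJ.62.v2",
    "BLA.100.v2", "SIJ.100.v2", "QIJ.100.v2",
]


@dataclass(frozen=True)
class SubstitutionMatrix:
    name: str  # BLOSUM62 | BLOSUM100
    kind: str  # BLA | SIJ | QIJ
    values: pd.DataFrame

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.values.loc[a, b])
        except KeyError:
            raise KeyError(f"unknown residue pair ({a!r}, {b!r})") from None


@lru_cache(maxsize=None)
def _bla(name: str) -> pd.DataFrame:
    import biotite.sequence as seq
    import biotite.sequence.align as align

    alph = seq.ProteinSequence.alphabet
    mat = align.SubstitutionMatrix(alph, alph, name)
    df = pd.DataFrame(
        [[float(mat.get_score(a, b)) for b in AA] for a in AA], index=AA, columns=AA
    )
    return df


@lru_cache(maxsize=None)
def get_matrix(name: str, kind: str) -> SubstitutionMatrix:
    """A substitution matrix by name (BLOSUM62/BLOSUM100) and index kind.

    BLA holds the published half-bit integer scores.  SIJ converts them to
    bit units (BLA/2).  QIJ reconstructs clustered target frequencies from
    the bit scores and Robinson-Robinson backgrounds, normalised to sum to 1.
    """
    if name not in ("BLOSUM62", "BLOSUM100"):
        raise ValueError(f"unknown matrix {name!r}")
    if kind not in ("BLA", "SIJ", "QIJ"):
        raise ValueError(f"unknown index kind {kind!r}")
    bla = _bla(name)
    if kind == "BLA":
        values = bla
    elif kind == "SIJ":
        values = bla / 2.0
    else:
        sij = bla / 2.0
        p = pd.Series(_BACKGROUND)
        q = pd.DataFrame(
            np.outer(p[AA], p[AA]) * np.power(2.0, sij.values),
            index=AA, columns=AA,
        )
        values = q / q.values.sum()
    return SubstitutionMatrix(name=name, kind=kind, values=values)


def read_ncbi_matrix(path, name: str, kind: str) -> SubstitutionMatrix:
    """Parse an NCBI-distributed substitution matrix file as an override.

    Handles both the square score layout (bla/sij/iij: header row of
    residues, one labelled row per residue) and the lower-triangular qij
    layout.  Lines starting with ``#`` are comments.  Only the 20 canonical
    residues are kept; the matrix is symmetrized from the triangle when
    needed.
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    header = lines[0].split()
    values = pd.DataFrame(np.nan, index=AA, columns=AA, dtype=float)
    body = lines[1:]
    labelled = body and body[0].split()[0].isalpha()
    for i, ln in enumerate(body):
        fields = ln.split()
        row_aa = fields.pop(0) if labelled else header[i]
        if row_aa not in values.index:
            continue
        for col, val in zip(header, fields):
            if col in values.columns:
                values.loc[row_aa, col] = float(val)
                values.loc[col, row_aa] = float(val)
    if values.isna().any().any():
        missing = values.index[values.isna().any(axis=1)].tolist()
        raise ValueError(f"matrix file incomplete for residues {missing}")
    return SubstitutionMatrix(name=name, kind=kind, values=values)


def adjusted_blosum(substitution: tuple[str, str], matrix: SubstitutionMatrix) -> float:
    """Adjusted index: M[from][to] - (M[from][from] + M[to][to]) / 2."""
    a, b = substitution
    return matrix.score(a, b) - (matrix.score(a, a) + matrix.score(b, b)) / 2.0


@lru_cache(maxsize=1)
def adjusted_index_table() -> pd.DataFrame:
    """Adjusted values of all six indices for every ordered residue pair."""
    rows = []
    for label in ADJUSTED_INDEX_NAMES:
        kind, num, _ = label.split(".")
        matrix = get_matrix(f"BLOSUM{num}", kind)
        for a in AA:
            for b in AA:
                rows.append(
                    {
                        "index": label,
                        "from_aa": a,
                        "to_aa": b,
                        "adjusted": adjusted_blosum((a, b), matrix),
                    }
                )
    return pd.DataFrame(rows)
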