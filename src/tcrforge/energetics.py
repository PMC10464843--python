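"""CDR3-peptide interface energies, dEnergy along pathways, valuable positions.

Energies are computed only over CDR3 <-> peptide atom pairs (face1 = CDR3
residues, face2 = peptide residues) under three term presets:

* ``large_patch``: fa_atr, fa_sol, hbond_sr_bb, hbond_lr_bb, hbond_bb_sc,
  hbond_sc
* ``small_patch``: large_patch minus hbond_sr_bb and hbond_bb_sc
* ``full``: all of the above plus a repulsive clash term (fa_rep)

The surrogate term forms keep the Rosetta term taxonomy but are simple
finite-ranged pair potentials (documented in docs/methods.md); they produce
relative energies with the right structure for the downstream correlation
analyses, not Rosetta-comparable values.  Real score tables can be supplied
through the ``precomputed`` dialect instead.  Every pairwise contribution is
attributed to the CDR3-side residue, so per-residue profiles over CDR3
positions sum exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contacts import (
    Residue,
    Structure,
    _acceptor_names,
    _donor_names,
)

__all__ = [
    "EnergyPreset",
    "PRESETS",
    "InterfaceEnergy",
    "DEnergy",
    "interface_energy",
    "denergy",
    "valuable_positions",
    "valuable_substitution_rate",
    "min_residue_distance",
]

LARGE_PATCH_TERMS = (
    "fa_atr",
    "fa_sol",
    "hbond_sr_bb",
    "hbond_lr_bb",
    "hbond_bb_sc",
    "hbond_sc",
)
SMALL_PATCH_TERMS = tuple(
    t for t in LARGE_PATCH_TERMS if t not in ("hbond_sr_bb", "hbond_bb_sc")
)
FULL_TERMS = LARGE_PATCH_TERMS + ("fa_rep",)


@dataclass(frozen=True)
class EnergyPreset:
    name: str
    terms: tuple[str, ...]


PRESETS: dict[str, EnergyPreset] = {
    "full": EnergyPreset("full", FULL_TERMS),
    "large_patch": EnergyPreset("large_patch", LARGE_PATCH_TERMS),
    "small_patch": EnergyPreset("small_patch", SMALL_PATCH_TERMS),
}

# surrogate constants (arbitrary units / A); all terms are finite-ranged
ATR_EPS = 0.10
ATR_CUT = 6.0
REP_EPS = 1.0
SOL_PENALTY = 0.2
SOL_CUT = 4.5
HBOND_WELL = -1.5
HBOND_R_ON = 2.6
HBOND_R_OFF = 3.5
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass
class InterfaceEnergy:
    model_id: str
    preset: str
    total: float
    per_residue: dict[int, float] = field(default_factory=dict)
    per_term: dict[str, float] = field(default_factory=dict)


@dataclass
class DEnergy:
    """Interface-energy change caused by one substitution (child - parent)."""

    parent_id: str
    child_id: str
    preset: str
    value: float
    substitution: tuple[int, str, str]
    min_substitution_distance: float
    optimization: str = ""
    chain: str = ""
    contact_status: str = ""

    @property
    def abs_value(self) -> float:
        return abs(self.value)


def _switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """1 below r_on, smooth cosine taper to 0 at r_off."""
    s = 0.5 * (1.0 + np.cos(np.pi * (r - r_on) / (r_off - r_on)))
    return np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, s))


def _pair_terms(cres: Residue, pres: Residue) -> dict[str, float]:
    """All surrogate term values for one CDR3-residue/peptide-residue pair."""
    catoms = cres.heavy_atoms()
    patoms = pres.heavy_atoms()
    cxyz = np.array([a.coord for a in catoms])
    pxyz = np.array([a.coord for a in patoms])
    d = np.linalg.norm(cxyz[:, None, :] - pxyz[None, :, :], axis=-1)

    terms = {t: 0.0 for t in FULL_TERMS}
    if d.size == 0 or np.min(d) > max(ATR_CUT, SOL_CUT, HBOND_R_OFF):
        return terms

    radii_c = np.array([ELEMENT_RADII.get(a.element, 1.7) for a in catoms])
    radii_p = np.array([ELEMENT_RADII.get(a.element, 1.7) for a in patoms])
    rm = radii_c[:, None] + radii_p[None, :]

    # attractive Lennard-Jones branch, flat at -eps inside the minimum
    in_range = d <= ATR_CUT
    ratio = np.where(d < rm, 1.0, rm / np.maximum(d, 1e-9))
    terms["fa_atr"] = float(np.sum(np.where(in_range, -ATR_EPS * ratio**6, 0.0)))

    # repulsive branch (full preset only)
    clash = d < rm
    if np.any(clash):
        rr = (rm / np.maximum(d, 1e-9)) ** 6
        rep = REP_EPS * (rr**2 - 2.0 * rr + 1.0)
        terms["fa_rep"] = float(np.sum(np.where(clash, rep, 0.0)))

    # burial penalty for polar atoms dragged into the interface
    polar_c = np.array([a.element in ("N", "O") for a in catoms])
    polar_p = np.array([a.element in ("N", "O") for a in patoms])
    polar_pair = polar_c[:, None] | polar_p[None, :]
    terms["fa_sol"] = float(SOL_PENALTY * np.sum((d <= SOL_CUT) & polar_pair))

    # distance-switched hydrogen-bond wells, classed by backbone flags
    cnames = [a.name for a in catoms]
    pnames = [a.name for a in patoms]
    for donor_res, donor_names, acc_res, acc_names, donor_is_cdr3 in (
        (cres, _donor_names(cres), pres, _acceptor_names(pres), True),
        (pres, _donor_names(pres), cres, _acceptor_names(cres), False),
    ):
        for dn in donor_names:
            for an in acc_names:
                if donor_is_cdr3:
                    i, j = cnames.index(dn), pnames.index(an)
                    r = d[i, j]
                    d_bb = catoms[i].is_backbone
                    a_bb = patoms[j].is_backbone
                else:
                    i, j = pnames.index(dn), cnames.index(an)
                    r = d[j, i]
                    d_bb = patoms[i].is_backbone
                    a_bb = catoms[j].is_backbone
                if r >= HBOND_R_OFF:
                    continue
                e = HBOND_WELL * float(_switch(np.array([r]), HBOND_R_ON, HBOND_R_OFF)[0])
                if d_bb and a_bb:
                    # CDR3 and peptide are different chains: backbone-backbone
                    # interface bonds are long-range by definition
                    terms["hbond_lr_bb"] += e
                elif d_bb or a_bb:
                    terms["hbond_bb_sc"] += e
                else:
                    terms["hbond_sc"] += e
    return terms


def interface_energy(
    model: Structure,
    cdr3_chain: str,
    cdr3_range: tuple[int, int],
    peptide_chain: str,
    preset: str = "full",
    model_id: str = "",
) -> InterfaceEnergy:
    """Interface energy over CDR3 <-> peptide pairs under a named preset.

    Per-residue contributions are indexed by CDR3 position (1-based from the
    start of the CDR3 substructure) and sum to the total exactly.
    """
    try:
        preset_def = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown energy preset {preset!r}") from None
    lo, hi = cdr3_range
    cdr3_residues = [
        r for r in model.chain(cdr3_chain).residues if lo <= r.position <= hi
    ]
    pep_residues = model.chain(peptide_chain).residues
    per_residue: dict[int, float] = {}
    per_term = {t: 0.0 for t in preset_def.terms}
    for cres in cdr3_residues:
        contribution = 0.0
        for pres in pep_residues:
            terms = _pair_terms(cres, pres)
            for t in preset_def.terms:
                per_term[t] += terms[t]
                contribution += terms[t]
        per_residue[cres.position - lo + 1] = contribution
    total = float(sum(per_residue.values()))
    return InterfaceEnergy(
        model_id=model_id, preset=preset, total=total,
        per_residue=per_residue, per_term=per_term,
    )


def min_residue_distance(
    model: Structure, chain_id: str, position: int, other_chain: str
) -> float:
    """Minimum heavy-atom distance from one residue to any residue of a chain."""
    res = model.chain(chain_id).residue_at(position)
    rc = res.coords()
    best = np.inf
    for other in model.chain(other_chain).residues:
        d = float(
            np.min(np.linalg.norm(rc[:, None, :] - other.coords()[None, :, :], axis=-1))
        )
        best = min(best, d)
    return best


def denergy(
    parent: InterfaceEnergy,
    child: InterfaceEnergy,
    substitution: tuple[int, str, str],
    min_substitution_distance: float,
    optimization: str = "",
    chain: str = "",
    contact_status: str = "",
) -> DEnergy:
    """dEnergy = E(child) - E(parent) for models one substitution apart."""
    if parent.preset != child.preset:
        raise ValueError(
            f"preset mismatch: {parent.preset!r} vs {child.preset!r}"
        )
    return DEnergy(
        parent_id=parent.model_id,
        child_id=child.model_id,
        preset=parent.preset,
        value=child.total - parent.total,
        substitution=substitution,
        min_substitution_distance=min_substitution_distance,
        optimization=optimization,
        chain=chain,
        contact_status=contact_status,
    )


def read_precomputed_energies(path) -> dict[tuple[str, str], InterfaceEnergy]:
    """Load per-model energies from a TSV standing in for external scoring.

    Dialect: columns model_id, preset, total, position, per_residue — one
    row per (model, preset, CDR3 position).  Returns a mapping
    (model_id, preset) -> :class:`InterfaceEnergy`.  The decomposition
    invariant (per-residue sum equals total) is verified on load.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"model_id", "preset", "total", "position", "per_residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"precomputed table missing column(s): {sorted(missing)}")
    out: dict[tuple[str, str], InterfaceEnergy] = {}
    for (model_id, preset), block in df.groupby(["model_id", "preset"], sort=True):
        totals = block["total"].unique()
        if len(totals) != 1:
            raise ValueError(f"inconsistent totals for {model_id}/{preset}")
        per_residue = dict(
            zip(block["position"].astype(int), block["per_residue"].astype(float))
        )
        total = float(totals[0])
        if abs(total - sum(per_residue.values())) > 1e-6:
            raise ValueError(
                f"{model_id}/{preset}: per-residue sum does not match total"
            )
        out[(str(model_id), str(preset))] = InterfaceEnergy(
            model_id=str(model_id), preset=str(preset),
            total=total, per_residue=per_residue,
        )
    return out


def valuable_positions(
    energies_by_preset: Mapping[str, InterfaceEnergy], tol: float = 1e-9
) -> set[int]:
    """Energetically valuable CDR3 positions of a template.

    For each preset the position(s) attaining the minimal per-residue energy
    are selected (ties within ``tol`` all qualify); the result is the union
    over presets, so scoring ambiguity widens rather than drops candidates.
    """
    out: set[int] = set()
    for energy in energies_by_preset.values():
        if not energy.per_residue:
            continue
        emin = min(energy.per_residue.values())
        out |= {p for p, e in energy.per_residue.items() if e <= emin + tol}
    return out


def valuable_substitution_rate(
    substitutions: Sequence[tuple[int, str]],
    valuable: Iterable[int],
) -> tuple[float, float]:
    """Fractions of substitutions in valuable positions.

    ``substitutions`` holds (CDR3 position, contact status) per modeled
    substitution; returns (rate over all, rate over contacting only).
    NaN when a denominator is empty.
    """
    valuable = set(valuable)
    if not substitutions:
        return (float("nan"), float("nan"))
    hits = [pos in valuable for pos, _ in substitutions]
    all_rate = float(np.mean(hits))
    contacting = [
        pos in valuable for pos, status in substitutions if status == "contacting"
    ]
    contact_rate = float(np.mean(contacting)) if contacting else float("nan")
    return (all_rate, contact_rate)
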