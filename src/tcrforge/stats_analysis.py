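"""Correlation analyses relating substitutions, geometry and energies.

Three analyses are provided, all operating on tidy pandas tables produced by
the energetics and descriptors modules:

* Pearson correlation between adjusted substitution-matrix indices and
  |dEnergy|, per (index x matrix x preset x optimization arm), for all
  substitutions and for substitutions in contacting positions, pooled and
  per TCR chain.  Absolute dEnergy is used because substitution scores
  measure exchangeability, not the direction of the energy change.
* Pearson correlation between the substituted residue's minimum distance to
  the peptide and |dEnergy|, per (preset x arm), pooled and per chain.
* Spearman correlations between CDR3-side and peptide-side descriptor
  scales within physicochemical property groups, with Shapiro-Wilk tests on
  each group's correlation distribution and multiplicity-adjusted p-values
  (Bonferroni by default, Benjamini-Hochberg selectable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .descriptors import (
    ADJUSTED_INDEX_NAMES,
    DescriptorTable,
    adjusted_blosum,
    default_table,
    get_matrix,
)

__all__ = [
    "CorrelationResult",
    "blosum_energy_correlations",
    "distance_energy_correlations",
    "descriptor_pair_correlations",
    "adjust_pvalues",
    "results_frame",
]


@dataclass
class CorrelationResult:
    x: str
    y: str
    method: str  # pearson | spearman
    r: float
    p_value: float
    n: int
    stratum: str = "all"  # all | alpha | beta
    arm: str = ""  # minimized | repacked
    subset: str = ""  # all_mutations | contacting_mutations
    group: str = ""
    adjusted_p: float = float("nan")
    computable: bool = True

    @property
    def significant(self) -> bool:
        return self.computable and self.adjusted_p <= 0.05


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float, bool]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), False
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        r, p = sps.spearmanr(x, y)
    return float(r), float(p), math.isfinite(r)


def adjust_pvalues(results: Sequence[CorrelationResult], method: str = "bonferroni") -> None:
    """Fill ``adjusted_p`` in place over all computable results.

    ``m`` is the number of tests actually performed in this run; the method
    and m are what the output records — no attempt is made to reproduce any
    external multiplicity universe.
    """
    from statsmodels.stats.multitest import multipletests

    live = [r for r in results if r.computable]
    if not live:
        return
    pvals = [r.p_value for r in live]
    if method == "bonferroni":
        adj = np.minimum(1.0, np.asarray(pvals) * len(pvals))
    elif method in ("bh", "fdr_bh"):
        adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    for r, a in zip(live, adj):
        r.adjusted_p = float(a)


def _strata(df: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    out = [("all", df)]
    if "chain" in df.columns:
        for chain in ("alpha", "beta"):
            sub = df[df["chain"] == chain]
            if len(sub):
                out.append((chain, sub))
    return out


def blosum_energy_correlations(
    denergy: pd.DataFrame,
    indices: Iterable[str] = ADJUSTED_INDEX_NAMES,
    use_absolute: bool = True,
    adjust: str = "bonferroni",
) -> list[CorrelationResult]:
    """Pearson r between adjusted substitution indices and |dEnergy|.

    ``denergy`` needs columns from_aa, to_aa, preset, optimization, chain,
    contact_status and value (signed dEnergy).  One result per
    (index x preset x arm x subset x stratum) cell; cells with n < 3 or zero
    variance are flagged not computable and kept in the output.
    """
    results: list[CorrelationResult] = []
    y_all = denergy["value"].abs() if use_absolute else denergy["value"]
    denergy = denergy.assign(_y=y_all)
    for index_name in indices:
        kind, num, _ = index_name.split(".")
        matrix = get_matrix(f"BLOSUM{num}", kind)
        xvals = denergy.apply(
            lambda row: adjusted_blosum((row["from_aa"], row["to_aa"]), matrix), axis=1
        ) if len(denergy) else pd.Series(dtype=float)
        work = denergy.assign(_x=xvals)
        for (preset, arm), cell in work.groupby(["preset", "optimization"], sort=True):
            for subset_name, sub in (
                ("all_mutations", cell),
                ("contacting_mutations", cell[cell["contact_status"] == "contacting"]),
            ):
                for stratum, block in _strata(sub):
                    r, p, ok = _correlate(block["_x"], block["_y"], "pearson")
                    results.append(
                        CorrelationResult(
                            x=index_name, y="abs_dEnergy" if use_absolute else "dEnergy",
                            method="pearson", r=r, p_value=p, n=len(block),
                            stratum=stratum, arm=str(arm), subset=subset_name,
                            computable=ok,
                        )
                    )
    adjust_pvalues(results, adjust)
    return results


def distance_energy_correlations(
    denergy: pd.DataFrame, adjust: str = "bonferroni"
) -> list[CorrelationResult]:
    """Pearson r between substitution-to-peptide minimum distance and |dEnergy|."""
    results: list[CorrelationResult] = []
    work = denergy.assign(_y=denergy["value"].abs())
    for (preset, arm), cell in work.groupby(["preset", "optimization"], sort=True):
        for stratum, block in _strata(cell):
            r, p, ok = _correlate(
                block["min_substitution_distance"], block["_y"], "pearson"
            )
            results.append(
                CorrelationResult(
                    x="min_substitution_distance", y="abs_dEnergy",
                    method="pearson", r=r, p_value=p, n=len(block),
                    stratum=stratum, arm=str(arm), subset=str(preset),
                    computable=ok,
                )
            )
    adjust_pvalues(results, adjust)
    return results


@dataclass
class GroupSummary:
    group: str
    n_pairs: int
    shapiro_w: float
    shapiro_p: float
    median_abs_r: float


def descriptor_pair_correlations(
    features: pd.DataFrame,
    table: DescriptorTable | None = None,
    groups: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> tuple[list[CorrelationResult], list[GroupSummary]]:
    """Spearman correlations of CDR3-side vs peptide-side scales within groups.

    ``features`` holds one row per contact pair (already restricted upstream
    to the analysis slice, e.g. closest side-chain contacts at mutated
    positions) with ``cdr3.<scale>`` and ``p.<scale>`` columns.  Within each
    property group every (cdr3 scale, peptide scale) combination is tested;
    each group's r distribution gets a Shapiro-Wilk normality test.
    """
    table = table or default_table()
    if groups is None:
        groups = ["hydrophobicity", "steric", "electronic", "secondary_structure"]
    results: list[CorrelationResult] = []
    summaries: list[GroupSummary] = []
    for group in groups:
        scales = table.group_scales(group)
        rs = []
        for sc_c in scales:
            col_c = f"cdr3.{sc_c}"
            if col_c not in features.columns:
                continue
            for sc_p in scales:
                col_p = f"p.{sc_p}"
                if col_p not in features.columns:
                    continue
                r, p, ok = _correlate(features[col_c], features[col_p], "spearman")
                if not ok:
                    warnings.warn(
                        f"descriptor pair ({sc_c}, {sc_p}) not computable", stacklevel=2
                    )
                results.append(
                    CorrelationResult(
                        x=f"cdr3.{sc_c}", y=f"p.{sc_p}", method="spearman",
                        r=r, p_value=p, n=len(features), group=group, computable=ok,
                    )
                )
                if ok:
                    rs.append(r)
        if len(rs) >= 3:
            w, sp = sps.shapiro(rs)
        else:
            w, sp = float("nan"), float("nan")
        summaries.append(
            GroupSummary(
                group=group, n_pairs=len(rs), shapiro_w=float(w),
                shapiro_p=float(sp),
                median_abs_r=float(np.median(np.abs(rs))) if rs else float("nan"),
            )
        )
    adjust_pvalues(results, adjust)
    return results, summaries


def results_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tidy table of correlation results (one row per cell)."""
    return pd.DataFrame(
        {
            "x": [r.x for r in results],
            "y": [r.y for r in results],
            "method": [r.method for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "n": [r.n for r in results],
            "stratum": [r.stratum for r in results],
            "arm": [r.arm for r in results],
            "subset": [r.subset for r in results],
            "group": [r.group for r in results],
            "computable": [r.computable for r in results],
        }
    )
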