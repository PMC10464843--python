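"""Reading and validation of TCR specificity records and structural templates.

Defines the shared domain vocabulary: a :class:`SpecificityRecord` is one
VDJdb-style row (CDR3 sequence, chain, V/J genes, epitope, MHC allele); a
:class:`TemplateComplex` is a solved TCR-peptide-MHC structure annotated with
chain roles and CDR3 ranges, whose CDR3 sequences anchor sequence clusters.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .contacts import AMINO_ACIDS, Structure, read_pdb

__all__ = [
    "TcrChain",
    "SpecificityRecord",
    "TemplateAnnotation",
    "TemplateComplex",
    "ModelGroupKey",
    "FormatError",
    "ValidationError",
    "AnnotationError",
    "read_records",
    "write_records",
    "read_template",
    "load_template_config",
    "file_checksum",
    "strip_allele",
]

_AA_SET = frozenset(AMINO_ACIDS)


class TcrChain(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"


class FormatError(ValueError):
    """A required column is missing or the dialect is unknown."""


class ValidationError(ValueError):
    """A row violates the record invariants."""


class AnnotationError(ValueError):
    """Template annotation inconsistent with the structure."""


@dataclass(frozen=True)
class SpecificityRecord:
    """One antigen-specificity record.

    ``record_id`` is an opaque identifier; duplicated (cdr3, chain, v, j,
    epitope) rows are collapsed into one record with merged ids.
    """

    cdr3: str
    chain: TcrChain
    v_gene: str
    j_gene: str
    epitope: str
    mhc_allele: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3 or not set(self.cdr3) <= _AA_SET:
            raise ValidationError(
                f"cdr3 {self.cdr3!r} must be non-empty and use the 20 canonical residues"
            )
        if not self.epitope:
            raise ValidationError("epitope must be non-empty")

    @property
    def dedup_key(self) -> tuple:
        return (self.cdr3, self.chain, self.v_gene, self.j_gene, self.epitope)


def strip_allele(gene: str) -> str:
    """Drop the ``*NN`` allele suffix for gene-level comparisons."""
    return gene.split("*", 1)[0]


# column maps per dialect: ours -> theirs
_DIALECTS = {
    "vdjdb_tsv": {
        "chain": "gene",
        "cdr3": "cdr3",
        "v_gene": "v.segm",
        "j_gene": "j.segm",
        "epitope": "antigen.epitope",
        "mhc_allele": "mhc.a",
    },
    "simple_tsv": {
        "chain": "chain",
        "cdr3": "cdr3",
        "v_gene": "v_gene",
        "j_gene": "j_gene",
        "epitope": "epitope",
        "mhc_allele": "mhc",
    },
}

_CHAIN_ALIASES = {
    "alpha": TcrChain.ALPHA,
    "beta": TcrChain.BETA,
    "tra": TcrChain.ALPHA,
    "trb": TcrChain.BETA,
    "a": TcrChain.ALPHA,
    "b": TcrChain.BETA,
}


def read_records(
    path, format: str = "simple_tsv", strict: bool = False
) -> list[SpecificityRecord]:
    """Read, validate and deduplicate specificity records from a TSV file.

    Invalid rows are reported with their 1-based data row number (warning by
    default, :class:`ValidationError` when ``strict``).  Duplicate
    (cdr3, chain, v, j, epitope) tuples collapse to a single record whose
    ``record_id`` joins the constituent ids with ``;``.
    """
    if format not in _DIALECTS:
        raise FormatError(f"unknown dialect {format!r}")
    colmap = _DIALECTS[format]
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[SpecificityRecord] = []
    bad: list[tuple[int, str]] = []
    for row_no in range(1, len(df) + 1):
        row = df.iloc[row_no - 1]
        data = {k: row[v] for k, v in colmap.items()}
        chain_raw = str(data["chain"]).strip().lower()
        try:
            chain = _CHAIN_ALIASES[chain_raw]
        except KeyError:
            bad.append((row_no, f"unknown chain {data['chain']!r}"))
            continue
        rid = ""
        if "complex.id" in df.columns:
            rid = str(row["complex.id"])
        if not rid:
            rid = f"row{row_no}"
        try:
            rec = SpecificityRecord(
                cdr3=str(data["cdr3"]).strip().upper(),
                chain=chain,
                v_gene=str(data["v_gene"]).strip(),
                j_gene=str(data["j_gene"]).strip(),
                epitope=str(data["epitope"]).strip().upper(),
                mhc_allele=str(data["mhc_allele"]).strip(),
                record_id=rid,
            )
        except ValidationError as err:
            bad.append((row_no, str(err)))
            continue
        records.append(rec)

    if bad:
        msg = "; ".join(f"row {n}: {m}" for n, m in bad)
        if strict:
            raise ValidationError(msg)
        warnings.warn(f"skipped {len(bad)} invalid row(s): {msg}", stacklevel=2)

    merged: dict[tuple, SpecificityRecord] = {}
    for rec in records:
        key = rec.dedup_key
        if key in merged:
            prev = merged[key]
            ids = prev.record_id.split(";") + [rec.record_id]
            merged[key] = replace(prev, record_id=";".join(ids))
        else:
            merged[key] = rec
    return list(merged.values())


def write_records(records: Sequence[SpecificityRecord], path) -> None:
    """Write records in the ``simple_tsv`` dialect (round-trips read_records)."""
    cols = _DIALECTS["simple_tsv"]
    df = pd.DataFrame(
        {
            cols["chain"]: [r.chain.value for r in records],
            cols["cdr3"]: [r.cdr3 for r in records],
            cols["v_gene"]: [r.v_gene for r in records],
            cols["j_gene"]: [r.j_gene for r in records],
            cols["epitope"]: [r.epitope for r in records],
            cols["mhc_allele"]: [r.mhc_allele for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def file_checksum(path) -> str:
    """SHA-256 of an input file, recorded in outputs in lieu of a DB version."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class TemplateAnnotation:
    """Template metadata prior to structure attachment."""

    pdb_id: str
    chain_map: Mapping[str, str]  # roles: tcr_alpha, tcr_beta, mhc, peptide
    cdr3_alpha_range: tuple[int, int] | None = None
    cdr3_beta_range: tuple[int, int] | None = None
    core_records: Mapping[TcrChain, SpecificityRecord] = field(default_factory=dict)


@dataclass(eq=False)
class TemplateComplex:
    """An annotated TCR-peptide-MHC structure serving as a cluster core."""

    pdb_id: str
    structure: Structure
    chain_map: dict[str, str]
    cdr3_alpha_range: tuple[int, int] | None = None
    cdr3_beta_range: tuple[int, int] | None = None
    core_records: dict[TcrChain, SpecificityRecord] = field(default_factory=dict)

    def cdr3_range(self, chain: TcrChain) -> tuple[int, int]:
        rng = (
            self.cdr3_alpha_range if chain is TcrChain.ALPHA else self.cdr3_beta_range
        )
        if rng is None:
            raise AnnotationError(f"{self.pdb_id}: no CDR3 range for {chain.value}")
        return rng

    def tcr_chain_id(self, chain: TcrChain) -> str:
        role = "tcr_alpha" if chain is TcrChain.ALPHA else "tcr_beta"
        try:
            return self.chain_map[role]
        except KeyError:
            raise AnnotationError(f"{self.pdb_id}: no chain mapped to {role}") from None

    def cdr3_sequence(self, chain: TcrChain) -> str:
        return self.structure.subsequence(
            self.tcr_chain_id(chain), self.cdr3_range(chain)
        )

    @property
    def tcr_chain_sequences(self) -> frozenset[str]:
        seqs = []
        for role in ("tcr_alpha", "tcr_beta"):
            cid = self.chain_map.get(role)
            if cid is not None and cid in self.structure.chains:
                seqs.append(self.structure.chain(cid).sequence)
        return frozenset(seqs)

    def validate(self) -> None:
        for role, cid in self.chain_map.items():
            if cid not in self.structure.chains:
                raise AnnotationError(
                    f"{self.pdb_id}: chain {cid!r} ({role}) absent from structure"
                )
        for chain in (TcrChain.ALPHA, TcrChain.BETA):
            rng = (
                self.cdr3_alpha_range
                if chain is TcrChain.ALPHA
                else self.cdr3_beta_range
            )
            if rng is None:
                continue
            extracted = self.cdr3_sequence(chain)
            if len(extracted) != rng[1] - rng[0] + 1:
                raise AnnotationError(
                    f"{self.pdb_id}: CDR3 {chain.value} range {rng} exceeds chain"
                )
            core = self.core_records.get(chain)
            if core is not None and core.cdr3 != extracted:
                raise AnnotationError(
                    f"{self.pdb_id}: annotated CDR3 {chain.value} {core.cdr3!r} "
                    f"does not match structure residues {extracted!r}"
                )
        pep_id = self.chain_map.get("peptide")
        if pep_id is not None and self.core_records:
            pep_len = len(self.structure.chain(pep_id).residues)
            for core in self.core_records.values():
                if len(core.epitope) != pep_len:
                    raise AnnotationError(
                        f"{self.pdb_id}: peptide chain length {pep_len} != "
                        f"epitope length {len(core.epitope)}"
                    )


@dataclass(frozen=True)
class ModelGroupKey:
    """Models with equal keys form one non-redundant group."""

    chain_sequences: frozenset[str]
    final_cdr3: str
    chain: TcrChain


def read_template(pdb_path, annotation: TemplateAnnotation) -> TemplateComplex:
    """Load a PDB file and attach/verify the template annotation."""
    structure = read_pdb(pdb_path)
    template = TemplateComplex(
        pdb_id=annotation.pdb_id,
        structure=structure,
        chain_map=dict(annotation.chain_map),
        cdr3_alpha_range=annotation.cdr3_alpha_range,
        cdr3_beta_range=annotation.cdr3_beta_range,
        core_records=dict(annotation.core_records),
    )
    template.validate()
    return template


def load_template_config(path) -> list[tuple[Path, TemplateAnnotation]]:
    """Parse a YAML file naming template annotations.

    Layout: a list of entries with keys ``pdb_id``, ``pdb_path``,
    ``chain_map``, optional ``cdr3_alpha_range``/``cdr3_beta_range`` (1-based
    inclusive two-element lists) and ``core_records`` (chain -> record dict).
    """
    raw = yaml.safe_load(Path(path).read_text())
    out = []
    for entry in raw:
        cores = {}
        for chain_name, rec in (entry.get("core_records") or {}).items():
            chain = TcrChain(chain_name)
            cores[chain] = SpecificityRecord(
                cdr3=rec["cdr3"],
                chain=chain,
                v_gene=rec.get("v_gene", ""),
                j_gene=rec.get("j_gene", ""),
                epitope=rec["epitope"],
                mhc_allele=rec.get("mhc", ""),
                record_id=f"{entry['pdb_id']}:{chain_name}",
            )
        ann = TemplateAnnotation(
            pdb_id=entry["pdb_id"],
            chain_map=dict(entry["chain_map"]),
            cdr3_alpha_range=tuple(entry["cdr3_alpha_range"])
            if entry.get("cdr3_alpha_range")
            else None,
            cdr3_beta_range=tuple(entry["cdr3_beta_range"])
            if entry.get("cdr3_beta_range")
            else None,
            core_records=cores,
        )
        out.append((Path(entry["pdb_path"]), ann))
    return out
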