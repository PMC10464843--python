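"""CDR3 sequence clusters around structural cores and mutation pathways.

A cluster is anchored by the CDR3 of a solved complex (the core).  Database
records join the cluster when they share chain, V gene, J gene, epitope and
CDR3 length with the core, lie within Hamming distance 3 of it, and can be
reached from the core by single-substitution steps.  Mutation pathways are
the distance-monotone single-substitution chains from the core to each
member; they define the order in which child structures are modeled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_repertoire import (
    ModelGroupKey,
    SpecificityRecord,
    TcrChain,
    TemplateComplex,
    strip_allele,
)

__all__ = [
    "Cluster",
    "MutationPathway",
    "BuildOrder",
    "hamming",
    "build_cluster",
    "enumerate_pathways",
    "pathway_models",
    "count_unique_pathways",
    "pathway_graph",
]

MAX_CORE_DISTANCE = 3


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "insertions/deletions are not allowed"
        )
    return sum(x != y for x, y in zip(a, b))


def _substitution(parent: str, child: str) -> tuple[int, str, str]:
    """The single (1-based position, from, to) difference between two strings."""
    diffs = [(i + 1, x, y) for i, (x, y) in enumerate(zip(parent, child)) if x != y]
    if len(diffs) != 1:
        raise ValueError(f"{parent!r} -> {child!r} is not a single substitution")
    return diffs[0]


@dataclass
class Cluster:
    """A core CDR3 with the database records clustered around it."""

    core: SpecificityRecord
    members: list[SpecificityRecord]
    template: TemplateComplex | None
    chain: TcrChain
    mode: str = "observed"

    @property
    def member_cdr3s(self) -> list[str]:
        return [m.cdr3 for m in self.members]


@dataclass(frozen=True)
class MutationPathway:
    """An ordered chain of CDR3 sequences, each step one substitution deeper.

    ``steps[0]`` is the core; consecutive steps are at Hamming distance 1 and
    distance from the core increases by exactly 1 per step.
    """

    template: TemplateComplex | None
    chain: TcrChain
    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        core = self.steps[0]
        if not 1 <= len(self.steps) - 1 <= MAX_CORE_DISTANCE:
            raise ValueError("pathway must take between 1 and 3 steps")
        for i, seq in enumerate(self.steps):
            if hamming(core, seq) != i:
                raise ValueError(
                    f"step {i} of {self.steps} is not at distance {i} from the core"
                )

    @property
    def substitutions(self) -> list[tuple[int, str, str]]:
        return [
            _substitution(a, b) for a, b in zip(self.steps[:-1], self.steps[1:])
        ]

    @property
    def final(self) -> str:
        return self.steps[-1]


@dataclass(frozen=True)
class BuildOrder:
    """One model to build: apply one substitution to the parent of a prefix."""

    template: TemplateComplex | None
    chain: TcrChain
    prefix: tuple[str, ...]  # core ... child, inclusive

    @property
    def parent_cdr3(self) -> str:
        return self.prefix[-2]

    @property
    def child_cdr3(self) -> str:
        return self.prefix[-1]

    @property
    def substitution(self) -> tuple[int, str, str]:
        return _substitution(self.parent_cdr3, self.child_cdr3)

    @property
    def template_id(self) -> str:
        return self.template.pdb_id if self.template is not None else "-"

    def group_key(self) -> ModelGroupKey:
        chain_seqs = (
            self.template.tcr_chain_sequences
            if self.template is not None
            else frozenset()
        )
        return ModelGroupKey(
            chain_sequences=chain_seqs, final_cdr3=self.child_cdr3, chain=self.chain
        )


def _matches_core(
    rec: SpecificityRecord, core: SpecificityRecord, allele_level: bool, match_mhc: bool
) -> bool:
    def gene(g: str) -> str:
        return g if allele_level else strip_allele(g)

    return (
        rec.chain == core.chain
        and gene(rec.v_gene) == gene(core.v_gene)
        and gene(rec.j_gene) == gene(core.j_gene)
        and rec.epitope == core.epitope
        and len(rec.cdr3) == len(core.cdr3)
        and (not match_mhc or rec.mhc_allele == core.mhc_allele)
    )


def build_cluster(
    core: SpecificityRecord,
    template: TemplateComplex | None,
    records: Sequence[SpecificityRecord],
    mode: str = "observed",
    allele_level: bool = True,
    match_mhc: bool = False,
) -> Cluster:
    """Accrete database records around a template core CDR3.

    Candidates must match chain/V/J/epitope/length and lie within Hamming
    distance 3 of the core.  In ``observed`` mode a candidate is a member only
    if it is reachable from the core through single-substitution steps within
    the candidate set (accretion to a fixed point); in ``free`` mode every
    candidate within distance 3 is a member (intermediates need not be
    observed sequences).
    """
    if mode not in ("observed", "free"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    if template is not None:
        annotated = template.cdr3_sequence(core.chain)
        if annotated != core.cdr3:
            raise ValueError(
                f"core CDR3 {core.cdr3!r} does not match template "
                f"{template.pdb_id} CDR3 {annotated!r}"
            )
    candidates = {
        rec.cdr3: rec
        for rec in records
        if _matches_core(rec, core, allele_level, match_mhc)
        and 0 < hamming(rec.cdr3, core.cdr3) <= MAX_CORE_DISTANCE
    }
    if mode == "free":
        members = list(candidates.values())
    else:
        # BFS over the Hamming-1 graph on {core} | candidates
        seqs = set(candidates)
        reached: set[str] = set()
        frontier = [core.cdr3]
        while frontier:
            nxt = []
            for seq in frontier:
                for other in seqs - reached:
                    if hamming(seq, other) == 1:
                        reached.add(other)
                        nxt.append(other)
            frontier = nxt
        members = [candidates[s] for s in reached]
    members.sort(key=lambda r: r.cdr3)
    return Cluster(
        core=core, members=members, template=template, chain=core.chain, mode=mode
    )


def _monotone_paths(core: str, target: str, allowed: set[str] | None) -> list[tuple[str, ...]]:
    """All single-substitution chains core -> target with strictly increasing
    distance from core; intermediates restricted to ``allowed`` when given."""
    positions = [i for i, (x, y) in enumerate(zip(core, target)) if x != y]
    paths = []
    for order in itertools.permutations(positions):
        steps = [core]
        seq = list(core)
        ok = True
        for k, pos in enumerate(order):
            seq[pos] = target[pos]
            s = "".join(seq)
            is_final = k == len(order) - 1
            if not is_final and allowed is not None and s not in allowed:
                ok = False
                break
            steps.append(s)
        if ok:
            paths.append(tuple(steps))
    return sorted(set(paths))


def enumerate_pathways(cluster: Cluster) -> list[MutationPathway]:
    """Every distance-monotone pathway from the core to every member.

    In ``observed`` mode intermediates must themselves be cluster members;
    in ``free`` mode any intermediate sequence is admitted.  Pathways are
    unique as step sequences and emitted in lexicographic order.
    """
    allowed = set(cluster.member_cdr3s) if cluster.mode == "observed" else None
    pathways = []
    for member in cluster.member_cdr3s:
        for steps in _monotone_paths(cluster.core.cdr3, member, allowed):
            pathways.append(
                MutationPathway(
                    template=cluster.template, chain=cluster.chain, steps=steps
                )
            )
    pathways.sort(key=lambda p: (p.final, p.steps))
    return pathways


def pathway_models(pathways: Iterable[MutationPathway]) -> list[BuildOrder]:
    """One build order per pathway step, deduplicated on (template, prefix).

    Shared prefixes between pathways are built once; each order's parent is
    the previous prefix (the template itself for 1-step prefixes).
    """
    seen: set[tuple[str, TcrChain, tuple[str, ...]]] = set()
    orders: list[BuildOrder] = []
    for pw in pathways:
        for i in range(1, len(pw.steps)):
            prefix = pw.steps[: i + 1]
            key = (pw.template.pdb_id if pw.template else "-", pw.chain, prefix)
            if key in seen:
                continue
            seen.add(key)
            orders.append(
                BuildOrder(template=pw.template, chain=pw.chain, prefix=prefix)
            )
    orders.sort(key=lambda o: (o.template_id, o.chain.value, len(o.prefix), o.prefix))
    return orders


def count_unique_pathways(pathways: Sequence[MutationPathway]) -> dict[str, int]:
    """Both pathway counters: full core->leaf paths and unique build orders."""
    full = {
        (p.template.pdb_id if p.template else "-", p.chain, p.steps)
        for p in pathways
    }
    return {"full_pathways": len(full), "build_orders": len(pathway_models(pathways))}


def pathway_graph(pathways: Sequence[MutationPathway]):
    """The pathway DAG as a networkx DiGraph (nodes: CDR3 sequences)."""
    import networkx as nx

    g = nx.DiGraph()
    for pw in pathways:
        for parent, child in zip(pw.steps[:-1], pw.steps[1:]):
            g.add_edge(parent, child)
    return g


def write_pathway_dot(pathways: Sequence[MutationPathway], path) -> None:
    """Plain DOT export of the pathway DAG (no graphviz bindings needed)."""
    g = pathway_graph(pathways)
    lines = ["digraph pathways {"]
    for node in sorted(g.nodes):
        lines.append(f'    "{node}";')
    for a, b in sorted(g.edges):
        lines.append(f'    "{a}" -> "{b}";')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
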