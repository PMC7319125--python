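"""Basetypes, basegroups, and assignment of leftover clone sequences.

The molecular taxonomy is anchored on *basetypes*: unique sequence patterns
observed within single specimens that recur in the dataset. Basetypes that
co-occur inside at least one specimen are intragenomic variants of one
organism type and are grouped into *basegroups* (connected components of
the specimen co-occurrence graph). Clone sequences that did not qualify as
basetype members are assigned afterwards to the delimited genotypes by
sequence identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx

from .records import SequenceRecord
from .seqdist import pairwise_identity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Basetype:
    basetype_id: str
    nucleotides: str
    occurrence_count: int
    specimen_ids: frozenset[str]
    member_sequence_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.occurrence_count != len(self.member_sequence_ids):
            raise ValueError(
                f"{self.basetype_id}: occurrence_count != number of member sequences"
            )


@dataclass
class Basegroup:
    basegroup_id: str
    basetype_ids: frozenset[str]
    label: str = ""


class BasetypeExtraction(NamedTuple):
    basetypes: list[Basetype]
    #: sequence_id -> pattern, for clones whose pattern fell below the cutoff
    discarded: dict[str, str]


def extract_basetypes(
    records: list[SequenceRecord],
    min_occurrences: int = 2,
    count_mode: str = "clones",
) -> BasetypeExtraction:
    """Collapse identical clones within specimens and keep recurrent patterns.

    Within each specimen, character-identical clone sequences collapse to a
    single pattern. A pattern becomes a basetype iff its dataset-wide
    occurrence count reaches ``min_occurrences``. ``count_mode`` selects what
    is counted: ``"clones"`` (every clone sequence; default) or
    ``"specimens"`` (number of distinct specimens carrying the pattern).

    Basetype ids are deterministic: ordered by occurrence count descending,
    then by sequence lexicographically.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    if count_mode not in ("clones", "specimens"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    by_pattern: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_pattern.setdefault(r.nucleotides, []).append(r)
    basetypes: list[Basetype] = []
    discarded: dict[str, str] = {}
    kept: list[tuple[int, str, list[SequenceRecord]]] = []
    for pattern, members in by_pattern.items():
        clone_count = len(members)
        count = clone_count if count_mode == "clones" else len({m.specimen_id for m in members})
        if count >= min_occurrences:
            kept.append((clone_count, pattern, members))
        else:
            for m in members:
                discarded[m.sequence_id] = pattern
    kept.sort(key=lambda t: (-t[0], t[1]))
    width = max(3, len(str(len(kept))))
    for i, (clone_count, pattern, members) in enumerate(kept, start=1):
        basetypes.append(
            Basetype(
                basetype_id=f"bt{i:0{width}d}",
                nucleotides=pattern,
                occurrence_count=clone_count,
                specimen_ids=frozenset(m.specimen_id for m in members),
                member_sequence_ids=frozenset(m.sequence_id for m in members),
            )
        )
    if discarded:
        logger.info(
            "extract_basetypes: discarded %d singleton clone(s) across %d pattern(s)",
            len(discarded), len(set(discarded.values())),
        )
    return BasetypeExtraction(basetypes, discarded)


def build_basegroups(basetypes: list[Basetype]) -> list[Basegroup]:
    """Connected components of the specimen co-occurrence graph.

    Two basetypes are linked when they share at least one specimen.
    Basegroup ids are ordered by component size descending, ties broken by
    the lexicographically smallest member basetype id.
    """
    if not basetypes:
        raise ValueError("no basetypes given")
    graph = nx.Graph()
    graph.add_nodes_from(bt.basetype_id for bt in basetypes)
    by_specimen: dict[str, list[str]] = {}
    for bt in basetypes:
        for sp in bt.specimen_ids:
            by_specimen.setdefault(sp, []).append(bt.basetype_id)
    for members in by_specimen.values():
        first = members[0]
        for other in members[1:]:
            graph.add_edge(first, other)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(c)),
    )
    width = max(3, len(str(len(components))))
    return [
        Basegroup(basegroup_id=f"bg{i:0{width}d}", basetype_ids=comp)
        for i, comp in enumerate(components, start=1)
    ]


@dataclass
class AssignmentRow:
    sequence_id: str
    lineage: str
    genotype: str
    basegroup: str
    identity: float
    status: str  # basetype_member | assigned | unassigned(reason)


@dataclass
class TaxonomyAssignment:
    """Per-sequence hierarchical labels (or 'unassigned' with reason)."""

    rows: dict[str, AssignmentRow] = field(default_factory=dict)

    def genotype_of(self, sequence_id: str) -> str:
        return self.rows[sequence_id].genotype


def assign_remaining_sequences(
    records: list[SequenceRecord],
    basetypes: list[Basetype],
    taxonomy: dict[str, tuple[str, str, str]],
    min_identity: float = 0.97,
) -> TaxonomyAssignment:
    """Assign non-basetype clones to the delimited genotypes by identity.

    ``taxonomy`` maps basetype_id -> (lineage, genotype, basegroup) labels.
    Each leftover sequence is given the genotype of its best-identity
    basetype when the identity reaches ``min_identity`` and the best hit is
    unique at the genotype level; otherwise it is unassigned with a reason
    (``low_identity`` or ``ambiguous``). Basetype members inherit their
    basetype's labels with identity 1.
    """
    member_of: dict[str, Basetype] = {}
    for bt in basetypes:
        for sid in bt.member_sequence_ids:
            member_of[sid] = bt
    result = TaxonomyAssignment()
    for r in records:
        if r.sequence_id in member_of:
            bt = member_of[r.sequence_id]
            lin, gen, bg = taxonomy[bt.basetype_id]
            result.rows[r.sequence_id] = AssignmentRow(
                r.sequence_id, lin, gen, bg, 1.0, "basetype_member"
            )
            continue
        best_identity = -1.0
        best_genotypes: set[str] = set()
        best_labels: tuple[str, str, str] | None = None
        for bt in basetypes:
            ident = pairwise_identity(r.nucleotides, bt.nucleotides)
            if ident > best_identity + 1e-12:
                best_identity = ident
                best_genotypes = {taxonomy[bt.basetype_id][1]}
                best_labels = taxonomy[bt.basetype_id]
            elif abs(ident - best_identity) <= 1e-12:
                best_genotypes.add(taxonomy[bt.basetype_id][1])
        if best_identity < min_identity:
            row = AssignmentRow(
                r.sequence_id, "unassigned", "unassigned", "unassigned",
                max(best_identity, 0.0), "unassigned(low_identity)",
            )
        elif len(best_genotypes) > 1:
            row = AssignmentRow(
                r.sequence_id, "unassigned", "unassigned", "unassigned",
                best_identity, "unassigned(ambiguous)",
            )
        else:
            lin, gen, bg = best_labels  # type: ignore[misc]
            row = AssignmentRow(r.sequence_id, lin, gen, bg, best_identity, "assigned")
        result.rows[r.sequence_id] = row
    return result
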