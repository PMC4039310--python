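"""Bait-prey network assembly from peptide-level evidence.

The stages mirror a typical AP-MS post-processing chain:

1. :func:`collapse_isoforms` — drop isoform suffixes and merge counts.
2. :func:`group_proteins` — pool replicate runs of one pulldown and group
   proteins by shared peptides; proteins without any protein-specific
   peptide are discarded.
3. :func:`subtract_background` — remove everything seen in any negative
   control pulldown.
4. :func:`build_network` — one TAP edge per retained (bait, prey) pair.

Evidence tables are pandas DataFrames with columns
``run_id, peptide_id, protein_ids, spectral_count[, phospho_state]``
where ``protein_ids`` is a ``;``-joined list of identifiers.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from oncoint.errors import InputError

EVIDENCE_COLUMNS = ("run_id", "peptide_id", "protein_ids", "spectral_count")
MANIFEST_COLUMNS = ("run_id", "bait_id", "cell_line", "replicate", "is_control")

#: bait identifier used for negative-control pulldowns in manifests
CONTROL_BAIT = "CONTROL"

ROLE_BAIT = "bait"
ROLE_PREY = "prey"
ROLE_PY_ADDED = "pY-added"

EVIDENCE_TAP = "TAP"
EVIDENCE_DATABASE = "database"

_ROLE_RANK = {ROLE_BAIT: 2, ROLE_PREY: 1, ROLE_PY_ADDED: 0}


def _validate_evidence(evidence: pd.DataFrame) -> None:
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise InputError(f"evidence table missing columns: {missing}")
    if len(evidence) and (evidence["spectral_count"] < 0).any():
        raise InputError("evidence table contains negative spectral counts")


def split_protein_ids(cell: str) -> list[str]:
    """Split a ``;``-joined protein-identifier cell into a list."""
    return [p for p in str(cell).split(";") if p]


def strip_isoform(protein_id: str, delimiter: str = "-") -> str:
    """Strip a trailing isoform suffix (``P0001-2`` -> ``P0001``).

    Only a purely numeric suffix after the last ``delimiter`` is treated
    as isoform information; identifiers without the delimiter or with a
    non-numeric tail are returned unchanged.
    """
    head, sep, tail = protein_id.rpartition(delimiter)
    if sep and head and tail.isdigit():
        return head
    return protein_id


def collapse_isoforms(evidence: pd.DataFrame, delimiter: str = "-") -> pd.DataFrame:
    """Discard isoform suffixes and merge counts per (run, peptide).

    Rows that become identical after suffix stripping have their spectral
    counts summed.  Within one row, duplicate post-strip identifiers are
    deduplicated (sorted order).
    """
    _validate_evidence(evidence)
    if evidence.empty:
        return evidence.copy()
    out = evidence.copy()
    out["protein_ids"] = out["protein_ids"].map(
        lambda cell: ";".join(
            sorted({strip_isoform(p, delimiter) for p in split_protein_ids(cell)})
        )
    )
    keys = ["run_id", "peptide_id", "protein_ids"]
    if "phospho_state" in out.columns:
        keys.append("phospho_state")
    collapsed = (
        out.groupby(keys, as_index=False, sort=True)["spectral_count"]
        .sum()
        .reset_index(drop=True)
    )
    return collapsed[list(evidence.columns)]


@dataclass(frozen=True)
class ProteinGroup:
    """Proteins indistinguishable (or subsumed) by their peptide evidence.

    ``specific_peptides`` map only to members of this group; by
    construction it is never empty — groups lacking specific evidence are
    discarded during grouping.
    """

    group_id: str
    members: tuple[str, ...]
    peptides: frozenset[str]
    specific_peptides: frozenset[str]
    total_spectral_count: int

    def __post_init__(self) -> None:
        if not self.specific_peptides:
            raise InputError(f"protein group {self.group_id} has no specific peptides")


def group_proteins(
    evidence: pd.DataFrame, min_distinct_peptides: int = 1
) -> list[ProteinGroup]:
    """Group proteins of one pooled pulldown by shared peptides.

    Proteins with identical peptide sets are merged into one group whose
    id is the lexicographically smallest member.  A group is retained only
    if at least one of its peptides maps exclusively to its members and it
    has at least ``min_distinct_peptides`` distinct peptides; every other
    protein (all of its peptides shared with retained proteins) is
    discarded.  Output is sorted by total spectral count descending, ties
    by group id.
    """
    _validate_evidence(evidence)
    if evidence.empty:
        return []

    peptide_proteins: dict[str, set[str]] = {}
    protein_peptides: dict[str, set[str]] = {}
    for pep, cell in zip(evidence["peptide_id"], evidence["protein_ids"]):
        prots = split_protein_ids(cell)
        peptide_proteins.setdefault(pep, set()).update(prots)
        for p in prots:
            protein_peptides.setdefault(p, set()).add(pep)

    # merge proteins with identical peptide sets
    by_pepset: dict[frozenset[str], list[str]] = {}
    for prot, peps in protein_peptides.items():
        by_pepset.setdefault(frozenset(peps), []).append(prot)

    groups: list[ProteinGroup] = []
    for pepset, members in by_pepset.items():
        members_t = tuple(sorted(members))
        member_set = set(members_t)
        specific = frozenset(
            pep for pep in pepset if peptide_proteins[pep] <= member_set
        )
        if not specific or len(pepset) < min_distinct_peptides:
            continue
        total = int(
            sum(
                count
                for cell, count in zip(
                    evidence["protein_ids"], evidence["spectral_count"]
                )
                if member_set.intersection(split_protein_ids(cell))
            )
        )
        groups.append(
            ProteinGroup(
                group_id=members_t[0],
                members=members_t,
                peptides=frozenset(pepset),
                specific_peptides=specific,
                total_spectral_count=total,
            )
        )
    groups.sort(key=lambda g: (-g.total_spectral_count, g.group_id))
    return groups


def groups_to_evidence(groups: Sequence[ProteinGroup]) -> pd.DataFrame:
    """Re-express protein groups as an evidence table (one synthetic run).

    Used to check grouping idempotence; counts are spread uniformly over
    the group's peptides (remainder on the first).
    """
    rows = []
    pep_members: dict[str, set[str]] = {}
    for g in groups:
        for pep in g.peptides:
            pep_members.setdefault(pep, set()).update(g.members)
    for g in groups:
        peps = sorted(g.peptides)
        base, rem = divmod(g.total_spectral_count, len(peps))
        for i, pep in enumerate(peps):
            rows.append(
                {
                    "run_id": "pooled",
                    "peptide_id": pep,
                    "protein_ids": ";".join(sorted(pep_members[pep])),
                    "spectral_count": base + (rem if i == 0 else 0),
                }
            )
    return pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)).drop_duplicates(
        subset=["run_id", "peptide_id", "protein_ids"]
    )


def pool_pulldowns(
    evidence: pd.DataFrame, manifest: pd.DataFrame
) -> dict[tuple[str, str], pd.DataFrame]:
    """Split evidence into per-pulldown tables, pooling replicate runs.

    A pulldown is one (bait, cell line) pair; its replicate MS runs are
    concatenated.  Returns a dict keyed by ``(bait_id, cell_line)``;
    control pulldowns appear under bait id :data:`CONTROL_BAIT`.
    """
    _validate_evidence(evidence)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest missing columns: {missing}")
    run_key: dict[str, tuple[str, str]] = {}
    for row in manifest.itertuples(index=False):
        bait = CONTROL_BAIT if bool(row.is_control) else str(row.bait_id)
        run_key[str(row.run_id)] = (bait, str(row.cell_line))
    unknown = set(evidence["run_id"].astype(str)) - set(run_key)
    if unknown:
        raise InputError(f"evidence runs absent from manifest: {sorted(unknown)}")

    out: dict[tuple[str, str], pd.DataFrame] = {}
    keys = evidence["run_id"].astype(str).map(run_key.get)
    for key in sorted(set(run_key.values())):
        sub = evidence[keys == key]
        if len(sub):
            out[key] = sub.reset_index(drop=True)
        elif key[0] == CONTROL_BAIT:
            out[key] = evidence.iloc[0:0].copy()  # empty control is meaningful
    return out


def subtract_background(
    bait_groups: Mapping[tuple[str, str], Sequence[ProteinGroup]],
    control_groups: Mapping[tuple[str, str], Sequence[ProteinGroup]],
    per_cell_line: bool = False,
) -> dict[tuple[str, str], list[ProteinGroup]]:
    """Remove control-pulldown proteins from every bait pulldown.

    By default the union of *all* control pulldowns is subtracted from
    every bait pulldown; with ``per_cell_line=True`` only controls from
    the same cell line are used.  A group is removed if any of its member
    proteins was identified in the relevant control set.
    """
    global_union: set[str] = set()
    by_line: dict[str, set[str]] = {}
    for (_, line), groups in control_groups.items():
        members = {m for g in groups for m in g.members}
        global_union.update(members)
        by_line.setdefault(line, set()).update(members)

    out: dict[tuple[str, str], list[ProteinGroup]] = {}
    for key, groups in bait_groups.items():
        banned = by_line.get(key[1], set()) if per_cell_line else global_union
        out[key] = [g for g in groups if not banned.intersection(g.members)]
    return out


class InteractionNetwork:
    """Attributed undirected protein network.

    Nodes carry a ``role`` (``bait`` / ``prey`` / ``pY-added``) plus free
    annotations; edges carry an ``evidence`` tag (``TAP`` / ``database``)
    and a ``support`` value (summed spectral count for TAP edges).
    Backed by :class:`networkx.Graph`; insertion order is preserved.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, protein_id: str, role: str, **annotations) -> None:
        if role not in _ROLE_RANK:
            raise InputError(f"unknown node role: {role!r}")
        if protein_id in self.graph:
            current = self.graph.nodes[protein_id].get("role", ROLE_PY_ADDED)
            if _ROLE_RANK[role] > _ROLE_RANK[current]:
                self.graph.nodes[protein_id]["role"] = role
            self.graph.nodes[protein_id].update(annotations)
        else:
            self.graph.add_node(protein_id, role=role, **annotations)

    def add_edge(
        self, a: str, b: str, evidence: str, support: int | str = 0, **attrs
    ) -> None:
        if a == b:
            return  # self-edges are always dropped
        for end in (a, b):
            if end not in self.graph:
                raise InputError(f"edge endpoint {end!r} is not a node")
        self.graph.add_edge(a, b, evidence=evidence, support=support, **attrs)

    def annotate_sites(self, protein_id: str, sites: Iterable[str]) -> None:
        existing = self.graph.nodes[protein_id].get("sites", "")
        merged = sorted(set(filter(None, existing.split(";"))) | set(sites))
        self.graph.nodes[protein_id]["sites"] = ";".join(merged)

    # -- queries ------------------------------------------------------
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def role(self, protein_id: str) -> str:
        return self.graph.nodes[protein_id]["role"]

    def edges(self) -> list[tuple[str, str, dict]]:
        return [(a, b, dict(d)) for a, b, d in self.graph.edges(data=True)]

    def edge_set(self, evidence: str | None = None) -> set[frozenset[str]]:
        return {
            frozenset((a, b))
            for a, b, d in self.graph.edges(data=True)
            if evidence is None or d.get("evidence") == evidence
        }

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            if dict(self.graph.nodes[n]) != dict(other.graph.nodes[n]):
                return False
        if self.edge_set() != other.edge_set():
            return False
        for a, b, d in self.graph.edges(data=True):
            if dict(other.graph.edges[a, b]) != dict(d):
                return False
        return True


def build_network(
    filtered_pulldowns: Mapping[tuple[str, str], Sequence[ProteinGroup]],
) -> InteractionNetwork:
    """Assemble the TAP network from background-subtracted pulldowns.

    One node per bait and per retained prey group (keyed by group id); a
    prey that is itself used as a bait keeps the bait role.  One TAP edge
    per (bait, prey) with support summed over that bait's cell lines;
    per-cell-line counts are kept in the ``lines`` edge attribute.  A bait
    pulled down as its own prey contributes no edge.
    """
    net = InteractionNetwork()
    baits = sorted({bait for bait, _ in filtered_pulldowns})
    for bait in baits:
        net.add_node(bait, ROLE_BAIT)
    support: dict[tuple[str, str], dict[str, int]] = {}
    for (bait, line) in sorted(filtered_pulldowns):
        for grp in filtered_pulldowns[(bait, line)]:
            prey = grp.group_id
            if prey == bait:
                continue
            if prey not in net:
                net.add_node(prey, ROLE_PREY)
            support.setdefault((bait, prey), {})
            support[(bait, prey)][line] = (
                support[(bait, prey)].get(line, 0) + grp.total_spectral_count
            )
    for (bait, prey), lines in support.items():
        net.add_edge(
            bait,
            prey,
            evidence=EVIDENCE_TAP,
            support=int(sum(lines.values())),
            lines=";".join(f"{ln}={ct}" for ln, ct in sorted(lines.items())),
        )
    return net


def annotation_filter(
    network: InteractionNetwork,
    annotation_table: Mapping[str, set[str] | Sequence[str]],
    categories: Iterable[str],
) -> list[str]:
    """Nodes annotated to at least one of the requested categories.

    ``annotation_table`` maps protein -> set of category labels (user
    supplied).  Unknown category labels trigger a warning and match
    nothing.  Network (insertion) order is preserved.
    """
    wanted = set(categories)
    known: set[str] = set()
    for labels in annotation_table.values():
        known.update(labels)
    for c in sorted(wanted - known):
        warnings.warn(f"annotation category {c!r} not present in annotation table")
    return [
        n
        for n in network.nodes()
        if wanted.intersection(annotation_table.get(n, ()))
    ]
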