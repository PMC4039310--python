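"""Drug-target filtering, allele matching, bipartite networks and
diffusion-based compound ranking.

Affinity records come from four source classes with different retention
rules: competition-assay and kinase-assay Kd < 100 nM, BindingDB
Ki/Kd/IC50/EC50 < 10 nM (all strict), DrugBank kept on presence alone
(no comparable affinity; tagged low confidence).  Percent-inhibition
values are never filtered on affinity — they feed the diffusion ranking
only.

The diffusion ranking is an exponential-decay shortest-path kernel, a
deliberately simple reconstruction of an under-specified published
method: score(compound, kinase) = sum over measured kinases k' of
value(compound, k') * alpha^d(kinase, k'), with unreachable pairs
contributing nothing.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from oncoint.errors import InputError
from oncoint.tap_assembly import InteractionNetwork

RECORD_COLUMNS = ("compound_id", "target_protein", "allele", "affinity_type", "value", "source")

SOURCE_COMPETITION = "competition_assay"
SOURCE_KINASE_ASSAY = "kinase_assay"
SOURCE_BINDINGDB = "bindingdb"
SOURCE_DRUGBANK = "drugbank"

KD_CUTOFF_NM = 100.0
BINDINGDB_CUTOFF_NM = 10.0
_BINDINGDB_TYPES = {"Ki", "Kd", "IC50", "EC50"}

_SALT_SUFFIXES = (
    " hydrochloride",
    " dihydrochloride",
    " mesylate",
    " maleate",
    " tosylate",
    " sulfate",
    " citrate",
)


def canonical_compound(name: str) -> str:
    """Case-fold and strip common salt suffixes for cross-database identity."""
    n = str(name).strip().casefold()
    for suffix in _SALT_SUFFIXES:
        if n.endswith(suffix):
            n = n[: -len(suffix)]
            break
    return n


def _validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise InputError(f"drug-target table missing columns: {missing}")


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Apply per-source affinity cutoffs (strict inequalities).

    competition_assay / kinase_assay: Kd < 100 nM.  bindingdb: Ki, Kd,
    IC50 or EC50 < 10 nM.  drugbank: kept by presence.  Unknown sources
    are skipped with a warning.  Idempotent and order-invariant.
    """
    _validate_records(records)
    keep = []
    unknown: set[str] = set()
    for i, row in enumerate(records.itertuples(index=False)):
        src = str(row.source)
        atype = str(row.affinity_type)
        if src in (SOURCE_COMPETITION, SOURCE_KINASE_ASSAY):
            if atype == "Kd" and float(row.value) < KD_CUTOFF_NM:
                keep.append(i)
        elif src == SOURCE_BINDINGDB:
            if atype in _BINDINGDB_TYPES and float(row.value) < BINDINGDB_CUTOFF_NM:
                keep.append(i)
        elif src == SOURCE_DRUGBANK:
            keep.append(i)
        else:
            unknown.add(src)
    if unknown:
        warnings.warn(f"records with unknown sources skipped: {sorted(unknown)}")
    return records.iloc[keep].reset_index(drop=True)


def allele_match(
    records: pd.DataFrame, protein: str, allele: str | None = None
) -> pd.DataFrame:
    """Records targeting ``protein`` with the requested allele tag.

    ``allele=None`` (or empty) queries the wild-type protein and matches
    records whose allele field is empty.
    """
    _validate_records(records)
    query = str(allele) if allele else ""
    tags = records["allele"].fillna("").astype(str)
    mask = (records["target_protein"].astype(str) == protein) & (tags == query)
    return records[mask].reset_index(drop=True)


def micromolar_to_nanomolar(records: pd.DataFrame, unit_column: str = "unit") -> pd.DataFrame:
    """Convert rows with a declared µM unit to nM in place of the value."""
    if unit_column not in records.columns:
        return records.copy()
    out = records.copy()
    um = out[unit_column].astype(str).str.lower().isin({"um", "µm", "micromolar"})
    out.loc[um, "value"] = out.loc[um, "value"].astype(float) * 1000.0
    out.loc[um, unit_column] = "nM"
    return out


@dataclass
class DrugNetworkResult:
    """Bipartite compound-protein graph plus per-protein compound shares."""

    graph: nx.Graph
    proportions: pd.DataFrame  # protein, n_compounds, pct_of_compounds
    n_compounds: int


def build_drug_network(
    records: pd.DataFrame,
    core_proteins: Sequence[str],
    specificity_tags: Mapping[str, str] | None = None,
) -> DrugNetworkResult:
    """Bipartite drug-protein network restricted to the core proteins.

    Per protein the count and percentage of distinct linked compounds is
    reported (denominator: all distinct compounds in the network; a
    multi-target compound counts once per protein, so percentages need
    not sum to 100).  Core proteins with no passing record keep degree 0.
    """
    _validate_records(records)
    tags = dict(specificity_tags or {})
    core = list(dict.fromkeys(core_proteins))
    g = nx.Graph()
    for p in core:
        g.add_node(p, kind="protein", specificity=tags.get(p, ""))
    compounds_per_protein: dict[str, set[str]] = {p: set() for p in core}
    all_compounds: set[str] = set()
    for row in records.itertuples(index=False):
        protein = str(row.target_protein)
        if protein not in compounds_per_protein:
            continue
        compound = canonical_compound(row.compound_id)
        all_compounds.add(compound)
        compounds_per_protein[protein].add(compound)
        if compound not in g:
            g.add_node(compound, kind="compound")
        if not g.has_edge(compound, protein):
            g.add_edge(
                compound,
                protein,
                affinity_type=str(row.affinity_type),
                value=float(row.value),
                source=str(row.source),
            )
    n_total = len(all_compounds)
    proportions = pd.DataFrame(
        [
            {
                "protein": p,
                "n_compounds": len(compounds_per_protein[p]),
                "pct_of_compounds": (
                    100.0 * len(compounds_per_protein[p]) / n_total if n_total else 0.0
                ),
            }
            for p in core
        ],
        columns=["protein", "n_compounds", "pct_of_compounds"],
    )
    return DrugNetworkResult(graph=g, proportions=proportions, n_compounds=n_total)


@dataclass(frozen=True)
class DiffusionScore:
    compound_id: str
    target_protein: str
    score: float
    contributing: tuple[tuple[str, int, float], ...]  # (measured kinase, distance, weight)


def diffusion_rank(
    network: InteractionNetwork | nx.Graph,
    screening: pd.DataFrame,
    alpha: float = 0.5,
    targets: Sequence[str] | None = None,
) -> list[DiffusionScore]:
    """Rank (compound, kinase) pairs by diffused screening values.

    ``screening`` columns: compound_id, kinase, value.  For each compound
    c and target kinase k in the network:
    ``score(c, k) = sum over measured kinases k' of value(c, k') * alpha^d(k, k')``
    with d the unweighted shortest-path distance; unreachable (or absent)
    measured kinases contribute 0.  Results are sorted by score
    descending, ties by (compound, kinase).
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    g = network.graph if isinstance(network, InteractionNetwork) else network
    missing = [c for c in ("compound_id", "kinase", "value") if c not in screening.columns]
    if missing:
        raise InputError(f"screening table missing columns: {missing}")

    node_list = targets if targets is not None else sorted(g.nodes)
    measured: dict[str, list[tuple[str, float]]] = {}
    for row in screening.itertuples(index=False):
        measured.setdefault(str(row.compound_id), []).append(
            (str(row.kinase), float(row.value))
        )

    # distances from every measured kinase present in the network
    dist_from: dict[str, dict[str, int]] = {}
    for kinases in measured.values():
        for k, _ in kinases:
            if k in g and k not in dist_from:
                dist_from[k] = dict(nx.single_source_shortest_path_length(g, k))

    scores: list[DiffusionScore] = []
    for compound in sorted(measured):
        for target in node_list:
            if target not in g:
                continue
            contrib: list[tuple[str, int, float]] = []
            total = 0.0
            for k, value in sorted(measured[compound]):
                d = dist_from.get(k, {}).get(target)
                if d is None:
                    continue
                w = alpha**d
                contrib.append((k, int(d), w))
                total += value * w
            scores.append(
                DiffusionScore(
                    compound_id=compound,
                    target_protein=target,
                    score=total,
                    contributing=tuple(contrib),
                )
            )
    scores.sort(key=lambda s: (-s.score, s.compound_id, s.target_protein))
    return scores


def select_candidates(
    scores: Sequence[DiffusionScore], percentile: float = 95.0
) -> list[DiffusionScore]:
    """Top scores above the given percentile (default top 5%)."""
    if not scores:
        return []
    values = sorted(s.score for s in scores)
    k = int(len(values) * percentile / 100.0)
    cutoff = values[min(k, len(values) - 1)]
    return [s for s in scores if s.score >= cutoff and s.score > 0]


def diffusion_to_frame(scores: Sequence[DiffusionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": s.compound_id,
                "target_protein": s.target_protein,
                "score": s.score,
                "contributing": ";".join(f"{k}:{d}:{w:.6g}" for k, d, w in s.contributing),
            }
            for s in scores
        ],
        columns=["compound_id", "target_protein", "score", "contributing"],
    )
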