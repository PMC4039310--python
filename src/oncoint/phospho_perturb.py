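"""Per-site phosphorylation perturbation scoring and network extension.

Each phospho-site row carries four spectral counts — treated/control for
the phosphorylated and the non-phosphorylated peptide state.  Per state a
1-df Pearson goodness-of-fit statistic compares the observed
(treated, control) split against the split expected from the number of
runs per condition; the two state P-values are multiplied and the product
is thresholded (default 0.1, inclusive).

Significant sites on proteins already in the TAP network become node
annotations; significant proteins outside the network are attached via a
protein-protein interaction reference, with database-evidence edges.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from oncoint.errors import InputError
from oncoint.tap_assembly import (
    EVIDENCE_DATABASE,
    ROLE_PY_ADDED,
    InteractionNetwork,
)

PHOSPHO_COLUMNS = (
    "protein_id",
    "site",
    "n_treated_phos",
    "n_control_phos",
    "n_treated_nonphos",
    "n_control_nonphos",
)

DEFAULT_SCORE_THRESHOLD = 0.1


def state_pvalue(
    n_treated: int,
    n_control: int,
    n_runs_treated: int = 1,
    n_runs_control: int = 1,
    yates: bool = False,
) -> float:
    """Pearson goodness-of-fit P-value for one peptide state.

    Observed counts ``(n_treated, n_control)`` are tested against expected
    counts allocated proportionally to the number of runs per condition
    (equal runs => 50/50).  Zero total count carries no evidence and is
    assigned P = 1.  ``yates`` applies the continuity correction.
    """
    if n_treated < 0 or n_control < 0:
        raise InputError("spectral counts must be non-negative")
    if n_runs_treated <= 0 or n_runs_control <= 0:
        raise InputError("run counts must be positive")
    total = n_treated + n_control
    if total == 0:
        return 1.0
    f_treated = n_runs_treated / (n_runs_treated + n_runs_control)
    e_t = total * f_treated
    e_c = total * (1.0 - f_treated)
    d_t = abs(n_treated - e_t)
    d_c = abs(n_control - e_c)
    if yates:
        d_t = max(d_t - 0.5, 0.0)
        d_c = max(d_c - 0.5, 0.0)
    chi2 = d_t**2 / e_t + d_c**2 / e_c
    return float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class SitePerturbationResult:
    protein_id: str
    site: str
    p_phos: float
    p_nonphos: float
    score: float
    significant: bool


def site_perturbation_score(
    protein_id: str,
    site: str,
    n_treated_phos: int,
    n_control_phos: int,
    n_treated_nonphos: int,
    n_control_nonphos: int,
    n_runs_treated: int = 1,
    n_runs_control: int = 1,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    yates: bool = False,
) -> SitePerturbationResult:
    """Score one site: product of the two per-state chi-squared P-values.

    The site is flagged significant when ``score <= threshold``
    (inclusive boundary).
    """
    p_phos = state_pvalue(
        n_treated_phos, n_control_phos, n_runs_treated, n_runs_control, yates
    )
    p_nonphos = state_pvalue(
        n_treated_nonphos, n_control_nonphos, n_runs_treated, n_runs_control, yates
    )
    score = p_phos * p_nonphos
    return SitePerturbationResult(
        protein_id=protein_id,
        site=site,
        p_phos=p_phos,
        p_nonphos=p_nonphos,
        score=score,
        significant=score <= threshold,
    )


def call_significant_sites(
    table: pd.DataFrame,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    yates: bool = False,
) -> list[SitePerturbationResult]:
    """Score every row of a phospho-count table.

    Returns all rows (flagged or not), ordered by score ascending, ties
    broken by (protein, site).  Columns ``n_runs_treated`` and
    ``n_runs_control`` default to 1 when absent.
    """
    if not 0 < threshold <= 1:
        raise InputError("threshold must be in (0, 1]")
    missing = [c for c in PHOSPHO_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"phospho table missing columns: {missing}")
    results = []
    for row in table.itertuples(index=False):
        results.append(
            site_perturbation_score(
                str(row.protein_id),
                str(row.site),
                int(row.n_treated_phos),
                int(row.n_control_phos),
                int(row.n_treated_nonphos),
                int(row.n_control_nonphos),
                int(getattr(row, "n_runs_treated", 1)),
                int(getattr(row, "n_runs_control", 1)),
                threshold=threshold,
                yates=yates,
            )
        )
    results.sort(key=lambda r: (r.score, r.protein_id, r.site))
    return results


def results_to_frame(results: Sequence[SitePerturbationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "site": r.site,
                "p_phos": r.p_phos,
                "p_nonphos": r.p_nonphos,
                "score": r.score,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["protein_id", "site", "p_phos", "p_nonphos", "score", "significant"],
    )


class PPIReference:
    """Undirected, deduplicated protein-protein interaction lookup."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._adj: dict[str, set[str]] = {}
        for a, b in edges:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            return  # self-loops carry no extension information
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def neighbors(self, protein: str) -> set[str]:
        return set(self._adj.get(protein, ()))

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, nbrs in self._adj.items() for b in nbrs}

    def __len__(self) -> int:
        return len(self.edge_set())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PPIReference":
        """Build from a two-column (protein_a, protein_b) table."""
        if frame.shape[1] < 2:
            raise InputError("PPI table needs at least two columns")
        ref = cls()
        for a, b in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
            ref.add(str(a), str(b))
        return ref


def extend_network(
    network: InteractionNetwork,
    results: Sequence[SitePerturbationResult],
    ppi: PPIReference,
) -> InteractionNetwork:
    """Extend a TAP network with significantly perturbed phospho-proteins.

    Only significant results are used.  Significant sites on proteins
    already in the network are attached as node annotations.  A
    significant protein absent from the network is added (role
    ``pY-added``) with a database-evidence edge to every *original*
    network protein it interacts with in ``ppi``; proteins with no such
    link are not added.  The input network is never mutated and nothing is
    removed.
    """
    out = network.copy()
    original_nodes = list(network.nodes())
    sites_by_protein: dict[str, list[str]] = {}
    for r in results:
        if r.significant:
            sites_by_protein.setdefault(r.protein_id, []).append(r.site)

    for protein in sorted(sites_by_protein):
        sites = sites_by_protein[protein]
        if protein in out:
            out.annotate_sites(protein, sites)
            continue
        partners = sorted(p for p in original_nodes if ppi.has_edge(protein, p))
        if not partners:
            continue
        out.add_node(protein, ROLE_PY_ADDED)
        out.annotate_sites(protein, sites)
        for partner in partners:
            out.add_edge(
                protein, partner, evidence=EVIDENCE_DATABASE, support="ppi-reference"
            )
    return out


def read_phospho_table(path) -> pd.DataFrame:
    """Read a phospho-count TSV and validate its schema."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PHOSPHO_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"phospho table {path} missing columns: {missing}")
    if (table[list(PHOSPHO_COLUMNS[2:])] < 0).any().any():
        raise InputError("phospho table contains negative counts")
    bad = [s for s in table["site"].astype(str) if s[:1] not in {"S", "T", "Y"}]
    if bad:
        warnings.warn(f"{len(bad)} sites with residue outside S/T/Y (kept)")
    return table
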