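"""Viability-screen normalization, hit calling and specificity testing.

A screen is a long-format table of raw plate readouts, one row per
(cell line, gene, replicate) plus non-targeting control wells per line.
Readouts are normalized to the per-line control mean; a hit is a gene
with >50% viability inhibition and t-test P < 0.05 against the control
wells.  The core network is the exact intersection of per-line hit sets;
mutant vs wild-type specificity uses the two-sided Wilcoxon rank-sum test
on per-line replicate means (exact null up to group sizes of 10).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from oncoint.errors import InputError

SCREEN_COLUMNS = ("cell_line", "gene", "replicate", "readout", "is_control")

GROUP_MUTANT = "mutant"
GROUP_WILDTYPE = "wild-type"

TIER_STRONG = "##"  # P < 0.01
TIER_WEAK = "#"  # P < 0.05
TIER_NONE = ""


@dataclass
class ViabilityScreen:
    """Long-format screen readouts plus optional panel metadata.

    ``data`` columns: cell_line, gene, replicate, readout, is_control.
    ``meta`` (optional) columns: cell_line, group, resistant, parent_line.
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None
    readout_kind: str = "viability"
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"screen table missing columns: {missing}")
        lines = set(self.data["cell_line"])
        with_controls = set(self.data.loc[self.data["is_control"].astype(bool), "cell_line"])
        if lines - with_controls:
            raise InputError(
                f"cell lines without control wells: {sorted(lines - with_controls)}"
            )

    def cell_lines(self) -> list[str]:
        return sorted(set(self.data["cell_line"].astype(str)))

    def genes(self) -> list[str]:
        mask = ~self.data["is_control"].astype(bool)
        return sorted(set(self.data.loc[mask, "gene"].astype(str)))

    def replicates(self, cell_line: str, gene: str) -> np.ndarray:
        d = self.data
        mask = (
            (d["cell_line"] == cell_line)
            & (d["gene"] == gene)
            & (~d["is_control"].astype(bool))
        )
        return d.loc[mask, "readout"].to_numpy(dtype=float)

    def control_replicates(self, cell_line: str) -> np.ndarray:
        d = self.data
        mask = (d["cell_line"] == cell_line) & d["is_control"].astype(bool)
        return d.loc[mask, "readout"].to_numpy(dtype=float)

    def groups(self) -> dict[str, str]:
        if self.meta is None:
            raise InputError("screen has no panel metadata")
        return {
            str(r.cell_line): str(r.group) for r in self.meta.itertuples(index=False)
        }


def normalize(screen: ViabilityScreen) -> ViabilityScreen:
    """Divide every reading by its line's control-well mean.

    Controls normalize to mean 1.  Idempotent: normalizing an already
    normalized screen returns it unchanged.  A non-positive control mean
    raises an error naming the offending line.
    """
    if screen.normalized:
        return replace(screen, data=screen.data.copy())
    data = screen.data.copy()
    data["readout"] = data["readout"].astype(float)
    for line in screen.cell_lines():
        ctrl = screen.control_replicates(line)
        m = float(np.mean(ctrl)) if len(ctrl) else 0.0
        if m <= 0:
            raise InputError(f"non-positive control mean for cell line {line!r}")
        data.loc[data["cell_line"] == line, "readout"] /= m
    return replace(screen, data=data, normalized=True)


@dataclass(frozen=True)
class HitCall:
    cell_line: str
    gene: str
    mean_viability: float
    inhibition: float
    p_value: float
    is_hit: bool


def call_hits(
    screen: ViabilityScreen,
    inhibition_threshold: float = 0.5,
    alpha: float = 0.05,
    mode: str = "two-sample",
) -> list[HitCall]:
    """Per (line, gene) hit calls: inhibition > threshold AND P < alpha.

    ``mode='two-sample'`` (default) runs an equal-variance Student t-test
    of the gene's normalized replicates against the line's normalized
    control replicates; ``mode='one-sample'`` tests against a fixed mean
    of 1.  Genes with fewer than two replicates are skipped with a
    warning.
    """
    if mode not in {"two-sample", "one-sample"}:
        raise InputError(f"unknown t-test mode: {mode!r}")
    screen = normalize(screen)
    calls: list[HitCall] = []
    for line in screen.cell_lines():
        ctrl = screen.control_replicates(line)
        for gene in screen.genes():
            reps = screen.replicates(line, gene)
            if len(reps) == 0:
                continue
            if len(reps) < 2:
                warnings.warn(f"gene {gene!r} in line {line!r} has <2 replicates; skipped")
                continue
            mean_v = float(np.mean(reps))
            if mode == "two-sample":
                t, p = stats.ttest_ind(reps, ctrl, equal_var=True)
            else:
                t, p = stats.ttest_1samp(reps, 1.0)
            p = float(p) if np.isfinite(p) else 1.0
            inhibition = 1.0 - mean_v
            calls.append(
                HitCall(
                    cell_line=line,
                    gene=gene,
                    mean_viability=mean_v,
                    inhibition=inhibition,
                    p_value=p,
                    is_hit=bool(inhibition > inhibition_threshold and p < alpha),
                )
            )
    return calls


def hits_by_line(calls: Iterable[HitCall]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for c in calls:
        out.setdefault(c.cell_line, set())
        if c.is_hit:
            out[c.cell_line].add(c.gene)
    return out


def core_network(hit_sets: Iterable[set[str]]) -> list[str]:
    """Exact intersection of per-line hit gene sets, sorted."""
    sets = [set(s) for s in hit_sets]
    if len(sets) < 2:
        raise InputError("core network needs hit sets from at least two cell lines")
    core = set.intersection(*sets)
    return sorted(core)


def pair_overlap(
    parent_hits: Iterable[str], resistant_hits: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two hit sets into (shared, parent-only, resistant-only)."""
    p, r = set(parent_hits), set(resistant_hits)
    return p & r, p - r, r - p


def resistant_gain(
    screen: ViabilityScreen,
    parent_line: str,
    resistant_line: str,
    alpha: float = 0.05,
    min_delta: float = 0.15,
) -> list[str]:
    """Genes hitting the resistant line harder than the parent line.

    Reconstruction of an under-specified published rule: a gene is
    reported when resistant mean viability < parent mean − ``min_delta``
    and a two-sample equal-variance t-test gives P < ``alpha``.
    """
    screen = normalize(screen)
    out = []
    for gene in screen.genes():
        par = screen.replicates(parent_line, gene)
        res = screen.replicates(resistant_line, gene)
        if len(par) < 2 or len(res) < 2:
            continue
        if float(np.mean(res)) >= float(np.mean(par)) - min_delta:
            continue
        _, p = stats.ttest_ind(res, par, equal_var=True)
        if np.isfinite(p) and p < alpha:
            out.append(gene)
    return sorted(out)


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum P-value.

    Exact null distribution (enumeration of all rank assignments, ties
    handled by average ranks) when both group sizes are <= ``exact_max``;
    otherwise the normal approximation with tie correction (no continuity
    correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InputError("rank-sum test needs non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        dev = abs(w_obs - mu)
        total = comb(n, n1)
        hits = 0
        for idx in combinations(range(n), n1):
            w = sum(ranks[i] for i in idx)
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class SpecificityResult:
    gene: str
    p_value: float
    tier: str
    lower_in_mutant: bool


def specificity_test(
    screen: ViabilityScreen,
    groups: Mapping[str, str] | None = None,
    alpha_strong: float = 0.01,
    alpha_weak: float = 0.05,
) -> list[SpecificityResult]:
    """Mutant vs wild-type differential dependency per gene.

    Per-line per-gene summaries are replicate means.  The two-sided
    Wilcoxon rank-sum test compares mutant-line means against
    wild-type-line means; tiers: ``##`` (P < 0.01), ``#`` (P < 0.05),
    empty otherwise.  Both groups need at least two cell lines.
    """
    screen = normalize(screen)
    if groups is None:
        groups = screen.groups()
    mut_lines = sorted(l for l, g in groups.items() if g == GROUP_MUTANT)
    wt_lines = sorted(l for l, g in groups.items() if g == GROUP_WILDTYPE)
    if len(mut_lines) < 2 or len(wt_lines) < 2:
        raise InputError("each group needs at least two cell lines")
    out = []
    for gene in screen.genes():
        mut = [float(np.mean(screen.replicates(l, gene))) for l in mut_lines]
        wt = [float(np.mean(screen.replicates(l, gene))) for l in wt_lines]
        p = rank_sum_test(mut, wt)
        tier = TIER_STRONG if p < alpha_strong else TIER_WEAK if p < alpha_weak else TIER_NONE
        out.append(
            SpecificityResult(
                gene=gene,
                p_value=p,
                tier=tier,
                lower_in_mutant=bool(np.mean(mut) < np.mean(wt)),
            )
        )
    out.sort(key=lambda r: (r.p_value, r.gene))
    return out


def replicate_concordance(
    screen_day1: ViabilityScreen, screen_day2: ViabilityScreen
) -> float:
    """Spearman rank correlation of per-(line, gene) mean viabilities."""
    s1 = normalize(screen_day1)
    s2 = normalize(screen_day2)

    def means(s: ViabilityScreen) -> dict[tuple[str, str], float]:
        return {
            (l, g): float(np.mean(s.replicates(l, g)))
            for l in s.cell_lines()
            for g in s.genes()
            if len(s.replicates(l, g))
        }

    m1, m2 = means(s1), means(s2)
    shared = sorted(set(m1) & set(m2))
    if len(shared) < 3:
        raise InputError("replicate concordance needs at least 3 shared (line, gene) keys")
    rho, _ = stats.spearmanr([m1[k] for k in shared], [m2[k] for k in shared])
    return float(rho)


def viability_heatmap(
    screen: ViabilityScreen,
    gene_order: Sequence[str] | None = None,
    line_order: Sequence[str] | None = None,
    tsv_path=None,
    png_path=None,
) -> pd.DataFrame:
    """Genes x lines matrix of mean normalized viabilities.

    Deterministic (sorted) ordering unless explicit orders are given;
    optionally written as TSV and rendered to PNG.
    """
    screen = normalize(screen)
    genes = list(gene_order) if gene_order is not None else screen.genes()
    lines = list(line_order) if line_order is not None else screen.cell_lines()
    matrix = pd.DataFrame(
        [
            [float(np.mean(screen.replicates(l, g))) for l in lines]
            for g in genes
        ],
        index=pd.Index(genes, name="gene"),
        columns=lines,
    )
    if tsv_path is not None:
        matrix.to_csv(tsv_path, sep="\t")
    if png_path is not None:
        from matplotlib.figure import Figure

        fig = Figure(figsize=(max(4, 0.5 * len(lines)), max(4, 0.25 * len(genes))))
        ax = fig.add_subplot(111)
        im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="coolwarm")
        ax.set_xticks(range(len(lines)), lines, rotation=90, fontsize=6)
        ax.set_yticks(range(len(genes)), genes, fontsize=6)
        fig.colorbar(im, ax=ax, label="viability (fraction of control)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
    return matrix


def hits_to_frame(calls: Sequence[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": c.cell_line,
                "gene": c.gene,
                "mean_viability": c.mean_viability,
                "inhibition": c.inhibition,
                "p_value": c.p_value,
                "is_hit": c.is_hit,
            }
            for c in calls
        ],
        columns=["cell_line", "gene", "mean_viability", "inhibition", "p_value", "is_hit"],
    )


def specificity_to_frame(results: Sequence[SpecificityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "p_value": r.p_value,
                "tier": r.tier,
                "lower_in_mutant": r.lower_in_mutant,
            }
            for r in results
        ],
        columns=["gene", "p_value", "tier", "lower_in_mutant"],
    )
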