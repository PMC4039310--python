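"""Seeded generators for every pipeline input, with planted ground truth.

Each ``simulate_*`` function consumes one :class:`SimulationConfig` and
returns tables in the exact schemas the downstream modules read, plus a
:class:`GroundTruth` recording what was planted.  All randomness flows
from one global seed through named :class:`numpy.random.SeedSequence`
streams, so adding a generator never perturbs the others and a fixed
config yields byte-identical tables.

Identifier conventions: baits ``B001``, prey ``P0001``, background
``C0001``, phospho proteins ``Y0001``, filler screen genes ``F0001``,
compounds ``D0001``, dose-response drugs ``DR1``.  A small alias table
maps a few identifiers to familiar protein names for readable demos.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from oncoint.errors import ConfigurationError
from oncoint.rnai_screen import GROUP_MUTANT, GROUP_WILDTYPE, ViabilityScreen
from oncoint.synergy import additive_combo_fit, median_effect_fa, MedianEffectFit

# stream indices for stable seed splitting; append only, never reorder
_STREAM_TAP = 0
_STREAM_PHOSPHO = 1
_STREAM_SCREEN = 2
_STREAM_DRUG = 3
_STREAM_PPI = 4

#: demo-only aliases from synthetic identifiers to familiar protein names
ALIAS_TABLE = {
    "B001": "EGFR",
    "B002": "GRB2",
    "B003": "SHC1",
    "B004": "ERBB3",
    "G0001": "EGFR",
    "G0002": "GRB2",
    "G0003": "SHC1",
}

_DEFAULT_CORE = tuple(f"G{i:04d}" for i in range(1, 15))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic inputs; one seed drives everything."""

    seed: int = 0
    # TAP
    n_baits: int = 8
    n_prey_per_bait: int = 20
    n_background: int = 30
    shared_peptide_fraction: float = 0.1
    count_mean: float = 30.0
    tap_cell_lines: tuple[str, ...] = ("CL1",)
    tap_n_replicates: int = 2
    tap_n_controls: int = 2  # control pulldowns per cell line
    peptides_per_protein: int = 3
    isoform_fraction: float = 0.1
    overdispersion: float | None = None  # negative-binomial dispersion, None = Poisson
    # phospho
    phospho_n_sites: int = 200
    phospho_effect_fold: float = 10.0
    phospho_frac_perturbed: float = 0.15
    # PPI
    ppi_n_nodes: int = 150
    ppi_edge_prob: float = 0.02
    extension_link_fraction: float = 0.6
    # screen
    screen_n_lines: int = 17
    screen_n_mutant: int = 5
    screen_n_genes: int = 40
    screen_n_replicates: int = 3
    core_genes: tuple[str, ...] = _DEFAULT_CORE
    core_effect: float = 0.3
    replicate_cv: float = 0.05
    # drug
    drug_n_compounds: int = 60
    affinity_lognormal_params: tuple[float, float] = (3.5, 1.5)
    dose_response_params: tuple[tuple[float, float], ...] = ((1.0, 1.5), (2.0, 1.5))
    n_doses: int = 8
    dose_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        proportions = {
            "shared_peptide_fraction": self.shared_peptide_fraction,
            "phospho_frac_perturbed": self.phospho_frac_perturbed,
            "ppi_edge_prob": self.ppi_edge_prob,
            "extension_link_fraction": self.extension_link_fraction,
            "replicate_cv": self.replicate_cv,
            "core_effect": self.core_effect,
            "isoform_fraction": self.isoform_fraction,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if self.screen_n_mutant > self.screen_n_lines:
            raise ConfigurationError("screen_n_mutant exceeds screen_n_lines")
        if self.count_mean <= 0:
            raise ConfigurationError("count_mean must be positive")
        if self.phospho_effect_fold <= 0:
            raise ConfigurationError("phospho_effect_fold must be positive")
        for dm, m in self.dose_response_params:
            if dm <= 0 or m <= 0:
                raise ConfigurationError("dose-response Dm and m must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("tap_cell_lines", "core_genes"):
            if key in d:
                d[key] = tuple(d[key])
        if "dose_response_params" in d:
            d["dose_response_params"] = tuple(tuple(p) for p in d["dose_response_params"])
        if "affinity_lognormal_params" in d:
            d["affinity_lognormal_params"] = tuple(d["affinity_lognormal_params"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted; each generator fills its own slice."""

    true_edges: set[tuple[str, str]] = field(default_factory=set)
    true_background: set[str] = field(default_factory=set)
    shared_only_prey: set[str] = field(default_factory=set)
    true_perturbed_sites: set[tuple[str, str]] = field(default_factory=set)
    true_extension_proteins: set[str] = field(default_factory=set)
    true_core_genes: set[str] = field(default_factory=set)
    true_allele_binders: set[tuple[str, str, str]] = field(default_factory=set)
    true_dose_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        merged = GroundTruth()
        for f in fields(GroundTruth):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, dict):
                setattr(merged, f.name, {**a, **b})
            else:
                setattr(merged, f.name, set(a) | set(b))
        return merged

    def to_json(self, path) -> None:
        def _enc(value):
            if isinstance(value, set):
                return sorted(list(v) if isinstance(v, tuple) else v for v in value)
            if isinstance(value, dict):
                return {k: list(v) for k, v in sorted(value.items())}
            return value

        with open(path, "w", encoding="utf-8") as fh:
            json.dump({f.name: _enc(getattr(self, f.name)) for f in fields(GroundTruth)},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


def _counts(rng: np.random.Generator, mean: float, size: int, overdispersion: float | None):
    """Poisson counts, or negative binomial when overdispersion is set."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if overdispersion is None:
        return rng.poisson(mean, size=size)
    r = overdispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# TAP
# ---------------------------------------------------------------------------

def simulate_tap(config: SimulationConfig):
    """Peptide evidence + pulldown manifest over a planted interactome.

    Each bait pulldown contains its bait, its planted prey and the shared
    contaminant background; control (GFP-like) pulldowns contain only the
    background.  A ``shared_peptide_fraction`` of each bait's prey get no
    specific peptides (every peptide also maps to a retained partner
    prey), so downstream grouping discards exactly those.  A fraction of
    prey rows carry isoform-suffixed identifiers to exercise collapsing.

    Returns ``(evidence, manifest, GroundTruth)``.
    """
    if config.n_baits < 1:
        raise ConfigurationError("need at least one bait")
    if config.tap_n_controls < 1:
        raise ConfigurationError("need at least one control pulldown per cell line")
    if config.shared_peptide_fraction > 0.5:
        raise ConfigurationError("shared_peptide_fraction above 0.5 cannot be planted")
    rng = config.rng(_STREAM_TAP)

    baits = [f"B{i:03d}" for i in range(1, config.n_baits + 1)]
    truth = GroundTruth()
    truth.true_background = {f"C{i:04d}" for i in range(1, config.n_background + 1)}
    background = sorted(truth.true_background)

    # peptide map: peptide_id -> tuple of proteins it maps to
    peptide_map: dict[str, tuple[str, ...]] = {}
    protein_peptides: dict[str, list[str]] = {}

    def _add_protein(pid: str) -> None:
        peps = [f"pep_{pid}_{j}" for j in range(1, config.peptides_per_protein + 1)]
        protein_peptides[pid] = peps
        for pep in peps:
            peptide_map[pep] = (pid,)

    for b in baits:
        _add_protein(b)
    for c in background:
        _add_protein(c)

    prey_of: dict[str, list[str]] = {}
    isoform_prey: set[str] = set()
    counter = 0
    n_shared = int(round(config.shared_peptide_fraction * config.n_prey_per_bait))
    for b in baits:
        prey = []
        for _ in range(config.n_prey_per_bait):
            counter += 1
            prey.append(f"P{counter:04d}")
        retained, shared = prey[: len(prey) - n_shared], prey[len(prey) - n_shared:]
        for p in retained:
            _add_protein(p)
            if rng.random() < config.isoform_fraction:
                isoform_prey.add(p)
        for s, partner in zip(shared, retained):
            # every peptide of s also maps to its partner -> no specific evidence
            host_peps = protein_peptides[partner][: max(1, config.peptides_per_protein - 1)]
            protein_peptides[s] = list(host_peps)
            for pep in host_peps:
                peptide_map[pep] = tuple(sorted(set(peptide_map[pep]) | {s}))
            truth.shared_only_prey.add(s)
        prey_of[b] = prey
        truth.true_edges.update((b, p) for p in prey)

    per_pep_mean = max(config.count_mean / config.peptides_per_protein, 0.1)

    def _emit(rows: list, run_id: str, proteins: Sequence[str], guarantee: bool) -> None:
        affinity = {}
        for pid in proteins:
            affinity[pid] = 1.0 if pid in background else float(rng.uniform(0.6, 1.4))
        peps = sorted({pep for pid in proteins for pep in protein_peptides[pid]})
        for pep in peps:
            owners = peptide_map[pep]
            present = [p for p in owners if p in affinity]
            lam = per_pep_mean * max(affinity[p] for p in present)
            count = int(_counts(rng, lam, 1, config.overdispersion)[0])
            if guarantee and pep.endswith("_1"):
                count = max(count, 1)
            if count <= 0:
                continue
            shown = []
            for p in owners:
                if p in isoform_prey:
                    shown.append(f"{p}-{rng.integers(1, 3)}")
                else:
                    shown.append(p)
            rows.append(
                {
                    "run_id": run_id,
                    "peptide_id": pep,
                    "protein_ids": ";".join(sorted(set(shown))),
                    "spectral_count": count,
                    "phospho_state": 0,
                }
            )

    evidence_rows: list[dict] = []
    manifest_rows: list[dict] = []
    for line in config.tap_cell_lines:
        for b in baits:
            proteins = [b] + prey_of[b] + background
            for rep in range(1, config.tap_n_replicates + 1):
                run_id = f"run_{b}_{line}_r{rep}"
                manifest_rows.append(
                    {
                        "run_id": run_id,
                        "bait_id": b,
                        "cell_line": line,
                        "replicate": rep,
                        "is_control": False,
                    }
                )
                _emit(evidence_rows, run_id, proteins, guarantee=rep == 1)
        for rep in range(1, config.tap_n_controls + 1):
            run_id = f"run_GFP_{line}_r{rep}"
            manifest_rows.append(
                {
                    "run_id": run_id,
                    "bait_id": "CONTROL",
                    "cell_line": line,
                    "replicate": rep,
                    "is_control": True,
                }
            )
            _emit(evidence_rows, run_id, background, guarantee=True)

    evidence = pd.DataFrame(
        evidence_rows,
        columns=["run_id", "peptide_id", "protein_ids", "spectral_count", "phospho_state"],
    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["run_id", "bait_id", "cell_line", "replicate", "is_control"]
    )
    return evidence, manifest, truth


# ---------------------------------------------------------------------------
# phospho
# ---------------------------------------------------------------------------

def simulate_phospho(config: SimulationConfig, proteins: Sequence[str] | None = None):
    """Per-site four-cell spectral counts with planted treated effects.

    For perturbed sites the treated phosphorylated mean is the base mean
    divided by ``phospho_effect_fold`` (drug suppresses phosphorylation)
    with a compensating increase of the treated non-phosphorylated mean;
    null sites share one mean across all four cells.  ``proteins``
    optionally supplies identifiers (e.g. TAP preys) to host the sites;
    extras are invented as ``Y0001``-style ids.

    Returns ``(counts, GroundTruth)``.
    """
    if config.phospho_n_sites < 1:
        raise ConfigurationError("phospho_n_sites must be at least 1")
    rng = config.rng(_STREAM_PHOSPHO)
    n = config.phospho_n_sites
    n_proteins = max(1, n // 2)
    pool = list(proteins) if proteins else []
    for i in range(len(pool), n_proteins):
        pool.append(f"Y{i + 1:04d}")
    pool = pool[:n_proteins]

    host = [pool[int(i)] for i in rng.integers(0, n_proteins, size=n)]
    positions = rng.integers(50, 1400, size=n)
    sites = []
    seen: set[tuple[str, str]] = set()
    for p, pos in zip(host, positions):
        site = f"Y{int(pos)}"
        while (p, site) in seen:
            pos += 1
            site = f"Y{int(pos)}"
        seen.add((p, site))
        sites.append((p, site))

    n_perturbed = int(round(config.phospho_frac_perturbed * n))
    perturbed_idx = set(rng.choice(n, size=n_perturbed, replace=False).tolist())

    mean = config.count_mean
    fold = config.phospho_effect_fold
    rows = []
    truth = GroundTruth()
    for i, (p, site) in enumerate(sites):
        if i in perturbed_idx:
            m_tp = mean / fold
            m_tn = mean + (mean - m_tp)  # compensating non-phospho increase
            truth.true_perturbed_sites.add((p, site))
        else:
            m_tp = mean
            m_tn = mean
        rows.append(
            {
                "protein_id": p,
                "site": site,
                "n_treated_phos": int(_counts(rng, m_tp, 1, config.overdispersion)[0]),
                "n_control_phos": int(_counts(rng, mean, 1, config.overdispersion)[0]),
                "n_treated_nonphos": int(_counts(rng, m_tn, 1, config.overdispersion)[0]),
                "n_control_nonphos": int(_counts(rng, mean, 1, config.overdispersion)[0]),
                "n_runs_treated": 1,
                "n_runs_control": 1,
            }
        )
    counts = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "site",
            "n_treated_phos",
            "n_control_phos",
            "n_treated_nonphos",
            "n_control_nonphos",
            "n_runs_treated",
            "n_runs_control",
        ],
    )
    return counts, truth


def simulate_ppi(
    config: SimulationConfig,
    tap_proteins: Sequence[str],
    phospho_proteins: Sequence[str],
    perturbed_proteins: set[str],
):
    """PPI reference with planted extension edges.

    A fraction (``extension_link_fraction``) of the perturbed-site
    proteins that are outside the TAP network get one planted edge to a
    random TAP protein — these are the true extension proteins.  The
    remaining perturbed proteins are kept disconnected from the TAP set.
    Random filler edges with probability ``ppi_edge_prob`` are added
    among invented filler nodes and from fillers to TAP/phospho nodes
    that are not extension-relevant.

    Returns ``(ppi_table, GroundTruth)``.
    """
    rng = config.rng(_STREAM_PPI)
    tap_set = list(dict.fromkeys(tap_proteins))
    outside = [p for p in dict.fromkeys(phospho_proteins)
               if p in perturbed_proteins and p not in set(tap_set)]
    n_linked = int(round(config.extension_link_fraction * len(outside)))
    linked = set(
        rng.choice(len(outside), size=n_linked, replace=False).tolist()
    ) if outside else set()

    truth = GroundTruth()
    edges: set[tuple[str, str]] = set()
    for i, p in enumerate(outside):
        if i in linked:
            partner = tap_set[int(rng.integers(0, len(tap_set)))]
            edges.add(tuple(sorted((p, partner))))
            truth.true_extension_proteins.add(p)

    # filler noise edges that never touch an unlinked perturbed protein
    fillers = [f"N{i:04d}" for i in range(1, config.ppi_n_nodes + 1)]
    unlinked = {p for i, p in enumerate(outside) if i not in linked}
    candidates = fillers + [p for p in tap_set if p not in unlinked]
    for i, a in enumerate(fillers):
        for b in candidates[i + 1:]:
            if a == b or b in unlinked:
                continue
            if rng.random() < config.ppi_edge_prob:
                edges.add(tuple(sorted((a, b))))

    table = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])
    table["source"] = "simulated"
    return table, truth


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def simulate_screen(config: SimulationConfig):
    """Viability screen with a core gene set essential in mutant lines.

    Mutant-labelled lines have mean viability ``core_effect`` for the
    planted core genes; everything else (wild-type lines, non-core genes,
    control wells) has mean 1.  Multiplicative log-normal replicate noise
    with coefficient of variation ``replicate_cv`` (zero noise reproduces
    the planted means exactly).  Raw readouts are scaled to plate-reader
    magnitudes; normalization recovers the fractions.

    Returns ``(ViabilityScreen, GroundTruth)``.
    """
    if config.core_effect >= 0.5:
        raise ConfigurationError(
            "core_effect must be < 0.5 so planted core genes exceed 50% inhibition"
        )
    if config.screen_n_genes < len(config.core_genes):
        raise ConfigurationError("screen_n_genes smaller than the planted core gene list")
    if config.screen_n_replicates < 2:
        raise ConfigurationError("need at least two replicates per well")
    rng = config.rng(_STREAM_SCREEN)

    n_wt = config.screen_n_lines - config.screen_n_mutant
    lines = [(f"M{i:02d}", GROUP_MUTANT) for i in range(1, config.screen_n_mutant + 1)]
    lines += [(f"W{i:02d}", GROUP_WILDTYPE) for i in range(1, n_wt + 1)]
    genes = list(config.core_genes) + [
        f"F{i:04d}" for i in range(1, config.screen_n_genes - len(config.core_genes) + 1)
    ]

    cv = config.replicate_cv
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv * cv)))
        mu = -0.5 * sigma * sigma  # unit-mean log-normal

    def _noise(size: int) -> np.ndarray:
        if cv == 0:
            return np.ones(size)
        return rng.lognormal(mean=mu, sigma=sigma, size=size)

    scale = 2000.0
    rows = []
    core = set(config.core_genes)
    for line, group in lines:
        ctrl = scale * _noise(config.screen_n_replicates)
        for rep, value in enumerate(ctrl, start=1):
            rows.append(
                {
                    "cell_line": line,
                    "gene": "NTC",
                    "replicate": rep,
                    "readout": float(value),
                    "is_control": True,
                }
            )
        for gene in genes:
            planted = config.core_effect if (group == GROUP_MUTANT and gene in core) else 1.0
            values = scale * planted * _noise(config.screen_n_replicates)
            for rep, value in enumerate(values, start=1):
                rows.append(
                    {
                        "cell_line": line,
                        "gene": gene,
                        "replicate": rep,
                        "readout": float(value),
                        "is_control": False,
                    }
                )

    data = pd.DataFrame(rows, columns=list(("cell_line", "gene", "replicate", "readout", "is_control")))
    meta = pd.DataFrame(
        [{"cell_line": l, "group": g, "resistant": False, "parent_line": ""} for l, g in lines],
        columns=["cell_line", "group", "resistant", "parent_line"],
    )
    truth = GroundTruth(true_core_genes=set(config.core_genes))
    return ViabilityScreen(data=data, meta=meta), truth


# ---------------------------------------------------------------------------
# drugs
# ---------------------------------------------------------------------------

def simulate_drug_tables(config: SimulationConfig, targets: Sequence[str] | None = None):
    """Affinity records, allele-specific binders and dose-response curves.

    Affinities are log-normal in nM.  Two planted compounds bind an
    ``EGFR``-aliased target with a ``T790M`` allele tag below the 100 nM
    cutoff (plus one decoy above it).  Dose-response fractions follow the
    median-effect equation for each configured (Dm, m), with optional
    multiplicative noise; when at least two curves are configured an
    exactly-additive 1:1 combination curve of the first two is emitted as
    well.

    Returns ``(records, dose_response, GroundTruth)``.
    """
    if not config.dose_response_params:
        raise ConfigurationError("dose_response_params must be non-empty")
    rng = config.rng(_STREAM_DRUG)
    truth = GroundTruth()

    protein_pool = list(targets) if targets else list(config.core_genes)
    allele_target = protein_pool[0]
    mu, sigma = config.affinity_lognormal_params
    sources = ("competition_assay", "kinase_assay", "bindingdb", "drugbank")

    rows = []
    for i in range(1, config.drug_n_compounds + 1):
        compound = f"D{i:04d}"
        n_targets = int(rng.integers(1, 4))
        chosen = rng.choice(len(protein_pool), size=min(n_targets, len(protein_pool)), replace=False)
        for j in chosen:
            source = sources[int(rng.integers(0, len(sources)))]
            if source == "bindingdb":
                atype = ("Ki", "Kd", "IC50", "EC50")[int(rng.integers(0, 4))]
            elif source == "drugbank":
                atype = "presence"
            else:
                atype = "Kd"
            value = 0.0 if atype == "presence" else float(rng.lognormal(mu, sigma))
            rows.append(
                {
                    "compound_id": compound,
                    "target_protein": protein_pool[int(j)],
                    "allele": "",
                    "affinity_type": atype,
                    "value": round(value, 4),
                    "source": source,
                }
            )

    # planted allele-specific binders below the cutoff, plus one decoy above
    for i in (1, 2):
        compound = f"D{i:04d}"
        value = float(rng.uniform(1.0, 50.0))
        rows.append(
            {
                "compound_id": compound,
                "target_protein": allele_target,
                "allele": "T790M",
                "affinity_type": "Kd",
                "value": round(value, 4),
                "source": "competition_assay",
            }
        )
        truth.true_allele_binders.add((compound, allele_target, "T790M"))
    rows.append(
        {
            "compound_id": "D0003",
            "target_protein": allele_target,
            "allele": "T790M",
            "affinity_type": "Kd",
            "value": 500.0,
            "source": "competition_assay",
        }
    )
    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS_ORDER))

    # dose-response curves
    dr_rows = []
    fits = []
    for k, (dm, m) in enumerate(config.dose_response_params, start=1):
        drug = f"DR{k}"
        truth.true_dose_params[drug] = (float(dm), float(m))
        fits.append(MedianEffectFit(drug_id=drug, dm=float(dm), m=float(m), r=1.0, n_points=0))
        doses = dm * np.geomspace(2.0 ** (-(config.n_doses - 1) / 2), 2.0 ** ((config.n_doses - 1) / 2), config.n_doses)
        fa = median_effect_fa(doses, dm, m)
        if config.dose_noise_cv > 0:
            s = float(np.sqrt(np.log1p(config.dose_noise_cv**2)))
            fa = np.clip(fa * rng.lognormal(-0.5 * s * s, s, size=fa.size), 1e-4, 1 - 1e-4)
        for d, f in zip(doses, fa):
            dr_rows.append({"drug_id": drug, "dose": float(d), "fa": float(f), "ratio": ""})

    if len(fits) >= 2:
        combo = additive_combo_fit(fits[0], fits[1], ratio=(1.0, 1.0), ci=1.0)
        truth.true_dose_params[combo.drug_id] = (combo.dm, combo.m)
        doses = combo.dm * np.geomspace(
            2.0 ** (-(config.n_doses - 1) / 2), 2.0 ** ((config.n_doses - 1) / 2), config.n_doses
        )
        fa = median_effect_fa(doses, combo.dm, combo.m)
        for d, f in zip(doses, fa):
            dr_rows.append({"drug_id": combo.drug_id, "dose": float(d), "fa": float(f), "ratio": "1:1"})

    dose_response = pd.DataFrame(dr_rows, columns=["drug_id", "dose", "fa", "ratio"])
    return records, dose_response, truth


RECORD_COLUMNS_ORDER = ("compound_id", "target_protein", "allele", "affinity_type", "value", "source")
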