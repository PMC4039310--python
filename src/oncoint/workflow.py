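"""Shared I/O and end-to-end pipeline orchestration.

Canonical tabular interchange is TSV (header row, UTF-8, ``.`` decimal);
CSV is accepted on read.  Networks round-trip through GraphML (lossless
for node roles, site annotations and edge evidence) and export to SIF
(lossy: one ``a tap|db b`` line per edge, no attributes).  PPI references
read from PSI-MITAB 2.5 (first two columns, database prefixes stripped)
or plain two-column TSV.

:func:`run_pipeline` executes the full demo on simulated data:
simulate -> TAP build -> phospho score/extend -> screen hits/core/
specificity -> drug filter/build/rank -> synergy fit/ci.  Outputs are
deterministic for a fixed config (byte-identical TSVs across reruns).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from oncoint import __version__
from oncoint import drug_network as dn
from oncoint import phospho_perturb as pp
from oncoint import rnai_screen as rs
from oncoint import synergy as sy
from oncoint import synthetic_data as sd
from oncoint import tap_assembly as ta
from oncoint.errors import ConfigurationError, ParseError

logger = logging.getLogger("oncoint")

_FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a TSV (or CSV) table, checking required columns."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        table = pd.read_csv(path, sep=sep, keep_default_na=True)
    except Exception as exc:  # noqa: BLE001 - rewrap with location
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return table


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(network: ta.InteractionNetwork, path, fmt: str | None = None) -> None:
    """Write a network as GraphML (default) or SIF, by format or suffix."""
    import networkx as nx

    path = Path(path)
    fmt = fmt or ("sif" if path.suffix.lower() == ".sif" else "graphml")
    if fmt == "graphml":
        nx.write_graphml(network.graph, path, encoding="utf-8")
    elif fmt == "sif":
        rel = {ta.EVIDENCE_TAP: "tap", ta.EVIDENCE_DATABASE: "db"}
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, d in sorted(network.edges()):
                fh.write(f"{a}\t{rel.get(d.get('evidence'), 'pp')}\t{b}\n")
            for n in network.nodes():
                if network.graph.degree(n) == 0:
                    fh.write(f"{n}\n")
    else:
        raise ParseError(f"unknown network format: {fmt!r}")


def read_network(path, fmt: str | None = None) -> ta.InteractionNetwork:
    """Read GraphML (attribute-preserving) or SIF (roles default to prey)."""
    import networkx as nx

    path = Path(path)
    fmt = fmt or ("sif" if path.suffix.lower() == ".sif" else "graphml")
    if fmt == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path}: {exc}") from exc
        return ta.InteractionNetwork(nx.Graph(g))
    if fmt != "sif":
        raise ParseError(f"unknown network format: {fmt!r}")
    net = ta.InteractionNetwork()
    rel = {"tap": ta.EVIDENCE_TAP, "db": ta.EVIDENCE_DATABASE}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                net.add_node(parts[0], ta.ROLE_PREY)
            elif len(parts) == 3:
                a, r, b = parts
                for n in (a, b):
                    if n not in net:
                        net.add_node(n, ta.ROLE_PREY)
                net.add_edge(a, b, evidence=rel.get(r, r))
            elif any(parts):
                raise ParseError(f"{path}:{lineno}: malformed SIF line")
    return net


def read_mitab(path) -> pp.PPIReference:
    """PSI-MITAB 2.5 -> undirected deduplicated PPI reference.

    Only the first two columns (interactor identifiers) are used;
    ``db:`` prefixes are stripped, self-loops dropped, rows with fewer
    than 15 columns skipped (one aggregate warning).
    """
    ref = pp.PPIReference()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 15:
                skipped += 1
                continue
            a = parts[0].split(":", 1)[-1]
            b = parts[1].split(":", 1)[-1]
            if a and b:
                ref.add(a, b)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} MITAB rows with <15 columns")
    return ref


def read_ppi(path) -> pp.PPIReference:
    """Dispatch PPI reading by suffix: .mitab/.txt -> MITAB, else 2-col TSV."""
    path = Path(path)
    if path.suffix.lower() in {".mitab", ".mitab25"}:
        return read_mitab(path)
    return pp.PPIReference.from_frame(read_table(path))


# ---------------------------------------------------------------------------
# pipeline configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Demo-pipeline parameters; mirrors the YAML config file."""

    outdir: Path
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    phospho_threshold: float = 0.1
    inhibition_threshold: float = 0.5
    alpha: float = 0.05
    min_distinct_peptides: int = 2
    diffusion_alpha: float = 0.5
    fa_levels: tuple[float, ...] = (0.5, 0.75, 0.9)

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = sd.SimulationConfig.from_dict(raw.pop("simulation", {}))
        out = outdir or raw.pop("outdir", None)
        if out is None:
            raise ConfigurationError("pipeline config needs an outdir")
        raw.pop("outdir", None)
        if "fa_levels" in raw:
            raw["fa_levels"] = tuple(raw["fa_levels"])
        known = {"phospho_threshold", "inhibition_threshold", "alpha",
                 "min_distinct_peptides", "diffusion_alpha", "fa_levels"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline keys: {sorted(unknown)}")
        return cls(outdir=Path(out), simulation=sim, **raw)

    def config_hash(self) -> str:
        payload = {
            "simulation": {k: v for k, v in sorted(vars(self.simulation).items())},
            "phospho_threshold": self.phospho_threshold,
            "inhibition_threshold": self.inhibition_threshold,
            "alpha": self.alpha,
            "min_distinct_peptides": self.min_distinct_peptides,
            "diffusion_alpha": self.diffusion_alpha,
            "fa_levels": list(self.fa_levels),
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Append-only record of executed stages."""

    config_hash: str
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, outputs: list[str], parameters: dict, duration: float) -> None:
        self.stages.append(
            {
                "name": name,
                "outputs": outputs,
                "parameters": parameters,
                "status": "completed",
                "duration_s": round(duration, 3),
            }
        )

    def fail(self, name: str, error: str) -> None:
        self.stages.append({"name": name, "status": "failed", "error": error})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"version": self.version, "config_hash": self.config_hash, "stages": self.stages},
                fh,
                indent=2,
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def tap_build(
    evidence: pd.DataFrame,
    manifest: pd.DataFrame,
    min_distinct_peptides: int = 2,
    per_cell_line_controls: bool = False,
) -> ta.InteractionNetwork:
    """Evidence + manifest -> background-subtracted TAP network.

    Order of operations: collapse isoforms, pool replicate runs per
    pulldown, group proteins, subtract the control union, build.
    """
    collapsed = ta.collapse_isoforms(evidence)
    pulldowns = ta.pool_pulldowns(collapsed, manifest)
    bait_groups = {
        key: ta.group_proteins(ev, min_distinct_peptides=min_distinct_peptides)
        for key, ev in pulldowns.items()
        if key[0] != ta.CONTROL_BAIT
    }
    control_groups = {
        key: ta.group_proteins(ev, min_distinct_peptides=1)
        for key, ev in pulldowns.items()
        if key[0] == ta.CONTROL_BAIT
    }
    filtered = ta.subtract_background(
        bait_groups, control_groups, per_cell_line=per_cell_line_controls
    )
    return ta.build_network(filtered)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full demo pipeline on simulated inputs.

    Each stage writes its outputs before the next starts; a failure stops
    the run with the failing stage recorded in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash())
    sim = config.simulation
    state: dict = {}

    def stage(name: str, params: dict):
        def wrap(fn):
            start = time.perf_counter()
            logger.info("stage=%s parameters=%s", name, params)
            try:
                outputs = fn()
            except Exception as exc:
                manifest.fail(name, f"{type(exc).__name__}: {exc}")
                manifest.to_json(outdir / "manifest.json")
                raise
            manifest.record(name, outputs, params, time.perf_counter() - start)

        return wrap

    @stage("simulate_tap", {"seed": sim.seed, "n_baits": sim.n_baits})
    def _():
        evidence, pd_manifest, truth = sd.simulate_tap(sim)
        state.update(evidence=evidence, tap_manifest=pd_manifest, truth=truth)
        write_table(evidence, outdir / "evidence.tsv")
        write_table(pd_manifest, outdir / "pulldowns.tsv")
        return ["evidence.tsv", "pulldowns.tsv"]

    @stage("tap_build", {"min_distinct_peptides": config.min_distinct_peptides})
    def _():
        net = tap_build(state["evidence"], state["tap_manifest"], config.min_distinct_peptides)
        state["network"] = net
        write_network(net, outdir / "network.graphml")
        write_network(net, outdir / "network.sif")
        return ["network.graphml", "network.sif"]

    @stage("simulate_phospho_ppi", {"n_sites": sim.phospho_n_sites})
    def _():
        counts, ptruth = sd.simulate_phospho(sim)
        sig_proteins = {p for p, _ in ptruth.true_perturbed_sites}
        ppi_table, etruth = sd.simulate_ppi(
            sim, state["network"].nodes(), counts["protein_id"].tolist(), sig_proteins
        )
        state.update(phospho=counts, ppi_table=ppi_table)
        state["truth"] = state["truth"].merge(ptruth).merge(etruth)
        write_table(counts, outdir / "phospho_counts.tsv")
        write_table(ppi_table, outdir / "ppi.tsv")
        return ["phospho_counts.tsv", "ppi.tsv"]

    @stage("phospho_score", {"threshold": config.phospho_threshold})
    def _():
        results = pp.call_significant_sites(state["phospho"], threshold=config.phospho_threshold)
        state["site_results"] = results
        write_table(pp.results_to_frame(results), outdir / "sites.tsv")
        return ["sites.tsv"]

    @stage("phospho_extend", {})
    def _():
        ppi = pp.PPIReference.from_frame(state["ppi_table"])
        extended = pp.extend_network(state["network"], state["site_results"], ppi)
        state["extended"] = extended
        write_network(extended, outdir / "network_extended.graphml")
        return ["network_extended.graphml"]

    @stage(
        "simulate_screen",
        {"n_lines": sim.screen_n_lines, "core_effect": sim.core_effect, "cv": sim.replicate_cv},
    )
    def _():
        screen, struth = sd.simulate_screen(sim)
        state["screen"] = screen
        state["truth"] = state["truth"].merge(struth)
        write_table(screen.data, outdir / "screen.tsv")
        write_table(screen.meta, outdir / "screen_meta.tsv")
        return ["screen.tsv", "screen_meta.tsv"]

    @stage(
        "screen_hits",
        {"inhibition": config.inhibition_threshold, "alpha": config.alpha},
    )
    def _():
        normalized = rs.normalize(state["screen"])
        calls = rs.call_hits(
            normalized, inhibition_threshold=config.inhibition_threshold, alpha=config.alpha
        )
        state["normalized_screen"] = normalized
        state["hit_calls"] = calls
        write_table(rs.hits_to_frame(calls), outdir / "hits.tsv")
        return ["hits.tsv"]

    @stage("screen_core", {})
    def _():
        hits = rs.hits_by_line(state["hit_calls"])
        groups = state["screen"].groups()
        mutant_sets = [hits[l] for l in sorted(hits) if groups.get(l) == rs.GROUP_MUTANT]
        core = rs.core_network(mutant_sets)
        state["core"] = core
        (outdir / "core_genes.txt").write_text("\n".join(core) + "\n", encoding="utf-8")
        return ["core_genes.txt"]

    @stage("screen_specificity", {"alpha": config.alpha})
    def _():
        results = rs.specificity_test(state["normalized_screen"])
        write_table(rs.specificity_to_frame(results), outdir / "specificity.tsv")
        rs.viability_heatmap(
            state["normalized_screen"],
            tsv_path=outdir / "heatmap.tsv",
            png_path=outdir / "heatmap.png",
        )
        return ["specificity.tsv", "heatmap.tsv", "heatmap.png"]

    @stage("drug_filter", {"kd_cutoff_nM": dn.KD_CUTOFF_NM, "bindingdb_cutoff_nM": dn.BINDINGDB_CUTOFF_NM})
    def _():
        records, dose_response, dtruth = sd.simulate_drug_tables(sim, targets=state["core"])
        state["truth"] = state["truth"].merge(dtruth)
        state.update(drug_records=records, dose_response=dose_response)
        write_table(records, outdir / "drug_records.tsv")
        write_table(dose_response, outdir / "dose_response.tsv")
        filtered = dn.filter_records(records)
        state["filtered_records"] = filtered
        write_table(filtered, outdir / "drug_records_filtered.tsv")
        return ["drug_records.tsv", "dose_response.tsv", "drug_records_filtered.tsv"]

    @stage("drug_network", {})
    def _():
        result = dn.build_drug_network(state["filtered_records"], state["core"])
        write_table(result.proportions, outdir / "drug_proportions.tsv")
        import networkx as nx

        nx.write_graphml(result.graph, outdir / "drug_network.graphml", encoding="utf-8")
        return ["drug_proportions.tsv", "drug_network.graphml"]

    @stage("diffusion_rank", {"alpha": config.diffusion_alpha})
    def _():
        rng = sim.rng(9)  # dedicated stream for the kinase-screen demo matrix
        nodes = state["network"].nodes()
        kinases = nodes[: max(3, len(nodes) // 10)]
        compounds = sorted(set(state["filtered_records"]["compound_id"]))[:10]
        rows = [
            {"compound_id": c, "kinase": k, "value": float(rng.uniform(0, 100))}
            for c in compounds
            for k in kinases
        ]
        screening = pd.DataFrame(rows, columns=["compound_id", "kinase", "value"])
        write_table(screening, outdir / "kinase_screen.tsv")
        scores = dn.diffusion_rank(state["network"], screening, alpha=config.diffusion_alpha)
        write_table(dn.diffusion_to_frame(scores[:500]), outdir / "diffusion_ranking.tsv")
        return ["kinase_screen.tsv", "diffusion_ranking.tsv"]

    @stage("synergy", {"fa_levels": list(config.fa_levels)})
    def _():
        dr = state["dose_response"]
        fits = {}
        for drug in dict.fromkeys(dr["drug_id"]):
            sub = dr[dr["drug_id"] == drug]
            fits[drug] = sy.fit_median_effect(sub["dose"], sub["fa"], drug_id=str(drug))
        fit_frame = pd.DataFrame(
            [
                {"drug_id": f.drug_id, "Dm": f.dm, "m": f.m, "r": f.r, "n_points": f.n_points}
                for f in fits.values()
            ],
            columns=["drug_id", "Dm", "m", "r", "n_points"],
        )
        write_table(fit_frame, outdir / "median_effect_fits.tsv")
        outputs = ["median_effect_fits.tsv"]
        combos = [d for d in fits if "+" in d]
        if combos:
            combo = combos[0]
            d1, d2 = combo.split("+", 1)
            ci = sy.combination_index(
                fits[d1], fits[d2], fits[combo], ratio=(1.0, 1.0), fa_levels=config.fa_levels
            )
            ci_frame = pd.DataFrame(
                [
                    {
                        "pair_id": c.pair_id,
                        "fa": c.fa,
                        "d1": c.d1,
                        "d2": c.d2,
                        "Dx1": c.dx1,
                        "Dx2": c.dx2,
                        "CI": c.ci,
                        "call": c.call,
                    }
                    for c in ci
                ],
                columns=["pair_id", "fa", "d1", "d2", "Dx1", "Dx2", "CI", "call"],
            )
            write_table(ci_frame, outdir / "combination_index.tsv")
            sy.plot_curves(
                [fits[d1], fits[d2], fits[combo]], ci, png_path=outdir / "dose_response.png"
            )
            outputs += ["combination_index.tsv", "dose_response.png"]
        return outputs

    @stage("ground_truth", {})
    def _():
        state["truth"].to_json(outdir / "ground_truth.json")
        return ["ground_truth.json"]

    manifest.to_json(outdir / "manifest.json")
    return manifest
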