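"""Umbrella pipeline binding the stages in hierarchical integration order.

Transcription-factor inference from peaks comes first, its output joins
the proteomic prizes, the prize-collecting Steiner forest and its
robustness/specificity ensembles follow, then the validation statistics
and finally the fly-screen concordant-path network. Every stage writes
its artifacts under the output directory and the run manifest records
the config hash, seed, and per-artifact checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fly as flymod
from . import io as ofio
from . import pcsf, regulation, stats, synthetic

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "simulate",
    "fdr",
    "beta",
    "omega",
    "alpha",
    "noise_sd",
    "reps",
    "top_k",
    "max_dist",
    "promoter_halfwidth",
    "cpg_cutoff",
    "threshold_frac",
    "top_fraction",
    "max_path_len",
    "n_permutations",
    "synthetic",
    "stages",
}

_ALL_STAGES = ("regulation", "pcsf", "ensembles", "stats", "fly")


@dataclass
class PipelineConfig:
    """Validated stage parameters; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: bool = True
    fdr: float = 0.1
    beta: float = 1.0
    omega: float = 0.1
    alpha: float = 1.0
    noise_sd: float = 0.3
    reps: int = 20
    top_k: int = 50
    max_dist: int = 50_000
    promoter_halfwidth: int = 2_500
    cpg_cutoff: float = 0.6
    threshold_frac: float = 0.8
    top_fraction: float = 0.70
    max_path_len: int = 2
    n_permutations: int = 50
    stages: tuple[str, ...] = _ALL_STAGES
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict[str, str]
    stages_run: list[str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages on a synthetic bundle.

    With ``simulate`` (the default) the inputs are generated from
    ``config.seed``; artifacts and a manifest land in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        raise NotImplementedError(
            "external-input runs go through the per-stage CLI commands; "
            "the umbrella pipeline drives the synthetic bundle"
        )
    syn_cfg = synthetic.SyntheticConfig(seed=config.seed, **config.synthetic)
    bundle = synthetic.build_bundle(syn_cfg)
    ofio.write_bundle(bundle, out / "inputs")
    stages_run: list[str] = []
    artifacts: list[Path] = []

    tf_table = None
    if "regulation" in config.stages:
        enrichments = []
        diff = [p for p in bundle.peaks if p.fdr < config.fdr]
        fg = {p.id: bundle.peak_sequences[p.id] for p in diff}
        bg = dict(bundle.peak_sequences)
        for pwm in bundle.pwms:
            enrichments.append(
                regulation.motif_enrichment(
                    fg, bg, pwm, threshold_frac=config.threshold_frac,
                    peak_class="als_open",
                )
            )
        frame = pd.DataFrame([dataclasses.asdict(e) for e in enrichments])
        path = out / "motif_enrichment.tsv"
        ofio.write_table(frame, path)
        artifacts.append(path)
        tf_table = pd.DataFrame(
            [{"id": e.motif_id, "fdr": e.p} for e in enrichments if e.p < config.fdr]
        )
        stages_run.append("regulation")

    params = pcsf.Hyperparameters(
        beta=config.beta,
        omega=config.omega,
        alpha=config.alpha,
        noise_sd=config.noise_sd,
        reps=config.reps,
        top_k=config.top_k,
    )
    solution = None
    if "pcsf" in config.stages:
        prizes = bundle.prizes
        solution = pcsf.solve_pcsf(
            bundle.interactome, prizes, params, seed=config.seed
        )
        edges = pd.DataFrame(solution.edges, columns=["node_a", "node_b"])
        path = out / "forest_edges.tsv"
        ofio.write_table(edges, path)
        summary = {
            "nodes": list(solution.nodes),
            "n_trees": solution.n_trees,
            "objective": solution.objective,
            "provenance": solution.provenance,
        }
        spath = out / "forest_summary.json"
        spath.write_text(json.dumps(summary, indent=1, sort_keys=True))
        artifacts.extend([path, spath])
        stages_run.append("pcsf")

    if "ensembles" in config.stages:
        robustness = pcsf.robustness_ensemble(
            bundle.interactome, bundle.prizes, params,
            seed=synthetic.stage_seed(config.seed, "robustness"),
        )
        specificity = pcsf.specificity_ensemble(
            bundle.interactome, bundle.prizes, params,
            seed=synthetic.stage_seed(config.seed, "specificity"),
        )
        frame = pd.DataFrame(
            {
                "node": sorted(robustness.inclusion_frequency),
                "inclusion_frequency": [
                    robustness.inclusion_frequency[v]
                    for v in sorted(robustness.inclusion_frequency)
                ],
                "specificity_frequency": [
                    specificity[v] for v in sorted(robustness.inclusion_frequency)
                ],
                "selected": [
                    v in set(robustness.selected)
                    for v in sorted(robustness.inclusion_frequency)
                ],
            }
        )
        path = out / "ensembles.tsv"
        ofio.write_table(frame, path)
        artifacts.append(path)
        stages_run.append("ensembles")

    if "stats" in config.stages:
        null = stats.permutation_de_null(
            bundle.rna_counts,
            bundle.rna_labels,
            n_permutations=config.n_permutations,
            seed=synthetic.stage_seed(config.seed, "perm-null"),
            fdr=config.fdr,
        )
        report = {
            "observed_deg_count": null.observed,
            "empirical_p": stats.empirical_p(null, "conservative"),
        }
        if solution is not None:
            de = stats.simple_de(bundle.rna_counts, bundle.rna_labels, fdr=config.fdr)
            degs = set(de.index[de["is_de"]])
            background = set(bundle.rna_counts.index)
            net_nodes = set(solution.nodes) & background
            if net_nodes:
                overlap = stats.fisher_overlap(net_nodes, degs, background)
                report["network_deg_overlap"] = dataclasses.asdict(overlap)
        path = out / "validation_stats.json"
        path.write_text(json.dumps(report, indent=1, sort_keys=True))
        artifacts.append(path)
        stages_run.append("stats")

    if "fly" in config.stages:
        per_fly: dict[str, float | None] = {}
        for fly_gene, grp in bundle.fly_screen.groupby("fly_gene"):
            reps = [
                list(rep_grp["score"])
                for _, rep_grp in grp.groupby("replicate")
            ]
            rec = flymod.average_eye_score(str(fly_gene), reps)
            per_fly[str(fly_gene)] = rec.rounded_score
        labels = []
        directions = bundle.truth["protein_directions"]
        for gene in sorted(bundle.ortholog_map.mapping):
            ws = flymod.weighted_eye_score(gene, bundle.ortholog_map, per_fly)
            call = flymod.call_modifier(gene, ws)
            if call.call == "untestable":
                continue
            labels.append(flymod.classify_gene(directions[gene], call))
        interactions = [
            flymod.DirectedInteraction(r.source, r.target, int(r.sign))
            for r in bundle.directed_interactions.itertuples()
        ]
        mean_expr = bundle.normalized_expression.mean(axis=1).to_dict()
        expressed = flymod.expression_filter(mean_expr, config.top_fraction)
        network = flymod.build_concordant_network(
            labels, interactions, expressed, directions, config.max_path_len
        )
        frame = pd.DataFrame(
            [{"human_gene": l.human_gene, "direction": l.protein_direction,
              "label": l.label} for l in labels]
        )
        lpath = out / "fly_labels.tsv"
        ofio.write_table(frame, lpath)
        npath = out / "concordant_network.json"
        npath.write_text(
            json.dumps(
                {
                    "nodes": sorted(network.nodes),
                    "edges": sorted(list(e) for e in network.edges),
                    "paths": [list(p) for p in network.paths],
                    "labels": network.labels,
                },
                indent=1,
                sort_keys=True,
            )
        )
        artifacts.extend([lpath, npath])
        stages_run.append("fly")

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        checksums={p.name: _checksum(p) for p in artifacts},
        stages_run=stages_run,
    )
    manifest.write(out / "manifest.json")
    return manifest
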