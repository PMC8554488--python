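"""Synthetic multi-omic bundles with planted ground truth.

Every input the integration pipeline consumes can be generated here with
known truth labels: a scale-free interactome with a planted high-prize
connected module, negative-binomial RNA counts with condition effects,
a differential protein table, peak sequences with planted motif
occurrences and bimodal CpG structure, genotypes with planted
expression-linked variants, signed directed pathway edges, and a fly
eye-score screen with planted causal/compensatory genes.

All randomness flows from one root seed. Each stage derives its own
sub-seed by hashing ``"<seed>:<stage name>"`` (SHA-256, first 4 bytes,
mod 2^31), so stages are independently reproducible and reordering one
stage never perturbs another.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .fly import OrthologMap
from .pcsf import Interactome, PrizeMap
from .regulation import PWM, GeneAnnotation, GenomicInterval, Peak

__all__ = [
    "SyntheticConfig",
    "OmicsBundle",
    "stage_seed",
    "generate_interactome",
    "plant_disease_module",
    "generate_expression",
    "generate_peaks_and_sequences",
    "generate_fly_screen",
    "generate_genotypes",
    "build_bundle",
]


def stage_seed(seed: int, stage: str) -> int:
    """Sub-seed for a named stage: SHA-256 of "seed:stage", 4 bytes, mod 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with defaults at desk scale.

    Sample sizes mirror the study design (a handful of iPSC lines per
    condition); noise and effect sizes are calibration choices discussed
    in docs/methods.md.
    """

    seed: int = 0
    n_genes: int = 1000
    n_samples_per_group: int = 4
    n_nodes: int = 300
    attachment_m: int = 2
    module_size: int = 15
    prize_effect: float = 5.0
    confidence_range: tuple[float, float] = (0.3, 0.95)
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    lfc_sd: float = 1.0
    n_peaks: int = 200
    peak_len: int = 200
    motif_plant_rate: float = 0.8
    n_variants: int = 100
    eqtl_effect: float = 1.5
    fly_frac_causal: float = 0.15
    fly_frac_comp: float = 0.10

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes,
            n_samples_per_group=self.n_samples_per_group,
            n_nodes=self.n_nodes,
            attachment_m=self.attachment_m,
            module_size=self.module_size,
            n_peaks=self.n_peaks,
            peak_len=self.peak_len,
            n_variants=self.n_variants,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("de_fraction", "motif_plant_rate", "fly_frac_causal", "fly_frac_comp"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.fly_frac_causal + self.fly_frac_comp > 1:
            raise ValueError("causal and compensatory fractions must sum to <= 1")
        lo, hi = self.confidence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("confidence_range must lie within (0, 1]")
        if self.prize_effect <= 0 or self.nb_dispersion <= 0 or self.lfc_sd <= 0:
            raise ValueError("effect and noise scales must be positive")
        if self.n_nodes < self.attachment_m + 1:
            raise ValueError("need n_nodes >= attachment_m + 1")
        if self.module_size > self.n_nodes:
            raise ValueError("module_size cannot exceed n_nodes")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_interactome(config: SyntheticConfig) -> Interactome:
    """Scale-free-like interactome by preferential attachment.

    The seed graph is a complete graph on ``attachment_m`` nodes; every
    further node attaches to ``attachment_m`` distinct existing nodes
    with probability proportional to degree, giving exactly
    m*(n - m) + C(m, 2) edges. Confidences are uniform on
    ``confidence_range``.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "interactome"))
    n, m = config.n_nodes, config.attachment_m
    ids = _gene_ids(n)
    edges: list[tuple[str, str]] = []
    repeated: list[int] = []
    for i in range(m):
        for j in range(i + 1, m):
            edges.append((ids[i], ids[j]))
            repeated.extend([i, j])
    if m == 1:
        repeated.append(0)
    for new in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            pick = int(repeated[rng.integers(len(repeated))])
            targets.add(pick)
        for t in sorted(targets):
            edges.append((ids[t], ids[new]))
            repeated.extend([t, new])
    lo, hi = config.confidence_range
    confs = lo + (hi - lo) * rng.random(len(edges))
    return Interactome((u, v, float(s)) for (u, v), s in zip(edges, confs))


def plant_disease_module(
    interactome: Interactome, config: SyntheticConfig
) -> tuple[PrizeMap, set[str]]:
    """Plant a connected prized module by random BFS from a random node.

    Module nodes receive prizes |Normal(prize_effect, prize_effect/4)|
    (folded normal); all other nodes get prize zero.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "module"))
    nodes = interactome.nodes
    start = nodes[int(rng.integers(len(nodes)))]
    visited = [start]
    seen = {start}
    frontier = [start]
    while frontier and len(visited) < config.module_size:
        node = frontier.pop(0)
        nbrs = sorted(interactome.graph.neighbors(node))
        rng.shuffle(nbrs)
        for nbr in nbrs:
            if nbr not in seen:
                seen.add(nbr)
                visited.append(nbr)
                frontier.append(nbr)
                if len(visited) == config.module_size:
                    break
    if len(visited) < config.module_size:
        raise RuntimeError(
            f"could not grow a connected module of size {config.module_size}"
        )
    truth = set(visited)
    draws = np.abs(
        rng.normal(config.prize_effect, config.prize_effect / 4, len(visited))
    )
    prizes = {v: float(p) for v, p in zip(visited, draws)}
    provenance = {v: "protein" for v in visited}
    return PrizeMap(prizes=prizes, provenance=provenance), truth


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[str], set[str]]:
    """Negative-binomial RNA counts with planted condition effects.

    Baseline means are log-normal; a ``de_fraction`` of genes receive a
    group log2 fold change drawn Normal(0, lfc_sd) and truncated away
    from zero (|lfc| >= 0.25) so the planted differential set is
    unambiguous. Counts have variance mu + mu^2 * nb_dispersion.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need at least two samples per group")
    rng = np.random.default_rng(stage_seed(config.seed, "expression"))
    genes = _gene_ids(config.n_genes)
    n_per = config.n_samples_per_group
    labels = ["CTR"] * n_per + ["ALS"] * n_per
    mu = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=config.n_genes)
    lfc = np.zeros(config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    for i in de_idx:
        draw = 0.0
        while abs(draw) < 0.25:
            draw = rng.normal(0.0, config.lfc_sd)
        lfc[i] = draw
    r = 1.0 / config.nb_dispersion
    counts = np.empty((config.n_genes, 2 * n_per), dtype=np.int64)
    for j in range(2 * n_per):
        mu_j = mu * np.where(np.array(labels)[j] == "ALS", 2.0**lfc, 1.0)
        p = r / (r + mu_j)
        counts[:, j] = rng.negative_binomial(r, p)
    frame = pd.DataFrame(
        counts, index=genes, columns=[f"S{j:02d}" for j in range(2 * n_per)]
    )
    truth = {genes[i] for i in de_idx}
    return frame, labels, truth


_MOTIF_CONSENSUS = "TGACGTCA"
_DECOY_CONSENSUS = "CATTCCAT"


def _pwm_from_consensus(motif_id: str, consensus: str, p_major: float = 0.85) -> PWM:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - p_major) / 3)
    for i, b in enumerate(consensus):
        mat[i, base_idx[b]] = p_major
    return PWM(motif_id=motif_id, matrix=mat)


def _random_seq(rng: np.random.Generator, length: int, p_g_after_c: float) -> str:
    """Markov sequence with controlled CpG dinucleotide rate.

    After a C the next base is G with probability ``p_g_after_c`` (the
    rest uniform); elsewhere bases are uniform. Low values emulate the
    genomic CpG depletion outside islands.
    """
    bases = "ACGT"
    out = []
    prev = ""
    for _ in range(length):
        if prev == "C":
            if rng.random() < p_g_after_c:
                ch = "G"
            else:
                ch = "ACT"[int(rng.integers(3))]
        else:
            ch = bases[int(rng.integers(4))]
        out.append(ch)
        prev = ch
    return "".join(out)


def generate_peaks_and_sequences(
    config: SyntheticConfig,
) -> tuple[list[Peak], dict[str, str], list[PWM], dict]:
    """Peak set with planted motif occurrences and bimodal CpG classes.

    Half the peaks are high-CpG (CpG-island-like transition structure),
    half low-CpG. Half are differential (small FDR, signed lfc); the
    planted motif consensus is inserted into differential peaks at
    ``motif_plant_rate``. A decoy motif is never planted.
    """
    pwm = _pwm_from_consensus("MOTIF1", _MOTIF_CONSENSUS)
    decoy = _pwm_from_consensus("MOTIF2", _DECOY_CONSENSUS)
    if config.peak_len < len(pwm):
        raise ValueError("peak_len must be at least the motif length")
    rng = np.random.default_rng(stage_seed(config.seed, "peaks"))
    peaks: list[Peak] = []
    sequences: dict[str, str] = {}
    high_cpg: set[str] = set()
    differential: set[str] = set()
    planted: set[str] = set()
    spacing = config.peak_len + 100
    for i in range(config.n_peaks):
        pid = f"peak{i:05d}"
        is_high = i % 2 == 0
        is_diff = (i // 2) % 2 == 0
        seq = _random_seq(
            rng, config.peak_len, p_g_after_c=0.45 if is_high else 0.03
        )
        if is_diff and rng.random() < config.motif_plant_rate:
            pos = int(rng.integers(config.peak_len - len(_MOTIF_CONSENSUS) + 1))
            seq = seq[:pos] + _MOTIF_CONSENSUS + seq[pos + len(_MOTIF_CONSENSUS):]
            planted.add(pid)
        start = 1000 + i * spacing
        lfc = float(rng.normal(1.5 if is_diff else 0.0, 0.3)) * (
            1 if i % 4 < 2 else -1
        )
        peaks.append(
            Peak(
                interval=GenomicInterval("chr1", start, start + config.peak_len),
                id=pid,
                lfc=lfc if is_diff else 0.0,
                fdr=float(rng.uniform(0.0, 0.05)) if is_diff else float(rng.uniform(0.3, 1.0)),
            )
        )
        sequences[pid] = seq
        if is_high:
            high_cpg.add(pid)
        if is_diff:
            differential.add(pid)
    truth = {
        "high_cpg_peaks": high_cpg,
        "differential_peaks": differential,
        "motif_planted_peaks": planted,
        "planted_motif_id": "MOTIF1",
    }
    return peaks, sequences, [pwm, decoy], truth


def generate_fly_screen(
    config: SyntheticConfig,
    protein_directions: dict[str, str],
) -> tuple[OrthologMap, pd.DataFrame, dict[str, str]]:
    """Fly screen with planted causal/compensatory genes.

    Causal genes get a rough-eye score opposing their protein direction
    under the classification rule (up -> suppressor near -2, down ->
    enhancer near +2); compensatory genes the reverse; all others score
    near 0. Each human gene maps to 1-3 fly orthologs with DIOPT-like
    weights; replicate noise is added per biological replicate and
    scores are clipped to [-4, 4].
    """
    rng = np.random.default_rng(stage_seed(config.seed, "fly"))
    genes = sorted(protein_directions)
    n = len(genes)
    n_causal = int(round(config.fly_frac_causal * n))
    n_comp = int(round(config.fly_frac_comp * n))
    order = list(rng.permutation(n))
    causal = {genes[i] for i in order[:n_causal]}
    comp = {genes[i] for i in order[n_causal : n_causal + n_comp]}
    mapping: dict[str, list[tuple[str, float, str]]] = {}
    rows: list[dict] = []
    truth: dict[str, str] = {}
    fly_counter = 0
    for gene in genes:
        direction = protein_directions[gene]
        if gene in causal:
            base = -2.0 if direction == "up" else 2.0
            truth[gene] = "causal"
        elif gene in comp:
            base = 2.0 if direction == "up" else -2.0
            truth[gene] = "compensatory"
        else:
            base = float(rng.uniform(-0.4, 0.4))
            truth[gene] = "non-contributory"
        n_orth = int(rng.integers(1, 4))
        orths = []
        for k in range(n_orth):
            fly_gene = f"Dmel{fly_counter:04d}"
            fly_counter += 1
            rank = "high" if k == 0 else str(rng.choice(["high", "moderate", "low"]))
            weight = float(rng.uniform(5.0, 15.0))
            orths.append((fly_gene, weight, rank))
            for rep in range(1, 4):
                for fly in range(1, 4):
                    score = float(np.clip(base + rng.normal(0.0, 0.15), -4, 4))
                    rows.append(
                        {
                            "fly_gene": fly_gene,
                            "replicate": rep,
                            "fly_id": fly,
                            "score": score,
                        }
                    )
        mapping[gene] = orths
    screen = pd.DataFrame(rows)
    return OrthologMap(mapping=mapping), screen, truth


def generate_genotypes(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Variant dosage matrix in {0,1,2} plus planted expression-linked pairs.

    Minor allele frequencies are uniform on [0.1, 0.5]; one in ten
    variants (at least one) is linked to a gene, and
    :func:`build_bundle` adds ``eqtl_effect * dosage`` to that gene's
    normalized expression.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "genotypes"))
    n_samples = 2 * config.n_samples_per_group
    variants = [f"var{i:04d}" for i in range(config.n_variants)]
    maf = rng.uniform(0.1, 0.5, size=config.n_variants)
    geno = rng.binomial(2, maf[:, None], size=(config.n_variants, n_samples))
    frame = pd.DataFrame(
        geno, index=variants, columns=[f"S{j:02d}" for j in range(n_samples)]
    )
    genes = _gene_ids(config.n_genes)
    n_links = max(1, config.n_variants // 10)
    var_idx = rng.choice(config.n_variants, size=n_links, replace=False)
    gene_idx = rng.choice(config.n_genes, size=n_links, replace=False)
    pairs = [(genes[g], variants[v]) for g, v in zip(gene_idx, var_idx)]
    return frame, pairs


def _log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).astype(float)
    return np.log2(counts.div(lib, axis=1) * 1e6 + 0.5)


@dataclass
class OmicsBundle:
    """Every pipeline input plus the planted truth labels."""

    config: SyntheticConfig
    interactome: Interactome
    prizes: PrizeMap
    rna_counts: pd.DataFrame
    rna_labels: list[str]
    normalized_expression: pd.DataFrame
    protein_table: pd.DataFrame
    peaks: list[Peak]
    peak_sequences: dict[str, str]
    pwms: list[PWM]
    gene_annotations: list[GeneAnnotation]
    genotypes: pd.DataFrame
    ortholog_map: OrthologMap
    fly_screen: pd.DataFrame
    directed_interactions: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        """Schema check: every planted-truth id resolves in its table."""
        import networkx as nx

        module = self.truth["module_nodes"]
        sub = self.interactome.graph.subgraph(module)
        if not nx.is_connected(sub):
            raise AssertionError("planted module is not connected")
        if not set(self.truth["de_genes"]) <= set(self.rna_counts.index):
            raise AssertionError("planted DE gene missing from count matrix")
        peak_ids = {p.id for p in self.peaks}
        for key in ("high_cpg_peaks", "differential_peaks", "motif_planted_peaks"):
            if not set(self.truth[key]) <= peak_ids:
                raise AssertionError(f"planted {key} id missing from peak list")
        for gene, variant in self.truth["eqtl_pairs"]:
            if gene not in self.normalized_expression.index:
                raise AssertionError(f"eQTL gene {gene} missing")
            if variant not in self.genotypes.index:
                raise AssertionError(f"eQTL variant {variant} missing")
        for gene in self.truth["fly_labels"]:
            if gene not in self.ortholog_map.mapping:
                raise AssertionError(f"fly-screen gene {gene} missing orthologs")


def build_bundle(config: SyntheticConfig) -> OmicsBundle:
    """Generate the full synthetic study; pure function of the config."""
    rng = np.random.default_rng(stage_seed(config.seed, "bundle"))
    interactome = generate_interactome(config)
    prizes, module_truth = plant_disease_module(interactome, config)
    counts, labels, de_truth = generate_expression(config)
    peaks, sequences, pwms, peak_truth = generate_peaks_and_sequences(config)
    genotypes, eqtl_pairs = generate_genotypes(config)

    # differential protein table: the planted module is strongly differential
    genes = list(counts.index)
    rows = []
    for gene in genes[: config.n_nodes]:
        if gene in module_truth:
            lfc = float(rng.normal(0, 1))
            lfc = math.copysign(max(abs(lfc), 0.6), lfc if lfc != 0 else 1)
            fdr = float(rng.uniform(0, 0.01))
        else:
            lfc = float(rng.normal(0, 0.2))
            fdr = float(rng.uniform(0.2, 1.0))
        rows.append({"id": gene, "log2fc": lfc, "fdr": fdr})
    protein_table = pd.DataFrame(rows)

    # gene TSS annotations along chr1, interleaved with the peaks
    annotations = [
        GeneAnnotation(gene_id=g, chrom="chr1", tss=500 + i * 700, strand="+")
        for i, g in enumerate(genes)
    ]

    normalized = _log_cpm(counts)
    for gene, variant in eqtl_pairs:
        normalized.loc[gene] = (
            normalized.loc[gene] + config.eqtl_effect * genotypes.loc[variant]
        )

    directions = {
        row["id"]: ("up" if row["log2fc"] > 0 else "down")
        for _, row in protein_table.iterrows()
        if row["fdr"] < 0.1
    }
    ortholog_map, fly_screen, fly_truth = generate_fly_screen(config, directions)

    # signed directed pathway edges among measured genes; a planted
    # fraction are concordant with the protein directions
    fly_genes = sorted(directions)
    edges = []
    if len(fly_genes) >= 2:
        for _ in range(max(10, 4 * len(fly_genes))):
            i, j = rng.choice(len(fly_genes), size=2, replace=False)
            u, v = fly_genes[int(i)], fly_genes[int(j)]
            if rng.random() < 0.7:  # concordant edge
                sign = 1 if directions[u] == directions[v] else -1
            else:
                sign = -1 if directions[u] == directions[v] else 1
            edges.append({"source": u, "target": v, "sign": sign})
    directed = pd.DataFrame(edges).drop_duplicates(
        subset=["source", "target"]
    ) if edges else pd.DataFrame(columns=["source", "target", "sign"])

    truth = {
        "module_nodes": module_truth,
        "de_genes": de_truth,
        "eqtl_pairs": eqtl_pairs,
        "fly_labels": fly_truth,
        "protein_directions": directions,
        **peak_truth,
    }
    bundle = OmicsBundle(
        config=config,
        interactome=interactome,
        prizes=prizes,
        rna_counts=counts,
        rna_labels=labels,
        normalized_expression=normalized,
        protein_table=protein_table,
        peaks=peaks,
        peak_sequences=sequences,
        pwms=pwms,
        gene_annotations=annotations,
        genotypes=genotypes,
        ortholog_map=ortholog_map,
        fly_screen=fly_screen,
        directed_interactions=directed,
        truth=truth,
    )
    bundle.validate()
    return bundle
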