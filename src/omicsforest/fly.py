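"""Fly modifier-screen scoring and the causal/compensatory concordant-path network.

Knockdown of candidate genes in a fly eye model of the G4C2 repeat
expansion yields a rough-eye modification index per cross, from -4
(complete rescue) to +4 (no eye). Scores are averaged over replicates,
rounded to the nearest half point, aggregated from fly orthologs to
human genes by DIOPT-weighted averaging, and crossed with the human
protein direction to label genes causal, compensatory, or
non-contributory. Labeled genes are then connected through signed
directed pathway edges by short paths that are concordant with the
measured protein directions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EyeScoreRecord",
    "OrthologMap",
    "ModifierCall",
    "CausalLabel",
    "DirectedInteraction",
    "ConcordantPathNetwork",
    "average_eye_score",
    "weighted_eye_score",
    "call_modifier",
    "classify_gene",
    "filter_experiments",
    "expression_filter",
    "build_concordant_network",
]

LETHAL = "lethal"


@dataclass(frozen=True)
class EyeScoreRecord:
    """Averaged rough-eye score for one fly experiment.

    ``mean_score``/``rounded_score`` are None when any replicate was
    lethal (no progeny eclosed).
    """

    fly_gene: str
    replicate_means: tuple[float | str, ...]
    mean_score: float | None
    rounded_score: float | None

    @property
    def is_lethal(self) -> bool:
        return self.mean_score is None


@dataclass(frozen=True)
class ModifierCall:
    human_gene: str
    weighted_score: float | None
    call: str  # suppressor | enhancer | none | lethal | untestable


@dataclass(frozen=True)
class CausalLabel:
    human_gene: str
    protein_direction: str  # up | down
    label: str  # causal | compensatory | non-contributory


@dataclass(frozen=True)
class DirectedInteraction:
    source: str
    target: str
    sign: int  # +1 activating, -1 inhibiting

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class ConcordantPathNetwork:
    """Union of concordant short paths between causal/compensatory genes."""

    nodes: set[str]
    edges: set[tuple[str, str, int]]
    paths: list[tuple[str, ...]]
    labels: dict[str, str]
    dropped_missing_sign: int = 0


def _round_half(x: float) -> float:
    """Round to the nearest 0.5, halves away from zero."""
    return math.copysign(math.floor(abs(x) * 2 + 0.5) / 2, x)


def average_eye_score(
    fly_gene: str, replicates: Sequence[Sequence[float] | str]
) -> EyeScoreRecord:
    """Average per-replicate fly scores, then average replicates and round.

    Each replicate is a list of per-fly scores in [-4, 4], or the string
    'lethal' when the cross failed to eclose; one lethal replicate makes
    the whole record lethal.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    rep_means: list[float | str] = []
    lethal = False
    for rep in replicates:
        if isinstance(rep, str):
            if rep != LETHAL:
                raise ValueError(f"unknown replicate marker {rep!r}")
            rep_means.append(LETHAL)
            lethal = True
            continue
        if not rep:
            raise ValueError("replicate must contain at least one fly score")
        if any(abs(s) > 4 for s in rep):
            raise ValueError("fly scores must lie in [-4, 4]")
        rep_means.append(sum(rep) / len(rep))
    if lethal:
        return EyeScoreRecord(fly_gene, tuple(rep_means), None, None)
    mean = sum(rep_means) / len(rep_means)  # type: ignore[arg-type]
    return EyeScoreRecord(fly_gene, tuple(rep_means), mean, _round_half(mean))


@dataclass
class OrthologMap:
    """human gene -> [(fly_gene, diopt_weight, rank)], rank in {high, moderate, low}."""

    mapping: dict[str, list[tuple[str, float, str]]] = field(default_factory=dict)

    def retained(self, human_gene: str) -> list[tuple[str, float]]:
        """Orthologs kept for scoring: only high/moderate DIOPT rank."""
        out = []
        for fly_gene, weight, rank in self.mapping.get(human_gene, []):
            if rank in ("high", "moderate"):
                if weight <= 0:
                    raise ValueError(f"nonpositive weight for {fly_gene!r}")
                out.append((fly_gene, weight))
        return out


def weighted_eye_score(
    human_gene: str,
    ortholog_map: OrthologMap,
    fly_scores: Mapping[str, float | None],
) -> float | None:
    """DIOPT-weighted average of fly ortholog scores for one human gene.

    Low-rank orthologs and lethal (None) scores are excluded; returns
    None when no scorable ortholog remains (flagged untestable upstream).
    """
    num = 0.0
    denom = 0.0
    for fly_gene, weight in ortholog_map.retained(human_gene):
        score = fly_scores.get(fly_gene)
        if score is None:
            continue
        num += weight * score
        denom += weight
    if denom == 0:
        return None
    return num / denom


def call_modifier(
    human_gene: str,
    weighted_score: float | None,
    threshold: float = 1.0,
) -> ModifierCall:
    """Classify a weighted eye score as suppressor (<= -1), enhancer (>= +1), or none.

    Negative scores rescue the eye (knockdown suppresses degeneration);
    positive scores worsen it.
    """
    if weighted_score is None:
        return ModifierCall(human_gene, None, "untestable")
    if weighted_score <= -threshold:
        call = "suppressor"
    elif weighted_score >= threshold:
        call = "enhancer"
    else:
        call = "none"
    return ModifierCall(human_gene, weighted_score, call)


def classify_gene(protein_direction: str, modifier: ModifierCall) -> CausalLabel:
    """Cross protein direction with the fly modifier call.

    A gene up in ALS whose knockdown rescues the eye (suppressor) was
    driving toxicity: causal. Up + enhancer means the change was
    protective: compensatory. Directions invert for genes down in ALS;
    'none' calls are non-contributory. Lethal records are excluded
    before this step.
    """
    if protein_direction not in ("up", "down"):
        raise ValueError(f"unknown protein direction {protein_direction!r}")
    if modifier.call == "lethal":
        raise ValueError("lethal records are excluded from classification")
    if modifier.call == "none":
        label = "non-contributory"
    elif modifier.call == "suppressor":
        label = "causal" if protein_direction == "up" else "compensatory"
    elif modifier.call == "enhancer":
        label = "compensatory" if protein_direction == "up" else "causal"
    else:
        raise ValueError(f"cannot classify modifier call {modifier.call!r}")
    return CausalLabel(modifier.human_gene, protein_direction, label)


def filter_experiments(
    experiments: Iterable[Mapping],
) -> tuple[list[Mapping], dict[str, int]]:
    """Drop lethal crosses and non-modifiers flagged by the control cross.

    Each experiment record carries boolean flags ``lethal`` and
    ``not_modifier`` (the latter determined externally from the
    driver-only control cross); a record failing either flag is removed
    once even if it fails both. Returns (kept, report counts).
    """
    kept = []
    n_lethal = n_not_modifier = n_both = 0
    for rec in experiments:
        lethal = bool(rec.get("lethal", False))
        notmod = bool(rec.get("not_modifier", False))
        if lethal:
            n_lethal += 1
        if notmod:
            n_not_modifier += 1
        if lethal and notmod:
            n_both += 1
        if not (lethal or notmod):
            kept.append(rec)
    report = {
        "total": n_lethal + n_not_modifier - n_both + len(kept),
        "lethal": n_lethal,
        "not_modifier": n_not_modifier,
        "both": n_both,
        "removed": n_lethal + n_not_modifier - n_both,
        "remaining": len(kept),
    }
    return kept, report


def expression_filter(
    mean_expression: Mapping[str, float], top_fraction: float = 0.70
) -> set[str]:
    """Genes in the top fraction of mean normalized expression.

    Retains ceil(top_fraction * m) genes; ties at the cutoff value are
    all included.
    """
    if not mean_expression:
        raise ValueError("expression table must be non-empty")
    items = sorted(mean_expression.items(), key=lambda kv: (-kv[1], kv[0]))
    m = len(items)
    k = min(m, math.ceil(top_fraction * m))
    if k == 0:
        return set()
    cutoff = items[k - 1][1]
    return {g for g, v in items if v >= cutoff}


def _edge_concordant(
    u: str, v: str, sign: int, protein_signs: Mapping[str, str]
) -> bool | None:
    """Whether edge u->v with the given sign matches measured directions.

    An activating edge predicts target moves with the source; an
    inhibiting edge predicts it moves against. Returns None when either
    endpoint lacks a measured direction.
    """
    du = protein_signs.get(u)
    dv = protein_signs.get(v)
    if du is None or dv is None:
        return None
    return (dv == du) if sign == 1 else (dv != du)


def build_concordant_network(
    labels: Sequence[CausalLabel],
    interactions: Sequence[DirectedInteraction],
    expressed: set[str],
    protein_signs: Mapping[str, str],
    max_len: int = 2,
) -> ConcordantPathNetwork:
    """Connect causal/compensatory genes by concordant directed paths.

    For every ordered pair of distinct labeled genes, all simple directed
    paths with at most ``max_len`` edges are enumerated; a path survives
    only if every intermediate node is in the expressed set and every
    edge on it is sign-concordant with the measured protein directions
    (path endpoints are exempt from the expression filter — they are
    measured proteins). The returned network is the union of surviving
    paths.
    """
    if not labels:
        raise ValueError("need at least one labeled gene")
    terminal = sorted(
        {
            lab.human_gene
            for lab in labels
            if lab.label in ("causal", "compensatory")
        }
    )
    label_map = {lab.human_gene: lab.label for lab in labels}
    out_edges: dict[str, list[tuple[str, int]]] = {}
    for inter in interactions:
        out_edges.setdefault(inter.source, []).append((inter.target, inter.sign))

    dropped_missing = 0
    paths: list[tuple[str, ...]] = []
    edges: set[tuple[str, str, int]] = set()

    terminal_set = set(terminal)

    def record(path: list[str], signs: list[int]) -> None:
        paths.append(tuple(path))
        for (a, b), s in zip(itertools.pairwise(path), signs):
            edges.add((a, b, s))

    def extend(path: list[str], signs: list[int]) -> None:
        nonlocal dropped_missing
        node = path[-1]
        for nxt, sign in out_edges.get(node, []):
            if nxt in path:
                continue
            conc = _edge_concordant(node, nxt, sign, protein_signs)
            if conc is None:
                dropped_missing += 1
                continue
            if not conc:
                continue
            if nxt in terminal_set and nxt != path[0]:
                record(path + [nxt], signs + [sign])
            # continuing makes nxt an intermediate: it must be expressed
            if len(signs) + 1 < max_len and nxt in expressed:
                extend(path + [nxt], signs + [sign])

    for start in terminal:
        extend([start], [])

    nodes = {v for p in paths for v in p}
    return ConcordantPathNetwork(
        nodes=nodes,
        edges=edges,
        paths=sorted(paths),
        labels={v: label_map.get(v, "intermediate") for v in nodes},
        dropped_missing_sign=dropped_missing,
    )
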