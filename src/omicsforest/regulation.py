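"""Transcription-factor inference from chromatin accessibility.

ATAC peaks are assigned to the nearest gene TSS, partitioned into
proximal/distal and high/low CpG classes, scanned with position weight
matrices, and tested for motif enrichment in differential peak classes
relative to a background; enriched motifs are then checked for
concordance with the TF's own transcript fold change.

The CpG metric is the observed/expected CpG dinucleotide ratio
(#CG x length / (#C x #G)) with a default high/low cutoff of 0.6; both
are configurable (see docs/methods.md for why this particular normalized
metric was adopted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import stats as ofstats

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneAnnotation",
    "PWM",
    "MotifEnrichmentResult",
    "PeakAssignment",
    "annotate_peak_to_gene",
    "cpg_observed_expected",
    "partition_by_cpg",
    "scan_pwm",
    "motif_enrichment",
    "tf_activity_concordance",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class Peak:
    """An accessibility peak with its differential statistics."""

    interval: GenomicInterval
    id: str
    lfc: float = 0.0
    fdr: float = 1.0

    def direction(self, fdr_threshold: float = 0.1) -> str:
        """'als_open', 'ctr_open', or 'unchanged' at the given FDR."""
        if self.fdr < fdr_threshold:
            return "als_open" if self.lfc > 0 else "ctr_open"
        return "unchanged"


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be nonnegative")


@dataclass(frozen=True)
class PeakAssignment:
    gene_id: str
    distance: float
    is_promoter: bool


@dataclass
class PWM:
    """Position weight matrix of per-position base probabilities (A,C,G,T)."""

    motif_id: str
    matrix: np.ndarray  # length x 4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be length x 4")
        if len(self) < 4:
            raise ValueError("motif must span at least 4 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each position must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def consensus_score(self, background: Sequence[float] = (0.25,) * 4) -> float:
        bg = np.asarray(background)
        with np.errstate(divide="ignore"):
            lods = np.log2(np.maximum(self.matrix, 1e-9) / bg)
        return float(lods.max(axis=1).sum())


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p: float
    peak_class: str = ""


def annotate_peak_to_gene(
    peak: Peak,
    genes: Sequence[GeneAnnotation],
    max_dist: int = 50_000,
    promoter_halfwidth: int = 2_500,
) -> PeakAssignment | None:
    """Assign a peak to the nearest gene TSS on the same chromosome.

    Distance is measured from the peak midpoint; assignments farther than
    ``max_dist`` return None, and an assignment within
    ``promoter_halfwidth`` is flagged as a promoter. Equidistant TSS ties
    go to the lexicographically smaller gene id.
    """
    mid = peak.interval.midpoint
    best: tuple[float, str] | None = None
    for gene in genes:
        if gene.chrom != peak.interval.chrom:
            continue
        d = abs(mid - gene.tss)
        if best is None or (d, gene.gene_id) < best:
            best = (d, gene.gene_id)
    if best is None or best[0] > max_dist:
        return None
    distance, gene_id = best
    return PeakAssignment(
        gene_id=gene_id,
        distance=distance,
        is_promoter=distance <= promoter_halfwidth,
    )


def cpg_observed_expected(sequence: str) -> float:
    """Observed/expected CpG ratio: (#CG dinucleotides x L) / (#C x #G).

    Returns 0 when the sequence contains no C or no G. Invariant under
    reverse complementation (CG is its own reverse complement and C/G
    counts swap).
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence alphabet must be A/C/G/T/N")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    return n_cg * len(seq) / (n_c * n_g)


def partition_by_cpg(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    cutoff: float = 0.6,
) -> tuple[list[Peak], list[Peak], list[str]]:
    """Split peaks into high-CpG (o/e >= cutoff) and low-CpG classes.

    Peaks without a sequence are skipped and reported in the third
    element. The two classes partition the peaks that have sequences.
    """
    high: list[Peak] = []
    low: list[Peak] = []
    skipped: list[str] = []
    for peak in peaks:
        seq = sequences.get(peak.id)
        if seq is None:
            skipped.append(peak.id)
            continue
        (high if cpg_observed_expected(seq) >= cutoff else low).append(peak)
    return high, low, skipped


def _window_scores(seq: str, pwm: PWM, background: np.ndarray) -> np.ndarray:
    L = len(pwm)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    with np.errstate(divide="ignore"):
        lods = np.log2(np.maximum(pwm.matrix, 1e-9) / background)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mapping = np.full(256, -1, dtype=int)
    for base, i in _BASE_INDEX.items():
        mapping[ord(base)] = i
    idx = mapping[arr]
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for offset in range(L):
        col = idx[offset : offset + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, lods[offset, np.clip(col, 0, 3)], 0.0)
    scores[~valid] = -np.inf  # windows containing N never hit
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_threshold: float,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> int:
    """Count log-odds windows scoring >= threshold on both strands.

    Windows are scored as sum of log2(p_pos(base)/background(base));
    overlapping hits count separately; a sequence shorter than the motif
    has zero hits.
    """
    seq = sequence.upper()
    bg = np.asarray(background, dtype=float)
    hits = 0
    for strand_seq in (seq, reverse_complement(seq)):
        scores = _window_scores(strand_seq, pwm, bg)
        hits += int(np.sum(scores >= score_threshold))
    return hits


def motif_enrichment(
    fg_sequences: Mapping[str, str],
    bg_sequences: Mapping[str, str],
    pwm: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    peak_class: str = "",
) -> MotifEnrichmentResult:
    """One-sided hypergeometric enrichment of motif-hit peaks in the foreground.

    A peak is a binary "hit" when it has >= 1 window above threshold
    (default: ``threshold_frac`` of the consensus score). The foreground
    must be a subset of the background universe; p is the upper tail of
    Hypergeometric(bg_total, bg_hits, fg_total) at fg_hits.
    """
    if not fg_sequences:
        raise ValueError("foreground must be non-empty")
    if not set(fg_sequences) <= set(bg_sequences):
        raise ValueError("foreground ids must be contained in the background")
    if threshold is None:
        threshold = threshold_frac * pwm.consensus_score(background)
    bg_hit_ids = {
        pid
        for pid, seq in bg_sequences.items()
        if scan_pwm(seq, pwm, threshold, background) > 0
    }
    fg_hits = sum(1 for pid in fg_sequences if pid in bg_hit_ids)
    p = ofstats.hypergeom_upper(
        fg_hits, len(bg_hit_ids), len(fg_sequences), len(bg_sequences)
    )
    return MotifEnrichmentResult(
        motif_id=pwm.motif_id,
        fg_hits=fg_hits,
        fg_total=len(fg_sequences),
        bg_hits=len(bg_hit_ids),
        bg_total=len(bg_sequences),
        p=p,
        peak_class=peak_class,
    )


def tf_activity_concordance(
    enrichments: Iterable[MotifEnrichmentResult],
    motif_to_gene: Mapping[str, str],
    rna_table: Mapping[str, tuple[float, float]],
) -> list[dict]:
    """Cross TF activity predictions with the TF's own transcript change.

    For each motif the peak class with the smallest enrichment p (ties:
    larger fg_hits, then the ALS class) determines the condition the TF
    is predicted active in; the prediction is concordant when the TF
    transcript moves the same way (ALS-active and RNA up, or CTR-active
    and RNA down). ``rna_table`` maps gene -> (lfc, fdr); TFs missing
    from it are flagged with concordant=None.
    """
    by_motif: dict[str, list[MotifEnrichmentResult]] = {}
    for res in enrichments:
        by_motif.setdefault(res.motif_id, []).append(res)
    out = []
    for motif_id in sorted(by_motif):
        results = by_motif[motif_id]

        def rank(r: MotifEnrichmentResult) -> tuple:
            is_als = r.peak_class.startswith("als")
            return (r.p, -r.fg_hits, 0 if is_als else 1)

        best = min(results, key=rank)
        active_in = "ALS" if best.peak_class.startswith("als") else "CTR"
        gene = motif_to_gene.get(motif_id)
        record: dict = {
            "motif_id": motif_id,
            "tf_gene": gene,
            "predicted_active_in": active_in,
            "best_class": best.peak_class,
            "best_p": best.p,
        }
        if gene is None or gene not in rna_table:
            record.update(rna_lfc=None, rna_fdr=None, concordant=None)
        else:
            lfc, fdr = rna_table[gene]
            concordant = (active_in == "ALS" and lfc > 0) or (
                active_in == "CTR" and lfc < 0
            )
            record.update(rna_lfc=lfc, rna_fdr=fdr, concordant=concordant)
        out.append(record)
    return out
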