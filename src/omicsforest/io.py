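"""Readers and writers for the pipeline's interchange formats.

TSV everywhere for tables ('.' as missing marker, UTF-8, opaque
case-sensitive ids), BED6 (+lfc, fdr columns) for peaks, FASTA for peak
sequences, JASPAR text for position weight matrices, JSON for truth
labels and reports. All round-trip bit-exactly for their schemas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fly import OrthologMap
from .pcsf import Interactome, PrizeMap
from .regulation import PWM, GenomicInterval, Peak, reverse_complement

__all__ = [
    "read_table",
    "write_table",
    "read_interactome",
    "write_interactome",
    "read_prizes",
    "write_prizes",
    "read_bed_fasta",
    "write_bed",
    "write_fasta",
    "read_jaspar",
    "write_jaspar",
    "read_ortholog_map",
    "write_ortholog_map",
    "write_bundle",
]


class SchemaError(ValueError):
    pass


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a TSV with a header, validating required columns and types.

    '.' cells are treated as missing. Malformed numeric cells raise a
    :class:`SchemaError` naming the column and (1-based data) row.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = set(schema) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for col, typ in schema.items():
        if typ in (float, int):
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise SchemaError(
                    f"{path}: malformed numeric value in column {col!r}, row {row}"
                )
            frame[col] = converted.astype(typ) if not converted.isna().any() else converted
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep=".")


def read_interactome(path: str | Path) -> Interactome:
    frame = read_table(path, {"node_a": str, "node_b": str, "confidence": float})
    return Interactome(
        (r.node_a, r.node_b, float(r.confidence)) for r in frame.itertuples()
    )


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    frame = pd.DataFrame(
        interactome.edges(), columns=["node_a", "node_b", "confidence"]
    )
    write_table(frame, path)


def read_prizes(path: str | Path) -> PrizeMap:
    frame = read_table(path, {"node": str, "prize": float, "provenance": str})
    return PrizeMap(
        prizes={r.node: float(r.prize) for r in frame.itertuples()},
        provenance={r.node: r.provenance for r in frame.itertuples()},
    )


def write_prizes(prizes: PrizeMap, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"node": v, "prize": p, "provenance": prizes.provenance.get(v, "none")}
            for v, p in sorted(prizes.prizes.items())
        ]
    )
    write_table(frame, path)


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6 with score=lfc plus an extra fdr column."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t{p.lfc:g}\t"
                f"{iv.strand if iv.strand in '+-' else '.'}\t{p.fdr:g}\n"
            )


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed_fasta(
    bed_path: str | Path, fasta_path: str | Path
) -> tuple[list[Peak], dict[str, str]]:
    """Load peaks from BED6(+fdr) and extract half-open sequences from FASTA.

    The FASTA is keyed by chromosome name; minus-strand intervals are
    reverse-complemented. Out-of-bounds or zero-length intervals raise
    with the offending interval id.
    """
    chroms = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    peaks: list[Peak] = []
    sequences: dict[str, str] = {}
    with open(bed_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise SchemaError(f"{bed_path}:{line_no}: need >= 4 BED fields")
            chrom, start, end, name = fields[:4]
            start, end = int(start), int(end)
            lfc = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            fdr = float(fields[6]) if len(fields) > 6 else 1.0
            if end <= start:
                raise SchemaError(f"interval {name!r} is empty or inverted")
            if chrom not in chroms:
                raise SchemaError(f"interval {name!r}: unknown sequence {chrom!r}")
            if end > len(chroms[chrom]):
                raise SchemaError(f"interval {name!r} out of bounds for {chrom!r}")
            seq = chroms[chrom][start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    id=name,
                    lfc=lfc,
                    fdr=fdr,
                )
            )
            sequences[name] = seq
    return peaks, sequences


def write_jaspar(pwms: Sequence[PWM], path: str | Path, pseudo_total: int = 100) -> None:
    """Write probability matrices as JASPAR count matrices (x pseudo_total)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            counts = np.round(pwm.matrix * pseudo_total).astype(int)
            for i, base in enumerate("ACGT"):
                row = " ".join(str(c) for c in counts[:, i])
                fh.write(f"{base}  [ {row} ]\n")


def read_jaspar(path: str | Path) -> list[PWM]:
    """Parse JASPAR-format matrices (via Biopython) into probability PWMs."""
    out = []
    with open(path) as fh:
        for motif in motifs.parse(fh, "jaspar"):
            counts = np.array(
                [[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)],
                dtype=float,
            )
            probs = counts / counts.sum(axis=1, keepdims=True)
            out.append(PWM(motif_id=motif.matrix_id or motif.name, matrix=probs))
    return out


def write_ortholog_map(mapping: OrthologMap, path: str | Path) -> None:
    rows = [
        {"human_gene": h, "fly_gene": f, "weight": w, "rank": r}
        for h, orths in sorted(mapping.mapping.items())
        for f, w, r in orths
    ]
    write_table(pd.DataFrame(rows), path)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    frame = read_table(
        path, {"human_gene": str, "fly_gene": str, "weight": float, "rank": str}
    )
    mapping: dict[str, list[tuple[str, float, str]]] = {}
    for r in frame.itertuples():
        mapping.setdefault(r.human_gene, []).append(
            (r.fly_gene, float(r.weight), r.rank)
        )
    return OrthologMap(mapping=mapping)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_bundle(bundle, out_dir: str | Path) -> dict[str, str]:
    """Write every table of a synthetic bundle; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    write_interactome(bundle.interactome, _p("interactome.tsv"))
    write_prizes(bundle.prizes, _p("prizes.tsv"))
    bundle.rna_counts.to_csv(_p("rna_counts.tsv"), sep="\t")
    with open(_p("rna_labels.txt"), "w") as fh:
        fh.write("\n".join(bundle.rna_labels) + "\n")
    write_table(bundle.protein_table, _p("proteins.tsv"))
    write_bed(bundle.peaks, _p("peaks.bed"))
    write_fasta(bundle.peak_sequences, _p("peaks.fasta"))
    write_jaspar(bundle.pwms, _p("motifs.jaspar"))
    bundle.genotypes.to_csv(_p("genotypes.tsv"), sep="\t")
    write_ortholog_map(bundle.ortholog_map, _p("orthologs.tsv"))
    write_table(bundle.fly_screen, _p("fly_screen.tsv"))
    write_table(bundle.directed_interactions, _p("directed_edges.tsv"))
    genes = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand}
            for g in bundle.gene_annotations
        ]
    )
    write_table(genes, _p("genes.tsv"))
    with open(_p("truth.json"), "w") as fh:
        json.dump(_jsonable(bundle.truth), fh, indent=1, sort_keys=True)
    return paths
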