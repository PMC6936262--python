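"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere; only the readers
  and writers convert (GTF-lite is 1-based inclusive, BED is native).
* For minus-strand genes the TSS is taken from the interval end, so the
  stored ``tss`` is the exclusive end coordinate of the annotated interval.
* Missing fold changes are allowed on input and propagated as NaN; the
  minimum-condition rule is enforced downstream in :mod:`plastiscope.gep`.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    FoldChangeMatrix,
    FormatError,
    GeneAnnotation,
    GenomicInterval,
    Pwm,
    ValidationError,
)

__all__ = [
    "read_fold_change_matrix",
    "write_fold_change_matrix",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_promoter_fasta",
    "write_promoter_fasta",
    "read_mapping_table",
    "read_obo_lite",
    "validate_file",
]


# ---------------------------------------------------------------------------
# fold-change matrices


def read_fold_change_matrix(
    path,
    missing_token: str = "NA",
    meta_path=None,
    blacklist=None,
) -> FoldChangeMatrix:
    """Read a gene x condition log2 fold-change TSV.

    The header row holds condition ids and the first column gene ids.
    Cells equal to ``missing_token`` become NaN.  ``blacklist`` is an
    optional iterable (or single-column file) of gene ids to drop at read
    time, e.g. operon members whose expression is not independently
    regulated.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene id(s) {dups}")
    values = df.replace(missing_token, np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    if blacklist is not None:
        if isinstance(blacklist, (str, Path)):
            blacklist = [
                line.strip()
                for line in Path(blacklist).read_text().splitlines()
                if line.strip()
            ]
        values = values.drop(index=[g for g in blacklist if g in values.index])
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return FoldChangeMatrix(values, meta)


def write_fold_change_matrix(fc: FoldChangeMatrix, path, missing_token: str = "NA"):
    fc.values.to_csv(path, sep="\t", na_rep=missing_token, index_label="gene_id")


# ---------------------------------------------------------------------------
# gene annotation


def _select_representative(records: list[GeneAnnotation]) -> list[GeneAnnotation]:
    by_gene: dict[str, GeneAnnotation] = {}
    for rec in records:
        cur = by_gene.get(rec.gene_id)
        if cur is None or rec.transcript_rank < cur.transcript_rank:
            by_gene[rec.gene_id] = rec
    return list(by_gene.values())


def read_gene_annotation(path, dialect: str = "gtf_lite") -> list[GeneAnnotation]:
    """Read gene annotation in ``gtf_lite`` or ``bed6`` dialect.

    gtf_lite: tab-separated ``gene_id chrom start end strand [rank]`` with
    1-based inclusive coordinates.  bed6: ``chrom start end name score
    strand`` with 0-based half-open coordinates; the BED score column is
    used as the transcript rank.  Multiple transcripts per gene collapse to
    the lowest rank (most abundant).
    """
    if dialect not in ("gtf_lite", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if dialect == "gtf_lite":
                gene_id, chrom, start, end, strand = parts[:5]
                rank = int(parts[5]) if len(parts) > 5 else 1
                start0, end0 = int(start) - 1, int(end)  # 1-based incl -> half-open
            else:
                chrom, start, end, gene_id = parts[:4]
                rank = int(float(parts[4])) if len(parts) > 4 and parts[4] != "." else 1
                strand = parts[5] if len(parts) > 5 else "+"
                start0, end0 = int(start), int(end)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
        if end0 <= start0:
            raise FormatError(f"{path}:{lineno}: end <= start")
        tss, tes = (start0, end0) if strand == "+" else (end0, start0)
        records.append(GeneAnnotation(gene_id, chrom, strand, tss, tes, rank))
    return _select_representative(records)


def write_gene_annotation(annotation, path, dialect: str = "gtf_lite"):
    lines = []
    for rec in annotation:
        start, end = rec.body
        if dialect == "gtf_lite":
            lines.append(
                f"{rec.gene_id}\t{rec.chrom}\t{start + 1}\t{end}\t{rec.strand}"
                f"\t{rec.transcript_rank}"
            )
        elif dialect == "bed6":
            lines.append(
                f"{rec.chrom}\t{start}\t{end}\t{rec.gene_id}"
                f"\t{rec.transcript_rank}\t{rec.strand}"
            )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# peaks


def read_bed_peaks(
    path, p_threshold: float | None = None, p_column: int | None = None
) -> list[GenomicInterval]:
    """Read BED peaks, optionally keeping only peaks with p < ``p_threshold``.

    ``p_column`` is the 0-based column index holding the peak p-value
    (ENCODE/Roadmap narrowPeak stores -log10 p in column 7; here a plain
    probability is expected).  Peaks with ``score_p >= p_threshold`` are
    dropped.
    """
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        score_p = None
        if p_column is not None and len(parts) > p_column and parts[p_column] != ".":
            score_p = float(parts[p_column])
        try:
            peak = GenomicInterval(chrom, start, end, score_p)
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if p_threshold is not None and score_p is not None and score_p >= p_threshold:
            continue
        peaks.append(peak)
    return peaks


def write_bed_peaks(peaks, path):
    lines = []
    for i, pk in enumerate(peaks):
        extra = f"\tpeak{i}\t0\t.\t{pk.score_p}" if pk.score_p is not None else ""
        lines.append(f"{pk.chrom}\t{pk.start}\t{pk.end}{extra}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motifs


def read_meme_motifs(path) -> list[Pwm]:
    """Parse MEME minimal motif format into position probability matrices.

    Rows off by more than 1e-1 from unit sum raise; rows within 1e-1 but
    beyond 1e-3 are renormalized with a warning; background defaults to
    uniform when the file lacks a background line.
    """
    text = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[Pwm] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = text[i].split()
            freqs = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freqs.get(b, 0.25) for b in "ACGT"])
            background = background / background.sum()
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(text) and not text[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(text):
                raise FormatError(f"{path}: motif {motif_id} has no matrix")
            rows = []
            i += 1
            while i < len(text):
                stripped = text[i].strip()
                fields = stripped.split()
                if not stripped or not _is_number(fields[0]):
                    break
                rows.append([float(x) for x in fields[:4]])
                i += 1
            matrix = np.array(rows, dtype=float)
            if (matrix < 0).any():
                raise FormatError(f"{path}: motif {motif_id}: negative probability")
            sums = matrix.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-1:
                raise FormatError(
                    f"{path}: motif {motif_id}: row sums deviate beyond 0.1"
                )
            if np.abs(sums - 1.0).max() > 1e-3:
                warnings.warn(
                    f"motif {motif_id}: renormalizing rows (max deviation "
                    f"{np.abs(sums - 1.0).max():.2g})"
                )
            matrix = matrix / sums[:, None]
            motifs.append(Pwm(motif_id, matrix, background.copy()))
            continue
        i += 1
    return motifs


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_meme_motifs(motifs, path, background=None):
    lines = ["MEME version 4", "", "ALPHABET= ACGT", ""]
    if background is not None:
        bg = np.asarray(background, float)
        lines += [
            "Background letter frequencies",
            " ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)),
            "",
        ]
    for pwm in motifs:
        lines.append(f"MOTIF {pwm.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0"
        )
        for row in pwm.matrix:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# promoter FASTA


def read_promoter_fasta(path) -> tuple[dict[str, str], dict[str, int]]:
    """Read promoter sequences keyed by gene id.

    Returns ``(sequences, offsets)``.  The record description may carry an
    ``offset=<int>`` token giving the position of the first base relative to
    the TSS in the direction of transcription (e.g. ``offset=-500``); genes
    without the token get no entry in ``offsets``.
    """
    seqs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate promoter record {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("offset="):
                offsets[rec.id] = int(token.split("=", 1)[1])
    return seqs, offsets


def write_promoter_fasta(sequences: dict[str, str], path, offset: int | None = None):
    with open(path, "w") as fh:
        for gene_id, seq in sequences.items():
            header = f">{gene_id}"
            if offset is not None:
                header += f" offset={offset}"
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# mapping tables


def read_mapping_table(path, kind: str):
    """Read one of the auxiliary mapping tables.

    kind:
      * ``orthologues`` — two-column TSV (species A id, species B id);
        restricted to one-to-one pairs, ids seen twice are dropped with a
        warning count.
      * ``gene_sets`` — TSV ``set_name<TAB>gene_id``; returns dict of lists.
      * ``disease`` — TSV ``gene_id<TAB>count``; returns Series.
      * ``ontology_annotations`` — TSV ``gene_id<TAB>term_id``; dict
        gene -> list of terms.
      * ``motif_clusters`` — TSV ``group<TAB>cluster_id<TAB>motif_id``;
        dict (group, cluster_id) -> list of motifs.
      * ``loops`` — TSV with six columns: chrom1 start1 end1 chrom2 start2
        end2; list of (anchor1, anchor2) GenomicInterval pairs.
    """
    if kind == "orthologues":
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
        dup_a = df["a"].duplicated(keep=False)
        dup_b = df["b"].duplicated(keep=False)
        dropped = int((dup_a | dup_b).sum())
        if dropped:
            warnings.warn(f"dropped {dropped} non one-to-one orthologue rows")
        return df[~(dup_a | dup_b)].reset_index(drop=True)
    if kind == "gene_sets":
        sets: dict[str, list[str]] = defaultdict(list)
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            name = parts[0]
            if len(parts) == 1 or not parts[1]:
                if name not in sets:
                    sets[name] = []
                    warnings.warn(f"gene set {name!r} is empty")
                continue
            sets[name].append(parts[1])
        return dict(sets)
    if kind == "disease":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "count"], dtype={0: str}
        )
        return df.set_index("gene_id")["count"]
    if kind == "ontology_annotations":
        anno: dict[str, list[str]] = defaultdict(list)
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            gene, term = line.split("\t")[:2]
            anno[gene].append(term)
        return dict(anno)
    if kind == "motif_clusters":
        clusters: dict[tuple[str, str], list[str]] = defaultdict(list)
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            group, cluster_id, motif_id = line.split("\t")[:3]
            clusters[(group, cluster_id)].append(motif_id)
        return dict(clusters)
    if kind == "loops":
        loops = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            c1, s1, e1, c2, s2, e2 = line.split("\t")[:6]
            a1 = GenomicInterval(c1, int(s1), int(e1))
            a2 = GenomicInterval(c2, int(s2), int(e2))
            if a1.chrom == a2.chrom and a1.overlaps(a2.start, a2.end):
                warnings.warn(f"loop at line {lineno} has overlapping anchors")
            loops.append((a1, a2))
        return loops
    raise ValueError(f"unknown mapping table kind {kind!r}")


def read_obo_lite(path):
    """Parse an OBO-lite ontology (id, name, is_a only) into a DiGraph.

    Edges point child -> parent.  Raises on cycles.
    """
    import networkx as nx

    graph = nx.DiGraph()
    term_id = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line == "[Term]":
            term_id = None
        elif line.startswith("id:"):
            term_id = line.split("id:", 1)[1].strip()
            graph.add_node(term_id)
        elif line.startswith("name:") and term_id:
            graph.nodes[term_id]["name"] = line.split("name:", 1)[1].strip()
        elif line.startswith("is_a:") and term_id:
            parent = line.split("is_a:", 1)[1].strip().split("!")[0].strip()
            graph.add_edge(term_id, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValidationError(f"{path}: ontology contains a cycle")
    return graph


# ---------------------------------------------------------------------------
# validation entry point (CLI `plastiscope validate`)

_VALIDATORS = {
    "foldchange": lambda p: read_fold_change_matrix(p),
    "annotation": lambda p: read_gene_annotation(p, "gtf_lite"),
    "bed6": lambda p: read_gene_annotation(p, "bed6"),
    "peaks": lambda p: read_bed_peaks(p),
    "meme": lambda p: read_meme_motifs(p),
    "fasta": lambda p: read_promoter_fasta(p),
    "obo": lambda p: read_obo_lite(p),
    "orthologues": lambda p: read_mapping_table(p, "orthologues"),
    "gene_sets": lambda p: read_mapping_table(p, "gene_sets"),
    "loops": lambda p: read_mapping_table(p, "loops"),
}


def validate_file(kind: str, path) -> dict:
    """Validate an input file; returns a small report dict.

    Raises FormatError/ValidationError with a descriptive message when the
    file is invalid.
    """
    if kind not in _VALIDATORS:
        raise ValueError(f"unknown kind {kind!r}; one of {sorted(_VALIDATORS)}")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        obj = _VALIDATORS[kind](path)
    if isinstance(obj, tuple):
        obj = obj[0]
    n = len(obj) if hasattr(obj, "__len__") else obj.shape[0]
    return {
        "kind": kind,
        "path": str(path),
        "n_records": int(n),
        "warnings": [str(w.message) for w in caught],
    }
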