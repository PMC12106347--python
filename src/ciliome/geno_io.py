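"""Sequence containers, variant genetic codes, format I/O and contig filtering.

Ciliate macronuclear genomes are collections of gene-sized, telomere-capped
"nanochromosomes".  This module provides the primitives the rest of the
pipeline builds on: genetic-code tables with lineage-specific stop-codon
reassignments (UGA read as cysteine in *Euplotes*; UAA/UAG read as glutamine
in *Oxytricha*/*Stylonychia*), frame-aware translation, telomere detection,
and the assembly-cleanup rule that discards short contigs redundantly
contained in longer ones.

Coordinate conventions: all tabular interfaces (BLAST outfmt 6, GFF3) use
1-based inclusive coordinates; internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("ciliome")

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP = "*"


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class InputError(ValueError):
    """Inputs are structurally valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Genetic codes
# ---------------------------------------------------------------------------

_BASES = "TCAG"
# Standard code, NCBI table 1, as one string over TCAG-major codon order.
_STANDARD_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


def _standard_table() -> dict[str, str]:
    table = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                table[b1 + b2 + b3] = _STANDARD_AAS[i]
                i += 1
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with explicit stop-codon reassignments.

    ``reassignments`` lists (codon, amino-acid) overrides applied on top of
    the standard code; every reassigned codon must be a stop in the standard
    code (that is the biological phenomenon being modelled).
    """

    name: str
    reassignments: tuple[tuple[str, str], ...] = ()
    table: Mapping[str, str] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        base = _standard_table()
        for codon, aa in self.reassignments:
            if base.get(codon) != STOP:
                raise ValueError(
                    f"reassigned codon {codon} is not a stop in the standard code"
                )
            base[codon] = aa
        object.__setattr__(self, "table", base)
        if len(self.table) != 64:
            raise ValueError("genetic code must map exactly 64 codons")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa == STOP)

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]


STANDARD = GeneticCode("standard")
# Euplotes: UGA -> Cys; TAA/TAG remain the only stops.
EUPLOTES = GeneticCode("euplotes", (("TGA", "C"),))
# Oxytricha / Stylonychia: UAA/UAG -> Gln; TGA is the only stop.
OXYTRICHA = GeneticCode("oxytricha", (("TAA", "Q"), ("TAG", "Q")))

GENETIC_CODES: dict[str, GeneticCode] = {
    "standard": STANDARD,
    "euplotes": EUPLOTES,
    "oxytricha": OXYTRICHA,
    "stylonychia": OXYTRICHA,
}


def get_code(name: str | GeneticCode) -> GeneticCode:
    if isinstance(name, GeneticCode):
        return name
    try:
        return GENETIC_CODES[name.lower()]
    except KeyError:
        raise InputError(f"unknown genetic code {name!r}; "
                         f"known: {sorted(GENETIC_CODES)}") from None


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def translate(seq: str, code: str | GeneticCode = STANDARD, frame: int = 1) -> str:
    """Translate ``seq`` in forward ``frame`` (+1/+2/+3), stops rendered '*'.

    The trailing partial codon is ignored.  Codons containing N (or any
    non-ACGT base) translate to 'X' and can never act as stops.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be +1, +2 or +3, got {frame}")
    code = get_code(code)
    seq = seq.upper()
    out = []
    for i in range(frame - 1, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append(code.table.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# Contigs and telomeres
# ---------------------------------------------------------------------------

#: Euplotes macronuclear telomere repeat on the 5' strand (C4A4).
TELOMERE_UNIT = "CCCCAAAA"


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str
    telomere_5p: bool = False
    telomere_3p: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


def detect_telomeres(
    contig: Contig,
    repeat_unit: str = TELOMERE_UNIT,
    min_units: int = 3,
    window: int = 100,
) -> Contig:
    """Flag telomeric ends: >= ``min_units`` tandem copies of ``repeat_unit``
    within the 5' terminal window, or of its reverse complement at the 3' end.
    """
    if not repeat_unit:
        raise ValueError("repeat_unit must be non-empty")
    seq = contig.seq.upper()
    window = max(window, min_units * len(repeat_unit))
    motif_5p = repeat_unit.upper() * min_units
    motif_3p = reverse_complement(repeat_unit.upper()) * min_units
    return replace(
        contig,
        telomere_5p=motif_5p in seq[:window],
        telomere_3p=motif_3p in seq[-window:],
    )


# ---------------------------------------------------------------------------
# Similarity hits (BLAST tabular outfmt-6 dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular similarity search.

    ``frame`` extends the classic format for translated searches: +1..+3
    (forward frames), -1..-3 (reverse), 0 for protein-protein.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    frame: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must be in [0, 100]")


HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


def read_hits_tabular(path: str | Path) -> list[HitRecord]:
    """Read 12-column BLAST outfmt-6 (optionally 13 columns with frame)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise FormatError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                hits.append(HitRecord(
                    query_id=parts[0], subject_id=parts[1],
                    pct_identity=float(parts[2]), aln_length=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    q_start=int(parts[6]), q_end=int(parts[7]),
                    s_start=int(parts[8]), s_end=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                    frame=int(parts[12]) if len(parts) == 13 else 0,
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_tabular(hits: Iterable[HitRecord], path: str | Path,
                       with_frame: bool = True) -> Path:
    path = Path(path)
    cols = HIT_COLUMNS + (["frame"] if with_frame else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for h in hits:
            row = [h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                   h.aln_length, h.mismatches, h.gap_opens, h.q_start,
                   h.q_end, h.s_start, h.s_end, f"{h.evalue:.3g}",
                   f"{h.bitscore:.1f}"]
            if with_frame:
                row.append(h.frame)
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercased sequence) pairs.

    The record id is the first whitespace-delimited token of the header.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            raise FormatError(f"{path}:1: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}:1: expected '>' header, got {first!r}")
        fh.seek(0)
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else ""
            if not name:
                raise FormatError(f"{path}: record with empty header")
            records.append((name, seq.upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Contig filtering (assembly cleanup)
# ---------------------------------------------------------------------------

REASON_HARD_MIN = "below_hard_minimum_length"
REASON_REDUNDANT = "redundant_fragment_of_longer_contig"


def filter_contigs(
    contigs: Sequence[Contig],
    hits: Sequence[HitRecord],
    min_len: int = 500,
    min_identity: float = 90.0,
    min_coverage: float = 80.0,
    hard_min_len: int = 100,
) -> tuple[list[Contig], list[tuple[Contig, str]]]:
    """Drop tiny contigs and short contigs redundantly contained in long ones.

    A contig is removed iff it is shorter than ``hard_min_len``, or it is
    shorter than ``min_len`` and has a hit (as query) onto a contig of at
    least ``min_len`` with percent identity >= ``min_identity`` and query
    coverage >= ``min_coverage``.  Coverage is computed on the query (the
    shorter fragment): aligned query span / query length x 100.
    """
    by_id = {c.id: c for c in contigs}
    for h in hits:
        if h.query_id not in by_id or h.subject_id not in by_id:
            raise InputError(
                f"hit references unknown contig id "
                f"{h.query_id if h.query_id not in by_id else h.subject_id!r}"
            )
    kept: list[Contig] = []
    removed: list[tuple[Contig, str]] = []
    hits_by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query_id, []).append(h)

    for contig in contigs:
        if contig.length < hard_min_len:
            removed.append((contig, REASON_HARD_MIN))
            continue
        redundant = False
        if contig.length < min_len:
            for h in hits_by_query.get(contig.id, ()):
                subject = by_id[h.subject_id]
                if subject.length < min_len or subject.id == contig.id:
                    continue
                coverage = (abs(h.q_end - h.q_start) + 1) / contig.length * 100
                if h.pct_identity >= min_identity and coverage >= min_coverage:
                    redundant = True
                    break
        if redundant:
            removed.append((contig, REASON_REDUNDANT))
        else:
            kept.append(contig)
    logger.info("filter_contigs: kept %d, removed %d of %d",
                len(kept), len(removed), len(contigs))
    return kept, removed


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcript's exon structure.

    Exons are (start, end) 1-based inclusive on ``seqid``, sorted by start.
    """

    gene_id: str
    transcript_id: str
    seqid: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon features from GFF3 into gene models.

    mRNAs without an enclosing gene feature use their own ID as gene id.
    """
    path = Path(path)
    mrna_gene: dict[str, str] = {}
    mrna_loc: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            a = _gff3_attributes(attrs)
            if ftype == "mRNA":
                mid = a.get("ID", f"mRNA_{lineno}")
                mrna_gene[mid] = a.get("Parent", mid)
                mrna_loc[mid] = (seqid, strand)
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(
                        f"{path}:{lineno}: exon without Parent attribute")
                exons.setdefault(parent, []).append((start_i, end_i))
    models = []
    for mid, exon_list in exons.items():
        seqid, strand = mrna_loc.get(mid, ("?", "+"))
        models.append(GeneModel(
            gene_id=mrna_gene.get(mid, mid),
            transcript_id=mid,
            seqid=seqid,
            strand=strand,
            exons=tuple(sorted(exon_list)),
        ))
    models.sort(key=lambda m: (m.seqid, m.span, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write("\t".join([m.seqid, "ciliome", "gene", str(lo), str(hi),
                                ".", m.strand, ".", f"ID={m.gene_id}"]) + "\n")
            fh.write("\t".join([m.seqid, "ciliome", "mRNA", str(lo), str(hi),
                                ".", m.strand, ".",
                                f"ID={m.transcript_id};Parent={m.gene_id}"])
                     + "\n")
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write("\t".join([
                    m.seqid, "ciliome", "exon", str(s), str(e), ".",
                    m.strand, ".",
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}",
                ]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Edge lists and generic tables
# ---------------------------------------------------------------------------

def read_edgelist(path: str | Path) -> nx.Graph:
    """Read an undirected TSV edge list (nodeA<TAB>nodeB[<TAB>weight]).

    Duplicate edges are collapsed; self-loops are rejected.
    """
    graph = nx.Graph()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if a == b:
                raise FormatError(f"{path}:{lineno}: self-loop on {a!r}")
            if len(parts) == 3:
                try:
                    graph.add_edge(a, b, weight=float(parts[2]))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
            else:
                graph.add_edge(a, b)
    return graph


def write_edgelist(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node_a\tnode_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated table with an optional '#'-commented header."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        names = first.lstrip("#").strip().split("\t")
        return pd.read_csv(path, sep="\t", comment=None, skiprows=1,
                           names=names)
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    return path
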