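"""ORF discovery under variant genetic codes and gene-structure statistics.

ORFs are defined stop-to-stop by default: *Euplotes* macronuclear transcripts
are gene-sized units and the frameshift procedure downstream reasons about
"the starting reading frame", not start codons.  An ATG-anchored mode is
available by flag.  Because UGA encodes cysteine under the euplotes code,
an ORF is never split at a TGA codon there — that is the point.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .geno_io import GeneModel, GeneticCode, get_code, reverse_complement, translate

STOP = "*"


@dataclass(frozen=True)
class ORF:
    """An open reading frame on a transcript.

    ``start``/``end`` are 0-based half-open nucleotide coordinates of the
    coding region on the forward strand of the transcript; the terminating
    stop codon is *not* included in the interval.  ``stop_codon`` is None
    for ORFs truncated by the 3' transcript boundary.  Reverse-strand ORFs
    (``strand == '-'``) carry coordinates on the given sequence with the
    protein read from its reverse complement.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    stop_codon: str | None
    protein: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be divisible by 3")
        if STOP in self.protein:
            raise ValueError("ORF protein must not contain internal stops")


def _scan_frame(seq: str, code: GeneticCode, frame: int, min_aa: int,
                transcript_id: str, atg_anchored: bool, strand: str,
                seq_len: int) -> list[ORF]:
    orfs = []
    offset = frame - 1
    segment_start = offset
    aas: list[str] = []
    positions = list(range(offset, len(seq) - 2, 3))
    for i in positions:
        codon = seq[i:i + 3]
        aa = code.table.get(codon, "X")
        if aa == STOP:
            orfs.extend(_emit(seq, transcript_id, frame, segment_start, i,
                              codon, "".join(aas), min_aa, atg_anchored,
                              strand, seq_len))
            segment_start = i + 3
            aas = []
        else:
            aas.append(aa)
    if aas:
        end = positions[-1] + 3
        orfs.extend(_emit(seq, transcript_id, frame, segment_start, end,
                          None, "".join(aas), min_aa, atg_anchored,
                          strand, seq_len))
    return orfs


def _emit(seq: str, transcript_id: str, frame: int, start: int, end: int,
          stop_codon: str | None, protein: str, min_aa: int,
          atg_anchored: bool, strand: str, seq_len: int) -> list[ORF]:
    if atg_anchored:
        # anchor at the first ATG within the stop-to-stop segment
        idx = None
        for j in range(start, end, 3):
            if seq[j:j + 3] == "ATG":
                idx = j
                break
        if idx is None:
            return []
        protein = protein[(idx - start) // 3:]
        start = idx
    if len(protein) < min_aa:
        return []
    if strand == "-":
        # map coordinates back onto the forward strand of the input sequence
        start, end = seq_len - end, seq_len - start
    return [ORF(transcript_id=transcript_id, frame=frame, start=start,
                end=end, stop_codon=stop_codon, protein=protein,
                strand=strand)]


def find_orfs(
    transcript: str,
    code: str | GeneticCode = "euplotes",
    min_aa: int = 30,
    transcript_id: str = "",
    both_strands: bool = False,
    atg_anchored: bool = False,
) -> list[ORF]:
    """Find ORFs in all three forward frames (six with ``both_strands``).

    Every ORF starts either in-frame at the 5' boundary or immediately after
    a stop, and ends at a stop codon or the 3' boundary.  Sorted by start.
    """
    code = get_code(code)
    seq = transcript.upper()
    orfs: list[ORF] = []
    for frame in (1, 2, 3):
        orfs.extend(_scan_frame(seq, code, frame, min_aa, transcript_id,
                                atg_anchored, "+", len(seq)))
    if both_strands:
        rc = reverse_complement(seq)
        for frame in (1, 2, 3):
            orfs.extend(_scan_frame(rc, code, frame, min_aa, transcript_id,
                                    atg_anchored, "-", len(seq)))
    orfs.sort(key=lambda o: (o.start, o.strand, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# Structure statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureStats:
    """Gene-structure proportions: introns per gene, stop-codon usage, and
    the fraction of genes using programmed ribosomal frameshifting."""

    intron_histogram: Mapping[int, float]
    stop_usage: Mapping[str, float]
    prf_fraction: float

    def __post_init__(self) -> None:
        for dist in (self.intron_histogram, self.stop_usage):
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")


def intron_histogram(
    gene_models: Sequence[GeneModel],
    subset: Iterable[str] | None = None,
) -> dict[int, float]:
    """Proportion of genes by intron count (exons - 1), optionally over an
    explicit gene subset."""
    models = list(gene_models)
    if subset is not None:
        wanted = set(subset)
        models = [m for m in models if m.gene_id in wanted]
    if not models:
        raise ValueError("no gene models to summarize")
    counts = Counter(m.n_introns for m in models)
    total = len(models)
    return {k: counts[k] / total for k in sorted(counts)}


def stop_usage(orfs: Sequence[ORF]) -> dict[str, float]:
    """Proportion of terminating stop codons over ORFs that have one."""
    stops = [o.stop_codon for o in orfs if o.stop_codon is not None]
    if not stops:
        raise ValueError("no stop-terminated ORFs to summarize")
    counts = Counter(stops)
    total = len(stops)
    return {k: counts[k] / total for k in sorted(counts)}


def structure_stats(
    gene_models: Sequence[GeneModel],
    orfs: Sequence[ORF],
    prf_gene_ids: Iterable[str],
    subset: Iterable[str] | None = None,
) -> StructureStats:
    """Combined structural summary of an annotated gene set."""
    models = list(gene_models)
    if subset is not None:
        wanted = set(subset)
        models = [m for m in models if m.gene_id in wanted]
    if not models:
        raise ValueError("no gene models to summarize")
    prf = set(prf_gene_ids) & {m.gene_id for m in models}
    return StructureStats(
        intron_histogram=intron_histogram(models),
        stop_usage=stop_usage(orfs),
        prf_fraction=len(prf) / len(models),
    )
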