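"""Protein and translated similarity search, gene families, conservation.

The search engine performs Smith-Waterman local alignment (affine gaps,
BLOSUM62 by default) with Karlin-Altschul-style E-values, seeded by exact
amino-acid words so that all-vs-all scans stay fast; the per-pair scoring
path (:func:`align_pair`) is seedless and exact.  The statistical parameter
lambda is obtained by root-finding on the ungapped identity
``sum_ij p_i p_j exp(lambda * s_ij) = 1`` with Robinson-Robinson background
frequencies; K uses the standard ungapped-estimate approximation.

"Gene family" here means best-hit-to-exemplar: each protein joins the family
of its best-scoring curated exemplar, which models how curated query sets
define families in comparative ciliate surveys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .geno_io import GeneticCode, HitRecord, InputError, get_code, translate

AA20 = "ARNDCQEGHILKMFPSTWYV"

# Robinson & Robinson amino-acid background frequencies (order as AA20).
_BACKGROUND = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_KA_K = 0.1  # ungapped-estimate approximation


def karlin_altschul_lambda(matrix_name: str = "BLOSUM62") -> float:
    """Solve sum_ij p_i p_j exp(lambda s_ij) = 1 for lambda > 0."""
    mat = substitution_matrices.load(matrix_name)

    def f(lam: float) -> float:
        total = 0.0
        for a in AA20:
            for b in AA20:
                total += _BACKGROUND[a] * _BACKGROUND[b] * math.exp(
                    lam * mat[a, b])
        return total - 1.0

    return float(brentq(f, 1e-4, 2.0))


def evalue(score: float, query_len: int, db_len: int,
           lam: float, k: float = _KA_K) -> float:
    return k * query_len * db_len * math.exp(-lam * score)


def bitscore(score: float, lam: float, k: float = _KA_K) -> float:
    return (lam * score - math.log(k)) / math.log(2)


@dataclass
class AlignerConfig:
    """Local-alignment scoring; gap penalties follow the BLAST convention
    (a gap of length L costs open + L * extend)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_max: float = 1e-5
    word_size: int = 5
    min_seed_hits: int = 2
    _lambda: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._lambda is None:
            self._lambda = karlin_altschul_lambda(self.matrix)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def align_pair(
    query: str,
    subject: str,
    config: AlignerConfig | None = None,
) -> tuple[float, dict]:
    """Best local alignment of one pair: (score, detail dict).

    Detail keys: matches, aln_length, mismatches, gap_opens, q_start, q_end,
    s_start, s_end (coordinates 1-based inclusive on the input sequences).
    A score of 0 means no positive-scoring local alignment exists.
    """
    config = config or AlignerConfig()
    aligner = config.make_aligner()
    score = float(aligner.score(query, subject))
    if score <= 0:
        return 0.0, {}
    aln = aligner.align(query, subject)[0]
    blocks_q, blocks_s = aln.aligned
    matches = mismatches = aligned_cols = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for i in range(qe - qs):
            aligned_cols += 1
            if query[qs + i] == subject[ss + i]:
                matches += 1
            else:
                mismatches += 1
    gap_opens = len(blocks_q) - 1
    gap_len = 0
    for i in range(1, len(blocks_q)):
        gap_len += (blocks_q[i][0] - blocks_q[i - 1][1]) + (
            blocks_s[i][0] - blocks_s[i - 1][1])
    detail = {
        "matches": matches,
        "aln_length": aligned_cols + gap_len,
        "mismatches": mismatches,
        "gap_opens": gap_opens,
        "q_start": int(blocks_q[0][0]) + 1,
        "q_end": int(blocks_q[-1][1]),
        "s_start": int(blocks_s[0][0]) + 1,
        "s_end": int(blocks_s[-1][1]),
    }
    return score, detail


class SeedIndex:
    """Exact amino-acid word index over a subject set, built once and
    shared across queries (the expensive part of an all-vs-all scan)."""

    def __init__(self, subjects: Sequence[tuple[str, str]], word_size: int):
        self.subjects = list(subjects)
        self.word_size = word_size
        self.words: dict[str, set[int]] = {}
        for j, (_sid, seq) in enumerate(self.subjects):
            for i in range(len(seq) - word_size + 1):
                self.words.setdefault(seq[i:i + word_size], set()).add(j)
        self.short = {j for j, (_s, seq) in enumerate(self.subjects)
                      if len(seq) < 2 * word_size}

    def candidates(self, query: str, min_seed_hits: int) -> list[int]:
        if len(query) < self.word_size:
            return list(range(len(self.subjects)))
        counts: dict[int, int] = {}
        for i in range(len(query) - self.word_size + 1):
            for j in self.words.get(query[i:i + self.word_size], ()):
                counts[j] = counts.get(j, 0) + 1
        return sorted(j for j, c in counts.items()
                      if c >= min_seed_hits or j in self.short)


def search_protein(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    config: AlignerConfig | None = None,
    index: SeedIndex | None = None,
) -> list[HitRecord]:
    """All-vs-all seeded Smith-Waterman; best hit per (query, subject) pair,
    filtered at ``config.evalue_max``."""
    config = config or AlignerConfig()
    if not queries or not subjects:
        return []
    db_len = sum(len(s) for _i, s in subjects)
    if index is None:
        index = SeedIndex(subjects, config.word_size)
    hits: list[HitRecord] = []
    aligner = config.make_aligner()
    for qid, qseq in queries:
        if not qseq:
            continue
        for j in index.candidates(qseq, config.min_seed_hits):
            sid, sseq = subjects[j]
            score = float(aligner.score(qseq, sseq))
            if score <= 0:
                continue
            e = evalue(score, len(qseq), db_len, config._lambda)
            if e > config.evalue_max:
                continue
            _score, detail = align_pair(qseq, sseq, config)
            hits.append(HitRecord(
                query_id=qid, subject_id=sid,
                pct_identity=100.0 * detail["matches"] / detail["aln_length"],
                aln_length=detail["aln_length"],
                mismatches=detail["mismatches"],
                gap_opens=detail["gap_opens"],
                q_start=detail["q_start"], q_end=detail["q_end"],
                s_start=detail["s_start"], s_end=detail["s_end"],
                evalue=e, bitscore=bitscore(score, config._lambda),
                frame=0,
            ))
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
    return hits


def search_translated(
    transcripts: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    code: str | GeneticCode = "euplotes",
    config: AlignerConfig | None = None,
    both_strands: bool = False,
) -> list[HitRecord]:
    """Translated search: align all three forward-frame translations of each
    transcript (six with ``both_strands``) against protein subjects; the
    frame is recorded per hit and stop codons break translations into
    segments so frameshifted transcripts produce hits in several frames.

    Hit q_start/q_end are amino-acid coordinates within the frame's
    translation (1-based).
    """
    from .geno_io import reverse_complement

    config = config or AlignerConfig()
    hits: list[HitRecord] = []
    index = SeedIndex(subjects, config.word_size)
    # a local alignment shorter than this cannot reach the E-value cutoff
    min_segment = 12
    frames = [1, 2, 3] + ([-1, -2, -3] if both_strands else [])
    for tid, seq in transcripts:
        for frame in frames:
            dna = seq if frame > 0 else reverse_complement(seq)
            protein = translate(dna, code, abs(frame))
            # align each stop-free segment separately, preserving offsets
            pos = 0
            for segment in protein.split("*"):
                if len(segment) >= min_segment:
                    seg_hits = search_protein([(tid, segment)], subjects,
                                              config, index=index)
                    for h in seg_hits:
                        hits.append(HitRecord(
                            query_id=h.query_id, subject_id=h.subject_id,
                            pct_identity=h.pct_identity,
                            aln_length=h.aln_length,
                            mismatches=h.mismatches, gap_opens=h.gap_opens,
                            q_start=h.q_start + pos, q_end=h.q_end + pos,
                            s_start=h.s_start, s_end=h.s_end,
                            evalue=h.evalue, bitscore=h.bitscore,
                            frame=frame,
                        ))
                pos += len(segment) + 1
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id, h.frame))
    return hits


# ---------------------------------------------------------------------------
# Gene families and cross-species conservation
# ---------------------------------------------------------------------------

@dataclass
class FamilyCatalog:
    """Per-species gene-family membership.

    ``families`` maps family name -> species -> set of member gene ids; a
    gene id appears in at most one family per species.
    """

    species: list[str]
    families: dict[str, dict[str, set[str]]]
    unassigned: dict[str, set[str]] = field(default_factory=dict)

    def members(self, family: str) -> dict[str, set[str]]:
        return self.families.get(family, {})

    def presence(self, family: str) -> frozenset[str]:
        return frozenset(sp for sp, genes in self.members(family).items()
                         if genes)


@dataclass(frozen=True)
class VennPartition:
    """Count of families (or genes) exclusive to exactly this species set."""

    region: frozenset[str]
    count: int


def assign_families(
    proteins_by_species: Mapping[str, Sequence[tuple[str, str]]],
    family_exemplars: Mapping[str, Sequence[tuple[str, str]]],
    config: AlignerConfig | None = None,
) -> FamilyCatalog:
    """Assign each protein to the family of its best-scoring exemplar hit.

    Ties break by higher bitscore, then lower E-value, then lexicographic
    exemplar id.  Proteins with no hit at the E-value cutoff are recorded
    as unassigned.
    """
    config = config or AlignerConfig()
    exemplar_family = {}
    exemplar_records = []
    for family, members in family_exemplars.items():
        for eid, seq in members:
            if eid in exemplar_family:
                raise InputError(f"exemplar id {eid!r} occurs in two families")
            exemplar_family[eid] = family
            exemplar_records.append((eid, seq))

    species = sorted(proteins_by_species)
    families: dict[str, dict[str, set[str]]] = {
        fam: {sp: set() for sp in species} for fam in family_exemplars}
    unassigned: dict[str, set[str]] = {sp: set() for sp in species}

    for sp in species:
        records = list(proteins_by_species[sp])
        hits = search_protein(records, exemplar_records, config)
        best: dict[str, HitRecord] = {}
        for h in hits:
            cur = best.get(h.query_id)
            # higher bitscore wins; then lower evalue; then lex exemplar id
            if cur is None or h.bitscore > cur.bitscore or (
                h.bitscore == cur.bitscore and (
                    h.evalue < cur.evalue
                    or (h.evalue == cur.evalue
                        and h.subject_id < cur.subject_id))):
                best[h.query_id] = h
        for gid, _seq in records:
            if gid in best:
                families[exemplar_family[best[gid].subject_id]][sp].add(gid)
            else:
                unassigned[sp].add(gid)
    return FamilyCatalog(species=species, families=families,
                         unassigned=unassigned)


def venn_partition(catalog: FamilyCatalog,
                   granularity: str = "family") -> list[VennPartition]:
    """Exclusive-region counts over all non-empty species subsets.

    ``granularity='family'`` counts families per region; ``'gene'`` counts
    member genes of the families in each region.  The region counts form a
    true partition of the distinct families (or their genes).
    """
    if granularity not in ("family", "gene"):
        raise ValueError("granularity must be 'family' or 'gene'")
    regions: dict[frozenset[str], int] = {}
    for family in catalog.families:
        present = catalog.presence(family)
        if not present:
            continue
        if granularity == "family":
            regions[present] = regions.get(present, 0) + 1
        else:
            n_genes = sum(len(g) for g in catalog.members(family).values())
            regions[present] = regions.get(present, 0) + n_genes
    return [VennPartition(region=r, count=c)
            for r, c in sorted(regions.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0])))]


def conserved_core(catalog: FamilyCatalog) -> set[str]:
    """Families present in every species of the catalog."""
    all_species = frozenset(catalog.species)
    return {fam for fam in catalog.families
            if catalog.presence(fam) == all_species}
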