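"""Programmed ribosomal frameshift (PRF) gene detection.

In *Euplotes*, many genes are translated past an internal TAA/TAG stop codon
by a +1 or +2 ribosomal frameshift at a short "slippery" context.  The
detection procedure models the shift as an excision: remove the first one
("T", a +1 shift) or two ("TA", a +2 shift) bases of the internal stop and
re-translate in the original frame.  If the re-translation extends the
protein C-terminally along a homologous reference, the stop is called a PRF
event.  Candidate genes are transcripts whose translated-search hits cover
the same reference protein in different reading frames.

The slippery context (3 nt upstream + the stop codon, e.g. AAATAA) is
recorded for every event but never used as a filter by default: although
AAATAR dominates, accepted events at TGTTAG, TTCTAA, GGATAA and similar
contexts are real.  A strict ``require_aaatar`` mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .geno_io import GeneticCode, HitRecord, InputError, get_code, translate
from .homology import AlignerConfig, align_pair

logger = logging.getLogger("ciliome")

_STOPS_TAR = ("TAA", "TAG")


@dataclass(frozen=True)
class PRFEvent:
    """One detected frameshift at an internal stop codon.

    ``position`` is the 0-based index of the stop codon's first base in the
    original (unedited) transcript.  ``model`` +1 corresponds to excising
    "T", +2 to excising "TA".
    """

    position: int
    stop_codon: str
    slippery: str
    model: int
    excised: str

    def __post_init__(self) -> None:
        if not self.slippery.endswith(self.stop_codon):
            raise ValueError("slippery context must end with the stop codon")
        if (self.model, self.excised) not in ((1, "T"), (2, "TA")):
            raise ValueError("model +1 pairs with excised 'T', +2 with 'TA'")


@dataclass(frozen=True)
class PRFGene:
    """A transcript with one or more frameshift events against a reference."""

    transcript_id: str
    reference_id: str
    events: tuple[PRFEvent, ...]
    localization: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        positions = [e.position for e in self.events]
        if positions != sorted(set(positions)):
            raise ValueError("events must be strictly increasing in position")

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# Candidate discovery
# ---------------------------------------------------------------------------

def find_candidates(hits: Sequence[HitRecord]) -> list[tuple[str, str]]:
    """Transcript/reference pairs hit in two or more reading frames.

    A candidate requires >= 2 hits from the same transcript to the same
    reference in *different* frames, arranged colinearly: the hit starting
    earlier on the transcript covers a more N-terminal region of the
    reference.  Hits must carry frame information (translated search).
    """
    by_pair: dict[tuple[str, str], list[HitRecord]] = {}
    for h in hits:
        if h.frame == 0:
            raise InputError(
                f"hit {h.query_id}->{h.subject_id} lacks frame information; "
                "candidates need translated-search hits")
        by_pair.setdefault((h.query_id, h.subject_id), []).append(h)

    candidates = []
    for (tid, rid), pair_hits in sorted(by_pair.items()):
        frames = {h.frame for h in pair_hits}
        if len(frames) < 2:
            continue
        ordered = sorted(pair_hits, key=lambda h: h.q_start)
        colinear = any(
            a.frame != b.frame and a.s_start < b.s_start
            for i, a in enumerate(ordered) for b in ordered[i + 1:]
        )
        if colinear:
            candidates.append((tid, rid))
    return candidates


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

def _extension_matches(downstream_protein: str, reference_suffix: str,
                       config: AlignerConfig,
                       min_identity: float,
                       max_start_offset: int = 5) -> int:
    """Identical residues in the best local alignment of the candidate
    C-terminal extension against the reference suffix.

    The extension must be *contiguous* with the upstream ORF: the local
    alignment has to begin within ``max_start_offset`` residues of the
    start of both the downstream translation and the reference suffix.
    Without this anchor a mis-excised frame can skip a garbage stretch and
    re-align further downstream, mimicking a longer extension.  Returns 0
    when the anchor or the ``min_identity`` requirement fails.
    """
    if not downstream_protein or not reference_suffix:
        return 0
    score, detail = align_pair(downstream_protein, reference_suffix, config)
    if score <= 0:
        return 0
    if (detail["q_start"] > max_start_offset + 1
            or detail["s_start"] > max_start_offset + 1):
        return 0
    aligned = detail["matches"] + detail["mismatches"]
    if aligned == 0 or detail["matches"] / aligned < min_identity:
        return 0
    return detail["matches"]


def classify_event(
    transcript: str,
    stop_pos: int,
    reference_protein: str,
    code: str | GeneticCode = "euplotes",
    min_extension_aa: int = 10,
    orf_start: int = 0,
    config: AlignerConfig | None = None,
    min_extension_identity: float = 0.6,
) -> PRFEvent | None:
    """Test both excisions at an in-frame stop and return the winning event.

    For each excision ("T" removes the first base of the stop codon, "TA"
    the first two), the edited transcript is re-translated in the original
    frame and the translation downstream of the stop is aligned to the
    reference beyond the residues already accounted for upstream.  The
    excision producing the longer C-terminal extension (>=
    ``min_extension_aa`` matching residues) wins; ties break toward +1, the
    dominant model.  Returns None when neither excision extends.
    """
    code = get_code(code)
    config = config or AlignerConfig()
    seq = transcript.upper()
    stop_codon = seq[stop_pos:stop_pos + 3]
    if code.table.get(stop_codon) != "*":
        raise InputError(
            f"position {stop_pos} holds {stop_codon!r}, not a stop codon "
            f"under the {code.name} code")
    if stop_pos < orf_start + 3 or (stop_pos - orf_start) % 3:
        raise InputError("stop_pos must be in frame with at least one "
                         "upstream codon")
    upstream_aa = (stop_pos - orf_start) // 3
    reference_suffix = reference_protein[upstream_aa:]

    best: tuple[int, str] | None = None  # (matches, excised)
    for excised in ("T", "TA"):
        edited = seq[:stop_pos] + seq[stop_pos + len(excised):]
        downstream = translate(edited[stop_pos:], code, 1)
        downstream = downstream.split("*")[0]
        matches = _extension_matches(downstream, reference_suffix, config,
                                     min_extension_identity)
        if matches >= min_extension_aa:
            if best is None or matches > best[0]:
                best = (matches, excised)
    if best is None:
        return None
    excised = best[1]
    return PRFEvent(
        position=stop_pos,
        stop_codon=stop_codon,
        slippery=seq[stop_pos - 3:stop_pos + 3],
        model=1 if excised == "T" else 2,
        excised=excised,
    )


# ---------------------------------------------------------------------------
# Iterative detection
# ---------------------------------------------------------------------------

def _first_stop(seq: str, code: GeneticCode, start: int) -> int | None:
    for i in range(start, len(seq) - 2, 3):
        if code.table.get(seq[i:i + 3]) == "*":
            return i
    return None


def apply_excisions(transcript: str, events: Sequence[PRFEvent]) -> str:
    """Apply the detected excisions (positions in original coordinates),
    yielding the single-ORF edited transcript the ribosome effectively
    decodes."""
    seq = transcript
    removed = 0
    for ev in sorted(events, key=lambda e: e.position):
        pos = ev.position - removed
        seq = seq[:pos] + seq[pos + len(ev.excised):]
        removed += len(ev.excised)
    return seq


def detect_prf(
    transcripts: Sequence[tuple[str, str]],
    reference_proteins: Sequence[tuple[str, str]],
    hits: Sequence[HitRecord],
    code: str | GeneticCode = "euplotes",
    max_events: int = 5,
    min_extension_aa: int = 10,
    require_aaatar: bool = False,
    annotations: Mapping[str, str] | None = None,
    config: AlignerConfig | None = None,
) -> list[PRFGene]:
    """Detect PRF genes among candidate transcript/reference pairs.

    Per candidate, the terminal stop of the current reading frame is located,
    classified via :func:`classify_event`, and — if an event is found — the
    winning excision is applied to a working copy before continuing, until no
    further stop extends the protein or ``max_events`` is exceeded (the gene
    is then flagged truncated).  Event positions are reported in original
    transcript coordinates.  Only genes with >= 1 event are returned, in a
    deterministic order independent of input order.
    """
    code = get_code(code)
    config = config or AlignerConfig()
    tmap = dict(transcripts)
    rmap = dict(reference_proteins)
    annotations = annotations or {}

    genes: list[PRFGene] = []
    for tid, rid in find_candidates(hits):
        if tid not in tmap:
            raise InputError(f"hit references unknown transcript {tid!r}")
        if rid not in rmap:
            raise InputError(f"hit references unknown reference {rid!r}")
        transcript = tmap[tid].upper()
        reference = rmap[rid]
        # anchor the starting reading frame on the most upstream hit
        pair_hits = [h for h in hits
                     if h.query_id == tid and h.subject_id == rid]
        first = min(pair_hits, key=lambda h: (h.s_start, h.q_start))
        orf_start = abs(first.frame) - 1

        working = transcript
        removed = 0
        events: list[PRFEvent] = []
        truncated = False
        while True:
            stop = _first_stop(working, code, orf_start)
            if stop is None or stop < orf_start + 3:
                break
            if len(events) >= max_events:
                truncated = True
                break
            event = classify_event(
                working, stop, reference, code,
                min_extension_aa=min_extension_aa, orf_start=orf_start,
                config=config)
            if event is not None and require_aaatar and not (
                    event.slippery.startswith("AAA")
                    and event.stop_codon in _STOPS_TAR):
                event = None
            if event is None:
                break
            # report the event in original transcript coordinates
            events.append(PRFEvent(
                position=event.position + removed,
                stop_codon=event.stop_codon,
                slippery=event.slippery,
                model=event.model,
                excised=event.excised,
            ))
            working = (working[:event.position]
                       + working[event.position + len(event.excised):])
            removed += len(event.excised)
        if events:
            genes.append(PRFGene(
                transcript_id=tid, reference_id=rid, events=tuple(events),
                localization=annotations.get(tid, annotations.get(rid, "")),
                truncated=truncated,
            ))
    genes.sort(key=lambda g: (g.transcript_id, g.reference_id))
    logger.info("detect_prf: %d PRF genes among %d candidates",
                len(genes), len(find_candidates(hits)))
    return genes


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "Protein", "Transcript", "Slippery sequence", "Frameshifting model",
    "Numbers of frameshifting", "Positions", "Cellular localization",
]


def prf_report(genes: Sequence[PRFGene]) -> pd.DataFrame:
    """Summary table, one row per gene: slippery contexts and models are
    '/'-joined in transcript order."""
    rows = []
    for g in genes:
        rows.append({
            "Protein": g.reference_id,
            "Transcript": g.transcript_id,
            "Slippery sequence": "/".join(e.slippery for e in g.events),
            "Frameshifting model": "/".join(f"+{e.model}" for e in g.events),
            "Numbers of frameshifting": g.n_events,
            "Positions": "/".join(str(e.position) for e in g.events),
            "Cellular localization": g.localization,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def parse_prf_report(table: pd.DataFrame) -> list[PRFGene]:
    """Inverse of :func:`prf_report` (round-trip identity)."""
    genes = []
    for _, row in table.iterrows():
        contexts = str(row["Slippery sequence"]).split("/")
        models = [int(m) for m in
                  str(row["Frameshifting model"]).replace("+", "").split("/")]
        positions = [int(p) for p in str(row["Positions"]).split("/")]
        events = tuple(
            PRFEvent(position=p, stop_codon=ctx[-3:], slippery=ctx,
                     model=m, excised="T" if m == 1 else "TA")
            for p, ctx, m in zip(positions, contexts, models))
        loc = row["Cellular localization"]
        genes.append(PRFGene(
            transcript_id=str(row["Transcript"]),
            reference_id=str(row["Protein"]),
            events=events,
            localization="" if pd.isna(loc) else str(loc),
        ))
    return genes
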