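"""Seeded generators for every input the pipeline consumes, with ground truth.

The raw sequencing data behind this kind of ciliate survey is rarely
published in usable form, so every stage here is exercised on synthetic
inputs whose true structure is known exactly:

- telomere-capped single-gene nanochromosomes with intron counts and stop
  codons drawn from the proportions observed in cilia-associated gene sets
  (about 79% intron-free, TAA:TAG roughly 3:1);
- transcripts carrying planted +1/+2 programmed-frameshift events, built by
  *inserting* "T" or "TA" into a stop-forming slippery context — the exact
  inverse of the detector's excision, guaranteeing a consistent truth;
- four pseudo-species sharing gene families derived from common exemplars;
- interaction networks with planted hub nodes bridging dense modules;
- qPCR Cq tables with set ddCq effects, and straight/circular swimming
  tracks sampled at 0.3-s intervals.

Every generator is a pure function of its spec: the same spec produces
byte-identical outputs.  Reference proteins are random sequences with
BLOSUM62 (Robinson-Robinson) background composition, which avoids
accidental homology between unrelated records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geno_io import Contig, GeneModel, GeneticCode, get_code, TELOMERE_UNIT, reverse_complement
from .homology import AA20, _BACKGROUND
from .quantify import Track

_STOPS = ("TAA", "TAG")

#: Slippery-context repertoire observed in Euplotes PRF genes: AAATAR
#: dominates, but a minority of accepted events use other 3-nt prefixes.
CONTEXT_REPERTOIRE = (
    ["AAATAA"] * 10 + ["AAATAG"] * 2
    + ["AATTAA", "TTCTAA", "TATTAA", "AAGTAA", "TGATAG", "GGATAA",
       "ATATAG", "CGATAA", "AGTTAA", "ATATAA", "TGTTAG", "TTTTAG"]
)


@dataclass(frozen=True)
class PRFPlan:
    """One planned transcript: named events as (6-nt context, model)."""

    name: str
    events: tuple[tuple[str, int], ...] = ()
    ref_len: int = 400

    def __post_init__(self) -> None:
        for context, model in self.events:
            if len(context) != 6 or context[3:] not in _STOPS:
                raise ValueError(
                    f"context {context!r} must be 3 nt + TAA/TAG")
            if model not in (1, 2):
                raise ValueError("model must be +1 or +2")


def _normalized(mix: Mapping, what: str) -> dict:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities must sum to 1, got {total}")
    return dict(mix)


@dataclass(frozen=True)
class SynthSpec:
    """Study-condition parameters for all generators.

    Defaults mirror the observed structure of ciliate cilia-associated gene
    sets: ~79% intron-free genes, TAA:TAG stop usage about 3:1, ~30% of
    genes with programmed frameshifts, and a 300-node interaction network
    with 10 planted hubs over a 2% background edge density.
    """

    seed: int = 0
    n_contigs: int = 50
    n_transcripts: int = 200
    code: str = "euplotes"
    stop_mix: Mapping[str, float] = field(
        default_factory=lambda: {"TAA": 0.77, "TAG": 0.23})
    intron_mix: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.7909, 1: 0.134, 2: 0.05, 3: 0.02,
                                 4: 0.0051})
    prf_fraction: float = 0.30
    prf_plan: tuple[PRFPlan, ...] | None = None
    family_plan: Mapping[str, Sequence[str]] | None = None
    hub_plan: tuple[int, int, float] = (300, 10, 0.02)
    track_plan: tuple[tuple, ...] = (
        ("line", 33.333333333333336, 100, 0.5),
        ("circle", 50.0, 100, 0.5),
    )
    qpcr_plan: Mapping[str, float] = field(
        default_factory=lambda: {"CKAP5": -1.0, "ADCY3": -2.0,
                                 "BBS4": 1.0, "IFT88": 2.0, "ARL2BP": 0.0})

    def __post_init__(self) -> None:
        _normalized(self.stop_mix, "stop_mix")
        _normalized(self.intron_mix, "intron_mix")


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


_AA_P = np.array([_BACKGROUND[a] for a in AA20])
_AA_P = _AA_P / _AA_P.sum()


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random amino-acid sequence with BLOSUM62 background composition."""
    return "".join(rng.choice(list(AA20), size=length, p=_AA_P))


def _codons_for(code: GeneticCode) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in sorted(code.table.items()):
        if aa != "*":
            table.setdefault(aa, []).append(codon)
    return table


def back_translate(protein: str, code: str | GeneticCode,
                   rng: np.random.Generator,
                   fixed_codons: Mapping[int, str] | None = None) -> str:
    """Back-translate with uniformly random synonymous codons; positions in
    ``fixed_codons`` use the given codon (which must encode that residue)."""
    code = get_code(code)
    by_aa = _codons_for(code)
    fixed_codons = fixed_codons or {}
    codons = []
    for i, aa in enumerate(protein):
        if i in fixed_codons:
            codon = fixed_codons[i]
            if code.table.get(codon) != aa:
                raise ValueError(
                    f"fixed codon {codon} does not encode {aa} at {i}")
            codons.append(codon)
        else:
            codons.append(str(rng.choice(by_aa[aa])))
    return "".join(codons)


# ---------------------------------------------------------------------------
# PRF transcripts
# ---------------------------------------------------------------------------

def _event_residues(context: str, model: int, code: GeneticCode,
                    rng: np.random.Generator):
    """Residues and codons at the two constrained positions of one event.

    The clean CDS must read <context prefix codon> at aa c-1 and, at aa c,
    a codon beginning with the stop-codon remnant left by the excision
    (last 2 stop bases for a +1 event, last base for +2).  Re-inserting the
    excised bases then recreates the full 6-nt slippery context.
    """
    prefix, stop = context[:3], context[3:]
    aa_prev = code.table.get(prefix)
    if aa_prev in (None, "*"):
        raise ValueError(
            f"context prefix {prefix} is a stop under {code.name}; "
            "no upstream residue can encode it")
    remnant = stop[1:] if model == 1 else stop[2:]
    options = [c for c, aa in sorted(code.table.items())
               if c.startswith(remnant) and aa != "*"]
    codon_c = str(rng.choice(options))
    return (aa_prev, prefix), (code.table[codon_c], codon_c)


def build_prf_transcript(
    plan: PRFPlan,
    code: str | GeneticCode,
    rng: np.random.Generator,
    terminal_stop: str = "TAA",
    tail_len: int = 12,
) -> tuple[str, str, pd.DataFrame]:
    """Construct (transcript, reference protein, truth table) for one plan.

    Event aa positions are spaced evenly through the reference; each event
    inserts "T" (+1) or "TA" (+2) at a codon boundary so that the in-frame
    reading terminates at the planted stop and the planned excision exactly
    restores the clean coding sequence.
    """
    code = get_code(code)
    n = len(plan.events)
    ref_len = plan.ref_len
    if n:
        lo, hi = 40, ref_len - 30
        positions = [int(round(lo + (hi - lo) * (i + 1) / (n + 1)))
                     for i in range(n)]
        if len(set(positions)) != n or any(
                b - a < 15 for a, b in zip(positions, positions[1:])):
            raise ValueError("reference too short for the planned events")
    else:
        positions = []

    protein = list(random_protein(ref_len, rng))
    fixed: dict[int, str] = {}
    for c, (context, model) in zip(positions, plan.events):
        (aa_prev, codon_prev), (aa_c, codon_c) = _event_residues(
            context, model, code, rng)
        protein[c - 1] = aa_prev
        protein[c] = aa_c
        fixed[c - 1] = codon_prev
        fixed[c] = codon_c
    protein = "".join(protein)
    cds = back_translate(protein, code, rng, fixed)

    transcript = cds
    offset = 0
    truth_rows = []
    for c, (context, model) in zip(positions, plan.events):
        insert = context[3] if model == 1 else context[3:5]
        pos = 3 * c + offset
        transcript = transcript[:pos] + insert + transcript[pos:]
        truth_rows.append({
            "transcript_id": plan.name, "reference_id": f"{plan.name}_ref",
            "position": pos, "slippery": context, "stop_codon": context[3:],
            "model": model, "excised": insert,
        })
        offset += len(insert)
        assert transcript[pos:pos + 3] == context[3:]
        assert transcript[pos - 3:pos + 3] == context

    tail = "".join(rng.choice(list("ACGT"), size=tail_len))
    transcript = transcript + terminal_stop + tail
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "reference_id", "position", "slippery",
                 "stop_codon", "model", "excised"])
    return transcript, protein, truth


def default_prf_plans(spec: SynthSpec) -> tuple[PRFPlan, ...]:
    """The default 200-transcript plan: ~30% of transcripts carry 1-3
    events with contexts from the observed repertoire, models mostly +1."""
    rng = _rng(spec, 10)
    plans = []
    for i in range(spec.n_transcripts):
        name = f"tr{i:04d}"
        if rng.random() < spec.prf_fraction:
            n_events = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            events = tuple(
                (str(rng.choice(CONTEXT_REPERTOIRE)),
                 int(rng.choice([1, 2], p=[0.9, 0.1])))
                for _ in range(n_events))
            plans.append(PRFPlan(name=name, events=events))
        else:
            plans.append(PRFPlan(name=name))
    return tuple(plans)


def synth_prf_set(
    spec: SynthSpec,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """(transcripts, reference proteins, truth table) for the PRF stage."""
    code = get_code(spec.code)
    plans = spec.prf_plan if spec.prf_plan is not None else \
        default_prf_plans(spec)
    rng = _rng(spec, 11)
    stops = sorted(spec.stop_mix)
    stop_p = np.array([spec.stop_mix[s] for s in stops])
    transcripts, references, truths = [], [], []
    for plan in plans:
        terminal = str(rng.choice(stops, p=stop_p))
        seq, protein, truth = build_prf_transcript(plan, code, rng, terminal)
        transcripts.append((plan.name, seq))
        references.append((f"{plan.name}_ref", protein))
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return transcripts, references, truth


# ---------------------------------------------------------------------------
# Genome: telomere-capped single-gene nanochromosomes
# ---------------------------------------------------------------------------

def synth_genome(
    spec: SynthSpec,
) -> tuple[list[Contig], list[GeneModel], pd.DataFrame]:
    """Telomere-capped nanochromosomes, one gene each, with intron counts
    and stop codons drawn from the spec's mixes.  Returns (contigs, gene
    models, truth table)."""
    code = get_code(spec.code)
    rng = _rng(spec, 20)
    stops = sorted(spec.stop_mix)
    stop_p = np.array([spec.stop_mix[s] for s in stops])
    intron_counts = sorted(spec.intron_mix)
    intron_p = np.array([spec.intron_mix[k] for k in intron_counts])

    telo5 = TELOMERE_UNIT * 4
    telo3 = reverse_complement(TELOMERE_UNIT) * 4

    contigs, models, rows = [], [], []
    for i in range(spec.n_contigs):
        cid, gid, tid = f"ctg{i:04d}", f"gene{i:04d}", f"mRNA{i:04d}"
        protein = random_protein(int(rng.integers(120, 300)), rng)
        cds = back_translate(protein, code, rng)
        stop = str(rng.choice(stops, p=stop_p))
        coding = cds + stop
        n_introns = int(rng.choice(intron_counts, p=intron_p))
        # split the coding region into n_introns + 1 exon pieces
        cut_points = sorted(rng.choice(
            np.arange(10, len(coding) - 10), size=n_introns, replace=False))
        pieces, prev = [], 0
        for cut in cut_points:
            pieces.append(coding[prev:cut])
            prev = cut
        pieces.append(coding[prev:])

        spacer5 = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(20, 60))))
        spacer3 = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(20, 60))))
        seq = telo5 + spacer5
        exons = []
        for j, piece in enumerate(pieces):
            start = len(seq)  # 0-based
            seq += piece
            exons.append((start + 1, len(seq)))  # 1-based inclusive
            if j < len(pieces) - 1:
                intron = ("GT"
                          + "".join(rng.choice(list("ACT"),
                                               size=int(rng.integers(20, 40))))
                          + "AG")
                seq += intron
        seq += spacer3 + telo3

        contigs.append(Contig(id=cid, seq=seq))
        models.append(GeneModel(gene_id=gid, transcript_id=tid, seqid=cid,
                                strand="+", exons=tuple(exons)))
        rows.append({"contig_id": cid, "gene_id": gid, "transcript_id": tid,
                     "n_introns": n_introns, "stop_codon": stop,
                     "protein_len": len(protein)})
    truth = pd.DataFrame(rows)
    return contigs, models, truth


# ---------------------------------------------------------------------------
# Gene families across pseudo-species
# ---------------------------------------------------------------------------

DEFAULT_SPECIES = ("amieti", "octocarinatus", "lemnae", "trifallax")


def default_family_plan() -> dict[str, tuple[str, ...]]:
    """Five families: two core (all species) plus a few partial/unique."""
    sp = DEFAULT_SPECIES
    return {
        "tubulin": sp,
        "dynein": sp,
        "kinesin": sp[:3],
        "centrin": (sp[1],),
        "rab": (sp[3],),
    }


def synth_family_set(
    spec: SynthSpec,
    members_per_presence: int = 3,
    mutation_rate: float = 0.1,
    exemplar_len: int = 180,
):
    """(proteins per species, family exemplars, presence truth).

    Each family gets one exemplar protein; each species where the family is
    present gets ``members_per_presence`` members derived from the exemplar
    by random substitutions at ``mutation_rate``.
    """
    rng = _rng(spec, 30)
    plan = dict(spec.family_plan) if spec.family_plan else \
        default_family_plan()
    species = sorted({sp for present in plan.values() for sp in present})
    exemplars: dict[str, list[tuple[str, str]]] = {}
    proteins: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species}
    for family in sorted(plan):
        exemplar = random_protein(exemplar_len, rng)
        exemplars[family] = [(f"{family}_exemplar", exemplar)]
        for sp in sorted(plan[family]):
            for j in range(members_per_presence):
                mutant = list(exemplar)
                for i in range(len(mutant)):
                    if rng.random() < mutation_rate:
                        mutant[i] = str(rng.choice(list(AA20)))
                proteins[sp].append((f"{sp}_{family}_{j}", "".join(mutant)))
    truth = {family: frozenset(present) for family, present in plan.items()}
    return proteins, exemplars, truth


# ---------------------------------------------------------------------------
# Interaction network with planted hubs
# ---------------------------------------------------------------------------

def synth_ppi(spec: SynthSpec) -> tuple[nx.Graph, list[str]]:
    """Erdos-Renyi background with dense modules; planted hubs bridge many
    modules with high degree.  Returns (graph, planted hub ids)."""
    n_nodes, n_hubs, background_p = spec.hub_plan
    rng = _rng(spec, 40)
    n_modules = 8
    p_intra = 0.25
    hub_neighbor_frac = 0.15

    hubs = [f"hub{i:02d}" for i in range(n_hubs)]
    others = [f"n{i:04d}" for i in range(n_nodes - n_hubs)]
    graph = nx.Graph()
    graph.add_nodes_from(hubs + others)

    modules = np.array_split(np.array(others), n_modules)
    for module in modules:
        module = list(module)
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                if rng.random() < p_intra:
                    graph.add_edge(module[i], module[j])
    all_nodes = hubs + others
    for i in range(len(all_nodes)):
        for j in range(i + 1, len(all_nodes)):
            if rng.random() < background_p:
                graph.add_edge(all_nodes[i], all_nodes[j])
    n_hub_edges = max(int(hub_neighbor_frac * n_nodes), 1)
    for hub in hubs:
        targets = rng.choice(len(others), size=n_hub_edges, replace=False)
        for t in targets:
            graph.add_edge(hub, others[int(t)])
    return graph, hubs


# ---------------------------------------------------------------------------
# Tracks and qPCR tables
# ---------------------------------------------------------------------------

def synth_tracks(spec: SynthSpec, dt: float = 0.3) -> tuple[list[Track],
                                                            pd.DataFrame]:
    """Tracks per ``spec.track_plan``; entries are either
    ("line", speed_um_s, n_points, jitter_um) or
    ("circle", radius_um, n_points, jitter_um)."""
    rng = _rng(spec, 50)
    tracks, rows = [], []
    for idx, plan in enumerate(spec.track_plan):
        shape = plan[0]
        tid = f"track{idx:02d}_{shape}"
        n = int(plan[2])
        jitter = float(plan[3])
        t = np.arange(n) * dt
        if shape == "line":
            speed_um_s = float(plan[1])
            x = speed_um_s * t
            y = np.zeros(n)
            rows.append({"track": tid, "shape": shape,
                         "true_speed": speed_um_s, "true_radius": np.nan})
        elif shape == "circle":
            radius = float(plan[1])
            # one full revolution over the track
            theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
            x = radius * np.cos(theta)
            y = radius * np.sin(theta)
            step = 2 * radius * np.sin(np.pi / n)
            rows.append({"track": tid, "shape": shape,
                         "true_speed": step / dt, "true_radius": radius})
        else:
            raise ValueError(f"unknown track shape {shape!r}")
        x = x + rng.normal(0.0, jitter, size=n)
        y = y + rng.normal(0.0, jitter, size=n)
        tracks.append(Track(t=tuple(t), x=tuple(x), y=tuple(y), track_id=tid))
    return tracks, pd.DataFrame(rows)


def synth_qpcr(
    spec: SynthSpec,
    n_replicates: int = 6,
    baseline: float = 22.0,
    sigma: float = 0.1,
    reference_gene: str = "GAPDH",
    target_sample: str = "division",
    control_sample: str = "G0",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Long-format Cq table realizing ``spec.qpcr_plan`` (gene -> true ddCq).

    The reference gene sits at ``baseline`` in both samples; each target
    gene gets a gene-specific basal offset in the control sample and the
    planned ddCq shift added in the target sample, all with Gaussian
    measurement noise.  Returns (table, truth ddCq map).
    """
    rng = _rng(spec, 60)
    rows = []
    for sample in (control_sample, target_sample):
        for _ in range(n_replicates):
            rows.append({"sample": sample, "gene": reference_gene,
                         "cq": baseline + rng.normal(0, sigma)})
    for gene in sorted(spec.qpcr_plan):
        ddcq = spec.qpcr_plan[gene]
        basal = baseline + float(rng.uniform(-1, 1))
        for _ in range(n_replicates):
            rows.append({"sample": control_sample, "gene": gene,
                         "cq": basal + rng.normal(0, sigma)})
        for _ in range(n_replicates):
            rows.append({"sample": target_sample, "gene": gene,
                         "cq": basal + ddcq + rng.normal(0, sigma)})
    return pd.DataFrame(rows), dict(spec.qpcr_plan)
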