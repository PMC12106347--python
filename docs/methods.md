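# Methods

## Setting and assumptions

The package models the computational side of a cilia-gene survey in a
hypotrich ciliate. Three biological facts shape every design choice:

1. **Nanochromosome genome.** The somatic (macronuclear) genome is a
   collection of gene-sized contigs capped by C4A4 / G4T4 telomeric repeats.
   Contigs are therefore treated as single-gene units, transcripts as
   sense-oriented gene-sized mRNAs.
2. **Stop-codon reassignment.** Under the `euplotes` code UGA encodes
   cysteine, leaving TAA/TAG as the only stops; under the
   `oxytricha`/`stylonychia` code UAA/UAG encode glutamine, leaving TGA.
   Codes are built as explicit overrides of the standard table, and an
   override is only legal for a codon that is a stop in the standard code.
   Codons containing N translate to `X` and can never act as stops.
3. **Programmed ribosomal frameshifting (PRF).** Many genes contain internal
   TAA/TAG stops that the ribosome reads through by slipping +1 or +2
   nucleotides at a short "slippery" context. The computational model of
   the slip is an edit: excising the first one ("T", +1) or two ("TA", +2)
   bases of the stop codon restores a single reading frame.

## Contig filtering

A contig is removed iff it is shorter than 100 bp, or shorter than 500 bp
with a similarity hit onto a contig of at least 500 bp at percent identity
≥ 90 and query coverage ≥ 80. Coverage is computed on the query (the short
fragment): the rule targets redundant fragments, and containment of the
fragment is what makes it redundant. Each removal carries exactly one
machine-readable reason, the hard length minimum taking precedence; the
filter is idempotent by construction.

## ORF model

ORFs are stop-to-stop, not ATG-anchored: ciliate macronuclear transcripts
are gene-sized and the PRF procedure reasons about "the starting reading
frame" rather than start codons. An ATG-anchored mode and a
reverse-complement scan exist behind flags, both off by default. `min_aa`
defaults to 30 to suppress noise ORFs. Coordinates are 0-based half-open
with the terminating stop codon excluded from the interval, so
`(end − start)/3` always equals the protein length.

## PRF detection

**Candidates.** Translated search (all three forward frames; translations
split at stops, each stop-free segment aligned separately with its frame
recorded) finds transcripts with hits to the same reference protein in two
or more frames, arranged colinearly: the hit starting earlier on the
transcript covers a more N-terminal region of the reference.

**Event classification.** At an in-frame internal stop, both excisions are
tested. For each, the edited transcript is re-translated in the original
frame and the translation downstream of the stop (up to the next stop) is
locally aligned against the reference suffix not yet accounted for by the
upstream ORF. An excision is valid when the alignment has at least
`min_extension_aa = 10` identical residues (a guard against spurious 1–2
residue "extensions"; no published threshold exists), at least 60 %
identity over its aligned columns, and — critically — is *contiguous* with
the upstream ORF: the alignment must begin within 5 residues of both the
start of the downstream translation and the start of the reference suffix.
Without the contiguity anchor, a mis-excised frame on a multi-event
transcript can read a stop-free stretch of out-of-frame sequence until a
later frameshift site happens to resynchronize it, producing a longer but
non-contiguous match; anchoring removes this failure mode (observed on
roughly 4 % of planted events before the fix). When both excisions are
valid the longer extension wins, ties breaking toward +1, the dominant
model.

**Iteration.** Per candidate, the detector finds the first in-frame stop,
classifies it, applies the winning excision to a working copy, and repeats.
The terminal stop classifies as no event (nothing beyond the reference
C-terminus to extend into), so the loop is self-terminating; `max_events`
(default 5) bounds pathological inputs, flagging the gene truncated. Event
positions are reported in original transcript coordinates. Applying all
detected excisions yields a single uninterrupted ORF whose translation
matches the reference end to end — the algorithm's fixed point, asserted in
tests.

**Slippery contexts are recorded, never filtered.** Although the initial
ORF of known *Euplotes* PRF genes usually ends in 5′-AAATAR-3′, accepted
events at TGTTAG, TTCTAA, GGATAA and similar contexts are documented, so
the context is observational output. A strict `require_aaatar` mode exists
for users who want the conservative behaviour.

## Similarity search and E-values

Local alignment is Smith–Waterman (Biopython `PairwiseAligner`) with
BLOSUM62 and BLAST-convention affine gaps (open 11, extend 1: a gap of
length L costs 11 + L). The statistical parameter λ solves the ungapped
identity Σᵢⱼ pᵢ pⱼ exp(λ sᵢⱼ) = 1 with Robinson–Robinson background
frequencies (λ ≈ 0.32 for BLOSUM62); K is fixed at 0.1, the standard
ungapped-estimate approximation. E = K·m·n·e^(−λS) with n the summed
database length, filtered at 1e-5. All-vs-all scans are pre-filtered by
exact 5-mer seeds (two shared words required), mirroring BLAST's seeded
design; the per-pair scoring path is seedless and is validated against a
quadratic-time Gotoh oracle in the tests. Externally produced 12/13-column
tabular hit files can be imported wherever internal hits are accepted, for
users who need exact parity with a specific search engine.

**Families** are defined by best hit to a curated exemplar (bitscore, then
E-value, then lexicographic exemplar id), modelling how curated query sets
define families; no clustering is performed. Venn partitioning counts
exclusive species regions at family granularity by default, with a gene
granularity option, since conservation can be stated at either level.

## Network centralities

The twelve scores follow standard published formulations (exact plug-in
parity is a non-goal): harmonic Closeness; Radiality and the eccentricity
score (component diameter − eccentricity) computed per connected component;
Betweenness as unnormalised pair-fractions; Stress as raw shortest-path
counts; MCC as Σ(|C|−1)! over maximal cliques containing the node, equal to
the degree when the node sits in no triangle; MNC/DMNC from the largest
component of the open neighbourhood (DMNC exponent ε = 1.7); BottleNeck
counts source-rooted shortest-path trees (deterministic BFS with sorted
parent discovery) routing more than a quarter of the component through the
node; EPC is the Monte-Carlo mean component size under independent
edge-survival p = 0.5, reproducible given (seed, reps) with standard error
∝ reps^(−1/2). Rank ties take the minimum rank ("1224") so the top-k
boundary never drops tied candidates. The consensus rule (top 50 under at
least 6 of 12 methods) is deterministic given the score table.

## Quantification

ΔCq = Cq(target gene) − Cq(reference gene) within a sample, ΔΔCq =
ΔCq(target sample) − ΔCq(control sample), fold change = 2^−ΔΔCq. Replicates
are combined by the arithmetic mean of Cq before ΔCq (no aggregation rule
is published; the mean is the convention). Any replicate with Cq ≥ 30 is
invalid and its record is excluded with a logged warning. The per-replicate
ΔCq distributions (each target replicate against the sample's mean
reference Cq) feed a Welch unequal-variance t-test; two identical constant
groups report p = 1. Track speeds use consecutive-frame displacements
without smoothing; straightness is net displacement over path length (NaN
for a stationary track); circle fits use the algebraic (Kåsa) least-squares
system, returning infinite radius for rank-deficient (collinear) inputs.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of a `SynthSpec` (same spec ⇒ identical
bytes). Defaults encode the study conditions: 200 transcripts with ~30 %
carrying 1–3 PRF events; slippery contexts drawn from the observed
repertoire (AAATAR-dominated with a minority of other prefixes) and models
90 % +1 / 10 % +2; stop usage TAA 0.77 / TAG 0.23; intron counts 79.09 %
zero, 13.4 % one, the remainder spread over 2–4; a 300-node interaction
network with 10 planted hubs over a 2 % background; circular tracks of
radius 50 µm with 0.5 µm Gaussian jitter at 0.3-s sampling; Cq tables at
baseline ≈ 22 cycles with σ = 0.1 and six replicates per group.

PRF planting is the exact inverse of detection: a clean back-translated CDS
receives "T" or "TA" insertions at codon boundaries engineered (via two
constrained codons per event) so the in-frame reading terminates at the
planted stop inside the planned 6-nt context. Reference proteins are random
sequences with BLOSUM62 background composition, so unrelated records share
no detectable homology.

What passing tests therefore show: the pipeline recovers exactly what its
own model class generates — correct excision semantics, frame bookkeeping,
ranking and arithmetic. What they do not show: robustness to sequencing
error, paralogy, incomplete references, real codon bias, splice-form
ambiguity, or biological slippage signals beyond the excision model; real
headline counts from the field (hundreds of cilia genes, tens of hubs)
depend on external databases and are out of scope.

## Numerical choices and problem sizes

Tolerances in tests derive from the generators (binomial confidence bands
for proportions, ~5 Monte-Carlo standard errors for EPC). Brute-force
centrality oracles run on 100 random graphs of ≤ 7 nodes (exact percolation
enumeration restricted to ≤ 10 edges, where 2^|E| subsets are enumerable)
plus path-enumeration checks on ≤ 30-node graphs; the recovery suites use
200 transcripts and a 300-node network — sizes chosen so the full suite
runs in well under a minute per stage on a single CPU while every code path
and collision case is exercised.

## Known limitations

- −1 frameshifts and ribosome-profiling evidence are out of scope; only the
  excision (+1/+2) model is implemented.
- E-values use ungapped Karlin–Altschul parameters with gapped alignments;
  absolute E-values are approximate (rank order is what the pipeline uses).
- Whether a "+2" event is biologically a two-base slip or an annotation
  convention cannot be resolved computationally; the excision semantics are
  implemented exactly as stated.
- CytoHubba parity is not asserted for EPC and the eccentricity score,
  whose plug-in conventions are unpublished; definitions used here are
  documented above.
- GFF3 handling covers gene/mRNA/exon nesting only (no CDS phase
  arithmetic, no multi-transcript genes).
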