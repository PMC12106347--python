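"""Similarity search against a brute-force dynamic-programming oracle,
E-value behaviour, family assignment and Venn partitioning."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ciliome import (
    AlignerConfig, FamilyCatalog, SynthSpec, align_pair, assign_families,
    back_translate, conserved_core, random_protein, search_protein,
    search_translated, venn_partition,
)
from ciliome.homology import bitscore, evalue, karlin_altschul_lambda

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a, b, gap_open=11.0, gap_extend=1.0):
    """Quadratic-time affine-gap Smith-Waterman oracle (a gap of length L
    costs gap_open + L * gap_extend), independent of the search engine."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                                       Iy[i - 1][j - 1]))
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                           Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                           Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


class TestAlignPair:
    def test_matches_dp_oracle_on_random_pairs(self, rng):
        config = AlignerConfig()
        for _ in range(40):
            a = random_protein(int(rng.integers(5, 50)), rng)
            b = random_protein(int(rng.integers(5, 50)), rng)
            score, _ = align_pair(a, b, config)
            assert score == pytest.approx(gotoh_local_score(a, b))

    def test_matches_dp_oracle_on_related_pairs(self, rng):
        config = AlignerConfig()
        for _ in range(15):
            a = random_protein(40, rng)
            b = list(a)
            for i in range(len(b)):
                if rng.random() < 0.15:
                    b[i] = str(rng.choice(list("ARNDCQEGHILKMFPSTWYV")))
            b = "".join(b[:20]) + "".join(b[25:])  # introduce a deletion
            score, detail = align_pair(a, b, config)
            assert score == pytest.approx(gotoh_local_score(a, b))
            assert detail["matches"] > 0

    def test_identity_detail(self):
        score, detail = align_pair("MKVLAW", "MKVLAW")
        assert detail["matches"] == 6 and detail["mismatches"] == 0
        assert (detail["q_start"], detail["q_end"]) == (1, 6)


class TestEvalueModel:
    def test_lambda_is_positive_and_stable(self):
        lam = karlin_altschul_lambda()
        assert 0.2 < lam < 0.5

    def test_evalue_monotone_in_score(self):
        lam = karlin_altschul_lambda()
        scores = [20, 40, 60, 80]
        evs = [evalue(s, 100, 10000, lam) for s in scores]
        assert evs == sorted(evs, reverse=True)
        bits = [bitscore(s, lam) for s in scores]
        assert bits == sorted(bits)


class TestSearchProtein:
    def test_self_hit_full_coverage(self, rng):
        prot = random_protein(120, rng)
        hits = search_protein([("q", prot)], [("s", prot), ("other",
                              random_protein(120, rng))])
        (hit,) = [h for h in hits if h.subject_id == "s"]
        assert hit.pct_identity == 100.0
        assert (hit.q_start, hit.q_end) == (1, 120)

    def test_shuffled_decoys_produce_no_hits(self, rng):
        prot = random_protein(150, rng)
        decoys = []
        for i in range(50):
            shuffled = list(prot)
            rng.shuffle(shuffled)
            decoys.append((f"decoy{i}", "".join(shuffled)))
        assert search_protein([("q", prot)], decoys) == []

    def test_empty_inputs(self):
        assert search_protein([], [("s", "MKV")]) == []
        assert search_protein([("q", "MKV")], []) == []


class TestSearchTranslated:
    def test_back_translated_frame_hit(self, rng):
        prot = random_protein(100, rng)
        cds = back_translate(prot, "euplotes", rng)
        transcript = "GG" + cds  # shifts the coding region into frame +3
        hits = search_translated([("t", transcript)], [("ref", prot)],
                                 "euplotes")
        assert {h.frame for h in hits} == {3}
        assert hits[0].pct_identity == 100.0

    def test_frameshifted_transcript_hits_two_frames(self, rng):
        prot = random_protein(120, rng)
        cds = back_translate(prot, "euplotes", rng)
        broken = cds[:180] + "T" + cds[180:]  # insertion shifts downstream
        hits = search_translated([("t", broken)], [("ref", prot)],
                                 "euplotes")
        assert {h.frame for h in hits} == {1, 2}

    def test_random_dna_no_hits(self, rng):
        dna = "".join(rng.choice(list("ACGT"), size=600))
        refs = [(f"r{i}", random_protein(150, rng)) for i in range(10)]
        assert search_translated([("t", dna)], refs, "euplotes") == []


class TestFamilies:
    def test_best_bitscore_family_wins(self, rng):
        exemplar_a = random_protein(120, rng)
        exemplar_b = random_protein(120, rng)
        # protein = mutated copy of A: must join family A, not B
        member = list(exemplar_a)
        for i in range(0, len(member), 10):
            member[i] = "A"
        catalog = assign_families(
            {"sp1": [("p1", "".join(member))]},
            {"famA": [("exA", exemplar_a)], "famB": [("exB", exemplar_b)]})
        assert "p1" in catalog.families["famA"]["sp1"]
        assert catalog.unassigned["sp1"] == set()

    def test_no_hit_goes_unassigned(self, rng):
        catalog = assign_families(
            {"sp1": [("orphan", random_protein(80, rng))]},
            {"famA": [("exA", random_protein(120, rng))]})
        assert catalog.unassigned["sp1"] == {"orphan"}

    def test_planted_catalog_recovered_exactly(self):
        from ciliome import synth_family_set
        spec = SynthSpec(seed=3)
        proteins, exemplars, truth = synth_family_set(spec)
        catalog = assign_families(proteins, exemplars)
        for family, present in truth.items():
            assert catalog.presence(family) == present
        for sp in catalog.species:
            assert catalog.unassigned[sp] == set()


class TestVenn:
    def _catalog(self):
        sp = ["s1", "s2", "s3", "s4"]
        families = {}
        for fam in ("a", "b"):  # shared by everyone
            families[fam] = {s: {f"{s}_{fam}"} for s in sp}
        for s in sp:  # one unique family each
            families[f"uniq_{s}"] = {t: ({f"{s}_u"} if t == s else set())
                                     for t in sp}
        return FamilyCatalog(species=sp, families=families)

    def test_core_and_singletons(self):
        catalog = self._catalog()
        assert conserved_core(catalog) == {"a", "b"}
        parts = {tuple(sorted(p.region)): p.count
                 for p in venn_partition(catalog)}
        assert parts[("s1", "s2", "s3", "s4")] == 2
        for s in catalog.species:
            assert parts[(s,)] == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        catalog = self._catalog()
        parts = venn_partition(catalog)
        assert sum(p.count for p in parts) == len(catalog.families)
        assert len({p.region for p in parts}) == len(parts)

    def test_single_species(self):
        catalog = FamilyCatalog(species=["s1"],
                                families={"a": {"s1": {"g1", "g2"}}})
        (part,) = venn_partition(catalog)
        assert part.region == frozenset({"s1"}) and part.count == 1
        (gpart,) = venn_partition(catalog, granularity="gene")
        assert gpart.count == 2
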