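import numpy as np
import pytest

from ciliome import Contig, HitRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_hit(query_id, subject_id, pct_identity=95.0, q_start=1, q_end=100,
             s_start=1, s_end=100, evalue=1e-30, bitscore=200.0, frame=0,
             aln_length=None, mismatches=0, gap_opens=0):
    if aln_length is None:
        aln_length = q_end - q_start + 1
    return HitRecord(
        query_id=query_id, subject_id=subject_id, pct_identity=pct_identity,
        aln_length=aln_length, mismatches=mismatches, gap_opens=gap_opens,
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        evalue=evalue, bitscore=bitscore, frame=frame)


@pytest.fixture
def toy_contig_set(rng):
    """Twelve contigs exercising every branch of the assembly filter.

    Returns (contigs, hits, expected removed ids by reason).
    """
    def seq(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    contigs = [
        Contig("long1", seq(2000)),     # long, kept
        Contig("long2", seq(1500)),     # long, kept
        Contig("long3", seq(800)),      # long, kept
        Contig("short_red1", seq(300)),  # redundant: 95% id, 85% cov
        Contig("short_red2", seq(450)),  # redundant: 90% id, 80% cov (boundary)
        Contig("short_lowid", seq(300)),   # 85% identity -> kept
        Contig("short_lowcov", seq(300)),  # 70% coverage -> kept
        Contig("short_nohit", seq(250)),   # no hits -> kept
        Contig("short_vs_short", seq(300)),  # hit onto another short -> kept
        Contig("tiny1", seq(90)),        # below hard minimum
        Contig("tiny2", seq(50)),        # below hard minimum
        Contig("boundary100", seq(100)),  # exactly 100 bp, no hits -> kept
    ]
    hits = [
        make_hit("short_red1", "long1", pct_identity=95.0,
                 q_start=1, q_end=255),                       # cov 85%
        make_hit("short_red2", "long2", pct_identity=90.0,
                 q_start=1, q_end=360),                       # cov 80%
        make_hit("short_lowid", "long1", pct_identity=85.0,
                 q_start=1, q_end=270),                       # id below 90
        make_hit("short_lowcov", "long2", pct_identity=99.0,
                 q_start=1, q_end=210),                       # cov 70%
        make_hit("short_vs_short", "short_nohit", pct_identity=99.0,
                 q_start=1, q_end=270),                       # subject short
    ]
    expected_removed = {
        "short_red1": "redundant_fragment_of_longer_contig",
        "short_red2": "redundant_fragment_of_longer_contig",
        "tiny1": "below_hard_minimum_length",
        "tiny2": "below_hard_minimum_length",
    }
    return contigs, hits, expected_removed
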