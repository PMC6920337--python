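import numpy as np
import pytest

from mrakit.ampliconminer import IUPAC_SETS, MSPI, PSTI, AmpliconSite
from mrakit.seqmodel import Genome, revcomp

# hand-enumerable toy layouts (coordinates worked out by hand)
TOY1 = "A" * 10 + "CTGCAG" + "T" * 70 + "CCGG" + "A" * 10
TOY2 = "T" * 4 + "CCGG" + "A" * 65 + "CTGCAG" + "TT"
TOY3 = "A" * 4 + "CTGCAG" + "T" * 30 + "CCGG" + "T" * 30 + "CCGG"


@pytest.fixture
def toy1():
    return Genome([("t1", TOY1)])


@pytest.fixture
def toy2():
    return Genome([("t2", TOY2)])


@pytest.fixture
def toy3():
    return Genome([("t3", TOY3)])


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def naive_find_sites(seq, enzyme):
    """Positionwise IUPAC scan, independent of the regex-based implementation."""
    hits = set()
    for motif in {enzyme.recognition, revcomp(enzyme.recognition)}:
        m = len(motif)
        for p in range(len(seq) - m + 1):
            if all(seq[p + i] in IUPAC_SETS[motif[i]] for i in range(m)):
                hits.add(p)
    return sorted(hits)


def brute_force_amplicons(genome, enzyme_a=PSTI, enzyme_b=MSPI,
                          min_len=60, max_len=250):
    """All-pairs oracle: test every ordered (site, site) pair directly.

    Returns the set of (chrom, insert_start, insert_end, orientation) keys.
    """
    out = set()
    for chrom, seq in genome.items():
        occ = []
        for enz, t in ((enzyme_a, "A"), (enzyme_b, "B")):
            for p in naive_find_sites(seq, enz):
                occ.append((p, p + enz.size, t))
        for i, (s1, e1, t1) in enumerate(occ):
            for j, (s2, e2, t2) in enumerate(occ):
                if i == j or t1 == t2 or s2 < e1:
                    continue
                length = s2 - e1
                if not min_len <= length <= max_len:
                    continue
                if any(
                    k not in (i, j) and os < s2 and oe > e1
                    for k, (os, oe, _) in enumerate(occ)
                ):
                    continue
                out.add((chrom, e1, s2, "A-first" if t1 == "A" else "B-first"))
    return out


def amplicon_keys(amplicons: list[AmpliconSite]):
    return {
        (a.chrom, a.insert_start, a.insert_end, a.orientation) for a in amplicons
    }
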