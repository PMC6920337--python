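import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrakit.ampliconminer import find_amplicons
from mrakit.primerdesign import (
    DEFAULT_TM_ANCHORS,
    PrimerPool,
    build_fusion_primers,
    consensus_degenerate,
    count_primer_pairs,
    expand_iupac,
    extract_primer_pair,
    iupac_degeneracy,
    iupac_matches,
    parse_pool_name,
    pool_from_pairs,
    tm_threshold,
    top_pairs,
)
from mrakit.seqmodel import ION_A, M13_TAIL, TRP1B, Genome, generate_genome, revcomp
from .conftest import random_seq


class TestExtraction:
    def test_toy1_both_sides(self, toy1):
        (amp,) = find_amplicons(toy1)
        a, b = extract_primer_pair(toy1, amp, 12, 12)
        assert a.sequence == "AAAAAACTGCAG"
        assert b.sequence == "TTTTTTTTCCGG"

    def test_b_first_mirrors_by_reverse_complement(self):
        g = Genome([("c", "T" * 12 + "CCGG" + "A" * 65 + "CTGCAG" + "T" * 12)])
        (amp,) = find_amplicons(g)
        assert amp.orientation == "B-first"
        a, b = extract_primer_pair(g, amp, 12, 12)
        # right PstI site at [81,87): A-primer = revcomp(fwd[81:93])
        assert a.sequence == revcomp(g["c"][81:93]) == "A" * 6 + "CTGCAG"
        assert b.sequence == g["c"][4:16] == "T" * 8 + "CCGG"

    def test_flank_off_contig_absent(self, toy2):
        (amp,) = find_amplicons(toy2)
        # B-side flank needs 12-4=8 nt before the left site at 4: off contig
        assert extract_primer_pair(toy2, amp, 12, 12) is None

    def test_flank_with_n_absent(self):
        g = Genome([("c", "ANAAAAAAA" + "CTGCAG" + "T" * 70 + "CCGG" + "A" * 14)])
        (amp,) = find_amplicons(g)
        assert extract_primer_pair(g, amp, 14, 12) is None
        assert extract_primer_pair(g, amp, 12, 12) is not None

    def test_length_bounds_enforced(self, toy1):
        (amp,) = find_amplicons(toy1)
        with pytest.raises(ValueError):
            extract_primer_pair(toy1, amp, 11, 12)
        with pytest.raises(ValueError):
            extract_primer_pair(toy1, amp, 12, 19)


class TestTmThreshold:
    def test_anchors_and_interpolation(self):
        assert tm_threshold(12) == 38.0
        assert tm_threshold(16) == 50.0
        assert tm_threshold(14) == pytest.approx(44.0)
        assert tm_threshold(18) == 50.0  # flat above the top anchor


class TestPairCounting:
    def _planted_shared_flanks(self):
        """3 amplicons with identical 12-nt flank contexts, 100-nt inserts."""
        rng = np.random.default_rng(21)
        flank_a = "GGTTCG"  # before CTGCAG
        flank_b = "CGAACCTT"  # after CCGG on the forward strand
        chunks = []
        coords = []
        pos = 0
        for i in range(3):
            pad = random_seq(rng, 400)
            insert = random_seq(rng, 100)
            construct = flank_a + "CTGCAG" + insert + "CCGG" + flank_b
            chunks += [pad, construct]
            pos += len(pad)
            coords.append(pos + 12)
            pos += len(construct)
        chunks.append(random_seq(rng, 200))
        seq = "".join(chunks)
        # scrub incidental motifs outside the planted constructs
        from mrakit.seqmodel import _find_motifs, _scrub_motifs

        protected = []
        for c in coords:
            protected += [(c - 6, c), (c + 100, c + 104)]
        chars = list(seq)
        _scrub_motifs(chars, ["CTGCAG", "CCGG"], protected, rng, 0.45)
        return Genome([("c", "".join(chars))])

    def test_shared_context_counts_aggregate(self):
        g = self._planted_shared_flanks()
        res = count_primer_pairs(g, 12, 12, insert_range=(77, 202))
        assert res.n_qualifying == 3
        assert len(res.table) == 1
        assert res.table.at[0, "count"] == 3
        assert res.table.at[0, "a_primer"] == "GGTTCGCTGCAG"
        assert res.table.at[0, "b_primer"] == revcomp("CCGG" + "CGAACCTT")

    def test_insert_below_range_excluded(self):
        g, _ = generate_genome(1, 6000, planted=[(60, "A-first")], seed=4)
        assert len(find_amplicons(g, min_len=60, max_len=250)) == 1
        res = count_primer_pairs(g, 12, 12, insert_range=(77, 202))
        assert res.n_qualifying == 0
        assert res.diagnostics["length_excluded"] == 1

    def test_low_tm_flank_screened_out(self):
        # AT-only 10-nt flank + CTGCAG: 16-mer Tm far below the 50 degC screen
        g = Genome([
            ("c", "G" * 4 + "TATATATATA" + "CTGCAG" + random_seq(np.random.default_rng(5), 100)
             .replace("CTGCAG", "ACGTAC").replace("CCGG", "ATCG")
             + "CCGG" + "GCGCGCGCGCGC" + "G" * 4)
        ])
        amps = find_amplicons(g, min_len=77, max_len=202)
        assert len(amps) == 1
        res = count_primer_pairs(g, 16, 16, insert_range=(77, 202))
        assert res.n_qualifying == 0
        assert res.diagnostics["tm_failed"] == 1

    def test_conservation_on_random_genome(self):
        rng = np.random.default_rng(30)
        g = Genome([("c", random_seq(rng, 100_000))])
        res = count_primer_pairs(g, 12, 12)
        assert res.table["count"].sum() == res.n_qualifying
        # ranked descending, deterministic tie-break
        t = res.table
        assert (t["count"].diff().dropna() <= 0).all()
        res2 = count_primer_pairs(g, 12, 12)
        assert t.equals(res2.table)

    def test_top_pairs_shares(self):
        import pandas as pd

        table = pd.DataFrame(
            {"a_primer": ["A", "C", "G"], "b_primer": ["T", "T", "T"],
             "count": [10, 5, 5]}
        )
        table["rank"] = [1, 2, 3]
        table["cum_count"] = table["count"].cumsum()
        table["cum_share"] = table["cum_count"] / table["count"].sum()
        assert top_pairs(table, 1)["cum_share"].iloc[-1] == pytest.approx(0.5)
        assert top_pairs(table, 3)["cum_share"].iloc[-1] == pytest.approx(1.0)
        assert len(top_pairs(table, 10)) == 3  # n beyond size -> whole table


class TestDegeneracy:
    @pytest.mark.parametrize(
        "iupac,expected",
        [("ACGT", 1), ("NNNNNN", 4096), ("AM", 2), ("RYSWKM", 64), ("BDHV", 81)],
    )
    def test_degeneracy_products(self, iupac, expected):
        assert iupac_degeneracy(iupac) == expected

    def test_pair_degeneracy_worked_example(self):
        """A 48-fold A-side with a 384-fold B-side combines to 18,432."""
        a = "NNVCTGCAG"  # 4*4*3 = 48, anchored 3' in the PstI site
        b = "NNNVRCCGG"  # 4*4*4*3*2 = 384, anchored 3' in the MspI site
        assert iupac_degeneracy(a) == 48
        assert iupac_degeneracy(b) == 384
        assert iupac_degeneracy(a) * iupac_degeneracy(b) == 18_432

    def test_enumeration_identity(self):
        rng = np.random.default_rng(9)
        codes = list("ACGTRYSWKMBDHVN")
        for _ in range(50):
            pat = "".join(rng.choice(codes, size=5))
            if iupac_degeneracy(pat) > 1024:
                continue
            expansions = expand_iupac(pat)
            assert len(set(expansions)) == iupac_degeneracy(pat)
            assert all(iupac_matches(pat, s) for s in expansions)

    def test_matches_basic(self):
        assert iupac_matches("AM", "AC")
        assert not iupac_matches("AM", "AG")
        with pytest.raises(ValueError, match="length"):
            iupac_matches("AM", "ACG")

    def test_invalid_code_position_reported(self):
        with pytest.raises(ValueError, match="position 2"):
            iupac_degeneracy("ACXG")


class TestConsensus:
    def test_two_sequences(self):
        d = consensus_degenerate(["AA", "AC"])
        assert d.iupac == "AM" and d.degeneracy == 2

    def test_single_sequence_identity(self):
        d = consensus_degenerate(["ACGT"])
        assert d.iupac == "ACGT" and d.degeneracy == 1

    def test_positionwise_union_over_covers(self):
        d = consensus_degenerate(["AC", "GT"])
        assert d.iupac == "RY"
        assert d.degeneracy == 4  # >= 2 distinct inputs; over-covers AT, GC

    def test_every_input_matches(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(6)]
        d = consensus_degenerate(seqs)
        assert all(iupac_matches(d.iupac, s) for s in seqs)
        assert d.degeneracy >= len(set(seqs))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            consensus_degenerate(["AA", "AAA"])


class TestFusionPrimers:
    def test_forward_concatenation(self):
        p = build_fusion_primers("AAAAAA", "CCAATT")["PCR1-forward"]
        assert p.sequence == "GATGTAAAACGACGGCCAGTGAAAAAACTGCAG"
        assert len(p.sequence) == 33

    def test_reverse_with_degenerate_spacer(self):
        p = build_fusion_primers("AAAAAA", "NNNNNN")["PCR1-reverse"]
        assert p.sequence == TRP1B + "NNNNNN" + "CCGG"
        assert len(p.sequence) == 23 + 6 + 4

    def test_pcr2_forward_length_with_barcode(self):
        p = build_fusion_primers("AAAAAA", "CCAATT", barcode="ACGTACGTAC")
        fwd = p["PCR2-forward"]
        assert fwd.sequence == ION_A + "ACGTACGTAC" + M13_TAIL
        assert len(fwd.sequence) == 30 + 10 + 21 == 61
        assert p["PCR2-reverse"].sequence == TRP1B

    @pytest.mark.parametrize(
        "sa,sb,bc",
        [("AAAAA", "CCAATT", None), ("AAAAAA", "CC", None),
         ("AAAAAA", "CCAATT", "ACGT")],
    )
    def test_out_of_range_parts_rejected(self, sa, sb, bc):
        with pytest.raises(ValueError):
            build_fusion_primers(sa, sb, bc)


class TestPoolNaming:
    def test_round_trip(self):
        pool = PrimerPool(k=16, pairs=(("A" * 16, "C" * 16),) * 7)
        assert pool.name == "16-14"
        assert parse_pool_name(pool.name) == (16, 14)

    def test_en_dash_accepted(self):
        assert parse_pool_name("16–14") == (16, 14)

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_pool_name("pool16")

    def test_pool_from_pairs(self):
        rng = np.random.default_rng(31)
        g = Genome([("c", random_seq(rng, 80_000))])
        res = count_primer_pairs(g, 12, 12)
        pool = pool_from_pairs(res.table, 3)
        assert pool.k == 12 and len(pool.pairs) == 3
        assert pool.name == "12-6"
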