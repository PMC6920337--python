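"""Restriction-anchored primer extraction, pair counting and degenerate design.

Every amplicon target offers one primer per side: the k bases of genomic
sequence ending 3' in the recognition site (k = 12..18, site included).
Because many loci share identical flanking k-mers, a small number of
distinct primer pairs covers a large fraction of all targets; counting and
ranking those pairs genome-wide is what drives panel selection. Degenerate
primers (IUPAC codes in the non-site positions) trade specificity for
coverage; their degeneracy is the product of per-position cardinalities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .ampliconminer import (
    MSPI,
    PSTI,
    IUPAC_SETS,
    AmpliconSite,
    RestrictionEnzyme,
    find_amplicons,
)
from .seqmodel import ION_A, M13_TAIL, TRP1B, Genome, revcomp
from .thermo import DEFAULT_PARAMS, ThermoParams, nn_tm

#: Tm screen anchors: minimum acceptable primer Tm by total primer length.
#: Thresholds between the anchors are linearly interpolated; lengths above
#: the top anchor use its value.
DEFAULT_TM_ANCHORS = {12: 38.0, 16: 50.0}


@dataclass(frozen=True)
class PrimerCandidate:
    """One restriction-anchored primer: genomic flank + recognition 3' end."""

    side: str  # "A" (PstI-side / forward) or "B" (MspI-side / reverse)
    sequence: str  # 5'->3' synthesized strand, ends in the recognition site
    k: int
    tm: float | None = None

    def __post_init__(self):
        if len(self.sequence) != self.k:
            raise ValueError("sequence length != k")


def tm_threshold(k: int, anchors: dict[int, float] = DEFAULT_TM_ANCHORS) -> float:
    """Length-dependent minimum Tm, interpolated between anchor lengths."""
    ks = sorted(anchors)
    if k <= ks[0]:
        return anchors[ks[0]]
    if k >= ks[-1]:
        return anchors[ks[-1]]
    for lo, hi in zip(ks, ks[1:]):
        if lo <= k <= hi:
            w = (k - lo) / (hi - lo)
            return anchors[lo] * (1 - w) + anchors[hi] * w
    raise AssertionError("unreachable")


def extract_primer_pair(
    genome: Genome,
    amplicon: AmpliconSite,
    k_a: int = 16,
    k_b: int = 16,
    enzyme_a: RestrictionEnzyme = PSTI,
    enzyme_b: RestrictionEnzyme = MSPI,
) -> tuple[PrimerCandidate, PrimerCandidate] | None:
    """Extract the (A-side, B-side) primer candidates of one amplicon.

    For an A-first amplicon with A-site [p, p+|A|) the A-primer is the
    forward strand [p-(k_a-|A|), p+|A|); the B-primer is the reverse
    complement of [q, q+k_b) where the B-site is [q, q+|B|), so that each
    primer ends 3' in its recognition sequence and points into the insert.
    B-first amplicons mirror through the reverse complement. Returns None
    when a flank runs off the contig or contains N.
    """
    for k in (k_a, k_b):
        if not 12 <= k <= 18:
            raise ValueError(f"primer length {k} outside 12-18")
    seq = genome[amplicon.chrom]
    if amplicon.orientation == "A-first":
        p = amplicon.left_interval[0]
        q = amplicon.right_interval[0]
        a_start = p - (k_a - enzyme_a.size)
        if a_start < 0 or q + k_b > len(seq):
            return None
        a_seq = seq[a_start : p + enzyme_a.size]
        b_seq = revcomp(seq[q : q + k_b])
    else:  # B-first: A-site on the right, B-site on the left
        q = amplicon.left_interval[0]
        p = amplicon.right_interval[0]
        b_start = q - (k_b - enzyme_b.size)
        if b_start < 0 or p + k_a > len(seq):
            return None
        b_seq = seq[b_start : q + enzyme_b.size]
        a_seq = revcomp(seq[p : p + k_a])
    if "N" in a_seq or "N" in b_seq:
        return None
    return (
        PrimerCandidate("A", a_seq, k_a),
        PrimerCandidate("B", b_seq, k_b),
    )


@dataclass
class PairCountResult:
    """Ranked genome-wide primer-pair counts plus screening diagnostics."""

    table: pd.DataFrame  # a_primer, b_primer, count, rank, cum_count, cum_share
    n_qualifying: int
    diagnostics: dict[str, int] = field(default_factory=dict)


def count_primer_pairs(
    genome: Genome,
    k_a: int,
    k_b: int | None = None,
    insert_range: tuple[int, int] = (77, 202),
    tm_anchors: dict[int, float] = DEFAULT_TM_ANCHORS,
    params: ThermoParams = DEFAULT_PARAMS,
    enzyme_a: RestrictionEnzyme = PSTI,
    enzyme_b: RestrictionEnzyme = MSPI,
    amplicons: list[AmpliconSite] | None = None,
) -> PairCountResult:
    """Count amplicons per distinct (A-primer, B-primer) sequence pair.

    An amplicon qualifies when its insert length is within ``insert_range``,
    both flank primers are extractable (on-contig, N-free) and both pass
    the length-dependent Tm screen. Conservation holds by construction:
    the counts sum to the number of qualifying amplicons. Rows are ranked
    by count descending, ties broken lexicographically on (A, B) sequence.
    """
    if k_b is None:
        k_b = k_a
    if amplicons is None:
        # mine below the lower bound too, so short targets show up in the
        # length_excluded diagnostic rather than vanishing silently
        amplicons = find_amplicons(genome, enzyme_a, enzyme_b, 1, insert_range[1])
    thr_a = tm_threshold(k_a, tm_anchors)
    thr_b = tm_threshold(k_b, tm_anchors)
    diag = {"mined": len(amplicons), "length_excluded": 0,
            "flank_unavailable": 0, "tm_failed": 0}
    tm_cache: dict[str, float] = {}

    def cached_tm(s: str) -> float:
        if s not in tm_cache:
            tm_cache[s] = nn_tm(s, params)
        return tm_cache[s]

    counts: dict[tuple[str, str], int] = {}
    n_qual = 0
    for amp in amplicons:
        if not insert_range[0] <= amp.insert_len <= insert_range[1]:
            diag["length_excluded"] += 1
            continue
        pair = extract_primer_pair(genome, amp, k_a, k_b, enzyme_a, enzyme_b)
        if pair is None:
            diag["flank_unavailable"] += 1
            continue
        a, b = pair
        if cached_tm(a.sequence) < thr_a or cached_tm(b.sequence) < thr_b:
            diag["tm_failed"] += 1
            continue
        counts[(a.sequence, b.sequence)] = counts.get((a.sequence, b.sequence), 0) + 1
        n_qual += 1
    table = pd.DataFrame(
        [(a, b, c) for (a, b), c in counts.items()],
        columns=["a_primer", "b_primer", "count"],
    )
    table = table.sort_values(
        ["count", "a_primer", "b_primer"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = table.index + 1
    table["cum_count"] = table["count"].cumsum()
    total = table["count"].sum()
    table["cum_share"] = table["cum_count"] / total if total else 0.0
    return PairCountResult(table=table, n_qualifying=n_qual, diagnostics=diag)


def top_pairs(result: PairCountResult | pd.DataFrame, n: int) -> pd.DataFrame:
    """The n highest-count pairs with cumulative counts and shares."""
    if n < 1:
        raise ValueError("n must be >= 1")
    table = result.table if isinstance(result, PairCountResult) else result
    return table.head(n).copy()


# ---------------------------------------------------------------------------
# IUPAC degeneracy


def iupac_degeneracy(iupac: str) -> int:
    """Number of concrete sequences an IUPAC string represents."""
    d = 1
    for i, code in enumerate(iupac.upper()):
        if code not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}")
        d *= len(IUPAC_SETS[code])
    return d


def iupac_matches(iupac: str, seq: str) -> bool:
    """True iff every base of ``seq`` is within the IUPAC code at that position."""
    if len(iupac) != len(seq):
        raise ValueError(
            f"length mismatch: pattern {len(iupac)} vs sequence {len(seq)}"
        )
    return all(b in IUPAC_SETS[c] for c, b in zip(iupac.upper(), seq.upper()))


def expand_iupac(iupac: str, limit: int = 65536) -> list[str]:
    """All concrete expansions of an IUPAC string (guarded by ``limit``)."""
    if iupac_degeneracy(iupac) > limit:
        raise ValueError("degeneracy exceeds expansion limit")
    seqs = [""]
    for code in iupac.upper():
        seqs = [s + b for s in seqs for b in IUPAC_SETS[code]]
    return seqs


_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items()}


@dataclass(frozen=True)
class DegeneratePrimer:
    side: str
    iupac: str

    @property
    def degeneracy(self) -> int:
        return iupac_degeneracy(self.iupac)


def consensus_degenerate(primer_seqs: list[str], side: str = "A") -> DegeneratePrimer:
    """Minimal per-position IUPAC union covering all input sequences.

    Every input matches the result; the result's degeneracy is at least the
    number of distinct inputs (and can exceed it — the positionwise union
    over-covers combinations not present in the inputs).
    """
    if not primer_seqs:
        raise ValueError("need at least one sequence")
    n = len(primer_seqs[0])
    if any(len(s) != n for s in primer_seqs):
        raise ValueError("sequences must have equal length")
    out = []
    for i in range(n):
        union = frozenset().union(
            *(frozenset(IUPAC_SETS[s[i].upper()]) for s in primer_seqs)
        )
        out.append(_SET_TO_CODE[union])
    return DegeneratePrimer(side=side, iupac="".join(out))


# ---------------------------------------------------------------------------
# fusion primers (two-step PCR) and pool naming


@dataclass(frozen=True)
class FusionPrimer:
    role: str  # PCR1-forward | PCR1-reverse | PCR2-forward | PCR2-reverse
    parts: tuple[tuple[str, str], ...]  # (part name, sequence)

    @property
    def sequence(self) -> str:
        return "".join(s for _, s in self.parts)


def build_fusion_primers(
    spacer_a: str,
    spacer_b: str,
    barcode: str | None = None,
    site_a: str = "CTGCAG",
    site_b: str = "CCGG",
) -> dict[str, FusionPrimer]:
    """Assemble the two-step-PCR fusion primer set.

    PCR1 forward = M13 tail + spacer (6-10 nt, specific or IUPAC) + A-site;
    PCR1 reverse = trP1B + spacer (6-12 nt) + B-site; PCR2 forward =
    Ion-A adapter + barcode (10-12 nt) + M13 tail; PCR2 reverse = trP1B.
    """
    if not 6 <= len(spacer_a) <= 10:
        raise ValueError(f"A-spacer length {len(spacer_a)} outside 6-10")
    if not 6 <= len(spacer_b) <= 12:
        raise ValueError(f"B-spacer length {len(spacer_b)} outside 6-12")
    if barcode is not None and not 10 <= len(barcode) <= 12:
        raise ValueError(f"barcode length {len(barcode)} outside 10-12")
    primers = {
        "PCR1-forward": FusionPrimer(
            "PCR1-forward",
            (("m13_tail", M13_TAIL), ("spacer", spacer_a.upper()), ("site", site_a)),
        ),
        "PCR1-reverse": FusionPrimer(
            "PCR1-reverse",
            (("trp1b", TRP1B), ("spacer", spacer_b.upper()), ("site", site_b)),
        ),
        "PCR2-reverse": FusionPrimer("PCR2-reverse", (("trp1b", TRP1B),)),
    }
    if barcode is not None:
        primers["PCR2-forward"] = FusionPrimer(
            "PCR2-forward",
            (("ion_a", ION_A), ("barcode", barcode.upper()), ("m13_tail", M13_TAIL)),
        )
    return primers


@dataclass(frozen=True)
class PrimerPool:
    """A named pool of specific primer pairs, e.g. '16-14' = 16-mer A-primers,
    14 primers (7 pairs) total."""

    k: int
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("empty pool")
        if any(len(a) != self.k for a, _ in self.pairs):
            raise ValueError("all A-primers must have the pool's length")

    @property
    def name(self) -> str:
        return f"{self.k}-{2 * len(self.pairs)}"


_POOL_NAME_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


def parse_pool_name(name: str) -> tuple[int, int]:
    """Parse 'KK-NN' (hyphen or en-dash) -> (primer length, primer count)."""
    m = _POOL_NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed pool name {name!r}")
    return int(m.group(1)), int(m.group(2))


def pool_from_pairs(table: pd.DataFrame, n: int) -> PrimerPool:
    """Build a specific pool from the top-n rows of a pair-count table."""
    sub = table.head(n)
    pairs = tuple(zip(sub["a_primer"], sub["b_primer"]))
    return PrimerPool(k=len(pairs[0][0]), pairs=pairs)
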