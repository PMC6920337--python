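"""In-silico PCR: predict which mined amplicons a primer set amplifies, and
simulate the resulting two-step-PCR sequencing library.

Matching is anchored: only the k genomic bases ending at each restriction
site are compared against the primers — exact equality for specific pools,
IUPAC containment for degenerate pairs. Off-site binding and internal
mismatches are not modeled; flank identity is the selectivity mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ampliconminer import MSPI, PSTI, AmpliconSite, RestrictionEnzyme, find_amplicons
from .primerdesign import (
    DegeneratePrimer,
    PrimerPool,
    extract_primer_pair,
    iupac_matches,
    tm_threshold,
    DEFAULT_TM_ANCHORS,
)
from .seqmodel import M13_TAIL, TRP1B, Genome, ReadRecord, revcomp
from .thermo import DEFAULT_PARAMS, ThermoParams, nn_tm


@dataclass
class PrimerSet:
    """Either a pool of specific pairs or one degenerate pair.

    ``pairs`` holds (A-seq, B-seq) tuples for a specific pool;
    ``degenerate`` holds (A IUPAC, B IUPAC) for a degenerate pair.
    """

    kind: str  # "specific-pool" | "degenerate-pair"
    pairs: tuple[tuple[str, str], ...] = ()
    degenerate: tuple[str, str] | None = None

    def __post_init__(self):
        if self.kind == "specific-pool":
            if not self.pairs:
                raise ValueError("specific pool must contain at least one pair")
            self._index = {p: i for i, p in enumerate(self.pairs)}
            self._ks = sorted({(len(a), len(b)) for a, b in self.pairs})
        elif self.kind == "degenerate-pair":
            if self.degenerate is None:
                raise ValueError("degenerate-pair needs (A, B) IUPAC strings")
            self._ks = [(len(self.degenerate[0]), len(self.degenerate[1]))]
        else:
            raise ValueError(f"unknown primer set kind {self.kind!r}")

    @classmethod
    def from_pool(cls, pool: PrimerPool) -> "PrimerSet":
        return cls(kind="specific-pool", pairs=pool.pairs)

    @classmethod
    def from_degenerate(
        cls, a: DegeneratePrimer | str, b: DegeneratePrimer | str
    ) -> "PrimerSet":
        a = a.iupac if isinstance(a, DegeneratePrimer) else a
        b = b.iupac if isinstance(b, DegeneratePrimer) else b
        return cls(kind="degenerate-pair", degenerate=(a, b))

    def match(self, a_seq: str, b_seq: str) -> tuple[str, str] | None:
        """The matching member pair, or None."""
        if self.kind == "specific-pool":
            return (a_seq, b_seq) if (a_seq, b_seq) in self._index else None
        da, db = self.degenerate
        if iupac_matches(da, a_seq) and iupac_matches(db, b_seq):
            return (da, db)
        return None

    @property
    def k_sides(self) -> list[tuple[int, int]]:
        return list(self._ks)


@dataclass(frozen=True)
class PredictedAmplicon:
    site: AmpliconSite
    matched_pair: tuple[str, str]  # pool member or degenerate pattern
    a_candidate: str  # concrete genomic primer sequences
    b_candidate: str
    tm_a: float
    tm_b: float


def predict_amplicons(
    genome: Genome,
    primer_set: PrimerSet,
    insert_range: tuple[int, int] = (60, 250),
    tm_screen: bool = False,
    tm_anchors: dict[int, float] = DEFAULT_TM_ANCHORS,
    params: ThermoParams = DEFAULT_PARAMS,
    enzyme_a: RestrictionEnzyme = PSTI,
    enzyme_b: RestrictionEnzyme = MSPI,
    amplicons: list[AmpliconSite] | None = None,
) -> list[PredictedAmplicon]:
    """Amplicons whose anchored flank k-mers match the primer set on both sides.

    Predictions are always a subset of ``find_amplicons`` at the same
    length range; a fully degenerate (all-N spacer) pair with the Tm screen
    off predicts exactly the mined, primer-extractable set.
    """
    if amplicons is None:
        amplicons = find_amplicons(
            genome, enzyme_a, enzyme_b, insert_range[0], insert_range[1]
        )
    out: list[PredictedAmplicon] = []
    for amp in amplicons:
        if not insert_range[0] <= amp.insert_len <= insert_range[1]:
            continue
        for k_a, k_b in primer_set.k_sides:
            cand = extract_primer_pair(genome, amp, k_a, k_b, enzyme_a, enzyme_b)
            if cand is None:
                continue
            a, b = cand
            member = primer_set.match(a.sequence, b.sequence)
            if member is None:
                continue
            tm_a = nn_tm(a.sequence, params)
            tm_b = nn_tm(b.sequence, params)
            if tm_screen and (
                tm_a < tm_threshold(k_a, tm_anchors)
                or tm_b < tm_threshold(k_b, tm_anchors)
            ):
                continue
            out.append(
                PredictedAmplicon(amp, member, a.sequence, b.sequence, tm_a, tm_b)
            )
            break  # one prediction per amplicon
    return out


# ---------------------------------------------------------------------------
# library simulation

_BASES = np.array(list("ACGT"))


def _construct_read(
    barcode: str,
    spacer_a: str,
    insert: str,
    spacer_b_rc: str,
    site_a: str,
    site_b: str,
) -> str:
    """Full-length top strand of one sequenced amplicon (5'->3').

    Layout: barcode + M13 tail + A-spacer + A-site + insert + B-site +
    revcomp(B-spacer) + revcomp(trP1B).
    """
    return (
        barcode + M13_TAIL + spacer_a + site_a + insert + site_b
        + spacer_b_rc + revcomp(TRP1B)
    )


@dataclass
class LibrarySim:
    reads: list[ReadRecord]
    truth: pd.DataFrame  # read_id, sample, chrom, insert_start, insert_end


def simulate_library(
    genomes_by_sample: dict[str, Genome],
    primer_set: PrimerSet,
    barcodes_by_sample: dict[str, str],
    depth_mean: float = 5.0,
    depth_dispersion: float | None = 2.0,
    read_len_mean: float = 200.0,
    read_len_sd: float = 60.0,
    read_len_min: int = 25,
    error_rate: float = 0.0,
    seed: int = 0,
    insert_range: tuple[int, int] = (60, 250),
    enzyme_a: RestrictionEnzyme = PSTI,
    enzyme_b: RestrictionEnzyme = MSPI,
    qual_char: str = "I",
    error_qual_char: str = "#",
) -> LibrarySim:
    """Simulate variable-length amplicon reads for a multiplexed library.

    Per predicted amplicon and sample, the read count is drawn from a
    negative binomial (mean ``depth_mean``, dispersion ``depth_dispersion``;
    ``None`` gives a constant round(depth_mean) — useful for exact
    round-trip tests). Read lengths follow a normal distribution truncated
    below at ``read_len_min`` and above at the construct length. Substitution
    errors occur per base at ``error_rate`` and are flagged with a low
    quality character. Deterministic under ``seed``.
    """
    missing = set(genomes_by_sample) - set(barcodes_by_sample)
    if missing:
        raise ValueError(f"samples without barcode: {sorted(missing)}")
    barcodes = list(barcodes_by_sample.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")
    for s, bc in barcodes_by_sample.items():
        if not 10 <= len(bc) <= 12:
            raise ValueError(f"barcode for {s!r} must be 10-12 nt")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    truth_rows = []
    serial = 0
    for sample in sorted(genomes_by_sample):
        genome = genomes_by_sample[sample]
        barcode = barcodes_by_sample[sample]
        predicted = predict_amplicons(
            genome, primer_set, insert_range,
            enzyme_a=enzyme_a, enzyme_b=enzyme_b,
        )
        for pred in predicted:
            amp = pred.site
            if depth_dispersion is None:
                depth = int(round(depth_mean))
            else:
                p = depth_dispersion / (depth_dispersion + depth_mean)
                depth = int(rng.negative_binomial(depth_dispersion, p))
            if depth == 0:
                continue
            seq = genome[amp.chrom]
            insert = seq[amp.insert_start : amp.insert_end]
            if amp.orientation == "B-first":
                # sequencing proceeds from the A (forward-primer) side
                insert = revcomp(insert)
            k_a = len(pred.a_candidate)
            k_b = len(pred.b_candidate)
            spacer_a = pred.a_candidate[: k_a - enzyme_a.size]
            spacer_b = pred.b_candidate[: k_b - enzyme_b.size]
            full = _construct_read(
                barcode, spacer_a, insert, revcomp(spacer_b),
                enzyme_a.recognition, enzyme_b.recognition,
            )
            for _ in range(depth):
                L = int(round(rng.normal(read_len_mean, read_len_sd)))
                L = max(read_len_min, min(L, len(full)))
                bases = full[:L]
                qual = qual_char * L
                if error_rate > 0:
                    errs = np.flatnonzero(rng.random(L) < error_rate)
                    if errs.size:
                        blist = list(bases)
                        qlist = list(qual)
                        for i in errs:
                            blist[i] = str(
                                rng.choice([b for b in "ACGT" if b != blist[i]])
                            )
                            qlist[i] = error_qual_char
                        bases = "".join(blist)
                        qual = "".join(qlist)
                rid = f"{sample}.{serial}"
                serial += 1
                reads.append(ReadRecord(rid, bases, qual))
                truth_rows.append(
                    {
                        "read_id": rid,
                        "sample": sample,
                        "chrom": amp.chrom,
                        "insert_start": amp.insert_start,
                        "insert_end": amp.insert_end,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "chrom", "insert_start", "insert_end"],
    )
    return LibrarySim(reads=reads, truth=truth)
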