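"""Genome-wide mining of restriction-site-delimited amplicon targets.

An amplicon target is a genomic insert flanked by the recognition sites of
two *different* enzymes (default PstI/MspI), whose length (sites excluded)
falls in a configured window and which contains no further occurrence of
either recognition motif. Both forward-strand orders of the two site types
("either direction") are reported. Summaries cover inter-amplicon spacing,
per-megabase density and the insert-length spectrum with a linear trend.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .seqmodel import Genome, revcomp

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition motif plus the remnant kept in preprocessed reads."""

    name: str
    recognition: str
    remnant: str

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        if not self.recognition.endswith(self.remnant) and self.remnant != self.recognition:
            raise ValueError(
                f"{self.name}: remnant {self.remnant!r} is not a suffix of "
                f"recognition {self.recognition!r}"
            )

    @property
    def size(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


PSTI = RestrictionEnzyme("PstI", "CTGCAG", "TGCAG")
MSPI = RestrictionEnzyme("MspI", "CCGG", "CCGG")
ENZYMES = {"PstI": PSTI, "MspI": MSPI}


@dataclass(frozen=True)
class AmpliconSite:
    """One mined target; coordinates 0-based half-open, sites excluded."""

    chrom: str
    insert_start: int
    insert_end: int
    orientation: str  # "A-first" | "B-first" (forward-strand site order)
    left_site: str  # enzyme name
    right_site: str
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]

    @property
    def insert_len(self) -> int:
        return self.insert_end - self.insert_start


def iupac_regex(motif: str) -> str:
    """Translate an IUPAC motif into a regex character-class pattern."""
    parts = []
    for i, code in enumerate(motif.upper()):
        try:
            s = IUPAC_SETS[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}") from None
        parts.append(s if len(s) == 1 else f"[{s}]")
    return "".join(parts)


def find_sites(genome: Genome, enzyme: RestrictionEnzyme) -> dict[str, list[int]]:
    """All match start positions of the recognition motif per chromosome.

    Both the motif and its reverse complement are matched on the forward
    strand; palindromes are counted once. Motif windows containing N never
    match (the pattern classes exclude N).
    """
    patterns = {iupac_regex(enzyme.recognition)}
    patterns.add(iupac_regex(revcomp(enzyme.recognition)))
    out: dict[str, list[int]] = {}
    for chrom, seq in genome.items():
        hits: set[int] = set()
        for pat in patterns:
            hits.update(m.start() for m in re.finditer(f"(?={pat})", seq))
        out[chrom] = sorted(hits)
    return out


def find_amplicons(
    genome: Genome,
    enzyme_a: RestrictionEnzyme = PSTI,
    enzyme_b: RestrictionEnzyme = MSPI,
    min_len: int = 60,
    max_len: int = 250,
    with_diagnostics: bool = False,
):
    """Mine all A/B-delimited amplicon targets of a genome.

    A valid target is a pair of site occurrences of *different* enzymes,
    in either forward-strand order, whose insert (the open span between
    the two site intervals) has ``min_len <= length <= max_len`` and is
    intersected by no other occurrence of either motif. Output is sorted
    by (chromosome order, insert_start). With ``with_diagnostics`` the
    count of skipped overlapping A/B occurrences is also returned.
    """
    if enzyme_a.name == enzyme_b.name:
        raise ValueError("the two enzymes must be distinct")
    if not 1 <= min_len <= max_len:
        raise ValueError("require 1 <= min_len <= max_len")
    sites_a = find_sites(genome, enzyme_a)
    sites_b = find_sites(genome, enzyme_b)
    amplicons: list[AmpliconSite] = []
    n_overlapping = 0
    max_motif = max(enzyme_a.size, enzyme_b.size)
    for chrom in genome.names:
        occ = sorted(
            [(p, p + enzyme_a.size, "A") for p in sites_a[chrom]]
            + [(p, p + enzyme_b.size, "B") for p in sites_b[chrom]]
        )
        starts = [o[0] for o in occ]
        ends = {i: o[1] for i, o in enumerate(occ)}
        for i, (si, ei, ti) in enumerate(occ):
            for j in range(i + 1, len(occ)):
                sj, ej, tj = occ[j]
                if sj > ei + max_len:
                    break
                if ti == tj:
                    continue
                if sj < ei:  # the two site occurrences overlap each other
                    n_overlapping += 1
                    continue
                ins_len = sj - ei
                if ins_len < min_len or ins_len > max_len:
                    continue
                # intervening occurrence: interval intersects the open insert
                lo = bisect_left(starts, ei - max_motif + 1)
                hi = bisect_right(starts, sj - 1)
                if any(
                    k != i and k != j and ends[k] > ei and occ[k][0] < sj
                    for k in range(lo, hi)
                ):
                    continue
                left_enz, right_enz = (enzyme_a, enzyme_b) if ti == "A" else (enzyme_b, enzyme_a)
                amplicons.append(
                    AmpliconSite(
                        chrom=chrom,
                        insert_start=ei,
                        insert_end=sj,
                        orientation="A-first" if ti == "A" else "B-first",
                        left_site=left_enz.name,
                        right_site=right_enz.name,
                        left_interval=(si, ei),
                        right_interval=(sj, ej),
                    )
                )
    order = {name: k for k, name in enumerate(genome.names)}
    amplicons.sort(key=lambda a: (order[a.chrom], a.insert_start, a.insert_end))
    if with_diagnostics:
        return amplicons, {"overlapping_site_pairs_skipped": n_overlapping}
    return amplicons


def gap_stats(amplicons: list[AmpliconSite]) -> pd.DataFrame:
    """Start-to-start spacing statistics of consecutive amplicons per chromosome.

    Returns a frame indexed by chromosome with columns n, mean, sd, max;
    chromosomes with fewer than two amplicons get NaN statistics. The sd is
    the sample standard deviation (ddof=1).
    """
    rows = {}
    by_chrom: dict[str, list[int]] = {}
    for a in amplicons:
        by_chrom.setdefault(a.chrom, []).append(a.insert_start)
    for chrom, starts in by_chrom.items():
        starts = sorted(starts)
        if len(starts) < 2:
            rows[chrom] = {"n": len(starts), "mean": np.nan, "sd": np.nan, "max": np.nan}
            continue
        d = np.diff(starts).astype(float)
        rows[chrom] = {
            "n": len(starts),
            "mean": d.mean(),
            "sd": d.std(ddof=1) if len(d) > 1 else np.nan,
            "max": d.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DensityTrack:
    """Per-bin feature counts along chromosomes (default 1 Mb bins)."""

    bin_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": chrom, "bin_start": i * self.bin_size, "count": int(c)}
            for chrom, arr in self.counts.items()
            for i, c in enumerate(arr)
        ]
        return pd.DataFrame(rows, columns=["chrom", "bin_start", "count"])


def density_track(
    amplicons: list[AmpliconSite],
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
) -> DensityTrack:
    """Bin amplicons into half-open windows of ``bin_size`` by insert_start.

    Empty bins are reported as zero out to the chromosome end, and the sum
    of all bins equals the number of amplicons (conservation).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    track = DensityTrack(bin_size=int(bin_size))
    for chrom, length in chrom_lengths.items():
        n_bins = max(1, -(-length // bin_size))
        track.counts[chrom] = np.zeros(n_bins, dtype=int)
    for a in amplicons:
        track.counts[a.chrom][a.insert_start // bin_size] += 1
    return track


@dataclass
class LengthSpectrum:
    lengths: np.ndarray  # the integer length axis [min_len..max_len]
    counts: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None


def length_spectrum(
    amplicons: list[AmpliconSite],
    min_len: int,
    max_len: int,
    fit: bool = True,
) -> LengthSpectrum:
    """Insert-length histogram with an OLS count-vs-length trend line.

    The regression (count ~ length) quantifies skew of the spectrum; a
    negative slope means shorter inserts are over-represented. r2 is
    undefined (None) for degenerate fits (fewer than 2 distinct counts of
    variation, zero-variance axis).
    """
    lengths = np.arange(min_len, max_len + 1)
    counts = np.zeros(lengths.size, dtype=int)
    for a in amplicons:
        if min_len <= a.insert_len <= max_len:
            counts[a.insert_len - min_len] += 1
    spec = LengthSpectrum(lengths=lengths, counts=counts)
    if fit:
        if lengths.size < 2:
            raise ValueError("need >= 2 lengths to fit a trend")
        if np.ptp(counts) == 0:
            # flat spectrum: slope 0 explains all of nothing; report r2 = 0
            spec.slope = 0.0
            spec.intercept = float(counts[0])
            spec.r2 = 0.0
        else:
            res = _scipy_stats.linregress(lengths, counts)
            spec.slope = float(res.slope)
            spec.intercept = float(res.intercept)
            spec.r2 = None if np.isnan(res.rvalue) else float(res.rvalue**2)
    return spec


def amplicons_to_frame(amplicons: list[AmpliconSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom,
                "insert_start": a.insert_start,
                "insert_end": a.insert_end,
                "orientation": a.orientation,
                "insert_len": a.insert_len,
                "left_site": a.left_site,
                "right_site": a.right_site,
            }
            for a in amplicons
        ],
        columns=[
            "chrom", "insert_start", "insert_end", "orientation",
            "insert_len", "left_site", "right_site",
        ],
    )


def write_amplicon_tsv(amplicons: list[AmpliconSite], path) -> None:
    amplicons_to_frame(amplicons).to_csv(path, sep="\t", index=False)


def write_amplicon_bed(amplicons: list[AmpliconSite], path) -> None:
    """BED6 export: name = left/right site types, score = insert length."""
    with open(path, "w") as fh:
        for i, a in enumerate(amplicons):
            strand = "+" if a.orientation == "A-first" else "-"
            fh.write(
                f"{a.chrom}\t{a.insert_start}\t{a.insert_end}\t"
                f"{a.left_site}-{a.right_site}.{i}\t{a.insert_len}\t{strand}\n"
            )
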