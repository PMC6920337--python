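"""Sequence data model, FASTA/FASTQ I/O and synthetic-genome generation.

The synthetic generator plants restriction-site-delimited amplicon targets
(site + insert + site) at known, truth-tracked coordinates inside an
otherwise motif-free background, so that downstream mining can be checked
for exact recovery. Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: adapter/tail constants of the two-step PCR construct
M13_TAIL = "GATGTAAAACGACGGCCAGTG"
TRP1B = "CCTCTCTATGGGCAGTCGGTGAT"
ION_A = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Ordered collection of named nucleotide sequences (A/C/G/T/N).

    Names are unique, bases are uppercased on construction, and empty
    sequences are rejected.
    """

    def __init__(self, sequences: Iterable[tuple[str, str]]):
        self._names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, bases in sequences:
            if name in self._seqs:
                raise ValueError(f"duplicate sequence name: {name!r}")
            bases = bases.upper()
            if not bases:
                raise ValueError(f"empty sequence: {name!r}")
            bad = re.search(f"[^{''.join(sorted(IUPAC_ALPHABET))}]", bases)
            if bad:
                raise ValueError(
                    f"invalid character {bad.group()!r} in {name!r} "
                    f"at offset {bad.start()}"
                )
            self._names.append(name)
            self._seqs[name] = bases

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self._seqs[n]) for n in self._names}

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._names)

    def items(self):
        for n in self._names:
            yield n, self._seqs[n]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self._names == other._names and self._seqs == other._seqs

    def reverse_complement(self) -> "Genome":
        return Genome((n, revcomp(s)) for n, s in self.items())


@dataclass
class ReadRecord:
    """A FASTQ read with Sanger (Phred+33) quality."""

    id: str
    bases: str
    quality: str

    def __post_init__(self):
        if len(self.bases) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: bases ({len(self.bases)}) and quality "
                f"({len(self.quality)}) lengths differ"
            )


@dataclass
class PlantedAmplicon:
    """Truth record for one planted site-delimited target."""

    chrom: str
    insert_start: int  # 0-based, half-open; restriction sites excluded
    insert_end: int
    orientation: str  # "A-first" | "B-first"
    insert_seq: str
    left_site: str  # recognition sequence on the forward strand
    right_site: str

    @property
    def insert_len(self) -> int:
        return self.insert_end - self.insert_start


@dataclass
class PlantedTruth:
    """All planted amplicons of a synthetic genome."""

    amplicons: list[PlantedAmplicon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.amplicons)

    def intervals(self) -> set[tuple[str, int, int]]:
        return {(a.chrom, a.insert_start, a.insert_end) for a in self.amplicons}


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Genome:
    """Load a (possibly gzipped) multi-record FASTA into a Genome.

    Lowercase is normalized to uppercase; duplicate names and non-IUPAC
    characters raise ``ValueError`` naming the offending record/offset.
    """
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    return Genome(records)


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    """Write a Genome as wrapped FASTA (60 columns by default)."""
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[ReadRecord]:
    """Load a 4-line Sanger FASTQ; enforces the base/quality length invariant."""
    reads = []
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid = title.split()[0]
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {rid!r}: bases and quality lengths differ"
                )
            reads.append(ReadRecord(rid, seq, qual))
    return reads


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# synthetic genomes


def _find_motifs(seq: str, motifs: Sequence[str]) -> list[tuple[int, int]]:
    """All (start, end) occurrences of any motif or its reverse complement."""
    hits = set()
    for m in motifs:
        for pat in {m, revcomp(m)}:
            for match in re.finditer(f"(?={pat})", seq):
                hits.add((match.start(), match.start() + len(pat)))
    return sorted(hits)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _scrub_motifs(
    seq: list[str],
    motifs: Sequence[str],
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    gc: float,
    max_rounds: int = 200,
) -> None:
    """Mutate bases in place until the only motif occurrences are `protected`.

    Each offending occurrence gets one base (outside protected intervals)
    re-drawn; repeated until clean. Deterministic under the supplied rng.
    """
    protected_set = set(protected)
    protected_mask = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        protected_mask[s:e] = True
    for _ in range(max_rounds):
        hits = [
            h
            for h in _find_motifs("".join(seq), motifs)
            if h not in protected_set
        ]
        if not hits:
            return
        for s, e in hits:
            editable = [i for i in range(s, e) if not protected_mask[i]]
            if not editable:
                continue  # coincident with protected sites; cannot happen for distinct coords
            i = int(rng.choice(editable))
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[i] = str(rng.choice(alternatives))
    raise RuntimeError("failed to scrub spurious motifs from synthetic genome")


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    gc: float = 0.45,
    planted: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    site_a: str = "CTGCAG",
    site_b: str = "CCGG",
    chrom_prefix: str = "chr",
    margin: int = 300,
) -> tuple[Genome, PlantedTruth]:
    """Generate a motif-free background genome with planted amplicon targets.

    Parameters
    ----------
    planted
        List of ``(insert_len, orientation)`` with orientation ``"A-first"``
        (site_a + insert + site_b on the forward strand) or ``"B-first"``.
    margin
        Minimum spacing kept between planted constructs and to chromosome
        ends. It must cover the longest primer flank (12 nt) so every
        planted target is primer-extractable, and must exceed the upper
        insert bound used in mining (default 250) so that the facing sites
        of adjacent constructs can never pair into an unplanned target.

    Returns the genome and the exact planted truth. The planted sites are
    the *only* occurrences of either recognition motif (either strand), so
    mining output can be compared to the truth set exactly.
    """
    rng = np.random.default_rng(seed)
    motifs = [site_a, site_b]
    for L, orient in planted:
        if L < 1:
            raise ValueError("insert_len must be >= 1")
        if orient not in ("A-first", "B-first"):
            raise ValueError(f"bad orientation {orient!r}")

    # round-robin assignment of plants to chromosomes
    per_chrom: list[list[tuple[int, str]]] = [[] for _ in range(n_chrom)]
    for idx, item in enumerate(planted):
        per_chrom[idx % n_chrom].append(item)

    records = []
    truth = PlantedTruth()
    for ci in range(n_chrom):
        name = f"{chrom_prefix}{ci + 1}"
        plants = per_chrom[ci]
        construct_lens = [len(site_a) + L + len(site_b) for L, _ in plants]
        needed = sum(construct_lens) + margin * (len(plants) + 1)
        if needed > chrom_len:
            raise ValueError(
                f"{name}: cannot pack {len(plants)} inserts into {chrom_len} bp"
            )
        # draw start offsets: distribute the slack randomly between constructs
        slack = chrom_len - sum(construct_lens) - margin * (len(plants) + 1)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(plants)))
        seq = list(_random_bases(rng, chrom_len, gc))
        protected: list[tuple[int, int]] = []
        placements = []
        for k, ((L, orient), clen) in enumerate(zip(plants, construct_lens)):
            start = margin + int(cuts[k]) + sum(construct_lens[:k]) + margin * k
            left, right = (site_a, site_b) if orient == "A-first" else (site_b, site_a)
            construct = left + "".join(_random_bases(rng, L, gc)) + right
            seq[start : start + clen] = list(construct)
            protected.append((start, start + len(left)))
            protected.append((start + clen - len(right), start + clen))
            placements.append((start, L, orient, left, right, clen))
        _scrub_motifs(seq, motifs, protected, rng, gc)
        chrom_seq = "".join(seq)
        for start, L, orient, left, right, clen in placements:
            ins_s = start + len(left)
            ins_e = ins_s + L
            truth.amplicons.append(
                PlantedAmplicon(
                    chrom=name,
                    insert_start=ins_s,
                    insert_end=ins_e,
                    orientation=orient,
                    insert_seq=chrom_seq[ins_s:ins_e],
                    left_site=left,
                    right_site=right,
                )
            )
        records.append((name, chrom_seq))
    return Genome(records), truth


@dataclass
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


def mutate_genome(
    genome: Genome,
    substitution_rate: float,
    seed: int = 0,
    protect_sites: bool = False,
    motifs: Sequence[str] = ("CTGCAG", "CCGG"),
) -> tuple[Genome, list[Variant]]:
    """Apply random substitutions, e.g. to derive one parent from another.

    With ``protect_sites`` on, positions inside any occurrence of the given
    recognition motifs (either strand) are never mutated, and substitutions
    that would create a *new* motif occurrence are skipped, so a mutated
    genome retains exactly the original amplicon structure.
    """
    if not 0 <= substitution_rate <= 0.1:
        raise ValueError("substitution_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    out = []
    variants: list[Variant] = []
    for name, seq in genome.items():
        n = len(seq)
        k = rng.binomial(n, substitution_rate)
        if k == 0:
            out.append((name, seq))
            continue
        positions = rng.choice(n, size=k, replace=False)
        if protect_sites:
            mask = np.zeros(n, dtype=bool)
            for s, e in _find_motifs(seq, motifs):
                mask[s:e] = True
            positions = positions[~mask[positions]]
        max_motif = max(len(m) for m in motifs)
        chars = list(seq)
        for pos in sorted(int(p) for p in positions):
            ref = chars[pos]
            if ref == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            chars[pos] = alt
            if protect_sites:
                lo = max(0, pos - max_motif + 1)
                window = "".join(chars[lo : pos + max_motif])
                if _find_motifs(window, motifs):
                    chars[pos] = ref  # would create a new recognition site
                    continue
            variants.append(Variant(name, pos, ref, alt))
        out.append((name, "".join(chars)))
    return Genome(out), variants
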