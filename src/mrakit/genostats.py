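"""Marker statistics and filters on genotype matrices.

Calls are biallelic: homozygous-A, homozygous-B, heterozygous or missing.
Markers are filtered on minimum call rate (MCR — the fraction of samples
with a non-missing call), minor allele frequency (heterozygotes contribute
one copy of each allele) and maximum heterozygous-call rate; typical
thresholds are MAF >= 0.2 with <= 10% heterozygotes for biparental
populations and MAF >= 0.05 for natural populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ampliconminer import DensityTrack

HOM_A, HET, HOM_B, MISSING = 0, 1, 2, -1


@dataclass
class GenotypeMatrix:
    """markers x samples call matrix.

    ``calls`` is int8 with codes 0 = hom. allele A, 1 = het, 2 = hom.
    allele B, -1 = missing. ``markers`` carries id, chrom, pos (0-based)
    and the two alleles per marker.
    """

    markers: pd.DataFrame  # columns: id, chrom, pos, allele_a, allele_b
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.markers)}, {len(self.samples)})"
            )
        if (self.markers["pos"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        bad = ~np.isin(self.calls, [HOM_A, HET, HOM_B, MISSING])
        if bad.any():
            raise ValueError("invalid call codes present")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            markers=self.markers.loc[keep].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[keep],
        )


def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call_rate, maf and het_rate.

    call_rate = non-missing / samples. Allele counting: homA -> 2 A,
    homB -> 2 B, het -> 1 of each; maf = min(freq A, freq B). het_rate =
    het calls / non-missing calls. maf and het_rate are NaN for all-missing
    markers.
    """
    c = matrix.calls
    non_missing = (c != MISSING).sum(axis=1)
    n_het = (c == HET).sum(axis=1)
    n_a = 2 * (c == HOM_A).sum(axis=1) + n_het
    n_b = 2 * (c == HOM_B).sum(axis=1) + n_het
    total_alleles = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_a = np.where(total_alleles > 0, n_a / np.maximum(total_alleles, 1), np.nan)
        maf = np.where(total_alleles > 0, np.minimum(freq_a, 1 - freq_a), np.nan)
        het_rate = np.where(non_missing > 0, n_het / np.maximum(non_missing, 1), np.nan)
    return pd.DataFrame(
        {
            "id": matrix.markers["id"].to_numpy(),
            "call_rate": non_missing / matrix.n_samples,
            "maf": maf,
            "het_rate": het_rate,
        }
    )


def filter_markers(
    matrix: GenotypeMatrix,
    mcr_min: float = 0.2,
    maf_min: float = 0.2,
    het_max: float = 0.1,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Keep markers with call_rate >= mcr_min, maf >= maf_min, het <= het_max.

    The report attributes each removed marker to its first failing
    criterion in the order MCR -> MAF -> heterozygosity; markers with
    undefined maf/het (all-missing) fail MCR first for any mcr_min > 0.
    """
    for thr in (mcr_min, maf_min, het_max):
        if not 0 <= thr <= 1:
            raise ValueError("thresholds must be in [0, 1]")
    stats = marker_stats(matrix)
    fail_mcr = stats["call_rate"] < mcr_min
    fail_maf = ~fail_mcr & ~(stats["maf"] >= maf_min)
    fail_het = ~fail_mcr & ~fail_maf & ~(stats["het_rate"] <= het_max)
    keep = ~(fail_mcr | fail_maf | fail_het)
    report = {
        "input": matrix.n_markers,
        "removed_mcr": int(fail_mcr.sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_het": int(fail_het.sum()),
        "kept": int(keep.sum()),
    }
    return matrix.subset(keep.to_numpy()), report


def marker_density_map(
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
) -> DensityTrack:
    """Per-bin marker counts along chromosomes (physical marker density)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    track = DensityTrack(bin_size=int(bin_size))
    for chrom, length in chrom_lengths.items():
        track.counts[chrom] = np.zeros(max(1, -(-length // bin_size)), dtype=int)
    for _, row in matrix.markers.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in chrom_lengths:
            raise ValueError(f"marker {row['id']!r}: unknown chromosome {chrom!r}")
        if pos >= chrom_lengths[chrom]:
            raise ValueError(
                f"marker {row['id']!r}: position {pos} beyond end of {chrom}"
            )
        track.counts[chrom][pos // bin_size] += 1
    return track


def simulate_ril_matrix(
    n_markers: int,
    n_samples: int,
    missing_rate: float = 0.2,
    het_rate: float = 0.06,
    maf_distribution: float | Callable[[np.random.Generator, int], np.ndarray] = 0.5,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Simulate a biparental RIL-like genotype matrix.

    Each marker draws an allele-A frequency (a scalar, or a callable
    ``f(rng, n_markers) -> frequencies``; 0.5 reflects the 1:1 expectation
    of a biparental cross). Calls are heterozygous with probability
    ``het_rate`` (residual heterozygosity of inbred lines), otherwise
    homozygous per the allele frequency; each call is then masked missing
    with probability ``missing_rate``. Marker positions are placed uniformly
    on the provided chromosomes (one 50 Mb chromosome by default).
    """
    for r in (missing_rate, het_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if callable(maf_distribution):
        freq_a = np.asarray(maf_distribution(rng, n_markers), dtype=float)
    else:
        freq_a = np.full(n_markers, float(maf_distribution))
    u = rng.random((n_markers, n_samples))
    calls = np.where(u < het_rate, HET,
                     np.where(rng.random((n_markers, n_samples)) < freq_a[:, None],
                              HOM_A, HOM_B)).astype(np.int8)
    calls[rng.random((n_markers, n_samples)) < missing_rate] = MISSING
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 50_000_000}
    chroms = list(chrom_lengths)
    chrom_idx = rng.integers(0, len(chroms), size=n_markers)
    pos = np.array(
        [rng.integers(0, chrom_lengths[chroms[i]]) for i in chrom_idx]
    )
    order = np.lexsort((pos, chrom_idx))
    markers = pd.DataFrame(
        {
            "id": [f"M{i + 1}" for i in range(n_markers)],
            "chrom": [chroms[i] for i in chrom_idx[order]],
            "pos": pos[order],
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return GenotypeMatrix(
        markers=markers,
        samples=[f"S{j + 1}" for j in range(n_samples)],
        calls=calls[order],
    )


# ---------------------------------------------------------------------------
# HapMap / VCF I/O

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def write_hapmap(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix in HapMap TSV (TASSEL export dialect, 1-based pos)."""
    m = matrix.markers
    rows = []
    for i in range(matrix.n_markers):
        a = m.at[i, "allele_a"]
        b = m.at[i, "allele_b"]
        code = {HOM_A: a + a, HET: a + b, HOM_B: b + b, MISSING: "NN"}
        row = [
            m.at[i, "id"], f"{a}/{b}", m.at[i, "chrom"], int(m.at[i, "pos"]) + 1,
            "+", "NA", "NA", "NA", "NA", "NA", "NA",
        ] + [code[int(c)] for c in matrix.calls[i]]
        rows.append(row)
    pd.DataFrame(rows, columns=_HAPMAP_META + list(matrix.samples)).to_csv(
        path, sep="\t", index=False
    )


def read_hapmap(path, on_multiallelic: str = "drop") -> tuple[GenotypeMatrix, dict]:
    """Read a HapMap TSV; non-biallelic rows are dropped (tallied) or error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = list(df.columns[len(_HAPMAP_META):])
    markers_rows = []
    calls_rows = []
    n_multi = 0
    for _, row in df.iterrows():
        alleles = row["alleles"].split("/")
        if len(alleles) != 2 or any(a not in "ACGT" for a in alleles):
            if on_multiallelic == "drop":
                n_multi += 1
                continue
            raise ValueError(f"non-biallelic marker {row['rs#']!r}")
        a, b = alleles
        decode = {a + a: HOM_A, b + b: HOM_B, a + b: HET, b + a: HET, "NN": MISSING}
        try:
            calls_rows.append([decode[row[s]] for s in samples])
        except KeyError as exc:
            raise ValueError(
                f"marker {row['rs#']!r}: unexpected genotype {exc.args[0]!r}"
            ) from None
        markers_rows.append(
            {
                "id": row["rs#"], "chrom": row["chrom"],
                "pos": int(row["pos"]) - 1, "allele_a": a, "allele_b": b,
            }
        )
    matrix = GenotypeMatrix(
        markers=pd.DataFrame(
            markers_rows, columns=["id", "chrom", "pos", "allele_a", "allele_b"]
        ),
        samples=samples,
        calls=np.array(calls_rows, dtype=np.int8).reshape(len(markers_rows), len(samples)),
    )
    return matrix, {"multiallelic_dropped": n_multi}


def read_vcf(path) -> tuple[GenotypeMatrix, dict]:
    """Minimal VCF import (GT field only); biallelic SNVs kept, rest tallied."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers_rows = []
    calls_rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                row[j] = MISSING
            elif a1 == a2 == 0:
                row[j] = HOM_A
            elif a1 == a2 == 1:
                row[j] = HOM_B
            else:
                row[j] = HET
        calls_rows.append(row)
        markers_rows.append(
            {
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM, "pos": var.POS - 1,
                "allele_a": var.REF, "allele_b": var.ALT[0],
            }
        )
    matrix = GenotypeMatrix(
        markers=pd.DataFrame(
            markers_rows, columns=["id", "chrom", "pos", "allele_a", "allele_b"]
        ),
        samples=samples,
        calls=np.array(calls_rows, dtype=np.int8).reshape(len(markers_rows), len(samples)),
    )
    return matrix, {"non_biallelic_skipped": n_skipped}
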