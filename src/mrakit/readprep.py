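"""Read preprocessing for GBS-style SNP callers.

Raw amplicon reads carry barcode + M13 tail + spacer + restriction site
before any genomic sequence. GBS pipelines instead expect barcode
immediately followed by a remnant restriction site, so the tail and spacer
are excised (quality string co-edited at the same offsets) and short reads
are padded with 3' poly-A so the caller does not discard them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .ampliconminer import iupac_regex
from .seqmodel import M13_TAIL, ReadRecord


@dataclass
class PrepConfig:
    """Configuration for tail/spacer excision.

    ``spacer`` is either an exact sequence or an IUPAC pattern; with
    ``spacer_len_range`` set, the spacer instead matches any sequence whose
    length falls in the range (variable-spacer libraries). ``remnant``
    defaults to TGCAG — the recognition site minus the first base, the
    convention GBS keyfile-driven demultiplexers expect after the barcode;
    set it to the full site to retain all six bases.
    """

    barcodes: list[str]
    tail: str = M13_TAIL
    spacer: str = "NNNNNN"
    spacer_len_range: tuple[int, int] | None = None
    recognition: str = "CTGCAG"
    remnant: str = "TGCAG"
    polya_n: int = 80
    polya_qual_char: str = "!"
    on_unmatched: str = "drop"  # "drop" | "pass"

    def __post_init__(self):
        if not self.barcodes:
            raise ValueError("need at least one barcode")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if not self.recognition.endswith(self.remnant):
            raise ValueError("remnant must be a suffix of the recognition site")
        if self.polya_n < 0:
            raise ValueError("polya_n must be >= 0")
        if self.on_unmatched not in ("drop", "pass"):
            raise ValueError("on_unmatched must be 'drop' or 'pass'")

    def excision_regex(self) -> re.Pattern:
        if self.spacer_len_range is not None:
            lo, hi = self.spacer_len_range
            spacer_pat = f"[ACGT]{{{lo},{hi}}}?"
        else:
            spacer_pat = iupac_regex(self.spacer)
        return re.compile(
            f"^{iupac_regex(self.tail)}{spacer_pat}{iupac_regex(self.recognition)}"
        )


def strip_intervening(
    reads: list[ReadRecord], config: PrepConfig
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Excise tail+spacer so each read becomes barcode + remnant + genomic.

    Per read: the longest matching barcode prefix is located; the following
    tail + spacer + full recognition site is replaced by the remnant, and
    the quality string is cut at identical offsets (the remnant keeps the
    quality of the site bases it derives from). Reads already conformant
    (barcode immediately followed by the remnant) pass through unchanged,
    which makes the operation idempotent. Unmatched reads are dropped or
    passed per config; the report conserves counts
    (edited + conformant + unmatched_passed + dropped == input).
    """
    barcodes = sorted(config.barcodes, key=len, reverse=True)
    pattern = config.excision_regex()
    out: list[ReadRecord] = []
    tally = {"input": 0, "edited": 0, "conformant": 0,
             "unmatched_passed": 0, "dropped": 0}
    per_barcode: dict[str, int] = {bc: 0 for bc in barcodes}
    for read in reads:
        tally["input"] += 1
        barcode = next((bc for bc in barcodes if read.bases.startswith(bc)), None)
        disposition = None
        if barcode is not None:
            rest = read.bases[len(barcode):]
            if rest.startswith(config.remnant):
                disposition = "conformant"
                out.append(read)
            else:
                m = pattern.match(rest)
                if m:
                    # keep barcode, drop tail+spacer+site head, resume at the
                    # remnant (the site's trailing bases keep their quality)
                    remnant_start = len(barcode) + m.end() - len(config.remnant)
                    bases = read.bases[: len(barcode)] + read.bases[remnant_start:]
                    quality = read.quality[: len(barcode)] + read.quality[remnant_start:]
                    out.append(ReadRecord(read.id, bases, quality))
                    disposition = "edited"
        if disposition is None:
            if config.on_unmatched == "pass":
                out.append(read)
                disposition = "unmatched_passed"
            else:
                disposition = "dropped"
        else:
            per_barcode[barcode] += 1
        tally[disposition] = tally.get(disposition, 0) + 1
    report = pd.DataFrame(
        [{"metric": k, "count": v} for k, v in tally.items()]
        + [{"metric": f"barcode:{bc}", "count": n} for bc, n in per_barcode.items()]
    )
    return out, report


def pad_polya(
    reads: list[ReadRecord], n: int = 80, qual_char: str = "!"
) -> list[ReadRecord]:
    """Append n poly-A bases (with uniform quality) to every read's 3' end."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return [
        ReadRecord(r.id, r.bases + "A" * n, r.quality + qual_char * n)
        for r in reads
    ]


def write_keyfile(
    path,
    barcodes_by_sample: dict[str, str],
    flowcell: str = "SIMFLOW1",
    lane: int = 1,
) -> None:
    """Write a GBS-style keyfile (flowcell, lane, barcode, sample) TSV."""
    rows = [
        {"Flowcell": flowcell, "Lane": lane, "Barcode": bc, "FullSampleName": s}
        for s, bc in sorted(barcodes_by_sample.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
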